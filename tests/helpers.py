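"""Shared test utilities: brute-force DEA oracle and tiny panel builders."""

from __future__ import annotations

import numpy as np
import pandas as pd

from fgaps.panel import CountryYearPanel


def envelope_phi(xs, ys, x, y) -> float:
    """Brute-force output expansion for the 1-input/1-output VRS program.

    Enumerates every vertex of {lambda >= 0, sum lambda = 1,
    sum lambda x <= x}: single reference points with input <= x, and pairs
    straddling x combined so the input constraint binds. Independent of the
    LP implementation under test.
    """
    xs = np.asarray(xs, float)
    ys = np.asarray(ys, float)
    best = -np.inf
    for j in range(len(xs)):
        if xs[j] <= x:
            best = max(best, ys[j])
    for i in range(len(xs)):
        for j in range(i + 1, len(xs)):
            if (xs[i] - x) * (xs[j] - x) < 0:
                lam = (x - xs[j]) / (xs[i] - xs[j])
                best = max(best, lam * ys[i] + (1 - lam) * ys[j])
    return best / y


def toy_panel(
    countries: dict[str, dict],
    years: range,
    base_year: int,
) -> CountryYearPanel:
    """Build a small valid panel from per-country scalar or per-year values.

    ``countries`` maps country id to a dict of column -> scalar (constant
    over years) or sequence (one value per year). Columns not given default
    to plausible constants. Years > base_year are marked as forecasts.
    """
    defaults = {
        "gdp": 1e9,
        "gdp_pc": 1000.0,
        "maternal_education": 5.0,
        "dah_pc": 5.0,
        "ghe_s_pc": 20.0,
        "population": 1e6,
        "live_births": 3e4,
        "u5mr": 80.0,
        "income_group": "low",
    }
    rows = []
    for cid, vals in countries.items():
        merged = {**defaults, **vals}
        for k, year in enumerate(years):
            row = {"country_id": cid, "year": year,
                   "is_observed": year <= base_year}
            for col, v in merged.items():
                row[col] = v[k] if isinstance(v, (list, tuple, np.ndarray)) else v
            rows.append(row)
    return CountryYearPanel.from_dataframe(pd.DataFrame(rows))
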