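"""Potential child-health spending (PS) via a DEA spending frontier.

Potential spending is a country's ability to pay: the government health
spending of the best-performing peers at its level of development. It is
estimated with output-oriented, variable-returns-to-scale (VRS) data
envelopment analysis using a single input (GDP per capita) and a single
output (GHE-S per capita). For a country with input x and output y the
program is

    max  phi
    s.t. sum_j lambda_j * y_j >= phi * y
         sum_j lambda_j * x_j <= x
         sum_j lambda_j = 1,  lambda_j >= 0

over the reference cross-section {(x_j, y_j)}. The potential spending level
is phi * y — the height of the concave envelope of the reference points
(with free input disposability) at x. No bootstrap bias correction is
applied to the frontier.

Forecast potential spending evaluates the same base-year frontier at future
GDP per capita; GDP outside the reference range is clamped to the nearest
reference input (a VRS frontier is not extrapolated). Conversion to child
health applies the fraction model at the potential spending level
(counterfactual-consistent) by default.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import linprog

from .errors import AlignmentError, FgapsError, ModelError
from .expected_spend import FractionModel
from .panel import CountryYearPanel, RunConfig

_LAMBDA_TOL = 1e-7


@dataclass(frozen=True)
class FrontierModel:
    """Reference cross-section defining the VRS spending frontier."""

    country_ids: tuple[str, ...]
    gdp_pc: tuple[float, ...]
    ghe_s_pc: tuple[float, ...]
    reference_year: int
    orientation: str = "output"
    returns_to_scale: str = "variable"

    @property
    def n(self) -> int:
        return len(self.country_ids)


@dataclass(frozen=True)
class FrontierPoint:
    """One frontier evaluation: expansion factor, level and peer weights."""

    phi: float
    potential_ghe_pc: float
    peers: tuple[tuple[str, float], ...]  # (country_id, lambda), lambda > 0
    fallback: bool = False  # True when the LP was infeasible (x below range)


@dataclass(frozen=True)
class PotentialSpendResult:
    """Potential child-health spending path for one country."""

    country_id: str
    years: list[int]
    phi: list[float]               # expansion vs the reference-year output
    ps_ghe_pc: list[float]         # potential total government health spend pc
    ps_child_fraction: list[float]
    ps_pc: list[float]             # potential child-health spend pc
    ps_total_usd: float
    peers: tuple[str, ...]         # positive-weight peers at the base year


def fit_frontier(panel: CountryYearPanel, reference_year: int) -> FrontierModel:
    """Store the reference-year cross-section; DEA is solved per evaluation."""
    df = panel.df
    ref = df[(df["year"] == reference_year) & df["is_observed"]]
    if ref["country_id"].duplicated().any():
        dups = sorted(ref.loc[ref["country_id"].duplicated(), "country_id"])
        raise ModelError(f"duplicate countries in reference cross-section: {dups}")
    ref = ref.dropna(subset=["gdp_pc", "ghe_s_pc"])
    if len(ref) < 3:
        raise ModelError(
            f"need >= 3 reference points in {reference_year}, got {len(ref)}"
        )
    if not ((ref["gdp_pc"] > 0) & (ref["ghe_s_pc"] > 0)).all():
        bad = sorted(
            ref.loc[(ref["gdp_pc"] <= 0) | (ref["ghe_s_pc"] <= 0), "country_id"]
        )
        raise ModelError(f"nonpositive reference points for countries: {bad}")
    ref = ref.sort_values("country_id")
    return FrontierModel(
        country_ids=tuple(ref["country_id"]),
        gdp_pc=tuple(float(v) for v in ref["gdp_pc"]),
        ghe_s_pc=tuple(float(v) for v in ref["ghe_s_pc"]),
        reference_year=int(reference_year),
    )


def evaluate_frontier(
    model: FrontierModel, gdp_pc: float, ghe_s_pc: float
) -> FrontierPoint:
    """Solve the output-oriented VRS program at (gdp_pc, ghe_s_pc).

    Returns the expansion factor phi, the potential spending level phi * y
    and the positive-weight peers. When gdp_pc falls below every reference
    input the program is infeasible; the documented fallback returns the
    largest reference output among points with input <= gdp_pc, or the
    observed output if there is none, flagged via ``fallback``.
    """
    if gdp_pc <= 0 or ghe_s_pc <= 0:
        raise FgapsError("evaluate_frontier requires positive gdp_pc and ghe_s_pc")
    x = np.asarray(model.gdp_pc)
    y = np.asarray(model.ghe_s_pc)
    n = model.n
    if gdp_pc < x.min():
        below = x <= gdp_pc
        pot = float(y[below].max()) if below.any() else float(ghe_s_pc)
        return FrontierPoint(phi=pot / ghe_s_pc, potential_ghe_pc=pot,
                             peers=(), fallback=True)

    # Variables z = [phi, lambda_1..lambda_n]; minimise -phi.
    c = np.zeros(n + 1)
    c[0] = -1.0
    A_ub = np.zeros((2, n + 1))
    A_ub[0, 0] = ghe_s_pc          # phi*y - sum(lambda_j y_j) <= 0
    A_ub[0, 1:] = -y
    A_ub[1, 1:] = x                # sum(lambda_j x_j) <= x
    b_ub = np.array([0.0, gdp_pc])
    A_eq = np.zeros((1, n + 1))
    A_eq[0, 1:] = 1.0              # sum(lambda_j) = 1
    res = linprog(
        c, A_ub=A_ub, b_ub=b_ub, A_eq=A_eq, b_eq=[1.0],
        bounds=[(0, None)] * (n + 1), method="highs",
        options={"primal_feasibility_tolerance": 1e-9,
                 "dual_feasibility_tolerance": 1e-9},
    )
    if not res.success:  # pragma: no cover - guarded by the x-range check
        raise FgapsError(f"DEA linear program failed: {res.message}")
    phi = float(res.x[0])
    lam = res.x[1:]
    peers = tuple(
        (model.country_ids[j], float(lam[j]))
        for j in np.flatnonzero(lam > _LAMBDA_TOL)
    )
    return FrontierPoint(phi=phi, potential_ghe_pc=phi * ghe_s_pc, peers=peers)


def frontier_value(model: FrontierModel, gdp_pc: float) -> float:
    """Height of the VRS frontier at gdp_pc (clamped to the reference range)."""
    x = np.asarray(model.gdp_pc)
    xq = float(np.clip(gdp_pc, x.min(), x.max()))
    # Output level cancels: evaluate with unit output and take phi directly.
    return evaluate_frontier(model, xq, 1.0).potential_ghe_pc


def forecast_potential_spend(
    model: FrontierModel,
    fraction_model: FractionModel,
    panel: CountryYearPanel,
    config: RunConfig,
) -> list[PotentialSpendResult]:
    """Potential child-health spending per country over the horizon.

    Per year: ps_ghe_pc is the frontier height at forecast GDP per capita
    (clamped to the reference input range); the child-health fraction is the
    fraction model evaluated with ln(ps_ghe_pc) in place of ln(GHE-S pc)
    when ``config.ps_fraction_basis == "potential"``, or at observed/forecast
    GHE-S when "expected"; ps_total sums fraction * ps_ghe_pc * population.
    """
    years = config.horizon_years(panel)
    base_year = model.reference_year
    ref_y = dict(zip(model.country_ids, model.ghe_s_pc))
    results = []
    missing: list[tuple[str, int]] = []
    for cid in panel.countries:
        cdf = panel.country(cid).set_index("year")
        gap = [y for y in years if y not in cdf.index or pd.isna(cdf.loc[y, "gdp_pc"])]
        if gap:
            missing.extend((cid, y) for y in gap)
            continue
        y_ref = ref_y.get(cid)
        if y_ref is None:
            raise AlignmentError(
                f"{cid} absent from the {base_year} reference cross-section"
            )
        base_eval = evaluate_frontier(model, float(cdf.loc[base_year, "gdp_pc"]), y_ref)
        ps_ghe = np.array(
            [frontier_value(model, float(cdf.loc[y, "gdp_pc"])) for y in years]
        )
        gdp_pc = cdf.loc[years, "gdp_pc"].to_numpy(float)
        pop = cdf.loc[years, "population"].to_numpy(float)
        if config.ps_fraction_basis == "potential":
            frac_basis = ps_ghe
        else:
            frac_basis = cdf.loc[years, "ghe_s_pc"].to_numpy(float)
        frac = np.clip(
            fraction_model.predict_fraction(np.maximum(frac_basis, 1e-12), gdp_pc),
            0.0, 1.0,
        )
        ps_pc = frac * ps_ghe
        results.append(
            PotentialSpendResult(
                country_id=cid,
                years=list(years),
                phi=[float(v / y_ref) for v in ps_ghe],
                ps_ghe_pc=[float(v) for v in ps_ghe],
                ps_child_fraction=[float(f) for f in frac],
                ps_pc=[float(v) for v in ps_pc],
                ps_total_usd=float(np.sum(ps_pc * pop)),
                peers=tuple(p for p, _ in base_eval.peers),
            )
        )
    if missing:
        raise AlignmentError(
            "missing GDP per capita forecasts for: "
            + ", ".join(f"({c}, {y})" for c, y in missing[:20])
            + (" ..." if len(missing) > 20 else "")
        )
    return results


def ps_to_frame(results: list[PotentialSpendResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        for y, phi, g, f, p in zip(r.years, r.phi, r.ps_ghe_pc,
                                   r.ps_child_fraction, r.ps_pc):
            rows.append(
                (r.country_id, y, phi, g, f, p, r.ps_total_usd, ";".join(r.peers))
            )
    return pd.DataFrame(
        rows,
        columns=["country_id", "year", "phi", "ps_ghe_pc", "ps_child_fraction",
                 "ps_pc", "ps_total_usd", "peers"],
    )
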