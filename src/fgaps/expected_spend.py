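"""Expected child-health spending (ES) from the government-spending share.

For countries with child-health sub-accounts, the fraction of government
health spending (as agent) going to child health is regressed on
log GHE-S per capita and log GDP per capita; the fitted share, applied to
GHE-S forecasts and population, yields each country's expected child-health
spending through the horizon.

The share is regressed on the raw scale and clipped into [0, 1] at
prediction time; a logit link is available through the config. GHE-S
forecasts are expected as panel input columns; a per-country log-linear
trend extrapolation of the observed series is available behind an explicit
flag for standalone runs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .errors import AlignmentError, ModelError
from .panel import CountryYearPanel, RunConfig

MIN_ROWS = 10

FRACTION_COLUMNS = ("intercept", "ln_ghe_s_pc", "ln_gdp_pc")


@dataclass
class FractionModel:
    """Fitted child-health share model: share ~ ln GHE-S pc + ln GDP pc."""

    coefficients: dict[str, float]
    residual_sd: float
    n_obs: int
    link: str = "linear"

    def predict_fraction(self, ghe_s_pc, gdp_pc) -> np.ndarray:
        g = self.coefficients
        eta = (
            g["intercept"]
            + g["ln_ghe_s_pc"] * np.log(np.asarray(ghe_s_pc, float))
            + g["ln_gdp_pc"] * np.log(np.asarray(gdp_pc, float))
        )
        if self.link == "logit":
            return 1.0 / (1.0 + np.exp(-eta))
        return np.clip(eta, 0.0, 1.0)

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(self.__dict__, indent=2))

    @classmethod
    def from_json(cls, path) -> "FractionModel":
        return cls(**json.loads(Path(path).read_text()))


@dataclass(frozen=True)
class ExpectedSpendResult:
    """Expected child-health government spending path for one country."""

    country_id: str
    years: list[int]
    child_fraction: list[float]
    es_pc: list[float]         # USD per capita per year
    es_total_usd: float        # sum over horizon of es_pc * population


def fit_fraction_model(subaccounts: pd.DataFrame, link: str = "linear") -> FractionModel:
    """OLS of the child-health share on ln GHE-S pc and ln GDP pc.

    ``subaccounts`` needs columns country_id, year, child_fraction,
    ghe_s_pc, gdp_pc; fractions must lie strictly inside (0, 1), spending
    and GDP must be positive.
    """
    req = {"child_fraction", "ghe_s_pc", "gdp_pc"}
    missing = req - set(subaccounts.columns)
    if missing:
        raise ModelError(f"subaccounts table missing columns: {sorted(missing)}")
    if len(subaccounts) < MIN_ROWS:
        raise ModelError(f"need >= {MIN_ROWS} sub-account rows, got {len(subaccounts)}")
    frac = subaccounts["child_fraction"].to_numpy(float)
    if not ((frac > 0) & (frac < 1)).all():
        bad = subaccounts.index[(frac <= 0) | (frac >= 1)].tolist()
        raise ModelError(f"child_fraction outside (0, 1) at rows {bad}")
    for col in ("ghe_s_pc", "gdp_pc"):
        vals = subaccounts[col].to_numpy(float)
        if not (vals > 0).all():
            raise ModelError(f"{col} must be positive in the sub-accounts table")

    X = pd.DataFrame(
        {
            "intercept": 1.0,
            "ln_ghe_s_pc": np.log(subaccounts["ghe_s_pc"].to_numpy(float)),
            "ln_gdp_pc": np.log(subaccounts["gdp_pc"].to_numpy(float)),
        },
        index=subaccounts.index,
    )
    s = np.linalg.svd(X.to_numpy() / np.linalg.norm(X.to_numpy(), axis=0), compute_uv=False)
    if s[-1] < 1e-8 * s[0]:
        raise ModelError("collinear regressors in fraction model (ln GHE-S, ln GDP pc)")

    y = np.log(frac / (1 - frac)) if link == "logit" else frac
    res = sm.OLS(y, X).fit()
    return FractionModel(
        coefficients={c: float(res.params[c]) for c in FRACTION_COLUMNS},
        residual_sd=float(np.sqrt(res.ssr / res.df_resid)) if res.df_resid > 0 else 0.0,
        n_obs=int(res.nobs),
        link=link,
    )


def extrapolate_ghe_s(cdf: pd.DataFrame, years: list[int]) -> pd.Series:
    """Per-country log-linear trend extrapolation of observed GHE-S pc."""
    obs = cdf[cdf["is_observed"] & (cdf["ghe_s_pc"] > 0)]
    if len(obs) < 2:
        raise ModelError("need >= 2 positive observed GHE-S values to extrapolate")
    slope, intercept = np.polyfit(obs["year"].to_numpy(float),
                                  np.log(obs["ghe_s_pc"].to_numpy(float)), 1)
    return pd.Series(
        np.exp(intercept + slope * np.asarray(years, float)),
        index=pd.Index(years, name="year"),
    )


def forecast_expected_spend(
    model: FractionModel,
    panel: CountryYearPanel,
    config: RunConfig,
    extrapolate_missing_ghe: bool = False,
) -> list[ExpectedSpendResult]:
    """Expected child-health spending per country over the horizon.

    Per year: fraction = model share at (ghe_s_pc, gdp_pc), clipped into
    [0, 1]; es_pc = fraction * ghe_s_pc; es_total = sum of es_pc * population.
    Missing GHE-S forecast years raise an error listing the gaps unless
    ``extrapolate_missing_ghe`` substitutes the log-linear trend.
    """
    years = config.horizon_years(panel)
    results = []
    gaps: list[tuple[str, int]] = []
    for cid in panel.countries:
        cdf = panel.country(cid).set_index("year", drop=False)
        missing_years = [
            y for y in years if y not in cdf.index or pd.isna(cdf.loc[y, "ghe_s_pc"])
        ]
        if missing_years and not extrapolate_missing_ghe:
            gaps.extend((cid, y) for y in missing_years)
            continue
        ghe = pd.Series(index=pd.Index(years, name="year"), dtype=float)
        present = [y for y in years if y not in missing_years]
        ghe.loc[present] = cdf.loc[present, "ghe_s_pc"].to_numpy(float)
        if missing_years:
            ghe.loc[missing_years] = extrapolate_ghe_s(cdf, missing_years)
        gdp_pc = cdf.loc[years, "gdp_pc"].to_numpy(float)
        pop = cdf.loc[years, "population"].to_numpy(float)
        frac = model.predict_fraction(np.maximum(ghe.to_numpy(), 1e-12), gdp_pc)
        frac = np.clip(frac, 0.0, 1.0)
        es_pc = frac * ghe.to_numpy()
        results.append(
            ExpectedSpendResult(
                country_id=cid,
                years=list(years),
                child_fraction=[float(f) for f in frac],
                es_pc=[float(v) for v in es_pc],
                es_total_usd=float(np.sum(es_pc * pop)),
            )
        )
    if gaps:
        raise AlignmentError(
            "missing GHE-S forecasts for: "
            + ", ".join(f"({c}, {y})" for c, y in gaps[:20])
            + (" ..." if len(gaps) > 20 else "")
        )
    return results


def es_to_frame(results: list[ExpectedSpendResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        for y, f, e in zip(r.years, r.child_fraction, r.es_pc):
            rows.append((r.country_id, y, f, e, r.es_total_usd))
    return pd.DataFrame(
        rows, columns=["country_id", "year", "child_fraction", "es_pc", "es_total_usd"]
    )
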