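"""Log-linear under-five-mortality regression and expected-trend projection.

The expected trend is the mortality path a country would follow with no
change in donor or government health spending: ln(u5mr) is regressed by
pooled OLS on log GDP, log GDP per capita, maternal education,
log(1 + DAH pc), log(1 + GHE-S pc) and a linear year trend (a technology
proxy), then projected forward using forecast GDP / education covariates with
DAH and GHE-S frozen at base-year values.

Predictions are the plain exponentiated linear predictor. No smearing or
half-variance retransformation correction is applied, so predicted levels
carry the usual log-normal back-transform bias; see docs/methods.md.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .errors import AlignmentError, ModelError
from .panel import CountryYearPanel, RunConfig

#: Design-matrix columns, in coefficient order.
DESIGN_COLUMNS = (
    "const",
    "ln_gdp",
    "ln_gdp_pc",
    "maternal_education",
    "log1p_dah_pc",
    "log1p_ghe_s_pc",
    "year_trend",
)

MIN_ROWS = 30


@dataclass
class MortalityModel:
    """Fitted coefficients of the pooled log-mortality regression."""

    coefficients: dict[str, float]
    residual_sd: float
    base_year: int
    n_obs: int
    r_squared: float
    coef_se: dict[str, float]
    transform_spec: dict[str, str] = field(
        default_factory=lambda: {
            "gdp": "ln", "gdp_pc": "ln", "maternal_education": "identity",
            "dah_pc": "log1p", "ghe_s_pc": "log1p", "year": "linear, centred at base_year",
            "u5mr": "ln (response)",
        }
    )
    country_effects: dict[str, float] | None = None

    def coef_vector(self) -> np.ndarray:
        return np.array([self.coefficients[c] for c in DESIGN_COLUMNS])

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(self.__dict__, indent=2))

    @classmethod
    def from_json(cls, path) -> "MortalityModel":
        return cls(**json.loads(Path(path).read_text()))


def design_matrix(df: pd.DataFrame, base_year: int) -> pd.DataFrame:
    """Transformed covariates for the mortality regression."""
    return pd.DataFrame(
        {
            "const": 1.0,
            "ln_gdp": np.log(df["gdp"].to_numpy(float)),
            "ln_gdp_pc": np.log(df["gdp_pc"].to_numpy(float)),
            "maternal_education": df["maternal_education"].to_numpy(float),
            "log1p_dah_pc": np.log1p(df["dah_pc"].to_numpy(float)),
            "log1p_ghe_s_pc": np.log1p(df["ghe_s_pc"].to_numpy(float)),
            "year_trend": df["year"].to_numpy(float) - base_year,
        },
        index=df.index,
    )


def _check_rank(X: pd.DataFrame) -> None:
    arr = X.to_numpy(float)
    # Scale columns so the rank test is insensitive to units.
    norms = np.linalg.norm(arr, axis=0)
    scaled = arr / np.where(norms == 0, 1.0, norms)
    s = np.linalg.svd(scaled, compute_uv=False)
    if s[-1] < 1e-8 * s[0]:
        _, _, vt = np.linalg.svd(scaled)
        involved = [c for c, w in zip(X.columns, np.abs(vt[-1])) if w > 1e-6]
        raise ModelError(
            f"design matrix is rank deficient; collinear columns: {involved}"
        )


def fit_mortality_model(
    panel: CountryYearPanel,
    base_year: int | None = None,
    country_effects: bool = False,
) -> MortalityModel:
    """Pooled OLS of ln(u5mr) on the transformed covariates, observed rows only.

    Parameters
    ----------
    panel
        Validated country-year panel; at least 30 observed rows.
    base_year
        Year at which the linear trend is centred; defaults to the panel's
        last observed year.
    country_effects
        Add country fixed effects (dummy intercepts). Off by default: the
        pooled specification has only the six covariates plus trend.
    """
    obs = panel.observed()
    if base_year is None:
        base_year = panel.base_year()
    if len(obs) < MIN_ROWS:
        raise ModelError(f"need >= {MIN_ROWS} observed rows, got {len(obs)}")
    if obs[["gdp", "gdp_pc", "maternal_education", "dah_pc", "ghe_s_pc", "u5mr"]].isna().any().any():
        raise ModelError("observed rows contain missing covariates")

    X = design_matrix(obs, base_year)
    fe_names: list[str] = []
    if country_effects:
        dummies = pd.get_dummies(obs["country_id"], prefix="fe", dtype=float)
        fe_names = list(dummies.columns[1:])  # drop first level
        X = pd.concat([X, dummies.iloc[:, 1:]], axis=1)
    if X.shape[0] <= X.shape[1]:
        raise ModelError(
            f"fewer rows ({X.shape[0]}) than free parameters ({X.shape[1]})"
        )
    _check_rank(X)

    y = np.log(obs["u5mr"].to_numpy(float))
    res = sm.OLS(y, X).fit()
    resid_sd = float(np.sqrt(res.ssr / res.df_resid)) if res.df_resid > 0 else 0.0
    coefs = {c: float(res.params[c]) for c in DESIGN_COLUMNS}
    return MortalityModel(
        coefficients=coefs,
        residual_sd=resid_sd,
        base_year=int(base_year),
        n_obs=int(res.nobs),
        r_squared=float(res.rsquared),
        coef_se={c: float(res.bse[c]) for c in DESIGN_COLUMNS},
        country_effects=(
            {n.removeprefix("fe_"): float(res.params[n]) for n in fe_names}
            if country_effects
            else None
        ),
    )


@dataclass(frozen=True)
class ExpectedTrend:
    """Projected mortality path of one country under frozen health spending."""

    country_id: str
    years: list[int]
    u5mr_expected: list[float]

    def as_series(self) -> pd.Series:
        return pd.Series(self.u5mr_expected, index=pd.Index(self.years, name="year"))


def project_expected_trend(
    model: MortalityModel, panel: CountryYearPanel, config: RunConfig
) -> list[ExpectedTrend]:
    """Project each country's expected u5mr from base_year+1 to the target year.

    Forecast GDP, GDP per capita and education are taken from the panel's
    forecast rows; DAH pc and GHE-S pc are frozen at their base-year observed
    values (the no-change-in-health-spending counterfactual), and the time
    trend advances. Missing forecast covariates raise an error listing every
    (country, year) gap.
    """
    base_year = model.base_year
    years = config.horizon_years(panel)
    beta = model.coef_vector()
    trends: list[ExpectedTrend] = []
    missing: list[tuple[str, int]] = []

    for cid in panel.countries:
        cdf = panel.country(cid).set_index("year")
        if base_year not in cdf.index or not cdf.loc[base_year, "is_observed"]:
            raise AlignmentError(f"no observed base-year ({base_year}) row for {cid}")
        base = cdf.loc[base_year]
        have = [
            y for y in years
            if y in cdf.index
            and not cdf.loc[y, ["gdp", "gdp_pc", "maternal_education"]].isna().any()
        ]
        missing.extend((cid, y) for y in years if y not in have)
        if len(have) < len(years):
            continue
        fut = cdf.loc[years].copy()
        fut["year"] = years
        fut["dah_pc"] = float(base["dah_pc"])
        fut["ghe_s_pc"] = float(base["ghe_s_pc"])
        X = design_matrix(fut, base_year).to_numpy(float)
        pred = np.exp(X @ beta)
        if model.country_effects is not None:
            pred = pred * np.exp(model.country_effects.get(cid, 0.0))
        trends.append(ExpectedTrend(cid, list(years), [float(p) for p in pred]))

    if missing:
        raise AlignmentError(
            "missing forecast covariates (gdp, gdp_pc, maternal_education) for: "
            + ", ".join(f"({c}, {y})" for c, y in missing[:20])
            + (" ..." if len(missing) > 20 else "")
        )
    return trends


def trends_to_frame(trends: list[ExpectedTrend]) -> pd.DataFrame:
    """Long-format (country_id, year, u5mr_expected) table."""
    return pd.DataFrame(
        [
            (t.country_id, y, r)
            for t in trends
            for y, r in zip(t.years, t.u5mr_expected)
        ],
        columns=["country_id", "year", "u5mr_expected"],
    )


def trends_from_frame(df: pd.DataFrame) -> list[ExpectedTrend]:
    out = []
    for cid, grp in df.groupby("country_id", sort=True):
        grp = grp.sort_values("year")
        out.append(
            ExpectedTrend(
                str(cid), [int(y) for y in grp["year"]],
                [float(v) for v in grp["u5mr_expected"]],
            )
        )
    return out
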