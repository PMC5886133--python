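"""Synthetic country-year panels with known generating structure.

The generator emulates the statistical shape the pipeline assumes, so every
downstream stage can be tested by parameter recovery against a stored truth:

* under-five mortality follows a log-linear process in log GDP, log GDP per
  capita, maternal education, log(1 + DAH pc), log(1 + GHE-S pc) and a linear
  time trend, with Gaussian log-scale noise;
* government health spending per capita sits on (or below) a concave
  power-law frontier of GDP per capita, ``frontier(x) = a * x**b`` with
  ``0 < b < 1``, scaled by a per-country efficiency drawn from a fixed range;
* the child-health share of government health spending is linear in
  log GHE-S pc and log GDP pc;
* covariates are smooth: GDP per capita grows geometrically with a
  country-specific drift, education grows linearly with a cap, DAH per capita
  declines in income.

No attempt is made to match real-world country magnitudes.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .errors import ConfigError
from .panel import CountryYearPanel

#: Order of the log-mortality coefficient vector.
MORTALITY_COEF_NAMES = (
    "intercept",
    "ln_gdp",
    "ln_gdp_pc",
    "maternal_education",
    "log1p_dah_pc",
    "log1p_ghe_s_pc",
    "year_trend",
)

FRACTION_COEF_NAMES = ("intercept", "ln_ghe_s_pc", "ln_gdp_pc")


@dataclass(frozen=True)
class SyntheticSpec:
    """Generating parameters of a synthetic panel."""

    n_countries: int = 30
    year_start: int = 2000
    year_end_observed: int = 2015
    year_end_forecast: int = 2030
    true_mortality_coefficients: tuple[float, ...] = (
        8.0,    # intercept
        -0.05,  # ln GDP
        -0.35,  # ln GDP per capita
        -0.04,  # maternal education (years)
        -0.02,  # log1p DAH per capita
        -0.08,  # log1p GHE-S per capita
        -0.015, # linear year trend (per year since base)
    )
    mortality_noise_sd: float = 0.05
    #: (a, b) of the power-law spending frontier a * gdp_pc ** b, 0 < b < 1.
    frontier_params: tuple[float, float] = (0.08, 0.85)
    efficiency_range: tuple[float, float] = (0.3, 1.0)
    child_fraction_coefficients: tuple[float, float, float] = (0.35, -0.03, -0.02)
    fraction_noise_sd: float = 0.01
    #: mean and sd of per-country annual log GDP-per-capita growth.
    gdp_growth: tuple[float, float] = (0.03, 0.015)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_countries < 3:
            raise ConfigError("n_countries must be >= 3 (DEA needs 3 reference points)")
        if not (self.year_start <= self.year_end_observed <= self.year_end_forecast):
            raise ConfigError("years must satisfy start <= end_observed <= end_forecast")
        lo, hi = self.efficiency_range
        if not (0 < lo <= hi <= 1):
            raise ConfigError("efficiency_range must lie within (0, 1]")
        if self.mortality_noise_sd < 0 or self.fraction_noise_sd < 0:
            raise ConfigError("noise sds must be >= 0")
        a, b = self.frontier_params
        if not (a > 0 and 0 < b < 1):
            raise ConfigError("frontier_params require a > 0 and 0 < b < 1")
        if len(self.true_mortality_coefficients) != 7:
            raise ConfigError("true_mortality_coefficients must have length 7")


@dataclass(frozen=True)
class TruthRecord:
    """Generating parameters and latent per-country quantities, for oracles."""

    spec: SyntheticSpec
    mortality_coefficients: dict[str, float]
    fraction_coefficients: dict[str, float]
    frontier_a: float
    frontier_b: float
    efficiency: dict[str, float]

    def frontier(self, gdp_pc):
        """True spending frontier evaluated at GDP per capita."""
        return self.frontier_a * np.asarray(gdp_pc, dtype=float) ** self.frontier_b


def generate_panel(spec: SyntheticSpec) -> tuple[CountryYearPanel, TruthRecord]:
    """Generate a panel plus the truth record that produced it.

    Identical specs (including seed) yield identical output. GHE-S pc equals
    ``frontier(gdp_pc) * efficiency_country`` at every country-year, so the
    frontier-consistency invariant holds by construction; u5mr is
    ``exp(linear predictor + noise)`` clipped to (0.1, 999).
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_countries
    ids = np.array([f"C{i:03d}" for i in range(n)])
    years = np.arange(spec.year_start, spec.year_end_forecast + 1)
    t_idx = years - spec.year_start  # years since panel start
    base_year = spec.year_end_observed

    # Cross-country initial conditions.
    gdp_pc0 = np.exp(rng.normal(7.0, 0.9, n))            # ~ $250 .. $9000
    drift = rng.normal(spec.gdp_growth[0], spec.gdp_growth[1], n)
    pop0 = np.exp(rng.normal(np.log(2.0e7), 1.0, n))
    pop_growth = rng.normal(0.01, 0.004, n)
    edu0 = rng.uniform(2.0, 8.0, n)
    edu_growth = rng.uniform(0.05, 0.15, n)
    eff = rng.uniform(spec.efficiency_range[0], spec.efficiency_range[1], n)
    dah_offset = rng.normal(0.0, 2.0, n)

    # Country x year grids (n, T).
    gdp_pc = gdp_pc0[:, None] * np.exp(drift[:, None] * t_idx[None, :])
    pop = pop0[:, None] * np.exp(pop_growth[:, None] * t_idx[None, :])
    gdp = gdp_pc * pop
    edu = np.minimum(edu0[:, None] + edu_growth[:, None] * t_idx[None, :], 14.0)
    cbr = np.clip(0.045 - 0.004 * np.log(gdp_pc / 500.0), 0.01, 0.05)
    births = cbr * pop

    a, b = spec.frontier_params
    ghe_s_pc = a * gdp_pc**b * eff[:, None]
    dah_pc = np.maximum(0.0, 28.0 - 3.0 * np.log(gdp_pc) + dah_offset[:, None])

    c = np.asarray(spec.true_mortality_coefficients, dtype=float)
    lin = (
        c[0]
        + c[1] * np.log(gdp)
        + c[2] * np.log(gdp_pc)
        + c[3] * edu
        + c[4] * np.log1p(dah_pc)
        + c[5] * np.log1p(ghe_s_pc)
        + c[6] * (years - base_year)[None, :]
    )
    noise = (
        rng.normal(0.0, spec.mortality_noise_sd, lin.shape)
        if spec.mortality_noise_sd > 0
        else np.zeros_like(lin)
    )
    u5mr = np.clip(np.exp(lin + noise), 0.1, 999.0)

    # Income groups: terciles of base-year GDP per capita, frozen.
    gdp_pc_base = gdp_pc[:, t_idx[years == base_year][0]]
    cut = np.quantile(gdp_pc_base, [1 / 3, 2 / 3])
    groups = np.where(
        gdp_pc_base <= cut[0], "low",
        np.where(gdp_pc_base <= cut[1], "lower-middle", "upper-middle"),
    )

    df = pd.DataFrame(
        {
            "country_id": np.repeat(ids, len(years)),
            "year": np.tile(years, n),
            "gdp": gdp.ravel(),
            "gdp_pc": gdp_pc.ravel(),
            "maternal_education": edu.ravel(),
            "dah_pc": dah_pc.ravel(),
            "ghe_s_pc": ghe_s_pc.ravel(),
            "population": pop.ravel(),
            "live_births": births.ravel(),
            "u5mr": u5mr.ravel(),
            "income_group": np.repeat(groups, len(years)),
            "is_observed": np.tile(years <= base_year, n),
        }
    )
    panel = CountryYearPanel.from_dataframe(df)
    truth = TruthRecord(
        spec=spec,
        mortality_coefficients=dict(zip(MORTALITY_COEF_NAMES, c)),
        fraction_coefficients=dict(
            zip(FRACTION_COEF_NAMES, spec.child_fraction_coefficients)
        ),
        frontier_a=a,
        frontier_b=b,
        efficiency=dict(zip(ids, eff)),
    )
    return panel, truth


def generate_subaccounts(
    panel: CountryYearPanel, truth: TruthRecord, seed: int | None = None
) -> pd.DataFrame:
    """Emulate child-health sub-account observations for observed rows.

    Returns (country_id, year, child_fraction, ghe_s_pc, gdp_pc) where the
    fraction is the truth's linear share plus Gaussian noise, clipped into
    (0, 1) so the fraction regression's domain precondition always holds.
    """
    spec = truth.spec
    rng = np.random.default_rng(spec.seed + 1 if seed is None else seed)
    obs = panel.observed()
    g = truth.fraction_coefficients
    frac = (
        g["intercept"]
        + g["ln_ghe_s_pc"] * np.log(obs["ghe_s_pc"].to_numpy())
        + g["ln_gdp_pc"] * np.log(obs["gdp_pc"].to_numpy())
    )
    if spec.fraction_noise_sd > 0:
        frac = frac + rng.normal(0.0, spec.fraction_noise_sd, len(frac))
    frac = np.clip(frac, 1e-4, 1 - 1e-4)
    return pd.DataFrame(
        {
            "country_id": obs["country_id"].to_numpy(),
            "year": obs["year"].to_numpy(),
            "child_fraction": frac,
            "ghe_s_pc": obs["ghe_s_pc"].to_numpy(),
            "gdp_pc": obs["gdp_pc"].to_numpy(),
        }
    )


def truth_report(truth: TruthRecord) -> pd.DataFrame:
    """Tidy table of generating parameters, the oracle for recovery tests.

    One row per (kind, name) with kinds ``mortality_coefficient``,
    ``fraction_coefficient``, ``frontier_param`` and ``efficiency`` (the
    latter keyed by country id).
    """
    rows = []
    for name, val in truth.mortality_coefficients.items():
        rows.append(("mortality_coefficient", name, val))
    for name, val in truth.fraction_coefficients.items():
        rows.append(("fraction_coefficient", name, val))
    rows.append(("frontier_param", "a", truth.frontier_a))
    rows.append(("frontier_param", "b", truth.frontier_b))
    rows.append(("param", "mortality_noise_sd", truth.spec.mortality_noise_sd))
    for cid, e in truth.efficiency.items():
        rows.append(("efficiency", cid, e))
    return pd.DataFrame(rows, columns=["kind", "name", "value"])


def frozen_spending_spec(spec: SyntheticSpec) -> SyntheticSpec:
    """Variant with zero income growth and noise, so spending is flat in time.

    Useful when a closed-form mortality path with constant DAH / GHE-S is
    needed as an oracle.
    """
    return replace(spec, gdp_growth=(0.0, 0.0), mortality_noise_sd=0.0)
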