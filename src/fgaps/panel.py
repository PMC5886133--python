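"""Country-year panel data model, CSV I/O and run configuration.

The panel is the universal input of the pipeline: one row per country and
calendar year carrying demography (population, live births), the economy
(GDP, GDP per capita), maternal education, health financing (DAH per capita,
government health expenditure as source per capita) and under-five mortality.
Rows are either observed history (``is_observed = True``) or forecast
covariates (``is_observed = False``) supplied for the projection horizon.

All monetary columns are constant-USD of a single base year; no deflation is
performed here — unit harmonisation belongs upstream of the tool.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import pandas as pd
import yaml

from .errors import ConfigError, PanelValidationError, SchemaError

#: Canonical column order of a panel CSV.
PANEL_COLUMNS = [
    "country_id",
    "year",
    "gdp",
    "gdp_pc",
    "maternal_education",
    "dah_pc",
    "ghe_s_pc",
    "population",
    "live_births",
    "u5mr",
    "income_group",
    "is_observed",
]

INCOME_GROUPS = ("low", "lower-middle", "upper-middle", "high")

#: Cost per child life saved (constant USD) by World Bank income group.
DEFAULT_COST_SCHEDULE = {"low": 4205.0, "lower-middle": 6496.0, "upper-middle": 10016.0}

# Columns that must be strictly positive (on observed rows).
_POSITIVE = ("gdp", "gdp_pc", "population", "live_births")
# Columns that must be non-negative.
_NONNEG = ("dah_pc", "ghe_s_pc")
# Columns that may be NaN on forecast rows (unknown future outcomes/spending).
_FORECAST_OPTIONAL = ("u5mr", "dah_pc", "ghe_s_pc")


@dataclass(frozen=True)
class CountryYearPanel:
    """A validated long-format country-year panel.

    Thin wrapper over a :class:`pandas.DataFrame` sorted by
    ``(country_id, year)`` with the canonical column set. Construct through
    :meth:`from_dataframe` (or :func:`read_panel`) so invariants hold.
    """

    df: pd.DataFrame

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "CountryYearPanel":
        df = _coerce(df)
        violations = _validate(df)
        if violations:
            raise PanelValidationError(violations)
        df = df.sort_values(["country_id", "year"], kind="mergesort")
        df = df[PANEL_COLUMNS].reset_index(drop=True)
        return cls(df)

    # -- convenience accessors -------------------------------------------------

    @property
    def countries(self) -> list[str]:
        return sorted(self.df["country_id"].unique())

    def observed(self) -> pd.DataFrame:
        return self.df[self.df["is_observed"]]

    def country(self, country_id: str) -> pd.DataFrame:
        sub = self.df[self.df["country_id"] == country_id]
        if sub.empty:
            raise KeyError(f"country {country_id!r} not in panel")
        return sub

    def base_year(self) -> int:
        """Last observed year (must be common across countries)."""
        by = self.observed().groupby("country_id")["year"].max()
        if by.nunique() != 1:
            raise PanelValidationError(
                [f"countries end observation in different years: {sorted(by.unique())}"]
            )
        return int(by.iloc[0])

    def income_group_of(self, country_id: str) -> str:
        return str(self.country(country_id)["income_group"].iloc[0])

    def __len__(self) -> int:
        return len(self.df)

    def __eq__(self, other) -> bool:
        if not isinstance(other, CountryYearPanel):
            return NotImplemented
        return self.df.equals(other.df)


def _coerce(df: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in PANEL_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"panel is missing required columns: {missing}")
    df = df.copy()
    df["country_id"] = df["country_id"].astype(str)
    df["year"] = df["year"].astype(int)
    df["income_group"] = df["income_group"].astype(str)
    if df["is_observed"].dtype != bool:
        df["is_observed"] = df["is_observed"].map(_parse_bool)
    for col in PANEL_COLUMNS:
        if col not in ("country_id", "year", "income_group", "is_observed"):
            df[col] = pd.to_numeric(df[col], errors="coerce")
    return df


def _parse_bool(v) -> bool:
    if isinstance(v, bool):
        return v
    s = str(v).strip().lower()
    if s in ("true", "1", "t", "yes"):
        return True
    if s in ("false", "0", "f", "no"):
        return False
    raise SchemaError(f"cannot parse is_observed value {v!r}")


def _validate(df: pd.DataFrame) -> list[str]:
    v: list[str] = []
    dup = df.duplicated(subset=["country_id", "year"], keep=False)
    if dup.any():
        keys = df.loc[dup, ["country_id", "year"]].drop_duplicates()
        for _, row in keys.iterrows():
            v.append(f"duplicate (country_id, year) key ({row.country_id}, {row.year})")

    for cid, grp in df.groupby("country_id"):
        years = sorted(grp["year"])
        if years != list(range(years[0], years[-1] + 1)):
            v.append(f"years for {cid} are not a contiguous range: {years}")
        if grp["income_group"].nunique() > 1:
            v.append(f"income_group for {cid} is not constant over years")

    bad_group = ~df["income_group"].isin(INCOME_GROUPS)
    for idx in df.index[bad_group]:
        v.append(
            f"row {idx}: income_group {df.at[idx, 'income_group']!r} "
            f"not one of {INCOME_GROUPS}"
        )

    observed = df["is_observed"]
    for col in _POSITIVE + _NONNEG + ("u5mr", "maternal_education"):
        vals = df[col]
        nan_rows = vals.isna() & (observed | (col not in _FORECAST_OPTIONAL))
        for idx in df.index[nan_rows]:
            v.append(f"row {idx}: {col} is missing")
    for col in _POSITIVE:
        bad = df[col].notna() & (df[col] <= 0)
        for idx in df.index[bad]:
            v.append(f"row {idx}: {col} must be > 0, got {df.at[idx, col]}")
    for col in _NONNEG:
        bad = df[col].notna() & (df[col] < 0)
        for idx in df.index[bad]:
            v.append(f"row {idx}: {col} must be >= 0, got {df.at[idx, col]}")
    bad_u5 = df["u5mr"].notna() & ~((df["u5mr"] > 0) & (df["u5mr"] < 1000))
    for idx in df.index[bad_u5]:
        v.append(f"row {idx}: u5mr must lie in (0, 1000), got {df.at[idx, 'u5mr']}")
    return v


def read_panel(path, schema: Mapping[str, str] | None = None) -> CountryYearPanel:
    """Read and validate a panel CSV.

    Parameters
    ----------
    path
        CSV file (comma-separated, UTF-8, header row, '.' decimal).
    schema
        Optional map canonical-column-name -> column-name-in-file, for files
        whose headers differ from :data:`PANEL_COLUMNS`.
    """
    path = Path(path)
    if not path.exists():
        raise SchemaError(f"panel file not found: {path}")
    raw = pd.read_csv(path, float_precision="round_trip")
    if schema:
        missing = [src for src in schema.values() if src not in raw.columns]
        if missing:
            raise SchemaError(f"schema refers to absent columns: {missing}")
        raw = raw.rename(columns={src: dst for dst, src in schema.items()})
    return CountryYearPanel.from_dataframe(raw)


def write_panel(panel: CountryYearPanel, path) -> None:
    """Write a panel to CSV such that ``read_panel`` reproduces it exactly."""
    panel.df.to_csv(path, index=False, columns=PANEL_COLUMNS)


@dataclass
class RunConfig:
    """Run-wide configuration: the health goal, costing and allocation weights.

    Attributes
    ----------
    goal_target_rate
        Target under-five mortality, deaths per 1000 live births (SDG 3.2
        child-health target: 25).
    goal_target_year
        Calendar year by which the target must be met (2030).
    base_year
        Last observed year; inferred from the panel when ``None``.
    horizon_end
        Final forecast year; defaults to ``goal_target_year``.
    cost_schedule
        Cost per child life saved in constant USD, by income group. The
        defaults are the published marginal-cost constants ($4205 low,
        $6496 lower-middle, $10 016 upper-middle); high income has no cost
        and is excluded from need computation.
    alpha
        Donor share of the weighted financing gap, >= 0. ``None`` until set
        by the user or derived from ``budget``.
    beta
        Weight on Gap B (PS - ES), <= 1. Negative values reward domestic
        spending, beta = 0 ignores ES, beta = 1 funds the total gap N - ES.
    budget
        Optional donor budget in USD; when set, alpha is solved so that
        allocations sum to the budget.
    denominator
        Series the mortality-rate difference is multiplied by to obtain
        lives: "births" (default; 5q0 applies to live births) or
        "population".
    arr_mode
        "geometric" (constant annual percent reduction) or "continuous"
        (constant exponential rate); numerically near-identical.
    fraction_link
        Link for the child-health fraction regression: "linear" (raw-scale
        OLS with clipping) or "logit".
    ps_fraction_basis
        Whether the child-health fraction applied to potential spending is
        evaluated at the potential ("potential", counterfactual-consistent)
        or the expected ("expected") spending level.
    seed
        Seed for any stochastic step.
    """

    goal_target_rate: float = 25.0
    goal_target_year: int = 2030
    base_year: int | None = None
    horizon_end: int | None = None
    cost_schedule: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_COST_SCHEDULE)
    )
    alpha: float | None = None
    beta: float = 0.0
    budget: float | None = None
    denominator: str = "births"
    arr_mode: str = "geometric"
    fraction_link: str = "linear"
    ps_fraction_basis: str = "potential"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.goal_target_rate <= 0:
            raise ConfigError("goal_target_rate must be positive")
        if self.base_year is not None and self.goal_target_year <= self.base_year:
            raise ConfigError("goal_target_year must be after base_year")
        for group, cost in self.cost_schedule.items():
            if group not in INCOME_GROUPS:
                raise ConfigError(f"unknown income group in cost_schedule: {group!r}")
            if not (cost > 0 and math.isfinite(cost)):
                raise ConfigError(f"cost_schedule[{group!r}] must be > 0, got {cost}")
        if self.alpha is not None and self.alpha < 0:
            raise ConfigError(f"alpha must be >= 0, got {self.alpha}")
        if self.beta > 1:
            raise ConfigError(f"beta must be <= 1, got {self.beta}")
        if self.budget is not None and self.budget <= 0:
            raise ConfigError(f"budget must be > 0, got {self.budget}")
        if self.denominator not in ("births", "population"):
            raise ConfigError("denominator must be 'births' or 'population'")
        if self.arr_mode not in ("geometric", "continuous"):
            raise ConfigError("arr_mode must be 'geometric' or 'continuous'")
        if self.fraction_link not in ("linear", "logit"):
            raise ConfigError("fraction_link must be 'linear' or 'logit'")
        if self.ps_fraction_basis not in ("potential", "expected"):
            raise ConfigError("ps_fraction_basis must be 'potential' or 'expected'")

    def resolve_base_year(self, panel: CountryYearPanel) -> int:
        return self.base_year if self.base_year is not None else panel.base_year()

    def horizon_years(self, panel: CountryYearPanel) -> list[int]:
        t0 = self.resolve_base_year(panel)
        end = self.horizon_end if self.horizon_end is not None else self.goal_target_year
        return list(range(t0 + 1, end + 1))

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def load_config(path) -> RunConfig:
    """Load a :class:`RunConfig` from a JSON or YAML file.

    Absent fields take their defaults (SDG target 25 per 1000 by 2030; the
    published cost schedule); explicit values override them.
    """
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    text = path.read_text()
    if path.suffix.lower() == ".json":
        data = json.loads(text)
    else:
        data = yaml.safe_load(text)
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ConfigError(f"config root must be a mapping, got {type(data).__name__}")
    return config_from_dict(data)


def config_from_dict(data: Mapping) -> RunConfig:
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(data) - known
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    kwargs = dict(data)
    if "cost_schedule" in kwargs and kwargs["cost_schedule"] is not None:
        merged = dict(DEFAULT_COST_SCHEDULE)
        merged.update(kwargs["cost_schedule"])
        kwargs["cost_schedule"] = {k: float(v) for k, v in merged.items()}
    try:
        return RunConfig(**kwargs)
    except TypeError as exc:  # pragma: no cover - defensive
        raise ConfigError(str(exc)) from exc
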