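"""Financing gaps and the donor allocation rule DAH = alpha[(N-PS) + beta(PS-ES)].

Gap A = N - PS is the shortfall beyond what a country could itself fund;
Gap B = PS - ES is the unrealised domestic spending potential (negative when
expected spending already exceeds potential); their sum is the total
financing gap N - ES. The donor rule weights Gap B by beta (beta = 1
reduces to alpha[N - ES], beta = 0 to alpha[N - PS], beta < 0 rewards
domestic spending) and scales by alpha, the funded share of the gap. Raw
terms that come out negative are floored at zero — assistance cannot be
negative.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .errors import AlignmentError, ConfigError
from .expected_spend import ExpectedSpendResult
from .need import NeedResult
from .panel import CountryYearPanel, RunConfig
from .potential_spend import PotentialSpendResult

RANK_CRITERIA = ("gdp_pc", "gap_total", "gap_a", "u5mr")


@dataclass(frozen=True)
class GapResult:
    country_id: str
    need_usd: float  # N
    es_usd: float    # ES
    ps_usd: float    # PS

    @property
    def gap_a(self) -> float:
        return self.need_usd - self.ps_usd

    @property
    def gap_b(self) -> float:
        return self.ps_usd - self.es_usd

    @property
    def gap_total(self) -> float:
        # Defined as Gap A + Gap B so the decomposition identity is exact in
        # floating point; mathematically equal to N - ES.
        return self.gap_a + self.gap_b


@dataclass(frozen=True)
class AllocationResult:
    country_id: str
    alpha: float
    beta: float
    raw_term: float   # alpha * [(N - PS) + beta * (PS - ES)]
    dah_usd: float    # max(0, raw_term)

    @property
    def clipped(self) -> bool:
        return self.raw_term < 0


def compute_gaps(
    need: list[NeedResult],
    es: list[ExpectedSpendResult],
    ps: list[PotentialSpendResult],
) -> list[GapResult]:
    """Join N, ES, PS by country; the inputs must cover the same country set."""
    n_map = {r.country_id: r.need_usd for r in need}
    e_map = {r.country_id: r.es_total_usd for r in es}
    p_map = {r.country_id: r.ps_total_usd for r in ps}
    if not (set(n_map) == set(e_map) == set(p_map)):
        raise AlignmentError(
            "country sets differ: "
            f"need={sorted(n_map)}, es={sorted(e_map)}, ps={sorted(p_map)}"
        )
    return [
        GapResult(cid, n_map[cid], e_map[cid], p_map[cid]) for cid in sorted(n_map)
    ]


def gap_term(gap: GapResult, beta: float) -> float:
    return gap.gap_a + beta * gap.gap_b


def allocate(gaps: list[GapResult], config: RunConfig) -> list[AllocationResult]:
    """Apply the donor rule with the configured alpha and beta.

    When ``config.budget`` is set, alpha is solved so allocations sum to the
    budget (see :func:`allocate_budget`); otherwise ``config.alpha`` is
    required.
    """
    if config.budget is not None:
        return allocate_budget(gaps, config.budget, config.beta)
    if config.alpha is None:
        raise ConfigError("allocation needs either alpha or budget in the config")
    alpha, beta = config.alpha, config.beta
    out = []
    for g in gaps:
        raw = alpha * gap_term(g, beta)
        out.append(AllocationResult(g.country_id, alpha, beta, raw, max(0.0, raw)))
    return out


def allocate_budget(
    gaps: list[GapResult], budget: float, beta: float = 0.0
) -> list[AllocationResult]:
    """Solve alpha so that total DAH equals the donor budget.

    alpha = budget / sum_i max(0, (N_i - PS_i) + beta (PS_i - ES_i)); the
    floor keeps countries with negative terms from absorbing budget.
    """
    if budget <= 0:
        raise ConfigError(f"budget must be positive, got {budget}")
    floored = [max(0.0, gap_term(g, beta)) for g in gaps]
    total = sum(floored)
    if total <= 0:
        raise ConfigError("all gap terms are <= 0: nothing to fund")
    alpha = budget / total
    return [
        AllocationResult(g.country_id, alpha, beta, alpha * gap_term(g, beta),
                         alpha * f)
        for g, f in zip(gaps, floored)
    ]


def gaps_to_frame(gaps: list[GapResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (g.country_id, g.need_usd, g.es_usd, g.ps_usd,
             g.gap_a, g.gap_b, g.gap_total)
            for g in gaps
        ],
        columns=["country_id", "need_usd", "es_usd", "ps_usd",
                 "gap_a", "gap_b", "gap_total"],
    )


def allocation_to_frame(allocs: list[AllocationResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (a.country_id, a.alpha, a.beta, a.raw_term, a.dah_usd, a.clipped)
            for a in allocs
        ],
        columns=["country_id", "alpha", "beta", "raw_term", "dah_usd", "clipped"],
    )


def rank_countries(
    panel: CountryYearPanel, gaps: list[GapResult], criterion: str
) -> pd.DataFrame:
    """Rank countries under one allocation criterion.

    gdp_pc sorts ascending (poorest first, base-year values); gap_total,
    gap_a and u5mr sort descending (largest gap / highest mortality first).
    Ties break by country id ascending. Returns columns country_id, value,
    rank with ranks a permutation of 1..n.
    """
    if criterion not in RANK_CRITERIA:
        raise ConfigError(f"criterion must be one of {RANK_CRITERIA}")
    base_year = panel.base_year()
    base = panel.df[(panel.df["year"] == base_year)].set_index("country_id")
    if criterion == "gdp_pc":
        values = {g.country_id: float(base.loc[g.country_id, "gdp_pc"]) for g in gaps}
        ascending = True
    elif criterion == "u5mr":
        values = {g.country_id: float(base.loc[g.country_id, "u5mr"]) for g in gaps}
        ascending = False
    else:
        values = {g.country_id: getattr(g, criterion) for g in gaps}
        ascending = False
    df = pd.DataFrame(
        {"country_id": list(values), "value": list(values.values())}
    ).sort_values(
        ["value", "country_id"], ascending=[ascending, True], kind="mergesort"
    )
    df["rank"] = range(1, len(df) + 1)
    df["criterion"] = criterion
    return df.reset_index(drop=True)[["criterion", "rank", "country_id", "value"]]
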