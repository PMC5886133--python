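# Methods

This note documents the statistical model behind each pipeline stage, the
defaults and why they were chosen, what the synthetic generator does and does
not emulate, and the numerical conventions.

## Data model

The universal input is a long-format country-year panel: GDP and GDP per
capita (constant USD), maternal education (years), DAH per capita,
government health expenditure as source (GHE-S) per capita, population, live
births, under-five mortality (U5MR, deaths per 1000 live births) and a World
Bank-style income group. Rows are flagged observed or forecast; forecast
rows supply the GDP / education / spending covariates for the projection
horizon and may leave U5MR, DAH and GHE-S missing (future mortality is
unknown; spending forecasts are optional inputs). All bound checks
(U5MR ∈ (0, 1000), positive population and births, non-negative spending)
are enforced on observed rows; monetary fields are constant-USD of a single
base year, with deflation handled upstream. Income group is frozen at the
base year so the cost schedule lookup is stable over the horizon.

## Expected mortality trend

Pooled OLS across countries and observed years:

ln U5MR = b0 + b1 ln GDP + b2 ln GDPpc + b3 edu + b4 ln(1+DAHpc)
        + b5 ln(1+GHESpc) + b6 (year − base_year) + ε

Transform choices: the monetary regressors enter as logs, with a +1 shift
for the two spending series so zero DAH is representable; education enters
in raw years; the linear trend proxies technology. The shift-log transform
is recorded on the fitted model and the design matrix builder is the single
source of truth for both fitting and prediction. Country fixed effects are
available (`country_effects=True`) but off by default — the pooled
specification has only the six covariates plus trend.

The expected trend for year t > base_year is the exponentiated linear
predictor using forecast GDP, GDP per capita and education, the advancing
trend, and DAH / GHE-S **frozen at base-year values** — the
no-change-in-health-spending counterfactual. Perturbing post-base-year
spending columns provably cannot move the projection (tested). No smearing
or half-σ² retransformation correction is applied to the exponentiated
prediction; with log-scale residual sd around 0.05 the level bias is ≈0.1%,
and the correction would have to be propagated through every downstream
difference. The omission is deliberate and documented here.

Rank deficiency is detected on the column-normalised design (smallest
singular value < 1e-8 × largest) and reported with the set of columns
loading on the null vector, so e.g. a panel with constant population (making
ln GDP = ln GDPpc + const) fails loudly instead of returning an arbitrary
least-squares solution.

## Required trajectory and Need

For baseline mortality m0 above the goal rate m* with T years to the target,
the goal-compliant path declines geometrically at the annual rate of
reduction ARR = 1 − (m*/m0)^(1/T), hitting m* exactly at the target year
(to < 1e-9 relative; tested). A continuous-time variant is exposed in the
config; for a single start/end pair it is algebraically identical. If the
baseline is already at or below the goal, the required path is the expected
path capped at the goal, so no need is generated.

Lives to save in year t: max(0, m_expected(t) − m_required(t)) / 1000 ×
births(t). Live births is the default denominator because 5q0 is a
probability per live birth; total population is a config alternative
(`denominator: population`). Need is lives × the income-group cost per
child life saved — $4205 (low), $6496 (lower-middle), $10 016 (upper-middle)
in constant USD — summed over base_year+1 … target year. The framework
reports the cumulative horizon total; per-year columns are retained for
other horizons. No discounting is applied. High-income countries have no
defined unit cost: positive lives there raise an error, and the end-to-end
pipeline excludes high-income countries up front.

## Expected spending (ES)

Where child-health sub-accounts exist, the child-health share of government
health spending is regressed by OLS on ln GHE-S per capita and ln GDP per
capita, on the raw fraction scale; predictions are clipped into [0, 1]. A
logit link is available (`fraction_link: logit`) for settings where shares
approach the boundary. ES per capita in year t is share × GHE-S pc(t), and
the country total sums per-capita ES × population over the horizon. GHE-S
forecasts are an input column; when absent, a per-country log-linear trend
extrapolation of the observed series can be enabled explicitly
(`--extrapolate-ghe`) — it is a deliberate, flagged substitution, not a
default, because spending forecasting is a modelling exercise of its own.

## Potential spending (PS)

Ability to pay is the height of a best-practice spending frontier: one
input (GDP per capita), one output (GHE-S per capita), output orientation,
variable returns to scale. For evaluation point (x, y):

max φ  s.t.  Σλⱼyⱼ ≥ φy,  Σλⱼxⱼ ≤ x,  Σλⱼ = 1,  λ ≥ 0

solved with scipy's HiGHS solver (feasibility tolerances 1e-9). In the
1-in/1-out case the optimum equals the concave, non-decreasing envelope of
the reference points; the test suite checks the LP against an independent
vertex-enumeration oracle to 1e-6 relative error on random instances. φ ≥ 1
for in-sample reference points (domination) and at least one reference
point has φ = 1. Positive-weight peers (λ > 1e-7) are reported; when the
optimal peer set is not unique, the solver's deterministic vertex is
reported rather than a lexicographic canonical choice. No bootstrap bias
correction is applied to the frontier — the estimate is the raw envelope,
which is biased toward the data (an underestimate of any "true" frontier);
rankings and gaps inherit that conservatism.

The frontier is fitted on the base-year cross-section, not the pooled
panel, because forecasting evaluates the *same* frontier at future GDP;
pooling would mix price levels and trends. Forecast GDP outside the
reference input range is clamped to the nearest reference input — a VRS
envelope has no support for extrapolation. Evaluation points with input
below every reference input make the program infeasible; the documented
fallback returns the best reference output at or below the input, or the
observed output, flagged in the result. Conversion to child-health PS
applies the fraction model at the *potential* spending level
(counterfactual-consistent: if the country spent at potential, its share
would be predicted at that level); applying the expected-level share
instead is a config alternative (`ps_fraction_basis: expected`).

## Gaps, allocation, rankings

Gap A = N − PS, Gap B = PS − ES, and the total gap is **defined** as their
sum so the decomposition identity holds to machine precision (it equals
N − ES mathematically; computing N − ES separately can differ in the last
ulp). Gap B is never clipped: expected spending can exceed potential, and a
negative Gap B is meaningful (a country already spending beyond its peer
benchmark). The allocation rule multiplies (Gap A + β Gap B) by α and floors
the result at zero — negative assistance is not modelled; in budget mode α =
budget / Σ max(0, terms), so allocations sum to the budget exactly over the
floored terms. α and β are strictly user inputs; the `run-all` command
defaults to α = 0.1, β = 0 (the incentive-neutral case) only so the
end-to-end command is runnable without a config. Rankings use
cumulative-horizon gaps; ties break by country id ascending; GDP per capita
ranks ascending, the gap and mortality criteria descending.

Reporting conventions: the top-need table expresses Gap A as a share of
need, (N − PS)/N, and Gap B as a share of potential, (PS − ES)/PS.

## Synthetic generator

The generator produces panels with exactly the structure the stages assume,
plus a truth record for recovery tests:

- GDP per capita: log-normal cross-section (median ≈ $1100, log-sd 0.9)
  growing geometrically with country drift ~ N(3%, 1.5%)/yr; population
  log-normal (median 20 M) with country growth ~ N(1%, 0.4%)/yr; education
  starts U(2, 8) years and grows at U(0.05, 0.15) yr/yr, capped at 14.
  Heterogeneous growth rates keep the design full-rank even with country
  fixed effects.
- Spending frontier: GHE-S pc = a·GDPpc^b × efficiency, default a = 0.08,
  b = 0.85 (concave, increasing; ≈$28 pc at $1000 GDP pc), efficiency ~
  U(0.3, 1) frozen per country. Frontier consistency (spending ≤ frontier,
  equality iff efficiency 1) holds by construction.
- DAH pc declines in log income (28 − 3 ln GDPpc + country offset, floored
  at 0), so poorer countries receive more aid.
- Mortality: exp(linear predictor + N(0, 0.05²)) clipped to (0.1, 999),
  with default coefficients (8.0, −0.05, −0.35, −0.04, −0.02, −0.08,
  −0.015) giving U5MR roughly 10–200 across the income range and a ~1.5%/yr
  secular decline — the regime where the 2030 goal is binding for poor
  countries and already met by rich ones.
- Child-health share: 0.35 − 0.03 ln GHESpc − 0.02 ln GDPpc plus N(0, 0.01)
  observation noise, clipped into (0, 1) — a share near 10–20% that declines
  with income.
- Income groups are terciles of base-year GDP per capita (low /
  lower-middle / upper-middle); no high-income group is generated because
  the cost schedule does not cover it.

All draws come from one `numpy` Generator seeded from the spec, so identical
specs give byte-identical panels. What the generator does **not** emulate:
real-world magnitudes or country identities, demographic age structure,
spending shocks, measurement error in covariates, serially correlated
mortality residuals, or income-group transitions. Passing recovery tests
therefore show the estimators are correct *under the assumed model*, not
that the model captures any particular country's data.

## Problem sizes and numerics

Test and acceptance runs use 30–120 synthetic countries, 16 observed years
(2000–2015) and a 15-year horizon to 2030; Monte-Carlo recovery uses 200
replicates of 50 countries × 16 years (mortality) and 300 sub-account rows
(fraction), sizes at which the bias checks have comfortable power while the
whole suite runs in well under a minute of compute. LP tolerances are 1e-9;
the frontier-recovery tolerance (5% at interior GDP) covers the chord error
of a piecewise-linear envelope under a smooth concave frontier with ~120
support points. CSVs are written with full float repr and read back with
round-trip float parsing, so write→read is the identity on all fields.

## Known limitations

- The expected-trend regression is associational; projecting it forward
  assumes the fitted relationships are stable and ignores parameter and
  residual uncertainty (no intervals are produced).
- The DEA frontier inherits everything in the residual: omitted drivers of
  spending (fiscal capacity, governance) and measurement error all move the
  envelope. Potential spending should be read as a peer benchmark, not a
  causal capacity estimate.
- Cost per life saved is treated as constant within income group and over
  the horizon; marginal costs likely rise as coverage scales.
- Prepaid private spending is not modelled; the data model leaves room for
  it as an additional spending column upstream of ES.
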