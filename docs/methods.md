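# Methods

## The queueing network

A care system is an open network of M/M/c stations. Unit *i* has cᵢ
staffed beds, service rate μᵢ (reciprocal of the mean length of stay in
days), external arrival rate λ₀ᵢ (admissions/day from outside the system),
and a row of routing probabilities r₍ᵢⱼ₎ giving where a patient leaving *i*
goes next; the row shortfall 1 − Σⱼ r₍ᵢⱼ₎ is the discharge probability.
Effective arrival rates solve the linear traffic equations
(I − Rᵀ)·Eff λ = λ₀. We solve the system directly rather than propagating
in topological order, so cyclic routing (e.g. readmission loops) is
supported; the equations are singular when some strongly connected set of
units recirculates its whole population, which is detected by the spectral
radius of R and reported with the offending cycle named. Utilization is
ρ = λ/(c·μ) and may exceed 1: overload is a state the analysis must see,
not an input error. Stability of a unit is the separate predicate λ < c·μ.

## Pooling

A pooling plan partitions the unit ids into named groups. The pooled unit
takes the sum of its members' beds (integers summed, never averaged), the
sum of their external rates, and the element-wise sum of their nursing
staff. Two quantities are not determined by the members alone and had to be
designed:

* **pooled routing** — the arrival-weighted merge
  r(G→H) = Σ₍ᵢ∈G₎ wᵢ Σ₍ⱼ∈H₎ r₍ᵢⱼ₎ with wᵢ = Eff λᵢ / Σ₍G₎ Eff λᵢ, with
  intra-group mass dropped (a transfer inside a pooled unit is no longer a
  transfer). `apply_pooling(..., routing_override=...)` accepts re-measured
  group-level probabilities where historical data exist.
* **pooled service rate** — the arrival-weighted harmonic mean
  μ_G = Σ Eff λᵢ / Σ (Eff λᵢ/μᵢ), chosen so that the pooled expected
  occupancy Σ λ/μ is conserved exactly. Groups with no traffic fall back to
  the plain harmonic mean.

Both choices preserve total external inflow and total expected workload for
every plan, which is what a capacity comparison needs to hold fixed.

## The occupancy simulation

The simulation is a daily Monte Carlo, not a patient-level discrete-event
simulation. Each day, external arrivals are drawn Poisson(λ₀ᵢ) per unit
and converted to that day's effective arrivals by the traffic equations
(expected-value routing); an optional mode samples the transfer counts
multinomially instead (feed-forward networks only), default off. The day's
expected occupancy is U = ρ·c = Eff λ/μ, compared against the staffed beds
in fractional beds — no rounding, so a unit can be 0.4 beds over. Reported
aggregates: mean ± SD of the system's daily over- and under-utilized beds,
and the count of days with any overutilization (the days nurses must be
reallocated). Over- and under-utilization are reported as labelled
magnitudes; some published conventions print overutilization with a
negative sign, which is the same number with the direction moved into the
sign. All randomness comes from one `numpy` generator seeded by the
config; identical seeds give bit-identical results.

The daily census series feed a Pearson correlation analysis
(`census_correlation`) and the portfolio decomposition
Var(ΣX) = ΣVar + 2·ΣCov (`pooling_variance_gain`), which holds exactly on
every simulated series (sample variance and covariance with matching
ddof=1). Constant series yield an explicit `None` flag rather than a NaN.

## Entropy measures

All entropies are Shannon entropies in bits (log base 2), with
0·log 0 := 0 by continuity. Input vectors must be non-negative and sum to
one within 1e-6, else an `InvalidDistributionError` is raised.

* **Arrival entropy**: entropy of the relative demand dᵢ = Eff λᵢ/Σ Eff λ;
  its maximum is log₂ N (uniform demand over N units), so pooling always
  lowers the maximum.
* **Positional entropy**: Σₖ of the row entropies of a class × position
  probability matrix. When no matrix is supplied, one is derived from a
  feed-forward network: one class per external-entry stream, placed by
  one-step propagation of its entry unit's routing row, with the discharge
  shortfall on a `home` pseudo-position and absorbing entries kept in
  place (one-hot). The maximum variant is uniform over each class's
  declared support — the positions it can actually reach — rather than over
  all N units, because a class that can only reach 3 positions can never
  carry more than log₂ 3 bits.
* **Decision-structure entropy**: Σₐ of the entropies of each
  decision-maker's distribution over information sources. All
  distributions are uniform (the maximum-entropy principle: no empirical
  communication frequencies are assumed), so each maker contributes log₂
  of its source count and the totals decompose additively and exactly.

The total of a design is the exact sum of the three components. When
ranking designs the maximum arrival and maximum positional components are
combined with the decision entropy, so the ranking does not depend on a
particular year's demand distribution; ties (which occur when derived
positional entropy is zero for every pooled design) are broken by model
insertion order.

## Coordination structures

Three strategies, each with detailed or aggregated information, built from
the pooled network, the plan's team assignment, and the per-shift nurse
counts (default: day shift, selectable):

* **hierarchy** — planners uniform over their own unit's nurses, team
  managers uniform over their planners, one manager uniform over the team
  managers. Aggregated: nurse detail collapses to one workload signal per
  unit (planners then contribute nothing), team managers read their units'
  signals, the manager reads the team managers.
* **network** — one planner per unit; aggregated: uniform over the other
  A−1 planners' signals (total A·log₂(A−1)); detailed: uniform over the
  other units' nurses.
* **hub** — planners read a central information system; aggregated: a
  single certain source, hence 0 bits; detailed: each planner is uniform
  over its own unit's nurse-level records in the system.

With at least one nurse per unit, aggregation can never increase the
entropy of any strategy, and hub ≤ hierarchy ≤ network holds within each
design. A unit with zero nurses on the selected shift makes its planner's
detailed distribution degenerate (0 bits) and triggers a warning.

## The perinatology fixture

Five newborn-flow units (delivery room O3, NICU N1, post-IC N2, high/medium
care N3, nursery O1) with published beds, rates, and per-shift nurse
counts. Two variants:

* `printed` (default): the published per-unit effective rates
  (4.0, 1.2, 0.2, 0.9, 2.7)/day stored as external rates with no routing.
  This is the variant behind the utilization table, the entropies, and the
  simulation.
* `flows`: reconstructed flows — 4 births/day split 68.5/15.8/15.7% to
  nursery/NICU/high-medium care, external referrals 0.6/day (NICU) and
  0.4/day (high/medium care), and a NICU→post-IC transfer probability of
  0.2/1.232 chosen so the post-IC inflow matches its published 0.2/day.

The variants do not perfectly agree: the flows variant gives the
high/medium-care unit an inflow of 1.03/day where 0.9/day was published,
and the published utilizations of the NICU (85%) and post-IC (96%) do not
follow from the published rounded inputs (which give 86% and 83%) — the
original analysis evidently used unrounded historical rates. The fixture
stores the published values as printed and documents the discrepancy
instead of "fixing" either side. Presentation rounding (rates to 1
decimal, utilization to a whole percent, entropies to 1–2 decimals) lives
in the report layer; all computation is full precision.

Pooled downstream units are assigned to the neonatology team manager — the
only assignment consistent with the aggregated hierarchy entropies of all
four designs. Planner and team leader are one role.

## Synthetic scenarios

The generator fabricates a network of units (rates and beds drawn
uniformly from configurable ranges) together with a daily demand series
whose pairwise correlation is controlled. Counts are Poisson quantiles of
a Gaussian copula: each unit's daily latent is
sᵢ·(√w·G_day + √(1−w)·noise) with a shared factor G and signs sᵢ. A purely
additive shared Poisson component can only produce weak negative
correlation (its covariance is bounded), so the signed copula is used
instead: alternating signs make opposite-sign pairs hit a negative target
while same-sign pairs are positively correlated by the same magnitude. The
coupling strength w is calibrated by Brent root finding on the empirical
mean pairwise correlation of a fixed 4 000-day calibration sample (common
random numbers across evaluations keep the objective smooth); unattainable
targets — the copula extreme for low-rate Poisson counts can be well short
of ±1 — raise an error rather than silently missing. At a 10 000-day
horizon the realized correlation lands within about ±0.05 of the target.

What the generator emulates: daily Poisson external demand, fixed routing
fractions, controllable inter-unit demand correlation. What it does not:
within-day arrival timing, length-of-stay autocorrelation (a census is
positively autocorrelated in reality; here days are exchangeable),
seasonality, and patient-mix drift. Tests passing on synthetic data
therefore validate the algebra and the orderings, not forecasts for any
real ward.

## Problem sizes and numerical choices

Default horizons are 365 days (one published-style year) for design
comparisons and 10 000 days for law-of-large-numbers and correlation
checks, where the sampling error of a Pearson coefficient is about 0.01.
The days-overutilized ordering across pooling designs is a stochastic
property; it is asserted as a majority over 41 fixed seeds at 365 days,
since single-seed day counts differ by only a few days between the two
best designs. Traffic equations use LAPACK solves (no iterative
propagation); stability tolerance on the routing spectral radius is 1e-9;
probability-vector validation tolerance is 1e-6 on the sum.

## Limitations

* Occupancy is the analytic expectation ρ·c per day, not a sampled census
  with carry-over of patients between days; blocking, transfer queues, and
  length-of-stay sampling are out of scope.
* The five qualitative nurse-return policies (stay/return/ask variants)
  are not simulated; only the information structure of the coordination
  designs is scored.
* Closed-form M/M/c waiting-time quantities (Erlang C) are intentionally
  absent: the analysis uses only ρ and occupancy.
* Derived position matrices require feed-forward routing; cyclic systems
  need an explicitly supplied matrix.
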