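"""Daily Monte-Carlo occupancy simulation and census correlation analysis.

The simulation draws a Poisson number of external admissions per unit per
day, propagates them through the routing matrix to get each unit's daily
effective arrivals, and converts those to an expected occupancy
``U = eff_lambda / mu`` compared against the staffed beds ``c``.  Days on
which any unit's expected occupancy exceeds its staffed beds are the days on
which nurses must be reallocated; the simulation aggregates how often that
happens and by how many beds the system is over- or under-utilized.

The census (daily occupancy) series also feed the portfolio analysis:
pooling units whose demands are weakly or negatively correlated reduces the
variance of the pooled workload below the sum of the members' variances.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .network import (
    CareNetwork,
    CareNetError,
    PoolingPlan,
    _check_solvable,
)

__all__ = [
    "SimulationConfig",
    "SimulationResult",
    "GroupVariance",
    "simulate_days",
    "occupancy_profile",
    "census_correlation",
    "correlation_matrix",
    "pooling_variance_gain",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Horizon, seed, and arrival model of a simulation run.

    ``routing_mode`` selects how a day's sampled external arrivals become
    effective arrivals: ``"expected"`` (default) propagates them
    deterministically through the routing matrix, ``"sampled"`` draws the
    actual transfer counts multinomially (feed-forward networks only).
    """

    horizon_days: int = 365
    seed: int | np.random.SeedSequence = 0
    arrival_model: str = "poisson_daily"
    routing_mode: str = "expected"

    def __post_init__(self) -> None:
        if not (isinstance(self.horizon_days, (int, np.integer)) and self.horizon_days >= 1):
            raise CareNetError(f"horizon_days must be a positive integer, got {self.horizon_days!r}")
        if self.arrival_model != "poisson_daily":
            raise CareNetError(f"unknown arrival_model {self.arrival_model!r}")
        if self.routing_mode not in ("expected", "sampled"):
            raise CareNetError(f"unknown routing_mode {self.routing_mode!r}")


@dataclass(frozen=True)
class SimulationResult:
    """Per-day, per-unit traces plus system-level mismatch aggregates.

    All 2-D arrays have shape ``(horizon_days, n_units)`` with columns in
    ``unit_ids`` order.  ``occupancy`` is the expected number of occupied
    beds ``U = rho * c``; ``over_beds`` / ``under_beds`` are its positive /
    negative parts relative to the staffed beds (fractional, unrounded).
    """

    unit_ids: tuple[str, ...]
    staffed_beds: np.ndarray
    arrivals: np.ndarray
    eff_arrivals: np.ndarray
    utilization: np.ndarray
    occupancy: np.ndarray
    over_beds: np.ndarray
    under_beds: np.ndarray

    @property
    def horizon_days(self) -> int:
        return self.arrivals.shape[0]

    @property
    def system_over(self) -> np.ndarray:
        """Total overutilized beds per day (``U_over_S``)."""
        return self.over_beds.sum(axis=1)

    @property
    def system_under(self) -> np.ndarray:
        """Total underutilized beds per day (``U_under_S``)."""
        return self.under_beds.sum(axis=1)

    @property
    def mean_over(self) -> float:
        return float(self.system_over.mean())

    @property
    def sd_over(self) -> float:
        return float(self.system_over.std(ddof=1)) if self.horizon_days > 1 else 0.0

    @property
    def mean_under(self) -> float:
        return float(self.system_under.mean())

    @property
    def sd_under(self) -> float:
        return float(self.system_under.std(ddof=1)) if self.horizon_days > 1 else 0.0

    @property
    def days_overutilized(self) -> int:
        """Number of days on which nurses must be reallocated."""
        return int(np.count_nonzero(self.system_over > 0))

    def occupancy_series(self, unit_id: str) -> np.ndarray:
        return self.occupancy[:, self.unit_ids.index(unit_id)]

    def to_frame(self) -> pd.DataFrame:
        """Long-format table: one row per day per unit."""
        d, n = self.arrivals.shape
        return pd.DataFrame(
            {
                "day": np.repeat(np.arange(1, d + 1), n),
                "unit": np.tile(self.unit_ids, d),
                "arrivals": self.arrivals.ravel(),
                "eff_arrivals": self.eff_arrivals.ravel(),
                "utilization": self.utilization.ravel(),
                "occupancy": self.occupancy.ravel(),
                "over_beds": self.over_beds.ravel(),
                "under_beds": self.under_beds.ravel(),
            }
        )

    def summary(self) -> dict[str, float | int]:
        return {
            "mean_overutilized_beds": self.mean_over,
            "sd_overutilized_beds": self.sd_over,
            "mean_underutilized_beds": self.mean_under,
            "sd_underutilized_beds": self.sd_under,
            "days_overutilized": self.days_overutilized,
            "horizon_days": self.horizon_days,
        }


def occupancy_profile(
    eff_arrivals: np.ndarray, network: CareNetwork
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Utilization, occupancy and over/under beds from daily effective arrivals.

    ``eff_arrivals`` has shape ``(days, n_units)``.  Returns
    ``(rho, occupancy, over_beds, under_beds)`` of the same shape, with
    ``rho = eff / (c * mu)`` and ``occupancy = rho * c``.
    """
    eff = np.atleast_2d(np.asarray(eff_arrivals, dtype=float))
    c = np.array([u.staffed_beds for u in network.units], dtype=float)
    mu = np.array([u.service_rate for u in network.units], dtype=float)
    rho = eff / (c * mu)
    occ = rho * c
    over = np.clip(occ - c, 0.0, None)
    under = np.clip(c - occ, 0.0, None)
    return rho, occ, over, under


def _sampled_routing(
    arrivals: np.ndarray, network: CareNetwork, rng: np.random.Generator
) -> np.ndarray:
    """Propagate integer external arrivals with multinomially sampled transfers."""
    g = network.graph()
    if not nx.is_directed_acyclic_graph(g):
        raise CareNetError("sampled routing requires a feed-forward (acyclic) network")
    order = [network.unit_ids.index(u) for u in nx.topological_sort(g)]
    p = network.routing.probabilities
    d, n = arrivals.shape
    eff = arrivals.astype(float).copy()
    inflow = arrivals.astype(np.int64).copy()
    for i in order:
        probs = np.append(p[i], 1.0 - p[i].sum())
        probs = np.clip(probs, 0.0, None)
        probs = probs / probs.sum()
        moved = rng.multinomial(inflow[:, i], probs)  # (d, n+1); last = discharge
        inflow += moved[:, :n]
        eff += moved[:, :n]
    return eff


def simulate_days(network: CareNetwork, config: SimulationConfig) -> SimulationResult:
    """Run the daily arrival Monte Carlo over the configured horizon.

    Each day, external arrivals are drawn ``Poisson(lambda0_i)`` per unit and
    turned into that day's effective arrivals via the traffic equations
    (default) or by sampled transfers.  Identical seeds give bit-identical
    results.
    """
    _check_solvable(network)
    rng = np.random.default_rng(config.seed)
    lam0 = np.array([u.external_arrival_rate for u in network.units])
    d, n = config.horizon_days, network.n_units
    arrivals = rng.poisson(lam0, size=(d, n))
    if config.routing_mode == "sampled":
        eff = _sampled_routing(arrivals, network, rng)
    else:
        r = network.routing.probabilities
        # x_day solves (I - R^T) x = k  =>  stacked: X = K @ (I - R)^{-1}
        eff = arrivals @ np.linalg.inv(np.eye(n) - r)
    rho, occ, over, under = occupancy_profile(eff, network)
    return SimulationResult(
        unit_ids=network.unit_ids,
        staffed_beds=np.array([u.staffed_beds for u in network.units]),
        arrivals=arrivals,
        eff_arrivals=eff,
        utilization=rho,
        occupancy=occ,
        over_beds=over,
        under_beds=under,
    )


def census_correlation(
    result: SimulationResult,
    unit_pairs: list[tuple[str, str]] | None = None,
) -> dict[tuple[str, str], float | None]:
    """Pearson correlation of daily occupancy between unit pairs.

    Returns ``None`` (an explicit undefined-correlation flag, not a NaN) for
    pairs involving a constant series.  The pair ``(i, i)`` of a
    non-constant series is 1 by definition.
    """
    if result.horizon_days < 3:
        raise CareNetError("census correlation needs a horizon of at least 3 days")
    if unit_pairs is None:
        ids = result.unit_ids
        unit_pairs = [(a, b) for k, a in enumerate(ids) for b in ids[k + 1 :]]
    out: dict[tuple[str, str], float | None] = {}
    for a, b in unit_pairs:
        x = result.occupancy_series(a)
        y = result.occupancy_series(b)
        if x.std() == 0 or y.std() == 0:
            out[(a, b)] = None
        elif a == b:
            out[(a, b)] = 1.0
        else:
            out[(a, b)] = float(np.corrcoef(x, y)[0, 1])
    return out


def correlation_matrix(result: SimulationResult) -> pd.DataFrame:
    """Full census correlation matrix (undefined entries as NaN)."""
    ids = result.unit_ids
    pairs = [(a, b) for a in ids for b in ids]
    corr = census_correlation(result, pairs)
    mat = np.array([[np.nan if corr[(a, b)] is None else corr[(a, b)] for b in ids] for a in ids])
    return pd.DataFrame(mat, index=list(ids), columns=list(ids))


@dataclass(frozen=True)
class GroupVariance:
    """Variance decomposition of one pooled group's daily census."""

    group: str
    members: tuple[str, ...]
    pooled_variance: float
    member_variances: dict[str, float]
    covariance_sum: float  # sum of pairwise covariances (each pair once)

    @property
    def sum_member_variances(self) -> float:
        return float(sum(self.member_variances.values()))

    @property
    def reduction(self) -> float:
        """Variance gained by pooling: ``sum Var_i - Var(pooled)``.

        Positive when the members are (on balance) negatively correlated —
        the portfolio effect; equals ``-2 * covariance_sum``.
        """
        return self.sum_member_variances - self.pooled_variance


def pooling_variance_gain(
    result: SimulationResult, plan: PoolingPlan
) -> dict[str, GroupVariance]:
    """Variance decomposition ``Var(sum X_i) = sum Var X_i + 2 sum Cov`` per group.

    The identity holds exactly on every simulated census; a negative
    covariance sum means the pooled workload is less volatile than the
    members' workloads combined.
    """
    if result.horizon_days < 3:
        raise CareNetError("variance analysis needs a horizon of at least 3 days")
    out: dict[str, GroupVariance] = {}
    for name, members in plan.groups.items():
        series = {m: result.occupancy_series(m) for m in members}
        pooled = np.sum(list(series.values()), axis=0)
        member_vars = {m: float(np.var(s, ddof=1)) for m, s in series.items()}
        cov = 0.0
        mlist = list(members)
        for i, a in enumerate(mlist):
            for b in mlist[i + 1 :]:
                cov += float(np.cov(series[a], series[b], ddof=1)[0, 1])
        out[name] = GroupVariance(
            group=name,
            members=tuple(members),
            pooled_variance=float(np.var(pooled, ddof=1)),
            member_variances=member_vars,
            covariance_sum=cov,
        )
    return out
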