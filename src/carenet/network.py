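"""Care units, routing, traffic equations, and pooling.

A hospital care system is modelled as an open queueing network.  Each unit
(ward) is an M/M/c station: patients arrive according to a Poisson process,
stay for an exponentially distributed length of stay with mean ``1/mu`` days,
and occupy one of ``c`` staffed beds.  Patients leaving a unit are routed to
another unit with fixed probabilities or are discharged.  The effective
arrival rate of a unit is its external admissions plus the transfers routed
into it from the rest of the network; it is the solution of the linear
traffic equations

    eff_lambda_i = lambda0_i + sum_j eff_lambda_j * r_ji

Pooling merges several units into one larger unit, combining beds, demand,
and nursing staff.  The merge conserves total external inflow and total
expected occupancy (``sum_i lambda_i / mu_i``).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import networkx as nx
import numpy as np

__all__ = [
    "Unit",
    "RoutingMatrix",
    "CareNetwork",
    "PoolingPlan",
    "CareNetError",
    "InvalidUnitError",
    "UnstableNetworkError",
    "effective_arrival_rates",
    "utilization",
    "is_stable",
    "apply_pooling",
    "identity_plan",
]

SHIFTS = ("day", "evening", "night")

#: spectral-radius slack below 1 above which the traffic equations are
#: treated as singular
_STABILITY_TOL = 1e-9


class CareNetError(ValueError):
    """Base class for validation and computation errors."""


class InvalidUnitError(CareNetError):
    """A unit violates its invariants (beds, rates, staffing)."""


class UnstableNetworkError(CareNetError):
    """The routing matrix keeps patients circulating forever.

    Raised when the spectral radius of the routing matrix is >= 1, i.e. some
    cycle of units recirculates its entire population with no discharge
    leakage, so the traffic equations have no finite solution.
    """


@dataclass(frozen=True)
class Unit:
    """One care unit (ward) of the network.

    Parameters
    ----------
    id:
        Short label, unique within a network (e.g. ``"N1"``).
    name:
        Free-text description (e.g. ``"Neonatal IC unit"``).
    staffed_beds:
        Number of staffed beds ``c`` (servers of the M/M/c station).
    external_arrival_rate:
        External admissions per day (births, referrals from other
        hospitals); transfers from other units are *not* included here.
    service_rate:
        Departures per occupied bed per day, the reciprocal of the mean
        length of stay in days.
    nurses_per_shift:
        Scheduled nurses per shift label (``day`` / ``evening`` /
        ``night``); a missing shift means zero nurses.
    """

    id: str
    name: str = ""
    staffed_beds: int = 1
    external_arrival_rate: float = 0.0
    service_rate: float = 1.0
    nurses_per_shift: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.id:
            raise InvalidUnitError("unit id must be a non-empty string")
        if not (isinstance(self.staffed_beds, (int, np.integer)) and self.staffed_beds >= 1):
            raise InvalidUnitError(
                f"unit {self.id!r}: staffed_beds must be a positive integer, "
                f"got {self.staffed_beds!r}"
            )
        if not self.service_rate > 0:
            raise InvalidUnitError(
                f"unit {self.id!r}: service_rate must be > 0, got {self.service_rate!r}"
            )
        if self.external_arrival_rate < 0:
            raise InvalidUnitError(
                f"unit {self.id!r}: external_arrival_rate must be >= 0, "
                f"got {self.external_arrival_rate!r}"
            )
        bad = set(self.nurses_per_shift) - set(SHIFTS)
        if bad:
            raise InvalidUnitError(
                f"unit {self.id!r}: unknown shift labels {sorted(bad)}; "
                f"expected a subset of {list(SHIFTS)}"
            )
        for shift, n in self.nurses_per_shift.items():
            if not (isinstance(n, (int, np.integer)) and n >= 0):
                raise InvalidUnitError(
                    f"unit {self.id!r}: nurses in shift {shift!r} must be a "
                    f"non-negative integer, got {n!r}"
                )

    def nurses(self, shift: str = "day") -> int:
        """Scheduled nurse count for ``shift`` (0 when the shift is absent)."""
        if shift not in SHIFTS:
            raise InvalidUnitError(f"unknown shift {shift!r}")
        return int(self.nurses_per_shift.get(shift, 0))

    @property
    def mean_length_of_stay(self) -> float:
        """Mean length of stay in days (``1 / service_rate``)."""
        return 1.0 / self.service_rate


@dataclass(frozen=True)
class RoutingMatrix:
    """Transfer probabilities between units.

    ``probabilities[i, j]`` is the probability that a patient leaving the
    ``i``-th unit is transferred to the ``j``-th unit.  Row sums may be less
    than one; the shortfall is the probability of leaving the system
    (discharge home).
    """

    unit_ids: tuple[str, ...]
    probabilities: np.ndarray

    def __post_init__(self) -> None:
        p = np.asarray(self.probabilities, dtype=float)
        object.__setattr__(self, "probabilities", p)
        object.__setattr__(self, "unit_ids", tuple(self.unit_ids))
        n = len(self.unit_ids)
        if p.shape != (n, n):
            raise CareNetError(
                f"routing matrix shape {p.shape} does not match {n} unit ids"
            )
        if np.any(p < -1e-12) or np.any(p > 1 + 1e-12):
            raise CareNetError("routing probabilities must lie in [0, 1]")
        if np.any(np.abs(np.diag(p)) > 1e-12):
            raise CareNetError("routing diagonal must be zero (no self-transfer)")
        rows = p.sum(axis=1)
        if np.any(rows > 1 + 1e-9):
            bad = [self.unit_ids[i] for i in np.nonzero(rows > 1 + 1e-9)[0]]
            raise CareNetError(f"routing row sums exceed 1 for units {bad}")

    def __eq__(self, other) -> bool:  # ndarray field: compare element-wise
        if not isinstance(other, RoutingMatrix):
            return NotImplemented
        return self.unit_ids == other.unit_ids and np.array_equal(
            self.probabilities, other.probabilities
        )

    @classmethod
    def from_entries(
        cls, unit_ids: list[str] | tuple[str, ...], entries: dict[tuple[str, str], float]
    ) -> "RoutingMatrix":
        """Build from a sparse ``{(from_id, to_id): probability}`` mapping."""
        ids = tuple(unit_ids)
        index = {u: k for k, u in enumerate(ids)}
        p = np.zeros((len(ids), len(ids)))
        for (src, dst), prob in entries.items():
            if src not in index or dst not in index:
                raise CareNetError(f"routing entry ({src!r}, {dst!r}) uses unknown unit id")
            p[index[src], index[dst]] = prob
        return cls(ids, p)

    def entry(self, src: str, dst: str) -> float:
        return float(self.probabilities[self.unit_ids.index(src), self.unit_ids.index(dst)])

    def discharge_probability(self, src: str) -> float:
        """Probability a patient leaving ``src`` exits the system."""
        i = self.unit_ids.index(src)
        return float(1.0 - self.probabilities[i].sum())


@dataclass(frozen=True)
class CareNetwork:
    """An ordered collection of units plus their routing matrix."""

    units: tuple[Unit, ...]
    routing: RoutingMatrix

    def __post_init__(self) -> None:
        object.__setattr__(self, "units", tuple(self.units))
        ids = [u.id for u in self.units]
        if len(set(ids)) != len(ids):
            raise CareNetError(f"duplicate unit ids in {ids}")
        if tuple(ids) != self.routing.unit_ids:
            raise CareNetError(
                "routing unit ids do not match network units "
                f"({self.routing.unit_ids} vs {tuple(ids)})"
            )

    @classmethod
    def build(
        cls,
        units: list[Unit],
        routing_entries: dict[tuple[str, str], float] | None = None,
    ) -> "CareNetwork":
        ids = [u.id for u in units]
        return cls(tuple(units), RoutingMatrix.from_entries(ids, routing_entries or {}))

    @property
    def unit_ids(self) -> tuple[str, ...]:
        return tuple(u.id for u in self.units)

    @property
    def n_units(self) -> int:
        return len(self.units)

    def unit(self, unit_id: str) -> Unit:
        for u in self.units:
            if u.id == unit_id:
                return u
        raise CareNetError(f"no unit with id {unit_id!r}")

    def graph(self) -> nx.DiGraph:
        """Directed graph of the positive routing entries."""
        g = nx.DiGraph()
        g.add_nodes_from(self.unit_ids)
        p = self.routing.probabilities
        for i, src in enumerate(self.unit_ids):
            for j, dst in enumerate(self.unit_ids):
                if p[i, j] > 0:
                    g.add_edge(src, dst, probability=float(p[i, j]))
        return g

    def is_feed_forward(self) -> bool:
        return nx.is_directed_acyclic_graph(self.graph())


@dataclass(frozen=True)
class PoolingPlan:
    """A partition of unit ids into named pooled groups.

    ``team_assignment`` optionally maps each group to the team manager
    responsible for it (e.g. ``"neonatology"`` / ``"obstetrics"``); it is
    required only by the hierarchy coordination structure.
    """

    groups: dict[str, tuple[str, ...]]
    team_assignment: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        groups = {name: tuple(members) for name, members in self.groups.items()}
        object.__setattr__(self, "groups", groups)
        for name, members in groups.items():
            if not members:
                raise CareNetError(f"pooling group {name!r} is empty")
        all_members = [m for members in groups.values() for m in members]
        if len(set(all_members)) != len(all_members):
            raise CareNetError("pooling groups overlap: some unit id appears twice")

    def validate_against(self, network: CareNetwork) -> None:
        members = {m for g in self.groups.values() for m in g}
        net_ids = set(network.unit_ids)
        if members != net_ids:
            missing = net_ids - members
            unknown = members - net_ids
            parts = []
            if missing:
                parts.append(f"units not covered: {sorted(missing)}")
            if unknown:
                parts.append(f"unknown unit ids: {sorted(unknown)}")
            raise CareNetError("pooling plan does not partition the network: " + "; ".join(parts))

    def group_of(self, unit_id: str) -> str:
        for name, members in self.groups.items():
            if unit_id in members:
                return name
        raise CareNetError(f"unit {unit_id!r} not in any group")

    @property
    def is_identity(self) -> bool:
        return all(len(m) == 1 and name == m[0] for name, m in self.groups.items())


def identity_plan(network: CareNetwork, team_assignment: dict[str, str] | None = None) -> PoolingPlan:
    """The no-op plan: every unit is its own group, named after itself."""
    return PoolingPlan(
        groups={u: (u,) for u in network.unit_ids},
        team_assignment=dict(team_assignment or {}),
    )


def _check_solvable(network: CareNetwork) -> None:
    """Raise :class:`UnstableNetworkError` naming an offending cycle."""
    p = network.routing.probabilities
    radius = max(abs(np.linalg.eigvals(p))) if p.size else 0.0
    if radius < 1 - _STABILITY_TOL:
        return
    g = network.graph()
    ids = list(network.unit_ids)
    cycle_desc = "unknown cycle"
    for scc in nx.strongly_connected_components(g):
        if len(scc) < 2:
            continue
        idx = [ids.index(u) for u in scc]
        sub = p[np.ix_(idx, idx)]
        if max(abs(np.linalg.eigvals(sub))) >= 1 - _STABILITY_TOL:
            cycle = nx.find_cycle(g.subgraph(scc))
            cycle_desc = " -> ".join([e[0] for e in cycle] + [cycle[0][0]])
            break
    raise UnstableNetworkError(
        f"unstable network: routing spectral radius {radius:.6f} >= 1 "
        f"(patients recirculate along {cycle_desc} without discharge)"
    )


def effective_arrival_rates(network: CareNetwork) -> dict[str, float]:
    """Solve the traffic equations for every unit.

    Returns the unique solution of
    ``eff_i = lambda0_i + sum_j eff_j * r_ji`` as a ``{unit_id: rate}``
    mapping (patients/day).  For feed-forward networks this coincides with
    propagating external arrivals once in topological order; in general it is
    the solution of the linear system ``(I - R^T) x = lambda0``.
    """
    _check_solvable(network)
    lam0 = np.array([u.external_arrival_rate for u in network.units])
    r = network.routing.probabilities
    x = np.linalg.solve(np.eye(network.n_units) - r.T, lam0)
    return {u: float(v) for u, v in zip(network.unit_ids, x)}


def utilization(eff_arrival: float, unit: Unit) -> float:
    """Average utilization ``rho = lambda / (c * mu)`` of one unit.

    Values above 1 indicate overload and are returned as-is: an overloaded
    unit is a meaningful state of the system, not an input error.
    """
    if eff_arrival < 0:
        raise CareNetError(f"effective arrival rate must be >= 0, got {eff_arrival!r}")
    return eff_arrival / (unit.staffed_beds * unit.service_rate)


def is_stable(eff_arrival: float, unit: Unit) -> bool:
    """``True`` when the unit's queue is stable (``lambda < c * mu``)."""
    return eff_arrival < unit.staffed_beds * unit.service_rate


def _pooled_service_rate(eff: list[float], mus: list[float]) -> float:
    """Arrival-weighted harmonic mean of the members' service rates.

    Chosen so that the pooled expected occupancy equals the sum of the
    members' expected occupancies: ``(sum eff) / mu_pool = sum eff_i/mu_i``.
    Falls back to the plain harmonic mean when the group carries no traffic.
    """
    total = sum(eff)
    if total > 0:
        return total / sum(lam / mu for lam, mu in zip(eff, mus))
    return len(mus) / sum(1.0 / mu for mu in mus)


def apply_pooling(
    network: CareNetwork,
    plan: PoolingPlan,
    routing_override: dict[tuple[str, str], float] | None = None,
) -> CareNetwork:
    """Merge units group-wise into a redesigned network.

    The pooled unit of each group has the summed staffed beds, summed
    external arrival rate, element-wise summed nursing staff, and the
    arrival-weighted harmonic-mean service rate of its members (conserving
    total expected occupancy).  Pooled routing is the arrival-weighted merge

        r(G -> H) = sum_{i in G} w_i * sum_{j in H} r_ij,
        w_i = eff_i / sum_{i in G} eff_i,

    with intra-group transfers dropped (a move inside a pooled unit is no
    longer a transfer).  ``routing_override`` replaces the computed
    group-to-group probabilities with re-measured values where provided.
    """
    plan.validate_against(network)
    eff = effective_arrival_rates(network)
    group_names = list(plan.groups)
    index = {u.id: u for u in network.units}

    pooled_units: list[Unit] = []
    for name in group_names:
        members = [index[m] for m in plan.groups[name]]
        eff_members = [eff[m.id] for m in members]
        nurses: dict[str, int] = {}
        for m in members:
            for shift in SHIFTS:
                if m.nurses(shift) or shift in m.nurses_per_shift:
                    nurses[shift] = nurses.get(shift, 0) + m.nurses(shift)
        pooled_units.append(
            Unit(
                id=name,
                name=" + ".join(m.name or m.id for m in members),
                staffed_beds=sum(m.staffed_beds for m in members),
                external_arrival_rate=sum(m.external_arrival_rate for m in members),
                service_rate=_pooled_service_rate(eff_members, [m.service_rate for m in members]),
                nurses_per_shift=nurses,
            )
        )

    # arrival-weighted merge of routing rows, intra-group mass dropped
    p = network.routing.probabilities
    ids = list(network.unit_ids)
    k = len(group_names)
    pooled_p = np.zeros((k, k))
    for gi, gname in enumerate(group_names):
        members = plan.groups[gname]
        eff_members = np.array([eff[m] for m in members])
        total = eff_members.sum()
        if total > 0:
            weights = eff_members / total
        else:
            weights = np.full(len(members), 1.0 / len(members))
        for hj, hname in enumerate(group_names):
            if hj == gi:
                continue
            mass = 0.0
            for w, m in zip(weights, members):
                mi = ids.index(m)
                mass += w * sum(p[mi, ids.index(t)] for t in plan.groups[hname])
            pooled_p[gi, hj] = mass

    if routing_override:
        gidx = {g: i for i, g in enumerate(group_names)}
        for (src, dst), prob in routing_override.items():
            if src not in gidx or dst not in gidx:
                raise CareNetError(f"routing override ({src!r}, {dst!r}) uses unknown group")
            pooled_p[gidx[src], gidx[dst]] = prob

    return CareNetwork(tuple(pooled_units), RoutingMatrix(tuple(group_names), pooled_p))


def pooled_plan_rename(plan: PoolingPlan) -> dict[str, str]:
    """Map each original unit id to the pooled unit id it ends up in."""
    return {m: name for name, members in plan.groups.items() for m in members}
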