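"""Coordination structures for nurse reallocation: hierarchy, network, hub.

When a unit's expected occupancy exceeds its staffed beds, nurses have to be
reallocated.  Who decides, and from which information sources, is the
coordination design:

* **hierarchy** — decision power sits with a single manager at the top of
  the pyramid; unit planners watch their own nurses, team managers watch
  their planners, the manager watches the team managers;
* **network** — decision power sits with the unit planners, who contact each
  other peer-to-peer;
* **hub** — decision power also sits with the planners, but they read a
  centralized information system instead of contacting each other.

Each design can run on *detailed* information (nurse-level records) or on
*aggregated* information (one workload summary per unit).  Every
decision-maker's distribution over its sources is uniform — the
maximum-entropy choice when no empirical communication frequencies are
available — so a maker with ``k`` sources contributes ``log2 k`` bits.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

from .network import CareNetwork, CareNetError, PoolingPlan, Unit, apply_pooling

__all__ = [
    "DecisionStructure",
    "build_hierarchy",
    "build_network",
    "build_hub",
    "build_structure",
    "to_dot",
    "STRATEGIES",
]

STRATEGIES = ("hierarchy", "network", "hub")

MAKER_ROLES = ("manager", "team_manager", "planner")
SOURCE_ROLES = ("team_manager", "planner", "nurse", "aggregate_signal", "central_system")


@dataclass(frozen=True)
class DecisionStructure:
    """Bipartite decision-maker -> information-source structure.

    ``source_probabilities[maker]`` is that maker's probability distribution
    over source labels (empty when the maker has nothing to consult; it then
    contributes zero bits).  A maker may never be its own source.
    """

    makers: tuple[tuple[str, str], ...]  # (label, role)
    sources: tuple[tuple[str, str], ...]  # (label, role)
    source_probabilities: dict[str, dict[str, float]]

    def __post_init__(self) -> None:
        object.__setattr__(self, "makers", tuple(self.makers))
        object.__setattr__(self, "sources", tuple(self.sources))
        maker_labels = [m for m, _ in self.makers]
        if len(set(maker_labels)) != len(maker_labels):
            raise CareNetError("duplicate decision-maker labels")
        source_labels = {s for s, _ in self.sources}
        for maker, dist in self.source_probabilities.items():
            if maker not in maker_labels:
                raise CareNetError(f"distribution given for unknown maker {maker!r}")
            if maker in dist:
                raise CareNetError(f"decision maker {maker!r} cannot be its own source")
            unknown = set(dist) - source_labels
            if unknown:
                raise CareNetError(f"maker {maker!r} cites unknown sources {sorted(unknown)}")
            if dist:
                total = sum(dist.values())
                if abs(total - 1.0) > 1e-9:
                    raise CareNetError(
                        f"maker {maker!r} source probabilities sum to {total}, expected 1"
                    )

    @property
    def maker_labels(self) -> tuple[str, ...]:
        return tuple(m for m, _ in self.makers)

    @property
    def source_labels(self) -> tuple[str, ...]:
        return tuple(s for s, _ in self.sources)


def _uniform(labels: list[str]) -> dict[str, float]:
    if not labels:
        return {}
    return {lab: 1.0 / len(labels) for lab in labels}


def _nurse_sources(unit: Unit, shift: str) -> list[tuple[str, str]]:
    n = unit.nurses(shift)
    return [(f"{unit.id}.nurse{k}", "nurse") for k in range(1, n + 1)]


def _teams_of(plan: PoolingPlan, pooled: CareNetwork) -> dict[str, list[str]]:
    """Group pooled unit ids by team manager, preserving insertion order."""
    teams: dict[str, list[str]] = {}
    for gid in pooled.unit_ids:
        team = plan.team_assignment.get(gid)
        if team is None:
            raise CareNetError(
                f"hierarchy structure needs a team assignment for group {gid!r}"
            )
        teams.setdefault(team, []).append(gid)
    return teams


def build_hierarchy(
    network: CareNetwork,
    plan: PoolingPlan,
    aggregated: bool = True,
    shift: str = "day",
) -> DecisionStructure:
    """Hierarchy: nurses -> unit planners -> team managers -> one manager.

    Non-aggregated: each unit's planner is uniform over that unit's nurses
    on ``shift``, each team manager is uniform over its planners, and the
    manager is uniform over the team managers.  Aggregated: nurse-level
    detail collapses to one workload signal per (pooled) unit — planners
    then contribute nothing — each team manager is uniform over its units'
    signals, and the manager is uniform over the team managers.
    """
    pooled = apply_pooling(network, plan)
    teams = _teams_of(plan, pooled)
    makers: list[tuple[str, str]] = [("manager", "manager")]
    sources: list[tuple[str, str]] = []
    probs: dict[str, dict[str, float]] = {}

    tm_labels = [f"tm.{team}" for team in teams]
    makers += [(tm, "team_manager") for tm in tm_labels]
    sources += [(tm, "team_manager") for tm in tm_labels]
    probs["manager"] = _uniform(tm_labels)

    if aggregated:
        for team, gids in teams.items():
            signals = [f"{gid}.workload" for gid in gids]
            sources += [(s, "aggregate_signal") for s in signals]
            probs[f"tm.{team}"] = _uniform(signals)
    else:
        for team, gids in teams.items():
            planner_labels = [f"planner.{gid}" for gid in gids]
            makers += [(pl, "planner") for pl in planner_labels]
            sources += [(pl, "planner") for pl in planner_labels]
            probs[f"tm.{team}"] = _uniform(planner_labels)
            for gid, pl in zip(gids, planner_labels):
                nurse_sources = _nurse_sources(pooled.unit(gid), shift)
                if not nurse_sources:
                    warnings.warn(
                        f"unit {gid!r} has no nurses on the {shift} shift; "
                        "its planner contributes 0 bits",
                        stacklevel=2,
                    )
                    nurse_sources = [(f"{gid}.empty", "aggregate_signal")]
                sources += nurse_sources
                probs[pl] = _uniform([s for s, _ in nurse_sources])
    return DecisionStructure(tuple(makers), tuple(dict.fromkeys(sources)), probs)


def build_network(
    network: CareNetwork,
    plan: PoolingPlan,
    aggregated: bool = True,
    shift: str = "day",
) -> DecisionStructure:
    """Network: one planner per (pooled) unit, consulting its peers.

    Aggregated: each planner is uniform over the other ``A - 1`` planners'
    workload signals, giving ``A * log2(A - 1)`` bits in total.
    Non-aggregated: each planner is uniform over the *other* units' nurses
    on ``shift``.  With a single unit there is nobody to consult and the
    structure is empty (zero bits).
    """
    pooled = apply_pooling(network, plan)
    gids = list(pooled.unit_ids)
    makers = [(f"planner.{gid}", "planner") for gid in gids]
    sources: list[tuple[str, str]] = []
    probs: dict[str, dict[str, float]] = {}
    if aggregated:
        signals = {gid: f"{gid}.workload" for gid in gids}
        sources += [(s, "aggregate_signal") for s in signals.values()]
        for gid in gids:
            probs[f"planner.{gid}"] = _uniform([signals[o] for o in gids if o != gid])
    else:
        nurse_sources = {gid: _nurse_sources(pooled.unit(gid), shift) for gid in gids}
        for gid in gids:
            sources += nurse_sources[gid]
        for gid in gids:
            foreign = [s for o in gids if o != gid for s, _ in nurse_sources[o]]
            probs[f"planner.{gid}"] = _uniform(foreign)
    return DecisionStructure(tuple(makers), tuple(dict.fromkeys(sources)), probs)


def build_hub(
    network: CareNetwork,
    plan: PoolingPlan,
    aggregated: bool = True,
    shift: str = "day",
) -> DecisionStructure:
    """Hub: planners read a centralized information system.

    Aggregated: every planner's sole source is the central system's
    aggregate workload record — certainty about where to look, hence zero
    bits.  Non-aggregated: each planner must still decide which of its own
    unit's nurse-level records in the central system are essential, so it is
    uniform over its own unit's nurses on ``shift``.
    """
    pooled = apply_pooling(network, plan)
    gids = list(pooled.unit_ids)
    makers = [(f"planner.{gid}", "planner") for gid in gids]
    sources: list[tuple[str, str]] = []
    probs: dict[str, dict[str, float]] = {}
    if aggregated:
        sources.append(("central.workload", "central_system"))
        for gid in gids:
            probs[f"planner.{gid}"] = {"central.workload": 1.0}
    else:
        for gid in gids:
            nurse_sources = _nurse_sources(pooled.unit(gid), shift)
            if not nurse_sources:
                nurse_sources = [(f"{gid}.empty", "central_system")]
            sources += nurse_sources
            probs[f"planner.{gid}"] = _uniform([s for s, _ in nurse_sources])
    return DecisionStructure(tuple(makers), tuple(dict.fromkeys(sources)), probs)


_BUILDERS = {"hierarchy": build_hierarchy, "network": build_network, "hub": build_hub}


def build_structure(
    strategy: str,
    network: CareNetwork,
    plan: PoolingPlan,
    aggregated: bool = True,
    shift: str = "day",
) -> DecisionStructure:
    """Dispatch to the builder for ``strategy`` in :data:`STRATEGIES`."""
    try:
        builder = _BUILDERS[strategy]
    except KeyError:
        raise CareNetError(
            f"unknown strategy {strategy!r}; expected one of {list(STRATEGIES)}"
        ) from None
    return builder(network, plan, aggregated=aggregated, shift=shift)


def to_dot(structure: DecisionStructure, name: str = "coordination") -> str:
    """Render the maker -> source bipartite structure as a DOT digraph."""
    lines = [f'digraph "{name}" {{', "  rankdir=BT;"]
    for label, role in structure.makers:
        lines.append(f'  "{label}" [shape=box, label="{label}\\n({role})"];')
    maker_set = set(structure.maker_labels)
    for label, role in structure.sources:
        if label not in maker_set:
            lines.append(f'  "{label}" [shape=ellipse, label="{label}\\n({role})"];')
    for maker, dist in structure.source_probabilities.items():
        for source, p in dist.items():
            lines.append(f'  "{source}" -> "{maker}" [label="{p:.3g}"];')
    lines.append("}")
    return "\n".join(lines)
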