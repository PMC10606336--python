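"""Shannon-entropy measures of a care system's uncertainty.

Three kinds of uncertainty are quantified, all in bits (log base 2):

* **arrival entropy** — entropy of the relative demand across units,
  ``d_i = eff_lambda_i / sum_j eff_lambda_j``: how unpredictable it is
  *where* the next patient's demand lands;
* **positional entropy** — summed entropy of each patient class's
  distribution over positions in the system: how uncertain the expected
  workload is, given where patients may be;
* **decision-structure entropy** — summed entropy of each decision-maker's
  distribution over information sources: how much information a
  coordination design must process to act.

The total system uncertainty is the plain sum of the three components.
Maximum-entropy variants replace empirical distributions by uniform ones,
following the maximum-entropy principle: when probabilities are unknown, use
the distribution that assumes nothing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import TYPE_CHECKING

import networkx as nx
import numpy as np

from .network import CareNetwork, CareNetError, effective_arrival_rates

if TYPE_CHECKING:  # pragma: no cover
    from .org import DecisionStructure

__all__ = [
    "InvalidDistributionError",
    "shannon_entropy",
    "ArrivalEntropyReport",
    "arrival_entropy",
    "PositionMatrix",
    "PositionalEntropyReport",
    "positional_entropy",
    "derive_position_matrix",
    "DecisionEntropyReport",
    "decision_entropy",
    "total_entropy",
    "EntropyReport",
]

HOME = "home"  # pseudo-position for patients discharged from the system


class InvalidDistributionError(CareNetError):
    """A probability vector has negative mass or does not sum to one."""


def _validate_distribution(p: np.ndarray, what: str = "distribution") -> np.ndarray:
    p = np.asarray(p, dtype=float)
    if p.ndim != 1:
        raise InvalidDistributionError(f"{what} must be one-dimensional")
    if np.any(p < -1e-12):
        raise InvalidDistributionError(f"{what} has negative entries")
    total = p.sum()
    if abs(total - 1.0) > 1e-6:
        raise InvalidDistributionError(f"{what} sums to {total:.9f}, expected 1")
    return np.clip(p, 0.0, None)


def shannon_entropy(p) -> float:
    """Shannon entropy ``-sum p_i log2 p_i`` in bits.

    Zero-probability outcomes contribute nothing (``0 * log 0 := 0`` by
    continuity).  The result lies in ``[0, log2 n]`` for an ``n``-outcome
    distribution.
    """
    q = _validate_distribution(np.asarray(p, dtype=float))
    nz = q[q > 0]
    return float(-(nz * np.log2(nz)).sum())


@dataclass(frozen=True)
class ArrivalEntropyReport:
    """Relative demand per unit and its entropy, with the uniform maximum."""

    relative_demand: dict[str, float]
    entropy_bits: float
    max_entropy_bits: float


def arrival_entropy(network: CareNetwork) -> ArrivalEntropyReport:
    """Entropy of the relative effective demand across units.

    The relative demand of unit ``i`` is its effective arrival rate divided
    by the system total.  The maximum is attained by the uniform demand
    ``1/N``, i.e. ``log2 N`` bits.
    """
    eff = effective_arrival_rates(network)
    total = sum(eff.values())
    if total <= 0:
        raise InvalidDistributionError("arrival entropy undefined: no arrivals anywhere")
    demand = {u: lam / total for u, lam in eff.items()}
    h = shannon_entropy(np.array(list(demand.values())))
    return ArrivalEntropyReport(
        relative_demand=demand,
        entropy_bits=h,
        max_entropy_bits=math.log2(network.n_units),
    )


@dataclass(frozen=True)
class PositionMatrix:
    """Patient-class x position probabilities.

    Row ``k`` is the probability distribution of class ``k``'s placement
    over the positions (unit ids, optionally including the ``"home"``
    pseudo-position for discharged patients); every row sums to one.
    """

    classes: tuple[str, ...]
    positions: tuple[str, ...]
    probabilities: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "classes", tuple(self.classes))
        object.__setattr__(self, "positions", tuple(self.positions))
        p = np.asarray(self.probabilities, dtype=float)
        if p.shape != (len(self.classes), len(self.positions)):
            raise CareNetError(
                f"position matrix shape {p.shape} does not match "
                f"{len(self.classes)} classes x {len(self.positions)} positions"
            )
        for k, row in enumerate(p):
            _validate_distribution(row, what=f"position row for class {self.classes[k]!r}")
        object.__setattr__(self, "probabilities", p)

    def __eq__(self, other) -> bool:  # ndarray field: compare element-wise
        if not isinstance(other, PositionMatrix):
            return NotImplemented
        return (
            self.classes == other.classes
            and self.positions == other.positions
            and np.array_equal(self.probabilities, other.probabilities)
        )

    def row(self, cls: str) -> np.ndarray:
        return self.probabilities[self.classes.index(cls)]


@dataclass(frozen=True)
class PositionalEntropyReport:
    """Per-class and total positional entropy, with support-uniform maxima."""

    per_class_bits: dict[str, float]
    total_bits: float
    per_class_max_bits: dict[str, float]
    max_total_bits: float


def positional_entropy(positions: PositionMatrix) -> PositionalEntropyReport:
    """Positional entropy ``H_ps = sum_k H_k`` over patient classes.

    ``H_k`` is the entropy of class ``k``'s placement distribution.  The
    maximum variant replaces each row by the uniform distribution over that
    class's declared support (its positive-probability positions), so a
    class that can only ever occupy 3 positions maxes out at ``log2 3``.
    """
    per_class = {
        cls: shannon_entropy(row) for cls, row in zip(positions.classes, positions.probabilities)
    }
    per_class_max = {
        cls: math.log2(max(int(np.count_nonzero(row > 0)), 1))
        for cls, row in zip(positions.classes, positions.probabilities)
    }
    return PositionalEntropyReport(
        per_class_bits=per_class,
        total_bits=float(sum(per_class.values())),
        per_class_max_bits=per_class_max,
        max_total_bits=float(sum(per_class_max.values())),
    )


def derive_position_matrix(network: CareNetwork, include_discharge: bool = True) -> PositionMatrix:
    """Build a default position matrix from a feed-forward network's routing.

    One patient class per external-entry stream (each unit with a positive
    external arrival rate).  A class's placement distribution is the
    one-step propagation of its entry unit's routing row: mass ``r_ej`` on
    each downstream unit ``j`` and the discharge shortfall on the ``home``
    pseudo-position (dropped when ``include_discharge`` is false, in which
    case the row is renormalized).  An entry unit that routes nowhere keeps
    its class in place (a one-hot row).  For cyclic networks the placement
    distribution is not well defined by one-step propagation; supply a
    matrix explicitly instead.
    """
    if not network.is_feed_forward():
        raise CareNetError(
            "cannot derive a position matrix for a cyclic network; "
            "provide a PositionMatrix explicitly"
        )
    entries = [u for u in network.units if u.external_arrival_rate > 0]
    if not entries:
        raise CareNetError("no external-entry streams: every external arrival rate is zero")
    ids = list(network.unit_ids)
    p = network.routing.probabilities
    rows = []
    needs_home = False
    for u in entries:
        i = ids.index(u.id)
        row = p[i].astype(float).copy()
        leak = 1.0 - row.sum()
        if row.sum() <= 0:
            row[i] = 1.0  # absorbing entry: the class stays where it arrived
            leak = 0.0
        rows.append((row, leak))
        if leak > 1e-12:
            needs_home = True
    positions = tuple(ids) + ((HOME,) if (include_discharge and needs_home) else ())
    mat = np.zeros((len(entries), len(positions)))
    for k, (row, leak) in enumerate(rows):
        mat[k, : len(ids)] = row
        if include_discharge and needs_home:
            mat[k, -1] = leak
        elif leak > 1e-12:
            mat[k, : len(ids)] = row / row.sum()
    return PositionMatrix(
        classes=tuple(u.id for u in entries), positions=positions, probabilities=mat
    )


@dataclass(frozen=True)
class DecisionEntropyReport:
    """Per-decision-maker and total decision-structure entropy."""

    per_maker_bits: dict[str, float]
    total_bits: float


def decision_entropy(structure: "DecisionStructure") -> DecisionEntropyReport:
    """Decision-structure entropy ``H_ds = sum_a H_a`` in bits.

    ``H_a`` is the entropy of decision-maker ``a``'s distribution over its
    information sources; a maker with no sources (nothing to weigh up)
    contributes zero.  With uniform distributions, ``H_a`` is simply
    ``log2`` of the maker's source count.
    """
    per_maker: dict[str, float] = {}
    for maker in structure.maker_labels:
        dist = structure.source_probabilities.get(maker, {})
        if not dist:
            per_maker[maker] = 0.0
        else:
            per_maker[maker] = shannon_entropy(
                np.array(list(dist.values()), dtype=float)
            )
    return DecisionEntropyReport(
        per_maker_bits=per_maker, total_bits=float(sum(per_maker.values()))
    )


def total_entropy(arrival_bits: float, positional_bits: float, decision_bits: float) -> float:
    """Total system uncertainty: the exact sum of the three components."""
    return arrival_bits + positional_bits + decision_bits


@dataclass(frozen=True)
class EntropyReport:
    """All entropy measures of one design (model x coordination choice)."""

    arrival: ArrivalEntropyReport
    positional: PositionalEntropyReport | None
    decision_bits: dict[tuple[str, bool], float]  # (strategy, aggregated) -> H_ds

    def total_bits(self, strategy: str, aggregated: bool, use_max: bool = True) -> float:
        """Total per a given coordination choice.

        ``use_max=True`` combines the *maximum* arrival and positional
        components with the decision entropy — the convention used when
        ranking designs without assuming empirical demand distributions.
        """
        a = self.arrival.max_entropy_bits if use_max else self.arrival.entropy_bits
        if self.positional is None:
            p = 0.0
        else:
            p = self.positional.max_total_bits if use_max else self.positional.total_bits
        return total_entropy(a, p, self.decision_bits[(strategy, aggregated)])
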