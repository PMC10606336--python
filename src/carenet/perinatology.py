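"""Built-in perinatology case: a five-unit newborn-flow care network.

The network links the obstetric and neonatal local systems of a large
academic perinatology centre, restricted to the flow of newborns:

========  ==============================  ====  =========
id        unit                            beds  team
========  ==============================  ====  =========
``O3``    delivery room                      6  obstetrics
``N1``    neonatal intensive care (NICU)    14  neonatology
``N2``    neonatal post-intensive care       4  neonatology
``N3``    neonatal high/medium care         11  neonatology
``O1``    nursery ward (newborn beds)        7  obstetrics
========  ==============================  ====  =========

Births in the delivery room average four newborns per day; 68.5% of
newborns are healthy and go to the nursery ward, 15.8% need intensive care
and 15.7% need high/medium care.  The NICU and the high/medium-care unit
also admit newborns from other hospitals (0.6/day and 0.4/day).

Two fixture variants are provided:

* ``"printed"`` (default) — each unit's *effective* arrival rate, as
  published rounded to one decimal, is stored directly as its external rate
  with an empty routing matrix.  This is the variant behind the entropy and
  utilization figures and behind the occupancy simulation.
* ``"flows"`` — the reconstructed flow network: birth-routing fractions out
  of the delivery room, external referral rates into N1 and N3, and a
  NICU -> post-IC transfer probability chosen so the post-IC inflow matches
  its published 0.2/day.  Solving the traffic equations on this variant
  gives N3 an inflow of about 1.03/day where 0.9/day was published — the
  published figure evidently used unrounded historical fractions — so the
  two variants are kept side by side rather than reconciled.

Four pooling designs are studied: the current five-unit layout, and three
two-unit mergers of downstream units (high/medium care with the nursery,
post-IC with high/medium care, post-IC with the nursery).  Pooled units are
managed by the neonatology team manager.
"""

from __future__ import annotations

from .network import CareNetwork, PoolingPlan, Unit
from .simulate import SimulationConfig

__all__ = [
    "UNIT_ORDER",
    "PRINTED_EFFECTIVE_RATES",
    "SERVICE_RATES",
    "STAFFED_BEDS",
    "NURSES_PER_SHIFT",
    "BIRTH_ROUTING",
    "MODEL_NAMES",
    "perinatology_network",
    "perinatology_plans",
    "perinatology_scenario",
]

UNIT_ORDER = ("O3", "N1", "N2", "N3", "O1")

UNIT_NAMES = {
    "O3": "Delivery room",
    "N1": "Neonatal IC unit",
    "N2": "Neonatal post-IC unit",
    "N3": "Neonatal HC/MC unit",
    "O1": "Nursery ward",
}

STAFFED_BEDS = {"O3": 6, "N1": 14, "N2": 4, "N3": 11, "O1": 7}

#: published per-unit effective arrival rates, patients/day (1 decimal)
PRINTED_EFFECTIVE_RATES = {"O3": 4.0, "N1": 1.2, "N2": 0.2, "N3": 0.9, "O1": 2.7}

#: departures per occupied bed per day (1 / mean length of stay)
SERVICE_RATES = {"O3": 1.00, "N1": 0.10, "N2": 0.06, "N3": 0.19, "O1": 0.91}

#: scheduled nurses caring for newborns, per shift
NURSES_PER_SHIFT = {
    "O3": {"day": 3, "evening": 3, "night": 3},
    "N1": {"day": 12, "evening": 7, "night": 8},
    "N2": {"day": 2, "evening": 2, "night": 2},
    "N3": {"day": 4, "evening": 2, "night": 2},
    "O1": {"day": 1, "evening": 1, "night": 1},
}

#: where newborns go straight from the delivery room
BIRTH_ROUTING = {"O1": 0.685, "N1": 0.158, "N3": 0.157}

BIRTH_RATE = 4.0  # births/day in the delivery room
EXTERNAL_REFERRALS = {"N1": 0.6, "N3": 0.4}  # admissions/day from other hospitals

#: NICU -> post-IC transfer probability, chosen so the post-IC effective
#: inflow matches its published 0.2/day:
#: eff(N1) = 4.0 * 0.158 + 0.6 = 1.232, and 0.2 / 1.232 = 0.1623...
NICU_TO_POSTIC = 0.2 / (BIRTH_RATE * BIRTH_ROUTING["N1"] + EXTERNAL_REFERRALS["N1"])

MODEL_NAMES = ("Model 1", "Model 2", "Model 3", "Model 4")


def _units(external_rates: dict[str, float]) -> list[Unit]:
    return [
        Unit(
            id=uid,
            name=UNIT_NAMES[uid],
            staffed_beds=STAFFED_BEDS[uid],
            external_arrival_rate=external_rates.get(uid, 0.0),
            service_rate=SERVICE_RATES[uid],
            nurses_per_shift=dict(NURSES_PER_SHIFT[uid]),
        )
        for uid in UNIT_ORDER
    ]


def perinatology_network(variant: str = "printed") -> CareNetwork:
    """The five-unit newborn-flow network, in one of two variants.

    ``"printed"`` stores the published effective rates as external rates
    with no routing; ``"flows"`` stores the reconstructed external streams
    and transfer probabilities (see the module docstring).
    """
    if variant == "printed":
        return CareNetwork.build(_units(PRINTED_EFFECTIVE_RATES), {})
    if variant == "flows":
        routing = {("O3", dst): p for dst, p in BIRTH_ROUTING.items()}
        routing[("N1", "N2")] = NICU_TO_POSTIC
        external = {"O3": BIRTH_RATE, **EXTERNAL_REFERRALS}
        return CareNetwork.build(_units(external), routing)
    raise ValueError(f"unknown fixture variant {variant!r}; expected 'printed' or 'flows'")


_TEAMS = {"O3": "obstetrics", "O1": "obstetrics", "N1": "neonatology", "N2": "neonatology", "N3": "neonatology"}


def _plan(merge: tuple[str, str] | None) -> PoolingPlan:
    groups: dict[str, tuple[str, ...]] = {}
    teams: dict[str, str] = {}
    merged = set(merge) if merge else set()
    for uid in UNIT_ORDER:
        if uid in merged:
            continue
        groups[uid] = (uid,)
        teams[uid] = _TEAMS[uid]
    if merge:
        name = "+".join(merge)
        groups[name] = merge
        # pooled downstream units are run by the neonatology team manager
        teams[name] = "neonatology"
    return PoolingPlan(groups=groups, team_assignment=teams)


def perinatology_plans() -> dict[str, PoolingPlan]:
    """The four studied pooling designs, keyed ``Model 1`` .. ``Model 4``."""
    return {
        "Model 1": _plan(None),  # current situation, five separate units
        "Model 2": _plan(("N3", "O1")),  # high/medium care with the nursery
        "Model 3": _plan(("N2", "N3")),  # post-IC with high/medium care
        "Model 4": _plan(("N2", "O1")),  # post-IC with the nursery
    }


def perinatology_scenario(variant: str = "printed", horizon_days: int = 365, seed: int = 0):
    """The full built-in scenario: network, the four plans, all six designs."""
    from .scenario import ScenarioConfig  # local import to avoid a cycle

    return ScenarioConfig(
        network=perinatology_network(variant),
        pooling_models=perinatology_plans(),
        simulation=SimulationConfig(horizon_days=horizon_days, seed=seed),
        strategies=tuple(
            (s, a) for s in ("hierarchy", "network", "hub") for a in (True, False)
        ),
    )
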