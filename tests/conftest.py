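import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import carenet as cn

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def printed_net() -> cn.CareNetwork:
    """Five-unit fixture with the published effective rates as external rates."""
    return cn.perinatology_network("printed")


@pytest.fixture(scope="session")
def flows_net() -> cn.CareNetwork:
    """Five-unit fixture with reconstructed birth-routing flows."""
    return cn.perinatology_network("flows")


@pytest.fixture(scope="session")
def plans() -> dict[str, cn.PoolingPlan]:
    return cn.perinatology_plans()


def random_network(rng: np.random.Generator, n_units: int | None = None) -> cn.CareNetwork:
    """A random valid feed-forward network for property tests."""
    n = int(n_units or rng.integers(2, 7))
    units = [
        cn.Unit(
            id=f"U{i}",
            staffed_beds=int(rng.integers(1, 20)),
            external_arrival_rate=float(rng.uniform(0, 5)),
            service_rate=float(rng.uniform(0.05, 2.0)),
            nurses_per_shift={"day": int(rng.integers(1, 9))},
        )
        for i in range(n)
    ]
    entries = {}
    for i in range(n):
        # route only forward (guarantees an acyclic, solvable network)
        targets = list(range(i + 1, n))
        if not targets:
            continue
        mass = rng.uniform(0, 0.9)
        weights = rng.dirichlet(np.ones(len(targets)))
        for t, w in zip(targets, weights):
            p = float(mass * w)
            if p > 1e-9:
                entries[(f"U{i}", f"U{t}")] = p
    return cn.CareNetwork.build(units, entries)


def random_plan(rng: np.random.Generator, network: cn.CareNetwork) -> cn.PoolingPlan:
    """A random partition of the network's units into 1..n groups."""
    ids = list(network.unit_ids)
    n_groups = int(rng.integers(1, len(ids) + 1))
    assignment = rng.integers(0, n_groups, size=len(ids))
    groups: dict[str, list[str]] = {}
    for uid, g in zip(ids, assignment):
        groups.setdefault(f"G{g}", []).append(uid)
    teams = {g: ("neonatology" if k % 2 == 0 else "obstetrics") for k, g in enumerate(groups)}
    return cn.PoolingPlan(
        groups={g: tuple(m) for g, m in groups.items()}, team_assignment=teams
    )
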