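"""Traffic equations, utilization, and pooling of the queueing network."""

import numpy as np
import pytest

import carenet as cn
from conftest import random_network, random_plan


def brute_force_effective_rates(network: cn.CareNetwork) -> dict[str, float]:
    """Independent oracle: enumerate every routing path up to discharge.

    Each unit's effective rate is the sum, over all simple forward paths
    from every external entry stream to the unit, of the external rate times
    the product of routing probabilities along the path.  Valid for acyclic
    networks only.
    """
    ids = list(network.unit_ids)
    p = network.routing.probabilities
    eff = {u: 0.0 for u in ids}

    def walk(i: int, mass: float) -> None:
        eff[ids[i]] += mass
        for j in range(len(ids)):
            if p[i, j] > 0:
                walk(j, mass * p[i, j])

    for i, u in enumerate(network.units):
        if u.external_arrival_rate > 0:
            walk(i, u.external_arrival_rate)
    return eff


class TestEffectiveArrivalRates:
    def test_fixture_nicu_inflow(self, flows_net):
        """Births routed to intensive care plus external referrals: 1.232/day."""
        eff = cn.effective_arrival_rates(flows_net)
        assert eff["N1"] == pytest.approx(4.0 * 0.158 + 0.6)
        assert round(eff["N1"], 1) == 1.2
        assert eff["O1"] == pytest.approx(4.0 * 0.685)
        assert eff["N2"] == pytest.approx(0.2)

    def test_no_routing_returns_external_rates(self, printed_net):
        eff = cn.effective_arrival_rates(printed_net)
        for u in printed_net.units:
            assert eff[u.id] == pytest.approx(u.external_arrival_rate)

    def test_two_unit_chain(self):
        net = cn.CareNetwork.build(
            [
                cn.Unit(id="A", external_arrival_rate=2.0),
                cn.Unit(id="B", external_arrival_rate=0.0),
            ],
            {("A", "B"): 0.5},
        )
        eff = cn.effective_arrival_rates(net)
        assert eff["A"] == pytest.approx(2.0)
        assert eff["B"] == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_path_sum_oracle_on_acyclic_networks(self, seed):
        rng = np.random.default_rng(seed)
        net = random_network(rng)
        eff = cn.effective_arrival_rates(net)
        oracle = brute_force_effective_rates(net)
        for u in net.unit_ids:
            assert eff[u] == pytest.approx(oracle[u], abs=1e-10)

    def test_cyclic_network_solves_linear_system(self):
        # A <-> B with leakage: eff_A = 1 + 0.5*eff_B, eff_B = 0.5*eff_A
        net = cn.CareNetwork.build(
            [
                cn.Unit(id="A", external_arrival_rate=1.0),
                cn.Unit(id="B", external_arrival_rate=0.0),
            ],
            {("A", "B"): 0.5, ("B", "A"): 0.5},
        )
        eff = cn.effective_arrival_rates(net)
        assert eff["A"] == pytest.approx(4.0 / 3.0)
        assert eff["B"] == pytest.approx(2.0 / 3.0)

    def test_unstable_cycle_raises_and_names_cycle(self):
        net = cn.CareNetwork.build(
            [
                cn.Unit(id="A", external_arrival_rate=1.0),
                cn.Unit(id="B", external_arrival_rate=0.0),
            ],
            {("A", "B"): 1.0, ("B", "A"): 1.0},
        )
        with pytest.raises(cn.UnstableNetworkError, match="unstable network") as err:
            cn.effective_arrival_rates(net)
        assert "A" in str(err.value) and "B" in str(err.value)


class TestUtilization:
    @pytest.mark.parametrize(
        ("lam", "c", "mu", "expected_pct"),
        [(4.0, 6, 1.00, 67), (0.9, 11, 0.19, 43)],
    )
    def test_published_utilizations(self, lam, c, mu, expected_pct):
        unit = cn.Unit(id="x", staffed_beds=c, service_rate=mu)
        assert round(100 * cn.utilization(lam, unit)) == expected_pct

    def test_zero_arrivals_zero_utilization(self):
        assert cn.utilization(0.0, cn.Unit(id="x", staffed_beds=3, service_rate=0.5)) == 0.0

    def test_overload_is_returned_not_raised(self):
        unit = cn.Unit(id="x", staffed_beds=2, service_rate=0.5)
        assert cn.utilization(5.0, unit) == pytest.approx(5.0)
        assert not cn.is_stable(5.0, unit)
        assert cn.is_stable(0.9, unit)

    def test_invalid_units_rejected_at_construction(self):
        with pytest.raises(cn.InvalidUnitError):
            cn.Unit(id="x", staffed_beds=0)
        with pytest.raises(cn.InvalidUnitError):
            cn.Unit(id="x", service_rate=0.0)
        with pytest.raises(cn.InvalidUnitError):
            cn.Unit(id="x", external_arrival_rate=-1.0)
        with pytest.raises(cn.InvalidUnitError):
            cn.Unit(id="x", nurses_per_shift={"noon": 2})

    def test_negative_arrival_rejected(self):
        with pytest.raises(cn.CareNetError):
            cn.utilization(-1.0, cn.Unit(id="x"))

    @pytest.mark.parametrize("seed", range(5))
    def test_linearity_in_rate_and_capacity(self, seed):
        rng = np.random.default_rng(seed)
        lam = float(rng.uniform(0.1, 10))
        c = int(rng.integers(1, 30))
        mu = float(rng.uniform(0.05, 3))
        u1 = cn.Unit(id="x", staffed_beds=c, service_rate=mu)
        u2 = cn.Unit(id="x", staffed_beds=2 * c, service_rate=mu)
        u3 = cn.Unit(id="x", staffed_beds=c, service_rate=2 * mu)
        rho = cn.utilization(lam, u1)
        assert cn.utilization(2 * lam, u1) == pytest.approx(2 * rho)
        assert cn.utilization(lam, u2) == pytest.approx(rho / 2)
        assert cn.utilization(lam, u3) == pytest.approx(rho / 2)


class TestApplyPooling:
    def test_pooled_beds_sum(self, printed_net, plans):
        pooled = cn.apply_pooling(printed_net, plans["Model 3"])
        assert pooled.n_units == 4
        assert pooled.unit("N2+N3").staffed_beds == 4 + 11

    def test_identity_plan_is_noop(self, flows_net):
        pooled = cn.apply_pooling(flows_net, cn.identity_plan(flows_net))
        assert pooled.unit_ids == flows_net.unit_ids
        for a, b in zip(pooled.units, flows_net.units):
            assert a.staffed_beds == b.staffed_beds
            assert a.external_arrival_rate == pytest.approx(b.external_arrival_rate)
            assert a.service_rate == pytest.approx(b.service_rate)
            assert a.nurses_per_shift == b.nurses_per_shift
        assert np.allclose(
            pooled.routing.probabilities, flows_net.routing.probabilities
        )

    def test_expected_occupancy_conserved(self, printed_net, plans):
        # members' lambda/mu: 0.2/0.06 = 3.33 and 0.9/0.19 = 4.74, sum 8.07
        pooled = cn.apply_pooling(printed_net, plans["Model 3"])
        unit = pooled.unit("N2+N3")
        occ = unit.external_arrival_rate / unit.service_rate
        assert occ == pytest.approx(0.2 / 0.06 + 0.9 / 0.19)
        assert occ == pytest.approx(8.07, abs=0.005)

    @pytest.mark.parametrize("seed", range(6))
    def test_external_inflow_conserved_for_every_plan(self, seed):
        rng = np.random.default_rng(100 + seed)
        net = random_network(rng)
        plan = random_plan(rng, net)
        pooled = cn.apply_pooling(net, plan)
        before = sum(u.external_arrival_rate for u in net.units)
        after = sum(u.external_arrival_rate for u in pooled.units)
        assert after == pytest.approx(before)

    def test_pooled_effective_rate_is_member_sum_for_leaf_groups(self, flows_net, plans):
        eff = cn.effective_arrival_rates(flows_net)
        for model in ("Model 2", "Model 3", "Model 4"):
            plan = plans[model]
            pooled = cn.apply_pooling(flows_net, plan)
            pooled_eff = cn.effective_arrival_rates(pooled)
            for gname, members in plan.groups.items():
                if len(members) > 1:
                    assert pooled_eff[gname] == pytest.approx(
                        sum(eff[m] for m in members)
                    )

    def test_nurses_summed_elementwise(self, printed_net, plans):
        pooled = cn.apply_pooling(printed_net, plans["Model 2"])
        assert pooled.unit("N3+O1").nurses_per_shift == {
            "day": 5,
            "evening": 3,
            "night": 3,
        }

    def test_intra_group_transfer_dropped(self):
        net = cn.CareNetwork.build(
            [
                cn.Unit(id="A", external_arrival_rate=1.0),
                cn.Unit(id="B"),
                cn.Unit(id="C"),
            ],
            {("A", "B"): 0.4, ("A", "C"): 0.3},
        )
        plan = cn.PoolingPlan(groups={"AB": ("A", "B"), "C": ("C",)})
        pooled = cn.apply_pooling(net, plan)
        # A->B becomes internal; only A->C survives, weighted by A's share
        assert pooled.routing.entry("AB", "C") == pytest.approx(
            (1.0 / 1.4) * 0.3
        )

    def test_routing_override(self, flows_net, plans):
        pooled = cn.apply_pooling(
            flows_net, plans["Model 3"], routing_override={("N1", "N2+N3"): 0.25}
        )
        assert pooled.routing.entry("N1", "N2+N3") == pytest.approx(0.25)

    def test_plan_validation_errors(self, printed_net):
        with pytest.raises(cn.CareNetError, match="empty"):
            cn.PoolingPlan(groups={"G": ()})
        bad = cn.PoolingPlan(groups={"G": ("O3", "ZZ")})
        with pytest.raises(cn.CareNetError, match="partition"):
            cn.apply_pooling(printed_net, bad)
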