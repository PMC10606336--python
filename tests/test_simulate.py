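"""Daily occupancy Monte Carlo, census correlation, and the portfolio effect."""

import numpy as np
import pytest

import carenet as cn


def make_result(occupancy: np.ndarray, ids=None) -> cn.SimulationResult:
    """Wrap a hand-made occupancy matrix (days x units) in a result object."""
    occ = np.asarray(occupancy, dtype=float)
    d, n = occ.shape
    ids = tuple(ids or (f"U{i}" for i in range(n)))
    c = np.full(n, 10.0)
    return cn.SimulationResult(
        unit_ids=ids,
        staffed_beds=c,
        arrivals=np.zeros((d, n), dtype=int),
        eff_arrivals=np.zeros((d, n)),
        utilization=occ / c,
        occupancy=occ,
        over_beds=np.clip(occ - c, 0, None),
        under_beds=np.clip(c - occ, 0, None),
    )


class TestSimulateDays:
    def test_empty_system_is_always_underutilized(self):
        net = cn.CareNetwork.build(
            [cn.Unit(id="A", staffed_beds=3), cn.Unit(id="B", staffed_beds=5)], {}
        )
        res = cn.simulate_days(net, cn.SimulationConfig(horizon_days=30, seed=1))
        assert res.days_overutilized == 0
        assert np.all(res.system_under == 8.0)

    def test_single_unit_day_arithmetic(self):
        """0.3 arrivals against c=4, mu=0.06: rho=1.25, U=5, one bed over."""
        net = cn.CareNetwork.build(
            [cn.Unit(id="A", staffed_beds=4, service_rate=0.06)], {}
        )
        rho, occ, over, under = cn.occupancy_profile(np.array([[0.3]]), net)
        assert rho[0, 0] == pytest.approx(1.25)
        assert occ[0, 0] == pytest.approx(5.0)
        assert over[0, 0] == pytest.approx(1.0)
        assert under[0, 0] == 0.0

    def test_over_and_under_are_exclusive(self, printed_net):
        res = cn.simulate_days(printed_net, cn.SimulationConfig(horizon_days=200, seed=3))
        assert np.all((res.over_beds == 0) | (res.under_beds == 0))
        assert res.days_overutilized <= 200

    def test_identical_seeds_bit_identical(self, printed_net):
        cfg = cn.SimulationConfig(horizon_days=120, seed=42)
        a = cn.simulate_days(printed_net, cfg)
        b = cn.simulate_days(printed_net, cfg)
        assert np.array_equal(a.arrivals, b.arrivals)
        assert np.array_equal(a.occupancy, b.occupancy)
        c = cn.simulate_days(printed_net, cn.SimulationConfig(horizon_days=120, seed=43))
        assert not np.array_equal(a.arrivals, c.arrivals)

    def test_long_run_mean_occupancy_matches_theory(self, flows_net):
        """Law of large numbers: mean U_i -> eff_lambda_i / mu_i (3 SE band)."""
        d = 10_000
        res = cn.simulate_days(flows_net, cn.SimulationConfig(horizon_days=d, seed=7))
        eff = cn.effective_arrival_rates(flows_net)
        for u in flows_net.units:
            expected = eff[u.id] / u.service_rate
            observed = res.occupancy_series(u.id).mean()
            # occupancy is a linear map of Poisson draws; bound its SE by the
            # total inflow variance propagated with unit weight
            se = np.sqrt(eff[u.id] / d) / u.service_rate
            assert abs(observed - expected) < 3 * se

    def test_days_overutilized_monotone_in_bottleneck_beds(self, printed_net):
        def with_beds(n_beds):
            units = [
                cn.Unit(
                    id=u.id,
                    name=u.name,
                    staffed_beds=n_beds if u.id == "N2" else u.staffed_beds,
                    external_arrival_rate=u.external_arrival_rate,
                    service_rate=u.service_rate,
                    nurses_per_shift=dict(u.nurses_per_shift),
                )
                for u in printed_net.units
            ]
            return cn.CareNetwork.build(units, {})

        cfg = cn.SimulationConfig(horizon_days=365, seed=11)
        days = [
            cn.simulate_days(with_beds(b), cfg).days_overutilized for b in (4, 6, 8, 12)
        ]
        assert days == sorted(days, reverse=True)

    def test_sampled_routing_mode(self, flows_net):
        cfg = cn.SimulationConfig(horizon_days=100, seed=5, routing_mode="sampled")
        res = cn.simulate_days(flows_net, cfg)
        # sampled transfers are integer counts on top of integer arrivals
        assert np.allclose(res.eff_arrivals, np.round(res.eff_arrivals))
        # external arrivals are preserved; transfers only add
        assert np.all(res.eff_arrivals >= res.arrivals - 1e-9)
        again = cn.simulate_days(flows_net, cfg)
        assert np.array_equal(res.eff_arrivals, again.eff_arrivals)

    def test_result_frame_shape(self, printed_net):
        res = cn.simulate_days(printed_net, cn.SimulationConfig(horizon_days=10, seed=0))
        frame = res.to_frame()
        assert len(frame) == 10 * printed_net.n_units
        assert set(frame.columns) >= {"day", "unit", "occupancy", "over_beds"}


class TestCensusCorrelation:
    def test_self_correlation_is_one(self):
        rng = np.random.default_rng(0)
        res = make_result(rng.poisson(5, size=(100, 2)).astype(float))
        corr = cn.census_correlation(res, [("U0", "U0")])
        assert corr[("U0", "U0")] == pytest.approx(1.0)

    def test_perfect_anticorrelation(self):
        x = np.linspace(1, 9, 50)
        res = make_result(np.column_stack([x, -x]))
        corr = cn.census_correlation(res, [("U0", "U1")])
        assert corr[("U0", "U1")] == pytest.approx(-1.0)

    def test_independent_streams_near_zero(self):
        net = cn.CareNetwork.build(
            [
                cn.Unit(id="A", external_arrival_rate=3.0),
                cn.Unit(id="B", external_arrival_rate=2.0),
            ],
            {},
        )
        res = cn.simulate_days(net, cn.SimulationConfig(horizon_days=10_000, seed=21))
        corr = cn.census_correlation(res)
        assert abs(corr[("A", "B")]) < 0.05

    def test_zero_variance_flagged_not_nan(self):
        res = make_result(np.column_stack([np.full(20, 3.0), np.arange(20.0)]))
        corr = cn.census_correlation(res, [("U0", "U1")])
        assert corr[("U0", "U1")] is None

    def test_short_horizon_rejected(self):
        res = make_result(np.ones((2, 2)))
        with pytest.raises(cn.CareNetError, match="3 days"):
            cn.census_correlation(res)

    def test_matrix_is_symmetric_with_unit_diagonal(self, printed_net):
        res = cn.simulate_days(printed_net, cn.SimulationConfig(horizon_days=500, seed=2))
        mat = cn.correlation_matrix(res)
        assert np.allclose(mat.values, mat.values.T, equal_nan=True)
        assert np.allclose(np.diag(mat.values), 1.0)


class TestPoolingVarianceGain:
    def test_variance_decomposition_identity_exact(self, printed_net, plans):
        res = cn.simulate_days(printed_net, cn.SimulationConfig(horizon_days=365, seed=9))
        for plan in plans.values():
            for gv in cn.pooling_variance_gain(res, plan).values():
                assert gv.pooled_variance == pytest.approx(
                    gv.sum_member_variances + 2 * gv.covariance_sum, rel=1e-12
                )

    def test_independent_members_add_variances(self):
        rng = np.random.default_rng(4)
        res = make_result(rng.poisson(6, size=(20_000, 2)).astype(float))
        plan = cn.PoolingPlan(groups={"G": ("U0", "U1")})
        gv = cn.pooling_variance_gain(res, plan)["G"]
        assert gv.pooled_variance == pytest.approx(gv.sum_member_variances, rel=0.05)

    def test_anticorrelated_members_reduce_pooled_variance(self):
        rng = np.random.default_rng(5)
        x = rng.normal(10, 2, size=3000)
        res = make_result(np.column_stack([x, 20 - x + rng.normal(0, 0.5, size=3000)]))
        plan = cn.PoolingPlan(groups={"G": ("U0", "U1")})
        gv = cn.pooling_variance_gain(res, plan)["G"]
        assert gv.pooled_variance < gv.sum_member_variances
        assert gv.reduction > 0

    def test_duplicated_stream_quadruples_variance(self):
        rng = np.random.default_rng(6)
        x = rng.poisson(4, size=2000).astype(float)
        res = make_result(np.column_stack([x, x]))
        plan = cn.PoolingPlan(groups={"G": ("U0", "U1")})
        gv = cn.pooling_variance_gain(res, plan)["G"]
        assert gv.pooled_variance == pytest.approx(4 * np.var(x, ddof=1), rel=1e-12)
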