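"""Growth laws: closed forms, ODE consistency, clone competition invariants."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from clonesteer import (
    CloneSystem,
    GrowthCurve,
    GrowthParams,
    competition_rhs,
    growth_rhs,
    richards_solution,
    simulate_clonal_competition,
    simulate_growth,
    verhulst_solution,
)
from clonesteer.errors import InvalidParameterError
from oracles import rk4


class TestClosedForms:
    def test_equilibrium_and_no_growth(self):
        p_eq = GrowthParams(r=1.0, K=500.0, n0=500.0)
        t = np.linspace(0, 20, 11)
        assert np.allclose(verhulst_solution(p_eq, t), 500.0)
        p_flat = GrowthParams(r=0.0, K=500.0, n0=30.0)
        assert np.allclose(verhulst_solution(p_flat, t), 30.0)

    def test_logistic_midpoint(self):
        # N0=1, K=100, r=1: N(ln 99) = K/2 by the closed form
        p = GrowthParams(r=1.0, K=100.0, n0=1.0)
        t_mid = np.log(99.0)
        assert verhulst_solution(p, t_mid) == pytest.approx(50.0, rel=1e-12)
        # cross-check against an independent fine-step RK4 integration
        num = rk4(lambda _t, y: y * 1.0 * (1 - y / 100.0), [1.0], t_mid, 1e-4)
        assert num[0] == pytest.approx(50.0, rel=1e-6)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(InvalidParameterError):
            GrowthParams(r=np.nan, K=1.0, n0=1.0)
        with pytest.raises(InvalidParameterError):
            GrowthParams(r=1.0, K=-5.0, n0=1.0)
        with pytest.raises(InvalidParameterError):
            verhulst_solution(GrowthParams(r=1.0, K=10.0, n0=1.0, v=2.0), 1.0)

    def test_richards_solution_matches_ode(self):
        p = GrowthParams(r=0.5, K=1000.0, n0=10.0, v=2.0)
        oracle = rk4(lambda _t, y: 0.5 * y * (1 - (y / 1000.0) ** 2.0), [10.0], 10.0, 1e-4)
        assert richards_solution(p, 10.0) == pytest.approx(oracle[0], rel=1e-5)


class TestRhs:
    def test_equilibrium_derivative_zero(self):
        p = GrowthParams(r=0.7, K=1e4, n0=1.0, v=1.7)
        assert growth_rhs("richards", p, 1e4) == pytest.approx(0.0, abs=1e-12)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        n=st.floats(0, 1e6),
        r=st.floats(0, 5),
        k=st.floats(1e2, 1e7),
    )
    def test_richards_v1_equals_verhulst(self, n, r, k):
        pv = GrowthParams(r=r, K=k, n0=1.0, v=1.0)
        assert growth_rhs("richards", pv, n) == pytest.approx(
            growth_rhs("verhulst", pv, n), rel=1e-12, abs=1e-12
        )

    def test_gompertz_values_and_limit(self):
        # K = e, N = K/e = 1, r = 1 -> dN/dt = 1 * 1 * ln(e) = 1
        p = GrowthParams(r=1.0, K=np.e, n0=0.5)
        assert growth_rhs("gompertz", p, 1.0) == pytest.approx(1.0, rel=1e-12)
        # finite-difference of the Gompertz closed form at the same point
        from clonesteer import gompertz_solution

        t_at = np.log(np.log(np.e / 0.5))  # time when N = 1 for n0=0.5, K=e, r=1
        h = 1e-6
        fd = (gompertz_solution(p, t_at + h) - gompertz_solution(p, t_at - h)) / (2 * h)
        assert growth_rhs("gompertz", p, gompertz_solution(p, t_at)) == pytest.approx(
            fd, rel=1e-6
        )
        assert growth_rhs("gompertz", p, 0.0) == 0.0
        with pytest.raises(InvalidParameterError):
            growth_rhs("gompertz", p, -1.0)


class TestSimulateGrowth:
    def test_verhulst_ode_matches_closed_form_random_params(self, rng):
        t = np.linspace(0, 40, 81)
        for _ in range(100):
            p = GrowthParams(
                r=rng.uniform(0.1, 2.0),
                K=10 ** rng.uniform(3, 7),
                n0=10 ** rng.uniform(1, 3),
            )
            sim = simulate_growth("verhulst", p, t)
            err = np.max(np.abs(sim.counts - verhulst_solution(p, t))) / p.K
            assert err < 1e-6

    def test_flat_when_r_zero(self):
        p = GrowthParams(r=0.0, K=1e5, n0=500.0)
        sim = simulate_growth("richards", p, np.linspace(0, 10, 11))
        assert np.allclose(sim.counts, 500.0, rtol=1e-9)

    def test_richards_matches_fine_rk4_oracle(self):
        p = GrowthParams(r=0.5, K=1000.0, n0=10.0, v=2.0)
        sim = simulate_growth("richards", p, np.linspace(0, 10, 11))
        oracle = rk4(lambda _t, y: growth_rhs("richards", p, y), [10.0], 10.0, 1e-4)
        assert sim.counts[-1] == pytest.approx(oracle[0], rel=1e-5)

    def test_bad_grid_rejected(self):
        p = GrowthParams(r=1.0, K=100.0, n0=1.0)
        with pytest.raises(InvalidParameterError):
            simulate_growth("verhulst", p, [1.0, 2.0])


class TestCloneCompetition:
    def test_single_clone_reduces_to_verhulst(self):
        sys1 = CloneSystem(["a"], r=[0.9], K=[1e6], state=[1e3])
        t = np.linspace(0, 25, 26)
        traj = simulate_clonal_competition(sys1, t)
        expect = verhulst_solution(GrowthParams(r=0.9, K=1e6, n0=1e3), t)
        assert np.max(np.abs(traj.sizes[:, 0] - expect)) / 1e6 < 1e-6

    def test_identical_clones_split_capacity(self):
        sys2 = CloneSystem(["a", "b"], r=[1.0, 1.0], K=[1e6, 1e6], state=[10.0, 10.0])
        t = np.linspace(0, 40, 41)
        traj = simulate_clonal_competition(sys2, t)
        assert np.allclose(traj.sizes[:, 0], traj.sizes[:, 1], rtol=1e-9)
        assert traj.sizes[-1, 0] == pytest.approx(5e5, rel=1e-4)
        oracle = rk4(
            lambda _t, y: y * 1.0 * (1 - (y[0] + y[1]) / 1e6),
            [10.0, 10.0],
            40.0,
            1e-3,
        )
        assert traj.sizes[-1] == pytest.approx(oracle, rel=1e-5)

    def test_zero_rate_and_zero_seed_clones(self):
        sys3 = CloneSystem(
            ["grow", "still", "absent"],
            r=[1.0, 0.0, 2.0],
            K=[1e6, 1e6, 1e6],
            state=[100.0, 50.0, 0.0],
        )
        traj = simulate_clonal_competition(sys3, np.linspace(0, 15, 16))
        assert np.allclose(traj.sizes[:, 1], 50.0, rtol=1e-9)
        assert np.all(traj.sizes[:, 2] == 0.0)
        assert traj.sizes[-1, 0] > 100.0

    def test_nonnegative_growth_below_capacity_surface(self, rng):
        # seeded below the capacity surface, every clone's per-capita growth
        # rate r_i (1 - occupancy) stays nonnegative: the occupancy never
        # overshoots 1 by more than 1e-9 along the trajectory
        t = np.linspace(0, 30, 61)
        for _ in range(100):
            n = rng.integers(2, 5)
            K = 10 ** rng.uniform(4, 7, size=n)
            r = rng.uniform(0.0, 2.0, size=n)
            f = rng.dirichlet(np.ones(n))
            occupancy = rng.uniform(0.05, 0.95)
            state = occupancy * f * K  # sum(state/K) = occupancy < 1
            system = CloneSystem([f"c{i}" for i in range(n)], r=r, K=K, state=state)
            traj = simulate_clonal_competition(system, t, rtol=1e-11, atol=1e-8)
            occ = (traj.sizes / K).sum(axis=1)
            assert occ.max() <= 1 + 1e-9
            # equivalently the rhs never goes negative beyond that bound
            floors = traj.sizes * r * 1e-9
            rhs = np.array([competition_rhs(system, row) for row in traj.sizes])
            assert np.all(rhs >= -floors - 1e-300)

    def test_long_time_equilibrium_fills_capacity_surface(self):
        system = CloneSystem(
            ["a", "b", "c"],
            r=[0.8, 1.2, 0.5],
            K=[1e6, 5e5, 2e6],
            state=[1e3, 2e3, 5e2],
        )
        traj = simulate_clonal_competition(system, np.linspace(0, 200, 51))
        occupancy = np.sum(traj.sizes[-1] / system.K)
        assert abs(occupancy - 1.0) < 1e-4

    def test_mismatched_state_rejected(self):
        with pytest.raises(InvalidParameterError):
            CloneSystem(["a", "b"], r=[1.0, 1.0], K=[1e6, 1e6], state=[1.0])
        with pytest.raises(InvalidParameterError):
            CloneSystem(["a", "a"], r=[1.0, 1.0], K=[1e6, 1e6])


def test_growth_curve_validation():
    with pytest.raises(InvalidParameterError):
        GrowthCurve(times=[0.0, 1.0, 1.0], counts=[1.0, 2.0, 3.0])
    with pytest.raises(InvalidParameterError):
        GrowthCurve(times=[0.0, 1.0], counts=[1.0, np.inf])
    c = GrowthCurve(times=[0.0, 1.0], counts=[1.0, 2.0], population_id="x")
    assert list(c.to_frame().columns) == ["time_days", "count", "population_id"]
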