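"""Unit and property tests for both model forms and the reduction map."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from fibrophase import (
    DimensionalParams,
    DimensionalState,
    Environment,
    ReducedParams,
    ReducedState,
    full_rhs,
    healthy_state,
    qss_inflammation_link,
    reduce_model,
    reduced_rhs,
    switching_term,
)
from fibrophase.simulate import integrate, integrate_dimensional

positive = st.floats(min_value=1e-3, max_value=1e3, allow_nan=False, allow_infinity=False)


def unit_dimensional_params(**overrides):
    base = dict(l=1, d1=1, d2=1, d3=1, r=1, Y0=1, K=1, g=1, F0=1, k12=1, k21=1)
    base.update(overrides)
    return DimensionalParams(**base)


class TestSwitchingTerm:
    @pytest.mark.parametrize(
        "M1,M2,Y,k12,k21,expected",
        [
            (0, 0, 5.0, 2.0, 3.0, 0.0),
            (2, 3, 1.0, 1.0, 1.0, 1.0),  # -2 + 3
            (4, 7, 0.0, 0.5, 9.0, -2.0),  # Y=0: pure drain toward profibrotic
        ],
    )
    def test_values(self, M1, M2, Y, k12, k21, expected):
        assert switching_term(M1, M2, Y, k12, k21) == pytest.approx(expected)

    @given(
        M1=positive, M2=positive, Y=positive, k12=positive, k21=positive,
        c=st.floats(min_value=0.1, max_value=10),
    )
    @settings(max_examples=50, deadline=None)
    def test_linearity_in_each_argument(self, M1, M2, Y, k12, k21, c):
        base = switching_term(M1, M2, Y, k12, k21)
        only_m1 = switching_term(M1, 0, Y, k12, k21)
        only_m2 = switching_term(0, M2, Y, k12, k21)
        assert base == pytest.approx(only_m1 + only_m2, rel=1e-12, abs=1e-12)
        assert switching_term(c * M1, M2, Y, k12, k21) == pytest.approx(
            c * only_m1 + only_m2, rel=1e-9
        )

    def test_rejects_negative_input(self):
        with pytest.raises(ValueError):
            switching_term(-1, 0, 0, 1, 1)


class TestQssLink:
    @pytest.mark.parametrize(
        "M1,M2,lam,expected", [(3, 3, 1.0, 1.0), (0, 5, 2.0, 0.0), (4, 1, 2.0, 2.0)]
    )
    def test_values(self, M1, M2, lam, expected):
        assert qss_inflammation_link(M1, M2, lam) == pytest.approx(expected)

    def test_zero_profibrotic_pool_is_undefined(self):
        with pytest.raises(ValueError):
            qss_inflammation_link(1.0, 0.0, 1.0)


class TestFullRhs:
    def test_empty_tissue_only_recruits(self):
        p = unit_dimensional_params(l=3.5)
        d = full_rhs(DimensionalState(0, 0, 0), p, Environment(y=2.0, H=1.0))
        assert d == pytest.approx((3.5 * 2.0, 0.0, 0.0))

    def test_no_hypoxia_removes_growth_terms(self):
        # H = 0: M2 loses its proliferation term, F decays at rate d3
        p = unit_dimensional_params(d3=0.7)
        st_ = DimensionalState(2.0, 3.0, 5.0)
        dM1, dM2, dF = full_rhs(st_, p, Environment(y=1.0, H=0.0))
        e12 = switching_term(2.0, 3.0, 1.0, 1.0, 1.0)
        assert dM2 == pytest.approx(-e12 - 3.0)
        assert dF == pytest.approx(-0.7 * 5.0)

    def test_no_hypoxia_independent_of_growth_params(self):
        env = Environment(y=2.0, H=0.0)
        st_ = DimensionalState(1.0, 2.0, 3.0)
        a = full_rhs(st_, unit_dimensional_params(), env)
        b = full_rhs(st_, unit_dimensional_params(r=9, g=7, F0=5, K=3), env)
        assert a == pytest.approx(b)

    def test_unit_point_matches_termwise_recomputation(self):
        # independent term-by-term evaluation at the all-ones point
        p = unit_dimensional_params()
        env = Environment(y=1.0, H=1.0)
        d = full_rhs(DimensionalState(1, 1, 1), p, env)
        e12 = -1 * 1 + 1 * 1 * 1
        expect = (
            1 * 1 + e12 - 1 * 1,
            1 * 1 * 1 * 1 * (1 + 1) / (1 + 1) - e12 - 1 * 1,
            1 * 1 * 1 * 1 * (1 - 1) - 1 * 1,
        )
        assert d == pytest.approx(expect)
        assert d == pytest.approx((0.0, 0.0, -1.0))


class TestReducedRhs:
    def test_fibroblast_free_axis_is_invariant(self, baseline):
        for m in (0.0, 0.3, 2.0, 50.0):
            _, df = reduced_rhs(ReducedState(m=m, f=0.0), baseline, Environment(y=1.3, H=0.8))
            assert df == 0.0

    def test_healthy_state_is_a_fixed_point(self, baseline):
        env = Environment(y=1.0, H=0.6)
        hs = healthy_state(baseline, env.y)
        dm, df = reduced_rhs(hs, baseline, env)
        assert abs(dm) < 1e-14 and df == 0.0

    def test_baseline_point_matches_termwise_recomputation(self, baseline):
        # lam=1, d1=1, d2=0.5, a=1, b=4, y=1, H=1, (m, f) = (1, 0.5)
        dm, df = reduced_rhs(ReducedState(m=1.0, f=0.5), baseline, Environment(y=1.0, H=1.0))
        assert dm == pytest.approx(1 - 1 * 2 / 2 + 1 * 1 * 2 * 1 * 0.5 / (1 + 2))  # 1/3
        assert df == pytest.approx(4 * 1 * 1 * 0.5 * 0.5 / 2 - 0.5 * 0.5)  # 0.25

    def test_rejects_nonfinite_state(self, baseline):
        with pytest.raises(ValueError):
            ReducedState(m=float("nan"), f=0.0)


class TestForwardInvariance:
    @given(data=st.data())
    @settings(max_examples=15, deadline=None)
    def test_trajectories_stay_in_region(self, data):
        rng_vals = [
            data.draw(st.floats(min_value=0.2, max_value=5.0), label=k)
            for k in ("lam", "d1", "d2", "a", "b")
        ]
        p = ReducedParams(*rng_vals)
        env = Environment(
            y=data.draw(st.floats(min_value=0.0, max_value=5.0), label="y"),
            H=data.draw(st.floats(min_value=0.0, max_value=2.0), label="H"),
        )
        init = ReducedState(
            m=data.draw(st.floats(min_value=0.0, max_value=5.0), label="m0"),
            f=data.draw(st.floats(min_value=0.0, max_value=1.0), label="f0"),
        )
        traj = integrate(p, env, init, t_end=30.0)
        assert np.all(traj.states[:, 0] >= -1e-9)
        assert np.all(traj.states[:, 1] >= -1e-9)
        assert np.all(traj.states[:, 1] <= 1.0 + 1e-9)


class TestReduceModel:
    def test_equal_switch_rates_give_unit_lambda(self):
        rp, _ = reduce_model(unit_dimensional_params(k12=3.0, k21=3.0))
        assert rp.lam == pytest.approx(1.0)

    def test_dimensional_homogeneity(self):
        dp = DimensionalParams(l=2, d1=1, d2=1.5, d3=0.5, r=0.5, Y0=1, K=2, g=0.5, F0=4, k12=5, k21=5)
        rp1, rep1 = reduce_model(dp)
        doubled = DimensionalParams(
            l=4, d1=2, d2=3, d3=1, r=1, Y0=1, K=2, g=1, F0=4, k12=10, k21=10
        )
        rp2, rep2 = reduce_model(doubled)
        assert rp1 == rp2
        assert rep2["time_scale"] == pytest.approx(rep1["time_scale"] / 2)
        assert rep1["kappa"] == pytest.approx(rep2["kappa"])

    def test_canonical_flag_requires_scale_constraint(self):
        _, rep = reduce_model(unit_dimensional_params())  # K = l*Y0/d1 = 1
        assert rep["canonical"]
        _, rep = reduce_model(unit_dimensional_params(K=2))
        assert not rep["canonical"]
        assert rep["kappa"] == pytest.approx(2.0)

    def test_qss_ratio_converges_under_fast_switching(self):
        # k12, k21 >> deactivation rates: M1/(M2*Y) -> k21/k12 within 1%
        dp = unit_dimensional_params(k12=500.0, k21=500.0)
        env = Environment(y=2.0, H=0.5)
        traj = integrate_dimensional(dp, env, DimensionalState(1.0, 1.0, 0.5), t_end=5.0)
        M1, M2 = traj.states[-1, 0], traj.states[-1, 1]
        assert M1 / (M2 * env.y) == pytest.approx(dp.k21 / dp.k12, rel=0.01)

    def test_reduced_trajectory_matches_rescaled_dimensional(self):
        # canonical dp (kappa=1) mapping onto the baseline reduced set
        dp = DimensionalParams(
            l=2, d1=1, d2=1, d3=0.5, r=0.5, Y0=1, K=2, g=0.5, F0=4, k12=200, k21=200
        )
        rp, rep = reduce_model(dp)
        assert rep["canonical"]
        assert rp.to_dict() == pytest.approx(
            dict(lam=1.0, delta1=1.0, delta2=0.5, alpha=1.0, beta=4.0)
        )
        env = Environment(y=1.0, H=1.0)
        m0, f0 = 0.2, 0.25
        M = m0 * rep["macrophage_scale"]
        lam_y = rp.lam * env.y
        init_dim = DimensionalState(
            M1=M * lam_y / (1 + lam_y), M2=M / (1 + lam_y), F=f0 * rep["fibroblast_scale"]
        )
        t_end = 20.0
        traj_dim = integrate_dimensional(dp, env, init_dim, t_end=t_end / dp.d1, n_points=100)
        traj_red = integrate(rp, env, ReducedState(m=m0, f=f0), t_end=t_end, n_points=100)
        m_dim = (traj_dim.states[:, 0] + traj_dim.states[:, 1]) / rep["macrophage_scale"]
        f_dim = traj_dim.states[:, 2] / rep["fibroblast_scale"]
        # QSS error ~ d1/k12 = 0.5%
        assert np.allclose(m_dim, traj_red.states[:, 0], rtol=0.02, atol=0.02)
        assert np.allclose(f_dim, traj_red.states[:, 1], rtol=0.02, atol=0.02)
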