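"""Core network-model operations: compounding, steady states, symptoms,
growth capacity, relaxation dynamics, time averaging and regimen design."""

import numpy as np
import pytest

import homeomix as hx


def _system(eps, nu, delta=None, h0=None, k=None, n_ref=None):
    c, n_N = np.asarray(nu).shape
    delta = np.zeros((c, 1)) if delta is None else delta
    return hx.FeatureSystem(
        h0=np.zeros(c) if h0 is None else h0,
        eps=eps, k=np.ones(c) if k is None else k,
        nu=nu, delta=delta,
        n_ref=np.zeros(n_N) if n_ref is None else n_ref)


class TestCompounding:
    def test_identity_coupling_is_identity_map(self, rng):
        nu = rng.standard_normal((3, 4))
        delta = rng.standard_normal((3, 2))
        sys = _system(np.eye(3), nu, delta)
        comp = hx.compound_potencies(sys)
        np.testing.assert_array_equal(comp.nu_c, nu)
        np.testing.assert_array_equal(comp.delta_c, delta)

    def test_two_feature_hand_computation(self):
        sys = _system(np.array([[1.0, 0.5], [0.0, 1.0]]),
                      np.array([[1.0, 0.0], [0.0, 2.0]]))
        comp = hx.compound_potencies(sys)
        np.testing.assert_allclose(comp.nu_c, [[1.0, 1.0], [0.0, 2.0]])

    def test_matches_brute_force_sum(self, rng):
        c, n_N = 5, 3
        eps = 0.2 * rng.standard_normal((c, c))
        np.fill_diagonal(eps, 1.0)
        nu = rng.standard_normal((c, n_N))
        comp = hx.compound_potencies(_system(eps, nu))
        brute = np.array([[sum(eps[i, j] * nu[j, k] for j in range(c))
                           for k in range(n_N)] for i in range(c)])
        np.testing.assert_allclose(comp.nu_c, brute, rtol=1e-13)

    def test_deviation_from_raw_potency_linear_in_coupling(self, rng):
        """One-pass compounding departs from the raw potencies linearly in
        the off-diagonal coupling magnitude."""
        c, n_N = 5, 5
        base = rng.standard_normal((c, c))
        nu = rng.standard_normal((c, n_N))
        gaps = []
        for scale in (1e-2, 1e-3):
            eps = scale * base
            np.fill_diagonal(eps, 1.0)
            comp = hx.compound_potencies(_system(eps, nu))
            gaps.append(np.linalg.norm(comp.nu_c - nu))
        assert gaps[0] / gaps[1] == pytest.approx(10.0, rel=1e-9)

    def test_true_baseline_absorbs_reference_regimen(self, small_system):
        comp = hx.compound_potencies(small_system)
        np.testing.assert_allclose(
            comp.h, small_system.h0 - comp.nu_c @ small_system.n_ref,
            rtol=1e-14)

    def test_self_consistent_agrees_to_first_order(self, rng):
        c = 4
        base = rng.standard_normal((c, c))
        nu = rng.standard_normal((c, 3))
        gaps = []
        for scale in (1e-2, 1e-3):
            eps = scale * base
            np.fill_diagonal(eps, 1.0)
            sys = _system(eps, nu)
            one = hx.compound_potencies(sys).nu_c
            sc = hx.compound_potencies(sys, mode="self_consistent").nu_c
            gaps.append(np.linalg.norm(one - sc))
        # the two modes differ at second order in the coupling scale
        assert gaps[0] / gaps[1] == pytest.approx(100.0, rel=0.2)


class TestSteadyStateAndSymptoms:
    def test_no_exposure_returns_baseline(self, small_comp):
        E = hx.steady_state(small_comp, hx.Regimen.zero(small_comp.n_N))
        np.testing.assert_array_equal(E, small_comp.h)

    def test_scalar_toy_arithmetic(self):
        comp = hx.CompoundedSystem(nu_c=[[2.0]], delta_c=[[3.0]], h=[5.0])
        E = hx.steady_state(comp, hx.Regimen(N=[1.0]),
                            hx.DiseaseState(D=[1.0]))
        assert E[0] == pytest.approx(4.0)

    def test_superposition_to_machine_precision(self, small_comp, rng):
        D = hx.DiseaseState(D=rng.uniform(0, 1, small_comp.n_D))
        N1 = rng.uniform(0, 2, small_comp.n_N)
        N2 = rng.uniform(0, 2, small_comp.n_N)
        lhs = (hx.steady_state(small_comp, hx.Regimen(N=N1 + N2), D)
               - hx.steady_state(small_comp, hx.Regimen(N=N1), D)
               - hx.steady_state(small_comp, hx.Regimen(N=N2), D)
               + hx.steady_state(small_comp, hx.Regimen.zero(small_comp.n_N), D))
        np.testing.assert_allclose(lhs, 0.0, atol=1e-12)

    def test_symptoms_vanish_when_contributions_cancel(self, rng):
        """Nutrition/disease symmetry: a disease whose compounded virulence
        load equals the regimen's compounded potency load is symptom-free."""
        nu_c = rng.standard_normal((4, 3))
        N = rng.uniform(0.1, 1, 3)
        delta_c = (nu_c @ N)[:, None]  # single disease with matched load
        comp = hx.CompoundedSystem(nu_c=nu_c, delta_c=delta_c,
                                   h=rng.uniform(1, 5, 4))
        S = hx.symptoms(comp, hx.Regimen(N=N), hx.DiseaseState(D=[1.0]))
        np.testing.assert_allclose(S, 0.0, atol=1e-12)

    def test_symptom_sign_symmetry(self, small_comp, rng):
        """Pure nutritional departure mirrors the pure disease state when
        the loads are opposite: S(N, 0) = -S(0, D)."""
        N = rng.uniform(0, 1, small_comp.n_N)
        s_nut = hx.symptoms(small_comp, hx.Regimen(N=N))
        target = small_comp.nu_c @ N
        # build D with delta_c @ D = target via least squares (n_D may be < c)
        D, *_ = np.linalg.lstsq(small_comp.delta_c, target, rcond=None)
        if np.all(D >= 0):  # only meaningful when a valid disease exists
            s_dis = hx.symptoms(small_comp,
                                hx.Regimen.zero(small_comp.n_N),
                                hx.DiseaseState(D=D))
            resid = small_comp.delta_c @ D - target
            np.testing.assert_allclose(s_nut + s_dis, resid, atol=1e-10)

    def test_perfect_regimen_fixture_is_symptom_free(self):
        fx = hx.generate_fixture(hx.FixtureSpec(
            c=6, n_N=4, mode="perfect-regimen-consistent", seed=11))
        comp = hx.compound_potencies(fx.system)
        S = hx.symptoms(comp, hx.Regimen(N=fx.system.n_ref))
        np.testing.assert_allclose(S, 0.0, atol=1e-10)


class TestGrowthCapacity:
    def test_zero_regimen_gives_basal_capacity(self):
        gs = hx.GrowthSystem(hG=[1.5, 0.5], nuG_c=[[1.0, -1.0], [0.5, 0.5]])
        np.testing.assert_array_equal(
            hx.growth_capacity(gs, hx.Regimen.zero(2)), gs.hG)

    def test_exact_suppression_dose(self, rng):
        nuG_c = rng.standard_normal((2, 4))
        N = rng.uniform(0.1, 1, 4)
        gs = hx.GrowthSystem(hG=-(nuG_c @ N), nuG_c=nuG_c)
        np.testing.assert_allclose(hx.growth_capacity(gs, hx.Regimen(N=N)),
                                   0.0, atol=1e-12)

    def test_linearity_in_dose(self, rng):
        gs = hx.GrowthSystem(hG=rng.uniform(0.5, 2, 3),
                             nuG_c=rng.standard_normal((3, 4)))
        N = rng.uniform(0, 1, 4)
        g1 = hx.growth_capacity(gs, hx.Regimen(N=N)) - gs.hG
        g2 = hx.growth_capacity(gs, hx.Regimen(N=2 * N)) - gs.hG
        np.testing.assert_allclose(g2, 2 * g1, rtol=1e-12)


class TestRelaxDynamics:
    def test_uncoupled_scalar_exponential(self):
        sys = _system(np.eye(1), np.zeros((1, 1)), h0=np.array([2.0]),
                      k=np.array([0.8]))
        comp = hx.compound_potencies(sys)
        t = np.linspace(0, 5, 101)
        traj = hx.relax_dynamics(sys, comp, E0=comp.h + 1.0,
                                 regimen=hx.Regimen.zero(1), disease=None,
                                 t_grid=t)
        np.testing.assert_allclose(traj.E[:, 0],
                                   comp.h[0] + np.exp(-0.8 * t), rtol=1e-10)
        # at t = 1/k the deviation has decayed to 1/e
        idx = np.argmin(np.abs(t - 1 / 0.8))
        assert traj.E[idx, 0] - comp.h[0] == pytest.approx(np.exp(-1.0),
                                                           rel=1e-2)

    def test_terminal_state_matches_algebraic_steady_state(self, small_system,
                                                           small_comp, rng):
        reg = hx.Regimen(N=rng.uniform(0, 1, small_system.n_N))
        dis = hx.DiseaseState(D=rng.uniform(0, 1, small_system.n_D))
        t_end = 50.0 / small_system.k.min()
        traj = hx.relax_dynamics(small_system, small_comp,
                                 E0=small_comp.h + rng.standard_normal(4),
                                 regimen=reg, disease=dis,
                                 t_grid=np.linspace(0, t_end, 50))
        target = hx.steady_state(small_comp, reg, dis)
        assert np.max(np.abs(traj.E[-1] - target)) < 1e-8

    def test_steady_state_is_fixed_point(self, small_system, small_comp):
        reg = hx.Regimen.zero(small_system.n_N)
        traj = hx.relax_dynamics(small_system, small_comp, E0=small_comp.h,
                                 regimen=reg, disease=None,
                                 t_grid=np.linspace(0, 10, 20))
        np.testing.assert_allclose(traj.E, np.tile(small_comp.h, (20, 1)),
                                   atol=1e-10)

    def test_unstable_coupling_raises_named_stability_error(self):
        eps = np.array([[1.0, 2.0], [2.0, 1.0]])  # off-diag spectral radius 2
        sys = _system(eps, np.zeros((2, 1)))
        comp = hx.compound_potencies(sys)
        with pytest.raises(hx.StabilityError, match="spectral"):
            hx.relax_dynamics(sys, comp, E0=np.zeros(2),
                              regimen=hx.Regimen.zero(1), disease=None,
                              t_grid=np.linspace(0, 1, 5))


class TestTimeAverage:
    def test_constant_trajectory_averages_to_constant(self):
        traj = hx.Trajectory(t=np.linspace(0, 2, 21), E=np.full((21, 3), 7.0))
        np.testing.assert_allclose(hx.time_average(traj, 1.0), 7.0)

    def test_decay_average_above_limit(self):
        t = np.linspace(0, 3, 301)
        traj = hx.Trajectory(t=t, E=(2.0 + np.exp(-t))[:, None])
        assert hx.time_average(traj, 3.0)[0] > 2.0

    def test_sinusoid_full_period_mean(self):
        T = 2.0
        t = np.linspace(0, 4, 4001)
        traj = hx.Trajectory(t=t, E=(1.5 + np.sin(2 * np.pi * t / T))[:, None])
        assert hx.time_average(traj, T)[0] == pytest.approx(1.5, abs=1e-6)

    def test_window_longer_than_span_rejected(self):
        traj = hx.Trajectory(t=np.linspace(0, 1, 5), E=np.zeros((5, 1)))
        with pytest.raises(hx.DomainError, match="span"):
            hx.time_average(traj, 2.0)


class TestDesignRegimen:
    def test_empty_objective_is_usage_error(self, small_comp):
        with pytest.raises(hx.UsageError):
            hx.design_regimen(small_comp)

    def test_overdetermined_unconstrained_hits_numerical_zero(self, rng):
        """More chemicals than features with full-rank potencies: exact
        symptom cancellation exists without the nonnegativity constraint."""
        c, n_N = 4, 7
        nu_c = rng.standard_normal((c, n_N))
        delta_c = rng.standard_normal((c, 1))
        comp = hx.CompoundedSystem(nu_c=nu_c, delta_c=delta_c,
                                   h=np.zeros(c))
        design = hx.design_regimen(
            comp, disease=hx.DiseaseState(D=[1.0]),
            options=hx.DesignOptions(nonneg=False))
        assert design.max_residual < 1e-8

    def test_therapy_solvable_fixture_cancels_symptoms(self):
        fx = hx.generate_fixture(hx.FixtureSpec(
            c=6, n_N=8, n_D=2, n_G=2, mode="therapy-solvable", seed=21))
        comp = hx.compound_potencies(fx.system)
        design = hx.design_regimen(comp, gs=fx.growth, disease=fx.disease)
        assert design.max_residual < 1e-8
        # the designed regimen is genuinely symptom-free and suppressive
        S = hx.symptoms(comp, design.regimen, fx.disease)
        G = hx.growth_capacity(fx.growth, design.regimen)
        assert np.max(np.abs(S)) < 1e-7 and np.max(np.abs(G)) < 1e-7

    def test_zero_growth_potency_leaves_basal_residual(self):
        gs = hx.GrowthSystem(hG=[2.0, 1.0], nuG_c=np.zeros((2, 3)))
        comp = hx.CompoundedSystem(nu_c=np.zeros((2, 3)),
                                   delta_c=np.zeros((2, 1)), h=[0.0, 0.0])
        design = hx.design_regimen(comp, gs=gs)
        np.testing.assert_allclose(np.abs(design.growth_residuals),
                                   gs.hG, rtol=1e-12)

    def test_residual_grows_continuously_with_perturbation(self, rng):
        fx = hx.generate_fixture(hx.FixtureSpec(
            c=5, n_N=6, mode="therapy-solvable", seed=5))
        comp0 = hx.compound_potencies(fx.system)
        residuals = []
        for scale in (0.0, 1e-3, 1e-1):
            delta_c = comp0.delta_c + scale * np.linalg.norm(comp0.delta_c) \
                * rng.standard_normal(comp0.delta_c.shape)
            comp = hx.CompoundedSystem(nu_c=comp0.nu_c, delta_c=delta_c,
                                       h=comp0.h)
            residuals.append(hx.design_regimen(
                comp, disease=fx.disease).max_residual)
        assert residuals[0] < 1e-8
        assert residuals[0] <= residuals[1] <= residuals[2]

    def test_growth_sign_conventions_differ(self):
        gs = hx.GrowthSystem(hG=[1.0], nuG_c=[[1.0]])
        comp = hx.CompoundedSystem(nu_c=np.zeros((1, 1)),
                                   delta_c=np.zeros((1, 1)), h=[0.0])
        sup = hx.design_regimen(
            comp, gs=gs, options=hx.DesignOptions(
                host_weight=0.0, growth_sign="suppress", nonneg=False))
        lit = hx.design_regimen(
            comp, gs=gs, options=hx.DesignOptions(
                host_weight=0.0, growth_sign="literal", nonneg=False))
        assert sup.regimen.N[0] == pytest.approx(-1.0)
        assert lit.regimen.N[0] == pytest.approx(1.0)

    def test_summary_mentions_residuals(self, small_comp):
        design = hx.design_regimen(
            small_comp, disease=hx.DiseaseState(D=np.ones(small_comp.n_D)))
        assert "residual" in design.summary()
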