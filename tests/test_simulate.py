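"""Integration, influx noise, divergence reports, trajectory statistics."""
import numpy as np
import pytest

from cosubflux import (EnzymeParams, InfluxNoiseProcess, PoolSpec,
                       analytic_single_steady_state, branch_flux_ratio,
                       build_branched_model, build_coupled_model,
                       build_linear_pathway_model, cosubstrate_steady_fractions,
                       detect_divergence, feasibility_thresholds,
                       generate_influx_schedule, integrate, numeric_steady_state,
                       output_correlation, pool_ratio_series,
                       simulate_with_influx_noise, simulate_with_switches)

ENZ = EnzymeParams(kcat=100.0, Etot=0.01, KM_f=0.05)


class TestIntegrate:
    def test_trajectory_stays_at_fixed_point(self, ref_single_model,
                                             worked_fixed_point):
        traj = integrate(ref_single_model, (0.0, 500.0),
                         y0=worked_fixed_point["state"], n_points=200)
        drift = np.abs(traj.states - worked_fixed_point["state"][:, None])
        assert drift.max() < 1e-6

    def test_zero_influx_keeps_pathway_empty(self, ref_single_model):
        m = ref_single_model.with_influx(0, 0.0)
        traj = integrate(m, (0.0, 200.0), n_points=100)
        assert np.all(traj.species("M0") == 0.0)
        assert np.all(traj.species("M1") == 0.0)

    def test_pool_conservation_along_trajectory(self, ref_single_model):
        traj = integrate(ref_single_model, (0.0, 1000.0), n_points=300)
        total = traj.species("A0") + traj.species("A1")
        assert np.max(np.abs(total - 1.0)) < 1e-9

    def test_switch_to_infeasible_builds_up_m0_and_drains_a0(self,
                                                             ref_single_model):
        """Run at a feasible operating point, then switch the influx above
        the binding limit: M0 rises without plateau and A0 declines."""
        thr = feasibility_thresholds(ref_single_model)
        infeasible = ref_single_model.with_influx(0, 1.3 * thr.T_binding)
        traj = simulate_with_switches(ref_single_model,
                                      [(500.0, infeasible)], (0.0, 3000.0),
                                      n_points=600)
        t = traj.times
        m0, a0 = traj.species("M0"), traj.species("A0")
        pre = (t > 300) & (t < 500)
        assert np.ptp(m0[pre]) < 1e-4          # settled before the switch
        post = t > 600
        assert np.all(np.diff(m0[post]) > 0)       # monotone build-up after
        assert np.all(np.diff(a0[post]) < 0)       # steady decline of A0
        assert a0[-1] < 0.8 * a0[pre].mean()


class TestInfluxNoise:
    def test_schedule_is_seed_reproducible(self):
        proc = InfluxNoiseProcess(tau=5.0, mean_kin=0.1, seed=11)
        s1 = generate_influx_schedule(proc, 500.0)
        s2 = generate_influx_schedule(proc, 500.0)
        np.testing.assert_array_equal(s1.times, s2.times)
        np.testing.assert_array_equal(s1.kin1, s2.kin1)

    def test_influx_pair_mean_held_fixed(self):
        proc = InfluxNoiseProcess(tau=2.0, mean_kin=0.1, seed=3)
        s = generate_influx_schedule(proc, 2000.0)
        np.testing.assert_allclose(s.kin1 + s.kin2, 0.2, rtol=1e-12)
        assert np.all(s.kin1 > 0) and np.all(s.kin2 > 0)

    def test_long_waiting_time_means_constant_symmetric_influx(self):
        proc = InfluxNoiseProcess(tau=1e9, mean_kin=0.1, seed=5)
        s = generate_influx_schedule(proc, 100.0)
        assert len(s) == 0
        assert s.initial == (0.1, 0.1)

    def test_log_ratio_draws_are_standard_normal(self):
        proc = InfluxNoiseProcess(tau=1.0, mean_kin=0.1, seed=9)
        s = generate_influx_schedule(proc, 10000.0)
        z = np.log(s.kin1 / s.kin2)
        n = z.size
        assert abs(z.mean()) < 3.0 / np.sqrt(n)
        assert abs(z.std() - 1.0) < 0.05

    def test_noisy_simulation_records_events_and_is_reproducible(self):
        m = build_coupled_model(Atot=1.0, kin1=0.1, kin2=0.1)
        proc = InfluxNoiseProcess(tau=20.0, mean_kin=0.1, seed=21)
        t1 = simulate_with_influx_noise(m, proc, (0.0, 300.0), n_points=300)
        t2 = simulate_with_influx_noise(m, proc, (0.0, 300.0), n_points=300)
        assert t1.events == t2.events
        assert len(t1.events) > 0
        np.testing.assert_array_equal(t1.states, t2.states)

    def test_invalid_tau_rejected(self):
        with pytest.raises(ValueError):
            InfluxNoiseProcess(tau=0.0)


class TestDivergenceReport:
    def test_below_threshold_is_steady(self, ref_single_model):
        traj = integrate(ref_single_model, (0.0, 2000.0), n_points=300)
        rep = detect_divergence(traj)
        assert rep.classification == "steady"
        assert rep.diverging_species == ()

    def test_above_threshold_flags_m0(self, ref_single_model):
        thr = feasibility_thresholds(ref_single_model)
        m = ref_single_model.with_influx(0, 1.2 * thr.T_binding)
        traj = integrate(m, (0.0, 5000.0), n_points=300)
        rep = detect_divergence(traj)
        assert rep.classification == "diverging"
        assert rep.diverging_species == ("M0",)

    def test_linear_pathway_diverging_set_is_upstream_of_first_cycling(self):
        """In a reversible chain with cycling consumed at step 3, everything
        upstream of that reaction (M0, M1, M2) accumulates above threshold:
        the blocked step backs the chain up through the reversible steps."""
        enz_rev = EnzymeParams(kcat=100.0, Etot=0.01, KM_f=0.05,
                               reversible=True, kcat_r=100.0, KM_r=0.05)
        m = build_linear_pathway_model(4, [(3, 4, "A", 1)], enzymes=enz_rev,
                                       pools=[PoolSpec("A", 0.2)],
                                       kin=1.18, kout=0.1)
        traj = integrate(m, (0.0, 20000.0), n_points=400)
        rep = detect_divergence(traj)
        assert rep.classification == "diverging"
        assert rep.diverging_species == ("M0", "M1", "M2")


class TestTrajectoryStatistics:
    def test_correlation_of_identical_and_mirrored_series(self,
                                                          ref_single_model):
        traj = integrate(ref_single_model, (0.0, 500.0), n_points=300)
        assert output_correlation(traj, "M0", "M0") == pytest.approx(1.0)

    def test_constant_series_gives_undefined_flag(self, ref_single_model):
        m = ref_single_model.with_influx(0, 0.0)
        traj = integrate(m, (0.0, 500.0), n_points=300)
        assert output_correlation(traj, "M0", "M1") is None

    def test_anticorrelated_outputs_reach_minus_one(self):
        # large pool: each output tracks its own (anti-correlated) influx
        m = build_coupled_model(Atot=50.0, kin1=0.1, kin2=0.1)
        proc = InfluxNoiseProcess(tau=5.0, mean_kin=0.1, seed=17)
        traj = simulate_with_influx_noise(m, proc, (0.0, 1500.0), n_points=1500)
        assert output_correlation(traj, "M1_1", "M1_2") < -0.9

    def test_branch_flux_ratio_symmetry_and_reciprocity(self):
        m_sym = build_branched_model(Atot=1.0, Btot=1.0, kin=0.5)
        res = numeric_steady_state(m_sym, t_max=2e5)
        assert branch_flux_ratio(m_sym, res) == pytest.approx(1.0, rel=1e-8)
        m_ab = build_branched_model(Atot=4.0, Btot=1.0, kin=0.5)
        m_ba = build_branched_model(Atot=1.0, Btot=4.0, kin=0.5)
        r_ab = branch_flux_ratio(m_ab, numeric_steady_state(m_ab, t_max=2e5))
        r_ba = branch_flux_ratio(m_ba, numeric_steady_state(m_ba, t_max=2e5))
        assert r_ab * r_ba == pytest.approx(1.0, rel=1e-6)

    def test_pool_ratio_starts_at_initial_split(self, ref_single_model):
        traj = integrate(ref_single_model, (0.0, 100.0), n_points=50)
        ratio = pool_ratio_series(traj, "A")
        assert ratio[0] == pytest.approx(1.0)

    def test_pool_ratio_converges_to_analytic_split(self, ref_single_model):
        a0, a1 = cosubstrate_steady_fractions(ref_single_model, 0.5)
        traj = integrate(ref_single_model, (0.0, 2000.0), n_points=300)
        ratio = pool_ratio_series(traj, "A")
        assert ratio[-1] == pytest.approx(a0 / a1, rel=1e-6)
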