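"""Motif construction, right-hand-side fidelity, conservation, validation."""
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cosubflux import (BoundarySpec, ConfigError, EnzymeParams, MotifModel,
                       PoolCoupling, PoolSpec, ReactionSpec,
                       build_branched_model, build_coupled_model,
                       build_linear_pathway_model, build_single_reaction_model,
                       integrate, model_rhs, validate_model)

ENZ = EnzymeParams(kcat=100.0, Etot=0.01, KM_f=0.05)


def _eq4_rhs(y, kin=0.5, kout=0.1, V0=1.0, K0=0.05, Va=1.2, Ka=0.05):
    """Hand-coded four-equation ODE system of the single-reaction motif."""
    m0, m1, a0, a1 = y
    r0 = V0 * a0 * m0 / (K0 + a0 * m0)
    ra = Va * a1 / (Ka + a1)
    return np.array([kin - r0, r0 - kout * m1, ra - r0, r0 - ra])


class TestSingleReaction:
    def test_vmax_values_from_reference_parameters(self, ref_single_model):
        prim, bg = ref_single_model.reactions
        assert prim.enzyme.Vmax == pytest.approx(1.0)
        assert bg.enzyme.Vmax == pytest.approx(1.2)

    def test_rhs_matches_four_equation_system_termwise(self, ref_single_model):
        rng = np.random.default_rng(0)
        for _ in range(20):
            y = rng.uniform(0.0, 5.0, size=4)
            np.testing.assert_allclose(model_rhs(ref_single_model, y),
                                       _eq4_rhs(y), rtol=1e-14, atol=1e-14)

    def test_influx_only_term_at_empty_state(self, ref_single_model):
        dy = model_rhs(ref_single_model, np.zeros(4))
        assert dy[0] == 0.5          # dm0/dt = kin exactly
        assert np.all(dy[1:] == 0.0)

    @given(y=st.lists(st.floats(min_value=0, max_value=10), min_size=4, max_size=4))
    @settings(max_examples=50, derandomize=True)
    def test_pool_form_derivatives_cancel(self, y):
        m = build_single_reaction_model(
            enzyme_primary=ENZ,
            enzyme_background=EnzymeParams(kcat=100.0, Etot=0.012, KM_f=0.05),
            pool=PoolSpec("A", 1.0), kin=0.5, kout=0.1)
        dy = model_rhs(m, np.array(y))
        assert dy[2] + dy[3] == pytest.approx(0.0, abs=1e-15)

    def test_dimension_mismatch_rejected(self, ref_single_model):
        with pytest.raises(ValueError):
            model_rhs(ref_single_model, np.zeros(5))


class TestPoolSynthesisDegradation:
    def test_pool_total_relaxes_to_synthesis_degradation_balance(self):
        """With synthesis/degradation the pool total follows the linear
        closed form (ksyn0+ksyn1)/kdeg*(1-exp(-kdeg t)) + tot0*exp(-kdeg t)."""
        ksyn0, ksyn1, kdeg = 2e-4, 1e-4, 1e-3
        pool = PoolSpec("A", 1.0, ksyn0=ksyn0, ksyn1=ksyn1, kdeg=kdeg)
        m = build_single_reaction_model(
            enzyme_primary=ENZ,
            enzyme_background=EnzymeParams(kcat=100.0, Etot=0.012, KM_f=0.05),
            pool=pool, kin=0.05, kout=0.1)
        traj = integrate(m, (0.0, 3000.0), n_points=200)
        total = traj.species("A0") + traj.species("A1")
        expected = (ksyn0 + ksyn1) / kdeg * (1 - np.exp(-kdeg * traj.times)) \
            + 1.0 * np.exp(-kdeg * traj.times)
        np.testing.assert_allclose(total, expected, rtol=1e-6)

    def test_synthesis_without_degradation_rejected(self):
        with pytest.raises(ConfigError):
            PoolSpec("A", 1.0, ksyn0=0.1)


class TestLinearPathway:
    def test_n4_intra_pathway_cycling_builds_seven_species(self):
        m = build_linear_pathway_model(4, [(2, 4, "A", 1)], enzymes=ENZ,
                                       pools=[PoolSpec("A", 1.0)],
                                       kin=0.1, kout=0.1)
        assert m.n_species == 7
        assert validate_model(m) == []
        assert m.metadata["first_cycling_step"] == 2

    def test_unbalanced_cycling_is_config_error(self):
        with pytest.raises(ConfigError, match="not conserved"):
            build_linear_pathway_model(4, [(2, None, "A", 1)], enzymes=ENZ,
                                       pools=[PoolSpec("A", 1.0)],
                                       kin=0.1, kout=0.1)

    def test_two_pool_totals_conserved_under_integration(self):
        m = build_linear_pathway_model(
            4, [(1, 3, "A", 1), (2, 4, "B", 1)], enzymes=ENZ,
            pools=[PoolSpec("A", 1.0), PoolSpec("B", 0.5)], kin=0.1, kout=0.1)
        traj = integrate(m, (0.0, 2000.0), n_points=200)
        for pid, tot in (("A", 1.0), ("B", 0.5)):
            i0 = m.pool_index(pid)
            drift = np.abs(traj.states[i0] + traj.states[i0 + 1] - tot) / tot
            assert drift.max() < 1e-9

    def test_nu_two_consumes_pool_quadratically(self):
        m = build_linear_pathway_model(2, [(1, 2, "A", 2)], enzymes=ENZ,
                                       pools=[PoolSpec("A", 1.0)],
                                       kin=0.05, kout=0.1)
        y = m.initial_state()
        y[:3] = [0.2, 0.1, 0.0]
        # consuming step sees a0^2 * m0 as its composite substrate
        a0, m0 = y[3], y[0]
        s = a0 * a0 * m0
        assert m.reaction_rate(m.reactions[0], y) == pytest.approx(
            ENZ.Vmax * s / (ENZ.KM_f + s))
        dy = model_rhs(m, y)
        assert dy[3] + dy[4] == pytest.approx(0.0, abs=1e-15)

    def test_single_step_with_background_reduces_to_single_motif(self,
                                                                 ref_single_model):
        ea = EnzymeParams(kcat=100.0, Etot=0.012, KM_f=0.05)
        m = build_linear_pathway_model(
            1, [(1, None, "A", 1)], enzymes=ENZ, pools=[PoolSpec("A", 1.0)],
            kin=0.5, kout=0.1, background_turnover={"A": ea})
        rng = np.random.default_rng(1)
        for _ in range(10):
            y = rng.uniform(0, 3, size=4)
            np.testing.assert_allclose(model_rhs(m, y),
                                       model_rhs(ref_single_model, y),
                                       rtol=1e-14, atol=1e-15)


class TestBranchedAndCoupled:
    def test_branched_model_structure(self):
        m = build_branched_model(Atot=1.0, Btot=2.0, kin=0.5)
        assert m.n_species == 9
        assert validate_model(m) == []
        assert len(m.boundary.outfluxes) == 2

    def test_branched_pool_swap_mirrors_trajectories(self):
        """Relabeling the two pools swaps the branch trajectories exactly."""
        m_ab = build_branched_model(Atot=4.0, Btot=1.0, kin=0.5)
        m_ba = build_branched_model(Atot=1.0, Btot=4.0, kin=0.5)
        t_ab = integrate(m_ab, (0.0, 200.0), n_points=100)
        t_ba = integrate(m_ba, (0.0, 200.0), n_points=100)
        # M1_1/M2_1 of one run match M1_2/M2_2 of the mirrored run
        np.testing.assert_allclose(t_ab.species("M1_1"), t_ba.species("M1_2"),
                                   rtol=1e-7, atol=1e-10)
        np.testing.assert_allclose(t_ab.species("M2_1"), t_ba.species("M2_2"),
                                   rtol=1e-7, atol=1e-10)

    def test_coupled_symmetric_influx_keeps_pathways_identical(self):
        m = build_coupled_model(Atot=1.0, kin1=0.1, kin2=0.1)
        traj = integrate(m, (0.0, 300.0), n_points=100)
        np.testing.assert_allclose(traj.species("M1_1"), traj.species("M1_2"),
                                   rtol=1e-8, atol=1e-12)

    def test_negative_pool_size_rejected(self):
        with pytest.raises(ConfigError):
            build_branched_model(Atot=-1.0, Btot=1.0, kin=0.5)


class TestValidateModel:
    def test_reference_model_is_clean(self, ref_single_model):
        assert validate_model(ref_single_model) == []

    def test_consume_only_coupling_reported_as_pool_not_conserved(self):
        m = MotifModel(
            2, (PoolSpec("A", 1.0),),
            (ReactionSpec(0, 1, ENZ, (PoolCoupling("A", +1),)),),
            BoundarySpec(((0, 0.1),), ((1, 0.1),)))
        assert any("pool not conserved" in v for v in validate_model(m))

    def test_zero_outflux_reported(self, ref_single_model):
        from dataclasses import replace
        m = replace(ref_single_model,
                    boundary=BoundarySpec(((0, 0.5),), ((1, 0.0),)))
        assert any("no outflux" in v for v in validate_model(m))

    def test_unreachable_outflux_reported(self):
        ea = EnzymeParams(kcat=100.0, Etot=0.012, KM_f=0.05)
        m = MotifModel(
            3, (PoolSpec("A", 1.0),),
            (ReactionSpec(0, 1, ENZ, (PoolCoupling("A", +1),)),
             ReactionSpec(None, None, ea, (PoolCoupling("A", -1),))),
            BoundarySpec(((0, 0.1),), ((2, 0.1),)))
        assert any("unreachable" in v for v in validate_model(m))
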