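"""Integrator correctness against closed forms, plus protocol behavior."""

import math

import numpy as np
import pytest

from abagrn import (
    ModelDefinition,
    ParameterTable,
    ReactionSpec,
    SpeciesDecl,
    RD29A_MRNA,
    build_model,
    equilibrate,
    run_aba_protocol,
    simulate,
)
from abagrn.network import CORE_PROTEINS, ParamEntry, pool_concentration


def _pair_model(kf=3600.0, kr=3600.0, a0=0.1, b0=0.1):
    """Isolated reversible binding A + B <-> C, no turnover."""
    params = ParameterTable({"kf": ParamEntry(kf, "1/(uM*h)"),
                             "kr": ParamEntry(kr, "1/h")})
    species = (SpeciesDecl("A", "protein", initial_concentration=a0),
               SpeciesDecl("B", "protein", initial_concentration=b0),
               SpeciesDecl("C", "protein_complex"))
    rxn = ReactionSpec("bind", (("A", 1), ("B", 1)), (("C", 1),),
                       "reversible_binding", "kf", "kr")
    return ModelDefinition(species, (rxn,), params)


class TestClosedFormOracles:
    @pytest.mark.parametrize("kf,kr", [(3600.0, 3600.0), (3.6e6, 7200.0)])
    def test_reversible_binding_equilibrium(self, kf, kr):
        """Long integration reproduces the quadratic binding equilibrium."""
        a0 = b0 = 0.1
        kd = kr / kf
        s = a0 + b0
        c_eq = ((s + kd) - math.sqrt((s + kd) ** 2 - 4 * a0 * b0)) / 2
        m = _pair_model(kf, kr, a0, b0)
        traj = simulate(m, m.initial_state(), np.linspace(0, 50.0, 11))
        assert traj["C"][-1] == pytest.approx(c_eq, rel=1e-6)
        # detailed balance: [C]/([A][B]) = kf/kr
        ratio = traj["C"][-1] / (traj["A"][-1] * traj["B"][-1])
        assert ratio == pytest.approx(kf / kr, rel=1e-6)

    def test_pure_exponential_decay(self):
        """Birth-death oracle: half-life of a 0.05/h decay is ln2/0.05 h."""
        params = ParameterTable({"kd": ParamEntry(0.05, "1/h")})
        m = ModelDefinition(
            (SpeciesDecl("X", "protein", initial_concentration=1.0),),
            (ReactionSpec("decay", (("X", 1),), (), "degradation", "kd"),),
            params)
        t_half = math.log(2) / 0.05  # 13.8629 h
        traj = simulate(m, m.initial_state(), np.array([0.0, t_half]))
        assert traj["X"][-1] == pytest.approx(0.5, rel=1e-6)

    def test_clamped_species_column_constant(self):
        m = _pair_model()
        traj = simulate(m, m.initial_state(), np.linspace(0, 10, 5),
                        clamps={"A": 0.25})
        assert np.all(traj["A"] == 0.25)


class TestEquilibrate:
    def test_zero_duration_returns_initial_state(self, model):
        eq = equilibrate(model, duration=0.0)
        assert np.array_equal(eq.state, model.initial_state())

    def test_feedback_off_core_protein_pools_near_design_value(self, nofb_eq, model):
        """Constitutive expression alone holds each protein pool at ~0.1 uM.

        DREB2A is the designed exception: its proteasomal proteolysis keeps
        it well below the 0.1 uM baseline even without ABA.
        """
        for protein in ("PYR", "PP2C", "SnRK2", "ABF", "MAP3K", "PROT26S"):
            pool = pool_concentration(model, nofb_eq.state, protein)
            assert pool == pytest.approx(0.1, rel=0.02), protein
        # free PYR: nothing binds it at ABA = 0
        assert nofb_eq.state[model.species_index("PYR")] == pytest.approx(
            0.1, rel=0.02)

    def test_dreb2a_held_below_baseline_by_proteolysis(self, nofb_eq, model):
        dreb = pool_concentration(model, nofb_eq.state, "DREB2A")
        assert dreb < 0.05  # far under the 0.1 uM constitutive design level

    def test_quasi_steady_state_diagnostic_small(self, nofb_eq):
        assert nofb_eq.max_relative_derivative < 1e-3


class TestAbaProtocol:
    def test_zero_dose_trace_is_flat(self, model, pre_state):
        traj = run_aba_protocol(model, 0.0, post_duration=48.0,
                                pre_state=pre_state)
        y = traj[RD29A_MRNA]
        assert y.max() <= y[0] * 1.05 + 1e-12

    def test_100uM_response_is_transient_within_24h(self, wt_traj):
        y = wt_traj[RD29A_MRNA]
        i = int(np.argmax(y))
        assert 0 < wt_traj.times[i] < 24.0
        assert wt_traj.at_time(RD29A_MRNA, 24.0) < 0.8 * y[i]

    def test_no_transcription_channel_means_no_message(self, model, pre_state):
        silent = model.with_parameters({"kf27": 0.0})
        traj = run_aba_protocol(silent, 100.0, post_duration=48.0)
        assert traj[RD29A_MRNA].max() == 0.0

    def test_negative_dose_rejected(self, model):
        with pytest.raises(ValueError):
            run_aba_protocol(model, -1.0)

    def test_tolerance_robustness_of_peak(self, model, pre_state, wt_traj):
        """Halving rtol/atol moves the RD29A peak by far less than 0.1%."""
        tight = run_aba_protocol(model, 100.0, pre_state=None,
                                 rtol=5e-9, atol=5e-13)
        p0 = wt_traj[RD29A_MRNA].max()
        assert abs(tight[RD29A_MRNA].max() - p0) / p0 < 1e-3

    def test_protocol_idempotence_longer_equilibration(self, model, wt_traj):
        """600 h of pre-equilibration changes the peak by < 1%."""
        long_pre = run_aba_protocol(model, 100.0, pre_duration=600.0)
        p0 = wt_traj[RD29A_MRNA].max()
        assert abs(long_pre[RD29A_MRNA].max() - p0) / p0 < 0.01


def test_trajectory_csv_round_trip(tmp_path, model, pre_state):
    traj = run_aba_protocol(model, 10.0, post_duration=30.0,
                            pre_state=pre_state)
    path = tmp_path / "traj.csv"
    traj.to_csv(path)
    from abagrn import Trajectory

    back = Trajectory.from_csv(path)
    assert back.dose == 10.0
    assert np.allclose(back.states, traj.states)
    assert back.species == traj.species
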