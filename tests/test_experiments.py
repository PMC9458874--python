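"""Peak metrics, genetics operations, fold changes and sensitivity plumbing."""

import numpy as np
import pytest

from abagrn import (
    RD29A_MRNA,
    Trajectory,
    feedback_ablation,
    fold_change,
    knockout,
    local_sensitivity,
    peak_metrics,
    run_aba_protocol,
    transient_score,
)


def _traj(times, y, species="X"):
    return Trajectory(times=np.asarray(times, float),
                      states=np.asarray(y, float)[:, None],
                      species=(species,))


class TestPeakMetrics:
    def test_constant_trace(self):
        t = np.linspace(0, 30, 61)
        pk = peak_metrics(_traj(t, np.full_like(t, 2.5)), "X")
        assert pk.peak_value == 2.5
        assert pk.decline_ratio == 1.0

    def test_synthetic_pulse_peaks_at_five_hours(self):
        """Calculus oracle: A*(t/5)*exp(1-t/5) has its maximum A at t=5."""
        t = np.arange(0, 30.001, 0.01)
        amp = 3.7
        y = amp * (t / 5) * np.exp(1 - t / 5)
        pk = peak_metrics(_traj(t, y), "X")
        assert pk.peak_time == pytest.approx(5.0, abs=0.011)
        assert pk.peak_value == pytest.approx(amp, rel=1e-4)
        assert pk.value_at_5h >= pk.value_at_24h

    def test_unknown_species_rejected(self, wt_traj):
        with pytest.raises(KeyError):
            peak_metrics(wt_traj, "NOT_A_SPECIES")

    def test_wild_type_peak_order_of_magnitude(self, wt_traj):
        pk = peak_metrics(wt_traj, RD29A_MRNA)
        assert 1e-5 < pk.peak_value < 1e-3  # ~1e-4 uM scale


class TestFoldChange:
    def test_identical_trajectories(self, wt_traj):
        assert fold_change(wt_traj, wt_traj) == 1.0

    def test_scaled_trajectory(self, wt_traj):
        scaled = Trajectory(times=wt_traj.times, states=3 * wt_traj.states,
                            species=wt_traj.species, dose=wt_traj.dose)
        assert fold_change(scaled, wt_traj) == pytest.approx(3.0)

    def test_zero_reference_rejected(self, wt_traj):
        zero = Trajectory(times=wt_traj.times,
                          states=np.zeros_like(wt_traj.states),
                          species=wt_traj.species)
        with pytest.raises(ZeroDivisionError):
            fold_change(wt_traj, zero)


class TestGeneticOperations:
    def test_knockout_disables_expected_channels(self, model):
        ko = knockout(model, "ABF")
        assert "translate_ABF_const" in ko.disabled_reactions
        assert "translate_ABF_fb" in ko.disabled_reactions
        ko = knockout(model, "PYR")  # no feedback channel to silence
        assert ko.disabled_reactions == {"translate_PYR_const"}

    def test_knockout_leaves_original_untouched(self, model):
        knockout(model, "SnRK2")
        assert not model.disabled_reactions

    def test_unknown_target_rejected(self, model):
        with pytest.raises(KeyError):
            knockout(model, "DREB2A")  # not in the validated mutant set

    def test_feedback_ablation_targets_only_abre_channel(self, model):
        abl = feedback_ablation(model, "PP2C")
        assert abl.disabled_reactions == {"transcribe_PP2C_fb"}
        with pytest.raises(KeyError):
            feedback_ablation(model, "PYR")


class TestLocalSensitivity:
    def test_disconnected_parameter_has_zero_index(self, model):
        """A rate constant no reaction references cannot move the output."""
        table = local_sensitivity(model, ["kf49", "kr10"])
        by_name = table.set_index("parameter")["sensitivity_index"]
        assert by_name["kf49"] == 0.0
        assert by_name["kr10"] > 0.0

    def test_nonpositive_perturbation_rejected(self, model):
        with pytest.raises(ValueError):
            local_sensitivity(model, ["kr10"], perturbation=0.0)

    def test_ranks_are_a_permutation(self, model):
        table = local_sensitivity(model, ["kr10", "kr14", "kr16"])
        assert sorted(table["rank"]) == [1, 2, 3]

    def test_finite_difference_convergence(self, model):
        """Halving the perturbation changes the index by well under 5%."""
        a = local_sensitivity(model, ["kr7"], perturbation=0.01)
        b = local_sensitivity(model, ["kr7"], perturbation=0.005)
        ia, ib = a["sensitivity_index"][0], b["sensitivity_index"][0]
        assert abs(ia - ib) / ib < 0.05


def test_weaker_dre_binding_lowers_but_keeps_transient(model, wt_traj):
    """DRE affinity shifts the RD29A level without destroying the pulse."""
    weak = model.with_parameters({
        "kr11": model.parameters.value("kr11") * 100,
        "kr13": model.parameters.value("kr13") * 100,
    })
    traj = run_aba_protocol(weak, 100.0)
    assert traj[RD29A_MRNA].max() < 0.5 * wt_traj[RD29A_MRNA].max()
    assert transient_score(traj).is_transient
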