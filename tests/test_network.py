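"""Unit tests for the reaction network: units, parameters, topology, RHS."""

import math

import numpy as np
import pytest

from abagrn import (
    FEEDBACK_GENES,
    ModelDefinition,
    ParameterTable,
    ReactionSpec,
    SpeciesDecl,
    build_model,
    build_parameter_table,
    mass_action_rhs,
    molecules_to_concentration,
)
from abagrn.network import ParamEntry

# independent oracle: 2 / (N_A * 50e-15 L), in uM
TWO_COPIES_UM = 2.0 / (6.02214076e23 * 50e-15) * 1e6  # ~6.642e-5


class TestMoleculesToConcentration:
    def test_two_copies_in_model_cell(self):
        assert molecules_to_concentration(2, 50) == pytest.approx(
            TWO_COPIES_UM, rel=1e-12)
        assert molecules_to_concentration(2, 50) == pytest.approx(
            6.64e-5, rel=1e-2)

    def test_zero_copies(self):
        assert molecules_to_concentration(0, 50) == 0.0

    def test_linearity_in_copies(self):
        assert molecules_to_concentration(1, 50) == pytest.approx(
            molecules_to_concentration(2, 50) / 2, rel=1e-12)

    @pytest.mark.parametrize("volume", [0.0, -1.0])
    def test_nonpositive_volume_rejected(self, volume):
        with pytest.raises(ValueError):
            molecules_to_concentration(2, volume)


class TestParameterTable:
    def test_curated_equilibrium_constants(self):
        """kr/kf ratios reproduce the curated affinities after unit conversion."""
        t = build_parameter_table()
        assert t.value("kr10") / t.value("kf10") == pytest.approx(0.002)   # 2 nM
        assert t.value("kr2") / t.value("kf2") == pytest.approx(1e-4)      # 100 pM
        assert t.value("kr3") / t.value("kf3") == pytest.approx(0.097)
        assert t.value("kr1") / t.value("kf1") == pytest.approx(69.0)

    def test_unit_conversion_to_hours(self):
        t = build_parameter_table()
        assert t.value("kf1") == pytest.approx(1000.0 * 3600)
        assert t.value("kf15") == pytest.approx(14.0 * 3600)
        assert t.value("kf29") == 1.0  # already per hour

    def test_only_expression_parameters_are_free(self):
        t = build_parameter_table()
        assert sorted(t.free_names) == ["kf26", "kf27", "kf28"]

    def test_override_changes_only_named_entry(self):
        base = build_parameter_table()
        new = build_parameter_table({"kf27": 0.0})
        assert new.value("kf27") == 0.0
        diffs = [n for n in base if base.value(n) != new.value(n)]
        assert diffs == ["kf27"]

    def test_unknown_override_rejected(self):
        with pytest.raises(KeyError):
            build_parameter_table({"kf99": 1.0})

    def test_negative_override_rejected(self):
        with pytest.raises(ValueError):
            build_parameter_table({"kf27": -1.0})

    def test_text_round_trip(self):
        t = build_parameter_table()
        back = ParameterTable.from_text(t.to_text())
        assert all(back.value(n) == t.value(n) and back[n].fixed == t[n].fixed
                   for n in t)


class TestBuildModel:
    def test_promoter_families_sum_to_locus_concentration(self, model):
        x0 = model.initial_state()
        names = model.species_names
        for gene in ("RD29A",) + FEEDBACK_GENES:
            total = sum(x0[names.index(s)] for s in model.promoter_states(gene))
            assert total == pytest.approx(TWO_COPIES_UM, rel=1e-12)

    def test_network_size_and_feedback_genes(self, model):
        assert len(model.species) >= 30
        fb = {r.name for r in model.reactions if r.forward_param == "kf26"}
        assert len(fb) == 3  # exactly PP2C, ABF, DREB2A carry ABRE feedback

    def test_all_initial_values_zero_except_gene_loci(self, model):
        for sp in model.species:
            if sp.role in ("gene_locus", "promoter_state"):
                continue
            assert sp.initial_concentration == 0.0

    def test_missing_parameter_rejected(self):
        table = build_parameter_table()
        crippled = ParameterTable(
            {n: table[n] for n in table if n != "kf26"})
        with pytest.raises(KeyError):
            build_model(crippled)


class TestMassActionRhs:
    def _tiny(self, reactions, species):
        params = ParameterTable({
            "k_syn": ParamEntry(1.0, "1/h"),
            "kb": ParamEntry(10.0, "1/(uM*h)"),
            "ku": ParamEntry(2.0, "1/h"),
        })
        return ModelDefinition(tuple(species), tuple(reactions), params)

    def test_zero_state_gives_zero_derivative(self):
        m = self._tiny(
            [ReactionSpec("bind", (("A", 1), ("B", 1)), (("C", 1),),
                          "reversible_binding", "kb", "ku")],
            [SpeciesDecl("A", "protein"), SpeciesDecl("B", "protein"),
             SpeciesDecl("C", "protein_complex")])
        assert np.all(mass_action_rhs(m, np.zeros(3)) == 0.0)

    def test_single_transcription_flux(self):
        locus = molecules_to_concentration(2, 50)
        m = self._tiny(
            [ReactionSpec("tx", (("G", 1),), (("G", 1), ("mRNA", 1)),
                          "synthesis", "k_syn")],
            [SpeciesDecl("G", "gene_locus", initial_concentration=locus),
             SpeciesDecl("mRNA", "mrna")])
        dx = mass_action_rhs(m, m.initial_state())
        assert dx[1] == pytest.approx(1.0 * locus)   # kf29-style: k * [G]
        assert dx[0] == 0.0                          # template is catalytic

    def test_clamped_species_has_zero_derivative(self, model):
        x = model.initial_state()
        x[model.species_index("ABA")] = 100.0
        x[model.species_index("PYR")] = 0.1
        dx = mass_action_rhs(model, x)
        assert dx[model.species_index("ABA")] == 0.0
        assert dx[model.species_index("PYR")] < 0  # consumed by binding

    def test_invalid_state_names_offender(self, model):
        x = model.initial_state()
        x[model.species_index("PP2C")] = np.nan
        with pytest.raises(ValueError, match="PP2C"):
            mass_action_rhs(model, x)


def test_gene_locus_conservation_along_trajectory(model, wt_traj):
    """Promoter-state families stay at the locus concentration throughout."""
    for gene in ("RD29A",) + FEEDBACK_GENES:
        total = sum(wt_traj[s] for s in model.promoter_states(gene))
        assert np.allclose(total, TWO_COPIES_UM, rtol=1e-6)


def test_trajectory_nonnegative(wt_traj):
    assert wt_traj.states.min() >= 0.0
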