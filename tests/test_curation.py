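"""Curation recipes: content, engine semantics, and the designed phenotypes
(C1 auxotrophy; serine-cycle growth on formaldehyde)."""

import random

import pytest

from c1flux.curation import (
    CurationEdit,
    apply_curation,
    base_curation_recipe,
    recipe_from_json,
    recipe_to_json,
    serine_cycle_recipe,
    write_edit_log,
)
from c1flux.errors import CurationError
from c1flux.medium import build_medium
from c1flux.model import Reaction
from c1flux.phase_plane import fba

#: the reaction stoichiometries the recipes must carry verbatim
QUOTED_STOICHIOMETRIES = {
    "THFSPONT": {"thf_c": -1, "fald_c": -1, "mlthf_c": 1, "h2o_c": 1},
    "EtMaCoA": {
        "b2coa_c": -1, "nadph_c": -1, "co2_c": -1, "q8_c": -1, "h2o_c": -1,
        "glx_c": 1, "ppcoa_c": 1, "nadp_c": 1, "q8h2_c": 1,
    },
    "MMCDr": {
        "ppcoa_c": -1, "atp_c": -1, "hco3_c": -1,
        "mmcoa__S_c": 1, "adp_c": 1, "h_c": 1, "pi_c": 1,
    },
    "SGAT1": {"ser__L_c": -1, "akg_c": -1, "glu__L_c": 1, "hpyr_c": 1},
    "SGAT2": {"gly_c": -1, "akg_c": -1, "glx_c": 1, "glu__L_c": 1},
    "MTK": {"mal__L_c": -1, "atp_c": -1, "coa_c": -1,
            "malylcoa_c": 1, "adp_c": 1, "pi_c": 1},
    "MCL": {"malylcoa_c": -1, "accoa_c": 1, "glx_c": 1},
}


class TestRecipeContent:
    def test_base_recipe_thfspont_stoichiometry(self):
        adds = [e for e in base_curation_recipe() if e.action == "add_reaction"]
        assert len(adds) == 1
        assert adds[0].reaction.stoichiometry == QUOTED_STOICHIOMETRIES["THFSPONT"]
        assert adds[0].reaction.lower_bound == 0  # irreversible: net rate

    def test_base_recipe_removes_5_and_knocks_out_2(self):
        recipe = base_curation_recipe()
        removed = {e.target for e in recipe if e.action == "remove_reaction"}
        knocked = {e.target for e in recipe if e.action == "knockout"}
        assert removed == {"POR5", "GLYCK", "PFL", "OBTFL", "FTHFLi"}
        assert knocked == {"GLYCL", "GHMT2r"}

    def test_base_recipe_directionality_edits(self):
        recipe = base_curation_recipe()
        irr = {e.target for e in recipe if e.action == "make_irreversible"}
        rev = {e.target for e in recipe if e.action == "make_reversible"}
        assert irr == {"FTHFD", "GARFT", "AICART"}
        assert rev == {"THYMt3pp"}

    def test_serine_recipe_removes_6_beyond_base(self):
        removed = {
            e.target for e in serine_cycle_recipe() if e.action == "remove_reaction"
        }
        assert removed == {"GLXCL", "GLYCL", "THRD", "THRA2", "THRA", "SERD_L"}

    def test_serine_recipe_mcl_stoichiometry(self):
        mcl = next(e for e in serine_cycle_recipe() if e.target == "MCL")
        assert mcl.reaction.stoichiometry == QUOTED_STOICHIOMETRIES["MCL"]

    def test_all_quoted_stoichiometries_present_after_both_recipes(
        self, serine_model
    ):
        for rid, stoich in QUOTED_STOICHIOMETRIES.items():
            assert serine_model.reactions[rid].stoichiometry == pytest.approx(stoich)
        # FDH (assumed stoichiometry) and the proton-corrected THD2pp
        assert serine_model.reactions["FDH"].stoichiometry == {
            "for_c": -1, "nad_c": -1, "co2_c": 1, "nadh_c": 1
        }
        assert serine_model.reactions["THD2pp"].stoichiometry["h_p"] == -1
        assert serine_model.reactions["THD2pp"].stoichiometry["h_c"] == 1


class TestEngine:
    def test_returns_new_model_original_untouched(self, core_model):
        n = len(core_model.reactions)
        curated = apply_curation(core_model, base_curation_recipe())
        assert len(core_model.reactions) == n
        assert "THFSPONT" not in core_model.reactions
        assert "THFSPONT" in curated.reactions
        assert len(curated.edit_log) == len(base_curation_recipe())

    def test_single_removal_shrinks_by_one(self, toy_factory):
        model, _ = toy_factory()
        out = apply_curation(
            model, [CurationEdit("remove_reaction", "PRESYN")]
        )
        assert len(out.reactions) == len(model.reactions) - 1

    def test_missing_target_names_edit_and_target(self, toy_factory):
        model, _ = toy_factory()
        with pytest.raises(CurationError, match="FOO"):
            apply_curation(model, [CurationEdit("remove_reaction", "FOO")])

    def test_duplicate_add_is_an_error(self, core_model):
        curated = apply_curation(core_model, base_curation_recipe())
        add = [e for e in base_curation_recipe() if e.action == "add_reaction"]
        with pytest.raises(CurationError, match="THFSPONT"):
            apply_curation(curated, add)

    def test_second_application_fails_cleanly(self, core_model):
        curated = apply_curation(core_model, base_curation_recipe())
        with pytest.raises(CurationError):
            apply_curation(curated, base_curation_recipe())

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_recipe_application_is_order_insensitive(self, core_model, seed):
        """Shuffled application of each shipped recipe yields the same model."""
        rng = random.Random(seed)
        base = base_curation_recipe()
        shuffled = base[:]
        rng.shuffle(shuffled)
        a = apply_curation(core_model, base)
        b = apply_curation(core_model, shuffled)
        assert a.reactions == b.reactions
        serine = serine_cycle_recipe()
        shuffled2 = serine[:]
        rng.shuffle(shuffled2)
        assert (
            apply_curation(a, serine).reactions
            == apply_curation(b, shuffled2).reactions
        )

    def test_untargeted_reactions_unchanged(self, core_model, base_curated):
        targets = {e.target for e in base_curation_recipe()}
        for rid, rxn in core_model.reactions.items():
            if rid in targets:
                continue
            assert base_curated.reactions[rid].stoichiometry == rxn.stoichiometry
            assert base_curated.reactions[rid].bounds == rxn.bounds

    def test_edit_log_tsv(self, base_curated, tmp_path):
        path = tmp_path / "log.tsv"
        write_edit_log(base_curated, str(path))
        lines = path.read_text().splitlines()
        assert lines[0].startswith("edit\taction\ttarget")
        assert len(lines) == 1 + len(base_curated.edit_log)

    def test_recipe_json_round_trip(self):
        for recipe in (base_curation_recipe(), serine_cycle_recipe()):
            back = recipe_from_json(recipe_to_json(recipe))
            assert [e.to_dict() for e in back] == [e.to_dict() for e in recipe]


class TestDesignedPhenotypes:
    def test_auxotroph_cannot_grow_without_condensation(self, base_curated):
        """Glucose + glycine + thymidine, no formaldehyde, THFSPONT blocked:
        the engineered strain has no route to 5,10-methylene-THF."""
        model = base_curated.copy()
        model.reactions["THFSPONT"].bounds = (0, 0)
        medium = build_medium(model, "thy")
        medium.uptake.pop("EX_fald_e", None)
        assert fba(model, medium).objective_value == pytest.approx(0, abs=1e-9)

    def test_formaldehyde_rescues_growth(self, base_curated):
        sol = fba(base_curated, build_medium(base_curated, "thy"))
        assert sol.status == "optimal" and sol.objective_value > 0.1

    def test_mlthf_only_producible_via_thfspont(self, base_curated):
        """A C1 sink (5,10-methylene-THF -> THF) can carry flux only while
        THFSPONT is open."""
        model = base_curated.copy()
        model.add_reaction(Reaction("C1SINK", {"mlthf_c": -1.0, "thf_c": 1.0}, 0, 1000))
        model.objective_reaction_id = "C1SINK"
        medium = build_medium(model, "thy")
        assert fba(model, medium).objective_value > 1
        model.reactions["THFSPONT"].bounds = (0, 0)
        assert fba(model, medium).objective_value == pytest.approx(0, abs=1e-9)

    def test_serine_cycle_grows_on_formaldehyde_only(self, serine_model):
        sol = fba(serine_model, build_medium(serine_model, "formaldehyde_only"))
        assert sol.status == "optimal" and sol.objective_value > 0.01

    def test_no_growth_without_malyl_coa_lyase(self, serine_model):
        model = serine_model.copy()
        model.reactions["MCL"].bounds = (0, 0)
        sol = fba(model, build_medium(model, "formaldehyde_only"))
        assert sol.objective_value == pytest.approx(0, abs=1e-9)

    def test_no_growth_on_co2_alone(self, serine_model):
        medium = build_medium(serine_model, "formaldehyde_only")
        medium.uptake.pop("EX_fald_e")
        assert fba(serine_model, medium).objective_value == pytest.approx(0, abs=1e-9)
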