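"""Declarative model curation: ordered edit lists and an engine to apply them.

Two recipes are shipped. ``base_curation_recipe`` turns the *E. coli*
genome-scale network into the engineered C1 auxotroph: both native routes to
5,10-methylene-THF (GlyA / SHMT and the glycine cleavage system) are knocked
out, routes that could charge THF with formate or bypass the deletion are
removed or made irreversible, and the spontaneous formaldehyde + THF
condensation (THFSPONT) becomes the sole 5,10-methylene-THF source.
``serine_cycle_recipe`` then builds the hypothetical formaldehyde-assimilating
organism: serine cycle plus ethylmalonyl-CoA cycle reactions are added and
potential carbon-fixation shortcuts removed.

Edits are order-independent for both shipped recipes (their targets are
disjoint except where an edit explicitly depends on a previous add, which
neither recipe does), and strictly validated: a missing remove/modify target
or a duplicate add raises :class:`CurationError` naming the edit.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

from .errors import CurationError
from .model import BIG, Reaction, StoichiometricModel

__all__ = [
    "CurationEdit",
    "apply_curation",
    "base_curation_recipe",
    "serine_cycle_recipe",
    "recipe_to_json",
    "recipe_from_json",
    "write_edit_log",
]

ACTIONS = (
    "remove_reaction",
    "add_reaction",
    "set_bounds",
    "make_irreversible",
    "make_reversible",
    "replace_stoichiometry",
    "knockout",
)


@dataclass
class CurationEdit:
    """One declarative model edit.

    ``target`` is a reaction id for everything except ``add_reaction``, which
    carries the full :class:`Reaction` payload. ``coefficients`` holds the
    stoichiometry overrides for ``replace_stoichiometry`` (metabolites not
    listed are preserved; a 0 coefficient drops the metabolite).
    """

    action: str
    target: str = ""
    reaction: Reaction | None = None
    bounds: tuple[float, float] | None = None
    coefficients: dict[str, float] | None = None
    note: str = ""

    def __post_init__(self) -> None:
        if self.action not in ACTIONS:
            raise ValueError(f"unknown curation action '{self.action}'")
        if self.action == "add_reaction":
            if self.reaction is None:
                raise ValueError("add_reaction requires a Reaction payload")
            self.target = self.reaction.id
        elif not self.target:
            raise ValueError(f"action '{self.action}' requires a target reaction id")
        if self.action == "set_bounds" and self.bounds is None:
            raise ValueError("set_bounds requires a bounds payload")
        if self.action == "replace_stoichiometry" and not self.coefficients:
            raise ValueError("replace_stoichiometry requires coefficient overrides")

    # -- JSON round trip (recipes as config files) ------------------------
    def to_dict(self) -> dict:
        d: dict = {"action": self.action, "target": self.target}
        if self.reaction is not None:
            d["reaction"] = {
                "id": self.reaction.id,
                "stoichiometry": self.reaction.stoichiometry,
                "lower_bound": self.reaction.lower_bound,
                "upper_bound": self.reaction.upper_bound,
                "name": self.reaction.name,
            }
        if self.bounds is not None:
            d["bounds"] = list(self.bounds)
        if self.coefficients is not None:
            d["coefficients"] = self.coefficients
        if self.note:
            d["note"] = self.note
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "CurationEdit":
        rxn = None
        if "reaction" in d:
            r = d["reaction"]
            rxn = Reaction(
                id=r["id"],
                stoichiometry={k: float(v) for k, v in r["stoichiometry"].items()},
                lower_bound=float(r.get("lower_bound", 0.0)),
                upper_bound=float(r.get("upper_bound", BIG)),
                name=r.get("name", ""),
            )
        bounds = tuple(d["bounds"]) if "bounds" in d else None
        return cls(
            action=d["action"],
            target=d.get("target", ""),
            reaction=rxn,
            bounds=bounds,
            coefficients=d.get("coefficients"),
            note=d.get("note", ""),
        )


def recipe_to_json(recipe: list[CurationEdit]) -> str:
    return json.dumps([e.to_dict() for e in recipe], indent=2)


def recipe_from_json(text: str) -> list[CurationEdit]:
    return [CurationEdit.from_dict(d) for d in json.loads(text)]


# -- engine ----------------------------------------------------------------

def _require(model: StoichiometricModel, edit_idx: int, edit: CurationEdit) -> Reaction:
    rxn = model.reactions.get(edit.target)
    if rxn is None:
        raise CurationError(
            f"edit #{edit_idx} ({edit.action}): reaction '{edit.target}' "
            f"not present in model '{model.id}'"
        )
    return rxn


def apply_curation(
    model: StoichiometricModel, recipe: list[CurationEdit]
) -> StoichiometricModel:
    """Apply an edit list to a copy of ``model``; the original is untouched.

    Every applied edit is appended to the returned model's ``edit_log``
    (index, action, target, before, after) for provenance. Applying a recipe
    a second time fails cleanly per edit (removes/adds are not idempotent by
    design: a silent no-op would hide a wrong model state).
    """
    out = model.copy()
    for i, edit in enumerate(recipe):
        before: object = None
        after: object = None
        if edit.action == "remove_reaction":
            rxn = _require(out, i, edit)
            before = _rxn_repr(rxn)
            out.remove_reaction(edit.target)
        elif edit.action == "add_reaction":
            assert edit.reaction is not None
            if edit.reaction.id in out.reactions:
                raise CurationError(
                    f"edit #{i} (add_reaction): reaction '{edit.reaction.id}' "
                    f"already present in model '{out.id}'"
                )
            out.add_reaction(edit.reaction.copy(), create_missing=True)
            after = _rxn_repr(edit.reaction)
        elif edit.action == "set_bounds":
            rxn = _require(out, i, edit)
            before = rxn.bounds
            assert edit.bounds is not None
            rxn.bounds = edit.bounds
            after = rxn.bounds
        elif edit.action == "make_irreversible":
            rxn = _require(out, i, edit)
            before = rxn.bounds
            rxn.lower_bound = max(rxn.lower_bound, 0.0)
            after = rxn.bounds
        elif edit.action == "make_reversible":
            rxn = _require(out, i, edit)
            before = rxn.bounds
            rxn.lower_bound = min(rxn.lower_bound, -BIG)
            after = rxn.bounds
        elif edit.action == "replace_stoichiometry":
            rxn = _require(out, i, edit)
            before = dict(rxn.stoichiometry)
            assert edit.coefficients is not None
            missing = [m for m in edit.coefficients if m not in rxn.stoichiometry]
            if missing:
                raise CurationError(
                    f"edit #{i} (replace_stoichiometry): '{edit.target}' has no "
                    f"metabolite(s) {missing} to replace"
                )
            for met_id, coef in edit.coefficients.items():
                if coef == 0:
                    del rxn.stoichiometry[met_id]
                else:
                    rxn.stoichiometry[met_id] = float(coef)
            after = dict(rxn.stoichiometry)
        elif edit.action == "knockout":
            rxn = _require(out, i, edit)
            before = rxn.bounds
            rxn.bounds = (0.0, 0.0)
            after = rxn.bounds
        out.edit_log.append(
            {
                "index": i,
                "action": edit.action,
                "target": edit.target,
                "before": before,
                "after": after,
                "note": edit.note,
            }
        )
    out.validate()
    return out


def write_edit_log(model: StoichiometricModel, path: str) -> None:
    """Emit the provenance log as TSV (edit#, action, target, before, after)."""
    with open(path, "w") as fh:
        fh.write("edit\taction\ttarget\tbefore\tafter\tnote\n")
        for rec in model.edit_log:
            fh.write(
                f"{rec['index']}\t{rec['action']}\t{rec['target']}\t"
                f"{rec['before']}\t{rec['after']}\t{rec['note']}\n"
            )


def _rxn_repr(rxn: Reaction) -> dict:
    return {"stoichiometry": dict(rxn.stoichiometry), "bounds": rxn.bounds}


# -- shipped recipes -------------------------------------------------------

#: the spontaneous formaldehyde + THF condensation, written irreversible;
#: the flux derived against it is a net rate (condensation minus
#: 5,10-methylene-THF dissociation), so no separate reverse reaction exists.
THFSPONT = Reaction(
    id="THFSPONT",
    stoichiometry={"thf_c": -1.0, "fald_c": -1.0, "mlthf_c": 1.0, "h2o_c": 1.0},
    lower_bound=0.0,
    upper_bound=BIG,
    name="spontaneous formaldehyde-THF condensation",
)


def base_curation_recipe() -> list[CurationEdit]:
    """Edits producing the C1-auxotroph model from the *E. coli*
    genome-scale network (iML1515 reaction ids).

    Removals: POR5 and GLYCK (not active in *E. coli* cells), PFL and OBTFL
    (oxygen-sensitive enzymes, inactive aerobically), FTHFLi (would charge
    THF directly with formate). THD2pp is rewritten to translocate one proton
    instead of two. FTHFD, GARFT and AICART become irreversible so nucleotide
    degradation cannot charge THF; THYMt3pp becomes reversible so thymidine
    can be taken up. GLYCL (glycine cleavage system) and GHMT2r (GlyA) are
    knocked out, and THFSPONT is added.
    """
    return [
        CurationEdit("remove_reaction", "POR5", note="not present in E. coli cells"),
        CurationEdit("remove_reaction", "GLYCK", note="not present in E. coli cells"),
        CurationEdit(
            "replace_stoichiometry",
            "THD2pp",
            coefficients={"h_p": -1.0, "h_c": 1.0},
            note="transhydrogenase translocates one proton, not two",
        ),
        CurationEdit("remove_reaction", "PFL", note="oxygen-sensitive enzyme"),
        CurationEdit("remove_reaction", "OBTFL", note="oxygen-sensitive enzyme"),
        CurationEdit(
            "remove_reaction", "FTHFLi", note="would charge THF with formate directly"
        ),
        CurationEdit("make_irreversible", "FTHFD", note="no nucleotide degradation to charge THF"),
        CurationEdit("make_irreversible", "GARFT", note="no nucleotide degradation to charge THF"),
        CurationEdit("make_irreversible", "AICART", note="no nucleotide degradation to charge THF"),
        CurationEdit(
            "make_reversible", "THYMt3pp", note="thymidine uptake rescues growth"
        ),
        CurationEdit("knockout", "GLYCL", note="glycine cleavage system deletion"),
        CurationEdit("knockout", "GHMT2r", note="glyA deletion"),
        CurationEdit("add_reaction", reaction=THFSPONT.copy()),
    ]


def serine_cycle_recipe() -> list[CurationEdit]:
    """Further edits enabling growth on formaldehyde as sole carbon source
    via the serine cycle + ethylmalonyl-CoA cycle; applied on top of
    :func:`base_curation_recipe`.

    GHMT2r (SHMT) is re-opened: glycine + 5,10-methylene-THF -> serine is the
    cycle's only organic-carbon entry point, so the hypothetical organism must
    carry it even though the auxotroph strain had it deleted. SGAT1 and SGAT2
    carry the stoichiometries as quoted for the model of record; SGAT2 is made
    reversible because the cycle runs it in the glyoxylate -> glycine
    direction. FDH stoichiometry (not printed anywhere) is the standard
    NAD-dependent formate dehydrogenase.
    """
    return [
        CurationEdit(
            "set_bounds",
            "GHMT2r",
            bounds=(-BIG, BIG),
            note="restore SHMT: sole organic-carbon entry of the serine cycle",
        ),
        CurationEdit("remove_reaction", "GLXCL", note="avoid carbon-fixation cycles"),
        CurationEdit("remove_reaction", "GLYCL", note="avoid carbon-fixation cycles"),
        CurationEdit("remove_reaction", "THRD", note="avoid carbon-fixation cycles"),
        CurationEdit("remove_reaction", "THRA2", note="avoid carbon-fixation cycles"),
        CurationEdit("remove_reaction", "THRA", note="avoid carbon-fixation cycles"),
        CurationEdit("remove_reaction", "SERD_L", note="avoid carbon-fixation cycles"),
        CurationEdit(
            "add_reaction",
            reaction=Reaction(
                id="FDH",
                stoichiometry={
                    "for_c": -1.0,
                    "nad_c": -1.0,
                    "co2_c": 1.0,
                    "nadh_c": 1.0,
                },
                lower_bound=0.0,
                name="NAD-dependent formate dehydrogenase (assumed stoichiometry)",
            ),
        ),
        CurationEdit(
            "add_reaction",
            reaction=Reaction(
                id="EtMaCoA",
                stoichiometry={
                    "b2coa_c": -1.0,
                    "nadph_c": -1.0,
                    "co2_c": -1.0,
                    "q8_c": -1.0,
                    "h2o_c": -1.0,
                    "glx_c": 1.0,
                    "ppcoa_c": 1.0,
                    "nadp_c": 1.0,
                    "q8h2_c": 1.0,
                },
                lower_bound=0.0,
                name="crotonyl-CoA carboxylase (ethylmalonyl-CoA cycle, lumped)",
            ),
        ),
        CurationEdit(
            "add_reaction",
            reaction=Reaction(
                id="MMCDr",
                stoichiometry={
                    "ppcoa_c": -1.0,
                    "atp_c": -1.0,
                    "hco3_c": -1.0,
                    "mmcoa__S_c": 1.0,
                    "adp_c": 1.0,
                    "h_c": 1.0,
                    "pi_c": 1.0,
                },
                lower_bound=0.0,
                name="propionyl-CoA carboxylase",
            ),
        ),
        CurationEdit("make_reversible", "MMM", note="recycle methylmalonyl-CoA"),
        CurationEdit(
            "add_reaction",
            reaction=Reaction(
                id="SGAT1",
                stoichiometry={
                    "ser__L_c": -1.0,
                    "akg_c": -1.0,
                    "glu__L_c": 1.0,
                    "hpyr_c": 1.0,
                },
                lower_bound=0.0,
                name="serine-hydroxypyruvate aminotransferase",
            ),
        ),
        CurationEdit(
            "add_reaction",
            reaction=Reaction(
                id="SGAT2",
                stoichiometry={
                    "gly_c": -1.0,
                    "akg_c": -1.0,
                    "glx_c": 1.0,
                    "glu__L_c": 1.0,
                },
                lower_bound=-BIG,
                name="glycine-glyoxylate aminotransferase (cycle uses reverse)",
            ),
        ),
        CurationEdit(
            "add_reaction",
            reaction=Reaction(
                id="MTK",
                stoichiometry={
                    "mal__L_c": -1.0,
                    "atp_c": -1.0,
                    "coa_c": -1.0,
                    "malylcoa_c": 1.0,
                    "adp_c": 1.0,
                    "pi_c": 1.0,
                },
                lower_bound=0.0,
                name="malate thiokinase",
            ),
        ),
        CurationEdit(
            "add_reaction",
            reaction=Reaction(
                id="MCL",
                stoichiometry={"malylcoa_c": -1.0, "accoa_c": 1.0, "glx_c": 1.0},
                lower_bound=0.0,
                name="malyl-CoA lyase",
            ),
        ),
    ]
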