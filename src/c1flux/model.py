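"""Stoichiometric-model data structures and readers/writers.

The in-memory representation is deliberately plain: dataclasses holding ids,
stoichiometries and bounds, plus an explicit S-matrix assembler. File IO
(BiGG-dialect JSON and SBML L3/FBC) and linear programming are delegated to
cobrapy; conversion helpers `to_cobra` / `from_cobra` bridge the two worlds.
Keeping our own container makes the curation engine (see `curation`) easy to
reason about and keeps provenance independent of any solver state.

Ids follow the BiGG dialect: compartment-suffixed metabolites ("thf_c"),
exchange reactions prefixed "EX_".
"""

from __future__ import annotations

import copy as _copy
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np

from .errors import ParseError, UsageError

__all__ = [
    "Metabolite",
    "Reaction",
    "StoichiometricModel",
    "read_model",
    "write_model",
    "to_cobra",
    "from_cobra",
]

#: default magnitude used for "unbounded" fluxes (mmol gCDW^-1 h^-1)
BIG = 1000.0

_KNOWN_COMPARTMENTS = ("c", "p", "e")


def _infer_compartment(met_id: str) -> str:
    tail = met_id.rsplit("_", 1)
    if len(tail) == 2 and tail[1] in _KNOWN_COMPARTMENTS:
        return tail[1]
    return ""


@dataclass
class Metabolite:
    """A chemical species in one compartment.

    ``carbons`` is the number of carbon atoms (used by the medium builder to
    distinguish organic from inorganic exchanges); ``None`` means unknown.
    """

    id: str
    name: str = ""
    compartment: str = ""
    carbons: int | None = None
    formula: str | None = None

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("metabolite id must be non-empty")
        inferred = _infer_compartment(self.id)
        if not self.compartment:
            self.compartment = inferred
        elif inferred and inferred != self.compartment:
            raise ValueError(
                f"metabolite '{self.id}': compartment suffix '{inferred}' "
                f"does not match declared compartment '{self.compartment}'"
            )


@dataclass
class Reaction:
    """A stoichiometric conversion with flux bounds.

    ``stoichiometry`` maps metabolite id to a signed coefficient
    (negative = consumed). Bounds are in mmol gCDW^-1 h^-1.
    """

    id: str
    stoichiometry: dict[str, float]
    lower_bound: float = -BIG
    upper_bound: float = BIG
    name: str = ""

    def __post_init__(self) -> None:
        if not self.stoichiometry:
            raise ValueError(f"reaction '{self.id}': stoichiometry must be non-empty")
        if self.lower_bound > self.upper_bound:
            raise ValueError(
                f"reaction '{self.id}': lower_bound {self.lower_bound} > "
                f"upper_bound {self.upper_bound}"
            )

    @property
    def reversible(self) -> bool:
        return self.lower_bound < 0

    @property
    def bounds(self) -> tuple[float, float]:
        return (self.lower_bound, self.upper_bound)

    @bounds.setter
    def bounds(self, value: tuple[float, float]) -> None:
        lb, ub = value
        if lb > ub:
            raise ValueError(f"reaction '{self.id}': bounds {value} inverted")
        self.lower_bound, self.upper_bound = float(lb), float(ub)

    def copy(self) -> "Reaction":
        return Reaction(
            id=self.id,
            stoichiometry=dict(self.stoichiometry),
            lower_bound=self.lower_bound,
            upper_bound=self.upper_bound,
            name=self.name,
        )


@dataclass
class StoichiometricModel:
    """Metabolites, reactions with bounds, and a biomass objective.

    The steady-state matrix S has one row per metabolite and one column per
    reaction (see :meth:`stoichiometric_matrix`).
    """

    id: str = "model"
    metabolites: dict[str, Metabolite] = field(default_factory=dict)
    reactions: dict[str, Reaction] = field(default_factory=dict)
    objective_reaction_id: str = ""
    #: provenance of curation edits applied to this model instance
    edit_log: list[dict] = field(default_factory=list, repr=False, compare=False)

    # -- construction -----------------------------------------------------
    def add_metabolite(self, met: Metabolite) -> None:
        if met.id in self.metabolites:
            raise ValueError(f"duplicate metabolite '{met.id}'")
        self.metabolites[met.id] = met

    def add_reaction(self, rxn: Reaction, create_missing: bool = True) -> None:
        """Add a reaction; unknown metabolites are created with inferred
        compartments when ``create_missing`` (the BiGG-JSON add-reaction
        convention), otherwise this is an error."""
        if rxn.id in self.reactions:
            raise ValueError(f"duplicate reaction '{rxn.id}'")
        for met_id in rxn.stoichiometry:
            if met_id not in self.metabolites:
                if not create_missing:
                    raise ValueError(
                        f"reaction '{rxn.id}' references undeclared metabolite "
                        f"'{met_id}'"
                    )
                self.metabolites[met_id] = Metabolite(id=met_id)
        self.reactions[rxn.id] = rxn

    def remove_reaction(self, rxn_id: str) -> Reaction:
        try:
            return self.reactions.pop(rxn_id)
        except KeyError:
            raise KeyError(f"reaction '{rxn_id}' not in model '{self.id}'") from None

    # -- queries ----------------------------------------------------------
    @property
    def exchanges(self) -> list[Reaction]:
        """Boundary reactions: single-metabolite reactions (conventionally
        prefixed ``EX_``) that exchange a species with the environment."""
        return [
            r
            for r in self.reactions.values()
            if len(r.stoichiometry) == 1 or r.id.startswith("EX_")
        ]

    def validate(self) -> None:
        for rxn in self.reactions.values():
            for met_id in rxn.stoichiometry:
                if met_id not in self.metabolites:
                    raise ValueError(
                        f"reaction '{rxn.id}' references undeclared metabolite "
                        f"'{met_id}'"
                    )
        if self.objective_reaction_id and self.objective_reaction_id not in self.reactions:
            raise ValueError(
                f"objective reaction '{self.objective_reaction_id}' not in model"
            )

    def stoichiometric_matrix(self) -> tuple[np.ndarray, list[str], list[str]]:
        """Assemble S (metabolites x reactions) independently of any solver."""
        met_ids = list(self.metabolites)
        rxn_ids = list(self.reactions)
        met_index = {m: i for i, m in enumerate(met_ids)}
        S = np.zeros((len(met_ids), len(rxn_ids)))
        for j, rid in enumerate(rxn_ids):
            for met_id, coef in self.reactions[rid].stoichiometry.items():
                S[met_index[met_id], j] = coef
        return S, met_ids, rxn_ids

    def copy(self) -> "StoichiometricModel":
        return _copy.deepcopy(self)


# -- cobra conversion ------------------------------------------------------

def to_cobra(model: StoichiometricModel):
    """Convert to a cobra.Model (for LP solving and file export)."""
    import cobra

    cmodel = cobra.Model(model.id)
    cmets = {}
    for met in model.metabolites.values():
        cm = cobra.Metabolite(
            met.id,
            name=met.name,
            compartment=met.compartment or "c",
            formula=met.formula,
        )
        cmets[met.id] = cm
    cmodel.add_metabolites(list(cmets.values()))
    crxns = []
    for rxn in model.reactions.values():
        cr = cobra.Reaction(rxn.id, name=rxn.name)
        cr.lower_bound = rxn.lower_bound
        cr.upper_bound = rxn.upper_bound
        crxns.append(cr)
    cmodel.add_reactions(crxns)
    for rxn in model.reactions.values():
        cmodel.reactions.get_by_id(rxn.id).add_metabolites(
            {cmets[m]: c for m, c in rxn.stoichiometry.items()}
        )
    if model.objective_reaction_id:
        cmodel.objective = model.objective_reaction_id
    return cmodel


def from_cobra(cmodel) -> StoichiometricModel:
    """Convert a cobra.Model into the plain container used here."""
    from cobra.util.solver import linear_reaction_coefficients

    model = StoichiometricModel(id=cmodel.id or "model")
    for cm in cmodel.metabolites:
        carbons = None
        try:
            elements = cm.elements
            if elements:
                carbons = int(elements.get("C", 0))
        except Exception:
            carbons = None
        model.metabolites[cm.id] = Metabolite(
            id=cm.id,
            name=cm.name or "",
            compartment=cm.compartment or _infer_compartment(cm.id),
            carbons=carbons,
            formula=cm.formula,
        )
    for cr in cmodel.reactions:
        model.reactions[cr.id] = Reaction(
            id=cr.id,
            stoichiometry={m.id: float(c) for m, c in cr.metabolites.items()},
            lower_bound=float(cr.lower_bound),
            upper_bound=float(cr.upper_bound),
            name=cr.name or "",
        )
    coeffs = linear_reaction_coefficients(cmodel)
    if coeffs:
        model.objective_reaction_id = max(coeffs, key=lambda r: coeffs[r]).id
    model.validate()
    return model


# -- file IO ---------------------------------------------------------------

_DIALECTS = ("bigg_json", "sbml")


def _infer_dialect(path: str) -> str:
    p = str(path).lower()
    if p.endswith(".json"):
        return "bigg_json"
    if p.endswith((".xml", ".sbml", ".xml.gz")):
        return "sbml"
    raise UsageError(
        f"cannot infer model dialect from '{path}'; pass dialect explicitly "
        f"(one of {_DIALECTS})"
    )


def read_model(path: str, dialect: str | None = None) -> StoichiometricModel:
    """Read a metabolic model from BiGG-dialect JSON or SBML L3/FBC.

    Raises :class:`ParseError` naming the offending element on malformed
    input and :class:`UsageError` on an unknown dialect.
    """
    import cobra.io

    if dialect is None:
        dialect = _infer_dialect(path)
    if dialect not in _DIALECTS:
        raise UsageError(f"unknown dialect '{dialect}'; expected one of {_DIALECTS}")
    try:
        if dialect == "bigg_json":
            cmodel = cobra.io.load_json_model(str(path))
        else:
            cmodel = cobra.io.read_sbml_model(str(path))
    except FileNotFoundError:
        raise
    except Exception as exc:  # cobra raises heterogeneous exception types
        raise ParseError(f"failed to parse '{path}' as {dialect}: {exc}") from exc
    try:
        return from_cobra(cmodel)
    except Exception as exc:
        raise ParseError(f"model '{path}' is inconsistent: {exc}") from exc


def write_model(model: StoichiometricModel, path: str, dialect: str | None = None) -> None:
    """Write a model as BiGG-dialect JSON or SBML; round-trips with
    :func:`read_model` (reaction count, stoichiometry, bounds)."""
    import cobra.io

    if dialect is None:
        dialect = _infer_dialect(path)
    if dialect not in _DIALECTS:
        raise UsageError(f"unknown dialect '{dialect}'; expected one of {_DIALECTS}")
    cmodel = to_cobra(model)
    if dialect == "bigg_json":
        cobra.io.save_json_model(cmodel, str(path))
    else:
        cobra.io.write_sbml_model(cmodel, str(path))
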