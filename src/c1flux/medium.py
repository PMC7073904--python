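"""Growth-medium construction as exchange-bound sets.

Scenarios mirror the growth experiments: glucose, glycine, formaldehyde and
thymidine as carbon sources (``thy``), optionally plus methionine and/or
pantothenate, and a hypothetical ``formaldehyde_only`` condition where the
condensation reaction supplies all organic carbon.

The rule applied to a model's exchange reactions: every organic-carbon
exchange is closed for uptake unless it is a scenario carbon source; CO2 and
bicarbonate stay open (inorganic carbon is not an organic source — the serine
cycle legitimately fixes CO2); carbon-free exchanges (O2, NH4, phosphate,
water, protons, trace metals, ...) stay open; and trace organic supplements
already present in the model at a tiny uptake bound (vitamins such as B12 in
genome-scale reconstructions) are preserved, since their carbon contribution
is negligible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .errors import UsageError
from .model import BIG, StoichiometricModel

__all__ = ["MediumSpec", "build_medium", "apply_medium", "SCENARIOS"]

#: metabolite base ids opened for uptake in each scenario (exchange id is
#: ``EX_<base>_e``); glucose gets its own (conventional) bound.
SCENARIOS: dict[str, tuple[str, ...]] = {
    "thy": ("glc__D", "gly", "fald", "thymd"),
    "thy_pan": ("glc__D", "gly", "fald", "thymd", "pnto__R"),
    "thy_met": ("glc__D", "gly", "fald", "thymd", "met__L"),
    "thy_met_pan": ("glc__D", "gly", "fald", "thymd", "met__L", "pnto__R"),
    "formaldehyde_only": ("fald",),
}

#: inorganic-carbon species never counted as organic sources
_INORGANIC_CARBON = {"co2", "hco3", "cynt"}


@dataclass
class MediumSpec:
    """Exchange bounds: max uptake (>= 0) and max secretion (>= 0) per
    exchange reaction id. Exchanges not listed are closed for uptake but
    left open for secretion."""

    uptake: dict[str, float] = field(default_factory=dict)
    secretion: dict[str, float] = field(default_factory=dict)
    scenario: str = ""

    def validate_against(self, model: StoichiometricModel) -> None:
        missing = [
            ex
            for ex in list(self.uptake) + list(self.secretion)
            if ex not in model.reactions
        ]
        if missing:
            raise UsageError(
                f"medium references exchanges absent from model '{model.id}': "
                f"{sorted(set(missing))}"
            )


def _exchange_metabolite(model: StoichiometricModel, rxn_id: str) -> str:
    stoich = model.reactions[rxn_id].stoichiometry
    # exchanges are single-metabolite by convention; take the consumed species
    return min(stoich, key=lambda m: stoich[m])


def _base_id(met_id: str) -> str:
    parts = met_id.rsplit("_", 1)
    return parts[0] if len(parts) == 2 else met_id


def build_medium(
    model: StoichiometricModel,
    scenario: str,
    glucose_uptake: float = 10.0,
    supplement_uptake: float = BIG,
    trace_threshold: float = 0.1,
) -> MediumSpec:
    """Build the exchange-bound set for a named scenario.

    ``glucose_uptake`` defaults to the conventional 10 mmol gCDW^-1 h^-1;
    supplement uptakes (glycine, thymidine, methionine, pantothenate,
    formaldehyde) default to effectively unlimited. Carbon exchanges whose
    existing uptake bound is nonzero but <= ``trace_threshold`` are treated
    as trace vitamins and preserved. Unknown scenario -> :class:`UsageError`.
    """
    if scenario not in SCENARIOS:
        raise UsageError(
            f"unknown medium scenario '{scenario}'; expected one of "
            f"{sorted(SCENARIOS)}"
        )
    sources = SCENARIOS[scenario]
    # the primary carbon source gets the conventional carbon-source bound;
    # supplements are effectively unlimited
    primary = "fald" if scenario == "formaldehyde_only" else "glc__D"
    medium = MediumSpec(scenario=scenario)
    for rxn in model.exchanges:
        ex_id = rxn.id
        met_id = _exchange_metabolite(model, ex_id)
        met = model.metabolites[met_id]
        base = _base_id(met_id)
        carbons = met.carbons
        organic = (carbons is None or carbons > 0) and base not in _INORGANIC_CARBON
        medium.secretion[ex_id] = BIG
        if base in sources:
            medium.uptake[ex_id] = (
                glucose_uptake if base == primary else supplement_uptake
            )
        elif not organic:
            medium.uptake[ex_id] = BIG
        elif rxn.lower_bound < 0 and abs(rxn.lower_bound) <= trace_threshold:
            # trace organic supplement (e.g. vitamin B12) already in the model
            medium.uptake[ex_id] = abs(rxn.lower_bound)
        # otherwise: organic, not a source -> closed for uptake (unlisted)
    return medium


def apply_medium(
    model: StoichiometricModel, medium: MediumSpec
) -> StoichiometricModel:
    """Return a copy of ``model`` with exchange bounds set from ``medium``."""
    medium.validate_against(model)
    out = model.copy()
    for rxn in out.exchanges:
        uptake = medium.uptake.get(rxn.id, 0.0)
        secretion = medium.secretion.get(rxn.id, BIG)
        rxn.bounds = (-abs(uptake), abs(secretion))
    return out
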