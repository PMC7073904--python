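"""In vitro rate law of the spontaneous formaldehyde + THF condensation and
the unit conversions between culture, biomass and intracellular scales.

The condensation rate under mass-action kinetics is

    v = k_forward * [HCHO] * [THF] * [H+]        (M s^-1)

with k_forward = 8.7e8 s^-1 M^-2. Rates are carried internally in SI (M, s)
and converted at the interface; the biomass-specific unit is fixed as
mmol gCDW^-1 h^-1, using an intracellular density of 300 mgCDW mL^-1
(= 300 gCDW L^-1). The extracellular formaldehyde concentration is used as a
proxy for the intracellular one (a documented assumption — the true
intracellular level may be somewhat higher), and the reverse reaction
(5,10-methylene-THF dissociation) is not modeled: the in vivo flux this rate
is compared against is already a net rate.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

from .errors import DomainError

__all__ = [
    "CellConstants",
    "RateLawInput",
    "RateResult",
    "pool_to_intracellular",
    "in_vitro_rate",
    "volumetric_to_specific",
    "specific_to_volumetric",
    "fold_difference",
    "direct_growth_estimate",
    "load_constants",
]

SECONDS_PER_HOUR = 3600.0


@dataclass
class CellConstants:
    """Physical constants of the measurement platform.

    biomass_per_od   : culture biomass, mgCDW mL^-1 OD600^-1
    cell_density     : intracellular biomass density, mgCDW mL^-1 (= gCDW L^-1)
    ph               : cytosolic pH; [H+] = 10^-pH M
    c1_carbon_fraction : fraction of biomass carbon from non-thymidine C1
                         moieties (dimensionless)
    k_forward        : condensation rate constant, s^-1 M^-2
    thf_pool         : measured THF(+5,10-methylene-THF) pool,
                       pmol mL^-1 OD600^-1
    formaldehyde_um  : extracellular formaldehyde during growth, uM
    """

    biomass_per_od: float = 0.39
    cell_density: float = 300.0
    ph: float = 7.5
    c1_carbon_fraction: float = 0.023
    k_forward: float = 8.7e8
    thf_pool: float = 23.0
    formaldehyde_um: float = 100.0

    def __post_init__(self) -> None:
        for name in ("biomass_per_od", "cell_density", "ph", "k_forward"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @property
    def h_molar(self) -> float:
        """Proton concentration from pH, M (pH 7.5 -> 31.6 nM)."""
        return 10.0 ** (-self.ph)

    def to_json(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, sort_keys=True)


def load_constants(path: str | None = None) -> CellConstants:
    """Load constants from a JSON config, or the shipped defaults."""
    if path is None:
        from importlib import resources

        text = resources.files("c1flux").joinpath("data/constants.json").read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    return CellConstants(**json.loads(text))


@dataclass
class RateLawInput:
    """Concentrations for the mass-action rate law, all in M."""

    formaldehyde: float
    thf: float
    h: float
    k_forward: float = 8.7e8

    def __post_init__(self) -> None:
        for name in ("formaldehyde", "thf", "h", "k_forward"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass
class RateResult:
    volumetric_M_s: float
    specific_mmol_gcdw_h: float


def pool_to_intracellular(pool: float, consts: CellConstants | None = None) -> float:
    """Convert a culture pool (pmol mL^-1 OD600^-1) to an intracellular
    concentration (uM): pool / biomass-per-OD * intracellular density.

    pmol/mL/OD / (mgCDW/mL/OD) = pmol/mgCDW; * mgCDW/mL = pmol/mL = nM*...
    -> /1000 gives umol/L.
    """
    if pool < 0:
        raise DomainError(f"pool must be >= 0, got {pool}")
    consts = consts or CellConstants()
    return pool / consts.biomass_per_od * consts.cell_density / 1000.0


def volumetric_to_specific(rate_M_s: float, consts: CellConstants | None = None) -> float:
    """M s^-1 -> mmol gCDW^-1 h^-1 at the intracellular biomass density."""
    consts = consts or CellConstants()
    # mol L^-1 s^-1 / (gCDW L^-1) * s/h * mmol/mol
    return rate_M_s / consts.cell_density * SECONDS_PER_HOUR * 1000.0


def specific_to_volumetric(rate: float, consts: CellConstants | None = None) -> float:
    """Inverse of :func:`volumetric_to_specific` (unit round trip)."""
    consts = consts or CellConstants()
    return rate * consts.cell_density / SECONDS_PER_HOUR / 1000.0


def in_vitro_rate(
    inp: RateLawInput, consts: CellConstants | None = None
) -> RateResult:
    """Evaluate the mass-action rate law; returns the volumetric rate (M s^-1)
    and the biomass-specific rate (mmol gCDW^-1 h^-1)."""
    consts = consts or CellConstants()
    v = inp.k_forward * inp.formaldehyde * inp.thf * inp.h
    return RateResult(v, volumetric_to_specific(v, consts))


def fold_difference(in_vivo: float, in_vitro: float) -> float:
    """Ratio of the in vivo derived flux to the in vitro expected rate."""
    if in_vitro <= 0:
        raise DomainError(f"in vitro rate must be > 0, got {in_vitro}")
    return in_vivo / in_vitro


def direct_growth_estimate(mu_measured: float, carbon_fraction: float) -> float:
    """Closed-form growth bound: the measured growth rate scaled by the
    biomass-carbon fraction the condensation reaction supplied.

    If the condensation supports growth at ``mu_measured`` while providing
    only ``carbon_fraction`` of biomass carbon, supplying all carbon at the
    same condensation flux supports mu_measured * carbon_fraction.
    """
    if mu_measured <= 0:
        raise DomainError("mu_measured must be positive")
    if not (0 < carbon_fraction <= 1):
        raise DomainError("carbon_fraction must be in (0, 1]")
    return mu_measured * carbon_fraction
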