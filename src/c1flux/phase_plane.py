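"""FBA engine and phenotypic phase planes for the condensation reaction.

The phase plane of a target flux against growth rate is computed by fixing
the biomass flux at each point of a growth grid and minimizing/maximizing the
target reaction (flux variability restricted to one reaction). The slope of
the lower envelope is the stoichiometric 5,10-methylene-THF requirement per
unit biomass (mmol gCDW^-1): intersecting it with a measured growth rate
yields the in vivo condensation flux, and intersecting the serine-cycle
phase plane with that flux yields the maximal growth rate of an organism
living off the spontaneous condensation.

LPs are solved with GLPK through cobrapy (single-threaded, deterministic);
solutions are additionally checked against an independently assembled
stoichiometric matrix (S.v residual) rather than trusting the solver report.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import DomainError, InfeasibleError, SolverError
from .growth import GrowthMeasurement
from .medium import MediumSpec, apply_medium
from .model import StoichiometricModel, to_cobra

__all__ = [
    "FluxSolution",
    "PhasePlane",
    "FluxEstimate",
    "fba",
    "phase_plane",
    "derive_flux",
    "derive_max_growth",
]

#: LP feasibility/optimality tolerance requested from the solver
LP_TOLERANCE = 1e-9


@dataclass
class FluxSolution:
    """An FBA optimum: objective value, flux vector, solver status, and the
    independently computed steady-state residual max|S.v|."""

    objective_value: float | None
    fluxes: dict[str, float]
    status: str
    residual: float | None = None


@dataclass
class FluxEstimate:
    """Condensation flux (mmol gCDW^-1 h^-1) with linearly propagated SD and
    provenance (scenario + slope used)."""

    flux: float
    sd: float
    provenance: str = ""

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValueError("sd must be >= 0")


@dataclass
class PhasePlane:
    """Feasible (growth rate, min/max target flux) envelope plus the fitted
    lower-bound line."""

    reaction_id: str
    growth_grid: np.ndarray
    min_flux: np.ndarray
    max_flux: np.ndarray
    feasible: np.ndarray
    slope: float
    intercept: float
    r2: float
    intercept_flagged: bool
    scenario: str = ""
    diagnostics: dict = field(default_factory=dict)

    @property
    def feasible_range(self) -> tuple[float, float]:
        mus = self.growth_grid[self.feasible]
        return float(mus.min()), float(mus.max())

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "mu": self.growth_grid,
                "min_flux": self.min_flux,
                "max_flux": self.max_flux,
                "feasible": self.feasible,
            }
        )

    def to_tsv(self, path: str) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    def summary(self) -> dict:
        lo, hi = self.feasible_range
        return {
            "reaction": self.reaction_id,
            "scenario": self.scenario,
            "slope": self.slope,
            "intercept": self.intercept,
            "r2": self.r2,
            "intercept_flagged": self.intercept_flagged,
            "mu_feasible_min": lo,
            "mu_feasible_max": hi,
            "n_grid": int(len(self.growth_grid)),
        }


# -- solving ---------------------------------------------------------------

def _prepare_cobra(model: StoichiometricModel, medium: MediumSpec | None):
    if medium is not None:
        model = apply_medium(model, medium)
    cmodel = to_cobra(model)
    cmodel.solver = "glpk"
    try:
        cmodel.tolerance = LP_TOLERANCE
    except ValueError:
        # backend refuses a tolerance this tight; keep its minimum
        cmodel.tolerance = 1e-9
    cmodel.solver.configuration.verbosity = 0
    return model, cmodel


def _residual(model: StoichiometricModel, fluxes: dict[str, float]) -> float:
    S, _, rxn_ids = model.stoichiometric_matrix()
    v = np.array([fluxes.get(r, 0.0) for r in rxn_ids])
    # boundary (_e) metabolites are balanced by their exchange column, so the
    # full S.v must vanish at steady state
    return float(np.abs(S @ v).max()) if len(v) else 0.0


def fba(
    model: StoichiometricModel,
    medium: MediumSpec | None = None,
    check_residual: bool = True,
) -> FluxSolution:
    """Maximize the model's biomass objective; returns status faithfully.

    Solver failures are reported as :class:`SolverError`; infeasibility is a
    normal outcome returned in ``status``.
    """
    bounded, cmodel = _prepare_cobra(model, medium)
    try:
        sol = cmodel.optimize()
    except Exception as exc:
        raise SolverError(
            f"LP backend failure on model '{model.id}' "
            f"(medium={getattr(medium, 'scenario', None)}): {exc}"
        ) from exc
    if sol.status != "optimal":
        return FluxSolution(None, {}, sol.status)
    fluxes = {r: float(v) for r, v in sol.fluxes.items()}
    res = _residual(bounded, fluxes) if check_residual else None
    return FluxSolution(float(sol.objective_value), fluxes, "optimal", res)


def phase_plane(
    model: StoichiometricModel,
    medium: MediumSpec | None,
    reaction_id: str,
    growth_grid: np.ndarray | None = None,
    n_grid: int = 30,
    intercept_tolerance: float = 0.01,
) -> PhasePlane:
    """Compute the phenotypic phase plane of ``reaction_id`` vs growth rate.

    At each grid growth rate the biomass flux is fixed and the target flux is
    minimized and maximized. The default grid is ``n_grid`` evenly spaced
    points from 0 to the FBA maximum. The lower-envelope slope/intercept come
    from ordinary least squares over the feasible points; the intercept is
    flagged when |intercept| > ``intercept_tolerance`` x slope x max feasible
    growth rate (a nonlinearity warning).
    """
    if reaction_id not in model.reactions:
        raise KeyError(f"reaction '{reaction_id}' not in model '{model.id}'")
    bounded, cmodel = _prepare_cobra(model, medium)
    biomass_id = model.objective_reaction_id
    if not biomass_id:
        raise DomainError("model has no objective reaction")

    if growth_grid is None:
        ref = cmodel.optimize()
        if ref.status != "optimal" or ref.objective_value <= 0:
            raise InfeasibleError(
                f"model '{model.id}' cannot grow under medium "
                f"'{getattr(medium, 'scenario', None)}'; no phase plane"
            )
        growth_grid = np.linspace(0.0, float(ref.objective_value), n_grid)
    else:
        growth_grid = np.asarray(growth_grid, dtype=float)
        if len(growth_grid) < 3 or np.any(np.diff(growth_grid) <= 0):
            raise DomainError("growth grid must be strictly increasing with >= 3 points")

    biomass = cmodel.reactions.get_by_id(biomass_id)
    target = cmodel.reactions.get_by_id(reaction_id)
    n = len(growth_grid)
    vmin = np.full(n, np.nan)
    vmax = np.full(n, np.nan)
    feasible = np.zeros(n, dtype=bool)
    for i, mu in enumerate(growth_grid):
        biomass.bounds = (mu, mu)
        cmodel.objective = target
        cmodel.objective_direction = "min"
        lo = cmodel.slim_optimize(error_value=np.nan)
        cmodel.objective_direction = "max"
        hi = cmodel.slim_optimize(error_value=np.nan)
        if np.isfinite(lo) and np.isfinite(hi):
            vmin[i], vmax[i] = lo, hi
            feasible[i] = True
    if not feasible.any():
        raise InfeasibleError(
            f"phase plane of '{reaction_id}' infeasible over the whole grid "
            f"[{growth_grid[0]:g}, {growth_grid[-1]:g}]; shrink the grid"
        )

    mus = growth_grid[feasible]
    lows = vmin[feasible]
    if len(mus) >= 2:
        slope, intercept = np.polyfit(mus, lows, 1)
        pred = slope * mus + intercept
        ss_res = float(np.sum((lows - pred) ** 2))
        ss_tot = float(np.sum((lows - lows.mean()) ** 2))
        r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    else:
        slope, intercept, r2 = np.nan, float(lows[0]), np.nan
    flagged = bool(
        abs(intercept) > intercept_tolerance * abs(slope) * float(mus.max())
    )
    return PhasePlane(
        reaction_id=reaction_id,
        growth_grid=growth_grid,
        min_flux=vmin,
        max_flux=vmax,
        feasible=feasible,
        slope=float(slope),
        intercept=float(intercept),
        r2=float(r2),
        intercept_flagged=flagged,
        scenario=getattr(medium, "scenario", "") or "",
        diagnostics={"n_feasible": int(feasible.sum())},
    )


# -- derivations -----------------------------------------------------------

def derive_flux(pp: PhasePlane, g: GrowthMeasurement) -> FluxEstimate:
    """Intersect the lower envelope with a measured growth rate.

    flux = slope * mu + intercept, with the SD propagated linearly
    (sd_flux = slope * sd_mu). The fitted line, not the nearest grid point,
    is used, so the result is independent of grid resolution.
    """
    lo, hi = pp.feasible_range
    if not (lo <= g.mean <= hi):
        raise DomainError(
            f"growth rate {g.mean:g} h^-1 outside the feasible range "
            f"[{lo:g}, {hi:g}] of the phase plane"
        )
    flux = pp.slope * g.mean + pp.intercept
    sd = abs(pp.slope) * g.sd
    return FluxEstimate(
        flux=flux,
        sd=sd,
        provenance=f"scenario={pp.scenario or 'unnamed'} slope={pp.slope:.6g}",
    )


def derive_max_growth(pp: PhasePlane, fe: FluxEstimate) -> GrowthMeasurement:
    """Invert the (serine-cycle) lower envelope at a given condensation flux:
    mu = (flux - intercept) / slope, sd = sd_flux / slope."""
    if not np.isfinite(pp.slope) or pp.slope <= 0:
        raise DomainError(
            f"phase-plane slope must be positive to invert (got {pp.slope!r})"
        )
    mu = (fe.flux - pp.intercept) / pp.slope
    sd = fe.sd / pp.slope
    return GrowthMeasurement(mean=mu, sd=sd, n=1)
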