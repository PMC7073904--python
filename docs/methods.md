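# Methods

## The inference model

The central object is the phenotypic phase plane of the spontaneous
formaldehyde–THF condensation (THFSPONT) against growth rate: for each μ on
a grid the biomass flux is fixed and the THFSPONT flux is minimized and
maximized subject to steady state (S·v = 0) and flux bounds. Because every
C1 moiety in biomass must pass through 5,10-methylene-THF, and the curated
network leaves THFSPONT as its only source, the lower envelope is exactly
linear through the origin with slope equal to the biomass C1 requirement
(mmol gCDW⁻¹). The derivation chain is then pure arithmetic on that line:

* condensation flux: v = s·μ + c, SD(v) = s·SD(μ) (linear propagation);
* growth bound on the serine-cycle model: μ_max = (v − c)/s′, SD = SD(v)/s′.

Assumptions inherited from the experimental design and carried by the code:

* the condensation flux is growth-limiting, so growth rate and C1 demand
  are proportional (verified internally: two media with different C1
  demands must yield the same flux);
* the derived value is a **net** rate (condensation minus
  5,10-methylene-THF dissociation); THFSPONT is therefore modeled
  irreversible and no reverse reaction is added;
* C1-THF is not wasted through futile cycles — the curation recipe encodes
  this (deformylase-type routes removed or made irreversible).

## Curation recipes

`base_curation_recipe()` produces the C1-auxotroph model: remove POR5,
GLYCK (not active in *E. coli*), PFL, OBTFL (oxygen-sensitive), FTHFLi
(would charge THF with formate); rewrite THD2pp to translocate one proton
(implemented as coefficient overrides h_p: −1, h_c: +1, preserving all
other participants); make FTHFD, GARFT, AICART irreversible; make THYMt3pp
reversible (thymidine uptake); knock out GLYCL and GHMT2r; add THFSPONT.

`serine_cycle_recipe()` builds the hypothetical formaldehyde assimilator on
top: remove GLXCL, GLYCL, THRD, THRA2, THRA, SERD_L (potential
carbon-fixation shortcuts); add FDH, EtMaCoA, MMCDr, SGAT1, SGAT2, MTK,
MCL; make MMM reversible. Two design choices were genuinely open:

* **GHMT2r is re-opened** as the recipe's first edit. Glycine +
  5,10-methylene-THF → serine (SHMT) is the serine cycle's only entry point
  for organic carbon; with GHMT2r still knocked out the cycle is
  structurally incapable of carrying flux. The hypothetical organism is not
  the auxotroph strain, so it carries SHMT.
* **SGAT2 is reversible.** Its stoichiometry is carried exactly as written
  for the model of record (gly + akg → glx + glu), but the cycle runs it in
  the glyoxylate → glycine direction, so the lower bound is opened.
* **FDH stoichiometry** is nowhere printed; the standard NAD-dependent
  formate dehydrogenase (for + NAD⁺ → CO₂ + NADH, cytosolic) is assumed.

Recipes are declarative edit lists, strictly validated (missing target or
duplicate add aborts with the edit named), order-independent for the two
shipped recipes (asserted by shuffled application in the tests), and logged
per edit for provenance.

## Media

Scenario media are built by rule rather than by list: organic-carbon
exchanges are closed for uptake unless they are scenario sources; CO₂ and
bicarbonate stay open (the serine cycle legitimately fixes inorganic
carbon — this is why its slope is roughly half the total biomass carbon);
carbon-free exchanges stay open; organic exchanges already bounded at
≤ 0.1 mmol gCDW⁻¹ h⁻¹ in the input model are treated as trace vitamins and
preserved. The primary carbon source (glucose, or formaldehyde in the
formaldehyde-only scenario) gets the conventional 10 mmol gCDW⁻¹ h⁻¹;
supplements are effectively unlimited (1000). Both bounds are parameters.
The phase-plane slope is invariant to the carbon-supply bound (tested):
the lower envelope reflects biomass stoichiometry, not supply.

## Numerical choices

* LP backend: GLPK through cobrapy, single-threaded, requested tolerance
  1e−9. Feasibility is declared from solver status **and** an independent
  steady-state residual max|S·v| computed from a separately assembled
  stoichiometric matrix (≤ 1e−9 at every reported optimum).
* Growth grid: 30 evenly spaced points from 0 to the FBA maximum.
  Slope/intercept come from ordinary least squares over the feasible lower
  envelope; OLS over the whole envelope is robust to curvature near the
  feasibility edge, and the intercept is flagged whenever
  |c| > 1% · s · μ_max as a nonlinearity warning. The intersection uses the
  fitted line, not the nearest grid point, so results are independent of
  grid resolution.
* Degenerate flux alternatives are irrelevant: only the objective value and
  the min/max of the single target reaction are consumed.

## Growth fitting and statistics

N = N₀·e^{μt} is fitted by OLS of log(OD) on time — the exact maximum-
likelihood fit under multiplicative lognormal noise, which is how
photometric error behaves. The exponential window is selected
automatically: contiguous runs with OD in [0.04, 0.5] (the photometer's
reliable range) are scanned; among windows of ≥ 4 points with r² ≥ 0.95 the
**longest** is chosen, ties broken by r². Preferring length over marginal
r² keeps the estimator stable under noise (a 4-point window can achieve
spuriously high r²), and on noiseless data every window gives the same
slope, so the choice is immaterial there. SE(μ) comes from the OLS slope
variance. A nonlinear refit of the same model (lmfit) is available
(`refine_nonlinear=True`) but off by default: under the multiplicative
noise model the log-linear fit is already the right estimator. Replicates
are fitted individually and pooled (mean ± SD, ddof = 1), configurable.

Group comparison uses the t-test from summary statistics; Welch's
unequal-variance form is the default since growth-rate variances across
media are not assumed equal (the classical pooled form is available via
`equal_var=True`; both reproduce the published verdicts).

Nash-assay calibration is an OLS line through the standards, not forced
through the origin (reagent blanks are nonzero); standards must be monotone
and ≥ 3; inversions outside the linear 0–1 mM range are returned flagged
rather than refused.

## Constants

Shipped in `c1flux/data/constants.json` and as `CellConstants` defaults:

| constant | value | unit |
|---|---|---|
| biomass per OD600 | 0.39 | mgCDW mL⁻¹ OD⁻¹ |
| intracellular density | 300 | mgCDW mL⁻¹ |
| cytosolic pH | 7.5 | — ([H⁺] = 10^(−pH) = 31.6 nM; tests accept the rounded 32 nM within 2%) |
| k_forward | 8.7×10⁸ | s⁻¹ M⁻² |
| THF(+5,10-CH₂-THF) pool | 23 | pmol mL⁻¹ OD⁻¹ (→ 17.7 μM intracellular) |
| formaldehyde during growth | 100 | μM |
| non-thymidine C1 carbon fraction | 2.3 | % of biomass carbon |

The extracellular formaldehyde concentration proxies the intracellular one
(exposed as a parameter; the true intracellular level may be somewhat
higher). The rate-law comparison reports the ~43-fold lower bound only;
since free THF is at most the measured THF + 5,10-methylene-THF pool and
the dissociation reaction further lowers the net in vitro expectation, the
true discrepancy is larger, but quantifying it would require an unmeasured
free-THF fraction (also exposed as an input, not defaulted).

## Synthetic data: what it emulates, and what it does not

The generators exist so the whole pipeline is testable offline.

* **Growth curves**: lag → exact exponential → slope-matched exponential
  relaxation to a carrying capacity, with multiplicative lognormal noise
  (CV 0.03 by default). Defaults mirror the slow-growth condition
  (μ = 0.036 h⁻¹, N₀ = 0.02, capacity 0.65). Biological between-replicate
  scatter is added at the replicate level in `analysis/01` using the
  reported per-condition SDs.
* **Formaldehyde trajectories** are phenomenological shape models of the
  two observed regimes (monotone saturation toward ~1000 μM without growth;
  rise to a ~100 μM plateau then first-order decline with growth), not a
  mechanistic sarcosine-oxidation model. They exercise parsers and the
  Nash calibration loop, nothing more.
* **Toy stoichiometric models** have an analytically known phase plane
  (slope = the biomass C1 coefficient b, intercept 0, for any medium) and
  serve as the oracle for the FBA machinery, including decoy dead-end
  pathways that must not affect the envelope.
* **The core network** (~80 reactions, hand-built) is a synthetic stand-in
  for the genome-scale reconstruction: it carries every reaction id the
  curation recipes target, is carbon-conserving by construction (asserted
  at build time against per-metabolite carbon counts), grows on glucose
  before curation, becomes a strict C1 auxotroph after the base recipe
  (slopes 0.704/0.700/0.544/0.540 across the four thymidine media — exact
  consequences of its biomass coefficients: 2×0.27 C1 per IMP, 0.16 per
  methionine, 0.004 per pantothenate), and grows on formaldehyde alone
  after the serine-cycle recipe with slope 21.4 (> 20, ~half of its 42 mmol
  biomass carbon per gCDW, the other half fixed as CO₂/bicarbonate). Its
  energy metabolism is abstracted (free ATP cycling, lumped NADH oxidation)
  so growth is carbon- and C1-limited; the ethylmalonyl-CoA branch supplies
  the net glyoxylate that the serine cycle's 1:1 glycine regeneration
  cannot.

Passing tests on these generators demonstrate correctness of the inference
machinery — envelope extraction, derivations, error propagation, curation
semantics — under exactly known ground truth. They do **not** validate the
genome-scale slopes themselves (0.7 / 0.54 / > 20), which depend on the
real biomass composition; those are reproduced only when an iML1515 file is
supplied locally (within 10%, per the conditional test), as the file is not
redistributable here.

## Problem sizes

Defaults were chosen as the smallest sizes that exercise every code path
with clean statistics: 30-point phase-plane grids (60 LPs per plane),
9–18 replicates per growth condition, 20 seeds for parameter-recovery
properties. The full suite and the acceptance script each run in well under
a minute on a single CPU.

## Known limitations

* No gene–protein–reaction logic beyond reaction knockouts; no loopless or
  parsimonious FBA; no dynamic FBA. None affect a single-reaction envelope.
* The iML1515 release used for the published slopes is unspecified;
  reaction ids are assumed stable across releases, and the conditional
  genome-scale test tolerates 10%.
* Whether formaldehyde uptake in the thymidine scenarios should be bounded
  to the rate a ~100 μM pool can support is unknowable from the summary
  data; it is left free (the lower envelope is unaffected).
* The kinetic explanation of the thymidine requirement (ThyA outcompeted
  for 5,10-methylene-THF) is outside the scope of stoichiometric modeling;
  FBA on the curated model will happily grow without thymidine, and no
  attempt is made to encode enzyme kinetics.
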