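#!/usr/bin/env python
"""Curate the stoichiometric network and compute the condensation-reaction
phase planes.

Applies the C1-auxotroph recipe to the packaged core network (a hand-built
stand-in carrying the same reaction ids as the genome-scale *E. coli*
reconstruction; drop an iML1515 JSON at data/iML1515.json to run the real
thing), verifies the designed phenotypes (no growth without formaldehyde;
5,10-methylene-THF only via THFSPONT), and computes the phase-plane slopes
for all media plus the serine-cycle model on formaldehyde alone.

Writes results/phase_planes/*.tsv and results/phase_planes/summary.json.
"""

import json
from pathlib import Path

from c1flux.curation import (
    apply_curation,
    base_curation_recipe,
    serine_cycle_recipe,
    write_edit_log,
)
from c1flux.medium import build_medium
from c1flux.model import read_model
from c1flux.phase_plane import fba, phase_plane
from c1flux.synth import gen_core_model

ROOT = Path(__file__).resolve().parent.parent
OUT = ROOT / "results" / "phase_planes"
GENOME_SCALE = ROOT / "data" / "iML1515.json"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    if GENOME_SCALE.exists():
        model = read_model(str(GENOME_SCALE))
        print(f"using genome-scale model ({len(model.reactions)} reactions)")
    else:
        model = gen_core_model()
        print(f"using packaged core network ({len(model.reactions)} reactions); "
              f"place an iML1515 JSON at {GENOME_SCALE} for the genome-scale run")

    curated = apply_curation(model, base_curation_recipe())
    write_edit_log(curated, str(OUT / "base_curation_log.tsv"))

    no_fald = build_medium(curated, "thy")
    no_fald.uptake.pop("EX_fald_e", None)
    mu0 = fba(curated, no_fald).objective_value
    print(f"auxotrophy check: growth without formaldehyde = {mu0:.2e} h^-1")

    summary = {}
    for scen in ("thy", "thy_pan", "thy_met", "thy_met_pan"):
        pp = phase_plane(curated, build_medium(curated, scen), "THFSPONT")
        pp.to_tsv(str(OUT / f"{scen}.tsv"))
        summary[scen] = pp.summary()
        print(f"{scen}: slope {pp.slope:.3f} mmol gCDW^-1 "
              f"(intercept {pp.intercept:.1e})")

    serine = apply_curation(curated, serine_cycle_recipe())
    pp = phase_plane(serine, build_medium(serine, "formaldehyde_only"), "THFSPONT")
    pp.to_tsv(str(OUT / "formaldehyde_only.tsv"))
    summary["formaldehyde_only"] = pp.summary()
    print(f"serine cycle on formaldehyde: slope {pp.slope:.2f} mmol gCDW^-1 "
          f"({'>' if pp.slope > 20 else '<='} 20), "
          f"max mu {pp.feasible_range[1]:.3f} h^-1")

    (OUT / "summary.json").write_text(json.dumps(summary, indent=2) + "\n")


if __name__ == "__main__":
    main()
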