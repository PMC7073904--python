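#!/usr/bin/env python
"""Generate the synthetic measurement bundle the downstream analyses consume.

Emulates the growth experiments: OD600 time series for the thymidine
condition (slow growth, ~0.036 h^-1), the thymidine+methionine condition
(~0.047 h^-1), and formaldehyde trajectories in both observed regimes
(monotone accumulation toward ~1000 uM without growth; plateau near 100 uM
then decline with growth), plus Nash-assay standards.

Writes results/synthetic/*.tsv.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from c1flux.synth import (
    FormaldehydeScenario,
    GrowthScenario,
    gen_formaldehyde_series,
    gen_growth_curve,
    gen_nash_standards,
)

SEED = 20260928
OUT = Path(__file__).resolve().parent.parent / "results" / "synthetic"

#: per-condition mean growth rate, between-replicate biological SD, and
#: replicate count, matching the measured summaries
CONDITIONS = {
    "thy": dict(mu=0.037, bio_sd=0.007, n=9),
    "thy_pan": dict(mu=0.035, bio_sd=0.005, n=9),
    "thy_met": dict(mu=0.047, bio_sd=0.004, n=18),
}


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    rows = []
    seed = SEED
    rng = np.random.default_rng(SEED)
    for scen, spec in CONDITIONS.items():
        for rep in range(spec["n"]):
            # biological replicate scatter on top of measurement noise
            mu_rep = max(rng.normal(spec["mu"], spec["bio_sd"]), 1e-3)
            curve = gen_growth_curve(GrowthScenario(mu=mu_rep, seed=seed))
            seed += 1
            for t, od in zip(curve.times, curve.od):
                rows.append(
                    {"time_h": t, "od600": od, "replicate": rep, "scenario": scen}
                )
    growth = pd.DataFrame(rows)
    growth.to_csv(OUT / "growth_curves.tsv", sep="\t", index=False)
    print(f"growth curves: {growth['scenario'].nunique()} conditions, "
          f"{len(rows)} samples -> {OUT/'growth_curves.tsv'}")

    for mode in ("growing_plateau", "non_growing_accumulation"):
        series = gen_formaldehyde_series(
            FormaldehydeScenario(mode=mode, seed=SEED, t_end=120)
        )
        df = pd.DataFrame(series)
        df.to_csv(OUT / f"formaldehyde_{mode}.tsv", sep="\t", index=False)
        print(f"formaldehyde {mode}: peak {df['um'].max():.0f} uM, "
              f"final {df['um'].iloc[-1]:.0f} uM")

    std = pd.DataFrame(
        gen_nash_standards(slope=1.2, intercept=0.05, noise_sd=0.01, seed=SEED),
        columns=["mM", "absorbance"],
    )
    std.to_csv(OUT / "nash_standards.tsv", sep="\t", index=False)
    print(f"nash standards: {len(std)} points spanning 0-1 mM")


if __name__ == "__main__":
    main()
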