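#!/usr/bin/env python
"""Generate synthetic confocal fields with known cilia and distractors.

Writes OME-TIFF stacks under scratch/imaging/ (binary, regenerable) and
the ground-truth tables under results/.  Three conditions are produced:
a noiseless field, a Poisson-noise field, and a ciliation field with
nuclei (9 cilia over 12 nuclei, truth frequency 0.75).
"""

from pathlib import Path

import numpy as np
import pandas as pd

from ciliascreen import CiliumTruth, make_cilium_stack, write_ome_tiff

RESULTS = Path("results")
SCRATCH = Path("scratch/imaging")
SEED = 1


def field_truths(rng, n=6, shape=(256, 256)):
    truths = []
    for _ in range(n):
        truths.append(CiliumTruth(
            center=(40 + (shape[0] - 80) * rng.random(),
                    40 + (shape[1] - 80) * rng.random()),
            orientation_deg=float(rng.uniform(0, 180)),
            probe_intensity_cilium=float(rng.uniform(80, 400)),
        ))
    return truths


def main():
    RESULTS.mkdir(exist_ok=True)
    SCRATCH.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(SEED)

    tables = []
    for condition, noise in [("noiseless", "none"), ("poisson", "poisson")]:
        stack, truth = make_cilium_stack(
            field_truths(rng), distractors="default", noise_model=noise,
            seed=SEED,
        )
        write_ome_tiff(stack, SCRATCH / f"field_{condition}.ome.tif")
        tables.append(truth.assign(condition=condition))

    centers = [(30.0 + 50.0 * (i // 4), 30.0 + 60.0 * (i % 4)) for i in range(12)]
    cil = [CiliumTruth(center=(r + 22.0, c + 22.0), orientation_deg=15.0 * i)
           for i, (r, c) in enumerate(centers[:9])]
    stack, truth = make_cilium_stack(cil, shape=(5, 256, 300),
                                     nuclei_centers=centers,
                                     nuclei_radius_px=8.0, seed=SEED)
    write_ome_tiff(stack, SCRATCH / "field_ciliation.ome.tif")
    tables.append(truth.assign(condition="ciliation"))

    out = pd.concat(tables, ignore_index=True)
    out.to_csv(RESULTS / "imaging_truth.tsv", sep="\t", index=False)
    print(f"wrote {len(out)} planted cilia across 3 fields")
    print(f"stacks -> {SCRATCH}/, truth -> {RESULTS}/imaging_truth.tsv")


if __name__ == "__main__":
    main()
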