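#!/usr/bin/env python
"""Generate the synthetic study inputs and check they round-trip.

Produces the two pooled count datasets (a marker-identified WT/hog1 pool
and a barcoded deletion pool), promoter-activity traces for the induced
and repressed reporters, microscopy frames, growth curves and the bulk
fold-change consensus table.  Raw matrices go to scratch/simulated/ (they
are large); the ground-truth summaries land in results/tables/.
"""

from pathlib import Path

import pandas as pd

from _common import driver_args
from osmohet import save_dataset
from osmohet.data import load_dataset_dir
from osmohet.syndata import (GenotypeSpec, SimSpec, TraceSimSpec,
                             generate_counts, generate_frames,
                             generate_growth_and_fc, generate_traces)


def main() -> None:
    args = driver_args(__doc__)
    scratch = Path("scratch/simulated")
    scratch.mkdir(parents=True, exist_ok=True)

    # marker pool: WT and hog1, distinguished by selection cassettes
    marker_pool = SimSpec(
        genotype_table=[
            GenotypeSpec("WT", 600, markers={"KAN": 5}),
            GenotypeSpec("hog1", 600, effect_mean=0.25,
                         markers={"NAT": 5, "HPH": 5}, null_genes=("HOG1",)),
        ],
        seed=args.seed)
    ds, truth = generate_counts(marker_pool)
    save_dataset(ds, scratch / "marker_pool")
    back = load_dataset_dir(scratch / "marker_pool")
    assert (ds.counts != back.counts).nnz == 0, "round trip failed"
    truth.to_csv(args.out / "tables" / "marker_pool_truth.tsv", sep="\t",
                 index=False)
    print(f"marker pool: {ds.n_cells} cells x {ds.n_genes} genes "
          f"(round-trip exact)")

    # barcoded deletion pool with planted high-variance mutants; the WT
    # reference strains get more cells so the variability threshold is
    # estimated tightly
    gt = [GenotypeSpec("WT-1", 150), GenotypeSpec("WT-2", 150)]
    gt += [GenotypeSpec(f"null{i:02d}", 50) for i in range(50)]
    gt += [GenotypeSpec(f"var{i}", 50, effect_sd=2.5) for i in range(5)]
    screen_pool = SimSpec(genotype_table=gt, doublet_rate=0.03,
                          seed=args.seed + 1)
    ds2, truth2 = generate_counts(screen_pool)
    save_dataset(ds2, scratch / "screen_pool")
    truth2.to_csv(args.out / "tables" / "screen_pool_truth.tsv", sep="\t",
                  index=False)
    print(f"screen pool: {ds2.n_cells} cells x {ds2.n_genes} genes, "
          f"{truth2['doublet'].sum()} planted doublets")

    # reporter traces (repressed pEFT2-like and induced pHSP12-like)
    for kind, extra in (("repressed", {}),
                        ("induced", {"fraction_high_basal": 0.1})):
        ts, t_truth = generate_traces(
            TraceSimSpec(n_traces=500, kind=kind, seed=args.seed + 2,
                         **extra))
        ts.to_csv(scratch / f"traces_{kind}.csv")
        t_truth.to_csv(args.out / "tables" / f"traces_{kind}_truth.tsv",
                       sep="\t", index=False)
        print(f"{kind} traces: {ts.n_traces} x {ts.n_points} points")

    frames = generate_frames(n_frames=40, noise_sd=5.0, seed=args.seed + 3)
    frames.truth.to_csv(args.out / "tables" / "frames_truth.tsv", sep="\t",
                        index=False)
    print(f"frames: {len(frames.frames)} "
          f"({int(frames.truth['has_spot'].sum())} with planted spots)")

    growth, fc = generate_growth_and_fc(
        ["WT", "ada2", "gcn5", "lsm1"],
        {"WT": 2.0, "ada2": 9.0, "gcn5": 7.0, "lsm1": 0.0},
        seed=args.seed + 4)
    growth.to_csv(scratch / "growth_curves.csv", index=False)
    fc.to_csv(args.out / "tables" / "bulk_fold_changes.tsv", sep="\t",
              index=False)
    print(f"growth: {growth['genotype'].nunique()} genotypes, "
          f"fold-change table: {len(fc)} genes")


if __name__ == "__main__":
    main()
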