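#!/usr/bin/env python
"""Fitness readouts: pre-stress growth benefit, competition, reporters.

Computes each genotype's prestress/direct-stress endpoint growth ratio
against the wild-type reference, a competition time course of a sorted
subpopulation against a reference strain, and the reporter fold change
of pre-stressed versus untreated cultures.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from _common import driver_args
from osmohet.fitness import (competition_analysis, growth_ratio,
                             reporter_fold_change)


def main() -> None:
    args = driver_args(__doc__)
    rng = np.random.default_rng(args.seed + 5)
    scratch = Path("scratch/simulated")

    growth = pd.read_csv(scratch / "growth_curves.csv")
    ratios = growth_ratio(growth, wt_label="WT")
    ratios.to_csv(args.out / "tables" / "growth_ratios.tsv", sep="\t",
                  index=False)
    better = ratios[ratios["higher_than_wt"]]["genotype"].tolist()
    print("growth ratios (prestress/direct endpoint):")
    print(ratios.to_string(index=False))
    print(f"genotypes adapting faster than WT when pre-stressed: {better}")

    # competition of a sorted top subpopulation vs the reference strain:
    # the sorted population expands under stress
    counts = []
    for tp, advantage in ((0, 1.0), (24, 1.6), (48, 2.6)):
        for rep in range(3):
            a = rng.poisson(10_000 * advantage)
            b = rng.poisson(10_000)
            counts.append({"timepoint": tp, "replicate": rep,
                           "count_a": a, "count_b": b})
    comp = competition_analysis(pd.DataFrame(counts))
    comp.to_csv(args.out / "tables" / "competition.tsv", sep="\t",
                index=False)
    print("\ncompetition (sorted subpopulation vs reference):")
    print(comp.to_string(index=False))

    # reporter fold change: pre-stressed vs untreated medians
    medians = []
    for strain, fold in (("WT", 1.3), ("ada2", 2.2)):
        for rep in range(3):
            base = rng.normal(1000, 40)
            medians.append({"strain": strain, "prestressed": False,
                            "replicate": rep, "median_expression": base})
            medians.append({"strain": strain, "prestressed": True,
                            "replicate": rep,
                            "median_expression": base * fold
                            * rng.normal(1.0, 0.03)})
    fcs = reporter_fold_change(pd.DataFrame(medians))
    fcs.to_csv(args.out / "tables" / "reporter_fold_change.tsv", sep="\t",
               index=False)
    print("\nreporter fold change (pre-stressed / untreated):")
    print(fcs.to_string(index=False))
    print(f"cross-strain rank test p = {fcs.attrs['cross_strain_pval']:.3f}")


if __name__ == "__main__":
    main()
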