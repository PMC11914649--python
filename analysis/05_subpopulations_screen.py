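#!/usr/bin/env python
"""Classify stress-related subpopulations and score the deletion screen.

Wild-type thresholds (the score last decile per condition) define
basal-stressed cells; six-sentinel co-expression above mean + Gini mean
difference defines hyper-responsive cells; and every genotype of the
barcoded pool is screened for basal / hyper / variability phenotypes
against the two wild-type strains.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from _common import INDUCED, driver_args
from osmohet import PipelineConfig, preprocess
from osmohet.data import load_dataset_dir
from osmohet.screen import (basal_threshold, classify_basal_stressed,
                            classify_hyper_responsive, coexpression_score,
                            screen_genotypes)
from osmohet.signatures import GeneSignature, score_signature


def main() -> None:
    args = driver_args(__doc__)
    cfg = PipelineConfig(seed=args.seed)
    scratch = Path("scratch/simulated")
    ds = preprocess(load_dataset_dir(scratch / "screen_pool_demuxed"), cfg)
    truth = pd.read_csv(args.out / "tables" / "screen_pool_truth.tsv",
                        sep="\t").set_index("cell_id")
    sig = GeneSignature("induced_consensus", INDUCED, "induced")
    scores = score_signature(ds, sig, cfg)

    # basal-stressed cells among pooled wild-type control cells
    wt_ctrl = scores[(scores["genotype"].str.startswith("WT"))
                     & (scores["condition"] == "control")]
    thr = basal_threshold(wt_ctrl["score"], cfg)
    frac = classify_basal_stressed(wt_ctrl["score"], thr).mean()
    planted = truth.loc[wt_ctrl.index, "basal_stressed"].mean()
    print(f"WT control: threshold {thr:.3f}; {100*frac:.1f}% basal-stressed "
          f"(planted {100*planted:.1f}%)")

    # hyper-responsive cells among stressed cells
    stressed = ds.subset_cells((ds.cell_meta["condition"] == "NaCl").to_numpy())
    co = coexpression_score(stressed)
    flags, co_thr = classify_hyper_responsive(co)
    hyper_truth = truth.loc[co.index, "hyper"].to_numpy()
    tp = int((np.asarray(flags) & hyper_truth).sum())
    print(f"stressed pool: co-expression threshold {co_thr:.3f}; "
          f"{int(np.asarray(flags).sum())} hyper-responsive cells "
          f"(precision {tp/max(int(np.asarray(flags).sum()),1):.2f}, "
          f"recall {tp/max(int(hyper_truth.sum()),1):.2f})")
    hyper_flags = pd.Series(np.asarray(flags), index=co.index)

    # full genotype screen
    tab = screen_genotypes(scores, cfg, wt_label="WT",
                           hyper_flags=hyper_flags)
    tab.to_csv(args.out / "tables" / "screen_table.tsv", sep="\t",
               index=False)
    stress_rows = tab[tab["condition"] == "NaCl"]
    flagged = stress_rows[stress_rows["flag_variable"]]["genotype"].tolist()
    print(f"variability screen: flagged {sorted(flagged)} "
          f"(planted: var0..var4)")


if __name__ == "__main__":
    main()
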