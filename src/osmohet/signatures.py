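"""Gene signatures and rank-based per-cell signature scores.

The consensus builder distils induced / repressed / unresponsive gene sets
from a bulk fold-change table (top 200 by log2 fold change among genes
clearing log2FC >= 1 and p < 0.05, mirrored for repression; unresponsive =
200 genes nearest zero change).  The per-cell score is a Mann-Whitney U
statistic on the within-cell gene ranking of the log-normalized expression,
capped at ``rank_cap`` so that genes buried in the untranscribed tail
contribute a fixed floor: score = 1 - U / (n_sig * rank_cap), clamped to
[0, 1].  A cell expressing the whole signature at the top of its ranking
scores 1; a cell expressing none of it scores the capped floor.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.stats

from .config import PipelineConfig
from .data import CountDataset, FormatError, lognorm_dense

log = logging.getLogger("osmohet")

SIGNATURE_CLASSES = ("induced", "repressed", "unresponsive",
                     "tf_targets", "daughter")


@dataclass
class GeneSignature:
    """Named, ordered gene list with its class and selection thresholds."""

    name: str
    genes: list[str]
    klass: str
    selection_record: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError(f"signature {self.name!r} is empty")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError(f"signature {self.name!r} has duplicate genes")
        if self.klass not in SIGNATURE_CLASSES:
            raise ValueError(f"unknown signature class {self.klass!r}")

    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame({"gene": self.genes, "class": self.klass}
                     ).to_csv(path, sep="\t", index=False)

    @staticmethod
    def from_tsv(path: str | Path, name: str | None = None) -> "GeneSignature":
        df = pd.read_csv(path, sep="\t")
        if not {"gene", "class"} <= set(df.columns):
            raise FormatError("signature TSV needs 'gene' and 'class' columns")
        klass = df["class"].iloc[0]
        return GeneSignature(name=name or Path(path).stem,
                             genes=df["gene"].tolist(), klass=klass)


def build_consensus_signatures(
        fc_table: pd.DataFrame | str | Path,
        cfg: PipelineConfig | None = None,
        n_top: int = 200,
        log2fc_min: float = 1.0,
        unresponsive_band: float = 0.5,
        alpha: float = 0.05) -> dict[str, GeneSignature]:
    """Build induced / repressed / unresponsive consensus signatures.

    ``fc_table`` needs columns ``gene``, ``log2fc`` and ``pval``.  Induced =
    the ``n_top`` largest log2 fold changes among genes with log2fc >=
    ``log2fc_min`` and p < ``alpha``; repressed is the mirror image;
    unresponsive = the ``n_top`` genes with |log2fc| <= ``unresponsive_band``
    nearest zero (no p criterion: a no-change class has no significance to
    demand).  When fewer than ``n_top`` genes qualify, all qualifiers are
    returned with a warning.
    """
    if not isinstance(fc_table, pd.DataFrame):
        fc_table = pd.read_csv(fc_table, sep="\t")
    needed = {"gene", "log2fc", "pval"}
    if not needed <= set(fc_table.columns):
        raise FormatError(f"fold-change table needs columns {sorted(needed)}")

    lfc, p = fc_table["log2fc"], fc_table["pval"]

    ind = fc_table[(lfc >= log2fc_min) & (p < alpha)]
    ind = ind.sort_values("log2fc", ascending=False).head(n_top)

    rep = fc_table[(lfc <= -log2fc_min) & (p < alpha)]
    rep = rep.sort_values("log2fc", ascending=True).head(n_top)

    unr = fc_table[lfc.abs() <= unresponsive_band]
    unr = unr.iloc[np.argsort(np.abs(unr["log2fc"].to_numpy()),
                              kind="stable")].head(n_top)

    record = {"n_top": n_top, "log2fc_min": log2fc_min,
              "unresponsive_band": unresponsive_band, "alpha": alpha}
    out: dict[str, GeneSignature] = {}
    for key, sel in (("induced", ind), ("repressed", rep),
                     ("unresponsive", unr)):
        if len(sel) == 0:
            log.warning("%s signature: no qualifying genes, omitted", key)
            continue
        if len(sel) < n_top:
            log.warning("%s signature: only %d of %d qualifying genes",
                        key, len(sel), n_top)
        out[key] = GeneSignature(f"{key}_consensus", sel["gene"].tolist(),
                                 key, record)
    return out


def score_signature(ds: CountDataset, sig: GeneSignature,
                    cfg: PipelineConfig) -> pd.DataFrame:
    """Per-cell rank-based signature score in [0, 1].

    Within each cell, all genes are ranked by lognorm expression in
    descending order with ties given their average rank; ranks beyond
    ``rank_cap`` are replaced by ``rank_cap + 1``.  With n signature genes
    present, U = sum of their (capped) ranks - n(n+1)/2 and score =
    clamp(1 - U / (n * rank_cap), 0, 1).

    Returns a DataFrame indexed by cell id with columns ``score``,
    ``signature``, ``rank_cap`` plus the genotype/condition/time metadata.
    """
    expr = lognorm_dense(ds)
    present = np.isin(ds.gene_ids, sig.genes)
    n_sig = int(present.sum())
    if n_sig == 0:
        raise ValueError(
            f"no gene of signature {sig.name!r} present in the dataset")
    if n_sig < len(sig.genes):
        log.warning("signature %s: %d of %d genes present",
                    sig.name, n_sig, len(sig.genes))

    # descending ranks with average ties, capped
    ranks = scipy.stats.rankdata(-expr, axis=1, method="average")
    ranks = np.minimum(ranks, cfg.rank_cap + 1)
    u = ranks[:, present].sum(axis=1) - n_sig * (n_sig + 1) / 2.0
    score = np.clip(1.0 - u / (n_sig * cfg.rank_cap), 0.0, 1.0)

    out = pd.DataFrame({"score": score,
                        "signature": sig.name,
                        "rank_cap": cfg.rank_cap},
                       index=pd.Index(ds.cell_ids, name="cell_id"))
    for col in ("genotype", "condition", "time_min"):
        if col in ds.cell_meta.columns:
            out[col] = ds.cell_meta[col].to_numpy()
    return out


def percent_expressing(ds: CountDataset, sig: GeneSignature,
                       group_by: str = "condition") -> pd.DataFrame:
    """Per-gene expressing fraction and (scaled) mean expression by group.

    The expressing fraction uses raw count > 0; ``mean_lognorm`` averages
    the log-normalized expression over the group's cells, and
    ``scaled_mean`` min-max scales that mean over the signature genes
    within each group.  Empty groups are omitted with a warning.
    """
    present = [g for g in sig.genes if g in set(ds.gene_ids)]
    absent = set(sig.genes) - set(present)
    if absent:
        log.warning("percent_expressing: %d signature genes absent",
                    len(absent))
    gidx = np.array([ds.gene_index(g) for g in present])
    counts = np.asarray(ds.counts[:, gidx].todense())
    expr = lognorm_dense(ds)[:, gidx]

    rows = []
    for group, idx in ds.cell_meta.groupby(group_by, sort=True).groups.items():
        pos = ds.cell_meta.index.get_indexer(idx)
        if len(pos) == 0:
            log.warning("percent_expressing: empty group %r omitted", group)
            continue
        frac = (counts[pos] > 0).mean(axis=0)
        mean = expr[pos].mean(axis=0)
        rng = mean.max() - mean.min()
        scaled = (mean - mean.min()) / rng if rng > 0 else np.zeros_like(mean)
        rows.append(pd.DataFrame({
            "gene": present, "group": group, "fraction_expressing": frac,
            "mean_lognorm": mean, "scaled_mean": scaled}))
    return pd.concat(rows, ignore_index=True)
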