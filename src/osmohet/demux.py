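"""Genotype assignment and cell quality control.

Two assignment routes mirror the two experimental designs: selection-marker
genes (KAN/NAT/HPH plus absence of the deleted ORF) for small strain pools,
and transcribed genotype barcodes (``bc-`` pseudo-genes, one per deletion
strain) for the pooled deletion screen.  Cells failing either route are
labelled ``Excluded``/``Unassigned``/``Doublet`` so that the label set
always partitions the population.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import yaml

from .config import PipelineConfig
from .data import CountDataset

log = logging.getLogger("osmohet")

UNASSIGNED = "Unassigned"
DOUBLET = "Doublet"
EXCLUDED = "Excluded"


class ConfigurationError(ValueError):
    """Rule refers to features absent from the dataset."""


@dataclass
class MarkerRule:
    """Assign ``label`` when every positive marker reaches the count floor
    and every zero marker is fully absent."""

    label: str
    positive_markers: list[str]
    zero_markers: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        overlap = set(self.positive_markers) & set(self.zero_markers)
        if overlap:
            raise ValueError(
                f"markers {sorted(overlap)} both positive and zero "
                f"in rule {self.label!r}")

    @staticmethod
    def from_yaml(path) -> list["MarkerRule"]:
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return [MarkerRule(label=r["label"],
                           positive_markers=list(r.get("positive_markers", [])),
                           zero_markers=list(r.get("zero_markers", [])))
                for r in raw]


def filter_cells_by_gene_count(ds: CountDataset,
                               cfg: PipelineConfig) -> CountDataset:
    """Retain cells with qc_min_genes <= detected genes <= qc_max_genes.

    The exclusion wording is strict ("fewer than" / "more than"), so the
    boundary values themselves are retained.  Idempotent.
    """
    n = ds.cell_meta["n_genes_detected"].to_numpy()
    keep = (n >= cfg.qc_min_genes) & (n <= cfg.qc_max_genes)
    frac = keep.mean() if len(keep) else 0.0
    log.info("QC filter: retained %d/%d cells (%.1f%%)",
             int(keep.sum()), len(keep), 100 * frac)
    if not keep.any():
        log.warning("QC filter removed every cell")
    return ds.subset_cells(keep)


def assign_by_markers(ds: CountDataset, rules: list[MarkerRule],
                      cfg: PipelineConfig) -> CountDataset:
    """Label cells by selection-marker expression and drop the marker genes.

    A cell receives a rule's label iff every positive marker has count >=
    ``marker_min_count`` and every zero marker has count 0.  Several rules
    may share a label (a strain carrying alternative cassettes); a cell
    whose positive markers satisfy rules of more than one *label* carries
    more than one strain's cassette (a marker doublet) and is
    ``Excluded``, as are cells matching no rule.  The positive-marker
    features (the selection cassettes) are removed from the matrix
    afterwards; zero markers may be ordinary genes (e.g. the deleted ORF)
    and are kept.
    """
    marker_genes = sorted({g for r in rules
                           for g in r.positive_markers + r.zero_markers})
    missing = [g for g in marker_genes if g not in set(ds.gene_ids)]
    if missing:
        raise ConfigurationError(f"marker genes absent from dataset: {missing}")
    cols = {g: np.asarray(ds.counts[:, ds.gene_index(g)].todense()).ravel()
            for g in marker_genes}

    labels = np.full(ds.n_cells, EXCLUDED, dtype=object)
    reasons = np.full(ds.n_cells, "no_rule_matched", dtype=object)
    label_fired: dict[str, np.ndarray] = {}
    for rule in rules:
        pos = np.ones(ds.n_cells, dtype=bool)
        for g in rule.positive_markers:
            pos &= cols[g] >= cfg.marker_min_count
        hit = pos.copy()
        for g in rule.zero_markers:
            hit &= cols[g] == 0
        labels[hit] = rule.label
        reasons[hit] = f"rule:{rule.label}"
        fired = label_fired.setdefault(rule.label,
                                       np.zeros(ds.n_cells, dtype=bool))
        fired |= pos
    multi = sum(f.astype(int) for f in label_fired.values()) > 1
    labels[multi] = EXCLUDED
    reasons[multi] = "multiple_rules"
    log.info("marker assignment: %s",
             {lab: int((labels == lab).sum()) for lab in np.unique(labels)})

    cassette_genes = sorted({g for r in rules for g in r.positive_markers})
    out = ds.subset_genes(~np.isin(ds.gene_ids, cassette_genes))
    out.cell_meta["genotype"] = labels
    out.cell_meta["assignment_reason"] = reasons
    return out


def assign_by_barcodes(ds: CountDataset,
                       barcode_prefix: str = "bc-") -> CountDataset:
    """Label cells by their transcribed genotype barcode.

    Exactly one barcode feature with count >= 1 assigns that genotype
    (the barcode name with the prefix stripped); zero detected barcodes
    gives ``Unassigned`` and more than one gives ``Doublet``.  Barcode
    features are removed from the matrix afterwards.
    """
    is_bc = np.array([str(g).startswith(barcode_prefix) for g in ds.gene_ids])
    if not is_bc.any():
        raise ConfigurationError(
            f"no features match barcode prefix {barcode_prefix!r}")
    bc_counts = np.asarray(ds.counts[:, is_bc].todense())
    bc_names = np.array([str(g)[len(barcode_prefix):]
                         for g in ds.gene_ids[is_bc]], dtype=object)
    detected = bc_counts >= 1
    n_det = detected.sum(axis=1)

    labels = np.full(ds.n_cells, UNASSIGNED, dtype=object)
    labels[n_det > 1] = DOUBLET
    single = n_det == 1
    labels[single] = bc_names[np.argmax(detected[single], axis=1)]
    reasons = np.select(
        [n_det == 0, n_det == 1, n_det > 1],
        np.array(["no_barcode", "single_barcode", "multiple_barcodes"],
                 dtype=object), default="")
    log.info("barcode assignment: %d assigned, %d unassigned, %d doublets",
             int(single.sum()), int((n_det == 0).sum()), int((n_det > 1).sum()))

    out = ds.subset_genes(~is_bc)
    out.cell_meta["genotype"] = labels
    out.cell_meta["assignment_reason"] = reasons
    return out
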