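"""Count-matrix container and file I/O.

A :class:`CountDataset` holds a sparse cell x gene UMI matrix, its cell and
gene identifiers, a per-cell metadata table and optional real-valued layers
(e.g. the log-normalized expression).  On disk a dataset is a directory of
plain-text files: a Matrix Market coordinate file (cells as rows, 1-based
indices per that format's convention), one-id-per-line ``genes.tsv`` and
``barcodes.tsv`` sidecars, a ``metadata.tsv`` with header, and one ``.mtx``
per layer.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from .config import PipelineConfig

log = logging.getLogger("osmohet")

#: metadata columns guaranteed to exist on every dataset
META_COLUMNS = ("genotype", "condition", "time_min",
                "n_genes_detected", "n_molecules")


class FormatError(ValueError):
    """Malformed input file (bad dimensions, missing columns...)."""


class ValidationError(ValueError):
    """Structurally valid input violating a dataset invariant."""


@dataclass
class CountDataset:
    """Sparse cell x gene UMI counts plus per-cell annotations.

    ``cell_meta`` is indexed by ``cell_ids`` and always carries the columns
    in :data:`META_COLUMNS`; ``n_genes_detected`` and ``n_molecules`` are
    derived from the counts and refreshed whenever the matrix changes.
    """

    counts: sp.csr_matrix
    cell_ids: np.ndarray
    gene_ids: np.ndarray
    cell_meta: pd.DataFrame
    layers: dict[str, sp.csr_matrix] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.counts = sp.csr_matrix(self.counts)
        self.cell_ids = np.asarray(self.cell_ids, dtype=object)
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        if len(set(self.cell_ids)) != len(self.cell_ids):
            raise ValidationError("duplicate cell ids")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValidationError("duplicate gene ids")
        if self.counts.shape != (len(self.cell_ids), len(self.gene_ids)):
            raise FormatError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.cell_ids)} cells x {len(self.gene_ids)} genes")
        if self.counts.nnz and self.counts.data.min() < 0:
            raise ValidationError("negative counts")
        for name, layer in self.layers.items():
            if layer.shape != self.counts.shape:
                raise ValidationError(f"layer {name!r} shape mismatch")
        self.cell_meta = self.cell_meta.reindex(self.cell_ids)
        self.refresh_derived()

    # -- derived per-cell quantities ------------------------------------
    def refresh_derived(self) -> None:
        """Recompute n_genes_detected and n_molecules from the counts."""
        counts = self.counts
        self.cell_meta["n_genes_detected"] = np.diff(counts.indptr)
        self.cell_meta["n_molecules"] = np.asarray(
            counts.sum(axis=1)).ravel().astype(np.int64)
        for col, default in (("genotype", "Unassigned"),
                             ("condition", "control"),
                             ("time_min", 0)):
            if col not in self.cell_meta.columns:
                self.cell_meta[col] = default

    @property
    def n_cells(self) -> int:
        return self.counts.shape[0]

    @property
    def n_genes(self) -> int:
        return self.counts.shape[1]

    def gene_index(self, gene: str) -> int:
        idx = np.flatnonzero(self.gene_ids == gene)
        if idx.size == 0:
            raise KeyError(f"gene {gene!r} not in dataset")
        return int(idx[0])

    def subset_cells(self, mask: np.ndarray) -> "CountDataset":
        mask = np.asarray(mask)
        return CountDataset(
            counts=self.counts[mask],
            cell_ids=self.cell_ids[mask],
            gene_ids=self.gene_ids.copy(),
            cell_meta=self.cell_meta.loc[self.cell_ids[mask]].copy(),
            layers={k: v.tocsr()[mask] for k, v in self.layers.items()},
        )

    def subset_genes(self, mask: np.ndarray) -> "CountDataset":
        mask = np.asarray(mask)
        return CountDataset(
            counts=self.counts[:, mask].tocsr(),
            cell_ids=self.cell_ids.copy(),
            gene_ids=self.gene_ids[mask],
            cell_meta=self.cell_meta.copy(),
            layers={k: v.tocsr()[:, mask].tocsr()
                    for k, v in self.layers.items()},
        )


# ---------------------------------------------------------------------- I/O

def load_dataset(counts_path: str | Path,
                 genes_path: str | Path,
                 cells_path: str | Path,
                 meta_path: str | Path | None = None) -> CountDataset:
    """Read a dataset from a Matrix Market triplet file and its sidecars.

    Cells are rows of the matrix; the row/column order of the sidecar files
    is preserved.  ``meta_path`` (TSV with a ``cell_id`` column) is merged
    when given; derived QC columns are always recomputed.
    """
    try:
        mat = scipy.io.mmread(str(counts_path))
    except ValueError as exc:
        raise FormatError(f"bad Matrix Market file {counts_path}: {exc}") from exc
    genes = _read_id_column(genes_path)
    cells = _read_id_column(cells_path)
    if mat.shape != (len(cells), len(genes)):
        raise FormatError(
            f"matrix is {mat.shape} but sidecars declare "
            f"{len(cells)} cells x {len(genes)} genes")
    if meta_path is not None:
        meta = pd.read_csv(meta_path, sep="\t", dtype={"cell_id": str})
        if "cell_id" not in meta.columns:
            raise FormatError("metadata TSV lacks a cell_id column")
        meta = meta.set_index("cell_id")
        missing = set(cells) - set(meta.index)
        if missing:
            raise FormatError(f"metadata missing {len(missing)} cell ids")
        meta = meta.loc[cells]
        meta.index = cells
    else:
        meta = pd.DataFrame(index=cells)
    ds = CountDataset(counts=sp.csr_matrix(mat, dtype=np.int64),
                      cell_ids=cells, gene_ids=genes, cell_meta=meta)
    layer_dir = Path(counts_path).parent
    for layer_file in sorted(layer_dir.glob("layer_*.mtx")):
        name = layer_file.stem[len("layer_"):]
        lmat = sp.csr_matrix(scipy.io.mmread(str(layer_file)))
        if lmat.shape != ds.counts.shape:
            raise FormatError(f"layer file {layer_file} shape mismatch")
        ds.layers[name] = lmat
    return ds


def save_dataset(ds: CountDataset, out_dir: str | Path) -> dict[str, Path]:
    """Write a dataset to ``out_dir``; round-trips exactly via load_dataset."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "counts": out / "matrix.mtx",
        "genes": out / "genes.tsv",
        "cells": out / "barcodes.tsv",
        "meta": out / "metadata.tsv",
    }
    scipy.io.mmwrite(str(paths["counts"]), ds.counts.tocoo(), field="integer")
    paths["genes"].write_text("".join(f"{g}\n" for g in ds.gene_ids))
    paths["cells"].write_text("".join(f"{c}\n" for c in ds.cell_ids))
    meta = ds.cell_meta.copy()
    meta.insert(0, "cell_id", ds.cell_ids)
    meta.to_csv(paths["meta"], sep="\t", index=False)
    for name, layer in ds.layers.items():
        p = out / f"layer_{name}.mtx"
        # precision 17 makes the float64 text round-trip exact
        scipy.io.mmwrite(str(p), layer.tocoo(), field="real", precision=17)
        paths[f"layer_{name}"] = p
    return paths


def load_dataset_dir(in_dir: str | Path) -> CountDataset:
    """Convenience loader for a directory written by :func:`save_dataset`."""
    d = Path(in_dir)
    meta = d / "metadata.tsv"
    return load_dataset(d / "matrix.mtx", d / "genes.tsv", d / "barcodes.tsv",
                        meta if meta.exists() else None)


def _read_id_column(path: str | Path) -> np.ndarray:
    ids = [line.strip() for line in Path(path).read_text().splitlines()
           if line.strip()]
    return np.asarray(ids, dtype=object)


# -------------------------------------------------------------- preprocess

RIBOSOMAL_PREFIXES = ("RPL", "RPS")


def preprocess(ds: CountDataset, cfg: PipelineConfig) -> CountDataset:
    """Drop ribosomal protein genes and add the log-normalized layer.

    Genes whose id starts with ``RPL`` or ``RPS`` (case-sensitive) are
    removed; the retained counts are library-size scaled to ``norm_scale``
    molecules and log1p-transformed into a ``lognorm`` layer.  Counts are
    left untouched.  Cells with zero molecules after the gene filter get an
    all-zero lognorm row and a warning.
    """
    keep = np.array([not str(g).startswith(RIBOSOMAL_PREFIXES)
                     for g in ds.gene_ids])
    n_dropped = int((~keep).sum())
    if n_dropped:
        log.info("preprocess: removed %d ribosomal protein genes", n_dropped)
    out = ds.subset_genes(keep)

    counts = out.counts.tocoo()
    n_mol = out.cell_meta["n_molecules"].to_numpy(dtype=np.float64)
    zero_cells = n_mol == 0
    if zero_cells.any():
        log.warning("preprocess: %d cells with zero molecules; lognorm rows "
                    "set to 0", int(zero_cells.sum()))
    scale = np.where(zero_cells, 0.0, cfg.norm_scale / np.maximum(n_mol, 1.0))
    data = np.log1p(counts.data * scale[counts.row])
    out.layers["lognorm"] = sp.csr_matrix(
        (data, (counts.row, counts.col)), shape=out.counts.shape)
    return out


def lognorm_dense(ds: CountDataset) -> np.ndarray:
    """Dense view of the lognorm layer (errors if preprocess was not run)."""
    if "lognorm" not in ds.layers:
        raise ValidationError("dataset has no lognorm layer; run preprocess")
    return np.asarray(ds.layers["lognorm"].todense())
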