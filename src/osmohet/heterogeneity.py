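"""Population statistics of signature expression.

Moments and Fano factor per group, per-cell gene-usage fingerprints,
usage-vs-strength correlation, the induction-repression coupling fit, and
rank-sum differential tests with Benjamini-Hochberg control.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
import scipy.stats
from scipy.stats import false_discovery_control

from .config import PipelineConfig
from .data import CountDataset, lognorm_dense
from .signatures import GeneSignature

log = logging.getLogger("osmohet")

#: significance-star thresholds shared by the figure-style outputs
STAR_LEVELS = ((0.0001, "****"), (0.001, "***"), (0.01, "**"), (0.05, "*"))


def p_to_stars(p: float) -> str:
    for cut, stars in STAR_LEVELS:
        if p < cut:
            return stars
    return "ns"


def fano_factor(x: np.ndarray) -> float:
    """Variance over mean (sample variance, n-1); NaN when mean is 0."""
    x = np.asarray(x, dtype=float)
    m = x.mean()
    if m == 0 or len(x) < 2:
        return float("nan")
    return float(x.var(ddof=1) / m)


def gene_fano(counts: np.ndarray) -> np.ndarray:
    """Per-gene Fano factor of a dense cell x gene count block."""
    m = counts.mean(axis=0)
    v = counts.var(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        return np.where(m > 0, v / m, np.nan)


def group_stats(scores: pd.DataFrame, group_by: str | list[str],
                value_col: str = "score") -> pd.DataFrame:
    """Mean/median/SD/variance/Fano of a score column per group.

    Uses sample variance (n-1).  Groups of size 1 get NaN SD/variance; the
    Fano factor is NaN whenever the group mean is 0.
    """
    rows = []
    for key, sub in scores.groupby(group_by, sort=True, observed=True):
        x = sub[value_col].to_numpy(dtype=float)
        n = len(x)
        mean = x.mean()
        var = x.var(ddof=1) if n > 1 else float("nan")
        rows.append({
            "group": key if np.isscalar(key) or isinstance(key, str) else tuple(key),
            "n_cells": n,
            "mean": mean,
            "median": float(np.median(x)),
            "sd": float(np.sqrt(var)) if n > 1 else float("nan"),
            "variance": float(var) if n > 1 else float("nan"),
            "fano": float(var / mean) if n > 1 and mean > 0 else float("nan"),
        })
    return pd.DataFrame(rows)


def expression_fingerprint(ds: CountDataset, sig: GeneSignature
                           ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Binary usage fingerprint of a signature per cell.

    Returns (binary cell x gene DataFrame of lognorm > 0, per-cell summary
    with the detected-gene count and the top-expressed signature gene; ties
    resolve to the lexicographically first gene id and are logged).  Cells
    expressing no signature gene get top_gene = NaN.
    """
    present = [g for g in sig.genes if g in set(ds.gene_ids)]
    if len(present) < len(sig.genes):
        log.warning("fingerprint: %d signature genes absent",
                    len(sig.genes) - len(present))
    order = np.argsort(np.asarray(present, dtype=object))
    genes_sorted = list(np.asarray(present, dtype=object)[order])
    gidx = np.array([ds.gene_index(g) for g in genes_sorted])
    expr = lognorm_dense(ds)[:, gidx]

    detected = expr > 0
    fingerprint = pd.DataFrame(detected.astype(np.int8),
                               index=pd.Index(ds.cell_ids, name="cell_id"),
                               columns=genes_sorted)
    # argmax over gene-id-sorted columns implements the lexicographic tie rule
    top_idx = expr.argmax(axis=1)
    n_ties = int((np.sum(expr == expr.max(axis=1, keepdims=True), axis=1) > 1)
                 .sum())
    if n_ties:
        log.info("fingerprint: %d cells with tied top gene "
                 "(first by gene id)", n_ties)
    any_expr = detected.any(axis=1)
    summary = pd.DataFrame({
        "n_detected": detected.sum(axis=1),
        "top_gene": np.where(any_expr,
                             np.asarray(genes_sorted, dtype=object)[top_idx],
                             None),
    }, index=pd.Index(ds.cell_ids, name="cell_id"))
    return fingerprint, summary


def usage_vs_strength(ds: CountDataset, sig: GeneSignature,
                      detected_only: bool = False
                      ) -> tuple[pd.DataFrame, float]:
    """Detected signature genes vs mean signature expression per cell.

    Returns (per-cell table with ``n_detected`` and ``mean_score``,
    Spearman rho with average-rank ties).  ``detected_only`` averages the
    lognorm over detected genes instead of the whole signature.  The
    correlation is NaN when either vector is constant or n < 3.
    """
    present = [g for g in sig.genes if g in set(ds.gene_ids)]
    gidx = np.array([ds.gene_index(g) for g in present])
    expr = lognorm_dense(ds)[:, gidx]
    n_det = (expr > 0).sum(axis=1)
    if detected_only:
        with np.errstate(invalid="ignore"):
            mean_score = np.where(n_det > 0,
                                  expr.sum(axis=1) / np.maximum(n_det, 1), 0.0)
    else:
        mean_score = expr.mean(axis=1)
    table = pd.DataFrame({"n_detected": n_det, "mean_score": mean_score},
                         index=pd.Index(ds.cell_ids, name="cell_id"))
    if len(table) < 3 or np.ptp(n_det) == 0 or np.ptp(mean_score) == 0:
        return table, float("nan")
    rho = scipy.stats.spearmanr(n_det, mean_score).statistic
    return table, float(rho)


def coupling_correlation(induced_scores: pd.DataFrame,
                         repressed_scores: pd.DataFrame,
                         group_by: str = "condition") -> pd.DataFrame:
    """Pearson correlation and least-squares line, induced vs repressed.

    Both inputs are score tables indexed by cell id (as returned by
    ``score_signature``); the induced score is x, the repressed score y.
    Per group: Pearson r, slope, intercept and the 95% CI of the slope.
    Groups with n < 3 get NaN statistics.
    """
    merged = pd.DataFrame({
        "induced": induced_scores["score"],
        "repressed": repressed_scores.loc[induced_scores.index, "score"],
        "group": induced_scores[group_by],
    })
    rows = []
    for key, sub in merged.groupby("group", sort=True):
        n = len(sub)
        if n < 3 or np.ptp(sub["induced"]) == 0 or np.ptp(sub["repressed"]) == 0:
            rows.append({"group": key, "n_cells": n, "pearson_r": np.nan,
                         "slope": np.nan, "intercept": np.nan,
                         "slope_ci_low": np.nan, "slope_ci_high": np.nan})
            continue
        fit = scipy.stats.linregress(sub["induced"], sub["repressed"])
        tcrit = scipy.stats.t.ppf(0.975, n - 2)
        rows.append({"group": key, "n_cells": n,
                     "pearson_r": float(fit.rvalue),
                     "slope": float(fit.slope),
                     "intercept": float(fit.intercept),
                     "slope_ci_low": float(fit.slope - tcrit * fit.stderr),
                     "slope_ci_high": float(fit.slope + tcrit * fit.stderr)})
    return pd.DataFrame(rows)


def de_wilcoxon(ds: CountDataset, cells_a: np.ndarray, cells_b: np.ndarray,
                cfg: PipelineConfig) -> pd.DataFrame:
    """Per-gene two-sided rank-sum test of group A vs group B.

    Tests the lognorm expression; the fold change back-transforms the group
    means: log2FC = log2((mean expm1 A + eps) / (mean expm1 B + eps)) with
    eps = 1e-9.  BH q-values are computed over all tested genes; the ``up``
    flag requires log2FC >= log2(de_min_fc) and p < de_alpha (``down`` is
    the mirror image).
    """
    mask_a, mask_b = (np.asarray(m) for m in (cells_a, cells_b))
    if mask_a.dtype != bool:
        mask_a = np.isin(ds.cell_ids, mask_a)
    if mask_b.dtype != bool:
        mask_b = np.isin(ds.cell_ids, mask_b)
    if mask_a.sum() == 0 or mask_b.sum() == 0:
        raise ValueError("both groups must contain at least one cell")

    expr = lognorm_dense(ds)
    a, b = expr[mask_a], expr[mask_b]
    res = scipy.stats.mannwhitneyu(a, b, axis=0, alternative="two-sided")
    eps = 1e-9
    log2fc = np.log2((np.expm1(a).mean(axis=0) + eps)
                     / (np.expm1(b).mean(axis=0) + eps))
    q = false_discovery_control(res.pvalue, method="bh")
    lfc_min = np.log2(cfg.de_min_fc)
    out = pd.DataFrame({
        "gene": ds.gene_ids,
        "log2fc": log2fc,
        "pval": res.pvalue,
        "qval": q,
        "up": (log2fc >= lfc_min) & (res.pvalue < cfg.de_alpha),
        "down": (log2fc <= -lfc_min) & (res.pvalue < cfg.de_alpha),
    })
    log.info("de_wilcoxon: %d up, %d down of %d genes",
             int(out["up"].sum()), int(out["down"].sum()), len(out))
    return out


def cluster_vs_population_test(scores: pd.DataFrame,
                               cluster_labels: pd.Series | np.ndarray,
                               value_col: str = "score") -> pd.DataFrame:
    """Two-sided rank-sum of each cluster against the whole population.

    Each cluster is tested against all cells (the population including the
    cluster); BH adjustment runs across clusters and significance stars
    are mapped at 0.05 / 0.01 / 0.001 / 0.0001.  Clusters of size < 2 get
    NaN p-values.
    """
    values = scores[value_col].to_numpy(dtype=float)
    labels = np.asarray(cluster_labels)
    rows = []
    for lab in pd.unique(labels):
        idx = labels == lab
        if idx.sum() < 2:
            rows.append({"cluster": lab, "n_cells": int(idx.sum()),
                         "pval": np.nan})
            continue
        p = scipy.stats.mannwhitneyu(values[idx], values,
                                     alternative="two-sided").pvalue
        rows.append({"cluster": lab, "n_cells": int(idx.sum()),
                     "pval": float(p)})
    out = pd.DataFrame(rows)
    tested = out["pval"].notna()
    out["qval"] = np.nan
    if tested.any():
        out.loc[tested, "qval"] = false_discovery_control(
            out.loc[tested, "pval"].to_numpy(), method="bh")
    out["stars"] = [p_to_stars(q) if np.isfinite(q) else "ns"
                    for q in out["qval"]]
    return out
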