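"""Subpopulation classifiers and the deletion-screen scoring.

Basal-stressed cells are unstressed cells whose induced-signature score
exceeds the wild-type 90th-percentile threshold; hyper-responsive cells
co-express a six-gene sentinel panel above the mean plus the Gini mean
difference of the joint co-expression score.  The screen summarises every
genotype x condition by these classifiers plus a variability flag against
the wild-type strains.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from sklearn.neighbors import NearestNeighbors

from .config import PipelineConfig
from .data import CountDataset, lognorm_dense

log = logging.getLogger("osmohet")

#: sentinel genes of the hyper-responsive co-expression panel
SENTINEL_GENES = ("STL1", "ALD3", "CTT1", "HSP12", "GRE1", "HXT5")


def basal_threshold(wt_scores: np.ndarray | pd.Series,
                    cfg: PipelineConfig) -> float:
    """Wild-type score quantile (linear interpolation) defining 'basal'.

    The last decile (``basal_quantile`` = 0.9) of the wild-type score
    distribution, computed per condition by the caller.  Fewer than 10
    wild-type cells triggers a warning but the quantile is still returned.
    """
    x = np.asarray(wt_scores, dtype=float)
    if len(x) < 10:
        log.warning("basal_threshold: only %d wild-type cells", len(x))
    return float(np.quantile(x, cfg.basal_quantile, method="linear"))


def classify_basal_stressed(scores: np.ndarray | pd.Series,
                            threshold: float) -> np.ndarray:
    """Strictly above the wild-type-derived threshold -> basal-stressed."""
    return np.asarray(scores, dtype=float) > threshold


def coexpression_score(ds: CountDataset,
                       sentinel_genes: tuple[str, ...] = SENTINEL_GENES,
                       neighbor_k: int = 30) -> pd.Series:
    """Joint co-expression score of the sentinel panel per cell.

    Each sentinel's lognorm value is smoothed over the cell's ``neighbor_k``
    nearest neighbours (Euclidean distance on the per-cell vector of
    sentinel lognorm values, the cell included), min-max scaled over cells,
    and the six scaled values are combined by their geometric mean.
    Deterministic given input order.
    """
    gene_set = set(ds.gene_ids)
    for g in sentinel_genes:
        if g not in gene_set:
            raise ValueError(f"sentinel gene {g!r} absent from dataset")
    gidx = np.array([ds.gene_index(g) for g in sentinel_genes])
    expr = lognorm_dense(ds)[:, gidx]

    k = min(neighbor_k, ds.n_cells)
    nn = NearestNeighbors(n_neighbors=k).fit(expr)
    _, idx = nn.kneighbors(expr)
    smooth = expr[idx].mean(axis=1)

    rng = smooth.max(axis=0) - smooth.min(axis=0)
    rng[rng == 0] = 1.0
    scaled = (smooth - smooth.min(axis=0)) / rng
    joint = np.exp(np.log(np.maximum(scaled, 0.0) + 1e-300).mean(axis=1))
    joint[np.any(scaled == 0, axis=1)] = 0.0
    return pd.Series(joint, index=pd.Index(ds.cell_ids, name="cell_id"),
                     name="coexpression")


def gini_mean_difference(x: np.ndarray) -> float:
    """Mean absolute difference over all pairs, 2/(n(n-1)) * sum_{i<j}|xi-xj|.

    Computed by the O(n log n) sorted identity
    sum_{i<j}(x_(j) - x_(i)) = sum_k (2k - n - 1) x_(k) (1-based k).
    NaN for n < 2.
    """
    x = np.asarray(x, dtype=float)
    n = len(x)
    if n < 2:
        return float("nan")
    xs = np.sort(x)
    k = np.arange(1, n + 1)
    total = np.sum((2 * k - n - 1) * xs)
    return float(2.0 * total / (n * (n - 1)))


def classify_hyper_responsive(coexp_scores: np.ndarray | pd.Series
                              ) -> tuple[np.ndarray, float]:
    """Threshold = mean + GMD of the co-expression score; strictly above
    -> hyper-responsive.  Constant scores flag no cell (GMD = 0 and the
    strict inequality excludes the boundary)."""
    x = np.asarray(coexp_scores, dtype=float)
    gmd = gini_mean_difference(x)
    threshold = float(x.mean() + (gmd if np.isfinite(gmd) else 0.0))
    return x > threshold, threshold


def screen_genotypes(scores: pd.DataFrame, cfg: PipelineConfig,
                     wt_label: str = "WT",
                     wt_strains: list[str] | None = None,
                     hyper_flags: pd.Series | None = None,
                     stress_condition: str = "NaCl") -> pd.DataFrame:
    """Score every genotype of the deletion screen.

    ``scores`` is a per-cell table (index = cell id) with columns ``score``,
    ``genotype`` and ``condition``.  Wild-type strains (``wt_strains``, or
    every genotype starting with ``wt_label``) define, per condition, the
    basal threshold (their pooled ``basal_quantile`` score quantile) and the
    variability reference.  Per genotype x condition the table reports cell
    count, score moments and Fano, the percentage of cells strictly above
    the condition's wild-type threshold, and — when ``hyper_flags`` (a
    per-cell boolean Series from the co-expression classifier) is given —
    the percentage of hyper-responsive cells.

    Flags: ``flag_basal`` / ``flag_hyper`` when the respective percentage
    is >= ``screen_flag_fraction`` (25%); ``flag_variable`` when the
    stress-condition score SD clears the wild-type variability rule
    (see ``PipelineConfig.variability_rule``).  Genotypes with fewer than
    ``screen_min_cells`` cells in a condition keep their values but are
    marked ``excluded_low_n`` with all flags suppressed.
    """
    needed = {"score", "genotype", "condition"}
    if not needed <= set(scores.columns):
        raise ValueError(f"scores table needs columns {sorted(needed)}")
    if wt_strains is None:
        wt_strains = sorted({g for g in scores["genotype"].unique()
                             if str(g).startswith(wt_label)})
    if not wt_strains:
        raise ValueError(f"no wild-type strains matching {wt_label!r}")

    is_wt = scores["genotype"].isin(wt_strains)
    thresholds = {
        cond: basal_threshold(sub.loc[is_wt, "score"], cfg)
        for cond, sub in scores.groupby("condition")
        if is_wt[sub.index].any()
    }
    for cond in scores["condition"].unique():
        if cond not in thresholds:
            raise ValueError(f"wild type absent from condition {cond!r}")

    # wild-type variability reference in the stress condition
    wt_stress = scores[is_wt & (scores["condition"] == stress_condition)]
    wt_sds = wt_stress.groupby("genotype")["score"].std(ddof=1)
    pooled_wt_sd = float(wt_stress["score"].std(ddof=1))
    if cfg.variability_rule == "replicate_sd":
        var_threshold = float(wt_sds.mean()
                              + cfg.wt_sd_multiplier * wt_sds.std(ddof=1))
    else:
        var_threshold = cfg.wt_sd_multiplier * pooled_wt_sd

    rows = []
    for (genotype, cond), sub in scores.groupby(["genotype", "condition"],
                                                sort=True):
        x = sub["score"].to_numpy(dtype=float)
        n = len(x)
        mean = x.mean()
        var = x.var(ddof=1) if n > 1 else float("nan")
        sd = float(np.sqrt(var)) if n > 1 else float("nan")
        pct_basal = 100.0 * float((x > thresholds[cond]).mean())
        if hyper_flags is not None:
            pct_hyper = 100.0 * float(
                hyper_flags.reindex(sub.index).eq(True).mean())
        else:
            pct_hyper = float("nan")
        low_n = n < cfg.screen_min_cells
        flag_pct = 100.0 * cfg.screen_flag_fraction
        rows.append({
            "genotype": genotype,
            "condition": cond,
            "n_cells": n,
            "mean": mean,
            "sd": sd,
            "variance": var,
            "fano": var / mean if n > 1 and mean > 0 else float("nan"),
            "pct_above_basal_threshold": pct_basal,
            "pct_hyper_responsive": pct_hyper,
            "excluded_low_n": low_n,
            "flag_basal": (not low_n) and pct_basal >= flag_pct,
            "flag_hyper": (not low_n) and np.isfinite(pct_hyper)
                          and pct_hyper >= flag_pct,
            "flag_variable": (not low_n) and cond == stress_condition
                             and np.isfinite(sd) and sd > var_threshold,
        })
    out = pd.DataFrame(rows)
    out.attrs["basal_thresholds"] = thresholds
    out.attrs["variability_threshold"] = var_threshold
    log.info("screen: %d genotype x condition rows, %d basal flags, "
             "%d hyper flags, %d variability flags", len(out),
             int(out["flag_basal"].sum()), int(out["flag_hyper"].sum()),
             int(out["flag_variable"].sum()))
    return out
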