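"""Growth-curve, competition and reporter-expression analytics.

Growth benefit of a mild pre-stress is summarised as the ratio of endpoint
optical densities (pre-stressed then high salt, over directly salt-shocked)
with the wild-type ratio as the reference; competition assays track the
proportion of a sorted subpopulation against a reference strain over time;
reporter fold changes compare median fluorescence of pre-stressed vs
untreated cultures.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
import scipy.stats

log = logging.getLogger("osmohet")

CONTROL = "control"
STRESS = "stress"
PRESTRESS = "prestress_then_stress"
CONDITIONS = (CONTROL, STRESS, PRESTRESS)


def _endpoint(curves: pd.DataFrame, genotype: str, condition: str,
              use_auc: bool = False) -> np.ndarray:
    """Per-replicate endpoint OD (or area under the curve) for one
    genotype x condition."""
    sub = curves[(curves["genotype"] == genotype)
                 & (curves["condition"] == condition)]
    if sub.empty:
        raise ValueError(
            f"no growth data for {genotype!r} in condition {condition!r}")
    vals = []
    for _, rep in sub.groupby("replicate"):
        rep = rep.sort_values("t_min")
        if use_auc:
            vals.append(np.trapezoid(rep["od"].to_numpy(),
                                     rep["t_min"].to_numpy()))
        else:
            vals.append(rep["od"].iloc[-1])
    return np.asarray(vals, dtype=float)


def growth_ratio(curves: pd.DataFrame, wt_label: str = "WT",
                 use_auc: bool = False) -> pd.DataFrame:
    """Pre-stress benefit ratio per genotype, classified against wild type.

    ``curves`` is long format (genotype, condition, replicate, t_min, od).
    Per genotype: ratio = mean endpoint OD(prestress_then_stress) / mean
    endpoint OD(stress); a genotype is classified ``higher`` when its ratio
    exceeds the wild-type ratio.  A zero direct-stress endpoint leaves the
    ratio NaN.  ``use_auc`` swaps the endpoint for the area under the
    curve.
    """
    ratios = {}
    for genotype in sorted(curves["genotype"].unique()):
        pre = _endpoint(curves, genotype, PRESTRESS, use_auc).mean()
        direct = _endpoint(curves, genotype, STRESS, use_auc).mean()
        if direct == 0:
            log.warning("growth_ratio: zero direct-stress endpoint for %s",
                        genotype)
            ratios[genotype] = float("nan")
        else:
            ratios[genotype] = float(pre / direct)
    if wt_label not in ratios:
        raise ValueError(f"wild type {wt_label!r} absent from growth table")
    wt_ratio = ratios[wt_label]
    out = pd.DataFrame({
        "genotype": list(ratios),
        "ratio": list(ratios.values()),
    })
    out["wt_ratio"] = wt_ratio
    out["higher_than_wt"] = out["ratio"] > wt_ratio
    return out


def competition_analysis(counts: pd.DataFrame) -> pd.DataFrame:
    """Population proportions over a competition time course.

    ``counts`` is long format (timepoint, replicate, count_a, count_b).
    Per replicate the proportion of population A is a/(a+b) (replicates
    with a+b = 0 are dropped with a warning); per timepoint the mean and
    SD across replicates are reported with a two-sided Welch t-test of the
    replicate proportions against the first (reference) timepoint.  With
    fewer than 2 replicates at either side the test is NaN.
    """
    df = counts.copy()
    total = df["count_a"] + df["count_b"]
    empty = total == 0
    if empty.any():
        log.warning("competition: dropped %d empty replicates",
                    int(empty.sum()))
        df, total = df[~empty], total[~empty]
    df = df.assign(proportion=df["count_a"] / total)

    timepoints = sorted(df["timepoint"].unique())
    ref = df[df["timepoint"] == timepoints[0]]["proportion"].to_numpy()
    rows = []
    for tp in timepoints:
        props = df[df["timepoint"] == tp]["proportion"].to_numpy()
        if tp == timepoints[0]:
            p = 1.0 if len(props) >= 2 else float("nan")
        elif len(props) >= 2 and len(ref) >= 2:
            if np.ptp(np.concatenate([props, ref])) == 0:
                p = 1.0    # identical constant proportions: no evidence
            else:
                p = float(scipy.stats.ttest_ind(props, ref,
                                                equal_var=False).pvalue)
        else:
            p = float("nan")
        rows.append({"timepoint": tp, "n_replicates": len(props),
                     "mean_proportion": float(props.mean()),
                     "sd_proportion": float(props.std(ddof=1))
                     if len(props) > 1 else float("nan"),
                     "pval_vs_t0": p})
    return pd.DataFrame(rows)


def reporter_fold_change(medians: pd.DataFrame) -> pd.DataFrame:
    """Per-strain mean pre-stress/untreated ratio of reporter medians.

    ``medians`` is long format (strain, prestressed [bool], replicate,
    median_expression).  Per replicate: ratio of the pre-stressed median to
    the matched untreated median (values above 1 mean the pre-stress raised
    expression).  Per strain the mean ratio over replicates is reported;
    with exactly two strains a two-sided rank-sum test compares their
    replicate ratios.  Zero denominators leave that replicate's ratio NaN.
    """
    rows = []
    per_strain_ratios = {}
    for strain, sub in medians.groupby("strain", sort=True):
        ratios = []
        for _, rep in sub.groupby("replicate"):
            pre = rep[rep["prestressed"]]["median_expression"]
            base = rep[~rep["prestressed"]]["median_expression"]
            if pre.empty or base.empty:
                continue
            denom = float(base.iloc[0])
            if denom == 0:
                log.warning("reporter_fold_change: zero baseline median for "
                            "%s", strain)
                ratios.append(float("nan"))
            else:
                ratios.append(float(pre.iloc[0]) / denom)
        ratios = np.asarray(ratios, dtype=float)
        finite = ratios[np.isfinite(ratios)]
        per_strain_ratios[strain] = finite
        rows.append({"strain": strain, "n_replicates": len(ratios),
                     "mean_ratio": float(finite.mean()) if len(finite)
                     else float("nan")})
    out = pd.DataFrame(rows)

    pval = float("nan")
    if len(per_strain_ratios) == 2:
        a, b = per_strain_ratios.values()
        if len(a) >= 2 and len(b) >= 2:
            pval = float(scipy.stats.mannwhitneyu(
                a, b, alternative="two-sided").pvalue)
    out.attrs["cross_strain_pval"] = pval
    return out
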