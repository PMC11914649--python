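"""Synthetic inputs with planted ground truth for every classifier.

The count generator emulates the statistical structure the analysis
assumes in droplet scRNA-seq of stressed yeast: negative-binomial UMI
counts around per-cell expected masses; stress-induced genes that are
essentially silent in non-responding cells and switch on in responding
cells with a per-gene usage probability and a per-cell response amplitude;
constitutively high repressed genes that lose a tunable fraction of their
mass to the induced program (budget reallocation, the planted
induction-repression coupling); genotype barcode and selection-marker
pseudo-genes; and planted basal-stressed, hyper-responsive and doublet
subpopulations recorded in an exhaustive ground-truth table.

Trace, frame and growth/fold-change generators provide the corresponding
inputs of the live-imaging and fitness analyses.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .data import CountDataset
from .traces import TraceSet

log = logging.getLogger("osmohet")

SENTINELS = ("STL1", "ALD3", "CTT1", "HSP12", "GRE1", "HXT5")
#: expression frequencies of the sentinel panel under stress, spanning
#: near-universal to rare usage
SENTINEL_USAGE = {"STL1": 1.0, "HSP12": 0.5, "CTT1": 0.35,
                  "ALD3": 0.25, "GRE1": 0.15, "HXT5": 0.1}

CONTROL = "control"
STRESS = "NaCl"


@dataclass
class GenotypeSpec:
    """One strain of the pool: cell number per condition and its effect on
    the response-amplitude distribution (multipliers on mean and SD)."""

    name: str
    n_cells: int
    effect_mean: float = 1.0
    effect_sd: float = 1.0
    markers: dict[str, float] = field(default_factory=dict)
    null_genes: tuple[str, ...] = ()


@dataclass
class SimSpec:
    """Parameters of the count-matrix generator.

    Masses are relative units per gene; a cell's expected counts scale its
    masses to a lognormal library size.  Induced genes carry a tiny off
    mass (``induced_baseline_mass``) and, when used by a responding cell,
    a mass of ``induced_baseline_mass * 2**(amplitude * log2fc_g)`` capped
    at ``induced_mass_cap``.  Repressed genes start high
    (``repressed_baseline_mass``) and lose the fraction
    ``coupling_kappa * amplitude`` of their mass, reallocated pro rata to
    the cell's used induced genes so the per-cell expected total is
    invariant to the coupling strength.
    """

    n_cells_per_group: int = 1000
    n_signature_genes: int = 200
    n_background_genes: int = 3600
    usage_prob_alpha: float = 2.0
    usage_prob_beta: float = 2.3
    induction_mean_log2fc: float = 13.5
    induction_sd_log2fc: float = 1.0
    induced_baseline_mass: float = 1e-4
    induced_mass_cap: float = 2.0
    repressed_baseline_mass: float = 20.0
    nb_dispersion: float = 10.0
    library_size_lognorm_mu: float = 8.0
    library_size_lognorm_sigma: float = 0.25
    basal_fraction: float = 0.06
    hyper_fraction: float = 0.10
    hyper_sentinel_fold: float = 5.0
    amplitude_mean: float = 1.0
    amplitude_cv: float = 0.35
    coupling_kappa: float = 0.5
    genotype_table: list[GenotypeSpec] | None = None
    doublet_rate: float = 0.0
    barcode_mean: float = 6.0
    conditions: tuple[str, ...] = (CONTROL, STRESS)
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("basal_fraction", "hyper_fraction", "doublet_rate",
                     "coupling_kappa"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be > 0")
        if self.usage_prob_alpha <= 0 or self.usage_prob_beta <= 0:
            raise ValueError("Beta shape parameters must be > 0")
        if self.n_signature_genes < len(SENTINELS):
            raise ValueError(
                f"need at least {len(SENTINELS)} signature genes")

    @property
    def genotypes(self) -> list[GenotypeSpec]:
        if self.genotype_table is None:
            return [GenotypeSpec("WT", self.n_cells_per_group)]
        return self.genotype_table


def _nb_counts(rng: np.random.Generator, mean: np.ndarray,
               dispersion: float) -> np.ndarray:
    """Negative-binomial counts via the gamma-Poisson mixture."""
    lam = rng.gamma(dispersion, mean / dispersion)
    return rng.poisson(lam)


def generate_counts(spec: SimSpec,
                    return_masses: bool = False
                    ) -> tuple[CountDataset, pd.DataFrame] | tuple[
                        CountDataset, pd.DataFrame, np.ndarray]:
    """Generate a UMI count dataset plus its exhaustive ground-truth table.

    Gene panel: ``n_signature_genes`` induced genes (the first six are the
    sentinel panel with fixed usage frequencies, the rest draw usage
    probabilities from Beta(alpha, beta)), the same number of repressed
    genes, ``n_background_genes`` background genes, one genotype barcode
    pseudo-gene per strain (``bc-<name>``) and any selection-marker
    pseudo-genes named in the genotype table.

    Every cell of the stress condition responds; control cells respond
    only when planted basal-stressed (probability ``basal_fraction``).  A
    planted ``hyper_fraction`` of stressed cells uses all six sentinels at
    ``hyper_sentinel_fold`` times the induced level.  Doublet cells carry
    a second strain's barcode.

    Ground truth columns: cell_id, genotype, condition, amplitude,
    responding, basal_stressed, hyper, doublet, n_used.
    """
    rng = np.random.default_rng(spec.seed)
    n_sig = spec.n_signature_genes
    induced_genes = list(SENTINELS) + [f"IND{i:04d}"
                                       for i in range(len(SENTINELS), n_sig)]
    repressed_genes = ["EFT2"] + [f"REP{i:04d}" for i in range(1, n_sig)]
    background_genes = [f"BG{i:04d}" for i in range(spec.n_background_genes)]

    genotypes = spec.genotypes
    marker_genes = sorted({m for g in genotypes for m in g.markers})
    null_refs = sorted({g for gt in genotypes for g in gt.null_genes})
    extra_null = [g for g in null_refs
                  if g not in set(induced_genes + repressed_genes
                                  + background_genes)]
    background_genes = extra_null + background_genes
    barcode_genes = [f"bc-{g.name}" for g in genotypes]
    gene_ids = (induced_genes + repressed_genes + background_genes
                + marker_genes + barcode_genes)
    n_ind, n_rep = len(induced_genes), len(repressed_genes)
    n_bg = len(background_genes)
    n_core = n_ind + n_rep + n_bg

    # per-gene parameters, drawn once
    usage_p = rng.beta(spec.usage_prob_alpha, spec.usage_prob_beta,
                       size=n_ind)
    usage_p[:len(SENTINELS)] = [SENTINEL_USAGE[g] for g in SENTINELS]
    log2fc = rng.normal(spec.induction_mean_log2fc,
                        spec.induction_sd_log2fc, size=n_ind)
    rep_base = spec.repressed_baseline_mass * rng.lognormal(0.0, 0.3,
                                                            size=n_rep)
    bg_base = rng.lognormal(0.0, 0.4, size=n_bg)

    amp_cv = spec.amplitude_cv
    blocks, truth_rows, mass_blocks = [], [], []
    cell_counter = 0
    for geno in genotypes:
        geno_idx = genotypes.index(geno)
        null_cols = [gene_ids.index(g) for g in geno.null_genes]
        for cond in spec.conditions:
            n = geno.n_cells
            stressed = cond == STRESS
            responding = (np.ones(n, dtype=bool) if stressed
                          else rng.random(n) < spec.basal_fraction)
            mean_a = spec.amplitude_mean * geno.effect_mean
            sd_a = max(amp_cv * spec.amplitude_mean * geno.effect_sd, 1e-9)
            shape = (mean_a / sd_a) ** 2
            amp = rng.gamma(shape, mean_a / shape, size=n) * responding
            hyper = (rng.random(n) < spec.hyper_fraction if stressed
                     else np.zeros(n, dtype=bool))
            # hyper-responsive cells are strong responders by construction
            amp[hyper] = np.maximum(amp[hyper], mean_a)
            used = rng.random((n, n_ind)) < usage_p[None, :]
            used[hyper, :len(SENTINELS)] = True

            # expected masses
            on = responding[:, None] & used
            ind_mass = np.full((n, n_ind), spec.induced_baseline_mass)
            with np.errstate(over="ignore"):
                active_mass = np.minimum(
                    spec.induced_baseline_mass
                    * np.exp2(np.clip(amp[:, None] * log2fc[None, :],
                                      None, 60.0)),
                    spec.induced_mass_cap)
            ind_mass = np.where(on, active_mass, ind_mass)

            loss = np.minimum(spec.coupling_kappa * amp, 0.95)
            rep_mass = rep_base[None, :] * (1.0 - loss[:, None])
            removed = rep_base.sum() * loss
            used_sum = np.where(on, ind_mass, 0.0).sum(axis=1)
            can_realloc = used_sum > 0
            scale = np.ones(n)
            scale[can_realloc] = 1.0 + (removed[can_realloc]
                                        / used_sum[can_realloc])
            # cells with no used induced gene keep the repressed mass
            rep_mass[~can_realloc] = rep_base[None, :]
            ind_mass = np.where(on, ind_mass * scale[:, None], ind_mass)
            # sentinel boost after reallocation: hyper cells sit a fixed
            # fold above same-amplitude responders on the sentinel panel
            ind_mass[hyper, :len(SENTINELS)] *= spec.hyper_sentinel_fold

            mass = np.concatenate(
                [ind_mass, rep_mass,
                 np.broadcast_to(bg_base, (n, n_bg)).copy()], axis=1)
            for col in null_cols:
                if col < n_core:
                    mass[:, col] = 0.0

            lib = rng.lognormal(spec.library_size_lognorm_mu,
                                spec.library_size_lognorm_sigma, size=n)
            # depth is technical: scale masses by depth over the baseline
            # (uninduced) mass total, so a cell's response does not dilute
            # the counts of unrelated genes
            baseline_total = (bg_base.sum() + rep_base.sum()
                              + n_ind * spec.induced_baseline_mass)
            base_row = np.full(n, baseline_total)
            for col in null_cols:
                if col < n_core:
                    if col < n_ind:
                        base_row -= spec.induced_baseline_mass
                    elif col < n_ind + n_rep:
                        base_row -= rep_base[col - n_ind]
                    else:
                        base_row -= bg_base[col - n_ind - n_rep]
            lam = mass * (lib / base_row)[:, None]
            counts_core = _nb_counts(rng, lam, spec.nb_dispersion)

            # marker and barcode pseudo-genes
            markers = np.zeros((n, len(marker_genes)), dtype=np.int64)
            for j, m in enumerate(marker_genes):
                if m in geno.markers:
                    markers[:, j] = 2 + rng.poisson(
                        max(geno.markers[m] - 2, 0.0), size=n)
            barcodes = np.zeros((n, len(genotypes)), dtype=np.int64)
            barcodes[:, geno_idx] = 1 + rng.poisson(
                max(spec.barcode_mean - 1, 0.0), size=n)
            doublet = rng.random(n) < spec.doublet_rate
            if doublet.any() and len(genotypes) > 1:
                others = [i for i in range(len(genotypes)) if i != geno_idx]
                second = rng.choice(others, size=int(doublet.sum()))
                rows = np.flatnonzero(doublet)
                barcodes[rows, second] = 1 + rng.poisson(
                    max(spec.barcode_mean - 1, 0.0), size=len(rows))
            else:
                doublet = np.zeros(n, dtype=bool)

            block = np.concatenate(
                [counts_core, markers, barcodes], axis=1)
            blocks.append(sp.csr_matrix(block))
            if return_masses:
                mass_blocks.append(mass)

            ids = [f"cell_{cell_counter + i:06d}" for i in range(n)]
            cell_counter += n
            truth_rows.append(pd.DataFrame({
                "cell_id": ids,
                "genotype": geno.name,
                "condition": cond,
                "time_min": 15 if stressed else 0,
                "amplitude": amp,
                "responding": responding,
                "basal_stressed": responding & ~stressed,
                "hyper": hyper,
                "doublet": doublet,
                "n_used": on.sum(axis=1),
            }))

    truth = pd.concat(truth_rows, ignore_index=True)
    counts = sp.vstack(blocks).tocsr()
    meta = truth.set_index("cell_id")[["genotype", "condition",
                                       "time_min"]].copy()
    ds = CountDataset(counts=counts,
                      cell_ids=truth["cell_id"].to_numpy(dtype=object),
                      gene_ids=np.asarray(gene_ids, dtype=object),
                      cell_meta=meta)
    log.info("generate_counts: %d cells x %d genes, %d genotypes, "
             "%d conditions", ds.n_cells, ds.n_genes, len(genotypes),
             len(spec.conditions))
    if return_masses:
        return ds, truth, np.concatenate(mass_blocks, axis=0)
    return ds, truth


# ------------------------------------------------------------------ traces

@dataclass
class TraceSimSpec:
    """Parameters of the promoter-activity trace generator.

    ``kind`` selects the reporter class: ``"induced"`` traces rest at
    baseline and fire a double-exponential pulse after the stimulus;
    ``"repressed"`` traces transcribe at a high baseline and drop after
    the stimulus by ``repressed_drop_fraction`` (a planted
    ``fraction_low_repressor`` drops by less than half instead).  A
    planted ``fraction_high_basal`` receives a pre-stimulus baseline
    elevated by ``high_basal_offset_sd`` population SDs.
    """

    n_traces: int = 500
    kind: str = "repressed"
    dt_s: float = 15.0
    n_pre_points: int = 10
    n_post_points: int = 50
    baseline: float = 100.0
    baseline_cv: float = 0.10
    noise_sd: float = 12.0
    induced_amplitude: float = 300.0
    rise_tau_s: float = 60.0
    decay_tau_s: float = 300.0
    repressed_drop_fraction: float = 0.8
    low_repressor_drop: float = 0.15
    transition_tau_s: float = 45.0
    fraction_high_basal: float = 0.0
    fraction_low_repressor: float = 0.15
    high_basal_offset_sd: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_pre_points < 1:
            raise ValueError("n_pre_points must be >= 1")
        if self.kind not in ("induced", "repressed"):
            raise ValueError("kind must be 'induced' or 'repressed'")
        for name in ("rise_tau_s", "decay_tau_s", "transition_tau_s"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        for name in ("fraction_high_basal", "fraction_low_repressor",
                     "repressed_drop_fraction", "low_repressor_drop"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")


def generate_traces(spec: TraceSimSpec) -> tuple[TraceSet, pd.DataFrame]:
    """Generate transcription-site intensity traces with ground truth.

    Induced traces: baseline before the stimulus, then baseline +
    A * (1 - exp(-t/tau_rise)) * exp(-t/tau_decay) + noise.  Repressed
    traces: per-trace baseline decaying exponentially to
    baseline * (1 - drop).  Detection booleans mark the time points where
    the noiseless nascent signal sits above threshold (pre-stimulus for
    repressed and high-basal traces, during the pulse for induced ones).

    Ground truth columns: trace_id, kind, high_basal, repressor_class
    (high/low/n-a), baseline, drop.
    """
    rng = np.random.default_rng(spec.seed)
    n, pre, post = spec.n_traces, spec.n_pre_points, spec.n_post_points
    t_post = np.arange(post) * spec.dt_s
    n_points = pre + post

    base_sd = spec.baseline_cv * spec.baseline
    baselines = spec.baseline + base_sd * rng.standard_normal(n)
    high_basal = rng.random(n) < spec.fraction_high_basal
    baselines[high_basal] += spec.high_basal_offset_sd * base_sd

    intensities = np.empty((n, n_points))
    detections = np.zeros((n, n_points), dtype=bool)
    drops = np.zeros(n)
    rep_class = np.full(n, "n/a", dtype=object)

    if spec.kind == "induced":
        pulse_unit = (1.0 - np.exp(-t_post / spec.rise_tau_s)) \
            * np.exp(-t_post / spec.decay_tau_s)
        for i in range(n):
            signal = np.concatenate([
                np.full(pre, baselines[i]),
                baselines[i] + spec.induced_amplitude * pulse_unit])
            intensities[i] = signal
            detections[i, pre:] = (spec.induced_amplitude * pulse_unit
                                   > 0.1 * spec.induced_amplitude)
            detections[i, :pre] = high_basal[i]
    else:
        low = rng.random(n) < spec.fraction_low_repressor
        drops = np.where(low, spec.low_repressor_drop,
                         spec.repressed_drop_fraction)
        rep_class = np.where(low, "low", "high").astype(object)
        decay = np.exp(-t_post / spec.transition_tau_s)
        for i in range(n):
            target = baselines[i] * (1.0 - drops[i])
            signal = np.concatenate([
                np.full(pre, baselines[i]),
                target + (baselines[i] - target) * decay])
            intensities[i] = signal
            detections[i, :pre] = True
            detections[i, pre:] = signal[pre:] > 0.45 * baselines[i]

    intensities += spec.noise_sd * rng.standard_normal(intensities.shape)

    ids = [f"trace_{i:04d}" for i in range(n)]
    ts = TraceSet(intensities=intensities, dt_s=spec.dt_s, stimulus_idx=pre,
                  trace_ids=ids, channel=spec.kind, detections=detections)
    truth = pd.DataFrame({
        "trace_id": ids,
        "kind": spec.kind,
        "high_basal": high_basal,
        "repressor_class": rep_class,
        "baseline": baselines,
        "drop": drops,
    })
    return ts, truth


# ------------------------------------------------------------------ frames

@dataclass
class ImageFrameSet:
    """Synthetic single-channel frames with one shared disk nucleus mask."""

    frames: np.ndarray            # (n_frames, h, w)
    nucleus_mask: np.ndarray      # (h, w) bool
    truth: pd.DataFrame           # frame, has_spot, spot_row, spot_col


def generate_frames(n_frames: int, img_size: int = 64,
                    nucleus_radius: int = 12, spot_px: int = 12,
                    spot_amplitude: float = 200.0, background: float = 100.0,
                    noise_sd: float = 0.0, spot_fraction: float = 0.5,
                    seed: int = 0) -> ImageFrameSet:
    """Generate frames of a disk nucleus, half of them carrying a spot.

    Each frame is constant ``background`` plus Gaussian noise; frames
    flagged as spot frames carry a compact connected blob of exactly
    ``spot_px`` pixels at ``background + spot_amplitude`` inside the
    nucleus.  Deterministic given the seed.
    """
    rng = np.random.default_rng(seed)
    h = w = img_size
    cy = cx = img_size // 2
    yy, xx = np.mgrid[:h, :w]
    mask = (yy - cy) ** 2 + (xx - cx) ** 2 <= nucleus_radius ** 2
    if spot_px > int(mask.sum()):
        raise ValueError(f"spot_px={spot_px} exceeds nucleus area "
                         f"{int(mask.sum())}")

    has_spot = np.zeros(n_frames, dtype=bool)
    has_spot[: int(round(spot_fraction * n_frames))] = True
    rng.shuffle(has_spot)

    frames = np.full((n_frames, h, w), background, dtype=float)
    if noise_sd > 0:
        frames += noise_sd * rng.standard_normal(frames.shape)
    rows, cols = [], []
    inner = np.flatnonzero(mask.ravel())
    for f in range(n_frames):
        if not has_spot[f]:
            rows.append(-1)
            cols.append(-1)
            continue
        center = inner[rng.integers(len(inner))]
        r0, c0 = divmod(center, w)
        # compact blob: the spot_px in-nucleus pixels nearest the center
        d2 = (yy - r0) ** 2 + (xx - c0) ** 2
        d2_flat = np.where(mask.ravel(), d2.ravel(), np.inf)
        blob = np.argsort(d2_flat, kind="stable")[:spot_px]
        fr = frames[f].ravel()
        fr[blob] += spot_amplitude
        frames[f] = fr.reshape(h, w)
        rows.append(r0)
        cols.append(c0)

    truth = pd.DataFrame({"frame": np.arange(n_frames), "has_spot": has_spot,
                          "spot_row": rows, "spot_col": cols})
    return ImageFrameSet(frames=frames, nucleus_mask=mask, truth=truth)


# --------------------------------------------------- growth & fold changes

def generate_growth_and_fc(
        genotypes: list[str],
        prestress_benefit: dict[str, float],
        n_replicates: int = 6,
        t_max_min: int = 3000,
        dt_min: int = 30,
        carrying_capacity: float = 1.2,
        od0: float = 0.025,
        growth_rate_per_h: float = 0.15,
        stress_lag_h: float = 30.0,
        control_lag_h: float = 4.0,
        od_noise_cv: float = 0.03,
        fc_spec: dict | None = None,
        seed: int = 0) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate logistic growth curves and a bulk fold-change table.

    Growth: logistic curves OD(t) = od0 + (K - od0) / (1 + exp(-r (t -
    t_mid))) for three conditions per genotype — control (short lag),
    direct high-salt stress (``stress_lag_h``) and pre-stressed then
    high salt, where the pre-stress shortens the lag by the genotype's
    ``prestress_benefit`` (hours); replicates carry multiplicative noise.
    Benefits longer than the stress lag are rejected.

    Fold changes: ``fc_spec`` plants induced (log2FC >= 1), repressed
    (<= -1) and unresponsive genes with p-values
    (defaults: 250 / 250 / 300 planted plus 1200 null genes).

    Returns (growth long-format DataFrame, fold-change DataFrame).
    """
    rng = np.random.default_rng(seed)
    for g in genotypes:
        if prestress_benefit.get(g, 0.0) > stress_lag_h:
            raise ValueError(
                f"benefit for {g!r} exceeds the stress lag")
    t = np.arange(0, t_max_min + 1, dt_min, dtype=float)
    t_h = t / 60.0
    rows = []
    from .fitness import CONTROL as FIT_CONTROL, STRESS as FIT_STRESS, \
        PRESTRESS as FIT_PRESTRESS
    for g in genotypes:
        benefit = prestress_benefit.get(g, 0.0)
        lags = {FIT_CONTROL: control_lag_h,
                FIT_STRESS: stress_lag_h,
                FIT_PRESTRESS: stress_lag_h - benefit}
        for cond, lag in lags.items():
            t_mid = lag + 8.0    # inflection sits 8 h past the lag
            for rep in range(n_replicates):
                noise = rng.lognormal(0.0, od_noise_cv, size=len(t))
                od = (od0 + (carrying_capacity - od0)
                      / (1.0 + np.exp(-growth_rate_per_h * (t_h - t_mid))))
                od = od * noise
                rows.append(pd.DataFrame({
                    "genotype": g, "condition": cond, "replicate": rep,
                    "t_min": t.astype(int), "od": od}))
    growth = pd.concat(rows, ignore_index=True)

    fc_spec = fc_spec or {}
    n_ind = fc_spec.get("n_induced", 250)
    n_rep = fc_spec.get("n_repressed", 250)
    n_unr = fc_spec.get("n_unresponsive", 300)
    n_null = fc_spec.get("n_null", 1200)
    genes, lfc, pval = [], [], []
    genes += [f"UP{i:04d}" for i in range(n_ind)]
    lfc += list(1.0 + rng.exponential(1.0, size=n_ind))
    pval += list(rng.uniform(1e-6, 0.01, size=n_ind))
    genes += [f"DN{i:04d}" for i in range(n_rep)]
    lfc += list(-(1.0 + rng.exponential(1.0, size=n_rep)))
    pval += list(rng.uniform(1e-6, 0.01, size=n_rep))
    genes += [f"NR{i:04d}" for i in range(n_unr)]
    lfc += list(rng.uniform(-0.4, 0.4, size=n_unr))
    pval += list(rng.uniform(0.0, 1.0, size=n_unr))
    genes += [f"NULL{i:04d}" for i in range(n_null)]
    lfc += list(rng.normal(0.0, 0.5, size=n_null))
    pval += list(rng.uniform(0.0, 1.0, size=n_null))
    fc = pd.DataFrame({"gene": genes, "log2fc": lfc, "pval": pval})
    return growth, fc
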