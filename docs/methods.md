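# Methods

This note documents the models, estimators and numerical choices behind
`osmohet`, and what the synthetic data do and do not establish.

## Data model and preprocessing

A dataset is a sparse cell × gene UMI matrix with per-cell annotations
(genotype, condition, time) and derived QC quantities (detected genes,
total molecules). On disk it is plain text: Matrix Market coordinate
format (cells as rows, 1-based indices) with one-id-per-line sidecars and
a TSV metadata table; real-valued layers are written at 17 significant
digits so float64 values round-trip exactly.

Preprocessing removes ribosomal protein genes by id prefix (`RPL`/`RPS`,
case-sensitive — the families are named, not enumerated) and adds a
log-normalized layer `ln(1 + count · s / n_molecules)` with scale
s = 10,000, the community-standard transform. Cells with zero molecules
get an all-zero row and a warning rather than an error. No mitochondrial
or other housekeeping filter is applied.

## Genotype assignment

Two routes mirror two pooling designs. *Selection markers*: a rule is a
label plus positive markers (count ≥ 2, reading "more than 1 count"
strictly) and zero markers (count = 0). Several rules may share a label,
because one strain can carry alternative cassettes. A cell whose positive
markers satisfy rules of more than one label carries two strains'
cassettes and is `Excluded` — the marker analogue of a doublet. Cassette
features are then removed from the matrix; zero markers may be ordinary
genes (the deleted ORF) and are kept. *RNA barcodes*: exactly one
detected `bc-` feature (count ≥ 1, "detectable expression") assigns the
genotype; zero gives `Unassigned`, more than one gives `Doublet`; barcode
features are removed afterwards. The QC window keeps cells with 500–3000
detected genes inclusive (the exclusion wording is strict).

## Rank-based signature score

The score is the rank-sum module score re-implemented from its
definition rather than called from a package: within-cell descending
ranks of the log-normalized expression, average ranks for ties, ranks
beyond the cap (default 1500) replaced by cap + 1, U statistic scaled to
[0, 1] and clamped. Two consequences matter downstream. First, the score
is invariant to any reshuffling of non-signature expression and to
per-cell monotone transforms — which makes it robust to library-size and
composition effects. Second, in a panel with more genes than the rank cap,
every cell that expresses *no* signature gene receives one identical
floor score (all its signature genes sit in the capped tie of undetected
genes). The wild-type control distribution therefore carries a large
point mass at the floor, the 0.9-quantile threshold lands exactly on it,
and "strictly above threshold" cleanly separates cells with any real
program activity. An independent naive implementation (explicit
comparison counts per gene) serves as the oracle in the tests.

The consensus builder takes log2 fold changes: induced = top 200 by
log2FC among genes with log2FC ≥ 1 and p < 0.05; repressed is the mirror;
unresponsive = the 200 genes with |log2FC| ≤ 0.5 nearest zero, with no p
criterion (demanding significance of a no-change class is incoherent).
Thresholds are configurable; shortfalls return all qualifiers with a
warning.

## Subpopulation classifiers

*Basal-stressed*: score strictly greater than the wild-type
`basal_quantile` (0.9) empirical quantile (linear interpolation),
computed per condition.

*Hyper-responsive*: the six-sentinel panel (*STL1, ALD3, CTT1, HSP12,
GRE1, HXT5*) spans expression frequencies from near-universal to rare, so
joint co-expression is informative. Each sentinel's lognorm value is
smoothed over the cell's k = 30 nearest neighbours in the 6-dimensional
sentinel space (Euclidean; deterministic given input order), min-max
scaled across cells, and combined by geometric mean; the threshold is
mean + Gini mean difference (GMD), strictly above. The k-NN-smoothed
geometric mean replaces the joint-density estimate of interactive
plotting tools: it is deterministic, embedding-free and testable. GMD is
computed by the O(n log n) sorted identity
Σ<sub>i&lt;j</sub>(x₍ⱼ₎ − x₍ᵢ₎) = Σ_k (2k − n − 1) x₍ₖ₎ and must agree
with the O(n²) sum to 1e−12 relative.

*Screen*: per genotype × condition, the table reports cell count, score
moments, Fano factor (sample variance over mean; undefined when the mean
is 0), the percentage of cells above the wild-type-derived condition
threshold, and flags. Genotypes under 6 cells keep their values but have
flags suppressed. The variability rule compares a genotype's
stress-condition score SD with the wild-type reference; with only two
wild-type strains the between-strain SD-of-SDs is estimated from two
numbers and is far too noisy to set a threshold (its sampling error alone
produces several false flags per fifty null genotypes), so the default
rule is SD > 2 × pooled wild-type SD; the strain-replicate rule
(mean + 2·SD of per-strain SDs) remains selectable via
`variability_rule="replicate_sd"`. All classification boundaries are
strict inequalities, consistent with "higher than"/"above".

## Transcription-site traces

Frame level: the nucleus mask is dilated by 5 px (disk structuring
element); HighPix = the 10 brightest pixels of the expanded nucleus, ties
broken by raster order; the site is called when ≥ 5 HighPix pixels form
one connected component (8-connectivity by default, 4 selectable). Only
pixels strictly brighter than the expanded-nucleus mean enter the
component check, so a perfectly flat field — where the tie-broken top-10
would be a contiguous arc of the disk — yields no call; with any noise or
a real spot the rule is unchanged. Intensity = mean(HighPix) −
mean(expanded nucleus).

Trace level: ≥ 3 consecutive detections anywhere = actively
transcribing; the same run strictly before the stimulus = basally
transcribing (the activity call is deliberately not restricted to
post-stimulus points). Basal level = mean of the 10 points before the
stimulus; normalized = (x − min)/(basal − min), guarded when basal equals
the minimum; peak = max − basal. Repressor class (basally transcribing
traces only): drop = 1 − mean of the last 10 normalized points (the
post-induction window is not specified by the source analysis; the final
10 points are the default, exposed as `post_window`); high iff
drop > 0.5, strictly. High-basal split: basal level strictly above
population mean + 1 sample SD.

Note the min-referenced normalization has a structural bias for traces
that never shut off: the trace minimum then tracks the post-stimulus
plateau minus a noise excursion, so a true fractional drop d is measured
as roughly d/(d + c·σ/baseline) with c ≈ 2–3. Mild repressors are
therefore pushed toward the 50% boundary; the classifier is accurate when
the two planted classes sit clearly on either side of the boundary in
*measured* units, which the generator's defaults do.

## Synthetic-data generator

The count generator emulates droplet scRNA-seq of a stressed pool.
Per-gene expected "masses" (relative expression): background genes at
lognormal(0, 0.4); repressed genes at 20 × lognormal(0, 0.3) — the
repressed program is the translation machinery, among the most expressed
genes in the cell, which also keeps their rank positions clear of the
induced genes' count range; induced genes at a near-zero off mass 1e−4.
Per cell: a response amplitude (Gamma, mean 1, CV 0.35; zero for
non-responding cells) multiplied by genotype effects on mean and SD; each
induced gene is "used" with probability p_g ~ Beta(2, 2.3) (mean ≈ 0.47,
so a responding cell fires ~93 of 200 genes); sentinel usage is fixed at
1.0/0.5/0.35/0.25/0.15/0.1, spanning near-universal to rare. A used gene
in a responding cell has mass 1e−4 · 2^(amplitude · log2FC_g) with
log2FC_g ~ N(13.5, 1), capped at 2 — stress genes switch from essentially
silent to background-comparable levels.

Coupling is a mass budget: repressed genes lose the fraction
κ · amplitude (clipped at 0.95) of their mass, reallocated pro rata to
the cell's used induced genes, so the per-cell expected total is
invariant to κ and κ = 0 is an exact null. Counts are negative binomial
(gamma–Poisson, dispersion 10) around masses scaled by a lognormal
library size (μ = 8, σ = 0.25) over the *baseline* (uninduced) mass
total: sequencing depth is treated as technical, so one gene's induction
does not dilute the measured counts of unrelated genes. Planted
subpopulations: a `basal_fraction` (default 6%) of control cells respond
like stressed cells; a `hyper_fraction` (default 10%) of stressed cells
are strong responders (amplitude at least the mean) that use all six
sentinels at 5× the same-amplitude level; doublets carry a second
strain's barcode. Every cell's amplitude, usage, and labels are recorded
in an exhaustive ground-truth table.

Traces: repressed-reporter traces start at baseline 100 (CV 10% across
traces), decay exponentially (τ = 45 s) to baseline × (1 − drop) with
drop 0.8 for high repressors and 0.15 for the planted low-repressor
fraction (15%); induced-reporter traces fire a double-exponential pulse
(rise 60 s, decay 300 s, amplitude 300); point noise SD 12 models
site-intensity fluctuation; sampling every 15 s with 10 pre-stimulus
points. High-basal traces sit `high_basal_offset_sd` (default 5)
population SDs above the baseline. Frames are a disk nucleus with
constant background, optional Gaussian noise, and compact `spot_px`-pixel
blobs at +amplitude. Growth curves are logistic with condition-specific
lag (control 4 h, direct high salt 30 h, pre-stressed 30 h − benefit),
sampled every 30 min for 50 h with multiplicative replicate noise, so the
endpoint OD at 50 h still reflects the lag difference.

What the generator does **not** emulate: ambient RNA, empty droplets,
batch effects, cell-cycle structure, burst kinetics within traces, the
optics of a real PSF, or biological correlation between genes beyond the
planted amplitude/usage/coupling structure. Recovery results therefore
demonstrate that the estimators implement their definitions and separate
the planted structure at realistic noise levels — not that they are
robust to every artefact of real data.

## Statistical tests

Differential expression: per-gene two-sided Wilcoxon rank-sum on the
lognorm layer; log2FC from back-transformed group means with pseudocount
1e−9; Benjamini–Hochberg over tested genes; up set = log2FC ≥ 0.58
(linear 1.5×) and p < 0.05. Cluster-vs-population: each cluster is tested
against all cells including itself (the reference population), BH across
clusters, stars at 0.05/0.01/0.001/0.0001. Group moments use sample
(n−1) variance throughout, including the Fano factor. Competition
time courses use Welch's two-sided t-test of replicate proportions
against the reference time point (identical constant proportions give
p = 1 by definition); reporter fold changes compare strains by a
two-sided exact rank-sum test on replicate ratios. Growth benefit is the
ratio of mean endpoint ODs (pre-stressed over directly stressed), with
area-under-curve selectable; it is scale-invariant.

## Problem sizes and determinism

Recovery checks run at the sizes of their stated conditions: 3,000
wild-type control cells (basal), 2,000 stressed cells (hyper, coupling),
57 genotypes × 50 cells × 2 conditions (screen), 500 traces, 500 label
permutations (DE calibration). Every generator and estimator is
deterministic given its seed; k-NN smoothing and tie-breaks are
deterministic given input order. The usage-vs-strength correlation treats
the per-cell mean over *all* signature genes as the default strength
measure (detected-only selectable), so the correlation partly reflects
the zero-padding of unused genes — matching how the quantity is defined,
not an artefact.
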