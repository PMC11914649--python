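# osmohet — transcriptional heterogeneity of the yeast osmostress response

When budding yeast meets hyperosmotic shock (NaCl), the Hog1 SAPK drives a
transient transcriptional program: a few hundred genes are induced, the
translation machinery is repressed, and — at single-cell resolution — the
population turns out to be strikingly heterogeneous: each cell fires only
part of the induced program, some unstressed cells fire it spontaneously
("basal-stressed" cells), a small subpopulation co-expresses the whole
sentinel panel ("hyper-responsive" cells), and induction is coupled to how
strongly a cell represses the rest of its transcriptome.

`osmohet` is a tested re-implementation of the analysis pipeline behind
these observations, for computational biologists who want to run, probe or
extend it: genotype demultiplexing of pooled strains (selection-marker or
RNA-barcode based), rank-based signature scoring, subpopulation
classifiers, a deletion-screen scorer, live transcription-site trace
quantification, and growth/competition fitness readouts. A synthetic-data
module generates every input with planted ground truth, so each classifier
is validated by recovery, not by eye.

## The statistics at the core

**Signature score.** For cell *c* and signature *G* (|G| = n), rank all
genes by log-normalized expression within the cell (descending, average
ties), cap ranks at *r*<sub>max</sub> (default 1500), and compute the
Mann–Whitney U statistic of the signature's ranks:

    U_c = Σ_{g∈G} min(rank_c(g), r_max + 1) − n(n+1)/2
    score_c = clamp(1 − U_c / (n · r_max), 0, 1)

A cell expressing the entire signature at the top of its transcriptome
scores 1; a cell expressing none of it scores a fixed floor.

**Subpopulation thresholds.** Basal-stressed: score strictly above the
wild-type last decile (0.9 quantile), computed per condition.
Hyper-responsive: six-sentinel (*STL1, ALD3, CTT1, HSP12, GRE1, HXT5*)
co-expression — k-NN-smoothed, min-max-scaled geometric mean — strictly
above mean + GMD, where GMD is the Gini mean difference
2/(n(n−1)) Σ<sub>i&lt;j</sub> |x<sub>i</sub> − x<sub>j</sub>|.

**Screen rules.** Genotypes with ≥ 6 cells per condition; flagged when
≥ 25% of cells exceed the wild-type-derived threshold; flagged variable
when the stress-condition score SD exceeds 2× the pooled wild-type SD.

**Transcription sites.** Per frame: dilate the nucleus mask by 5 px, take
the 10 brightest pixels (HighPix); a site is called when ≥ 5 of them form
one connected component; intensity = mean(HighPix) − mean(expanded
nucleus). Per trace: 3 consecutive detections = actively transcribing
(before the stimulus = basally transcribing); basal level = mean of the 10
pre-stimulus points; normalized = (x − min)/(basal − min); high repressors
drop > 50% in normalized units; high-basal cells sit above
mean + 1 SD of the population's basal levels.

## Worked example

```python
import numpy as np
from osmohet import PipelineConfig, preprocess
from osmohet.syndata import SimSpec, generate_counts, SENTINELS
from osmohet.signatures import GeneSignature, score_signature
from osmohet.screen import basal_threshold, classify_basal_stressed

cfg = PipelineConfig()
spec = SimSpec(n_cells_per_group=3000, conditions=("control",), seed=1)
ds, truth = generate_counts(spec)          # 3000 cells x 4001 genes
ds = preprocess(ds, cfg)                   # drop RPL/RPS, add lognorm layer

induced = GeneSignature(
    "induced_consensus",
    list(SENTINELS) + [f"IND{i:04d}" for i in range(6, 200)], "induced")
scores = score_signature(ds, induced, cfg)["score"].to_numpy()
thr = basal_threshold(scores, cfg)
frac = classify_basal_stressed(scores, thr).mean()
print(f"threshold {thr:.4f}; basal-stressed {100*frac:.2f}% "
      f"(planted {100*truth['basal_stressed'].mean():.2f}%)")
```

prints

```
threshold 0.0663; basal-stressed 6.13% (planted 5.60%)
```

The threshold lands on the score floor shared by control cells that
express no induced gene, and the strictly-above rule recovers the planted
basal-stressed fraction plus a small leakage from cells with sporadic
single-molecule expression.

The full analysis is laid out as numbered drivers under `analysis/`
(simulate → demultiplex/QC → signatures → heterogeneity →
subpopulations/screen → traces → fitness); each prints what it found and
writes its tables under `results/tables/`:

```
python analysis/01_simulate.py --seed 0
python analysis/02_demultiplex_qc.py --seed 0
...
python analysis/07_fitness.py --seed 0
```

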