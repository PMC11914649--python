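"""Transcription-site detection and promoter-activity trace classification.

Detection works per frame: the nucleus mask is dilated, the brightest
``highpix_n`` pixels inside the expanded nucleus form the HighPix object,
and a transcription site is called when at least ``connected_min`` of them
form one connected component.  The site intensity is the mean HighPix
intensity minus the mean expanded-nucleus intensity.  Trace-level calls
(active / basally transcribing, normalization, repressor and high-basal
splits) operate on the resulting per-time-point detection and intensity
series.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import skimage.measure
import skimage.morphology

from .config import PipelineConfig

log = logging.getLogger("osmohet")


@dataclass
class TraceSet:
    """Per-cell transcription-site intensity time series.

    ``intensities`` is traces x time points (arbitrary fluorescence
    units), sampled on a uniform grid of ``dt_s`` seconds;
    ``stimulus_idx`` is the first post-stimulus time point.  ``detections``
    holds the per-time-point ConnectedHighPix boolean when available.
    """

    intensities: np.ndarray
    dt_s: float
    stimulus_idx: int
    trace_ids: list[str] = field(default_factory=list)
    channel: str = ""
    detections: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.intensities = np.atleast_2d(np.asarray(self.intensities,
                                                    dtype=float))
        if not self.trace_ids:
            self.trace_ids = [f"trace_{i:04d}"
                              for i in range(self.intensities.shape[0])]
        if len(self.trace_ids) != self.intensities.shape[0]:
            raise ValueError("trace_ids length mismatch")
        if self.detections is not None:
            self.detections = np.atleast_2d(np.asarray(self.detections,
                                                       dtype=bool))
            if self.detections.shape != self.intensities.shape:
                raise ValueError("detections shape mismatch")

    @property
    def n_traces(self) -> int:
        return self.intensities.shape[0]

    @property
    def n_points(self) -> int:
        return self.intensities.shape[1]

    @property
    def time_s(self) -> np.ndarray:
        """Time grid in seconds, 0 at the stimulus."""
        return (np.arange(self.n_points) - self.stimulus_idx) * self.dt_s

    def to_csv(self, path) -> None:
        """Long-format CSV: trace_id, t_index, intensity[, detected]."""
        n, t = self.intensities.shape
        df = pd.DataFrame({
            "trace_id": np.repeat(self.trace_ids, t),
            "t_index": np.tile(np.arange(t), n),
            "intensity": self.intensities.ravel(),
        })
        if self.detections is not None:
            df["detected"] = self.detections.ravel().astype(int)
        df.to_csv(path, index=False)

    @staticmethod
    def from_csv(path, dt_s: float, stimulus_idx: int,
                 channel: str = "") -> "TraceSet":
        df = pd.read_csv(path)
        ids = list(pd.unique(df["trace_id"]))
        wide = df.pivot(index="trace_id", columns="t_index",
                        values="intensity").loc[ids]
        det = None
        if "detected" in df.columns:
            det = df.pivot(index="trace_id", columns="t_index",
                           values="detected").loc[ids].to_numpy(bool)
        return TraceSet(intensities=wide.to_numpy(float), dt_s=dt_s,
                        stimulus_idx=stimulus_idx, trace_ids=ids,
                        channel=channel, detections=det)


# ------------------------------------------------------------- detection

def detect_ts_in_frame(frame: np.ndarray, nucleus_mask: np.ndarray,
                       cfg: PipelineConfig) -> tuple[float, bool]:
    """Transcription-site call on a single frame.

    The expanded nucleus is the binary dilation of ``nucleus_mask`` by
    ``dilation_px``; HighPix = the ``highpix_n`` brightest pixels inside it
    (ties broken by raster order, logged); the site is called when some
    connected component of HighPix has >= ``connected_min`` pixels
    (8-connectivity by default).  Only HighPix pixels strictly brighter
    than the expanded-nucleus mean enter the component check, so a flat
    field (all ties) yields no call.  Returns (mean(HighPix) -
    mean(expanded nucleus), connected?).
    """
    frame = np.asarray(frame, dtype=float)
    mask = np.asarray(nucleus_mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty nucleus mask")
    expanded = skimage.morphology.dilation(
        mask, skimage.morphology.disk(cfg.dilation_px)).astype(bool)
    n_px = int(expanded.sum())
    if n_px < cfg.highpix_n:
        raise ValueError(
            f"expanded nucleus has {n_px} px < highpix_n={cfg.highpix_n}")

    flat_idx = np.flatnonzero(expanded.ravel())
    vals = frame.ravel()[flat_idx]
    # stable sort on descending value keeps raster order within ties
    order = np.argsort(-vals, kind="stable")[:cfg.highpix_n]
    cutoff = vals[order[-1]]
    if (vals == cutoff).sum() > (vals[order] == cutoff).sum():
        log.debug("HighPix tie at intensity %g broken by raster order", cutoff)
    high_idx = flat_idx[order]

    high_mask = np.zeros(frame.shape, dtype=bool)
    high_mask.ravel()[high_idx[vals[order] > vals.mean()]] = True
    labels = skimage.measure.label(high_mask, connectivity=cfg.connectivity)
    sizes = np.bincount(labels.ravel())[1:]
    connected = bool(sizes.size and sizes.max() >= cfg.connected_min)

    intensity = float(vals[order].mean() - vals.mean())
    return intensity, connected


def detect_ts_in_stack(frames: np.ndarray, nucleus_mask: np.ndarray,
                       cfg: PipelineConfig) -> tuple[np.ndarray, np.ndarray]:
    """Apply :func:`detect_ts_in_frame` to every frame of one cell's stack."""
    out_i = np.empty(len(frames))
    out_c = np.empty(len(frames), dtype=bool)
    for t, frame in enumerate(frames):
        out_i[t], out_c[t] = detect_ts_in_frame(frame, nucleus_mask, cfg)
    return out_i, out_c


# ----------------------------------------------------------- trace calls

def _has_run(detections: np.ndarray, run: int) -> bool:
    """True when >= run consecutive True values occur."""
    d = np.asarray(detections, dtype=bool)
    if len(d) < run:
        return False
    count = 0
    for v in d:
        count = count + 1 if v else 0
        if count >= run:
            return True
    return False


def call_activity(detections: np.ndarray, stimulus_idx: int,
                  cfg: PipelineConfig) -> tuple[bool, bool]:
    """(active, basal_transcribing) from the detection series.

    Active: >= ``trace_consecutive`` consecutive detections anywhere.
    Basally transcribing: such a run strictly before the stimulus.
    """
    d = np.asarray(detections, dtype=bool)
    if len(d) < cfg.trace_consecutive:
        log.warning("call_activity: series of %d points shorter than the "
                    "%d-point run rule", len(d), cfg.trace_consecutive)
        return False, False
    active = _has_run(d, cfg.trace_consecutive)
    basal = _has_run(d[:stimulus_idx], cfg.trace_consecutive)
    return active, basal


def basal_and_normalize(trace: np.ndarray, stimulus_idx: int,
                        cfg: PipelineConfig
                        ) -> tuple[float, np.ndarray | None, float]:
    """Basal level, normalized series and peak intensity of one trace.

    basal_level = mean of the ``trace_basal_points`` values immediately
    before the stimulus; normalized = (x - min) / (basal - min); peak =
    max(trace) - basal.  When basal equals the minimum the normalization
    is undefined and None is returned in its place.
    """
    x = np.asarray(trace, dtype=float)
    if stimulus_idx < cfg.trace_basal_points:
        raise ValueError(
            f"need >= {cfg.trace_basal_points} pre-stimulus points, "
            f"stimulus at {stimulus_idx}")
    basal = float(x[stimulus_idx - cfg.trace_basal_points:stimulus_idx].mean())
    minval = float(x.min())
    peak = float(x.max() - basal)
    if basal == minval:
        log.warning("basal level equals trace minimum; normalization "
                    "undefined")
        return basal, None, peak
    return basal, (x - minval) / (basal - minval), peak


def classify_repressor(normalized: np.ndarray | None, stimulus_idx: int,
                       cfg: PipelineConfig,
                       basal_transcribing: bool = True) -> str:
    """Repressor class of a basally transcribing trace.

    post level = mean of the last ``post_window`` normalized points; drop =
    1 - post level; "high" iff drop > ``repressor_drop`` (strict), else
    "low".  Traces that are not basally transcribing (or whose
    normalization is undefined) are "n/a".
    """
    if not basal_transcribing or normalized is None:
        return "n/a"
    x = np.asarray(normalized, dtype=float)
    post = float(x[-cfg.post_window:].mean())
    return "high" if (1.0 - post) > cfg.repressor_drop else "low"


def classify_high_basal(basal_levels: np.ndarray,
                        sd_multiplier: float = 1.0
                        ) -> tuple[np.ndarray, float]:
    """Split a population on basal level at mean + sd_multiplier * SD.

    Sample SD; strictly above the threshold -> high.  With n < 2 all
    traces are low (threshold NaN) and a warning is logged.
    """
    x = np.asarray(basal_levels, dtype=float)
    if len(x) < 2:
        log.warning("classify_high_basal: fewer than 2 traces")
        return np.zeros(len(x), dtype=bool), float("nan")
    threshold = float(x.mean() + sd_multiplier * x.std(ddof=1))
    return x > threshold, threshold


def call_traces(ts: TraceSet, cfg: PipelineConfig) -> pd.DataFrame:
    """Run the full trace-calling pipeline on a TraceSet.

    Requires per-time-point detections.  Returns one row per trace with
    active/basal calls, basal level, peak intensity, repressor class and
    the population-level high/low basal split.
    """
    if ts.detections is None:
        raise ValueError("TraceSet has no detection series")
    rows = []
    normalized = []
    for i in range(ts.n_traces):
        active, basal_tx = call_activity(ts.detections[i], ts.stimulus_idx,
                                         cfg)
        basal, norm, peak = basal_and_normalize(ts.intensities[i],
                                                ts.stimulus_idx, cfg)
        rep = classify_repressor(norm, ts.stimulus_idx, cfg,
                                 basal_transcribing=basal_tx)
        rows.append({"trace_id": ts.trace_ids[i], "active": active,
                     "basal_transcribing": basal_tx, "basal_level": basal,
                     "peak_intensity": peak, "repressor_class": rep})
        normalized.append(norm)
    out = pd.DataFrame(rows).set_index("trace_id")
    high, thr = classify_high_basal(out["basal_level"].to_numpy(),
                                    cfg.high_basal_sd)
    out["basal_class"] = np.where(high, "high", "low")
    out.attrs["high_basal_threshold"] = thr
    out.attrs["normalized"] = normalized
    return out
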