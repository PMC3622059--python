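"""Image-to-trace analysis: ROI extraction, ratioing, and kinetic metrics.

Implements the analysis chain used on ratiometric Cl-Sensor recordings:
per-ROI background-subtracted channel traces, alignment of frames taken at
different camera binnings, pairing of 430/500 nm acquisitions into ratio
traces, first-point normalization (dF/F, dR/R), and the scalar estimators
(pulse-induced inhibition, steady-state plateau, recovery half-time,
expression-window filtering, correlation statistics).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats

from .imaging import FrameStack

__all__ = [
    "ROISet",
    "Trace",
    "RatioTrace",
    "NormalizedTrace",
    "HalfTime",
    "align_binning",
    "extract_traces",
    "pair_ratio",
    "normalize_first",
    "inhibition_percent",
    "peak_drop_percent",
    "half_time",
    "steady_state_level",
    "expression_filter",
    "pearson_r",
    "gain_balance_factor",
]


@dataclass(frozen=True)
class ROISet:
    """Labelled integer mask on the unbinned grid; label 0 is background."""

    labels: np.ndarray
    background_labels: Tuple[int, ...] = (0,)

    def __post_init__(self) -> None:
        bg = np.isin(self.labels, self.background_labels)
        if not bg.any():
            raise ValueError("background region is empty")

    def roi_ids(self) -> List[int]:
        ids = np.unique(self.labels)
        return [int(i) for i in ids if i not in self.background_labels]


@dataclass
class Trace:
    """Background-subtracted mean counts of one ROI in one channel."""

    roi_id: int
    channel: int
    t: np.ndarray
    value: np.ndarray

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, float)
        self.value = np.asarray(self.value, float)
        if np.any(np.diff(self.t) <= 0):
            raise ValueError("trace times must be strictly increasing")


@dataclass
class RatioTrace:
    """Paired R430/500 series, one sample per acquisition cycle."""

    roi_id: int
    t: np.ndarray
    r: np.ndarray
    dropped: int = 0

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, float)
        self.r = np.asarray(self.r, float)


@dataclass
class NormalizedTrace:
    roi_id: int
    t: np.ndarray
    value: np.ndarray  # dF/F or dR/R; first sample exactly 0


@dataclass(frozen=True)
class HalfTime:
    """Recovery half-time in minutes; extrapolated marks an exponential-fit estimate."""

    minutes: float
    extrapolated: bool


def align_binning(image: np.ndarray, from_bin: int, to_bin: int) -> np.ndarray:
    """Convert an image between binnings, preserving mean intensity.

    Downsampling (to coarser binning) is a block mean; upsampling is pixel
    replication.  The binning ratio must be an integer.
    """
    if from_bin == to_bin:
        return image
    if from_bin < to_bin:
        b, rem = divmod(to_bin, from_bin)
        if rem:
            raise ValueError("binnings must have an integer ratio")
        h, w = image.shape
        if h % b or w % b:
            raise ValueError("image shape not divisible by binning ratio")
        return image.reshape(h // b, b, w // b, b).mean(axis=(1, 3))
    b, rem = divmod(from_bin, to_bin)
    if rem:
        raise ValueError("binnings must have an integer ratio")
    return np.repeat(np.repeat(image, b, axis=0), b, axis=1)


def extract_traces(stack: FrameStack, rois: ROISet) -> List[Trace]:
    """Per-frame ROI mean minus background mean, grouped by (roi, channel).

    ROI masks live on the unbinned pixel grid; each frame is replicated back
    to that grid according to its metadata binning before averaging.
    """
    shape = rois.labels.shape
    bg_mask = np.isin(rois.labels, rois.background_labels)
    roi_masks = {rid: rois.labels == rid for rid in rois.roi_ids()}
    for rid, m in roi_masks.items():
        if not m.any():
            raise ValueError(f"ROI {rid} is empty")

    samples: Dict[Tuple[int, int], List[Tuple[float, float]]] = {}
    for frame, meta in zip(stack.frames, stack.metadata):
        b = int(meta.get("binning", 1))
        img = align_binning(frame, b, 1)
        if img.shape != shape:
            raise ValueError(
                f"frame shape {img.shape} does not match ROI mask {shape}"
            )
        bg = float(img[bg_mask].mean())
        for rid, m in roi_masks.items():
            samples.setdefault((rid, int(meta["channel"])), []).append(
                (float(meta["t_s"]), float(img[m].mean()) - bg)
            )
    out = []
    for (rid, ch), pts in sorted(samples.items()):
        pts.sort(key=lambda p: p[0])
        t, v = zip(*pts)
        out.append(Trace(roi_id=rid, channel=ch, t=np.array(t), value=np.array(v)))
    return out


def pair_ratio(f430: Trace, f500: Trace, order: str = "500_first") -> RatioTrace:
    """Pair alternating 430/500 acquisitions into one ratio per cycle.

    R = F430/F500 after background subtraction; the sample is timestamped at
    the cycle's first acquisition.  Orphan frames at the end of the stack
    are dropped and counted.
    """
    if order not in ("430_first", "500_first"):
        raise ValueError("order must be '430_first' or '500_first'")
    first, second = (f430, f500) if order == "430_first" else (f500, f430)
    n = min(len(first.t), len(second.t))
    dropped = (len(first.t) - n) + (len(second.t) - n)
    if dropped:
        warnings.warn(f"dropped {dropped} unpaired frame(s)", stacklevel=2)
    if n == 0:
        return RatioTrace(f430.roi_id, np.array([]), np.array([]), dropped=dropped)
    t = first.t[:n]
    if order == "430_first":
        r = first.value[:n] / second.value[:n]
    else:
        r = second.value[:n] / first.value[:n]
    if np.any(r <= 0):
        raise ValueError("non-positive ratio; check background subtraction")
    return RatioTrace(f430.roi_id, t, r, dropped=dropped)


def normalize_first(trace: Trace | RatioTrace) -> NormalizedTrace:
    """(v - v0)/v0 relative to the first recorded value."""
    v = trace.value if isinstance(trace, Trace) else trace.r
    if v[0] == 0:
        raise ValueError("first value is zero; cannot normalize")
    return NormalizedTrace(trace.roi_id, trace.t.copy(), (v - v[0]) / v[0])


def _values(trace) -> Tuple[np.ndarray, np.ndarray]:
    v = trace.value if hasattr(trace, "value") else trace.r
    return np.asarray(trace.t, float), np.asarray(v, float)


def inhibition_percent(trace, event_time: float, n_baseline: int = 3) -> float:
    """Percent drop of the first post-event sample below the pre-event baseline.

    Baseline is the mean of the last ``n_baseline`` samples strictly before
    ``event_time``; scale-invariant by construction.
    """
    t, v = _values(trace)
    pre = np.flatnonzero(t < event_time)
    post = np.flatnonzero(t >= event_time)
    if pre.size < n_baseline or post.size < 1:
        raise ValueError("need >= n_baseline samples before and 1 after the event")
    baseline = v[pre[-n_baseline:]].mean()
    return 100.0 * (baseline - v[post[0]]) / baseline


def peak_drop_percent(trace, window: Tuple[float, float], n_baseline: int = 3) -> float:
    """Largest percent drop below baseline reached inside a time window."""
    t, v = _values(trace)
    pre = np.flatnonzero(t < window[0])
    inside = (t >= window[0]) & (t <= window[1])
    if pre.size < n_baseline or not inside.any():
        raise ValueError("need baseline samples before and samples inside the window")
    baseline = v[pre[-n_baseline:]].mean()
    return 100.0 * (baseline - v[inside].min()) / baseline


def half_time(trace, peak_time: float, baseline_value: float) -> HalfTime:
    """Half-recovery time (minutes) from peak toward a baseline level.

    Finds the peak sample at/after ``peak_time`` and the first crossing of
    the midpoint (peak + baseline)/2, linearly interpolated between the two
    bracketing samples.  If the trace never crosses within the record, a
    single-exponential decay onto the baseline is fitted to the post-peak
    samples and the half-time extrapolated from its time constant.
    """
    t, v = _values(trace)
    after = np.flatnonzero(t >= peak_time)
    if after.size < 3:
        raise ValueError("peak not found: too few samples after peak_time")
    k_peak = after[np.argmax(np.abs(v[after] - baseline_value))]
    peak = v[k_peak]
    mid = 0.5 * (peak + baseline_value)
    sgn = 1.0 if peak > baseline_value else -1.0
    tt, vv = t[k_peak:], v[k_peak:]
    below = np.flatnonzero(sgn * (vv - mid) <= 0)
    if below.size:
        j = below[0]
        if j == 0:
            return HalfTime(0.0, False)
        t_cross = tt[j - 1] + (tt[j] - tt[j - 1]) * (mid - vv[j - 1]) / (vv[j] - vv[j - 1])
        return HalfTime((t_cross - tt[0]) / 60.0, False)
    # never crossed: exponential extrapolation v = baseline + (peak - baseline) e^{-t/tau}
    excess = sgn * (vv - baseline_value)
    good = excess > 0
    if good.sum() < 3:
        raise ValueError("cannot fit exponential: too few decaying samples")
    slope, _ = np.polyfit(tt[good] - tt[0], np.log(excess[good]), 1)
    if slope >= 0:
        raise ValueError("trace does not decay toward baseline")
    tau = -1.0 / slope
    return HalfTime(tau * math.log(2.0) / 60.0, True)


def steady_state_level(trace, tail_n: int = 5) -> float:
    """Mean of the last ``tail_n`` samples as percent of the first sample."""
    t, v = _values(trace)
    if v.size < tail_n + 1:
        raise ValueError("need at least tail_n + 1 samples")
    return 100.0 * v[-tail_n:].mean() / v[0]


def expression_filter(
    baselines: Dict[int, float], low: float = 1000.0, high: float = 8000.0
) -> Dict[int, float]:
    """Keep cells whose baseline F430 lies in [low, high] (inclusive)."""
    return {k: v for k, v in baselines.items() if low <= v <= high}


def pearson_r(
    x: Sequence[float],
    y: Sequence[float],
    strata: Optional[Sequence[Tuple[float, float]]] = None,
) -> List[Tuple[float, float, int]]:
    """Pearson correlation with two-tailed t-test p-value, optionally per x-stratum.

    Returns (r, p, n) tuples, one per stratum (one overall if none given).
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if strata is None:
        strata = [(-np.inf, np.inf)]
    out = []
    for lo, hi in strata:
        sel = (x >= lo) & (x <= hi)
        n = int(sel.sum())
        if n < 3:
            raise ValueError(f"need n >= 3 in stratum [{lo}, {hi}]")
        if np.std(x[sel]) == 0 or np.std(y[sel]) == 0:
            raise ValueError("zero variance in stratum")
        r, p = stats.pearsonr(x[sel], y[sel])
        out.append((float(r), float(p), n))
    return out


def gain_balance_factor(f430: Trace, f500: Trace) -> float:
    """Recommended F500 exposure multiplier so the median ratio is ~1."""
    return float(np.median(f430.value) / np.median(f500.value))
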