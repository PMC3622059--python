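"""Calibration and KCC2 assays.

Nernst calibration from simulated perforated-patch data (reversal-potential
estimation from a voltage-current relationship), four-parameter logistic
dose-response fitting and its closed-form inverse for crude [Cl-]i
estimation, and the scalar KCC2 assays (reverse-mode influx, extrusion
half-time) with the two-sample Kolmogorov-Smirnov comparison used for
group statistics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy import optimize, stats

from .traces import HalfTime, RatioTrace, half_time

__all__ = [
    "VCRData",
    "DoseResponseCurve",
    "AssayResult",
    "estimate_reversal",
    "fit_dose_response",
    "cl_from_ratio",
    "kcc2_influx_assay",
    "extrusion_assay",
    "ks_two_sample",
]


@dataclass(frozen=True)
class VCRData:
    """Voltage-current relationship: agonist peak currents at holding potentials."""

    holding_mv: Sequence[float]
    current_pa: Sequence[float]

    def __post_init__(self) -> None:
        if len(set(self.holding_mv)) < 2:
            raise ValueError("need >= 2 distinct holding potentials")
        if len(self.holding_mv) != len(self.current_pa):
            raise ValueError("holding_mv and current_pa lengths differ")


@dataclass(frozen=True)
class DoseResponseCurve:
    """Four-parameter logistic in log10([Cl-]):

    R(cl) = r_min + (r_max - r_min) / (1 + 10^(slope_h (log_ec50_app - log10 cl)))
    """

    r_min: float
    r_max: float
    log_ec50_app: float
    slope_h: float

    def __post_init__(self) -> None:
        if not self.r_max > self.r_min > 0:
            raise ValueError("need r_max > r_min > 0")
        if self.slope_h <= 0:
            raise ValueError("slope_h must be > 0")

    def value(self, cl: float | np.ndarray) -> float | np.ndarray:
        logc = np.log10(cl)
        out = self.r_min + (self.r_max - self.r_min) / (
            1.0 + 10.0 ** (self.slope_h * (self.log_ec50_app - logc))
        )
        return float(out) if np.isscalar(cl) else out


@dataclass(frozen=True)
class AssayResult:
    kind: str       # resting_ratio | extrusion_half_time | influx_delta_r | delta_r_over_r | cl_estimate
    value: float
    units: str
    group: str = ""
    extrapolated: bool = False

    _UNITS = {
        "resting_ratio": "ratio units",
        "extrusion_half_time": "min",
        "influx_delta_r": "ratio units",
        "delta_r_over_r": "%",
        "cl_estimate": "mM",
    }

    def __post_init__(self) -> None:
        if self.kind not in self._UNITS:
            raise ValueError(f"unknown assay kind {self.kind!r}")
        if self.units != self._UNITS[self.kind]:
            raise ValueError(f"{self.kind} must be reported in {self._UNITS[self.kind]!r}")


def estimate_reversal(vcr: VCRData) -> float:
    """Reversal potential (mV): zero crossing of the least-squares I(V) line."""
    v = np.asarray(vcr.holding_mv, float)
    i = np.asarray(vcr.current_pa, float)
    slope, intercept = np.polyfit(v, i, 1)
    if abs(slope) < 1e-12 * max(1.0, abs(intercept)):
        raise ValueError("degenerate VCR: zero slope")
    return float(-intercept / slope)


def _p4l(logc, r_min, r_max, log_ec50, h):
    return r_min + (r_max - r_min) / (1.0 + 10.0 ** (h * (log_ec50 - logc)))


def fit_dose_response(points: Sequence[Tuple[float, float]]) -> DoseResponseCurve:
    """Least-squares 4PL fit of (cl mM, ratio) calibration points.

    Requires >= 4 points spanning at least one decade of chloride.  Exact
    (residual < 1e-8) on noise-free 4PL-generated data.
    """
    pts = np.asarray(points, float)
    if pts.shape[0] < 4:
        raise ValueError("need >= 4 calibration points")
    cl, r = pts[:, 0], pts[:, 1]
    if np.log10(cl.max() / cl.min()) < 1.0:
        raise ValueError("calibration points must span >= 1 decade")
    logc = np.log10(cl)
    # r_min can be at most the smallest observed ratio, r_max at least the
    # largest; the EC50 gets one decade of headroom on either side
    lo = [1e-9, r.max(), logc.min() - 1.0, 0.05]
    hi = [r.min(), 10.0 * r.max(), logc.max() + 1.0, 8.0]
    p0 = [0.5 * r.min(), 1.2 * r.max(), float(np.median(logc)), 1.0]
    try:
        popt, _ = optimize.curve_fit(
            _p4l, logc, r, p0=p0, bounds=(lo, hi), maxfev=50000
        )
    except RuntimeError as exc:  # pragma: no cover - diagnostics path
        raise RuntimeError(f"dose-response fit did not converge: {exc}") from exc
    return DoseResponseCurve(*[float(x) for x in popt])


def cl_from_ratio(r: float, curve: DoseResponseCurve) -> float:
    """Closed-form inverse of the 4PL: [Cl-]i (mM) for a measured ratio."""
    if not curve.r_min < r < curve.r_max:
        raise ValueError(
            f"ratio {r} outside the curve's open range "
            f"({curve.r_min}, {curve.r_max})"
        )
    frac = (curve.r_max - curve.r_min) / (r - curve.r_min) - 1.0
    return 10.0 ** (curve.log_ec50_app - math.log10(frac) / curve.slope_h)


def kcc2_influx_assay(
    ratio: RatioTrace, kcl_time: float, group: str = ""
) -> AssayResult:
    """Reverse-mode influx: dR between 30 s before and 5 min after KCl.

    Nearest-sample lookup at kcl_time - 30 s and kcl_time + 300 s, matching
    a 20 s acquisition cadence.
    """
    t = ratio.t
    for t_query in (kcl_time - 30.0, kcl_time + 300.0):
        if t_query < t[0] or t_query > t[-1]:
            raise ValueError("assay window extends outside the trace")
    r_pre = ratio.r[np.argmin(np.abs(t - (kcl_time - 30.0)))]
    r_post = ratio.r[np.argmin(np.abs(t - (kcl_time + 300.0)))]
    return AssayResult("influx_delta_r", float(r_post - r_pre), "ratio units", group)


def extrusion_assay(
    ratio: RatioTrace, load_window: Tuple[float, float], group: str = ""
) -> AssayResult:
    """Half decay time of the ratio after a chloride load.

    Baseline is the pre-load mean; the peak is looked up inside
    ``load_window`` and the half-time delegated to :func:`half_time`
    (exponential extrapolation when recovery never crosses the midpoint).
    """
    pre = ratio.t < load_window[0]
    if not pre.any():
        raise ValueError("no samples before the load window")
    baseline = float(ratio.r[pre].mean())
    inside = (ratio.t >= load_window[0]) & (ratio.t <= load_window[1])
    if not inside.any():
        raise ValueError("no peak: load window contains no samples")
    t_peak = float(ratio.t[inside][np.argmax(ratio.r[inside])])
    ht = half_time(ratio, t_peak, baseline)
    return AssayResult("extrusion_half_time", ht.minutes, "min", group,
                       extrapolated=ht.extrapolated)


def ks_two_sample(a: Sequence[float], b: Sequence[float]) -> Tuple[float, float]:
    """Two-sample Kolmogorov-Smirnov test: exact D, asymptotic p."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.size < 5 or b.size < 5:
        raise ValueError("both samples must have >= 5 observations")
    res = stats.ks_2samp(a, b, method="asymp")
    return float(res.statistic), float(res.pvalue)
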