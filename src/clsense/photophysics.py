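"""Forward model of Cl-Sensor fluorescence.

Cl-Sensor is a CFP::YFP_Cl chimera.  Chloride quenches the YFP_Cl moiety
(single-site binding, apparent EC50 of tens of mM), so fluorescence excited
at 500 nm (pure YFP_Cl) falls as [Cl-]i rises, while fluorescence excited at
430 nm is a mixture of a Cl-insensitive CFP part and a Cl-sensitive YFP_Cl
part.  On top of the chloride dependence, 430 nm light drives YFP_Cl into a
reversible dark state far more potently than 500 nm light does; each
excitation wavelength populates its own dark pool that recovers
exponentially in the dark.  This module models those three processes --
quenching, use-dependent darkening, and recovery -- at the level of a single
cell's mean fluorescence.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

__all__ = [
    "PhotophysicsParams",
    "SensorState",
    "IlluminationEvent",
    "yfp_quench_factor",
    "dark_increment",
    "dark_recovery",
    "emitted_rate",
    "emitted_signal",
    "steady_state_dark",
]

# slow dark sub-pool (enabled via slow_pool_weight) recovers this many times
# slower than the main pool
SLOW_POOL_TAU_FACTOR = 20.0


@dataclass(frozen=True)
class PhotophysicsParams:
    """Sensor constants.

    Parameters
    ----------
    ec50 : float
        Apparent chloride half-quench concentration, mM.
    hill : float
        Hill exponent of the quench curve (default 1, single site).
    residual_q : float
        Unquenchable YFP_Cl fraction at saturating chloride, in [0, 1).
    alpha_rest : float
        YFP_Cl-origin share of the 430 nm channel signal at the resting
        reference state (``cl_ref``); the remaining ``1 - alpha_rest`` is
        photostable, Cl-insensitive CFP (any FRET contribution is absorbed
        here too).
    cl_ref : float
        Chloride of the resting reference state, mM.  ``alpha_rest`` is the
        YFP share of F430 when [Cl-]i equals ``cl_ref`` and no dark states
        are populated.
    fmax_430, fmax_500 : float
        Maximal darkenable YFP_Cl fraction per excitation wavelength.
    tau_inact_430, tau_inact_500 : float
        Darkening time constants (s) at full lamp intensity.
    tau_rec_430, tau_rec_500 : float
        Dark-state recovery time constants (s).
    slow_pool_weight : float
        Fraction of each darkening increment routed to a slowly recovering
        sub-pool (default 0: single-exponential recovery).
    """

    ec50: float
    hill: float = 1.0
    residual_q: float = 0.0
    alpha_rest: float = 0.287
    cl_ref: float = 0.0
    fmax_430: float = 0.30
    tau_inact_430: float = 0.22
    tau_rec_430: float = 50.0
    fmax_500: float = 0.12
    tau_inact_500: float = 35.0
    tau_rec_500: float = 60.0
    slow_pool_weight: float = 0.0

    def __post_init__(self) -> None:
        if self.ec50 <= 0:
            raise ValueError("ec50 must be > 0")
        if self.hill <= 0:
            raise ValueError("hill must be > 0")
        if not 0.0 <= self.residual_q < 1.0:
            raise ValueError("residual_q must be in [0, 1)")
        if not 0.0 <= self.alpha_rest <= 1.0:
            raise ValueError("alpha_rest must be in [0, 1]")
        if self.cl_ref < 0:
            raise ValueError("cl_ref must be >= 0")
        for name in ("fmax_430", "fmax_500"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        for name in ("tau_inact_430", "tau_inact_500", "tau_rec_430", "tau_rec_500"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if not 0.0 <= self.slow_pool_weight <= 1.0:
            raise ValueError("slow_pool_weight must be in [0, 1]")

    def fmax(self, wavelength: int) -> float:
        return self.fmax_430 if wavelength == 430 else self.fmax_500

    def tau_inact(self, wavelength: int) -> float:
        return self.tau_inact_430 if wavelength == 430 else self.tau_inact_500

    def tau_rec(self, wavelength: int) -> float:
        return self.tau_rec_430 if wavelength == 430 else self.tau_rec_500


@dataclass(frozen=True)
class SensorState:
    """Per-cell photophysical state: dark-pool occupancies and expression."""

    dark_430: float = 0.0
    dark_500: float = 0.0
    expression: float = 1.0
    dark_430_slow: float = 0.0
    dark_500_slow: float = 0.0

    def __post_init__(self) -> None:
        for name in ("dark_430", "dark_500", "dark_430_slow", "dark_500_slow"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.expression < 0:
            raise ValueError("expression must be >= 0")

    def dark_total(self, wavelength: int) -> float:
        if wavelength == 430:
            return self.dark_430 + self.dark_430_slow
        return self.dark_500 + self.dark_500_slow


@dataclass(frozen=True)
class IlluminationEvent:
    """A timed excitation pulse: wavelength, duration (s), ND attenuation."""

    wavelength: int
    duration: float
    intensity_factor: float = 1.0

    def __post_init__(self) -> None:
        if self.wavelength not in (430, 500):
            raise ValueError("wavelength must be 430 or 500")
        if self.duration < 0:
            raise ValueError("duration must be >= 0")
        if not 0.0 < self.intensity_factor <= 1.0:
            raise ValueError("intensity_factor must be in (0, 1]")

    @property
    def dose(self) -> float:
        """Effective dose in full-intensity seconds (reciprocity)."""
        return self.duration * self.intensity_factor


def yfp_quench_factor(cl: float, p: PhotophysicsParams) -> float:
    """Fraction of YFP_Cl fluorescence remaining at chloride ``cl`` (mM).

    Q(cl) = residual_q + (1 - residual_q) / (1 + (cl/ec50)^hill); strictly
    decreasing from Q(0) = 1 toward residual_q.
    """
    if cl < 0:
        raise ValueError("cl must be >= 0")
    return p.residual_q + (1.0 - p.residual_q) / (1.0 + (cl / p.ec50) ** p.hill)


def dark_increment(
    state: SensorState, ev: IlluminationEvent, p: PhotophysicsParams
) -> SensorState:
    """Advance the dark pool of the event's wavelength by one exposure.

    The occupied fraction approaches f_max as a saturating exponential in the
    delivered dose (duration x intensity), leaving the other wavelength's
    pool untouched.
    """
    if ev.duration == 0:
        return state
    fmax = p.fmax(ev.wavelength)
    a = 1.0 - math.exp(-ev.dose / p.tau_inact(ev.wavelength))
    d_tot = state.dark_total(ev.wavelength)
    delta = (fmax - d_tot) * a
    fast = delta * (1.0 - p.slow_pool_weight)
    slow = delta * p.slow_pool_weight
    if ev.wavelength == 430:
        return replace(
            state,
            dark_430=state.dark_430 + fast,
            dark_430_slow=state.dark_430_slow + slow,
        )
    return replace(
        state,
        dark_500=state.dark_500 + fast,
        dark_500_slow=state.dark_500_slow + slow,
    )


def dark_recovery(state: SensorState, dt: float, p: PhotophysicsParams) -> SensorState:
    """Exponential dark-state recovery over a dark interval ``dt`` (s)."""
    if dt < 0:
        raise ValueError("dt must be >= 0")
    if dt == 0:
        return state
    r430 = math.exp(-dt / p.tau_rec_430)
    r500 = math.exp(-dt / p.tau_rec_500)
    rs430 = math.exp(-dt / (SLOW_POOL_TAU_FACTOR * p.tau_rec_430))
    rs500 = math.exp(-dt / (SLOW_POOL_TAU_FACTOR * p.tau_rec_500))
    return replace(
        state,
        dark_430=state.dark_430 * r430,
        dark_500=state.dark_500 * r500,
        dark_430_slow=state.dark_430_slow * rs430,
        dark_500_slow=state.dark_500_slow * rs500,
    )


def emitted_rate(channel: int, cl: float, state: SensorState, p: PhotophysicsParams) -> float:
    """Fluorescence rate per unit expression, dose and gain (dimensionless).

    F500 is pure YFP_Cl: proportional to Q(cl) and to both dark-pool
    survivals.  F430 mixes a photostable CFP part, weighted 1 - alpha_rest,
    with a YFP_Cl part weighted alpha_rest and normalized to the resting
    reference state (cl = cl_ref, empty dark pools).
    """
    dark_surv = (1.0 - state.dark_total(430)) * (1.0 - state.dark_total(500))
    q = yfp_quench_factor(cl, p)
    if channel == 500:
        return q * dark_surv
    if channel == 430:
        q_ref = yfp_quench_factor(p.cl_ref, p)
        return (1.0 - p.alpha_rest) + p.alpha_rest * (q / q_ref) * dark_surv
    raise ValueError("channel must be 430 or 500")


def emitted_signal(
    channel: int,
    cl: float,
    state: SensorState,
    ev: IlluminationEvent,
    gain: float,
    background: float,
    p: PhotophysicsParams,
) -> float:
    """Camera counts for one acquisition: gain x expression x dose x rate + background."""
    rate = emitted_rate(channel, cl, state, p)
    return gain * state.expression * ev.dose * rate + background


def steady_state_dark(
    pulse: IlluminationEvent, interval: float, p: PhotophysicsParams
) -> float:
    """Fixed point of the pulse-then-recover cycle, measured at pulse onset.

    With per-pulse entry a = 1 - exp(-dose/tau_inact) and per-interval
    survival rho = exp(-interval/tau_rec), iterating
    d -> (d + (f_max - d) a) rho converges to
    d* = f_max a rho / (1 - rho (1 - a)).
    """
    if interval <= pulse.duration:
        raise ValueError("interval must exceed pulse duration")
    a = 1.0 - math.exp(-pulse.dose / p.tau_inact(pulse.wavelength))
    rho = math.exp(-interval / p.tau_rec(pulse.wavelength))
    fmax = p.fmax(pulse.wavelength)
    return fmax * a * rho / (1.0 - rho * (1.0 - a))
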