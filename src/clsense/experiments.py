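"""Experiment runner: ion dynamics x photophysics x imaging x analysis.

`run_experiment` integrates the chloride dynamics of a configuration, walks
the acquisition timeline updating the sensor's dark states once per
illumination event, and produces either per-cell traces directly (the
noise-free forward prediction) or a rendered image stack that is then fed
through the ROI extraction pipeline.  The two paths agree exactly on
noise-free data because scenes keep cell masks aligned to camera binning
blocks.

The `measure_*` functions execute the canned protocols and return the
scalar quantities of interest (inhibition percentages, plateau levels,
recovery half-times, assay amplitudes, calibration curves).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import configs
from .assays import (
    DoseResponseCurve,
    VCRData,
    estimate_reversal,
    extrusion_assay,
    fit_dose_response,
    kcc2_influx_assay,
)
from .configs import ExperimentConfig
from .imaging import FrameStack, NoiseModel, render_frame
from .ion_dynamics import invert_nernst, simulate_cli
from .photophysics import SensorState, dark_increment, dark_recovery, emitted_rate
from .traces import (
    RatioTrace,
    ROISet,
    Trace,
    extract_traces,
    half_time,
    inhibition_percent,
    pair_ratio,
    peak_drop_percent,
    steady_state_level,
)

__all__ = [
    "RunResult",
    "run_experiment",
    "measure_photoinactivation",
    "measure_plateau",
    "measure_glycine_kcl",
    "measure_strychnine_recovery",
    "measure_extrusion",
    "measure_influx",
    "measure_calibration",
    "measure_compartment_kinetics",
    "measure_ratio_drift",
    "population_expression",
    "population_resting_ratio",
]


@dataclass
class RunResult:
    config: ExperimentConfig
    traces: List[Trace]
    ratios: Dict[int, RatioTrace]
    ground_truth: pd.DataFrame
    stack: Optional[FrameStack] = None

    def trace(self, cell_id: int, channel: int) -> Trace:
        for tr in self.traces:
            if tr.roi_id == cell_id and tr.channel == channel:
                return tr
        raise KeyError((cell_id, channel))


def _dark_timeline(cfg: ExperimentConfig):
    """Dark-state trajectory shared by all cells (illumination is global).

    Returns (acquisition records, per-event states): for each acquisition,
    (t, step, SensorState at pulse onset).
    """
    state = SensorState()
    t_prev = 0.0
    acq = []
    for t, ev, step in cfg.plan.timeline():
        state = dark_recovery(state, t - t_prev, cfg.params)
        t_prev = t
        if step is not None:
            acq.append((t, step, state))
        state = dark_increment(state, ev, cfg.params)
    return acq


def run_experiment(
    cfg: ExperimentConfig,
    render: bool = False,
    noise: Optional[NoiseModel] = None,
) -> RunResult:
    """Run one canned (or custom) experiment end to end.

    With ``render=False`` the per-cell traces are the forward-model values
    (background already subtracted); with ``render=True`` frames are
    rendered and traces extracted through the ROI pipeline.
    """
    noise = noise if noise is not None else cfg.noise
    sim = simulate_cli(
        cfg.protocol, cfg.transport, cfg.comps,
        dt=cfg.dt, t_end=cfg.plan.t_end, mm=cfg.membrane, cl0=cfg.cl0,
    )
    acq = _dark_timeline(cfg)

    comp_idx = {c.name: i for i, c in enumerate(cfg.comps)}
    cell_comp = {
        cell.cell_id: comp_idx[cell.compartment] for cell in cfg.scene.cells
    }

    gt_rows = []
    samples: Dict[Tuple[int, int], List[Tuple[float, float]]] = {}
    frames, metadata = [], []
    rng = noise.rng() if noise.enabled else None
    for t, step, state in acq:
        snapshot = {}
        for cell in cfg.scene.cells:
            cl = sim.cl_at(t, cell_comp[cell.cell_id])
            cstate = replace(state, expression=cell.expression)
            snapshot[cell.cell_id] = (cl, cstate)
            gt_rows.append(
                dict(t_s=t, cell_id=cell.cell_id, cl_i_mM=cl,
                     dark430=state.dark_total(430), dark500=state.dark_total(500),
                     channel=step.channel)
            )
            if not render:
                rate = emitted_rate(step.channel, cl, cstate, cfg.params)
                dose = step.exposure_ms / 1000.0 * step.intensity_factor
                samples.setdefault((cell.cell_id, step.channel), []).append(
                    (t, step.gain * cell.expression * dose * rate)
                )
        if render:
            frames.append(
                render_frame(cfg.scene, snapshot, step, cfg.params, noise, rng)
            )
            metadata.append(
                dict(t_s=t, channel=step.channel, exposure_ms=step.exposure_ms,
                     binning=step.binning, intensity_factor=step.intensity_factor,
                     gain=step.gain, background=step.background)
            )

    stack = None
    if render:
        stack = FrameStack(frames=frames, metadata=metadata)
        rois = ROISet(labels=cfg.scene.label_mask())
        traces = extract_traces(stack, rois)
    else:
        traces = [
            Trace(roi_id=rid, channel=ch, t=np.array([p[0] for p in pts]),
                  value=np.array([p[1] for p in pts]))
            for (rid, ch), pts in sorted(samples.items())
        ]

    by_cell: Dict[int, Dict[int, Trace]] = {}
    for tr in traces:
        by_cell.setdefault(tr.roi_id, {})[tr.channel] = tr
    ratios = {}
    for rid, chans in by_cell.items():
        if 430 in chans and 500 in chans:
            ratios[rid] = pair_ratio(chans[430], chans[500], order=cfg.plan_order)
    gt = pd.DataFrame(gt_rows)
    return RunResult(config=cfg, traces=traces, ratios=ratios,
                     ground_truth=gt, stack=stack)


# ---------------------------------------------------------------------------
# canned measurements


def measure_photoinactivation(
    probe_wavelength: int, probe_duration_s: float, render: bool = True
) -> float:
    """Percent F500 inhibition by a single probe pulse on the 500 nm routine.

    Reproduces the single-wavelength photoinactivation paradigm: repetitive
    50 ms / 10 s acquisitions at 500 nm with one additional light pulse
    inserted immediately before an acquisition.
    """
    cfg = configs.photoinactivation_config(probe_wavelength, probe_duration_s)
    res = run_experiment(cfg, render=render)
    return inhibition_percent(res.trace(1, 500), cfg.meta["probe_time"])


def measure_plateau(render: bool = True, n_cycles: int = 180) -> float:
    """F430 steady-state plateau (percent of initial) under 20 ms / 10 s 430 nm pulsing."""
    cfg = configs.plateau_430_config(n_cycles=n_cycles)
    res = run_experiment(cfg, render=render)
    return steady_state_level(res.trace(1, 430), tail_n=5)


def measure_glycine_kcl(render: bool = True, strychnine: bool = False) -> dict:
    """Glycine + 100 mM KCl challenge on N2a/GlyR cells.

    Returns peak percent drops of F430 and F500 during the application, the
    peak dR/R of the ratio, and the half recovery time after washout.
    """
    cfg = (configs.fig5_strychnine_config() if strychnine
           else configs.fig5_glycine_kcl_config())
    res = run_experiment(cfg, render=render)
    win = cfg.meta["app_window"]
    f430 = res.trace(1, 430)
    f500 = res.trace(1, 500)
    ratio = res.ratios[1]
    pre = ratio.t < win[0]
    baseline_r = float(ratio.r[pre].mean())
    in_app = (ratio.t >= win[0]) & (ratio.t <= win[1])
    dr_over_r = 100.0 * (ratio.r[in_app].max() - baseline_r) / baseline_r
    assay = extrusion_assay(ratio, win)
    return dict(
        f430_drop_percent=peak_drop_percent(f430, win),
        f500_drop_percent=peak_drop_percent(f500, win),
        dr_over_r_percent=dr_over_r,
        half_time_min=assay.value,
        extrapolated=assay.extrapolated,
    )


def measure_strychnine_recovery(render: bool = True) -> dict:
    """Half recovery time with tonic GlyR blocked (0.3 uM strychnine)."""
    out = measure_glycine_kcl(render=render, strychnine=True)
    return dict(half_time_min=out["half_time_min"], extrapolated=out["extrapolated"])


def measure_extrusion(furosemide: bool = False, render: bool = True) -> dict:
    """KCC2 extrusion assay: ratio half decay time after a glycine/KCl load."""
    cfg = configs.fig7_extrusion_config(furosemide=furosemide)
    res = run_experiment(cfg, render=render)
    assay = extrusion_assay(res.ratios[1], cfg.meta["app_window"])
    return dict(half_time_min=assay.value, extrapolated=assay.extrapolated)


def measure_influx(group: str = "kcc2", render: bool = True) -> float:
    """Reverse-mode KCC2 influx: dR between -30 s and +5 min around 140 mM KCl."""
    cfg = configs.fig7_influx_config(group)
    res = run_experiment(cfg, render=render)
    return kcc2_influx_assay(res.ratios[1], cfg.meta["kcl_time"], group).value


def measure_calibration(render: bool = True) -> dict:
    """Simulated perforated-patch calibration experiment.

    Imposed chloride steps under voltage clamp; plateau (Cl, R) pairs are
    fitted with the 4PL; the synthetic VCR at rest yields E_GABA and a
    Nernst [Cl-]i estimate.
    """
    cfg = configs.fig8_calibration_config()
    res = run_experiment(cfg, render=render)
    ratio = res.ratios[1]
    gt = res.ground_truth
    points = []
    for t_read in cfg.meta["plateau_times"]:
        cl = float(np.interp(t_read, gt.t_s, gt.cl_i_mM))
        r = float(ratio.r[np.argmin(np.abs(ratio.t - t_read))])
        points.append((cl, r))
    curve = fit_dose_response(points)

    cl_rest = points[0][0]
    sol = cfg.protocol[0].solution
    vcr = synth_vcr(cl_rest, sol.cl_o)
    e_rev = estimate_reversal(vcr)
    return dict(
        curve=curve,
        r_at_5=curve.value(5.0),
        r_at_150=curve.value(150.0),
        plateaus=points,
        e_gaba_mv=e_rev,
        cl_rest_estimate_mM=invert_nernst(e_rev, sol.cl_o),
    )


def synth_vcr(
    cl_i: float,
    cl_o: float,
    holding_mv: Sequence[float] = (-107.0, -95.0, -60.0, -45.0),
    conductance_pa_per_mv: float = 0.5,
    noise_sd_pa: float = 0.0,
    rng: Optional[np.random.Generator] = None,
) -> VCRData:
    """Synthetic agonist voltage-current relationship at a known [Cl-]i."""
    from .ion_dynamics import nernst_ecl

    e = nernst_ecl(cl_o, cl_i)
    i = np.array([conductance_pa_per_mv * (v - e) for v in holding_mv])
    if noise_sd_pa > 0:
        rng = rng if rng is not None else np.random.default_rng(0)
        i = i + rng.normal(0.0, noise_sd_pa, i.shape)
    return VCRData(tuple(holding_mv), tuple(i))


def measure_compartment_kinetics(render: bool = False) -> Dict[str, float]:
    """Recovery half-times (min) of soma, dendrite and spine after a Cl load."""
    cfg = configs.fig9_neuron_config()
    res = run_experiment(cfg, render=render)
    out = {}
    for cell in cfg.scene.cells:
        assay = extrusion_assay(res.ratios[cell.cell_id], cfg.meta["app_window"])
        out[cell.compartment] = assay.value
    return out


def measure_ratio_drift(protocol: str = "original", render: bool = False) -> float:
    """Percent ratio drift over 30 min at rest.

    ``protocol='original'``: full-intensity 430-then-500 ordering.
    ``protocol='improved'``: 5 % ND on 430 nm and 500-then-430 ordering.
    """
    cfg = configs.drift_config(protocol)
    res = run_experiment(cfg, render=render)
    r = res.ratios[1].r
    return 100.0 * abs(r[-1] - r[0]) / r[0]


def population_expression(n: int = 184, seed: int = 1) -> pd.DataFrame:
    """Expression-heterogeneous, chloride-homogeneous population (with noise).

    Returns one row per cell: baseline F430 counts, baseline ratio, peak
    dR/R of the glycine/KCl response, and the ground-truth expression.
    """
    cfg = configs.population_config(n=n, seed=seed)
    res = run_experiment(cfg, render=True)
    win = cfg.meta["app_window"]
    rows = []
    for cell in cfg.scene.cells:
        f430 = res.trace(cell.cell_id, 430)
        ratio = res.ratios[cell.cell_id]
        pre_f = f430.t < win[0]
        pre_r = ratio.t < win[0]
        in_app = (ratio.t >= win[0]) & (ratio.t <= win[1])
        base_r = float(ratio.r[pre_r].mean())
        rows.append(dict(
            cell_id=cell.cell_id,
            expression=cell.expression,
            f430_baseline=float(f430.value[pre_f].mean()),
            ratio_baseline=base_r,
            dr_over_r_percent=100.0 * (ratio.r[in_app].max() - base_r) / base_r,
        ))
    return pd.DataFrame(rows)


def population_resting_ratio(
    group: str, n: int = 45, seed: int = 2
) -> np.ndarray:
    """Resting ratios of a simulated cell population (mock or KCC2).

    Both groups are imaged with the gain block of the extrusion
    configuration (one comparison experiment, one set of camera settings).
    KCC2 cells rest near the transporter's thermodynamic fixed point; mock
    cells lack the exogenous extruder and rest at the leak/tonic balance.
    Per-cell transporter strength and leak equilibrium vary log-normally
    (expression variability); ~1 % multiplicative measurement noise is
    added per channel.
    """
    from .ion_dynamics import resting_cl
    from .photophysics import SensorState as _S

    if group not in ("mock", "kcc2"):
        raise ValueError("group must be 'mock' or 'kcc2'")
    cfg = configs.fig7_extrusion_config()
    rng = np.random.default_rng(seed + (0 if group == "kcc2" else 1000))
    sol = cfg.protocol[0].solution
    tp = cfg.transport if group == "kcc2" else replace(cfg.transport, u_kcc2=0.0)
    comp = cfg.comps[0]
    step430 = next(s for s in cfg.plan.steps if s.channel == 430)
    step500 = next(s for s in cfg.plan.steps if s.channel == 500)
    out = []
    for _ in range(n):
        u = tp.u_kcc2 * rng.lognormal(0.0, 0.35)
        leak = tp.cl_leak * rng.lognormal(0.0, 0.10)
        tp_i = replace(tp, u_kcc2=u, cl_leak=leak)
        rest = resting_cl(sol, tp_i, comp, cfg.membrane)
        s = _S()
        dose430 = step430.exposure_ms / 1000.0 * step430.intensity_factor
        dose500 = step500.exposure_ms / 1000.0 * step500.intensity_factor
        f430 = step430.gain * dose430 * emitted_rate(430, rest, s, cfg.params)
        f500 = step500.gain * dose500 * emitted_rate(500, rest, s, cfg.params)
        r = (f430 * rng.normal(1.0, 0.01)) / (f500 * rng.normal(1.0, 0.01))
        out.append(r)
    return np.asarray(out)
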