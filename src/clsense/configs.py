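"""Canned experiment configurations and frozen model constants.

Each builder returns an :class:`ExperimentConfig` bundling photophysics
parameters, chloride-transport parameters, a bath/voltage protocol, an
acquisition plan, a scene and a noise model.  The configurations mirror the
recording paradigms of the study this package models: single-wavelength
photoinactivation probing, repetitive 430 nm pulsing, glycine/KCl
challenges of N2a cells with and without strychnine or KCC2, reverse-mode
KCC2 influx under 140 mM KCl, the perforated-patch calibration experiment,
and multi-compartment neuron recordings.

Constants marked "derived" are solved from pairs of printed observations
(see clsense.calibrate, which re-derives every one of them numerically);
constants marked "tuned" are solved by root-finding the full simulated
measurement against the corresponding published value.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .imaging import AcquisitionPlan, CellSpec, NoiseModel, PlanStep, SceneSpec, grid_scene
from .ion_dynamics import (
    BathSolution,
    CompartmentSpec,
    MembraneModel,
    ProtocolEvent,
    TransportParams,
    resting_cl,
)
from .photophysics import (
    IlluminationEvent,
    PhotophysicsParams,
    SensorState,
    dark_increment,
    dark_recovery,
    yfp_quench_factor,
)

__all__ = [
    "ExperimentConfig",
    "SOLUTIONS",
    "default_photophysics",
    "photoinactivation_config",
    "plateau_430_config",
    "fig5_glycine_kcl_config",
    "fig5_strychnine_config",
    "fig7_extrusion_config",
    "fig7_influx_config",
    "fig8_calibration_config",
    "fig9_neuron_config",
    "drift_config",
    "population_config",
    "CANNED_CONFIGS",
]

# --- derived sensor constants (re-derivable via clsense.calibrate) ---------

#: YFP share of the 430 nm channel at rest: 6.2 % / 21.6 % printed drops
ALPHA_REST = 0.062 / 0.216

#: in-cell apparent chloride EC50 (mM) and zero-chloride ratio anchor,
#: solved from the calibration dynamic range R(5) = 0.7, R(150) = 4.0
EC50_APP_MM = 18.3641975308642
R0_CALIBRATION = 0.5862068965517241

#: 430 nm dark pool solved from 2.6 % (20 ms) and 30 % (1 s) inhibitions
FMAX_430 = 0.3034427671676707
TAU_INACT_430_S = 0.2232682359201559
TAU_REC_430_S = 50.0

#: 500 nm dark pool solved from 0.34 % (1 s) and 3.0 % (10 s) inhibitions
FMAX_500 = 0.12075034596498717
TAU_INACT_500_S = 35.012427561851126
TAU_REC_500_S = 60.0

# --- tuned transport constants (solved in clsense.calibrate) ---------------

#: leak-only recovery gives the 56.6 min strychnine half-time
K_LEAK_PER_MIN = math.log(2.0) / 56.6
CL_LEAK_MM = 7.0

#: GlyR strength: glycine + 100 mM KCl load peaks at a 21.6 % F500 drop
G_GLYR = 0.0033564235102327713
#: tonic GlyR drive: control washout half-recovery of 6.8 min
P_TONIC = 0.18014976628144913
#: KCC2 strength of the extrusion config: 2 min ratio half-decay
U_KCC2_EXTRUSION = 0.056155234293692784
#: KCC2 strength of the influx config: +4.5 ratio units in 5 min at 140 K+
U_KCC2_INFLUX = 0.7676714455355067
#: endogenous KCC strength of mock cells: +0.9 ratio units
U_ENDO_MOCK = 0.03738957307536228
#: GABAAR strength of the calibration config: first jet plateau ~17.6 mM
G_GABAAR_FIG8 = 0.03937657766955932
#: furosemide block fraction: residual KCl influx of +1.3 ratio units
FUROSEMIDE_BLOCK = 0.9177253149934218
#: neuron KCC2 strength (soma-scale recovery of a few minutes)
U_KCC2_NEURON = 0.02

#: resting-ratio anchor of the influx config gain block
R_REST_INFLUX = 1.05

NEURON_REST_MM = 5.7

DT_S = 0.1
BG_COUNTS = 100.0
F500_REST_COUNTS = 2000.0


# --- solutions library -----------------------------------------------------

def _sol(label: str, nacl: float, kcl: float, **drugs: float) -> BathSolution:
    s = BathSolution.from_salts(nacl=nacl, kcl=kcl, **drugs)
    return replace(s, label=label)


SOLUTIONS: Dict[str, BathSolution] = {
    "control": _sol("control", 140.0, 2.5),
    "control_strychnine": _sol("control_strychnine", 140.0, 2.5, strychnine=0.3),
    "glycine_100kcl": _sol("glycine_100kcl", 42.5, 100.0, glycine=50.0),
    "kcl140": _sol("kcl140", 2.5, 140.0),
    "kcl140_furosemide": _sol("kcl140_furosemide", 2.5, 140.0, furosemide=1000.0),
    "control_strychnine_furosemide": _sol(
        "control_strychnine_furosemide", 140.0, 2.5, strychnine=0.3, furosemide=1000.0
    ),
    "control_strychnine_glycine_100kcl": _sol(
        "strychnine_glycine_100kcl", 42.5, 100.0, glycine=50.0, strychnine=0.0
    ),
    "isoguvacine_jet": _sol("isoguvacine_jet", 140.0, 2.5, isoguvacine=30.0),
    "iso_25kcl": _sol("iso_25kcl", 117.5, 25.0, isoguvacine=30.0),
}


@dataclass
class ExperimentConfig:
    """Everything needed to run one simulated recording."""

    name: str
    params: PhotophysicsParams
    transport: TransportParams
    comps: Sequence[CompartmentSpec]
    protocol: Sequence[ProtocolEvent]
    plan: AcquisitionPlan
    scene: SceneSpec
    membrane: MembraneModel = MembraneModel()
    noise: NoiseModel = NoiseModel(enabled=False)
    cl0: float | Sequence[float] = 7.0
    dt: float = DT_S
    meta: Dict = field(default_factory=dict)

    @property
    def plan_order(self) -> str:
        return "430_first" if self.plan.steps[0].channel == 430 else "500_first"


def default_photophysics(cl_ref: float = 0.0, **over) -> PhotophysicsParams:
    base = dict(
        ec50=EC50_APP_MM,
        hill=1.0,
        residual_q=0.0,
        alpha_rest=ALPHA_REST,
        cl_ref=cl_ref,
        fmax_430=FMAX_430,
        tau_inact_430=TAU_INACT_430_S,
        tau_rec_430=TAU_REC_430_S,
        fmax_500=FMAX_500,
        tau_inact_500=TAU_INACT_500_S,
        tau_rec_500=TAU_REC_500_S,
    )
    base.update(over)
    return PhotophysicsParams(**base)


_N2A = CompartmentSpec(name="cell", volume=1767.146, surface=706.858)


def _one_cell_scene() -> SceneSpec:
    return grid_scene(1, cell_px=16, gap_px=8)


def _ratiometric_steps(
    g430: float, g500: float, exposure_500_ms: float = 50.0
) -> Tuple[PlanStep, ...]:
    """Improved-protocol cycle: 500 nm first, then attenuated 430 nm."""
    return (
        PlanStep(0.0, 500, exposure_500_ms, binning=2, intensity_factor=1.0,
                 gain=g500, background=BG_COUNTS),
        PlanStep(exposure_500_ms / 1000.0 + 0.05, 430, 50.0, binning=4,
                 intensity_factor=0.05, gain=g430, background=BG_COUNTS),
    )


def _balanced_gains(rest: float, params: PhotophysicsParams,
                    r_rest: float = 1.0) -> Tuple[float, float]:
    """Gain pair putting F500 at ~2000 counts and the resting ratio at r_rest."""
    q = yfp_quench_factor(rest, params)
    g500 = F500_REST_COUNTS / (0.05 * q)
    # K = g430*dose430 / (g500*dose500); resting ratio ~ K / q at cl_ref=rest
    g430 = r_rest * q * g500 * (0.05 / 0.0025)
    return g430, g500


# --- single-wavelength photoinactivation protocols -------------------------

def photoinactivation_config(
    probe_wavelength: int, probe_duration_s: float
) -> ExperimentConfig:
    """500 nm routine (50 ms / 10 s) with one probe pulse before an acquisition.

    The probe is modelled as a point dose delivered 1 ms before the
    acquisition at t = 360 s, mirroring the paradigm in which a test flash
    reads out the inactivation immediately after the inserted pulse.
    """
    rest = 7.0
    params = default_photophysics(cl_ref=rest)
    g500 = F500_REST_COUNTS / (0.05 * yfp_quench_factor(rest, params))
    steps = (PlanStep(0.0, 500, 50.0, binning=2, gain=g500, background=BG_COUNTS),)
    probe = IlluminationEvent(probe_wavelength, probe_duration_s, 1.0)
    plan = AcquisitionPlan(steps=steps, period=10.0, n_cycles=60,
                           extra_pulses=((359.999, probe),))
    return ExperimentConfig(
        name=f"fig3_probe_{probe_wavelength}_{probe_duration_s}s",
        params=params,
        transport=TransportParams(),
        comps=[_N2A],
        protocol=[ProtocolEvent(0.0, SOLUTIONS["control"])],
        plan=plan,
        scene=_one_cell_scene(),
        cl0=rest,
        meta={"probe_time": 355.0},
    )


def plateau_430_config(n_cycles: int = 180) -> ExperimentConfig:
    """Repetitive 20 ms / 10 s full-intensity 430 nm pulsing (30 min default)."""
    rest = 7.0
    params = default_photophysics(cl_ref=rest)
    steps = (PlanStep(0.0, 430, 20.0, binning=2, gain=1.0e5, background=BG_COUNTS),)
    plan = AcquisitionPlan(steps=steps, period=10.0, n_cycles=n_cycles)
    return ExperimentConfig(
        name="fig3b_plateau",
        params=params,
        transport=TransportParams(),
        comps=[_N2A],
        protocol=[ProtocolEvent(0.0, SOLUTIONS["control"])],
        plan=plan,
        scene=_one_cell_scene(),
        cl0=rest,
        meta={},
    )


# --- N2a glycine / KCl challenges ------------------------------------------

def _n2a_transport(**over) -> TransportParams:
    base = dict(
        g_glyr=G_GLYR,
        p_tonic=P_TONIC,
        k_leak=K_LEAK_PER_MIN,
        cl_leak=CL_LEAK_MM,
        furosemide_block=FUROSEMIDE_BLOCK,
    )
    base.update(over)
    return TransportParams(**base)


def fig5_glycine_kcl_config(
    g_glyr: float = G_GLYR, p_tonic: float = P_TONIC
) -> ExperimentConfig:
    """Stable-protocol recording of a 5 min glycine + 100 mM KCl challenge."""
    tp = _n2a_transport(g_glyr=g_glyr, p_tonic=p_tonic)
    rest = resting_cl(SOLUTIONS["control"], tp, _N2A)
    params = default_photophysics(cl_ref=rest)
    g430, g500 = _balanced_gains(rest, params)
    plan = AcquisitionPlan(steps=_ratiometric_steps(g430, g500),
                           period=20.0, n_cycles=135)
    protocol = [
        ProtocolEvent(0.0, SOLUTIONS["control"]),
        ProtocolEvent(600.0, SOLUTIONS["glycine_100kcl"]),
        ProtocolEvent(900.0, SOLUTIONS["control"]),
    ]
    return ExperimentConfig(
        name="fig5_glycine_kcl",
        params=params,
        transport=tp,
        comps=[_N2A],
        protocol=protocol,
        plan=plan,
        scene=_one_cell_scene(),
        cl0=rest,
        meta={"app_window": (600.0, 905.0)},
    )


def fig5_strychnine_config(g_glyr: float = G_GLYR) -> ExperimentConfig:
    """Same challenge with 0.3 uM strychnine in the control solution.

    Tonic GlyR is blocked at baseline and during washout, so recovery is
    carried by the first-order leak alone; the applied glycine/KCl solution
    is strychnine-free (the agonist jet displaces the antagonist).
    """
    tp = _n2a_transport(g_glyr=g_glyr)
    rest = resting_cl(SOLUTIONS["control_strychnine"], tp, _N2A)
    params = default_photophysics(cl_ref=rest)
    g430, g500 = _balanced_gains(rest, params)
    plan = AcquisitionPlan(steps=_ratiometric_steps(g430, g500),
                           period=20.0, n_cycles=135)
    protocol = [
        ProtocolEvent(0.0, SOLUTIONS["control_strychnine"]),
        ProtocolEvent(600.0, SOLUTIONS["glycine_100kcl"]),
        ProtocolEvent(900.0, SOLUTIONS["control_strychnine"]),
    ]
    return ExperimentConfig(
        name="fig5_strychnine",
        params=params,
        transport=tp,
        comps=[_N2A],
        protocol=protocol,
        plan=plan,
        scene=_one_cell_scene(),
        cl0=rest,
        meta={"app_window": (600.0, 905.0)},
    )


# --- KCC2 assays ------------------------------------------------------------

def fig7_extrusion_config(
    furosemide: bool = False, u_kcc2: float = U_KCC2_EXTRUSION
) -> ExperimentConfig:
    """Cl extrusion by KCC2 after a glycine/KCl load (strychnine throughout)."""
    tp = _n2a_transport(u_kcc2=u_kcc2)
    rest = resting_cl(SOLUTIONS["control_strychnine"], tp, _N2A)
    params = default_photophysics(cl_ref=rest)
    g430, g500 = _balanced_gains(rest, params)
    plan = AcquisitionPlan(steps=_ratiometric_steps(g430, g500),
                           period=20.0, n_cycles=90)
    washout = (SOLUTIONS["control_strychnine_furosemide"] if furosemide
               else SOLUTIONS["control_strychnine"])
    protocol = [
        ProtocolEvent(0.0, SOLUTIONS["control_strychnine"]),
        ProtocolEvent(600.0, SOLUTIONS["glycine_100kcl"]),
        ProtocolEvent(900.0, washout),
    ]
    return ExperimentConfig(
        name="fig7_extrusion" + ("_furosemide" if furosemide else ""),
        params=params,
        transport=tp,
        comps=[_N2A],
        protocol=protocol,
        plan=plan,
        scene=_one_cell_scene(),
        cl0=rest,
        meta={"app_window": (600.0, 905.0)},
    )


def fig7_influx_config(group: str = "kcc2") -> ExperimentConfig:
    """Reverse-mode KCC2 influx under 140 mM KCl (no GlyR expressed).

    All three groups (mock / kcc2 / kcc2_furosemide) share one gain block
    anchored so the resting ratio of the KCC2 group is ~1.05, matching how
    the acquisitions of one comparison experiment share camera settings.
    """
    if group not in ("mock", "kcc2", "kcc2_furosemide"):
        raise ValueError("group must be mock, kcc2 or kcc2_furosemide")
    u = U_ENDO_MOCK if group == "mock" else U_KCC2_INFLUX
    tp = _n2a_transport(g_glyr=0.0, p_tonic=0.0, u_kcc2=u)
    tp_anchor = _n2a_transport(g_glyr=0.0, p_tonic=0.0, u_kcc2=U_KCC2_INFLUX)
    rest_anchor = resting_cl(SOLUTIONS["control_strychnine"], tp_anchor, _N2A)
    rest = resting_cl(SOLUTIONS["control_strychnine"], tp, _N2A)
    params = default_photophysics(cl_ref=rest_anchor)
    g430, g500 = _balanced_gains(rest_anchor, params, r_rest=R_REST_INFLUX)
    plan = AcquisitionPlan(steps=_ratiometric_steps(g430, g500),
                           period=20.0, n_cycles=60)
    if group == "kcc2_furosemide":
        protocol = [
            ProtocolEvent(0.0, SOLUTIONS["control_strychnine"]),
            ProtocolEvent(300.0, SOLUTIONS["control_strychnine_furosemide"]),
            ProtocolEvent(600.0, SOLUTIONS["kcl140_furosemide"]),
        ]
    else:
        protocol = [
            ProtocolEvent(0.0, SOLUTIONS["control_strychnine"]),
            ProtocolEvent(600.0, SOLUTIONS["kcl140"]),
        ]
    return ExperimentConfig(
        name=f"fig7_influx_{group}",
        params=params,
        transport=tp,
        comps=[_N2A],
        protocol=protocol,
        plan=plan,
        scene=_one_cell_scene(),
        cl0=rest,
        meta={"kcl_time": 600.0, "furosemide_time": 300.0},
    )


# --- calibration ------------------------------------------------------------

def _steady_dark_product_at_500(plan: AcquisitionPlan,
                                params: PhotophysicsParams) -> float:
    """(1-d430)(1-d500) at the 500 nm acquisition of a settled cycle."""
    state = SensorState()
    t_prev = 0.0
    last = 1.0
    for t, ev, step in plan.timeline():
        state = dark_recovery(state, t - t_prev, params)
        t_prev = t
        if step is not None and step.channel == 500:
            last = (1.0 - state.dark_total(430)) * (1.0 - state.dark_total(500))
        state = dark_increment(state, ev, params)
    return last


def fig8_calibration_config(g_gabaar: float = G_GABAAR_FIG8) -> ExperimentConfig:
    """Simultaneous imaging / perforated-patch calibration of a neuron.

    Voltage-clamped isoguvacine jets impose chloride loads (depolarized
    jets raise, hyperpolarized jets lower [Cl-]i) and patch-membrane
    breakthrough with a 150 mM Cl pipette saturates the sensor.  The gain
    block anchors the zero-chloride ratio at R0 including compensation of
    the steady-state darkening, as the experimenter's gain balancing on a
    settled recording would.
    """
    tp = TransportParams(g_gabaar=g_gabaar, k_leak=0.005, cl_leak=NEURON_REST_MM)
    params = default_photophysics(cl_ref=0.0)
    q_rest = yfp_quench_factor(NEURON_REST_MM, params)
    g500 = F500_REST_COUNTS / (0.05 * q_rest)
    probe_plan = AcquisitionPlan(steps=_ratiometric_steps(1.0, 1.0),
                                 period=20.0, n_cycles=30)
    d_product = _steady_dark_product_at_500(probe_plan, params)
    g430 = R0_CALIBRATION * d_product * g500 * (0.05 / 0.0025)
    plan = AcquisitionPlan(steps=_ratiometric_steps(g430, g500),
                           period=20.0, n_cycles=75)
    ctrl = SOLUTIONS["control"]
    iso = SOLUTIONS["isoguvacine_jet"]
    protocol = [
        ProtocolEvent(0.0, ctrl, clamp=-78.0),
        ProtocolEvent(300.0, iso, clamp=-45.0),
        ProtocolEvent(322.0, ctrl, clamp=-78.0),
        ProtocolEvent(600.0, iso, clamp=-45.0),
        ProtocolEvent(622.0, ctrl, clamp=-78.0),
        ProtocolEvent(900.0, iso, clamp=-107.0),
        ProtocolEvent(922.0, ctrl, clamp=-78.0),
        ProtocolEvent(1200.0, ctrl, clamp=-78.0, set_cl=150.0),
    ]
    return ExperimentConfig(
        name="fig8_calibration",
        params=params,
        transport=tp,
        comps=[CompartmentSpec(name="cell", volume=1767.146, surface=706.858)],
        protocol=protocol,
        plan=plan,
        scene=_one_cell_scene(),
        cl0=NEURON_REST_MM,
        meta={"plateau_times": [280.0, 580.0, 880.0, 1180.0, 1440.0],
              "jet_times": [300.0, 600.0, 900.0],
              "breakthrough_time": 1200.0},
    )


# --- neuron compartments -----------------------------------------------------

def fig9_neuron_config() -> ExperimentConfig:
    """Soma / dendrite / spine recording with an isoguvacine + 25 mM KCl jet.

    Geometry: soma as a 15 um sphere (surface/volume reference), dendrite
    as a thin cylinder with 6x the reference surface/volume, spine head
    with 15x but diffusion-limited by its neck (coupling 0.2, effective 3x).
    """
    soma = CompartmentSpec(name="soma", volume=1767.146, surface=706.858)
    dend = CompartmentSpec(name="dendrite", volume=21.82, surface=52.36)
    spine = CompartmentSpec(name="spine", volume=0.5236, surface=3.1416,
                            coupling=0.2)
    tp = TransportParams(g_gabaar=0.015, u_kcc2=U_KCC2_NEURON,
                         k_leak=K_LEAK_PER_MIN, cl_leak=CL_LEAK_MM)
    rest = resting_cl(SOLUTIONS["control"], tp, soma)
    params = default_photophysics(cl_ref=rest)
    g430, g500 = _balanced_gains(rest, params)
    steps = (
        PlanStep(0.0, 500, 200.0, binning=2, gain=g500 / 4.0, background=BG_COUNTS),
        PlanStep(0.3, 430, 50.0, binning=8, intensity_factor=0.05, gain=g430,
                 background=BG_COUNTS),
    )
    plan = AcquisitionPlan(steps=steps, period=20.0, n_cycles=36)
    protocol = [
        ProtocolEvent(0.0, SOLUTIONS["control"]),
        ProtocolEvent(120.0, SOLUTIONS["iso_25kcl"]),
        ProtocolEvent(145.0, SOLUTIONS["control"]),
    ]
    cells = (
        CellSpec(1, (8, 24), (8, 24), expression=1.0, compartment="soma"),
        CellSpec(2, (8, 24), (32, 48), expression=0.6, compartment="dendrite"),
        CellSpec(3, (32, 48), (8, 24), expression=0.3, compartment="spine"),
    )
    scene = SceneSpec(shape=(56, 56), cells=cells)
    return ExperimentConfig(
        name="fig9_neuron",
        params=params,
        transport=tp,
        comps=[soma, dend, spine],
        protocol=protocol,
        plan=plan,
        scene=scene,
        cl0=rest,
        meta={"app_window": (120.0, 260.0)},
    )


# --- protocol-comparison and population configs ------------------------------

def drift_config(protocol: str = "original") -> ExperimentConfig:
    """Resting 30 min recording with the original or the improved protocol.

    'original': full-intensity 430 nm immediately followed by 500 nm.
    'improved': 5 % ND on 430 nm, 500 nm first (20 s to the next 430 pulse).
    """
    rest = 7.0
    params = default_photophysics(cl_ref=rest)
    q = yfp_quench_factor(rest, params)
    g500 = F500_REST_COUNTS / (0.05 * q)
    if protocol == "original":
        g430 = q * g500 * (0.05 / 0.02)
        steps = (
            PlanStep(0.0, 430, 20.0, binning=2, intensity_factor=1.0,
                     gain=g430, background=BG_COUNTS),
            PlanStep(0.025, 500, 50.0, binning=2, gain=g500, background=BG_COUNTS),
        )
    elif protocol == "improved":
        g430 = q * g500 * (0.05 / 0.0025)
        steps = _ratiometric_steps(g430, g500)
    else:
        raise ValueError("protocol must be 'original' or 'improved'")
    plan = AcquisitionPlan(steps=steps, period=20.0, n_cycles=90)
    return ExperimentConfig(
        name=f"drift_{protocol}",
        params=params,
        transport=TransportParams(),
        comps=[_N2A],
        protocol=[ProtocolEvent(0.0, SOLUTIONS["control"])],
        plan=plan,
        scene=_one_cell_scene(),
        cl0=rest,
        meta={},
    )


def population_config(n: int = 184, seed: int = 1) -> ExperimentConfig:
    """Expression-heterogeneous population under the improved protocol.

    Expression levels are log-uniform so baseline F430 spans roughly
    700-9000 counts (the stratification range); all cells share one
    ground-truth chloride trajectory.  Camera noise is enabled.
    """
    tp = _n2a_transport()
    rest = resting_cl(SOLUTIONS["control"], tp, _N2A)
    params = default_photophysics(cl_ref=rest)
    rng = np.random.default_rng(seed)
    expr = np.exp(rng.uniform(np.log(0.7), np.log(9.0), n))
    g430 = 1000.0 / 0.0025
    g500 = g430 * 0.05 / yfp_quench_factor(rest, params)
    plan = AcquisitionPlan(steps=_ratiometric_steps(g430, g500),
                           period=20.0, n_cycles=25)
    protocol = [
        ProtocolEvent(0.0, SOLUTIONS["control"]),
        ProtocolEvent(200.0, SOLUTIONS["glycine_100kcl"]),
    ]
    scene = grid_scene(n, cell_px=8, gap_px=8, expressions=expr)
    return ExperimentConfig(
        name="fig6_population",
        params=params,
        transport=tp,
        comps=[_N2A],
        protocol=protocol,
        plan=plan,
        scene=scene,
        cl0=rest,
        noise=NoiseModel(enabled=True, read_noise_sd=20.0, shot_noise=True,
                         seed=seed),
        meta={"app_window": (200.0, 500.0)},
    )


CANNED_CONFIGS = {
    "fig2_unmodified": lambda: drift_config("original"),
    "fig3a_1s": lambda: photoinactivation_config(500, 1.0),
    "fig3a_10s": lambda: photoinactivation_config(500, 10.0),
    "fig3b": plateau_430_config,
    "fig3c_20ms": lambda: photoinactivation_config(430, 0.02),
    "fig3c_1s": lambda: photoinactivation_config(430, 1.0),
    "fig4_improved": lambda: drift_config("improved"),
    "fig5_glycine_kcl": fig5_glycine_kcl_config,
    "fig5_strychnine": fig5_strychnine_config,
    "fig6_population": population_config,
    "fig7_extrusion": fig7_extrusion_config,
    "fig7_extrusion_furosemide": lambda: fig7_extrusion_config(furosemide=True),
    "fig7_influx_mock": lambda: fig7_influx_config("mock"),
    "fig7_influx_kcc2": lambda: fig7_influx_config("kcc2"),
    "fig7_influx_kcc2_furosemide": lambda: fig7_influx_config("kcc2_furosemide"),
    "fig8_calibration": fig8_calibration_config,
    "fig9_neuron": fig9_neuron_config,
}
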