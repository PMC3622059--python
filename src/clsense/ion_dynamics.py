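"""Compartmental intracellular chloride dynamics.

[Cl-]i in each compartment is driven by (i) ligand-gated anion channels
(GlyR, GABA_A R) whose flux follows the driving force Vm - E_Cl, (ii) the
electroneutral cotransporters KCC2 and NKCC1, whose direction is set by the
summed chemical-potential products (K+ x Cl- for KCC2), and (iii) a
first-order leak toward an equilibrium concentration.  Membrane potential
is either clamped or follows a two-parameter mixture of the K+ Nernst
potential and a fixed offset, which reproduces depolarization by raised
bath KCl.  All fluxes scale with compartment surface-to-volume ratio, so
thin dendrites equilibrate faster than somata.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "BathSolution",
    "CompartmentSpec",
    "TransportParams",
    "MembraneModel",
    "ProtocolEvent",
    "SimResult",
    "nernst_ecl",
    "invert_nernst",
    "channel_flux",
    "kcc2_flux",
    "nkcc1_flux",
    "membrane_potential",
    "simulate_cli",
]

NERNST_SLOPE_MV = 59.16      # mV per decade at the recording temperature
SV_REF_PER_UM = 0.4          # surface/volume (um^-1) of the reference cell
K_I_DEFAULT = 140.0          # mM, intracellular potassium
NA_I_DEFAULT = 10.0          # mM, intracellular sodium (NKCC1 only)
EC50_GLY_UM = 300.0          # uM, glycine half-activation of GlyR
EC50_ISO_UM = 10.0           # uM, isoguvacine half-activation of GABA_A R
CL_FLOOR_MM = 0.1            # numerical floor on [Cl-]i


@dataclass(frozen=True)
class BathSolution:
    """Extracellular solution: ion concentrations (mM) and drugs (uM)."""

    na_o: float = 140.0
    k_o: float = 2.5
    cl_o: float = 150.5
    glycine: float = 0.0
    isoguvacine: float = 0.0
    strychnine: float = 0.0
    furosemide: float = 0.0
    bumetanide: float = 10.0
    label: str = "control"

    def __post_init__(self) -> None:
        for name in ("na_o", "k_o", "cl_o", "glycine", "isoguvacine",
                     "strychnine", "furosemide", "bumetanide"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    @classmethod
    def from_salts(
        cls,
        nacl: float,
        kcl: float,
        cacl2: float = 2.0,
        mgcl2: float = 2.0,
        **drugs: float,
    ) -> "BathSolution":
        """Build a solution from its salt composition; Cl- is computed."""
        return cls(
            na_o=nacl,
            k_o=kcl,
            cl_o=nacl + kcl + 2.0 * cacl2 + 2.0 * mgcl2,
            **drugs,
        )


@dataclass(frozen=True)
class CompartmentSpec:
    """Geometry of a cellular compartment.

    ``coupling`` scales the effective membrane flux below its geometric
    surface/volume value (used for diffusion-limited spine necks).
    """

    name: str = "cell"
    volume: float = 1767.0     # fL (= um^3); 15 um diameter sphere
    surface: float = 707.0     # um^2
    k_i: float = K_I_DEFAULT   # mM
    coupling: float = 1.0

    def __post_init__(self) -> None:
        if self.volume <= 0 or self.surface <= 0:
            raise ValueError("volume and surface must be > 0")
        if not 0.0 < self.coupling <= 1.0:
            raise ValueError("coupling must be in (0, 1]")

    @property
    def sv_scale(self) -> float:
        """Flux scale relative to the reference surface/volume ratio."""
        return (self.surface / self.volume) / SV_REF_PER_UM * self.coupling


@dataclass(frozen=True)
class TransportParams:
    """Channel, cotransporter and leak strengths.

    Units: channel strengths g_* in mM s^-1 mV^-1 (at reference
    surface/volume and full open probability); transporter strengths u_* in
    mM s^-1 per unit of ln-product disequilibrium; k_leak in min^-1.
    """

    g_glyr: float = 0.0
    g_gabaar: float = 0.0
    p_tonic: float = 0.0
    u_kcc2: float = 0.0
    u_nkcc1: float = 0.0
    k_leak: float = 0.0
    cl_leak: float = 5.0
    furosemide_block: float = 0.85
    bumetanide_block: float = 1.0
    strychnine_block: float = 1.0

    def __post_init__(self) -> None:
        for name in ("g_glyr", "g_gabaar", "p_tonic", "u_kcc2", "u_nkcc1",
                     "k_leak", "cl_leak"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("furosemide_block", "bumetanide_block", "strychnine_block"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")


@dataclass(frozen=True)
class MembraneModel:
    """Vm = vm_weight * E_K + (1 - vm_weight) * v_offset, unless clamped."""

    vm_weight: float = 0.35
    v_offset: float = -60.0
    clamp: Optional[float] = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.vm_weight <= 1.0:
            raise ValueError("vm_weight must be in [0, 1]")


@dataclass(frozen=True)
class ProtocolEvent:
    """A timed change of bath solution and/or voltage clamp.

    ``set_cl`` imposes [Cl-]i instantaneously in all compartments (models
    whole-cell dialysis, e.g. patch-membrane breakthrough with a 150 mM
    KCl pipette).
    """

    t_start: float
    solution: Optional[BathSolution] = None
    clamp: Optional[float] = None
    release_clamp: bool = False
    set_cl: Optional[float] = None


@dataclass
class SimResult:
    t: np.ndarray                 # s, shape (T,)
    cl: np.ndarray                # mM, shape (n_comp, T)
    vm: np.ndarray                # mV, shape (T,)
    compartments: Sequence[CompartmentSpec]

    def cl_at(self, t: float, comp: int = 0) -> float:
        return float(np.interp(t, self.t, self.cl[comp]))

    def vm_at(self, t: float) -> float:
        return float(np.interp(t, self.t, self.vm))


def nernst_ecl(cl_o: float, cl_i: float, slope_mv: float = NERNST_SLOPE_MV) -> float:
    """Chloride Nernst potential E_Cl = -slope * log10(cl_o / cl_i), in mV."""
    if cl_o <= 0 or cl_i <= 0:
        raise ValueError("concentrations must be > 0")
    return -slope_mv * math.log10(cl_o / cl_i)


def invert_nernst(e_mv: float, cl_o: float, slope_mv: float = NERNST_SLOPE_MV) -> float:
    """[Cl-]i (mM) from a reversal potential: exact inverse of nernst_ecl."""
    if cl_o <= 0:
        raise ValueError("cl_o must be > 0")
    return cl_o * 10.0 ** (e_mv / slope_mv)


def channel_flux(
    g: float, p_open: float, vm: float, e_cl: float, comp: CompartmentSpec
) -> float:
    """d[Cl-]i/dt (mM/s) through an anion channel.

    Positive (influx) when vm > e_cl, zero at reversal; outward current at
    depolarized potentials carries Cl- into the cell.
    """
    return g * p_open * (vm - e_cl) * comp.sv_scale


def kcc2_flux(
    k_o: float,
    cl_o: float,
    k_i: float,
    cl_i: float,
    u: float,
    furosemide_factor: float,
    comp: CompartmentSpec,
    block: float = 0.85,
) -> float:
    """d[Cl-]i/dt (mM/s) through KCC2.

    Zero at product equality k_i*cl_i = k_o*cl_o; efflux (negative) when the
    intracellular product is larger, influx when the bath product is larger
    (reverse mode under high bath K+).
    """
    if min(k_o, cl_o, k_i, cl_i) <= 0:
        raise ValueError("concentrations must be > 0")
    eff = u * (1.0 - furosemide_factor * block)
    return -eff * math.log((k_i * cl_i) / (k_o * cl_o)) * comp.sv_scale


def nkcc1_flux(
    na_o: float,
    k_o: float,
    cl_o: float,
    k_i: float,
    cl_i: float,
    u: float,
    comp: CompartmentSpec,
    na_i: float = NA_I_DEFAULT,
) -> float:
    """d[Cl-]i/dt (mM/s) through NKCC1 (Na:K:2Cl stoichiometry)."""
    if u == 0.0:
        return 0.0
    if min(na_o, k_o, cl_o, na_i, k_i, cl_i) <= 0:
        raise ValueError("concentrations must be > 0")
    arg = (na_o * k_o * cl_o**2) / (na_i * k_i * cl_i**2)
    return u * math.log(arg) * comp.sv_scale


def membrane_potential(sol: BathSolution, mm: MembraneModel, k_i: float = K_I_DEFAULT) -> float:
    """Membrane potential (mV): clamp if set, else K-Nernst/offset mixture."""
    if mm.clamp is not None:
        return mm.clamp
    if sol.k_o <= 0:
        raise ValueError("k_o must be > 0")
    e_k = -NERNST_SLOPE_MV * math.log10(k_i / sol.k_o)
    return mm.vm_weight * e_k + (1.0 - mm.vm_weight) * mm.v_offset


def glyr_open_prob(sol: BathSolution, tp: TransportParams) -> float:
    """GlyR open probability: agonist activation plus tonic drive, gated by strychnine."""
    act = sol.glycine / (sol.glycine + EC50_GLY_UM) + tp.p_tonic
    if sol.strychnine > 0:
        act *= 1.0 - tp.strychnine_block
    return min(act, 1.0)


def gabaar_open_prob(sol: BathSolution) -> float:
    return sol.isoguvacine / (sol.isoguvacine + EC50_ISO_UM)


def total_flux(
    cl_i: float,
    sol: BathSolution,
    vm: float,
    tp: TransportParams,
    comp: CompartmentSpec,
) -> float:
    """Sum of channel, KCC2, NKCC1 and leak contributions, mM/s."""
    e_cl = nernst_ecl(sol.cl_o, cl_i)
    flux = 0.0
    p_gly = glyr_open_prob(sol, tp)
    if tp.g_glyr > 0 and p_gly > 0:
        flux += channel_flux(tp.g_glyr, p_gly, vm, e_cl, comp)
    p_iso = gabaar_open_prob(sol)
    if tp.g_gabaar > 0 and p_iso > 0:
        flux += channel_flux(tp.g_gabaar, p_iso, vm, e_cl, comp)
    if tp.u_kcc2 > 0:
        furo = 1.0 if sol.furosemide > 0 else 0.0
        flux += kcc2_flux(sol.k_o, sol.cl_o, comp.k_i, cl_i, tp.u_kcc2,
                          furo, comp, block=tp.furosemide_block)
    if tp.u_nkcc1 > 0:
        bum = tp.bumetanide_block if sol.bumetanide > 0 else 0.0
        flux += nkcc1_flux(sol.na_o, sol.k_o, sol.cl_o, comp.k_i, cl_i,
                           tp.u_nkcc1 * (1.0 - bum), comp)
    flux += tp.k_leak / 60.0 * (tp.cl_leak - cl_i) * comp.sv_scale
    return flux


def simulate_cli(
    protocol: Sequence[ProtocolEvent],
    tp: TransportParams,
    comps: Sequence[CompartmentSpec],
    dt: float = 0.1,
    t_end: float = 600.0,
    mm: MembraneModel = MembraneModel(),
    cl0: float | Sequence[float] = 7.0,
) -> SimResult:
    """Fixed-step explicit Euler integration of [Cl-]i under a bath/clamp protocol.

    ``protocol`` is a time-ordered list of events; the first event must start
    at t <= 0 and carry a solution.  Deterministic; halving ``dt`` moves any
    output point by well under 0.5 % at the rates modelled here.
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    if not protocol or protocol[0].solution is None or protocol[0].t_start > 0:
        raise ValueError("protocol must begin with a solution event at t <= 0")
    starts = [ev.t_start for ev in protocol]
    if any(b < a for a, b in zip(starts, starts[1:])):
        raise ValueError("protocol events must be time-ordered")

    n = len(comps)
    cl = np.full(n, cl0, dtype=float) if np.isscalar(cl0) else np.asarray(cl0, float).copy()
    if cl.shape != (n,):
        raise ValueError("cl0 length must match number of compartments")

    times = np.arange(0.0, t_end + dt / 2, dt)
    out_cl = np.empty((n, times.size))
    out_vm = np.empty(times.size)

    sol = protocol[0].solution
    clamp: Optional[float] = None
    next_ev = 0
    for k, t in enumerate(times):
        while next_ev < len(protocol) and protocol[next_ev].t_start <= t + 1e-9:
            ev = protocol[next_ev]
            if ev.solution is not None:
                sol = ev.solution
            if ev.clamp is not None:
                clamp = ev.clamp
            if ev.release_clamp:
                clamp = None
            if ev.set_cl is not None:
                cl[:] = ev.set_cl
            next_ev += 1
        mm_now = MembraneModel(mm.vm_weight, mm.v_offset, clamp if clamp is not None else mm.clamp)
        vm = membrane_potential(sol, mm_now, comps[0].k_i)
        out_cl[:, k] = cl
        out_vm[k] = vm
        for i, comp in enumerate(comps):
            cl[i] += dt * total_flux(cl[i], sol, vm, tp, comp)
            if cl[i] < CL_FLOOR_MM:
                cl[i] = CL_FLOOR_MM
    return SimResult(t=times, cl=out_cl, vm=out_vm, compartments=list(comps))


def resting_cl(
    sol: BathSolution,
    tp: TransportParams,
    comp: CompartmentSpec = CompartmentSpec(),
    mm: MembraneModel = MembraneModel(),
    bracket: tuple[float, float] = (CL_FLOOR_MM, 140.0),
) -> float:
    """Steady-state [Cl-]i: root of the total flux in a given solution."""
    from scipy.optimize import brentq

    vm = membrane_potential(sol, mm, comp.k_i)
    f = lambda c: total_flux(c, sol, vm, tp, comp)
    lo, hi = bracket
    if f(lo) * f(hi) > 0:
        raise ValueError("no sign change in bracket; is any flux active?")
    return float(brentq(f, lo, hi, xtol=1e-10))
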