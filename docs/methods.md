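# Methods

## Sensor model

Cl-Sensor fluorescence is modelled per cell (not per pixel) as the product
of three factors: chloride quenching, dark-state survival, and channel
composition.

**Quenching.** The YFP_Cl moiety follows single-site quenching,
`Q(Cl) = residual_q + (1 − residual_q)/(1 + (Cl/EC₅₀)^hill)`, with
`hill = 1` and `residual_q = 0` by default. The apparent in-cell EC₅₀ is
not taken from in vitro estimates (30–50 mM); it is solved, together with
the zero-chloride ratio anchor R₀, from the two ends of the measured
dynamic range — R(5 mM) = 0.7 and R(150 mM) = 4.0 ratio units — under the
channel-composition model below. The solution is EC₅₀ ≈ 18.36 mM,
R₀ ≈ 0.586. That the in-cell apparent affinity is higher than in vitro is
left as an empirical fact (pH and organic-anion sensitivity of YFP are
plausible but unquantified contributors; the model exposes them only
through the per-configuration EC₅₀).

**Dark states.** Each excitation wavelength populates its own reversible
dark pool. An exposure of duration t at relative intensity i delivers dose
`t·i` (reciprocity) and advances the pool as
`d ← d + (f_max − d)(1 − e^(−dose/τ_inact))`; pools recover exponentially
with `τ_rec` between exposures and act multiplicatively on the YFP_Cl
fluorescence through `(1 − d₄₃₀)(1 − d₅₀₀)`. Each wavelength's
`(f_max, τ_inact)` pair is root-found from two printed pulse inhibitions:
2.6 % @ 20 ms and 30 % @ 1 s for 430 nm (giving f_max ≈ 0.303,
τ ≈ 0.223 s), 0.34 % @ 1 s and 3.0 % @ 10 s for 500 nm (f_max ≈ 0.121,
τ ≈ 35.0 s) — about a hundred-fold difference in darkening efficacy per
unit dose. Recovery constants (50 s and 60 s) are chosen to satisfy,
simultaneously, the 97–98 % F₄₃₀ plateau under 20 ms/10 s pulsing, full
recovery at 5 min inter-pulse intervals, and 500 nm recovery within 3 min.
A single reversible pool per wavelength cannot also reproduce the report
that recovery after a 1 s 430 nm pulse is only partial over minutes; an
optional slowly recovering sub-pool (`slow_pool_weight`, recovering 20×
slower) is provided but defaults to 0 because a slow pool is inconsistent
with the stable repetitive-pulsing plateau.

**Channel composition.** F₅₀₀ is pure YFP_Cl:
`F₅₀₀ ∝ X·Q(Cl)·(1−d₄₃₀)(1−d₅₀₀)` for expression level X. F₄₃₀ mixes a
photostable, chloride-blind CFP part with a YFP_Cl part:
`F₄₃₀ ∝ X·[(1−α) + α·(Q/Q_ref)·(1−d₄₃₀)(1−d₅₀₀)]`, where α
(`alpha_rest` = 0.062/0.216 ≈ 0.287) is the YFP share of the 430 nm signal
at a stated reference chloride `cl_ref`. FRET from CFP to YFP is not
modelled separately; whatever YFP-derived light reaches the detector under
430 nm excitation is absorbed into α. Each configuration states its
reference: N2a configurations use their resting chloride (so α is the
share *at rest*, which makes the 6.2 %/21.6 % drop pair exact), while the
calibration configuration uses `cl_ref = 0` (the unquenched state, the
convention under which the solved EC₅₀/R₀ pair reproduces the dynamic
range). Counts are `gain·X·dose·rate + background` per acquisition.

## Chloride dynamics

Each compartment integrates
`d[Cl]ᵢ/dt = Σ fluxes · (S/V)/(S/V)_ref · coupling` by explicit Euler with
dt = 0.1 s and a 0.1 mM floor (halving dt moves results by ≪0.5 %; the
dynamics are not stiff at these rates, and determinism matters more than
order of accuracy here).

* Ligand-gated flux: `g·p_open·(V_m − E_Cl)` with
  `E_Cl = −59.16·log₁₀([Cl]ₒ/[Cl]ᵢ)` mV. Open probability is a
  single-site agonist activation (glycine EC₅₀ 300 μM, isoguvacine EC₅₀
  10 μM) plus a tonic term `p_tonic` for GlyR; any strychnine in the bath
  removes the whole GlyR term (`strychnine_block = 1`).
* KCC2/NKCC1: thermodynamic flux `−u·ln(productᵢₙ/productₒᵤₜ)` — zero at
  product equality, reversing into influx when bath K⁺ is raised. NKCC1 is
  typed but silent by default because every bath solution carries 10 μM
  bumetanide. Furosemide scales both by `1 − furosemide_block`.
* Leak: first-order relaxation `k_leak(cl_leak − Cl)` with cl_leak = 7 mM.

**Membrane potential** is a clamp when set, else
`V_m = w·E_K + (1−w)·v_offset`. The defaults are w = 0.35,
v_offset = −60 mV, giving −75 mV at 2.5 mM K⁺ (within the measured
−72…−78 mV range) but only ≈ −42 mV at 100 mM K⁺. A stronger K-electrode
(w = 0.7, offset 0) was tried first and rejected: with a ~−6 mV
depolarization during the 100 mM KCl load, the GlyR conductance consistent
with the observed 21.6 % F₅₀₀ drop is *smaller* than the tonic conductance
required for a 6.8 min washout half-recovery — no parameter pair exists.
Partial depolarization (a sizeable voltage-independent conductance in this
cell line) lowers the loading driving force and makes the published
load/recovery pair jointly attainable. The cost is that V_m at 140 mM KCl
is ≈ −39 mV rather than ~0; nothing downstream depends on it (the 140 mM
KCl assays drive chloride through the voltage-independent cotransporter).

**Tuned strengths.** All transport strengths are root-found against the
full simulated measurement (the trace-level forward model, which the
imaging pipeline reproduces to 1e−15 on noise-free data):

| constant | solved against | value |
|---|---|---|
| k_leak | 56.6 min strychnine half-recovery (exact: ln 2 / 56.6 min⁻¹, since R is linear in Cl and leak-only decay is a single exponential) | 0.01225 min⁻¹ |
| g_glyr | 21.6 % peak F₅₀₀ drop of the glycine/KCl load | 3.356e−3 |
| p_tonic | 6.8 min control half-recovery | 0.180 |
| u_kcc2 (extrusion) | 2 min ratio half-decay | 0.0561 |
| u_kcc2 (influx) | +4.5 ratio units at +5 min of 140 mM KCl | 0.768 |
| u (mock, endogenous) | +0.9 ratio units | 0.0374 |
| furosemide_block | +1.3 residual influx (the response is concave in u, so the block giving the printed residual is solved, not assumed; 0.918 still satisfies the >70 % reduction expectation) | 0.918 |
| g_gabaar (calibration) | first depolarized jet plateau ≈ 17.6 mM | 0.0394 |

A tonic open probability of 0.18 is far above what ~45 nM contaminating
glycine could produce on real receptors; it is a phenomenological stand-in
for whatever strychnine-sensitive efflux path carries the observed
recovery, kept on the GlyR term because strychnine abolishes it.

The influx configuration's u_kcc2 is ~14× the extrusion configuration's:
one strength cannot give both a 2 min extrusion half-time and a 25-fold
larger influx amplitude in 5 min. The two assays come from different
transfections with independent absolute ratio scales (the influx amplitude
of 4.5 even exceeds the 4.0 dynamic-range ceiling of the calibration), so
each configuration carries its own transporter strength and gain block;
this is expression variability between batches, not a claim about one
cell. Relatedly, an endogenous-KCC strength large enough to reproduce the
mock cells' +0.9 influx would also pin mock resting chloride near the KCC
equilibrium, erasing the resting-ratio difference between mock and KCC2
groups; the resting-ratio comparison therefore models mock cells with the
extruder absent (leak/tonic-set resting point), and the mock influx
strength is treated as a protocol-specific reverse-mode capacity. This is
a known internal tension of the reproduced observations, not of the code.

## Synthetic imaging

Scenes are rectangular cells on a uniform background, block-aligned to the
coarsest camera binning so that binned pixels never straddle a cell edge —
this keeps noise-free ROI means *exactly* equal to the forward model and
makes pipeline-vs-model agreement a machine-precision test rather than a
tolerance judgement. Binning is a block mean (per-pixel intensities are
binning-invariant, matching exposure-based gain balancing); counts stay
float internally and are rounded to 16 bit only on file write; noise is
Gaussian read noise plus signal-proportional shot variance, divided by the
binning factor (a binned pixel averages b² sensor pixels), seeded and
reproducible. Dark-state bookkeeping is per illumination event and per
cell, not per pixel. What the generator does *not* emulate: optics (PSF,
focus drift), cell movement, segmentation ambiguity, per-pixel expression
gradients, pH/anion modulation of YFP. Passing tests therefore validate
the estimators and protocol logic, not robustness to those real-world
effects.

## Analysis estimators

Choices the source observations leave open, fixed here: inhibition
baselines use the mean of the last 3 pre-event samples; steady-state level
uses a 5-sample tail; half-times interpolate linearly between the samples
bracketing the midpoint, and when the record never crosses (the strychnine
case) a single exponential onto the pre-load baseline is fitted to the
post-peak samples and flagged as extrapolated. Assay windows (−30 s /
+300 s around KCl) use nearest-sample lookup at the 20 s cadence. Pearson
p-values are two-tailed (printed p-values in the source are consistent
with neither a two-tailed nor an obvious one-tailed t test and are not
reproduced as targets). ROI masks live on the unbinned grid, row-major,
origin top-left; frames are aligned to that grid by block replication
before extraction. The 4PL dose–response fit is bounded
(r_min ≤ min R, r_max ≥ max R, EC₅₀ within a decade of the data) because
the underlying ratio–chloride relation is linear in Cl under this sensor
model and an unbounded fit drifts toward a degenerate infinite-r_max
limit; within the bounds the fit recovers true 4PL data to <1e−8.

## Problem sizes and determinism

Canned runs use one to three 16×16-px cells in ~50-px fields, 10–45 min of
simulated time at 20 s acquisition cadence, dt = 0.1 s — a full
render-and-analyze cycle takes well under a second, and the whole
benchmark suite about two seconds. The population analyses use 184 cells
(expression correlations, with camera noise) and 45 cells per group
(resting-ratio comparison). Every result is a pure function of
(configuration, seed); noise-free paths are seed-independent.

## Known limitations

Single dark pool per wavelength (no slow component by default); no
bicarbonate permeability, volume regulation or Ca²⁺ dynamics; membrane
potential is phenomenological, not GHK; compartments are independent (no
axial diffusion — the spine neck is a flux-scaling factor, not a diffusion
equation); absolute chloride accuracy is explicitly "crude estimation" —
the calibration inverse recovers imposed plateaus within 10 %/1 mM under
noise-free conditions only.
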