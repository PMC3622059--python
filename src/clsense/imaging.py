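"""Synthetic two-channel time-lapse imaging.

Renders image stacks from scenes of cells whose per-frame fluorescence is
given by the photophysics forward model; the stand-in for the microscope
and CCD camera.  Counts are kept as floats internally and rounded to 16-bit
integers only when written to disk, so analytic round-trip tests stay
exact.  On-camera binning is modelled as a block *mean* (not sum), which
makes per-pixel intensities binning-invariant.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .photophysics import IlluminationEvent, PhotophysicsParams, SensorState, emitted_rate

__all__ = [
    "CellSpec",
    "SceneSpec",
    "PlanStep",
    "AcquisitionPlan",
    "NoiseModel",
    "FrameStack",
    "grid_scene",
    "render_frame",
    "write_stack",
    "read_stack",
]

SATURATION = 65535


@dataclass(frozen=True)
class CellSpec:
    """One cell: integer label, pixel mask bounds, expression, compartment."""

    cell_id: int
    rows: Tuple[int, int]          # half-open pixel row range
    cols: Tuple[int, int]
    expression: float = 1.0
    compartment: str = "cell"

    def mask(self, shape: Tuple[int, int]) -> np.ndarray:
        m = np.zeros(shape, dtype=bool)
        m[self.rows[0]:self.rows[1], self.cols[0]:self.cols[1]] = True
        return m


@dataclass(frozen=True)
class SceneSpec:
    """Field of block-aligned rectangular cells over a uniform background.

    Masks are kept aligned to the coarsest camera binning in use so that
    binned pixels never straddle a cell border and noise-free ROI means
    equal the forward model exactly.
    """

    shape: Tuple[int, int] = (64, 64)
    pixel_size_um: float = 0.65
    cells: Sequence[CellSpec] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if not self.cells:
            return
        occupancy = np.zeros(self.shape, dtype=np.int32)
        for c in self.cells:
            occupancy += c.mask(self.shape)
        if occupancy.max() > 1:
            raise ValueError("cell masks must be disjoint")
        if occupancy.min() > 0:
            raise ValueError("scene must keep at least one background region")

    def label_mask(self) -> np.ndarray:
        """Integer ROI labels on the unbinned grid; 0 = background."""
        lab = np.zeros(self.shape, dtype=np.uint16)
        for c in self.cells:
            lab[c.mask(self.shape)] = c.cell_id
        return lab


@dataclass(frozen=True)
class PlanStep:
    """One acquisition inside a cycle: offset from cycle start, optics, camera."""

    offset: float                  # s from cycle start
    channel: int                   # 430 | 500
    exposure_ms: float
    binning: int = 1
    intensity_factor: float = 1.0
    gain: float = 1000.0           # counts s^-1 per expression unit
    background: float = 100.0      # counts

    def __post_init__(self) -> None:
        if self.channel not in (430, 500):
            raise ValueError("channel must be 430 or 500")
        if self.binning not in (1, 2, 4, 8):
            raise ValueError("binning must be 1, 2, 4 or 8")
        if self.exposure_ms <= 0:
            raise ValueError("exposure must be > 0")

    def event(self) -> IlluminationEvent:
        return IlluminationEvent(self.channel, self.exposure_ms / 1000.0,
                                 self.intensity_factor)


@dataclass(frozen=True)
class AcquisitionPlan:
    """Repeated cycle of acquisitions plus optional non-acquired light pulses.

    ``extra_pulses`` are illumination events (e.g. test pulses probing
    photoinactivation) that darken the sensor but produce no frame.
    """

    steps: Sequence[PlanStep]
    period: float = 20.0
    n_cycles: int = 10
    extra_pulses: Sequence[Tuple[float, IlluminationEvent]] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        offs = [s.offset for s in self.steps]
        if any(b <= a for a, b in zip(offs, offs[1:])):
            raise ValueError("step offsets must be strictly increasing")
        if self.steps and self.period <= max(offs):
            raise ValueError("period must exceed the last step offset")

    @property
    def t_end(self) -> float:
        return self.period * self.n_cycles

    def acquisitions(self) -> List[Tuple[float, PlanStep]]:
        out = [
            (c * self.period + s.offset, s)
            for c in range(self.n_cycles)
            for s in self.steps
        ]
        return out

    def timeline(self) -> List[Tuple[float, object, Optional[PlanStep]]]:
        """All illumination events in time order as (t, event, step-or-None)."""
        items: List[Tuple[float, object, Optional[PlanStep]]] = [
            (t, s.event(), s) for t, s in self.acquisitions()
        ]
        items += [(t, ev, None) for t, ev in self.extra_pulses]
        items.sort(key=lambda x: x[0])
        return items


@dataclass(frozen=True)
class NoiseModel:
    """Camera noise: Gaussian read noise plus signal-proportional shot variance."""

    enabled: bool = False
    read_noise_sd: float = 20.0
    shot_noise: bool = True
    seed: int = 0

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


@dataclass
class FrameStack:
    """Rendered frames (float counts) with one metadata record per frame."""

    frames: List[np.ndarray]
    metadata: List[dict]

    def __post_init__(self) -> None:
        if len(self.frames) != len(self.metadata):
            raise ValueError("metadata length must equal frame count")


def _block_mean(img: np.ndarray, b: int) -> np.ndarray:
    if b == 1:
        return img
    h, w = img.shape
    if h % b or w % b:
        raise ValueError("binning must divide the field size")
    return img.reshape(h // b, b, w // b, b).mean(axis=(1, 3))


def render_frame(
    scene: SceneSpec,
    snapshot: Dict[int, Tuple[float, SensorState]],
    step: PlanStep,
    params: PhotophysicsParams,
    noise: NoiseModel = NoiseModel(),
    rng: Optional[np.random.Generator] = None,
) -> np.ndarray:
    """Render one acquisition: per-pixel counts at the step's binning.

    ``snapshot`` maps cell_id to ([Cl-]i, SensorState) at the pulse onset.
    Dark-state bookkeeping is the caller's job (once per event per cell).
    """
    img = np.full(scene.shape, step.background, dtype=float)
    dose = step.exposure_ms / 1000.0 * step.intensity_factor
    for cell in scene.cells:
        cl, state = snapshot[cell.cell_id]
        rate = emitted_rate(step.channel, cl, state, params)
        img[cell.rows[0]:cell.rows[1], cell.cols[0]:cell.cols[1]] += (
            step.gain * state.expression * dose * rate
        )
    img = _block_mean(img, step.binning)
    if noise.enabled:
        if rng is None:
            rng = noise.rng()
        var = np.full_like(img, noise.read_noise_sd**2)
        if noise.shot_noise:
            var += np.clip(img, 0, None)
        # binning averages b^2 independent pixels
        img = img + rng.normal(0.0, np.sqrt(var) / step.binning, img.shape)
        img = np.clip(img, 0.0, None)
    return img


def grid_scene(
    n_cells: int,
    cell_px: int = 8,
    gap_px: int = 8,
    expressions: Optional[Sequence[float]] = None,
) -> SceneSpec:
    """Lay out square cells on a grid, block-aligned to 8-px binning."""
    if cell_px % 8 or gap_px % 8:
        raise ValueError("cell and gap sizes must be multiples of 8")
    per_row = int(np.ceil(np.sqrt(n_cells)))
    pitch = cell_px + gap_px
    side = per_row * pitch + gap_px
    side = int(np.ceil(side / 8) * 8)
    if expressions is None:
        expressions = [1.0] * n_cells
    cells = []
    for i in range(n_cells):
        r, c = divmod(i, per_row)
        r0 = gap_px + r * pitch
        c0 = gap_px + c * pitch
        cells.append(CellSpec(i + 1, (r0, r0 + cell_px), (c0, c0 + cell_px),
                              expression=float(expressions[i])))
    return SceneSpec(shape=(side, side), cells=tuple(cells))


def write_stack(
    stack: FrameStack,
    out_dir: str | Path,
    scene: Optional[SceneSpec] = None,
    ground_truth=None,
) -> Dict[str, Path]:
    """Write TIFF stack + JSON-lines metadata (+ ROI mask, ground-truth CSV)."""
    import tifffile

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: Dict[str, Path] = {}

    tif_path = out / "stack.tif"
    with tifffile.TiffWriter(tif_path) as tw:
        for frame in stack.frames:
            tw.write(np.clip(np.rint(frame), 0, SATURATION).astype(np.uint16))
    paths["stack"] = tif_path

    meta_path = out / "frames.jsonl"
    with open(meta_path, "w") as fh:
        for i, (frame, meta) in enumerate(zip(stack.frames, stack.metadata)):
            rec = dict(meta)
            rec["index"] = i
            rec["saturated"] = bool(np.any(frame >= SATURATION))
            fh.write(json.dumps(rec) + "\n")
    paths["metadata"] = meta_path

    if scene is not None:
        roi_path = out / "rois.tif"
        tifffile.imwrite(roi_path, scene.label_mask())
        paths["rois"] = roi_path
    if ground_truth is not None:
        gt_path = out / "ground_truth.csv"
        ground_truth.to_csv(gt_path, index=False)
        paths["ground_truth"] = gt_path
    return paths


def read_stack(run_dir: str | Path) -> FrameStack:
    """Read a stack written by :func:`write_stack` (or conforming data)."""
    import tifffile

    run = Path(run_dir)
    frames = [page.asarray().astype(float) for page in tifffile.TiffFile(run / "stack.tif").pages]
    metadata = [json.loads(line) for line in open(run / "frames.jsonl")]
    if len(frames) != len(metadata):
        raise ValueError("frame count does not match metadata records")
    return FrameStack(frames=frames, metadata=metadata)
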