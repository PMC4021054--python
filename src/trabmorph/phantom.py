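"""Synthetic trabecular-bone phantoms with paired microCT-like and MR-like renderings.

Real peri-articular specimens are imaged twice in the validation design:
once at very fine, isotropic resolution with bright bone (microCT) and once
at clinical resolution with dark bone and strong through-plane partial
volume averaging (a steady-state gradient-echo MR sequence).  The phantom
module produces a ground-truth binary microstructure with an exactly
prescribed bone volume fraction (BV/TV), plus both renderings, so every
downstream measurement stage can be exercised and checked against a known
truth.

The microstructure is a thresholded Gaussian random field: smoothed white
noise cut at the empirical quantile ``1 - target_bvtv`` of its own values.
Quantile thresholding pins the realized bone fraction to the target up to a
single voxel of rank granularity, which is what makes the phantom usable as
an exact oracle.  A slab of pure bone is prepended on the superior face to
mimic the subchondral cortical plate; it is excluded from the trabecular
BV/TV accounting.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .volume import BinaryVolume, ImageVolume

__all__ = [
    "PhantomSpec",
    "MicroCTRenderSpec",
    "MRRenderSpec",
    "LesionBox",
    "PhantomBundle",
    "generate_microstructure",
    "trabecular_region",
    "render_microct",
    "render_mr",
    "cortical_calibration_volume",
    "generate_cohort",
]

#: Axis order of all extent/spacing triples: (anterior-posterior, vertical, medial-lateral).
AXIS_NAMES = ("anterior-posterior", "vertical", "medial-lateral")


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry and composition of one synthetic specimen.

    ``voi_extent`` is the trabecular volume of interest in mm, axis order
    (anterior-posterior, vertical, medial-lateral); the cortical plate is
    added on top of (superior to) this extent.  ``fine_spacing`` is the
    isotropic grid step of the ground truth — a scaled-up stand-in for the
    9 micron acquisition grid, kept coarse enough for desk-scale work.
    ``trabecular_scale`` is the correlation length (mm) of the Gaussian
    random field, set to typical trabecular spacing.
    """

    target_bvtv: float
    trabecular_scale: float = 0.3
    voi_extent: tuple[float, float, float] = (10.0, 4.0, 10.0)
    fine_spacing: float = 0.05
    cortical_plate_thickness: float = 0.4
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.target_bvtv <= 1.0:
            raise ValueError(f"target_bvtv must be in [0, 1], got {self.target_bvtv}")
        if any(e <= 0 for e in self.voi_extent):
            raise ValueError(f"voi_extent must be positive, got {self.voi_extent}")
        if self.fine_spacing <= 0 or self.trabecular_scale <= 0:
            raise ValueError("fine_spacing and trabecular_scale must be positive")
        if self.cortical_plate_thickness < 0:
            raise ValueError("cortical_plate_thickness must be >= 0")

    @property
    def plate_voxels(self) -> int:
        return int(round(self.cortical_plate_thickness / self.fine_spacing))

    @property
    def trabecular_shape(self) -> tuple[int, int, int]:
        return tuple(int(round(e / self.fine_spacing)) for e in self.voi_extent)


@dataclass(frozen=True)
class MicroCTRenderSpec:
    """8-bit bright-bone rendering: bone ~``bone_gray``, marrow ~``marrow_gray``,
    independent Gaussian noise, clipped to [0, 255]."""

    bone_gray: float = 180.0
    marrow_gray: float = 40.0
    noise_sigma: float = 5.0

    def __post_init__(self) -> None:
        if not 0 <= self.marrow_gray < self.bone_gray <= 255:
            raise ValueError(
                f"need 0 <= marrow_gray < bone_gray <= 255, got {self.marrow_gray}, {self.bone_gray}"
            )
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")


@dataclass(frozen=True)
class LesionBox:
    """Axis-aligned box (mm, half-open) where marrow signal is multiplied by ``factor``.

    Emulates a hyperintense bone-marrow lesion on the MR rendering.
    """

    lo: tuple[float, float, float]
    hi: tuple[float, float, float]
    factor: float = 2.0

    def __post_init__(self) -> None:
        if any(h <= l for l, h in zip(self.lo, self.hi)):
            raise ValueError("lesion box must have hi > lo on every axis")
        if self.factor <= 0:
            raise ValueError("lesion factor must be positive")


@dataclass(frozen=True)
class MRRenderSpec:
    """Dark-bone clinical-resolution rendering.

    The MR grid is a block-decimation of the fine grid: each MR voxel is the
    block average of the underlying truth (the partial-volume mechanism),
    the noiseless signal is ``f * bone_signal + (1 - f) * marrow_signal``
    for bone fraction ``f``, and Rician noise (magnitude of a complex
    Gaussian perturbation) is applied.  ``mr_spacing`` components must be
    integer multiples of the truth's fine spacing; the default emulates the
    clinical geometry (1 mm slices, ~quarter-mm in-plane) on the 0.05 mm
    desk-scale fine grid.
    """

    bone_signal: float = 20.0
    marrow_signal: float = 200.0
    mr_spacing: tuple[float, float, float] = (1.0, 0.25, 0.25)
    rician_sigma: float = 10.0
    lesion_regions: tuple[LesionBox, ...] = ()

    def __post_init__(self) -> None:
        if self.bone_signal >= self.marrow_signal:
            raise ValueError("bone must be darker than marrow on this sequence")
        if any(s <= 0 for s in self.mr_spacing):
            raise ValueError("mr_spacing must be positive")
        if self.rician_sigma < 0:
            raise ValueError("rician_sigma must be >= 0")


@dataclass
class PhantomBundle:
    """One synthetic specimen: ground truth plus both renderings."""

    truth: BinaryVolume
    microct_volume: ImageVolume
    mr_volume: ImageVolume
    true_bvtv: float
    spec: PhantomSpec


def generate_microstructure(spec: PhantomSpec) -> BinaryVolume:
    """Draw the ground-truth binary microstructure for ``spec``.

    A Gaussian random field with correlation length ``trabecular_scale`` is
    thresholded at the empirical quantile ``1 - target_bvtv`` of its own
    values, so the realized trabecular bone fraction matches the target up
    to one voxel of rank granularity.  The cortical plate (pure bone) is
    prepended on the superior face (vertical rows ``0 .. plate_voxels``) and
    takes no part in the trabecular fraction.
    """
    rng = np.random.default_rng(spec.seed)
    shape = spec.trabecular_shape
    noise = rng.standard_normal(shape)
    sigma = spec.trabecular_scale / spec.fine_spacing
    fld = gaussian_filter(noise, sigma)

    t = spec.target_bvtv
    if t <= 0.0:
        trab = np.zeros(shape, dtype=bool)
    elif t >= 1.0:
        trab = np.ones(shape, dtype=bool)
    else:
        trab = fld >= np.quantile(fld, 1.0 - t)

    if spec.plate_voxels:
        plate = np.ones((shape[0], spec.plate_voxels, shape[2]), dtype=bool)
        mask = np.concatenate([plate, trab], axis=1)
    else:
        mask = trab
    return BinaryVolume(mask, (spec.fine_spacing,) * 3)


def trabecular_region(truth: BinaryVolume, spec: PhantomSpec) -> BinaryVolume:
    """The truth volume with the cortical plate rows stripped off."""
    sub = truth.mask[:, spec.plate_voxels :, :]
    origin = list(truth.origin)
    origin[1] += spec.plate_voxels * truth.spacing[1]
    return BinaryVolume(sub, truth.spacing, tuple(origin))


def render_microct(
    truth: BinaryVolume, render: MicroCTRenderSpec = MicroCTRenderSpec(), seed: int = 0
) -> ImageVolume:
    """Render the bright-bone, fine-grid microCT-like volume of ``truth``."""
    rng = np.random.default_rng(seed)
    img = np.where(truth.mask, render.bone_gray, render.marrow_gray)
    if render.noise_sigma > 0:
        img = img + rng.normal(0.0, render.noise_sigma, truth.mask.shape)
    img = np.clip(img, 0.0, 255.0)
    return ImageVolume(img, truth.spacing, truth.origin, intensity_range=(0, 255))


def _block_factors(
    mr_spacing: tuple[float, float, float], fine: tuple[float, float, float]
) -> tuple[int, int, int]:
    factors = []
    for axis, (coarse, f) in enumerate(zip(mr_spacing, fine)):
        ratio = coarse / f
        k = round(ratio)
        if k < 1:
            raise ValueError(
                f"mr_spacing finer than the truth grid on {AXIS_NAMES[axis]} axis "
                f"({coarse} mm < {f} mm)"
            )
        if abs(ratio - k) > 1e-6:
            raise ValueError(
                f"mr_spacing must be an integer multiple of fine spacing on "
                f"{AXIS_NAMES[axis]} axis: {coarse} / {f} = {ratio}"
            )
        factors.append(k)
    return tuple(factors)


def _block_average(arr: np.ndarray, factors: tuple[int, int, int]) -> np.ndarray:
    # Trailing voxels that do not fill a block are cropped; the superior
    # face (row 0, where the plate sits) is always preserved.
    keep = [(n // k) * k for n, k in zip(arr.shape, factors)]
    a = arr[: keep[0], : keep[1], : keep[2]]
    na = [keep[i] // factors[i] for i in range(3)]
    return a.reshape(na[0], factors[0], na[1], factors[1], na[2], factors[2]).mean(axis=(1, 3, 5))


def rician_noise(signal: np.ndarray, sigma: float, rng: np.random.Generator) -> np.ndarray:
    """Magnitude-image noise: |(s + g1*sigma) + i*g2*sigma| with g1, g2 iid N(0,1)."""
    if sigma == 0:
        return np.asarray(signal, dtype=float)
    re = signal + sigma * rng.standard_normal(signal.shape)
    im = sigma * rng.standard_normal(signal.shape)
    return np.hypot(re, im)


def render_mr(
    truth: BinaryVolume, render: MRRenderSpec = MRRenderSpec(), seed: int = 0
) -> ImageVolume:
    """Render the dark-bone, partial-volume MR-like volume of ``truth``.

    The bone fraction of each MR voxel is the block average of the truth;
    lesion boxes multiply the marrow signal locally before mixing; Rician
    noise is applied to the noiseless magnitude signal.
    """
    rng = np.random.default_rng(seed)
    factors = _block_factors(render.mr_spacing, truth.spacing)

    marrow = np.full(truth.mask.shape, render.marrow_signal)
    for box in render.lesion_regions:
        idx = []
        for axis in range(3):
            lo = (box.lo[axis] - truth.origin[axis]) / truth.spacing[axis]
            hi = (box.hi[axis] - truth.origin[axis]) / truth.spacing[axis]
            idx.append(slice(max(0, math.ceil(lo - 1e-9)), max(0, math.ceil(hi - 1e-9))))
        marrow[tuple(idx)] *= box.factor

    fine_signal = np.where(truth.mask, render.bone_signal, marrow)
    signal = _block_average(fine_signal, factors)
    img = rician_noise(signal, render.rician_sigma, rng)
    return ImageVolume(img, render.mr_spacing, truth.origin)


def cortical_calibration_volume(
    render: MRRenderSpec = MRRenderSpec(),
    fine_spacing: float = 0.05,
    extent: tuple[float, float, float] = (4.0, 4.0, 8.0),
    seed: int = 0,
) -> ImageVolume:
    """MR rendering of a pure cortical-bone block, for threshold calibration.

    Stands in for the thick cortical bone of the femoral condyles on which
    the signal-intensity threshold is calibrated in the real protocol — a
    region of solid bone well away from the measurement ROI, so every pixel
    carries the (noisy) bone signal.
    """
    shape = tuple(int(round(e / fine_spacing)) for e in extent)
    truth = BinaryVolume(np.ones(shape, dtype=bool), (fine_spacing,) * 3)
    return render_mr(truth, render, seed=seed)


def _child_seed(root: np.random.SeedSequence) -> int:
    """Next independent integer seed derived from ``root`` (stateful spawn)."""
    return int(root.spawn(1)[0].generate_state(1)[0] % (2**31))


def generate_cohort(
    n: int,
    bvtv_range: tuple[float, float] = (0.10, 0.45),
    phantom: PhantomSpec | None = None,
    microct_render: MicroCTRenderSpec = MicroCTRenderSpec(),
    mr_render: MRRenderSpec = MRRenderSpec(),
    seed: int = 0,
) -> tuple[list[PhantomBundle], pd.DataFrame]:
    """Generate ``n`` paired specimens with true BV/TV spread over ``bvtv_range``.

    Targets are evenly spaced across the range.  Specimens are labelled like
    a paired-knee cohort: consecutive specimens share a donor id and
    alternate right/left — the labels only exist to exercise the per-side
    subgroup analysis, no anatomical asymmetry is modelled.

    Returns the bundles and a truth table with columns
    ``id, side, true_bvtv_percent``.
    """
    if n < 2:
        raise ValueError("cohort needs n >= 2")
    lo, hi = bvtv_range
    if not (0 <= lo <= hi <= 1):
        raise ValueError(f"bvtv_range must satisfy 0 <= lo <= hi <= 1, got {bvtv_range}")
    base = phantom if phantom is not None else PhantomSpec(target_bvtv=lo, seed=seed)
    targets = np.linspace(lo, hi, n)

    root = np.random.SeedSequence(seed)
    bundles: list[PhantomBundle] = []
    rows = []
    for i, t in enumerate(targets):
        spec = replace(base, target_bvtv=float(t), seed=_child_seed(root))
        truth = generate_microstructure(spec)
        true_bvtv = trabecular_region(truth, spec).bone_fraction()
        ct = render_microct(truth, microct_render, seed=_child_seed(root))
        mr = render_mr(truth, mr_render, seed=_child_seed(root))
        bundles.append(PhantomBundle(truth, ct, mr, true_bvtv, spec))
        rows.append(
            {
                "id": i // 2 + 1,
                "side": "right" if i % 2 == 0 else "left",
                "true_bvtv_percent": 100.0 * true_bvtv,
            }
        )
    return bundles, pd.DataFrame(rows)
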