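"""End-to-end synthetic experiment: simulate -> measure -> validate.

Drives the full validation loop on synthetic specimens: generate a cohort
of paired phantoms, calibrate the MR cortical threshold on a pure-cortical
calibration block, measure MR apparent BV/TV and microCT BV/TV on every
specimen, and compute the cross-modality agreement statistics.  The same
functions back the command-line interface and the test suite.

Desk-scale protocol: the default phantom VOI is 10 x 4 x 10 mm on a 0.05 mm
fine grid, so the MR analysis uses all ten 1 mm slices (rather than the
twenty of the full-size clinical protocol) and an 8 mm wide ROI that fits
the phantom's medial-lateral extent.  The ROI is anchored at the superior
face so it includes the cortical plate, as in the clinical measurement.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .agreement import AgreementReport, PairedMeasurements, compute_agreement
from .microct_morphometry import VOISpec, binarize_global, extract_voi, marching_cubes_bvtv, voxel_count_bvtv
from .mr_morphometry import (
    CALIBRATION_ROI_SIZE_MM,
    N_CALIBRATION_ROIS,
    PhysicalROI,
    ThresholdCalibration,
    apparent_bvtv,
    calibrate_cortical_threshold,
    central_roi_stack,
)
from .phantom import (
    MicroCTRenderSpec,
    MRRenderSpec,
    PhantomBundle,
    PhantomSpec,
    cortical_calibration_volume,
    generate_cohort,
)
from .volume import ImageVolume

__all__ = [
    "MRAnalysisConfig",
    "MicroCTAnalysisConfig",
    "StatsConfig",
    "PipelineConfig",
    "ExperimentResult",
    "calibration_roi_grid",
    "calibrate_phantom_threshold",
    "measure_mr",
    "measure_microct",
    "measure_cohort",
    "run_synthetic_experiment",
    "write_manifest",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class MRAnalysisConfig:
    """MR measurement block: ROI geometry and threshold statistic.

    ``roi_anchor`` is the (row, column) mm position of the measurement
    rectangle's top-left corner; anchoring at row 0 includes the
    subchondral cortical plate, as the clinical protocol prescribes.
    """

    roi_anchor: tuple[float, float] = (0.0, 1.0)
    roi_height: float = 3.75
    roi_width: float = 8.0
    n_slices: int = 10
    threshold_statistic: str = "pooled_mean"
    calibration_extent: tuple[float, float, float] = (4.0, 4.0, 8.0)


@dataclass(frozen=True)
class MicroCTAnalysisConfig:
    """MicroCT measurement block: thresholds, estimator, plate handling."""

    lower: float = 80.0
    upper: float = 255.0
    estimator: str = "marching_cubes"
    include_plate: bool = False


@dataclass(frozen=True)
class StatsConfig:
    ci_level: float = 0.95
    ci_method: str = "fisher"
    round_digits: int = 2


@dataclass(frozen=True)
class PipelineConfig:
    """Everything needed to rerun a synthetic validation experiment."""

    n_specimens: int = 10
    bvtv_range: tuple[float, float] = (0.10, 0.45)
    phantom: PhantomSpec = field(default_factory=lambda: PhantomSpec(target_bvtv=0.10))
    microct_render: MicroCTRenderSpec = field(default_factory=MicroCTRenderSpec)
    mr_render: MRRenderSpec = field(default_factory=MRRenderSpec)
    mr_analysis: MRAnalysisConfig = field(default_factory=MRAnalysisConfig)
    microct_analysis: MicroCTAnalysisConfig = field(default_factory=MicroCTAnalysisConfig)
    stats: StatsConfig = field(default_factory=StatsConfig)
    seed: int = 0

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        def _tup(x):
            return tuple(x) if isinstance(x, (list, tuple)) else x
        kwargs: dict = {}
        if "n_specimens" in d:
            kwargs["n_specimens"] = int(d["n_specimens"])
        if "bvtv_range" in d:
            kwargs["bvtv_range"] = _tup(d["bvtv_range"])
        if "seed" in d:
            kwargs["seed"] = int(d["seed"])
        for key, typ in (
            ("phantom", PhantomSpec),
            ("microct_render", MicroCTRenderSpec),
            ("mr_render", MRRenderSpec),
            ("mr_analysis", MRAnalysisConfig),
            ("microct_analysis", MicroCTAnalysisConfig),
            ("stats", StatsConfig),
        ):
            if key in d:
                block = {k: _tup(v) for k, v in dict(d[key]).items()}
                if key == "phantom":
                    block.setdefault("target_bvtv", 0.10)
                if key == "mr_render":
                    block.pop("lesion_regions", None)
                kwargs[key] = typ(**block)
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


@dataclass
class ExperimentResult:
    truth: pd.DataFrame
    measurements: pd.DataFrame
    calibration: ThresholdCalibration
    agreement: AgreementReport


def calibration_roi_grid(
    volume: ImageVolume,
    n_rois: int = N_CALIBRATION_ROIS,
    size_mm: float = CALIBRATION_ROI_SIZE_MM,
) -> list[PhysicalROI]:
    """A deterministic grid of small square ROIs spread over a volume.

    Used to place the cortical calibration ROIs on the pure-cortical
    calibration block: ROIs are laid out row-major over slices with ~1 mm
    pitch until ``n_rois`` are placed.
    """
    ext = volume.extent
    pitch = size_mm + 0.31  # ~1 mm pitch for the standard 0.69 mm ROI
    per_row = max(1, int((ext[2] - size_mm) / pitch) + 1)
    per_col = max(1, int((ext[1] - size_mm) / pitch) + 1)
    rois = []
    for s in range(volume.shape[0]):
        for j in range(per_col):
            for k in range(per_row):
                if len(rois) == n_rois:
                    return rois
                rois.append(
                    PhysicalROI(
                        slice_index=s,
                        top_left=(j * pitch, k * pitch),
                        height=size_mm,
                        width=size_mm,
                    )
                )
    raise ValueError(
        f"volume too small to host {n_rois} calibration ROIs (placed {len(rois)})"
    )


def calibrate_phantom_threshold(config: PipelineConfig, seed: int) -> ThresholdCalibration:
    """Calibrate the MR threshold on a rendered pure-cortical block."""
    cal_vol = cortical_calibration_volume(
        render=config.mr_render,
        fine_spacing=config.phantom.fine_spacing,
        extent=config.mr_analysis.calibration_extent,
        seed=seed,
    )
    rois = calibration_roi_grid(cal_vol)
    return calibrate_cortical_threshold(
        cal_vol, rois, statistic=config.mr_analysis.threshold_statistic
    )


def measure_mr(bundle: PhantomBundle, config: PipelineConfig, threshold: float) -> float:
    """MR apparent BV/TV (percent) of one phantom bundle."""
    mra = config.mr_analysis
    rois = central_roi_stack(
        bundle.mr_volume,
        anchor=mra.roi_anchor,
        height_mm=mra.roi_height,
        width_mm=mra.roi_width,
        n_slices=mra.n_slices,
    )
    return apparent_bvtv(bundle.mr_volume, rois, threshold).mean_bvtv_percent


def measure_microct(bundle: PhantomBundle, config: PipelineConfig) -> float:
    """MicroCT BV/TV (percent) of one phantom bundle.

    The cortical plate is excluded from the VOI by default (the microCT VOI
    sits in the trabecular compartment); ``include_plate=True`` keeps it,
    to probe the MR/microCT region-of-interest mismatch.
    """
    cta = config.microct_analysis
    mask = binarize_global(bundle.microct_volume, lower=cta.lower, upper=cta.upper)
    if not cta.include_plate:
        plate_mm = bundle.spec.cortical_plate_thickness
        ext = mask.extent
        voi = VOISpec(
            extent=(ext[0], ext[1] - plate_mm, ext[2]),
            placement=(0.0, plate_mm, 0.0),
        )
        mask = extract_voi(mask, voi)
    if cta.estimator == "marching_cubes":
        est = marching_cubes_bvtv(mask)
    elif cta.estimator == "voxel_count":
        est = voxel_count_bvtv(mask)
    else:
        raise ValueError(f"unknown estimator {cta.estimator!r}")
    return est.bvtv_percent


def measure_cohort(
    bundles: list[PhantomBundle],
    truth: pd.DataFrame,
    config: PipelineConfig,
    threshold: float,
) -> pd.DataFrame:
    """Measure every bundle on both modalities; rows match the truth table."""
    rows = []
    for bundle, (_, trow) in zip(bundles, truth.iterrows()):
        rows.append(
            {
                "id": trow["id"],
                "side": trow["side"],
                "microct_bvtv_percent": measure_microct(bundle, config),
                "mr_bvtv_percent": measure_mr(bundle, config, threshold),
            }
        )
    return pd.DataFrame(rows)


def run_synthetic_experiment(config: PipelineConfig | None = None, seed: int | None = None) -> ExperimentResult:
    """Simulate a cohort, measure both modalities, and compute agreement."""
    config = config or PipelineConfig()
    seed = config.seed if seed is None else seed
    logger.info("simulating cohort: n=%d, seed=%d", config.n_specimens, seed)
    bundles, truth = generate_cohort(
        n=config.n_specimens,
        bvtv_range=config.bvtv_range,
        phantom=config.phantom,
        microct_render=config.microct_render,
        mr_render=config.mr_render,
        seed=seed,
    )
    calibration = calibrate_phantom_threshold(config, seed=seed + 1)
    logger.info("calibrated cortical threshold: %.2f", calibration.threshold)
    measurements = measure_cohort(bundles, truth, config, calibration.threshold)
    agreement = compute_agreement(
        PairedMeasurements(measurements),
        ci_level=config.stats.ci_level,
        ci_method=config.stats.ci_method,
    )
    return ExperimentResult(truth, measurements, calibration, agreement)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(
    path: str | Path,
    config: PipelineConfig,
    seed: int,
    files: list[str | Path],
) -> Path:
    """Record config, seed, package version and output digests for a run."""
    path = Path(path)
    manifest = {
        "package": "trabmorph",
        "version": __version__,
        "timestamp": datetime.now(timezone.utc).isoformat(),
        "seed": seed,
        "config": config.to_dict(),
        "files": {str(f): _sha256(Path(f)) for f in files},
    }
    path.write_text(json.dumps(manifest, indent=2, default=str))
    return path
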