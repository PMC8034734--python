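"""End-to-end orchestration: electrograms in, 2D/3D tip statistics out.

``run_case`` chains the stages in the canonical order — QRS template
subtraction, 1.5-25 Hz zero-phase band-pass, per-channel dominant cycle
length, sinusoidal recomposition, 2D lattice and 3D mesh phase maps,
winding-number tip detection, persistence tracking, 7x7 tip densities and
the 2D-vs-3D comparison report.  It is the single entry point used by the
CLI, the examples and the acceptance script.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .compare import ComparisonReport, compare_densities, region_masks
from .geometry import BasketMesh, GridMesh2D, vertex_curvatures
from .io_formats import (
    BASKET_CHANNELS,
    AnalysisConfig,
    BasketLayout,
    ElectrodeGeometry,
    ElectrogramSet,
)
from .preprocess import CycleLength, preprocess_set
from .recompose import sinusoidal_recomposition
from .singularity import (
    TipDensityMatrix,
    Track,
    build_frames_2d,
    build_frames_3d,
    detect_ps_2d,
    detect_ps_3d,
    tip_density,
    track_singularities,
)

CANONICAL_LAYOUT = BasketLayout.from_labels(list(BASKET_CHANNELS))


@dataclass
class CaseResult:
    """Everything one mapping window produces."""

    config: AnalysisConfig
    cycle_lengths: list[CycleLength]
    t_cl_ms: float  # median over channels, used for persistence
    n_frames: int
    frame_dt_ms: float
    tips2d: list  # per-frame lists of PhaseSingularity
    tips3d: list
    density2d: TipDensityMatrix
    density3d: TipDensityMatrix
    tracks2d: list[Track]
    tracks3d: list[Track]
    report: ComparisonReport
    basket: BasketMesh
    grid: GridMesh2D
    recomposed: np.ndarray = field(repr=False, default=None)  # type: ignore


def run_case(
    egm: ElectrogramSet,
    geometry: ElectrodeGeometry,
    config: AnalysisConfig | None = None,
    ecg_label: str | None = None,
    curvature_masks: bool = False,
) -> CaseResult:
    """Run the full pipeline on one recording + basket geometry."""
    config = config or AnalysisConfig()
    layout = BasketLayout.from_labels(egm.labels)
    block = layout.matrix(egm.samples).reshape(64, -1)  # spline-major order

    ecg = None
    if ecg_label is not None:
        ecg = egm.channel(ecg_label)
    elif "ECG" in egm.labels:
        ecg = egm.channel("ECG")

    filtered, cls_, _timing = preprocess_set(
        block,
        egm.fs,
        ecg=ecg,
        band=(config.band_low_hz, config.band_high_hz),
        order=config.filter_order,
        qrs_window_ms=(config.qrs_pre_ms, config.qrs_post_ms),
        search_band=(config.df_low_hz, config.df_high_hz),
        nperseg=config.welch_nperseg,
    )
    rec = np.stack(
        [
            sinusoidal_recomposition(filtered[ch], cls_[ch].t_cl_ms, egm.fs).values
            for ch in range(64)
        ]
    )
    t_cl = float(np.median([c.t_cl_ms for c in cls_]))

    frames2d = build_frames_2d(rec, CANONICAL_LAYOUT, egm.fs, config.frame_stride)
    tips2d = [detect_ps_2d(fr, k) for k, fr in enumerate(frames2d)]

    basket = BasketMesh.build(geometry, config.subdivision_rounds)
    frames3d = build_frames_3d(
        rec, CANONICAL_LAYOUT, basket, egm.fs, config.frame_stride
    )
    tips3d = [detect_ps_3d(basket, fr, k) for k, fr in enumerate(frames3d)]

    n_frames = len(frames2d)
    frame_dt = config.frame_stride * 1000.0 / egm.fs
    d2 = tip_density(tips2d, n_frames)
    d3 = tip_density(tips3d, n_frames)

    tracks2d = track_singularities(
        tips2d, frame_dt, t_cl, min_cycles=config.persistence_cycles
    )
    tracks3d = track_singularities(
        tips3d, frame_dt, t_cl, min_cycles=config.persistence_cycles
    )

    masks = None
    if curvature_masks:
        masks = region_masks(vertex_curvatures(basket.refined), basket)
    report = compare_densities(
        d2, d3, masks=masks, spacing_mm=config.electrode_spacing_mm
    )
    return CaseResult(
        config=config,
        cycle_lengths=cls_,
        t_cl_ms=t_cl,
        n_frames=n_frames,
        frame_dt_ms=frame_dt,
        tips2d=tips2d,
        tips3d=tips3d,
        density2d=d2,
        density3d=d3,
        tracks2d=tracks2d,
        tracks3d=tracks3d,
        report=report,
        basket=basket,
        grid=GridMesh2D.build(),
        recomposed=rec,
    )


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def write_manifest(
    out_dir: Path,
    config: AnalysisConfig,
    inputs: dict[str, Path],
    outputs: dict[str, Path],
    seed: int | None = None,
) -> Path:
    """Write a reproducibility manifest: config snapshot, input hashes,
    package version, seed and per-stage output paths."""
    from . import __version__

    manifest = {
        "version": __version__,
        "seed": seed,
        "config": {k: getattr(config, k) for k in vars(config)},
        "inputs": {k: {"path": str(p), "sha256": _sha256(Path(p))}
                   for k, p in inputs.items()},
        "outputs": {k: str(p) for k, p in outputs.items()},
    }
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, default=str))
    return path
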