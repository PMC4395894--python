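"""End-to-end analysis: frames -> contours -> decomposition -> report.

`analyze_sequence` chains the stages with one configuration object and
supports an on-disk cache so re-analysis of the same recording skips the
contour detection (the dominant cost). The cache is invalidated whenever the
source, the calibration or any analysis parameter changes.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from . import io
from .contours import ContourSet, DetectionConfig, detect_sequence_contours
from .decomposition import (
    DeformationField,
    SpectralMap,
    compute_deformation_field,
    split_eyeball_cornea,
    highpass_vibration,
    fft_amplitude_map,
    median_filter_map,
    MEDIAN_MASKS,
)
from .parameters import BiomechanicalReport, ParameterConfig, build_report

__all__ = ["AnalysisConfig", "AnalysisResult", "analyze_sequence", "recompute_from_contours"]

PIPELINE_VERSION = "0.1.0"


@dataclass
class AnalysisConfig:
    """Everything the pipeline needs beyond the frames themselves."""

    baseline_frames: int = 10
    scleral_margin: int = 50
    cutoff_hz: float = 100.0
    median_mask: int | None = None
    histogram_equalize: bool = False
    detection: DetectionConfig = field(default_factory=DetectionConfig)
    parameters: ParameterConfig = field(default_factory=ParameterConfig)

    def __post_init__(self) -> None:
        if self.median_mask not in (None, "none") and int(self.median_mask) not in MEDIAN_MASKS:
            raise ValueError(
                f"median_mask must be none or one of {MEDIAN_MASKS}, got {self.median_mask!r}"
            )

    def digest(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]

    def contour_digest(self) -> str:
        """Digest of the parameters the detected contours depend on.

        Decomposition and parameter settings (median mask, cutoff, margins)
        deliberately do not invalidate a contour cache.
        """
        blob = json.dumps(
            {"detection": asdict(self.detection), "equalize": self.histogram_equalize},
            sort_keys=True,
        )
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


@dataclass
class AnalysisResult:
    contours: ContourSet
    field: DeformationField
    spectrum: SpectralMap
    report: BiomechanicalReport
    config: AnalysisConfig
    source_id: str
    from_cache: bool = False


def _cache_meta(seq: io.FrameSequence, config: AnalysisConfig) -> dict:
    return {
        "pipeline_version": PIPELINE_VERSION,
        "source_id": seq.source_id,
        "n_frames": seq.n_frames,
        "frame_interval_us": seq.frame_interval_us,
        "pixel_pitch_mm": seq.pixel_pitch_mm,
        "config_digest": config.contour_digest(),
    }


def _decompose_and_report(
    contours: ContourSet, seq_meta: dict, config: AnalysisConfig
) -> tuple[DeformationField, SpectralMap, BiomechanicalReport]:
    field = compute_deformation_field(
        contours,
        baseline_frames=config.baseline_frames,
        frame_interval_us=seq_meta["frame_interval_us"],
        pixel_pitch_mm=seq_meta["pixel_pitch_mm"],
    )
    if config.median_mask not in (None, "none"):
        field.full = median_filter_map(field.full, config.median_mask)
    field = split_eyeball_cornea(field, config.scleral_margin)
    field = highpass_vibration(field, config.cutoff_hz)
    spectrum = fft_amplitude_map(field)
    report = build_report(
        contours, field, spectrum, config.parameters, baseline_frames=config.baseline_frames
    )
    return field, spectrum, report


def recompute_from_contours(
    contours: ContourSet,
    config: AnalysisConfig,
    frame_interval_us: float = io.DEFAULT_FRAME_INTERVAL_US,
    pixel_pitch_mm: float = io.DEFAULT_PIXEL_PITCH_MM,
    source_id: str = "",
) -> AnalysisResult:
    """Re-run decomposition and parameters from existing contours.

    This is the path taken after changing the median-filter mask: the
    contours stand, every derived quantity is recalculated.
    """
    meta = {"frame_interval_us": frame_interval_us, "pixel_pitch_mm": pixel_pitch_mm}
    field, spectrum, report = _decompose_and_report(contours, meta, config)
    return AnalysisResult(contours, field, spectrum, report, config, source_id)


def analyze_sequence(
    seq: io.FrameSequence,
    config: AnalysisConfig | None = None,
    cache_path: str | Path | None = None,
) -> AnalysisResult:
    """Full analysis of a frame sequence, optionally cached on disk.

    With ``cache_path`` set, a fresh cache holding the detected contours is
    reused (decomposition is cheap and always recomputed so that parameter
    changes take effect); a stale or missing cache triggers detection and is
    rewritten.
    """
    config = config or AnalysisConfig()
    if config.histogram_equalize:
        seq = io.equalize_histogram(seq)

    meta = _cache_meta(seq, config)
    contours = None
    from_cache = False
    if cache_path is not None:
        hit = io.load_results(cache_path, expected_meta=meta)
        if hit is not None:
            arrays, _ = hit
            contours = ContourSet(
                outer=arrays["outer"],
                inner=arrays["inner"],
                valid_outer=arrays["valid_outer"].astype(bool),
                valid_inner=arrays["valid_inner"].astype(bool),
                height=seq.height,
                width=seq.width,
                n_frames=seq.n_frames,
            )
            from_cache = True
    if contours is None:
        contours = detect_sequence_contours(seq, config.detection)
        if cache_path is not None:
            io.save_results(
                {
                    "outer": contours.outer,
                    "inner": contours.inner,
                    "valid_outer": contours.valid_outer,
                    "valid_inner": contours.valid_inner,
                },
                meta,
                cache_path,
            )

    seq_meta = {
        "frame_interval_us": seq.frame_interval_us,
        "pixel_pitch_mm": seq.pixel_pitch_mm,
    }
    field, spectrum, report = _decompose_and_report(contours, seq_meta, config)
    return AnalysisResult(contours, field, spectrum, report, config, seq.source_id, from_cache)
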