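"""Biomechanical parameters of the air-puff corneal response.

All quantities are computed in pixel/frame units from the deformation
decomposition and duplicated in physical units (mm, ms) through the spatial
and temporal calibration constants. Definitions that the underlying method
leaves open (applanation flatness thresholds, ratio denominators, the sign
convention of the asymmetry score) are implementation choices documented on
each function and surfaced in :class:`ParameterConfig`.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from decimal import Decimal, ROUND_HALF_UP
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.signal import find_peaks, hilbert

from .contours import ContourSet
from .decomposition import (
    DeformationField,
    SpectralMap,
    FirstHarmonic,
    first_harmonic,
)

__all__ = [
    "ParameterConfig",
    "ApplanationEvent",
    "HighestConcavity",
    "BiomechanicalReport",
    "max_flat_run",
    "detect_applanations",
    "highest_concavity",
    "amplitude_metrics",
    "corneal_length_change",
    "compute_ratios",
    "vibration_metrics",
    "asymmetry_and_side",
    "curvature_points",
    "convert_units",
    "build_report",
]

REPORT_SCHEMA_VERSION = 1


@dataclass
class ParameterConfig:
    """Thresholds for event detection, with pixel-domain defaults.

    flatness_tol_px: max deviation from the least-squares line over a column
        run for the run to count as applanated.
    min_applanation_len_px: shortest flat run accepted as an applanation.
    applanation_halfwidth: half-width (columns) of the apex-centred window
        searched for flat runs.
    side_threshold_px: |asymmetry score| below which the eye side is
        reported as undetermined.
    vibration_threshold_px: per-frame peak |vibration| above which a frame
        counts toward the vibration duration.
    curvature_halfstep_px: column half-step of the discrete second
        difference used to track local curvature at the flanking crests.
    """

    flatness_tol_px: float = 0.4
    min_applanation_len_px: int = 60
    applanation_halfwidth: int = 100
    side_threshold_px: float = 0.5
    vibration_threshold_px: float = 0.1
    min_harmonic_hz: float = 100.0
    harmonic_skirt_transition_hz: float = 180.0
    curvature_halfstep_px: int = 5
    arc_length_span: tuple[int, int] | None = None


@dataclass
class ApplanationEvent:
    time_frames: int
    length_px: float
    velocity_px_per_frame: float


@dataclass
class HighestConcavity:
    time_frames: int
    apex_col: int
    peak_distance_px: float | None
    peak_cols: tuple[int, int] | None
    radius_px: float  # inf flags a degenerate (collinear) central segment


# ---------------------------------------------------------------------------
# applanation: flat-run machinery


def _flat_windows(y: np.ndarray, length: int, tol: float) -> np.ndarray:
    """Boolean flags: for each start, is the length-L window flat within tol?

    Flat means every sample deviates less than tol from the window's own
    least-squares line.
    """
    n = y.size
    if length > n:
        return np.zeros(0, dtype=bool)
    windows = np.lib.stride_tricks.sliding_window_view(y, length)
    x = np.arange(length, dtype=np.float64)
    sx = x.sum()
    sxx = (x * x).sum()
    sy = windows.sum(axis=1)
    sxy = windows @ x
    denom = length * sxx - sx * sx
    slope = (length * sxy - sx * sy) / denom
    intercept = (sy - slope * sx) / length
    resid = windows - (slope[:, None] * x[None, :] + intercept[:, None])
    return np.abs(resid).max(axis=1) < tol


def max_flat_run(y: np.ndarray, tol: float, min_len: int) -> tuple[int, int | None]:
    """Longest flat run of length >= min_len in a contour slice.

    Returns (length, start column) or (0, None) when no run of min_len is
    flat. The search is a bisection over run length, valid because a flat
    run stays flat when shortened in practice.
    """
    y = np.asarray(y, dtype=np.float64)
    if not _flat_windows(y, min_len, tol).any():
        return 0, None
    lo, hi = min_len, y.size  # flat at lo; hi+1 known non-flat once hi < size fails
    while lo < hi:
        mid = (lo + hi + 1) // 2
        if _flat_windows(y, mid, tol).any():
            lo = mid
        else:
            hi = mid - 1
    starts = np.flatnonzero(_flat_windows(y, lo, tol))
    return lo, int(starts[0])


def detect_applanations(
    field: DeformationField,
    contours: ContourSet,
    config: ParameterConfig | None = None,
    apex_col: int | None = None,
) -> tuple[ApplanationEvent | None, ApplanationEvent | None, dict]:
    """Find the two applanation events from flatness of the outer contour.

    Applanation 1 is the first frame, up to and including highest concavity,
    whose apex window contains a flat run of at least
    ``min_applanation_len_px`` columns; applanation 2 is the first such frame
    after highest concavity. Event velocity is the central-difference apex
    displacement rate (px/frame). Missing events are returned as None with
    counts in the diagnostics dict.
    """
    config = config or ParameterConfig()
    if field.cornea is None:
        raise ValueError("decomposition incomplete: cornea component missing")
    if apex_col is None:
        apex_col = int(np.argmax(field.cornea.max(axis=0)))
    hw = config.applanation_halfwidth
    lo = max(0, apex_col - hw)
    hi = min(field.width, apex_col + hw + 1)

    hc_frame = int(np.argmax(field.cornea[:, apex_col]))
    flat = np.array(
        [
            _flat_windows(
                contours.outer[t, lo:hi], config.min_applanation_len_px, config.flatness_tol_px
            ).any()
            for t in range(field.n_frames)
        ]
    )

    apex_trace = field.full[:, apex_col]
    velocity = np.gradient(apex_trace)

    def event(frame_range: np.ndarray) -> ApplanationEvent | None:
        hits = frame_range[flat[frame_range]]
        if hits.size == 0:
            return None
        t = int(hits[0])
        length, _ = max_flat_run(
            contours.outer[t, lo:hi], config.flatness_tol_px, config.min_applanation_len_px
        )
        return ApplanationEvent(t, float(length), float(velocity[t]))

    app1 = event(np.arange(0, hc_frame + 1))
    app2 = event(np.arange(hc_frame + 1, field.n_frames))
    diagnostics = {
        "apex_col": apex_col,
        "highest_concavity_frame": hc_frame,
        "n_flat_frames": int(flat.sum()),
        "window": (lo, hi),
    }
    return app1, app2, diagnostics


# ---------------------------------------------------------------------------
# highest concavity, peak distance, radius


def _fit_circle_radius(cols: np.ndarray, rows: np.ndarray) -> float:
    """Algebraic (Kasa) least-squares circle fit; inf for collinear points."""
    x = np.asarray(cols, dtype=np.float64)
    y = np.asarray(rows, dtype=np.float64)
    a = np.column_stack([x, y, np.ones_like(x)])
    b = x * x + y * y
    sol, _, rank, _ = np.linalg.lstsq(a, b, rcond=None)
    if rank < 3:
        return math.inf
    cx, cy = sol[0] / 2.0, sol[1] / 2.0
    r2 = sol[2] + cx * cx + cy * cy
    if r2 <= 0 or not np.isfinite(r2):
        return math.inf
    radius = math.sqrt(r2)
    # collinear data drive the fitted radius to absurd scale; flag as flat
    span = max(np.ptp(x), 1.0)
    return math.inf if radius > 1e6 * span else radius


def highest_concavity(
    field: DeformationField, contours: ContourSet, config: ParameterConfig | None = None
) -> HighestConcavity:
    """Frame of maximal corneal deflection with peak distance and radius.

    Peak distance is the column gap between the two highest contour points
    (local minima of row position) flanking the apex at that frame; the
    radius is the circle fit through the outer contour between those peaks.
    """
    config = config or ParameterConfig()
    if field.cornea is None:
        raise ValueError("decomposition incomplete: cornea component missing")
    t_star, apex_col = np.unravel_index(np.argmax(field.cornea), field.cornea.shape)
    t_star, apex_col = int(t_star), int(apex_col)
    y = contours.outer[t_star]

    crest_idx, _ = find_peaks(-y, prominence=0.5)
    left = crest_idx[crest_idx < apex_col]
    right = crest_idx[crest_idx > apex_col]
    if left.size and right.size:
        lcol = int(left[np.argmin(y[left])])
        rcol = int(right[np.argmin(y[right])])
        peak_cols: tuple[int, int] | None = (lcol, rcol)
        peak_distance: float | None = float(rcol - lcol)
        seg = slice(lcol, rcol + 1)
    else:
        peak_cols = None
        peak_distance = None
        hw = config.applanation_halfwidth
        seg = slice(max(0, apex_col - hw), min(field.width, apex_col + hw + 1))

    cols = np.arange(field.width)[seg]
    radius = _fit_circle_radius(cols, y[seg])
    return HighestConcavity(t_star, apex_col, peak_distance, peak_cols, radius)


# ---------------------------------------------------------------------------
# amplitudes, arc length, ratios, vibration, asymmetry


def amplitude_metrics(field: DeformationField) -> dict[str, float]:
    """Extremes of the deformation components.

    max_eyeball is the largest per-frame mean eyeball displacement;
    diff_min/diff_max bound the frame-to-frame change of the corneal
    deformation; absolute_cornea_reaction is max |cornea|.
    """
    if field.cornea is None or field.eyeball is None:
        raise ValueError("decomposition incomplete")
    diff = np.diff(field.cornea, axis=0)
    return {
        "max_deformation_px": float(field.full.max()),
        "max_cornea_deformation_px": float(field.cornea.max()),
        "max_eyeball_amplitude_px": float(field.eyeball.mean(axis=1).max()),
        "deformation_diff_min_px": float(diff.min()),
        "deformation_diff_max_px": float(diff.max()),
        "absolute_cornea_reaction_px": float(np.abs(field.cornea).max()),
    }


def corneal_length_change(
    contours: ContourSet,
    baseline: np.ndarray,
    span: tuple[int, int] | None = None,
) -> np.ndarray:
    """Arc-length change of the outer contour per frame (px).

    L[t] is the polyline length of the outer contour over the column span
    (default: full width); the change is relative to the baseline contour's
    length over the same span. Rigid translation leaves it at zero.
    """
    lo, hi = span if span is not None else (0, contours.width)
    seg = contours.outer[:, lo:hi]
    base = np.asarray(baseline)[lo:hi]

    def arc_length(rows: np.ndarray) -> np.ndarray:
        dy = np.diff(rows, axis=-1)
        return np.sqrt(1.0 + dy * dy).sum(axis=-1)

    return arc_length(seg) - arc_length(base)


def compute_ratios(
    max_cornea_px: float, delta_length_px: np.ndarray, baseline_apex_row: float
) -> tuple[float | None, float | None]:
    """The two dimensionless ratios of the report.

    ratio_amp_over_length = max corneal deformation / max arc-length change;
    ratio_reaction_over_static = max corneal deformation / baseline apex row.
    Both are 0 for a zero deformation; a vanishing denominator with non-zero
    deformation yields None (undefined).
    """
    if max_cornea_px == 0.0:
        return 0.0, 0.0
    max_dl = float(np.max(delta_length_px)) if np.size(delta_length_px) else 0.0
    r1 = max_cornea_px / max_dl if max_dl > 0 else None
    r2 = max_cornea_px / baseline_apex_row if baseline_apex_row > 0 else None
    return r1, r2


def vibration_metrics(
    field: DeformationField, threshold_px: float = 0.1
) -> tuple[float, int]:
    """Peak |vibration| and the number of frames whose vibration envelope
    exceeds the threshold.

    The duration uses the analytic-signal (Hilbert) envelope per column, so
    an oscillation does not drop out of the count at every zero crossing of
    its carrier.
    """
    if field.vibration is None:
        raise ValueError("vibration component not computed")
    max_amp = float(np.abs(field.vibration).max())
    if max_amp == 0.0:
        return 0.0, 0
    envelope = np.abs(hilbert(field.vibration, axis=0))
    per_frame = envelope.max(axis=1)
    return max_amp, int((per_frame > threshold_px).sum())


def asymmetry_and_side(
    field: DeformationField, side_threshold_px: float = 0.5
) -> tuple[float, str]:
    """Scleral reaction asymmetry and the eye-side label.

    The score is the signed left-minus-right anchor difference at the frame
    where its magnitude peaks (so mirroring the image negates it exactly).
    Labels: 'left' for score > +threshold, 'right' for score < -threshold,
    else 'undetermined'. The anatomical mapping is a convention of this
    implementation, not a property of the device.
    """
    left, right = field.scleral_anchors()
    diff = left - right
    score = float(diff[np.argmax(np.abs(diff))])
    if score > side_threshold_px:
        label = "left"
    elif score < -side_threshold_px:
        label = "right"
    else:
        label = "undetermined"
    return score, label


def curvature_points(
    contours: ContourSet,
    field: DeformationField,
    spectrum: SpectralMap,
    peak_cols: tuple[int, int] | None,
    config: ParameterConfig | None = None,
) -> tuple[tuple[int, int] | None, tuple[float, float] | None]:
    """Times of maximal local curvature at the flanking crest columns.

    For each crest column found at highest concavity, the frame maximising
    the magnitude of the discrete second difference of the outer contour
    along columns (half-step ``curvature_halfstep_px``) is returned together
    with the amplitude, at that column, of the sequence-wide first-harmonic
    frequency bin. Absent crests give (None, None).
    """
    config = config or ParameterConfig()
    if peak_cols is None:
        return None, None
    fh = first_harmonic(spectrum, config.min_harmonic_hz, config.harmonic_skirt_transition_hz)
    h = config.curvature_halfstep_px
    times = []
    amps = []
    for col in peak_cols:
        c = int(np.clip(col, h, contours.width - 1 - h))
        kappa = (
            contours.outer[:, c - h] - 2.0 * contours.outer[:, c] + contours.outer[:, c + h]
        ) / (h * h)
        times.append(int(np.argmax(np.abs(kappa))))
        if fh.frequency_hz is None:
            amps.append(0.0)
        else:
            k = int(np.argmin(np.abs(spectrum.freqs - fh.frequency_hz)))
            amps.append(float(spectrum.amplitude[k, col]))
    return (times[0], times[1]), (amps[0], amps[1])


# ---------------------------------------------------------------------------
# unit conversion


def convert_units(
    value: float,
    axis: str,
    pixel_pitch_mm: float = 0.15,
    frame_interval_us: float = 231.0,
    decimals: int | None = None,
) -> float:
    """Convert a pixel (spatial) or frame (temporal) value to mm or ms.

    spatial: value * pixel_pitch_mm -> mm; temporal: value *
    frame_interval_us / 1000 -> ms. With ``decimals`` set, the result is
    rounded half away from zero at that precision (96 frames at 231 us ->
    22.2 ms).
    """
    if not (pixel_pitch_mm > 0 and frame_interval_us > 0):
        raise ValueError("calibration constants must be positive")
    if axis == "spatial":
        out = value * pixel_pitch_mm
    elif axis == "temporal":
        out = value * frame_interval_us / 1000.0
    else:
        raise ValueError(f"unknown axis {axis!r}: use 'spatial' or 'temporal'")
    if decimals is None:
        return out
    quantum = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(out)).quantize(quantum, rounding=ROUND_HALF_UP))


# ---------------------------------------------------------------------------
# report assembly


@dataclass
class BiomechanicalReport:
    """Every scalar parameter of the analysis, in pixel/frame units.

    ``to_physical`` converts lengths to mm, times to ms and velocities to
    mm/ms via the stored calibration. Optional events are None when absent.
    """

    applanation1_time_frames: int | None
    applanation2_time_frames: int | None
    applanation1_length_px: float | None
    applanation2_length_px: float | None
    applanation1_velocity_px_per_frame: float | None
    applanation2_velocity_px_per_frame: float | None
    highest_concavity_time_frames: int
    apex_col: int
    peak_distance_px: float | None
    radius_px: float
    max_deformation_px: float
    max_cornea_deformation_px: float
    max_eyeball_amplitude_px: float
    deformation_diff_min_px: float
    deformation_diff_max_px: float
    absolute_cornea_reaction_px: float
    corneal_length_change_px: np.ndarray
    max_corneal_length_change_px: float
    ratio_amp_over_length: float | None
    ratio_reaction_over_static: float | None
    max_vibration_amplitude_px: float
    vibration_duration_frames: int
    first_harmonic_hz: float | None
    first_harmonic_amplitude_px: float
    frequency_resolution_hz: float
    curvature_point_times_frames: tuple[int, int] | None
    curvature_point_harmonic_amp_px: tuple[float, float] | None
    asymmetry_score_px: float
    eye_side_label: str
    pachymetry_px: float
    pixel_pitch_mm: float
    frame_interval_us: float
    schema_version: int = REPORT_SCHEMA_VERSION
    definition_notes: str = (
        "ratio denominators, applanation thresholds and the asymmetry sign "
        "convention are implementation-defined; pachymetry is the contour "
        "gap, not optical pachymetry"
    )

    _SPATIAL = (
        "applanation1_length_px",
        "applanation2_length_px",
        "peak_distance_px",
        "radius_px",
        "max_deformation_px",
        "max_cornea_deformation_px",
        "max_eyeball_amplitude_px",
        "deformation_diff_min_px",
        "deformation_diff_max_px",
        "absolute_cornea_reaction_px",
        "max_corneal_length_change_px",
        "max_vibration_amplitude_px",
        "first_harmonic_amplitude_px",
        "asymmetry_score_px",
        "pachymetry_px",
    )
    _TEMPORAL = (
        "applanation1_time_frames",
        "applanation2_time_frames",
        "highest_concavity_time_frames",
        "vibration_duration_frames",
    )

    def to_physical(self) -> dict[str, float | None]:
        """Parameters converted to mm / ms / mm-per-ms."""
        out: dict[str, float | None] = {}
        ms_per_frame = self.frame_interval_us / 1000.0
        for name in self._SPATIAL:
            v = getattr(self, name)
            key = name.replace("_px", "_mm")
            out[key] = None if v is None else convert_units(v, "spatial", self.pixel_pitch_mm)
        for name in self._TEMPORAL:
            v = getattr(self, name)
            key = name.replace("_frames", "_ms")
            out[key] = None if v is None else convert_units(
                v, "temporal", frame_interval_us=self.frame_interval_us
            )
        for i in (1, 2):
            v = getattr(self, f"applanation{i}_velocity_px_per_frame")
            out[f"applanation{i}_velocity_mm_per_ms"] = (
                None if v is None else v * self.pixel_pitch_mm / ms_per_frame
            )
        if self.curvature_point_times_frames is not None:
            out["curvature_point_times_ms"] = tuple(
                convert_units(t, "temporal", frame_interval_us=self.frame_interval_us)
                for t in self.curvature_point_times_frames
            )
        return out

    def to_dict(self) -> dict:
        d = asdict(self)
        d["corneal_length_change_px"] = np.asarray(self.corneal_length_change_px).tolist()
        d["physical"] = self.to_physical()
        return d

    def to_json(self, path: str | Path | None = None) -> str:
        def default(o):
            if isinstance(o, (np.floating, np.integer)):
                return o.item()
            if isinstance(o, np.ndarray):
                return o.tolist()
            raise TypeError(type(o))

        text = json.dumps(self.to_dict(), indent=2, default=default)
        if path is not None:
            Path(path).write_text(text)
        return text

    def to_csv_row(self) -> pd.DataFrame:
        d = self.to_dict()
        d.pop("corneal_length_change_px")
        physical = d.pop("physical")
        for k, v in physical.items():
            d[k] = str(v) if isinstance(v, tuple) else v
        for k, v in list(d.items()):
            if isinstance(v, tuple):
                d[k] = str(v)
        return pd.DataFrame([d])


def build_report(
    contours: ContourSet,
    field: DeformationField,
    spectrum: SpectralMap,
    config: ParameterConfig | None = None,
    baseline_frames: int = 10,
) -> BiomechanicalReport:
    """Assemble the full biomechanical report from a completed decomposition."""
    config = config or ParameterConfig()
    if field.cornea is None or field.vibration is None:
        raise ValueError("decomposition incomplete: run split and highpass first")

    hc = highest_concavity(field, contours, config)
    app1, app2, _ = detect_applanations(field, contours, config, apex_col=hc.apex_col)
    amps = amplitude_metrics(field)
    dl = corneal_length_change(contours, field.baseline, config.arc_length_span)
    baseline_apex = float(field.baseline[hc.apex_col])
    r1, r2 = compute_ratios(amps["max_cornea_deformation_px"], dl, baseline_apex)
    vib_amp, vib_dur = vibration_metrics(field, config.vibration_threshold_px)
    fh = first_harmonic(spectrum, config.min_harmonic_hz, config.harmonic_skirt_transition_hz)
    curv_t, curv_a = curvature_points(contours, field, spectrum, hc.peak_cols, config)
    asym, side = asymmetry_and_side(field, config.side_threshold_px)

    k = int(baseline_frames)
    pachy = float(np.nanmean(contours.inner[:k, hc.apex_col] - contours.outer[:k, hc.apex_col]))

    return BiomechanicalReport(
        applanation1_time_frames=None if app1 is None else app1.time_frames,
        applanation2_time_frames=None if app2 is None else app2.time_frames,
        applanation1_length_px=None if app1 is None else app1.length_px,
        applanation2_length_px=None if app2 is None else app2.length_px,
        applanation1_velocity_px_per_frame=None if app1 is None else app1.velocity_px_per_frame,
        applanation2_velocity_px_per_frame=None if app2 is None else app2.velocity_px_per_frame,
        highest_concavity_time_frames=hc.time_frames,
        apex_col=hc.apex_col,
        peak_distance_px=hc.peak_distance_px,
        radius_px=hc.radius_px,
        corneal_length_change_px=dl,
        max_corneal_length_change_px=float(dl.max()),
        ratio_amp_over_length=r1,
        ratio_reaction_over_static=r2,
        max_vibration_amplitude_px=vib_amp,
        vibration_duration_frames=vib_dur,
        first_harmonic_hz=fh.frequency_hz,
        first_harmonic_amplitude_px=fh.amplitude_px,
        frequency_resolution_hz=fh.resolution_hz,
        curvature_point_times_frames=curv_t,
        curvature_point_harmonic_amp_px=curv_a,
        asymmetry_score_px=asym,
        eye_side_label=side,
        pachymetry_px=pachy,
        pixel_pitch_mm=field.pixel_pitch_mm,
        frame_interval_us=field.frame_interval_us,
        **amps,
    )
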