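"""Sub-pixel corneal contour detection.

Each frame is converted into two per-column waveforms — the outer and inner
corneal edges — by locating, for every image column, the largest brightness
gradient along the rows. The outer edge is the first rising (dark-to-bright)
gradient peak scanning from the image top; the inner edge is the strongest
falling peak within a bounded thickness window below it. Integer peaks are
refined to sub-pixel positions by parabolic interpolation of the gradient
sample and its two row neighbours. Outliers are repaired per frame by a
running-median test and linear interpolation.

Coordinate convention: row 0 at the top, rows increase downward, columns are
0-based left to right; a reported position r refers to pixel-centre
coordinates (pixel r spans [r, r + 1)).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from .io import FrameSequence

__all__ = [
    "DetectionConfig",
    "ContourSet",
    "ContourDetectionError",
    "smoothed_gradient",
    "column_gradient_peak",
    "detect_contours",
    "repair_contour",
    "detect_sequence_contours",
]


class ContourDetectionError(RuntimeError):
    pass


@dataclass
class DetectionConfig:
    """Tunable knobs of the gradient-peak detector.

    min_gradient: smallest smoothed gradient magnitude (grey levels / px)
        accepted as an edge.
    max_thickness_px: how far below the outer edge the inner edge may lie.
    jump_tol_px: deviation from the per-frame running median beyond which a
        column is declared an outlier and re-interpolated.
    median_window: running-median window width (columns) used by the repair.
    max_failed_frames: frames whose detection fails outright are interpolated
        in time, up to this count; beyond it the sequence is rejected.
    """

    min_gradient: float = 8.0
    max_thickness_px: int = 40
    jump_tol_px: float = 6.0
    median_window: int = 7
    max_failed_frames: int = 5


@dataclass
class ContourSet:
    """Per-frame, per-column sub-pixel edge rows with validity flags.

    ``valid_*`` marks columns where the edge was detected directly; repaired
    (interpolated) columns carry finite positions but False flags.
    """

    outer: np.ndarray  # [t][col] float
    inner: np.ndarray
    valid_outer: np.ndarray  # [t][col] bool
    valid_inner: np.ndarray
    height: int
    width: int
    n_frames: int

    def to_dataframe(self) -> pd.DataFrame:
        t, c = np.meshgrid(np.arange(self.n_frames), np.arange(self.width), indexing="ij")
        return pd.DataFrame(
            {
                "frame": t.ravel(),
                "column": c.ravel(),
                "outer_row": self.outer.ravel(),
                "inner_row": self.inner.ravel(),
                "outer_valid": self.valid_outer.ravel(),
                "inner_valid": self.valid_inner.ravel(),
            }
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, index=False)


_BINOMIAL = np.array([0.25, 0.5, 0.25])


def smoothed_gradient(intensity: np.ndarray) -> np.ndarray:
    """Row-direction brightness gradient after 3-tap binomial smoothing.

    Works on a single column profile (1D) or a whole frame (rows x cols);
    smoothing and the central difference both run along the row axis.
    """
    arr = np.asarray(intensity, dtype=np.float64)
    smooth = ndimage.convolve1d(arr, _BINOMIAL, axis=0, mode="nearest")
    return np.gradient(smooth, axis=0)


def _parabolic_offset(gm: np.ndarray, g0: np.ndarray, gp: np.ndarray) -> np.ndarray:
    denom = gm - 2.0 * g0 + gp
    with np.errstate(divide="ignore", invalid="ignore"):
        delta = np.where(denom != 0.0, 0.5 * (gm - gp) / denom, 0.0)
    # sub-pixel refinement never moves a peak by more than half a pixel
    return np.clip(delta, -0.5, 0.5)


def column_gradient_peak(
    column: np.ndarray,
    search_range: tuple[int, int] | None = None,
    polarity: str = "rising",
    min_gradient: float = 8.0,
) -> float | None:
    """Sub-pixel row of the largest signed gradient in one column profile.

    polarity 'rising' finds dark-to-bright edges (positive gradient),
    'falling' bright-to-dark. Returns None when the best peak magnitude is
    below min_gradient ("no edge"). Ties go to the smallest row index.
    """
    column = np.asarray(column, dtype=np.float64)
    if column.ndim != 1 or column.size < 3:
        raise ValueError("column must be a 1D profile of length >= 3")
    lo, hi = (1, column.size - 1) if search_range is None else search_range
    lo = max(int(lo), 1)
    hi = min(int(hi), column.size - 1)
    if hi <= lo:
        raise ValueError("empty search range")

    g = smoothed_gradient(column)
    signed = g if polarity == "rising" else -g
    if polarity not in ("rising", "falling"):
        raise ValueError(f"unknown polarity {polarity!r}")
    window = signed[lo:hi]
    k = int(np.argmax(window)) + lo
    if signed[k] < min_gradient:
        return None
    delta = float(_parabolic_offset(signed[k - 1], signed[k], signed[k + 1]))
    return k + delta


def _first_rising_peak(signed: np.ndarray, min_gradient: float) -> tuple[np.ndarray, np.ndarray]:
    """First local gradient maximum >= min_gradient per column (2D input).

    Plateaus resolve to their first row, so equal-gradient ties go to the
    smallest (outermost) row. Returns (row index, found flag).
    """
    h = signed.shape[0]
    inner = signed[1 : h - 1]
    is_peak = (inner > signed[: h - 2]) & (inner >= signed[2:]) & (inner >= min_gradient)
    found = is_peak.any(axis=0)
    rows = np.argmax(is_peak, axis=0) + 1
    return rows, found


def detect_contours(
    frame: np.ndarray, config: DetectionConfig | None = None
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Detect outer and inner corneal edges on one frame.

    Returns (outer, inner, valid_outer, valid_inner), each of length width;
    positions are NaN where invalid. Raises ContourDetectionError when more
    than half the columns have no detectable outer edge.
    """
    config = config or DetectionConfig()
    frame = np.asarray(frame, dtype=np.float64)
    h, w = frame.shape
    if h < 16 or w < 16:
        raise ValueError("frame must be at least 16 x 16 pixels")

    g = smoothed_gradient(frame)
    rows_o, valid_o = _first_rising_peak(g, config.min_gradient)

    # inner edge: strongest falling peak in (outer, outer + max_thickness]
    fg = -g
    row_idx = np.arange(h)[:, None]
    in_window = (row_idx > rows_o[None, :]) & (row_idx <= rows_o[None, :] + config.max_thickness_px)
    in_window[0] = False
    in_window[h - 1] = False
    masked = np.where(in_window & valid_o[None, :], fg, -np.inf)
    rows_i = np.argmax(masked, axis=0)
    best = masked[rows_i, np.arange(w)]
    valid_i = valid_o & np.isfinite(best) & (best >= config.min_gradient)

    cols = np.arange(w)

    def refine(rows: np.ndarray, signed: np.ndarray, valid: np.ndarray) -> np.ndarray:
        rows = np.clip(rows, 1, h - 2)
        delta = _parabolic_offset(
            signed[rows - 1, cols], signed[rows, cols], signed[rows + 1, cols]
        )
        out = rows + delta
        return np.where(valid, out, np.nan)

    outer = refine(rows_o, g, valid_o)
    inner = refine(rows_i, fg, valid_i)

    n_invalid = int((~valid_o).sum())
    if n_invalid > w // 2:
        raise ContourDetectionError(
            f"contour detection failed: {n_invalid}/{w} columns below "
            f"min_gradient={config.min_gradient}"
        )
    return outer, inner, valid_o, valid_i


def repair_contour(
    raw: np.ndarray, validity: np.ndarray, config: DetectionConfig | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Invalidate outliers and fill gaps so every column has a finite position.

    A valid column deviating from the running median by more than jump_tol_px
    is re-flagged invalid. Invalid runs are filled by linear interpolation
    between the nearest valid neighbours; runs touching the edges extend the
    nearest valid value. Returns (repaired positions, updated validity) where
    the flags mark columns kept from the raw detection.
    """
    config = config or DetectionConfig()
    raw = np.asarray(raw, dtype=np.float64)
    valid = np.asarray(validity, dtype=bool).copy()
    cols = np.arange(raw.size)
    if valid.sum() < 2:
        raise ContourDetectionError("fewer than 2 valid columns; cannot repair contour")

    filled = np.interp(cols, cols[valid], raw[valid])
    running_med = ndimage.median_filter(filled, size=config.median_window, mode="nearest")
    outlier = valid & (np.abs(raw - running_med) > config.jump_tol_px)
    valid &= ~outlier
    if valid.sum() < 2:
        raise ContourDetectionError("fewer than 2 valid columns after outlier removal")

    # np.interp extends edge runs with the nearest valid value
    repaired = np.where(valid, raw, np.interp(cols, cols[valid], raw[valid]))
    return repaired, valid


def detect_sequence_contours(
    sequence: FrameSequence, config: DetectionConfig | None = None
) -> ContourSet:
    """Run detection + repair on every frame of a sequence.

    Frames whose detection fails outright (dark frame, blink artefact) are
    interpolated in time from their neighbours and flagged invalid, up to
    ``max_failed_frames``; beyond that the sequence is rejected with the
    offending frame indices.
    """
    config = config or DetectionConfig()
    t_n, h, w = sequence.frames.shape
    outer = np.full((t_n, w), np.nan)
    inner = np.full((t_n, w), np.nan)
    valid_o = np.zeros((t_n, w), dtype=bool)
    valid_i = np.zeros((t_n, w), dtype=bool)
    failed: list[int] = []

    for t in range(t_n):
        try:
            o, i, vo, vi = detect_contours(sequence.frames[t], config)
            outer[t], valid_o[t] = repair_contour(o, vo, config)
            if vi.sum() >= 2:
                inner[t], valid_i[t] = repair_contour(i, vi, config)
            else:
                inner[t] = outer[t] + config.max_thickness_px / 2.0
        except ContourDetectionError:
            failed.append(t)

    if failed:
        if len(failed) > config.max_failed_frames:
            raise ContourDetectionError(
                f"{len(failed)} frames failed contour detection "
                f"(max {config.max_failed_frames}): frames {failed}"
            )
        ok = np.setdiff1d(np.arange(t_n), failed)
        for arr in (outer, inner):
            arr[failed] = np.array(
                [np.interp(failed, ok, arr[ok, c]) for c in range(w)]
            ).T
        valid_o[failed] = False
        valid_i[failed] = False

    return ContourSet(
        outer=outer,
        inner=inner,
        valid_outer=valid_o,
        valid_inner=valid_i,
        height=h,
        width=w,
        n_frames=t_n,
    )
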