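"""Sequence input/output: image directories, AVI video, and result caching.

A recording is an ordered stack of 2D grayscale Scheimpflug frames plus
spatial/temporal calibration. Directories of numbered JPEG/PNG frames are
ordered by natural (numeric-aware) sort on the trailing digit run of each
file name; AVI containers are read in stream order.
"""

from __future__ import annotations

import json
import re
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import imageio.v2 as iio
from skimage import exposure

from . import _avi

DEFAULT_FRAME_INTERVAL_US = 231.0
DEFAULT_PIXEL_PITCH_MM = 0.15

#: Rec. 601 luma weights used to collapse colour frames to grayscale.
_LUMA = np.array([0.299, 0.587, 0.114])

IMAGE_EXTENSIONS = {".jpg", ".jpeg", ".png", ".bmp", ".tif", ".tiff"}

CACHE_VERSION = 1
CACHE_EXTENSION = ".cdk"


class SequenceError(ValueError):
    """Raised for unreadable, inconsistent or too-short sequences."""


@dataclass
class FrameSequence:
    """An ordered grayscale frame stack with calibration metadata.

    frames holds intensities in [0, 255] indexed ``[t][row][col]`` with row 0
    at the image top. ``frame_interval_us`` is the time between consecutive
    frames and ``pixel_pitch_mm`` the physical size of one pixel.
    """

    frames: np.ndarray
    frame_interval_us: float = DEFAULT_FRAME_INTERVAL_US
    pixel_pitch_mm: float = DEFAULT_PIXEL_PITCH_MM
    source_id: str = ""

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3:
            raise SequenceError("frames must be a (T, H, W) array")
        if self.n_frames < 2:
            raise SequenceError("sequence too short: need at least 2 frames")
        if not (self.frame_interval_us > 0 and self.pixel_pitch_mm > 0):
            raise SequenceError("calibration constants must be positive")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def height(self) -> int:
        return self.frames.shape[1]

    @property
    def width(self) -> int:
        return self.frames.shape[2]

    @property
    def sampling_rate_hz(self) -> float:
        return 1e6 / self.frame_interval_us


_DIGIT_RUN = re.compile(r"\d+")


def normalize_and_sort_paths(file_names: list[str]) -> list[str]:
    """Order file names by natural sort on the last digit run of the stem.

    Numbered exports ("Test2.jpg", "Test10.jpg") sort by their numeric
    suffix rather than lexicographically. Names with no digits are flagged
    with a warning and placed last, in lexicographic order.
    """
    if not file_names:
        raise SequenceError("no input files")

    numbered: list[tuple[int, str, str]] = []
    unnumbered: list[str] = []
    for name in file_names:
        stem = Path(name).stem
        runs = _DIGIT_RUN.findall(stem)
        if runs:
            numbered.append((int(runs[-1]), name.lower(), name))
        else:
            unnumbered.append(name)
    if unnumbered:
        warnings.warn(
            f"{len(unnumbered)} file name(s) contain no digits; placing last: "
            + ", ".join(sorted(unnumbered)[:5]),
            stacklevel=2,
        )
    ordered = [name for _, _, name in sorted(numbered)]
    ordered.extend(sorted(unnumbered))
    return ordered


def _to_gray(img: np.ndarray, path: str) -> np.ndarray:
    arr = np.asarray(img)
    if arr.ndim == 2:
        return arr.astype(np.float32)
    if arr.ndim == 3 and arr.shape[2] in (3, 4):
        return (arr[:, :, :3].astype(np.float64) @ _LUMA).astype(np.float32)
    raise SequenceError(f"unsupported image layout in {path}: shape {arr.shape}")


def load_sequence(
    path: str | Path,
    frame_interval_us: float | None = None,
    pixel_pitch_mm: float | None = None,
) -> FrameSequence:
    """Load a FrameSequence from an image directory or an AVI file.

    Directory frames are ordered by :func:`normalize_and_sort_paths`; video
    frames keep container order. Colour inputs are converted to luminance.
    Calibration overrides replace the 231 us / 0.15 mm defaults.
    """
    path = Path(path)
    interval = DEFAULT_FRAME_INTERVAL_US if frame_interval_us is None else frame_interval_us

    if path.is_dir():
        names = [p.name for p in path.iterdir() if p.suffix.lower() in IMAGE_EXTENSIONS]
        if not names:
            raise SequenceError(f"no input files in {path}")
        ordered = normalize_and_sort_paths(names)
        frames = []
        shape = None
        for name in ordered:
            fp = path / name
            try:
                img = iio.imread(fp)
            except Exception as exc:  # noqa: BLE001 - report the offending file
                raise SequenceError(f"unreadable file {fp}: {exc}") from exc
            gray = _to_gray(img, str(fp))
            if shape is None:
                shape = gray.shape
            elif gray.shape != shape:
                raise SequenceError(
                    f"inconsistent frame size: {fp} is {gray.shape}, expected {shape}"
                )
            frames.append(gray)
        stack = np.stack(frames)
    elif path.suffix.lower() == ".avi":
        rgb, container_interval = _avi.read_avi(path)
        if frame_interval_us is None and container_interval > 0:
            interval = container_interval
        stack = (rgb.astype(np.float64) @ _LUMA).astype(np.float32)
    elif path.is_file():
        raise SequenceError(f"unsupported input {path}: expected a directory or .avi file")
    else:
        raise SequenceError(f"input not found: {path}")

    return FrameSequence(
        frames=stack,
        frame_interval_us=interval,
        pixel_pitch_mm=DEFAULT_PIXEL_PITCH_MM if pixel_pitch_mm is None else pixel_pitch_mm,
        source_id=str(path.resolve()),
    )


def equalize_histogram(sequence: FrameSequence) -> FrameSequence:
    """Equalize each frame independently by its cumulative intensity CDF.

    Output intensities span [0, 255]; the mapping is monotone, so pixel rank
    order within a frame is preserved. A constant frame maps to a single level.
    """
    out = np.empty_like(sequence.frames, dtype=np.float32)
    for t in range(sequence.n_frames):
        out[t] = exposure.equalize_hist(sequence.frames[t], nbins=256) * 255.0
    return replace(sequence, frames=out)


# ---------------------------------------------------------------------------
# Result cache: a single .cdk archive = NumPy zip of arrays + JSON metadata.


def save_results(arrays: dict[str, np.ndarray], meta: dict, path: str | Path) -> None:
    """Write an analysis cache: named numeric arrays plus a JSON metadata block.

    meta must identify the source sequence and calibration so that stale
    caches can be rejected on load (see :func:`load_results`).
    """
    meta = dict(meta)
    meta["cache_version"] = CACHE_VERSION
    payload = {k: np.asarray(v) for k, v in arrays.items()}
    payload["__meta__"] = np.array(json.dumps(meta, sort_keys=True))
    with open(path, "wb") as fh:
        np.savez_compressed(fh, **payload)


def load_results(path: str | Path, expected_meta: dict | None = None):
    """Load a cache written by :func:`save_results`.

    Returns ``(arrays, meta)`` or ``None`` when the cache is absent, corrupt
    or stale. Staleness is decided by comparing every key in expected_meta
    against the stored metadata; mismatches emit a warning and the cache is
    ignored so the caller recomputes.
    """
    path = Path(path)
    if not path.exists():
        return None
    try:
        with np.load(path, allow_pickle=False) as npz:
            meta = json.loads(str(npz["__meta__"]))
            arrays = {k: npz[k] for k in npz.files if k != "__meta__"}
    except Exception as exc:  # noqa: BLE001 - any corrupt cache is just ignored
        warnings.warn(f"ignoring unreadable cache {path}: {exc}", stacklevel=2)
        return None
    if meta.get("cache_version") != CACHE_VERSION:
        warnings.warn(f"ignoring cache {path}: version mismatch", stacklevel=2)
        return None
    if expected_meta:
        for key, value in expected_meta.items():
            if meta.get(key) != value:
                warnings.warn(
                    f"ignoring stale cache {path}: {key}={meta.get(key)!r} != {value!r}",
                    stacklevel=2,
                )
                return None
    return arrays, meta


def cache_path_for(source: str | Path) -> Path:
    """Default cache location: a sibling file with the .cdk extension."""
    source = Path(source)
    if source.is_dir():
        return source / f"{source.name}{CACHE_EXTENSION}"
    return source.with_suffix(CACHE_EXTENSION)
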