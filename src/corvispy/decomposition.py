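"""Decomposition of the outer-contour motion into physiological components.

The outer contour time series is split into:

* ``baseline`` — the static cornea before the air puff (mean of the first K
  frames per column);
* ``full`` — displacement relative to the baseline, positive when the
  contour moves to larger rows (inward, toward the retina);
* ``eyeball`` — the slow whole-eye response, modelled per frame as a linear
  field anchored at the mean displacement of the scleral (outermost) columns
  on each side — a rigid retraction plus tilt;
* ``cornea`` — full minus eyeball: the corneal shape change proper;
* ``vibration`` — the high-frequency (> 100 Hz by default) part of the
  corneal deformation, extracted per column by zeroing FFT bins below the
  cutoff (zero-phase, exactly invertible); ``cornea_low`` is the remainder.

Additivity is exact by construction: ``full = eyeball + cornea`` and
``cornea = cornea_low + vibration`` element-wise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .contours import ContourSet
from .io import DEFAULT_FRAME_INTERVAL_US, DEFAULT_PIXEL_PITCH_MM

__all__ = [
    "DeformationField",
    "SpectralMap",
    "FirstHarmonic",
    "compute_deformation_field",
    "split_eyeball_cornea",
    "highpass_vibration",
    "fft_amplitude_map",
    "first_harmonic",
    "median_filter_map",
    "MEDIAN_MASKS",
]

MEDIAN_MASKS = (3, 5, 9, 11, 23)


@dataclass
class DeformationField:
    """Per-frame, per-column displacement of the outer contour and its parts."""

    baseline: np.ndarray  # [col] static contour rows
    full: np.ndarray  # [t][col] displacement in px, positive = inward
    eyeball: np.ndarray | None = None
    cornea: np.ndarray | None = None
    vibration: np.ndarray | None = None
    cornea_low: np.ndarray | None = None
    scleral_margin: int | None = None
    cutoff_hz: float | None = None
    frame_interval_us: float = DEFAULT_FRAME_INTERVAL_US
    pixel_pitch_mm: float = DEFAULT_PIXEL_PITCH_MM

    @property
    def n_frames(self) -> int:
        return self.full.shape[0]

    @property
    def width(self) -> int:
        return self.full.shape[1]

    @property
    def sampling_rate_hz(self) -> float:
        return 1e6 / self.frame_interval_us

    def scleral_anchors(self) -> tuple[np.ndarray, np.ndarray]:
        """Per-frame mean displacement over the left / right scleral margins."""
        if self.scleral_margin is None:
            raise ValueError("eyeball component not computed yet")
        m = self.scleral_margin
        return self.full[:, :m].mean(axis=1), self.full[:, -m:].mean(axis=1)


@dataclass
class SpectralMap:
    """Single-sided temporal FFT amplitude of the corneal deformation.

    amplitude[k][col] is in px on the signal scale: a bin-centred sinusoid of
    amplitude a yields amplitude a at its bin.
    """

    amplitude: np.ndarray  # [freq_bin][col]
    freqs: np.ndarray  # [freq_bin] Hz
    n_frames: int
    sampling_rate_hz: float

    @property
    def resolution_hz(self) -> float:
        return self.sampling_rate_hz / self.n_frames


@dataclass
class FirstHarmonic:
    frequency_hz: float | None
    amplitude_px: float
    column: int | None
    resolution_hz: float


def compute_deformation_field(
    contours: ContourSet,
    baseline_frames: int = 10,
    frame_interval_us: float = DEFAULT_FRAME_INTERVAL_US,
    pixel_pitch_mm: float = DEFAULT_PIXEL_PITCH_MM,
) -> DeformationField:
    """Baseline (pre-puff mean of the first K frames) and full displacement."""
    k = int(baseline_frames)
    if not 1 <= k < contours.n_frames:
        raise ValueError(f"baseline_frames={k} out of range [1, {contours.n_frames})")
    baseline = contours.outer[:k].mean(axis=0)
    full = contours.outer - baseline[None, :]
    return DeformationField(
        baseline=baseline,
        full=full,
        frame_interval_us=frame_interval_us,
        pixel_pitch_mm=pixel_pitch_mm,
    )


def split_eyeball_cornea(field: DeformationField, scleral_margin: int = 50) -> DeformationField:
    """Fill the eyeball and cornea components.

    The eyeball field is linear across columns each frame, anchored so its
    mean over each scleral margin equals the observed margin mean (anchors sit
    at the margin centroids). ``cornea = full - eyeball`` exactly.
    """
    m = int(scleral_margin)
    w = field.width
    if m < 1 or 2 * m >= w:
        raise ValueError(f"scleral_margin={m} too large for width {w}")
    left = field.full[:, :m].mean(axis=1)
    right = field.full[:, -m:].mean(axis=1)
    x_left = (m - 1) / 2.0
    x_right = (w - 1) - (m - 1) / 2.0
    cols = np.arange(w)
    weight = (cols - x_left) / (x_right - x_left)
    field.eyeball = left[:, None] + (right - left)[:, None] * weight[None, :]
    field.cornea = field.full - field.eyeball
    field.scleral_margin = m
    return field


def highpass_vibration(field: DeformationField, cutoff_hz: float = 100.0) -> DeformationField:
    """Extract the > cutoff_hz vibration from the corneal deformation.

    Per column, the corneal deformation spectrum has every bin below the
    cutoff (including DC) zeroed and is inverted back to the time domain;
    the result is real and zero-mean. ``cornea_low = cornea - vibration``.
    """
    if field.cornea is None:
        raise ValueError("cornea component not computed; call split_eyeball_cornea first")
    fs = field.sampling_rate_hz
    if not cutoff_hz < fs / 2.0:
        raise ValueError(f"cutoff {cutoff_hz} Hz at or above Nyquist ({fs / 2:.1f} Hz)")
    n = field.n_frames
    spectrum = np.fft.rfft(field.cornea, axis=0)
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    spectrum[freqs < cutoff_hz] = 0.0
    field.vibration = np.fft.irfft(spectrum, n=n, axis=0)
    field.cornea_low = field.cornea - field.vibration
    field.cutoff_hz = cutoff_hz
    return field


def fft_amplitude_map(field: DeformationField) -> SpectralMap:
    """Single-sided FFT amplitude of the corneal deformation, per column.

    amplitude[k] = (2/N)|X_k| for interior bins, (1/N)|X_0| for DC and, when
    N is even, (1/N)|X_{N/2}| for the Nyquist bin, so Parseval's identity
    maps cleanly onto the time-domain energy.
    """
    if field.cornea is None:
        raise ValueError("cornea component not computed; call split_eyeball_cornea first")
    n = field.n_frames
    fs = field.sampling_rate_hz
    spectrum = np.abs(np.fft.rfft(field.cornea, axis=0))
    amplitude = spectrum * (2.0 / n)
    amplitude[0] /= 2.0
    if n % 2 == 0:
        amplitude[-1] /= 2.0
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    return SpectralMap(amplitude=amplitude, freqs=freqs, n_frames=n, sampling_rate_hz=fs)


def first_harmonic(
    spectrum: SpectralMap,
    min_freq_hz: float = 100.0,
    skirt_transition_hz: float | None = 180.0,
) -> FirstHarmonic:
    """Dominant vibration line over all columns at frequencies >= min_freq_hz.

    The deformation transient (the air-puff pulse itself) has a spectral
    skirt extending past 100 Hz that can exceed a sub-pixel vibration line
    by an order of magnitude. To keep the search pointed at sustained
    oscillations rather than that skirt, bin *selection* applies a
    raised-cosine weight rising from 0 at min_freq_hz to 1 at
    min_freq_hz + skirt_transition_hz; the *reported* amplitude is the
    unweighted spectral amplitude of the selected bin, so lines above the
    transition are reported without bias. ``skirt_transition_hz=None``
    disables the weighting (plain argmax). Returns frequency None when the
    map is identically zero above the floor. The spectral resolution fs/N is
    reported alongside as the frequency uncertainty.
    """
    sel = spectrum.freqs >= min_freq_hz
    if not sel.any():
        raise ValueError(f"no FFT bins at or above {min_freq_hz} Hz")
    sub = spectrum.amplitude[sel]
    freqs = spectrum.freqs[sel]
    if skirt_transition_hz:
        phase = np.clip((freqs - min_freq_hz) / skirt_transition_hz, 0.0, 1.0)
        weight = 0.5 * (1.0 - np.cos(np.pi * phase))
    else:
        weight = np.ones_like(freqs)
    k, col = np.unravel_index(np.argmax(sub * weight[:, None]), sub.shape)
    amp = float(sub[k, col])
    if amp == 0.0 or weight[k] == 0.0:
        return FirstHarmonic(None, 0.0, None, spectrum.resolution_hz)
    return FirstHarmonic(float(freqs[k]), amp, int(col), spectrum.resolution_hz)


def median_filter_map(map2d: np.ndarray, mask: int | str | None) -> np.ndarray:
    """Square median filter over a (t, col) map with edge replication.

    mask must be one of none/3/5/9/11/23 (the artefact-suppression masks of
    the original workflow); 'none' returns an unchanged copy. Downstream
    parameters are meant to be recomputed from the filtered map.
    """
    if mask in (None, "none", "None"):
        return np.array(map2d, copy=True)
    try:
        size = int(mask)
    except (TypeError, ValueError):
        size = -1
    if size not in MEDIAN_MASKS:
        raise ValueError(
            f"mask {mask!r} not allowed; choose one of none, " + ", ".join(map(str, MEDIAN_MASKS))
        )
    return ndimage.median_filter(np.asarray(map2d, dtype=np.float64), size=size, mode="nearest")
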