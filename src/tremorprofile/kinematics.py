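"""Preprocessing of raw movement channels into 1-D movement-parameter signals.

Movement recordings arrive as multichannel time series: joint angles in
degrees, hand acceleration in m/s^2, hand angular velocity in deg/s.  Tremor
is quantified per *movement parameter*, a 1-D signal per joint or per hand
degree of freedom.  This module provides the plumbing from one to the other:
window extraction, zero-phase band-pass filtering to the 2-10 Hz tremor band,
principal-component projection onto the dominant tremor axis, and conversion
of hand acceleration to band-limited displacement.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Sequence

import numpy as np
from scipy import signal as sps

__all__ = [
    "MovementRecording",
    "AnalysisWindow",
    "AxisProjection",
    "WindowSegment",
    "extract_windows",
    "band_pass",
    "dominant_axis",
    "accel_to_displacement",
    "TREMOR_BAND",
]

#: Tremor band bounds in Hz used throughout the package.
TREMOR_BAND = (2.0, 10.0)

#: Recognised channel kinds.
CHANNEL_KINDS = (
    "joint_angle",
    "acceleration_x",
    "acceleration_y",
    "acceleration_z",
    "angular_velocity_x",
    "angular_velocity_y",
    "angular_velocity_z",
)


@dataclass
class MovementRecording:
    """A labelled multichannel movement time series.

    Parameters
    ----------
    subject_id, day_id :
        Opaque identity labels (subject and visit/date).
    instance_id :
        Task execution index within the day.
    fs :
        Sampling rate in Hz.  Must satisfy ``fs >= 20`` so that the Nyquist
        frequency covers the 2-10 Hz tremor band.
    channels :
        Ordered mapping of channel name to 1-D sample array.  All channels
        must have equal length.
    kinds :
        Mapping of channel name to channel kind (``joint_angle``,
        ``acceleration_x`` ... ``angular_velocity_z``).
    """

    subject_id: str
    day_id: str
    instance_id: int
    fs: float
    channels: Dict[str, np.ndarray]
    kinds: Dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if self.fs < 2 * TREMOR_BAND[1]:
            raise ValueError(
                f"fs={self.fs} Hz cannot resolve the {TREMOR_BAND[1]} Hz "
                "upper tremor band edge (need fs >= 20 Hz)"
            )
        lengths = {name: len(np.asarray(x)) for name, x in self.channels.items()}
        if len(set(lengths.values())) > 1:
            raise ValueError(f"channels differ in length: {lengths}")
        self.channels = {
            name: np.asarray(x, dtype=float) for name, x in self.channels.items()
        }
        for name, kind in self.kinds.items():
            if kind not in CHANNEL_KINDS:
                raise ValueError(f"unknown channel kind {kind!r} for {name!r}")

    @property
    def n_samples(self) -> int:
        if not self.channels:
            return 0
        return len(next(iter(self.channels.values())))

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs


@dataclass(frozen=True)
class AnalysisWindow:
    """A manually annotated analysis window, in seconds within a recording."""

    start_s: float
    end_s: float
    label: str = ""

    def __post_init__(self) -> None:
        if not (0 <= self.start_s < self.end_s):
            raise ValueError(
                f"invalid window [{self.start_s}, {self.end_s}] ({self.label!r}): "
                "need 0 <= start < end"
            )

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s


@dataclass
class WindowSegment:
    """One analysis window's worth of every channel of a recording."""

    window: AnalysisWindow
    fs: float
    channels: Dict[str, np.ndarray]

    @property
    def duration_s(self) -> float:
        return self.window.duration_s


@dataclass
class AxisProjection:
    """A 3-D signal projected onto its dominant (first principal) tremor axis."""

    axis: np.ndarray
    series: np.ndarray
    variance_fraction: float

    def __post_init__(self) -> None:
        self.axis = np.asarray(self.axis, dtype=float)
        if abs(np.linalg.norm(self.axis) - 1.0) > 1e-9:
            raise ValueError("axis must have unit norm")
        if not (0.0 <= self.variance_fraction <= 1.0 + 1e-12):
            raise ValueError("variance_fraction must lie in [0, 1]")


def extract_windows(
    recording: MovementRecording, annotations: Sequence[AnalysisWindow]
) -> List[WindowSegment]:
    """Slice every channel of *recording* at each annotated window.

    Window times are mapped to samples half-open, ``[round(start*fs),
    round(end*fs))``.  Windows extending beyond the recording raise
    ``ValueError`` naming the offending window; an empty annotation list
    yields an empty result.
    """
    segments: List[WindowSegment] = []
    duration = recording.duration_s
    for window in annotations:
        if window.end_s > duration + 0.5 / recording.fs:
            raise ValueError(
                f"window [{window.start_s}, {window.end_s}] ({window.label!r}) "
                f"extends beyond the {duration:.3f} s recording"
            )
        i0 = int(round(window.start_s * recording.fs))
        i1 = int(round(window.end_s * recording.fs))
        segments.append(
            WindowSegment(
                window=window,
                fs=recording.fs,
                channels={name: x[i0:i1].copy() for name, x in recording.channels.items()},
            )
        )
    return segments


def _band_sos(fs: float, lo: float, hi: float) -> np.ndarray:
    # 4th-order Butterworth per pass; forward-backward application doubles
    # the effective attenuation, meeting >=20 dB at lo/2 and hi+(hi-lo)/2.
    return sps.butter(4, [lo, hi], btype="bandpass", fs=fs, output="sos")


def band_pass(
    series: np.ndarray, fs: float, lo: float = TREMOR_BAND[0], hi: float = TREMOR_BAND[1]
) -> np.ndarray:
    """Zero-phase band-pass of a 1-D signal to [lo, hi] Hz.

    Uses a forward-backward (zero-phase) 4th-order Butterworth filter, so
    short segments suffer no phase distortion.  Raises on segments too short
    for the filter's edge padding.
    """
    if not (0 < lo < hi < fs / 2):
        raise ValueError(f"need 0 < lo < hi < fs/2, got lo={lo}, hi={hi}, fs={fs}")
    x = np.asarray(series, dtype=float)
    sos = _band_sos(fs, lo, hi)
    padlen = 3 * (2 * sos.shape[0] + 1)
    if x.shape[-1] <= padlen:
        raise ValueError(
            f"segment too short to filter ({x.shape[-1]} samples, need > {padlen})"
        )
    return sps.sosfiltfilt(sos, x, axis=-1)


def dominant_axis(signal3d: np.ndarray, fs: float) -> AxisProjection:
    """Project a 3-D signal onto its dominant tremor axis.

    Each axis is band-passed to 2-10 Hz, the first principal axis of the
    resulting 3 x n cloud is found by eigendecomposition of the covariance,
    and the band-passed signal is projected onto it.  The axis sign is fixed
    so that its first nonzero component is positive, making outputs
    reproducible (PCA sign is otherwise arbitrary).
    """
    x = np.asarray(signal3d, dtype=float)
    if x.ndim != 2 or x.shape[0] != 3:
        raise ValueError(f"expected a 3 x n array, got shape {x.shape}")
    if x.shape[1] < 3:
        raise ValueError("need at least 3 samples")
    banded = band_pass(x, fs)
    banded = banded - banded.mean(axis=1, keepdims=True)
    cov = banded @ banded.T / banded.shape[1]
    if not np.any(cov):
        raise ValueError("no variance in band")
    eigvals, eigvecs = np.linalg.eigh(cov)
    order = np.argsort(eigvals)[::-1]
    eigvals = eigvals[order]
    axis = eigvecs[:, order[0]]
    nz = np.flatnonzero(np.abs(axis) > 1e-12)
    if nz.size and axis[nz[0]] < 0:
        axis = -axis
    total = eigvals.sum()
    frac = float(eigvals[0] / total) if total > 0 else 0.0
    return AxisProjection(
        axis=axis, series=axis @ banded, variance_fraction=min(frac, 1.0)
    )


def accel_to_displacement(accel3d: np.ndarray, fs: float) -> np.ndarray:
    """Convert triaxial acceleration (m/s^2) to band-limited displacement (mm).

    Double integration is performed in the frequency domain — division of the
    Fourier transform by ``(i 2 pi f)^2`` restricted to the 2-10 Hz band —
    which sidesteps the drift accumulation of time-domain integration.  For a
    sinusoidal acceleration of amplitude ``a`` at frequency ``f`` the output
    displacement amplitude is ``a / (2 pi f)^2`` (reported in millimetres).
    """
    if fs <= 20:
        raise ValueError(f"fs={fs} Hz cannot resolve the 2-10 Hz band (need > 20 Hz)")
    x = np.atleast_2d(np.asarray(accel3d, dtype=float))
    n = x.shape[-1]
    if n / fs < 1.5:
        raise ValueError("need at least 1.5 s of acceleration data")
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    spectrum = np.fft.rfft(x, axis=-1)
    in_band = (freqs >= TREMOR_BAND[0]) & (freqs <= TREMOR_BAND[1])
    transfer = np.zeros_like(freqs)
    transfer[in_band] = 1.0 / (2.0 * np.pi * freqs[in_band]) ** 2
    displacement_m = np.fft.irfft(-spectrum * transfer, n=n, axis=-1)
    # -1/(2 pi f)^2 is (1/(i 2 pi f))^2: each integration divides by i*2*pi*f.
    out = displacement_m * 1000.0
    return out if np.asarray(accel3d).ndim > 1 else out[0]
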