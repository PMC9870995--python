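"""Preprocessing: referencing, downsampling, channel interpolation,
epoch selection and band-pass filtering.

Pipeline order is fixed: average reference -> downsample -> (interpolation
when needed) -> epoch selection -> per-band filtering.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
from numpy.polynomial import legendre
from scipy import signal as sps

__all__ = [
    "Recording", "EpochSet", "BandDefinition", "CANONICAL_BANDS",
    "PreprocessError", "SubjectExclusionError",
    "average_reference", "downsample", "interpolate_channels",
    "select_epochs", "bandpass",
    "MAX_INTERPOLATED_CHANNELS", "DEFAULT_AMPLITUDE_LIMIT_UV",
]

MAX_INTERPOLATED_CHANNELS = 6
DEFAULT_AMPLITUDE_LIMIT_UV = 100.0


class PreprocessError(ValueError):
    """Invalid input to a preprocessing operation."""


class SubjectExclusionError(PreprocessError):
    """The recording cannot be salvaged and the subject must be dropped."""


@dataclass
class Recording:
    """Channel-labelled multichannel signal in microvolts.

    ``signals`` is (n_channels, n_samples); ``positions`` are optional
    unit-sphere coordinates used by spherical-spline interpolation.
    ``reference`` is ``"raw"`` or ``"average"``.
    """

    signals: np.ndarray
    sample_rate: float
    channel_labels: list[str]
    positions: np.ndarray | None = None
    reference: str = "raw"

    def __post_init__(self) -> None:
        self.signals = np.asarray(self.signals, dtype=float)
        if self.signals.ndim != 2:
            raise PreprocessError("signals must be 2-D (channels x samples)")
        if len(self.channel_labels) != self.n_channels:
            raise PreprocessError("one label per channel required")
        if len(set(self.channel_labels)) != len(self.channel_labels):
            raise PreprocessError("channel labels must be unique")
        if self.sample_rate <= 0:
            raise PreprocessError("sample_rate must be positive")
        if self.positions is not None:
            self.positions = np.asarray(self.positions, dtype=float)
            norms = np.linalg.norm(self.positions, axis=1)
            if not np.allclose(norms, 1.0, atol=1e-6):
                self.positions = self.positions / norms[:, None]

    @property
    def n_channels(self) -> int:
        return self.signals.shape[0]

    @property
    def n_samples(self) -> int:
        return self.signals.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.sample_rate


@dataclass
class BandDefinition:
    name: str
    low: float
    high: float

    def __post_init__(self) -> None:
        if not self.low < self.high:
            raise PreprocessError(f"band {self.name}: low must be < high")


#: Canonical analysis bands (half-open [low, high) in spectral binning).
CANONICAL_BANDS: tuple[BandDefinition, ...] = (
    BandDefinition("delta", 0.5, 4.0),
    BandDefinition("theta", 4.0, 8.0),
    BandDefinition("alpha", 8.0, 13.0),
    BandDefinition("beta", 13.0, 20.0),
)


@dataclass
class EpochSet:
    """Fixed-length artifact-free segments, optionally band-filtered."""

    epochs: list[np.ndarray]
    epoch_length: float
    sample_rate: float
    band: BandDefinition | None = None
    channel_labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        want = int(round(self.epoch_length * self.sample_rate))
        for k, ep in enumerate(self.epochs):
            if ep.shape[-1] != want:
                raise PreprocessError(
                    f"epoch {k} has {ep.shape[-1]} samples, expected {want}")

    @property
    def n_epochs(self) -> int:
        return len(self.epochs)

    @property
    def n_channels(self) -> int:
        return self.epochs[0].shape[0]


def average_reference(rec: Recording) -> Recording:
    """Re-reference to the common average (zero mean across channels)."""
    if rec.n_channels < 2:
        raise PreprocessError("average reference needs at least 2 channels")
    out = rec.signals - rec.signals.mean(axis=0, keepdims=True)
    return dataclasses.replace(rec, signals=out, reference="average")


def downsample(rec: Recording, target_rate: float) -> Recording:
    """Decimate to ``target_rate`` with polyphase anti-alias filtering.

    The source rate must be an integer multiple of the target rate
    (2048 -> 1024 in the standard pipeline).
    """
    q = rec.sample_rate / target_rate
    if abs(q - round(q)) > 1e-9 or q < 1:
        raise PreprocessError(
            f"sample rate {rec.sample_rate} is not an integer multiple of "
            f"target {target_rate}")
    q = int(round(q))
    if q == 1:
        return dataclasses.replace(rec)
    out = sps.resample_poly(rec.signals, up=1, down=q, axis=1)
    return dataclasses.replace(rec, signals=out, sample_rate=float(target_rate))


def _spline_gm(cosang: np.ndarray, order: int = 4, n_terms: int = 50) -> np.ndarray:
    # Legendre expansion g(x) = 1/4pi * sum (2n+1) / (n(n+1))^order * Pn(x)
    n = np.arange(1, n_terms + 1)
    coef = np.zeros(n_terms + 1)
    coef[1:] = (2 * n + 1) / (n * (n + 1.0)) ** order
    return legendre.legval(cosang, coef) / (4 * np.pi)


def interpolate_channels(rec: Recording, bad: list[str],
                         max_bad: int = MAX_INTERPOLATED_CHANNELS,
                         order: int = 4, reg: float = 1e-5) -> Recording:
    """Replace ``bad`` channels with spherical-spline estimates.

    Uses the regularized spline on the unit sphere (order 4).  More than
    ``max_bad`` bad channels is a subject-exclusion condition.
    """
    if not bad:
        return dataclasses.replace(rec)
    unknown = set(bad) - set(rec.channel_labels)
    if unknown:
        raise PreprocessError(f"unknown channels: {sorted(unknown)}")
    if len(bad) > max_bad:
        raise SubjectExclusionError(
            f"{len(bad)} bad channels exceed the maximum of {max_bad}; "
            "subject must be excluded")
    if rec.positions is None:
        raise PreprocessError("channel positions required for interpolation")

    idx = {lab: i for i, lab in enumerate(rec.channel_labels)}
    bad_i = np.array([idx[b] for b in bad])
    good_i = np.array([i for i in range(rec.n_channels) if i not in set(bad_i)])

    pg = rec.positions[good_i]
    pb = rec.positions[bad_i]
    g_gg = _spline_gm(pg @ pg.T, order)
    g_bg = _spline_gm(pb @ pg.T, order)
    m = len(good_i)
    lhs = np.zeros((m + 1, m + 1))
    lhs[:m, :m] = g_gg + reg * np.eye(m)
    lhs[:m, m] = 1.0
    lhs[m, :m] = 1.0
    rhs = np.zeros((m + 1, rec.n_samples))
    rhs[:m] = rec.signals[good_i]
    sol = np.linalg.solve(lhs, rhs)
    est = g_bg @ sol[:m] + sol[m]

    out = rec.signals.copy()
    out[bad_i] = est
    return dataclasses.replace(rec, signals=out)


def select_epochs(rec: Recording, epoch_length: float = 4.0,
                  n_epochs: int = 15,
                  amplitude_limit: float = DEFAULT_AMPLITUDE_LIMIT_UV) -> EpochSet:
    """Select the first ``n_epochs`` clean non-overlapping epochs.

    Windows advance on a fixed grid from the start of the recording; a
    window whose peak absolute amplitude exceeds ``amplitude_limit`` on any
    channel is skipped whole, never truncated.
    """
    L = int(round(epoch_length * rec.sample_rate))
    epochs: list[np.ndarray] = []
    n_windows = rec.n_samples // L
    for k in range(n_windows):
        if len(epochs) == n_epochs:
            break
        seg = rec.signals[:, k * L:(k + 1) * L]
        if np.max(np.abs(seg)) <= amplitude_limit:
            epochs.append(seg.copy())
    if len(epochs) < n_epochs:
        raise PreprocessError(
            f"{len(epochs)} clean epochs found, {n_epochs} requested")
    return EpochSet(epochs, epoch_length, rec.sample_rate,
                    channel_labels=list(rec.channel_labels))


def bandpass(eps: EpochSet, band: BandDefinition, order: int = 4) -> EpochSet:
    """Zero-phase Butterworth band-pass (forward-backward, no group delay).

    An order-``order`` design applied with ``sosfiltfilt`` doubles the
    effective attenuation; the passband is flat (maximally flat magnitude).
    """
    nyq = eps.sample_rate / 2
    if band.high >= nyq:
        raise PreprocessError(
            f"band {band.name} upper edge {band.high} Hz >= Nyquist {nyq} Hz")
    sos = sps.butter(order, [band.low, band.high], btype="band",
                     fs=eps.sample_rate, output="sos")
    filtered = [sps.sosfiltfilt(sos, ep, axis=1) for ep in eps.epochs]
    return EpochSet(filtered, eps.epoch_length, eps.sample_rate, band=band,
                    channel_labels=list(eps.channel_labels))
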