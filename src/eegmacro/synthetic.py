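"""Synthetic multichannel EEG-like recordings and cohorts with known structure.

Recordings are built from band-limited narrowband processes plus 1/f
background noise, with controllable pairwise phase coupling (shared phase
series with a fixed added lag, blended by a coupling strength), envelope
coupling (correlated log-envelopes on independent carriers) and an
instantaneous linear mixing step standing in for volume conduction.

Cohorts are feature tables over the closed 60-name vocabulary with planted
group shifts, plus clinical tables with PANSS trajectories; the positive
subscale change follows a configurable linear link over (z-scored)
features.  All outputs are bit-reproducible under a fixed seed.

Spectral defaults (band amplitudes, noise level) are conventions of this
module, not literature values.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as sps

from .features import FEATURE_NAMES
from .montage import BIOSEMI64_LABELS, standard_positions
from .preprocess import CANONICAL_BANDS, Recording

__all__ = ["SignalSpec", "CohortSpec", "PanssModel",
           "generate_recording", "generate_cohort", "SyntheticError"]

_BAND_EDGES = {b.name: (b.low, b.high) for b in CANONICAL_BANDS}

# PANSS subscale score ranges (7/7/16 items, 1-7 points each).
_PANSS_RANGE = {"pos": (7, 49), "neg": (7, 49), "gen": (16, 112)}


class SyntheticError(ValueError):
    pass


@dataclass
class SignalSpec:
    """Parameters of one synthetic recording.

    ``phase_coupling`` entries are (chan_i, chan_j, band, strength, lag_rad)
    with strength in [0, 1]; ``envelope_coupling`` entries are
    (chan_i, chan_j, band, envelope_correlation in [-1, 1]).  ``mixing`` is
    an instantaneous channel x channel weight matrix applied last (identity
    = no volume conduction).
    """

    duration: float
    n_channels: int = 64
    sample_rate: float = 2048.0
    band_amplitudes: dict[str, float] = field(
        default_factory=lambda: {"delta": 8.0, "theta": 6.0,
                                 "alpha": 10.0, "beta": 4.0})
    noise_exponent: float = 1.0
    noise_amplitude: float = 5.0
    phase_coupling: list[tuple] = field(default_factory=list)
    envelope_coupling: list[tuple] = field(default_factory=list)
    mixing: np.ndarray | None = None
    seed: int = 0

    def validate(self) -> None:
        if self.duration <= 0:
            raise SyntheticError("duration must be positive")
        if self.sample_rate <= 0:
            raise SyntheticError("sample_rate must be positive")
        if self.n_channels < 1:
            raise SyntheticError("n_channels must be positive")
        n_samp = self.duration * self.sample_rate
        if abs(n_samp - round(n_samp)) > 1e-9:
            raise SyntheticError(
                "duration x sample_rate must be an integer sample count")
        for i, j, band, strength, _lag in self.phase_coupling:
            if band not in _BAND_EDGES:
                raise SyntheticError(f"unknown band {band!r} in phase_coupling")
            if not 0 <= strength <= 1:
                raise SyntheticError("coupling_strength must lie in [0, 1]")
            self._check_chan(i, "phase_coupling")
            self._check_chan(j, "phase_coupling")
        for i, j, band, rho in self.envelope_coupling:
            if band not in _BAND_EDGES:
                raise SyntheticError(f"unknown band {band!r} in envelope_coupling")
            if not -1 <= rho <= 1:
                raise SyntheticError("envelope correlation must lie in [-1, 1]")
            self._check_chan(i, "envelope_coupling")
            self._check_chan(j, "envelope_coupling")
        if self.mixing is not None:
            m = np.asarray(self.mixing, dtype=float)
            if m.shape != (self.n_channels, self.n_channels):
                raise SyntheticError("mixing must be n_channels x n_channels")
            if not np.all(np.isfinite(m)):
                raise SyntheticError("mixing weights must be finite")

    def _check_chan(self, c: int, where: str) -> None:
        if not 0 <= c < self.n_channels:
            raise SyntheticError(f"channel {c} out of range in {where}")


def _narrowband(rng: np.random.Generator, n: int, fs: float,
                band: str) -> np.ndarray:
    """Unit-RMS band-limited Gaussian noise."""
    low, high = _BAND_EDGES[band]
    sos = sps.butter(4, [low, high], btype="band", fs=fs, output="sos")
    x = sps.sosfiltfilt(sos, rng.standard_normal(n))
    return x / x.std()


def _phase_shift(x: np.ndarray, lag: float) -> np.ndarray:
    """Shift the instantaneous phase of a narrowband signal by ``lag``."""
    return (sps.hilbert(x) * np.exp(-1j * lag)).real


def _one_over_f(rng: np.random.Generator, n: int, exponent: float) -> np.ndarray:
    """Unit-RMS noise with |X(f)| ~ f^(-exponent/2) (power slope -exponent)."""
    spec = np.fft.rfft(rng.standard_normal(n))
    f = np.fft.rfftfreq(n, d=1.0)
    scale = np.zeros_like(f)
    scale[1:] = f[1:] ** (-exponent / 2)
    x = np.fft.irfft(spec * scale, n)
    return x / x.std()


def _slow_envelope(z: np.ndarray, fs: float, cutoff: float = 1.0) -> np.ndarray:
    """Smooth positive envelope from a Gaussian series (log-normal).

    Low-pass by FFT masking: linear, transient-free, and applied
    identically to correlated inputs so their correlation is preserved.
    """
    spec = np.fft.rfft(z)
    f = np.fft.rfftfreq(z.size, d=1.0 / fs)
    spec[f > cutoff] = 0
    s = np.fft.irfft(spec, z.size)
    s = s / s.std()
    return np.exp(0.5 * s)


def generate_recording(spec: SignalSpec) -> Recording:
    """Deterministic synthetic recording for a validated ``SignalSpec``."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n = int(round(spec.duration * spec.sample_rate))
    fs = spec.sample_rate
    nc = spec.n_channels
    signals = np.zeros((nc, n))

    # per-band independent oscillations, possibly overridden below
    components: dict[str, np.ndarray] = {}
    for band, amp in spec.band_amplitudes.items():
        if band not in _BAND_EDGES:
            raise SyntheticError(f"unknown band {band!r} in band_amplitudes")
        comp = np.stack([_narrowband(rng, n, fs, band) for _ in range(nc)])
        components[band] = comp * amp

    for i, j, band, strength, lag in spec.phase_coupling:
        amp = spec.band_amplitudes.get(band, 1.0)
        shared = _narrowband(rng, n, fs, band)
        indep = _narrowband(rng, n, fs, band)
        comp = components.setdefault(band, np.zeros((nc, n)))
        comp[i] = amp * shared
        comp[j] = amp * (strength * _phase_shift(shared, lag)
                         + np.sqrt(1 - strength ** 2) * indep)

    for i, j, band, rho in spec.envelope_coupling:
        amp = spec.band_amplitudes.get(band, 1.0)
        z_i = rng.standard_normal(n)
        z_j = rho * z_i + np.sqrt(1 - rho ** 2) * rng.standard_normal(n)
        comp = components.setdefault(band, np.zeros((nc, n)))
        for chan, z in ((i, z_i), (j, z_j)):
            carrier = _narrowband(rng, n, fs, band)
            carrier = np.cos(np.angle(sps.hilbert(carrier)))
            comp[chan] = amp * _slow_envelope(z, fs) * carrier

    for comp in components.values():
        signals += comp
    if spec.noise_amplitude > 0:
        noise = np.stack([_one_over_f(rng, n, spec.noise_exponent)
                          for _ in range(nc)])
        signals += spec.noise_amplitude * noise

    if spec.mixing is not None:
        signals = np.asarray(spec.mixing, dtype=float) @ signals

    if nc == len(BIOSEMI64_LABELS):
        labels = list(BIOSEMI64_LABELS)
        positions = standard_positions(labels)
    else:
        labels = [f"CH{k:03d}" for k in range(nc)]
        positions = None
    return Recording(signals=signals, sample_rate=fs, channel_labels=labels,
                     positions=positions)


@dataclass
class PanssModel:
    """Baseline distributions and change model for PANSS trajectories.

    ``coef`` is a linear link over z-scored features generating the change
    in the positive subscale on top of ``delta_means['pos']``; the other
    subscales change by their mean plus noise.  Defaults follow typical
    first-episode cohort magnitudes.
    """

    baseline: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {"pos": (18.57, 4.38), "neg": (18.47, 6.99),
                                 "gen": (37.50, 9.01)})
    delta_means: dict[str, float] = field(
        default_factory=lambda: {"pos": -5.18, "neg": -1.25, "gen": -7.44})
    coef: dict[str, float] = field(default_factory=dict)
    noise_sd: float = 3.0

    def validate(self) -> None:
        if self.noise_sd <= 0:
            raise SyntheticError("noise SD must be positive")
        unknown = set(self.coef) - set(FEATURE_NAMES)
        if unknown:
            raise SyntheticError(
                f"unknown feature(s) in panss coef: {sorted(unknown)}; "
                f"valid names: {list(FEATURE_NAMES)}")


@dataclass
class CohortSpec:
    """Cohort of synthetic feature vectors plus clinical outcomes.

    ``effect_map`` maps feature name -> (patient shift, control median);
    unmapped features share a common base distribution in both groups.
    ``n_followup`` patients (default: all) receive follow-up PANSS scores.
    """

    n_patients: int
    n_controls: int
    effect_map: dict[str, tuple[float, float]] = field(default_factory=dict)
    panss_model: PanssModel = field(default_factory=PanssModel)
    n_followup: int | None = None
    feature_sd: float = 0.05
    seed: int = 0

    def validate(self) -> None:
        if self.n_patients < 2 or self.n_controls < 2:
            raise SyntheticError("need at least 2 subjects per group")
        unknown = set(self.effect_map) - set(FEATURE_NAMES)
        if unknown:
            raise SyntheticError(
                f"unknown feature(s) in effect_map: {sorted(unknown)}; "
                f"valid names: {list(FEATURE_NAMES)}")
        self.panss_model.validate()


# baseline centers per feature kind; plausible magnitudes, not data
_BASE_CENTER = {"relpower": {"delta": 0.30, "theta": 0.18,
                             "alpha": 0.35, "beta": 0.17},
                "pli": 0.11, "aecc": 0.55,
                "kmax": 0.15, "leaf": 0.50, "diameter": 0.30,
                "bcmax": 0.60, "ecc": 0.155, "th": 0.40}


def _base_center(name: str) -> float:
    parts = name.split("_")
    if parts[1] == "relpower":
        return _BASE_CENTER["relpower"][parts[0]]
    if parts[1] == "mst":
        return _BASE_CENTER[parts[2]]
    return _BASE_CENTER[parts[1]]


def _round_clip(x: np.ndarray, subscale: str) -> np.ndarray:
    lo, hi = _PANSS_RANGE[subscale]
    return np.clip(np.round(x), lo, hi)


def generate_cohort(spec: CohortSpec) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Feature table (one row per subject, 60 columns) and clinical table.

    The clinical table has columns ``subject_id``, ``group`` and
    ``panss_{total,pos,neg,gen}_{baseline,followup}``; follow-up values are
    NaN for controls and for patients without follow-up.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n_p, n_c = spec.n_patients, spec.n_controls
    ids = ([f"P{k + 1:03d}" for k in range(n_p)]
           + [f"C{k + 1:03d}" for k in range(n_c)])
    groups = np.array(["patient"] * n_p + ["control"] * n_c)

    table = pd.DataFrame(index=pd.Index(ids, name="subject_id"),
                         columns=list(FEATURE_NAMES), dtype=float)
    for name in FEATURE_NAMES:
        if name in spec.effect_map:
            shift, control_median = spec.effect_map[name]
            center = np.where(groups == "patient",
                              control_median + shift, control_median)
        else:
            center = np.full(n_p + n_c, _base_center(name))
        table[name] = np.clip(
            center + spec.feature_sd * rng.standard_normal(n_p + n_c), 0, 1)

    pm = spec.panss_model
    clin = pd.DataFrame({"subject_id": ids, "group": groups})
    base = {}
    for sub, (mu, sd) in pm.baseline.items():
        vals = np.full(n_p + n_c, np.nan)
        vals[:n_p] = _round_clip(mu + sd * rng.standard_normal(n_p), sub)
        base[sub] = vals

    # linear link over z-scored patient features drives the positive change
    link = np.zeros(n_p)
    if pm.coef:
        feats = table.iloc[:n_p][list(pm.coef)].to_numpy()
        sd = feats.std(axis=0)
        sd[sd == 0] = 1.0
        z = (feats - feats.mean(axis=0)) / sd
        link = z @ np.array(list(pm.coef.values()))
    deltas = {"pos": pm.delta_means["pos"] + link
              + pm.noise_sd * rng.standard_normal(n_p)}
    for sub in ("neg", "gen"):
        deltas[sub] = (pm.delta_means[sub]
                       + pm.noise_sd * rng.standard_normal(n_p))

    n_fu = n_p if spec.n_followup is None else min(spec.n_followup, n_p)
    followup_mask = np.zeros(n_p + n_c, dtype=bool)
    followup_mask[rng.choice(n_p, size=n_fu, replace=False)] = True

    for sub in ("pos", "neg", "gen"):
        clin[f"panss_{sub}_baseline"] = base[sub]
        fu = np.full(n_p + n_c, np.nan)
        fu[:n_p] = _round_clip(base[sub][:n_p] + deltas[sub], sub)
        fu[~followup_mask] = np.nan
        clin[f"panss_{sub}_followup"] = fu
    clin["panss_total_baseline"] = (clin["panss_pos_baseline"]
                                    + clin["panss_neg_baseline"]
                                    + clin["panss_gen_baseline"])
    clin["panss_total_followup"] = (clin["panss_pos_followup"]
                                    + clin["panss_neg_followup"]
                                    + clin["panss_gen_followup"])
    return table, clin
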