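"""FFT power spectra and relative band power.

Spectra use rectangular-window periodograms so Parseval consistency with
the time-domain variance is exact; 4 s epochs give 0.25 Hz bins.  Relative
power divides each band's power by the summed power of the four canonical
bands only.  Band edges shared by adjacent bands are assigned to the lower
band via half-open intervals [low, high).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .preprocess import CANONICAL_BANDS, BandDefinition, EpochSet

__all__ = ["PowerSpectrum", "power_spectrum", "relative_band_power", "SpectralError"]


class SpectralError(ValueError):
    pass


@dataclass
class PowerSpectrum:
    """Per-bin absolute power averaged over epochs and channels.

    ``bin_low`` holds the lower edge of each bin; bin width is
    1/epoch_length.  ``per_channel`` is (n_channels, n_bins), averaged over
    epochs only.
    """

    bin_low: np.ndarray
    power: np.ndarray
    bin_width: float
    per_channel: np.ndarray | None = None

    @property
    def bin_high(self) -> np.ndarray:
        return self.bin_low + self.bin_width


def power_spectrum(eps: EpochSet, window: str = "boxcar") -> PowerSpectrum:
    """Average periodogram of a broadband (unfiltered) epoch set."""
    if eps.n_epochs == 0:
        raise SpectralError("empty EpochSet")
    if eps.band is not None:
        raise SpectralError("power_spectrum expects a broadband EpochSet")
    data = np.stack(eps.epochs)                       # (epochs, channels, t)
    freqs, pxx = sps.periodogram(data, fs=eps.sample_rate, window=window,
                                 scaling="spectrum", axis=-1)
    per_channel = pxx.mean(axis=0)
    return PowerSpectrum(bin_low=freqs,
                         power=per_channel.mean(axis=0),
                         bin_width=1.0 / eps.epoch_length,
                         per_channel=per_channel)


def band_mask(spec: PowerSpectrum, band: BandDefinition) -> np.ndarray:
    """Bins whose lower edge falls in [band.low, band.high)."""
    return (spec.bin_low >= band.low - 1e-9) & (spec.bin_low < band.high - 1e-9)


def relative_band_power(spec: PowerSpectrum,
                        bands: tuple[BandDefinition, ...] = CANONICAL_BANDS,
                        ) -> dict[str, float]:
    """Band power fractions normalized by the four-band total."""
    absolute = {b.name: float(spec.power[band_mask(spec, b)].sum())
                for b in bands}
    total = sum(absolute.values())
    if total <= 0:
        raise SpectralError("zero total band power")
    return {name: p / total for name, p in absolute.items()}
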