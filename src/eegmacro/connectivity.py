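"""Phase lag index (PLI) and corrected amplitude envelope correlation (AEC-c).

Both metrics operate on band-filtered epoch sets and are designed to
resist instantaneous (zero-lag) mixing: PLI discards zero-lag phase
differences by construction, and AEC-c removes the instantaneously
collinear component of one analytic signal with respect to the other
before correlating envelopes.

Phases and envelopes come from the analytic (Hilbert) signal computed per
epoch; a margin at each epoch edge (default 1/8 of the epoch) is dropped
before averaging to suppress transform edge effects.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .preprocess import BandDefinition, EpochSet

__all__ = ["ConnectivityMatrix", "pli", "aec_c", "mean_connectivity",
           "ConnectivityError"]

EDGE_MARGIN_FRACTION = 1 / 8


class ConnectivityError(ValueError):
    pass


@dataclass
class ConnectivityMatrix:
    """Symmetric channel x channel coupling values in [0, 1].

    The diagonal is excluded from all summaries; ``metric`` is ``"pli"`` or
    ``"aecc"``.
    """

    values: np.ndarray
    metric: str
    band: BandDefinition | None
    channel_labels: list[str]

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ConnectivityError("connectivity matrix must be square")
        if not np.allclose(v, v.T, atol=1e-10):
            raise ConnectivityError("connectivity matrix must be symmetric")
        self.values = v

    @property
    def n(self) -> int:
        return self.values.shape[0]


def _analytic_cropped(epoch: np.ndarray) -> np.ndarray:
    """Analytic signal with the edge margin removed."""
    a = sps.hilbert(epoch, axis=1)
    margin = int(epoch.shape[1] * EDGE_MARGIN_FRACTION)
    return a[:, margin:epoch.shape[1] - margin]


def _check_variance(eps: EpochSet) -> None:
    for k, ep in enumerate(eps.epochs):
        flat = np.where(ep.std(axis=1) == 0)[0]
        if flat.size:
            name = (eps.channel_labels[flat[0]] if eps.channel_labels
                    else str(flat[0]))
            raise ConnectivityError(
                f"channel {name} is constant in epoch {k}")


def pli(eps: EpochSet) -> ConnectivityMatrix:
    """Phase lag index per channel pair, averaged over epochs.

    Per epoch, PLI(i, j) = |mean_t sign(sin(phi_i(t) - phi_j(t)))| with
    instantaneous phases from the analytic signal.  Zero-lag differences
    contribute 0, so identical signals score 0 and a constant nonzero lag
    scores 1.
    """
    if eps.band is None:
        raise ConnectivityError("pli requires a band-filtered EpochSet")
    _check_variance(eps)
    n = eps.n_channels
    acc = np.zeros((n, n))
    for ep in eps.epochs:
        a = _analytic_cropped(ep)
        z = a / np.abs(a)                         # unit-modulus phase factors
        mat = np.zeros((n, n))
        for i in range(n - 1):
            # sign(sin(phi_i - phi_j)) == sign(Im(z_i * conj(z_j)));
            # |Im| below 1e-12 (|z| = 1) is rounding noise from a genuinely
            # zero-lag pair and must count as zero, not as +/-1
            im = (z[i] * z[i + 1:].conj()).imag
            im[np.abs(im) < 1e-12] = 0.0
            s = np.sign(im)
            mat[i, i + 1:] = np.abs(s.mean(axis=1))
        acc += mat + mat.T
    return ConnectivityMatrix(acc / eps.n_epochs, "pli", eps.band,
                              list(eps.channel_labels))


def aec_c(eps: EpochSet, degenerate_tol: float = 1e-6) -> ConnectivityMatrix:
    """Orthogonalized amplitude envelope correlation, rescaled to [0, 1].

    For each ordered pair (seed i, target j) the target's analytic signal
    is orthogonalized sample-wise with respect to the seed's, the Pearson
    correlation between the seed envelope and the orthogonalized target
    envelope is taken, the two directions are averaged, and the result is
    mapped through (r + 1) / 2 so 0.5 means no coupling.

    Exactly collinear pairs leave a zero residual; their value is reported
    as 0.5 with a warning.
    """
    if eps.band is None:
        raise ConnectivityError("aec_c requires a band-filtered EpochSet")
    _check_variance(eps)
    n = eps.n_channels
    acc = np.zeros((n, n))
    degenerate = False
    for ep in eps.epochs:
        a = _analytic_cropped(ep)
        env = np.abs(a)
        u = a / env                               # unit phase factors
        env_c = env - env.mean(axis=1, keepdims=True)
        env_sd = env_c.std(axis=1)
        r_dir = np.zeros((n, n))                  # r_dir[i, j]: seed i
        for i in range(n):
            # orthogonalize every channel w.r.t. seed i (Hipp-style):
            # resid_j(t) = Im(a_j(t) * conj(a_i(t)) / |a_i(t)|)
            resid_env = np.abs((a * u[i].conj()).imag)
            rc = resid_env - resid_env.mean(axis=1, keepdims=True)
            rsd = rc.std(axis=1)
            ok = rsd > degenerate_tol * env_sd
            ok[i] = False
            r = np.zeros(n)
            cov = (rc * env_c[i]).mean(axis=1)
            with np.errstate(invalid="ignore", divide="ignore"):
                r[ok] = cov[ok] / (rsd[ok] * env_sd[i])
            if not np.all(ok[np.arange(n) != i]):
                degenerate = True
            r_dir[i] = r
        r_sym = (r_dir + r_dir.T) / 2
        np.fill_diagonal(r_sym, 0.0)
        acc += (r_sym + 1) / 2
    if degenerate:
        warnings.warn("collinear channel pair: orthogonalized residual is "
                      "zero, AEC-c reported as 0.5", RuntimeWarning,
                      stacklevel=2)
    out = acc / eps.n_epochs
    np.fill_diagonal(out, 0.0)
    return ConnectivityMatrix(out, "aecc", eps.band, list(eps.channel_labels))


def mean_connectivity(cm: ConnectivityMatrix) -> float:
    """Arithmetic mean of the strict upper triangle (n(n-1)/2 pairs)."""
    iu = np.triu_indices(cm.n, k=1)
    return float(cm.values[iu].mean())
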