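"""Idealized 64-channel 10-10 montage on the unit sphere.

Positions are constructed geometrically rather than copied from a vendor
file: the vertex Cz sits at the pole, midline electrodes step along the
nasion-inion meridian in 18 degree increments, the outer 10% ring lies at a
polar angle of 72 degrees with electrodes every 18 degrees of azimuth, and
intermediate electrodes are placed at equal fractions along the great
circle joining their midline and ring row-mates.  P9/P10 and Iz sit on the
equator.  The construction reproduces the standard layout closely enough
for spherical-spline interpolation and smooth-field tests.
"""

from __future__ import annotations

import numpy as np

__all__ = ["BIOSEMI64_LABELS", "standard_positions"]

# BioSemi 64-channel cap, A1..A32 then B1..B32 in equivalent 10-10 names.
BIOSEMI64_LABELS: tuple[str, ...] = (
    "Fp1", "AF7", "AF3", "F1", "F3", "F5", "F7", "FT7",
    "FC5", "FC3", "FC1", "C1", "C3", "C5", "T7", "TP7",
    "CP5", "CP3", "CP1", "P1", "P3", "P5", "P7", "P9",
    "PO7", "PO3", "O1", "Iz", "Oz", "POz", "Pz", "CPz",
    "Fpz", "Fp2", "AF8", "AF4", "AFz", "Fz", "F2", "F4",
    "F6", "F8", "FT8", "FC6", "FC4", "FC2", "FCz", "Cz",
    "C2", "C4", "C6", "T8", "TP8", "CP6", "CP4", "CP2",
    "P2", "P4", "P6", "P8", "P10", "PO8", "PO4", "O2",
)


def _point(polar_deg: float, az_deg: float) -> np.ndarray:
    """Unit vector; polar angle from vertex, azimuth from +x (right ear),
    counter-clockwise seen from above (front = 90 deg)."""
    p = np.deg2rad(polar_deg)
    a = np.deg2rad(az_deg)
    return np.array([np.sin(p) * np.cos(a), np.sin(p) * np.sin(a), np.cos(p)])


def _slerp(u: np.ndarray, v: np.ndarray, t: float) -> np.ndarray:
    """Great-circle interpolation between unit vectors."""
    omega = np.arccos(np.clip(u @ v, -1.0, 1.0))
    if omega < 1e-12:
        return u.copy()
    w = (np.sin((1 - t) * omega) * u + np.sin(t * omega) * v) / np.sin(omega)
    return w / np.linalg.norm(w)


def _build() -> dict[str, np.ndarray]:
    pos: dict[str, np.ndarray] = {}
    # outer ring, polar 72 deg, every 18 deg of azimuth starting at Fpz (front)
    ring = ["Fpz", "Fp1", "AF7", "F7", "FT7", "T7", "TP7", "P7", "PO7", "O1",
            "Oz", "O2", "PO8", "P8", "TP8", "T8", "FT8", "F8", "AF8", "Fp2"]
    for k, name in enumerate(ring):
        pos[name] = _point(72.0, 90.0 + 18.0 * k)
    # midline
    pos["Cz"] = _point(0.0, 0.0)
    for name, polar, az in [("FCz", 18, 90), ("Fz", 36, 90), ("AFz", 54, 90),
                            ("CPz", 18, 270), ("Pz", 36, 270), ("POz", 54, 270),
                            ("Iz", 90, 270)]:
        pos[name] = _point(polar, az)
    # below-ring pair on the equator
    pos["P9"] = _point(90.0, 90.0 + 18.0 * 7)
    pos["P10"] = _point(90.0, 90.0 + 18.0 * 13)
    # intermediate rows: equal great-circle fractions midline -> ring
    rows = {
        "AF": ("AFz", "AF7", "AF8", {"3": 0.5}),
        "F": ("Fz", "F7", "F8", {"1": 0.25, "3": 0.5, "5": 0.75}),
        "FC": ("FCz", "FT7", "FT8", {"1": 0.25, "3": 0.5, "5": 0.75}),
        "C": ("Cz", "T7", "T8", {"1": 0.25, "3": 0.5, "5": 0.75}),
        "CP": ("CPz", "TP7", "TP8", {"1": 0.25, "3": 0.5, "5": 0.75}),
        "P": ("Pz", "P7", "P8", {"1": 0.25, "3": 0.5, "5": 0.75}),
        "PO": ("POz", "PO7", "PO8", {"3": 0.5}),
    }
    for row, (mid, left, right, fracs) in rows.items():
        for num, t in fracs.items():
            odd = str(int(num))               # left side: odd numbers
            even = str(int(num) + 1)          # right side: next even number
            pos[f"{row}{odd}"] = _slerp(pos[mid], pos[left], t)
            pos[f"{row}{even}"] = _slerp(pos[mid], pos[right], t)
    return pos


_POSITIONS = _build()


def standard_positions(labels=BIOSEMI64_LABELS) -> np.ndarray:
    """Return an (n, 3) array of unit-sphere positions for ``labels``.

    Raises ``KeyError`` for labels outside the idealized 10-10 set.
    """
    return np.array([_POSITIONS[lab] for lab in labels])
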