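"""Assembly of the 60-feature macroscale vector and cohort feature tables.

Per band (delta, theta, alpha, beta): relative power, mean PLI, mean
AEC-c, and the six spanning-tree topology measures on each of the two
connectivity bases — 15 features per band, 60 in total.  Names follow
``band_metric`` / ``band_mst_metric_basis`` (e.g. ``alpha_mst_th_aecc``).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import connectivity as conn
from . import mstnet, spectral
from .preprocess import (CANONICAL_BANDS, DEFAULT_AMPLITUDE_LIMIT_UV,
                         Recording, SubjectExclusionError, average_reference,
                         bandpass, downsample, interpolate_channels,
                         select_epochs)

__all__ = ["FeatureVector", "FEATURE_NAMES", "feature_names", "band_of",
           "extract_features", "build_feature_table", "FeatureError"]

BANDS = tuple(b.name for b in CANONICAL_BANDS)
_MST_SHORT = {"kmax": "kmax", "leaf_fraction": "leaf", "diameter": "diameter",
              "bc_max": "bcmax", "ecc_mean": "ecc", "tree_hierarchy": "th"}


class FeatureError(ValueError):
    pass


def feature_names() -> list[str]:
    """The closed 60-name feature vocabulary, in canonical order."""
    names = []
    for band in BANDS:
        names.append(f"{band}_relpower")
        names.append(f"{band}_pli")
        names.append(f"{band}_aecc")
        for basis in ("pli", "aecc"):
            for short in _MST_SHORT.values():
                names.append(f"{band}_mst_{short}_{basis}")
    return names


FEATURE_NAMES: tuple[str, ...] = tuple(feature_names())


def band_of(name: str) -> str:
    """Frequency-band tag of a feature name."""
    band = name.split("_", 1)[0]
    if band not in BANDS:
        raise FeatureError(f"unknown feature name: {name}")
    return band


@dataclass
class FeatureVector:
    """The 60 named macroscale features for one subject."""

    values: dict[str, float]
    provenance: dict[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = set(FEATURE_NAMES) - set(self.values)
        extra = set(self.values) - set(FEATURE_NAMES)
        if missing or extra:
            raise FeatureError(
                f"feature vector mismatch: missing {sorted(missing)}, "
                f"unexpected {sorted(extra)}")
        bad = [k for k, v in self.values.items() if not np.isfinite(v)]
        if bad:
            raise FeatureError(f"non-finite features: {bad}")

    def as_series(self) -> pd.Series:
        return pd.Series({k: self.values[k] for k in FEATURE_NAMES})


def extract_features(rec: Recording,
                     epoch_length: float = 4.0,
                     n_epochs: int = 15,
                     target_rate: float = 1024.0,
                     amplitude_limit: float = DEFAULT_AMPLITUDE_LIMIT_UV,
                     bad_channels: list[str] | None = None) -> FeatureVector:
    """Run the full pipeline on one recording and return all 60 features.

    Order: average reference -> downsample -> interpolation (if bad
    channels are flagged) -> epoch selection -> broadband spectrum and
    per-band connectivity/network analysis.  Exclusion conditions
    (too many bad channels, too few clean epochs) propagate as errors.
    """
    if rec.reference != "average":
        rec = average_reference(rec)
    if target_rate is not None and rec.sample_rate > target_rate:
        rec = downsample(rec, target_rate)
    if bad_channels:
        rec = interpolate_channels(rec, bad_channels)
    eps = select_epochs(rec, epoch_length=epoch_length, n_epochs=n_epochs,
                        amplitude_limit=amplitude_limit)

    values: dict[str, float] = {}
    spec = spectral.power_spectrum(eps)
    for band_name, frac in spectral.relative_band_power(spec).items():
        values[f"{band_name}_relpower"] = frac

    for band in CANONICAL_BANDS:
        filtered = bandpass(eps, band)
        for basis, fn in (("pli", conn.pli), ("aecc", conn.aec_c)):
            cm = fn(filtered)
            values[f"{band.name}_{basis}"] = conn.mean_connectivity(cm)
            metrics = mstnet.mst_metrics(mstnet.build_mst(cm))
            for long, short in _MST_SHORT.items():
                values[f"{band.name}_mst_{short}_{basis}"] = getattr(metrics, long)

    provenance = {"sample_rate": rec.sample_rate, "epoch_length": epoch_length,
                  "n_epochs": n_epochs, "amplitude_limit": amplitude_limit,
                  "bands": {b.name: (b.low, b.high) for b in CANONICAL_BANDS}}
    return FeatureVector(values, provenance)


def build_feature_table(recordings: dict[str, Recording],
                        clinical: pd.DataFrame | None = None,
                        bad_channels_by_subject: dict[str, list[str]] | None = None,
                        **extract_kwargs) -> tuple[pd.DataFrame, list[dict]]:
    """Feature rows for every includable subject plus an exclusion report.

    ``recordings`` maps subject id to Recording.  Subjects hitting an
    exclusion rule are dropped and reported with the triggering rule.
    Clinical rows (indexed or keyed by ``subject_id``) are joined when
    given; subjects without clinical data keep their row with NaNs.
    """
    if not recordings:
        raise FeatureError("no recordings given")
    ids = list(recordings)
    if len(set(ids)) != len(ids):
        raise FeatureError("duplicate subject ids")

    bad_map = bad_channels_by_subject or {}
    rows, exclusions = {}, []
    for sid, rec in recordings.items():
        try:
            rows[sid] = extract_features(
                rec, bad_channels=bad_map.get(sid), **extract_kwargs).as_series()
        except SubjectExclusionError as err:
            exclusions.append({"subject_id": sid, "rule": str(err)})
    if not rows:
        raise FeatureError("all subjects excluded")
    table = pd.DataFrame(rows).T
    table.index.name = "subject_id"

    if clinical is not None:
        cl = clinical.set_index("subject_id") if "subject_id" in clinical else clinical
        if cl.index.has_duplicates:
            raise FeatureError("duplicate subject ids in clinical table")
        table = table.join(cl, how="left")
    return table, exclusions
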