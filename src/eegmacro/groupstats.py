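"""Univariate patient-control comparisons with multiple-testing control.

Feature comparisons use two-sided Mann-Whitney U tests (exact enumeration
for small tie-free samples, tie-corrected normal approximation otherwise)
with step-down Holm-Bonferroni adjustment over the 60-test family.  The
per-bin power-spectrum comparison is reported uncorrected and flagged as
exploratory.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .features import FEATURE_NAMES

__all__ = ["ComparisonResult", "mann_whitney", "holm_bonferroni",
           "compare_cohort", "per_bin_comparison", "StatsError"]

EXACT_MAX_N = 20


class StatsError(ValueError):
    pass


@dataclass
class ComparisonResult:
    feature: str
    median_a: float
    median_b: float
    u_stat: float
    p_raw: float
    p_adjusted: float
    significant: bool


def mann_whitney(a, b) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test; returns (U of sample a, p).

    Exact enumeration when the pooled sample has at most 20 observations
    and no ties; tie-corrected normal approximation otherwise.  Samples
    with zero rank variance (all pooled values equal) give p = 1.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise StatsError("both samples must be non-empty")
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        return a.size * b.size / 2, 1.0
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (pooled.size <= EXACT_MAX_N and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(min(res.pvalue, 1.0))


def holm_bonferroni(pvals) -> np.ndarray:
    """Step-down Holm adjustment, capped at 1, input order preserved."""
    p = np.asarray(pvals, dtype=float)
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise StatsError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    adjusted = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * p[idx])
        adjusted[idx] = min(running, 1.0)
    return adjusted


def compare_cohort(features: pd.DataFrame, groups,
                   alpha: float = 0.05,
                   feature_names=FEATURE_NAMES) -> pd.DataFrame:
    """Per-feature group comparison, jointly Holm-adjusted.

    ``groups`` is a per-row label vector with values ``patient`` /
    ``control``.  Returns a frame with medians, U, raw p, adjusted p, and
    flags at ``alpha`` both corrected and uncorrected.
    """
    groups = np.asarray(groups)
    pat = features.loc[groups == "patient"]
    con = features.loc[groups == "control"]
    if len(pat) < 2 or len(con) < 2:
        raise StatsError("both groups need at least 2 subjects")

    rows = []
    for name in feature_names:
        u, p = mann_whitney(pat[name].to_numpy(), con[name].to_numpy())
        rows.append({"feature": name,
                     "median_patient": float(pat[name].median()),
                     "median_control": float(con[name].median()),
                     "u_stat": u, "p_raw": p})
    out = pd.DataFrame(rows)
    out["p_adjusted"] = holm_bonferroni(out["p_raw"].to_numpy())
    out["significant"] = out["p_adjusted"] < alpha
    out["significant_uncorrected"] = out["p_raw"] < alpha
    return out


def per_bin_comparison(spectra: np.ndarray, groups, bin_low: np.ndarray,
                       f_min: float = 0.5, f_max: float = 20.0) -> pd.DataFrame:
    """Uncorrected per-bin Mann-Whitney comparison of absolute power.

    ``spectra`` is (n_subjects, n_bins) on a shared bin grid; only bins
    with lower edge in [f_min, f_max) are tested (78 bins at 0.25 Hz
    resolution).  Exploratory by design: p-values are not adjusted.
    """
    spectra = np.asarray(spectra, dtype=float)
    bin_low = np.asarray(bin_low, dtype=float)
    if spectra.shape[1] != bin_low.size:
        raise StatsError("spectra and bin grid have mismatched sizes")
    groups = np.asarray(groups)
    pat = spectra[groups == "patient"]
    con = spectra[groups == "control"]
    if len(pat) < 2 or len(con) < 2:
        raise StatsError("both groups need at least 2 subjects")

    keep = (bin_low >= f_min - 1e-9) & (bin_low < f_max - 1e-9)
    rows = []
    for k in np.where(keep)[0]:
        _, p = mann_whitney(pat[:, k], con[:, k])
        rows.append({"bin_low_hz": bin_low[k],
                     "mean_patient": float(pat[:, k].mean()),
                     "mean_control": float(con[:, k].mean()),
                     "p_raw": p,
                     "significant_uncorrected": p < 0.05})
    return pd.DataFrame(rows)
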