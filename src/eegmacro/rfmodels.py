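"""Random-forest group classification and permutation-validated regression.

Classification balances the cohort by drawing repeated majority-class
subsets of minority size, screens features against an injected random
noise covariate, and averages tenfold cross-validated accuracy,
sensitivity and specificity (patients = positive class) over the subsets.

Regression predicts PANSS change scores from the 60 features with tenfold
cross-validation and tests significance with a label-permutation test on
the out-of-bag R^2 (one forest refit per permutation; the add-one
correction keeps p strictly positive).

Forest defaults follow the fixed rules ntree = 500 and
mtry = round(sqrt(number of features)).  Variable importance (VIMP) is
permutation importance measured on held-out folds, not impurity
importance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier, RandomForestRegressor
from sklearn.inspection import permutation_importance
from sklearn.model_selection import KFold, StratifiedKFold

__all__ = ["mtry_rule", "delta_panss", "noise_screen", "classify_balanced",
           "rf_regress_permute", "ClassifierReport", "RegressionReport",
           "ModelError", "PANSS_SUBSCALES"]

PANSS_SUBSCALES = ("total", "pos", "neg", "gen")
POSITIVE_CLASS = "patient"


class ModelError(ValueError):
    pass


def mtry_rule(n_features: int) -> int:
    """Square-root rule, rounded to the nearest integer (40 -> 6, 60 -> 8)."""
    if n_features < 1:
        raise ModelError("need at least one feature")
    return max(1, int(np.floor(np.sqrt(n_features) + 0.5)))


def delta_panss(clinical: pd.DataFrame) -> pd.DataFrame:
    """Change scores (follow-up minus baseline) per subscale.

    Negative values mean improvement.  Subjects lacking any follow-up
    value are excluded; the count is stored in ``attrs['n_excluded']``.
    """
    for sub in PANSS_SUBSCALES:
        if f"panss_{sub}_baseline" not in clinical.columns:
            raise ModelError(f"missing column panss_{sub}_baseline")
    has_base = clinical["panss_total_baseline"].notna()
    has_fu = clinical["panss_total_followup"].notna()
    keep = clinical.loc[has_base & has_fu]
    out = pd.DataFrame(index=keep.index)
    if "subject_id" in keep.columns:
        out["subject_id"] = keep["subject_id"]
    for sub in PANSS_SUBSCALES:
        out[f"delta_{sub}"] = (keep[f"panss_{sub}_followup"]
                               - keep[f"panss_{sub}_baseline"])
    out.attrs["n_excluded"] = int((has_base & ~has_fu).sum())
    return out


def _vimp(X: np.ndarray, y: np.ndarray, is_classifier: bool, ntree: int,
          mtry: int, rng: np.random.Generator, n_repeats: int = 5,
          n_folds: int = 3) -> np.ndarray:
    """Held-out permutation importance, averaged over a small CV."""
    seed = int(rng.integers(2 ** 31))
    splitter = (StratifiedKFold if is_classifier else KFold)(
        n_splits=n_folds, shuffle=True, random_state=seed)
    imps = np.zeros(X.shape[1])
    for tr, te in splitter.split(X, y):
        if is_classifier:
            model = RandomForestClassifier(
                n_estimators=ntree, max_features=mtry, random_state=seed)
        else:
            model = RandomForestRegressor(
                n_estimators=ntree, max_features=mtry, random_state=seed)
        model.fit(X[tr], y[tr])
        res = permutation_importance(model, X[te], y[te],
                                     n_repeats=n_repeats, random_state=seed)
        imps += res.importances_mean
    return imps / n_folds


def noise_screen(features: pd.DataFrame, labels, seed: int,
                 ntree: int = 500) -> tuple[list[str], pd.Series]:
    """Drop features that beat a random noise covariate no better than noise.

    A uniform-random noise column is appended, a forest is fitted, and
    features whose VIMP is less than or equal to the noise feature's VIMP
    are dropped; the noise column itself is never retained.  Returns the
    retained names and the full VIMP series (noise included).
    """
    if features.shape[1] < 2:
        raise ModelError("noise screening needs at least 2 features")
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ModelError("both classes must be present")
    rng = np.random.default_rng(seed)
    X = np.column_stack([features.to_numpy(dtype=float),
                         rng.uniform(size=len(features))])
    names = list(features.columns) + ["__noise__"]
    mtry = mtry_rule(X.shape[1])
    imps = _vimp(X, labels, True, ntree, mtry, rng)
    vimp = pd.Series(imps, index=names)
    retained = [n for n in features.columns if vimp[n] > vimp["__noise__"]]
    if not retained:
        raise ModelError(
            "noise screening dropped every feature; inspect the data "
            "before modelling")
    return retained, vimp


@dataclass
class ClassifierReport:
    retained_features: list[list[str]]
    mtry: list[int]
    ntree: int
    accuracy: list[float]
    sensitivity: list[float]
    specificity: list[float]
    vimp: pd.Series | None = None

    @property
    def mean_accuracy(self) -> float:
        return float(np.mean(self.accuracy))

    @property
    def mean_sensitivity(self) -> float:
        return float(np.mean(self.sensitivity))

    @property
    def mean_specificity(self) -> float:
        return float(np.mean(self.specificity))

    def summary(self) -> dict:
        return {"mean_accuracy": self.mean_accuracy,
                "mean_sensitivity": self.mean_sensitivity,
                "mean_specificity": self.mean_specificity,
                "ntree": self.ntree, "mtry": self.mtry,
                "n_subsets": len(self.accuracy)}


def _cv_predict_class(X, y, ntree, mtry, n_folds, seed):
    splitter = StratifiedKFold(n_splits=n_folds, shuffle=True,
                               random_state=seed)
    pred = np.empty(len(y), dtype=object)
    for k, (tr, te) in enumerate(splitter.split(X, y)):
        model = RandomForestClassifier(n_estimators=ntree, max_features=mtry,
                                       random_state=seed + k)
        model.fit(X[tr], y[tr])
        pred[te] = model.predict(X[te])
    return pred


def confusion_rates(y_true, y_pred,
                    positive: str = POSITIVE_CLASS) -> tuple[float, float, float]:
    """(accuracy, sensitivity, specificity) with patients as positives."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    pos = y_true == positive
    tp = np.sum(pos & (y_pred == positive))
    tn = np.sum(~pos & (y_pred != positive))
    acc = (tp + tn) / len(y_true)
    sens = tp / pos.sum() if pos.sum() else np.nan
    spec = tn / (~pos).sum() if (~pos).sum() else np.nan
    return float(acc), float(sens), float(spec)


def classify_balanced(features: pd.DataFrame, labels, n_subsets: int = 10,
                      ntree: int = 500, seed: int = 0, n_folds: int = 10,
                      screen: bool = True) -> ClassifierReport:
    """Balanced-subset random-forest classification of patients vs controls.

    Each subset pairs all minority-class subjects with an equal-size
    random draw (without replacement) of the majority class, screens
    features against noise, and evaluates a forest by stratified tenfold
    cross-validation.
    """
    labels = np.asarray(labels)
    classes, counts = np.unique(labels, return_counts=True)
    if len(classes) != 2:
        raise ModelError("exactly two classes required")
    k = int(np.argmin(counts))      # ties resolve to the first class
    minority, majority = classes[k], classes[1 - k]
    n_min = counts.min()
    if n_min < 10:
        raise ModelError("minority class must have at least 10 subjects")

    rng = np.random.default_rng(seed)
    min_idx = np.where(labels == minority)[0]
    maj_idx = np.where(labels == majority)[0]

    report = ClassifierReport([], [], ntree, [], [], [])
    for _ in range(n_subsets):
        sub_seed = int(rng.integers(2 ** 31))
        sub_rng = np.random.default_rng(sub_seed)
        chosen = sub_rng.choice(maj_idx, size=n_min, replace=False)
        idx = np.concatenate([min_idx, chosen])
        X_df = features.iloc[idx]
        y = labels[idx]
        if screen:
            retained, _ = noise_screen(X_df, y, seed=sub_seed, ntree=ntree)
        else:
            retained = list(features.columns)
        mtry = mtry_rule(len(retained))
        pred = _cv_predict_class(X_df[retained].to_numpy(dtype=float), y,
                                 ntree, mtry, n_folds, sub_seed)
        acc, sens, spec = confusion_rates(y, pred)
        report.retained_features.append(retained)
        report.mtry.append(mtry)
        report.accuracy.append(acc)
        report.sensitivity.append(sens)
        report.specificity.append(spec)
    return report


@dataclass
class RegressionReport:
    outcome: str
    rmse_mean: float
    rmse_sd: float
    r2_mean: float
    r2_sd: float
    cv_r2: float
    oob_r2: float
    permutation_p: float | None
    n_permutations: int
    mtry: int
    ntree: int
    vimp: pd.Series = field(default_factory=pd.Series)

    def summary(self) -> dict:
        return {"outcome": self.outcome, "rmse_mean": self.rmse_mean,
                "rmse_sd": self.rmse_sd, "r2_mean": self.r2_mean,
                "r2_sd": self.r2_sd, "cv_r2": self.cv_r2,
                "oob_r2": self.oob_r2, "permutation_p": self.permutation_p,
                "n_permutations": self.n_permutations,
                "mtry": self.mtry, "ntree": self.ntree}


def _oob_r2(X, y, ntree, mtry, seed) -> float:
    model = RandomForestRegressor(n_estimators=ntree, max_features=mtry,
                                  oob_score=True, bootstrap=True,
                                  random_state=seed)
    with warnings.catch_warnings():
        # tiny test forests may leave a sample with no OOB trees; the
        # statistic is still computed identically for observed and
        # permuted fits, which is all exchangeability needs
        warnings.simplefilter("ignore", UserWarning)
        model.fit(X, y)
    return float(model.oob_score_)


def rf_regress_permute(features: pd.DataFrame, outcome, outcome_name: str = "",
                       n_perm: int = 1000, ntree: int = 500, seed: int = 0,
                       n_folds: int = 10, compute_vimp: bool = True,
                       ) -> RegressionReport:
    """Tenfold-CV random-forest regression with a permutation test.

    Reports per-fold RMSE and R^2 (mean and SD), the pooled
    cross-validated R^2 (1 - SSE/SST over held-out predictions), and a
    permutation p computed as (1 + #{R2_perm >= R2_obs}) / (n_perm + 1)
    where the permutation statistic is the out-of-bag R^2 of a forest
    refitted on permuted outcomes.  VIMP is rescaled to 0-100 with the top
    feature at 100.
    """
    y = np.asarray(outcome, dtype=float)
    if y.size != len(features):
        raise ModelError("outcome and features are misaligned")
    if y.size < 10:
        raise ModelError("need at least 10 subjects with outcome data")
    if np.any(~np.isfinite(y)):
        raise ModelError("outcome contains missing values")
    if np.all(y == y[0]):
        raise ModelError("outcome is constant")

    X = features.to_numpy(dtype=float)
    mtry = mtry_rule(X.shape[1])
    rng = np.random.default_rng(seed)
    cv_seed = int(rng.integers(2 ** 31))

    fold_rmse, fold_r2 = [], []
    pred = np.empty_like(y)
    for k, (tr, te) in enumerate(KFold(n_splits=n_folds, shuffle=True,
                                       random_state=cv_seed).split(X)):
        model = RandomForestRegressor(n_estimators=ntree, max_features=mtry,
                                      random_state=cv_seed + k)
        model.fit(X[tr], y[tr])
        pred[te] = model.predict(X[te])
        resid = y[te] - pred[te]
        fold_rmse.append(float(np.sqrt(np.mean(resid ** 2))))
        sst = np.sum((y[te] - y[te].mean()) ** 2)
        fold_r2.append(float(1 - np.sum(resid ** 2) / sst) if sst > 0 else np.nan)
    cv_r2 = float(1 - np.sum((y - pred) ** 2) / np.sum((y - y.mean()) ** 2))

    oob_seed = int(rng.integers(2 ** 31))
    r2_obs = _oob_r2(X, y, ntree, mtry, oob_seed)

    perm_p = None
    if n_perm > 0:
        hits = 0
        for _ in range(n_perm):
            y_perm = rng.permutation(y)
            if _oob_r2(X, y_perm, ntree, mtry,
                       int(rng.integers(2 ** 31))) >= r2_obs:
                hits += 1
        perm_p = (1 + hits) / (n_perm + 1)

    vimp = pd.Series(dtype=float)
    if compute_vimp:
        raw = _vimp(X, y, False, ntree, mtry, rng)
        top = raw.max()
        scaled = np.zeros_like(raw) if top <= 0 else 100 * np.clip(raw, 0, None) / top
        vimp = pd.Series(scaled, index=features.columns).sort_values(
            ascending=False)

    return RegressionReport(
        outcome=outcome_name, rmse_mean=float(np.mean(fold_rmse)),
        rmse_sd=float(np.std(fold_rmse, ddof=1)),
        r2_mean=float(np.nanmean(fold_r2)),
        r2_sd=float(np.nanstd(fold_r2, ddof=1)),
        cv_r2=cv_r2, oob_r2=r2_obs, permutation_p=perm_p,
        n_permutations=n_perm, mtry=mtry, ntree=ntree, vimp=vimp)
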