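import numpy as np
import pandas as pd
import pytest

from eegmacro.rfmodels import (ModelError, classify_balanced, confusion_rates,
                               delta_panss, mtry_rule, noise_screen,
                               rf_regress_permute)
from eegmacro.synthetic import CohortSpec, PanssModel, generate_cohort


def test_mtry_rule():
    assert mtry_rule(40) == 6
    assert mtry_rule(60) == 8
    assert mtry_rule(1) == 1
    with pytest.raises(ModelError):
        mtry_rule(0)


class TestDeltaPanss:
    @pytest.fixture
    def clinical(self):
        return pd.DataFrame({
            "subject_id": ["P1", "P2", "P3"],
            "group": ["patient"] * 3,
            "panss_total_baseline": [71.42, 80.0, 75.0],
            "panss_total_followup": [57.56, 80.0, np.nan],
            "panss_pos_baseline": [17.91, 20.0, 18.0],
            "panss_pos_followup": [12.73, 20.0, np.nan],
            "panss_neg_baseline": [18.0, 20.0, 19.0],
            "panss_neg_followup": [16.0, 20.0, np.nan],
            "panss_gen_baseline": [35.0, 40.0, 38.0],
            "panss_gen_followup": [29.0, 40.0, np.nan],
        })

    def test_subtraction(self, clinical):
        d = delta_panss(clinical)
        assert d["delta_total"].iloc[0] == pytest.approx(57.56 - 71.42)
        assert d["delta_total"].iloc[0] == pytest.approx(-13.86)
        assert d["delta_pos"].iloc[0] == pytest.approx(-5.18)

    def test_identical_timepoints_zero(self, clinical):
        d = delta_panss(clinical)
        assert (d.iloc[1][["delta_total", "delta_pos",
                           "delta_neg", "delta_gen"]] == 0).all()

    def test_missing_followup_excluded_and_counted(self, clinical):
        d = delta_panss(clinical)
        assert len(d) == 2
        assert d.attrs["n_excluded"] == 1


class TestNoiseScreen:
    def test_separating_feature_always_retained(self, rng):
        for seed in range(20):
            local = np.random.default_rng(seed)
            n = 40
            labels = np.array(["patient"] * (n // 2) + ["control"] * (n // 2))
            X = pd.DataFrame(local.standard_normal((n, 10)),
                             columns=[f"f{k}" for k in range(10)])
            X["f0"] = np.where(labels == "patient", 1.0, -1.0)
            retained, vimp = noise_screen(X, labels, seed=seed, ntree=60)
            assert "f0" in retained
            assert "__noise__" not in retained
            assert vimp["f0"] == vimp.max()

    def test_all_dropped_raises(self, monkeypatch):
        # force the noise column to dominate every real feature
        import eegmacro.rfmodels as rf

        def fake_vimp(X, y, *args, **kwargs):
            out = np.zeros(X.shape[1])
            out[-1] = 1.0  # the appended noise column wins
            return out

        monkeypatch.setattr(rf, "_vimp", fake_vimp)
        labels = np.array(["patient", "control"] * 6)
        X = pd.DataFrame({"a": np.zeros(12), "b": np.zeros(12)})
        with pytest.raises(ModelError, match="inspect"):
            noise_screen(X, labels, seed=0, ntree=30)


def test_confusion_rates_oracle():
    y_true = np.array(["patient", "patient", "patient", "control", "control"])
    y_pred = np.array(["patient", "control", "patient", "control", "patient"])
    acc, sens, spec = confusion_rates(y_true, y_pred)
    assert acc == pytest.approx(3 / 5)
    assert sens == pytest.approx(2 / 3)   # patients correctly flagged
    assert spec == pytest.approx(1 / 2)   # controls correctly cleared


def separated_cohort(seed, n=30, shift=0.25):
    effect = {"alpha_pli": (shift, 0.3), "delta_relpower": (-shift, 0.6),
              "beta_aecc": (shift, 0.4)}
    feats, clin = generate_cohort(CohortSpec(n_patients=n, n_controls=n,
                                             effect_map=effect, seed=seed))
    groups = clin.set_index("subject_id").loc[feats.index, "group"].to_numpy()
    return feats, groups


class TestClassifyBalanced:
    def test_strong_effects_high_accuracy(self):
        feats, groups = separated_cohort(seed=0)
        rep = classify_balanced(feats, groups, n_subsets=3, ntree=80, seed=1)
        assert rep.mean_accuracy > 0.9

    def test_balanced_subset_sizes(self):
        feats, clin = generate_cohort(CohortSpec(n_patients=12, n_controls=30,
                                                 seed=3))
        groups = clin.set_index("subject_id").loc[feats.index,
                                                  "group"].to_numpy()
        rep = classify_balanced(feats, groups, n_subsets=2, ntree=30, seed=0,
                                screen=False)
        # 12 + 12 per subset, 10-fold CV must see all 24 subjects
        assert len(rep.accuracy) == 2

    def test_determinism(self):
        feats, groups = separated_cohort(seed=5, n=15)
        r1 = classify_balanced(feats, groups, n_subsets=2, ntree=40, seed=9)
        r2 = classify_balanced(feats, groups, n_subsets=2, ntree=40, seed=9)
        assert r1.accuracy == r2.accuracy
        assert r1.retained_features == r2.retained_features

    def test_missing_class_rejected(self):
        feats, _ = separated_cohort(seed=0, n=12)
        with pytest.raises(ModelError):
            classify_balanced(feats, np.array(["patient"] * len(feats)),
                              seed=0)


def linked_cohort(seed, n=100, noise_sd=0.5):
    # baseline centered high enough that the planted change never hits the
    # subscale floor (clipping would truncate the linear link)
    pm = PanssModel(
        baseline={"pos": (28.0, 3.0), "neg": (18.5, 7.0), "gen": (37.5, 9.0)},
        delta_means={"pos": 0.0, "neg": -1.25, "gen": -7.44},
        coef={"alpha_pli": -4.0, "beta_pli": 3.0, "delta_mst_bcmax_pli": -3.0},
        noise_sd=noise_sd)
    spec = CohortSpec(n_patients=n, n_controls=2, panss_model=pm, seed=seed)
    feats, clin = generate_cohort(spec)
    deltas = delta_panss(clinical=clin)
    X = feats.loc[deltas["subject_id"]]
    return X, deltas["delta_pos"].to_numpy()


class TestRegression:
    def test_linear_link_recovered(self):
        X, y = linked_cohort(seed=2, n=200)
        rep = rf_regress_permute(X, y, n_perm=99, ntree=150, seed=0,
                                 compute_vimp=True)
        assert rep.cv_r2 > 0.5
        assert rep.permutation_p <= 0.01
        assert rep.mtry == 8  # 60 features -> sqrt rule
        # the three truly linked features occupy high VIMP ranks
        top5 = set(rep.vimp.index[:5])
        assert len(top5 & {"alpha_pli", "beta_pli",
                           "delta_mst_bcmax_pli"}) >= 2
        assert rep.vimp.iloc[0] == pytest.approx(100.0)

    def test_permutation_p_never_zero(self):
        X, y = linked_cohort(seed=3, n=40)
        rep = rf_regress_permute(X, y, n_perm=19, ntree=30, seed=1,
                                 compute_vimp=False)
        assert rep.permutation_p >= 1 / 20

    def test_determinism(self):
        X, y = linked_cohort(seed=4, n=30)
        r1 = rf_regress_permute(X, y, n_perm=9, ntree=25, seed=7)
        r2 = rf_regress_permute(X, y, n_perm=9, ntree=25, seed=7)
        assert r1.summary() == r2.summary()
        assert r1.vimp.equals(r2.vimp)

    def test_null_outcome_rarely_significant(self):
        # zero-coefficient link: permutation p non-significant in >= 90%
        sig = 0
        for seed in range(10):
            feats, clin = generate_cohort(CohortSpec(
                n_patients=30, n_controls=2,
                panss_model=PanssModel(noise_sd=3.0), seed=seed + 50))
            deltas = delta_panss(clin)
            X = feats.loc[deltas["subject_id"]]
            rep = rf_regress_permute(X, deltas["delta_pos"].to_numpy(),
                                     n_perm=99, ntree=25, seed=seed,
                                     compute_vimp=False)
            sig += bool(rep.permutation_p <= 0.05)
        assert sig <= 1

    def test_constant_outcome_rejected(self):
        X, y = linked_cohort(seed=5, n=20)
        with pytest.raises(ModelError):
            rf_regress_permute(X, np.zeros_like(y), seed=0)

    def test_misaligned_rejected(self):
        X, y = linked_cohort(seed=6, n=20)
        with pytest.raises(ModelError):
            rf_regress_permute(X, y[:-1], seed=0)
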