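import numpy as np
import pytest
from scipy.stats import spearmanr

from eegmacro.connectivity import aec_c, pli
from eegmacro.preprocess import CANONICAL_BANDS, bandpass, select_epochs
from eegmacro.synthetic import (CohortSpec, PanssModel, SignalSpec,
                                SyntheticError, generate_cohort,
                                generate_recording)

ALPHA = CANONICAL_BANDS[2]


def alpha_pli(rec, n_epochs=10):
    eps = select_epochs(rec, 4.0, n_epochs, amplitude_limit=1e6)
    return pli(bandpass(eps, ALPHA))


class TestGenerateRecording:
    def test_shape_and_determinism(self):
        spec = SignalSpec(duration=2.0, n_channels=4, sample_rate=256.0, seed=9)
        a = generate_recording(spec)
        b = generate_recording(SignalSpec(duration=2.0, n_channels=4,
                                          sample_rate=256.0, seed=9))
        assert a.signals.shape == (4, 512)
        np.testing.assert_array_equal(a.signals, b.signals)

    def test_different_seed_differs(self):
        a = generate_recording(SignalSpec(duration=1.0, n_channels=2,
                                          sample_rate=256.0, seed=1))
        b = generate_recording(SignalSpec(duration=1.0, n_channels=2,
                                          sample_rate=256.0, seed=2))
        assert not np.array_equal(a.signals, b.signals)

    def test_invalid_fields_named(self):
        with pytest.raises(SyntheticError, match="duration"):
            SignalSpec(duration=-1.0).validate()
        with pytest.raises(SyntheticError, match="sample_rate"):
            SignalSpec(duration=1.0, sample_rate=0).validate()
        with pytest.raises(SyntheticError, match="coupling_strength"):
            SignalSpec(duration=1.0, phase_coupling=[(0, 1, "alpha", 1.5, 0.0)]
                       ).validate()

    def test_zero_coupling_pli_near_zero_monte_carlo(self):
        # mean PLI over seeds vs the analytic zero for independent channels
        vals = []
        for seed in range(20):
            rec = generate_recording(SignalSpec(
                duration=44.0, n_channels=3, sample_rate=256.0, seed=seed))
            v = alpha_pli(rec).values
            vals.append(v[np.triu_indices(3, 1)].mean())
        assert np.mean(vals) < 0.2

    def test_full_coupling_pli_one(self):
        rec = generate_recording(SignalSpec(
            duration=44.0, n_channels=3, sample_rate=256.0,
            band_amplitudes={"alpha": 10.0}, noise_amplitude=0.0,
            phase_coupling=[(0, 1, "alpha", 1.0, np.pi / 2)], seed=0))
        assert alpha_pli(rec).values[0, 1] > 0.99

    def test_pli_monotone_in_coupling_strength(self):
        strengths = np.linspace(0, 1, 6)
        mean_pli = []
        for s in strengths:
            per_seed = [
                alpha_pli(generate_recording(SignalSpec(
                    duration=44.0, n_channels=2, sample_rate=256.0,
                    noise_amplitude=1.0,
                    phase_coupling=[(0, 1, "alpha", float(s), np.pi / 2)],
                    seed=seed))).values[0, 1]
                for seed in range(10)]
            mean_pli.append(np.mean(per_seed))
        rho, _ = spearmanr(strengths, mean_pli)
        assert rho > 0.9

    def test_mixing_robustness(self):
        # zero-lag mixing must not create PLI or AEC-c coupling, but must
        # inflate uncorrected envelope correlation
        from scipy.signal import hilbert
        n = 6
        mix = np.eye(n) + 0.3 * (np.ones((n, n)) - np.eye(n))
        unmixed, mixed = [], []
        for seed in (11, 12, 13):
            kw = dict(duration=44.0, n_channels=n, sample_rate=256.0, seed=seed)
            unmixed.append(generate_recording(SignalSpec(**kw)))
            mixed.append(generate_recording(SignalSpec(mixing=mix, **kw)))
        iu = np.triu_indices(n, 1)
        for rec_u, rec_m in zip(unmixed, mixed):
            eps = bandpass(select_epochs(rec_m, 4.0, 10, amplitude_limit=1e6),
                           ALPHA)
            p = pli(eps).values[iu].mean()
            a = aec_c(eps).values[iu].mean()
            p0 = alpha_pli(rec_u).values[iu].mean()
            assert p < p0 + 0.1          # PLI not inflated by mixing
            assert abs(a - 0.5) < 0.05   # AEC-c stays at no-coupling level
            env = np.abs(hilbert(np.hstack(eps.epochs), axis=1))
            raw = np.corrcoef(env)[iu].mean()
            assert raw > a - 0.5 + 0.2   # raw envelope correlation inflates


class TestGenerateCohort:
    def test_row_counts_62_106(self):
        feats, clin = generate_cohort(CohortSpec(n_patients=62, n_controls=106,
                                                 seed=0))
        assert (clin["group"] == "patient").sum() == 62
        assert (clin["group"] == "control").sum() == 106
        assert feats.shape == (168, 60)

    def test_planted_delta_relpower_medians(self):
        spec = CohortSpec(n_patients=200, n_controls=200,
                          effect_map={"delta_relpower": (0.659 - 0.575, 0.575)},
                          seed=4)
        feats, clin = generate_cohort(spec)
        pat = feats.loc[clin.set_index("subject_id")["group"] == "patient",
                        "delta_relpower"]
        con = feats.loc[clin.set_index("subject_id")["group"] == "control",
                        "delta_relpower"]
        assert pat.median() == pytest.approx(0.659, abs=0.02)
        assert con.median() == pytest.approx(0.575, abs=0.02)

    def test_unknown_feature_name_lists_vocabulary(self):
        with pytest.raises(SyntheticError, match="delta_relpower"):
            generate_cohort(CohortSpec(n_patients=5, n_controls=5,
                                       effect_map={"nope": (0.1, 0.5)}))

    def test_determinism(self):
        s = CohortSpec(n_patients=10, n_controls=10, seed=77)
        f1, c1 = generate_cohort(s)
        f2, c2 = generate_cohort(CohortSpec(n_patients=10, n_controls=10,
                                            seed=77))
        assert f1.equals(f2) and c1.equals(c2)

    def test_panss_integer_and_in_range(self):
        _, clin = generate_cohort(CohortSpec(n_patients=50, n_controls=5,
                                             seed=1))
        pos = clin.loc[clin.group == "patient", "panss_pos_baseline"]
        assert (pos == pos.round()).all()
        assert pos.between(7, 49).all()
        gen = clin.loc[clin.group == "patient", "panss_gen_baseline"]
        assert gen.between(16, 112).all()

    def test_followup_subset(self):
        _, clin = generate_cohort(CohortSpec(n_patients=62, n_controls=10,
                                             n_followup=45, seed=2))
        pat = clin[clin.group == "patient"]
        assert pat["panss_pos_followup"].notna().sum() == 45
        assert clin.loc[clin.group == "control",
                        "panss_pos_followup"].isna().all()

    def test_linear_link_drives_delta_positive(self):
        coef = {"alpha_pli": -4.0}
        spec = CohortSpec(n_patients=300, n_controls=2,
                          panss_model=PanssModel(coef=coef, noise_sd=1.0),
                          seed=3)
        feats, clin = generate_cohort(spec)
        pat = clin[clin.group == "patient"]
        delta = (pat["panss_pos_followup"] - pat["panss_pos_baseline"])
        r = np.corrcoef(feats.iloc[:300]["alpha_pli"], delta)[0, 1]
        assert r < -0.5

    def test_invalid_sizes_rejected(self):
        with pytest.raises(SyntheticError):
            generate_cohort(CohortSpec(n_patients=1, n_controls=10))
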