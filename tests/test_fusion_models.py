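"""Fusion primitives: AUC-proportional weights, concatenation, classifiers."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from silistage import (
    QUICK_GRIDS,
    BranchAUCs,
    ClassifierSpec,
    FusionWeights,
    compute_auc_weights,
    early_fuse,
    estimate_branch_aucs,
    fit_modality_model,
    hybrid_fuse_predict,
    late_fuse_predict,
    predict_pmf_probability,
)

pytestmark = pytest.mark.filterwarnings("ignore::UserWarning")


class TestEarlyFuse:
    def test_15_plus_18_gives_33(self, rng):
        fused = early_fuse(rng.standard_normal(15), rng.standard_normal(18))
        assert fused.shape == (33,)

    def test_zero_inputs_give_zero_vector(self):
        np.testing.assert_array_equal(early_fuse(np.zeros(15), np.zeros(18)), np.zeros(33))

    def test_image_latents_come_first(self, rng):
        latent, panel = rng.standard_normal(15), rng.standard_normal(18)
        fused = early_fuse(latent, panel)
        assert fused[0] == latent[0] and fused[15] == panel[0]

    def test_matrix_row_alignment_checked(self, rng):
        with pytest.raises(ValueError, match="rows"):
            early_fuse(rng.standard_normal((4, 15)), rng.standard_normal((5, 18)))


class TestAucWeights:
    @pytest.mark.parametrize(
        "aucs,expected",
        [
            ((0.8, 0.2), (0.8, 0.2)),
            ((0.7, 0.7), (0.5, 0.5)),
            ((0.6, 0.9), (0.4, 0.6)),
        ],
    )
    def test_proportionality(self, aucs, expected):
        w = compute_auc_weights(BranchAUCs(*aucs))
        assert w.w_image == pytest.approx(expected[0])
        assert w.w_biomarker == pytest.approx(expected[1])

    def test_both_zero_falls_back_to_equal_weights(self):
        with pytest.warns(UserWarning, match="equal weights"):
            w = compute_auc_weights(BranchAUCs(0.0, 0.0))
        assert (w.w_image, w.w_biomarker) == (0.5, 0.5)

    def test_negative_auc_rejected(self):
        with pytest.raises(ValueError, match="nonnegative"):
            BranchAUCs(-0.1, 0.5)

    @given(
        auc_i=st.floats(0, 1, allow_nan=False),
        auc_b=st.floats(0, 1, allow_nan=False),
    )
    @settings(max_examples=200, deadline=None)
    def test_weights_always_simplex(self, auc_i, auc_b):
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            w = compute_auc_weights(BranchAUCs(auc_i, auc_b))
        assert w.w_image >= 0 and w.w_biomarker >= 0
        assert w.w_image + w.w_biomarker == pytest.approx(1.0, abs=1e-12)

    def test_weights_must_sum_to_one(self):
        with pytest.raises(ValueError, match="sum to 1"):
            FusionWeights(0.7, 0.2)


class TestLateFusion:
    def test_threshold_is_inclusive_at_half(self):
        p = late_fuse_predict(0.9, 0.1, FusionWeights(0.5, 0.5))
        assert p.probability_pmf == pytest.approx(0.5)
        assert p.label == 1

    def test_weighted_average(self):
        p = late_fuse_predict(0.8, 0.2, FusionWeights(0.75, 0.25))
        assert p.probability_pmf == pytest.approx(0.65)
        assert p.label == 1

    def test_degenerate_weight_reduces_to_one_branch(self):
        p = late_fuse_predict(0.37, 0.99, FusionWeights(1.0, 0.0))
        assert p.probability_pmf == pytest.approx(0.37)

    @given(
        p1=st.floats(0, 1), p2=st.floats(0, 1), q1=st.floats(0, 1), q2=st.floats(0, 1),
        wi=st.floats(0, 1),
    )
    @settings(max_examples=200, deadline=None)
    def test_monotone_in_both_inputs(self, p1, p2, q1, q2, wi):
        w = FusionWeights(wi, 1.0 - wi)
        lo = late_fuse_predict(min(p1, p2), min(q1, q2), w).probability_pmf
        hi = late_fuse_predict(max(p1, p2), max(q1, q2), w).probability_pmf
        assert lo <= hi + 1e-12

    def test_probability_out_of_range_rejected(self):
        with pytest.raises(ValueError, match=r"\[0, 1\]"):
            late_fuse_predict(1.2, 0.5, FusionWeights(0.5, 0.5))


class TestHybridFusion:
    def test_agreement_case_is_scheme_independent(self):
        b = BranchAUCs(0.7, 0.9)
        for scheme in ("mean", "auc_proportional"):
            assert hybrid_fuse_predict(0.42, 0.42, b, scheme).probability_pmf == pytest.approx(0.42)

    def test_mean_scheme(self):
        assert hybrid_fuse_predict(0.6, 0.8).probability_pmf == pytest.approx(0.7)

    def test_equal_branch_aucs_make_schemes_agree(self):
        b = BranchAUCs(0.8, 0.8)
        m = hybrid_fuse_predict(0.3, 0.9, b, "mean").probability_pmf
        a = hybrid_fuse_predict(0.3, 0.9, b, "auc_proportional").probability_pmf
        assert m == pytest.approx(a)

    def test_unknown_scheme_rejected(self):
        with pytest.raises(ValueError, match="scheme"):
            hybrid_fuse_predict(0.5, 0.5, scheme="geometric")


@pytest.mark.parametrize("family", ["svm", "rf", "gbdt"])
class TestModalityModels:
    def _separable(self, rng, n=60):
        y = np.repeat([0, 1], n // 2)
        X = rng.standard_normal((n, 2)) + 6.0 * y[:, None]
        return X, y

    def _params(self, family):
        return {k: v[0] for k, v in QUICK_GRIDS[family].items()}

    def test_separable_data_fits_perfectly(self, family, rng):
        X, y = self._separable(rng)
        spec = ClassifierSpec(family, grid=QUICK_GRIDS[family], seed=0)
        model = fit_modality_model(X, y, spec, self._params(family))
        assert (model.predict(X) == y).all()

    def test_seeded_refit_is_deterministic(self, family, rng):
        X, y = self._separable(rng)
        spec = ClassifierSpec(family, grid=QUICK_GRIDS[family], seed=3)
        p1 = predict_pmf_probability(fit_modality_model(X, y, spec, self._params(family)), X)
        p2 = predict_pmf_probability(fit_modality_model(X, y, spec, self._params(family)), X)
        np.testing.assert_array_equal(p1, p2)

    def test_probabilities_sum_to_one(self, family, rng):
        X, y = self._separable(rng)
        spec = ClassifierSpec(family, grid=QUICK_GRIDS[family], seed=0)
        model = fit_modality_model(X, y, spec, self._params(family))
        np.testing.assert_allclose(model.predict_proba(X).sum(axis=1), 1.0, atol=1e-9)

    def test_single_class_rejected(self, family, rng):
        X = rng.standard_normal((10, 2))
        spec = ClassifierSpec(family, grid=QUICK_GRIDS[family], seed=0)
        with pytest.raises(ValueError, match="single-class"):
            fit_modality_model(X, np.ones(10), spec, self._params(family))


class TestBranchAucEstimation:
    def _grouped(self, rng, n_patients=40, reps=3):
        pids = np.repeat([f"P{i}" for i in range(n_patients)], reps)
        y = np.repeat((rng.random(n_patients) > 0.5).astype(int), reps)
        return pids, y

    def test_image_signal_dominates_noise_biomarkers(self):
        linear = {"C": 1, "kernel": "linear"}
        wins = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            pids, y = self._grouped(rng)
            n = len(y)
            X_img = rng.standard_normal((n, 10)) + 1.5 * np.outer(y, np.ones(10) / np.sqrt(10))
            X_bio = rng.standard_normal((n, 8))  # pure noise
            spec = ClassifierSpec("svm", grid=QUICK_GRIDS["svm"], seed=seed)
            b = estimate_branch_aucs(X_img, X_bio, y, pids, spec, linear, linear, seed=seed)
            wins += b.auc_image > b.auc_biomarker
        assert wins >= 18

    def test_shuffled_labels_give_null_aucs(self):
        linear = {"C": 1, "kernel": "linear"}
        rng = np.random.default_rng(7)
        pids, y = self._grouped(rng, n_patients=40, reps=3)
        X_img = rng.standard_normal((len(y), 10))
        X_bio = rng.standard_normal((len(y), 8))
        b = estimate_branch_aucs(X_img, X_bio, y, pids, spec=ClassifierSpec("svm", seed=0),
                                 params_image=linear, params_biomarker=linear, seed=1)
        assert abs(b.auc_image - 0.5) <= 0.12
        assert abs(b.auc_biomarker - 0.5) <= 0.12

    def test_identical_inputs_give_symmetric_branches(self):
        linear = {"C": 1, "kernel": "linear"}
        rng = np.random.default_rng(3)
        pids, y = self._grouped(rng, n_patients=50, reps=3)
        X = rng.standard_normal((len(y), 8)) + 2.0 * np.outer(y, np.ones(8) / np.sqrt(8))
        spec = ClassifierSpec("svm", grid=QUICK_GRIDS["svm"], seed=0)
        b = estimate_branch_aucs(X, X, y, pids, spec, linear, linear, seed=3)
        assert abs(b.auc_image - b.auc_biomarker) <= 0.02

    def test_too_few_patients_errors(self, rng):
        pids = np.array(["P0", "P0", "P1", "P1"], dtype=object)
        y = np.array([0, 0, 1, 1])
        X = rng.standard_normal((4, 3))
        spec = ClassifierSpec("svm", seed=0)
        with pytest.raises(ValueError):
            estimate_branch_aucs(X, X, y, pids, spec, {}, {}, n_subfolds=3, seed=0)
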