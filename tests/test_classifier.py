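"""Feature construction, model training, indicators and Monte Carlo CV."""

import numpy as np
import pandas as pd
import pytest

from methsignal.classifier import (
    FAMILY_CHOICES,
    FEATURES,
    ClassifierSpec,
    build_feature_frame,
    confusion_metrics,
    load_classifier,
    monte_carlo_cv,
    predict,
    save_classifier,
    train_classifier,
)


def feature_table(X, labels):
    df = pd.DataFrame(X, columns=FEATURES)
    df["label"] = labels
    return df


def gaussian_clouds(rng, n=100, sep=8.0):
    """Two well-separated 4-d Gaussian clouds labelled CT/TT."""
    a = rng.normal(0, 1, size=(n, 4))
    b = rng.normal(sep, 1, size=(n, 4))
    X = np.vstack([a, b])
    labels = np.array(["CT"] * n + ["TT"] * n)
    return feature_table(X, labels)


class TestBuildFeatureFrame:
    def _pdmps(self):
        return pd.DataFrame(
            {
                "sample_id": ["c1", "t1"],
                "group": ["control", "treatment"],
                "chrom": ["chr1", "chr1"],
                "pos": [500, 1000],
                "tv": [0.4, -0.6],
                "tv_abs": [0.4, 0.6],
                "hdiv": [2.0, 5.0],
                "weight": [10.0, 10.0],
                "log2_tailp": [-3.0, -8.0],
            }
        )

    def test_rel_pos_and_labels(self):
        out = build_feature_frame(self._pdmps(), {"chr1": 1000})
        assert out["rel_pos"].tolist() == [0.5, 1.0]  # pos == length -> 1.0
        assert out["label"].tolist() == ["CT", "TT"]

    def test_missing_chrom_length(self):
        with pytest.raises(KeyError, match="chr1"):
            build_feature_frame(self._pdmps(), {"chr2": 1000})

    def test_exact_feature_matrix(self):
        out = build_feature_frame(self._pdmps(), {"chr1": 2000})
        expected = np.array(
            [[0.4, 2.0, 0.25, -3.0], [0.6, 5.0, 0.5, -8.0]]
        )
        assert np.allclose(out[FEATURES].to_numpy(), expected)


class TestConfusionMetrics:
    def test_crafted_confusion(self):
        # TP=90, FN=10, TN=80, FP=20
        y_true = ["TT"] * 100 + ["CT"] * 100
        y_pred = ["TT"] * 90 + ["CT"] * 10 + ["CT"] * 80 + ["TT"] * 20
        m = confusion_metrics(y_true, y_pred)
        assert m["sensitivity"] == pytest.approx(0.90)
        assert m["specificity"] == pytest.approx(0.80)
        assert m["ppv"] == pytest.approx(90 / 110)
        assert m["fdr"] == pytest.approx(20 / 110)
        assert m["accuracy"] == pytest.approx(0.85)
        assert m["detection_rate"] == pytest.approx(90 / 200)
        assert m["npv"] == pytest.approx(80 / 90)

    def test_perfect_prediction(self):
        m = confusion_metrics(["TT", "CT"], ["TT", "CT"])
        assert (m["accuracy"], m["kappa"], m["fdr"]) == (1.0, 1.0, 0.0)

    def test_degenerate_all_positive(self):
        y_true = ["TT"] * 50 + ["CT"] * 50
        m = confusion_metrics(y_true, ["TT"] * 100)
        assert m["sensitivity"] == 1.0
        assert m["specificity"] == 0.0
        assert m["accuracy"] == 0.5

    def test_identities(self, rng):
        y_true = rng.choice(["CT", "TT"], 200)
        y_pred = rng.choice(["CT", "TT"], 200)
        m = confusion_metrics(y_true, y_pred)
        assert m["fdr"] + m["ppv"] == pytest.approx(1.0)
        assert m["detection_rate"] == m["tp"] / 200
        assert m["detection_rate"] <= m["sensitivity"] + 1e-12


class TestTrainPredict:
    @pytest.mark.parametrize("family", FAMILY_CHOICES)
    def test_separable_training_accuracy(self, family, rng):
        features = gaussian_clouds(rng)
        model = train_classifier(features, ClassifierSpec(family=family), seed=0)
        labels, posterior = predict(model, features)
        assert (labels == features["label"].to_numpy()).all()
        assert ((posterior >= 0) & (posterior <= 1)).all()

    def test_posterior_normalized_and_threshold(self, rng):
        features = gaussian_clouds(rng, sep=2.0)
        model = train_classifier(features, ClassifierSpec(family="logistic"), seed=0)
        labels, posterior = predict(model, features)
        assert ((posterior >= 0.5) == (labels == "TT")).all()
        proba = model.pipeline.predict_proba(features[FEATURES].to_numpy())
        assert np.allclose(proba.sum(axis=1), 1.0)

    def test_logistic_decision_boundary(self, rng):
        features = gaussian_clouds(rng, sep=2.0)
        model = train_classifier(features, ClassifierSpec(family="logistic"), seed=0)
        est = model.pipeline.named_steps["model"]
        X = features[FEATURES].to_numpy()
        score = X @ est.coef_.ravel() + est.intercept_[0]
        labels, _ = predict(model, features)
        tt_is_positive = est.classes_[1] == "TT"
        flips = (score > 0) == (labels == ("TT" if tt_is_positive else "CT"))
        assert flips.all()

    def test_pca_scores_uncorrelated(self, rng):
        features = gaussian_clouds(rng)
        model = train_classifier(features, ClassifierSpec(family="pca_lda"), seed=0)
        X = features[FEATURES].to_numpy()
        Xs = model.pipeline.named_steps["scale"].transform(X)
        scores = model.pipeline.named_steps["pca"].transform(Xs)
        cov = np.cov(scores.T)
        off = cov - np.diag(np.diag(cov))
        assert np.abs(off).max() < 1e-8

    def test_pca_rotation_orthonormal(self, rng):
        features = gaussian_clouds(rng)
        model = train_classifier(features, ClassifierSpec(family="pca_qda"), seed=0)
        R = model.rotation
        assert np.allclose(R @ R.T, np.eye(R.shape[0]), atol=1e-10)

    def test_pca_recovers_dominant_axis(self, rng):
        # rank-2-ish data with dominant variance along a known direction
        direction = np.array([1.0, 1.0, 0.0, 0.0]) / np.sqrt(2)
        t = rng.normal(size=300)[:, None]
        X = t * direction * 10 + rng.normal(0, 0.1, size=(300, 4))
        labels = np.where(t.ravel() > 0, "TT", "CT")
        features = feature_table(X, labels)
        model = train_classifier(
            features, ClassifierSpec(family="pca_lda", scale=False), seed=0
        )
        pc1 = model.rotation[0]
        assert abs(pc1 @ direction) == pytest.approx(1.0, abs=1e-3)

    def test_single_class_rejected(self, rng):
        features = gaussian_clouds(rng)
        features["label"] = "CT"
        with pytest.raises(ValueError, match="both classes"):
            train_classifier(features, ClassifierSpec(), seed=0)

    def test_save_load_round_trip(self, tmp_path, rng):
        for family in FAMILY_CHOICES:
            features = gaussian_clouds(rng, sep=3.0)
            model = train_classifier(features, ClassifierSpec(family=family), seed=0)
            path = save_classifier(model, tmp_path / f"{family}.json")
            back = load_classifier(path)
            l1, p1 = predict(model, features)
            l2, p2 = predict(back, features)
            assert (l1 == l2).all()
            assert np.allclose(p1, p2, atol=1e-10)


class TestMonteCarloCv:
    def test_separable_all_indicators_one(self, rng):
        features = gaussian_clouds(rng)
        report = monte_carlo_cv(features, n_resamples=30, seed=1)
        for k in ("accuracy", "kappa", "sensitivity", "specificity", "ppv", "npv"):
            assert report.means[k] == pytest.approx(1.0)
        assert report.means["fdr"] == pytest.approx(0.0)

    def test_permutation_null_kappa_near_zero(self, rng):
        features = gaussian_clouds(rng, n=150, sep=6.0)
        features["label"] = rng.permutation(features["label"].to_numpy())
        report = monte_carlo_cv(
            features, ClassifierSpec(family="logistic"), n_resamples=200, seed=2
        )
        assert abs(report.means["kappa"]) < 0.05
        assert abs(report.means["accuracy"] - 0.5) < 0.05

    def test_same_seed_identical_report(self, rng):
        features = gaussian_clouds(rng, sep=2.0)
        a = monte_carlo_cv(features, n_resamples=25, seed=11)
        b = monte_carlo_cv(features, n_resamples=25, seed=11)
        assert a.means == b.means
        assert a.ci_lower == b.ci_lower
        assert a.ci_upper == b.ci_upper
        assert (a.confusion == b.confusion).all()

    def test_resample_count_stability(self, rng):
        features = gaussian_clouds(rng, n=80, sep=1.5)
        a = monte_carlo_cv(features, n_resamples=150, seed=3)
        b = monte_carlo_cv(features, n_resamples=300, seed=3)
        for k in ("accuracy", "kappa", "sensitivity", "specificity"):
            assert abs(a.means[k] - b.means[k]) < 0.01

    def test_ci_bounds_contain_mean(self, rng):
        features = gaussian_clouds(rng, n=60, sep=1.0)
        report = monte_carlo_cv(features, n_resamples=100, seed=4)
        for k in ("accuracy", "kappa"):
            assert report.ci_lower[k] <= report.means[k] <= report.ci_upper[k]

    def test_tiny_class_rejected(self, rng):
        features = gaussian_clouds(rng, n=3)
        with pytest.raises(ValueError, match=">= 5 rows"):
            monte_carlo_cv(features, n_resamples=10, seed=0)
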