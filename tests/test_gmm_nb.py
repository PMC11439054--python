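"""EM fitting, component selection and the Bayes decision rule."""

import json

import numpy as np
import pytest

from ghcs.gmm_nb import (
    ABNORMAL,
    NORMAL,
    ClassGMM,
    EMConfig,
    GaussianComponent,
    _em_single,
    class_conditional,
    em_fit,
    fit_classifier,
    gaussian_pdf,
    load_model,
    log_class_conditional,
    log_gaussian_pdf,
    posterior_abnormal,
    predict,
    save_model,
    select_num_components,
)
from ghcs.synthetic import FeatureSimSpec, make_feature_dataset


def _direct_pdf(x, mean, cov):
    """Closed-form density with explicit inverse and determinant."""
    q = len(mean)
    diff = np.asarray(x) - mean
    return float(
        np.exp(-0.5 * diff @ np.linalg.inv(cov) @ diff)
        / np.sqrt((2 * np.pi) ** q * np.linalg.det(cov))
    )


class TestGaussianPdf:
    def test_standard_normal_at_mean(self):
        assert gaussian_pdf([0.0], [0.0], [[1.0]]) == pytest.approx(
            1 / np.sqrt(2 * np.pi), abs=1e-9
        )

    def test_bivariate_identity_at_mean(self):
        assert gaussian_pdf([0, 0], [0, 0], np.eye(2)) == pytest.approx(
            1 / (2 * np.pi), abs=1e-9
        )

    def test_matches_direct_formula_random_spd(self, rng):
        A = rng.normal(size=(3, 3))
        cov = A @ A.T + 0.5 * np.eye(3)
        mean = rng.normal(size=3)
        for _ in range(5):
            x = rng.normal(size=3)
            assert gaussian_pdf(x, mean, cov) == pytest.approx(
                _direct_pdf(x, mean, cov), rel=1e-10
            )

    def test_singular_covariance_raises(self):
        with pytest.raises(np.linalg.LinAlgError):
            log_gaussian_pdf(np.zeros((1, 2)), np.zeros(2), np.zeros((2, 2)))


class TestEMFit:
    def test_single_component_equals_closed_form_mle(self, rng):
        X = rng.normal(2.0, 1.5, size=(400, 2))
        config = EMConfig(seed=0, n_init=1, reg_covar=1e-6)
        gmm = em_fit(X, 1, config)
        c = gmm.components[0]
        np.testing.assert_allclose(c.mean, X.mean(axis=0), atol=1e-8)
        np.testing.assert_allclose(
            c.cov, np.cov(X.T, bias=True) + 1e-6 * np.eye(2), atol=1e-8
        )
        assert c.weight == pytest.approx(1.0)

    def test_two_component_recovery(self):
        rng = np.random.default_rng(42)
        X = np.concatenate(
            [rng.normal(0, 1, 2000), rng.normal(5, 1, 2000)]
        )[:, None]
        gmm = em_fit(X, 2, EMConfig(seed=0, n_init=3))
        means = np.sort(gmm.means.ravel())
        assert abs(means[0] - 0.0) < 0.15 and abs(means[1] - 5.0) < 0.15
        assert np.all(np.abs(gmm.weights - 0.5) < 0.05)

    @pytest.mark.parametrize("s", [1, 2, 3])
    def test_log_likelihood_trace_monotone(self, s, rng):
        X = np.concatenate(
            [rng.normal(-3, 1, (300, 2)), rng.normal(3, 1, (300, 2))]
        )
        _, _, trace = _em_single(X, s, EMConfig(seed=1), np.random.default_rng(1))
        diffs = np.diff(trace)
        assert np.all(diffs >= -1e-8 * np.maximum(1.0, np.abs(trace[:-1])))

    def test_weights_sum_to_one(self, rng):
        X = rng.normal(size=(200, 3))
        gmm = em_fit(X, 2, EMConfig(seed=0, n_init=1))
        assert gmm.weights.sum() == pytest.approx(1.0, abs=1e-9)

    def test_too_few_samples_raises(self, rng):
        with pytest.raises(ValueError, match="samples"):
            em_fit(rng.normal(size=(5, 3)), 4, EMConfig())

    def test_matches_sklearn_likelihood(self):
        """Independent EM (scikit-learn) reaches the same optimum on a
        well-separated instance; likelihoods agree closely."""
        sklearn_mixture = pytest.importorskip("sklearn.mixture")
        rng = np.random.default_rng(5)
        X = np.concatenate(
            [rng.normal(0, 1, (1000, 2)), rng.normal(6, 1, (1000, 2))]
        )
        ours = em_fit(X, 2, EMConfig(seed=0, n_init=3))
        from ghcs.gmm_nb import log_likelihood

        ref = sklearn_mixture.GaussianMixture(
            2, covariance_type="full", reg_covar=1e-6, n_init=3, random_state=0
        ).fit(X)
        ll_ours = log_likelihood(X, ours) / len(X)
        ll_ref = ref.score(X)
        assert ll_ours == pytest.approx(ll_ref, abs=5e-3)


class TestComponentSelection:
    def test_three_component_mixture_recovered(self):
        rng = np.random.default_rng(3)
        X = np.concatenate(
            [rng.normal(c, 0.6, 1000) for c in (-6.0, 0.0, 6.0)]
        )[:, None]
        config = EMConfig(
            seed=0, component_grid=(1, 2, 3, 4, 5), n_init=2, n_val_splits=3
        )
        assert select_num_components(X, config) == 3

    def test_single_gaussian_selects_one(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(800, 2))
        config = EMConfig(seed=0, component_grid=(1, 2, 3), n_init=2, n_val_splits=3)
        assert select_num_components(X, config) == 1

    def test_degenerate_grid(self, rng):
        X = rng.normal(size=(400, 1))
        assert select_num_components(X, EMConfig(component_grid=(4,), n_init=1)) == 4


class TestClassConditional:
    def test_single_component_equals_pdf(self, rng):
        mean, cov = rng.normal(size=2), np.eye(2)
        gmm = ClassGMM("normal", (GaussianComponent(1.0, mean, cov),))
        x = rng.normal(size=2)
        assert class_conditional(x, gmm) == pytest.approx(
            gaussian_pdf(x, mean, cov), rel=1e-12
        )

    def test_two_components_direct_sum(self):
        m1, m2 = np.array([0.0]), np.array([4.0])
        cov = np.eye(1)
        gmm = ClassGMM(
            "normal",
            (GaussianComponent(0.5, m1, cov), GaussianComponent(0.5, m2, cov)),
        )
        expected = 0.5 * _direct_pdf([0.0], m1, cov) + 0.5 * _direct_pdf(
            [0.0], m2, cov
        )
        assert class_conditional([0.0], gmm) == pytest.approx(expected, rel=1e-12)

    def test_far_tail_no_underflow_in_log_space(self):
        gmm = ClassGMM(
            "normal", (GaussianComponent(1.0, np.zeros(1), np.eye(1)),)
        )
        logp = log_class_conditional(np.array([[60.0]]), gmm)[0]
        assert np.isfinite(logp) and logp < -1000

    def test_dimension_mismatch_raises(self):
        gmm = ClassGMM("normal", (GaussianComponent(1.0, np.zeros(2), np.eye(2)),))
        with pytest.raises(ValueError, match="dimension"):
            class_conditional([0.0, 0.0, 0.0], gmm)


def _toy_model(sep=10.0, prior=0.5, tau=0.5):
    normal = ClassGMM(
        NORMAL, (GaussianComponent(1.0, np.zeros(1), np.eye(1)),), prior=prior
    )
    abn = ClassGMM(
        ABNORMAL,
        (GaussianComponent(1.0, np.array([sep]), np.eye(1)),),
        prior=1 - prior,
    )
    from ghcs.gmm_nb import FittedModel

    return FittedModel(
        classes=(normal, abn), feature_mean=np.zeros(1), feature_std=np.ones(1),
        tau=tau,
    )


class TestPredict:
    def test_point_at_abnormal_mean_is_abnormal(self):
        labels, post = predict(np.array([[10.0]]), _toy_model())
        assert labels[0] == ABNORMAL and post[0] > 0.99

    def test_equidistant_point_posterior_half_tie_to_abnormal(self):
        labels, post = predict(np.array([[5.0]]), _toy_model())
        assert post[0] == pytest.approx(0.5, abs=1e-9)
        assert labels[0] == ABNORMAL  # >= rule

    def test_low_threshold_flags_abnormal(self):
        # posterior just under 0.5: MAP says normal, screening tau flags it
        x = np.array([[4.9]])
        labels_map, post = predict(x, _toy_model(), tau=0.5)
        labels_low, _ = predict(x, _toy_model(), tau=0.2)
        assert post[0] < 0.5
        assert labels_map[0] == NORMAL and labels_low[0] == ABNORMAL

    def test_posteriors_of_two_classes_sum_to_one(self, rng):
        from dataclasses import replace as dc_replace

        from ghcs.gmm_nb import FittedModel

        model = _toy_model(prior=0.3)
        # swapped model: the normal density plays the abnormal role
        swapped = FittedModel(
            classes=(
                dc_replace(model.abnormal, label=NORMAL),
                dc_replace(model.normal, label=ABNORMAL),
            ),
            feature_mean=model.feature_mean,
            feature_std=model.feature_std,
        )
        X = rng.normal(5, 4, size=(50, 1))
        p_ab = posterior_abnormal(X, model)
        p_norm = posterior_abnormal(X, swapped)
        np.testing.assert_allclose(p_ab + p_norm, 1.0, atol=1e-12)

    def test_lower_tau_never_decreases_recall(self, rng):
        X, labels, _ = make_feature_dataset(
            FeatureSimSpec(n_per_class=(300, 300), seed=8)
        )
        model = fit_classifier(
            X, labels, EMConfig(seed=0, component_grid=(1, 2), n_init=1,
                                n_val_splits=2)
        )
        recalls = []
        truth_ab = labels == ABNORMAL
        for tau in (0.9, 0.5, 0.2, 0.05):
            pred, _ = predict(X, model, tau=tau)
            recalls.append(((pred == ABNORMAL) & truth_ab).sum() / truth_ab.sum())
        assert all(b >= a for a, b in zip(recalls, recalls[1:]))


class TestFitClassifier:
    def test_priors_match_class_proportions(self):
        X, labels, _ = make_feature_dataset(
            FeatureSimSpec(n_per_class=(140, 60), seed=2)
        )
        model = fit_classifier(
            X, labels, EMConfig(seed=0, component_grid=(1,), n_init=1,
                                n_val_splits=2)
        )
        assert model.normal.prior == pytest.approx(0.7)
        assert model.abnormal.prior == pytest.approx(0.3)

    def test_single_class_raises(self, rng):
        X = rng.normal(size=(50, 2))
        with pytest.raises(ValueError, match="both classes"):
            fit_classifier(X, [NORMAL] * 50)

    def test_held_out_accuracy_on_default_mixtures(self):
        spec = FeatureSimSpec(n_per_class=(700, 700), seed=0)
        X, labels, _ = make_feature_dataset(spec)
        rng = np.random.default_rng(0)
        perm = rng.permutation(len(labels))
        cut = int(0.7 * len(labels))
        tr, te = perm[:cut], perm[cut:]
        model = fit_classifier(
            X[tr], labels[tr],
            EMConfig(seed=0, component_grid=(1, 2, 3), n_init=2, n_val_splits=3),
        )
        pred, _ = predict(X[te], model)
        assert (pred == labels[te]).mean() >= 0.95

    def test_agrees_with_quadratic_discriminant_oracle(self):
        """With one component per class the decision equals QDA built
        from closed-form MLEs."""
        rng = np.random.default_rng(11)
        Xn = rng.multivariate_normal([0, 0], [[1, 0.3], [0.3, 1]], 400)
        Xa = rng.multivariate_normal([2.0, 1.0], [[1.5, -0.2], [-0.2, 0.8]], 400)
        X = np.concatenate([Xn, Xa])
        labels = np.array([NORMAL] * 400 + [ABNORMAL] * 400)
        model = fit_classifier(
            X, labels, EMConfig(seed=0, component_grid=(1,), n_init=1,
                                n_val_splits=2)
        )
        # oracle on the same standardized coordinates
        mu, sd = X.mean(axis=0), X.std(axis=0)
        Z = (X - mu) / sd
        Zn, Za = Z[:400], Z[400:]

        def qda_logp(z, S):
            m = S.mean(axis=0)
            C = np.cov(S.T, bias=True) + 1e-6 * np.eye(2)
            d = z - m
            return -0.5 * (
                np.log(np.linalg.det(C)) + d @ np.linalg.inv(C) @ d
            )

        grid = rng.normal(scale=1.5, size=(200, 2)) + [1.0, 0.5]
        pred, _ = predict(grid, model)
        zg = (grid - mu) / sd
        oracle = np.array(
            [
                ABNORMAL if qda_logp(z, Za) >= qda_logp(z, Zn) else NORMAL
                for z in zg
            ]
        )
        assert (pred == oracle).mean() == 1.0


class TestModelIO:
    def _model(self):
        X, labels, _ = make_feature_dataset(
            FeatureSimSpec(n_per_class=(100, 100), seed=5)
        )
        return (
            fit_classifier(
                X, labels,
                EMConfig(seed=0, component_grid=(1, 2), n_init=1, n_val_splits=2),
            ),
            X,
        )

    def test_save_load_save_identical_bytes(self, tmp_path):
        model, _ = self._model()
        p1, p2 = tmp_path / "m1.json", tmp_path / "m2.json"
        save_model(model, p1)
        save_model(load_model(p1), p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_round_trip_lossless_parameters(self, tmp_path):
        model, X = self._model()
        save_model(model, tmp_path / "m.json")
        loaded = load_model(tmp_path / "m.json")
        for a, b in zip(model.classes, loaded.classes):
            assert a.prior == b.prior
            for ca, cb in zip(a.components, b.components):
                np.testing.assert_allclose(ca.cov, cb.cov, atol=1e-12)
        _, p1 = predict(X, model)
        _, p2 = predict(X, loaded)
        np.testing.assert_array_equal(p1, p2)

    def test_truncated_file_clean_error(self, tmp_path):
        model, _ = self._model()
        save_model(model, tmp_path / "m.json")
        text = (tmp_path / "m.json").read_text()
        (tmp_path / "bad.json").write_text(text[: len(text) // 2])
        with pytest.raises(ValueError, match="truncated|corrupt"):
            load_model(tmp_path / "bad.json")

    def test_schema_version_mismatch(self, tmp_path):
        (tmp_path / "v9.json").write_text(json.dumps({"schema_version": 9}))
        with pytest.raises(ValueError, match="schema"):
            load_model(tmp_path / "v9.json")
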