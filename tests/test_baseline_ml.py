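import numpy as np
import pytest

from pulsegate.baseline_ml import (
    FEATURE_NAMES,
    KlrBaseline,
    RandomForestBaseline,
    SvmBaseline,
    dnn_features,
    extract_feature_matrix,
    extract_features,
    fuzzy_entropy,
    gaussian_kernel,
)
from pulsegate.dnn_models import S1Config, S2Config, build_s1, build_s2
from pulsegate.evaluation import patient_weighted_metrics
from pulsegate.preprocessing import dataset_to_arrays, preprocess
from pulsegate.synthetic import generate_dataset, generate_patient, pr_defaults


@pytest.fixture(scope="module")
def clusters():
    """Two well-separated 2-D Gaussian clusters."""
    rng = np.random.default_rng(0)
    V = np.vstack([rng.standard_normal((30, 2)) + 4.0,
                   rng.standard_normal((30, 2)) - 4.0])
    y = np.array(["PR"] * 30 + ["PEA"] * 30)
    return V, y


class TestFeatures:
    def test_nine_named_features(self):
        assert len(FEATURE_NAMES) == 9
        seg = generate_patient(pr_defaults(), 1, seed=0)[0]
        v = extract_features(preprocess(seg))
        assert v.shape == (9,)
        assert np.all(np.isfinite(v))

    def test_flat_signal_defined_fallbacks(self):
        v = extract_features(np.zeros(500))
        assert v[FEATURE_NAMES.index("qrs_rate_bpm")] == 0.0
        assert v[FEATURE_NAMES.index("slope_steepness")] == 0.0
        assert v[FEATURE_NAMES.index("fuzzy_entropy")] == 0.0
        assert np.all(np.isfinite(v))

    def test_rate_feature_tracks_programmed_rate(self):
        params = pr_defaults(heart_rate_bpm=80.0, rate_cv=0.0,
                             ectopy_prob=0.0, noise_sd_mv=0.0)
        seg = generate_patient(params, 1, seed=5)[0]
        v = extract_features(preprocess(seg))
        assert 72.0 <= v[FEATURE_NAMES.index("qrs_rate_bpm")] <= 88.0

    def test_rate_and_entropy_scale_invariant(self):
        seg = generate_patient(pr_defaults(), 1, seed=9)[0]
        x = preprocess(seg).s
        v1, v2 = extract_features(x), extract_features(2.0 * x)
        i_rate = FEATURE_NAMES.index("qrs_rate_bpm")
        i_ent = FEATURE_NAMES.index("fuzzy_entropy")
        assert v1[i_rate] == v2[i_rate]
        assert abs(v1[i_ent] - v2[i_ent]) < 1e-9

    def test_short_signal_rejected(self):
        with pytest.raises(ValueError):
            extract_features(np.zeros(150))

    def test_fuzzy_entropy_higher_for_noise_than_periodic(self, rng):
        periodic = np.sin(2 * np.pi * np.arange(400) / 25.0)
        noise = rng.standard_normal(400)
        assert fuzzy_entropy(noise) > fuzzy_entropy(periodic)


class TestGaussianKernel:
    def test_self_similarity_is_one(self, rng):
        v = rng.standard_normal(9)
        assert gaussian_kernel(v, v, 3.0) == 1.0

    def test_unit_distance_value(self):
        a, b = np.zeros(2), np.array([1.0, 0.0])
        assert abs(gaussian_kernel(a, b, 1.0) - np.exp(-1.0)) < 1e-12

    def test_symmetry(self, rng):
        a, b = rng.standard_normal(5), rng.standard_normal(5)
        assert gaussian_kernel(a, b, 0.7) == gaussian_kernel(b, a, 0.7)

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError):
            gaussian_kernel(np.zeros(3), np.zeros(4), 1.0)


class TestClassifiers:
    def test_svm_separable_training_accuracy(self, clusters):
        V, y = clusters
        clf = SvmBaseline(C=10.0, gamma_s=0.5).fit(V, y)
        assert np.all(clf.predict(V) == y)

    def test_svm_label_flip_flips_predictions(self, clusters):
        V, y = clusters
        flipped = np.where(y == "PR", "PEA", "PR")
        p1 = SvmBaseline(C=10.0, gamma_s=0.5).fit(V, y).predict(V)
        p2 = SvmBaseline(C=10.0, gamma_s=0.5).fit(V, flipped).predict(V)
        assert np.all(p1 != p2)

    def test_single_class_rejected(self):
        V = np.zeros((5, 2))
        for clf in (SvmBaseline(), KlrBaseline()):
            with pytest.raises(ValueError):
                clf.fit(V, ["PR"] * 5)

    def test_klr_separable_and_probabilities(self, clusters):
        V, y = clusters
        clf = KlrBaseline(lambda_l=1e-3, gamma_s=0.5).fit(V, y)
        assert np.all(clf.predict(V) == y)
        p = clf.predict_proba(V)
        assert np.all((p > 0) & (p < 1))

    def test_klr_heavy_regularization_shrinks_to_half(self, clusters):
        V, y = clusters
        clf = KlrBaseline(lambda_l=1e7, gamma_s=0.5).fit(V, y)
        # coefficients shrink toward zero; only the intercept remains
        assert np.max(np.abs(clf._alpha)) < 1e-3

    def test_rf_memorizes_distinct_training_points(self, clusters):
        V, y = clusters
        clf = RandomForestBaseline(resample_fraction=1.0, features_per_node=2,
                                   n_trees=1).fit(V, y)
        assert np.all(clf.predict(V) == y)

    def test_rf_holdout_accuracy_on_separable_clusters(self, clusters):
        V, y = clusters
        rng = np.random.default_rng(3)
        Vtest = np.vstack([rng.standard_normal((20, 2)) + 4.0,
                           rng.standard_normal((20, 2)) - 4.0])
        ytest = np.array(["PR"] * 20 + ["PEA"] * 20)
        clf = RandomForestBaseline(resample_fraction=0.7,
                                   features_per_node=1).fit(V, y)
        assert np.mean(clf.predict(Vtest) == ytest) > 0.9

    def test_rf_too_many_features_per_node(self, clusters):
        V, y = clusters
        with pytest.raises(ValueError):
            RandomForestBaseline(features_per_node=3).fit(V, y)


class TestOnSyntheticEcg:
    def test_all_classifiers_beat_majority_class(self):
        for seed in range(10):
            tr = generate_dataset(8, 8, (2, 3), seed=100 + seed)
            te = generate_dataset(4, 4, (2, 3), seed=900 + seed)
            Xtr, ytr, _ = dataset_to_arrays(tr)
            Xte, yte, pte = dataset_to_arrays(te)
            Vtr, Vte = extract_feature_matrix(Xtr), extract_feature_matrix(Xte)
            # scale-normalize for the kernel machines
            mu, sd = Vtr.mean(0), Vtr.std(0) + 1e-9
            for clf in (RandomForestBaseline(0.75, 3),
                        SvmBaseline(C=10.0, gamma_s=0.1),
                        KlrBaseline(lambda_l=1e-2, gamma_s=0.1)):
                if isinstance(clf, RandomForestBaseline):
                    clf.fit(Vtr, ytr)
                    pred = clf.predict(Vte)
                else:
                    clf.fit((Vtr - mu) / sd, ytr)
                    pred = clf.predict((Vte - mu) / sd)
                m = patient_weighted_metrics(pred, yte, pte)
                assert m.bac_pct > 50.0, f"{type(clf).__name__} seed {seed}"

    def test_network_features_feed_the_classifiers(self, small_data):
        Xtr, ytr, _ = small_data["train"]
        s1 = build_s1(S1Config(2, 8, 5, 0.1), 500, seed=0)
        s2 = build_s2(S2Config(1, 8, 5, 0.1, gru_units=6), 500, seed=0)
        v1 = dnn_features(s1, Xtr)
        v2 = dnn_features(s2, Xtr)
        assert v1.shape == (Xtr.shape[0], 8)      # M features from S1
        assert v2.shape == (Xtr.shape[0], 12)     # 2*theta features from S2
        clf = RandomForestBaseline(0.8, 2).fit(v1, ytr)
        assert set(clf.predict(v1)) <= {"PR", "PEA"}
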