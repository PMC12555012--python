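import joblib
import numpy as np
import pytest

from hfokit.classify import (
    InferenceConfig,
    LocalRegistry,
    ModelSource,
    distill_model,
    load_classifier,
    predict_batch,
    run_cascade,
    save_classifier,
    train_classifier,
)


@pytest.fixture(scope="module")
def small_pool(image_pool):
    """First 200 images of the shared pool (memory- and time-friendly)."""
    images, labels = image_pool
    return images[:200], labels[:200]


@pytest.fixture(scope="module")
def trained(small_pool):
    images, labels = small_pool
    return train_classifier(images, labels, {"seed": 0})


class TestCheckpointRoundTrip:
    def test_reload_reproduces_validation_predictions(self, trained, small_pool, tmp_path):
        clf, log = trained
        images, _ = small_pool
        path = save_classifier(clf, tmp_path / "clf.joblib")
        back = load_classifier(ModelSource("local_checkpoint", str(path)))
        assert np.array_equal(back.predict(images[:50]), clf.predict(images[:50]))

    def test_missing_path_named(self, tmp_path):
        missing = tmp_path / "nope.joblib"
        with pytest.raises(FileNotFoundError, match="nope.joblib"):
            load_classifier(ModelSource("local_checkpoint", str(missing)))

    def test_wrong_input_shape_rejected(self, trained, tmp_path):
        clf, _ = trained
        path = save_classifier(clf, tmp_path / "clf.joblib")
        payload = joblib.load(path)
        payload["input_shape"] = (1, 64, 64)
        joblib.dump(payload, path)
        with pytest.raises(ValueError, match="shape mismatch"):
            load_classifier(f"local:{path}")

    def test_registry_resolution_and_cache(self, trained, tmp_path):
        clf, _ = trained
        root = tmp_path / "registry"
        root.mkdir()
        save_classifier(clf, root / "artifact-v1.joblib")
        registry = LocalRegistry(root, cache_dir=tmp_path / "cache")
        back = load_classifier(ModelSource.parse("registry:artifact-v1"), registry=registry)
        assert (tmp_path / "cache" / "artifact-v1.joblib").exists()
        assert back.classes_.tolist() == clf.classes_.tolist()

    def test_registry_source_without_registry(self):
        with pytest.raises(ValueError, match="registry"):
            load_classifier("registry:some-model")


class TestPredictBatch:
    def test_batch_size_invariance(self, trained, small_pool):
        clf, _ = trained
        images, _ = small_pool
        p1 = predict_batch(clf, images[:100], InferenceConfig(batch_size=1))
        p64 = predict_batch(clf, images[:100], InferenceConfig(batch_size=64))
        assert np.max(np.abs(p1 - p64)) <= 1e-5

    def test_rows_sum_to_one(self, trained, small_pool):
        clf, _ = trained
        proba = predict_batch(clf, small_pool[0][:32])
        assert np.allclose(proba.sum(axis=1), 1.0)

    def test_duplicated_image_identical_rows(self, trained, small_pool):
        clf, _ = trained
        img = small_pool[0][3]
        proba = predict_batch(clf, np.stack([img, img]))
        assert np.array_equal(proba[0], proba[1])

    def test_empty_input(self, trained):
        clf, _ = trained
        out = predict_batch(clf, np.zeros((0, 3, 224, 224)))
        assert out.shape == (0, len(clf.classes_))


class _ConstantClassifier:
    """Predicts a fixed positive-class probability for every image."""

    classes_ = np.array([0, 1])

    def __init__(self, p):
        self.p = p

    def predict_proba(self, images):
        n = np.asarray(images).shape[0]
        return np.tile([1 - self.p, self.p], (n, 1))


class TestCascade:
    def _images(self, n):
        return np.zeros((n, 3, 224, 224), dtype=np.float32)

    def test_all_artifacts_short_circuits(self):
        res = run_cascade([0] * 10, self._images(10),
                          {"artifact": _ConstantClassifier(0.9),
                           "spk": _ConstantClassifier(0.8),
                           "ehfo": _ConstantClassifier(0.8)})
        assert res.n_artifact == 10
        assert res.n_real == res.n_spk == res.n_ehfo == 0
        assert np.all(np.isnan(res.p_spk))

    def test_count_conservation(self, trained, small_pool):
        clf, _ = trained
        images, _ = small_pool
        res = run_cascade(list(range(100)), images[:100],
                          {"artifact": clf, "spk": clf, "ehfo": clf})
        assert res.n_artifact + res.n_real == res.n_total == 100
        assert res.n_spk <= res.n_real and res.n_ehfo <= res.n_real
        defined = np.count_nonzero(~np.isnan(res.p_spk))
        assert defined == res.n_real

    def test_omitted_ehfo_stage_absent(self):
        res = run_cascade([0] * 6, self._images(6),
                          {"artifact": _ConstantClassifier(0.2),
                           "spk": _ConstantClassifier(0.7)})
        assert res.n_ehfo is None
        assert res.n_spk == 6

    def test_missing_artifact_model_rejected(self):
        with pytest.raises(ValueError, match="artifact"):
            run_cascade([0], self._images(1), {"spk": _ConstantClassifier(0.5)})

    def test_threshold_tie_is_artifact(self):
        res = run_cascade([0] * 3, self._images(3), {"artifact": _ConstantClassifier(0.5)})
        assert res.n_artifact == 3


class TestTraining:
    def test_seeded_training_is_deterministic(self, small_pool):
        images, labels = small_pool
        a, _ = train_classifier(images, labels, {"seed": 3, "max_iter": 50})
        b, _ = train_classifier(images, labels, {"seed": 3, "max_iter": 50})
        for wa, wb in zip(a.mlp.coefs_, b.mlp.coefs_):
            assert np.array_equal(wa, wb)

    def test_single_class_rejected(self, small_pool):
        images, _ = small_pool
        with pytest.raises(ValueError, match="two classes"):
            train_classifier(images[:20], np.zeros(20, dtype=int))

    def test_shuffled_labels_give_chance_accuracy(self, small_pool):
        """Permuting labels destroys the signal: held-out accuracy falls in the
        binomial 95% band around 0.5."""
        images, labels = small_pool
        rng = np.random.default_rng(0)
        _, log = train_classifier(images, rng.permutation(labels),
                                  {"seed": 0, "max_iter": 100})
        n = log["n_val"]
        half_width = 1.96 * np.sqrt(0.25 / n)
        assert abs(log["val_accuracy"] - 0.5) <= half_width + 0.05


class TestDistillation:
    def test_single_class_teacher_aborts(self, small_pool):
        images, _ = small_pool

        class Teacher(_ConstantClassifier):
            pass

        with pytest.raises(ValueError, match="single class"):
            distill_model(Teacher(0.99), images[:40])

    def test_deterministic_given_seed(self, trained, small_pool):
        clf, _ = trained
        images, _ = small_pool
        s1, r1 = distill_model(clf, images, {"seed": 5, "max_iter": 50})
        s2, r2 = distill_model(clf, images, {"seed": 5, "max_iter": 50})
        assert r1 == r2
        for wa, wb in zip(s1.mlp.coefs_, s2.mlp.coefs_):
            assert np.array_equal(wa, wb)
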