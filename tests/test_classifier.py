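import numpy as np
import pytest

from ventpulse.classifier import (
    ClassifierOutput,
    ModelSpec,
    TrainConfig,
    WeakEffortCNN,
    build_model,
    predict,
    preprocess_breath,
)
from ventpulse.dataio import BreathSegment
from ventpulse.pipeline import truth_segments
from ventpulse.simulate import CohortEntry


@pytest.fixture(scope="module")
def toy_data():
    """Separable by construction: weak breaths are short low-amplitude flow
    bumps, strong breaths long high-amplitude ones."""
    rng = np.random.default_rng(0)
    X, y = [], []
    for _ in range(200):
        for weak in (True, False):
            amp = rng.uniform(0.1, 0.25) if weak else rng.uniform(0.6, 1.0)
            width = rng.integers(6, 12) if weak else rng.integers(24, 40)
            x = np.zeros((2, 64), dtype=np.float32)
            start = rng.integers(0, 5)
            x[0, start : start + width] = amp * np.hanning(width)
            x[1, start : start + width] = 0.5 * amp
            x += rng.normal(0, 0.01, x.shape).astype(np.float32)
            X.append(x)
            y.append(weak)
    X = np.stack(X)
    y = np.array(y)
    return X[:320], y[:320], X[320:], y[320:]


class TestPreprocess:
    def test_shape_padding_and_determinism(self, sim_recording):
        rec, _ = sim_recording
        cfg = TrainConfig()
        from ventpulse.segment import segment_breaths

        seg = [s for s in segment_breaths(rec) if s.valid][0]
        a = preprocess_breath(rec, seg, cfg)
        b = preprocess_breath(rec, seg, cfg)
        assert a.shape == (2, cfg.segment_len)
        np.testing.assert_array_equal(a, b)
        # breath shorter than segment_len: zero right padding
        n_resampled = int(np.floor(seg.ttot * cfg.fs_model)) + 1
        if n_resampled < cfg.segment_len:
            assert np.all(a[:, n_resampled:] == 0)

    def test_invalid_segment_refused(self, sim_recording):
        rec, _ = sim_recording
        seg = BreathSegment.from_indices(0, 50, 100, rec.fs, valid=False)
        with pytest.raises(ValueError):
            preprocess_breath(rec, seg)

    def test_blind_to_esophageal_pressure(self, sim_recording):
        """The model input must not change when Pes/Pga change."""
        import dataclasses

        rec, _ = sim_recording
        from ventpulse.segment import segment_breaths

        seg = [s for s in segment_breaths(rec) if s.valid][0]
        scrambled = dataclasses.replace(rec, pes=np.zeros_like(rec.pes))
        np.testing.assert_array_equal(
            preprocess_breath(rec, seg), preprocess_breath(scrambled, seg)
        )


class TestBuildModel:
    def test_zero_weight_model_outputs_half_probability(self):
        model = build_model(ModelSpec(), 64)
        model.set_weights([np.zeros_like(p) for p in model.params])
        x = np.random.default_rng(1).standard_normal((3, 2, 64)).astype(np.float32)
        from ventpulse.nn import sigmoid

        p = sigmoid(model.forward(x)[:, 0])
        np.testing.assert_allclose(p, 0.5)

    def test_output_strictly_within_unit_interval(self):
        model = build_model(ModelSpec(), 96, np.random.default_rng(2))
        x = np.random.default_rng(3).standard_normal((8, 2, 96)).astype(np.float32)
        from ventpulse.nn import sigmoid

        p = sigmoid(model.forward(x)[:, 0])
        assert np.all((p > 0) & (p < 1))

    def test_too_short_input_rejected(self):
        with pytest.raises(ValueError):
            build_model(ModelSpec(), 16)

    def test_parameter_count_is_architectural_constant(self):
        # conv: sum over blocks of 2 convs (C*K*F + F); dense from 32*L/32
        model = build_model(ModelSpec(), 300)
        assert model.n_params == 1_311_553

    def test_architecture_audit_golden(self):
        model = build_model(ModelSpec(), 64)
        audit = model.describe()
        convs = [d for d in audit if d["layer"] == "Conv1d"]
        assert [(d["filters"], d["kernel"]) for d in convs] == [
            (64, 3), (64, 3),
            (64, 9), (64, 9),
            (128, 9), (128, 9),
            (256, 9), (256, 9),
            (32, 7), (32, 7),
        ]
        assert sum(d["layer"] == "MaxPool1d" for d in audit) == 5
        dense = [d for d in audit if d["layer"] == "Dense"]
        assert [d["units"] for d in dense] == [128, 128, 1]
        assert sum(d["layer"] == "Dropout" for d in audit) == 2
        # a different kernel size must change the audit
        other = build_model(
            ModelSpec(conv_blocks=((64, 5), (64, 9), (128, 9), (256, 9), (32, 7))),
            64,
        )
        assert other.describe() != audit


class TestTraining:
    def test_separable_toy_set_learned(self, toy_data):
        Xtr, ytr, Xval, yval = toy_data
        clf = WeakEffortCNN(max_epochs=12, patience=4, batch_size=32, seed=1)
        clf.fit(Xtr, ytr, Xval, yval)
        acc = (clf.predict(Xval) == yval).mean()
        assert acc >= 0.95

    def test_permuted_labels_give_chance_accuracy(self, toy_data):
        Xtr, ytr, Xval, yval = toy_data
        rng = np.random.default_rng(5)
        clf = WeakEffortCNN(max_epochs=3, patience=3, batch_size=32, seed=2,
                            decision_threshold=0.5)
        clf.fit(Xtr, rng.permutation(ytr), Xval, rng.permutation(yval))
        acc = (clf.predict(Xval) == rng.permutation(yval)).mean()
        assert 0.4 <= acc <= 0.6

    def test_single_class_labels_rejected(self, toy_data):
        Xtr, _, _, _ = toy_data
        clf = WeakEffortCNN(max_epochs=1)
        with pytest.raises(ValueError):
            clf.fit(Xtr, np.ones(len(Xtr)))

    def test_seeded_training_reproducible(self, toy_data):
        Xtr, ytr, Xval, yval = toy_data
        runs = []
        for _ in range(2):
            clf = WeakEffortCNN(max_epochs=2, batch_size=64, seed=3)
            clf.fit(Xtr[:128], ytr[:128], Xval[:64], yval[:64])
            runs.append((clf.history_["train_loss"], clf.threshold_,
                         clf.predict_proba(Xval[:32])[:, 1]))
        assert runs[0][0] == runs[1][0]
        assert runs[0][1] == runs[1][1]
        np.testing.assert_array_equal(runs[0][2], runs[1][2])


class TestPredict:
    def _fixed_prob_clf(self):
        clf = WeakEffortCNN()
        clf.model_ = build_model(ModelSpec(), 64)
        clf.model_.set_weights([np.zeros_like(p) for p in clf.model_.params])
        clf.threshold_ = 0.5
        return clf

    def test_probability_equal_to_threshold_predicts_weak(self):
        clf = self._fixed_prob_clf()  # every prob is exactly 0.5
        X = np.zeros((4, 2, 64), dtype=np.float32)
        outs = predict(clf, X, decision_threshold=0.5)
        assert all(o.pred_weak for o in outs)
        outs = predict(clf, X, decision_threshold=0.5000001)
        assert not any(o.pred_weak for o in outs)

    def test_outputs_order_preserving(self):
        clf = self._fixed_prob_clf()
        X = np.zeros((7, 2, 64), dtype=np.float32)
        keys = [("p", i) for i in range(7)]
        outs = predict(clf, X, keys=keys)
        assert [o.key for o in outs] == keys
        assert len(outs) == 7
        assert all(isinstance(o, ClassifierOutput) for o in outs)
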