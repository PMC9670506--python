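"""Focal loss, training loop and evaluation metrics."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from bgcnn.models import MLPBaseline, MLPBaselineConfig
from bgcnn.training_eval import (
    TrainConfig,
    evaluate,
    focal_loss,
    focal_loss_grad,
    train,
)


class _StubModel:
    """Deterministic 'model' whose forward returns canned probabilities."""

    def __init__(self, probs):
        self.probs = np.asarray(probs, dtype=float)
        self.params = {}

    def forward_batch(self, x):
        return self.probs[np.asarray(x, dtype=int)], {}


class TestFocalLoss:
    def test_gamma_zero_uniform_alpha_is_cross_entropy(self, rng):
        for _ in range(20):
            p = rng.dirichlet(np.ones(4), size=8)
            y = rng.integers(0, 4, size=8)
            ce = -np.mean(np.log(p[np.arange(8), y]))
            assert focal_loss(p, y, gamma=0.0) == pytest.approx(ce, rel=1e-12)

    def test_confident_correct_prediction_costs_nothing(self):
        assert focal_loss(np.array([[1.0, 0.0]]), [0], gamma=2.0) == 0.0

    def test_reference_value(self):
        # γ=2, α_label=0.25, p_label=0.5 → 0.25 · 0.25 · ln 2
        got = focal_loss(np.array([[0.5, 0.5]]), [0], gamma=2.0, alpha=(0.25, 0.75))
        assert got == pytest.approx(0.25 * 0.25 * np.log(2.0), rel=1e-12)

    def test_zero_probability_is_clamped_not_raised(self):
        val = focal_loss(np.array([[0.0, 1.0]]), [0], gamma=2.0)
        assert np.isfinite(val) and val > 0

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        p=st.floats(0.01, 0.98),
        delta=st.floats(0.001, 0.02),
        gamma=st.floats(0.0, 4.0),
    )
    def test_nonnegative_and_monotone_decreasing_in_p(self, p, delta, gamma):
        lo = focal_loss(np.array([[p, 1 - p]]), [0], gamma=gamma)
        hi = focal_loss(np.array([[p + delta, 1 - p - delta]]), [0], gamma=gamma)
        assert lo >= 0 and hi <= lo

    def test_gradient_matches_numeric(self, rng):
        """Logit gradient of the focal loss vs central differences."""
        z = rng.normal(size=(4, 3))
        y = np.array([0, 2, 1, 2])
        gamma, alpha = 2.0, (0.2, 0.5, 0.3)

        def loss_of(zz):
            e = np.exp(zz - zz.max(axis=1, keepdims=True))
            return focal_loss(e / e.sum(axis=1, keepdims=True), y, gamma, alpha)

        e = np.exp(z - z.max(axis=1, keepdims=True))
        g = focal_loss_grad(e / e.sum(axis=1, keepdims=True), y, gamma, alpha)
        eps = 1e-6
        for i in range(4):
            for j in range(3):
                zp, zm = z.copy(), z.copy()
                zp[i, j] += eps
                zm[i, j] -= eps
                num = (loss_of(zp) - loss_of(zm)) / (2 * eps)
                assert g[i, j] == pytest.approx(num, rel=1e-5, abs=1e-9)

    def test_invalid_alpha_rejected(self):
        with pytest.raises(ValueError):
            TrainConfig(focal_alpha=(0.5, 1.5))
        with pytest.raises(ValueError):
            focal_loss(np.array([[0.5, 0.5]]), [0], alpha=(0.5,))


def _toy_separable(rng, n=60):
    """Linearly separable 2-class toy set in 5 dimensions."""
    x0 = rng.normal(size=(n // 2, 5)) + np.array([2, 0, 0, 0, 0])
    x1 = rng.normal(size=(n // 2, 5)) - np.array([2, 0, 0, 0, 0])
    x = np.vstack([x0, x1])
    y = np.array([0] * (n // 2) + [1] * (n // 2))
    return x, y


class TestTrain:
    def test_same_seed_identical_weights(self, rng):
        x, y = _toy_separable(rng)
        runs = []
        for _ in range(2):
            m = MLPBaseline(MLPBaselineConfig((5, 4, 2), seed=3))
            train(m, x, y, TrainConfig(epochs=5, seed=3))
            runs.append({k: v.copy() for k, v in m.params.items()})
        for k in runs[0]:
            assert np.array_equal(runs[0][k], runs[1][k])

    def test_loss_decreases_on_separable_data(self, rng):
        x, y = _toy_separable(rng)
        m = MLPBaseline(MLPBaselineConfig((5, 4, 2), seed=0))
        hist = train(m, x, y, TrainConfig(epochs=10, seed=0, learning_rate=0.01))
        losses = [h["loss"] for h in hist]
        assert all(b < a for a, b in zip(losses, losses[1:]))

    def test_matches_cross_entropy_reference_step_for_step(self, rng):
        """With γ=0 and uniform α the trainer follows an independently coded
        softmax-regression + Adam reference to 1e-6."""
        x, y = _toy_separable(rng, n=40)
        m = MLPBaseline(MLPBaselineConfig((5, 2), seed=1))
        w0, b0 = m.params["w0"].copy(), m.params["b0"].copy()
        cfg = TrainConfig(epochs=3, seed=2, learning_rate=0.01, batch_size=8)
        train(m, x, y, cfg)

        # reference: explicit CE gradients and textbook Adam
        w, b = w0, b0
        mom = {"w": np.zeros_like(w), "b": np.zeros_like(b)}
        vel = {"w": np.zeros_like(w), "b": np.zeros_like(b)}
        t = 0
        rng2 = np.random.default_rng(2)
        for _ in range(3):
            order = rng2.permutation(len(y))
            for lo in range(0, len(order), 8):
                sel = order[lo : lo + 8]
                z = x[sel] @ w + b
                e = np.exp(z - z.max(axis=1, keepdims=True))
                p = e / e.sum(axis=1, keepdims=True)
                p[np.arange(len(sel)), y[sel]] -= 1.0
                p /= len(sel)
                gw, gb = x[sel].T @ p, p.sum(axis=0)
                t += 1
                for key, g, arr in (("w", gw, w), ("b", gb, b)):
                    mom[key] = 0.9 * mom[key] + 0.1 * g
                    vel[key] = 0.999 * vel[key] + 0.001 * g * g
                    mhat = mom[key] / (1 - 0.9**t)
                    vhat = vel[key] / (1 - 0.999**t)
                    arr -= 0.01 * mhat / (np.sqrt(vhat) + 1e-8)
        assert np.allclose(m.params["w0"], w, atol=1e-6)
        assert np.allclose(m.params["b0"], b, atol=1e-6)

    def test_empty_dataset_rejected(self):
        m = MLPBaseline(MLPBaselineConfig((5, 2)))
        with pytest.raises(ValueError):
            train(m, np.empty((0, 5)), np.empty(0), TrainConfig())

    def test_early_stopping_on_monitored_class(self, rng):
        x, y = _toy_separable(rng)
        m = MLPBaseline(MLPBaselineConfig((5, 4, 2), seed=0))
        cfg = TrainConfig(epochs=200, seed=0, early_stop_class=0, patience=3)
        hist = train(m, x, y, cfg, validation=(x, y))
        assert len(hist) < 200  # recall saturates at 1.0 and stops early


class TestEvaluate:
    def test_perfect_predictions(self):
        model = _StubModel(np.eye(3))
        y = np.array([0, 1, 2, 1, 0])
        rep = evaluate(model, y, y, n_classes=3)
        assert rep.overall_accuracy == 1.0
        assert rep.per_class_accuracy == [1.0, 1.0, 1.0]
        assert rep.per_class_dice == [1.0, 1.0, 1.0]

    def test_hand_computed_confusion_matrix(self):
        """Truth/prediction stream realizing the matrix [[40,10],[20,30]]."""
        model = _StubModel(np.eye(2))
        y_true = np.array([0] * 50 + [1] * 50)
        y_pred = np.array([0] * 40 + [1] * 10 + [0] * 20 + [1] * 30)
        rep = evaluate(model, y_pred, y_true, n_classes=2)
        assert np.array_equal(rep.confusion_matrix, [[40, 10], [20, 30]])
        assert rep.per_class_accuracy[0] == pytest.approx(0.8)
        assert rep.per_class_dice[0] == pytest.approx(2 * 40 / (80 + 10 + 20))
        assert rep.overall_accuracy == pytest.approx(0.7)
        # overall accuracy equals trace/total of the confusion matrix
        cm = rep.confusion_matrix
        assert rep.overall_accuracy == np.trace(cm) / cm.sum()

    def test_all_one_class_predictor_on_balanced_data(self):
        model = _StubModel(np.tile([1.0, 0.0], (2, 1)))
        y = np.array([0] * 10 + [1] * 10)
        rep = evaluate(model, y, y, n_classes=2)
        assert rep.overall_accuracy == 0.5

    def test_absent_class_recall_is_undefined_not_zero(self):
        model = _StubModel(np.eye(3))
        y_true = np.array([0, 0, 1, 1])
        rep = evaluate(model, y_true, y_true, n_classes=3)
        assert rep.per_class_accuracy[2] is None
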