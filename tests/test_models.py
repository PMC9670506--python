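"""Model assembly: shapes, parameter accounting, invariance, gradients."""

import numpy as np
import pytest

from bgcnn.models import (
    ClassifierConfig,
    GCNNClassifier,
    MLPBaseline,
    MLPBaselineConfig,
    count_parameters,
    load_checkpoint,
    save_checkpoint,
)
from bgcnn.sphere_geometry import build_icosahedron
from bgcnn.spherical_interp import SphericalSignal
from bgcnn.training_eval import focal_loss, focal_loss_grad
from conftest import random_unit_vectors


def _random_signal(rng, n=90):
    return SphericalSignal(random_unit_vectors(rng, n), rng.normal(size=n))


@pytest.mark.parametrize("n_classes,expected", [(2, 164), (4, 286), (6, 408)])
def test_reference_parameter_counts(n_classes, expected):
    model = GCNNClassifier(ClassifierConfig(n_classes=n_classes))
    assert count_parameters(model) == expected


def test_layer_shapes_reference_config():
    m = GCNNClassifier(ClassifierConfig(n_classes=2))
    assert m.params["lift_w"].shape == (1, 1, 11)
    assert m.params["lift_b"].shape == (1,)
    assert m.params["conv_w"].shape == (1, 5, 5)
    assert m.params["conv_b"].shape == (5,)
    assert m.params["fc_w"].shape == (60, 2)
    assert m.params["fc_b"].shape == (2,)


def test_parameter_count_closed_form(rng):
    """Nc·Nl·11 + Nl + Nl·Ncv·5 + Ncv + 12·Ncv·K + K for random configs."""
    for _ in range(20):
        nc, nl, ncv, k = rng.integers(1, 6, size=4)
        m = GCNNClassifier(
            ClassifierConfig(
                n_classes=int(k) + 1, n_input_channels=int(nc),
                n_lift_channels=int(nl), n_conv_channels=int(ncv),
            )
        )
        expect = nc * nl * 11 + nl + nl * ncv * 5 + ncv + 12 * ncv * (k + 1) + (k + 1)
        assert count_parameters(m) == expect


@pytest.mark.parametrize(
    "widths,hidden_norm,expected",
    [((90, 50, 30, 2), False, 6142), ((90, 50, 30, 2), True, 6302),
     ((80, 50, 30, 2), True, 5802)],
)
def test_baseline_parameter_counts(widths, hidden_norm, expected):
    m = MLPBaseline(MLPBaselineConfig(layer_widths=widths, hidden_norm=hidden_norm))
    assert count_parameters(m) == expected


def test_forward_outputs_probabilities(rng):
    m = GCNNClassifier(ClassifierConfig(n_classes=4, seed=7))
    p = m.forward(_random_signal(rng))
    assert p.shape == (4,) and (p >= 0).all()
    assert p.sum() == pytest.approx(1.0, abs=1e-6)


def test_zero_signal_gives_uniform_probabilities(rng):
    m = GCNNClassifier(ClassifierConfig(n_classes=3))
    sig = SphericalSignal(random_unit_vectors(rng, 90), np.zeros(90))
    assert np.allclose(m.forward(sig), 1.0 / 3.0, atol=1e-12)


def test_seeded_init_is_deterministic():
    a = GCNNClassifier(ClassifierConfig(n_classes=2, seed=11))
    b = GCNNClassifier(ClassifierConfig(n_classes=2, seed=11))
    for k in a.params:
        assert np.array_equal(a.params[k], b.params[k])


def test_channel_mismatch_rejected(rng):
    m = GCNNClassifier(ClassifierConfig(n_classes=2, n_input_channels=2))
    with pytest.raises(ValueError):
        m.forward(_random_signal(rng))


def test_invalid_config_rejected():
    with pytest.raises(ValueError):
        ClassifierConfig(n_classes=0)
    with pytest.raises(ValueError):
        ClassifierConfig(n_classes=2, kernel_radius=-1.0)
    with pytest.raises(ValueError):
        MLPBaselineConfig(layer_widths=(90,))


class TestEndToEndInvariance:
    """Discrete path independence: the projected output does not depend on
    the per-vertex frame anchoring (up to grid rotations) or, after snapping
    to the induced grid, on the choice of base vertex."""

    def test_invariant_under_2pi5_reanchoring(self, rng):
        m = GCNNClassifier(ClassifierConfig(n_classes=3, seed=2))
        sig = _random_signal(rng)
        p0 = m.forward(sig)
        chart = m.chart
        ks = rng.integers(0, 5, size=12)
        m.set_chart(
            chart.with_frames(
                [f.rotated(2 * np.pi / 5 * int(k)) for f, k in zip(chart.frames, ks)]
            )
        )
        assert np.allclose(m.forward(sig), p0, atol=1e-6)

    def test_invariant_under_base_vertex_change_snapped(self, rng):
        m = GCNNClassifier(ClassifierConfig(n_classes=3, seed=2))
        sig = _random_signal(rng)
        p0 = m.forward(sig)
        old = m.chart
        for base in (3, 7):
            new = build_icosahedron(base_index=base)
            snapped = []
            for f_new, f_old in zip(new.frames, old.frames):
                ang = np.arctan2(f_new.e1 @ f_old.e2, f_new.e1 @ f_old.e1)
                k = round(ang / (2 * np.pi / 5))
                snapped.append(f_old.rotated(2 * np.pi / 5 * k))
            m.set_chart(old.with_frames(snapped))
            assert np.allclose(m.forward(sig), p0, atol=1e-6)
            m.set_chart(old)

    def test_raw_base_change_approximately_invariant(self, rng):
        """Arbitrary-angle re-anchorings move the interpolation sample points,
        so invariance is only approximate for a smoothly varying signal."""
        m = GCNNClassifier(ClassifierConfig(n_classes=3, seed=2))
        d = random_unit_vectors(rng, 90)
        sig = SphericalSignal(d, d[:, 0] ** 2 + 0.5 * d[:, 2])  # smooth field
        p0 = m.forward(sig)
        m.set_chart(build_icosahedron(base_index=5))
        p1 = m.forward(sig)
        assert np.abs(p1 - p0).max() / np.abs(p0).max() < 0.05


@pytest.mark.parametrize("kind", ["gcnn", "mlp"])
def test_analytic_gradients_match_numeric(kind, rng):
    """Central-difference check of the full forward/backward pass on a
    3-sample batch, focal loss with γ=2 and nonuniform α."""
    if kind == "gcnn":
        model = GCNNClassifier(ClassifierConfig(n_classes=2, seed=5))
        x = rng.normal(size=(3, 12, 1, 11))
    else:
        model = MLPBaseline(
            MLPBaselineConfig(layer_widths=(7, 6, 2), hidden_norm=True, seed=5)
        )
        x = rng.normal(size=(3, 7))
    y = np.array([0, 1, 0])
    gamma, alpha = 2.0, (0.25, 0.75)

    def loss():
        probs, _ = model.forward_batch(x)
        return focal_loss(probs, y, gamma, alpha)

    probs, cache = model.forward_batch(x)
    grads = model.backward_batch(cache, focal_loss_grad(probs, y, gamma, alpha))
    eps = 1e-6
    for name, p in model.params.items():
        flat = p.reshape(-1)
        for idx in rng.choice(flat.size, size=min(6, flat.size), replace=False):
            orig = flat[idx]
            flat[idx] = orig + eps
            up = loss()
            flat[idx] = orig - eps
            down = loss()
            flat[idx] = orig
            num = (up - down) / (2 * eps)
            ana = grads[name].reshape(-1)[idx]
            assert ana == pytest.approx(num, rel=1e-4, abs=1e-8), name


def test_checkpoint_roundtrip(tmp_path, rng):
    m = GCNNClassifier(ClassifierConfig(n_classes=2, seed=9))
    path = tmp_path / "ckpt.json"
    save_checkpoint(m, str(path))
    loaded = load_checkpoint(str(path))
    for k in m.params:
        assert np.array_equal(m.params[k], loaded.params[k])
    sig = _random_signal(rng)
    assert np.allclose(m.forward(sig), loaded.forward(sig), atol=1e-15)

    mlp = MLPBaseline(MLPBaselineConfig((9, 5, 2), hidden_norm=True, seed=1))
    path2 = tmp_path / "mlp.json"
    save_checkpoint(mlp, str(path2))
    loaded2 = load_checkpoint(str(path2))
    for k in mlp.params:
        assert np.array_equal(mlp.params[k], loaded2.params[k])
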