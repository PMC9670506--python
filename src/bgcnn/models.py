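"""Voxel classifiers: the manifold G-CNN and a dense baseline.

The proposed classifier is lift → ReLU → group correlation → ReLU →
max-projection → fully connected → softmax.  With the reference settings
(1 lift channel, 5 group channels, 11-point kernel grid, 5 rotations,
12-vertex dense head) the parameter totals are 164 / 286 / 408 for
2 / 4 / 6 classes.

Models are plain numpy: parameters live in an ordered ``params`` dict, the
forward pass returns class probabilities plus a cache, and ``backward``
turns a gradient w.r.t. the logits into parameter gradients.  The trainer in
:mod:`bgcnn.training_eval` only relies on this interface.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np

from . import gcnn_layers as L
from .sphere_geometry import (
    IcosahedralChart,
    KernelGrid,
    all_sample_points,
    build_icosahedron,
    build_kernel_grid,
)
from .spherical_interp import SphericalSignal, watson_weight_matrix

__all__ = [
    "ClassifierConfig",
    "MLPBaselineConfig",
    "GCNNClassifier",
    "MLPBaseline",
    "build_classifier",
    "build_mlp_baseline",
    "count_parameters",
    "save_checkpoint",
    "load_checkpoint",
]

CHART_CONVENTION = "icosahedron-golden-ratio-northpole-v1"
CHECKPOINT_VERSION = 1


@dataclass(frozen=True)
class ClassifierConfig:
    """Reference architecture: ``k = (1, 5, n)`` channels for lift, group
    correlation and the dense head, kernel radius 0.6 rad, 5 rays × 2
    samples (+ center), Watson concentration κ for the input interpolation.
    """

    n_classes: int
    n_input_channels: int = 1
    n_lift_channels: int = 1
    n_conv_channels: int = 5
    kernel_radius: float = 0.6
    n_rays: int = 5
    n_samples_per_ray: int = 2
    kappa: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "n_classes", "n_input_channels", "n_lift_channels", "n_conv_channels",
            "n_rays", "n_samples_per_ray",
        ):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        if self.kernel_radius <= 0 or self.kappa <= 0:
            raise ValueError("kernel_radius and kappa must be positive")


def _he_uniform(rng: np.random.Generator, shape: tuple, fan_in: int) -> np.ndarray:
    bound = np.sqrt(6.0 / fan_in)
    return rng.uniform(-bound, bound, size=shape)


class GCNNClassifier:
    """lift–ReLU–conv–ReLU–projection–FC–softmax voxel classifier."""

    def __init__(self, config: ClassifierConfig, chart: IcosahedralChart | None = None):
        self.config = config
        self.chart = chart if chart is not None else build_icosahedron()
        self.grid: KernelGrid = build_kernel_grid(
            config.kernel_radius, config.n_rays, config.n_samples_per_ray, True
        )
        self.perm = self.grid.rotation_permutations()
        self._refresh_sample_points()
        rng = np.random.default_rng(config.seed)
        g = len(self.grid)
        ci, cl, cc, nc = (
            config.n_input_channels,
            config.n_lift_channels,
            config.n_conv_channels,
            config.n_classes,
        )
        self.params: dict[str, np.ndarray] = {
            "lift_w": _he_uniform(rng, (ci, cl, g), ci * g),
            "lift_b": np.zeros(cl),
            "conv_w": _he_uniform(rng, (cl, cc, config.n_rays), cl * config.n_rays),
            "conv_b": np.zeros(cc),
            "fc_w": _he_uniform(rng, (12 * cc, nc), 12 * cc),
            "fc_b": np.zeros(nc),
        }

    def _refresh_sample_points(self) -> None:
        pts = all_sample_points(self.chart, self.grid)  # (12, n_grid, 3)
        self.sample_points = pts.reshape(-1, 3)

    def set_chart(self, chart: IcosahedralChart) -> None:
        """Swap the chart (e.g. with re-anchored frames); weights are kept."""
        self.chart = chart
        self._refresh_sample_points()

    # ------------------------------------------------------------------ #
    # featurization: fixed linear resampling onto the chart sample points #
    # ------------------------------------------------------------------ #
    def featurize(self, directions: np.ndarray, values: np.ndarray) -> np.ndarray:
        """Watson-resample a batch of signals onto the chart sample points.

        Parameters
        ----------
        directions : (batch, n_dir, 3) per-sample acquisition directions
        values : (batch, n_dir) or (batch, n_dir, n_channels)

        Returns
        -------
        (batch, 12, n_channels, n_grid) array feeding the lifting layer.
        """
        directions = np.asarray(directions, dtype=float)
        values = np.asarray(values, dtype=float)
        if values.ndim == 2:
            values = values[..., None]
        B, _, n_ch = values.shape
        n_grid = len(self.grid)
        out = np.empty((B, 12 * n_grid, n_ch))
        kappa = self.config.kappa
        q = self.sample_points
        for lo in range(0, B, 512):  # chunked: the weight tensor is per-sample
            hi = min(lo + 512, B)
            cos2 = np.einsum("qd,bnd->bqn", q, directions[lo:hi]) ** 2
            w = np.exp(kappa * (cos2 - cos2.max(axis=2, keepdims=True)))
            w /= w.sum(axis=2, keepdims=True)
            out[lo:hi] = np.einsum("bqn,bnc->bqc", w, values[lo:hi])
        return out.reshape(B, 12, n_grid, n_ch).transpose(0, 1, 3, 2)

    def featurize_signal(self, signal: SphericalSignal) -> np.ndarray:
        w = watson_weight_matrix(signal.directions, self.sample_points, self.config.kappa)
        vals = signal.values if signal.values.ndim == 2 else signal.values[:, None]
        res = (w @ vals).reshape(12, len(self.grid), -1)
        return res.transpose(0, 2, 1)[None]

    # ----------------------------- forward ---------------------------- #
    def forward_batch(self, x: np.ndarray) -> tuple[np.ndarray, dict]:
        """Probabilities for featurized input ``x`` (batch, 12, Cin, n_grid)."""
        p = self.params
        z1 = L.lift_forward(x, p["lift_w"], p["lift_b"], self.perm)
        a1 = L.relu(z1)
        z2 = L.group_correlate(a1, p["conv_w"], p["conv_b"])
        a2 = L.relu(z2)
        m = L.project_max(a2)  # (B, 12, Cconv)
        flat = m.reshape(m.shape[0], -1)  # vertex-major
        logits = flat @ p["fc_w"] + p["fc_b"]
        logits -= logits.max(axis=1, keepdims=True)
        e = np.exp(logits)
        probs = e / e.sum(axis=1, keepdims=True)
        cache = {"x": x, "z1": z1, "a1": a1, "z2": z2, "a2": a2, "flat": flat}
        return probs, cache

    def forward(self, signal: SphericalSignal) -> np.ndarray:
        """Class probabilities for a single raw signal."""
        if signal.n_channels != self.config.n_input_channels:
            raise ValueError("signal channel count does not match the model")
        return self.forward_batch(self.featurize_signal(signal))[0][0]

    def backward_batch(self, cache: dict, grad_logits: np.ndarray) -> dict:
        p = self.params
        grads: dict[str, np.ndarray] = {}
        grads["fc_w"] = cache["flat"].T @ grad_logits
        grads["fc_b"] = grad_logits.sum(axis=0)
        g_flat = grad_logits @ p["fc_w"].T
        g_m = g_flat.reshape(cache["a2"].shape[0], 12, -1)
        g_a2 = L.project_max_backward(cache["a2"], g_m)
        g_z2 = L.relu_backward(cache["z2"], g_a2)
        g_a1, grads["conv_w"], grads["conv_b"] = L.group_correlate_backward(
            cache["a1"], p["conv_w"], g_z2
        )
        g_z1 = L.relu_backward(cache["z1"], g_a1)
        grads["lift_w"], grads["lift_b"] = L.lift_backward(cache["x"], self.perm, g_z1)
        return grads


@dataclass(frozen=True)
class MLPBaselineConfig:
    """Dense stack FC(w0)-ReLU-…-FC(w_last) on the raw per-direction values.

    ``hidden_norm`` inserts a trainable per-unit scale and shift after each
    hidden ReLU (adds ``2·width`` parameters per hidden layer).
    """

    layer_widths: tuple
    hidden_norm: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.layer_widths) < 2 or any(w < 1 for w in self.layer_widths):
            raise ValueError("need >= 2 positive layer widths")


class MLPBaseline:
    """Multilayer perceptron on the fixed-direction resampled values."""

    def __init__(self, config: MLPBaselineConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        w = config.layer_widths
        self.n_layers = len(w) - 1
        self.params: dict[str, np.ndarray] = {}
        for i in range(self.n_layers):
            self.params[f"w{i}"] = _he_uniform(rng, (w[i], w[i + 1]), w[i])
            self.params[f"b{i}"] = np.zeros(w[i + 1])
            if config.hidden_norm and i < self.n_layers - 1:
                self.params[f"g{i}"] = np.ones(w[i + 1])
                self.params[f"s{i}"] = np.zeros(w[i + 1])

    def forward_batch(self, x: np.ndarray) -> tuple[np.ndarray, dict]:
        cache: dict = {"h": [x]}
        h = x
        for i in range(self.n_layers):
            z = h @ self.params[f"w{i}"] + self.params[f"b{i}"]
            cache[f"z{i}"] = z
            if i < self.n_layers - 1:
                h = L.relu(z)
                if self.config.hidden_norm:
                    cache[f"a{i}"] = h
                    h = h * self.params[f"g{i}"] + self.params[f"s{i}"]
                cache["h"].append(h)
        logits = z - z.max(axis=1, keepdims=True)
        e = np.exp(logits)
        probs = e / e.sum(axis=1, keepdims=True)
        return probs, cache

    def backward_batch(self, cache: dict, grad_logits: np.ndarray) -> dict:
        grads: dict[str, np.ndarray] = {}
        g = grad_logits
        for i in reversed(range(self.n_layers)):
            h = cache["h"][i]
            grads[f"w{i}"] = h.T @ g
            grads[f"b{i}"] = g.sum(axis=0)
            if i > 0:
                g = g @ self.params[f"w{i}"].T
                if self.config.hidden_norm:
                    a = cache[f"a{i-1}"]
                    grads[f"g{i-1}"] = (g * a).sum(axis=0)
                    grads[f"s{i-1}"] = g.sum(axis=0)
                    g = g * self.params[f"g{i-1}"]
                g = L.relu_backward(cache[f"z{i-1}"], g)
        return grads


def build_classifier(
    config: ClassifierConfig, chart: IcosahedralChart | None = None
) -> GCNNClassifier:
    """Construct the proposed classifier (seeded, deterministic structure)."""
    return GCNNClassifier(config, chart)


def build_mlp_baseline(config: MLPBaselineConfig) -> MLPBaseline:
    return MLPBaseline(config)


def count_parameters(model) -> int:
    """Total count of trainable scalars, biases included."""
    return int(sum(v.size for v in model.params.values()))


def save_checkpoint(model, path: str) -> None:
    """Versioned JSON checkpoint: config + weights + chart convention id."""
    kind = "gcnn" if isinstance(model, GCNNClassifier) else "mlp"
    blob = {
        "version": CHECKPOINT_VERSION,
        "kind": kind,
        "chart": CHART_CONVENTION if kind == "gcnn" else None,
        "config": asdict(model.config),
        "params": {k: v.tolist() for k, v in model.params.items()},
    }
    with open(path, "w") as fh:
        json.dump(blob, fh)


def load_checkpoint(path: str):
    with open(path) as fh:
        blob = json.load(fh)
    if blob.get("version") != CHECKPOINT_VERSION:
        raise ValueError(f"unsupported checkpoint version {blob.get('version')}")
    if blob["kind"] == "gcnn":
        if blob["chart"] != CHART_CONVENTION:
            raise ValueError(f"unknown chart convention {blob['chart']!r}")
        model = GCNNClassifier(ClassifierConfig(**blob["config"]))
    else:
        cfg = blob["config"]
        cfg["layer_widths"] = tuple(cfg["layer_widths"])
        model = MLPBaseline(MLPBaselineConfig(**cfg))
    for k, v in blob["params"].items():
        model.params[k] = np.array(v, dtype=float)
    return model
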