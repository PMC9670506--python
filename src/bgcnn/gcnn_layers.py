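"""The three manifold-network layers: lifting, group correlation, projection.

Discrete setting: the sphere is charted by 12 icosahedron vertices, the
tangent-plane kernel lives on an 11-point polar grid with 5-fold symmetry,
and the rotation group of each tangent plane is discretized by the 5
rotations ``2πk/5`` that map the grid onto itself.

* The lifting layer correlates the parallel-transported kernel with the
  signal at every discrete rotation, producing a feature indexed by
  (vertex, rotation, channel) — a function on the bundle of tangent
  rotations.
* The group-correlation layer correlates along the rotation axis with a
  5-tap kernel, the discrete Haar integral being the uniform sum over the
  cyclic group C5.
* The projection layer takes the per-vertex maximum over rotations, which
  removes the dependence on the base point and on the choice of transport
  paths (any re-anchoring of a frame by a grid rotation only cyclically
  shifts the rotation axis).

Layers are plain functions on numpy arrays; each has a matching ``*_backward``
used by the trainer.  Features are ``float64`` arrays shaped
``(batch, vertex, rotation, channel)`` (``LiftedFeature``) or
``(batch, vertex, channel)`` (``ManifoldFeature``).
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "lift_forward",
    "lift_backward",
    "group_correlate",
    "group_correlate_backward",
    "project_max",
    "project_max_backward",
    "relu",
    "relu_backward",
]


def _rotated_view(sampled_values: np.ndarray, perm: np.ndarray) -> np.ndarray:
    """(B, V, Cin, J) -> (B, V, K, Cin, J) with slot j reading sample σ_k(j)."""
    return sampled_values[..., perm].transpose(0, 1, 3, 2, 4)


def lift_forward(
    sampled_values: np.ndarray,
    weights: np.ndarray,
    bias: np.ndarray,
    perm: np.ndarray,
) -> np.ndarray:
    """Lifting layer.

    ``F[b, v, k, co] = Σ_{ci,j} weights[ci, co, j] · sampled[b, v, ci, σ_k(j)]
    + bias[co]`` — the tangent-plane correlation of the transported kernel
    with the signal, evaluated at every discrete rotation ``k`` via the grid's
    cyclic-shift permutations ``perm`` (see
    :meth:`~bgcnn.sphere_geometry.KernelGrid.rotation_permutations`).

    Parameters
    ----------
    sampled_values : (batch, 12, n_in, n_grid)
        signal resampled at each vertex's tangent-plane sample points
    weights : (n_in, n_out, n_grid)
    bias : (n_out,)
    perm : (n_rotations, n_grid) σ_k permutations; requires 5-fold grid symmetry
    """
    if perm.shape[1] != sampled_values.shape[-1]:
        raise ValueError("kernel grid size mismatch")
    xr = _rotated_view(sampled_values, perm)
    return np.einsum("bvkcj,coj->bvko", xr, weights) + bias


def lift_backward(
    sampled_values: np.ndarray, perm: np.ndarray, grad_out: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Gradients of the lifting layer w.r.t. weights and bias."""
    xr = _rotated_view(sampled_values, perm)
    grad_w = np.einsum("bvko,bvkcj->coj", grad_out, xr)
    grad_b = grad_out.sum(axis=(0, 1, 2))
    return grad_w, grad_b


def _expanded_group_kernel(weights: np.ndarray) -> np.ndarray:
    """(Cin, Cout, R) -> (Cin, Cout, S, R) with entry [.., s, r] = w[.., (r−s) mod R]."""
    n_rot = weights.shape[2]
    s, r = np.meshgrid(np.arange(n_rot), np.arange(n_rot), indexing="ij")
    return weights[:, :, (r - s) % n_rot]


def group_correlate(
    lifted: np.ndarray, weights: np.ndarray, bias: np.ndarray
) -> np.ndarray:
    """Group correlation over the discrete rotation group of each tangent plane.

    ``out[b, v, s, co] = Σ_{ci,r} F[b, v, r, ci] · weights[ci, co, (r−s) mod R]
    + bias[co]`` — the group-theoretic correlation with the Haar integral
    realized as the uniform sum over the R rotations.  The same kernel indices
    are shared across vertices: conjugating a rotation by the transport
    isometry preserves its angle on consistently oriented tangent planes.
    """
    if weights.shape[0] != lifted.shape[-1]:
        raise ValueError(
            f"group kernel expects {weights.shape[0]} input channels, "
            f"feature has {lifted.shape[-1]}"
        )
    if weights.shape[2] != lifted.shape[2]:
        raise ValueError("rotation count mismatch between feature and kernel")
    wexp = _expanded_group_kernel(weights)
    return np.einsum("bvrc,cdsr->bvsd", lifted, wexp) + bias


def group_correlate_backward(
    lifted: np.ndarray, weights: np.ndarray, grad_out: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Gradients of group correlation w.r.t. input feature, weights, bias."""
    n_rot = weights.shape[2]
    wexp = _expanded_group_kernel(weights)
    grad_in = np.einsum("bvsd,cdsr->bvrc", grad_out, wexp)
    gexp = np.einsum("bvsd,bvrc->cdsr", grad_out, lifted)
    grad_w = np.zeros_like(weights)
    for s in range(n_rot):
        for r in range(n_rot):
            grad_w[:, :, (r - s) % n_rot] += gexp[:, :, s, r]
    grad_b = grad_out.sum(axis=(0, 1, 2))
    return grad_in, grad_w, grad_b


def project_max(lifted: np.ndarray) -> np.ndarray:
    """Projection layer: per-vertex maximum over the rotation axis.

    Collapses the bundle feature back to a function on the sphere; the max is
    invariant to cyclic shifts of the rotation axis, which is what removes the
    base-point and transport-path dependence of the preceding layers.
    """
    return lifted.max(axis=2)


def project_max_backward(lifted: np.ndarray, grad_out: np.ndarray) -> np.ndarray:
    """Route the gradient to the (first) argmax rotation slot per (b, v, c)."""
    idx = lifted.argmax(axis=2)
    grad_in = np.zeros_like(lifted)
    b, v, c = np.meshgrid(
        np.arange(lifted.shape[0]),
        np.arange(lifted.shape[1]),
        np.arange(lifted.shape[3]),
        indexing="ij",
    )
    grad_in[b, v, idx, c] = grad_out
    return grad_in


def relu(x: np.ndarray) -> np.ndarray:
    """Elementwise ``max(x, 0)``."""
    return np.maximum(x, 0.0)


def relu_backward(x: np.ndarray, grad_out: np.ndarray) -> np.ndarray:
    return grad_out * (x > 0.0)
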