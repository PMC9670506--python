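"""Watson-kernel interpolation of directional signals.

DWI signals are sampled at a fixed set of gradient directions; the network
needs values at the chart's tangent-plane sample points.  Interpolation uses
the antipodally symmetric Watson weighting ``exp(κ (q·g)²)``, row-normalized
so the weights form a partition of unity (the Watson normalizing constant
cancels).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["SphericalSignal", "watson_weight_matrix", "resample"]


@dataclass
class SphericalSignal:
    """A single voxel's directional samples.

    Parameters
    ----------
    directions : (n, 3) unit vectors
    values : (n,) or (n, n_channels) per-direction values
    """

    directions: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.directions = np.asarray(self.directions, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        norms = np.linalg.norm(self.directions, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-6):
            raise ValueError("signal directions must be unit vectors")
        if self.values.shape[0] != self.directions.shape[0]:
            raise ValueError("one value row per direction required")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("signal values must be finite")

    @property
    def n_channels(self) -> int:
        return 1 if self.values.ndim == 1 else self.values.shape[1]


def watson_weight_matrix(
    directions: np.ndarray, queries: np.ndarray, kappa: float
) -> np.ndarray:
    """Row-normalized Watson weights, shape ``(n_queries, n_directions)``.

    Entry ``(q, g)`` is proportional to ``exp(κ (q·g)²)``; each row sums to 1.
    The squared cosine makes the kernel antipodally symmetric, matching the
    antipodal symmetry of diffusion acquisitions.
    """
    if kappa <= 0:
        raise ValueError("kappa must be positive")
    directions = np.asarray(directions, dtype=float)
    queries = np.asarray(queries, dtype=float)
    cos2 = (queries @ directions.T) ** 2
    # subtract the row max before exponentiating; cancels under normalization
    w = np.exp(kappa * (cos2 - cos2.max(axis=1, keepdims=True)))
    return w / w.sum(axis=1, keepdims=True)


def resample(signal: SphericalSignal, weights: np.ndarray) -> np.ndarray:
    """Interpolated values at the query points: ``weights @ values``.

    Linear in the signal and convex per query point (weights are nonnegative
    and row-normalized), channel-wise for multi-channel signals.
    """
    weights = np.asarray(weights, dtype=float)
    if weights.shape[1] != signal.values.shape[0]:
        raise ValueError(
            f"weight matrix has {weights.shape[1]} columns but signal has "
            f"{signal.values.shape[0]} directions"
        )
    return weights @ signal.values
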