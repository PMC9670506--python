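"""Synthetic rotation-classification dataset.

Each class is one fixed spherical function — values drawn i.i.d. from a
common Gaussian at 90 directions sampled uniformly on a hemisphere — and the
members of the class are random 3D rotations of that function.  Classes are
therefore indistinguishable by value statistics alone; only the arrangement
of values on the sphere, up to rotation, separates them.  This isolates
exactly the property the rotation-invariant network is built for, and a
plain multilayer perceptron on the raw values should sit at chance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

__all__ = [
    "SyntheticSpec",
    "SyntheticSample",
    "sample_hemisphere_directions",
    "make_class_prototypes",
    "random_rotation",
    "generate_dataset",
    "save_dataset",
    "load_dataset",
]


@dataclass(frozen=True)
class SyntheticSpec:
    """Generation parameters; the defaults are the study conditions."""

    n_classes: int = 2
    n_directions: int = 90
    n_train_per_class: int = 50
    n_test_per_class: int = 1000
    value_mean: float = 0.0
    value_std: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_classes < 2:
            raise ValueError("need at least 2 classes")
        if min(self.n_directions, self.n_train_per_class, self.n_test_per_class) < 1:
            raise ValueError("counts must be positive")


@dataclass(frozen=True)
class SyntheticSample:
    directions: np.ndarray  # (n_directions, 3): rotation @ base directions
    values: np.ndarray  # (n_directions,): the class prototype values
    label: int
    rotation: np.ndarray = field(repr=False, default=None)  # (3, 3), det +1


def sample_hemisphere_directions(n: int, seed: int) -> np.ndarray:
    """``n`` unit vectors uniform on the upper hemisphere (z >= 0)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    z = rng.uniform(0.0, 1.0, size=n)  # area element is uniform in z
    phi = rng.uniform(0.0, 2.0 * np.pi, size=n)
    s = np.sqrt(1.0 - z**2)
    return np.column_stack([s * np.cos(phi), s * np.sin(phi), z])


def make_class_prototypes(spec: SyntheticSpec) -> np.ndarray:
    """Per-class value vectors, shape ``(n_classes, n_directions)``.

    All classes draw from the same Gaussian so their value scales are
    identical and only the spatial arrangement distinguishes them.
    """
    rng = np.random.default_rng(spec.seed + 1)
    return rng.normal(
        spec.value_mean, spec.value_std, size=(spec.n_classes, spec.n_directions)
    )


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """One Haar-uniform rotation matrix from the given stream."""
    return Rotation.random(random_state=rng).as_matrix()


def generate_dataset(
    spec: SyntheticSpec,
) -> tuple[list[SyntheticSample], list[SyntheticSample]]:
    """Build the train and test splits.

    Every sample applies a fresh independent rotation to the shared base
    directions and pairs them with its class's fixed values; train and test
    rotations come from one seeded stream, split by position.
    """
    base = sample_hemisphere_directions(spec.n_directions, spec.seed)
    prototypes = make_class_prototypes(spec)
    rng = np.random.default_rng(spec.seed + 2)
    train: list[SyntheticSample] = []
    test: list[SyntheticSample] = []
    for c in range(spec.n_classes):
        for split, count in ((train, spec.n_train_per_class), (test, spec.n_test_per_class)):
            for _ in range(count):
                rot = random_rotation(rng)
                split.append(
                    SyntheticSample(
                        directions=base @ rot.T,
                        values=prototypes[c],
                        label=c,
                        rotation=rot,
                    )
                )
    return train, test


def save_dataset(samples: list[SyntheticSample], prefix: str) -> None:
    """Write ``<prefix>.signals.tsv`` (per sample: 3·n direction components
    then n values, whitespace-separated) and ``<prefix>.labels.tsv`` (one
    label per row)."""
    sig = np.array(
        [np.concatenate([s.directions.ravel(), s.values]) for s in samples]
    )
    np.savetxt(f"{prefix}.signals.tsv", sig, fmt="%.17g", delimiter="\t")
    np.savetxt(
        f"{prefix}.labels.tsv",
        np.array([s.label for s in samples], dtype=int)[:, None],
        fmt="%d",
    )


def load_dataset(prefix: str) -> list[SyntheticSample]:
    """Inverse of :func:`save_dataset` (rotation matrices are not persisted)."""
    sig = np.atleast_2d(np.loadtxt(f"{prefix}.signals.tsv", delimiter="\t"))
    labels = np.loadtxt(f"{prefix}.labels.tsv", dtype=int).reshape(-1)
    n = sig.shape[1] // 4
    out = []
    for row, lab in zip(sig, labels):
        out.append(
            SyntheticSample(
                directions=row[: 3 * n].reshape(n, 3),
                values=row[3 * n :],
                label=int(lab),
            )
        )
    return out
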