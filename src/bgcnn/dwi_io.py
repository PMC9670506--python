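"""DWI volume plumbing: NIfTI images, FSL gradient tables, shell extraction,
b0 normalization, label handling and per-class voxel subsampling.

The classifier consumes one voxel at a time — a spherical signal sampled at
the acquisition's gradient directions — so this module's job is to turn a
4D scan plus bval/bvec tables into per-voxel
:class:`~bgcnn.spherical_interp.SphericalSignal` batches.
"""

from __future__ import annotations

from dataclasses import dataclass

import nibabel as nib
import numpy as np

__all__ = [
    "GradientTable",
    "LabeledVoxelSet",
    "load_dwi",
    "extract_shell",
    "normalize_by_b0",
    "subsample_training_voxels",
    "write_synthetic_scan",
]

B0_TOLERANCE = 50.0  # s/mm²: volumes with b <= this count as unweighted


@dataclass(frozen=True)
class GradientTable:
    """FSL-style gradient table: one b-value and one direction per volume."""

    bvals: np.ndarray  # (n,)
    bvecs: np.ndarray  # (n, 3); zero rows allowed for b0 volumes

    def __post_init__(self) -> None:
        if len(self.bvals) != len(self.bvecs):
            raise ValueError("bvals and bvecs length mismatch")
        norms = np.linalg.norm(self.bvecs, axis=1)
        nz = norms > 1e-6
        if not np.allclose(norms[nz], 1.0, atol=1e-3):
            raise ValueError("nonzero bvecs must be unit vectors (within 1e-3)")

    def __len__(self) -> int:
        return len(self.bvals)


@dataclass
class LabeledVoxelSet:
    """Flattened voxel signals with labels: the network's training table."""

    indices: np.ndarray  # (n_voxels, 3) integer voxel coordinates
    directions: np.ndarray  # (n_dir, 3) shared acquisition directions
    values: np.ndarray  # (n_voxels, n_dir)
    labels: np.ndarray  # (n_voxels,)


def _read_fsl_table(bval_path: str, bvec_path: str) -> GradientTable:
    bvals = np.loadtxt(bval_path).reshape(-1)
    bvecs = np.loadtxt(bvec_path)
    if bvecs.ndim != 2:
        raise ValueError("bvec file must be a 2-D table")
    if bvecs.shape == (3, 3):
        raise ValueError("ambiguous 3x3 bvec table: cannot infer orientation")
    if bvecs.shape[0] == 3 and bvecs.shape[1] != 3:
        bvecs = bvecs.T  # FSL stores 3 rows x N columns
    if bvecs.shape[1] != 3:
        raise ValueError("bvec table must be 3xN or Nx3")
    return GradientTable(bvals=bvals, bvecs=np.asarray(bvecs, dtype=float))


def load_dwi(image_path: str, bval_path: str, bvec_path: str):
    """Load a 4D NIfTI DWI volume with its gradient table.

    Returns ``(data, affine, GradientTable)``; the table length must match the
    number of volumes.
    """
    img = nib.load(image_path)
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim != 4:
        raise ValueError(f"expected a 4-D DWI image, got {data.ndim}-D")
    table = _read_fsl_table(bval_path, bvec_path)
    if data.shape[3] != len(table):
        raise ValueError(
            f"{data.shape[3]} volumes but {len(table)} gradient-table entries"
        )
    return data, img.affine, table


def extract_shell(
    data: np.ndarray,
    table: GradientTable,
    b_target: float,
    tolerance: float = 100.0,
    b0_tolerance: float = B0_TOLERANCE,
):
    """Split the 4D data into one shell plus the b0 volumes.

    Shell volumes satisfy ``|b − b_target| <= tolerance``; b0 volumes satisfy
    ``b <= b0_tolerance``.  Returns ``(shell_values, shell_directions,
    b0_values)`` with values shaped ``(x, y, z, n)``.
    """
    b = np.asarray(table.bvals, dtype=float)
    is_b0 = b <= b0_tolerance
    in_shell = (np.abs(b - b_target) <= tolerance) & ~is_b0
    if not in_shell.any():
        raise ValueError(f"no volumes found for shell b={b_target}")
    if not is_b0.any():
        raise ValueError("no b0 volumes found")
    return data[..., in_shell], table.bvecs[in_shell], data[..., is_b0]


def normalize_by_b0(shell_values: np.ndarray, b0_values: np.ndarray):
    """Divide each voxel's shell values by its mean b0 value.

    Voxels whose mean b0 is <= 0 are masked out (returned separately), not
    divided.  Returns ``(normalized, valid_mask)``.
    """
    if b0_values.shape[:-1] != shell_values.shape[:-1]:
        raise ValueError("shell and b0 grids differ")
    mean_b0 = b0_values.mean(axis=-1)
    if not (mean_b0 > 0).any():
        raise ValueError("all b0 values are zero or negative")
    valid = mean_b0 > 0
    out = np.zeros_like(shell_values)
    out[valid] = shell_values[valid] / mean_b0[valid][..., None]
    return out, valid


def subsample_training_voxels(
    labels: np.ndarray, per_class_counts: dict, seed: int
) -> np.ndarray:
    """Seeded uniform subsample without replacement, exact per-class counts.

    ``labels`` is a flat integer array (flatten a label volume first);
    ``per_class_counts`` maps class -> requested count.  Returns the selected
    flat indices, sorted.
    """
    labels = np.asarray(labels).reshape(-1)
    rng = np.random.default_rng(seed)
    chosen = []
    for cls, count in per_class_counts.items():
        pool = np.where(labels == cls)[0]
        if count > len(pool):
            raise ValueError(
                f"class {cls}: requested {count} voxels but only {len(pool)} available"
            )
        chosen.append(rng.choice(pool, size=count, replace=False))
    return np.sort(np.concatenate(chosen))


def voxel_signals(
    shell_values: np.ndarray,
    directions: np.ndarray,
    labels: np.ndarray | None = None,
    mask: np.ndarray | None = None,
) -> LabeledVoxelSet:
    """Flatten a shell volume into a per-voxel signal table."""
    shape = shell_values.shape[:-1]
    if mask is None:
        mask = np.ones(shape, dtype=bool)
    idx = np.argwhere(mask)
    vals = shell_values[mask]
    labs = (
        np.asarray(labels)[mask].astype(int)
        if labels is not None
        else np.full(len(idx), -1)
    )
    return LabeledVoxelSet(indices=idx, directions=directions, values=vals, labels=labs)


def write_synthetic_scan(
    prefix: str,
    shape: tuple = (6, 6, 6),
    n_directions: int = 12,
    n_b0: int = 2,
    b_value: float = 1000.0,
    seed: int = 0,
):
    """Write a tiny synthetic two-tissue NIfTI scan with FSL tables.

    Synthetic fixture for offline IO and end-to-end tests: the volume is split
    into two blocks along x.  Tissue 0 voxels carry an isotropic profile,
    tissue 1 an anisotropic one (signal suppressed along a fixed axis), plus
    mild seeded noise.  Returns the written paths
    ``(image, bval, bvec, labels)``.
    """
    rng = np.random.default_rng(seed)
    dirs = rng.normal(size=(n_directions, 3))
    dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
    bvals = np.concatenate([np.zeros(n_b0), np.full(n_directions, b_value)])
    bvecs = np.vstack([np.zeros((n_b0, 3)), dirs])
    labels = np.zeros(shape, dtype=np.int16)
    labels[shape[0] // 2 :] = 1
    axis = np.array([1.0, 0.0, 0.0])
    iso = np.full(n_directions, 0.6)
    aniso = 0.9 - 0.8 * (dirs @ axis) ** 2
    data = np.empty(shape + (n_b0 + n_directions,))
    b0_level = 100.0
    for ix in np.ndindex(shape):
        profile = aniso if labels[ix] else iso
        noise = 1.0 + 0.02 * rng.normal(size=n_directions)
        data[ix] = np.concatenate(
            [np.full(n_b0, b0_level), b0_level * profile * noise]
        )
    affine = np.eye(4)
    img_path = f"{prefix}.nii"
    nib.save(nib.Nifti1Image(data, affine), img_path)
    np.savetxt(f"{prefix}.bval", bvals[None], fmt="%g")
    np.savetxt(f"{prefix}.bvec", bvecs.T, fmt="%.8f")
    lab_path = f"{prefix}_labels.nii"
    nib.save(nib.Nifti1Image(labels, affine), lab_path)
    return img_path, f"{prefix}.bval", f"{prefix}.bvec", lab_path
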