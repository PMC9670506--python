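"""Geometry of the unit sphere S² and its icosahedral chart.

The network discretizes the sphere by the 12 vertices of a regular
icosahedron.  Each vertex carries an orthonormal tangent frame obtained by
parallel-transporting a reference frame at a base vertex along minimizing
geodesics, and a polar grid of tangent-plane offsets (the kernel support)
that is mapped onto the sphere with the exponential map.

All points and ambient tangent vectors are plain ``float64`` numpy arrays of
shape ``(3,)``; tangent-plane coordinates are 2-vectors in a vertex's frame,
measured in radians of arc length.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "TangentFrame",
    "IcosahedralChart",
    "KernelGrid",
    "exp_map",
    "log_map",
    "rotate_about_axis",
    "build_icosahedron",
    "transport_frame",
    "build_kernel_grid",
    "sample_points_for_vertex",
]

_GOLDEN = (1.0 + np.sqrt(5.0)) / 2.0
# cosine of the icosahedral edge arc: adjacent vertices satisfy x·y = 1/√5
ADJACENT_DOT = 1.0 / np.sqrt(5.0)
EDGE_ARC = float(np.arccos(ADJACENT_DOT))


def _unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    if n == 0.0:
        raise ValueError("cannot normalize the zero vector")
    return v / n


def rotate_about_axis(v: np.ndarray, axis: np.ndarray, angle: float) -> np.ndarray:
    """Rodrigues rotation of ``v`` about the unit ``axis`` by ``angle``."""
    axis = _unit(np.asarray(axis, dtype=float))
    v = np.asarray(v, dtype=float)
    c, s = np.cos(angle), np.sin(angle)
    return v * c + np.cross(axis, v) * s + axis * np.dot(axis, v) * (1.0 - c)


def exp_map(x: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Riemannian exponential at ``x``: follow the geodesic with initial
    velocity ``v`` (ambient tangent vector, |v| = arc length) for unit time.
    """
    x = np.asarray(x, dtype=float)
    v = np.asarray(v, dtype=float)
    theta = np.linalg.norm(v)
    if theta < 1e-300:
        return x.copy()
    return np.cos(theta) * x + np.sin(theta) * (v / theta)


def log_map(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Inverse of :func:`exp_map`: the ambient tangent vector at ``x``
    pointing to ``y`` with |log| = geodesic distance.

    Raises
    ------
    ValueError
        if ``y`` is antipodal to ``x`` (the log is undefined on the cut locus).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    c = float(np.clip(np.dot(x, y), -1.0, 1.0))
    if c <= -1.0 + 1e-12:
        raise ValueError("log_map undefined for antipodal points")
    theta = np.arccos(c)
    if theta < 1e-12:
        return np.zeros(3)
    w = y - c * x
    return theta * w / np.linalg.norm(w)


@dataclass(frozen=True)
class TangentFrame:
    """Right-handed orthonormal frame (e1, e2, vertex) of a tangent plane."""

    vertex: np.ndarray
    e1: np.ndarray
    e2: np.ndarray

    def to_ambient(self, p: np.ndarray) -> np.ndarray:
        """Ambient tangent vector for tangent-plane coordinates ``p``."""
        return p[0] * self.e1 + p[1] * self.e2

    def rotated(self, angle: float) -> "TangentFrame":
        """Frame re-anchored by an in-plane rotation about the vertex."""
        return TangentFrame(
            vertex=self.vertex,
            e1=rotate_about_axis(self.e1, self.vertex, angle),
            e2=rotate_about_axis(self.e2, self.vertex, angle),
        )


@dataclass(frozen=True)
class IcosahedralChart:
    """12-vertex discretization of S² with parallel-transported frames.

    ``frames[base_index]`` is the reference frame; every other frame is its
    parallel transport along the minimizing geodesic from the base vertex
    (two-leg path through the base's first neighbor for the antipode, where
    the minimizing geodesic is not unique).
    """

    vertices: np.ndarray  # (12, 3)
    adjacency: tuple  # 12 tuples of 5 neighbor indices
    frames: tuple  # 12 TangentFrames
    base_index: int

    def with_frames(self, frames) -> "IcosahedralChart":
        return IcosahedralChart(self.vertices, self.adjacency, tuple(frames), self.base_index)


def _canonical_vertices() -> np.ndarray:
    """Golden-ratio icosahedron rotated so vertex 0 sits at the north pole."""
    g = _GOLDEN
    raw = np.array(
        [
            [0, 1, g], [0, -1, g], [0, 1, -g], [0, -1, -g],
            [1, g, 0], [-1, g, 0], [1, -g, 0], [-1, -g, 0],
            [g, 0, 1], [-g, 0, 1], [g, 0, -1], [-g, 0, -1],
        ],
        dtype=float,
    )
    raw /= np.linalg.norm(raw, axis=1, keepdims=True)
    # rotate vertex 0 to (0,0,1): rotation about the x-axis
    v0 = raw[0]
    angle = np.arccos(np.clip(v0[2], -1, 1))
    axis = np.cross(v0, [0.0, 0.0, 1.0])
    out = np.array([rotate_about_axis(v, axis, angle) for v in raw])
    out[0] = [0.0, 0.0, 1.0]
    return out


def transport_frame(chart: IcosahedralChart, to_vertex: int) -> TangentFrame:
    """Parallel transport of the chart's base frame to ``to_vertex``.

    Transport along the minimizing geodesic is a rotation about the axis
    ``x0 × x`` by the arc ``arccos(x0·x)``.  For the base's antipode the
    minimizing geodesic is not unique; the chart uses the fixed two-leg path
    base → first neighbor → antipode, each leg minimizing.
    """
    x0 = chart.vertices[chart.base_index]
    base = chart.frames[chart.base_index]
    x = chart.vertices[to_vertex]
    if to_vertex == chart.base_index:
        return base

    def one_leg(frame: TangentFrame, a: np.ndarray, b: np.ndarray) -> TangentFrame:
        c = float(np.clip(np.dot(a, b), -1.0, 1.0))
        axis = np.cross(a, b)
        angle = np.arccos(c)
        return TangentFrame(
            vertex=b,
            e1=rotate_about_axis(frame.e1, axis, angle),
            e2=rotate_about_axis(frame.e2, axis, angle),
        )

    if np.dot(x0, x) <= -1.0 + 1e-10:  # antipode: fixed two-leg path
        mid = chart.vertices[chart.adjacency[chart.base_index][0]]
        return one_leg(one_leg(base, x0, mid), mid, x)
    return one_leg(base, x0, x)


def build_icosahedron(base_index: int = 0) -> IcosahedralChart:
    """Build the canonical icosahedral chart.

    The base frame anchors e1 to the direction of the base's first (lowest
    index) neighbor and e2 = vertex × e1; all other frames are parallel
    transports of it.  Deterministic: two builds are bitwise identical.
    """
    vertices = _canonical_vertices()
    if not 0 <= base_index < len(vertices):
        raise ValueError("base_index must be in 0..11")
    dots = vertices @ vertices.T
    adjacency = tuple(
        tuple(int(j) for j in np.where(np.abs(dots[i] - ADJACENT_DOT) < 1e-9)[0])
        for i in range(12)
    )
    x0 = vertices[base_index]
    first = vertices[adjacency[base_index][0]]
    e1 = _unit(log_map(x0, first))
    base = TangentFrame(vertex=x0, e1=e1, e2=np.cross(x0, e1))
    frames = [base] * 12
    tmp = IcosahedralChart(vertices, adjacency, tuple(frames), base_index)
    frames = tuple(transport_frame(tmp, i) for i in range(12))
    return tmp.with_frames(frames)


@dataclass(frozen=True)
class KernelGrid:
    """Polar sampling pattern of a tangent-plane kernel.

    Offsets are 2-vectors (arc-length units) laid out center-first then
    ray-major: index 0 is the center (when included), then ray ``i`` holds
    samples at radii ``radius·j/n_samples_per_ray``.  ``ray_of``/``radial_of``
    map offset index to its polar slot (-1 marks the center).
    """

    offsets: np.ndarray  # (n, 2)
    n_rays: int
    n_samples_per_ray: int
    radius: float
    include_center: bool
    ray_of: np.ndarray = field(repr=False, default=None)
    radial_of: np.ndarray = field(repr=False, default=None)

    def __len__(self) -> int:
        return len(self.offsets)

    def rotation_permutations(self) -> np.ndarray:
        """``perm[k, j] = σ_k(j)``: the center is fixed and kernel slot
        ``(ray i, radial s)`` reads the sample at ``(ray (i−k) mod n_rays,
        radial s)``.  This is the cyclic-shift evaluation the lifting layer
        uses to correlate the kernel at each discrete rotation.
        """
        n = len(self)
        perm = np.empty((self.n_rays, n), dtype=int)
        for k in range(self.n_rays):
            for j in range(n):
                if self.ray_of[j] < 0:
                    perm[k, j] = j
                else:
                    ray = (self.ray_of[j] - k) % self.n_rays
                    perm[k, j] = self._index_of(ray, self.radial_of[j])
        return perm

    def _index_of(self, ray: int, radial: int) -> int:
        off = 1 if self.include_center else 0
        return off + ray * self.n_samples_per_ray + radial


def build_kernel_grid(
    radius: float = 0.6,
    n_rays: int = 5,
    n_samples_per_ray: int = 2,
    include_center: bool = True,
) -> KernelGrid:
    """Polar grid of ``n_rays·n_samples_per_ray (+1 center)`` offsets with
    radii ``radius·j/n_samples_per_ray`` along rays at angles ``2πi/n_rays``.
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    if n_rays < 1 or n_samples_per_ray < 1:
        raise ValueError("n_rays and n_samples_per_ray must be >= 1")
    offsets, ray_of, radial_of = [], [], []
    if include_center:
        offsets.append([0.0, 0.0])
        ray_of.append(-1)
        radial_of.append(-1)
    for i in range(n_rays):
        ang = 2.0 * np.pi * i / n_rays
        d = np.array([np.cos(ang), np.sin(ang)])
        for j in range(1, n_samples_per_ray + 1):
            offsets.append(list(radius * j / n_samples_per_ray * d))
            ray_of.append(i)
            radial_of.append(j - 1)
    return KernelGrid(
        offsets=np.array(offsets),
        n_rays=n_rays,
        n_samples_per_ray=n_samples_per_ray,
        radius=radius,
        include_center=include_center,
        ray_of=np.array(ray_of),
        radial_of=np.array(radial_of),
    )


def sample_points_for_vertex(
    chart: IcosahedralChart, vertex: int, grid: KernelGrid
) -> np.ndarray:
    """Sphere points ``exp_map(x_v, offset)`` for every grid offset expressed
    in the vertex's transported frame.  Shape ``(len(grid), 3)``.
    """
    frame = chart.frames[vertex]
    x = chart.vertices[vertex]
    return np.array([exp_map(x, frame.to_ambient(p)) for p in grid.offsets])


def all_sample_points(chart: IcosahedralChart, grid: KernelGrid) -> np.ndarray:
    """Stacked sample points for every vertex, shape ``(12, len(grid), 3)``."""
    return np.stack([sample_points_for_vertex(chart, v, grid) for v in range(12)])
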