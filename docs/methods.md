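# Methods

## The model

A voxel of single-shell diffusion-weighted MRI is a function on the unit
sphere: one scalar per gradient direction. `bgcnn` classifies such voxels
with a convolutional network built directly on S² rather than on a Euclidean
embedding, so that the learned features are invariant to rotations of the
signal.

Three layers carry the construction:

1. **Lifting.** A kernel k lives on the tangent plane at a base vertex x₀,
   supported on the ball of radius r. It is carried to every other vertex x
   by parallel transport along the minimizing geodesic x₀ → x (a rotation of
   the ambient frame about the axis x₀ × x by arccos⟨x₀, x⟩). At each vertex
   the signal is pulled back to the tangent plane with the exponential map
   and correlated with the kernel at every rotation S of the tangent plane:

   F(x, S) = Σᵢ ∫ kᵢ(S⁻¹v) fᵢ(Exp_x v) dv .

   The result is a function on the bundle of tangent rotations, one circle's
   worth of responses per vertex.

2. **Group correlation.** F(x, ·) is correlated with a second kernel K over
   the rotation group of each tangent plane, the Haar integral realized
   discretely as the uniform sum over the grid rotations. Because transport
   conjugation preserves rotation angles on consistently oriented tangent
   planes, the same kernel taps are shared across vertices.

3. **Projection.** The per-vertex maximum over rotations collapses the
   bundle feature back to a function on the sphere. The choice of base
   point and of transport paths only rotates each tangent circle, so the
   maximum removes that dependence entirely.

ReLU follows the lifting and group-correlation layers (without a
nonlinearity in between, the pair would collapse into a single lifting —
verified as a property test). Biases are per output kernel. A single dense
layer on the flattened (vertex-major) projected features, followed by
softmax, produces class probabilities.

## Discretization

* **Chart.** The 12 vertices of a regular icosahedron (golden-ratio
  construction, rotated so the base vertex sits at (0,0,1)). Adjacent
  vertices satisfy ⟨x, y⟩ = 1/√5, giving an edge arc of ≈ 1.107 rad. The
  base frame anchors e₁ at the direction of the base's first neighbor; all
  other frames are its parallel transports. For the base's antipode the
  minimizing geodesic is not unique; a fixed two-leg path through the first
  neighbor keeps the chart deterministic, and the projection layer absorbs
  the arbitrariness.
* **Kernel grid.** A polar pattern on the tangent plane: 5 rays at angles
  2πi/5, 2 samples per ray at radii 0.3 and 0.6 (uniform radial spacing of
  the 0.6-rad kernel radius), plus the center — 11 points. The center is
  included because the resulting parameter totals (164/286/408 for 2/4/6
  classes) are the structural checksum of the architecture. With radius
  0.6 the kernel supports of adjacent vertices overlap (2·0.6 > 1.107).
* **Rotations.** The grid's 5-fold symmetry fixes the discrete rotation set
  to the five multiples of 2π/5; the lifting evaluates each rotation by a
  cyclic permutation of ray indices (center fixed), σ_k: (ray i, radial s)
  ↦ (ray i−k mod 5, radial s), and the group correlation is a 5-tap cyclic
  correlation.
* **Interpolation.** Acquisition directions never coincide with the 132
  chart sample points, so values are interpolated with a row-normalized
  Watson kernel, w(q, g) ∝ exp(κ⟨q, g⟩²). The squared cosine matches the
  antipodal symmetry of diffusion signals; row normalization makes the
  weights a partition of unity, so the Watson normalizing constant is never
  needed and constants are reproduced exactly. κ defaults: 5 for the
  synthetic task, 10 for scan data (smoother signals need less smoothing).
  Because the chart and grid are fixed, resampling is one precomputable
  linear map per acquisition scheme; the network proper is the learned part.

### Invariance, exactly and approximately

Re-anchoring any vertex's frame by a multiple of 2π/5 permutes that
vertex's sample points among themselves, cyclically shifts its rotation
axis, and leaves the projected output bit-identical (float tolerance 1e-6
end to end). The same holds for changing the base vertex once the induced
frames are snapped to the nearest grid rotation of the original frames.
Re-anchorings by arbitrary angles move the interpolation sample points to
genuinely new locations, so invariance there is approximate and is tested
at 5% relative tolerance on a smooth signal. Full SO(3) invariance of the
whole classifier is likewise approximate — limited by the 12-vertex
discretization and the interpolation — which is exactly what the synthetic
rotation experiment measures empirically.

## Training

Focal loss FL(p_t) = −α_t (1 − p_t)^γ log p_t (p_t clamped at 1e-8),
reducing to cross-entropy at γ = 0 with uniform α. The imbalanced
tissue-classification settings use γ = 2 with per-class α as configured;
the balanced synthetic task trains with plain cross-entropy (γ = 0, the
loss the task's class balance calls for). Optimization is Adam (standard
moments) — the learning rates are 0.005 for 200 epochs on the synthetic
task and 0.001 for scan-style data; minibatch size 32 by default. All
randomness (data generation, initialization, shuffling) flows from explicit
integer seeds; identical seeds reproduce identical weights bitwise.

Weights are He-style uniform fan-in initialized. The reference classifier
has only 164–408 parameters, and a minority of initializations (roughly a
quarter, in our measurements across seeds) converge to a visibly poor
optimum: their final *training* loss stays an order of magnitude above that
of well-converged runs, and their rotation generalization suffers. The
synthetic-experiment driver therefore trains a small number of independent
restarts (default 4) and keeps the one with the lowest final training
loss. Selection never touches test data; it formalizes the otherwise
manual practice of discarding bad initializations.

Early stopping (for scan experiments) monitors one class's validation
recall with a patience of 5 epochs — the patience value is this package's
choice, as is the Adam optimizer.

## The synthetic generator

Each class is one fixed spherical function: 90 directions sampled uniformly
on the upper hemisphere (shared by all classes) with values drawn i.i.d.
N(0,1) (the common scale is deliberate: value magnitudes carry no class
information by construction). Class members are Haar-uniform random
rotations of that function — 50 train and 1000 test rotations per class,
drawn independently from one seeded stream. The task therefore isolates
rotation-invariant pattern recognition: a classifier must recognize the
arrangement of values on the sphere regardless of orientation.

What the generator does *not* emulate: diffusion physics (no tensors, no
fiber geometry, no Rician noise), within-class signal variability (every
member of a class carries the exact same values), and realistic acquisition
noise. Passing the synthetic experiment demonstrates rotation-invariant
discrimination at matched value scales; it says nothing about robustness to
scanner noise or biological variability.

One property of the generator deserves emphasis. Because each class's
values are a *finite* draw of 90 Gaussians, the classes differ slightly in
their empirical value statistics (mean, spread, extremes), and any
rotation-invariant functional of the signal — including simple summaries of
the Watson-smoothed field — inherits that difference. A dense network fed
the smoothed values at fixed directions can therefore separate classes
without learning anything about spatial structure, and in our measurements
it does so reliably. Consequently the dense baseline here performs far
above chance on this task; its value is as a parameter-count and
architecture reference, not as a demonstration of task impossibility.

## Numerical choices and degenerate inputs

* log map at antipodal points raises (cut locus); the chart itself never
  needs it (the antipodal frame uses the two-leg transport path).
* Watson weights are computed with a row-max shift before exponentiation,
  so large κ cannot overflow; κ ≤ 0 is rejected.
* Max projection ties route gradients to the first maximal rotation slot.
* Voxels with nonpositive mean b0 are masked out of normalization and
  reported, not divided.
* b0 volumes are those with b ≤ 50 s/mm² (configurable); shell membership
  uses |b − b_target| ≤ 100 s/mm² by default.
* Label volumes must share the DWI grid (nearest-neighbor resampling onto
  the DWI grid is assumed done upstream for affine-related grids).

## Problem sizes

The synthetic experiments train on 50 samples per class and evaluate on
1000 per class (2000–6000 test signals), with 4 restarts of 200 epochs
each; a full 2-class run takes a few seconds on one CPU core. The DWI
self-consistency fixture is a 6×6×6×12 synthetic scan with two tissue
blocks (isotropic vs anisotropic profiles), small enough to regenerate at
test time.

## Known limitations

* The chart is the plain 12-vertex icosahedron; no icosphere refinement,
  no general meshes, no manifolds other than S².
* Rotation invariance is exact only for the discrete 2π/5 grid; SO(3)
  invariance is approximate through the Watson interpolation.
* The trainer is a straightforward numpy implementation intended for
  models of this scale (hundreds of parameters, tens of thousands of
  voxels); it does not target GPU-scale workloads.
* Multi-shell data are supported only channel-wise (one model per shell or
  shells as channels); no joint multi-shell modeling.
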