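# Methods

This note documents the models, numerical choices, and limitations behind
`nemadetect`. Lengths are quoted in *cell diameters*, estimated per frame as
`d = sqrt(box area / n_cells)`; angles are radians.

## Director field and order parameter

Cell orientations are nematic (θ ≡ θ + π), so all averaging and
interpolation is done on the double-angle components `(cos 2θ, sin 2θ)`;
averaging raw angles is wrong across the π wrap. Scattered cell values are
interpolated linearly (Delaunay-based) to a regular grid, with
nearest-neighbour fill outside the convex hull for bounded frames and
ghost-cell replication for periodic ones. A square boxcar window (side
`window`, default 1.5 d, rounded to an odd number of grid nodes) then yields
the windowed nematic tensor components `Qxx = ⟨cos 2θ⟩`, `Qxy = ⟨sin 2θ⟩`.

One windowed average serves two purposes: its direction
`θ̄ = ½ atan2(Qxy, Qxx)` is the smoothed director, and its magnitude
`S = √(Qxx² + Qxy²)` is the scalar order parameter — the largest eigenvalue
of the traceless symmetric 2×2 nematic tensor, computed in closed form
rather than by an eigensolver (exact equivalence in 2D). S is deliberately
computed from the *raw* interpolated components, not from the
already-smoothed director: smoothing first would renormalize the director to
unit magnitude and make even an isotropic field look ordered. With the
default window (1.5 d ≈ 2.25 cells), fully isotropic orientations give a
mean S near 0.4 — the Rayleigh mean resultant of the few effectively
independent cells per window — while aligned fields give S = 1 to machine
precision.

Defaults: grid spacing 0.25 d ("fine grid", ~4 nodes per cell), window
1.5 d. Both are configuration parameters; the detection threshold below is
calibrated to them.

## Candidate detection and ROIs

Nodes with `S < S_th` (default 0.15) are grouped into maximal connected
components, 8-connected by default so diagonal low-order filaments are not
split (4-connectivity is available). On periodic fields, labels touching
across the wrap are merged by a union-find pass and centroids use a circular
mean per axis. Each region's center of mass becomes the center of a square
ROI: 9×9 directors sampled by nearest-grid-node lookup (the ROI grid is a
subset of the fine grid; no re-interpolation) spanning 6 d — the midpoint of
the 5–7-cell range that captures a defect core without swallowing its
neighbour. ROIs that would cross a non-periodic boundary are skipped with a
logged warning. Overlapping candidates are all kept: with S_th tuned so
regions stay distinct, suppression would be an extra, unmotivated filter.

## Winding-number classification

The 32 perimeter directors of the ROI are traversed counter-clockwise from
the bottom-left corner. Successive differences are wrapped into
(−π/2, π/2] — the smallest rotation consistent with head–tail symmetry, the
half-open interval breaking exact ±π/2 ties deterministically — and summed.
The total is a multiple of π exactly (the wrapped increments telescope
modulo π); charge `k = total / 2π` is accepted as ±1/2 or 0 within a
tolerance of 0.1 charge units (noise-free loops are exact; the tolerance
only matters for noisy data). Counter-clockwise director rotation under
counter-clockwise traversal is positive. Outcomes with |k| ≥ 1 are reported
as `other` and mapped to `none` for three-class comparisons, not silently
dropped. The legacy on-lattice baseline evaluates the same winding test on
8-point square loops centered at the nodes of a coarse lattice (default
pitch 2 d) and reports defects *at the lattice points*, which caps its
positional accuracy at pitch/√2 — the weakness that off-lattice candidate
detection removes.

## Convolutional classifier

ROIs are encoded as two channels `(cos 2θ, sin 2θ)` per node: the double
angle removes the artificial discontinuity of raw angles at the π wrap and
builds head–tail symmetry into the input exactly. The network is two valid
3×3 convolutions with 32 feature maps each (9 → 7 → 5; no pooling — the
input is too small for it), a fully connected layer of 100 ReLU units with
50% inverted dropout during training, and a 3-way softmax ordered
(+1/2, none, −1/2) everywhere; the class order is serialized with the model
to preclude label-permutation bugs. 3×3 is the smallest standard kernel that
leaves a 5×5 spatial map before the dense layer.

Training minimizes cross-entropy by plain SGD (no momentum or weight decay):
batch 64, 30 epochs, learning rate 0.025 for epochs 1–15 and 0.005 for
16–30, Glorot-normal weights, zero biases. A seeded 10% holdout never enters
a gradient step and is evaluated with dropout disabled at each epoch's end.
Everything — split, shuffling, initialization, dropout masks — derives from
one seed, so training logs are exactly repeatable. The implementation is
pure numpy (im2col convolutions with hand-written backprop, verified against
finite differences in the test suite); at this input size a full training
run on a few thousand ROIs takes tens of seconds on one CPU.

Augmentation multiplies a labeled set by exactly 8: rotations by
0, ±π/2, π (rotating the patch grid *and* adding the same angle to every
director, mod π) and reflection about the vertical centerline
(θ → π − θ). Defect charge is invariant under both, so labels are copied;
the winding oracle is exactly equivariant, which the tests exploit.
Reflecting about the vertical rather than horizontal centerline is an
arbitrary choice — the two differ by a rotation already in the group.

## Synthetic data

The generator plants *recoverable patterns with exact ground truth*; it does
not simulate tissue mechanics, and passing tests demonstrate correct
recovery of planted structure, not performance on real monolayers (real
segmentation noise is not i.i.d., cell shapes correlate with local order,
and real defect cores are extended). Components:

- **Cell positions**: jittered triangular lattice at the configured density
  (default jitter 0.3 lattice constants — enough to break lattice artifacts
  while keeping the packing confluent-like).
- **Orientations**: the ideal multi-defect field
  `θ = Σ_j k_j φ_j + θ0` in the plane. On a torus this superposition is
  either discontinuous (nearest-image) or non-periodic (single-image), so
  periodic frames instead take the double angle as the argument of a product
  of Jacobi ϑ₁ factors — one simple zero per core, hence the right winding —
  plus the smallest uniform tilt `γy` cancelling the quasi-periodic phase;
  the result is periodic mod π to machine precision. Total charge must
  vanish on the torus, and cores must sit ≥ 3 d apart to be resolvable.
- **Angular noise**: a von Mises perturbation of the *double* angle with
  concentration κ, halved and added to θ. One dial spans isotropic (κ = 0)
  to noise-free (κ = ∞/None); κ = 8 is mild (≈ 10° director noise), κ = 3
  moderate (≈ 17°).
- **Flow**: each +1/2 core contributes the divergence-free template
  `Ψ = v0 Y exp(−r²/2L²)` in its polarity frame — a forward jet of speed v0
  at the core flanked by two counter-rotating vortices at transverse
  distance L (default 2 d) — plus isotropic Gaussian noise. It is a planted,
  recoverable pattern; no hydrodynamic fidelity is claimed.
- **Labeled ROIs**: balanced +1/2 / none / −1/2 patches (default spacing
  0.75 d, so a 9×9 patch spans 6 d) with the core jittered off-node and a
  random phase. The *none* class mixes two hard-negative recipes 50/50: a
  uniform base orientation under per-node noise (disorder without a defect)
  and the far field between a ±1/2 pair whose cores lie safely outside the
  patch (winding 0 by neutrality).

Ground-truth polarity of each planted +1/2 core is computed numerically from
the exact noise-free field (the closed form ψ = 2θ0 holds only for an
isolated core in the plane).

## Defect polarity and oriented averaging

The polarity of a +1/2 defect is
`p = (∂x Qxx + ∂y Qxy, ∂x Qxy − ∂y Qxx)`, evaluated with centered finite
differences on the director grid and averaged over the 3×3 node block around
the core; `ψ = atan2(p_y, p_x)`. For the ideal field `θ = φ/2 + θ0` this
gives ψ = 2θ0 (verified analytically: `Q = (x/r, y/r)` so `p = (1/r, 0)` at
θ0 = 0), and rigid rotation by α rotates ψ by α. |p| below tolerance
(uniform fields, −1/2 cores, whose three-fold symmetry cancels p) raises an
error and excludes the defect from oriented averaging with a log entry.

Oriented averaging samples each defect's window on a grid rotated by ψ
(bilinear interpolation; grid-wrap for periodic fields), rotates the sampled
vectors by −ψ so every polarity points along +x, and averages element-wise.
Director fields are averaged the same way on Q components (which rotate by
−2ψ) before extracting the mean director. The single-point correlation
between two averaged fields is the mean dot product normalized by the
product of rms magnitudes — scale-free, bounded in [−1, 1], with
self-correlation exactly 1.

## Problem sizes and frozen benchmark conditions

The repeatable benchmark behind the classifier comparison uses 150 base ROIs
per class drawn over noise levels {noise-free, κ = 8, κ = 3}, augmented ×8
to 3600 training inputs, and a 600-ROI test set (200 per class, half
noise-free and half at κ = 3). These sizes make a full train-and-score cycle
take well under a minute while leaving the noise regime demanding enough
that the winding number makes errors the CNN avoids. The oriented-averaging
demonstration uses 150 planted templates under vector noise equal to the
signal amplitude, the ensemble size at which the mean-field pattern is
essentially fully recovered.

## Known limitations

- The synthetic frames idealize cell packing and noise; no claim is made
  about absolute accuracy figures on experimental data — only about the
  internal consistency and relative ordering of the methods.
- Defect tracking across frames, pairing/annihilation statistics, and
  integer (±1) defects are out of scope.
- The on-lattice baseline reports defects at lattice points by design; its
  positional error is bounded by the lattice pitch, not by the grid.
- `S = 1` holds to machine precision, but values within one ulp of 1 are
  clipped into [0, 1] to keep the order-parameter invariant strict.
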