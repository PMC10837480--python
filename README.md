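# nemadetect

Detection and classification of ±1/2 nematic topological defects in
confluent cell layers, from per-cell centroids and orientations.

## The problem

Epithelial monolayers and other confluent tissues behave as active nematics:
each cell's long axis defines a local orientation (a *director*, defined
modulo π), and the resulting orientation field carries point singularities —
comet-shaped +1/2 and trefoil-shaped −1/2 topological defects — that have
been linked to cell extrusion, collective motion, and morphogenesis. Finding
these defects in segmented imaging data is hard precisely because epithelial
cells are often nearly isotropic: regions of low nematic order do **not**
necessarily contain a defect, so the classical winding-number test produces
false positives.

`nemadetect` implements a complete detection pipeline for this setting:

1. **Director field** — scattered cell orientations are interpolated to a
   fine grid on the double-angle components (cos 2θ, sin 2θ) and smoothed
   with a sliding window. The scalar nematic order parameter is the largest
   eigenvalue of the window-averaged nematic tensor
   `Q = ⟨2 û_m û_n − δ_mn⟩`, computed in closed form as
   `S = √(Qxx² + Qxy²)` with `Qxx = ⟨cos 2θ⟩`, `Qxy = ⟨sin 2θ⟩`
   (S = 1 perfectly aligned, S = 0 isotropic).
2. **Candidates** — contiguous regions with `S < S_th` (default 0.15) are
   candidate defects; their centers of mass become the centers of square
   9×9 director patches (ROIs) spanning ≈ 6 cell diameters.
3. **Classification** — each ROI is labeled +1/2, −1/2, or *no defect*
   either by the winding number (total director rotation around the ROI
   edge, a multiple of π; ±π ↦ charge ±1/2) or by a small convolutional
   network (two 3×3 convolutions × 32 features, FC-100, 3-way softmax)
   trained on labeled ROIs with eightfold rotation/reflection augmentation.
   The legacy "on-lattice" winding method is included as a baseline.
4. **Evaluation & defect properties** — per-class precision, sensitivity and
   F1 (`F1 = 2·P·Sens/(P+Sens)`) with class-size-weighted totals; polarity
   of +1/2 defects from `p = ∇·Q`; and ensemble averaging of velocity or
   director fields in the defect-aligned frame, scored by a normalized
   single-point correlation.

Because the pipeline needs labeled ground truth to train and score, the
package includes a first-class synthetic generator: cell centroids on a
jittered triangular lattice, orientations drawn from ideal multi-defect
director fields (exactly periodic on a torus via Jacobi ϑ₁ products) with
tunable angular noise, planted flow templates around +1/2 cores, and
balanced labeled ROI datasets — all reproducible from a single seed.

## Worked example

```bash
python examples/01_detect_planted_defects.py
```

```
2 defect(s) detected in a 896-cell frame

 charge   x_det   y_det  x_true  y_true    err
   +1/2    9.00   15.00    9.00   15.00   0.00
   -1/2   21.00   15.00   21.00   15.00   0.00

+1/2 polarity: detected 4.65 rad, planted 4.80 rad
```

A planted ±1/2 pair in a noisy 900-cell frame is recovered at the correct
positions and charges; the +1/2 polarity (comet-axis angle) agrees with the
planted orientation to ≈ 0.15 rad. `examples/02_train_and_compare_classifiers.py`
trains the CNN and prints a per-class P/Sens/F1 table against the winding
number (on moderate-noise synthetic ROIs the CNN reaches accuracy 1.000 vs
0.923 for winding), and `examples/03_average_flow_field.py` shows the
oriented average of 150 noise-buried +1/2 flow templates recovering the
clean pattern (correlation 0.79 → 0.94 → 0.98 for ensembles of 10/50/150).

## Command line

A thin CLI wraps the library for shell use:

```bash
nemadetect simulate --out-dir data --seed 1 --pairs 2 --kappa 5
nemadetect detect --frames data/frames.csv --method winding --box 30 --out defects.csv
nemadetect train --rois data/rois.npz --out model.npz
nemadetect evaluate --pred defects.csv --truth data/ground_truth.csv --box 30
nemadetect average-field --defects defects.csv --frames data/frames.csv --box 30
```

Input frames are delimited text with columns `x, y, theta[, vx, vy, frame]`
(radians; `--degrees` converts on read). Every output embeds the resolved
configuration hash and seed.

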