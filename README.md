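# vdissect

Geometric parsing ("virtual dissection") of left-atrial anatomy from 3D
binary heart masks.

Catheter ablation for atrial fibrillation needs a segmented left atrium
(LA) with its pulmonary veins (PVs) and left atrial appendage (LAA)
individually labelled, because the PV ostia are the primary ablation
targets. Given an already-binarized blood-pool shell (e.g. from cardiac
CT), `vdissect` splits it into LA body, LSPV, LIPV, RSPV, RIPV and LAA —
plus anatomic variants (common left trunk, supplemental veins) — using
mathematical morphology guided by a simple geometric model: the LA is an
ellipsoid, PVs are cylinders, the LAA is a paraboloid.

The pipeline:

1. **Iterative erosion** tracked by an *Erosion Index* — the digital
   solidity (volume over voxelized convex-hull volume) of the largest
   component. Erosion stops once the residual is convex enough
   (index ≥ τ_e, default 0.94): the tubular veins and appendage have been
   severed and the convex LA core remains.
2. **Geodesic dilation** tracked by a *Dilation Index* (restored volume
   fraction), stopping at the step where the number of structure-scale
   remnants of `shell \ core` peaks — the appendages have detached but
   none has been swallowed.
3. **Anatomical classification** of remnants by centroid octants in a
   fixed frame (+x left, +y anterior, +z superior).
4. **Centerline refinement**: medial (Voronoi-style) centerlines from the
   LA centroid to each structure, and a perpendicular cut plane placed
   where each centerline crosses a moment-fitted LA ellipsoid, cleaning
   every LA–PV/LAA boundary. A residual check against the same fit
   recovers appendages the dilation swallowed.
5. **Evaluation**: Dice, IoU with the strict IoU > 0.5 success criterion,
   average surface distance, centroid-boundary distance (CBD), LA volume
   and sphericity index, Bland–Altman limits of agreement, Pearson
   correlation, and McNemar's exact test for paired success rates.

A parametric generator of synthetic digital atria (with analytic
ground-truth labels, ostial planes and CBDs) makes the whole pipeline
testable without any patient data. Two small SVMs, trained on a handful
of sweep-labelled "seed" shells, can predict the erosion/dilation
iteration counts for new shells in place of the automatic rules.

## Worked example

```python
import vdissect as vd

# a synthetic atrium: ellipsoidal LA (71-140 ml), four PVs, one LAA
spec = vd.sample_spec(seed=0, variant="standard4pv")
shell, truth = vd.rasterize(spec, spacing=(1.0, 1.0, 1.0))

result = vd.dissect(shell)              # erosion + dilation + classify + refine
report = vd.evaluate_case(result.labelmap, truth.labelmap)

print(f"erosion iterations: {result.n_e}, dilation iterations: {result.n_d}")
for s in report.structures:
    print(f"{s.name:>6}: dice {s.dice:.3f}  iou {s.iou:.3f}  success {s.success}")
print(f"LSPV centroid-boundary distance: "
      f"{vd.centroid_boundary_distance(result.labelmap, vd.Label.LSPV):.1f} mm "
      f"(analytic {truth.analytic_cbd[vd.Label.LSPV]:.1f} mm)")
```

Output:

```
erosion iterations: 11, dilation iterations: 12
    LA: dice 0.995  iou 0.991  success True
  LSPV: dice 0.977  iou 0.954  success True
  LIPV: dice 0.990  iou 0.980  success True
  RSPV: dice 0.995  iou 0.991  success True
  RIPV: dice 0.847  iou 0.734  success True
   LAA: dice 0.963  iou 0.929  success True
LSPV centroid-boundary distance: 26.5 mm (analytic 26.3 mm)
```

Reading: all six structures were recovered with Dice ≥ 0.85 and every
IoU clears the 0.5 success threshold, so this case counts as successfully
parsed; the predicted LSPV ostium sits where the analytic ground-truth
plane puts it (CBD error 0.2 mm for this case).

The same pipeline runs from the shell:

```bash
vdissect synth --n 20 --seed 7 --variant-mix standard4pv=0.8,common_left_trunk=0.2 \
         --spacing 1.0 --out cohort/
vdissect dissect cohort/case_000_shell.nii.gz --out labels.nii.gz --trace trace.csv
vdissect eval compare labels.nii.gz cohort/case_000_truth.nii.gz --out report.json
vdissect svm-fit --manifest seeds.csv --out predictor.json
vdissect dissect cohort/case_001_shell.nii.gz --predictor predictor.json --out labels1.nii.gz
```

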