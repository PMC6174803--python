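# ropseg

Registration-based liver positioning and coarse-to-fine liver/tumor
segmentation for abdominal CT, with a synthetic-phantom test bed.

## The problem

Delineating the liver (and tumors inside it) on CT is hard for two reasons:
the liver's position and size vary across patients, and its gray values
overlap those of neighbouring organs (spleen, stomach wall), so thresholds
and plain clustering bleed across organ boundaries.  `ropseg` implements a
classical, fully deterministic pipeline that attacks both problems:

1. **Registration-based organ positioning (ROP).**  From a labelled cohort,
   the subject whose convex-hull liver volume is closest to the cohort mean
   becomes the *standard* template.  For every slice of an unseen volume the
   corresponding template slice is registered *onto* it (template = float
   image, unseen slice = reference; coarse stage driven by cross-correlation,
   fine stage by mean squared difference with a 10× smaller step and 4× the
   iterations) and the template's liver-label support is pushed through the
   recovered affine `T`.  The min/max of the transformed label coordinates,
   rounded outward, give a per-slice liver bounding box — one registration
   per slice, never an inverse transform.
2. **Coarse segmentation inside the box.**  Slices are preprocessed with the
   liver gray window (default 130–150), a linear contrast stretch of the
   surviving band onto [1, 255] and a 5×5 median filter.  Two independent
   stages then run per box:
   * **FCM** — fuzzy c-means (c = 4, fuzzifier m = 2) on the windowed gray
     values, `u_ik = 1/Σ_j (|x_k−v_i|/|x_k−v_j|)^{2/(m−1)}`; the non-dark
     clusters' largest connected component (closed, hole-filled) is the
     deliberately permissive candidate — it oversegments when a neighbouring
     organ shares the window.
   * **ELM** — an extreme learning machine over a fixed 126-dimensional
     per-pixel texture descriptor (Gaussian derivatives, LBP, Gabor, Laws,
     co-occurrence, sum-and-difference histograms, …).  The single hidden
     layer has 630 sine units with random uniform [−1, 1] input weights; only
     the output weights are learned, in closed form via the Moore–Penrose
     pseudo-inverse, `β = H†T` with `H = sin(XWᵀ + b)`.  It errs in the
     opposite direction (undersegmentation).
   The two stage decisions are fused with weights proportional to their
   training accuracies (`w_F = A_F/(A_F+A_E)` per slice, averaged over the
   top-K slices), median-filtered, and thresholded at 0.5.
3. **Fine segmentation.**  The coarse boundary seeds an active contour
   minimizing `E = Σ α|p_{i+1}−p_i|² + β|Δ²p_i|² − w·G(p_i)` (G = normalized
   gradient magnitude of the σ=2 smoothed image), evolved semi-implicitly
   with an energy-decrease guarantee.
4. **Tumor segmentation.**  A second ELM classifies each liver-interior
   pixel from the same 126-d descriptor computed on the raw intensities;
   its output is a subset of the liver mask by construction.

Quality is reported with the six standard volumetric/surface criteria:
VOE (%), RVD (%), ASD/RMSD/MSD (mm, symmetric nearest-surface distances
between face-connected surface voxels, spacing-aware) and Dice (%).

Because no patient data ships with the package, a **phantom** module
generates abdominal look-alikes — a smoothly deformed ellipsoidal liver with
gray values inside the 130–150 window, darker tumors strictly inside it, a
spleen-like confounder overlapping the window, per-subject affine pose/size
variation — sized so a default 3D cohort averages ≈1700 cm³ of liver.

## Worked example

```python
from ropseg import (PhantomParams, generate_cohort,
                    JointSegmentationModel, evaluate_all)

cohort = generate_cohort(8, PhantomParams.fast_2d(seed=5))
results = JointSegmentationModel(cohort[:6]).fit()
print(results.summary())

vol, liver, tumor = cohort[7]              # held-out subject
seg = results.segment(vol)
print(evaluate_all(liver.voxels, seg.fine.voxels, vol.spacing))
pred = results.segment_tumor(vol, seg.fine)
print(evaluate_all(tumor.voxels, pred.voxels, vol.spacing))
```

prints

```
Joint liver/tumor segmentation — fit summary
====================================================
training subjects          6
template subject           phantom-5-s5 (hull volume 194 cm3)
liver ELM                  630 hidden sine units, 40000 training pixels
fusion weights (FCM, ELM)  (0.4975, 0.5025)
mean FCM stage accuracy    0.9853
mean ELM stage accuracy    0.9953
tumor ELM                  fitted

VOE   3.14%  RVD   -1.77%  ASD  0.032mm  RMSD  0.278mm  MSD  6.400mm  DSC  98.41%
VOE   2.19%  RVD   -2.19%  ASD  0.018mm  RMSD  0.168mm  MSD  1.600mm  DSC  98.89%
```

The first report scores the fine liver mask against ground truth on the
held-out phantom (Dice 98.4%); the second scores the tumor cascade
(Dice 98.9%).  The near-equal fusion weights say both coarse stages were
almost equally accurate on this clean training cohort.

The same workflow is available from the shell:

```bash
ropseg phantom --n 8 --shape 1x128x128 --seed 5 --out cohort/
ropseg train   --cohort cohort/ --out bundle/
ropseg segment --bundle bundle/ --volume cohort/subject_007.nii.gz --out pred.nii.gz
ropseg evaluate --pred pred.nii.gz --truth cohort/subject_007_liver.nii.gz
```

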