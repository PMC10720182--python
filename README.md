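# myoarch

Cardiac myoarchitecture mapping and its electrophysiological consequences,
end to end on synthetic phantoms.

At the basal inferoseptal left ventricle, near the right-ventricular
insertion point, the usual circumferential arrangement of aggregate
cardiomyocytes is interrupted by a transmural, triangle-sectioned bundle of
myocytes running in the apex–base direction, with an abrupt orientation
discontinuity at its border. `myoarch` implements the full computational
chain used to characterise such a structure and to ask what it does to
electrical propagation:

* **phantoms** — a ventricular-wedge fiber field with the triangular
  bundle, a diffusion-weighted forward model
  S = S₀·exp(−b·gᵀDg) with Rician noise, and a microCT-like laminar
  texture aligned with the fibers; every downstream stage is testable
  against exact ground truth.
* **dti** — log-linear least-squares diffusion tensor fitting, FA / ADC /
  colour-coded FA and the principal eigenvector v1
  (FA = √(3/2)·‖λ−MD‖/‖λ‖), trilinear up-sampling, and band-pass
  threshold segmentation of the myocardium.
* **sti** — 3D structure tensor J = G_σ ∗ (∇I ∇Iᵀ) on intensity volumes;
  the smallest-eigenvalue eigenvector is the myocyte direction.
* **geometry** — LV frame fitting, helix-angle maps, and log-Euclidean
  tensor downsampling to in-vivo voxel sizes (averaging matrix logarithms
  preserves positive-definiteness and emulates partial-volume averaging).
* **tracto** — deterministic streamline tractography (FA stop, turn limit,
  step 0.05 mm, length window), preferential-orientation filtering,
  track-density imaging, threshold delineation of the bundle, and its
  morphometrics (volume, dBA/dSLA/dCR/dCL/dWT distances, FA histograms).
* **epsim** — monodomain reaction–diffusion on the wedge,
  ∂v/∂t = ∇·(G∇v) + I_ion with G = σ_T I + (σ_L−σ_T) ffᵀ and a
  two-variable excitable membrane: rule-based vs measured-style fiber
  fields, a non-conducting holed interface at the bundle border, LAT maps
  and 1/r lead-field pseudo-ECGs.
* **io / pipeline** — NIfTI, FSL-dialect bval/bvec, TCK and tensor-field
  readers/writers, plus a config-driven pipeline with a hashing manifest
  for exact re-runs.

The package is a library: import it, or start from the narrative scripts in
`examples/`.

## Worked example

Delineating the bundle from a simulated acquisition
(`examples/03_bundle_delineation.py`):

```text
80767 streamlines tracked, 3176 kept by the long-axis orientation filter
Dice vs ground-truth bundle: 0.811
bundle volume 0.473 cm^3, long-axis extent 17.4 mm
bundle FA 0.322 +/- 0.048, whole wedge FA 0.323 +/- 0.048
```

Streamlines are seeded throughout the myocardium, kept when their mean
direction lies within 30° of the long axis, and rasterised into a
track-density image whose thresholded core is the bundle mask: Dice 0.81
against the generative label means the recipe recovers the structure with
high overlap, and the reported volume and ~17 mm long-axis extent are the
morphometrics a study would tabulate. With the phantom's homogeneous
diffusivities the bundle and whole-wedge FA distributions coincide by
construction.

The tensor-fit accuracy behind this
(`examples/01_phantom_and_tensor_fit.py`):

```text
myocardial FA: 0.323 +/- 0.048  (fixed ex-vivo myocardium sits near 0.3)
v1 angular error vs ground truth: mean 5.99 deg, median 5.46 deg at SNR 50
```

And the in-vivo-resolution question (`examples/04_downsample_to_invivo.py`):

```text
2.0x2.0x5.0 mm^3: 922 tissue voxels, 36 still showing apex-base orientation
2.5x2.5x8.0 mm^3: 353 tissue voxels, 13 still showing apex-base orientation
```

— after log-Euclidean downsampling to clinical voxel sizes a handful of
voxels still carry the bundle's apex–base signature.

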