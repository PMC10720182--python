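# Methods

`myoarch` characterises a cardiac structural discontinuity — a transmural,
triangle-sectioned bundle of apex–base-oriented cardiomyocytes embedded in
circumferentially oriented myocardium at the basal inferoseptal left
ventricle — and its electrophysiological consequences. Because the original
ex-vivo specimens are not shipped with the package, every stage operates on
synthetic phantoms whose ground truth is known exactly; this note records
the models, the parameters that matter, the numerical choices, and what the
phantoms do and do not establish about real data.

## Conventions

World coordinates are millimetres, voxel-centre convention, with NIfTI-style
affines as the single source of geometric truth. Axis roles: `x`
circumferential, `y` transmural, `z` left-ventricular long axis with the
base toward +z. Eigenvalues are sorted descending; eigenvector signs follow
the antipodal convention v·ẑ ≥ 0 (ties broken by y, then x). The helix angle
is the signed angle in (−90°, +90°] between a fiber's tangent-plane
projection and the local circumferential direction
(circumferential = long_axis × radial), positive toward the base; fibers
whose tangent-plane projection norm falls below 0.2 are flagged undefined.

## The wedge phantom

`phantoms.make_fiber_phantom` builds a myocardial slab (default
30 × 20 × 30 mm at 0.6 mm isotropic voxels, two voxels of surrounding
fixative fluid) of unit circumferential fibers containing a triangular-prism
bundle: base width 8 mm along x at the RV-side wall, transmural depth 10 mm,
long-axis extent 18 mm ending at the base. The bundle's direction is the
circumferential axis tilted toward the long axis by the *discontinuity
angle*; the default is 90°, i.e. a purely apex–base bundle, which both
matches the described anatomy and guarantees the orientation jump at the
border exceeds any plausible lower bound. The one-voxel interface shell
(label 3) is the 26-neighbourhood of the bundle within the surrounding
myocardium; the electrophysiology stage uses it to place the non-conducting
border. Fluid slabs on the two transmural faces carry cavity labels (RV
side = 1, LV side = 2) for the distance measurements. A cylindrical-annulus
variant with a prescribed linear transmural helix ramp exists purely to
exercise the frame fit and helix-angle mapping against a closed form.

The bundle-geometry defaults are round numbers in the anatomical range
reported for this structure (long-axis extent ~2 cm, volume a few tenths of
a cm³); they are scale choices, not fitted quantities.

## Diffusion forward model and tensor fit

The forward model is the single-tensor signal equation
S = S₀·exp(−b·gᵀDg) with an axially symmetric tensor per voxel,
eigenvalues (1.0, 0.65, 0.55)·10⁻³ mm²/s — FA ≈ 0.31, in the range measured
in fixed ex-vivo myocardium — and isotropic 2.2·10⁻³ mm²/s in the
surrounding fluid, giving the background the hyperintense trace that the
segmentation exploits. The default acquisition is one b = 0 volume plus the
classic six noncollinear directions at b = 1000 s/mm². Rician noise is the
magnitude of a complex Gaussian perturbation with σ = S₀/SNR. The default
study SNR is 50, chosen to represent a long-averaged high-field ex-vivo
acquisition; at that level the fitted principal eigenvector deviates from
the true fiber by ~5° (median) and the median per-voxel Frobenius error of
the tensor is under 10%. At SNR 20 the v1 angular error grows to ~18°
(mean) for FA ≈ 0.31 tissue — first-order noise propagation predicts this
(the orientation contrast b(λ₁−λ₂) is only ≈ 0.35 at b = 1000) — so
regression tests at SNR 20 assert measured pilot bounds (25° angular, 30%
median Frobenius) rather than aspirational ones.

The fit is ordinary log-linear least squares on
ln S = ln S₀ − b gᵀDg; with the 6+1 design the inversion is exact on
noiseless data (verified to < 10⁻⁸ relative Frobenius error on 1,000 random
SPD tensors). Negative eigenvalues are clamped to 10⁻¹² mm²/s and counted;
voxels with nonpositive signals are excluded from the output mask with a
warning. Up-sampling (factor 2 to 0.3 mm, trilinear, voxel-centre-preserving
affine) precedes fitting when the in-vivo-style workflow is emulated.

Myocardium segmentation is a conjunction of band-pass thresholds on FA
([0.05, 0.95]), trace (1st–99th percentile) and the mean DW image (above
its Otsu threshold), followed by the largest 26-connected component. The
published workflow delegates its exact cutoffs to earlier protocol papers,
so these defaults are this package's decisions, all overridable.

## Structure-tensor orientation

For intensity volumes the structure tensor is
J = G_{σ_avg} ∗ (∇I ∇Iᵀ) with derivative-of-Gaussian gradients at
σ_grad = 1 voxel and tensor smoothing at σ_avg = 6 voxels (σ interpreted in
voxel units; the acquisition-side value is dimensionless in the source
protocol). All convolutions reflect at boundaries and a border of width 3σ
is flagged in the QC mask, as are near-isotropic voxels (λ₃/λ₁ > 0.99). The
fiber is the smallest-eigenvalue eigenvector; the anisotropy volume applies
the FA formula to the structure-tensor eigenvalues, standing in for the
FA-style stopping threshold of intensity-based tractography.

The microCT-like texture generator writes two sinusoidal carriers in the
plane perpendicular to the local fiber — full contrast along the sheet
normal, half contrast along the in-sheet transverse direction — because a
single stripe family leaves J rank-1 and the smallest-eigenvalue eigenvector
degenerate; myocyte rods modulate intensity in both transverse directions.
The texture is rendered on a grid 3× finer than the DW grid (`upsample=3`):
the real resolution ratio between microCT and DTI is ~30×, and at equal
grids the σ = 6 integration scale would be larger than the bundle itself.
With this scaled-down ratio the noiseless median orientation error over
tissue is below 0.001°, and agreement with DTI-v1 of the same phantom is
limited by the DTI noise (~5–7° median at SNR 50).

## Tractography and bundle delineation

Tracking is deterministic fixed-step Euler integration (step 0.05 mm)
along the principal direction, bidirectional from every masked voxel
centre, with antipodal sign alignment at each sample. Direction sampling is
nearest-voxel (FACT-style) by default: at a sharp interface between fiber
populations this concentrates the orientation change into a single step, so
the maximum-turn-angle criterion actually gates crossings (with trilinear
sampling the interpolated direction rotates smoothly across the boundary
voxel and per-step turns never exceed a few degrees, making the angle
threshold inert there); trilinear sampling remains available. Termination:
FA below the stopping threshold, per-step turn above the angle limit,
half-length reaching max_len/2, or leaving the mask/grid; streamlines
shorter than min_len are discarded. Visualization defaults are FA-stop 0.1,
45°, lengths 1–20 mm; the delineation recipe uses FA-stop 0.2 and 30°.
Tracking runs internally in origin-subtracted coordinates so a global
translation of the affine cannot flip any floating-point termination
decision — translation invariance is exact.

Delineation: streamlines are filtered by antipodally rectified mean
direction within 30° of the long axis, rasterised into a track-density
image (each streamline counts at most once per voxel; the sum over voxels
exactly equals the number of distinct streamline–voxel visits), thresholded,
reduced to the largest 26-connected component and closed with a one-voxel
structuring element (the deterministic replacement for interactive mask
cleanup). The default threshold is Otsu's method on the *nonzero* TDI
counts: it adaptively separates the dense bundle core from sparse stray
visits and, unlike a fixed high quantile, cannot by construction discard
the bulk of the structure it is supposed to delineate. Quantile and
absolute-count thresholds are available for data where a calibrated cut is
preferred.

Morphometrics report voxel-count volumes, long-axis extents of the tissue
(dBA) and bundle (dSLA), Euclidean distances from the bundle centroid to
the nearest RV- and LV-side cavity voxels (dCR, dCL; dWT = dCR + dCL), and
64-bin unit-mass FA histograms with means ± sd for bundle and whole tissue.

## Log-Euclidean downsampling

Tensors are resampled to in-vivo voxel sizes (2.0 × 2.0 × 5.0 and
2.5 × 2.5 × 8 mm³) by averaging matrix logarithms with box-footprint
partial-volume weights and exponentiating — scanner-like averaging that
preserves positive-definiteness. Masked-out sources are excluded; an output
voxel is masked out below 50% footprint coverage. A constant field is
reproduced to 10⁻¹⁰ and the two-voxel worked example
{I, diag(e², 1, 1)} → diag(e, 1, 1) holds to machine precision. One caveat
discovered during testing: the FA of a log-Euclidean mean is *not* bounded
by the maximum input FA (averaging differently oriented anisotropic tensors
can raise it); the property suite asserts the true invariant instead —
det(mean) equals the geometric mean of the input determinants.

## Monodomain wedge electrophysiology

The wedge model solves ∂v/∂t = ∇·(G∇v) + I_ion on a regular lattice with
G = σ_T·I + (σ_L−σ_T)·ffᵀ, lumped to effective diffusivities
σ_L = 0.12, σ_T = 0.03 mm²/ms (conduction velocities ≈ 0.34 and
0.17 mm/ms, a physiological 2:1 anisotropy). The membrane is a
two-variable Mitchell–Schaeffer-class model (τ_in 0.3, τ_out 6, τ_open 120,
τ_close 150 ms, gate 0.13) with the dimensionless voltage mapped to
Vm = −80 + 100·v mV; all comparative claims are sign- and symmetry-based,
not waveform-exact, precisely so that they do not depend on this membrane
choice. Space is discretised with conservative face fluxes — harmonic-mean
diagonal conductances, face-averaged cross terms, zero flux at domain
boundaries and into non-tissue — and stepped with explicit Euler (dt
checked against the diffusion stability bound; |Vm| > 500 mV aborts with a
report). LAT is the first upstroke crossing of −20 mV with sub-dt linear
interpolation; unactivated nodes stay NaN and are flagged. The pseudo-ECG
is the infinite-homogeneous-medium lead field φ_e ∝ Σ (G∇Vm)·∇(1/r) per
node volume; bipolar traces are differences of labelled pairs.

Quantitative checks use quasi-1D bars at dx = 0.05 mm, where the measured
CV anisotropy matches √(σ_L/σ_T) to ≈ 0.1% and halving dx and dt moves CV
by < 0.1%. The comparison study runs at dx = 0.3 mm (the up-sampled DTI
resolution) where the depolarisation front is under-resolved and CV carries
lattice error — acceptable because all its claims are paired contrasts at
identical discretisation.

The study compares, per pacing face (patch stimulus at the face centre,
radius 1.5 mm, 1 ms): (1) a rule-based linear transmural helix ramp
(+60°→−60°); (2) the *measured-style* field — the DTI v1 of the phantom
simulated at SNR 50 and fitted, carrying genuine measurement dispersion,
exactly how experimental orientations enter such models; (3) the same field
with inter-node conductances across the bundle border zeroed except for a
seeded 5% subset of faces (discrete holes). The ROI wedge
(12 × 9 × 18 mm) keeps the bundle fully interior with 3 mm / 1.5 mm
standoffs so no pacing site stimulates it directly, and the bundle is ~5%
of the tissue. Electrode registry: A1/B1 (long axis), T1/T2 (transmural)
and E1/E2 (circumferential) straddle the bundle; E2/E3 and the F1/F2
reference pair sit at the basal-lateral edge, a region activated before the
wavefront reaches the bundle under every protocol.

Findings at the frozen conditions (seed 1): the holed interface raises mean
bundle-interior LAT by 7–11 ms for every protocol, and the
measured+interface configuration is slower than rule-based for all three
pacing directions (ΔLAT +2.8 to +6.7 ms). Without the interface the
measured-style field is slower for circumferential and transmural pacing
(+1.3 ms each) but *faster* by 1.3 ms for long-axis pacing: a perfectly
coherent apex–base bundle is a conduction highway along the paced axis.
Real measured fiber fields are globally incoherent (disarray, partial
volume), which is what produces uniformly positive delays in the original
wedge experiments; the phantom intentionally omits that incoherence, so
this sign difference is a property of the idealisation, not of the solver.
The crossing-pair pseudo-ECG amplitude shifts exceed 5% for long-axis and
circumferential pacing (6% and 44%) but not for transmural pacing in a
9 mm wall, where the peak is dominated by near-face activation ahead of the
interface; the F1/F2 reference pair stays near 1% except under
circumferential pacing (10%), every electrode being near-field to the
bundle at desk scale.

## Problem sizes and reproducibility

Default problem sizes — 54 × 37 × 54 phantom grid, 3× refined texture for
the structure tensor, 42 × 32 × 62 EP wedge, quasi-1D CV bars — were chosen
so the full test suite and the acceptance script each complete on a single
CPU in minutes while keeping every measured statistic stable to well inside
its asserted tolerance. All randomness flows from one root seed through
named CRC-32-keyed substreams (`core.substream`), so stages re-run
identically in isolation; the pipeline manifest records parameters, seeds
and SHA-256 hashes of every output, and identical configurations produce
bit-identical outputs.

## Limitations

The phantoms are geometric idealisations: no fixation-state variation, no
epicardial fat or vessels, no intravoxel disarray, rectilinear rather than
curved anatomy, and a single-tensor diffusion model. Passing tests
establish that the *algorithms* recover known structure under controlled
noise — not that real hearts meet these assumptions. The electrophysiology
wedge uses a phenomenological membrane and effective conductivities; its
outputs are comparative (signs, ratios, symmetry), and absolute
milliseconds and millivolts should not be read as predictions for tissue.
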