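# Methods

## The feature: supervoxel-based volumetric histons

The package characterizes a structural MRI subject through the joint spatial
distribution of its tissue probabilities. Input is a triplet of co-registered
3D probability maps — grey matter (GM), white matter (WM), cerebrospinal
fluid (CSF) — as produced by a unified-segmentation preprocessing. The three
maps are treated as the spectral channels of one colour volume, quantized to
L = 256 intensity levels (round-half-up: v → ⌊v·(L−1)+0.5⌋).

A *histon* is a contour laid on top of an intensity histogram: every voxel
adds 1 to its intensity bin, plus 1 more if it lies inside a "similar colour
sphere" of its neighbourhood,

    H_vi(g) = Σ_voxels (1 + S2(x,y,z)) · [I(x,y,z,v_i) = g].

Here the neighbourhood is the *supervoxel* containing the voxel (a 3D SLIC
over-segmentation of the aggregate GM/WM/CSF volume), and the sphere radius
per tissue is the *expanse* E_vi. A voxel is similar (S2 = 1) iff, for every
tissue simultaneously,

    |I(x,y,z,v_i) − mean_supervoxel(v_i)| < E_vi   (strict inequality).

One S2 field is shared by the three per-tissue histons; the 3 × 256 bins
concatenate (order GM, WM, CSF) into a 768-component subject descriptor.
By construction histogram(g) ≤ histon(g) ≤ 2·histogram(g) per bin, and the
histon mass equals masked voxels + |{S2=1}|.

### Expanse definition

Two modes are provided because the defining formula and its surrounding
description genuinely disagree:

* `mean_of_sds` (default): E_vi is the mean over supervoxels of the
  within-supervoxel population standard deviation — the mean local deviation
  of the volume in the supervoxel-defined space. A deviation is
  dimensionally the natural radius of a similarity sphere, and it adapts to
  the volume's local homogeneity.
* `mean_of_means`: E_vi is the mean over supervoxels of supervoxel mean
  intensities — the formula as printed. On bright tissues this makes almost
  every voxel "similar" (the threshold is of the order of the signal itself),
  collapsing the histon toward 2× the histogram, which is why it is not the
  default.

The supervoxel reference intensity in the similarity test is the supervoxel's
*mean* intensity per channel, not the intensity at its spatial-centroid
voxel; a centroid voxel is an arbitrary sample while the mean is the
statistic the expanse is defined against.

### 3D SLIC

SLIC is a spatially constrained k-means. Seeds lie on a regular grid with
spacing I_n = round((masked voxels / N_s)^(1/3)), snapped onto the mask
(nearest masked voxel via Euclidean distance transform). Each masked voxel
inside the 2·I_n cube around a centre competes for it under

    D_w = sqrt((d_c/m)² + (d_s/I_n)²),

with d_c the Euclidean distance over the three quantized tissue channels and
d_s the 3D Euclidean voxel distance. This is the "colour divided by m"
normalization; the alternative m·d_s/I_n weighting found elsewhere in the
SLIC literature is intentionally not used. Defaults: m = 10 on the 0–255
scale, 10 iterations with early stop when total centroid displacement (L1)
falls below one voxel. Ties in D_w go to the lower centre index; voxels no
window reaches are assigned to the globally nearest centre (logged). Both
choices make segmentation deterministic.

Connectivity is enforced afterwards under 6-connectivity: the largest
component of each label keeps the label; other components smaller than
min_region_frac · I_n³ (default 0.25) merge into the largest 6-adjacent
label, while components at or above that size become new labels. The split
step goes beyond plain small-island merging, but it is required to guarantee
the documented invariant that every final label is one 6-connected region.
Merging is iterative because an island's only settled neighbour may itself be
pending; an isolated group of islands promotes one member per round, which
guarantees termination.

All computation — SLIC, expanse, similarity, histons — is restricted to the
brain mask (voxels with gm+wm+csf > 0 by default). Background is constant
and would otherwise swamp bin 0 with uninformative counts.

## Classification

Features are standardized (training mean/variance; zero-variance columns
dropped and logged) and reduced by PCA fit on training rows only. The
component count is 5 by default, mirroring a scree-elbow choice; an automated
scree mode picks the component before the largest drop in consecutive
eigenvalue differences, clamped to [2, 30], falling back to 5 when the
spectrum is too short to have an elbow.

The classifier is a soft-margin SVM with default parameters — cost 1,
degree 3, gamma = 1/n_features — and deliberately *no* hyperparameter
search: with small cohorts, tuning on the training set erodes
generalization. Kernels linear (default), polynomial and radial can be
compared on the same splits.

Evaluation uses ten random 80/20 splits, stratified by diagnosis × gender ×
age decade. Test slots are allocated to strata hierarchically — first per
diagnosis, then across gender/age strata within a diagnosis — with
largest-remainder rounding (remainder ties go to the larger stratum, then to
key order). The hierarchy guarantees class proportions never depend on tie
order. Strata with a single subject trigger a coarser stratification (drop
age, then gender), with a warning.

Seven measures are reported per split and as means: Acc, Bacc = (Sen+Spe)/2,
NPV, PPV, Sen, Spe, F-score, with AD the positive class. Zero-denominator
ratios are NaN with a warning, never silently 0; means skip NaNs.

Paired classifiers on the same test subjects are compared with McNemar's
test on the discordant counts b, c: the continuity-corrected statistic
(|b−c|−1)²/(b+c) against χ²(1), with an exact binomial option for small
b + c, and p = 1 when b + c = 0.

The comparison baseline mirrors a voxel-feature approach: flattened GM
probability volumes, a linear Gram-matrix kernel, and a cost grid search
(2⁻⁵…2⁵, inner 5-fold CV on balanced accuracy, ties to the smallest cost).
A leakage guard rejects test rows identical to training rows.

## Synthetic phantoms

The generator emulates unified-segmentation output with three concentric
smoothed ellipsoids: WM core (radius 10 voxels), GM shell (16), CSF rim (20)
on a 48³ grid, mildly anisotropic (axis ratios 1.0/0.9/0.95). Tissue
membership uses sigmoidal radial profiles of width ω; probabilities sum to at
most 1 and the background is exactly zero.

Two orthogonal class knobs translate the disease's imaging phenotype:

* **atrophy** Δ_gm: the AD phantom moves a fraction Δ_gm of GM probability
  mass into CSF (default 0.2) — mass is conserved, only redistributed;
* **ambiguity** ω: the width in voxels of the inter-tissue transitions
  (default ω_AD = 3 vs ω_CN = 1) — wider transitions mean more
  partial-volume, "ambiguous" voxels.

The brain/background boundary deliberately does *not* widen with ω: a fixed
0.5-voxel envelope models a skull-stripped edge. This matters: if ω applied
to the outer boundary, mask size would differ between classes and a trivial
brain-size artifact — not tissue ambiguity — would drive classification.
With the envelope, the analysis mask is identical across ω.

Per subject: independent ±5% jitter on the three radii, additive Gaussian
noise (sd σ = 0.02 in probability units) on voxels with tissue signal,
clipped to [0,1] and renormalized where the sum exceeds 1; age uniform on
[60, 90], genders balanced within class. Everything derives deterministically
from a master seed (per-subject sub-seeds for geometry and noise).

What the phantom does **not** model: real anatomy (cortical folding,
hippocampus, ventricle geometry), spatially focal atrophy, registration
error, scanner bias fields, or site effects. Passing the end-to-end tests
shows the pipeline detects the two encoded effects at realistic noise — not
that it reaches any particular accuracy on real MRI cohorts.

### How ω expresses itself

Wider transitions increase the *count* of intermediate-probability voxels
(monotone in ω), which is where the class signal lives in the histon's
ambiguity bins. The expanse quantity itself — the mean within-supervoxel
standard deviation — *decreases* with ω on these phantoms: with supervoxel
size fixed by I_n, within-supervoxel spread is slope-limited and the sigmoid
slope scales like 1/ω. Both directions are asserted in the tests. One might
expect the deviation to grow with ambiguity; that holds only when transition
zones are thin relative to supervoxels, a regime these smooth phantoms leave
quickly.

### Null-cohort calibration

With both knobs off (Δ_gm = 0, equal ω) AD and CN generation is bitwise
identical given the same seeds, so any residual separability is cohort-level
sampling luck: with 20 subjects per class, the jittered geometry gives the
classifier a few stable nuisance dimensions whose chance class imbalance is
learnable *within* a cohort. Mean balanced accuracy over splits therefore
scatters around 0.5 with more-than-binomial spread across cohort seeds; the
seeded null test asserts the binomial 95% interval for its fixed seed.

## Problem sizes

Defaults were chosen so a complete study runs in minutes on one CPU: 48³
grids (≈ 40k masked voxels), ≈ 300 supervoxels (I_n = 5), 20 + 20 subjects,
ten splits. Feature extraction takes ≈ 1.5 s per subject; the dominant cost
is the SLIC assignment sweeps.

## Numerical and degenerate-case choices

* Quantization rounds half up; quantizing already-quantized data is an error.
* Empty masks, single-class training sets, unquantized inputs to SLIC or the
  histon, and dimension mismatches are hard errors naming the offender.
* Population (divisor N) standard deviations throughout supervoxel
  statistics; single-voxel supervoxels get sd 0.
* Strict inequality in the similarity test: with a constant volume the
  expanse is 0 and S2 ≡ 0 (histon = histogram), rather than S2 ≡ 1.
* PCA uses SVD of the standardized training matrix; eigenvalues use the 1/n
  convention consistent with the population variance of the scores.
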