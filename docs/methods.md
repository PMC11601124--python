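# Methods

This note documents the models, numerical choices and deliberate design
decisions behind `billflex`, and what the synthetic-data tests do and do
not demonstrate about real data.

## Coordinate conventions

Lateral view, 2D: x increases from the rostral bill tip toward the base,
y increases ventral → dorsal, lengths in mm. Dorsal deflection of the
bill tip is therefore positive in y. Along the CT axis, z = 0 at the
rostral *bony* tip and increases toward the cranial base. Landmark
indices run 1 (tip) to 21 (end of the exposed culmen) per profile line;
the three lines are concatenated culmen, tomium, ventrum into 63-landmark
frame configurations.

## Semi-landmark kinematics

Profile traces are resampled to 21 points at arc-length fractions
k/20 on the piecewise-linear trace, endpoints preserved exactly. Eleven
equally spaced frames represent one lick cycle (indices
round(k·(N−1)/10), round-half-up, always including the first and last
frame of the cycle).

GPA centers each configuration, scales it to unit centroid size, and
iteratively rotates it to the running consensus (orthogonal Procrustes
with determinant +1; reflections are disallowed because lateral-view
images share handedness). The consensus is the renormalized mean; because
a collective rotation of all aligned shapes is a gauge freedom of the
superimposition, the consensus orientation is pinned to the previous
iterate each iteration so the convergence test (consensus change <
1e-10, ≤ 100 iterations) measures shape change only. Non-convergence is
flagged on the result, never silent. Alignment is run per subject over
all frames of all cycles collectively, so frames share one consensus.

Per-landmark variance S² = var(x) + var(y) (denominator n−1) is computed
within each cycle over its 11 aligned frames and summarized across cycles
by the mean and a Student-t 95% CI (df = n_cycles − 1; small n makes the
t interval the appropriate choice). Variance profiles are always computed
*without* semi-landmark sliding: sliding redistributes exactly the
dorsoventral signal being measured. Sliding (tangent directions from
central differences of the consensus, per-specimen tangential projection
onto the consensus, re-GPA, outer loop tolerance 1e-8, ≤ 20 iterations)
is available for the PCA trajectory analysis only, and is a monotone
descent on the total Procrustes sum of squares. Relative warps are
computed as PCA of the Procrustes-aligned coordinates (uniform and
non-uniform components pooled), which yields the same scores and percent
variances as a partial-warp-based analysis without thin-plate-spline
machinery; wireframe reconstructions accept a 1.5–7× magnification.

### Hinge localization

Under rigid rotation of the segment distal to a hinge, the
GPA-superimposed displacement field is piecewise linear in arc position
with a kink at the hinge: the superimposition superposes a compensating
rigid motion, so each branch crosses zero at a cancellation node flanking
the hinge, and √S² exhibits an interior local maximum exactly at the
hinge. The hinge estimator takes the most prominent interior peak of √S²,
refined by parabolic interpolation. (A broken-stick fit instead finds the
distal cancellation node, which is biased ~3 landmarks distally — hence
the peak detector.) The same detector localizes a localized-flex bending
zone, whose variance peaks at the zone itself. Across 20 random
scenarios (hinge fraction 0.3–0.8 from the base, 0.5 mm tip deflection,
0.02 mm tracking noise, 10 cycles), the estimator recovers the hinge
within ±1 landmark spacing.

### Procrustes leakage

Because superimposition distributes localized landmark motion across the
configuration, the package includes the control experiment: replicate a
single frame, perturb only a few landmarks uniformly within lick-scale
ranges (defaults ±0.05 mm along and ±0.25 mm across the bill axis,
matching the within-lick displacement scale of the default scenario),
GPA-align, and report the ratio of summed variance at unvaried landmarks
to that at varied landmarks. Perturbations are applied in the bill's own
long/transverse axes so the experiment is invariant to frame orientation.
Perturbing 1–5 interior semi-landmarks (line endpoints are anatomically anchored corner points and are not perturbed) leaks ≈ 2.5–4.5% depending on the subset —
small enough that variance profiles are interpretable landmark-locally.

Leakage grows with the *coordinated* moving fraction of the
configuration: when both maxillary lines rotate distal to a mid-bill
hinge, the compensating rigid motion puts up to ~6–9% of the peak
variance on static landmarks near the hinge and the bill base. The
proximal-leakage bound below 5% of the profile maximum therefore holds
for single-line deflections (measured ≈ 1.3%); tests of that bound use a
culmen-only scenario, while hinge-recovery and ANOVA tests use the
realistic whole-upper-bill default.

## Procrustes ANOVA with RRPP

The response is the (frames × 126) matrix of aligned coordinates. Sums
of squares are traces of residual cross-product differences between
nested least-squares fits; F is Goodall's trace statistic
(SS_term/df_term)/(SS_res/df_res), appropriate for the high p:n ratios of
landmark data. Type III SS (full model vs. full minus term) are used for
testing; R² is reported from the sequential decomposition with blocking
factors (cycle, tracking dataset) entered first, separating estimation
from testing. For each term, significance comes from permuting the
residuals of the reduced model (RRPP), adding them back to the reduced
fits and recomputing F; the observed statistic is counted among the
permutations, so p ≥ 1/(n_perm + 1). Cycle is treated as a fixed
blocking factor. An effect size Z is reported as the standardized
log-F location within the permutation distribution. Default n_perm is
9999; calibration simulations use 999. Under a true null (pure-noise
response, 4 cycles × 11 frames, 6 response columns, 200 simulations at
999 permutations) the empirical type-I error at α = 0.05 falls within
[0.02, 0.09].

Tracking repeatability uses the same machinery with "dataset" (observer ×
attempt) as a block, plus a per-landmark error-variance profile: S²
across replicate trackings within each frame, summarized across frames
with a t-based 95% CI. A landmark is flagged as genuinely mobile when its
lick-cycle S² CI lies entirely above the tracking-error CI
(non-overlapping intervals). With synthetic replicates equal to truth
plus isotropic noise of sd σ, the mean error variance reproduces 2σ²
(expressed in unit-centroid-size shape space) within 15% at 30
replicates.

## Flexural rigidity

EI per slice is Σ E·(y − y_axis)²·dA over ROI pixels, with dA = pixel
area, y the pixel-center height, densities from the linear phantom
calibration (OLS of density on mean gray), and E(ρ) = a·ρ^b a
configurable monotone power law (coefficients are config, not baked-in
constants; all tests use synthetic calibrations with known truth).
Negative calibrated densities (air/soft tissue) clamp to zero with a
logged count, so non-bone pixels never contribute negative stiffness. The
default bending axis is the E-weighted centroid height of the ROI union
per slice — the mechanically consistent neutral axis for a heterogeneous
section — with a fixed-height override. Per-ROI EIs are computed about
that shared axis, so ROIs that partition a section sum exactly to the
combined profile. Half-pixel edge effects are accepted and bounded: the
phantom generator renders partial-volume densities (area-weighted
subpixel coverage, as a real CT reconstruction does), under which the
pixel-sum EI converges to the closed forms with error ratios ≤ 0.6 per
pixel-size halving; at practical resolutions (≥ 40–60 px across the
section) agreement is within 0.1%.

Region segmentation smooths the combined profile (moving average, window
2% of the profile length) and takes the two most prominent peaks — the
rostral fusion of the premaxillae and the craniofacial hinge — labeling
the span between them region 2 (bending zone), distal slices region 3
(symphysial) and proximal slices region 1 (nasal). Profiles without two
detectable peaks are flagged undefined rather than force-segmented.

Axis alignment maps CT z to the landmark axis affinely: the CT bony span
is scaled to (total culmen − keratin tip offset) and shifted by the
keratin-only tip length measured from the scans, so z = 0 (bony tip) maps
to landmark fraction keratin_offset/total from the keratinous tip. The
merged table interpolates S² at the fractional landmark index of each
slice. In the coupled synthetic scenario (flexing zone at the phantom
waist) the EI minimum and the S² peak co-localize within 0.1% of bill
length, far inside the ±5% acceptance band.

## Annular Couette–Poiseuille transport

The model treats the tongue (radius R₀) reciprocating in the bill lumen
(radius h(z) > R₀) in the Stokes/lubrication regime: the axial velocity
satisfies no-slip at both walls and is affine in (U, dp/dz). The flow
rate is integrated analytically; because the printed closed form of this
integral (and the shear-stress display that substitutes it) is
typographically corrupted in the source describing the model, the
implementation derives the closed form independently and validates it
against adaptive quadrature (≤ 1e-9 relative over a 10×10 grid of U and
dp/dz — the quadrature is the authoritative oracle). Mass conservation
fixes dp/dz(z) by an exact linear solve at each z. Wall shear stress on
the tongue comes from the analytic radial derivative; the resisting force
integrates τ·2πR₀ along the immersed length.

For the blunt-tip limit R₀ ≪ h, dropping O(R₀²/h²) terms while keeping
D = ln(R₀/h) gives the mass-conserving asymptotic

F ≈ 2πLμ·(U − 2Q₀/(πh²))/(D + 1),   Q₀ ≈ πR₀²U,

with shear-dominated limit F ≈ 2πLμU/D. This form converges to the full
force (relative error 4.6e-4 at R₀/h = 0.01, monotone over
R₀/h = 0.5 → 0.005) and preserves the physical conclusions: the
resistance is governed by the logarithmic shear term, and widening the
lumen relative to the tongue reduces the force.

Cycle-level transport integrates flow and work over one reciprocation
(fixed-step trapezoid, ≥ 200 steps/cycle, step-halving checked): the
instantaneous flux is the Couette flux of the tongue motion plus any
tip-wringing source flux, and the mass-conserving pressure gradient
yields the force. Symmetric reciprocation with no source nets exactly
zero (Couette flux is linear in U); a protrusion-phase source produces
basal transport equal to the injected volume, linear in the source.
Sign conventions: z tip → base, retraction U > 0, Q > 0 toward the base.
Units are mm/s/Pa·s, so forces are in µN-scale consistent units. Demo
parameters (μ = 1.7 mPa·s for ~20% w/w sucrose, R₀ ≈ 0.25 mm,
h ≈ 0.3–0.35 mm, 15 Hz) are illustrative only and never serve as test
oracles.

## Synthetic data: what it emulates, and what it does not

The lick-cycle generator deforms a parametric bill template (18 mm
exposed culmen, 20 mm total culmen, 1.2 mm keratin-only tip, tapering
upper and lower bill depths — proportions of a straight-billed
hummingbird) by either rigid rotation distal to hinge points (with the
hinge inserted as an exact polyline vertex, so proximal semi-landmark
positions are exactly frame-invariant at zero noise) or a localized
Gaussian dorsoventral flex bump; a smooth sin² phase profile over the 11
frames closes each cycle. Hinge fractions are measured from the bill
base toward the tip, so large fractions are distal rhynchokinesis.
Tracking noise is isotropic Gaussian per landmark (default sd 0.02 mm —
a repo choice on the scale implied by digitizing error in high-speed
video, since no numeric tracking-error magnitude is published). All
randomness flows from one integer seed per call.

The beam phantoms provide closed-form EI for annulus and rectangle and a
quadrature-validated closed form for the arched shell; the waisted
annulus places a Gaussian trough in outer radius at a commanded fraction
of the bony length. What passing these tests shows: the estimators
recover known geometry, variance, rigidity and flow quantities under
controlled noise. What they do not show: robustness to real videographic
artifacts (out-of-plane motion, occlusion by nectar, observer drift),
real bone heterogeneity/anisotropy, or free-surface effects in the
tongue–bill gap — all outside the model class by design.

## Problem sizes

Default analyses use 10 cycles × 11 frames × 63 landmarks; statistical
calibration uses 200 null simulations at 999 permutations (4 cycles × 11
frames, 6 response columns); hinge recovery uses 20 scenarios; phantoms
use 30–60 slices at 0.02–0.04 mm pixels. These sizes were chosen so the
full suite exercises every claim at desk scale while each property
remains comfortably resolved.

## Known limitations

- The superimposition leakage floor means variance profiles are
  landmark-local only down to ~2–9% of the peak, depending on how much of
  the configuration moves coherently; bending-zone flags should always be
  read against the tracking-error CI.
- Region segmentation assumes two dominant rigidity peaks; double
  bending zones with three peaks are labeled by the two most prominent.
- The fluid model is 1D-lubrication: radial velocities, entrance effects
  and free surfaces are neglected.
- GPA at the default 100-iteration cap can fail to converge on
  pathological shape sets with no shared structure; the result carries an
  explicit converged flag.
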