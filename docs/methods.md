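# Methods

This package implements an elastic (diffeomorphometric) analysis of cochlear
midline curves and the comparative-evolutionary statistics that sit on top
of it, exercised end to end on a synthetic cohort that emulates the
structure of a fossil-and-extant hominoid study.

## Shape space and registration

A cochlear midline arrives as an ordered open polyline, base to apex,
resampled to N = 200 semi-landmarks equally spaced in chord length
(resampling iterates to the fixed point at which the *output* polyline's
chords are exactly equal, which makes the operation idempotent to machine
precision). Size is removed by scaling to unit arc length and translation
by centring; left-side curves are mirrored across x = 0 before analysis so
all specimens share chirality. The unit-length curve is mapped to its
square-root-velocity function q = c′/√‖c′‖, under which the elastic metric
is the flat L2 metric and, after projection to exact unit norm, shapes live
on the unit sphere of L2([0,1], R³).

Two shapes are registered over rotation and reparameterization. Rotation is
solved globally by SVD of the cross-covariance (Kabsch), with reflections
disallowed — chirality is handled by the side-mirroring contract, never by
the optimizer. Reparameterization is solved by dynamic programming over
monotone lattice paths on the native 200-point grid, with step offsets
(di, dj) ∈ {1..5}² (gcd 1), bounding local slopes to [1/5, 5]. After each
DP pass a smoothed variant of the warp (moving-average on its increments,
which preserves monotonicity) is also evaluated and the closer registration
kept, since the continuum optimum is smooth while the raw DP warp is
piecewise linear. Rotation and warp alternate for at most 3 rounds or until
the distance improves by less than 1e-4: measured improvements beyond the
third round are at the 1e-4 level on 200-point grids while the additional
rounds dominate the cost of the pairwise stages. The distance is the sphere
arc length arccos⟨q₁, q₂⟩ after registration, evaluated in both directions
with the smaller residual kept — the discrete warp search is directional,
and taking the minimum makes the distance exactly symmetric while tightening
the discretization bias.

Numerical notes. Derivatives for the SRVF are fourth-order finite
differences (one-sided at the endpoints); no smoothing is applied at this
stage. The inverse transform integrates c′ = q‖q‖ through a cubic-spline
antiderivative rather than the trapezoid rule: trapezoid error oscillates
point-to-point and, although negligible positionally, it is large at the
derivative (SRVF) level. With the trapezoid-rule L2 inner product the
discrete norm of a unit-length curve's SRVF equals 1 to O(h²) ≈ 4e-5 at
N = 200; `normalize_srvf` then projects exactly to the sphere. Two genuine
limitations of the discrete registration are documented by the tests rather
than hidden: (i) a geodesic midpoint re-extracted as a curve and re-registered
independently to both ends is equidistant only up to warp-discretization
error (a few percent), though it is exactly equidistant on the sphere by
construction; (ii) composing warps across alignment rounds can produce local
slopes outside [1/5, 5], and for *unrelated* curves the resulting extreme
compression genuinely loses local shape information at fixed N. Cochlear
curves are mutually similar, so the pipeline operates far from that regime.

## Fréchet mean and tangent PCA

The Karcher mean is initialised at the sample medoid (smallest sum of
squared elastic distances, ties broken by lexicographically smallest
specimen id; the medoid scan uses single-direction registrations, which is
sufficient for an initialiser). Each iteration registers every specimen to
the current estimate, averages the log-map (shooting) vectors and shoots by
the exponential map, with the step halved on cost increase. Iteration stops
when the mean update norm falls below `tol` (default 1e-6) or when the
Fréchet cost stalls (relative change below 10·tol): the discrete warps put
a floor under the update norm, and a stalled cost means the estimate is at
the achievable optimum. An optional `init` curve warm-starts the iteration.

Tangent PCA decomposes the shooting vectors at the mean. The PCA is taken
about the origin of the tangent space rather than re-centred: at the
converged mean the average shooting vector vanishes, and this convention
makes the mean's own scores exactly zero. Components are orthonormal in the
trapezoid-weighted L2 metric; variance fractions are ordered and sum to 1.

## Curvature and torsion maps

κ = ‖c′×c″‖/‖c′‖³ and τ = (c′×c″)·c‴/‖c′×c″‖² are evaluated from
quintic-smoothing-spline derivatives fitted per coordinate against arc
length. The smoothing parameter defaults to 0 (interpolation), which passes
the circle/helix closed-form suite at 1% with N = 200; raise it for noisy
digitizations. Torsion is flagged undefined where κ < 1e-6/arc-length (its
denominator vanishes with κ), and the three samples at each end are flagged
lower-confidence. Sign convention: right-handed frame, positive τ is a
right-handed twist. Under reflection κ is invariant and τ flips sign; both
scale as 1/λ under uniform scaling by λ.

## Labyrinth indices and error statistics

TLI and the two inclination angles are inputs measured on images; the
package derives the six ratio indices (HZL/ANL, HZL/POL, POL/ANL, ECL/HZL,
ECL/POL, ECL/ANL), propagating missing-value masks (a specimen with a
damaged anterior canal keeps every ANL-free column usable). The index PCA
standardizes columns — angles and ratios are on different scales — and drops
(with a warning) columns that are constant to within 1e-12 relative.
Repeatability uses ICC(2,1): two-way random effects, absolute agreement,
single measurement, computed from the ANOVA mean squares (cross-checked in
the tests against `pingouin`). The placement-error permutation test compares
mean between-specimen to mean within-repeat shape distance, permuting the
placement-to-specimen assignment (default 1000 permutations; the smallest
attainable p is 1/1001). The 3DGM baseline is a standard generalized
Procrustes superimposition (translate, scale to unit centroid size, rotate
without reflection, iterate to 1e-11) followed by PCA of the aligned
coordinates.

## Covariance comparison (drift vs selection)

W is the pooled within-taxon covariance Σ(n_g−1)S_g/Σ(n_g−1) over the first
three PC scores (singleton taxa are excluded with a warning); B is the
covariance of the unweighted taxon means (divisor G−1, no phylogenetic
weighting — the phylogeny enters separately through the OU stage). The
relative eigenvalues solve B v = λ W v. Proportionality (B = cW, the drift
expectation) is tested by the Mauchly-type likelihood ratio on the
log-eigenvalue dispersion,

T = (n_eff − c_box) · (p·log λ̄ − Σ log λᵢ),  df = p(p+1)/2 − 1,

with c_box = (2p²+p+2)/(6p) the standard Box small-sample factor and
n_eff = n₁n₂/(n₁+n₂) when both matrices are estimates with Wishart degrees
of freedom n₁ and n₂ (the log-eigenvalue variance contributions add). The
simulation calibration in the acceptance tests puts the type-I error at
5 ± 2% for n = 50, p = 3 and the power above 0.9 in the strongly
anisotropic (40, 5, 0.3) regime. Note that when B is built from only six
taxon means its degrees of freedom are 5, so n_eff ≈ 4.7: the test is then
deliberately conservative, and the end-to-end benchmark's p-value reflects
that small-G honesty rather than a defect.

Covariance matrices are ordinated by classical MDS of the Riemannian
distance d(S₁,S₂) = √Σ log²λᵢ(S₁|S₂). Drift comparison maps an F_ST value
to the eigenvalue (between/within ratio) scale as F/(1−F); an eigenvalue is
flagged as exceeding drift when it exceeds the image of the *lower* edge of
the among-species band (0.49 → 0.96), the most conservative bound that a
between-species ratio under pure drift can take; both mapped bands and the
raw eigenvalues are always reported so the comparison is transparent. On
the eigenvalue triple (44.79, 5.89, 0.24) this flags the first two and the
leading ratio exceeds 7.

## Ornstein–Uhlenbeck trait evolution

Tip values on a dated tree (branch lengths in Ma; fossil tips at nonzero
ages, ultrametricity not required) are jointly Gaussian with
E[xᵢ] = x₀e^{−αTᵢ} + θ(1−e^{−αTᵢ}) and
cov(xᵢ,xⱼ) = σ²/(2α)·e^{−αd_ij}(1−e^{−2αt_ij}), where t_ij is the shared
root-to-MRCA duration and d_ij the separating time; as α → 0 this converges
to the Brownian limit σ²t_ij (computed through expm1 so the limit is exact
numerically). Two built-in divergence scenarios encode the open phylogenetic
question: continuity (MRCA of *P. robustus* and *Homo* at 2.8 Ma, the
*A. africanus* lineage splitting just above) and sister (MRCA at 3.5 Ma
with *A. africanus* outside). Shared calibrations: root (Gorilla) 9 Ma,
Homo–Pan 7 Ma, Pan split 2 Ma; fossil tips at 2.5 (*A. africanus*) and
1.8 Ma (*P. robustus*). These ages are config-exposed defaults, not
reconstructions.

Inference is random-walk Metropolis over (log α, log σ², θ, x₀) with
log-uniform priors on α over [1e-3, 100]/Ma and σ², and Gaussian priors on
θ and x₀ scaled from the tip dispersion. Chains start from deterministic
moment heuristics (α ~ 1/depth, σ² ~ var/depth, θ = x₀ = mean); the
proposal scale adapts toward 35% acceptance during the first third
(discarded), and summaries report posterior means, 90% credible intervals
and split-chain R-hat. The desk default is 50,000 iterations; the
configuration accepts the full 5,000,000 used at publication scale.
Marginal likelihoods for scenario comparison use stepping-stone with a
cubic β-ladder (rungs concentrate near the prior); the harmonic-mean
estimate is reported but flagged unreliable.

A structural finding the tests document: with a single trait realization on
the six-taxon trees, the KL divergence between the two scenarios' tip
distributions is below 0.1 nat for all α, so no method can prefer the
generating scenario much beyond chance — the analysis script reports the
comparison with that caveat. The scenario-recovery benchmark therefore uses
tree pairs that actually differ (distinct 12-tip topologies over a shared
tip set, three independent trait replicates), where the generating scenario
is recovered in well over 80% of replicates; parameter-recovery coverage is
checked on 40-tip trees.

## The synthetic cohort

The generator is the stand-in for an undeposited micro-CT dataset, and its
defaults are the study conditions. A cochlear template is a helico-spiral
x = ae^{−bθ}cosθ, y = ae^{−bθ}sinθ, with z the integral of a pitch profile,
over ~2–3 turns (parameters in mm and radians). An apical hook multiplies
the pitch by (1−hook_strength·w)³ and accelerates the radial decay by
(1−0.35·hook_strength·w), where w rises smoothly over the first 40% of the
hook span and stays at 1 after: at hook_strength 1 the apical section is
exactly planar, so torsion vanishes there while curvature rises — the
cubic suppression matters because τ ≈ p/(r²+p²) only vanishes once the
pitch drops well below the (small) apical r². Ground truth κ/τ for any
template comes from dense high-order differentiation of the exact
parametric formula, an oracle independent of the spline estimator.

The default study draws six taxa plus one unknown specimen at group sizes
16/16/16/15/9/8/1. Four extant-analogue templates occupy a shared region of
parameter space; the *Australopithecus* analogue and the unknown sit
together at moderate displacement; the *Paranthropus* analogue is strongly
displaced (pronounced hook, hook_strength 0.8, hook_span 0.4) with
within-taxon template variation at 40% of the other taxa — "distinctive
and relatively invariant" as a testable configuration. Template separations
were chosen so the benchmark has the designed properties: leave-one-out
1-NN balanced accuracy above 0.9 on the first three PCs, and a 3-cluster
solution that isolates the displaced taxon. Placement error is a smooth
random displacement field (six Fourier modes, amplitude 0.1% of arc length)
rather than independent per-landmark jitter: digitized midlines deviate
smoothly from the truth, and white noise at the landmark scale would be
amplified catastrophically by the derivative-based representation.
Labyrinth angles and arc lengths are per-taxon Gaussians at hominoid-like
magnitudes; they are not derived from the curve geometry, whose image-based
definitions are out of scope. All randomness flows from one root seed
through named substreams.

What passing on this cohort does and does not show: the synthetic curves
are structurally faithful (turn counts, decaying radius, hook, noise
scales) but not anatomically calibrated per taxon, so taxon-level numbers
(variance fractions, eigenvalues, cluster topology) characterise the
pipeline under a known truth, not the biology of any real assemblage.

## Problem sizes

Default analyses run at N = 200 semi-landmarks and the full 81-specimen
cohort. The test suite uses 60–200-point grids, 100 MCMC-recovery
replicates at 4,000 iterations, 50 scenario-recovery replicates, 500
proportionality-test calibration draws and 400 permutation-null replicates;
these sizes keep each statistical check's Monte-Carlo error well inside the
asserted tolerance.
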