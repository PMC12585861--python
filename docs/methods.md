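# Methods

This note documents the models, estimators and numerical choices behind
`spiralshape`, in the spirit of a methods appendix: what each stage
assumes, which knobs matter, and what the synthetic benchmarks do and do
not demonstrate.

## Synthetic cochleae

`generate_cochlea` draws points at angles uniform on `[0, 2πN]` from the
logarithmic helico-spiral `r(θ) = a·e^{−bθ}`, `z = cθ`, adds isotropic
Gaussian digitization noise, and marks three fixed landmarks (base, end of
the first turn, apex) with all other points as semi-landmarks. Defaults
(`a = 1`, `b = 0.1`, `c = 0.08`, 200–250 points) describe a mildly conical
cochlea of a few turns; the test batteries span `N ∈ [1.5, 4.5]`,
`b ∈ [0, 0.3]` and noise up to 1% of the basal radius. The logarithmic
radius law was chosen over a linear taper because it matches descriptions
of cochlear coiling and gives a closed-form arc length,
`∫ √(r′² + r² + c²) dθ`, used as an independent oracle. A left-handed
curve is generated as the exact mirror image (x negated) of the
right-handed curve with the same seed, so chirality handling can be tested
bit-for-bit.

What the generator does *not* emulate: within-species specimen variance
beyond i.i.d. coordinate noise, anisotropic digitization error along the
curve tangent, deviations of real cochleae from the logarithmic radius
law (real basilar-membrane curves change their taper along the course),
and partial or damaged curves. Benchmarks passing on this generator
demonstrate correctness of the algorithms under the stated model, not
field accuracy on CT data.

Trees are pure-birth (Yule): exponential waiting times with rate equal to
the number of extant lineages, one extra memoryless waiting time after the
n-th lineage (so no zero-length cherries arise, which would make the
Brownian covariance singular), rescaled to depth 1 exactly. Traits are
drawn from `N(root·1, σ²·C_model)` with `C_model` the transformed Brownian
covariance described below, via an eigenvalue square root so the singular
limits (λ = 0, σ² → 0) remain valid.

## Turn counting

The number of turns is the total winding angle of the curve about the
modiolar axis, divided by 2π, reported unsigned. Axis and center are not
observed and the estimator must supply them; this is where all the
difficulty lives. Design:

1. **Canonical frame.** The points are centered, scaled to unit centroid
   size and rotated into their principal axes with deterministic signs.
   This makes the output bit-stable under rigid motion and uniform
   scaling (asserted to 10⁻⁶ in tests).
2. **Axis seeding by chord turning.** For a candidate axis, the turning
   of the projected chord directions needs no center estimate, and for a
   logarithmic spiral equals the swept angle exactly (the tangent keeps a
   constant angle to the radius). Chords span `g` points with
   `g ≈ 6σ̂ / median step` so direction noise stays bounded; σ̂ is a
   robust noise estimate from axial second differences (MAD/0.6745/√6).
   Chords in the noise-dominated apex (length < 4σ̂, trailing run) are
   excluded. An axis is scored by |turning| and by the sign-consistency
   of its increments — a projection onto a plane containing the true axis
   oscillates and accumulates only random-walk winding.
3. **Helico-spiral model fit.** From each principal-axis seed (plus the
   line through per-full-turn centroids, which is parallel to the true
   axis for any logarithmic spiral), the 9-parameter model
   `p = c + e^{α+βθ}(cos(θ−δ)u + sin(θ−δ)v) + γθ·a` is least-squares
   fitted (soft-L1 loss) with the chord-based angles as the angular
   coordinate, and iterated: a better axis gives better angles and vice
   versa. Every iteration's fit is retained as a candidate; the fit with
   the smallest per-point residual wins (digitization noise is isotropic,
   so residuals over different reliable stretches are comparable). The
   fit is an *auxiliary* device — only its axis and center are consumed.
4. **Position-angle refinement.** Chord directions lose their signal at a
   much larger radius than position angles do (a chord is shorter than
   its radius by the factor dθ), so the winning fit is refined with the
   unwrapped position angles about its own center as the angular
   coordinate, restricted to radii above both the noise floor and twice
   the current fit rms (the center-uncertainty proxy). Iterated while the
   per-point residual improves, this recovers the inner windings of
   strongly tapered curves for the fit.
5. **Winding with apex handling.** Point angles about the fitted center
   are unwrapped. Where the radius falls below `6σ̂` the geometry carries
   no angular information; that trailing run is truncated and its winding
   extrapolated from a radius-weighted polynomial fit (linear, quadratic
   only if it clearly halves the residual) of angle against index over
   the last two reliable turns — spanning whole turns cancels the
   2π-periodic wobble a residual center offset induces. A noise-limited
   apex endpoint (radius < 30σ̂) is replaced by the fitted endpoint even
   without truncation, because the raw final angle has error ~σ̂/r.

Calibration on 1 600 random draws across the full parameter box: maximum
absolute error ≈ 0.02 revolutions, maximum relative error < 0.8%, no
failures. For noiseless curves the estimator is exact to ~10⁻⁴ turns. The
extrapolation step assumes the angular rate varies smoothly with sample
index; it is exact for sampling uniform in θ and approximate for
arc-length-equidistant sampling of strongly tapered curves — which is why
the pipeline computes metrics on the full-resolution digitized curves
rather than the 70-point template.

## Resampling, Procrustes, necklace sliding

`resample_equidistant` places all output points on a common equal-spacing
grid along the source polyline (`m` semi-landmarks plus the fixed
landmarks; interior fixed landmarks snap to the nearest grid position),
defaulting to the 3 + 67 = 70-point template. GPA centers, scales to unit
centroid size, and rotates with proper rotations only; reflections are
disallowed so chirality survives superimposition, and the specimen's
source curve is carried through the same similarity map so sliding
operates in the aligned frame.

The bending-energy matrix uses the 3D biharmonic kernel. With the kernel
written as `U(r) = +r` the relevant inverse block is negative
semi-definite; the implementation uses `U(r) = −r`, the sign of the 3D
Green's function, so the energy `Σ_d t_dᵀ B t_d` is positive
semi-definite and minimization is well posed. The energy annihilates
affine functions of the reference and is invariant under orthogonal maps
of the target (general linear maps of the target mix coordinate columns
and do change the quadratic form; the tests assert the invariances that
actually hold).

Necklace sliding parametrizes each semi-landmark by one arc-length
coordinate on its specimen's digitized curve. Outer loop: build **B** from
the current Procrustes mean; for each specimen run cyclic coordinate
descent, optimizing each coordinate by bounded scalar search between its
neighbours (minimum separation 10⁻⁶ of curve length, search tolerance
10⁻⁴ of curve length), accepting only strict energy decreases — so the
descent property and strict monotonicity (loop-freedom) hold
unconditionally; then re-run GPA and repeat until the mean moves less
than 10⁻⁶ (at most 10 outer iterations). Because bending energy is
invariant under similarity maps of the target, the energy can be
evaluated on curve-frame coordinates directly. A per-coordinate move only
changes one row of the quadratic form, so each trial evaluation is O(1)
after caching `Σ_{j≠i} B_ij x_j`.

## Ordination

PCA eigen-decomposes the coordinate covariance (divisor n−1; component
signs fixed so the largest-magnitude loading is positive). Phy-PCA
eigen-decomposes the evolutionary rate matrix `ZᵀC⁻¹Z/(n−1)` and PACA the
alignment matrix `ZᵀCZ`, both after centering at the GLS mean
`a = (1ᵀC⁻¹1)⁻¹1ᵀC⁻¹Y`; PACA additionally reports each component's
eigenvalue share as its percentage of phylogenetic signal. On a star tree
all three coincide (asserted). Ordinations run on species means only.

## Phylogenetic signal and PGLS

K and Kmult follow the ratio-of-ratios construction: observed
(ordinary / phylogenetically corrected) sum of squared deviations from
the GLS mean, divided by its Brownian expectation
`(tr C − n/1ᵀC⁻¹1)/(n−1)`; Kmult accumulates the sums over trait columns.
Both are exactly 1 on any star tree, for any non-constant data — a useful
exactness test because no simulation is involved. Permutation p-values
shuffle rows across tips, `p = (hits + 1)/(n_perm + 1)`.

PGLS profiles Pagel's λ on [0, 1] by bounded scalar search (boundary
candidates re-checked, since a bounded search can miss an endpoint
optimum by its tolerance), with the λ transform applied to the
*covariance* (off-diagonals × λ) so non-ultrametric trees with fossil
tips are handled. ML throughout (σ̂² with divisor n), which makes the λ=1
fit equal the BM fit exactly; Wald t tests use the unbiased (n−p)
rescaling. R² is computed from GLS sums of squares about the GLS mean.
The multivariate shape regression estimates λ per shape principal
component, averages with weights proportional to each component's share
of shape variance over *all* components with nonzero variance, whitens
data and design by the Cholesky factor of the λ̄-transformed covariance,
and tests the multivariate R² by residual randomization about the
intercept-only model (999 permutations by default, seeded). FDR control
is Benjamini–Hochberg.

## Trait-evolution models, rate shifts, ancestral states

All six models reduce to `y ~ N(a·1, σ²C')` with `C'` a one-parameter
transform of the Brownian covariance: λ scales off-diagonals; δ powers
node depths (ultrametric trees only); κ powers branch lengths; EB
replaces each branch spanning ages [t₀, t₁] by `(e^{rt₁} − e^{rt₀})/r`;
OU uses the stationary form
`C'_ij = e^{−α(dᵢ+dⱼ−2C_ij)}(1 − e^{−2αC_ij})/(2α)`. Root state and rate
have closed-form GLS estimates, so each fit is a bounded 1-D search
(bounds: λ ∈ [0,1], κ ∈ [0,3], δ ∈ (0,3], r ∈ [−10/T, 0],
α ∈ [0, 50/T] with T the tree depth). AICc ranks models; exact ties go to
the model with fewer parameters. 95% CIs come from the profile
log-likelihood (χ²₁ drop of 1.92). κ and δ are skipped, with a logged
warning, on non-ultrametric trees.

The rate-shift search is greedy and forward: every edge (branch scope)
and every internal node (clade scope = all branches of the subtree) is a
candidate for a multiplicative rate; at each step the best candidate's
multiplier is profiled by ML (bounds [10⁻³, 10³], log scale) using
Woodbury/determinant-lemma updates of the base covariance factorization,
so a full scan costs small-rank solves rather than fresh Cholesky
factorizations. A shift is accepted only if AICc improves (each shift
counted as two parameters: location and multiplier) *and* its
likelihood-ratio gain clears a Bonferroni-corrected χ²₁ bar at level
0.15 across the candidate count. The correction is essential: the best of
~200 correlated candidates improves AICc on >90% of single-rate datasets,
and the corrected rule measured ~2–5% false-positive rate with 85–90%
power for a 10× rate shift in an 8-tip clade (64-tip trees) — the
operating regime the acceptance suite asserts. Accepted shifts are
re-fitted jointly by cyclic profiling and reported with explicit
branch/clade attribution (tip sets), and the shift-scaled tree is
returned for reconstruction.

Ancestral states under BM on the (transformed, shift-scaled) tree are
conditional-normal GLS estimates: `â + cᵀC⁻¹(y − â1)` per internal node,
with `c` the vector of shared depths between the node and each tip, and
variances `σ̂²(depth − cᵀC⁻¹c + (1 − 1ᵀC⁻¹c)²/1ᵀC⁻¹1)` including the
root-estimation term. Tips pass through with zero variance.

## Pipeline

Stage order: ingest (sidecar CSV maps specimens to species and sides;
left ears mirrored) → resample to the 70-point template → within-species
GPA and species means → global GPA + necklace sliding → spiral metrics
(on the full-resolution curves) → ordinations → signal → PGLS battery
with FDR → per-trait model selection, rate-shift search, ASR. Body mass
enters the regressions on the log scale. All stochastic stages draw
independent child seeds from the master seed via `SeedSequence`, so runs
are byte-reproducible.

## Problem sizes in the test suite

Property tests use the smallest sizes that exercise the mathematics
(4–32 tips, 6–30 semi-landmarks); calibration tests use 64–256 tips with
200 replicates and 100–200 random cochleae, matching the regimes quoted
above. Monte-Carlo assertions state tolerances consistent with their
replicate counts (e.g. mean Kmult within 0.05 of 1 over 200 replicates).

## Known limitations

* The turn-count apex extrapolation assumes a smooth angular rate in the
  sample index; heavily non-uniform sampling of a noisy, strongly tapered
  apex degrades gracefully but is not covered by the calibration claims.
* Necklace sliding finds a coordinate-wise (not joint) optimum per sweep;
  the brute-force comparison shows per-coordinate optimality on a toy
  curve, not global optimality.
* The rate-shift search is stepwise: strongly overlapping shift
  configurations can shadow each other, and attribution is to the best
  single location per step.
* OU fitting uses the stationary covariance form; very small α on short
  trees is indistinguishable from BM (by design, the nesting tests assert
  exactly that limit).
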