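# Methods

This note documents the models, estimators, numerical choices and known
limitations of `phyloles`. Everything stated here is computed by the
package's tests or scripts; nothing is quoted from external sources.

## The analysis in one paragraph

Nine leaf economic traits — leaf life span (LLS), leaf mass per area
(LMA), construction cost (CC), water-to-dry-mass ratio (Wm), nitrogen
and phosphorus per dry mass (Nmass, Pmass), mass-based photosynthesis
and respiration (Amass, Rmass), and photosynthetic nitrogen-use
efficiency (PNUE) — are measured on co-occurring evergreen and
deciduous tree species at three elevations. After log10 transformation,
a PCA in the correlation metric yields one dominant axis (the leaf
economics spectrum); each species' oriented axis-1 score (PASS) is a
scalar proxy for its acquisitive-vs-conservative strategy. The package
then asks three questions: (i) how strong is phylogenetic signal in
each trait (Pagel's λ) and what is the tempo of its evolution (Brownian
motion vs single-optimum Ornstein–Uhlenbeck, α); (ii) how do traits and
PASS respond to leaf habit, elevation and environment once shared
ancestry is controlled for (PGLS); and (iii) does pairwise economic
distance |PASS_A − PASS_B| increase with pairwise phylogenetic distance
(TN93 model-based or patristic)?

## Derived traits

* Construction cost (g glucose g⁻¹) from carbon content C (mg g⁻¹):
  CC = (5.39·C − 1191)/1000. Carbon contents at or below
  1191/5.39 ≈ 220.96 mg g⁻¹ imply non-positive cost and are rejected:
  leaf tissue is roughly half carbon, so such inputs indicate unit
  errors rather than real leaves.
* PNUE (μmol CO₂ mol⁻¹ N s⁻¹) = Amass · 14.0067 / Nmass, with Amass in
  nmol g⁻¹ s⁻¹ and Nmass in mg g⁻¹. The factor is the molar mass of
  nitrogen; it converts nmol CO₂ per mg N to μmol CO₂ per mol N. The
  choice is validated by the printed group means the formula reproduces
  (92, 20.9 → 61.7 ≈ printed 62; 183, 25.6 → 100.1 ≈ printed 101).

## Phylogenetic covariance

For a rooted tree with branch lengths, `tree_vcv` builds
C_ij = root-to-MRCA(i, j) path length, with tip depths on the diagonal.
This matrix (possibly λ-scaled) is the expected residual covariance of
every GLS computation. Subsetting rows/columns equals recomputing the
matrix on the pruned tree (checked against dendropy pruning), which is
how habit- and elevation-restricted fits are done. Patristic distance
is D_ij = t_i + t_j − 2 C_ij. Trees need not be ultrametric anywhere;
branch lengths may be substitutions per site.

## TN93 pairwise distance

The Tamura–Nei model distinguishes the two transition types from
transversions under unequal base frequencies. With difference fractions
P1 (A↔G), P2 (C↔T), Q (transversions) and pooled empirical frequencies
of the two sequences, the closed-form distance is
d = −k1·ln w1 − k2·ln w2 − k3·ln w3 (coefficients and w's in the
`tn93_distance` docstring). Design choices:

* Pooled frequencies over the pair: symmetric (d(a,b) = d(b,a) exactly)
  and standard for pairwise estimation.
* Pairwise deletion of gap/ambiguity sites by default; complete
  deletion available per alignment.
* Gamma rate-variation correction off by default; when a shape a is
  supplied each −k·ln w becomes k·a·(w^(−1/a) − 1), which is never
  smaller than the log form (convexity) and converges to it as a → ∞.
* Any non-positive logarithm argument is reported as a flagged,
  NaN-valued "saturated" result with a diagnostic, never silently.
* A class of differences observed while the required bases have zero
  pooled frequency is an error naming the term; the same class with
  zero observed differences contributes zero (so identical sequences
  give d = 0 regardless of composition).

Neighbor joining (Q-criterion) is provided only as a convenience for
synthetic end-to-end runs; ML tree inference is out of scope. Negative
NJ branch lengths are clamped to zero with a logged count, and the
output is rooted at the final agglomeration (flagged arbitrary).

## Trait-evolution models

All three models are Gaussian on the tips and fitted by exact profile
ML; every log-likelihood is tested against a dense
multivariate-normal density at the fitted parameters (1e-8).

* **BM**: x ~ MVN(μ1, σ²C). Closed form: μ̂ = (1ᵀC⁻¹x)/(1ᵀC⁻¹1),
  σ̂² = (x−μ̂1)ᵀC⁻¹(x−μ̂1)/n (ML divisor n, so σ̂² has O(1/n) downward
  bias — verified ≈ within 10% at n = 128).
* **Pagel's λ**: off-diagonals of C scaled by λ ∈ [0, 1]; profile
  log-likelihood maximised by bounded Brent searches over the brackets
  between {0, 0.25, 0.5, 0.75, 1} (xatol 1e-8), endpoints evaluated
  exactly so lnL(λ=1) equals the BM value. LRTs against λ = 0 and
  λ = 1 use the χ²₁ tail. The search is restricted to [0, 1]; no
  extension to the PD-maximal λ.
* **Single-optimum OU**: root at the optimum θ, so the mean is θ1 and
  V_ij = σ²/(2α)·exp(−α d_ij)·(1 − exp(−2α s_ij)) with d the patristic
  distance and s the MRCA depth — valid for non-ultrametric trees and
  reducing to σ²C as α → 0 (checked to 1e-3 at α = 1e-6). α is profiled
  on a 33-point log10 grid over [1e-6, 1e2] and Brent-refined; fits
  pinned at a bound carry a boundary flag (the lower bound is the
  benign BM limit).

The BM-vs-OU LRT uses D = 2(lnL_OU − lnL_BM) clipped at zero against
χ²₁. The α = 0 null lies on the parameter boundary, so the test is
conservative; the measured type-I rate at nominal 5% is ~3% (n = 128,
200 BM replicates), within the ≤ 7.5% acceptance band. The α–λ
tempo/signal correlation across the nine traits is Pearson's r on the
raw estimates by default (a log10 α variant is provided), because α
estimates are log-scale noisy and the choice affects r; both are
reported by the pipeline.

Numerics: all solves against covariance matrices go through a Cholesky
factorisation with a single +1e-10 diagonal jitter retry (logged); the
log-determinant comes from the factor. Optimisers are deterministic
(fixed grids and brackets), so fits are bit-reproducible.

## PGLS

GLS with Cov(e) = σ²C(λ). Modes: `fixed-bm` (λ = 1, default — the
plainest reading of a "phylogenetic covariance" correction) and
`lambda-ml` (λ estimated by ML on the regression residuals); the active
mode and λ are always recorded. Categorical predictors are
treatment-coded with evergreen/low as reference levels; the overall
effect is the F-test against the intercept-only nested model in the
same covariance, with R² = 1 − RSS/RSS₀ in the GLS metric. On a star
phylogeny every statistic reduces to OLS (checked coefficient-by-
coefficient against statsmodels to 1e-10), and under fixed BM the
simple-regression slope equals the through-origin regression of
independent contrasts (checked to 1e-8 on 100 random instances).

The habit/elevation table tests habit within each elevation subset and
elevation within each habit subset, restricting the covariance to the
subset's species; subsets with n < 3 are flagged, not fitted. The
phylogenetic correlation r(x, y) = xᵀPy/√(xᵀPx·yᵀPy), with P the
covariance-weighted intercept-removing projector, is exactly symmetric
and equals sign(slope)·√R² of the simple PGLS.

PIC (Felsenstein pruning with the branch-length adjustment
v' = v + v₁v₂/(v₁+v₂)) is implemented as an internal oracle; polytomies
are resolved with zero-length branches in input order. The identity
Σ(contrasts²) = n·σ̂²_BM (ML divisor) is asserted directly.

## Distance regressions

PASS distance is |PASS_A − PASS_B| over unordered pairs; the filter
`intra_elevation_habit_cross` keeps same-elevation evergreen×deciduous
pairs (the ecologically co-occurring contrasts). Economic distance is
regressed on phylogenetic distance by OLS; Pearson r and the parametric
p are reported as the source analyses do, with an explicit warning that
pairs sharing species are not independent, plus an optional
Mantel-style permutation p (permute species labels of the PASS vector,
recompute pair distances, two-sided tail with a (permutations + 1)
denominator; default 9999 in the CLI, seeded from the run
configuration). The phylogenetic distance source is TN93 when an
alignment is supplied, else patristic; the active source is recorded.

## Synthetic study generator

The generator emulates the study design so every stage runs with no
external data: 34 species (19 evergreen / 15 deciduous), three
elevations, a Yule tree (depth 1, terminal-branch lognormal jitter 0.1
so the tree is non-ultrametric like a substitutions-per-site tree), and
one latent economics axis g simulated under Pagel's λ = 0.8 — the
middle of the signal range the real traits show.

* Habit is assigned in contiguous clade blocks by default
  (phylogenetically conserved, as leaf habit is in real communities);
  an iid option exists. Elevations are balanced within habit.
* g is shifted +0.65/−0.65 for deciduous/evergreen (gap 1.3 latent SD)
  and 0/−0.45/−1.0 for low/middle/high elevation, then standardized.
* Each log10 trait is base_k ± 0.15·g plus iid noise; conservative
  traits (LLS, LMA, CC) load negatively. The noise variance is solved
  from a per-trait communality h = 0.8085, because with nine equally
  communal traits the correlation-matrix axis-1 fraction is
  (1 + 8h)/9 — targeting the observed 0.834 dominant axis. Tables are
  exponentiated to the natural scale so the pipeline's own log10 step
  is exercised.
* The alignment evolves under TN93 (ITS-like: 600 bp, unequal
  frequencies, two transition/transversion ratios 4 and 5) along the
  same tree scaled to 0.35 substitutions/site max depth.
* Environment: MAT follows the lapse rule
  MAT = 12.8 + 0.55·(1200 − elev)/100 °C for plots at 900/1500/1900 m,
  with replicate noise (SD 0.3); soil variables are drawn per replicate
  (5 per elevation) from the per-elevation means/SDs of the study's
  soil table (e.g. N/P 3.5/4.7/10.2).

What the generator does **not** emulate: a second trait axis beyond
residual noise, intraspecific variation and measurement error,
covariance between habit and the latent axis beyond the mean shift,
non-Gaussian trait distributions, indels or rate heterogeneity in the
alignment, and spatial structure within plots. Passing tests therefore
show the estimators and pipeline are correct and well calibrated under
the assumed generating models — not that real communities satisfy
those models.

Determinism: one `numpy` Generator seeded from the config drives the
whole fixture; identical config + seed gives byte-identical output
files.

## Problem sizes and calibration checks

Recovery experiments use n = 128 tips and 200 replicates per setting —
large enough that the acceptance bands (λ = 0.8 → median λ̂ ∈
[0.7, 0.9]; α = 8 → median α̂ ∈ [4, 16]; habit effect 1.0 → mean β̂ ∈
[0.9, 1.1]; OU-LRT type-I ≤ 7.5%) are informative, small enough that
the whole suite runs in well under a minute per block. TN93 simulation
consistency uses L = 100 000 sites on a single cherry. The ANOVA
power of the designed soil-N/P differences measures ≈ 99.5% of seeds at
p < 0.001 on the raw scale and ≈ 93% after the log10 transform (the log
compresses the large high-elevation mean); the tests assert these
measured rates.

## Known limitations

* The OU fit assumes a single optimum shared by all species; no
  multi-regime or early-burst models.
* PGLS power for clade-aligned predictors is intrinsically low: when
  habit coincides with deep clades, the GLS standard error of the habit
  coefficient is dominated by a few deep-branch contrasts. The
  strong-separation tests therefore use the generator's iid habit
  option.
* Parametric p-values for pair regressions ignore the non-independence
  of pairs sharing a species; the permutation test is the defensible
  alternative and is always available.
* χ²₁ is used for all LRTs including the boundary-afflicted OU test
  (conservative, noted in results).
* No multiple-testing correction is applied anywhere; the report logs
  this explicitly.
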