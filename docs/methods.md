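# Methods

`drivephy` implements a comparative framework for asking whether plant
lineages whose female meiosis is asymmetric — and which therefore provide an
arena for centromere drive — differ from lineages with fully symmetric
meiosis in (a) the rate at which mean chromosome size evolves and (b) the
frequency of positive selection on the centromeric histone CENH3.  The unit
of analysis is the clade: each clade contributes one rate statistic and one
selection frequency per sequence region, and the cross-clade contrast between
the two meiosis regimes is assessed with multi-regime Ornstein–Uhlenbeck (OU)
models and phylogenetic regression on a clade-level tree.

## The clade-level rate of chromosome-size evolution

For each species, mean chromosome size is the diploid genome size divided by
the diploid chromosome count, 2C/2n (Mb).  Within each clade the sizes are
z-standardized (sample SD, n−1 divisor) so that clades with wildly different
genome sizes contribute comparable traits; Felsenstein's phylogenetic
independent contrasts are then computed on the clade's ultrametric species
tree, and the clade's rate statistic is the **median of the absolute
standardized contrasts**.

Two analytic properties of this statistic matter for interpretation and are
asserted by tests:

* It is exactly invariant to affine transformation of the raw trait — the
  z-transform removes location and scale, so a uniform inflation of the
  Brownian rate σ² leaves the statistic's distribution unchanged.
* Under uniform rescaling of branch lengths by s it scales as 1/√s.  The
  statistic therefore responds to *clade age* (and to departures from
  Brownian proportionality), not to the raw diffusion rate.  Young clades
  with the same standardized trait dispersion yield larger values.

Branch lengths are treated as relative time and never rescaled; medians of
|PIC| are compared across clades on whatever time scale the input trees
carry.  Polytomies are rejected by default; an explicit opt-in resolves them
into bifurcations with branches of length 1e−8 × tree depth, since silent
resolution would change contrasts.  Species missing from either the tree or
the karyotype table are dropped with a logged manifest; clades with fewer
than `min_species` (default 3: at least two contrasts, so a median is
meaningful) become skip records rather than silent omissions.  Duplicate
karyotype records per species collapse to the median 2C and smallest modal
2n; a `2C_pg` column is converted at 978 Mb/pg.

## The composite CENH3 selection frequency

The package consumes tabulated outputs of branch-level (aBSREL-style) and
codon-level (MEME-style) episodic selection tests; it does not refit codon
models.  Per clade,

* `f_branch` = significant orthologous-group branches / all
  orthologous-group branches (branches in paralogous-duplication subtrees
  are excluded from numerator and denominator via a per-branch flag);
* `f_codon` = significant codons / aligned codons, per region (full-length,
  N-terminal, C-terminal);
* the composite frequency is `F = f_branch × f_codon`.

Significance uses uncorrected P-values with strict thresholds (branches
P < 0.05, codons P < 0.1), the convention for exploratory scans; a P equal to
the threshold is not significant.  No multiple-testing correction is applied.
Branch tables are per clade (not per region), so region differences enter
through the codon component only.  Both thresholds are configurable, and
tightening a threshold can never raise the corresponding frequency.

## Multi-regime trait models

The regime (asymmetric/symmetric) is painted onto every branch of the
clade-level tree by Fitch parsimony from tip states, ties resolved to the
parent's state and the root fixed by the user (symmetric is ancestral for
land plants).  Seven models are fitted to each clade-level response:

| model | optima θ | pull α | diffusion σ² | k (2 regimes) |
|-------|----------|--------|--------------|---------------|
| BM1   | — (root mean) | 0 | shared       | 2 |
| BMS   | — (root mean) | 0 | per regime   | 3 |
| OU1   | single   | shared | shared       | 3 |
| OUM   | per regime | shared | shared     | 4 |
| OUMV  | per regime | shared | per regime | 5 |
| OUMA  | per regime | per regime | shared | 5 |
| OUMVA | per regime | per regime | per regime | 6 |

The trait follows dX = α(t)(θ(t) − X)dt + σ(t)dW with piecewise-constant
parameters along each root-to-tip path.  Tips are jointly Gaussian: the mean
is Wθ, where W is the row-stochastic matrix of exponentially discounted
regime occupancies (a segment of length ℓ in regime r, followed by total
attenuation A to the present, contributes e^{−A}(1 − e^{−α_r ℓ}) to column
r); the covariance accumulates per-branch variance increments
(σ²_r/2α_r)(1 − e^{−2α_r ℓ}) along the shared root→MRCA path, attenuated
along both tails.  By default the root is **fixed** at the root regime's
optimum with zero variance (no extra parameter, matching the parameter
counts above); `root_mode="stationary"` instead adds the root regime's
stationary variance σ²/2α to every covariance entry.  Both modes are
exercised by tests; which the original analyses used is not documentable, so
both are exposed.

### Estimation

At every likelihood evaluation the optima are profiled out by GLS,
θ̂ = (WᵀV⁻¹W)⁻¹WᵀV⁻¹y, and the overall σ² scale has the closed-form ML
solution rᵀV₀⁻¹r/n.  Numerical optimization therefore runs only over log α
(one or two values) and log variance ratios — at most three dimensions — by
bounded L-BFGS-B from a deterministic grid (α spans [1e−4/T, 50/T] with T
the tree depth; ratio grid 0.25–4), polishing the best few grid points.
Fits are deterministic given the configuration; an α estimate at the upper
bound raises a warning flag on the result.  BM1 is fully closed-form.
Standard errors come from the numerically observed information matrix
(central differences of the full log-likelihood); the GLS covariance
(WᵀV⁻¹W)⁻¹ is available as a cheaper θ-only alternative.

Internally, per-tree quantities are assembled from a node×branch path
indicator matrix, so one likelihood evaluation is a handful of
matrix-vector products plus one Cholesky factorization; this keeps the
bootstrap loops below cheap.

### Model comparison

Models are ranked by AICc by default — with 27 clades the small-sample
correction matters; plain AIC is a switch.  Akaike weights are
w_m = exp(−Δ_m/2)/Σexp(−Δ/2); the selected set is the best model plus every
model whose evidence ratio w_best/w_m is below 3.0.  Ties break toward fewer
parameters, then a fixed model order.  Models whose AICc is undefined at the
sample size (n ≤ k+1) are excluded with a logged reason.  Because a nested
model richer by one parameter loses at most 2 AIC units plus the AICc
correction, near-parity data routinely select two models — the
"two equally probable models" situation.

## Regime-difference inference

**Parametric bootstrap.** Under the best model's MLEs, tip data are
re-simulated and the model refitted (warm-started at the generating values)
`n_bootstrap` times (default 100); failed refits are redrawn and counted.
The two per-regime θ̂ distributions are compared with the two-sided
Mann–Whitney U test (exact enumeration when n₁n₂ ≤ 100 and tie-free,
otherwise the tie- and continuity-corrected normal approximation).  This
reproduces the descriptive workflow, but it is **not a calibrated test**:
under a true common optimum the two bootstrap distributions still separate
by the original fit's sampling error, so its P overstates significance.

**Calibrated optimum test.** `theta_difference_test` refits the model with a
single shared optimum, simulates under that null fit, refits both the
constrained and regime-specific models to each replicate, and compares the
observed likelihood-ratio statistic against its simulated null distribution
(Monte-Carlo P = (1 + #{LR* ≥ LR})/(R + 1)).  The LR statistic — rather than
the raw θ̂ difference — is used because the null fit inflates σ̂² when the
regimes truly differ, which would widen a θ-difference reference
distribution and destroy power; the LR is insensitive to that inflation.
The suite verifies a ~5% rejection rate under a true common optimum at the
study's sample size.

**PGLS.** Each clade-level response is regressed on the regime indicator
(symmetric = 0, asymmetric = 1) under Brownian residual covariance from the
clade tree, with Pagel's λ fixed at 1 by default (λ = 0 reduces exactly to
OLS; a profile-ML λ ∈ [0, 1] is a switch).  The response is square-root
transformed by default for variance stabilization (raw scale retained for
sensitivity).  t tests use n − 2 df.

## The synthetic study generator

The generator emulates the study design so every stage is testable without
external data: a Yule clade-level tree with 27 tips (depth 475 Myr), the
first 6 tips in preorder painted symmetric (a basal, grade-like group, as
bryophytes + lycophytes + ferns are on the land-plant tree; symmetric is the
root state), 21 asymmetric; 384 taxa across clades, 290 of them with
karyotypes, and 475 sequences once within-clade paralogues (allocated to
asymmetric clades) are counted.

* **Clade-level responses** can be drawn directly under a named scenario:
  `paper_like` (regime optima 0.118/0.058, stationary SD 0.02, α = 3 per
  tree depth), `null` (shared optimum 0.088), `strong_effect` (optimum gap
  of 4 stationary SDs).
* **Species-level karyotypes**: per-clade Yule species trees; log mean
  chromosome size evolves by Brownian motion (log scale because sizes are
  positive and right-skewed) from a root near 150 Mb; 2n is an even base
  count (4–48) with rare doublings (rate 0.05) mimicking polyploidy — a
  doubling moves 2C and 2n jointly, leaving mean size unchanged, as it
  should; 2C is back-computed as size × 2n.
* **Clade ages are the regime lever for rates**: asymmetric clades are young
  (42–65 Myr, genus/family scale) and symmetric clades old (187–281 Myr,
  class scale).  Because the rate statistic is invariant to σ² (see above),
  an age contrast — not a diffusion-rate contrast — is what produces the
  asymmetric > symmetric rate ordering in real data shaped like this, and
  the default ages place the regime mean rates at the study-scale optima
  (≈0.118 and ≈0.058).  Regime-specific log-scale σ² values (0.004 vs
  0.001 per Myr) are retained as parameters but are not the driver.
* **Selection tables** are Bernoulli draws at regime- and region-specific
  true rates chosen so the expected composite frequencies sit at study
  scale (full ≈ 0.007 vs 0.003; C-terminus ≈ 0.0029 vs 0.0001; N-terminus
  ≈ 0.163 in both regimes), with P-values drawn uniform below/above the
  significance threshold, and ω values log-normal below 1 for
  non-significant branches and 1 + exponential for significant ones.

All randomness descends from one master seed through counter-based
sub-seeds (`SeedSequence(seed, spawn_key=(clade, stream))`), so regenerating
is byte-identical and adding clades does not perturb earlier clades'
streams.

What the generator does **not** emulate: real clade-size imbalance (taxa are
spread nearly evenly), correlated evolution between chromosome size and
selection pressure (the two data layers are independent given the regime),
measurement error in 2C, non-Yule tree shape, or any mechanistic model of
drive, fusions or post-polyploid diploidization.  Passing tests therefore
show that the pipeline recovers the regime structure its inputs encode —
not that real data must encode it.

## Numerical choices and degenerate inputs

* Ultrametricity is checked at relative tolerance 1e−6 before OU fitting;
  non-ultrametric trees are rejected (the weight/covariance formulas assume
  a common present).
* Unrooted input is rejected rather than midpoint-rooted: painting and the
  OU root term depend on the root.
* α = 0 is reserved for the BM models; inside OU fits α is bounded below at
  1e−4/T, which behaves like BM (the suite checks the α→0 limit matches BM
  likelihoods to < 0.01).
* Zero-variance traits, empty orthologous-branch sets, singular designs and
  covariances all raise typed validation errors; clade-level wrappers turn
  them into skip records.
* Simulation adds a 1e−12 relative jitter before Cholesky factorization to
  tolerate numerically semidefinite covariances at extreme α.

## Problem sizes used by the checked claims

Oracle equivalence uses 100 random ≤5-tip two-regime trees against
ODE-integrated moments; parameter recovery uses 16 replicates at n ∈ {50,
200, 800}; model-selection power uses 50 replicates at n = 200; the type-I
check uses 200 null datasets with 60 bootstrap replicates each; composite
frequency convergence uses 1000 branches × 1000 codons.  The acceptance
script analyses one full synthetic study (27 clades, 290 karyotyped taxa,
475 sequences) with 100 bootstrap replicates.

## Known limitations

* Two regimes are exercised throughout; the machinery accepts more, but
  multi-regime behaviour beyond two is untested.
* The OU root options cover fixed-at-optimum and stationary; estimating a
  free ancestral state θ₀ is not implemented.
* BMS carries no trend parameters: it is a two-rate Brownian model only.
* PGLS supports a single binary predictor; no OU-based correlation
  structures or phylogenetic logistic regression.
* The Mann–Whitney comparison of bootstrap optima is reported for
  comparability but should not be read as a test level; use the calibrated
  LR bootstrap for inference.
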