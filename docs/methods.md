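# Methods

## Model

Two binary characters — riparian habitat and narrowly lanceolate leaf
shape — are collapsed to a single four-state character over the combined
states 1=(0,0), 2=(0,1), 3=(1,0), 4=(1,1).  Evolution along each branch is
a homogeneous continuous-time Markov chain with generator Q; simultaneous
changes of both traits have probability zero in an instant, so the four
"diagonal" entries Q₁₄, Q₄₁, Q₂₃, Q₃₂ are structurally zero.  The
dependent model frees all eight remaining off-diagonal rates; the
independent model ties them in pairs (q13=q24, q31=q42, q12=q34, q21=q43)
so each trait's dynamics ignore the other trait.  The two models are
strictly nested with four constrained dimensions.

Rates are in events per unit branch length of the input tree; the package
applies no internal rescaling, so trees whose branch lengths are in
substitutions per site yield rates per unit substitution distance.

Assumptions worth keeping in mind: a single homogeneous process across the
whole tree (no branch-specific or time-varying rates), independence of
lineages after splitting, and error-free tip states.

## Likelihood

Felsenstein pruning over the four combined states.  Tip partial vectors
are indicators of the states consistent with the observation; a missing
habitat or leaf value leaves its component free (the tip partial is the
union), and a completely unscored tip is all-ones, which provably cannot
decrease the likelihood.  Internal partials combine children in input
order (polytomies natively supported), each node is rescaled by its
maximum partial with the log accumulated, and the root partial is dotted
with the root prior.  The default root prior is uniform (¼ each) because
the original analyses do not state their root treatment; stationary and
fixed priors are available and every report records which was used.

P(t) for one branch uses scipy's scaling-and-squaring Padé exponential.
During fitting, all branches are computed at once from one
eigendecomposition of Q when its eigenbasis is well conditioned (a 1-norm
condition proxy below 1e8 *and* row sums within 1e-9 of 1), falling back
to per-branch Padé otherwise; entries are clipped to [0,1] after the
accuracy check.  The inner pruning loop runs as a numba-compiled kernel
over flat post-order arrays, with an identical pure-NumPy fallback when
numba is unavailable.

A brute-force likelihood that enumerates all 4^k internal-state
assignments (k ≤ 8) is kept as an independent oracle, along with a
closed-form two-state pruning routine used to verify the per-trait
factorization of the independent model.

## Maximum likelihood

Rates are optimized as logarithms within [1e-8, 1e3] — the published
estimates span an order of magnitude (7.08 vs 62.90), so a log scale and
log-uniform restarts are the natural choice.  Each repeat draws `n_tries`
starts (default 1000, after the original design), ranks them by
likelihood, and refines the best `refine_top` (default 10).  Benchmarks on
simulated 300-tip data showed the ranked-restart scheme reaches the same
optimum as refining every start, at a small fraction of the cost.

Refinement is two-stage: L-BFGS-B with finite-difference gradients,
followed by an adaptive Nelder-Mead polish (capped at 250·d evaluations).
The second stage exists because the 8-parameter surface has curved ridges
on which quasi-Newton steps terminate early; the simplex reliably walks
the remaining distance.  Nested-model comparisons additionally warm-start
the alternative model from the null model's optimum, which guarantees the
likelihood-ratio statistic is non-negative numerically and not just in
expectation (a negative statistic is clamped to zero with a warning in any
case).  Ties across restarts break first-found in seed order; identical
seed and configuration give bit-identical results.

Degrees of freedom: dependent (8) vs independent (4) → df 4; each single
fix-zero or equality restriction → df 1.  Both the maximum and the mean of
the per-repeat best likelihoods are reported — comparisons use the max by
default; the mean mirrors the original report, which averaged repeats.

## Bayesian estimation

Metropolis–Hastings over log-rates with per-parameter normal steps
(multiplicative log-normal on the rate scale, with the log-transform
Jacobian in the target), auto-tuned during burn-in to an acceptance
fraction of 0.2–0.4 and then frozen so the chain stays a valid MCMC.  The
default prior mirrors a hyper-prior design: rate ~ Gamma(shape, scale)
with shape and scale uniform on (0, 10], updated by their own moves.
Because "default parameters" of that mechanism are not fully specified
anywhere, an exponential(mean 10) prior and a bounded uniform prior are
offered as explicit alternatives, and every report names the prior used.

Marginal likelihoods use stepping-stone sampling with K powers at the
quantiles of Beta(0.4, 1) (the standard spacing, concentrating stones near
the prior): one tempered chain per stone, warm-started from the previous
stone, estimator Σₖ log mean L^(β_{k+1}−β_k).  With a flat likelihood the
estimator is exactly zero, a useful self-check.  The estimator is run
`n_repeats` times (default 10) and the mean is reported with the
per-repeat values, following the repeat-and-average design.  The package
default budget is 200,000 iterations split across 100 stones
(`iterations_per_stone` makes the split explicit; the original 10-million
budget is reachable by flag).  On the one-parameter validation fixture the
default-scale estimator sits within ~0.01 log units of a 10,000-point
quadrature, comfortably inside the 0.1 tolerance used in the checks.

The model-comparison statistic is the log Bayes factor in the
2·Δ(log marginal likelihood) convention — the convention the published
marginal likelihoods and Bayes factors satisfy exactly — graded ≥2
positive, ≥5 strong, ≥10 very strong.

## Trait coding

The leaf-shape index is the species mean of per-specimen means of per-leaf
width/length ratios.  Two wording variants exist for this quantity
(length/width vs width/length); width/length is adopted because only that
direction makes the "< 0.15 is narrowly lanceolate" threshold meaningful.
The boundary itself codes as state 1 (narrow), per the operational "less
than (including) 0.15" rule; the threshold is a parameter.  A pooled
per-leaf aggregation is available behind a flag; it differs from the
specimen-wise default only for unbalanced designs and is logged when used.

Habitat coding maps a controlled vocabulary (stream_bank,
swamp_or_pool_margin, other_wet, dry, forest, alpine, other_dry) to binary
states: the narrow riparian definition accepts only stream_bank, the broad
one any wet category, so the narrow-sense riparian set is always a subset
of the broad-sense set.  How species with mixed wet/dry populations should
be coded is genuinely open; the mapping is exposed rather than hard-coded.
Missing cells become the ambiguous state and are counted in the log.

## Synthetic data

The generator emulates the study design, not any particular dataset:

* **Trees** — pure-birth (Yule) trees grown to n tips (dendropy), with the
  terminal branches extended by one Exp(n·λ) holding time so the youngest
  cherry is not at zero height; ultrametric, tips t1…tn.  Default sizes
  50–300 tips bracket the ~50-taxon reduced tree of the motivating study.
* **Traits** — endpoint sampling: the root combined state is fixed or
  drawn, then each child's state is drawn from the parent's row of
  P(branch).  Exact for tip-observed data; no path simulation needed.
* **Measurements** — 3 leaves × 10 specimens per species; log-normal
  lengths around 80 mm; width = length × ratio, with the ratio centred at
  0.08 (narrow) or 0.30 (wide) and specimen- and leaf-level log-normal
  noise (σ = 0.10 and 0.20).  The two classes sit ~4 log-sd on either side
  of the 0.15 threshold after averaging 30 leaves, giving the near-perfect
  round-trip a herbarium protocol of this depth would produce.

Named scenarios: `independent_null` (all four independent rates 0.1,
100 tips), `dependent_strong` and `preadaptation` (both with q24 = 10·q13,
300 tips; preadaptation additionally makes the leaf change from state
(0,0) fast), `tiny_oracle` (5 tips, enumerable).  Rates are chosen so
trees of total length ≈ n carry a handful to a few dozen expected events
per rate class — informative but far from saturation.

What passing these simulations does *not* show about real data: the
generator has no habitat misclassification, no phylogenetic error or
branch-length noise, no rate heterogeneity across lineages, and balanced
measurement designs — so the validation quantifies correctness of the
machinery, not robustness to violations of the model.

## Validation studies and problem sizes

The seeded studies in `traitlink.validation` (run by
`scripts/acceptance.py` and the acceptance tests) use: 50 replicates of
300-tip trees for asymmetry recovery and equality-test power; one 100-tip
tree × 200 trait datasets for the type-I error of the df-4 LRT (nominal
5%, assessed against the exact binomial band, conservative behaviour
acceptable); a 4-tip one-free-parameter fixture for stepping-stone
accuracy (32 stones × 1000 iterations × 3 repeats vs dense quadrature);
500 species for the coding round trip; 40 random small trees for the
parsimony-vs-enumeration check.  Within the replicated fits the
multi-start budget is 64 ranked starts with 2 refined — the setting the
optimizer benchmarks showed to be equivalent to much larger budgets on
these surfaces.

## Numerical choices and edge cases

* Zero-length branches are legal; their transition matrix is the identity.
  Conflicting tips joined by zero-length paths give likelihood 0 → −∞ with
  a warning.
* Per-node rescaling keeps partials in range on deep trees (log-scale
  accumulation).
* The stationary distribution requires irreducibility, checked as strong
  connectivity of the positive-rate graph (a chain with unreachable states
  still has a one-dimensional null space, so a rank test alone is not
  enough); reducible generators raise an error suggesting a uniform root
  prior.
* The parsimony counter is unit-cost Sankoff dynamic programming (exact
  for polytomies, unlike classic two-set Fitch); ties in total changes
  resolve toward the fewest 0→1 gains when reporting the gain count with
  the root fixed at 0.
* Statistics print to 4 decimals to avoid the rounding ambiguities that
  arise when statistics are recomputed from 2-decimal likelihoods (e.g.
  2×(29.70−22.45) = 14.50 vs a printed 14.48).
* The χ²₄ upper tail at 27.86 is ≈1.3×10⁻⁵; a p-value printed as
  "< 0.00001" for that statistic is consistent only to within rounding of
  the underlying likelihoods.

## Known limitations

Two traits only, binary states only; no covarion/hidden-rate models, no
branch-specific rates, no ancestral-state posteriors, no rate-variation
priors beyond the gamma hyper-prior; MCMC convergence monitoring is
acceptance fraction plus repeat spread, not full diagnostics; the pipeline
consumes a rooted tree and never infers or re-roots one beyond treating a
basal trifurcation as the root.
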