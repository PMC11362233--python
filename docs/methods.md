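# Methods

## Model

### Divide-by-total building blocks

Ordinal responses Y ∈ {0,…,K} are modeled divide-by-total: category
probabilities are category-specific components normalized by their sum.
The GPCM (dominance) uses a single exponential component per category
with linear predictor α(s_y θ − Σ_{k≤y} β_k), β₀ ≡ 0 and default
scoring weights s_y = y.  The GGUM (ideal point) uses the sum of two
exponentials per observable category — a "from below" term with weight
s_y and a "from above" term with weight M − s_y, M = 2K + 1 — sharing
cumulative thresholds ξ (ξ₀ ≡ 0).  Observable probabilities are
symmetric in θ − δ.  Scoring weights are stored explicitly everywhere;
reversed weights such as (2, 1, 0) are first class.  All probabilities
are computed in log space with max subtraction, since exponents grow
linearly in M·|θ − δ|; distributions are validated to sum to 1 within
1e-12.

No ordering constraint is placed on thresholds at evaluation time:
ordered thresholds are a descriptive property of well-behaved items,
not a requirement of the likelihood.

### Co-occurring processes

A pseudo-item may carry R processes, each dominance or ideal point,
each with its own trait, weights and discrimination.  A dominance
predictor is duplicated into both exponential terms (doubling every
component, which cancels in the normalization); process predictors are
summed within each term.  Only the combined category intercepts
τ_k = Σ_r α_r β_kr + λ_r ξ_kr are identified, so the estimation-facing
parameterization is (discriminations, locations, τ) and
process-specific thresholds exist only on the generation side.  The
linear-predictor form is the canonical compute path; the equivalent
probability-aggregation form (softmax of summed log process
probabilities) is kept as an independent oracle for testing.  With two
or more ideal-point processes in one pseudo-item the two forms genuinely
differ — the product of two-term components contains cross terms the
summed-predictor form lacks — so the package treats the equivalence as
holding only for at most one ideal-point process, and the test suite
asserts the *divergence* beyond that.

Tied parameters (the midscale model's δᵢ := β₂ᵢ) are represented as
named references into a parameter table, never value copies, so the tie
survives estimation, where β₂ᵢ itself is the derived quantity
τ₂ᵢ/α₂ᵢ.

### Tree composition

A `TreeMapping` tabulates ordinal category → pseudo-item responses with
an explicit missing-by-design sentinel, distinct from respondent-level
missingness (which drops that item for that person).  The response
probability is the product of pseudo-item probabilities over
non-missing cells.  Intensity pseudo-items are coded inner → outer
(least to most intense); direction is carried by reversed trait
weights on the disagreement side, not by reordering categories.

For the five-point midscale family the pseudo-item coding is: X₁ = 1
iff Y = 2 (midscale); given X₁ = 0, X₂ = 1 iff Y ∈ {3, 4} (agreement);
X₃ = 1 iff Y = 4 (extreme | agree); X₄ = 1 iff Y = 0 (extreme |
disagree).  This coding is consistent with ERS weights (0, 1) and
reversed trait weights (1, 0) on the disagreement side, and is stated
here explicitly because it is one of the places where a convention had
to be fixed.

## Synthetic data

The generator reproduces the reference simulation design for the
six-point agreement/intensity family: θ, η iid N(0,1); discriminations
LogN(0, 0.25); δ ~ U(−3, 3); ideal-point thresholds normal with sd 0.2
around means (−2.2, −1.3 | intense disagreement), −1.0 (agreement),
(−0.8, −0.2 | intense agreement), the means ordered along the ordinal
scale; dominance thresholds β_k = β + ζ_k with β ~ U(−1, 1) and
ζ ~ N(∓0.5, 0.2).  Two notational choices are resolved as follows and
are configurable: the second argument of every distribution is read as
an *sd* (the convention of the R functions `rnorm`/`rlnorm` in which
such designs are typically written), so LogN(0, 0.25) has sdlog 0.25
(`synthesis.DISC_SDLOG`); and the ζ second arguments are sds likewise.

The five-point midscale family has no stated generating distributions,
so defaults were chosen once for realistic category shares (~20 %
midscale, ~30 % extremes): MRS threshold β₁ ~ N(1.0, 0.3), agreement
threshold β₂ ~ U(−1.5, 1.5) (doubling as the tied ideal-point
location), midscale ideal threshold ξ ~ N(−1, 0.2), ERS thresholds
N(0.5, 0.3), extreme-trait thresholds N(0, 0.3).

Response times follow the log-normal mixed model below with the
reference slope magnitudes as generating fixed effects and variance
components (person/item/residual sds) 0.3 / 0.1 / 0.5 — values typical
of item-level RT data, since none are stated.

Each replication owns one seed sequence sub-streamed by purpose
(persons / items / responses / RTs), so adding RTs never perturbs the
simulated responses.  A grid constructor enumerates the full
2 (N) × 2 (I) × 3 (generating model) × 100-replication design; every
cell is re-runnable from its stored design alone.

What the generator does *not* emulate: non-normal or correlated trait
distributions, person-specific process mixtures, item content effects,
or the exact marginals of any empirical questionnaire.  Passing
recovery tests therefore show that the estimator inverts the model
under its own assumptions at the stated sizes — not that those
assumptions hold for any particular real instrument.

## Estimation

Priors: discriminations Gamma(1.5, 1.5) (shape–rate, mean 1; sampled on
the log scale with the Jacobian included); τ ~ N(0, 5); δ hierarchical
with mean ~ N(0, 5) and half-normal(5) sd; trait distributions fixed to
N(0, 1) for identification.  RT fixed effects N(0, 5); RT variance
components half-normal(5).

The sampler is an adaptive Metropolis-within-Gibbs scheme, fully
vectorized:

* **persons** — joint random-walk proposal over a person's traits,
  accepted in parallel across persons (conditionally independent given
  item parameters); two sweeps per iteration;
* **items** — per-item joint random-walk over all of an item's
  parameters with a covariance learned from the chain history
  (adaptive Metropolis), global scale tuned toward 0.23 acceptance,
  10 % of proposals widened 3× for heavy tails; four sweeps per
  iteration, plus a coordinate-wise sweep;
* **ridge moves** — slice sampling along the two widest eigendirections
  of each item's adapted covariance.  Ideal-point items located near
  the edge of the trait range have long, curved (δ, τ) posterior
  ridges on which random walks mix poorly; a slice move along the
  ridge always lands inside the slice and traverses it in O(1) moves;
* **auxiliaries** — conjugate Gibbs for the δ-hierarchy mean and, in
  the joint RT model, for the mixed-model coefficients and random
  intercepts; scalar Metropolis on log variance components.

Adaptation (scales and covariances) continues for the entire run with a
learning rate decaying as t^(−0.6) — diminishing adaptation, which
preserves the stationary distribution.  Proposal-covariance estimates
refresh every 25 iterations once 100 adaptation steps have accrued.

The estimation protocol mirrors standard practice for unfolding models:
first a constrained model with discriminations and intercepts shared
across items (one chain, 500 warmup + 500 draws) whose EAPs, expanded
item-wise, initialize the full model; then four chains with 500 warmup
+ 1000 post-warmup draws, extended in steps of 500 up to 3000 whenever
any parameter has R-hat > 1.05 or bulk/tail ESS < 100 (arviz
diagnostics; a fit that exhausts the budget is flagged, never silently
accepted).  The ideal-point continuum is sign-unidentified — flipping
(θ, δ) jointly leaves the likelihood unchanged — so orientation is
fixed through δ initial values from a user-supplied sign template (±1
per item; for simulated data the generating signs, for empirical data
content knowledge or reference estimates).  After fitting, the δ EAP
signs are checked against the template; a fit that crossed to the
mirrored solution is automatically re-fitted with a different seed.
The midscale family needs no template: its tied location τ₂/α₂ is
identified by the dominance agreement node.

Point estimates are EAPs (posterior means over pooled post-warmup
draws).  The per-observation log-likelihood for LOO is recomputed from
thinned draws (≤ 250 per chain) on the *observed ordinal responses* —
in the joint RT model the response likelihood only, so LOO comparisons
across response models remain commensurable.

## Evaluation

Recovery is summarized by mean absolute bias (MAB) of EAPs against
generating values, averaged within replication first, then across
replications.  Model comparison uses PSIS-LOO on the deviance scale
(−2·elpd; smaller is better), with the PSIS relative efficiency taken
from the fit's own ESS diagnostics and the count of Pareto-k > 0.7
observations carried as warning metadata.  The grid report pivots MAB
into (generating model × fitted model) rows — averaging over N by
default, since person-parameter precision is driven by test length —
and reports, per generating condition, the proportion of replications
in which each fitted model attained the smallest LOO; aggregation axes
are recorded in the table metadata and are configurable.

## Response-time joint model

log RT_vi = γ₀₀₀ + (γ₁₀₀ + γ₁₁₀ η₁ᵥ)·X₁ᵥᵢ + (γ₂₀₀ + γ₂₂₀ η₂ᵥ)·Xextᵥᵢ
+ γ₀₁₁·|θᵥ − β₂ᵢ| + u_v + u_i + ε, with X₁/Xext the manifest
midscale/extreme indicators (the two extreme pseudo-items share one
coefficient), u_v, u_i random intercepts and normal residuals.  The
person-item distance is *the same quantity* that locates the midscale
ideal-point process, and the response-style levels entering the slopes
are the latent η of the IRTree — estimated in one step within a single
posterior, so the slopes are free of the attenuation a two-step
plug-in of point estimates induces.  A two-step mode (mixed model on
frozen EAPs) exists for diagnosing exactly that attenuation.  RT cells
with missing responses are dropped pairwise.

## Problem sizes and numerical choices

The test suite and the acceptance script run the full estimation
protocol at N = 500, I = 10 for the single-fit recovery study and
N = 500, I = 14 for the RT sign-recovery study, and scale the
multi-replication model-selection study down to 5 (or 3) replications
at N = 120, I = 8 with shortened chains — at these sizes the LOO
separation between the co-occurring and sequential models is an order
of magnitude larger than its standard error, so the comparison is
insensitive to the scale reduction.  Full-scale reproduction of the
2×2×3×100 grid is supported by the grid constructor and the fitting
API but is a multi-day single-CPU computation.

Degenerate inputs: respondent-missing responses are encoded as any
negative integer and excluded item-wise; probability aggregation
rejects zero probabilities (log undefined); discriminations must be
strictly positive at construction.  Ties in LOO model selection are
broken by table order (first-listed model wins `best`), which never
occurred in practice.

## Known limitations

* Recovery of the extreme-response-style trait is information-limited
  in the six-point design: ERS enters only the intensity sub-decisions,
  and items located far from the person mass produce mostly
  maximally-intense disagreements, so even the exact posterior mean
  cannot push the ERS EAP correlation much past ~0.8 at I = 10.
  Longer tests (I = 20) help; larger N does not (person precision is
  test-length-bound).
* Items whose location |δ| approaches the edge of its U(−3, 3) support
  have wide, skewed posteriors; they dominate the convergence time and
  occasionally hold max R-hat just above 1.05 at the 3000-draw cap,
  in which case the fit is flagged non-converged and reported as such.
* The sampler trades per-draw efficiency for simplicity and
  vectorization; gradient-based samplers would need fewer draws but a
  differentiable likelihood.
* One composition of processes is assumed for all respondents; person
  mixtures (some respondents ignoring a process, or responding in a
  dominance rather than ideal-point fashion) are out of scope.
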