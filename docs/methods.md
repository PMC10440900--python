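# Methods

## The model

`nbblca` implements a classifier family for binary (0/1) attributes with a
categorical class label, built around a latent class layer.

**Naive Bayes (baseline).** With attributes x_1..x_M and class C, plain NB
assumes mutual conditional independence of the attributes given C and
scores P(c | x) ∝ P(c) ∏_m P(x_m | c).  Counts are Laplace-smoothed by a
pseudo-count s (default 1; s = 0 gives the pure maximum-likelihood fit,
which the fitter logs at fit time because published applications rarely
state their smoothing).  All products are accumulated in log space, so
posteriors stay finite up to at least 10^4 features.

**Bayesian latent class analysis (BLCA).** A finite mixture of independent
Bernoulli components: mixing weights τ (length G, Dirichlet(δ) prior) and
item probabilities θ_gm (Beta(α_gm, β_gm) priors).  Two fitters:

* *MAP EM.* E-step: responsibilities Z_ig ∝ τ_g P(x_i | θ_g).  M-step
  (posterior mode under the conjugate priors):

      θ_gm ← (Σ_i X_im Z_ig + α_gm − 1) / (Σ_i Z_ig + α_gm + β_gm − 2)
      τ_g  ← (Σ_i Z_ig + δ_g − 1) / (N + Σ_h δ_h − G)

  Hyperparameters below 1 would place the mode outside the open unit
  interval and are rejected for EM.  With the default flat priors
  (α = β = δ = 1) the updates are exactly the MLE ones.
* *Gibbs sampling.* Sweeps cycle the conjugate full conditionals:
  θ_gm ~ Beta(Σ X_im Z_ig + α, Σ Z_ig(1 − X_im) + β),
  τ ~ Dirichlet(Σ Z_i1 + δ_1, …, Σ Z_iG + δ_G), then each membership from
  its multinomial posterior.  Any positive hyperparameters are allowed.
  Chains store post-burn-in, thinned draws and are relabeled (below).

**NB-BLCA.** The observed class C parents K latent class variables
L_1..L_K; each L_k parents a disjoint block of attributes.  Parameters:
class prior q(c); latent conditionals q_k(l | c); per-block item
probabilities θ^(k).  At the latent level the naive factorisation is exact:
P(c | L) ∝ q(c) ∏_k q_k(L_k | c).  Prediction marginalises the latent
variables by default,

    P(c | x) ∝ q(c) ∏_k Σ_l q_k(l | c) P(x_block_k | θ^(k)_l),

because hard-assigning each block's level discards the mixture uncertainty
(a `mode="hard"` variant exists).  Training conditions on the observed
class: EM responsibilities use q_k(l | y_i) in place of a free mixing
weight, and the Gibbs sampler adds one extra conditional — each subject's
latent level drawn from a multinomial ∝ q_k(l | y_i) P(x_i,block k | θ^(k)_l) —
plus Dirichlet draws for q(c) and q_k(· | c).  A `method="two_stage"`
option fits each block unsupervised first and then estimates q_k(l | c)
from per-class mean responsibilities; the joint EM is the default because
it maximises the stated posterior.  The adjusted EM and Gibbs steps are
derived here directly from the network factorisation and the conjugate
prior structure; this derivation is the central design element of the
package.

**Comparators.** AODE averages all one-dependence estimators
P(c, x_p) ∏_{m≠p} P(x_m | c, x_p) over parents whose observed value has at
least `min_support` (default 1) training occurrences, falling back to NB
when none qualifies.  The default support of 1 suits moderate-n binary
data; the literature's m = 30 default would disable most parents at
n = 500.  TAN-HC hill-climbs from the NB structure, greedily adding the
single extra-parent arc (≤ 1 parent per attribute, acyclic) that most
improves resubstitution accuracy with Laplace-smoothed tables, stopping
when no arc improves; ties break toward the first-enumerated arc so the
search is deterministic.

## Numerical choices

* θ (and probability tables generally) are clamped to [1e-12, 1 − 1e-12]
  after updates and before logs; matrix-form log likelihoods clamp first so
  that 0 · (−inf) cannot produce NaN.
* EM stops when the relative change of the log posterior falls below
  `tol = 1e-8` or at `max_iter = 1000`; the objective is checked
  non-decreasing to 1e-10 in tests.
* EM restarts: `n_restarts = 10` by default, best final log posterior wins.
  Initialisation draws each component's item probabilities from
  U(0.2, 0.8) (and mixing weights / latent conditionals from flat
  Dirichlets).  Per-row random responsibilities were tried first and fail
  at large N: averaged over thousands of rows they are almost exactly
  uniform, so the first M-step lands every component on the grand column
  mean — a symmetric saddle EM cannot leave.  O(1) separation in the item
  probabilities avoids it.
* An EM component whose responsibility mass empties is re-seeded on the
  worst-fit observation, keeping G fixed.
* Gibbs defaults: 5000 sweeps, burn-in 1000, thinning 5 (the conventional
  1000–5000 burn-in rule).  Label switching is undone per draw by choosing
  the component permutation closest (squared distance on θ) to a running
  mean of the relabeled draws; the procedure is deterministic, idempotent,
  and applied per block for NB-BLCA chains.  Convergence diagnostics
  (split-R̂, effective sample size via ArviZ, flag at R̂ > 1.1) operate on
  any stored chain.
* Model choice: AIC = −2ℓ + 2p, BIC = −2ℓ + p log N with
  p = Σ_k (G_k − 1)|C| + Σ_k G_k |block_k| + (|C| − 1), and
  DIC = mean deviance + p_D, p_D = mean deviance − deviance at the
  posterior mean (requires a chain).  `select_levels_bic` scans single-block
  layouts over G ∈ {2, 3, 4} by default.

## The simulation study generator

Each replicate draws fresh feature-law parameters: per 5-dimensional
batch, marginals HMP_i ~ U(0, 1) and pairwise odds ratios
OR_ij ~ U(0.25, 4).  A 2^5 joint table is fitted by iterative proportional
fitting: each pair's 2×2 margin is computed in closed form (the Plackett
root for two fixed margins and an odds ratio), and IPFP cycles over the
ten pairwise margins from the independence seed until the largest margin
error is below 1e-12.  Fitted tables therefore hit the univariate margins
to 1e-10 and preserve all pairwise odds ratios to 1e-6 (verified
exhaustively in tests).  Batches are mutually independent because
associations are only specified within a batch.

Labels follow Z = α + β Σ_i x_i + ε, ε ~ N(0, σ), with β = 2 and σ = 4,
and P = 1/(1 + e^Z) exactly as written (decreasing in Z; the tuned
intercept absorbs the sign, so prevalences are unaffected while the
per-feature effect direction follows the formula).  The intercept α is
re-tuned once per replicate by bisection on a pilot sample of 20 000 rows
until the mean of P is within 0.002 of the scenario prevalence
(0.3 / 0.5 / 0.7).  The default `label_mechanism="bernoulli"` draws one
Bernoulli trial per subject with its subject-specific P.  An alternative
`"latent_threshold"` reading sets y = 1{Z < 0}, treating the Gaussian term
as the label noise itself; it is exposed because the two readings imply
materially different irreducible label noise (see limitations).

The study runner replicates: generate → 70/30 uniform split (stratification
available behind a flag, off by default because the source procedure says
only "randomly selected") → fit each registered model → score the held-out
part → average sensitivity, specificity, PPV, NPV and precision (precision
is PPV, duplicated in output for fidelity with the conventional layout)
across replicates, with Monte-Carlo standard errors and counts of
replicates where each metric was defined.  Undefined ratios are missing
(NaN), never zero, so means are over defined replicates only.  Fit
failures are logged and the replicate is redrawn (bounded, counted).

### Problem sizes used by the shipped checks

The published grid uses 1000 replicates per cell.  The acceptance checks
re-run representative cells at 120–200 replicates for the NB rows and 30–40
replicates for the NB-BLCA(EM) row (10 restarts, BIC scan over
G ∈ {2, 3, 4}); Monte-Carlo standard errors at these sizes are about one
percentage point and are reported alongside the means.

## The questionnaire-shaped fixture

`make_gcnud_like()` emulates the *schema* of a two-class clinical
questionnaire cohort: exactly 976 cases and 1189 controls, 64 binary
attributes in five subdomain blocks (12/16/12/14/10).  Rows are drawn from
a fixed, moderately separated NB-BLCA generative model (two latent levels
per block, latent-given-class conditionals between 0.6/0.4 and 0.85/0.15).
It is synthetic: it reproduces sizes and structure, not any real cohort's
values, so pipeline results on it demonstrate mechanics and relative model
ordering — not clinical performance.

## What the synthetic experiments do and do not show

* Parameter recovery (single latent, two levels, M = 10, n = 5000) shows
  both learners recover θ and q_k(l | c) to ±0.05 after label alignment —
  correctness of the estimators under the model's own assumptions.
* On the questionnaire-shaped fixture, whose generative truth is an
  NB-BLCA, the latent-layer models outperform plain NB — the mechanism
  works when the latent structure is real.
* On the simulation generator, where the class depends on the *sum* of all
  features, a single discrete latent with few levels is an information
  bottleneck: the class reaches the attributes only through one G-level
  variable, and held-out sensitivity falls at or below NB.  Batch-aligned
  multi-block layouts recover some specificity but not sensitivity.  The
  published claim of large NB-BLCA gains on this generator could not be
  reproduced under any layout; indeed the Bayes-optimal classifier itself
  (computable here because P(y | x) depends on x only through Σx) attains
  roughly 55–57% sensitivity at p = 20 and prevalence 0.3, far below the
  98%+ figures published for that cell.  Any classifier evaluated on truly
  held-out data is bounded by this ceiling.

## Known limitations

* Binary attributes only; no missing-data handling; latent block structure
  is supplied, never learned.
* The balanced-prevalence NB cells of the published grid reproduce to
  within a few percentage points; at prevalences 0.3/0.7 the re-run
  minority-class detection runs several points below the published values
  under the as-written label mechanism (the `latent_threshold` reading
  roughly halves the gap).  The residual discrepancy is a property of the
  published description, not a free parameter here.
* AODE's support threshold and TAN-HC's scoring function are not stated in
  the source material; the defaults documented above are this package's
  choices, so those comparator rows are indicative rather than exact.
* DIC uses the posterior-mean plug-in deviance; for strongly multimodal
  posteriors p_D can misbehave (chains are relabeled first, which
  mitigates the usual mixture pathology).
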