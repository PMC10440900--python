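# nbblca

Naive Bayes classification through a Bayesian latent class layer, for
binary (0/1) attribute data with a categorical class label — the kind of
data produced by structured clinical questionnaires, symptom checklists
and recoded risk-factor tables.

## The problem and the model

The plain Naive Bayes (NB) classifier scores

    P(c | x₁..x_M) ∝ P(c) ∏ₘ P(xₘ | c)

and works remarkably well — until the attributes are dependent within a
class, which in health data they almost always are.  `nbblca` implements
**NB-BLCA**: the observed class C parents one or more latent class
variables L₁..L_K (defined by Bayesian Latent Class Analysis, a finite
mixture of independent Bernoullis with Beta/Dirichlet priors), and each
latent variable parents a disjoint block of attributes.  The latent layer
absorbs the within-block dependence, so the naive factorisation becomes
exact at the latent level:

    P(c | L) ∝ q(c) ∏ₖ q_k(L_k | c)
    P(c | x) ∝ q(c) ∏ₖ Σ_l q_k(l | c) · P(x_block_k | θ⁽ᵏ⁾_l)

Parameters are learned either by MAP expectation-maximisation or by Gibbs
sampling over the conjugate full conditionals (Beta, Dirichlet,
Multinomial), with burn-in, thinning, deterministic relabeling and
ArviZ-based convergence diagnostics.  The package also ships the standard
comparators (plain NB, AODE, hill-climbing TAN), a correlated-binary
simulation generator (IPFP-fitted multivariate Bernoulli batches with
logistic class labels), and the conventional validity-metric panel
(sensitivity/specificity/PPV/NPV, exact binomial accuracy CI,
no-information rate, Cohen's kappa, McNemar, k-fold CV).  See
`docs/methods.md` for the full model account.

## A worked example

`examples/03_nbblca_questionnaire.py` runs the whole pipeline on a
synthetic questionnaire-shaped cohort (2165 subjects, 64 binary attributes
in five subdomain blocks, two classes sized 976/1189):

```text
NB               acc 82.43 (79.28-85.29)  NIR 55.47  kappa 0.64  McNemar p 1      sens 79.58  spec 84.72
NB-BLCA (EM)     acc 84.59 (81.58-87.28)  NIR 55.47  kappa 0.69  McNemar p 0.0824 sens 80.62  spec 87.78
NB-BLCA (Gibbs)  acc 84.59 (81.58-87.28)  NIR 55.47  kappa 0.69  McNemar p 0.0824 sens 80.62  spec 87.78
```

Read: every model clears the 55.47% no-information rate by a wide margin
(real signal); the latent-layer models gain ~2 accuracy points and ~3
specificity points over plain NB because this cohort's dependence really
is block-structured; kappa ≈ 0.69 means agreement well beyond chance.
The other examples cover the NB basics (`01`), unsupervised latent class
analysis with EM-vs-Gibbs agreement and chain diagnostics (`02`), and a
slice of the simulation-grid comparison (`04`).

A thin CLI mirrors the library: `nbblca fit|predict|simulate|evaluate`
(models serialize to JSON; fixtures and study results to CSV).

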