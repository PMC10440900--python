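"""Bayesian latent class analysis: a finite mixture of independent Bernoullis.

The model has G unobserved components ("latent classes").  Component g
carries item probabilities theta_{g,1..M}; the mixing weights tau are a
probability vector.  Conjugate priors are Beta(alpha_gm, beta_gm) on each
theta and Dirichlet(delta) on tau.  Two fitters are provided:

* :func:`blca_em` — MAP expectation-maximisation.  The E-step computes the
  membership responsibilities; the M-step maximises the log posterior, i.e.

      theta_gm <- (sum_i X_im Z_ig + alpha_gm - 1) / (sum_i Z_ig + alpha_gm + beta_gm - 2)
      tau_g    <- (sum_i Z_ig + delta_g - 1) / (N + sum_h delta_h - G)

  Hyperparameters below 1 would push the MAP outside [0,1] and are rejected.

* :func:`blca_gibbs` — collapsed-nothing Gibbs sampling cycling through the
  conjugate full conditionals Beta → Dirichlet → Multinomial, with burn-in,
  thinning and deterministic post-hoc relabeling to undo label switching.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp

from .data_model import BinaryDataset, PriorConfig, RunConfig

__all__ = [
    "BLCAParams",
    "Responsibilities",
    "GibbsChain",
    "component_loglik",
    "mixture_loglik",
    "posterior_z",
    "log_posterior",
    "blca_em",
    "blca_gibbs",
    "relabel_chain",
    "chain_diagnostics",
]

THETA_FLOOR = 1e-12  # keep logs finite after updates


@dataclass(frozen=True)
class BLCAParams:
    """Mixing weights ``tau`` (G,) and item probabilities ``theta`` (G, M)."""

    tau: np.ndarray
    theta: np.ndarray
    priors: PriorConfig | None = None

    def __post_init__(self):
        tau = np.atleast_1d(np.asarray(self.tau, dtype=float))
        theta = np.atleast_2d(np.asarray(self.theta, dtype=float))
        if tau.shape[0] != theta.shape[0]:
            raise ValueError("tau and theta disagree on the number of components")
        if (tau < -1e-12).any() or not np.isclose(tau.sum(), 1.0):
            raise ValueError("tau must be a probability vector")
        if ((theta < 0) | (theta > 1)).any():
            raise ValueError("theta entries must lie in [0, 1]")
        object.__setattr__(self, "tau", tau)
        object.__setattr__(self, "theta", theta)

    @property
    def G(self) -> int:
        return self.theta.shape[0]

    @property
    def M(self) -> int:
        return self.theta.shape[1]


@dataclass(frozen=True)
class Responsibilities:
    """Membership matrix Z (N, G); rows sum to 1. ``hard`` marks one-hot rows."""

    Z: np.ndarray
    hard: bool = False

    def __post_init__(self):
        Z = np.asarray(self.Z, dtype=float)
        if not np.allclose(Z.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("responsibility rows must sum to 1")
        object.__setattr__(self, "Z", Z)

    def labels(self) -> np.ndarray:
        return np.argmax(self.Z, axis=1)


@dataclass
class GibbsChain:
    """Retained post-burn-in, thinned draws from a mixture Gibbs sampler."""

    tau: np.ndarray           # (D, G)
    theta: np.ndarray         # (D, G, M)
    z: np.ndarray             # (D, N) hard component labels
    iterations: np.ndarray    # sweep index of each retained draw
    burn_in: int
    thin: int
    permutations: np.ndarray | None = None  # (D, G) relabeling applied per draw

    @property
    def n_draws(self) -> int:
        return self.tau.shape[0]

    @property
    def G(self) -> int:
        return self.tau.shape[1]

    def posterior_mean(self) -> BLCAParams:
        tau = self.tau.mean(axis=0)
        return BLCAParams(tau / tau.sum(), self.theta.mean(axis=0))


def component_loglik(theta_row: np.ndarray, x: np.ndarray) -> float:
    """Bernoulli log likelihood of one observation under one component.

    ``sum_m x_m log theta_m + (1 - x_m) log(1 - theta_m)``, with log 0 = -inf.
    """
    theta_row = np.asarray(theta_row, dtype=float)
    x = np.asarray(x, dtype=float)
    if theta_row.shape != x.shape:
        raise ValueError("theta_row and x must have matching lengths")
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(x == 1, np.log(theta_row), np.log1p(-theta_row))
    return float(terms.sum())


def _loglik_matrix(theta: np.ndarray, X: np.ndarray) -> np.ndarray:
    """(N, G) per-observation per-component Bernoulli log likelihoods.

    Theta is clamped to [1e-12, 1 - 1e-12] so the matrix products stay
    finite (0 * -inf would poison them with NaN).
    """
    th = np.clip(theta, THETA_FLOOR, 1 - THETA_FLOOR)
    X = np.asarray(X, dtype=float)
    return X @ np.log(th).T + (1.0 - X) @ np.log1p(-th).T


def mixture_loglik(params: BLCAParams, X: np.ndarray) -> float:
    """Observed-data log likelihood sum_i log sum_g tau_g P(x_i | theta_g)."""
    ll = _loglik_matrix(params.theta, np.atleast_2d(X))
    with np.errstate(divide="ignore"):
        log_tau = np.log(params.tau)
    return float(logsumexp(ll + log_tau, axis=1).sum())


def posterior_z(params: BLCAParams, X: np.ndarray) -> Responsibilities:
    """Posterior membership probabilities Z_ig ∝ tau_g P(x_i | theta_g)."""
    ll = _loglik_matrix(params.theta, np.atleast_2d(X))
    with np.errstate(divide="ignore"):
        log_w = ll + np.log(params.tau)
    log_w -= logsumexp(log_w, axis=1, keepdims=True)
    return Responsibilities(np.exp(log_w))


def log_posterior(params: BLCAParams, X: np.ndarray, priors: PriorConfig) -> float:
    """Mixture log likelihood plus (unnormalised) log prior density."""
    lp = mixture_loglik(params, X)
    tau = np.maximum(params.tau, THETA_FLOOR)
    th = np.clip(params.theta, THETA_FLOOR, 1 - THETA_FLOOR)
    lp += float(((priors.delta - 1) * np.log(tau)).sum())
    lp += float(((priors.alpha - 1) * np.log(th) + (priors.beta - 1) * np.log1p(-th)).sum())
    return lp


def _m_step(X: np.ndarray, Z: np.ndarray, priors: PriorConfig) -> BLCAParams:
    G = Z.shape[1]
    Nk = Z.sum(axis=0)
    denom = np.maximum(Nk[:, None] + priors.alpha + priors.beta - 2, 1e-10)
    theta = (Z.T @ X + priors.alpha - 1) / denom
    theta = np.clip(theta, THETA_FLOOR, 1 - THETA_FLOOR)
    tau = (Nk + priors.delta - 1) / (X.shape[0] + priors.delta.sum() - G)
    tau = np.maximum(tau, 0)
    tau = tau / tau.sum()
    return BLCAParams(tau, theta, priors)


def blca_em(
    X: np.ndarray,
    G: int,
    priors: PriorConfig | None = None,
    run: RunConfig | None = None,
) -> tuple[BLCAParams, Responsibilities, np.ndarray]:
    """MAP EM for the Bernoulli mixture; best of ``run.n_restarts`` restarts.

    Returns the fitted parameters, the final soft responsibilities and the
    log-posterior trace of the winning restart.  The trace is non-decreasing
    (an EM guarantee, up to numerical tolerance).
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    N, M = X.shape
    if G < 1:
        raise ValueError("G must be at least 1")
    if G > N:
        raise ValueError("more components than observations")
    priors = priors or PriorConfig.uniform(G, M)
    if (priors.alpha < 1).any() or (priors.beta < 1).any():
        raise ValueError("MAP EM requires alpha >= 1 and beta >= 1 (interior mode)")
    run = run or RunConfig()
    rng = run.rng()

    best = None
    for _ in range(max(1, run.n_restarts)):
        # random item-probability start: O(1) component separation avoids the
        # symmetric saddle that averaged random responsibilities land on
        params = BLCAParams(rng.dirichlet(np.ones(G)), rng.uniform(0.2, 0.8, size=(G, M)), priors)
        trace = [log_posterior(params, X, priors)]
        for _it in range(run.max_iter):
            resp = posterior_z(params, X)
            Z = resp.Z
            # re-seed an emptied component from the worst-fit observation
            Nk = Z.sum(axis=0)
            if (Nk < 1e-8).any():
                ll = _loglik_matrix(params.theta, X)
                worst = int(np.argmin(logsumexp(ll + np.log(np.maximum(params.tau, THETA_FLOOR)), axis=1)))
                for g in np.flatnonzero(Nk < 1e-8):
                    Z[worst] = 0.0
                    Z[worst, g] = 1.0
            params = _m_step(X, Z, priors)
            lp = log_posterior(params, X, priors)
            trace.append(lp)
            prev = trace[-2]
            if abs(lp - prev) <= run.tol * (abs(prev) + 1e-12):
                break
        if best is None or trace[-1] > best[2][-1]:
            best = (params, posterior_z(params, X), np.asarray(trace))
    return best


def blca_gibbs(
    X: np.ndarray,
    G: int,
    priors: PriorConfig | None = None,
    run: RunConfig | None = None,
    relabel: bool = True,
) -> GibbsChain:
    """Gibbs sampler for the Bernoulli mixture with conjugate full conditionals.

    Each sweep draws, in order,
    ``theta_gm ~ Beta(sum_i X_im Z_ig + alpha_gm, sum_i Z_ig (1 - X_im) + beta_gm)``,
    ``tau ~ Dirichlet(sum_i Z_i1 + delta_1, ..., sum_i Z_iG + delta_G)`` and
    ``Z_i ~ Multinomial(1, posterior membership of row i)``.  An empty design
    (N=0) is allowed and yields draws from the prior.
    """
    X = np.asarray(X, dtype=float)
    if X.size == 0:
        X = X.reshape(0, X.shape[1] if X.ndim == 2 else 0)
    else:
        X = np.atleast_2d(X)
    N, M = X.shape
    priors = priors or PriorConfig.uniform(G, M)
    run = run or RunConfig()
    rng = run.rng()

    z = rng.integers(0, G, size=N)  # random hard initial assignment
    draws_tau, draws_theta, draws_z, kept_iters = [], [], [], []
    for sweep in range(run.gibbs_iters):
        Z = np.zeros((N, G))
        if N:
            Z[np.arange(N), z] = 1.0
        ones = Z.T @ X if N else np.zeros((G, M))
        Nk = Z.sum(axis=0)
        theta = rng.beta(ones + priors.alpha, Nk[:, None] - ones + priors.beta)
        tau = rng.dirichlet(Nk + priors.delta)
        if N:
            resp = posterior_z(BLCAParams(tau, theta), X)
            # vectorised categorical draw per row
            cum = np.cumsum(resp.Z, axis=1)
            u = rng.random(N)[:, None]
            z = (u > cum).sum(axis=1)
        if sweep >= run.burn_in and (sweep - run.burn_in) % run.thin == 0:
            draws_tau.append(tau)
            draws_theta.append(theta)
            draws_z.append(z.copy())
            kept_iters.append(sweep)
    chain = GibbsChain(
        tau=np.asarray(draws_tau),
        theta=np.asarray(draws_theta),
        z=np.asarray(draws_z),
        iterations=np.asarray(kept_iters),
        burn_in=run.burn_in,
        thin=run.thin,
    )
    return relabel_chain(chain) if relabel and G > 1 else chain


def relabel_chain(chain: GibbsChain) -> GibbsChain:
    """Undo label switching: permute each draw's components to best match a
    running-mean reference of theta.  Deterministic and idempotent."""
    if chain.n_draws == 0:
        raise ValueError("empty chain")
    G = chain.G
    perms = list(itertools.permutations(range(G)))
    tau = chain.tau.copy()
    theta = chain.theta.copy()
    z = chain.z.copy()
    applied = np.zeros((chain.n_draws, G), dtype=np.int64)
    ref = theta[0].copy()
    count = 0
    for d in range(chain.n_draws):
        best_p, best_cost = perms[0], np.inf
        for p in perms:
            cost = float(((theta[d, list(p)] - ref) ** 2).sum())
            if cost < best_cost - 1e-15:
                best_cost, best_p = cost, p
        p = list(best_p)
        tau[d] = tau[d, p]
        theta[d] = theta[d, p]
        inv = np.argsort(p)
        if z.ndim > 1 and z.shape[1] > 0:
            z[d] = inv[z[d]]
        applied[d] = p
        count += 1
        ref += (theta[d] - ref) / count
    return GibbsChain(tau, theta, z, chain.iterations.copy(), chain.burn_in, chain.thin, applied)


def chain_diagnostics(chain: GibbsChain) -> "pd.DataFrame":
    """Split-R̂ and effective sample size per scalar parameter via ArviZ.

    Returns a table indexed by parameter name with columns ``mean``, ``ess``,
    ``rhat`` and ``flagged`` (R̂ > 1.1).  Degenerate (constant) traces yield
    NaN diagnostics rather than an error.
    """
    import arviz as az
    import pandas as pd

    if chain.n_draws < 2:
        raise ValueError("need at least two retained draws for diagnostics")
    names, traces = [], []
    for g in range(chain.G):
        names.append(f"tau[{g}]")
        traces.append(chain.tau[:, g])
        for m in range(chain.theta.shape[2]):
            names.append(f"theta[{g},{m}]")
            traces.append(chain.theta[:, g, m])
    rows = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for name, tr in zip(names, traces):
            half = len(tr) // 2  # split the chain in two for split-R̂
            arr = np.vstack([tr[:half], tr[half:2 * half]])
            if np.ptp(tr) == 0:
                rhat = np.nan
                ess = np.nan
            else:
                rhat = float(az.rhat(az.convert_to_dataset(arr))["x"].values)
                ess = float(az.ess(az.convert_to_dataset(arr))["x"].values)
            rows.append(
                {"parameter": name, "mean": float(tr.mean()), "ess": ess, "rhat": rhat,
                 "flagged": bool(rhat > 1.1) if np.isfinite(rhat) else False}
            )
    return pd.DataFrame(rows).set_index("parameter")
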