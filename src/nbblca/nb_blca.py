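"""The NB-BLCA classifier: Naive Bayes mediated by latent class variables.

Structure.  The observed class C is the root; its only children are K
latent class variables L_1..L_K; each L_k parents a disjoint block of
binary attributes.  The latent layer absorbs within-block dependence, so the
naive factorisation holds at the latent level:

    P(c | L) ∝ q(c) ∏_k q_k(L_k | c)

where q(c) is the class prior and q_k(l | c) the latent-level conditional.
Given attributes x, prediction marginalises the latent variables:

    P(c | x) ∝ q(c) ∏_k Σ_l q_k(l | c) P(x_block_k | theta^(k)_l)

with theta^(k) the Bernoulli item probabilities of block k — a product of
independent Bernoulli-mixture likelihoods, one per block, whose mixing
weights depend on the class.

Learning.  With C observed in training data, both fitters decompose over
blocks.  The EM fitter alternates block responsibilities
r_ik(l) ∝ q_k(l | y_i) P(x_i,block k | theta^(k)_l) with MAP updates of
theta (Beta prior), q_k(l|c) (Dirichlet within class) and q(c) (Dirichlet);
the Gibbs fitter replaces the maximisations with conjugate Beta/Dirichlet
draws and adds a multinomial draw of each subject's latent level.  The
algorithmic layout mirrors the plain latent class analysis in
:mod:`nbblca.blca` with the class variable conditioning every latent draw.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp

from .blca import THETA_FLOOR, _loglik_matrix, blca_em
from .data_model import BinaryDataset, PriorConfig, RunConfig

__all__ = [
    "LatentLayout",
    "NBBLCAModel",
    "NBBLCAChain",
    "class_posterior_given_latents",
    "predict_proba",
    "predict",
    "loglik",
    "fit_em",
    "fit_gibbs",
    "information_criteria",
    "select_levels_bic",
    "model_to_json",
    "model_from_json",
]


@dataclass(frozen=True)
class LatentLayout:
    """Partition of the attribute columns into latent blocks.

    ``blocks[k]`` lists the column indices parented by latent variable k;
    ``levels[k]`` is the number of latent levels G_k.
    """

    blocks: tuple[tuple[int, ...], ...]
    levels: tuple[int, ...]

    def __post_init__(self):
        blocks = tuple(tuple(int(j) for j in b) for b in self.blocks)
        levels = tuple(int(g) for g in self.levels)
        if len(blocks) != len(levels):
            raise ValueError("blocks and levels must have equal length")
        if any(g < 1 for g in levels):
            raise ValueError("each latent variable needs at least one level")
        flat = [j for b in blocks for j in b]
        if len(flat) == 0 or any(len(b) == 0 for b in blocks):
            raise ValueError("empty block")
        if sorted(flat) != list(range(len(flat))):
            raise ValueError("blocks must partition the attribute columns 0..M-1")
        object.__setattr__(self, "blocks", blocks)
        object.__setattr__(self, "levels", levels)

    @property
    def K(self) -> int:
        return len(self.blocks)

    @property
    def M(self) -> int:
        return sum(len(b) for b in self.blocks)

    @classmethod
    def single(cls, M: int, G: int) -> "LatentLayout":
        """One latent variable over all M attributes with G levels."""
        return cls((tuple(range(M)),), (G,))

    @classmethod
    def from_sizes(cls, sizes: list[int], levels: list[int]) -> "LatentLayout":
        blocks, start = [], 0
        for s in sizes:
            blocks.append(tuple(range(start, start + s)))
            start += s
        return cls(tuple(blocks), tuple(levels))


@dataclass(frozen=True)
class NBBLCAModel:
    """Fitted NB-BLCA parameters.

    ``q_c[c]`` is the class prior; ``q_given_c[k][c, l]`` = q_k(l | c);
    ``thetas[k][l, j]`` the item probability of the j-th attribute of
    block k under latent level l.
    """

    q_c: np.ndarray
    q_given_c: tuple[np.ndarray, ...]
    thetas: tuple[np.ndarray, ...]
    layout: LatentLayout
    class_labels: tuple[str, ...]

    def __post_init__(self):
        q_c = np.asarray(self.q_c, dtype=float)
        if not np.isclose(q_c.sum(), 1.0):
            raise ValueError("q_c must sum to 1")
        qs = tuple(np.asarray(q, dtype=float) for q in self.q_given_c)
        for k, q in enumerate(qs):
            if q.shape != (len(self.class_labels), self.layout.levels[k]):
                raise ValueError(f"q_given_c[{k}] has wrong shape {q.shape}")
            if not np.allclose(q.sum(axis=1), 1.0, atol=1e-9):
                raise ValueError(f"q_given_c[{k}] rows must sum to 1")
        ths = tuple(np.asarray(t, dtype=float) for t in self.thetas)
        for k, t in enumerate(ths):
            if t.shape != (self.layout.levels[k], len(self.layout.blocks[k])):
                raise ValueError(f"thetas[{k}] has wrong shape {t.shape}")
            if ((t < 0) | (t > 1)).any():
                raise ValueError("theta entries must lie in [0, 1]")
        object.__setattr__(self, "q_c", q_c)
        object.__setattr__(self, "q_given_c", qs)
        object.__setattr__(self, "thetas", ths)

    @property
    def n_classes(self) -> int:
        return len(self.class_labels)

    def n_parameters(self) -> int:
        """Free-parameter count: sum_k (G_k - 1)|C| + sum_k G_k |block_k| + (|C| - 1)."""
        C = self.n_classes
        lay = self.layout
        return (
            sum((g - 1) * C for g in lay.levels)
            + sum(g * len(b) for g, b in zip(lay.levels, lay.blocks))
            + (C - 1)
        )


@dataclass
class NBBLCAChain:
    """Retained Gibbs draws of all NB-BLCA parameters."""

    q_c: np.ndarray                      # (D, C)
    q_given_c: list[np.ndarray]          # per block (D, C, G_k)
    thetas: list[np.ndarray]             # per block (D, G_k, B_k)
    iterations: np.ndarray
    burn_in: int
    thin: int
    layout: LatentLayout = None
    class_labels: tuple[str, ...] = ()

    @property
    def n_draws(self) -> int:
        return self.q_c.shape[0]

    def draw_model(self, d: int) -> NBBLCAModel:
        return NBBLCAModel(
            self.q_c[d],
            tuple(q[d] for q in self.q_given_c),
            tuple(t[d] for t in self.thetas),
            self.layout,
            self.class_labels,
        )

    def posterior_mean(self) -> NBBLCAModel:
        q_c = self.q_c.mean(axis=0)
        qs = []
        for q in self.q_given_c:
            m = q.mean(axis=0)
            qs.append(m / m.sum(axis=1, keepdims=True))
        return NBBLCAModel(
            q_c / q_c.sum(), tuple(qs), tuple(t.mean(axis=0) for t in self.thetas),
            self.layout, self.class_labels,
        )


# ---------------------------------------------------------------------------
# prediction

def class_posterior_given_latents(model: NBBLCAModel, latent_profile) -> np.ndarray:
    """P(c | L) ∝ q(c) ∏_k q_k(L_k | c), normalised over classes."""
    profile = list(latent_profile)
    if len(profile) != model.layout.K:
        raise ValueError("latent profile length must equal the number of latent variables")
    log_p = np.log(np.maximum(model.q_c, THETA_FLOOR)).copy()
    for k, l in enumerate(profile):
        if not 0 <= l < model.layout.levels[k]:
            raise ValueError(f"invalid level index {l} for latent variable {k}")
        log_p += np.log(np.maximum(model.q_given_c[k][:, l], THETA_FLOOR))
    p = np.exp(log_p - logsumexp(log_p))
    return p / p.sum()


def _block_logliks(model: NBBLCAModel, X: np.ndarray) -> list[np.ndarray]:
    """Per block k, the (N, G_k) Bernoulli log-likelihood matrix."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != model.layout.M:
        raise ValueError(f"expected {model.layout.M} attribute columns, got {X.shape[1]}")
    return [_loglik_matrix(model.thetas[k], X[:, list(b)]) for k, b in enumerate(model.layout.blocks)]


def predict_proba(model: NBBLCAModel, X: np.ndarray, mode: str = "marginalize") -> np.ndarray:
    """Per-row class posterior under the latent-layer factorisation.

    ``marginalize`` (default) sums each block's likelihood over latent
    levels; ``hard`` first fixes each block's latent level at its MAP
    unsupervised assignment and then applies the P(c | L) formula.
    """
    bll = _block_logliks(model, X)
    N = bll[0].shape[0]
    C = model.n_classes
    with np.errstate(divide="ignore"):
        log_post = np.tile(np.log(np.maximum(model.q_c, THETA_FLOOR)), (N, 1))
        if mode == "marginalize":
            for k in range(model.layout.K):
                log_q = np.log(np.maximum(model.q_given_c[k], THETA_FLOOR))  # (C, G_k)
                # (N, C): logsumexp over levels of log q_k(l|c) + loglik(l)
                log_post += logsumexp(bll[k][:, None, :] + log_q[None, :, :], axis=2)
        elif mode == "hard":
            for k in range(model.layout.K):
                marg = model.q_c @ model.q_given_c[k]  # (G_k,) marginal level weights
                l_star = np.argmax(bll[k] + np.log(np.maximum(marg, THETA_FLOOR)), axis=1)
                log_post += np.log(np.maximum(model.q_given_c[k][:, l_star].T, THETA_FLOOR))
        else:
            raise ValueError("mode must be 'marginalize' or 'hard'")
    return np.exp(log_post - logsumexp(log_post, axis=1, keepdims=True))


def predict(model: NBBLCAModel, X: np.ndarray, mode: str = "marginalize") -> np.ndarray:
    proba = predict_proba(model, X, mode=mode)
    idx = np.argmax(proba, axis=1)
    return np.asarray(model.class_labels, dtype=object)[idx].astype(str)


def loglik(model: NBBLCAModel, data: BinaryDataset) -> float:
    """Joint log likelihood sum_i log P(y_i, x_i) under the fitted model."""
    bll = _block_logliks(model, data.X)
    yi = data.y_indices()
    with np.errstate(divide="ignore"):
        total = np.log(np.maximum(model.q_c, THETA_FLOOR))[yi].sum()
        for k in range(model.layout.K):
            log_q = np.log(np.maximum(model.q_given_c[k], THETA_FLOOR))[yi]  # (N, G_k)
            total += logsumexp(log_q + bll[k], axis=1).sum()
    return float(total)


# ---------------------------------------------------------------------------
# EM fitting

def _default_priors(layout: LatentLayout) -> list[PriorConfig]:
    return [PriorConfig.uniform(g, len(b)) for g, b in zip(layout.levels, layout.blocks)]


def _em_objective(model, data, priors, yi, bll=None) -> float:
    lp = loglik(model, data)
    for k, pr in enumerate(priors):
        th = np.clip(model.thetas[k], THETA_FLOOR, 1 - THETA_FLOOR)
        lp += float(((pr.alpha - 1) * np.log(th) + (pr.beta - 1) * np.log1p(-th)).sum())
        q = np.maximum(model.q_given_c[k], THETA_FLOOR)
        lp += float(((pr.delta - 1) * np.log(q)).sum())
    return lp


def fit_em(
    train: BinaryDataset,
    layout: LatentLayout,
    priors: list[PriorConfig] | None = None,
    run: RunConfig | None = None,
    method: str = "joint",
) -> NBBLCAModel:
    """MAP EM for NB-BLCA with the class variable observed.

    ``method='joint'`` (default) maximises the full joint posterior; the
    latent responsibilities condition on each subject's observed class.
    ``method='two_stage'`` first fits each block as an unsupervised latent
    class model ignoring y, then estimates q_k(l|c) from the per-class mean
    responsibilities — the sequential reading of the construction.
    """
    if train.y is None:
        raise ValueError("training data must carry class labels")
    if layout.M != train.m:
        raise ValueError("layout does not cover the dataset's attribute columns")
    priors = priors if priors is not None else _default_priors(layout)
    run = run or RunConfig()
    yi = train.y_indices()
    C = len(train.class_labels)
    n_c = np.bincount(yi, minlength=C).astype(float)
    if (n_c == 0).any():
        raise ValueError("every class must appear in the training data")
    q_c = n_c / n_c.sum()  # MAP with flat Dirichlet = observed frequencies
    X = train.X.astype(float)

    if method == "two_stage":
        qs, ths = [], []
        for k, b in enumerate(layout.blocks):
            params, resp, _ = blca_em(X[:, list(b)], layout.levels[k], priors[k], run)
            ths.append(params.theta)
            q = np.vstack([resp.Z[yi == c].mean(axis=0) for c in range(C)])
            qs.append(q / q.sum(axis=1, keepdims=True))
        return NBBLCAModel(q_c, tuple(qs), tuple(ths), layout, train.class_labels)
    if method != "joint":
        raise ValueError("method must be 'joint' or 'two_stage'")

    rng = run.rng()
    class_masks = [yi == c for c in range(C)]
    best_model, best_lp = None, -np.inf
    for _ in range(max(1, run.n_restarts)):
        qs, ths = [], []
        # random item-probability start per block (breaks the symmetric saddle)
        for k, b in enumerate(layout.blocks):
            G = layout.levels[k]
            ths.append(rng.uniform(0.2, 0.8, size=(G, len(b))))
            qs.append(rng.dirichlet(np.ones(G), size=C))
        prev = -np.inf
        for _it in range(run.max_iter):
            model = NBBLCAModel(q_c, tuple(qs), tuple(ths), layout, train.class_labels)
            lp = _em_objective(model, train, priors, yi)
            if np.isfinite(prev) and abs(lp - prev) <= run.tol * (abs(prev) + 1e-12):
                break
            prev = lp
            bll = _block_logliks(model, X)
            qs, ths = [], []
            for k, b in enumerate(layout.blocks):
                log_q = np.log(np.maximum(model.q_given_c[k], THETA_FLOOR))[yi]
                log_r = log_q + bll[k]
                log_r -= logsumexp(log_r, axis=1, keepdims=True)
                R = np.exp(log_r)
                th, q = _m_step_block(X[:, list(b)], R, class_masks, n_c, priors[k])
                ths.append(th)
                qs.append(q)
        model = NBBLCAModel(q_c, tuple(qs), tuple(ths), layout, train.class_labels)
        lp = _em_objective(model, train, priors, yi)
        if lp > best_lp:
            best_lp, best_model = lp, model
    return best_model


def _m_step_block(Xb, R, class_masks, n_c, pr: PriorConfig):
    """MAP update of one block's theta and q_k(l|c) from responsibilities R."""
    G = R.shape[1]
    Nk = R.sum(axis=0)
    denom = np.maximum(Nk[:, None] + pr.alpha + pr.beta - 2, 1e-10)
    theta = (R.T @ Xb + pr.alpha - 1) / denom
    theta = np.clip(theta, THETA_FLOOR, 1 - THETA_FLOOR)
    q = np.zeros((len(class_masks), G))
    for c, mask in enumerate(class_masks):
        num = R[mask].sum(axis=0) + pr.delta - 1
        q[c] = np.maximum(num, 0)
        denom = q[c].sum()
        q[c] = q[c] / denom if denom > 0 else np.full(G, 1.0 / G)
    return theta, q


# ---------------------------------------------------------------------------
# Gibbs fitting

def fit_gibbs(
    train: BinaryDataset,
    layout: LatentLayout,
    priors: list[PriorConfig] | None = None,
    run: RunConfig | None = None,
    class_delta: float = 1.0,
    relabel: bool = True,
) -> tuple[NBBLCAModel, NBBLCAChain]:
    """Gibbs sampler for NB-BLCA; returns the posterior-mean model and chain.

    Each sweep draws per block theta from its Beta conditional, q_k(.|c)
    from its Dirichlet conditional given latent-level counts within class c,
    q(c) from Dirichlet over observed class counts, and finally each
    subject's latent level from the multinomial with probabilities
    ∝ q_k(l | y_i) P(x_i,block k | theta^(k)_l).
    """
    if train.y is None:
        raise ValueError("training data must carry class labels")
    priors = priors if priors is not None else _default_priors(layout)
    run = run or RunConfig()
    rng = run.rng()
    yi = train.y_indices()
    C = len(train.class_labels)
    n_c = np.bincount(yi, minlength=C).astype(float)
    X = train.X.astype(float)
    N = train.n
    class_masks = [yi == c for c in range(C)]

    L = [rng.integers(0, g, size=N) for g in layout.levels]
    kept = {"q_c": [], "q": [[] for _ in layout.blocks], "th": [[] for _ in layout.blocks], "it": []}
    for sweep in range(run.gibbs_iters):
        q_c = rng.dirichlet(n_c + class_delta)
        ths, qs = [], []
        for k, b in enumerate(layout.blocks):
            G = layout.levels[k]
            Xb = X[:, list(b)]
            Z = np.zeros((N, G))
            Z[np.arange(N), L[k]] = 1.0
            ones = Z.T @ Xb
            Nk = Z.sum(axis=0)
            theta = rng.beta(ones + priors[k].alpha, Nk[:, None] - ones + priors[k].beta)
            q = np.zeros((C, G))
            for c, mask in enumerate(class_masks):
                counts = np.bincount(L[k][mask], minlength=G)
                q[c] = rng.dirichlet(counts + priors[k].delta)
            bll = _loglik_matrix(theta, Xb)
            log_w = bll + np.log(np.maximum(q[yi], THETA_FLOOR))
            log_w -= logsumexp(log_w, axis=1, keepdims=True)
            cum = np.cumsum(np.exp(log_w), axis=1)
            u = rng.random(N)[:, None]
            L[k] = (u > cum).sum(axis=1)
            ths.append(theta)
            qs.append(q)
        if sweep >= run.burn_in and (sweep - run.burn_in) % run.thin == 0:
            kept["q_c"].append(q_c)
            for k in range(layout.K):
                kept["q"][k].append(qs[k])
                kept["th"][k].append(ths[k])
            kept["it"].append(sweep)
    chain = NBBLCAChain(
        q_c=np.asarray(kept["q_c"]),
        q_given_c=[np.asarray(a) for a in kept["q"]],
        thetas=[np.asarray(a) for a in kept["th"]],
        iterations=np.asarray(kept["it"]),
        burn_in=run.burn_in,
        thin=run.thin,
        layout=layout,
        class_labels=train.class_labels,
    )
    if relabel:
        chain = relabel_nbblca_chain(chain)
    return chain.posterior_mean(), chain


def relabel_nbblca_chain(chain: NBBLCAChain) -> NBBLCAChain:
    """Per-block running-mean relabeling of latent levels (cf. mixture chains)."""
    for k in range(chain.layout.K):
        G = chain.layout.levels[k]
        if G == 1:
            continue
        perms = list(itertools.permutations(range(G)))
        theta = chain.thetas[k]
        q = chain.q_given_c[k]
        ref = theta[0].copy()
        for d in range(chain.n_draws):
            best_p, best_cost = perms[0], np.inf
            for p in perms:
                cost = float(((theta[d, list(p)] - ref) ** 2).sum())
                if cost < best_cost - 1e-15:
                    best_cost, best_p = cost, p
            p = list(best_p)
            theta[d] = theta[d, p]
            q[d] = q[d][:, p]
            ref += (theta[d] - ref) / (d + 1)
    return chain


# ---------------------------------------------------------------------------
# model choice

def information_criteria(
    model: NBBLCAModel,
    train: BinaryDataset,
    chain: NBBLCAChain | None = None,
) -> dict:
    """AIC, BIC and (given a chain) DIC for a fitted NB-BLCA model.

    AIC = -2 loglik + 2p, BIC = -2 loglik + p log N with p the free-parameter
    count; DIC = mean deviance + p_D, p_D = mean deviance - deviance at the
    posterior mean.
    """
    ll = loglik(model, train)
    p = model.n_parameters()
    out = {"loglik": ll, "p": p, "AIC": -2 * ll + 2 * p, "BIC": -2 * ll + p * np.log(train.n)}
    if chain is not None:
        devs = np.array([-2.0 * loglik(chain.draw_model(d), train) for d in range(chain.n_draws)])
        d_bar = float(devs.mean())
        d_hat = -2.0 * loglik(chain.posterior_mean(), train)
        out["p_D"] = d_bar - d_hat
        out["DIC"] = d_bar + out["p_D"]
    return out


def select_levels_bic(
    train: BinaryDataset,
    candidates=(2, 3, 4),
    priors_for=None,
    run: RunConfig | None = None,
) -> tuple[NBBLCAModel, dict]:
    """Scan single-latent layouts over candidate level counts, keep lowest BIC."""
    best, scores = None, {}
    for G in candidates:
        layout = LatentLayout.single(train.m, G)
        model = fit_em(train, layout, None if priors_for is None else priors_for(layout), run)
        bic = information_criteria(model, train)["BIC"]
        scores[G] = bic
        if best is None or bic < best[1]:
            best = (model, bic)
    return best[0], scores


# ---------------------------------------------------------------------------
# serialization

def model_to_json(model: NBBLCAModel) -> str:
    return json.dumps(
        {
            "class_labels": list(model.class_labels),
            "q_c": model.q_c.tolist(),
            "q_given_c": [q.tolist() for q in model.q_given_c],
            "thetas": [t.tolist() for t in model.thetas],
            "blocks": [list(b) for b in model.layout.blocks],
            "levels": list(model.layout.levels),
        },
        indent=1,
    )


def model_from_json(text: str) -> NBBLCAModel:
    d = json.loads(text)
    layout = LatentLayout(tuple(tuple(b) for b in d["blocks"]), tuple(d["levels"]))
    return NBBLCAModel(
        np.asarray(d["q_c"]),
        tuple(np.asarray(q) for q in d["q_given_c"]),
        tuple(np.asarray(t) for t in d["thetas"]),
        layout,
        tuple(d["class_labels"]),
    )
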