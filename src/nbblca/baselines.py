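"""Comparator classifiers: AODE and hill-climbing tree-augmented Naive Bayes.

Both relax the Naive Bayes independence assumption by allowing a single
extra parent per attribute.  AODE averages over all one-dependence
estimators, each designating one attribute as the shared parent of the
others; TAN-HC greedily adds individual parent arcs while they improve
resubstitution accuracy.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp

from .data_model import BinaryDataset

__all__ = [
    "AODEParams",
    "TANParams",
    "aode_fit",
    "aode_predict_proba",
    "aode_predict",
    "tan_hc_fit",
    "tan_predict_proba",
    "tan_predict",
]

_EPS = 1e-300


@dataclass(frozen=True)
class AODEParams:
    """Sufficient joint counts for averaged one-dependence estimation.

    ``n_cpv[c, p, v]`` counts rows with class c and attribute p equal to v;
    ``n_cpvmu[c, p, v, m, u]`` additionally conditions attribute m on value
    u.  Probabilities are derived on demand with the stored pseudo-count.
    """

    n: int
    n_c: np.ndarray
    n_cpv: np.ndarray
    n_cpvmu: np.ndarray
    class_labels: tuple[str, ...]
    smoothing: float = 1.0
    min_support: int = 1


def aode_fit(train: BinaryDataset, smoothing: float = 1.0, min_support: int = 1) -> AODEParams:
    if train.y is None:
        raise ValueError("training data must carry class labels")
    yi = train.y_indices()
    C, M = len(train.class_labels), train.m
    X = train.X
    n_c = np.bincount(yi, minlength=C).astype(float)
    n_cpv = np.zeros((C, M, 2))
    n_cpvmu = np.zeros((C, M, 2, M, 2))
    for c in range(C):
        Xc = X[yi == c]
        for v in (0, 1):
            sel = Xc[:, :, None] == v  # (nc, M, 1) broadcast per parent
            n_cpv[c, :, v] = sel[:, :, 0].sum(axis=0)
            for p in range(M):
                rows = Xc[Xc[:, p] == v]
                if len(rows):
                    ones = rows.sum(axis=0)
                    n_cpvmu[c, p, v, :, 1] = ones
                    n_cpvmu[c, p, v, :, 0] = len(rows) - ones
    return AODEParams(train.n, n_c, n_cpv, n_cpvmu, train.class_labels, smoothing, min_support)


def aode_predict_proba(params: AODEParams, X: np.ndarray) -> np.ndarray:
    """Average the one-dependence posteriors over all qualifying parents.

    Parent p qualifies for a row when its observed value occurred at least
    ``min_support`` times in training; with no qualifying parent the
    posterior falls back to plain Naive Bayes built from the same counts.
    """
    X = np.atleast_2d(np.asarray(X))
    C, M = params.n_cpv.shape[:2]
    if X.shape[1] != M:
        raise ValueError(f"expected {M} attribute columns, got {X.shape[1]}")
    N = X.shape[0]
    s = params.smoothing
    support = params.n_cpv.sum(axis=0)  # (M, 2) value counts across classes

    # log P(c, x_p = v), Laplace over the C*2 joint cells
    log_joint = np.log((params.n_cpv + s) / (params.n + s * C * 2) + _EPS)
    # log P(x_m = u | c, x_p = v)
    denom = params.n_cpv[:, :, :, None, None] + 2 * s
    log_cond = np.log((params.n_cpvmu + s) / denom + _EPS)

    out = np.zeros((N, C))
    for i in range(N):
        x = X[i]
        qualifying = [p for p in range(M) if support[p, x[p]] >= params.min_support]
        if not qualifying:
            out[i] = _aode_nb_fallback(params, x)
            continue
        per_parent = np.empty((len(qualifying), C))
        for j, p in enumerate(qualifying):
            v = x[p]
            ll = log_joint[:, p, v].copy()
            for m in range(M):
                if m == p:
                    continue
                ll += log_cond[:, p, v, m, x[m]]
            per_parent[j] = ll
        # average the estimators in probability space, then normalise
        mix = logsumexp(per_parent, axis=0) - np.log(len(qualifying))
        out[i] = np.exp(mix - logsumexp(mix))
    return out


def _aode_nb_fallback(params: AODEParams, x: np.ndarray) -> np.ndarray:
    s = params.smoothing
    C, M = params.n_cpv.shape[:2]
    prior = (params.n_c + s) / (params.n + s * C)
    ones = params.n_cpv[:, :, 1]
    cond = (ones + s) / (params.n_c[:, None] + 2 * s)
    ll = np.log(prior + _EPS)
    ll = ll + np.where(x == 1, np.log(cond + _EPS), np.log(1 - cond + _EPS)).sum(axis=1)
    return np.exp(ll - logsumexp(ll))


def aode_predict(params: AODEParams, X: np.ndarray) -> np.ndarray:
    proba = aode_predict_proba(params, X)
    return np.asarray(params.class_labels, dtype=object)[np.argmax(proba, axis=1)].astype(str)


# ---------------------------------------------------------------------------
# TAN by hill climbing


@dataclass(frozen=True)
class TANParams:
    """Learned augmenting arcs and conditional tables.

    ``parent[m]`` is the extra parent attribute of m, or -1; root attributes
    use P(x_m | c), augmented ones P(x_m | c, x_parent).
    """

    class_prior: np.ndarray
    parent: np.ndarray
    root_tables: np.ndarray       # (C, M) P(x_m=1 | c)
    arc_tables: dict              # m -> (C, 2) P(x_m=1 | c, x_parent=v)
    class_labels: tuple[str, ...]
    smoothing: float
    score_trace: tuple[float, ...]


def _creates_cycle(parent: dict, p: int, m: int) -> bool:
    node = p
    while node in parent:
        node = parent[node]
        if node == m:
            return True
    return False


def tan_hc_fit(train: BinaryDataset, smoothing: float = 1.0) -> TANParams:
    """Greedy structure search: starting from Naive Bayes, repeatedly add the
    single parent arc that most improves training-set accuracy; stop when no
    arc improves.  Each attribute receives at most one extra parent and the
    arc set stays acyclic over attributes."""
    if train.y is None:
        raise ValueError("training data must carry class labels")
    yi = train.y_indices()
    C, M, N = len(train.class_labels), train.m, train.n
    X = train.X
    s = smoothing
    n_c = np.bincount(yi, minlength=C).astype(float)
    prior = (n_c + s) / (N + s * C)
    log_prior = np.log(prior)

    # per-attribute root log-term matrices (N, C)
    ones = np.zeros((C, M))
    for c in range(C):
        ones[c] = X[yi == c].sum(axis=0)
    root_p1 = (ones + s) / (n_c[:, None] + 2 * s)
    log_root = [
        np.where(X[:, [m]] == 1, np.log(root_p1[:, m]), np.log(1 - root_p1[:, m]))
        for m in range(M)
    ]  # each (N, C)

    def arc_table(m: int, p: int) -> np.ndarray:
        """(C, 2) table of P(x_m=1 | c, x_p=v)."""
        tab = np.zeros((C, 2))
        for c in range(C):
            Xc = X[yi == c]
            for v in (0, 1):
                rows = Xc[Xc[:, p] == v]
                tab[c, v] = (rows[:, m].sum() + s) / (len(rows) + 2 * s)
        return tab

    def arc_logterm(m: int, p: int, tab: np.ndarray) -> np.ndarray:
        p1 = tab[:, X[:, p]].T  # (N, C)
        return np.where(X[:, [m]] == 1, np.log(p1), np.log(1 - p1))

    def accuracy(total_ll: np.ndarray) -> float:
        return float((np.argmax(total_ll, axis=1) == yi).mean())

    terms = [lt.copy() for lt in log_root]
    total = log_prior[None, :] + sum(terms)
    parent: dict[int, int] = {}
    tables: dict[int, np.ndarray] = {}
    trace = [accuracy(total)]
    while True:
        best = None
        for m in range(M):
            if m in parent:
                continue
            for p in range(M):
                if p == m or _creates_cycle(parent, p, m):
                    continue
                tab = arc_table(m, p)
                cand_total = total - terms[m] + arc_logterm(m, p, tab)
                acc = accuracy(cand_total)
                if acc > trace[-1] + 1e-12 and (best is None or acc > best[0] + 1e-12):
                    best = (acc, m, p, tab)
        if best is None:
            break
        acc, m, p, tab = best
        parent[m] = p
        tables[m] = tab
        terms[m] = arc_logterm(m, p, tab)
        total = log_prior[None, :] + sum(terms)
        trace.append(acc)
    parent_arr = np.full(M, -1, dtype=np.int64)
    for m, p in parent.items():
        parent_arr[m] = p
    return TANParams(prior, parent_arr, root_p1, tables, train.class_labels, s, tuple(trace))


def tan_predict_proba(params: TANParams, X: np.ndarray) -> np.ndarray:
    X = np.atleast_2d(np.asarray(X))
    C, M = params.root_tables.shape
    if X.shape[1] != M:
        raise ValueError(f"expected {M} attribute columns, got {X.shape[1]}")
    ll = np.tile(np.log(params.class_prior), (X.shape[0], 1))
    for m in range(M):
        p = params.parent[m]
        if p < 0:
            p1 = np.tile(params.root_tables[:, m], (X.shape[0], 1))
        else:
            p1 = params.arc_tables[m][:, X[:, p]].T
        ll += np.where(X[:, [m]] == 1, np.log(p1 + _EPS), np.log(1 - p1 + _EPS))
    return np.exp(ll - logsumexp(ll, axis=1, keepdims=True))


def tan_predict(params: TANParams, X: np.ndarray) -> np.ndarray:
    proba = tan_predict_proba(params, X)
    return np.asarray(params.class_labels, dtype=object)[np.argmax(proba, axis=1)].astype(str)
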