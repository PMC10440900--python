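"""Ordinary Naive Bayes for binary attributes.

The classifier assumes the attributes are mutually independent given the
class, so the posterior is

    P(c | x) ∝ P(c) ∏_m P(x_m | c),

normalised over classes.  Counts are optionally Laplace-smoothed; smoothing
defaults to 1 and a value of 0 reproduces the pure maximum-likelihood fit.
All likelihood products are accumulated in the log domain.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp

from .data_model import BinaryDataset

__all__ = ["NBParams", "nb_fit", "nb_predict_proba", "nb_predict"]

logger = logging.getLogger(__name__)

_EPS = 1e-300  # floor inside logs so a zero-count cell yields -inf cleanly


@dataclass(frozen=True)
class NBParams:
    """Fitted Naive Bayes parameters.

    ``class_prior[c]`` is P(C=c); ``cond_prob[c, m]`` is P(X_m=1 | C=c).
    """

    class_prior: np.ndarray
    cond_prob: np.ndarray
    class_labels: tuple[str, ...]
    smoothing: float = 1.0

    def __post_init__(self):
        object.__setattr__(self, "class_prior", np.asarray(self.class_prior, dtype=float))
        object.__setattr__(self, "cond_prob", np.asarray(self.cond_prob, dtype=float))
        if not np.isclose(self.class_prior.sum(), 1.0):
            raise ValueError("class_prior must sum to 1")
        if ((self.cond_prob < 0) | (self.cond_prob > 1)).any():
            raise ValueError("cond_prob entries must lie in [0, 1]")


def nb_fit(train: BinaryDataset, smoothing: float = 1.0) -> NBParams:
    """Fit class priors and per-class Bernoulli parameters by (smoothed) counting.

    ``class_prior_c = (n_c + s) / (N + s*|C|)`` and
    ``cond_prob_{c,m} = (#{X_m=1 in class c} + s) / (n_c + 2 s)``.
    """
    if train.y is None:
        raise ValueError("training data must carry class labels")
    if smoothing < 0:
        raise ValueError("smoothing must be nonnegative")
    logger.info("Naive Bayes fit with smoothing pseudo-count %g", smoothing)
    yi = train.y_indices()
    C = len(train.class_labels)
    counts = np.bincount(yi, minlength=C).astype(float)
    if (counts == 0).any():
        raise ValueError("every class label must appear at least once in training data")
    ones = np.zeros((C, train.m))
    for c in range(C):
        ones[c] = train.X[yi == c].sum(axis=0)
    prior = (counts + smoothing) / (train.n + smoothing * C)
    cond = (ones + smoothing) / (counts[:, None] + 2.0 * smoothing)
    return NBParams(prior, cond, train.class_labels, smoothing)


def _check_columns(params_m: int, X: np.ndarray) -> np.ndarray:
    X = np.asarray(X)
    if X.ndim == 1:
        X = X[None, :]
    if X.shape[1] != params_m:
        raise ValueError(f"expected {params_m} attribute columns, got {X.shape[1]}")
    return X


def nb_predict_proba(params: NBParams, X: np.ndarray) -> np.ndarray:
    """Per-row class posterior; rows sum to 1. M=0 returns the class prior."""
    X = _check_columns(params.cond_prob.shape[1], X)
    log_prior = np.log(np.maximum(params.class_prior, _EPS))
    log_p1 = np.log(np.maximum(params.cond_prob, _EPS))
    log_p0 = np.log(np.maximum(1.0 - params.cond_prob, _EPS))
    # (N, C): sum of per-feature log likelihoods
    ll = X @ log_p1.T + (1 - X) @ log_p0.T + log_prior
    return np.exp(ll - logsumexp(ll, axis=1, keepdims=True))


def nb_predict(params: NBParams, X: np.ndarray) -> np.ndarray:
    """MAP labels; posterior ties broken toward the larger prior, then label order."""
    proba = nb_predict_proba(params, X)
    labels = np.asarray(params.class_labels, dtype=object)
    # lexsort keys: last key dominates → posterior, then prior, then reversed index
    order = np.arange(proba.shape[1])[::-1]
    idx = np.empty(proba.shape[0], dtype=np.int64)
    for i, row in enumerate(proba):
        keys = np.lexsort((order, params.class_prior, row))
        idx[i] = keys[-1]
    return labels[idx].astype(str)
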