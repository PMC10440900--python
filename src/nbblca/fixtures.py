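"""Deterministic worked datasets for examples and tests.

Includes a synthetic stand-in for a two-class clinical questionnaire:
2165 patients (976 cases, 1189 controls) with 64 binary attributes in five
subdomain blocks, drawn from a moderately separated NB-BLCA generative
model.  It emulates only the schema of such data — it is not a
reconstruction of any real cohort.
"""

from __future__ import annotations

import numpy as np

from .data_model import BinaryDataset
from .nb_blca import LatentLayout, NBBLCAModel

__all__ = ["make_toy", "sample_from_model", "make_gcnud_like", "GCNUD_BLOCK_SIZES"]

GCNUD_BLOCK_SIZES = (12, 16, 12, 14, 10)  # five subdomains, 64 attributes
GCNUD_CLASS_SIZES = {"GC": 976, "NUD": 1189}


def make_toy(name: str, seed: int = 1234) -> BinaryDataset:
    """Small named fixtures with hand-checkable structure.

    - ``nb4``: 4 rows, one attribute perfectly aligned with the class.
    - ``sep2``: N=200 draws from a well-separated 2-component mixture.
    - ``xor``: two attributes deterministically equal within each class
      but jointly informative — the classic structure plain NB misses.
    - ``aode2``: an enumerable M=2 table for one-dependence averaging.
    - ``gcnud-like``: see :func:`make_gcnud_like`.
    """
    rng = np.random.default_rng(seed)
    if name == "nb4":
        X = np.array([[1], [1], [0], [0]])
        y = np.array(["+", "+", "-", "-"])
        return BinaryDataset(X=X, y=y, feature_names=("x",), class_labels=("+", "-"))
    if name == "sep2":
        z = rng.integers(0, 2, size=200)
        theta = np.where(z[:, None] == 0, 0.9, 0.1)
        X = (rng.random((200, 6)) < theta).astype(int)
        return BinaryDataset(X=X, y=z.astype(str))
    if name == "xor":
        n = 400
        y = rng.integers(0, 2, size=n)
        a = rng.integers(0, 2, size=n)
        b = np.where(y == 1, a, 1 - a)  # x1 == x2 exactly within class 1
        noise = (rng.random(n) < 0.5).astype(int)
        X = np.column_stack([a, b, noise])
        return BinaryDataset(X=X, y=y.astype(str))
    if name == "aode2":
        X = np.array([[0, 0], [0, 1], [1, 0], [1, 1], [1, 1], [0, 0], [1, 0], [0, 1]])
        y = np.array(["a", "a", "a", "b", "b", "b", "a", "b"])
        return BinaryDataset(X=X, y=y)
    if name == "gcnud-like":
        return make_gcnud_like(seed=seed)
    raise ValueError(f"unknown fixture {name!r}")


def sample_from_model(model: NBBLCAModel, n: int, rng: np.random.Generator) -> BinaryDataset:
    """Generative draw: c ~ q(c); per block l_k ~ q_k(.|c); x ~ Bernoulli(theta)."""
    c = rng.choice(model.n_classes, size=n, p=model.q_c)
    return _draw_given_classes(model, c, rng)


def _draw_given_classes(model: NBBLCAModel, c: np.ndarray, rng: np.random.Generator) -> BinaryDataset:
    n = len(c)
    X = np.zeros((n, model.layout.M), dtype=np.int8)
    for k, block in enumerate(model.layout.blocks):
        G = model.layout.levels[k]
        cum = np.cumsum(model.q_given_c[k], axis=1)[c]  # (n, G)
        l = (rng.random(n)[:, None] > cum).sum(axis=1)
        theta = model.thetas[k][l]  # (n, |block|)
        X[:, list(block)] = (rng.random(theta.shape) < theta).astype(np.int8)
    y = np.asarray(model.class_labels, dtype=object)[c].astype(str)
    return BinaryDataset(X=X, y=y, class_labels=model.class_labels)


def gcnud_generative_model(seed: int = 7) -> NBBLCAModel:
    """The fixed synthetic generative model behind the questionnaire fixture."""
    rng = np.random.default_rng(seed)
    layout = LatentLayout.from_sizes(list(GCNUD_BLOCK_SIZES), [2] * 5)
    q_c = np.array([0.45, 0.55])
    qs, ths = [], []
    for k, b in enumerate(layout.blocks):
        # moderately class-informative latent conditionals
        q1 = rng.uniform(0.6, 0.85)
        q2 = rng.uniform(0.15, 0.4)
        qs.append(np.array([[q1, 1 - q1], [q2, 1 - q2]]))
        th = rng.uniform(0.15, 0.45, size=(2, len(b)))
        th[0] += rng.uniform(0.25, 0.45, size=len(b))  # separated levels
        ths.append(np.clip(th, 0.02, 0.98))
    return NBBLCAModel(q_c, tuple(qs), tuple(ths), layout, ("GC", "NUD"))


def make_gcnud_like(seed: int = 1234) -> BinaryDataset:
    """Synthetic questionnaire-shaped cohort: exactly 976 'GC' and 1189 'NUD'
    rows, 64 binary attributes in five blocks, shuffled deterministically."""
    rng = np.random.default_rng(seed)
    model = gcnud_generative_model()
    c = np.concatenate([
        np.zeros(GCNUD_CLASS_SIZES["GC"], dtype=int),
        np.ones(GCNUD_CLASS_SIZES["NUD"], dtype=int),
    ])
    rng.shuffle(c)
    return _draw_given_classes(model, c, rng)
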