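"""Correlated-binary data generator and the scenario-grid study runner.

Features are produced in independent 5-dimensional batches.  Each batch
draws hypothetical marginal probabilities HMP_i ~ U(0,1) and pairwise odds
ratios OR_ij ~ U(0.25, 4), then fits a full 2^5 joint table whose
univariate margins equal the HMP and whose pairwise (marginal) odds ratios
equal the targets.  The fit proceeds in two steps, following the iterative
proportional fitting construction for multivariate Bernoulli
distributions: each pair's 2x2 margin is obtained in closed form from
(HMP_i, HMP_j, OR_ij) — the Plackett root of the quadratic with fixed
margins and cross-product ratio — and IPFP then rescales the joint table
to all pairwise margins simultaneously, starting from the independence
table.

Class labels follow a noisy logistic rule applied to the feature sum,

    Z = alpha + beta * sum_i x_i + N(0, sigma),   P = 1 / (1 + e^Z),
    y ~ Bernoulli(P),

with beta = 2 and sigma = 4 by default.  P is decreasing in Z as written;
the intercept alpha is tuned per replicate (bisection on a pilot sample) so
the class marginal hits the scenario's target prevalence, which absorbs the
sign convention.  An alternative reading, ``label_mechanism =
"latent_threshold"``, treats the Gaussian term as the label noise itself
(y = 1{Z < 0}); it produces noticeably more detectable minority classes
and is provided because the two readings differ materially in the
irreducible label noise they imply.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.special import expit

from .data_model import BinaryDataset, split_train_test
from .evaluation import confusion_metrics

__all__ = [
    "SimulationScenario",
    "BatchSpec",
    "IPFPError",
    "draw_batch_spec",
    "pair_cell_probs",
    "ipfp_fit_joint",
    "sample_features",
    "tune_alpha",
    "generate_dataset",
    "run_study",
    "default_models",
]

logger = logging.getLogger(__name__)

POSITIVE_LABEL = "1"


@dataclass(frozen=True)
class SimulationScenario:
    """One cell of the simulation grid."""

    p: int = 5
    n: int = 500
    target_prev: float = 0.5
    beta: float = 2.0
    sigma: float = 4.0
    or_low: float = 0.25
    or_high: float = 4.0
    batch: int = 5
    pilot_n: int = 20000
    label_mechanism: str = "bernoulli"

    def __post_init__(self):
        if self.p % self.batch != 0:
            raise ValueError("feature count must be divisible by the batch size")
        if not 0 < self.target_prev < 1:
            raise ValueError("target_prev must lie in (0, 1)")
        if self.label_mechanism not in ("bernoulli", "latent_threshold"):
            raise ValueError("label_mechanism must be 'bernoulli' or 'latent_threshold'")


@dataclass
class BatchSpec:
    """Marginals, pairwise odds ratios and (after fitting) the joint table."""

    hmp: np.ndarray
    or_matrix: np.ndarray
    joint: np.ndarray | None = None  # length 2^d, cell order = bit patterns

    @property
    def dim(self) -> int:
        return len(self.hmp)


class IPFPError(RuntimeError):
    pass


def draw_batch_spec(rng: np.random.Generator, dim: int = 5,
                    or_low: float = 0.25, or_high: float = 4.0) -> BatchSpec:
    """HMP_i ~ U(0,1); OR_ij ~ U(or_low, or_high) mirrored, unit diagonal."""
    hmp = rng.uniform(0, 1, size=dim)
    ors = np.ones((dim, dim))
    for i, j in combinations(range(dim), 2):
        ors[i, j] = ors[j, i] = rng.uniform(or_low, or_high)
    return BatchSpec(hmp, ors)


def pair_cell_probs(pi: float, pj: float, psi: float) -> np.ndarray:
    """2x2 cell probabilities with margins (pi, pj) and odds ratio psi.

    The (1,1) cell is the admissible root of the Plackett quadratic
    ``psi = p11 p00 / (p10 p01)``; psi = 1 gives the independence table.
    """
    if psi == 1.0:
        p11 = pi * pj
    else:
        S = 1.0 + (pi + pj) * (psi - 1.0)
        disc = S * S - 4.0 * psi * (psi - 1.0) * pi * pj
        p11 = (S - np.sqrt(disc)) / (2.0 * (psi - 1.0))
    p11 = float(np.clip(p11, max(0.0, pi + pj - 1.0), min(pi, pj)))
    return np.array([[1 - pi - pj + p11, pj - p11], [pi - p11, p11]])


def _patterns(dim: int) -> np.ndarray:
    """(2^dim, dim) matrix of bit patterns; cell index encodes the row."""
    return ((np.arange(2 ** dim)[:, None] >> np.arange(dim)[::-1]) & 1).astype(np.int8)


def ipfp_fit_joint(spec: BatchSpec, tol: float = 1e-12, max_sweeps: int = 5000) -> BatchSpec:
    """Fit the 2^d joint to all pairwise target margins by IPFP.

    Starts from the independence table and cycles through the pairs,
    rescaling the four matching cell groups to each pair's closed-form 2x2
    target, until the largest absolute pairwise-margin error drops below
    ``tol``.  Raises :class:`IPFPError` with the achieved error on
    non-convergence.
    """
    d = spec.dim
    pats = _patterns(d)
    targets = {
        (i, j): pair_cell_probs(spec.hmp[i], spec.hmp[j], spec.or_matrix[i, j])
        for i, j in combinations(range(d), 2)
    }
    # independence seed table
    joint = np.prod(np.where(pats == 1, spec.hmp, 1 - spec.hmp), axis=1).astype(float)
    joint = np.maximum(joint, 1e-300)
    masks = {
        (i, j, vi, vj): (pats[:, i] == vi) & (pats[:, j] == vj)
        for i, j in targets
        for vi in (0, 1)
        for vj in (0, 1)
    }
    err = np.inf
    for _sweep in range(max_sweeps):
        for (i, j), tgt in targets.items():
            for vi in (0, 1):
                for vj in (0, 1):
                    mask = masks[(i, j, vi, vj)]
                    cur = joint[mask].sum()
                    if cur > 0:
                        joint[mask] *= tgt[vi, vj] / cur
        joint /= joint.sum()
        err = max(
            abs(joint[masks[(i, j, vi, vj)]].sum() - tgt[vi, vj])
            for (i, j), tgt in targets.items()
            for vi in (0, 1)
            for vj in (0, 1)
        )
        if err < tol:
            return replace(spec, joint=joint)
    raise IPFPError(f"IPFP did not reach tol={tol} in {max_sweeps} sweeps (error {err:.3e})")


def sample_features(specs: list[BatchSpec], n: int, rng: np.random.Generator) -> np.ndarray:
    """n rows concatenating one draw from each fitted batch joint."""
    cols = []
    for spec in specs:
        if spec.joint is None:
            raise ValueError("batch spec must be fitted before sampling")
        pats = _patterns(spec.dim)
        idx = rng.choice(len(spec.joint), size=n, p=spec.joint)
        cols.append(pats[idx])
    return np.concatenate(cols, axis=1)


def tune_alpha(
    specs: list[BatchSpec],
    scenario: SimulationScenario,
    rng: np.random.Generator,
    pilot_n: int | None = None,
    tol: float = 0.002,
) -> float:
    """Bisection for the logistic intercept hitting the target prevalence.

    The mean of P = 1/(1+e^(alpha+base)) over a fixed pilot sample of
    ``base = beta * sum(x) + noise`` is strictly decreasing in alpha, so the
    bracket [-80, 80] is always valid.
    """
    pilot_n = pilot_n or scenario.pilot_n
    X = sample_features(specs, pilot_n, rng)
    base = scenario.beta * X.sum(axis=1) + rng.normal(0, scenario.sigma, size=pilot_n)
    if scenario.label_mechanism == "latent_threshold":
        # prevalence = P(Z < 0); the matching intercept is a quantile
        return float(-np.quantile(base, scenario.target_prev))

    def mean_p(alpha: float) -> float:
        return float(expit(-(alpha + base)).mean())

    lo, hi = -80.0, 80.0
    if not (mean_p(hi) <= scenario.target_prev <= mean_p(lo)):
        raise RuntimeError("target prevalence unreachable for this generator")
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        v = mean_p(mid)
        if abs(v - scenario.target_prev) < tol:
            return mid
        if v > scenario.target_prev:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def generate_dataset(scenario: SimulationScenario, rng: np.random.Generator) -> BinaryDataset:
    """One replicate: fresh HMP/OR per batch, tuned intercept, logistic labels."""
    specs = []
    for _ in range(scenario.p // scenario.batch):
        for attempt in range(10):
            spec = draw_batch_spec(rng, scenario.batch, scenario.or_low, scenario.or_high)
            try:
                specs.append(ipfp_fit_joint(spec))
                break
            except IPFPError:
                if attempt == 9:
                    raise
    alpha = tune_alpha(specs, scenario, rng)
    X = sample_features(specs, scenario.n, rng)
    Z = alpha + scenario.beta * X.sum(axis=1) + rng.normal(0, scenario.sigma, size=scenario.n)
    if scenario.label_mechanism == "latent_threshold":
        # the Gaussian term is the label noise: y indicates the noisy score
        # falling below the intercept-tuned cut
        y = np.where(Z < 0, POSITIVE_LABEL, "0")
    else:
        y = np.where(rng.random(scenario.n) < expit(-Z), POSITIVE_LABEL, "0")
    return BinaryDataset(X=X, y=y, class_labels=("0", POSITIVE_LABEL))


# ---------------------------------------------------------------------------
# study runner

METRICS = ("sensitivity", "specificity", "ppv", "npv", "precision")


def default_models(nbblca_candidates=(2, 3, 4), n_restarts: int = 10) -> dict:
    """The study's model registry: name -> fit(train, rng) -> predict(X)->labels."""
    from .baselines import aode_fit, aode_predict, tan_hc_fit, tan_predict
    from .data_model import RunConfig
    from .naive_bayes import nb_fit, nb_predict
    from .nb_blca import predict as nbblca_predict
    from .nb_blca import select_levels_bic

    def nb(train, rng):
        params = nb_fit(train, smoothing=1.0)
        return lambda X: nb_predict(params, X)

    def aode(train, rng):
        params = aode_fit(train)
        return lambda X: aode_predict(params, X)

    def tanhc(train, rng):
        params = tan_hc_fit(train)
        return lambda X: tan_predict(params, X)

    def nbblca_em(train, rng):
        run = RunConfig(seed=int(rng.integers(2 ** 31)), n_restarts=n_restarts)
        model, _ = select_levels_bic(train, candidates=nbblca_candidates, run=run)
        return lambda X: nbblca_predict(model, X)

    return {"nb": nb, "aode": aode, "tanhc": tanhc, "nbblca-em": nbblca_em}


def run_study(
    scenarios: list[SimulationScenario],
    models: dict,
    reps: int,
    master_seed: int = 0,
    train_fraction: float = 0.7,
    max_resamples: int = 5,
) -> pd.DataFrame:
    """Replicate the scenario-grid comparison.

    Per replicate: generate a dataset, split 70/30, fit every registered
    model on the training part and score the held-out part.  Reports
    per-scenario per-model means of the validity metrics (as percentages)
    together with Monte-Carlo standard errors and the count of replicates
    where each metric was defined.  Fit failures are logged and the
    replicate is resampled (bounded).
    """
    rows = []
    ss = np.random.SeedSequence(master_seed)
    for scen_idx, scenario in enumerate(scenarios):
        per_model = {name: {m: [] for m in METRICS} for name in models}
        resampled = 0
        rep_seqs = ss.spawn(1)[0].spawn(reps * (max_resamples + 1))
        seq_iter = iter(rep_seqs)
        done = 0
        while done < reps:
            rng = np.random.default_rng(next(seq_iter))
            try:
                data = generate_dataset(scenario, rng)
                train, test = split_train_test(data, train_fraction, rng)
                if train.y is not None and len(set(train.y)) < 2:
                    raise RuntimeError("single-class training split")
                preds = {}
                for name, spec_fn in models.items():
                    predictor = spec_fn(train, rng)
                    preds[name] = predictor(test.X)
            except Exception as exc:  # noqa: BLE001 - resample the replicate
                resampled += 1
                logger.warning("replicate resampled (%s): %s", type(exc).__name__, exc)
                if resampled > max_resamples * reps:
                    raise
                continue
            for name, y_pred in preds.items():
                report = confusion_metrics(test.y, y_pred, positive_label=POSITIVE_LABEL)
                for m in METRICS:
                    per_model[name][m].append(report[m])
            done += 1
        for name in models:
            for m in METRICS:
                vals = np.asarray(per_model[name][m], dtype=float)
                defined = vals[~np.isnan(vals)]
                rows.append(
                    {
                        "prev": scenario.target_prev,
                        "p": scenario.p,
                        "n": scenario.n,
                        "model": name,
                        "metric": m,
                        "mean": float(defined.mean()) if len(defined) else np.nan,
                        "mc_se": float(defined.std(ddof=1) / np.sqrt(len(defined)))
                        if len(defined) > 1
                        else np.nan,
                        "n_defined": int(len(defined)),
                        "reps": reps,
                        "resampled": resampled,
                    }
                )
    return pd.DataFrame(rows)
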