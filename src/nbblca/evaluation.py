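"""Validity metrics and comparison statistics for two-class prediction.

All rates are reported as percentages.  Undefined ratios (zero
denominators) are reported as NaN — never silently as 0 — so that
simulation means are taken over the replicates where a metric exists.
"precision" always duplicates the positive predictive value; both columns
are emitted for fidelity with the conventional report layout.
"""

from __future__ import annotations

import numpy as np
from scipy import stats
from statsmodels.stats.contingency_tables import mcnemar as _sm_mcnemar

from .data_model import BinaryDataset

__all__ = [
    "confusion_table",
    "confusion_metrics",
    "accuracy_inference",
    "kappa",
    "mcnemar",
    "kfold_cv",
    "full_report",
]


def _positive(labels, positive_label):
    labels = tuple(labels)
    if positive_label is None:
        return sorted(labels)[-1]  # lexicographically second by default
    return str(positive_label)


def confusion_table(y_true, y_pred, positive_label: str) -> dict:
    y_true = np.asarray(y_true).astype(str)
    y_pred = np.asarray(y_pred).astype(str)
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must have equal lengths")
    pos_t = y_true == positive_label
    pos_p = y_pred == positive_label
    return {
        "TP": int((pos_t & pos_p).sum()),
        "FP": int((~pos_t & pos_p).sum()),
        "FN": int((pos_t & ~pos_p).sum()),
        "TN": int((~pos_t & ~pos_p).sum()),
    }


def _rate(num: int, den: int) -> float:
    return 100.0 * num / den if den > 0 else np.nan


def confusion_metrics(y_true, y_pred, positive_label: str | None = None) -> dict:
    """Sensitivity, specificity, PPV, NPV, precision (= PPV), accuracy and
    balanced accuracy, each in percent, NaN where undefined."""
    y_true = np.asarray(y_true).astype(str)
    if len(set(y_true) | set(np.asarray(y_pred).astype(str))) > 2:
        raise ValueError("binary confusion metrics require a two-class label set")
    pos = _positive(set(y_true), positive_label)
    t = confusion_table(y_true, y_pred, pos)
    sens = _rate(t["TP"], t["TP"] + t["FN"])
    spec = _rate(t["TN"], t["TN"] + t["FP"])
    ppv = _rate(t["TP"], t["TP"] + t["FP"])
    npv = _rate(t["TN"], t["TN"] + t["FN"])
    acc = _rate(t["TP"] + t["TN"], sum(t.values()))
    return {
        **t,
        "positive_label": pos,
        "sensitivity": sens,
        "specificity": spec,
        "ppv": ppv,
        "npv": npv,
        "precision": ppv,
        "accuracy": acc,
        "balanced_accuracy": (sens + spec) / 2.0,
    }


def accuracy_inference(y_true, y_pred) -> dict:
    """Accuracy with exact (Clopper-Pearson) 95% CI, the no-information rate
    and the one-sided exact binomial p-value for accuracy > NIR."""
    y_true = np.asarray(y_true).astype(str)
    y_pred = np.asarray(y_pred).astype(str)
    n = len(y_true)
    if n == 0:
        raise ValueError("empty inputs")
    correct = int((y_true == y_pred).sum())
    _, counts = np.unique(y_true, return_counts=True)
    nir = counts.max() / n
    lo, hi = stats.binomtest(correct, n).proportion_ci(confidence_level=0.95, method="exact")
    p_gt_nir = stats.binomtest(correct, n, p=nir, alternative="greater").pvalue
    return {
        "accuracy": 100.0 * correct / n,
        "accuracy_ci": (100.0 * lo, 100.0 * hi),
        "nir": 100.0 * nir,
        "p_acc_gt_nir": float(p_gt_nir),
        "n": n,
    }


def kappa(y_true, y_pred) -> float:
    """Cohen's kappa; NaN when chance agreement is exactly 1 (degenerate)."""
    y_true = np.asarray(y_true).astype(str)
    y_pred = np.asarray(y_pred).astype(str)
    labels = sorted(set(y_true) | set(y_pred))
    n = len(y_true)
    p_o = (y_true == y_pred).mean()
    p_e = sum(
        (y_true == c).mean() * (y_pred == c).mean() for c in labels
    )
    if np.isclose(p_e, 1.0):
        return np.nan
    return float((p_o - p_e) / (1.0 - p_e))


def mcnemar(y_true, pred_a, pred_b) -> float:
    """McNemar's p-value for paired classifiers on the same cases.

    Exact binomial on the discordant counts (b, c); continuity-corrected
    chi-squared when b + c > 25.  b + c = 0 returns p = 1 by convention.
    """
    y_true = np.asarray(y_true).astype(str)
    a_ok = np.asarray(pred_a).astype(str) == y_true
    b_ok = np.asarray(pred_b).astype(str) == y_true
    b = int((a_ok & ~b_ok).sum())
    c = int((~a_ok & b_ok).sum())
    if b + c == 0:
        return 1.0
    table = [[int((a_ok & b_ok).sum()), b], [c, int((~a_ok & ~b_ok).sum())]]
    res = _sm_mcnemar(table, exact=(b + c) <= 25, correction=True)
    return float(res.pvalue)


def kfold_cv(model_spec, dataset: BinaryDataset, k: int = 10,
             rng: np.random.Generator | None = None,
             positive_label: str | None = None) -> dict:
    """Seeded k-fold cross-validation of a ``fit(train, rng) -> predict`` spec.

    Returns per-fold metric dictionaries and the metrics of the pooled
    confusion table.  A fold whose training part lacks a class is flagged
    and skipped (smoothed NB-family fits normally avoid this).
    """
    if k < 2 or dataset.n < k:
        raise ValueError("need 2 <= k <= N folds")
    rng = rng or np.random.default_rng(0)
    perm = rng.permutation(dataset.n)
    folds = np.array_split(perm, k)
    per_fold, pooled_true, pooled_pred, flagged = [], [], [], []
    for f, test_idx in enumerate(folds):
        mask = np.zeros(dataset.n, dtype=bool)
        mask[test_idx] = True
        train = dataset.subset(np.flatnonzero(~mask))
        test = dataset.subset(np.flatnonzero(mask))
        if train.y is not None and len(set(train.y)) < len(dataset.class_labels):
            flagged.append(f)
            continue
        predictor = model_spec(train, rng)
        y_pred = predictor(test.X)
        per_fold.append(confusion_metrics(test.y, y_pred, positive_label))
        pooled_true.append(test.y)
        pooled_pred.append(np.asarray(y_pred))
    pooled = confusion_metrics(
        np.concatenate(pooled_true), np.concatenate(pooled_pred), positive_label
    )
    return {"folds": per_fold, "pooled": pooled, "flagged_folds": flagged}


def full_report(y_true, pred, baseline_pred=None, positive_label: str | None = None) -> dict:
    """The conventional validity panel: accuracy with exact CI, NIR and its
    test, kappa, McNemar against a baseline, and the confusion rates."""
    rep = confusion_metrics(y_true, pred, positive_label)
    rep.update(accuracy_inference(y_true, pred))
    rep["kappa"] = kappa(y_true, pred)
    if baseline_pred is not None:
        rep["mcnemar_p"] = mcnemar(y_true, pred, baseline_pred)
    return rep
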