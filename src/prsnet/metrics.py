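"""Threshold-free classification metrics with bootstrap uncertainty.

``auroc`` uses the Mann-Whitney formulation (fraction of case-control
pairs ranked concordantly, ties counting one half), computed from average
ranks.  ``auprc`` is the area of the non-interpolated precision-recall
step function with tied scores grouped at one threshold.  Confidence
intervals use stratified percentile bootstrap; model comparison uses a
paired bootstrap of the auROC difference with a normal approximation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping

import numpy as np
from scipy import stats

__all__ = [
    "auroc",
    "auprc",
    "bootstrap_ci_auroc",
    "compare_auroc",
    "evaluate",
    "subgroup_eval",
    "EvalReport",
]


def _check(scores, labels):
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must have equal length")
    y = labels.astype(float)
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ValueError("labels must be binary 0/1")
    if y.min() == y.max():
        raise ValueError("both classes must be present")
    return scores, y.astype(int)


def auroc(scores, labels) -> float:
    """Mann-Whitney auROC: P(case score > control score) + 0.5 P(tie)."""
    scores, y = _check(scores, labels)
    n1 = int(y.sum())
    n0 = len(y) - n1
    ranks = stats.rankdata(scores, method="average")
    u = ranks[y == 1].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n0))


def auprc(scores, labels) -> float:
    """Area under the precision-recall step function (ties grouped)."""
    scores, y = _check(scores, labels)
    order = np.argsort(-scores, kind="mergesort")
    s = scores[order]
    t = y[order]
    # group tied thresholds
    distinct = np.flatnonzero(np.diff(s) != 0)
    bounds = np.concatenate([distinct, [len(s) - 1]])
    tp = np.cumsum(t)[bounds].astype(float)
    fp = (bounds + 1) - tp
    n_pos = y.sum()
    recall = tp / n_pos
    precision = tp / (tp + fp)
    prev_recall = np.concatenate([[0.0], recall[:-1]])
    return float(np.sum((recall - prev_recall) * precision))


def bootstrap_ci_auroc(scores, labels, B: int = 2000,
                       seed: int = 0) -> tuple[float, float]:
    """Stratified percentile bootstrap 95% interval for the auROC."""
    scores, y = _check(scores, labels)
    rng = np.random.default_rng(seed)
    pos = np.flatnonzero(y == 1)
    neg = np.flatnonzero(y == 0)
    vals = np.empty(B)
    for b in range(B):
        ip = rng.choice(pos, size=len(pos), replace=True)
        ineg = rng.choice(neg, size=len(neg), replace=True)
        idx = np.concatenate([ip, ineg])
        vals[b] = auroc(scores[idx], y[idx])
    lo, hi = np.percentile(vals, [2.5, 97.5])
    return float(lo), float(hi)


def compare_auroc(scores_a, scores_b, labels, B: int = 2000,
                  seed: int = 0) -> tuple[float, float]:
    """Paired bootstrap comparison of two models' auROCs.

    Returns ``(D, p)`` where ``D`` is the observed difference divided by
    its bootstrap standard deviation and ``p`` the two-sided normal
    p-value.  Identical score vectors give ``(0, 1)``.
    """
    scores_a = np.asarray(scores_a, dtype=float)
    scores_b = np.asarray(scores_b, dtype=float)
    _, y = _check(scores_a, labels)
    if np.array_equal(scores_a, scores_b):
        return 0.0, 1.0
    delta_obs = auroc(scores_a, y) - auroc(scores_b, y)
    rng = np.random.default_rng(seed)
    pos = np.flatnonzero(y == 1)
    neg = np.flatnonzero(y == 0)
    deltas = np.empty(B)
    for b in range(B):
        idx = np.concatenate([
            rng.choice(pos, size=len(pos), replace=True),
            rng.choice(neg, size=len(neg), replace=True),
        ])
        deltas[b] = auroc(scores_a[idx], y[idx]) - auroc(scores_b[idx], y[idx])
    sd = deltas.std(ddof=1)
    if sd == 0:
        return 0.0, 1.0
    d = float(delta_obs / sd)
    p = float(2.0 * stats.norm.sf(abs(d)))
    return d, p


@dataclass
class EvalReport:
    """Classification metrics for one sample set (or stratum)."""

    auroc: float
    auprc: float
    ci_low: float
    ci_high: float
    n_pos: int
    n_neg: int
    B: int
    seed: int
    evaluable: bool = True

    def summary(self) -> str:
        if not self.evaluable:
            return f"not evaluable (n_pos={self.n_pos}, n_neg={self.n_neg})"
        return (f"auROC {self.auroc:.4f} [{self.ci_low:.4f}, {self.ci_high:.4f}]  "
                f"auPRC {self.auprc:.4f}  (n_pos={self.n_pos}, n_neg={self.n_neg})")


def evaluate(scores, labels, B: int = 2000, seed: int = 0) -> EvalReport:
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(int)
    n_pos, n_neg = int((y == 1).sum()), int((y == 0).sum())
    if n_pos == 0 or n_neg == 0:
        return EvalReport(np.nan, np.nan, np.nan, np.nan, n_pos, n_neg, B,
                          seed, evaluable=False)
    lo, hi = bootstrap_ci_auroc(scores, y, B=B, seed=seed)
    return EvalReport(auroc(scores, y), auprc(scores, y), lo, hi,
                      n_pos, n_neg, B, seed)


def subgroup_eval(scores, labels, grouping: Mapping | np.ndarray,
                  B: int = 2000, seed: int = 0) -> dict[str, EvalReport]:
    """Metrics computed independently within each stratum.

    ``grouping`` maps each sample to exactly one stratum label (e.g. age
    band, sex, ancestry).  Strata missing a class are reported as not
    evaluable rather than raising.
    """
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(int)
    groups = np.asarray(grouping)
    if len(groups) != len(y):
        raise ValueError("grouping must assign every sample to one stratum")
    out: dict[str, EvalReport] = {}
    for g in np.unique(groups):
        m = groups == g
        if m.sum() == 0:
            warnings.warn(f"empty stratum {g!r}")
            continue
        out[str(g)] = evaluate(scores[m], y[m], B=B, seed=seed)
    return out
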