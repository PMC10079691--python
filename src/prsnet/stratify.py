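"""Gaussian-mixture stratification of risk scores into low/medium/high
groups, and association of the groups with disease status.

The mixture is a univariate K=3 (by default) Gaussian mixture fitted by
expectation-maximization with k-means initialisation.  Components are
reported sorted by ascending mean, so component 1 is the low-risk and
component 3 the high-risk distribution.  Membership probabilities default
to the posterior responsibilities, which sum to one exactly and satisfy
the "medium = 1 - low - high" identity; a heuristic ``mode="literal"``
evaluates the outer components' (mode-normalized) density heights
directly and derives the medium probability as the complement, clipping
into [0, 1] with a warning when needed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .datamodel import COVARIATE_COLUMNS, PhenotypeTable
from .assoc import logistic_irls

__all__ = [
    "GMMFit",
    "RiskGroups",
    "fit_gmm",
    "membership_probs",
    "assign_risk_groups",
    "risk_group_logistic",
]

GROUP_LABELS = ("low", "medium", "high")


@dataclass
class GMMFit:
    """Univariate Gaussian mixture, components sorted by ascending mean."""

    means: np.ndarray
    sds: np.ndarray
    weights: np.ndarray
    log_likelihood: float
    ll_trace: list[float] = field(repr=False)
    n_iter: int = 0
    converged: bool = False
    seed: int = 0

    @property
    def k(self) -> int:
        return len(self.means)

    def summary(self) -> str:
        lines = [f"{self.k}-component Gaussian mixture "
                 f"(loglik {self.log_likelihood:.3f}, "
                 f"{self.n_iter} iterations, converged={self.converged})"]
        for i, lab in enumerate(GROUP_LABELS[:self.k] if self.k == 3
                                else range(1, self.k + 1)):
            lines.append(f"  {lab}: mu={self.means[i]:+.4f} "
                         f"sigma={self.sds[i]:.4f} pi={self.weights[i]:.4f}")
        return "\n".join(lines)


def _log_pdf_matrix(x: np.ndarray, gmm_means, gmm_sds, gmm_weights) -> np.ndarray:
    return (np.log(gmm_weights)[None, :] +
            stats.norm.logpdf(x[:, None], gmm_means[None, :], gmm_sds[None, :]))


def _kmeans_1d(x: np.ndarray, k: int, rng: np.random.Generator,
               n_iter: int = 50):
    centers = np.sort(rng.choice(x, size=k, replace=False))
    for _ in range(n_iter):
        assign = np.argmin(np.abs(x[:, None] - centers[None, :]), axis=1)
        new = np.array([
            x[assign == j].mean() if np.any(assign == j) else centers[j]
            for j in range(k)
        ])
        if np.allclose(new, centers):
            break
        centers = new
    return centers, assign


def fit_gmm(scores, k: int = 3, max_iter: int = 200, tol: float = 1e-8,
            seed: int = 0, *, n_restarts: int = 5) -> GMMFit:
    """Fit a univariate Gaussian mixture by EM.

    Initialisation is k-means on the scores.  The log-likelihood trace is
    recorded and is guaranteed non-decreasing by EM theory.  If a
    component collapses (vanishing variance) the fit restarts with a new
    derived seed, up to ``n_restarts`` times, then raises.
    """
    x = np.asarray(scores, dtype=float).ravel()
    if not np.all(np.isfinite(x)):
        raise ValueError("scores must be finite")
    if len(x) < 5 * k:
        raise ValueError(f"need at least {5 * k} scores to fit {k} components")
    if k == 1:
        mu, sd = float(x.mean()), float(x.std())  # ML estimate, denominator n
        ll = float(stats.norm.logpdf(x, mu, sd).sum())
        return GMMFit(np.array([mu]), np.array([sd]), np.array([1.0]),
                      ll, [ll], 1, True, seed)
    floor = 1e-8 * max(np.ptp(x), 1.0)
    ss = np.random.SeedSequence(seed)
    for attempt, child in enumerate(ss.spawn(n_restarts)):
        rng = np.random.default_rng(child)
        centers, assign = _kmeans_1d(x, k, rng)
        means = centers.astype(float)
        sds = np.array([
            max(x[assign == j].std(), 0.1 * x.std() + 1e-12) if np.any(assign == j)
            else x.std() for j in range(k)
        ])
        weights = np.array([(assign == j).mean() for j in range(k)])
        weights = np.clip(weights, 1e-6, None)
        weights /= weights.sum()
        trace: list[float] = []
        collapsed = False
        converged = False
        it = 0
        for it in range(1, max_iter + 1):
            logp = _log_pdf_matrix(x, means, sds, weights)
            lse = np.logaddexp.reduce(logp, axis=1)
            ll = float(lse.sum())
            resp = np.exp(logp - lse[:, None])
            trace.append(ll)
            if len(trace) > 1 and abs(trace[-1] - trace[-2]) \
                    <= tol * abs(trace[-2]):
                converged = True
                break
            nk = resp.sum(axis=0)
            if nk.min() < 1e-10:
                collapsed = True
                break
            means = (resp * x[:, None]).sum(axis=0) / nk
            var = (resp * (x[:, None] - means[None, :]) ** 2).sum(axis=0) / nk
            sds = np.sqrt(var)
            if sds.min() < floor:
                collapsed = True
                break
            weights = nk / len(x)
        if collapsed:
            continue
        order = np.argsort(means)
        return GMMFit(means[order], sds[order], weights[order],
                      trace[-1], trace, it, converged, seed)
    raise RuntimeError(
        f"GMM fit collapsed in all {n_restarts} restarts (seed {seed})"
    )


def membership_probs(gmm: GMMFit, scores, mode: str = "posterior") -> np.ndarray:
    """Per-sample (p_low, p_med, p_high).

    ``posterior`` (default): responsibilities ``p_k ~ pi_k phi_k(score)``
    normalized to one — this satisfies the medium-group complement
    identity exactly.  ``literal``: p_low and p_high are the outer
    components' density heights relative to their modes, and
    ``p_med = 1 - p_low - p_high`` clipped into [0, 1].
    """
    if gmm.k != 3:
        raise ValueError("risk-group membership requires a 3-component fit")
    x = np.atleast_1d(np.asarray(scores, dtype=float))
    if mode == "posterior":
        logp = _log_pdf_matrix(x, gmm.means, gmm.sds, gmm.weights)
        lse = np.logaddexp.reduce(logp, axis=1)
        return np.exp(logp - lse[:, None])
    if mode == "literal":
        p_low = np.exp(-0.5 * ((x - gmm.means[0]) / gmm.sds[0]) ** 2)
        p_high = np.exp(-0.5 * ((x - gmm.means[2]) / gmm.sds[2]) ** 2)
        p_med = 1.0 - p_low - p_high
        if (p_med < 0).any() or (p_med > 1).any():
            warnings.warn("literal-mode medium probabilities clipped to [0,1]")
            p_med = np.clip(p_med, 0.0, 1.0)
        return np.column_stack([p_low, p_med, p_high])
    raise ValueError(f"unknown membership mode {mode!r}")


@dataclass
class RiskGroups:
    """Per-sample membership probabilities and hard low/medium/high labels."""

    probs: np.ndarray
    labels: np.ndarray

    def label_counts(self) -> dict[str, int]:
        return {lab: int((self.labels == lab).sum()) for lab in GROUP_LABELS}

    def to_frame(self, sample_ids=None) -> pd.DataFrame:
        out = pd.DataFrame(self.probs, columns=["p_low", "p_med", "p_high"])
        out["group"] = self.labels
        if sample_ids is not None:
            out.insert(0, "sample_id", list(sample_ids))
        return out


def assign_risk_groups(gmm: GMMFit, scores,
                       mode: str = "posterior") -> RiskGroups:
    """Hard labels are the argmax of the membership probabilities."""
    probs = membership_probs(gmm, scores, mode=mode)
    labels = np.asarray(GROUP_LABELS, dtype=object)[probs.argmax(axis=1)]
    return RiskGroups(probs=probs, labels=labels)


def risk_group_logistic(groups: RiskGroups, pheno: PhenotypeTable,
                        covariates: list[str] | None = None) -> pd.DataFrame:
    """Odds ratios for risk-group membership, low group as reference.

    Fits AD-vs-NC and MCI-vs-NC logistic models with the hard group label
    as a categorical predictor plus covariates.  Returns one row per
    (outcome, contrast) with OR, 95% CI and Wald p.  Contrasts whose
    groups are empty are skipped with a warning.
    """
    if covariates is None:
        covariates = list(COVARIATE_COLUMNS)
    labels = groups.labels
    rows = []
    for case_status in ("AD", "MCI"):
        y_all = pheno.binary_status(cases=(case_status,))
        keep = np.isfinite(y_all)
        y = y_all[keep]
        lab = labels[keep]
        cov = pheno.covariates(covariates)[keep] if covariates else \
            np.empty((int(keep.sum()), 0))
        if len(np.unique(y)) < 2:
            warnings.warn(f"{case_status}-vs-NC contrast skipped: one class absent")
            continue
        present = [g for g in GROUP_LABELS if np.any(lab == g)]
        if "low" not in present or len(present) < 2:
            warnings.warn(f"{case_status}-vs-NC contrasts skipped: "
                          "reference or comparison group empty")
            continue
        dummies = [g for g in ("medium", "high") if g in present]
        X = np.column_stack(
            [np.ones(len(y))]
            + [(lab == g).astype(float) for g in dummies]
            + ([cov] if cov.size else [])
        )
        coef, se, ok = logistic_irls(X, y)
        for i, g in enumerate(dummies, start=1):
            if not ok or not np.isfinite(se[i]) or se[i] == 0:
                warnings.warn(f"{case_status}-vs-NC {g}-vs-low fit unstable")
                continue
            z = coef[i] / se[i]
            rows.append({
                "outcome": f"{case_status}_vs_NC",
                "contrast": f"{g}_vs_low",
                "or": float(np.exp(coef[i])),
                "ci_low": float(np.exp(coef[i] - 1.959963984540054 * se[i])),
                "ci_high": float(np.exp(coef[i] + 1.959963984540054 * se[i])),
                "p": float(2.0 * stats.norm.sf(abs(z))),
            })
    return pd.DataFrame(rows)
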