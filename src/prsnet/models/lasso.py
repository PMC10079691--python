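"""L1-penalized logistic polygenic score.

The solver follows the classical penalized-IRLS scheme: an outer
iteratively-reweighted least-squares loop around cyclic coordinate descent
on the working response, with warm starts down a descending lambda grid.
Variant coefficients are penalized; the intercept and covariates are not.
Variant columns are standardized internally (the penalty applies on the
standardized scale) and coefficients are returned on the original scale.

Two covariate modes are provided, because the appropriate treatment of
confounders around a penalized fit is genuinely ambiguous:

* ``"unpenalized"`` (default): covariates enter the same model with zero
  penalty.
* ``"regress-out"``: a covariate-only logistic fit is obtained first and
  its linear predictor enters the lasso as a fixed offset.

The lambda retained for scoring is, among the grid values evaluated by
cross-validation, the one keeping the most nonzero variant coefficients
(i.e. the smallest grid value); the full CV path is recorded so other
rules can be applied downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from ..datamodel import COVARIATE_COLUMNS, GenotypeMatrix, PhenotypeTable
from ..assoc import logistic_irls

__all__ = ["LassoModel", "fit_lasso"]


def _soft(z: float, t: float) -> float:
    if z > t:
        return z - t
    if z < -t:
        return z + t
    return 0.0


def _cd_logistic_path(X: np.ndarray, C: np.ndarray, y: np.ndarray,
                      lambdas: np.ndarray, offset: np.ndarray,
                      *, max_outer: int = 60, tol: float = 1e-7):
    """Coordinate-descent logistic lasso along a descending lambda path.

    ``X`` holds standardized penalized columns, ``C`` unpenalized columns
    (without intercept).  Returns arrays ``betas`` (len(lambdas), p),
    ``gammas`` (covariate coefs) and ``intercepts``.
    """
    n, p = X.shape
    q = C.shape[1]
    beta = np.zeros(p)
    gamma = np.zeros(q)
    b0 = 0.0
    betas = np.empty((len(lambdas), p))
    gammas = np.empty((len(lambdas), q))
    b0s = np.empty(len(lambdas))
    xs2 = np.empty(p)
    for li, lam in enumerate(lambdas):
        for _outer in range(max_outer):
            eta = offset + b0 + X @ beta + C @ gamma
            mu = 1.0 / (1.0 + np.exp(-np.clip(eta, -35, 35)))
            w = np.maximum(mu * (1 - mu), 1e-6)
            z = eta - offset + (y - mu) / w
            # inner coordinate descent on the weighted LS problem
            r = z - (b0 + X @ beta + C @ gamma)
            sw = w.sum()
            np.einsum("ij,i,ij->j", X, w, X, out=xs2)
            for _sweep in range(100):
                max_delta = 0.0
                # intercept
                new0 = b0 + (w @ r) / sw
                r += b0 - new0
                max_delta = max(max_delta, abs(new0 - b0))
                b0 = new0
                # unpenalized covariates
                for j in range(q):
                    cj = C[:, j]
                    denom = w @ (cj * cj)
                    nj = gamma[j] + (w * r) @ cj / denom
                    r += (gamma[j] - nj) * cj
                    max_delta = max(max_delta, abs(nj - gamma[j]) *
                                    np.sqrt(denom / n))
                    gamma[j] = nj
                # penalized variants
                for j in range(p):
                    xj = X[:, j]
                    zj = (w * r) @ xj / n + xs2[j] / n * beta[j]
                    nj = _soft(zj, lam) / (xs2[j] / n)
                    if nj != beta[j]:
                        r += (beta[j] - nj) * xj
                        max_delta = max(max_delta, abs(nj - beta[j]))
                        beta[j] = nj
                if max_delta < tol:
                    break
            eta_new = offset + b0 + X @ beta + C @ gamma
            if np.max(np.abs(eta_new - eta)) < 1e-6:
                break
        betas[li] = beta
        gammas[li] = gamma
        b0s[li] = b0
    return betas, gammas, b0s


@dataclass
class LassoModel:
    """Fitted L1-logistic polygenic score model."""

    variant_ids: list[str]
    intercept: float
    variant_coefs: np.ndarray
    covariate_names: list[str]
    covariate_coefs: np.ndarray
    lambda_chosen: float
    cv_path: list[tuple[float, float, int]]  # (lambda, mean CV mse, n_nonzero)
    covariate_mode: str
    seed: int
    folds: np.ndarray = field(repr=False, default=None)
    offset_model: Optional[np.ndarray] = field(repr=False, default=None)
    _scale: tuple = field(repr=False, default=None)

    @property
    def n_nonzero(self) -> int:
        return int(np.sum(self.variant_coefs != 0))

    def score(self, geno: GenotypeMatrix,
              pheno: Optional[PhenotypeTable] = None,
              *, genetic_only: bool = True) -> np.ndarray:
        """Linear predictor; by default the genetic part only."""
        sub = geno.subset_variants(self.variant_ids).impute_mean()
        s = self.intercept + sub.dosage @ self.variant_coefs
        if not genetic_only and self.covariate_mode == "unpenalized":
            if pheno is None:
                raise ValueError("covariate scoring needs a phenotype table")
            cov = pheno.align(geno.sample_ids).covariates(self.covariate_names)
            s = s + cov @ self.covariate_coefs
        return s

    def summary(self) -> str:
        lines = [
            "L1-logistic polygenic score",
            f"  variants: {len(self.variant_ids)} "
            f"({self.n_nonzero} nonzero at lambda={self.lambda_chosen:.5g})",
            f"  covariate mode: {self.covariate_mode}",
            f"  intercept: {self.intercept:+.4f}",
        ]
        for vid, c in zip(self.variant_ids, self.variant_coefs):
            if c != 0:
                lines.append(f"    {vid:>12s}  {c:+.4f}")
        return "\n".join(lines)


def fit_lasso(geno: GenotypeMatrix, pheno: PhenotypeTable,
              covariates: Optional[list[str]] = None, *,
              nfolds: int = 5, n_lambda: int = 100,
              lambda_min_ratio: float = 1e-3,
              covariate_mode: str = "unpenalized",
              folds: Optional[np.ndarray] = None,
              seed: int = 0) -> LassoModel:
    """Fit the L1-penalized logistic score with K-fold cross-validation.

    The binary outcome is AD vs NC (MCI samples are excluded).  Fold
    labels can be supplied explicitly (for cross-tool comparability) or
    are assigned reproducibly from ``seed``.  The CV criterion recorded is
    the mean squared error between outcome and predicted probability.
    """
    if covariates is None:
        covariates = list(COVARIATE_COLUMNS)
    if covariate_mode not in ("unpenalized", "regress-out"):
        raise ValueError(f"unknown covariate mode {covariate_mode!r}")
    pheno = pheno.align(geno.sample_ids)
    y_all = pheno.binary_status()
    keep = np.isfinite(y_all)
    y = y_all[keep]
    if len(np.unique(y)) < 2:
        raise ValueError("outcome is not binary (one class absent)")
    D = geno.impute_mean().dosage[keep]
    if np.all(D.std(axis=0) == 0):
        raise ValueError("all genotype columns are constant")
    cov = pheno.covariates(covariates)[keep] if covariates else \
        np.empty((int(keep.sum()), 0))
    n, p = D.shape

    # standardize penalized columns (population sd); constant columns get
    # unit scale and can never enter the active set
    mean = D.mean(axis=0)
    sd = D.std(axis=0)
    sd = np.where(sd == 0, 1.0, sd)
    X = (D - mean) / sd
    cmean = cov.mean(axis=0) if cov.size else np.zeros(cov.shape[1])
    csd = cov.std(axis=0) if cov.size else np.ones(cov.shape[1])
    csd = np.where(csd == 0, 1.0, csd)
    C = (cov - cmean) / csd

    # offset from covariate-only logistic fit in regress-out mode
    offset = np.zeros(n)
    offset_coefs = None
    if covariate_mode == "regress-out" and C.shape[1]:
        Xc = np.column_stack([np.ones(n), C])
        coefs, _, _ = logistic_irls(Xc, y)
        offset = Xc @ coefs
        offset_coefs = coefs
        C_fit = np.empty((n, 0))
    else:
        C_fit = C

    # lambda grid from the covariate-adjusted null fit
    if covariate_mode == "regress-out" and offset_coefs is not None:
        mu0 = 1.0 / (1.0 + np.exp(-offset))  # offset already holds the null fit
    elif C_fit.shape[1]:
        Xc = np.column_stack([np.ones(n), C_fit])
        coefs, _, _ = logistic_irls(Xc, y)
        mu0 = 1.0 / (1.0 + np.exp(-(Xc @ coefs)))
    else:
        mu0 = np.full(n, y.mean())
    lam_max = np.max(np.abs(X.T @ (y - mu0))) / n
    lam_max = max(lam_max, 1e-6)
    lambdas = np.geomspace(lam_max, lam_max * lambda_min_ratio, n_lambda)

    # fold assignment
    if folds is None:
        rng = np.random.default_rng(seed)
        folds = np.empty(n, dtype=int)
        for cls in (0, 1):  # stratified, glmnet-like balanced folds
            idx = np.flatnonzero(y == cls)
            lab = np.tile(np.arange(nfolds), int(np.ceil(len(idx) / nfolds)))
            folds[idx] = rng.permutation(lab[: len(idx)])
    else:
        folds = np.asarray(folds, dtype=int)
        if len(folds) != n:
            raise ValueError("fold vector length does not match modeled samples")

    # cross-validated mse along the path
    cv_mse = np.zeros((nfolds, len(lambdas)))
    for f in range(nfolds):
        tr = folds != f
        te = ~tr
        bet, gam, b0s = _cd_logistic_path(
            X[tr], C_fit[tr], y[tr], lambdas, offset[tr]
        )
        for li in range(len(lambdas)):
            eta = offset[te] + b0s[li] + X[te] @ bet[li] + C_fit[te] @ gam[li]
            prob = 1.0 / (1.0 + np.exp(-np.clip(eta, -35, 35)))
            cv_mse[f, li] = np.mean((y[te] - prob) ** 2)

    # full-data path
    betas, gammas, b0s = _cd_logistic_path(X, C_fit, y, lambdas, offset)
    nnz = (betas != 0).sum(axis=1)
    cv_path = [(float(l), float(m), int(k))
               for l, m, k in zip(lambdas, cv_mse.mean(axis=0), nnz)]
    # the lambda retaining the most variants; ties resolve to the smallest
    # grid value (lambdas are descending, so take the last such index)
    li = int(np.flatnonzero(nnz == nnz.max())[-1])
    beta_std = betas[li]
    gamma_std = gammas[li]
    b0 = b0s[li]

    # back-transform to original scale
    variant_coefs = beta_std / sd
    intercept = b0 - float(mean @ variant_coefs)
    if covariate_mode == "unpenalized" and C.shape[1]:
        covariate_coefs = gamma_std / csd
        intercept -= float(cmean @ covariate_coefs)
    else:
        covariate_coefs = np.zeros(C.shape[1])
    return LassoModel(
        variant_ids=geno.variant_ids,
        intercept=intercept,
        variant_coefs=variant_coefs,
        covariate_names=list(covariates),
        covariate_coefs=covariate_coefs,
        lambda_chosen=float(lambdas[li]),
        cv_path=cv_path,
        covariate_mode=covariate_mode,
        seed=seed,
        folds=folds,
        offset_model=offset_coefs,
    )
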