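"""Synthetic case-control cohorts with controllable genetic architecture.

The generator emulates the statistical structure that the downstream
analyses assume: dosage genotypes organised in LD blocks, an optional
large-effect locus, additive plus epistatic liability, age/sex covariates,
case-control sampling, and latent-pathway-driven endophenotypes.

Genotypes use a Gaussian-copula construction: two latent haplotypes per
sample are drawn from block-wise equi-correlated Gaussians and thresholded
at the MAF quantile.  The latent correlation is calibrated numerically so
that the *dosage* correlation within a block matches the requested target
(thresholding attenuates correlation, so the latent value is larger).

Epistatic terms use centered dosage products ``(g_j - mean) * (g_k - mean)``
so that marginal per-variant effects are exactly zero by construction.

A single global seed governs all draws through `numpy.random.SeedSequence`
stream splitting, so the genotype, phenotype and endophenotype stages are
reproducible independently of call order.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .datamodel import GenotypeMatrix, PhenotypeTable, Variant

__all__ = [
    "SimSpec",
    "SimCohort",
    "simulate_genotypes",
    "simulate_phenotypes",
    "simulate_endophenotypes",
    "simulate_cohort",
]

# fixed child-stream indices of the global SeedSequence
_STREAM_GENO, _STREAM_PHENO, _STREAM_ENDO, _STREAM_ANNOT = 0, 1, 2, 3


@dataclass
class SimSpec:
    """Full description of a synthetic cohort.

    ``ld_blocks`` is a list of ``(block_size, target_r)`` pairs whose sizes
    must sum to ``n_variants``; ``target_r`` is the desired pairwise dosage
    correlation within the block.  ``additive_effects`` and
    ``epistatic_pairs`` are on the log-odds (liability) scale.
    ``pathway_map`` assigns each variant to one of ``n_pathways`` latent
    pathways (default: round-robin over 5), and ``endophenotype_loadings``
    (biomarkers x pathways) mixes pathway burdens into biomarker means.
    """

    n_samples: int = 2000
    n_variants: int = 50
    maf_range: tuple[float, float] = (0.1, 0.5)
    ld_blocks: Optional[list[tuple[int, float]]] = None
    additive_effects: dict[int, float] = field(default_factory=dict)
    large_effect: Optional[tuple[int, float]] = None
    epistatic_pairs: list[tuple[int, int, float]] = field(default_factory=list)
    n_pathways: int = 5
    pathway_map: Optional[dict[int, int]] = None
    covariate_effects: tuple[float, float] = (0.0, 0.0)  # (beta_age per SD, beta_sex)
    case_fraction: float = 0.5
    endophenotype_loadings: Optional[np.ndarray] = None  # biomarkers x pathways
    endophenotype_noise_sd: float = 1.0
    liability_noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must satisfy 0 < low <= high <= 0.5")
        if self.ld_blocks is None:
            self.ld_blocks = [(1, 0.0)] * self.n_variants
        if sum(b for b, _ in self.ld_blocks) != self.n_variants:
            raise ValueError("ld_blocks sizes must sum to n_variants")
        if self.n_pathways < 1:
            raise ValueError("n_pathways must be >= 1")
        if self.pathway_map is None:
            self.pathway_map = {j: j % self.n_pathways for j in range(self.n_variants)}
        for j, k, _ in self.epistatic_pairs:
            if not (0 <= j < self.n_variants and 0 <= k < self.n_variants):
                raise ValueError(f"epistatic pair ({j},{k}) references missing variant")
        if not (0 < self.case_fraction < 1):
            raise ValueError("case_fraction must lie in (0,1)")
        if self.endophenotype_loadings is not None:
            lam = np.atleast_2d(np.asarray(self.endophenotype_loadings, dtype=float))
            if lam.shape[1] != self.n_pathways:
                raise ValueError(
                    f"endophenotype_loadings has {lam.shape[1]} columns, "
                    f"expected n_pathways={self.n_pathways}"
                )
            self.endophenotype_loadings = lam

    def all_betas(self) -> np.ndarray:
        beta = np.zeros(self.n_variants)
        for j, b in self.additive_effects.items():
            beta[j] = b
        if self.large_effect is not None:
            j, b = self.large_effect
            beta[j] = b
        return beta


@dataclass
class SimCohort:
    genotypes: GenotypeMatrix
    phenotypes: PhenotypeTable
    truth: dict

    @property
    def spec(self) -> SimSpec:
        return self.truth["spec"]


def _latent_rho(target_r: float, maf: float) -> float:
    """Latent Gaussian correlation giving dosage correlation `target_r`.

    For thresholded indicators X = 1{Z < q} with q = Phi^{-1}(maf), the
    correlation of the indicators (and hence of two-haplotype dosages)
    is (P11 - maf^2) / (maf (1 - maf)) where P11 is the bivariate normal
    orthant mass; invert numerically.
    """
    if target_r <= 0:
        return 0.0
    q = stats.norm.ppf(maf)
    denom = maf * (1 - maf)

    def attenuated(rho: float) -> float:
        p11 = stats.multivariate_normal.cdf(
            [q, q], mean=[0, 0], cov=[[1, rho], [rho, 1]]
        )
        return (p11 - maf**2) / denom

    if target_r >= attenuated(0.9999):
        return 0.9999
    return optimize.brentq(lambda r: attenuated(r) - target_r, 0.0, 0.9999,
                           xtol=1e-4)


def simulate_genotypes(spec: SimSpec) -> GenotypeMatrix:
    """Draw dosage genotypes with block-wise LD via Gaussian thresholding."""
    ss = np.random.SeedSequence(spec.seed)
    children = ss.spawn(4)
    rng = np.random.default_rng(children[_STREAM_GENO])
    ann_rng = np.random.default_rng(children[_STREAM_ANNOT])

    # one MAF per block (shared within a block) keeps the threshold
    # calibration of the latent correlation exact
    block_mafs = rng.uniform(*spec.maf_range, size=len(spec.ld_blocks))
    mafs = np.repeat(block_mafs, [b for b, _ in spec.ld_blocks])
    dosage = np.empty((spec.n_samples, spec.n_variants))
    variants: list[Variant] = []
    start = 0
    pos = 1
    for b, (size, target_r) in enumerate(spec.ld_blocks):
        block_maf = float(np.mean(mafs[start:start + size]))
        rho = _latent_rho(target_r, block_maf) if size > 1 else 0.0
        cols = np.zeros((spec.n_samples, size))
        for _hap in range(2):
            shared = rng.standard_normal((spec.n_samples, 1))
            indiv = rng.standard_normal((spec.n_samples, size))
            z = math.sqrt(rho) * shared + math.sqrt(1.0 - rho) * indiv
            thresh = stats.norm.ppf(mafs[start:start + size])
            cols += (z < thresh).astype(float)
        dosage[:, start:start + size] = cols
        for i in range(size):
            j = start + i
            ann = {
                "coding": int(ann_rng.random() < 0.15),
                "utr": int(ann_rng.random() < 0.15),
                "histone": int(ann_rng.poisson(2.0)),
                "open_chromatin": int(ann_rng.poisson(1.0)),
                "polymerase": int(ann_rng.poisson(0.5)),
                "tfbs": int(ann_rng.poisson(1.5)),
            }
            variants.append(Variant(
                id=f"rs{j + 1:06d}", chrom="1", pos=pos,
                effect_allele="A", other_allele="G",
                locus_label=f"locus{b + 1}", annotations=ann,
            ))
            pos += 5_000
        start += size
        pos += 2_000_000  # blocks far apart so clumping windows separate them
    sample_ids = [f"S{i + 1:05d}" for i in range(spec.n_samples)]
    return GenotypeMatrix(sample_ids, variants, dosage)


def _liability(dosage: np.ndarray, age_z: np.ndarray, sex: np.ndarray,
               spec: SimSpec, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    beta = spec.all_betas()
    genetic = dosage @ beta
    centered = dosage - dosage.mean(axis=0, keepdims=True)
    for j, k, gamma in spec.epistatic_pairs:
        genetic = genetic + gamma * centered[:, j] * centered[:, k]
    b_age, b_sex = spec.covariate_effects
    eps = rng.normal(0.0, spec.liability_noise_sd, size=len(dosage))
    liability = genetic + b_age * age_z + b_sex * sex + eps
    return liability, genetic


def simulate_phenotypes(geno: GenotypeMatrix, spec: SimSpec) -> tuple[PhenotypeTable, dict]:
    """Liability-threshold phenotypes with case-control sampling.

    Status is drawn Bernoulli(logistic(L - mean L)); the cohort is then
    case-control subsampled to ``spec.case_fraction`` (error if the drawn
    prevalence cannot reach it).  Samples not retained are discarded, so
    the returned table may have fewer rows than the input genotypes; use
    :func:`simulate_cohort` to get genotypes and phenotypes already aligned.
    """
    ss = np.random.SeedSequence(spec.seed)
    rng = np.random.default_rng(ss.spawn(4)[_STREAM_PHENO])
    n = geno.n_samples
    age = rng.uniform(55.0, 90.0, size=n)
    age_z = (age - 72.5) / 10.1  # uniform [55,90] has sd ~10.1
    sex = rng.integers(0, 2, size=n).astype(float)
    dosage = geno.impute_mean().dosage
    liability, genetic = _liability(dosage, age_z, sex, spec, rng)
    prob = 1.0 / (1.0 + np.exp(-(liability - liability.mean())))
    case = rng.random(n) < prob

    idx_case = np.flatnonzero(case)
    idx_ctrl = np.flatnonzero(~case)
    f = spec.case_fraction
    n_keep = int(min(len(idx_case) / f, len(idx_ctrl) / (1 - f)))
    n_case = int(round(n_keep * f))
    n_ctrl = n_keep - n_case
    if n_case < 1 or n_ctrl < 1:
        achievable = len(idx_case) / max(n, 1)
        raise ValueError(
            f"case fraction {f} unreachable; simulated prevalence {achievable:.3f}"
        )
    keep = np.concatenate([
        rng.permutation(idx_case)[:n_case],
        rng.permutation(idx_ctrl)[:n_ctrl],
    ])
    keep.sort()

    # a slice of controls is relabelled MCI to exercise the 3-level status
    status = np.where(case, "AD", "NC").astype(object)
    nc_kept = [i for i in keep if not case[i]]
    n_mci = len(nc_kept) // 10
    for i in nc_kept[:n_mci]:
        status[i] = "MCI"

    pcs = rng.normal(0.0, 1.0, size=(n, 5))
    beta = spec.all_betas()
    burdens = np.zeros((n, spec.n_pathways))
    for j in range(spec.n_variants):
        k = spec.pathway_map[j]
        burdens[:, k] += beta[j] * dosage[:, j]

    table = pd.DataFrame({
        "sample_id": np.asarray(geno.sample_ids, dtype=object)[keep],
        "status": status[keep],
        "age": age[keep],
        "sex": sex[keep],
        **{f"pc{i + 1}": pcs[keep, i] for i in range(5)},
    })
    truth = {
        "spec": spec,
        "beta": beta,
        "gamma": list(spec.epistatic_pairs),
        "liability": liability[keep],
        "genetic_liability": genetic[keep],
        "pathway_burdens": burdens[keep],
        "kept_index": keep,
    }
    return PhenotypeTable(table), truth


def simulate_endophenotypes(truth: dict, spec: SimSpec,
                            pheno: PhenotypeTable) -> PhenotypeTable:
    """Mix pathway burdens into biomarker columns: ``b_m = Lambda_m . B + noise``."""
    lam = spec.endophenotype_loadings
    if lam is None:
        return pheno
    ss = np.random.SeedSequence(spec.seed)
    rng = np.random.default_rng(ss.spawn(4)[_STREAM_ENDO])
    burdens = truth["pathway_burdens"]
    table = pheno.table.copy()
    for m in range(lam.shape[0]):
        noise = rng.normal(0.0, spec.endophenotype_noise_sd, size=len(table))
        table[f"biomarker{m + 1}"] = burdens @ lam[m] + noise
    return PhenotypeTable(table)


def simulate_cohort(spec: SimSpec) -> SimCohort:
    """Genotypes + phenotypes + endophenotypes, aligned to the kept samples."""
    geno = simulate_genotypes(spec)
    pheno, truth = simulate_phenotypes(geno, spec)
    pheno = simulate_endophenotypes(truth, spec, pheno)
    geno = geno.subset_samples(pheno.sample_ids)
    return SimCohort(genotypes=geno, phenotypes=pheno, truth=truth)
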