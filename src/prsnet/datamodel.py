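"""Core domain containers for genotype, summary-statistic, phenotype and
expression data.

All containers are thin, validated wrappers around :mod:`numpy` arrays and
:mod:`pandas` frames.  Dosages are expected effect-allele counts in
``[0, 2]``; missing genotypes are carried as ``NaN`` and only imputed (per
variant, to the mean) immediately before model fitting, so that file I/O is
lossless.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Variant",
    "GenotypeMatrix",
    "SummaryStats",
    "PhenotypeTable",
    "ExpressionMatrix",
    "STATUS_LEVELS",
]

STATUS_LEVELS = ("NC", "MCI", "AD")

_CHROMS = {str(c) for c in range(1, 23)} | {"X"}

#: annotation keys carried per variant (counts of regulatory events plus
#: coding/UTR flags); used as node features by the graph classifier.
ANNOTATION_KEYS = (
    "coding",
    "utr",
    "histone",
    "open_chromatin",
    "polymerase",
    "tfbs",
)


@dataclass(frozen=True)
class Variant:
    """A biallelic variant keyed by rsID.

    Positions are 1-based as in VCF.  ``locus_label`` groups variants into
    loci/genes (used for sizing the locus-structured network layers);
    ``annotations`` carries non-negative functional-annotation counts.
    """

    id: str
    chrom: str
    pos: int
    effect_allele: str
    other_allele: str
    locus_label: str = ""
    annotations: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"variant {self.id}: pos must be >= 1, got {self.pos}")
        if self.effect_allele == self.other_allele:
            raise ValueError(f"variant {self.id}: effect allele equals other allele")
        chrom = str(self.chrom).removeprefix("chr")
        object.__setattr__(self, "chrom", chrom)
        if chrom not in _CHROMS:
            raise ValueError(f"variant {self.id}: unsupported chromosome {chrom!r}")
        for key, val in self.annotations.items():
            if val < 0:
                raise ValueError(f"variant {self.id}: annotation {key} < 0")

    @property
    def is_strand_ambiguous(self) -> bool:
        """True for A/T and G/C pairs, whose strand cannot be resolved."""
        pair = frozenset((self.effect_allele.upper(), self.other_allele.upper()))
        return pair in (frozenset("AT"), frozenset("GC"))

    def annotation_vector(self, keys: Sequence[str] = ANNOTATION_KEYS) -> np.ndarray:
        return np.array([float(self.annotations.get(k, 0.0)) for k in keys])


class GenotypeMatrix:
    """Samples x variants dosage matrix with variant metadata.

    Parameters
    ----------
    sample_ids : sequence of unique sample identifiers
    variants : ordered sequence of :class:`Variant`; column ``j`` of
        ``dosage`` counts copies of ``variants[j].effect_allele``
    dosage : (n_samples, n_variants) float array; missing entries are NaN
    """

    def __init__(self, sample_ids, variants, dosage) -> None:
        sample_ids = list(map(str, sample_ids))
        if len(set(sample_ids)) != len(sample_ids):
            raise ValueError("sample ids are not unique")
        variants = list(variants)
        ids = [v.id for v in variants]
        if len(set(ids)) != len(ids):
            raise ValueError("variant ids are not unique")
        dosage = np.asarray(dosage, dtype=float)
        if dosage.shape != (len(sample_ids), len(variants)):
            raise ValueError(
                f"dosage shape {dosage.shape} does not match "
                f"{len(sample_ids)} samples x {len(variants)} variants"
            )
        finite = dosage[np.isfinite(dosage)]
        if finite.size and (finite.min() < 0 or finite.max() > 2):
            raise ValueError("non-missing dosages must lie in [0, 2]")
        self.sample_ids = sample_ids
        self.variants = variants
        self.dosage = dosage

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    @property
    def variant_ids(self) -> list[str]:
        return [v.id for v in self.variants]

    def eaf(self) -> np.ndarray:
        """Effect-allele frequency per variant: mean dosage / 2 (missing skipped)."""
        with np.errstate(invalid="ignore"):
            return np.nanmean(self.dosage, axis=0) / 2.0

    def impute_mean(self) -> "GenotypeMatrix":
        """Return a copy with missing dosages replaced by the per-variant mean.

        All-missing columns impute to 0.
        """
        d = self.dosage.copy()
        mask = ~np.isfinite(d)
        if mask.any():
            col_mean = np.where(
                np.all(mask, axis=0), 0.0, np.nanmean(np.where(mask, np.nan, d), axis=0)
            )
            d[mask] = np.take(col_mean, np.nonzero(mask)[1])
        return GenotypeMatrix(self.sample_ids, self.variants, d)

    def subset_variants(self, ids: Sequence[str]) -> "GenotypeMatrix":
        index = {v: j for j, v in enumerate(self.variant_ids)}
        missing = [i for i in ids if i not in index]
        if missing:
            raise KeyError(f"variants absent from genotypes: {missing}")
        cols = [index[i] for i in ids]
        return GenotypeMatrix(
            self.sample_ids, [self.variants[j] for j in cols], self.dosage[:, cols]
        )

    def subset_samples(self, keep: Sequence[str]) -> "GenotypeMatrix":
        index = {s: i for i, s in enumerate(self.sample_ids)}
        rows = [index[s] for s in keep]
        return GenotypeMatrix(keep, self.variants, self.dosage[rows])

    def equals(self, other: "GenotypeMatrix", atol: float = 0.0) -> bool:
        return (
            self.sample_ids == other.sample_ids
            and self.variant_ids == other.variant_ids
            and np.allclose(self.dosage, other.dosage, atol=atol, equal_nan=True)
        )

    def __repr__(self) -> str:
        return f"GenotypeMatrix({self.n_samples} samples x {self.n_variants} variants)"


_SUMSTAT_COLUMNS = ["id", "chrom", "pos", "effect_allele", "other_allele",
                    "beta", "se", "p", "eaf", "n"]


class SummaryStats:
    """Per-variant GWAS summary statistics.

    Wraps a :class:`pandas.DataFrame` with canonical columns ``id, chrom,
    pos, effect_allele, other_allele, beta, se, p, eaf, n``.  Invariants:
    ``se > 0``, ``p`` in (0, 1], unique ids.  Extra columns are preserved
    opaquely.
    """

    def __init__(self, table: pd.DataFrame) -> None:
        missing = [c for c in _SUMSTAT_COLUMNS if c not in table.columns]
        if missing:
            raise ValueError(f"summary statistics missing columns: {missing}")
        table = table.reset_index(drop=True).copy()
        if table["id"].duplicated().any():
            dup = table.loc[table["id"].duplicated(), "id"].tolist()
            raise ValueError(f"duplicate variant ids in summary stats: {dup[:5]}")
        if len(table):
            if (table["se"] <= 0).any():
                raise ValueError("summary stats contain se <= 0")
            bad_p = (table["p"] <= 0) | (table["p"] > 1)
            if bad_p.any():
                raise ValueError("summary stats contain p outside (0, 1]")
        self.table = table

    def __len__(self) -> int:
        return len(self.table)

    @property
    def ids(self) -> list[str]:
        return self.table["id"].tolist()

    def subset(self, ids: Sequence[str]) -> "SummaryStats":
        sub = self.table.set_index("id").loc[list(ids)].reset_index()
        return SummaryStats(sub[self.table.columns])

    def lookup(self, column: str) -> pd.Series:
        return self.table.set_index("id")[column]

    def __repr__(self) -> str:
        return f"SummaryStats({len(self)} variants)"


_PHENO_REQUIRED = ["sample_id", "status", "age", "sex", "pc1", "pc2", "pc3", "pc4", "pc5"]
COVARIATE_COLUMNS = ["age", "sex", "pc1", "pc2", "pc3", "pc4", "pc5"]


class PhenotypeTable:
    """Sample-level phenotypes and covariates.

    ``status`` is one of NC/MCI/AD; ``sex`` is 0/1; ``pc1``-``pc5`` are the
    top genetic principal components.  Additional continuous columns (plasma
    biomarkers, cognitive scores, intracranial volume, ...) are treated as
    endophenotypes.
    """

    def __init__(self, table: pd.DataFrame) -> None:
        missing = [c for c in _PHENO_REQUIRED if c not in table.columns]
        if missing:
            raise ValueError(f"phenotype table missing columns: {missing}")
        table = table.reset_index(drop=True).copy()
        table["sample_id"] = table["sample_id"].astype(str)
        if table["sample_id"].duplicated().any():
            raise ValueError("duplicate sample ids in phenotype table")
        bad = set(table["status"]) - set(STATUS_LEVELS)
        if bad:
            raise ValueError(f"unknown status levels: {sorted(bad)}")
        self.table = table

    def __len__(self) -> int:
        return len(self.table)

    @property
    def sample_ids(self) -> list[str]:
        return self.table["sample_id"].tolist()

    @property
    def status(self) -> pd.Series:
        return self.table["status"]

    @property
    def endophenotype_columns(self) -> list[str]:
        return [c for c in self.table.columns if c not in _PHENO_REQUIRED]

    def covariates(self, columns: Sequence[str] = COVARIATE_COLUMNS) -> np.ndarray:
        sub = self.table[list(columns)]
        if sub.isna().any().any():
            raise ValueError("covariate columns contain missing values")
        return sub.to_numpy(dtype=float)

    def binary_status(self, cases=("AD",), controls=("NC",)) -> np.ndarray:
        """0/1 outcome restricted to samples in `cases` or `controls`;
        other samples (e.g. MCI by default) get NaN."""
        y = np.full(len(self), np.nan)
        y[self.status.isin(cases).to_numpy()] = 1.0
        y[self.status.isin(controls).to_numpy()] = 0.0
        return y

    def align(self, sample_ids: Sequence[str]) -> "PhenotypeTable":
        sub = self.table.set_index("sample_id").loc[list(map(str, sample_ids))]
        return PhenotypeTable(sub.reset_index())

    def __repr__(self) -> str:
        counts = self.status.value_counts().to_dict()
        return f"PhenotypeTable({len(self)} samples, status={counts})"


class ExpressionMatrix:
    """Genes x cell types expression matrix (FPKM, non-negative)."""

    def __init__(self, table: pd.DataFrame) -> None:
        if table.index.duplicated().any():
            raise ValueError("duplicate gene ids in expression matrix")
        if (table.to_numpy(dtype=float) < 0).any():
            raise ValueError("expression values must be non-negative")
        self.table = table.astype(float)

    @property
    def genes(self) -> list[str]:
        return self.table.index.tolist()

    @property
    def cell_types(self) -> list[str]:
        return self.table.columns.tolist()

    def __repr__(self) -> str:
        return (
            f"ExpressionMatrix({len(self.genes)} genes x "
            f"{len(self.cell_types)} cell types)"
        )
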