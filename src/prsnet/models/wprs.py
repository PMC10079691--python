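"""Weighted polygenic risk score: elementwise product of allele dosage and
GWAS effect size, summed per sample, with no normalization."""

from __future__ import annotations

import numpy as np

from ..datamodel import GenotypeMatrix, SummaryStats

__all__ = ["WeightedPRSModel", "weighted_prs"]


class WeightedPRSModel:
    """A set of variant ids with log-odds weights.

    Build from harmonized GWAS summary statistics with
    :meth:`from_summary_stats`, or directly from parallel id/weight
    sequences.
    """

    def __init__(self, variant_ids, weights) -> None:
        variant_ids = [str(v) for v in variant_ids]
        weights = np.asarray(weights, dtype=float)
        if len(variant_ids) != len(weights):
            raise ValueError("ids and weights must have equal length")
        if len(set(variant_ids)) != len(variant_ids):
            raise ValueError("variant ids must be unique")
        if not np.all(np.isfinite(weights)):
            raise ValueError("weights must be finite")
        self.variant_ids = variant_ids
        self.weights = weights

    @classmethod
    def from_summary_stats(cls, stats: SummaryStats,
                           ids=None) -> "WeightedPRSModel":
        t = stats.table.dropna(subset=["beta"])
        if ids is not None:
            t = t.set_index("id").loc[list(ids)].reset_index()
        return cls(t["id"].tolist(), t["beta"].to_numpy(float))

    def score(self, geno: GenotypeMatrix) -> np.ndarray:
        """Per-sample score ``sum_i w_i d_si``; missing dosages mean-imputed."""
        missing = [v for v in self.variant_ids if v not in set(geno.variant_ids)]
        if missing:
            raise KeyError(f"model variants absent from genotypes: {missing[:5]}")
        sub = geno.subset_variants(self.variant_ids).impute_mean()
        return sub.dosage @ self.weights

    def __repr__(self) -> str:
        return f"WeightedPRSModel({len(self.variant_ids)} variants)"


def weighted_prs(geno: GenotypeMatrix, model: WeightedPRSModel) -> np.ndarray:
    """Functional form of :meth:`WeightedPRSModel.score`."""
    return model.score(geno)
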