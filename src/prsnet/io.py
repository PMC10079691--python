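"""Readers, writers and effect-allele harmonization.

Supported text formats
----------------------
* VCF 4.x genotype input (``DS`` dosage field preferred, ``GT`` fallback),
  read through :mod:`cyvcf2`.
* Tab-delimited dosage table: first column ``sample_id``, one column per
  variant named by rsID.  Variant metadata (chrom/pos/alleles) travels in a
  side-car ``<path>.variants.tsv`` written by :func:`write_dosage_table`.
* GWAS summary statistics TSV with case-insensitive header aliases
  (SNP/CHR/POS/EA/OA/BETA/SE/P/EAF[/N]).
* Phenotype TSV and gene x cell-type expression TSV.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .datamodel import (
    ExpressionMatrix,
    GenotypeMatrix,
    PhenotypeTable,
    SummaryStats,
    Variant,
    _SUMSTAT_COLUMNS,
)

__all__ = [
    "read_dosage",
    "write_dosage_table",
    "read_summary_stats",
    "write_summary_stats",
    "read_phenotypes",
    "write_phenotypes",
    "read_expression",
    "write_expression",
    "harmonize",
    "HarmonizeReport",
]

MISSING = "NA"

# header aliases, lower-cased; the canonical name is the dict value
_SUMSTAT_ALIASES = {
    "snp": "id", "rsid": "id", "id": "id", "variant_id": "id", "markername": "id",
    "chr": "chrom", "chrom": "chrom", "chromosome": "chrom",
    "pos": "pos", "bp": "pos", "position": "pos",
    "ea": "effect_allele", "effect_allele": "effect_allele", "a1": "effect_allele",
    "oa": "other_allele", "other_allele": "other_allele", "a2": "other_allele",
    "beta": "beta", "effect": "beta", "b": "beta",
    "se": "se", "stderr": "se",
    "p": "p", "pval": "p", "pvalue": "p", "p_value": "p",
    "eaf": "eaf", "freq": "eaf", "af": "eaf",
    "n": "n", "nsample": "n",
}
_MANDATORY = ["id", "chrom", "pos", "effect_allele", "other_allele",
              "beta", "se", "p", "eaf"]


def read_dosage(path, format: str = "dosage-table") -> GenotypeMatrix:
    """Read genotype dosages from a VCF or a tab-delimited dosage table.

    For VCF input the ``DS`` FORMAT field is used when present; otherwise
    dosage is the ALT-allele count of the ``GT`` call.  Missing genotypes
    become NaN, never silent zeros.  Multi-allelic records are rejected and
    counted in a warning.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "vcf":
        return _read_vcf(path)
    if format == "dosage-table":
        return _read_dosage_table(path)
    raise ValueError(f"unknown genotype format {format!r}")


def _read_vcf(path: Path) -> GenotypeMatrix:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    sample_ids = list(vcf.samples)
    variants: list[Variant] = []
    columns: list[np.ndarray] = []
    n_multiallelic = 0
    for rec in vcf:
        if len(rec.ALT) != 1:
            n_multiallelic += 1
            continue
        try:
            var = Variant(
                id=rec.ID or f"{rec.CHROM}:{rec.POS}",
                chrom=str(rec.CHROM),
                pos=rec.POS,
                effect_allele=rec.ALT[0],
                other_allele=rec.REF,
            )
        except ValueError as exc:
            raise ValueError(f"malformed VCF record at {rec.CHROM}:{rec.POS}: {exc}")
        ds = None
        try:
            ds = rec.format("DS")
        except KeyError:
            ds = None
        if ds is not None:
            col = np.asarray(ds, dtype=float).reshape(-1)
            col = np.where(col < -0.5, np.nan, col)  # cyvcf2 missing sentinel
        else:
            # gt_types: 0=hom-ref 1=het 2=unknown 3=hom-alt
            gt = rec.gt_types.astype(float)
            col = np.select([gt == 0, gt == 1, gt == 3], [0.0, 1.0, 2.0], np.nan)
        finite = col[np.isfinite(col)]
        if finite.size and (finite.min() < 0 or finite.max() > 2):
            raise ValueError(
                f"dosage outside [0,2] in VCF record {rec.CHROM}:{rec.POS}"
            )
        variants.append(var)
        columns.append(col)
    if n_multiallelic:
        warnings.warn(f"skipped {n_multiallelic} multi-allelic VCF records")
    dosage = np.column_stack(columns) if columns else np.empty((len(sample_ids), 0))
    return GenotypeMatrix(sample_ids, variants, dosage)


def _read_dosage_table(path: Path) -> GenotypeMatrix:
    table = pd.read_csv(path, sep="\t", na_values=[MISSING], dtype={0: str})
    if table.columns[0] != "sample_id":
        raise ValueError(
            f"{path}: first column must be 'sample_id', got {table.columns[0]!r}"
        )
    sample_ids = table["sample_id"].tolist()
    dosage = table.iloc[:, 1:].to_numpy(dtype=float)
    meta_path = path.with_suffix(path.suffix + ".variants.tsv")
    variants = []
    if meta_path.exists():
        meta = pd.read_csv(meta_path, sep="\t", dtype=str).set_index("id")
        for vid in table.columns[1:]:
            row = meta.loc[vid]
            ann = {
                k: float(row[k])
                for k in meta.columns
                if k not in ("chrom", "pos", "effect_allele", "other_allele",
                             "locus_label")
            }
            variants.append(Variant(
                id=vid, chrom=row["chrom"], pos=int(row["pos"]),
                effect_allele=row["effect_allele"], other_allele=row["other_allele"],
                locus_label=row.get("locus_label", ""), annotations=ann,
            ))
    else:
        # bare table: fabricate placeholder metadata, one variant per column
        for j, vid in enumerate(table.columns[1:]):
            variants.append(Variant(id=vid, chrom="1", pos=j + 1,
                                    effect_allele="A", other_allele="G"))
    return GenotypeMatrix(sample_ids, variants, dosage)


def write_dosage_table(geno: GenotypeMatrix, path) -> None:
    """Write a dosage table plus a ``.variants.tsv`` metadata side-car."""
    path = Path(path)
    table = pd.DataFrame(geno.dosage, columns=geno.variant_ids)
    table.insert(0, "sample_id", geno.sample_ids)
    table.to_csv(path, sep="\t", index=False, na_rep=MISSING)
    ann_keys = sorted({k for v in geno.variants for k in v.annotations})
    rows = []
    for v in geno.variants:
        row = {
            "id": v.id, "chrom": v.chrom, "pos": v.pos,
            "effect_allele": v.effect_allele, "other_allele": v.other_allele,
            "locus_label": v.locus_label,
        }
        for k in ann_keys:
            row[k] = v.annotations.get(k, 0)
        rows.append(row)
    pd.DataFrame(rows).to_csv(
        path.with_suffix(path.suffix + ".variants.tsv"), sep="\t", index=False
    )


def read_summary_stats(path) -> SummaryStats:
    """Read a GWAS summary-statistics TSV.

    Header detection is alias-based and case-insensitive; unknown columns
    are preserved opaquely.  Rows violating ``se > 0`` or ``p`` in (0, 1]
    are dropped with a warning reporting the count.
    """
    path = Path(path)
    table = pd.read_csv(path, sep="\t")
    rename = {}
    for col in table.columns:
        canon = _SUMSTAT_ALIASES.get(col.strip().lower())
        if canon is not None and canon not in rename.values():
            rename[col] = canon
    table = table.rename(columns=rename)
    missing = [c for c in _MANDATORY if c not in table.columns]
    if missing:
        raise ValueError(f"{path}: missing mandatory columns {missing}")
    if "n" not in table.columns:
        table["n"] = np.nan
    if len(table) == 0:
        warnings.warn(f"{path}: no data rows after header")
        return SummaryStats(table.reindex(columns=_SUMSTAT_COLUMNS))
    ok = (table["se"] > 0) & (table["p"] > 0) & (table["p"] <= 1)
    n_rejected = int((~ok).sum())
    if n_rejected:
        warnings.warn(f"{path}: rejected {n_rejected} rows with invalid se or p")
        table = table[ok]
    table["id"] = table["id"].astype(str)
    table["chrom"] = table["chrom"].astype(str).str.removeprefix("chr")
    extra = [c for c in table.columns if c not in _SUMSTAT_COLUMNS]
    return SummaryStats(table[_SUMSTAT_COLUMNS + extra].reset_index(drop=True))


def write_summary_stats(stats: SummaryStats, path) -> None:
    out = stats.table.rename(columns={
        "id": "SNP", "chrom": "CHR", "pos": "POS", "effect_allele": "EA",
        "other_allele": "OA", "beta": "BETA", "se": "SE", "p": "P",
        "eaf": "EAF", "n": "N",
    })
    out.to_csv(path, sep="\t", index=False, na_rep=MISSING)


def read_phenotypes(path) -> PhenotypeTable:
    return PhenotypeTable(pd.read_csv(path, sep="\t", na_values=[MISSING]))


def write_phenotypes(pheno: PhenotypeTable, path) -> None:
    pheno.table.to_csv(path, sep="\t", index=False, na_rep=MISSING)


def read_expression(path) -> ExpressionMatrix:
    table = pd.read_csv(path, sep="\t", index_col=0)
    return ExpressionMatrix(table)


def write_expression(expr: ExpressionMatrix, path) -> None:
    expr.table.to_csv(path, sep="\t", index_label="gene")


@dataclass
class HarmonizeReport:
    n_kept: int = 0
    n_flipped: int = 0
    n_dropped_ambiguous: int = 0
    n_dropped_mismatch: int = 0
    flipped_ids: list = field(default_factory=list)
    dropped_ids: list = field(default_factory=list)


def harmonize(geno: GenotypeMatrix, stats: SummaryStats, *,
              drop_ambiguous: bool = True) -> tuple[GenotypeMatrix, SummaryStats, HarmonizeReport]:
    """Align genotype dosages to the summary-statistic effect alleles.

    Variants are matched by rsID.  If the counted (genotype effect) allele
    equals the statistics' effect allele the dosage is kept; if it equals
    the other allele the dosage is flipped ``d -> 2 - d``; strand-ambiguous
    A/T and G/C pairs are dropped by default; allele sets that do not match
    at all are dropped and counted.  Positions disagreeing at equal rsID
    raise a warning only.
    """
    if geno.n_variants == 0 or len(stats) == 0:
        raise ValueError("harmonize requires non-empty genotypes and statistics")
    report = HarmonizeReport()
    stat_rows = stats.table.set_index("id")
    keep_variants: list[Variant] = []
    keep_cols: list[np.ndarray] = []
    keep_ids: list[str] = []
    for j, var in enumerate(geno.variants):
        if var.id not in stat_rows.index:
            continue
        row = stat_rows.loc[var.id]
        if str(row["chrom"]) != var.chrom or int(row["pos"]) != var.pos:
            warnings.warn(
                f"{var.id}: chrom/pos mismatch between genotypes and statistics"
            )
        if drop_ambiguous and var.is_strand_ambiguous:
            report.n_dropped_ambiguous += 1
            report.dropped_ids.append(var.id)
            continue
        ea, oa = str(row["effect_allele"]).upper(), str(row["other_allele"]).upper()
        col = geno.dosage[:, j]
        if var.effect_allele.upper() == ea and var.other_allele.upper() == oa:
            report.n_kept += 1
        elif var.effect_allele.upper() == oa and var.other_allele.upper() == ea:
            col = 2.0 - col
            var = Variant(var.id, var.chrom, var.pos, ea, oa,
                          var.locus_label, var.annotations)
            report.n_flipped += 1
            report.flipped_ids.append(var.id)
        else:
            report.n_dropped_mismatch += 1
            report.dropped_ids.append(var.id)
            continue
        keep_variants.append(var)
        keep_cols.append(col)
        keep_ids.append(var.id)
    if not keep_ids:
        raise ValueError("no overlapping variants after harmonization")
    geno_out = GenotypeMatrix(
        geno.sample_ids, keep_variants, np.column_stack(keep_cols)
    )
    return geno_out, stats.subset(keep_ids), report
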