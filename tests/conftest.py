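import numpy as np
import pandas as pd
import pytest

from prsnet.datamodel import GenotypeMatrix, PhenotypeTable, SummaryStats, Variant


def make_variant(vid="rs1", chrom="1", pos=100, ea="A", oa="G", **kw):
    return Variant(id=vid, chrom=chrom, pos=pos, effect_allele=ea,
                   other_allele=oa, **kw)


def make_geno(dosage, ids=None, alleles=None, chrom="1", positions=None):
    dosage = np.asarray(dosage, dtype=float)
    n, m = dosage.shape
    ids = ids or [f"rs{j + 1}" for j in range(m)]
    alleles = alleles or [("A", "G")] * m
    positions = positions or [100 * (j + 1) for j in range(m)]
    variants = [
        Variant(id=ids[j], chrom=chrom, pos=positions[j],
                effect_allele=alleles[j][0], other_allele=alleles[j][1])
        for j in range(m)
    ]
    samples = [f"S{i + 1}" for i in range(n)]
    return GenotypeMatrix(samples, variants, dosage)


def make_stats(ids, betas, ses, ps, alleles=None, chrom="1",
               positions=None, eafs=None, ns=None):
    m = len(ids)
    alleles = alleles or [("A", "G")] * m
    return SummaryStats(pd.DataFrame({
        "id": ids,
        "chrom": [chrom] * m,
        "pos": positions or [100 * (j + 1) for j in range(m)],
        "effect_allele": [a[0] for a in alleles],
        "other_allele": [a[1] for a in alleles],
        "beta": betas,
        "se": ses,
        "p": ps,
        "eaf": eafs or [0.3] * m,
        "n": ns or [1000] * m,
    }))


def make_pheno(status, age=None, sex=None, sample_ids=None, **extra):
    n = len(status)
    rng = np.random.default_rng(11)
    table = pd.DataFrame({
        "sample_id": sample_ids or [f"S{i + 1}" for i in range(n)],
        "status": status,
        "age": age if age is not None else rng.uniform(55, 90, n),
        "sex": sex if sex is not None else rng.integers(0, 2, n),
        **{f"pc{i}": rng.normal(size=n) for i in range(1, 6)},
        **extra,
    })
    return PhenotypeTable(table)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
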