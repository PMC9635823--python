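import numpy as np
import pandas as pd
import pytest

from paleopop.genio import MISSING, GenotypeMatrix


def make_snps(n, chrom="1", start=1, spacing=1000, allele1="A", allele2="G"):
    """Minimal SNP table on one chromosome."""
    return pd.DataFrame(
        {
            "snp_id": [f"snp{i}" for i in range(n)],
            "chrom": chrom,
            "gen_pos": 0.0,
            "pos": np.arange(start, start + n * spacing, spacing)[:n],
            "allele1": allele1,
            "allele2": allele2,
        }
    )


def make_matrix(calls, pseudo_haploid=None, snps=None, sex=None, chrom="1"):
    """GenotypeMatrix from a nested list of calls (None -> missing)."""
    arr = np.array(
        [[MISSING if c is None else c for c in row] for row in calls], dtype=np.int8
    )
    n_ind, n_snp = arr.shape
    if snps is None:
        snps = make_snps(n_snp, chrom=chrom)
    if pseudo_haploid is None:
        pseudo_haploid = ~(arr == 1).any(axis=1)
    return GenotypeMatrix(
        snps=snps,
        individuals=[f"ind{i}" for i in range(n_ind)],
        calls=arr,
        pseudo_haploid=np.asarray(pseudo_haploid, dtype=bool),
        sex=None if sex is None else np.asarray(sex),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(0)
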