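"""Allele-frequency algebra: outgroup f3, D, f4, and block-jackknife errors.

All estimators work from a :class:`FreqTable` of per-population allele1
frequencies (individuals may be treated as populations of one, the standard
move for pairwise outgroup-f3 matrices on low-coverage data).  Standard
errors come from a weighted delete-one-block jackknife over contiguous
physical blocks, which is robust to linkage; Z = estimate / SE and two-sided
normal p-values follow.

SNP usage follows the "allsnps" convention by default: each statistic uses
every SNP at which all of its populations have data, so different statistics
may rest on different SNP sets.  A strict-intersection mode is available for
comparison.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .genio import GenotypeMatrix

DEFAULT_BLOCK_SPAN = 5_000_000  # bp; contiguous physical blocks per chromosome


@dataclass
class FreqTable:
    """Per-population allele1 frequencies and observed allele counts."""

    labels: list[str]
    p: np.ndarray  # (n_pop, n_snp), NaN where n == 0
    n: np.ndarray  # (n_pop, n_snp) allele counts
    snps: pd.DataFrame

    def row(self, label: str) -> np.ndarray:
        return self.p[self.labels.index(label)]


def allele_freqs(matrix: GenotypeMatrix, grouping: dict[str, str]) -> FreqTable:
    """Pool individuals into populations and compute allele1 frequencies.

    ``grouping`` maps individual id -> population label; unlisted individuals
    are ignored.  Pseudo-haploid individuals contribute a single allele per
    called site, diploid individuals two.
    """
    labels = sorted(set(grouping.values()))
    dos = matrix.dosage()
    ploidy = matrix.ploidy().astype(float)
    ploidy[np.isnan(dos)] = 0.0
    p = np.empty((len(labels), matrix.n_snps))
    n = np.empty_like(p)
    idx_of = {ind: i for i, ind in enumerate(matrix.individuals)}
    for k, lab in enumerate(labels):
        rows = [idx_of[i] for i, g in grouping.items() if g == lab]
        n[k] = ploidy[rows].sum(axis=0)
        with np.errstate(invalid="ignore"):
            p[k] = np.nansum(dos[rows], axis=0) / n[k]
    p[n == 0] = np.nan
    return FreqTable(labels=labels, p=p, n=n, snps=matrix.snps)


def assign_blocks(snps: pd.DataFrame, span_bp: int = DEFAULT_BLOCK_SPAN) -> np.ndarray:
    """Contiguous physical blocks: dense integer block id per SNP.

    Blocks are half-open ``[k*span, (k+1)*span)`` intervals within each
    chromosome; ids are dense over the blocks that actually contain SNPs.
    """
    chrom = snps["chrom"].to_numpy(dtype=object)
    bucket = (snps["pos"].to_numpy(dtype=np.int64) - 1) // span_bp
    key = pd.MultiIndex.from_arrays([chrom, bucket])
    return pd.factorize(key, sort=True)[0]


@dataclass
class FStatResult:
    statistic: str
    estimate: float
    se: float
    z: float
    p: float
    n_snps: int
    n_blocks: int
    p_adjusted: float | None = None


# ---------------------------------------------------------------------------
# weighted block jackknife (Busing-style, unequal block sizes)
# ---------------------------------------------------------------------------

def _jackknife_core(theta_full: float | np.ndarray, theta_loo: np.ndarray, m: np.ndarray):
    """Pseudovalues for the weighted delete-one jackknife.

    ``theta_loo`` holds the statistic recomputed with each block left out
    (first axis = blocks), ``m`` the block sizes.  With n = sum(m) and
    h_j = n / m_j, pseudovalues are tau_j = h_j*theta - (h_j-1)*theta_{-j};
    the variance is (1/g) * sum_j (tau_j - tau_bar)^2 / (h_j - 1).
    """
    m = np.asarray(m, dtype=float)
    n = m.sum()
    g = len(m)
    h = n / m
    shape = (g,) + (1,) * (np.ndim(theta_loo) - 1)
    hcol = h.reshape(shape)
    tau = hcol * np.asarray(theta_full) - (hcol - 1.0) * theta_loo
    tau_bar = tau.mean(axis=0)
    var = ((tau - tau_bar) ** 2 / (hcol - 1.0)).sum(axis=0) / g
    return tau, tau_bar, var


def block_jackknife_se(theta_full, theta_loo, m) -> float | np.ndarray:
    """SE of a statistic from its leave-one-block-out recomputations."""
    if len(np.asarray(m)) < 2:
        raise ValueError("block jackknife requires at least 2 non-empty blocks")
    _, _, var = _jackknife_core(theta_full, theta_loo, m)
    return np.sqrt(var)


def jackknife_cov(theta_full: np.ndarray, theta_loo: np.ndarray, m) -> np.ndarray:
    """Jackknife covariance matrix of a vector statistic (blocks on axis 0)."""
    m = np.asarray(m, dtype=float)
    g = len(m)
    h = (m.sum() / m)[:, None]
    tau = h * theta_full[None, :] - (h - 1.0) * theta_loo
    dev = tau - tau.mean(axis=0)
    # per-pair analogue of the scalar formula
    w = 1.0 / (h[:, 0] - 1.0)
    return (dev.T * w) @ dev / g


def _ratio_jackknife(num: np.ndarray, den: np.ndarray, blocks: np.ndarray):
    """Estimate sum(num)/sum(den) with leave-one-block-out values.

    Returns (estimate, loo estimates, block sizes, n_snps, n_blocks); inputs
    are per-usable-SNP arrays.
    """
    ids, counts = np.unique(blocks, return_counts=True)
    dense = np.searchsorted(ids, blocks)
    g = len(ids)
    num_b = np.bincount(dense, weights=num, minlength=g)
    den_b = np.bincount(dense, weights=den, minlength=g)
    tot_num, tot_den = num_b.sum(), den_b.sum()
    if tot_den == 0:
        raise ZeroDivisionError("statistic denominator is zero over all SNPs")
    est = tot_num / tot_den
    loo = (tot_num - num_b) / (tot_den - den_b)
    return est, loo, counts, len(num), g


def _finish(statistic: str, est, loo, m, n_snps, g) -> FStatResult:
    if g < 2:
        raise ValueError(f"{statistic}: a single block; SE undefined")
    se = float(block_jackknife_se(est, loo, m))
    z = est / se if se > 0 else np.inf * np.sign(est) if est else 0.0
    p = 2.0 * stats.norm.sf(abs(z)) if np.isfinite(z) else 0.0
    return FStatResult(statistic, float(est), se, float(z), float(p), n_snps, g)


# ---------------------------------------------------------------------------
# f-statistics
# ---------------------------------------------------------------------------

def f3_outgroup(
    freqs: FreqTable,
    outgroup: str,
    a: str,
    b: str,
    blocks: np.ndarray | None = None,
) -> FStatResult:
    """Outgroup f3(O; A, B) = mean over usable SNPs of (pO - pA)(pO - pB)."""
    if blocks is None:
        blocks = assign_blocks(freqs.snps)
    po, pa, pb = freqs.row(outgroup), freqs.row(a), freqs.row(b)
    use = np.isfinite(po) & np.isfinite(pa) & np.isfinite(pb)
    if not use.any():
        raise ValueError(f"f3({outgroup}; {a}, {b}): no SNP has data in all three")
    prod = (po[use] - pa[use]) * (po[use] - pb[use])
    res = _ratio_jackknife(prod, np.ones_like(prod), blocks[use])
    return _finish(f"f3({outgroup};{a},{b})", *res)


def f4(
    freqs: FreqTable,
    a: str,
    b: str,
    c: str,
    d: str,
    blocks: np.ndarray | None = None,
) -> FStatResult:
    """Unnormalized f4(A, B; C, D) = mean (pA - pB)(pC - pD)."""
    if blocks is None:
        blocks = assign_blocks(freqs.snps)
    pa, pb, pc, pd_ = (freqs.row(x) for x in (a, b, c, d))
    use = np.isfinite(pa) & np.isfinite(pb) & np.isfinite(pc) & np.isfinite(pd_)
    if not use.any():
        raise ValueError(f"f4({a},{b};{c},{d}): empty SNP set")
    prod = (pa[use] - pb[use]) * (pc[use] - pd_[use])
    res = _ratio_jackknife(prod, np.ones_like(prod), blocks[use])
    return _finish(f"f4({a},{b};{c},{d})", *res)


def d_statistic(
    freqs: FreqTable,
    w: str,
    x: str,
    y: str,
    z: str,
    blocks: np.ndarray | None = None,
) -> FStatResult:
    """ABBA-BABA D(W, X; Y, Z): normalized four-population test of treeness."""
    if blocks is None:
        blocks = assign_blocks(freqs.snps)
    pw, px, py, pz = (freqs.row(s) for s in (w, x, y, z))
    use = np.isfinite(pw) & np.isfinite(px) & np.isfinite(py) & np.isfinite(pz)
    if not use.any():
        raise ValueError(f"D({w},{x};{y},{z}): empty SNP set")
    pw, px, py, pz = pw[use], px[use], py[use], pz[use]
    num = (pw - px) * (py - pz)
    den = (pw + px - 2 * pw * px) * (py + pz - 2 * py * pz)
    res = _ratio_jackknife(num, den, blocks[use])
    return _finish(f"D({w},{x};{y},{z})", *res)


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(pvalues, dtype=float)
    if p.size and ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# pairwise (1 - f3) dissimilarity
# ---------------------------------------------------------------------------

def pairwise_f3_matrix(
    matrix: GenotypeMatrix,
    outgroup_ids: list[str],
    individuals: list[str] | None = None,
    min_overlap: int = 2000,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Symmetric (1 - outgroup f3) dissimilarity between individuals.

    Each individual is treated as a population of one.  Pairs whose
    usable-SNP count (SNPs called in both individuals and the outgroup) is
    below ``min_overlap`` are masked with NaN.  Returns (dissimilarity,
    overlap counts), both square DataFrames with zero/own-count diagonals.
    """
    if individuals is None:
        individuals = [i for i in matrix.individuals if i not in set(outgroup_ids)]
    grouping = {i: "_OG" for i in outgroup_ids}
    og = allele_freqs(matrix.take_individuals(outgroup_ids), grouping).p[0]
    sub = matrix.take_individuals(individuals)
    # per-individual allele1 frequency: call/2 regardless of ploidy encoding
    p_ind = np.where(sub.calls >= 0, sub.calls / 2.0, np.nan)
    # deviations from the outgroup, zero where unusable
    dev = og[None, :] - p_ind
    usable = np.isfinite(dev) & np.isfinite(og)[None, :]
    dev0 = np.where(usable, dev, 0.0)
    counts = usable.astype(float) @ usable.T.astype(float)
    with np.errstate(invalid="ignore"):
        f3 = (dev0 @ dev0.T) / counts
    diss = 1.0 - f3
    diss[counts < min_overlap] = np.nan
    np.fill_diagonal(diss, 0.0)
    return (
        pd.DataFrame(diss, index=individuals, columns=individuals),
        pd.DataFrame(counts.astype(int), index=individuals, columns=individuals),
    )
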