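"""Pairwise kinship from pseudo-haploid mismatch rates (READ-style).

For each pair of pseudo-haploid genomes the mismatch rate P0 is computed in
1-Mb physical windows; the genome-wide (overlap-weighted) P0 is normalized
by the sample median P0 — the median pair is assumed unrelated — and
theta = 1 - normalized P0 estimates the kinship coefficient.  Expected
normalized P0 is 0.5 for identical genomes/twins, 0.75 / 0.875 / 0.9375 for
first/second/third-degree relatives and 1.0 for unrelated pairs; degrees are
assigned at the midpoints between those expectations, require |Z| > 2
against the unrelated expectation, and a minimum overlapping-SNP count
(2000 autosomal, 200 X).

The same pipeline runs on non-pseudoautosomal X data, where paternal- and
maternal-side relationships of the same autosomal degree separate; the
module also carries the genotype-likelihood theta formula from the Jaccard
coefficients for cross-method comparison.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .genio import MISSING, GenotypeMatrix

logger = logging.getLogger(__name__)

WINDOW_BP = 1_000_000
MIN_SNPS_AUTO = 2000
MIN_SNPS_X = 200

#: expected normalized P0 per relationship class
EXPECTED_NORMALIZED = {
    "identical": 0.5,
    "first": 0.75,
    "second": 0.875,
    "third": 0.9375,
    "unrelated": 1.0,
}
#: classification cutoffs at midpoints between expectations
CUTOFFS = (0.625, 0.8125, 0.90625, 0.96875)
DEGREE_BINS = ("identical", "first", "second", "third", "unrelated")


@dataclass
class PairWindowStats:
    pair: tuple[str, str]
    chrom: str
    start: int  # 1-based, half-open [start, start + span)
    n_overlap: int
    n_mismatch: int

    @property
    def p0(self) -> float:
        return self.n_mismatch / self.n_overlap


@dataclass
class KinshipEstimate:
    pair: tuple[str, str]
    p0: float
    baseline: float | None
    normalized: float | None
    theta: float | None
    se: float | None
    z_unrelated: float | None
    degree: str
    n_snps: int
    n_windows: int
    chrom_class: str = "autosomal"


def _window_codes(matrix: GenotypeMatrix, window_bp: int):
    """Dense window index per SNP for half-open 1-based windows from position 1."""
    chrom = matrix.snps["chrom"].to_numpy(dtype=object)
    win = (matrix.snps["pos"].to_numpy(dtype=np.int64) - 1) // window_bp
    key = pd.MultiIndex.from_arrays([chrom, win])
    codes, uniques = pd.factorize(key, sort=True)
    return codes, list(uniques)


def _pair_window_counts(matrix, ia, ib, codes, n_windows):
    for i in (ia, ib):
        if not matrix.pseudo_haploid[i]:
            raise ValueError(
                f"{matrix.individuals[i]} is diploid; pseudo-haploidize before "
                "mismatch-rate kinship"
            )
    a, b = matrix.calls[ia], matrix.calls[ib]
    overlap = (a != MISSING) & (b != MISSING)
    mismatch = overlap & (a != b)
    n_over = np.bincount(codes[overlap], minlength=n_windows)
    n_mis = np.bincount(codes[mismatch], minlength=n_windows)
    return n_over, n_mis


def windowed_p0(
    matrix: GenotypeMatrix,
    pair: tuple[str, str],
    window_bp: int = WINDOW_BP,
) -> list[PairWindowStats]:
    """Per-window mismatch counts for one pair of pseudo-haploid genomes."""
    ia, ib = matrix.index_of(pair[0]), matrix.index_of(pair[1])
    codes, uniques = _window_codes(matrix, window_bp)
    n_over, n_mis = _pair_window_counts(matrix, ia, ib, codes, len(uniques))
    out = []
    for k, (c, w) in enumerate(uniques):
        if n_over[k] == 0:
            continue
        out.append(
            PairWindowStats(pair, str(c), int(w) * window_bp + 1, int(n_over[k]), int(n_mis[k]))
        )
    return out


def genome_wide_p0(windows: list[PairWindowStats]) -> tuple[float, float, int, int]:
    """Overlap-weighted genome-wide P0, its window-based SE, SNP and window counts.

    The SE is the overlap-weighted SD of window P0 values divided by
    sqrt(number of windows).
    """
    n = np.array([w.n_overlap for w in windows], dtype=float)
    p = np.array([w.p0 for w in windows])
    total = n.sum()
    mean = float((n * p).sum() / total)
    if len(windows) > 1:
        wvar = float((n * (p - mean) ** 2).sum() / total)
        se = np.sqrt(wvar) / np.sqrt(len(windows))
    else:
        se = np.nan
    return mean, float(se), int(total), len(windows)


def normalize_p0(
    p0_values: dict[tuple[str, str], float],
    method: str = "median-of-pairs",
    baseline: float | None = None,
) -> tuple[float, dict[tuple[str, str], float]]:
    """Normalize genome-wide P0 values by an unrelated-pair baseline.

    ``median-of-pairs`` (default) takes the sample median P0, assuming the
    median pair is unrelated; ``fixed-baseline`` divides by a supplied value.
    """
    if method == "median-of-pairs":
        if len(p0_values) < 3:
            raise ValueError("median baseline needs >= 3 pairs")
        baseline = float(np.median(list(p0_values.values())))
    elif method == "fixed-baseline":
        if baseline is None:
            raise ValueError("fixed-baseline mode needs an explicit baseline")
    else:
        raise ValueError(f"unknown normalization method {method!r}")
    if baseline == 0:
        raise ValueError("baseline P0 is zero")
    return baseline, {pair: p / baseline for pair, p in p0_values.items()}


def classify_degree(
    normalized: float,
    se: float,
    n_snps: int,
    min_snps: int = MIN_SNPS_AUTO,
    z_min: float = 2.0,
) -> tuple[str, float]:
    """Assign a degree bin with a |Z| > z_min significance requirement.

    Z is (normalized - 1) / SE against the unrelated expectation; pairs whose
    normalized P0 is not significantly below 1 are reported unrelated, and
    pairs below the overlapping-SNP threshold are 'insufficient-data'.
    """
    z = (normalized - 1.0) / se if se and se > 0 else -np.inf
    if n_snps <= min_snps:
        return "insufficient-data", z
    k = int(np.searchsorted(CUTOFFS, normalized))
    degree = DEGREE_BINS[k]
    if degree != "unrelated" and abs(z) <= z_min:
        degree = "unrelated"
    return degree, z


def estimate_pair(
    matrix: GenotypeMatrix,
    pair: tuple[str, str],
    baseline: float,
    min_snps: int,
    chrom_class: str,
    window_bp: int = WINDOW_BP,
    z_min: float = 2.0,
) -> KinshipEstimate:
    windows = windowed_p0(matrix, pair, window_bp)
    if not windows:
        return KinshipEstimate(pair, np.nan, baseline, None, None, None, None,
                               "insufficient-data", 0, 0, chrom_class)
    p0, se_p0, n_snps, n_win = genome_wide_p0(windows)
    norm = p0 / baseline
    se = se_p0 / baseline
    degree, z = classify_degree(norm, se, n_snps, min_snps, z_min)
    return KinshipEstimate(
        pair, p0, baseline, norm, 1.0 - norm, se, z, degree, n_snps, n_win, chrom_class
    )


def kinship_all_pairs(
    matrix: GenotypeMatrix,
    pairs: list[tuple[str, str]] | None = None,
    window_bp: int = WINDOW_BP,
    min_snps: int = MIN_SNPS_AUTO,
    chrom_class: str = "autosomal",
    z_min: float = 2.0,
    baseline: float | None = None,
) -> list[KinshipEstimate]:
    """READ-style kinship for every pair (or the pairs given).

    The baseline defaults to the median genome-wide P0 over all analyzed
    pairs; pass ``baseline`` to normalize against an external value.
    """
    if pairs is None:
        pairs = list(itertools.combinations(matrix.individuals, 2))
    codes, uniques = _window_codes(matrix, window_bp)
    p0s: dict[tuple[str, str], float] = {}
    cache: dict[tuple[str, str], tuple] = {}
    for pair in pairs:
        ia, ib = matrix.index_of(pair[0]), matrix.index_of(pair[1])
        n_over, n_mis = _pair_window_counts(matrix, ia, ib, codes, len(uniques))
        used = n_over > 0
        if not used.any():
            continue
        n, mis = n_over[used].astype(float), n_mis[used].astype(float)
        p = mis / n
        total = n.sum()
        mean = float((n * p).sum() / total)
        if used.sum() > 1:
            se = float(np.sqrt((n * (p - mean) ** 2).sum() / total) / np.sqrt(used.sum()))
        else:
            se = np.nan
        stats4 = (mean, se, int(total), int(used.sum()))
        cache[pair] = stats4
        p0s[pair] = stats4[0]
    if baseline is None:
        usable = {p: v for p, v in p0s.items() if cache[p][2] > min_snps} or p0s
        baseline, _ = normalize_p0(usable)
    out = []
    for pair in pairs:
        if pair not in cache:
            out.append(KinshipEstimate(pair, np.nan, baseline, None, None, None,
                                       None, "insufficient-data", 0, 0, chrom_class))
            continue
        p0, se_p0, n_snps, n_win = cache[pair]
        norm = p0 / baseline
        se = se_p0 / baseline
        degree, z = classify_degree(norm, se, n_snps, min_snps, z_min)
        out.append(KinshipEstimate(pair, p0, baseline, norm, 1.0 - norm, se, z,
                                   degree, n_snps, n_win, chrom_class))
    return out


def kinship_x(
    matrix: GenotypeMatrix,
    pairs: list[tuple[str, str]] | None = None,
    window_bp: int = WINDOW_BP,
    min_snps: int = MIN_SNPS_X,
    z_min: float = 2.0,
    baseline: float | None = None,
) -> list[KinshipEstimate]:
    """Kinship on non-pseudoautosomal X data with the 200-SNP threshold."""
    xmat = matrix.x_non_par()
    if xmat.n_snps == 0:
        raise ValueError("no non-PAR X SNPs in matrix")
    return kinship_all_pairs(xmat, pairs, window_bp, min_snps, "X", z_min, baseline)


def theta_from_jaccard(j: np.ndarray | list[float]) -> float:
    """Kinship coefficient from the nine condensed-identity Jaccard coefficients.

    theta = J1 + 0.5*(J3 + J5 + J7) + 0.25*J8.
    """
    j = np.asarray(j, dtype=float)
    if j.shape != (9,):
        raise ValueError("expected nine Jaccard coefficients")
    if (j < 0).any():
        raise ValueError("Jaccard coefficients must be non-negative")
    if abs(j.sum() - 1.0) > 1e-9:
        raise ValueError("Jaccard coefficients must sum to 1")
    return float(j[0] + 0.5 * (j[2] + j[4] + j[6]) + 0.25 * j[7])


# ---------------------------------------------------------------------------
# identical pairs
# ---------------------------------------------------------------------------

def detect_identicals(estimates: list[KinshipEstimate]) -> list[list[str]]:
    """Groups of individuals to merge: connected components of 'identical' pairs.

    Chained identity (A=B, B=C with A-C data-poor) merges the whole
    component, with a warning.
    """
    adj: dict[str, set[str]] = {}
    for est in estimates:
        if est.degree == "identical":
            a, b = est.pair
            adj.setdefault(a, set()).add(b)
            adj.setdefault(b, set()).add(a)
    seen: set[str] = set()
    groups = []
    for node in sorted(adj):
        if node in seen:
            continue
        comp, stack = [], [node]
        while stack:
            cur = stack.pop()
            if cur in seen:
                continue
            seen.add(cur)
            comp.append(cur)
            stack.extend(adj[cur] - seen)
        groups.append(sorted(comp))
        if len(comp) > 2:
            logger.warning("chained identity: merging %d individuals %s", len(comp), comp)
    return groups


def merge_individuals(
    matrix: GenotypeMatrix, ids: list[str], merged_id: str | None = None
) -> tuple[GenotypeMatrix, dict]:
    """Union the call vectors of identical individuals into one genome.

    Sites co-called with conflicting alleles become missing (conservative —
    preserves pseudo-haploid semantics); the conflict rate is reported.
    """
    if merged_id is None:
        merged_id = "+".join(ids)
    idx = [matrix.index_of(i) for i in ids]
    calls = matrix.calls[idx]
    present = calls != MISSING
    merged = np.full(matrix.n_snps, MISSING, dtype=np.int8)
    n_conflict = 0
    n_cocalled = 0
    for j in range(len(idx)):
        new = present[j] & (merged == MISSING)
        merged[new] = calls[j, new]
        both = present[j] & ~new & (merged != MISSING)
        conflict = both & (merged != calls[j])
        n_cocalled += int(both.sum())
        n_conflict += int(conflict.sum())
        merged[conflict] = MISSING
    keep = [i for i in matrix.individuals if i not in set(ids)]
    kept = matrix.take_individuals(keep)
    new_matrix = replace(
        kept,
        individuals=kept.individuals + [merged_id],
        calls=np.vstack([kept.calls, merged[None, :]]),
        pseudo_haploid=np.append(kept.pseudo_haploid, True),
        sex=None if kept.sex is None else np.append(kept.sex, matrix.sex[idx[0]]),
    )
    rate = n_conflict / n_cocalled if n_cocalled else 0.0
    if n_conflict:
        logger.info("merge %s: %.3f conflict rate at co-called sites", merged_id, rate)
    return new_matrix, {"merged_id": merged_id, "n_cocalled": n_cocalled,
                        "n_conflict": n_conflict, "conflict_rate": rate}


# ---------------------------------------------------------------------------
# autosomal vs X discordance
# ---------------------------------------------------------------------------

@dataclass
class DiscordanceReport:
    pair: tuple[str, str]
    theta_auto: float
    theta_x: float
    diff: float
    combined_se: float
    verdict: str  # paternal-side / maternal-side / concordant / inconclusive


def compare_auto_x(
    auto: KinshipEstimate,
    x: KinshipEstimate,
    z_min: float = 2.0,
    max_se: float = 0.125,
) -> DiscordanceReport:
    """Flag pairs whose X kinship departs from the autosomal estimate.

    theta_X above theta_auto by more than ``z_min`` combined SEs signals a
    paternal-side relationship (for female pairs); below, a maternal-side
    one; SEs too large to separate adjacent degrees give 'inconclusive'.
    """
    for est in (auto, x):
        if est.degree == "insufficient-data" or est.theta is None:
            raise ValueError(f"estimate for {est.pair} ({est.chrom_class}) unusable")
    diff = x.theta - auto.theta
    se = float(np.hypot(auto.se, x.se))
    if se > max_se:
        verdict = "inconclusive"
    elif diff > z_min * se:
        verdict = "paternal-side"
    elif diff < -z_min * se:
        verdict = "maternal-side"
    else:
        verdict = "concordant"
    return DiscordanceReport(auto.pair, auto.theta, x.theta, diff, se, verdict)


def estimates_table(estimates: list[KinshipEstimate]) -> pd.DataFrame:
    """Flat TSV-ready table of kinship estimates."""
    return pd.DataFrame(
        {
            "id1": [e.pair[0] for e in estimates],
            "id2": [e.pair[1] for e in estimates],
            "chrom_class": [e.chrom_class for e in estimates],
            "p0": [e.p0 for e in estimates],
            "normalized_p0": [e.normalized for e in estimates],
            "theta": [e.theta for e in estimates],
            "se": [e.se for e in estimates],
            "z": [e.z_unrelated for e in estimates],
            "n_snps": [e.n_snps for e in estimates],
            "degree": [e.degree for e in estimates],
        }
    )
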