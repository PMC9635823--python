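"""Spatial and permutation statistics on pairwise genetic distances.

Works from a pair table holding, for each unordered individual pair, the
genetic distance (1 - outgroup f3), the geodesic distance in km, the
absolute date gap in years, site/building labels and a close-kin flag.
Provides the isolation-by-distance regression with per-group residual
permutation tests, classical (Torgerson) MDS of the dissimilarity matrix,
within-site diversity contrasts and the coburial permutation test.

Permutations operate on individual labels, not on pairs, which respects the
dependence among pairs sharing an individual.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .fstats import bh_adjust

logger = logging.getLogger(__name__)

EARTH_RADIUS_KM = 6371.0088  # mean Earth radius
MAX_TIME_GAP_YEARS = 1000
MIN_OVERLAP_SNPS = 2000


def haversine_km(lat1, lon1, lat2, lon2, radius: float = EARTH_RADIUS_KM):
    """Great-circle distance on a sphere of mean Earth radius, in km."""
    lat1, lon1, lat2, lon2 = map(np.radians, (lat1, lon1, lat2, lon2))
    a = (
        np.sin((lat2 - lat1) / 2) ** 2
        + np.cos(lat1) * np.cos(lat2) * np.sin((lon2 - lon1) / 2) ** 2
    )
    return 2 * radius * np.arcsin(np.sqrt(a))


def build_pair_table(
    dissimilarity: pd.DataFrame,
    overlap: pd.DataFrame,
    meta: pd.DataFrame,
    close_kin_pairs: set[frozenset] | None = None,
    exclude_same_site: bool = False,
    max_time_gap: float | None = None,
    min_overlap: int | None = None,
) -> pd.DataFrame:
    """Per-pair table joining genetic, geographic and temporal distances.

    ``meta`` must carry id, site, building, lat, lon, date_mean.  Filters are
    opt-in: the isolation-by-distance configuration excludes same-site pairs,
    pairs > 1000 years apart and pairs under 2000 overlapping SNPs.  Pairs
    with missing coordinates or masked dissimilarities are dropped and
    logged.
    """
    close_kin_pairs = close_kin_pairs or set()
    m = meta.set_index("id")
    rows = []
    n_dropped = 0
    for a, b in itertools.combinations(dissimilarity.index, 2):
        gdist = dissimilarity.loc[a, b]
        if not np.isfinite(gdist):
            n_dropped += 1
            continue
        ra, rb = m.loc[a], m.loc[b]
        if pd.isna(ra["lat"]) or pd.isna(rb["lat"]):
            n_dropped += 1
            continue
        rows.append(
            {
                "id1": a,
                "id2": b,
                "genetic_dist": float(gdist),
                "km": float(haversine_km(ra["lat"], ra["lon"], rb["lat"], rb["lon"])),
                "time_gap": abs(float(ra["date_mean"]) - float(rb["date_mean"])),
                "same_site": ra["site"] == rb["site"],
                "same_building": (
                    pd.notna(ra.get("building"))
                    and ra.get("building") == rb.get("building")
                ),
                "close_kin": frozenset((a, b)) in close_kin_pairs,
                "n_overlap": int(overlap.loc[a, b]),
            }
        )
    if n_dropped:
        logger.info("build_pair_table: dropped %d pairs (masked or no coordinates)", n_dropped)
    table = pd.DataFrame(rows)
    if exclude_same_site:
        table = table[~table["same_site"]]
    if max_time_gap is not None:
        table = table[table["time_gap"] <= max_time_gap]
    if min_overlap is not None:
        table = table[table["n_overlap"] >= min_overlap]
    return table.reset_index(drop=True)


@dataclass
class RegressionFit:
    slope: float
    intercept: float
    r_squared: float
    p_value: float
    residuals: np.ndarray
    table: pd.DataFrame


def ibd_regression(table: pd.DataFrame) -> RegressionFit:
    """OLS of genetic distance on geographic distance (isolation by distance).

    The two-sided slope p-value is the naive lm-style one; pairs sharing an
    individual are not independent, so permutation-based checks
    (:func:`residuals_by_group`) accompany it.
    """
    if len(table) < 3:
        raise ValueError("need >= 3 pairs for regression")
    x = table["km"].to_numpy(dtype=float)
    y = table["genetic_dist"].to_numpy(dtype=float)
    if np.ptp(x) == 0:
        raise ValueError("zero variance in geographic distance")
    fit = stats.linregress(x, y)
    residuals = y - (fit.intercept + fit.slope * x)
    return RegressionFit(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
        p_value=float(fit.pvalue),
        residuals=residuals,
        table=table,
    )


def residuals_by_group(
    fit: RegressionFit,
    groups: pd.Series | np.ndarray,
    n_perm: int = 1999,
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Median regression residual per pair group, with permutation p-values.

    Group labels are shuffled across pairs; the statistic is the absolute
    median residual of the group.  P-values are BH-adjusted across groups.
    """
    rng = np.random.default_rng(seed)
    groups = np.asarray(groups)
    res = fit.residuals
    labels = [g for g in pd.unique(groups) if (groups == g).sum() >= 3]
    obs = {g: np.median(res[groups == g]) for g in labels}
    counts = {g: 1 for g in labels}
    sizes = {g: int((groups == g).sum()) for g in labels}
    for _ in range(n_perm):
        perm = rng.permutation(groups)
        for g in labels:
            null_stat = abs(np.median(res[perm == g]))
            if null_stat >= abs(obs[g]):
                counts[g] += 1
    pvals = np.array([counts[g] / (n_perm + 1) for g in labels])
    return pd.DataFrame(
        {
            "group": labels,
            "n_pairs": [sizes[g] for g in labels],
            "median_residual": [obs[g] for g in labels],
            "p": pvals,
            "p_adjusted": bh_adjust(pvals) if len(labels) else pvals,
        }
    )


def classical_mds(
    dissimilarity: pd.DataFrame | np.ndarray, k: int = 2
) -> tuple[np.ndarray, np.ndarray]:
    """Torgerson classical MDS: coordinates and eigenvalues.

    Masked (NaN) off-diagonal entries are imputed with the mean finite
    off-diagonal dissimilarity (with a warning).  B = -1/2 J D^2 J is
    eigendecomposed; coordinates use the top-k positive eigenpairs, with axis
    signs fixed so the largest-magnitude loading is positive.  If fewer than
    k positive eigenvalues exist, k shrinks with a warning.
    """
    D = np.asarray(dissimilarity, dtype=float).copy()
    if D.shape[0] != D.shape[1] or not np.allclose(np.diag(D), 0):
        raise ValueError("need a square dissimilarity matrix with zero diagonal")
    off = ~np.eye(len(D), dtype=bool)
    miss = ~np.isfinite(D) & off
    if miss.any():
        logger.warning("classical_mds: imputing %d masked entries with the mean", miss.sum())
        D[miss] = np.nanmean(D[off & ~miss])
    n = len(D)
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D**2) @ J
    vals, vecs = np.linalg.eigh((B + B.T) / 2)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    n_pos = int((vals > 1e-12).sum())
    if k > n_pos:
        logger.warning("classical_mds: only %d positive eigenvalues; shrinking k", n_pos)
        k = n_pos
    coords = vecs[:, :k] * np.sqrt(vals[:k])
    for ax in range(k):
        j = np.argmax(np.abs(coords[:, ax]))
        if coords[j, ax] < 0:
            coords[:, ax] = -coords[:, ax]
    return coords, vals


@dataclass
class PermutationResult:
    observed: float
    effect_size: float
    n_perm: int
    p_value: float
    sided: str
    seed: int | None


def _pair_index(ids: list, table: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    pos = {v: i for i, v in enumerate(ids)}
    return (
        table["id1"].map(pos).to_numpy(),
        table["id2"].map(pos).to_numpy(),
    )


def diversity_permutation(
    table: pd.DataFrame,
    meta: pd.DataFrame,
    n_perm: int = 9999,
    seed: int = 0,
) -> pd.DataFrame:
    """Within-site genetic diversity contrasts by permutation.

    For every site with >= 2 within-site pairs, the median within-site
    (1 - f3) is compared between site pairs; the null shuffles individual
    site labels and recomputes the difference of medians.  Two-sided p with
    add-one correction.
    """
    rng = np.random.default_rng(seed)
    ids = sorted(set(table["id1"]) | set(table["id2"]))
    site_of = meta.set_index("id")["site"]
    sites = np.asarray([site_of[i] for i in ids], dtype=object)
    i1, i2 = _pair_index(ids, table)
    gd = table["genetic_dist"].to_numpy()

    def within_medians(site_vec) -> dict:
        same = site_vec[i1] == site_vec[i2]
        out = {}
        for s in pd.unique(site_vec):
            mask = same & (site_vec[i1] == s)
            if mask.sum() >= 2:
                out[s] = np.median(gd[mask])
        return out

    obs = within_medians(sites)
    usable = sorted(obs)
    if len(usable) < 2:
        raise ValueError("need >= 2 sites with >= 2 within-site pairs")
    rows = []
    for sa, sb in itertools.combinations(usable, 2):
        d_obs = obs[sa] - obs[sb]
        count = 1
        n_valid = 0
        for _ in range(n_perm):
            perm = rng.permutation(sites)
            med = within_medians(perm)
            if sa in med and sb in med:
                n_valid += 1
                if abs(med[sa] - med[sb]) >= abs(d_obs):
                    count += 1
        rows.append(
            {
                "site_a": sa,
                "site_b": sb,
                "median_a": obs[sa],
                "median_b": obs[sb],
                "difference": d_obs,
                "p": count / (n_valid + 1),
                "n_perm_valid": n_valid,
            }
        )
    return pd.DataFrame(rows)


def coburial_permutation(
    table: pd.DataFrame,
    buildings: dict[str, object],
    n_perm: int = 9999,
    seed: int = 0,
) -> PermutationResult:
    """Are coburied (same-building) non-kin pairs genetically closer?

    ``buildings`` maps individual id -> building label (None/NaN = unknown,
    excluded).  Close-kin pairs are excluded; the effect size is mean
    (1 - f3) of between-building pairs minus same-building pairs, and the
    null permutes individuals' building assignments (building sizes
    preserved).  One-sided p for within-building pairs being closer, with
    add-one correction.
    """
    rng = np.random.default_rng(seed)
    t = table[~table["close_kin"]]
    ids = sorted(
        i for i in set(t["id1"]) | set(t["id2"])
        if buildings.get(i) is not None and not pd.isna(buildings.get(i))
    )
    t = t[t["id1"].isin(ids) & t["id2"].isin(ids)].reset_index(drop=True)
    labels = np.asarray([buildings[i] for i in ids], dtype=object)
    i1, i2 = _pair_index(ids, t)
    gd = t["genetic_dist"].to_numpy()

    def effect(lab) -> float:
        same = lab[i1] == lab[i2]
        if same.all() or not same.any():
            return np.nan
        return gd[~same].mean() - gd[same].mean()

    obs = effect(labels)
    if not np.isfinite(obs):
        raise ValueError("degenerate grouping: need within- and between-building pairs")
    count = 1
    n_valid = 0
    for _ in range(n_perm):
        e = effect(rng.permutation(labels))
        if np.isfinite(e):
            n_valid += 1
            if e >= obs:
                count += 1
    return PermutationResult(
        observed=obs,
        effect_size=obs,
        n_perm=n_valid,
        p_value=count / (n_valid + 1),
        sided="one-sided (within closer)",
        seed=seed if isinstance(seed, int) else None,
    )
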