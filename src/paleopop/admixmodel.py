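"""qpAdm-style admixture-weight estimation.

A target population is modeled as a mixture of k source ("left")
populations.  The fit works in f4 space: with a base reference population
r0 and further references r1..rJ, each left population l gets a profile
row(l)_j = f4(l, r0; r_j, r0).  Because f4 is linear in allele frequencies,
a target that truly is a mixture satisfies row(target) = sum_i w_i row(s_i)
with sum w_i = 1, whatever base is used.  Weights minimize the generalized
least-squares quadratic form of the residual under the block-jackknife
covariance of the residual vector; the minimized form is the model-fit
chi-square with dof = (J) - (k - 1) where J = number of non-base references,
giving a feasibility p-value.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .fstats import FreqTable, assign_blocks, block_jackknife_se, jackknife_cov

logger = logging.getLogger(__name__)

RIDGE_CONDITION = 1e12
RIDGE_SCALE = 1e-10


@dataclass
class F4Basis:
    """f4 profiles of [target] + sources against the reference set."""

    left: list[str]  # target first
    right: list[str]  # base first
    rows: np.ndarray  # (n_left, J) full-data f4 values
    rows_loo: np.ndarray  # (g, n_left, J) leave-one-block-out values
    m: np.ndarray  # (g,) usable-SNP count per block (min across cells)
    n_snps: np.ndarray  # (n_left, J) per-cell usable SNP counts


@dataclass
class AdmixtureModel:
    target: str
    sources: list[str]
    references: list[str]
    weights: np.ndarray
    weight_se: np.ndarray
    chi2: float
    dof: int
    p_value: float
    n_snps: np.ndarray
    feasible: bool

    def summary(self) -> str:
        lines = [f"target: {self.target}"]
        for s, w, se in zip(self.sources, self.weights, self.weight_se):
            lines.append(f"  {s}: {w:.3f} +/- {se:.3f}")
        lines.append(
            f"chi2 = {self.chi2:.2f}, dof = {self.dof}, p = {self.p_value:.3g}, "
            f"{'feasible' if self.feasible else 'infeasible'}"
        )
        return "\n".join(lines)


def build_f4_matrix(
    freqs: FreqTable,
    left: list[str],
    right: list[str],
    blocks: np.ndarray | None = None,
    allsnps: bool = True,
) -> F4Basis:
    """f4(l, r0; r_j, r0) for every left population and non-base reference.

    In ``allsnps`` mode each cell uses every SNP where l, r0 and r_j all have
    data; otherwise the global intersection across all populations is used.
    Leave-one-block-out cell values are returned for jackknife machinery.
    """
    if len(right) < 3:
        raise ValueError("need a base plus >= 2 further reference populations")
    if blocks is None:
        blocks = assign_blocks(freqs.snps)
    ids = np.unique(blocks)
    dense = np.searchsorted(ids, blocks)
    g = len(ids)
    n_left, J = len(left), len(right) - 1
    p = {lab: freqs.row(lab) for lab in set(left) | set(right)}
    if not allsnps:
        common = np.ones(len(blocks), dtype=bool)
        for lab in set(left) | set(right):
            common &= np.isfinite(p[lab])
    rows = np.empty((n_left, J))
    rows_loo = np.empty((g, n_left, J))
    n_snps = np.empty((n_left, J), dtype=int)
    m = np.full(g, np.inf)
    r0 = p[right[0]]
    for i, l in enumerate(left):
        dl = p[l] - r0
        for j, r in enumerate(right[1:]):
            dr = p[r] - r0
            use = np.isfinite(dl) & np.isfinite(dr)
            if not allsnps:
                use &= common
            if not use.any():
                raise ValueError(f"empty SNP set for f4({l},{right[0]};{r},{right[0]})")
            prod = dl[use] * dr[use]
            b = dense[use]
            sums = np.bincount(b, weights=prod, minlength=g)
            counts = np.bincount(b, minlength=g)
            tot, n = sums.sum(), counts.sum()
            rows[i, j] = tot / n
            with np.errstate(invalid="ignore", divide="ignore"):
                loo = (tot - sums) / (n - counts)
            loo[counts == n] = rows[i, j]  # degenerate: all SNPs in one block
            rows_loo[:, i, j] = loo
            n_snps[i, j] = n
            m = np.minimum(m, np.where(counts > 0, counts, np.inf))
    m = np.where(np.isfinite(m), m, 1.0)
    return F4Basis(list(left), list(right), rows, rows_loo, m.astype(float), n_snps)


def _solve_gls(c: np.ndarray, B: np.ndarray, siginv: np.ndarray) -> np.ndarray:
    if B.shape[1] == 0:
        return np.empty(0)
    A = B.T @ siginv @ B
    return np.linalg.solve(A, B.T @ siginv @ c)


def _weights_from_basis(rows: np.ndarray, siginv: np.ndarray) -> np.ndarray:
    """Solve for mixture weights given f4 rows [target; sources] and Sigma^-1."""
    t, S = rows[0], rows[1:]
    c = t - S[-1]
    B = (S[:-1] - S[-1]).T  # (J, k-1)
    v = _solve_gls(c, B, siginv)
    return np.append(v, 1.0 - v.sum())


def _inv_with_ridge(sigma: np.ndarray) -> np.ndarray:
    cond = np.linalg.cond(sigma)
    if not np.isfinite(cond) or cond > RIDGE_CONDITION:
        logger.warning("residual covariance ill-conditioned (%.3g); ridge applied", cond)
        sigma = sigma + RIDGE_SCALE * np.trace(sigma) * np.eye(len(sigma))
    return np.linalg.inv(sigma)


def fit_admixture(basis: F4Basis, n_iter: int = 3) -> AdmixtureModel:
    """Estimate admixture weights, jackknife SEs and the model-fit p-value.

    The residual e(w) = row(target) - sum_i w_i row(source_i) is scored under
    its block-jackknife covariance; weights and covariance are iterated a few
    times from an ordinary least-squares start.  Weight SEs come from
    refitting on each leave-one-block-out basis (covariance held fixed).
    """
    k = len(basis.left) - 1
    J = basis.rows.shape[1]
    if k < 1:
        raise ValueError("need at least one source")
    if k >= J + 1:
        raise ValueError(
            f"{k} sources need more than {J} non-base references (infeasible dimensions)"
        )
    siginv = np.eye(J)
    w = None
    for _ in range(max(1, n_iter)):
        w = _weights_from_basis(basis.rows, siginv)
        e_full = basis.rows[0] - w @ basis.rows[1:]
        e_loo = basis.rows_loo[:, 0, :] - np.einsum("i,gij->gj", w, basis.rows_loo[:, 1:, :])
        sigma = jackknife_cov(e_full, e_loo, basis.m)
        siginv = _inv_with_ridge(sigma)
    chi2 = float(e_full @ siginv @ e_full)
    dof = J - (k - 1)
    p = float(stats.chi2.sf(chi2, dof))
    # jackknife SEs of the weights
    w_loo = np.array(
        [_weights_from_basis(basis.rows_loo[j], siginv) for j in range(len(basis.m))]
    )
    w_se = np.atleast_1d(block_jackknife_se(w, w_loo, basis.m))
    feasible = bool(p > 0.05 and np.all((w >= 0) & (w <= 1)))
    return AdmixtureModel(
        target=basis.left[0],
        sources=basis.left[1:],
        references=list(basis.right),
        weights=w,
        weight_se=w_se,
        chi2=chi2,
        dof=dof,
        p_value=p,
        n_snps=basis.n_snps,
        feasible=feasible,
    )


def qpadm(
    freqs: FreqTable,
    target: str,
    sources: list[str],
    right: list[str],
    blocks: np.ndarray | None = None,
    allsnps: bool = True,
) -> AdmixtureModel:
    """One-call qpAdm-style fit from a frequency table."""
    basis = build_f4_matrix(freqs, [target] + list(sources), right, blocks, allsnps)
    return fit_admixture(basis)


def feasibility_report(model: AdmixtureModel) -> dict:
    """Classify a fitted model: feasible (p>0.05), marginal (0.05>p>0.01), rejected.

    A weight outside [0, 1] flags the model infeasible regardless of p.
    """
    if model.p_value > 0.05:
        cls = "feasible"
    elif model.p_value > 0.01:
        cls = "marginal"
    else:
        cls = "rejected"
    in_range = bool(np.all((model.weights >= 0) & (model.weights <= 1)))
    return {
        "classification": cls,
        "weights_in_range": in_range,
        "infeasible_weights": not in_range,
        "p_value": model.p_value,
    }
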