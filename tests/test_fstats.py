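import numpy as np
import pandas as pd
import pytest

from paleopop import fstats, simdata
from paleopop.fstats import (
    FreqTable,
    allele_freqs,
    assign_blocks,
    bh_adjust,
    block_jackknife_se,
    d_statistic,
    f3_outgroup,
    f4,
    pairwise_f3_matrix,
)

from conftest import make_matrix, make_snps


def freq_table(p_by_label, n_blocks=5):
    """FreqTable straight from frequency vectors (counts set to 2)."""
    labels = sorted(p_by_label)
    p = np.array([np.asarray(p_by_label[lab], dtype=float) for lab in labels])
    n_snp = p.shape[1]
    snps = make_snps(n_snp, spacing=max(1, 5_000_000 * n_blocks // n_snp))
    return FreqTable(labels=labels, p=p, n=np.full_like(p, 2.0), snps=snps)


# ---------------------------------------------------------------------------
# allele frequencies
# ---------------------------------------------------------------------------

class TestAlleleFreqs:
    def test_pseudo_haploid_counts_one_allele(self):
        m = make_matrix([[2], [0]], pseudo_haploid=[True, True])
        ft = allele_freqs(m, {"ind0": "p", "ind1": "p"})
        assert ft.p[0, 0] == pytest.approx(0.5)
        assert ft.n[0, 0] == 2  # one allele each

    def test_diploid_het(self):
        m = make_matrix([[1]], pseudo_haploid=[False])
        ft = allele_freqs(m, {"ind0": "p"})
        assert ft.p[0, 0] == pytest.approx(0.5)
        assert ft.n[0, 0] == 2

    def test_all_missing_is_nan(self):
        m = make_matrix([[None], [None]])
        ft = allele_freqs(m, {"ind0": "p", "ind1": "p"})
        assert np.isnan(ft.p[0, 0])


# ---------------------------------------------------------------------------
# f3 / D / f4 small examples and symmetries
# ---------------------------------------------------------------------------

class TestFStatistics:
    def test_f3_hand_arithmetic(self):
        ft = freq_table({"O": [1, 0], "A": [0.5, 0.5], "B": [0.5, 0.5]},
                        n_blocks=2)
        r = f3_outgroup(ft, "O", "A", "B")
        assert r.estimate == pytest.approx(0.25, abs=1e-15)

    def test_f3_symmetric_and_self_nonnegative(self, rng):
        p = {k: rng.random(200) for k in ("O", "A", "B")}
        ft = freq_table(p)
        ab = f3_outgroup(ft, "O", "A", "B")
        ba = f3_outgroup(ft, "O", "B", "A")
        assert ab.estimate == ba.estimate
        self_f3 = f3_outgroup(ft, "O", "A", "A")
        assert self_f3.estimate >= 0

    def test_d_fixed_configuration(self):
        ft = freq_table({"W": [1.0] * 10, "X": [0.0] * 10,
                         "Y": [1.0] * 10, "Z": [0.0] * 10}, n_blocks=2)
        r = d_statistic(ft, "W", "X", "Y", "Z")
        assert r.estimate == pytest.approx(1.0)

    def test_d_antisymmetry_and_null(self, rng):
        p = {k: rng.random(300) for k in ("W", "X", "Y", "Z")}
        ft = freq_table(p)
        d1 = d_statistic(ft, "W", "X", "Y", "Z")
        d2 = d_statistic(ft, "W", "X", "Z", "Y")
        assert d1.estimate == pytest.approx(-d2.estimate, abs=1e-12)
        p["Z"] = p["Y"]
        ftn = freq_table(p)
        assert d_statistic(ftn, "W", "X", "Y", "Z").estimate == 0.0

    def test_f4_sign_flip_on_swapping_last_pair(self, rng):
        p = {k: rng.random(100) for k in ("A", "B", "C", "D")}
        ft = freq_table(p)
        assert f4(ft, "A", "B", "C", "D").estimate == pytest.approx(
            -f4(ft, "A", "B", "D", "C").estimate, abs=1e-15
        )

    def test_z_se_estimate_consistency(self, rng):
        p = {k: rng.random(500) for k in ("O", "A", "B")}
        r = f3_outgroup(freq_table(p), "O", "A", "B")
        assert abs(r.z) * r.se == pytest.approx(abs(r.estimate), abs=1e-12)

    def test_empty_intersection_errors(self):
        ft = freq_table({"O": [np.nan], "A": [0.5], "B": [0.5]}, n_blocks=1)
        with pytest.raises(ValueError, match="no SNP"):
            f3_outgroup(ft, "O", "A", "B")


# ---------------------------------------------------------------------------
# brute-force oracle equivalence
# ---------------------------------------------------------------------------

def brute_f3(po, pa, pb):
    vals = [(o - a) * (o - b) for o, a, b in zip(po, pa, pb)
            if np.isfinite(o) and np.isfinite(a) and np.isfinite(b)]
    return sum(vals) / len(vals)


def brute_d(pw, px, py, pz):
    num = den = 0.0
    for w, x, y, z in zip(pw, px, py, pz):
        if any(not np.isfinite(v) for v in (w, x, y, z)):
            continue
        num += (w - x) * (y - z)
        den += (w + x - 2 * w * x) * (y + z - 2 * y * z)
    return num / den


class TestBruteForceOracle:
    @pytest.fixture
    def freqs_with_missing(self, rng):
        p = {k: rng.random(1000) for k in ("O", "A", "B", "C")}
        for k in p:
            p[k][rng.random(1000) < 0.1] = np.nan
        return freq_table(p)

    def test_f3_matches_loop(self, freqs_with_missing):
        ft = freqs_with_missing
        r = f3_outgroup(ft, "O", "A", "B")
        expected = brute_f3(ft.row("O"), ft.row("A"), ft.row("B"))
        assert r.estimate == pytest.approx(expected, abs=1e-12)

    def test_d_matches_loop(self, freqs_with_missing):
        ft = freqs_with_missing
        r = d_statistic(ft, "O", "A", "B", "C")
        expected = brute_d(ft.row("O"), ft.row("A"), ft.row("B"), ft.row("C"))
        assert r.estimate == pytest.approx(expected, abs=1e-12)


# ---------------------------------------------------------------------------
# block jackknife
# ---------------------------------------------------------------------------

class TestBlockJackknife:
    def test_equal_blocks_match_classical_se(self, rng):
        # one iid value per block: delete-one jackknife of the mean is
        # algebraically the classical SE of the mean
        x = rng.normal(size=500)
        est = x.mean()
        loo = np.array([np.delete(x, j).mean() for j in range(len(x))])
        se = block_jackknife_se(est, loo, np.ones(len(x)))
        classical = x.std(ddof=1) / np.sqrt(len(x))
        assert se == pytest.approx(classical, abs=1e-10)

    def test_all_loo_equal_gives_zero(self):
        se = block_jackknife_se(1.0, np.ones(5), np.full(5, 10))
        assert se == pytest.approx(0.0, abs=1e-15)

    def test_duplicating_blocks_halves_variance(self, rng):
        x = rng.normal(size=400)
        g = 8
        blocks = np.repeat(np.arange(g), 50)

        def jk(xv, bv):
            gids = np.unique(bv)
            est = xv.mean()
            loo = np.array([xv[bv != j].mean() for j in gids])
            m = np.array([(bv == j).sum() for j in gids])
            return block_jackknife_se(est, loo, m) ** 2

        v1 = jk(x, blocks)
        x2 = np.concatenate([x, x])
        b2 = np.concatenate([blocks, blocks + g])
        v2 = jk(x2, b2)
        assert v2 == pytest.approx(v1 / 2, rel=0.15)

    def test_single_block_errors(self):
        with pytest.raises(ValueError):
            block_jackknife_se(1.0, np.array([0.9]), np.array([10]))

    def test_assign_blocks_contiguous(self):
        snps = pd.concat(
            [make_snps(10, chrom="1", spacing=2_000_000),
             make_snps(10, chrom="2", spacing=2_000_000)],
            ignore_index=True,
        )
        blocks = assign_blocks(snps, span_bp=5_000_000)
        # block ids never repeat after changing
        changes = np.flatnonzero(np.diff(blocks)) + 1
        assert (np.diff(blocks)[np.diff(blocks) != 0] > 0).all()
        assert len(np.unique(blocks)) == blocks.max() + 1
        assert len(changes) == len(np.unique(blocks)) - 1


# ---------------------------------------------------------------------------
# Benjamini-Hochberg
# ---------------------------------------------------------------------------

def bh_oracle(p):
    """From-scratch step-up adjustment."""
    p = list(p)
    n = len(p)
    order = sorted(range(n), key=lambda i: p[i])
    adj = [0.0] * n
    prev = 1.0
    for rank in range(n, 0, -1):
        i = order[rank - 1]
        val = min(prev, p[i] * n / rank)
        adj[i] = val
        prev = val
    return adj


class TestBHAdjust:
    def test_forced_arithmetic(self):
        np.testing.assert_allclose(
            bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    def test_single_and_equal(self):
        assert bh_adjust([0.2])[0] == pytest.approx(0.2)
        np.testing.assert_allclose(bh_adjust([0.3, 0.3, 0.3]), [0.3, 0.3, 0.3])

    def test_matches_oracle_on_random_inputs(self, rng):
        for _ in range(20):
            p = rng.random(rng.integers(1, 30))
            np.testing.assert_allclose(bh_adjust(p), bh_oracle(p), atol=1e-12)

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])


# ---------------------------------------------------------------------------
# pairwise (1 - f3) matrix
# ---------------------------------------------------------------------------

class TestPairwiseF3Matrix:
    @pytest.fixture
    def world(self):
        specs = [
            simdata.PopulationSpec("og", drift=0.5, n_samples=3),
            simdata.PopulationSpec("p", drift=0.05, n_samples=4),
        ]
        return simdata.simulate_world(specs, simdata.SimConfig(n_snps=600, seed=3))

    def test_symmetric_zero_diagonal(self, world):
        og = [i for i in world.matrix.individuals if i.startswith("og")]
        diss, ov = pairwise_f3_matrix(world.matrix, og, min_overlap=10)
        d = diss.to_numpy()
        np.testing.assert_allclose(d, d.T, atol=1e-12)
        assert (np.diag(d) == 0).all()

    def test_matches_per_pair_brute_force(self, world):
        og = [i for i in world.matrix.individuals if i.startswith("og")]
        inds = [i for i in world.matrix.individuals if i.startswith("p")]
        diss, ov = pairwise_f3_matrix(world.matrix, og, inds, min_overlap=10)
        grouping = {i: "_OG" for i in og}
        ogp = allele_freqs(world.matrix.take_individuals(og), grouping).p[0]
        calls = world.matrix.take_individuals(inds).calls
        for a in range(len(inds)):
            for b in range(a + 1, len(inds)):
                pa = np.where(calls[a] >= 0, calls[a] / 2, np.nan)
                pb = np.where(calls[b] >= 0, calls[b] / 2, np.nan)
                expected = 1.0 - brute_f3(ogp, pa, pb)
                assert diss.iloc[a, b] == pytest.approx(expected, abs=1e-12)

    def test_low_overlap_masked(self, world):
        og = [i for i in world.matrix.individuals if i.startswith("og")]
        diss, ov = pairwise_f3_matrix(world.matrix, og, min_overlap=10**6)
        off = ~np.eye(len(diss), dtype=bool)
        assert np.isnan(diss.to_numpy()[off]).all()
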