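import numpy as np
import pytest

from paleopop import kinrel, simdata
from paleopop.kinrel import (
    KinshipEstimate,
    classify_degree,
    compare_auto_x,
    detect_identicals,
    kinship_all_pairs,
    merge_individuals,
    normalize_p0,
    theta_from_jaccard,
    windowed_p0,
)

from conftest import make_matrix, make_snps


def ph_matrix(rows, spacing=200_000):
    return make_matrix(rows, pseudo_haploid=[True] * len(rows),
                       snps=make_snps(len(rows[0]), spacing=spacing))


class TestWindowedP0:
    def test_identical_zero(self):
        m = ph_matrix([[0, 2, 0, 2], [0, 2, 0, 2]])
        stats = windowed_p0(m, ("ind0", "ind1"))
        assert all(w.p0 == 0 for w in stats)

    def test_complementary_one(self):
        m = ph_matrix([[0, 2, 0, 2], [2, 0, 2, 0]])
        stats = windowed_p0(m, ("ind0", "ind1"))
        assert all(w.p0 == 1 for w in stats)

    def test_toy_arithmetic(self):
        # 10 SNPs in one window, 8 overlapping, 3 mismatches
        a = [0, 0, 0, 0, 0, 0, 0, 0, None, 0]
        b = [2, 2, 2, 0, 0, 0, 0, 0, 0, None]
        m = ph_matrix([a, b], spacing=1000)
        stats = windowed_p0(m, ("ind0", "ind1"))
        assert len(stats) == 1
        assert stats[0].n_overlap == 8
        assert stats[0].p0 == pytest.approx(0.375)

    def test_diploid_rejected(self):
        m = make_matrix([[1, 1], [0, 2]], pseudo_haploid=[False, True])
        with pytest.raises(ValueError, match="diploid"):
            windowed_p0(m, ("ind0", "ind1"))


class TestNormalization:
    def test_median_baseline_arithmetic(self):
        p0 = {("a", "b"): 0.24, ("c", "d"): 0.25, ("e", "f"): 0.26,
              ("x", "y"): 0.1875}
        baseline, norm = normalize_p0(p0)
        assert baseline == pytest.approx(0.245)
        p0b = {("a", "b"): 0.24, ("c", "d"): 0.25, ("e", "f"): 0.26}
        baseline, norm = normalize_p0(p0b)
        assert baseline == pytest.approx(0.25)
        assert 0.1875 / baseline == pytest.approx(0.75)  # first-degree value

    def test_all_equal_gives_theta_zero(self):
        p0 = {k: 0.25 for k in (("a", "b"), ("c", "d"), ("e", "f"))}
        baseline, norm = normalize_p0(p0)
        assert all(v == pytest.approx(1.0) for v in norm.values())

    def test_fixed_baseline_reproduces_median(self):
        p0 = {("a", "b"): 0.2, ("c", "d"): 0.25, ("e", "f"): 0.3}
        b1, n1 = normalize_p0(p0)
        b2, n2 = normalize_p0(p0, method="fixed-baseline", baseline=0.25)
        assert n1 == n2

    def test_errors(self):
        with pytest.raises(ValueError):
            normalize_p0({("a", "b"): 0.2})
        with pytest.raises(ValueError):
            normalize_p0({k: 0.0 for k in (("a", "b"), ("c", "d"), ("e", "f"))})


class TestClassification:
    @pytest.mark.parametrize(
        "norm,se,n,expected",
        [
            (0.75, 0.001, 10_000, "first"),
            (0.55, 0.001, 10_000, "identical"),
            (0.875, 0.001, 10_000, "second"),
            (0.9375, 0.005, 10_000, "third"),
            (0.95, 0.05, 10_000, "unrelated"),  # |Z| = 1, insignificant
            (0.99, 0.001, 10_000, "unrelated"),
            (0.75, 0.001, 1500, "insufficient-data"),
        ],
    )
    def test_bins_and_z_rule(self, norm, se, n, expected):
        degree, _ = classify_degree(norm, se, n)
        assert degree == expected

    def test_x_threshold(self):
        assert classify_degree(0.75, 0.001, 150, min_snps=kinrel.MIN_SNPS_X)[0] \
            == "insufficient-data"
        assert classify_degree(0.75, 0.001, 300, min_snps=kinrel.MIN_SNPS_X)[0] \
            == "first"


class TestJaccardTheta:
    @pytest.mark.parametrize(
        "hot,expected", [(0, 1.0), (7, 0.25), (1, 0.0), (2, 0.5)]
    )
    def test_unit_vectors(self, hot, expected):
        j = np.zeros(9)
        j[hot] = 1.0
        assert theta_from_jaccard(j) == pytest.approx(expected)

    def test_rejects_bad_sum(self):
        with pytest.raises(ValueError):
            theta_from_jaccard(np.full(9, 0.2))


class TestSymmetry:
    def test_pair_order_invariance(self, rng):
        import itertools

        calls = rng.choice([0, 2, -1], size=(6, 400), p=[0.45, 0.45, 0.1]).tolist()
        m = ph_matrix(calls, spacing=100_000)
        pairs = list(itertools.combinations(m.individuals, 2))
        e1 = {frozenset(e.pair): e.theta
              for e in kinship_all_pairs(m, pairs=pairs, min_snps=10)}
        rev = kinship_all_pairs(m, pairs=[(b, a) for a, b in pairs], min_snps=10)
        for e in rev:
            assert e.theta == pytest.approx(e1[frozenset(e.pair)])


class TestIdenticalDetection:
    @pytest.fixture
    def twin_world(self):
        specs = [simdata.PopulationSpec("pop", drift=0.05, n_samples=10)]
        return simdata.simulate_world(
            specs, simdata.SimConfig(n_snps=6000, seed=21, missingness=0.6),
            identical_twins=[("pop_0", "twin")],
        )

    def test_planted_twin_flagged_and_merged(self, twin_world):
        m = twin_world.matrix
        ests = kinship_all_pairs(m)
        groups = detect_identicals(ests)
        assert groups == [["pop_0", "twin"]]
        merged, report = merge_individuals(m, groups[0])
        # twins share the diploid genome but are haploidized independently:
        # conflicts arise only at heterozygous sites, at rate ~ het/2
        assert 0.0 < report["conflict_rate"] < 0.5
        # merged call count >= each constituent's
        n_merged = (merged.calls[-1] >= 0).sum()
        for ind in groups[0]:
            assert n_merged >= (m.calls[m.index_of(ind)] >= 0).sum()

    def test_unrelated_not_flagged(self, twin_world):
        ests = kinship_all_pairs(twin_world.matrix.take_individuals(
            [f"pop_{i}" for i in range(10)]))
        assert detect_identicals(ests) == []

    def test_chained_identity_merges_component(self):
        def est(a, b, degree):
            return KinshipEstimate((a, b), 0.1, 0.25, 0.5, 0.5, 0.01, -50,
                                   degree, 5000, 100)
        ests = [est("A", "B", "identical"), est("B", "C", "identical"),
                est("A", "C", "insufficient-data")]
        assert detect_identicals(ests) == [["A", "B", "C"]]

    def test_merge_conflicts_become_missing(self):
        m = ph_matrix([[0, 2, 0], [2, 2, None]])
        merged, report = merge_individuals(m, ["ind0", "ind1"], "m")
        row = merged.calls[merged.index_of("m")]
        assert row[0] == kinrel.MISSING  # conflict
        assert row[1] == 2
        assert row[2] == 0  # union fills missing
        assert report["n_conflict"] == 1


class TestAutoXDiscordance:
    def est(self, theta, se, chrom_class):
        return KinshipEstimate(("a", "b"), 0.2, 0.25, 1 - theta, theta, se,
                               (1 - theta - 1) / se, "third", 5000, 100,
                               chrom_class)

    def test_paternal_side_flagged(self):
        rep = compare_auto_x(self.est(0.0625, 0.01, "autosomal"),
                             self.est(0.1875, 0.02, "X"))
        assert rep.verdict == "paternal-side"

    def test_concordant(self):
        rep = compare_auto_x(self.est(0.0625, 0.01, "autosomal"),
                             self.est(0.0625, 0.02, "X"))
        assert rep.verdict == "concordant"

    def test_huge_se_inconclusive(self):
        rep = compare_auto_x(self.est(0.0625, 0.2, "autosomal"),
                             self.est(0.25, 0.2, "X"))
        assert rep.verdict == "inconclusive"


@pytest.fixture(scope="module")
def x_world():
    chroms = tuple((str(i), 100_000_000) for i in range(1, 6)) + (("X", 100_000_000),)
    ped = simdata.PedigreeSpec(
        members=[("dad", "M", None, None), ("mom", "F", None, None),
                 ("son", "M", "dad", "mom"), ("dau", "F", "dad", "mom")],
        population="pop",
    )
    specs = [simdata.PopulationSpec("pop", drift=0.05, n_samples=12)]
    cfg = simdata.SimConfig(n_snps=12_000, chromosomes=chroms, seed=11)
    return simdata.simulate_world(specs, cfg, pedigrees=[ped])


class TestKinshipX:
    def test_mother_son_theta_half(self, x_world):
        ests = {frozenset(e.pair): e for e in kinrel.kinship_x(x_world.matrix)}
        e = ests[frozenset(("mom", "son"))]
        assert e.theta == pytest.approx(0.5, abs=3 * e.se)
        assert e.chrom_class == "X"

    def test_father_son_theta_zero(self, x_world):
        ests = {frozenset(e.pair): e for e in kinrel.kinship_x(x_world.matrix)}
        e = ests[frozenset(("dad", "son"))]
        assert e.theta == pytest.approx(0.0, abs=3 * e.se)

    def test_low_x_coverage_insufficient(self, x_world):
        sub = x_world.matrix.x_non_par().take_snps(np.arange(150))
        ests = kinrel.kinship_all_pairs(sub, min_snps=kinrel.MIN_SNPS_X,
                                        chrom_class="X")
        assert all(e.degree == "insufficient-data" for e in ests)
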