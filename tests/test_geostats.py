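import itertools

import numpy as np
import pandas as pd
import pytest

from paleopop import fstats, geostats, simdata
from paleopop.geostats import (
    build_pair_table,
    classical_mds,
    coburial_permutation,
    diversity_permutation,
    haversine_km,
    ibd_regression,
    residuals_by_group,
)


def square(df_vals, ids):
    return pd.DataFrame(np.asarray(df_vals, dtype=float), index=ids, columns=ids)


def toy_tables(n=4, seed=0, lat=None, lon=None, sites=None, dates=None,
               overlap=5000):
    """Small dissimilarity/overlap/meta triple for pair-table tests."""
    rng = np.random.default_rng(seed)
    ids = [f"i{k}" for k in range(n)]
    d = rng.random((n, n)) * 0.05 + 0.8
    d = (d + d.T) / 2
    np.fill_diagonal(d, 0.0)
    meta = pd.DataFrame(
        {
            "id": ids,
            "population": "p",
            "site": sites or ["s0", "s0", "s1", "s2"][:n],
            "building": [None] * n,
            "sex": "F",
            "lat": lat or [0.0, 0.1, 1.0, 2.0][:n],
            "lon": lon or [0.0, 0.1, 1.0, 2.0][:n],
            "date_mean": dates or [8000.0] * n,
        }
    )
    ov = square(np.full((n, n), overlap), ids)
    return square(d, ids), ov, meta


class TestHaversine:
    def test_one_degree_longitude_at_equator(self):
        assert haversine_km(0, 0, 0, 1) == pytest.approx(111.19, abs=0.01)

    def test_symmetric_and_zero(self):
        assert haversine_km(10, 20, 30, 40) == pytest.approx(
            haversine_km(30, 40, 10, 20)
        )
        assert haversine_km(12, 34, 12, 34) == 0.0


class TestPairTable:
    def test_ibd_filters(self):
        diss, ov, meta = toy_tables(dates=[8000, 8000, 9200, 8000])
        full = build_pair_table(diss, ov, meta)
        assert len(full) == 6
        tab = build_pair_table(diss, ov, meta, exclude_same_site=True,
                               max_time_gap=1000, min_overlap=2000)
        pairs = set(map(frozenset, zip(tab["id1"], tab["id2"])))
        assert frozenset(("i0", "i1")) not in pairs  # same site
        assert frozenset(("i0", "i2")) not in pairs  # 1200-year gap
        assert frozenset(("i0", "i3")) in pairs

    def test_low_overlap_excluded(self):
        diss, ov, meta = toy_tables(overlap=1500)
        tab = build_pair_table(diss, ov, meta, min_overlap=2000)
        assert len(tab) == 0

    def test_missing_coordinates_dropped(self):
        diss, ov, meta = toy_tables()
        meta.loc[meta["id"] == "i0", "lat"] = np.nan
        tab = build_pair_table(diss, ov, meta)
        assert not (tab[["id1", "id2"]] == "i0").any().any()


class TestIbdRegression:
    def test_exact_line(self):
        ids = ["a", "b", "c", "d"]
        km = np.array([0.0, 100.0, 200.0, 300.0])
        table = pd.DataFrame(
            {
                "id1": ids[:-1] + ["a"],
                "id2": ids[1:] + ["c"],
                "km": km,
                "genetic_dist": 0.001 + 1e-6 * km,
            }
        )
        fit = ibd_regression(table)
        assert fit.slope == pytest.approx(1e-6, rel=1e-9)
        assert fit.r_squared == pytest.approx(1.0)
        assert abs(fit.residuals.mean()) < 1e-10

    def test_matches_closed_form_ols(self, rng):
        x = rng.uniform(0, 500, 40)
        y = 0.8 + 1e-5 * x + rng.normal(0, 0.01, 40)
        table = pd.DataFrame({"id1": "a", "id2": "b", "km": x, "genetic_dist": y})
        fit = ibd_regression(table)
        xc = x - x.mean()
        slope = (xc * y).sum() / (xc**2).sum()
        intercept = y.mean() - slope * x.mean()
        assert fit.slope == pytest.approx(slope, abs=1e-10)
        assert fit.intercept == pytest.approx(intercept, abs=1e-10)

    def test_zero_variance_x(self):
        table = pd.DataFrame(
            {"id1": "a", "id2": "b", "km": [1.0, 1.0, 1.0],
             "genetic_dist": [0.1, 0.2, 0.3]}
        )
        with pytest.raises(ValueError, match="variance"):
            ibd_regression(table)


class TestResidualsByGroup:
    def test_single_group_p_one(self, rng):
        x = rng.uniform(0, 100, 12)
        table = pd.DataFrame(
            {"id1": "a", "id2": "b", "km": x,
             "genetic_dist": 0.8 + 1e-5 * x + rng.normal(0, 0.01, 12)}
        )
        fit = ibd_regression(table)
        rep = residuals_by_group(fit, ["g"] * 12, n_perm=99, seed=0)
        assert rep["p"].iloc[0] == pytest.approx(1.0)

    def test_null_groups_not_significant(self, rng):
        x = rng.uniform(0, 100, 40)
        table = pd.DataFrame(
            {"id1": "a", "id2": "b", "km": x,
             "genetic_dist": 0.8 + 1e-5 * x + rng.normal(0, 0.01, 40)}
        )
        fit = ibd_regression(table)
        groups = np.where(rng.random(40) < 0.5, "g1", "g2")
        rep = residuals_by_group(fit, groups, n_perm=199, seed=1)
        assert (rep["p_adjusted"] > 0.05).all()


class TestClassicalMds:
    def test_equilateral_triangle(self):
        D = np.ones((3, 3)) - np.eye(3)
        coords, vals = classical_mds(D, k=2)
        for i, j in itertools.combinations(range(3), 2):
            assert np.linalg.norm(coords[i] - coords[j]) == pytest.approx(
                1.0, abs=1e-9
            )

    def test_euclidean_reconstruction_exact(self, rng):
        pts = rng.normal(size=(10, 2))
        D = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
        coords, vals = classical_mds(D, k=2)
        D2 = np.linalg.norm(coords[:, None] - coords[None, :], axis=-1)
        np.testing.assert_allclose(D2, D, atol=1e-9)

    def test_sign_convention_deterministic(self, rng):
        pts = rng.normal(size=(8, 2))
        D = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
        c1, _ = classical_mds(D, k=2)
        c2, _ = classical_mds(D.copy(), k=2)
        np.testing.assert_allclose(c1, c2)
        for ax in range(2):
            assert c1[np.argmax(np.abs(c1[:, ax])), ax] > 0

    def test_masked_entries_imputed(self):
        D = np.ones((4, 4)) - np.eye(4)
        D[0, 1] = D[1, 0] = np.nan
        coords, vals = classical_mds(D, k=2)
        assert np.isfinite(coords).all()

    def test_bad_input(self):
        with pytest.raises(ValueError):
            classical_mds(np.ones((3, 3)), k=2)


class TestPermutationTests:
    def test_coburial_degenerate_grouping(self):
        table = pd.DataFrame(
            {"id1": ["a", "a", "b"], "id2": ["b", "c", "c"],
             "genetic_dist": [0.8, 0.81, 0.82], "close_kin": False}
        )
        with pytest.raises(ValueError, match="degenerate"):
            coburial_permutation(table, {"a": "B1", "b": "B1", "c": "B1"},
                                 n_perm=19, seed=0)

    def test_coburial_addone_bound(self, rng):
        ids = [f"i{k}" for k in range(8)]
        rows = []
        bld = {i: ("B1" if k < 4 else "B2") for k, i in enumerate(ids)}
        for a, b in itertools.combinations(ids, 2):
            same = bld[a] == bld[b]
            rows.append({"id1": a, "id2": b,
                         "genetic_dist": 0.7 + (0.0 if same else 0.2)
                         + rng.normal(0, 1e-4),
                         "close_kin": False})
        table = pd.DataFrame(rows)
        res = coburial_permutation(table, bld, n_perm=199, seed=0)
        assert res.p_value >= 1.0 / (res.n_perm + 1)
        assert res.effect_size > 0

    def test_diversity_requires_two_sites(self):
        diss, ov, meta = toy_tables(sites=["s0", "s0", "s1", "s2"])
        tab = build_pair_table(diss, ov, meta)
        with pytest.raises(ValueError, match="sites"):
            diversity_permutation(tab, meta, n_perm=19, seed=0)

    def test_diversity_detects_planted_low_diversity(self):
        specs = [
            simdata.PopulationSpec("outgroup", drift=0.5, n_samples=4),
            simdata.PopulationSpec("base", drift=0.02, n_samples=0),
            simdata.PopulationSpec("bigpop", drift=0.01,
                                   admixture_of=[("base", 1.0)], n_samples=8),
            simdata.PopulationSpec("smallpop", drift=0.10,
                                   admixture_of=[("base", 1.0)], n_samples=8),
        ]
        plan = {
            "bigpop": dict(site="big", lat=0.0, lon=0.0, date_mean=8000),
            "smallpop": dict(site="small", lat=0.0, lon=1.0, date_mean=8000),
            "outgroup": dict(site="og", lat=50.0, lon=50.0, date_mean=8000),
        }
        w = simdata.simulate_world(specs, simdata.SimConfig(n_snps=6000, seed=5),
                                   meta_plan=plan)
        og = [i for i in w.matrix.individuals if i.startswith("outgroup")]
        diss, ov = fstats.pairwise_f3_matrix(w.matrix, og)
        tab = build_pair_table(diss, ov, w.meta)
        rep = diversity_permutation(tab, w.meta, n_perm=499, seed=0)
        row = rep.iloc[0]
        # extra drift = smaller Ne = lower within-site diversity (lower 1 - f3)
        med = {row["site_a"]: row["median_a"], row["site_b"]: row["median_b"]}
        assert med["small"] < med["big"]
        assert row["p"] < 0.05
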