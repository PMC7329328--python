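"""Degrader ecology: lifestyles, permutation tests, cocktails, Mantel."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from dropculture import ecology
from dropculture.ecology import (
    classify_lifestyle,
    cluster_profiles,
    combo_coverage,
    combo_enrichment,
    mantel_test,
    normalize_by_glucose,
    phylum_lifestyle_permutation,
    primary_degraders,
)

POLYS = ["inulin", "gos", "dextrin", "xylan"]


def growth_matrix(rows, svs=None, columns=None):
    columns = columns or POLYS + ["glucose"]
    svs = svs or [f"sv{i:03d}" for i in range(len(rows))]
    return pd.DataFrame(rows, index=svs, columns=columns, dtype=bool)


class TestDegradersAndLifestyles:
    def test_definitions(self):
        m = growth_matrix([
            [0, 0, 0, 0, 1],   # glucose only -> excluded
            [0, 0, 0, 1, 0],   # xylan only -> specialist
            [1, 1, 0, 0, 1],   # inulin+gos -> generalist
            [0, 0, 0, 0, 0],   # nothing
        ])
        deg = primary_degraders(m, POLYS)
        assert list(deg) == ["sv001", "sv002"]
        labels = classify_lifestyle(m, POLYS)
        assert labels.tolist() == [
            "nondegrader", "specialist", "generalist", "nondegrader"
        ]

    def test_partition_identity(self, rng):
        rows = rng.random((40, 5)) < 0.3
        m = growth_matrix(rows.tolist())
        labels = classify_lifestyle(m, POLYS)
        n_deg = len(primary_degraders(m, POLYS))
        assert (labels == "specialist").sum() + (labels == "generalist").sum() == n_deg

    def test_all_false_empty(self):
        m = growth_matrix([[0, 0, 0, 0, 0]])
        assert len(primary_degraders(m, POLYS)) == 0

    def test_no_polysaccharides_is_error(self):
        m = growth_matrix([[0, 0, 0, 0, 1]])
        with pytest.raises(ValueError):
            primary_degraders(m, [])


class TestNormalizeByGlucose:
    def test_ratios(self):
        pd_stat = pd.Series({"d1": 12.0, "d2": 8.0})
        gc_stat = pd.Series({"d1": 24.0, "d2": 8.0})
        r = normalize_by_glucose(pd_stat, gc_stat)
        assert r["d1"] == 0.5 and r["d2"] == 1.0

    def test_scale_invariance(self):
        pd_stat = pd.Series({"d1": 3.0})
        gc_stat = pd.Series({"d1": 7.0})
        a = normalize_by_glucose(pd_stat, gc_stat)
        b = normalize_by_glucose(10 * pd_stat, 10 * gc_stat)
        pd.testing.assert_series_equal(a, b)

    def test_zero_glucose_flagged_undefined(self):
        with pytest.warns(UserWarning, match="d1"):
            r = normalize_by_glucose(pd.Series({"d1": 2.0}),
                                     pd.Series({"d1": 0.0}))
        assert math.isnan(r["d1"])


def exact_phylum_p(phyla, lifestyles, phylum, kind, observed):
    """Exhaustive-permutation tail probability P(count >= observed)."""
    hits = total = 0
    for perm in itertools.permutations(phyla):
        total += 1
        count = sum(1 for ph, ls in zip(perm, lifestyles)
                    if ph == phylum and ls == kind)
        hits += count >= observed
    return hits / total


class TestPhylumLifestylePermutation:
    def test_matches_exhaustive_enumeration(self):
        # 3 specialists all in phylum X, 3 generalists in Y: exact p = 1/20
        rows = [[1, 0, 0, 0, 1]] * 3 + [[1, 1, 0, 0, 1]] * 3
        m = growth_matrix(rows)
        tax = pd.Series(["X"] * 3 + ["Y"] * 3, index=m.index)
        exact = exact_phylum_p(tax.tolist(),
                               classify_lifestyle(m, POLYS).tolist(),
                               "X", "specialist", 3)
        assert exact == pytest.approx(1 / 20)
        res = phylum_lifestyle_permutation(m, tax, POLYS, n_perm=4000, seed=0)
        assert res[("X", "specialist")].p_value == pytest.approx(exact, abs=0.02)

    def test_single_phylum_p_is_one(self):
        rows = [[1, 0, 0, 0, 1], [1, 1, 0, 0, 1], [0, 0, 0, 1, 1]]
        m = growth_matrix(rows)
        tax = pd.Series(["OnlyOne"] * 3, index=m.index)
        res = phylum_lifestyle_permutation(m, tax, POLYS, n_perm=200, seed=1)
        assert all(r.p_value == 1.0 for r in res.values())

    def test_p_value_invariants(self, rng):
        rows = (rng.random((20, 5)) < 0.4).tolist()
        m = growth_matrix(rows)
        tax = pd.Series(rng.choice(["A", "B", "C"], 20), index=m.index)
        res = phylum_lifestyle_permutation(m, tax, POLYS, n_perm=500, seed=2)
        for r in res.values():
            assert 1 / 501 <= r.p_value <= 1.0
            assert r.p_value == (r.exceed_count + 1) / (r.n_permutations + 1)
        again = phylum_lifestyle_permutation(m, tax, POLYS, n_perm=500, seed=2)
        assert res == again

    def test_planted_association_detected(self):
        # all specialists in phylum A, all generalists in B: strong signal
        rows = [[1, 0, 0, 0, 1]] * 10 + [[1, 1, 1, 0, 1]] * 10
        m = growth_matrix(rows)
        tax = pd.Series(["A"] * 10 + ["B"] * 10, index=m.index)
        res = phylum_lifestyle_permutation(m, tax, POLYS, n_perm=2000, seed=3)
        assert res[("A", "specialist")].p_value < 0.05
        assert res[("B", "generalist")].p_value < 0.05

    def test_few_permutations_warns(self):
        m = growth_matrix([[1, 0, 0, 0, 1], [0, 1, 0, 0, 1]])
        tax = pd.Series(["A", "B"], index=m.index)
        with pytest.warns(UserWarning):
            phylum_lifestyle_permutation(m, tax, POLYS, n_perm=50, seed=0)


class TestComboCoverage:
    def test_full_set_covers_all_degraders(self):
        m = growth_matrix([[1, 0, 0, 0, 1], [0, 0, 0, 1, 0], [0, 1, 1, 0, 1]])
        cov = combo_coverage(m, POLYS, k=len(POLYS))
        assert cov.iloc[0] == 1.0

    def test_k1_equals_prevalence(self):
        m = growth_matrix([[1, 0, 0, 0, 0], [1, 0, 0, 1, 0], [0, 0, 0, 1, 0]])
        cov = combo_coverage(m, POLYS, k=1)
        assert cov[("inulin",)] == pytest.approx(2 / 3)
        assert cov[("xylan",)] == pytest.approx(2 / 3)
        assert cov[("gos",)] == 0.0

    def test_matches_brute_force_counting(self, rng):
        rows = (rng.random((5, 5)) < 0.5).tolist()
        m = growth_matrix(rows)
        if len(primary_degraders(m, POLYS)) == 0:
            pytest.skip("degenerate draw")
        cov = combo_coverage(m, POLYS, k=2)
        deg = m.loc[primary_degraders(m, POLYS), POLYS]
        for combo, frac in cov.items():
            stimulated = sum(
                1 for _, row in deg.iterrows() if any(row[c] for c in combo)
            )
            assert frac == pytest.approx(stimulated / len(deg))

    def test_monotone_in_subset_growth(self, rng):
        rows = (rng.random((12, 5)) < 0.4).tolist()
        m = growth_matrix(rows)
        if len(primary_degraders(m, POLYS)) == 0:
            pytest.skip("degenerate draw")
        cov1 = combo_coverage(m, POLYS, k=1)
        cov2 = combo_coverage(m, POLYS, k=2)
        for combo, frac in cov2.items():
            assert frac >= max(cov1[(combo[0],)], cov1[(combo[1],)]) - 1e-12

    def test_invalid_k(self):
        m = growth_matrix([[1, 0, 0, 0, 0]])
        with pytest.raises(ValueError):
            combo_coverage(m, POLYS, k=9)


class TestComboEnrichment:
    def test_nested_pattern_over_represented(self):
        # every xylan grower also grows on inulin; margins preserved null
        rows = [[1, 0, 0, 1, 0]] * 12 + [[0, 0, 0, 0, 0]] * 12
        m = growth_matrix(rows)
        res = combo_enrichment(m, ["inulin", "xylan"], n_perm=2000, seed=4)
        joint = res.loc[[(True, True)]]
        assert joint["p_over"].iloc[0] < 0.05

    def test_single_carbon_empty_result(self):
        m = growth_matrix([[1, 0, 0, 0, 0]])
        assert combo_enrichment(m, ["inulin"], n_perm=100, seed=0).empty

    def test_independent_columns_null_calibrated(self, rng):
        flagged = trials = 0
        for i in range(30):
            rows = (rng.random((40, 5)) < 0.4).tolist()
            m = growth_matrix(rows)
            res = combo_enrichment(m, POLYS, n_perm=300, seed=100 + i)
            flagged += int((res["p_over"] < 0.05).sum())
            trials += len(res)
        # under independence roughly 5% of patterns flag; allow 3-sigma slack
        rate = flagged / trials
        sigma = math.sqrt(0.05 * 0.95 / trials)
        assert rate < 0.05 + 4 * sigma


class TestClusterProfiles:
    def test_planted_partition_recovered(self, rng):
        single = rng.normal(5.0, 0.2, (10, 1))
        block_a = np.hstack([single, np.zeros((10, 3))])
        block_b = rng.normal(5.0, 0.2, (10, 4))
        data = pd.DataFrame(np.vstack([block_a, block_b]),
                            index=[f"sv{i:03d}" for i in range(20)],
                            columns=POLYS)
        _, labels = cluster_profiles(data, k=2)
        assert labels.iloc[:10].nunique() == 1
        assert labels.iloc[10:].nunique() == 1
        assert labels.iloc[0] != labels.iloc[-1]

    def test_duplicates_share_cluster(self):
        data = pd.DataFrame([[1.0, 2.0], [1.0, 2.0], [9.0, 9.0]],
                            index=["a", "b", "c"], columns=["x", "y"])
        _, labels = cluster_profiles(data, k=2)
        assert labels["a"] == labels["b"] != labels["c"]

    def test_k_equals_n_singletons(self):
        data = pd.DataFrame(np.diag([1.0, 2.0, 3.0]), index=list("abc"))
        _, labels = cluster_profiles(data, k=3)
        assert labels.nunique() == 3

    def test_single_row_rejected(self):
        with pytest.raises(ValueError):
            cluster_profiles(pd.DataFrame([[1.0]]))


def exact_mantel_p(X, Y):
    n = X.shape[0]
    iu = np.triu_indices(n, 1)
    r_obs = np.corrcoef(X[iu], Y[iu])[0, 1]
    hits = total = 0
    for perm in itertools.permutations(range(n)):
        p = np.array(perm)
        total += 1
        r = np.corrcoef(X[iu], Y[np.ix_(p, p)][iu])[0, 1]
        hits += r >= r_obs - 1e-12
    return hits / total


class TestMantel:
    @staticmethod
    def random_distance(rng, n):
        a = rng.random((n, n))
        d = (a + a.T) / 2
        np.fill_diagonal(d, 0.0)
        return d

    def test_identical_matrices(self, rng):
        d = self.random_distance(rng, 6)
        res = mantel_test(d, d, n_perm=999, seed=0)
        assert res.r == pytest.approx(1.0)
        # ties with r_obs arise only when a sampled permutation reproduces
        # the matrix (e.g. the identity), so p sits at the permutation floor
        assert 1 / 1000 <= res.p_value <= 3 / 1000

    def test_matches_exhaustive_enumeration(self, rng):
        X = self.random_distance(rng, 4)
        Y = self.random_distance(rng, 4)
        exact = exact_mantel_p(X, Y)
        res = mantel_test(X, Y, n_perm=9999, seed=1)
        assert res.p_value == pytest.approx(exact, abs=0.03)

    def test_r_matches_reference_implementation(self, rng):
        skbio = pytest.importorskip("skbio")
        from skbio.stats.distance import DistanceMatrix, mantel

        X = self.random_distance(rng, 8)
        Y = self.random_distance(rng, 8)
        r_ref, _, _ = mantel(DistanceMatrix(X), DistanceMatrix(Y),
                             permutations=0)
        res = mantel_test(X, Y, n_perm=99, seed=0)
        assert res.r == pytest.approx(float(r_ref), abs=1e-10)

    def test_independent_matrices_near_zero(self, rng):
        ps, rs = [], []
        for _ in range(20):
            X = self.random_distance(rng, 12)
            Y = self.random_distance(rng, 12)
            res = mantel_test(X, Y, n_perm=199, seed=5)
            ps.append(res.p_value)
            rs.append(res.r)
        assert abs(np.mean(rs)) < 0.15
        assert 0.25 < np.mean(ps) < 0.8

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            mantel_test(np.zeros((2, 2)), np.zeros((2, 2)))
        with pytest.raises(ValueError):
            mantel_test(np.ones((4, 3)), np.ones((4, 3)))
        asym = np.arange(16.0).reshape(4, 4)
        with pytest.raises(ValueError):
            mantel_test(asym, asym)
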