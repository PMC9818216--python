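import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.spatial.distance import pdist, squareform

from gutliver import diversity
from gutliver.diversity import (DistanceMatrix, ace, bray_curtis, chao1,
                                overlap_counts, pcoa, permanova, shannon,
                                simpson)
from gutliver.tables import FeatureTable, SampleMetadata

count_vectors = st.lists(st.integers(min_value=0, max_value=30),
                         min_size=2, max_size=25).filter(lambda v: sum(v) > 0)


class TestAlphaIndices:
    @pytest.mark.parametrize("counts, expected", [
        ([7, 0, 0], 0.0),
        ([5, 5, 5, 5], np.log(4)),
        ([2, 1, 1], 1.039721),
    ])
    def test_shannon_values(self, counts, expected):
        assert shannon(counts) == pytest.approx(expected, abs=1e-6)

    @pytest.mark.parametrize("counts, expected", [
        ([9, 0], 0.0),
        ([5, 5], 0.5),
        ([2, 1, 1], 0.625),
    ])
    def test_simpson_values(self, counts, expected):
        assert simpson(counts) == pytest.approx(expected, abs=1e-9)

    @pytest.mark.parametrize("counts, expected", [
        ([5, 5, 5], 3.0),        # no singletons: estimate equals S_obs
        ([1, 1, 2, 5], 4.5),     # 4 + 2*1/(2*(1+1))
        ([1, 1, 1], 6.0),        # 3 + 3*2/(2*1)
    ])
    def test_chao1_values(self, counts, expected):
        assert chao1(counts) == pytest.approx(expected)

    def test_ace_all_abundant_equals_observed(self):
        assert ace([15, 20, 30]) == 3.0

    def test_ace_hand_evaluated_mixture(self):
        # rare = {1,1,2,3}, N_rare=7, F1=2, C=5/7, gamma^2=1/15
        expected = 1 + 4 / (5 / 7) + (2 / (5 / 7)) * (1 / 15)
        assert ace([1, 1, 2, 3, 12]) == pytest.approx(expected)

    def test_ace_all_singletons_falls_back_to_chao1(self):
        with pytest.warns(UserWarning, match="falling back"):
            val = ace([1, 1, 1])
        assert val == pytest.approx(chao1([1, 1, 1]))

    def test_all_zero_vector_rejected(self):
        for fn in (shannon, simpson):
            with pytest.raises(ValueError, match="all-zero"):
                fn([0, 0])

    def test_non_integer_counts_rejected_by_richness_estimators(self):
        for fn in (chao1, ace):
            with pytest.raises(ValueError, match="integer"):
                fn([1.5, 2.0])

    @given(count_vectors)
    @settings(deadline=None, max_examples=200)
    def test_chao1_at_least_observed_richness(self, counts):
        assert chao1(counts) >= np.count_nonzero(counts) - 1e-12

    @given(count_vectors)
    @settings(deadline=None, max_examples=100)
    def test_adding_a_singleton_never_decreases_ace(self, counts):
        import warnings
        with warnings.catch_warnings():  # singleton-only vectors warn
            warnings.simplefilter("ignore")
            before = ace(counts)
            after = ace(list(counts) + [1])
        assert after >= before - 1e-9

    @given(count_vectors, st.integers(min_value=2, max_value=7))
    @settings(deadline=None, max_examples=100)
    def test_shannon_simpson_scale_invariant(self, counts, k):
        scaled = [c * k for c in counts]
        assert shannon(scaled) == pytest.approx(shannon(counts), abs=1e-9)
        assert simpson(scaled) == pytest.approx(simpson(counts), abs=1e-9)

    def test_matches_reference_implementation(self, rng):
        # independent oracle: scikit-bio on random integer vectors
        skbio_alpha = pytest.importorskip("skbio.diversity.alpha")
        for _ in range(25):
            v = rng.integers(0, 25, size=rng.integers(5, 40))
            if v.sum() == 0:
                continue
            assert shannon(v) == pytest.approx(
                float(skbio_alpha.shannon(v, base=np.e)), abs=1e-10)
            assert simpson(v) == pytest.approx(
                float(skbio_alpha.simpson(v)), abs=1e-10)
            assert chao1(v) == pytest.approx(
                float(skbio_alpha.chao1(v, bias_corrected=True)), abs=1e-10)
            if (v == 1).sum() < (v[(v > 0) & (v <= 10)]).sum():
                assert ace(v) == pytest.approx(float(skbio_alpha.ace(v)), abs=1e-8)


class TestBrayCurtis:
    def _table(self, cols):
        values = pd.DataFrame(cols)
        return FeatureTable("bacteria", values, "counts")

    def test_identical_columns_zero(self):
        d = bray_curtis(self._table({"a": [1, 2], "b": [1, 2]}))
        assert d.matrix[0, 1] == 0.0

    def test_disjoint_supports_one(self):
        d = bray_curtis(self._table({"a": [3, 0], "b": [0, 7]}))
        assert d.matrix[0, 1] == pytest.approx(1.0)

    def test_hand_evaluated_pair(self):
        d = bray_curtis(self._table({"a": [1, 2], "b": [2, 1]}))
        assert d.matrix[0, 1] == pytest.approx(2 / 6)

    def test_symmetry_range_and_zero_diagonal(self, rng):
        values = pd.DataFrame(rng.integers(0, 40, (12, 8)) + 1)
        d = bray_curtis(FeatureTable("virus", values, "counts"))
        assert np.allclose(d.matrix, d.matrix.T)
        assert np.allclose(np.diag(d.matrix), 0)
        assert ((d.matrix >= 0) & (d.matrix <= 1)).all()


class TestPCoA:
    def test_collinear_points_one_positive_eigenvalue(self):
        pts = np.array([0.0, 1.0, 2.0, 5.0])
        d = DistanceMatrix([f"s{i}" for i in range(4)],
                           np.abs(pts[:, None] - pts[None, :]))
        res = pcoa(d)
        assert (res.eigenvalues > 1e-9).sum() == 1
        recon = np.abs(res.coordinates[:, 0][:, None] - res.coordinates[:, 0][None, :])
        np.testing.assert_allclose(recon, d.matrix, atol=1e-9)

    def test_euclidean_reconstruction(self, rng):
        pts = rng.normal(size=(9, 4))
        d = DistanceMatrix([f"s{i}" for i in range(9)],
                           squareform(pdist(pts)))
        res = pcoa(d)
        recon = squareform(pdist(res.coordinates))
        np.testing.assert_allclose(recon, d.matrix, atol=1e-8)

    def test_eigenvalues_sorted_and_fractions_bounded(self, rng):
        values = pd.DataFrame(rng.integers(0, 30, (15, 10)) + 1)
        d = bray_curtis(FeatureTable("bacteria", values, "counts"))
        res = pcoa(d)
        assert (np.diff(res.eigenvalues) <= 1e-9).all()
        assert res.explained_fraction.sum() <= 1 + 1e-9


class TestPermanova:
    def test_null_p_uniformish(self, rng):
        n = 18
        pts = rng.normal(size=(n, 3))
        d = DistanceMatrix([f"s{i}" for i in range(n)], squareform(pdist(pts)))
        ps = []
        for seed in range(40):
            labels = rng.permutation(["A"] * 9 + ["B"] * 9)
            ps.append(permanova(d, labels, n_perm=99, seed=seed)[1])
        assert 0.3 < np.mean(ps) < 0.7

    def test_planted_separation_hits_floor(self, rng):
        # unbalanced groups: the label-swapped permutation is not the same
        # partition, so the p floor of 1/(1+n_perm) is attainable
        a = rng.normal(0, 1, size=(12, 3))
        b = rng.normal(8, 1, size=(8, 3))
        pts = np.vstack([a, b])
        d = DistanceMatrix([f"s{i}" for i in range(20)], squareform(pdist(pts)))
        f, p = permanova(d, ["A"] * 12 + ["B"] * 8, n_perm=999, seed=0)
        assert p == pytest.approx(1 / 1000)

    def test_zero_distances_do_not_crash(self):
        d = DistanceMatrix(["a", "b", "c", "d"], np.zeros((4, 4)))
        f, p = permanova(d, ["A", "A", "B", "B"], n_perm=49, seed=1)
        assert np.isfinite(f)

    def test_degenerate_groups_rejected(self):
        d = DistanceMatrix(["a", "b", "c"], np.zeros((3, 3)))
        with pytest.raises(ValueError):
            permanova(d, ["A", "A", "B"])


class TestOverlap:
    def _table_meta(self, presence):
        # presence: cohort -> set of features, 2 samples per cohort
        feats = sorted({f for s in presence.values() for f in s} | {"pad"})
        cols, labels = {}, {}
        for c, s in presence.items():
            for i in range(2):
                sid = f"{c}{i}"
                cols[sid] = [1 if f in s else 0 for f in feats]
                labels[sid] = c
        table = FeatureTable("bacteria", pd.DataFrame(cols, index=feats), "counts")
        return table, SampleMetadata(pd.Series(labels))

    def test_identical_presence_sets(self):
        s = {"f1", "f2", "f3"}
        table, meta = self._table_meta({"Ctrl": s, "LC": s, "HCC": s})
        oc = overlap_counts(table, meta)
        assert oc.shared_all() >= 3  # 'pad' row is absent everywhere
        assert all(oc.unique(c) == 0 for c in ("Ctrl", "LC", "HCC"))

    def test_disjoint_presence_sets(self):
        table, meta = self._table_meta(
            {"Ctrl": {"a"}, "LC": {"b"}, "HCC": {"c"}})
        oc = overlap_counts(table, meta)
        assert oc.shared_all() == 0
        assert oc.unique("Ctrl") == 1 and oc.unique("LC") == 1 and oc.unique("HCC") == 1

    def test_regions_match_set_arithmetic(self, rng):
        universe = [f"f{i}" for i in range(40)]
        presence = {c: set(rng.choice(universe, size=rng.integers(5, 30),
                                      replace=False))
                    for c in ("Ctrl", "LC", "HCC")}
        table, meta = self._table_meta(presence)
        oc = overlap_counts(table, meta)
        # brute-force region oracle
        for combo, count in oc.regions.items():
            inside = set(universe) | {"pad"}
            for c in ("Ctrl", "LC", "HCC"):
                inside = inside & presence[c] if c in combo else inside - presence[c]
            assert count == len(inside), combo
        assert sum(oc.regions.values()) == oc.union_size
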