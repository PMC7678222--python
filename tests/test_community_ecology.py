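from __future__ import annotations

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.spatial.distance import pdist, squareform

from lakevir.community_ecology import (
    AbundanceMatrix,
    bray_curtis,
    bray_curtis_matrix,
    group_abundance,
    hierarchical_cluster,
    nmds,
    paired_zone_season_scatter,
    relative_abundance,
    rpkg,
    shannon,
    simpson,
    zscore_rows,
)

from ._oracles import average_linkage_heights


def _matrix(vals, samples=None, zones=None, seasons=None):
    vals = np.asarray(vals, dtype=float)
    samples = samples or [f"s{i}" for i in range(vals.shape[1])]
    meta = pd.DataFrame(
        {
            "sample_id": samples,
            "depth_m": [5.0] * len(samples),
            "zone": zones or ["photic"] * len(samples),
            "season": seasons or ["winter"] * len(samples),
        }
    ).set_index("sample_id")
    df = pd.DataFrame(vals, index=[f"sc{i}" for i in range(vals.shape[0])], columns=samples)
    return AbundanceMatrix(values=df, metadata=meta)


class TestRpkg:
    def test_worked_example(self):
        assert rpkg(100, 10_000, 2.0) == pytest.approx(5.0)

    def test_zero_reads(self):
        assert rpkg(0, 10_000, 2.0) == 0.0

    def test_doubling_sample_size_halves_rpkg(self):
        assert rpkg(100, 10_000, 4.0) == pytest.approx(rpkg(100, 10_000, 2.0) / 2)

    def test_zero_length_rejected(self):
        with pytest.raises(ValueError):
            rpkg(100, 0, 2.0)


class TestRelativeAbundance:
    def test_column_normalisation(self):
        m = relative_abundance(_matrix([[2], [3], [5]]))
        assert m.values.iloc[:, 0].tolist() == pytest.approx([0.2, 0.3, 0.5])

    def test_all_zero_column_flagged(self):
        m = relative_abundance(_matrix([[0, 1], [0, 1]]))
        assert m.flagged_columns == ["s0"]
        assert (m.values["s0"] == 0).all()

    def test_columns_sum_to_one(self):
        rng = np.random.default_rng(0)
        m = relative_abundance(_matrix(rng.integers(1, 100, size=(20, 5))))
        np.testing.assert_allclose(m.values.sum(axis=0), 1.0, atol=1e-9)


class TestDiversityIndices:
    def test_shannon_uniform_closed_form(self):
        assert shannon(np.full(4, 0.25)) == pytest.approx(math.log(4), abs=1e-12)

    def test_shannon_single_taxon_zero(self):
        assert shannon(np.array([1.0, 0.0])) == 0.0

    def test_shannon_matches_direct_summation(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            p = rng.dirichlet(np.ones(50))
            direct = -sum(pi * math.log(pi) for pi in p if pi > 0)
            assert shannon(p) == pytest.approx(direct, abs=1e-12)

    def test_shannon_bounded_by_log_richness(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            p = rng.dirichlet(np.ones(30))
            assert shannon(p) <= math.log(30) + 1e-12

    def test_simpson_uniform_and_single(self):
        assert simpson(np.full(2, 0.5)) == pytest.approx(0.5)
        assert simpson(np.array([1.0])) == 0.0
        assert simpson(np.full(10_000, 1e-4)) == pytest.approx(0.9999)

    def test_simpson_bounds(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            p = rng.dirichlet(np.ones(25))
            assert 0.0 <= simpson(p) <= 1 - 1 / 25 + 1e-12

    def test_unnormalised_vector_rejected(self):
        with pytest.raises(ValueError):
            shannon(np.array([0.5, 0.2]))
        with pytest.raises(ValueError):
            simpson(np.array([0.5, 0.2]))


class TestBrayCurtis:
    def test_identity_and_disjoint(self):
        x = np.array([1.0, 2.0, 3.0])
        assert bray_curtis(x, x) == 0.0
        assert bray_curtis(np.array([1.0, 0.0]), np.array([0.0, 2.0])) == 1.0

    def test_formula_on_random_pairs(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            x, y = rng.random(30), rng.random(30)
            expected = np.abs(x - y).sum() / (x + y).sum()
            assert bray_curtis(x, y) == pytest.approx(expected)

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(
        st.lists(st.floats(0, 100), min_size=2, max_size=20),
        st.lists(st.floats(0, 100), min_size=2, max_size=20),
    )
    def test_symmetry_and_range(self, xs, ys):
        n = min(len(xs), len(ys))
        x, y = np.array(xs[:n]), np.array(ys[:n])
        if (x + y).sum() == 0:
            return
        d1, d2 = bray_curtis(x, y), bray_curtis(y, x)
        assert d1 == d2
        assert 0.0 <= d1 <= 1.0

    def test_both_zero_rejected(self):
        with pytest.raises(ValueError):
            bray_curtis(np.zeros(3), np.zeros(3))


class TestZscoreRows:
    def test_symmetric_row(self):
        m = zscore_rows(_matrix([[1, 2, 3]]))
        assert m.values.iloc[0].tolist() == pytest.approx([-1.0, 0.0, 1.0])

    def test_constant_row_flagged_zero(self):
        m = zscore_rows(_matrix([[5, 5, 5], [1, 2, 3]]))
        assert m.flagged_rows == ["sc0"]
        assert (m.values.iloc[0] == 0).all()

    def test_row_means_zero(self):
        rng = np.random.default_rng(5)
        m = zscore_rows(_matrix(rng.random((10, 6))))
        np.testing.assert_allclose(m.values.mean(axis=1), 0.0, atol=1e-12)


class TestHierarchicalCluster:
    def test_identical_samples_merge_first_at_zero(self):
        D = pd.DataFrame(
            [[0, 0, 0.9], [0, 0, 0.9], [0.9, 0.9, 0]],
            index=list("abc"), columns=list("abc"), dtype=float,
        )
        Z, order = hierarchical_cluster(D)
        assert Z[0, 2] == 0.0
        assert {int(Z[0, 0]), int(Z[0, 1])} == {0, 1}

    def test_clear_pair_merges_before_singleton(self):
        D = pd.DataFrame(
            [[0, 0.1, 0.8], [0.1, 0, 0.8], [0.8, 0.8, 0]],
            index=list("abc"), columns=list("abc"), dtype=float,
        )
        Z, _ = hierarchical_cluster(D)
        assert Z[0, 2] == pytest.approx(0.1)

    def test_merge_heights_match_naive_upgma_oracle(self):
        rng = np.random.default_rng(6)
        for _ in range(5):
            pts = rng.random((6, 3))
            D = squareform(pdist(pts))
            Ddf = pd.DataFrame(D, index=list("abcdef"), columns=list("abcdef"))
            Z, _ = hierarchical_cluster(Ddf)
            assert Z[:, 2].tolist() == pytest.approx(average_linkage_heights(D))

    def test_asymmetric_input_rejected(self):
        D = pd.DataFrame([[0, 0.5], [0.4, 0]], index=list("ab"), columns=list("ab"))
        with pytest.raises(ValueError):
            hierarchical_cluster(D)


class TestNmds:
    def test_planted_2d_configuration_recovered(self):
        rng = np.random.default_rng(7)
        X = rng.normal(size=(9, 2))
        D = pd.DataFrame(squareform(pdist(X)), index=range(9), columns=range(9))
        res = nmds(D, seed=0)
        assert res.stress < 0.01
        assert res.stress <= res.initial_stress

    def test_identical_samples_coincide(self):
        D = pd.DataFrame(
            [[0, 0, 0.8], [0, 0, 0.8], [0.8, 0.8, 0]], index=list("abc"), columns=list("abc"),
            dtype=float,
        )
        res = nmds(D, seed=1, n_restarts=5)
        a, b = res.coordinates[0], res.coordinates[1]
        assert np.linalg.norm(a - b) < 0.05 * np.linalg.norm(res.coordinates[2] - a)

    def test_too_few_samples_rejected(self):
        D = pd.DataFrame([[0.0, 1.0], [1.0, 0.0]], index=list("ab"), columns=list("ab"))
        with pytest.raises(ValueError):
            nmds(D, k=2)


class TestGroupAbundance:
    def test_single_label_equals_column_totals(self):
        m = relative_abundance(_matrix([[1, 2], [3, 4]]))
        g = group_abundance(m, {"sc0": "x", "sc1": "x"})
        np.testing.assert_allclose(g.loc["x"], m.values.sum(axis=0))

    def test_no_floor_matches_exhaustive_aggregation(self):
        rng = np.random.default_rng(8)
        m = relative_abundance(_matrix(rng.integers(0, 50, size=(12, 4))))
        grouping = {f"sc{i}": f"g{i % 3}" for i in range(12)}
        g = group_abundance(m, grouping, display_min=0.0)
        for label in {"g0", "g1", "g2"}:
            members = [s for s, l in grouping.items() if l == label]
            np.testing.assert_allclose(g.loc[label], m.values.loc[members].sum(axis=0))

    def test_floor_conserves_totals(self):
        rng = np.random.default_rng(9)
        m = relative_abundance(_matrix(rng.integers(0, 50, size=(30, 4))))
        grouping = {f"sc{i}": f"g{i}" for i in range(30)}  # every scaffold its own group
        g = group_abundance(m, grouping, display_min=0.05)
        assert "other" in g.index
        np.testing.assert_allclose(g.sum(axis=0), m.values.sum(axis=0), atol=1e-9)


class TestPairedScatter:
    def test_zone_specific_scaffold_hits_epsilon_floor(self):
        m = _matrix([[10, 0], [5, 5]], samples=["photic", "aphotic"])
        t = paired_zone_season_scatter(m, [("photic", "aphotic")], epsilon=1e-6)
        row = t[t.scaffold_id == "sc0"].iloc[0]
        assert row.y == 0.0
        assert row.log2_ratio > 20  # ~ log2(10/1e-6)

    def test_symmetric_abundances_zero_ratio(self):
        m = _matrix([[5, 5]], samples=["a", "b"])
        t = paired_zone_season_scatter(m, [("a", "b")])
        assert t.log2_ratio.iloc[0] == 0.0

    def test_missing_sample_rejected(self):
        m = _matrix([[1, 2]])
        with pytest.raises(KeyError):
            paired_zone_season_scatter(m, [("s0", "nope")])

    def test_zone_ratio_dominates_season_ratio_on_blocked_community(
        self, small_community
    ):
        rel = relative_abundance(small_community.counts)
        zone_pairs = [
            ("photic_5m_winter", "aphotic_1250m_winter"),
            ("photic_5m_summer", "aphotic_1250m_summer"),
        ]
        season_pairs = [
            ("photic_5m_winter", "photic_5m_summer"),
            ("aphotic_1250m_winter", "aphotic_1250m_summer"),
        ]
        tz = paired_zone_season_scatter(rel, zone_pairs)
        ts = paired_zone_season_scatter(rel, season_pairs)
        assert tz.log2_ratio.abs().mean() > ts.log2_ratio.abs().mean()
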