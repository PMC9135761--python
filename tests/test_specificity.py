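"""Quantile normalization, K-means organ-specific calling, marker tests,
and hypergeometric overlap enrichment."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
import scipy.stats

from gutdynamics.genomics import GenomicInterval, PeakSet
from gutdynamics.specificity import (
    NormalizedMatrix, call_marker_features_sc, call_organ_specific_peaks,
    depth_normalize, kmeans_partition, log2_transform, overlap_enrichment,
    overlap_enrichment_grid, quantile_normalize, select_high_dispersion_genes,
)


class TestQuantileNormalize:
    def test_forced_arithmetic(self):
        m = pd.DataFrame({"a": [1.0, 2.0, 3.0], "b": [4.0, 5.0, 6.0]})
        out = quantile_normalize(m).values
        assert out["a"].tolist() == [2.5, 3.5, 4.5]
        assert out["b"].tolist() == [2.5, 3.5, 4.5]

    def test_identical_columns_fixed_point(self):
        m = pd.DataFrame({"a": [3.0, 1.0, 2.0], "b": [3.0, 1.0, 2.0]})
        out = quantile_normalize(m).values
        pd.testing.assert_frame_equal(out, m)

    def test_columns_share_sorted_values(self, rng):
        m = pd.DataFrame(rng.lognormal(0, 1, size=(100, 4)), columns=list("abcd"))
        out = quantile_normalize(m).values
        ref = np.sort(out["a"].to_numpy())
        for c in "bcd":
            assert np.allclose(np.sort(out[c].to_numpy()), ref)

    def test_idempotent(self, rng):
        m = pd.DataFrame(rng.normal(0, 1, size=(50, 3)))
        once = quantile_normalize(m).values
        twice = quantile_normalize(once).values
        pd.testing.assert_frame_equal(once, twice)

    def test_single_sample_rejected(self):
        with pytest.raises(ValueError):
            quantile_normalize(pd.DataFrame({"a": [1.0, 2.0]}))

    def test_constant_column_warns(self):
        m = pd.DataFrame({"a": [1.0, 1.0], "b": [2.0, 3.0]})
        with pytest.warns(UserWarning, match="constant"):
            quantile_normalize(m)


class TestHighDispersion:
    def test_constant_gene_never_beats_varying(self):
        m = NormalizedMatrix(
            pd.DataFrame(
                {"s1": [5.0, 1.0], "s2": [5.0, 9.0]}, index=["const", "vary"]
            ),
            "quantile+log",
        )
        assert select_high_dispersion_genes(m, n=1) == ["vary"]

    def test_hand_computed_ranking(self):
        df = pd.DataFrame(
            {"s1": [2.0, 1.0, 4.0], "s2": [6.0, 5.0, 4.0]},
            index=["g1", "g2", "g3"],
        )
        # var/mean (ddof=0): g1 4/4=1, g2 4/3, g3 0
        m = NormalizedMatrix(df, "quantile+log")
        assert select_high_dispersion_genes(m, n=3) == ["g2", "g1", "g3"]

    def test_n_larger_than_genes_warns(self):
        m = NormalizedMatrix(
            pd.DataFrame({"s1": [1.0, 2.0], "s2": [2.0, 1.0]}, index=["a", "b"]),
            "quantile+log",
        )
        with pytest.warns(UserWarning):
            out = select_high_dispersion_genes(m, n=10)
        assert set(out) == {"a", "b"}


class TestKmeans:
    def test_planted_blocks_recovered(self, rng):
        block1 = rng.normal(0, 0.1, size=(20, 3))
        block2 = rng.normal(8, 0.1, size=(20, 3))
        m = NormalizedMatrix(pd.DataFrame(np.vstack([block1, block2])), "x")
        labels, _, _ = kmeans_partition(m, k=2, seed=0)
        first, second = set(labels.iloc[:20]), set(labels.iloc[20:])
        assert len(first) == 1 and len(second) == 1 and first != second

    def test_singleton_clusters_zero_wcss(self, rng):
        m = NormalizedMatrix(pd.DataFrame(rng.normal(size=(5, 2))), "x")
        labels, _, wcss = kmeans_partition(m, k=5, seed=0)
        assert labels.nunique() == 5 and wcss == pytest.approx(0.0, abs=1e-9)

    def test_deterministic_under_seed(self, rng):
        m = NormalizedMatrix(pd.DataFrame(rng.normal(size=(60, 4))), "x")
        l1, _, _ = kmeans_partition(m, k=4, seed=9)
        l2, _, _ = kmeans_partition(m, k=4, seed=9)
        assert (l1 == l2).all()

    def test_too_few_rows_rejected(self):
        m = NormalizedMatrix(pd.DataFrame(np.ones((2, 2))), "x")
        with pytest.raises(ValueError):
            kmeans_partition(m, k=3)


class TestOrganSpecificCalls:
    def _signal(self):
        # 4 organs, deterministic: 12 peaks specific per organ at fold 10,
        # one boundary peak at fold 2.4, plus flat background
        rng = np.random.default_rng(1)
        organs = ["o1", "o2", "o3", "o4"]
        rows, names = [], []
        for oi, organ in enumerate(organs):
            for j in range(12):
                row = np.ones(4)
                row[oi] = 10.0
                rows.append(row * (1 + 0.01 * j))
                names.append(f"{organ}_p{j}")
        row = np.ones(4)
        row[0] = 2.4
        rows.append(row)
        names.append("boundary")
        for j in range(40):
            rows.append(np.ones(4) * (1 + 0.005 * j))
            names.append(f"bg{j}")
        return pd.DataFrame(rows, index=names, columns=organs)

    def test_forced_arithmetic_and_boundary(self):
        sig = self._signal()
        sets = call_organ_specific_peaks(sig, k=5, seed=0)
        o1 = set(sets["o1"].features)
        assert {f"o1_p{j}" for j in range(12)} <= o1
        assert "boundary" not in o1  # 2.4 < 2.5
        for organ in ("o2", "o3", "o4"):
            assert {f"{organ}_p{j}" for j in range(12)} <= set(sets[organ].features)

    def test_sets_disjoint(self):
        sets = call_organ_specific_peaks(self._signal(), k=5, seed=0)
        seen = set()
        for s in sets.values():
            assert not (seen & set(s.features))
            seen |= set(s.features)

    def test_two_organ_minimum(self):
        with pytest.raises(ValueError):
            call_organ_specific_peaks(pd.DataFrame({"a": [1.0, 2.0]}))

    def test_planted_recovery_on_bulk(self, toy_sim):
        cfg, truth = toy_sim["cfg"], toy_sim["truth"]
        norm = depth_normalize(toy_sim["bulk"]["E9.5"])
        sig = pd.DataFrame(
            {o: norm[[c for c in norm if c.startswith(o)]].mean(axis=1) for o in cfg.organs}
        )
        sets = call_organ_specific_peaks(sig, k=6, seed=0)
        planted_by_peak = {
            p: o for o, ps in truth.organ_specific_peaks.items() for p in ps
        }
        for organ in cfg.organs:
            planted = set(truth.organ_specific_peaks[organ])
            got = set(sets[organ].features)
            assert len(got & planted) / len(planted) >= 0.9
            cross = [p for p in got if planted_by_peak.get(p, organ) != organ]
            assert len(cross) / max(len(got), 1) <= 0.05


class TestMarkerFeaturesSc:
    def test_constant_feature_never_called(self):
        m = pd.DataFrame(
            [[5, 5, 5, 5, 5, 5], [9, 8, 9, 1, 1, 2]], index=["flat", "marker"],
            columns=[f"c{i}" for i in range(6)],
        )
        m.loc["pad"] = 20 - m.sum(axis=0)  # equal depths: flat stays flat
        groups = pd.Series(["t"] * 3 + ["o"] * 3, index=m.columns)
        called, stats = call_marker_features_sc(m, groups, "t", fdr_max=1.0, log2fc_min=0.1)
        assert "flat" not in called.features
        assert stats.loc["flat", "log2fc"] == pytest.approx(0.0)

    def test_six_cell_exact_decision(self):
        # depth-normalized values equal raw values (equal depths);
        # marker: {9,8,9} vs {1,1,2} -> exact MWU two-sided p = 0.1
        m = pd.DataFrame(
            [[9, 8, 9, 1, 1, 2], [1, 2, 1, 2, 1, 2], [0, 0, 0, 6, 7, 5]],
            index=["up", "noise", "down"], columns=[f"c{i}" for i in range(6)],
        )
        m.loc["pad"] = [10 - m[c].sum() + 10 for c in m.columns]  # equalize depths
        groups = pd.Series(["t"] * 3 + ["o"] * 3, index=m.columns)
        called, stats = call_marker_features_sc(m, groups, "t", fdr_max=0.2, log2fc_min=1.0)
        assert stats.loc["up", "p"] == pytest.approx(0.1)
        scale = 1e4 / 20  # equal per-cell depth 20, normalized to 1e4
        expected_fc = math.log2((26 / 3 * scale + 1) / (4 / 3 * scale + 1))
        assert stats.loc["up", "log2fc"] == pytest.approx(expected_fc, rel=1e-6)
        assert "up" in called.features and "down" not in called.features

    def test_permutation_labels_destroy_calls(self, rng):
        # empirical false-call rate under label permutation stays below the
        # nominal FDR level
        n_feat, n_cells = 30, 24
        m = pd.DataFrame(
            rng.poisson(20, size=(n_feat, n_cells)).astype(float),
            index=[f"f{i}" for i in range(n_feat)],
            columns=[f"c{i}" for i in range(n_cells)],
        )
        n_called = 0
        for it in range(200):
            perm = rng.permutation(n_cells)
            groups = pd.Series(
                np.array(["t"] * 12 + ["o"] * 12)[perm], index=m.columns
            )
            called, _ = call_marker_features_sc(m, groups, "t", fdr_max=0.05, log2fc_min=0.0)
            n_called += len(called.features)
        rate = n_called / (200 * n_feat)
        assert rate <= 0.05

    def test_small_group_rejected(self):
        m = pd.DataFrame(np.ones((2, 3)), columns=["a", "b", "c"])
        groups = pd.Series(["t", "o", "o"], index=m.columns)
        with pytest.raises(ValueError):
            call_marker_features_sc(m, groups, "t")


def _interval_set(tuples, prefix):
    return PeakSet(
        [GenomicInterval("c", s, e, f"{prefix}{i}") for i, (s, e) in enumerate(tuples)]
    )


class TestOverlapEnrichment:
    def _universe(self, n):
        return _interval_set([(i * 100, i * 100 + 50) for i in range(n)], "u")

    def test_zero_overlap_p_one(self):
        universe = self._universe(10)
        a = _interval_set([(0, 50), (100, 150)], "a")
        b = _interval_set([(500, 550)], "b")
        p, obs, *_ = overlap_enrichment(a, b, universe)
        assert obs == 0 and p == pytest.approx(1.0)

    def test_complete_overlap_exact_p(self):
        universe = self._universe(10)
        tuples = [(i * 100, i * 100 + 50) for i in range(5)]
        a = _interval_set(tuples, "a")
        b = _interval_set(tuples, "b")
        p, obs, *_ = overlap_enrichment(a, b, universe)
        assert obs == 5
        assert p == pytest.approx(1 / math.comb(10, 5))  # 1/252

    @pytest.mark.parametrize("N,K,n", [(8, 3, 4), (10, 5, 5), (12, 6, 3)])
    def test_matches_enumeration(self, N, K, n):
        universe = self._universe(N)
        a_items = list(range(K))
        a = _interval_set([(i * 100, i * 100 + 50) for i in a_items], "a")
        for b_items in [tuple(range(n)), tuple(range(N - n, N))]:
            b = _interval_set([(i * 100, i * 100 + 50) for i in b_items], "b")
            obs = len(set(a_items) & set(b_items))
            # brute-force: all C(N, n) draws of a B-set, tail P(X >= obs)
            hits = total = 0
            for draw in itertools.combinations(range(N), n):
                total += 1
                if len(set(draw) & set(a_items)) >= obs:
                    hits += 1
            p, o, *_ = overlap_enrichment(a, b, universe)
            assert o == obs
            assert p == pytest.approx(hits / total, rel=1e-9)

    def test_empty_universe_rejected(self):
        a = _interval_set([(0, 50)], "a")
        with pytest.raises(ValueError):
            overlap_enrichment(a, a, PeakSet(pd.DataFrame(columns=PeakSet.COLUMNS)))

    def test_grid_bh_monotone(self):
        universe = self._universe(12)
        sets = {
            "x": _interval_set([(i * 100, i * 100 + 50) for i in range(6)], "x"),
            "y": _interval_set([(i * 100, i * 100 + 50) for i in range(6, 12)], "y"),
        }
        grid = overlap_enrichment_grid(sets, sets, universe)
        assert (grid["p_adj"] >= grid["p"] - 1e-12).all()
        assert len(grid) == 4
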