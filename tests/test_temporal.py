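"""Association score, PWM scanning, relative motif enrichment, lineage
restriction, and the exact binomial comparison."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
import scipy.stats

from gutdynamics.genomics import GenomicInterval, MotifModel, PeakSet
from gutdynamics.temporal import (
    AssociationInput, associate_genes_peaks, association_score,
    binomial_proportion_compare, exact_rank_sum_p, lineage_restriction,
    rank_temporal_changes, relative_motif_enrichment, scan_pwm,
)


def gene_frame(positions, contig="c"):
    return pd.DataFrame(
        {
            "contig": contig,
            "start": positions,
            "end": [p + 1_000 for p in positions],
            "name": [f"g{i}" for i in range(len(positions))],
            "strand": "+",
            "tss": positions,
        }
    )


class TestRankTemporalChanges:
    def test_tie_flood_flags_degenerate(self):
        s = pd.Series([3.0, 3.0, 3.0], index=["b", "a", "c"])
        with pytest.warns(UserWarning, match="tied"):
            top, degenerate = rank_temporal_changes(s, s, n_top=2)
        assert degenerate and top == ["a", "b"]

    def test_selected_dominate_excluded(self, rng):
        idx = [f"f{i}" for i in range(100)]
        early = pd.Series(rng.uniform(1, 50, 100), index=idx)
        late = pd.Series(rng.uniform(1, 50, 100), index=idx)
        top, _ = rank_temporal_changes(early, late, n_top=20)
        fc = (late + 0.5) / (early + 0.5)
        assert fc[top].min() >= fc.drop(top).max() - 1e-12

    def test_mismatched_universe_rejected(self):
        a = pd.Series([1.0], index=["x"])
        b = pd.Series([1.0], index=["y"])
        with pytest.raises(ValueError):
            rank_temporal_changes(a, b, n_top=1)


class TestAssociateGenesPeaks:
    def test_half_open_flank_boundary(self):
        genes = gene_frame([100_000])
        at_edge = PeakSet([GenomicInterval("c", 150_000, 150_100, "p0")])
        inside = PeakSet([GenomicInterval("c", 149_999, 150_100, "p1")])
        assert associate_genes_peaks(genes, at_edge)["g0"] == []
        assert associate_genes_peaks(genes, inside)["g0"] == ["p1"]

    def test_one_bp_overlap_counts(self):
        genes = gene_frame([100_000])
        just_in = PeakSet([GenomicInterval("c", 49_000, 50_001, "p0")])
        assert associate_genes_peaks(genes, just_in)["g0"] == ["p0"]

    def test_matches_brute_force(self, rng):
        genes = gene_frame(sorted(rng.integers(60_000, 2_000_000, size=50)))
        starts = rng.integers(0, 2_100_000, size=80)
        peaks = PeakSet(
            pd.DataFrame(
                {
                    "contig": "c",
                    "start": starts,
                    "end": starts + rng.integers(100, 600, size=80),
                    "name": [f"p{i}" for i in range(80)],
                }
            )
        )
        mapping = associate_genes_peaks(genes, peaks, flank_bp=50_000)
        for row in genes.itertuples():
            lo, hi = row.tss - 50_000, row.tss + 50_000
            expected = sorted(
                p.name for p in peaks if p.start < hi and p.end > lo
            )
            assert sorted(mapping[row.name]) == expected

    def test_missing_tss_rejected(self):
        genes = gene_frame([1000]).drop(columns=["tss"])
        with pytest.raises(ValueError):
            associate_genes_peaks(genes, PeakSet(pd.DataFrame(columns=PeakSet.COLUMNS)))


class TestAssociationScore:
    def test_identity_case(self):
        assert association_score(AssociationInput(G=10, O=4, G_T=10, O_T=4)) == 1.0

    def test_forced_arithmetic(self):
        assert association_score(
            AssociationInput(G=10, O=4, G_T=5, O_T=3)
        ) == pytest.approx(1.5)

    def test_zero_background_rejected(self):
        with pytest.raises(ValueError):
            association_score(AssociationInput(G=10, O=0, G_T=5, O_T=0))

    def test_count_invariants(self):
        with pytest.raises(ValueError):
            AssociationInput(G=10, O=4, G_T=5, O_T=5)

    def test_linear_in_target_hits(self):
        base = association_score(AssociationInput(G=100, O=40, G_T=10, O_T=2))
        double = association_score(AssociationInput(G=100, O=40, G_T=10, O_T=4))
        assert double == pytest.approx(2 * base)


class TestScanPwm:
    def _consensus_motif(self, letters="ACGT"):
        order = "ACGT"
        m = np.full((4, len(letters)), 0.001)
        for j, b in enumerate(letters):
            m[order.index(b), j] = 0.997
        return MotifModel("M", m)

    def test_consensus_hits(self):
        motif = self._consensus_motif("ACGT")
        sites = scan_pwm(motif, {"c": "ACGTACGT"}, threshold=1 / 256 + 1e-9)
        assert sites.df["start"].tolist() == [0, 4]

    def test_palindrome_collapses_to_dot_strand(self):
        # ACGT is its own reverse complement
        motif = self._consensus_motif("ACGT")
        sites = scan_pwm(motif, {"c": "ACGTAAAA"}, threshold=1 / 256 + 1e-9)
        assert sites.df["strand"].tolist() == ["."]

    def test_reverse_strand_hit(self):
        motif = self._consensus_motif("AACG")  # revcomp CGTT
        sites = scan_pwm(motif, {"c": "TTCGTTTT"}, threshold=1 / 256 + 1e-9)
        assert sites.df["strand"].tolist() == ["-"]
        assert sites.df["start"].tolist() == [2]

    def test_uniform_pwm_no_sites(self):
        motif = MotifModel("U", np.full((4, 6), 0.25))
        sites = scan_pwm(motif, {"c": "ACGT" * 20}, threshold=0.999)
        assert len(sites) == 0

    def test_threshold_matches_enumeration(self):
        # width-3 motif: compare the DP site threshold against explicit
        # enumeration of all 64 trimers under a uniform background
        rng = np.random.default_rng(0)
        probs = rng.dirichlet(np.ones(4) * 0.3, size=3).T
        motif = MotifModel("E", probs)
        lo = np.log2(probs / 0.25)
        scores = {}
        for trimer in itertools.product(range(4), repeat=3):
            scores[trimer] = sum(lo[b, j] for j, b in enumerate(trimer))
        svals = np.array(sorted(scores.values()))
        threshold = 10 / 64  # admit the top ~10 trimers
        admitted = {t for t, s in scores.items() if (64 - (svals < s).sum()) / 64 <= threshold}
        seq = "".join("ACGT"[b] for t in itertools.product(range(4), repeat=3) for b in t)
        sites = scan_pwm(motif, {"c": seq}, threshold=threshold)
        # every admitted trimer occurring at a scanned position must be hit
        hits = set(sites.df["start"])
        base_idx = {b: i for i, b in enumerate("ACGT")}
        for pos in range(len(seq) - 2):
            t = tuple(base_idx[ch] for ch in seq[pos : pos + 3])
            rc = tuple(3 - b for b in reversed(t))
            expect = t in admitted or rc in admitted
            assert (pos in hits) == expect, (pos, t)


class TestRankSum:
    def test_example_one_third(self):
        assert exact_rank_sum_p([3, 4], [1, 2]) == pytest.approx(1 / 3)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_matches_scipy_exact_without_ties(self, seed):
        r = np.random.default_rng(seed)
        x = r.normal(size=int(r.integers(2, 7)))
        y = r.normal(size=int(r.integers(2, 7)))
        ours = exact_rank_sum_p(x, y)
        ref = scipy.stats.mannwhitneyu(x, y, alternative="two-sided", method="exact").pvalue
        assert ours == pytest.approx(float(ref), rel=1e-9)


class TestRelativeMotifEnrichment:
    def _fixture(self):
        peaks = PeakSet(
            [GenomicInterval("c", i * 1_000, i * 1_000 + 500, f"p{i}") for i in range(4)]
        )
        sites = PeakSet(
            [GenomicInterval("c", i * 1_000 + 10, i * 1_000 + 20, f"s{i}") for i in range(2)]
        )
        names = [f"p{i}" for i in range(4)]
        early = pd.Series(1.0, index=names)
        # overlapping peaks p0/p1 get fold changes {3, 4}; p2/p3 get {1, 2}
        # under fc = (late + 0.5) / (early + 0.5) with early = 1
        late = pd.Series(
            [3 * 1.5 - 0.5, 4 * 1.5 - 0.5, 1 * 1.5 - 0.5, 2 * 1.5 - 0.5], index=names
        )
        return peaks, early, late, sites

    def test_exact_small_group_score(self):
        peaks, early, late, sites = self._fixture()
        (res,) = relative_motif_enrichment(peaks, early, late, {"m": sites})
        assert res.p == pytest.approx(1 / 3)
        assert res.score == pytest.approx(-math.log10(1 / 3))
        assert res.direction == "late-enriched"
        assert res.n_sites_in_peaks == 2

    def test_stage_swap_antisymmetry(self):
        peaks, early, late, sites = self._fixture()
        (fwd,) = relative_motif_enrichment(peaks, early, late, {"m": sites})
        (rev,) = relative_motif_enrichment(peaks, late, early, {"m": sites})
        assert rev.score == pytest.approx(-fwd.score)

    def test_empty_group_flagged(self):
        peaks, early, late, _ = self._fixture()
        nowhere = PeakSet([GenomicInterval("c", 900_000, 900_010, "s")])
        (res,) = relative_motif_enrichment(peaks, early, late, {"m": nowhere})
        assert not res.computable and math.isnan(res.score)

    def test_null_calibration_small(self, rng):
        # random site placement: ~5% of replicates reach |score| >= -log10(.05)
        n_peaks, n_rep = 100, 200
        peaks = PeakSet(
            [GenomicInterval("c", i * 1_000, i * 1_000 + 500, f"p{i}") for i in range(n_peaks)]
        )
        names = [f"p{i}" for i in range(n_peaks)]
        n_sig = 0
        cut = -math.log10(0.05)
        for _ in range(n_rep):
            early = pd.Series(rng.uniform(1, 10, n_peaks), index=names)
            late = pd.Series(rng.uniform(1, 10, n_peaks), index=names)
            chosen = rng.choice(n_peaks, size=30, replace=False)
            sites = PeakSet(
                [GenomicInterval("c", int(i) * 1_000 + 5, int(i) * 1_000 + 15, f"s{i}")
                 for i in chosen]
            )
            (res,) = relative_motif_enrichment(peaks, early, late, {"m": sites})
            n_sig += abs(res.score) >= cut
        assert 0.01 <= n_sig / n_rep <= 0.10


class TestLineageRestriction:
    def test_repression_arithmetic(self):
        # (1 + 0.5)/(3 + 0.5) < 0.5 -> repressed; 0/0 -> fold 1, kept
        assert (1 + 0.5) / (3 + 0.5) < 0.5
        assert (0 + 0.5) / (0 + 0.5) == 1.0

    def _fixture(self):
        # 6 genes at 1 Mb spacing; one common early peak near each gene
        positions = [i * 1_000_000 + 500_000 for i in range(6)]
        genes = gene_frame(positions)
        peak_ivs = [
            GenomicInterval("c", p + 10_000, p + 10_500, f"e{i}", 5.0)
            for i, p in enumerate(positions)
        ]
        early_sets = {
            organ: PeakSet([GenomicInterval(iv.contig, iv.start, iv.end, f"{organ}{i}", 5.0)
                            for i, iv in enumerate(peak_ivs)])
            for organ in ("stomach", "lung", "esophagus", "pharynx")
        }
        # late: stomach keeps peaks for genes 0-2 open; lung keeps 3-5 open
        def subset(idxs, organ):
            return PeakSet([GenomicInterval("c", peak_ivs[i].start, peak_ivs[i].end,
                                            f"L{organ}{i}", 5.0) for i in idxs])
        late_sets = {"stomach": subset([0, 1, 2], "st"), "lung": subset([3, 4, 5], "lu")}
        # genes 3,4 repressed in stomach only; gene 0 repressed in lung only;
        # gene 5 repressed in both
        expr_early = pd.DataFrame({"stomach": 10.0, "lung": 10.0}, index=genes["name"])
        expr_late = pd.DataFrame({"stomach": 10.0, "lung": 10.0}, index=genes["name"])
        expr_late.loc[["g3", "g4"], "stomach"] = 1.0
        expr_late.loc[["g0"], "lung"] = 1.0
        expr_late.loc[["g5"], ["stomach", "lung"]] = 1.0
        return early_sets, late_sets, expr_early, expr_late, genes

    def test_planted_refinement_exact(self):
        early_sets, late_sets, expr_early, expr_late, genes = self._fixture()
        res = lineage_restriction(
            early_sets, late_sets, expr_early, expr_late, genes,
            organ_pair=("stomach", "lung"),
        )
        # stomach-specific repressed: g3, g4 -- their peaks are closed in
        # stomach (open in lung) -> refined fraction 1.0
        assert res.repressed_genes["stomach"] == ["g3", "g4"]
        assert res.counts["stomach"] == (2, 2)
        # lung-specific repressed: g0, whose peak is closed in lung
        assert res.repressed_genes["lung"] == ["g0"]
        assert res.counts["lung"] == (1, 1)
        # g5 repressed in both, but no peak is closed in both organs
        assert res.repressed_genes["both"] == ["g5"]
        assert res.counts["both"] == (0, 1)

    def test_categories_disjoint_exhaustive(self):
        early_sets, late_sets, expr_early, expr_late, genes = self._fixture()
        res = lineage_restriction(early_sets, late_sets, expr_early, expr_late, genes)
        cats = [set(v) for v in res.repressed_genes.values()]
        union = set().union(*cats)
        assert sum(len(c) for c in cats) == len(union)
        fc = (expr_late + 0.5) / (expr_early + 0.5)
        all_repressed = set(fc.index[(fc < 0.5).any(axis=1)])
        assert union == all_repressed
        for cat, refined in res.refined_genes.items():
            assert set(refined) <= set(res.repressed_genes[cat])

    def test_missing_organ_rejected(self):
        early_sets, late_sets, expr_early, expr_late, genes = self._fixture()
        with pytest.raises(ValueError):
            lineage_restriction(early_sets, {}, expr_early, expr_late, genes)


class TestBinomialCompare:
    def test_equal_proportions_not_significant(self):
        assert binomial_proportion_compare(5, 10, 50, 100, "greater") >= 0.5

    def test_exact_tail_sum(self):
        # P(X >= 3 | n=4, p=0.5) = 5/16
        assert binomial_proportion_compare(3, 4, 1, 2, "greater") == pytest.approx(5 / 16)

    @pytest.mark.parametrize("k1,n1,k2,n2", [(3, 7, 2, 5), (9, 12, 1, 3), (0, 5, 4, 8)])
    def test_matches_enumeration(self, k1, n1, k2, n2):
        p0 = k2 / n2
        expected = sum(
            math.comb(n1, k) * p0**k * (1 - p0) ** (n1 - k) for k in range(k1, n1 + 1)
        )
        assert binomial_proportion_compare(k1, n1, k2, n2, "greater") == pytest.approx(expected)

    def test_zero_reference_rejected(self):
        with pytest.raises(ValueError):
            binomial_proportion_compare(1, 2, 0, 0)
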