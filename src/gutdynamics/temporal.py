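"""Temporal statistics: the gene-peak association score, the relative
motif enrichment score, and the early-to-late lineage-restriction
analysis.

The association score compares a target gene set's rate of carrying a
target peak within +/- 50 kb of the TSS against the genome-wide rate:

    score = (O_T / G_T) / (O / G)

where G genes exist in total, O of them have >= 1 target peak in the TSS
flank, and G_T / O_T are the same quantities within the target set.  A
score of 1 means no association beyond background.

The relative motif enrichment score for a motif is the signed -log10 p of
a two-sided rank-sum test comparing early-to-late accessibility fold
changes of motif-overlapping versus motif-free peaks; positive scores
mean motif peaks gain accessibility during development.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats

from .genomics import GenomicInterval, MotifModel, PeakSet, merge_iterative_overlap, overlaps_1bp

__all__ = [
    "AssociationInput",
    "MotifEnrichmentResult",
    "LineageRestrictionResult",
    "rank_temporal_changes",
    "associate_genes_peaks",
    "association_score",
    "scan_pwm",
    "exact_rank_sum_p",
    "rank_sum_p",
    "relative_motif_enrichment",
    "lineage_restriction",
    "binomial_proportion_compare",
]

SCORE_CAP = 320.0


@dataclass
class AssociationInput:
    """Counts entering the association score; flank fixed when built via
    :func:`associate_genes_peaks` (default 50 kb)."""

    G: int
    O: int
    G_T: int
    O_T: int
    flank_bp: int = 50_000

    def __post_init__(self) -> None:
        if not (0 <= self.O_T <= self.G_T <= self.G and self.O_T <= self.O <= self.G):
            raise ValueError("association counts must satisfy O_T <= G_T <= G and O_T <= O <= G")
        if self.flank_bp <= 0:
            raise ValueError("flank_bp must be positive")


@dataclass
class MotifEnrichmentResult:
    motif_id: str
    n_sites_in_peaks: int
    score: float
    direction: str | None
    p: float
    computable: bool = True
    capped: bool = False


@dataclass
class LineageRestrictionResult:
    closed_peaks: dict[str, list[str]]           # per organ + "both"
    repressed_genes: dict[str, list[str]]        # "both" / per-organ specific
    refined_genes: dict[str, list[str]]
    counts: dict[str, tuple[int, int]]           # category -> (k, n)
    binomial_p: dict[str, float] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Temporal ranking and gene-peak association

def rank_temporal_changes(
    early: pd.Series, late: pd.Series, n_top: int, pseudocount: float = 0.5
) -> tuple[list[str], bool]:
    """Top-``n_top`` features by late/early fold change.

    Fold change = (late + pc) / (early + pc) on depth-normalized values;
    ties break by identifier.  Returns (selection, degenerate) where
    degenerate flags an all-tied ranking.
    """
    if not early.index.equals(late.index):
        if set(early.index) != set(late.index):
            raise ValueError("early and late tables must share one feature universe")
        late = late.reindex(early.index)
    fc = (late + pseudocount) / (early + pseudocount)
    degenerate = bool(fc.nunique() == 1)
    if degenerate:
        warnings.warn("all fold changes tied; selection is identifier order")
    order = fc.to_frame("fc").reset_index(names="id")
    order = order.sort_values(["fc", "id"], ascending=[False, True], kind="mergesort")
    return order["id"].head(n_top).to_list(), degenerate


def associate_genes_peaks(
    genes: pd.DataFrame, peaks: PeakSet, flank_bp: int = 50_000
) -> dict[str, list[str]]:
    """Map each gene to the peaks overlapping its TSS +/- flank window.

    A gene is associated with a peak iff the peak overlaps
    [TSS - flank, TSS + flank) by >= 1 bp; strand does not shift the
    window.  Genes without an associated peak map to an empty list.
    """
    if "tss" not in genes.columns or genes["tss"].isna().any():
        raise ValueError("every gene needs a TSS")
    windows = PeakSet(
        pd.DataFrame(
            {
                "contig": genes["contig"],
                "start": np.maximum(0, genes["tss"] - flank_bp),
                "end": genes["tss"] + flank_bp,
                "name": genes["name"],
            }
        )
    )
    pairs, _, _ = overlaps_1bp(windows, peaks)
    win_names = windows.df["name"].to_list()
    peak_names = peaks.df["name"].to_list()
    mapping: dict[str, list[str]] = {g: [] for g in genes["name"]}
    for i, j in pairs:
        mapping[win_names[i]].append(peak_names[j])
    return mapping


def association_score(inp: AssociationInput) -> float:
    """(O_T / G_T) / (O / G); the target set's peak-association enrichment."""
    if inp.G <= 0 or inp.G_T <= 0:
        raise ValueError("G and G_T must be positive")
    if inp.O == 0:
        raise ValueError("O = 0: genome-wide association rate undefined")
    return (inp.O_T / inp.G_T) / (inp.O / inp.G)


# ---------------------------------------------------------------------------
# PWM scanning with exact score p-values

_BASE_INDEX = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate(b"ACGT"):
    _BASE_INDEX[_b] = _i
    _BASE_INDEX[_b + 32] = _i  # lowercase


def _log_odds_int(motif: MotifModel, scale: int = 100) -> np.ndarray:
    """Integer-scaled log2-odds matrix (4 x width)."""
    with np.errstate(divide="ignore"):
        lo = np.log2(motif.matrix / motif.background[:, None])
    lo[np.isneginf(lo)] = -100.0
    return np.round(lo * scale).astype(np.int64)


def _score_pvalues(scores_int: np.ndarray, background: np.ndarray) -> tuple[np.ndarray, int]:
    """Exact tail distribution of the integer score under the background.

    Dynamic programming over per-column score histograms; returns
    (pvalue array, offset) where pvalue[s - offset] = P(S >= s).
    """
    lo = int(scores_int.min(axis=0).sum())
    hi = int(scores_int.max(axis=0).sum())
    col0 = scores_int[:, 0]
    cur: dict[int, float] = {}
    for b in range(4):
        cur[int(col0[b])] = cur.get(int(col0[b]), 0.0) + background[b]
    for j in range(1, scores_int.shape[1]):
        nxt: dict[int, float] = {}
        colj = scores_int[:, j]
        for s, p in cur.items():
            for b in range(4):
                key = s + int(colj[b])
                nxt[key] = nxt.get(key, 0.0) + p * background[b]
        cur = nxt
    keys = np.array(sorted(cur))
    probs = np.array([cur[k] for k in keys])
    full = np.zeros(hi - lo + 1)
    full[keys - lo] = probs
    tail = np.cumsum(full[::-1])[::-1]  # P(S >= s)
    return tail, lo


def scan_pwm(
    motif: MotifModel,
    genome: dict[str, str],
    threshold: float = 1e-4,
    scale: int = 100,
) -> PeakSet:
    """Genome-wide motif sites by log-odds scanning on both strands.

    A position is a site iff the exact p-value of its score under the
    background model (computed by dynamic programming over the score
    histogram) is <= ``threshold``.  Sites found at identical coordinates
    on both strands collapse to one record with strand ".".
    """
    w = motif.width
    fwd = _log_odds_int(motif, scale)
    rev = _log_odds_int(motif.reverse_complement(), scale)
    tail, lo = _score_pvalues(fwd, motif.background)
    # minimal integer score whose tail p-value passes the threshold
    passing = np.flatnonzero(tail <= threshold)
    if len(passing) == 0:
        return PeakSet(pd.DataFrame(columns=PeakSet.COLUMNS))
    min_score = int(passing[0]) + lo

    records = []
    site_id = 0
    for contig in sorted(genome):
        seq = genome[contig]
        if len(seq) < w:
            warnings.warn(f"contig {contig!r} shorter than motif width; skipped")
            continue
        idx = _BASE_INDEX[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
        idx_safe = np.where(idx < 0, 0, idx)
        n_pos = len(seq) - w + 1
        valid = np.ones(n_pos, dtype=bool)
        s_fwd = np.zeros(n_pos, dtype=np.int64)
        s_rev = np.zeros(n_pos, dtype=np.int64)
        for j in range(w):
            sl = idx_safe[j : j + n_pos]
            s_fwd += fwd[sl, j]
            s_rev += rev[sl, j]
            valid &= idx[j : j + n_pos] >= 0
        hit_f = valid & (s_fwd >= min_score)
        hit_r = valid & (s_rev >= min_score)
        for pos in np.flatnonzero(hit_f | hit_r):
            both = hit_f[pos] and hit_r[pos]
            strand = "." if both else ("+" if hit_f[pos] else "-")
            score = max(s_fwd[pos], s_rev[pos]) / scale
            records.append(
                (contig, int(pos), int(pos) + w, f"{motif.id}_site{site_id}", score, strand)
            )
            site_id += 1
    return PeakSet(pd.DataFrame(records, columns=PeakSet.COLUMNS), provenance=f"scan:{motif.id}")


# ---------------------------------------------------------------------------
# Rank-sum tests

def exact_rank_sum_p(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided exact rank-sum p by full enumeration (midranks for ties).

    p = fraction of all C(n, m) group assignments whose rank-sum deviates
    from its expectation at least as much as observed.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    pooled = np.concatenate([x, y])
    ranks = scipy.stats.rankdata(pooled, method="average")
    m, n_tot = len(x), len(pooled)
    w_obs = ranks[:m].sum()
    ew = m * (n_tot + 1) / 2.0
    dev = abs(w_obs - ew)
    count = 0
    total = 0
    for combo in itertools.combinations(range(n_tot), m):
        total += 1
        if abs(ranks[list(combo)].sum() - ew) >= dev - 1e-9:
            count += 1
    return count / total


def rank_sum_p(
    x: np.ndarray, y: np.ndarray, exact_max_group: int = 8, exact_max_total: int = 20
) -> float:
    """Two-sided rank-sum p: exact enumeration for small groups, otherwise
    the normal approximation with continuity and tie correction."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if min(len(x), len(y)) <= exact_max_group and len(x) + len(y) <= exact_max_total:
        return exact_rank_sum_p(x, y)
    res = scipy.stats.mannwhitneyu(
        x, y, alternative="two-sided", method="asymptotic", use_continuity=True
    )
    return float(res.pvalue)


def relative_motif_enrichment(
    peaks: PeakSet,
    early_signal: pd.Series,
    late_signal: pd.Series,
    motif_sites: dict[str, PeakSet],
    pseudocount: float = 0.5,
) -> list[MotifEnrichmentResult]:
    """Signed -log10 rank-sum p comparing fold changes of motif-overlapping
    versus motif-free peaks.

    Per peak, fold change = (late + pc) / (early + pc) on normalized
    signal.  For each motif, peaks split by >= 1 bp overlap with its site
    set; a two-sided rank-sum test compares the two groups' fold changes.
    Positive score (= -log10 p) means the motif-overlapping group has the
    higher fold changes (accessibility gained during development); the
    sign flips otherwise.  Scores are capped at +/- 320 and flagged; a
    motif whose groups are not both nonempty is flagged not-computable.
    """
    names = peaks.df["name"].to_list()
    fc = (
        (late_signal.reindex(names) + pseudocount)
        / (early_signal.reindex(names) + pseudocount)
    ).to_numpy()
    results = []
    for motif_id, sites in motif_sites.items():
        _, in_motif, _ = overlaps_1bp(peaks, sites)
        x, y = fc[in_motif], fc[~in_motif]
        if len(x) == 0 or len(y) == 0:
            results.append(
                MotifEnrichmentResult(motif_id, int(in_motif.sum()), float("nan"), None,
                                      float("nan"), computable=False)
            )
            continue
        p = rank_sum_p(x, y)
        higher = scipy.stats.rankdata(fc)[in_motif].mean() > scipy.stats.rankdata(fc)[~in_motif].mean()
        if p <= 0:
            raw = SCORE_CAP
            capped = True
        else:
            raw = -math.log10(p)
            capped = raw > SCORE_CAP
            raw = min(raw, SCORE_CAP)
        score = raw if higher else -raw
        direction = "late-enriched" if score > 0 else "early-enriched"
        results.append(
            MotifEnrichmentResult(motif_id, int(in_motif.sum()), score, direction, p, capped=capped)
        )
    return results


# ---------------------------------------------------------------------------
# Lineage restriction

def lineage_restriction(
    early_peak_sets: dict[str, PeakSet],
    late_peak_sets: dict[str, PeakSet],
    expr_early: pd.DataFrame,
    expr_late: pd.DataFrame,
    genes: pd.DataFrame,
    organ_pair: tuple[str, str] = ("stomach", "lung"),
    flank_bp: int = 50_000,
    repress_fc: float = 0.5,
    pseudocount: float = 0.5,
) -> LineageRestrictionResult:
    """Early-to-late restriction of shared accessibility and expression.

    1. Common early peaks: the iterative-overlap merge of all early organ
       peak sets, restricted to peaks overlapping >= 1 peak from *every*
       early organ.
    2. Organ-specifically closed peaks: common early peaks with no 1 bp
       overlap in that organ's late set but overlap in the other's; peaks
       absent from both late sets are "closed in both".
    3. Repressed genes per organ of the pair: fold change
       (late + pc) / (early + pc) < ``repress_fc`` on normalized
       expression; categorized as both / first-organ-specific /
       second-organ-specific (pairwise disjoint).
    4. Each category refined to genes whose TSS flank contains >= 1
       correspondingly closed peak; (k, n) = (refined, category size).
    """
    organ_a, organ_b = organ_pair
    for organ in organ_pair:
        if organ not in late_peak_sets:
            raise ValueError(f"late peak set missing for {organ!r}")
        if organ not in expr_early.columns or organ not in expr_late.columns:
            raise ValueError(f"expression table missing organ {organ!r}")
    if not early_peak_sets:
        raise ValueError("no early organ peak sets supplied")

    merged = merge_iterative_overlap(list(early_peak_sets.values()))
    common_mask = np.ones(len(merged), dtype=bool)
    for ps in early_peak_sets.values():
        _, flag, _ = overlaps_1bp(merged, ps)
        common_mask &= flag
    common = PeakSet(merged.df.loc[common_mask], provenance="early-common")

    open_late = {}
    for organ in organ_pair:
        _, flag, _ = overlaps_1bp(common, late_peak_sets[organ])
        open_late[organ] = flag
    closed = {
        organ_a: common.df.loc[~open_late[organ_a] & open_late[organ_b], "name"].to_list(),
        organ_b: common.df.loc[~open_late[organ_b] & open_late[organ_a], "name"].to_list(),
        "both": common.df.loc[~open_late[organ_a] & ~open_late[organ_b], "name"].to_list(),
    }

    shared_genes = expr_early.index.intersection(expr_late.index)
    repressed = {}
    for organ in organ_pair:
        fc = (expr_late.loc[shared_genes, organ] + pseudocount) / (
            expr_early.loc[shared_genes, organ] + pseudocount
        )
        repressed[organ] = set(shared_genes[fc < repress_fc])
    categories = {
        "both": sorted(repressed[organ_a] & repressed[organ_b]),
        organ_a: sorted(repressed[organ_a] - repressed[organ_b]),
        organ_b: sorted(repressed[organ_b] - repressed[organ_a]),
    }

    refined: dict[str, list[str]] = {}
    counts: dict[str, tuple[int, int]] = {}
    for cat, gene_list in categories.items():
        closed_names = set(closed[cat])
        closed_ps = common.subset(closed_names) if closed_names else PeakSet(
            pd.DataFrame(columns=PeakSet.COLUMNS)
        )
        sub_genes = genes[genes["name"].isin(gene_list)]
        if len(sub_genes) and len(closed_ps):
            mapping = associate_genes_peaks(sub_genes, closed_ps, flank_bp=flank_bp)
            kept = sorted(g for g, ps in mapping.items() if ps)
        else:
            kept = []
        refined[cat] = kept
        counts[cat] = (len(kept), len(gene_list))

    binom = {}
    for label, (first, second) in {
        f"{organ_a}_vs_{organ_b}": (organ_a, organ_b),
        f"both_vs_{organ_b}": ("both", organ_b),
    }.items():
        k1, n1 = counts[first]
        k2, n2 = counts[second]
        if n1 > 0 and n2 > 0 and k2 >= 0:
            try:
                binom[label] = binomial_proportion_compare(k1, n1, k2, n2, "greater")
            except ValueError:
                pass
    return LineageRestrictionResult(
        closed_peaks=closed,
        repressed_genes=categories,
        refined_genes=refined,
        counts=counts,
        binomial_p=binom,
    )


def binomial_proportion_compare(
    k1: int, n1: int, k2: int, n2: int, direction: str = "greater"
) -> float:
    """One-sided exact binomial test of k1/n1 against the null p0 = k2/n2.

    Exact tail sum (no normal approximation); ``direction`` is the
    alternative for the first proportion relative to the second.
    """
    if not (0 <= k1 <= n1) or not (0 <= k2 <= n2):
        raise ValueError("need 0 <= k <= n for both proportions")
    if n2 == 0:
        raise ValueError("reference proportion undefined for n2 = 0")
    if direction not in ("greater", "less"):
        raise ValueError("direction must be 'greater' or 'less'")
    p0 = k2 / n2
    return float(scipy.stats.binomtest(k1, n1, p0, alternative=direction).pvalue)
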