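"""Per-cell QC, accessibility-derived gene activity scores, pseudo-bulk
aggregation, and marker-based organ labeling of cell clusters.

The gene score for gene *g* in cell *c* sums fragment counts in 500 bp
bins within 100 kb of the gene body, weighted by an exponentially decaying
function of the bin's distance to the gene-body edge, scaled by a 5-level
gene-length factor, and depth-normalized by the cell's total fragment
count.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse

from .genomics import PeakSet

__all__ = [
    "CellProfile",
    "GeneScoreParams",
    "MarkerTable",
    "compute_tss_enrichment",
    "qc_filter_cells",
    "bin_fragment_counts",
    "count_fragments_in_peaks",
    "compute_gene_scores",
    "make_pseudobulk",
    "assign_organ_labels",
]


@dataclass
class CellProfile:
    barcode: str
    n_fragments: int
    tss_enrichment: float
    cluster: str | None = None
    organ: str | None = None

    def __post_init__(self) -> None:
        if self.n_fragments < 0:
            raise ValueError("n_fragments must be >= 0")


@dataclass
class GeneScoreParams:
    """Tunable constants of the gene activity model.

    ``floor_weight`` keeps distal in-window bins from vanishing entirely;
    the default e^-1 makes w(0) = 1 + e^-1 and w(decay_bp) = 2 e^-1.
    """

    bin_bp: int = 500
    window_bp: int = 100_000
    decay_bp: float = 5_000.0
    floor_weight: float = math.exp(-1.0)
    n_length_levels: int = 5
    depth_norm_target: float = 10_000.0

    def __post_init__(self) -> None:
        if self.bin_bp <= 0:
            raise ValueError("bin_bp must be positive")
        if self.window_bp % self.bin_bp != 0:
            raise ValueError("window_bp must be a multiple of bin_bp")
        if self.n_length_levels < 1:
            raise ValueError("n_length_levels must be >= 1")

    def weight(self, distance_bp: np.ndarray | float) -> np.ndarray | float:
        """Distance weight w(d) = exp(-d / decay_bp) + floor_weight."""
        return np.exp(-np.asarray(distance_bp, dtype=float) / self.decay_bp) + self.floor_weight


@dataclass
class MarkerTable:
    """Organ -> marker gene identifiers, with optional secondary tables.

    ``secondary`` maps a parent organ label to a nested organ -> markers
    mapping used to refine clusters first assigned to the parent (one
    level of recursion), mirroring how broadly accessible foregut clusters
    are subdivided by accessibility at finer markers.
    """

    primary: dict[str, list[str]]
    secondary: dict[str, dict[str, list[str]]] | None = None

    def validate_against(self, gene_names: set[str]) -> None:
        tables = [self.primary] + list((self.secondary or {}).values())
        for table in tables:
            for organ, markers in table.items():
                missing = set(markers) - gene_names
                if missing:
                    raise ValueError(
                        f"markers for {organ!r} absent from annotation: {sorted(missing)}"
                    )


# ---------------------------------------------------------------------------
# TSS enrichment and QC

def compute_tss_enrichment(
    fragments: pd.DataFrame,
    genes: pd.DataFrame,
    tss_flank_bp: int = 50,
    background_band: tuple[int, int] = (1901, 2000),
) -> pd.Series:
    """Per-cell TSS enrichment score.

    Score = mean per-bp insertion count within +/- ``tss_flank_bp`` of the
    TSSs, divided by the mean per-bp insertion count in the distal
    ``background_band`` (bp distances on both sides of each TSS).  Both
    fragment ends count as insertions.  Cells with zero background
    coverage score 0.
    """
    if len(genes) == 0:
        raise ValueError("need at least one TSS")
    barcodes = pd.Index(fragments["barcode"].unique()) if len(fragments) else pd.Index([])
    if len(fragments) == 0:
        warnings.warn("empty fragment stream: all TSS enrichment scores are 0")
        return pd.Series(0.0, index=barcodes)

    cell_codes, cell_index = pd.factorize(fragments["barcode"], sort=True)
    n_cells = len(cell_index)
    tss_counts = np.zeros(n_cells)
    bg_counts = np.zeros(n_cells)
    lo_bg, hi_bg = background_band

    # both Tn5 insertion sites per fragment
    ins_pos = np.concatenate([fragments["start"].to_numpy(), fragments["end"].to_numpy() - 1])
    ins_cell = np.concatenate([cell_codes, cell_codes])
    ins_contig = np.concatenate([fragments["contig"].to_numpy()] * 2)

    order = np.lexsort((ins_pos, ins_contig))
    ins_pos, ins_cell, ins_contig = ins_pos[order], ins_cell[order], ins_contig[order]

    contig_bounds: dict[str, tuple[int, int]] = {}
    start = 0
    for i in range(1, len(ins_contig) + 1):
        if i == len(ins_contig) or ins_contig[i] != ins_contig[start]:
            contig_bounds[ins_contig[start]] = (start, i)
            start = i

    for row in genes.itertuples():
        bounds = contig_bounds.get(row.contig)
        if bounds is None:
            continue
        s, e = bounds
        pos, cells = ins_pos[s:e], ins_cell[s:e]
        lo = np.searchsorted(pos, row.tss - hi_bg)
        hi = np.searchsorted(pos, row.tss + hi_bg + 1)
        d = np.abs(pos[lo:hi] - row.tss)
        c = cells[lo:hi]
        np.add.at(tss_counts, c[d <= tss_flank_bp], 1)
        np.add.at(bg_counts, c[(d >= lo_bg) & (d <= hi_bg)], 1)

    n_tss = len(genes)
    tss_bp = n_tss * (2 * tss_flank_bp + 1)
    bg_bp = n_tss * 2 * (hi_bg - lo_bg + 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        score = (tss_counts / tss_bp) / (bg_counts / bg_bp)
    score[bg_counts == 0] = 0.0
    return pd.Series(score, index=cell_index).reindex(barcodes, fill_value=0.0)


def qc_filter_cells(
    profiles: pd.DataFrame, min_fragments: int = 1000, min_tss: float = 4.0
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Keep cells with n_fragments >= min_fragments and TSS score >= min_tss.

    Both thresholds are strict "less than" removals, so a cell at exactly
    1000 fragments and TSS 4.0 is retained.  Returns (retained, report)
    where report counts removals per criterion.
    """
    low_frag = profiles["n_fragments"] < min_fragments
    low_tss = profiles["tss_enrichment"] < min_tss
    retained = profiles.loc[~(low_frag | low_tss)].copy()
    report = {
        "n_input": int(len(profiles)),
        "removed_low_fragments": int(low_frag.sum()),
        "removed_low_tss": int(low_tss.sum()),
        "n_retained": int(len(retained)),
    }
    return retained, report


# ---------------------------------------------------------------------------
# Count matrices

def bin_fragment_counts(
    fragments: pd.DataFrame, bin_bp: int, contig_lengths: dict[str, int]
) -> tuple[scipy.sparse.csr_matrix, pd.DataFrame, pd.Index]:
    """Fragment counts per (contig, bin) x cell; fragments bin by start position.

    Returns (matrix, bins, barcodes) where bins has columns (contig, bin).
    """
    contigs = sorted(contig_lengths)
    n_bins_per = {c: -(-contig_lengths[c] // bin_bp) for c in contigs}
    offsets = {}
    total = 0
    for c in contigs:
        offsets[c] = total
        total += n_bins_per[c]
    cell_codes, barcodes = pd.factorize(fragments["barcode"], sort=True)
    off = fragments["contig"].map(offsets).to_numpy()
    rows = off + fragments["start"].to_numpy() // bin_bp
    counts = fragments["count"].to_numpy() if "count" in fragments else np.ones(len(fragments))
    mat = scipy.sparse.coo_matrix(
        (counts, (rows, cell_codes)), shape=(total, len(barcodes))
    ).tocsr()
    bins = pd.DataFrame(
        {
            "contig": np.repeat(contigs, [n_bins_per[c] for c in contigs]),
            "bin": np.concatenate([np.arange(n_bins_per[c]) for c in contigs]),
        }
    )
    return mat, bins, pd.Index(barcodes)


def count_fragments_in_peaks(
    fragments: pd.DataFrame, peaks: PeakSet
) -> tuple[scipy.sparse.csr_matrix, pd.Index, pd.Index]:
    """Peak x cell fragment counts; a fragment is assigned to the peak
    containing its start position (peaks are non-overlapping).

    The matrix total equals the number of fragment records assigned to
    peaks (conservation).
    """
    cell_codes, barcodes = pd.factorize(fragments["barcode"], sort=True)
    pdf = peaks.df
    rows_all, cols_all, vals_all = [], [], []
    counts = fragments["count"].to_numpy() if "count" in fragments else np.ones(len(fragments), dtype=int)
    for contig in pdf["contig"].unique():
        pmask = (pdf["contig"] == contig).to_numpy()
        pidx = np.flatnonzero(pmask)
        p_start = pdf["start"].to_numpy()[pidx]
        p_end = pdf["end"].to_numpy()[pidx]
        fmask = (fragments["contig"] == contig).to_numpy()
        fpos = fragments["start"].to_numpy()[fmask]
        j = np.searchsorted(p_start, fpos, side="right") - 1
        ok = (j >= 0) & (fpos < p_end[np.clip(j, 0, None)])
        rows_all.append(pidx[j[ok]])
        cols_all.append(cell_codes[fmask][ok])
        vals_all.append(counts[fmask][ok])
    if rows_all:
        rows = np.concatenate(rows_all)
        cols = np.concatenate(cols_all)
        vals = np.concatenate(vals_all)
    else:
        rows = cols = vals = np.array([], dtype=int)
    mat = scipy.sparse.coo_matrix(
        (vals, (rows, cols)), shape=(len(pdf), len(barcodes))
    ).tocsr()
    return mat, pd.Index(pdf["name"]), pd.Index(barcodes)


# ---------------------------------------------------------------------------
# Gene scores

def compute_gene_scores(
    bin_matrix: scipy.sparse.spmatrix,
    bins: pd.DataFrame,
    barcodes: pd.Index,
    genes: pd.DataFrame,
    params: GeneScoreParams | None = None,
    cell_totals: np.ndarray | None = None,
) -> pd.DataFrame:
    """Gene x cell activity scores from a binned fragment matrix.

    score(g, c) = L(g) * sum_b w(d_b) count(b, c) / depth(c) * target,
    with w(d) = exp(-d/decay) + floor and d the distance from the bin
    center to the nearest gene-body edge (0 inside the body).  L(g) is a
    5-level length factor, linearly spaced from ``n_length_levels``
    (smallest genes) down to 1 (largest), by quantile of the total region
    size (body + both flanks).  Zero-depth cells get all-zero columns.
    """
    params = params or GeneScoreParams()
    bin_matrix = scipy.sparse.csr_matrix(bin_matrix)
    if cell_totals is None:
        cell_totals = np.asarray(bin_matrix.sum(axis=0)).ravel()
    n_genes, n_cells = len(genes), bin_matrix.shape[1]

    bin_offset: dict[str, int] = {}
    n_bins_contig: dict[str, int] = {}
    for contig, grp in bins.groupby("contig", sort=False):
        bin_offset[contig] = int(grp.index[0])
        n_bins_contig[contig] = len(grp)

    region = (genes["end"] - genes["start"]).to_numpy() + 2 * params.window_bp
    n_levels = min(params.n_length_levels, max(n_genes, 1))
    if n_levels <= 1:
        factors = np.ones(n_genes)
    else:
        levels = pd.qcut(
            pd.Series(region).rank(method="first"), n_levels, labels=False
        ).to_numpy()
        factors = np.linspace(params.n_length_levels, 1.0, n_levels)[levels]

    rows, cols, vals = [], [], []
    for gi, row in enumerate(genes.itertuples()):
        if row.contig not in bin_offset:
            continue
        off = bin_offset[row.contig]
        nb = n_bins_contig[row.contig]
        lo_bin = max(0, (row.start - params.window_bp) // params.bin_bp)
        hi_bin = min(nb - 1, (row.end + params.window_bp) // params.bin_bp)
        b = np.arange(lo_bin, hi_bin + 1)
        center = b * params.bin_bp + params.bin_bp // 2
        d = np.maximum(0, np.maximum(row.start - center, center - row.end + 1))
        w = params.weight(d) * factors[gi]
        rows.append(np.full(len(b), gi))
        cols.append(off + b)
        vals.append(w)
    if rows:
        weight_mat = scipy.sparse.coo_matrix(
            (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
            shape=(n_genes, bin_matrix.shape[0]),
        ).tocsr()
        raw = np.asarray((weight_mat @ bin_matrix).todense())
    else:
        raw = np.zeros((n_genes, n_cells))
    with np.errstate(divide="ignore", invalid="ignore"):
        scores = raw / cell_totals[None, :] * params.depth_norm_target
    scores[:, cell_totals == 0] = 0.0
    return pd.DataFrame(scores, index=genes["name"].to_list(), columns=barcodes)


# ---------------------------------------------------------------------------
# Pseudo-bulk and labeling

def make_pseudobulk(
    matrix: scipy.sparse.spmatrix | np.ndarray | pd.DataFrame,
    labels: pd.Series,
) -> pd.DataFrame:
    """Sum feature x cell counts into feature x group pseudo-bulk columns.

    Column order follows first appearance of each label; the grand total
    is conserved.  Every cell must be labeled.
    """
    if isinstance(matrix, pd.DataFrame):
        index = matrix.index
        mat = scipy.sparse.csr_matrix(matrix.to_numpy())
        labels = labels.reindex(matrix.columns)
    else:
        index = pd.RangeIndex(matrix.shape[0])
        mat = scipy.sparse.csr_matrix(matrix)
    if labels.isna().any():
        raise ValueError("every cell must carry a group label")
    if mat.shape[1] != len(labels):
        raise ValueError("label length does not match cell count")
    groups = list(dict.fromkeys(labels))
    cols = {}
    lab = np.asarray(labels)
    for g in groups:
        sel = np.flatnonzero(lab == g)
        cols[g] = np.asarray(mat[:, sel].sum(axis=1)).ravel()
    return pd.DataFrame(cols, index=index)


def assign_organ_labels(
    gene_scores: pd.DataFrame,
    clusters: pd.Series,
    markers: MarkerTable,
) -> tuple[dict[str, str], list[str]]:
    """Label each cluster with the organ whose markers score highest.

    Per cluster, the mean marker gene score is computed per organ and
    z-scored across clusters; the argmax organ wins.  If that organ has a
    declared secondary marker table, the cluster is re-assigned within it
    using the secondary markers (one level of recursion).  Ties break by
    declared organ order and are flagged.  Empty clusters are skipped with
    a warning.

    Returns (cluster -> organ, flagged tie clusters).
    """
    markers.validate_against(set(gene_scores.index))
    clusters = clusters.reindex(gene_scores.columns)
    cluster_ids = list(dict.fromkeys(clusters.dropna()))
    flagged: list[str] = []

    def _organ_table(table: dict[str, list[str]], cols: pd.DataFrame) -> pd.DataFrame:
        # cols: marker-mean matrix (cluster x organ)
        data = {
            organ: cols.loc[:, gene_scores.index.isin(genes)].mean(axis=1)
            if len(genes)
            else pd.Series(0.0, index=cols.index)
            for organ, genes in table.items()
        }
        return pd.DataFrame(data)

    # cluster x gene mean score matrix
    means = {}
    for cl in cluster_ids:
        cells = clusters.index[clusters == cl]
        if len(cells) == 0:
            warnings.warn(f"cluster {cl!r} has no cells; skipped")
            continue
        means[cl] = gene_scores[cells].mean(axis=1)
    mean_df = pd.DataFrame(means).T  # cluster x gene
    if mean_df.empty:
        return {}, []
    z = (mean_df - mean_df.mean(axis=0)) / mean_df.std(axis=0, ddof=0)
    z = z.fillna(0.0)

    organ_scores = _organ_table(markers.primary, z)
    assignment: dict[str, str] = {}
    organ_order = list(markers.primary)
    for cl in organ_scores.index:
        row = organ_scores.loc[cl]
        best = row.max()
        winners = [o for o in organ_order if row[o] == best]
        if len(winners) > 1:
            flagged.append(cl)
        organ = winners[0]
        if markers.secondary and organ in markers.secondary:
            sub_table = markers.secondary[organ]
            cells = clusters.index[clusters == cl]
            # z-score marker genes across all cells, then mean per sub-organ
            cell_z = gene_scores.sub(gene_scores.mean(axis=1), axis=0).div(
                gene_scores.std(axis=1, ddof=0).replace(0.0, 1.0), axis=0
            )
            sub_scores = {
                sub: cell_z.loc[cell_z.index.isin(genes), cells].to_numpy().mean()
                if len(genes)
                else -np.inf
                for sub, genes in sub_table.items()
            }
            best_sub = max(sub_scores.values())
            sub_winners = [s for s in sub_table if sub_scores[s] == best_sub]
            if len(sub_winners) > 1 and cl not in flagged:
                flagged.append(cl)
            organ = sub_winners[0]
        assignment[cl] = organ
    return assignment, flagged
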