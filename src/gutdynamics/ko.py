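"""Knockout peak-fate analysis.

Peaks on the merged KO/WT peak set are partitioned into gained,
maintained, and lost by the KO/WT signal fold change (threshold 2, with a
0.5 pseudocount on normalized counts).  Peak sets are projected onto
single cells as deviation z-scores against depth expectation and
accessibility-matched background peak sets, and differentially expressed
genes are categorized by which peak-fate sets sit within 50 kb of their
TSS.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse

from .genomics import PeakSet, overlaps_1bp
from .temporal import associate_genes_peaks

__all__ = [
    "KOPeakCategories",
    "DeviationScores",
    "GeneCategoryTable",
    "categorize_ko_peaks",
    "deviation_zscore",
    "organ_overlap_fractions",
    "categorize_genes_by_peakset",
    "summarize_category_percentages",
]

CATEGORY_NAMES = ("gained", "maintained", "lost")


@dataclass
class KOPeakCategories:
    gained: list[str]
    maintained: list[str]
    lost: list[str]
    fold_threshold: float = 2.0

    def __post_init__(self) -> None:
        sets = [set(self.gained), set(self.maintained), set(self.lost)]
        total = sum(len(s) for s in sets)
        if len(sets[0] | sets[1] | sets[2]) != total:
            raise ValueError("gained/maintained/lost must be disjoint")

    def as_dict(self) -> dict[str, list[str]]:
        return {"gained": self.gained, "maintained": self.maintained, "lost": self.lost}


@dataclass
class DeviationScores:
    raw: pd.Series
    z: pd.Series
    n_background: int
    seed: int


@dataclass
class GeneCategoryTable:
    """Per-gene peak-fate association flags with UpSet-style classes."""

    table: pd.DataFrame          # columns: origin, gene, gained, maintained, lost, cls
    excluded: dict[str, int] = field(default_factory=dict)


def categorize_ko_peaks(
    ko_counts: pd.DataFrame,
    wt_counts: pd.DataFrame,
    merged: PeakSet,
    fold: float = 2.0,
    pseudocount: float = 0.5,
) -> KOPeakCategories:
    """Partition the merged peak set by KO/WT fold change.

    Inputs are depth-normalized counts on the merged set (one column per
    replicate; replicates are averaged).  FC = (KO + pc) / (WT + pc);
    FC > fold -> gained, FC < 1/fold -> lost, otherwise maintained
    (strict inequalities).
    """
    names = merged.df["name"]
    for tab, label in ((ko_counts, "KO"), (wt_counts, "WT")):
        missing = set(names) - set(tab.index)
        if missing:
            raise ValueError(f"{label} table missing {len(missing)} merged peaks")
    ko = ko_counts.loc[names].mean(axis=1)
    wt = wt_counts.loc[names].mean(axis=1)
    fc = (ko + pseudocount) / (wt + pseudocount)
    gained = names[(fc > fold).to_numpy()].to_list()
    lost = names[(fc < 1.0 / fold).to_numpy()].to_list()
    maintained = names[((fc <= fold) & (fc >= 1.0 / fold)).to_numpy()].to_list()
    return KOPeakCategories(gained, maintained, lost, fold_threshold=fold)


def deviation_zscore(
    cell_matrix: scipy.sparse.spmatrix | np.ndarray,
    peak_names: pd.Index,
    barcodes: pd.Index,
    annotation: set[str] | list[str],
    n_background: int = 50,
    seed: int = 0,
    n_bins: int = 10,
) -> DeviationScores:
    """Per-cell accessibility deviation of a peak set, standardized
    against accessibility-matched background peak sets.

    Expected in-set count per cell = cell depth x (set total / grand
    total); raw deviation = (observed - expected) / expected.  Each of
    ``n_background`` background sets samples, for every annotation peak,
    a peak from the same mean-accessibility decile; the z-score
    standardizes the raw deviation by the background mean and SD.
    Deterministic under ``seed``.
    """
    if n_background < 2:
        raise ValueError("n_background must be >= 2")
    mat = scipy.sparse.csr_matrix(cell_matrix)
    annotation = set(annotation)
    unknown = annotation - set(peak_names)
    if unknown:
        raise ValueError(f"{len(unknown)} annotation peaks absent from matrix")
    idx = np.flatnonzero(peak_names.isin(annotation))
    row_totals = np.asarray(mat.sum(axis=1)).ravel()
    depth = np.asarray(mat.sum(axis=0)).ravel()
    grand = depth.sum()
    if row_totals[idx].sum() == 0:
        raise ValueError("annotation peak set has zero total counts")

    bins = pd.qcut(
        pd.Series(row_totals).rank(method="first"), min(n_bins, len(row_totals)), labels=False
    ).to_numpy()
    by_bin = {b: np.flatnonzero(bins == b) for b in np.unique(bins)}

    def _raw(peak_idx: np.ndarray) -> np.ndarray:
        obs = np.asarray(mat[peak_idx].sum(axis=0)).ravel()
        expected = depth * (row_totals[peak_idx].sum() / grand)
        with np.errstate(divide="ignore", invalid="ignore"):
            r = (obs - expected) / expected
        r[expected == 0] = 0.0
        return r

    raw = _raw(idx)
    rng = np.random.default_rng(int(seed) % (2**31))
    bg = np.empty((n_background, mat.shape[1]))
    ann_bins = bins[idx]
    for b in range(n_background):
        sampled = np.array(
            [by_bin[bb][rng.integers(0, len(by_bin[bb]))] for bb in ann_bins]
        )
        bg[b] = _raw(sampled)
    mu = bg.mean(axis=0)
    sd = bg.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = (raw - mu) / sd
    z[sd == 0] = 0.0
    return DeviationScores(
        raw=pd.Series(raw, index=barcodes),
        z=pd.Series(z, index=barcodes),
        n_background=n_background,
        seed=seed,
    )


def organ_overlap_fractions(
    categories: KOPeakCategories,
    merged: PeakSet,
    organ_sets: dict[str, PeakSet],
) -> pd.DataFrame:
    """Fraction of each peak-fate category overlapping each organ set.

    fraction(category, organ) = |category peaks with >= 1 bp overlap of
    the organ set| / |category peaks|; empty categories yield NaN.
    """
    out = {}
    for cat, names in categories.as_dict().items():
        sub = merged.subset(names)
        row = {}
        for organ, ps in organ_sets.items():
            if len(sub) == 0:
                row[organ] = float("nan")
            else:
                _, flag, _ = overlaps_1bp(sub, ps)
                row[organ] = flag.sum() / len(sub)
        out[cat] = row
    return pd.DataFrame(out).T.loc[list(CATEGORY_NAMES)]


def categorize_genes_by_peakset(
    de_genes: dict[str, list[str]],
    categories: KOPeakCategories,
    genes: pd.DataFrame,
    merged: PeakSet,
    flank_bp: int = 50_000,
) -> GeneCategoryTable:
    """Flag each DE gene by which peak-fate sets sit within its TSS flank.

    ``de_genes`` maps an origin label (e.g. KO-specific / WT-specific) to
    a gene-identifier list.  The intersection class is the exact flag
    combination ("gained+lost", "none", ...); a gene uniquely associated
    with one category carries only that flag.  Genes absent from the
    annotation are excluded and counted.
    """
    assoc_flags: dict[str, dict[str, bool]] = {}
    known = set(genes["name"])
    all_de = sorted({g for lst in de_genes.values() for g in lst})
    present = [g for g in all_de if g in known]
    sub_genes = genes[genes["name"].isin(present)]
    for cat, names in categories.as_dict().items():
        ps = merged.subset(names)
        if len(sub_genes) and len(ps):
            mapping = associate_genes_peaks(sub_genes, ps, flank_bp=flank_bp)
        else:
            mapping = {g: [] for g in present}
        assoc_flags[cat] = {g: bool(mapping.get(g)) for g in present}

    rows = []
    excluded: dict[str, int] = {}
    for origin, gene_list in de_genes.items():
        n_missing = sum(1 for g in gene_list if g not in known)
        if n_missing:
            excluded[origin] = n_missing
        for g in gene_list:
            if g not in known:
                continue
            flags = {cat: assoc_flags[cat][g] for cat in CATEGORY_NAMES}
            on = [cat for cat in CATEGORY_NAMES if flags[cat]]
            cls = "+".join(on) if on else "none"
            rows.append((origin, g, flags["gained"], flags["maintained"], flags["lost"], cls))
    table = pd.DataFrame(
        rows, columns=["origin", "gene", "gained", "maintained", "lost", "cls"]
    )
    return GeneCategoryTable(table=table, excluded=excluded)


def summarize_category_percentages(table: GeneCategoryTable) -> pd.DataFrame:
    """Per-origin class counts and percentages (one decimal place).

    percentage = 100 * class_count / origin_total; counts conserve the
    origin totals.  Origins with zero genes are skipped.
    """
    classes = [
        "gained", "maintained", "lost",
        "gained+maintained", "gained+lost", "maintained+lost",
        "gained+maintained+lost", "none",
    ]
    rows = []
    for origin, grp in table.table.groupby("origin", sort=False):
        total = len(grp)
        if total == 0:
            continue
        counts = grp["cls"].value_counts()
        for cls in classes:
            k = int(counts.get(cls, 0))
            rows.append((origin, cls, k, total, round(100.0 * k / total, 1)))
    return pd.DataFrame(rows, columns=["origin", "class", "count", "total", "percent"])
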