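"""Synthetic gut-organogenesis data generator.

Emulates the statistical structure of the study inputs so every downstream
stage is testable without external downloads:

* a small random genome with an annotated gene set,
* organ-structured scATAC fragments in which each organ's cells are
  enriched (by ``signal_fold``) at that organ's planted specific peaks,
  plus a planted fraction of low-quality cells below the 1000-fragment bar,
* stage-paired bulk ATAC counts in which organ-specific peaks are elevated
  in their organ at both stages and temporally gained peaks are elevated
  only at the late stage,
* KO/WT bulk ATAC pairs with planted gained and lost peaks,
* stage-paired expression tables whose planted upregulated genes are
  partially co-located (within 50 kb of the TSS) with the gained peaks,
* motif consensus insertions planted preferentially into gained peaks.

All counts are negative binomial with user dispersion (Poisson in the
dispersion -> 0 limit).  Everything is deterministic under ``seed``: the
same configuration always emits byte-identical files.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse

from .genomics import PeakSet, MotifModel, write_bed, write_fasta, write_labeled_matrix, write_pwm

__all__ = [
    "SimConfig",
    "PlantedTruth",
    "generate_reference",
    "plant_truth",
    "simulate_scatac_fragments",
    "simulate_bulk_counts",
    "simulate_expression_tables",
    "simulate_to_dir",
]

_CONSENSUS_ALPHABET = np.frombuffer(b"ACGT", dtype=np.uint8)


class SimConfigError(ValueError):
    """Inconsistent simulation configuration."""


@dataclass
class SimConfig:
    """Study-condition parameters for the synthetic generator.

    Defaults describe a desk-scale version of the study design: five gut
    organs with a few hundred cells each, ~5000 accessibility peaks of
    which 20% are organ specific, an 8-fold planted accessibility gain,
    and one early/late stage pair.
    """

    seed: int = 0
    n_contigs: int = 4
    contig_length_bp: int = 5_000_000
    n_genes: int = 200
    organs: tuple[str, ...] = ("intestine", "stomach", "lung", "pancreas", "esophagus")
    n_cells_per_organ: int = 200
    n_peaks_total: int = 5000
    frac_organ_specific: float = 0.20
    signal_fold: float = 8.0
    stage_pairs: tuple[tuple[str, str], ...] = (("E9.5", "E13.5"),)
    n_temporal_gained_peaks: int = 200      # per organ
    n_temporal_up_genes: int = 40           # per organ
    frac_coloc: float = 0.8                 # up genes co-located with gained peaks
    n_ko_gained: int = 150
    n_ko_lost: int = 150
    noise_dispersion: float = 0.2
    fragment_rate: float = 2500.0           # mean fragments per good cell
    frac_low_qc: float = 0.05               # cells planted below the 1000-fragment bar
    low_fragment_rate: float = 300.0
    tss_frac: float = 0.25                  # fragment fraction placed at TSSs
    peak_frac: float = 0.35                 # fragment fraction placed inside peaks
    peak_width_bp: int = 500
    n_markers_per_organ: int = 3
    n_bulk_replicates: int = 2
    n_motifs: int = 6
    motif_width: int = 8

    def __post_init__(self) -> None:
        if not self.organs:
            raise SimConfigError("organs list must be nonempty")
        if not (0.0 <= self.frac_organ_specific <= 1.0):
            raise SimConfigError("frac_organ_specific must be in [0, 1]")
        if self.signal_fold <= 0 or self.fragment_rate < 0 or self.noise_dispersion < 0:
            raise SimConfigError("rates, folds and dispersion must be nonnegative")
        if not (0.0 <= self.frac_coloc <= 1.0):
            raise SimConfigError("frac_coloc must be in [0, 1]")
        if self.n_ko_gained + self.n_ko_lost > self.n_peaks_total:
            raise SimConfigError("n_ko_gained + n_ko_lost exceeds n_peaks_total")
        n_spec = int(self.frac_organ_specific * self.n_peaks_total)
        if self.n_peaks_total > 0 and n_spec < len(self.organs):
            raise SimConfigError(
                "frac_organ_specific * n_peaks_total must allow >= 1 peak per organ"
            )
        if self.tss_frac + self.peak_frac > 1.0:
            raise SimConfigError("tss_frac + peak_frac must be <= 1")


@dataclass
class PlantedTruth:
    """Ground truth of every planted structure, for recovery tests."""

    organ_specific_peaks: dict[str, list[str]] = field(default_factory=dict)
    temporal_gained_peaks: dict[str, list[str]] = field(default_factory=dict)
    temporal_up_genes: dict[str, list[str]] = field(default_factory=dict)
    ko_gained: list[str] = field(default_factory=list)
    ko_lost: list[str] = field(default_factory=list)
    motif_site_placement: dict[str, list[str]] = field(default_factory=dict)
    marker_genes: dict[str, list[str]] = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1, sort_keys=True) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "PlantedTruth":
        return cls(**json.loads(Path(path).read_text()))


def _rng(config: SimConfig, stream: int) -> np.random.Generator:
    # independent, order-insensitive stream per stage
    return np.random.default_rng([config.seed % (2**31), stream])


def _nb_sample(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """NB(mean, var = mean + dispersion * mean^2); Poisson when dispersion == 0."""
    mean = np.asarray(mean, dtype=float)
    if dispersion <= 0:
        return rng.poisson(mean)
    shape = 1.0 / dispersion
    lam = rng.gamma(shape, scale=mean * dispersion)
    return rng.poisson(lam)


# ---------------------------------------------------------------------------
# Reference genome and gene annotation

def generate_reference(config: SimConfig) -> tuple[dict[str, str], pd.DataFrame]:
    """Random i.i.d. ACGT contigs plus a uniformly placed gene annotation.

    Returns (genome, genes) where genes has columns
    (contig, start, end, name, length_class, strand, tss).
    """
    if config.n_genes > 0 and config.contig_length_bp < 10_000:
        raise SimConfigError("contig_length_bp too short for the requested gene count")
    if config.n_genes > config.n_contigs * (config.contig_length_bp // 2_000):
        raise SimConfigError("contigs too short for the requested gene count")
    rng = _rng(config, 1)
    genome: dict[str, str] = {}
    for c in range(config.n_contigs):
        seq = _CONSENSUS_ALPHABET[rng.integers(0, 4, size=config.contig_length_bp)]
        genome[f"chr{c + 1}"] = seq.tobytes().decode("ascii")
    if config.n_genes == 0:
        genes = pd.DataFrame(
            columns=["contig", "start", "end", "name", "length_class", "strand", "tss"]
        )
        return genome, genes

    contigs = rng.integers(0, config.n_contigs, size=config.n_genes)
    lengths = np.clip(
        rng.lognormal(mean=np.log(8_000), sigma=0.8, size=config.n_genes), 500, 100_000
    ).astype(int)
    margin = 100_001  # keep gene bodies inside contig bounds
    starts = rng.integers(margin, config.contig_length_bp - margin, size=config.n_genes)
    ends = np.minimum(starts + lengths, config.contig_length_bp - 1)
    strands = np.where(rng.random(config.n_genes) < 0.5, "+", "-")
    genes = pd.DataFrame(
        {
            "contig": [f"chr{c + 1}" for c in contigs],
            "start": starts,
            "end": ends,
            "name": [f"gene_{i:04d}" for i in range(config.n_genes)],
            "strand": strands,
        }
    )
    genes["tss"] = np.where(genes["strand"] == "+", genes["start"], genes["end"])
    # 5 quantile levels of total region size (body + 100 kb flanks); here the
    # flank is constant so the levels follow body length
    region = (genes["end"] - genes["start"]) + 200_000
    genes["length_class"] = (
        pd.qcut(region.rank(method="first"), 5, labels=False).astype(int) + 1
    )
    genes = genes.sort_values(["contig", "start"], kind="mergesort").reset_index(drop=True)
    return genome, genes[["contig", "start", "end", "name", "length_class", "strand", "tss"]]


# ---------------------------------------------------------------------------
# Peak placement and truth planting

def plant_truth(
    config: SimConfig, genes: pd.DataFrame
) -> tuple[PeakSet, PlantedTruth]:
    """Place non-overlapping peaks and assign every planted role.

    Peak roles (organ-specific, temporally gained, KO gained/lost) are
    pairwise disjoint.  Each organ's marker genes carry organ-specific
    peaks inside the gene-score window, and a ``frac_coloc`` fraction of
    each organ's planted up-genes gets a gained peak within 50 kb of its
    TSS; all remaining peaks are placed uniformly on a slot grid.
    """
    rng = _rng(config, 2)
    w = config.peak_width_bp
    slot = 4 * w
    # free slots across contigs, excluding contig edges
    slots = []
    for c in range(config.n_contigs):
        n_slots = (config.contig_length_bp - 2 * slot) // slot
        slots.extend((f"chr{c + 1}", s) for s in range(1, n_slots))
    if config.n_peaks_total > len(slots):
        raise SimConfigError("genome too small for the requested peak count")

    organs = list(config.organs)
    n_spec_total = int(config.frac_organ_specific * config.n_peaks_total)
    n_spec = n_spec_total // len(organs) if organs else 0
    truth = PlantedTruth()

    n_genes = len(genes)
    gene_names = genes["name"].to_list()
    gene_order = rng.permutation(n_genes)
    cursor = 0

    def _take_genes(k: int) -> list[int]:
        nonlocal cursor
        idx = gene_order[cursor : cursor + k]
        cursor += len(idx)
        return list(idx)

    taken_slots: set[tuple[str, int]] = set()

    def _slot_of(contig: str, pos: int) -> tuple[str, int]:
        return contig, int(pos) // slot

    def _place_near(gene_row, max_dist: int, min_dist: int = 2_000) -> tuple[str, int]:
        # a free slot whose peak midpoint lies within max_dist of the TSS
        # (but at least min_dist away, clear of TSS-proximal fragment pileups)
        for _ in range(200):
            offset = int(rng.integers(min_dist, max_dist - w))
            if rng.random() < 0.5:
                offset = -offset
            start = int(gene_row.tss) + offset
            start = max(slot, min(start, config.contig_length_bp - 2 * slot))
            key = _slot_of(gene_row.contig, start)
            if key not in taken_slots:
                taken_slots.add(key)
                return gene_row.contig, key[1] * slot + w  # snap into the slot
        raise SimConfigError("could not place a co-located peak; genome too crowded")

    records: list[tuple[str, int, int, str]] = []  # contig, start, end, name
    roles: dict[str, str] = {}

    def _emit(contig: str, start: int, name: str) -> None:
        records.append((contig, start, start + w, name))

    peak_counter = 0

    def _next_name() -> str:
        nonlocal peak_counter
        name = f"peak_{peak_counter:05d}"
        peak_counter += 1
        return name

    # marker genes first, so every organ's non-marker specific peaks can
    # stay clear of every marker window (otherwise a rival organ's peak
    # inside a marker's gene-score window would corrupt the marker signal)
    marker_gene_idx: dict[str, list[int]] = {}
    for organ in organs:
        marker_gene_idx[organ] = _take_genes(
            min(config.n_markers_per_organ, max(n_genes - cursor, 0))
        )
        truth.marker_genes[organ] = [gene_names[i] for i in marker_gene_idx[organ]]
    forbidden_slots: set[tuple[str, int]] = set()
    guard = 110_000
    for idxs in marker_gene_idx.values():
        for gi in idxs:
            row = genes.iloc[gi]
            lo = max(0, (int(row.tss) - guard)) // slot
            hi = (int(row.tss) + guard) // slot + 1
            forbidden_slots.update((row.contig, s) for s in range(lo, hi))
    # organ-specific peaks also stay off TSSs, whose shared insertion
    # pileup would otherwise dilute the planted organ fold at those peaks
    for row in genes.itertuples():
        t = int(row.tss)
        forbidden_slots.update(
            (row.contig, s) for s in range((t - 600) // slot, (t + 600) // slot + 1)
        )

    # organ-specific peaks; two per marker gene close to its TSS, the rest
    # on random slots outside all marker windows
    for organ in organs:
        names: list[str] = []
        for gi in marker_gene_idx[organ]:
            row = genes.iloc[gi]
            for _ in range(2):
                contig, start = _place_near(row, 10_000)
                name = _next_name()
                _emit(contig, start, name)
                names.append(name)
        attempts = 0
        while len(names) < n_spec:
            attempts += 1
            key = slots[int(rng.integers(0, len(slots)))]
            if key in taken_slots or (key in forbidden_slots and attempts < 50 * n_spec):
                continue
            taken_slots.add(key)
            name = _next_name()
            _emit(key[0], key[1] * slot + w, name)
            names.append(name)
        truth.organ_specific_peaks[organ] = names
        for nm in names:
            roles[nm] = f"specific:{organ}"

    # temporally gained peaks; frac_coloc of each organ's up genes get one
    for organ in organs:
        n_up = min(config.n_temporal_up_genes, max(n_genes - cursor, 0))
        up_idx = _take_genes(n_up)
        truth.temporal_up_genes[organ] = [gene_names[i] for i in up_idx]
        n_coloc = int(round(config.frac_coloc * len(up_idx)))
        names = []
        for gi in up_idx[:n_coloc]:
            row = genes.iloc[gi]
            contig, start = _place_near(row, 50_000 - w)
            name = _next_name()
            _emit(contig, start, name)
            names.append(name)
        while len(names) < config.n_temporal_gained_peaks:
            key = slots[int(rng.integers(0, len(slots)))]
            if key in taken_slots:
                continue
            taken_slots.add(key)
            name = _next_name()
            _emit(key[0], key[1] * slot + w, name)
            names.append(name)
        truth.temporal_gained_peaks[organ] = names
        for nm in names:
            roles.setdefault(nm, f"gained:{organ}")

    # remaining peaks: KO gained / lost / background
    n_remaining = config.n_peaks_total - peak_counter
    if n_remaining < 0:
        raise SimConfigError("planted roles exceed n_peaks_total; increase n_peaks_total")
    extra_names = []
    while len(extra_names) < n_remaining:
        key = slots[int(rng.integers(0, len(slots)))]
        if key in taken_slots:
            continue
        taken_slots.add(key)
        name = _next_name()
        _emit(key[0], key[1] * slot + w, name)
        extra_names.append(name)
    truth.ko_gained = extra_names[: config.n_ko_gained]
    truth.ko_lost = extra_names[config.n_ko_gained : config.n_ko_gained + config.n_ko_lost]

    df = pd.DataFrame(records, columns=["contig", "start", "end", "name"])
    df["score"] = np.round(rng.uniform(1.0, 100.0, size=len(df)), 3)
    df["strand"] = "."
    peaks = PeakSet(df, provenance="sim")
    return peaks, truth


def make_motifs(config: SimConfig) -> list[MotifModel]:
    """Near-deterministic PWMs with distinct random consensus sequences."""
    rng = _rng(config, 3)
    motifs = []
    for m in range(config.n_motifs):
        cons = rng.integers(0, 4, size=config.motif_width)
        counts = np.full((4, config.motif_width), 1.0)
        counts[cons, np.arange(config.motif_width)] = 50.0
        motifs.append(MotifModel.from_counts(f"motif_{m:02d}", counts, pseudo=0.5))
    return motifs


def consensus(motif: MotifModel) -> str:
    return "".join("ACGT"[i] for i in motif.matrix.argmax(axis=0))


def plant_motif_sites(
    config: SimConfig,
    genome: dict[str, str],
    peaks: PeakSet,
    truth: PlantedTruth,
    motifs: list[MotifModel],
) -> dict[str, str]:
    """Insert motif consensus strings into peak sequences.

    The first motif is planted in every temporally gained peak (so it is
    late-enriched by construction); the others go into random background
    peaks at a low rate.  Insertions overwrite bases in place, keeping
    coordinates fixed.  Returns the modified genome.
    """
    rng = _rng(config, 4)
    seqs = {c: bytearray(s, "ascii") for c, s in genome.items()}
    gained_all = sorted({p for names in truth.temporal_gained_peaks.values() for p in names})
    by_name = peaks.df.set_index("name")

    def _insert(peak_name: str, motif: MotifModel) -> None:
        row = by_name.loc[peak_name]
        cons = consensus(motif)
        lo, hi = int(row["start"]), int(row["end"]) - len(cons)
        pos = int(rng.integers(lo, hi))
        seqs[row["contig"]][pos : pos + len(cons)] = cons.encode("ascii")

    for name in gained_all:
        _insert(name, motifs[0])
    truth.motif_site_placement[motifs[0].id] = gained_all
    all_names = peaks.df["name"].to_list()
    for motif in motifs[1:]:
        chosen = sorted(
            rng.choice(len(all_names), size=min(100, len(all_names)), replace=False)
        )
        names = [all_names[i] for i in chosen]
        for nm in names:
            _insert(nm, motif)
        truth.motif_site_placement[motif.id] = names
    return {c: bytes(b).decode("ascii") for c, b in seqs.items()}


# ---------------------------------------------------------------------------
# scATAC fragments

def simulate_scatac_fragments(
    config: SimConfig,
    genes: pd.DataFrame,
    peaks: PeakSet,
    truth: PlantedTruth,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate barcode-tagged fragments for organ-structured cells.

    Cells of organ *o* place in-peak fragments with weight ``signal_fold``
    on that organ's planted specific peaks and weight 1 elsewhere.  A
    ``frac_low_qc`` fraction of cells is drawn at ``low_fragment_rate``
    (below the 1000-fragment QC bar) with negligible TSS concentration.

    Returns (fragments, cells): fragments has columns
    (contig, start, end, barcode, count) and cells has
    (barcode, organ, planted_low_qc).
    """
    rng = _rng(config, 5)
    organs = list(config.organs)
    cells = []
    for organ in organs:
        for i in range(config.n_cells_per_organ):
            cells.append((f"{organ}#c{i:04d}", organ))
    cells_df = pd.DataFrame(cells, columns=["barcode", "organ"])
    n_cells = len(cells_df)
    low = rng.random(n_cells) < config.frac_low_qc
    cells_df["planted_low_qc"] = low

    rate = np.where(low, config.low_fragment_rate, config.fragment_rate)
    n_frags = rng.poisson(rate)

    peak_contig = peaks.df["contig"].to_numpy()
    peak_start = peaks.df["start"].to_numpy()
    peak_end = peaks.df["end"].to_numpy()
    name_to_idx = {n: i for i, n in enumerate(peaks.df["name"])}

    organ_weights = {}
    for organ in organs:
        wvec = np.ones(len(peaks))
        idx = [name_to_idx[n] for n in truth.organ_specific_peaks.get(organ, [])]
        wvec[idx] = config.signal_fold
        organ_weights[organ] = wvec / wvec.sum()

    tss = genes["tss"].to_numpy() if len(genes) else np.array([], dtype=int)
    tss_contig = genes["contig"].to_numpy() if len(genes) else np.array([], dtype=str)

    frames = []
    for ci in range(n_cells):
        n = int(n_frags[ci])
        if n == 0:
            continue
        organ = cells_df.at[ci, "organ"]
        tss_frac = 0.02 if low[ci] else config.tss_frac
        u = rng.random(n)
        cat = np.where(
            (u < tss_frac) & (len(tss) > 0), 0,
            np.where(u < tss_frac + config.peak_frac, 1, 2),
        )
        contigs = np.empty(n, dtype=object)
        starts = np.empty(n, dtype=np.int64)
        # TSS-proximal fragments
        k = int((cat == 0).sum())
        if k:
            gi = rng.integers(0, len(tss), size=k)
            contigs[cat == 0] = tss_contig[gi]
            starts[cat == 0] = tss[gi] + rng.integers(-50, 51, size=k)
        # in-peak fragments
        k = int((cat == 1).sum())
        if k:
            pi = rng.choice(len(peaks), size=k, p=organ_weights[organ])
            contigs[cat == 1] = peak_contig[pi]
            starts[cat == 1] = peak_start[pi] + rng.integers(
                0, peak_end[pi] - peak_start[pi]
            )
        # background fragments: uniform over the genome, rejected out of
        # peak intervals so the planted in-peak fold stays multiplicative
        k = int((cat == 2).sum())
        if k:
            bc = rng.integers(0, config.n_contigs, size=k)
            bpos = rng.integers(0, config.contig_length_bp - 400, size=k)
            for _ in range(6):
                redo = np.zeros(k, dtype=bool)
                for c in range(config.n_contigs):
                    cname = f"chr{c + 1}"
                    sel = bc == c
                    if not sel.any():
                        continue
                    pmask = peak_contig == cname
                    ps, pe = peak_start[pmask], peak_end[pmask]
                    j = np.searchsorted(ps, bpos[sel], side="right") - 1
                    inside = (j >= 0) & (bpos[sel] < pe[np.clip(j, 0, None)])
                    redo[np.flatnonzero(sel)[inside]] = True
                if not redo.any():
                    break
                bpos[redo] = rng.integers(0, config.contig_length_bp - 400, size=int(redo.sum()))
            contigs[cat == 2] = np.array(
                [f"chr{c + 1}" for c in range(config.n_contigs)], dtype=object
            )[bc]
            starts[cat == 2] = bpos
        starts = np.clip(starts, 0, config.contig_length_bp - 400)
        lengths = rng.integers(80, 300, size=n)
        frames.append(
            pd.DataFrame(
                {
                    "contig": contigs,
                    "start": starts,
                    "end": starts + lengths,
                    "barcode": cells_df.at[ci, "barcode"],
                    "count": 1,
                }
            )
        )
    if frames:
        frags = pd.concat(frames, ignore_index=True)
        frags = frags.sort_values(["contig", "start", "end", "barcode"], kind="mergesort")
        frags = frags.reset_index(drop=True)
    else:
        frags = pd.DataFrame(columns=["contig", "start", "end", "barcode", "count"])
    return frags, cells_df


# ---------------------------------------------------------------------------
# Bulk counts

def simulate_bulk_counts(
    config: SimConfig, peaks: PeakSet, truth: PlantedTruth
) -> dict[str, pd.DataFrame]:
    """Peak x sample count tables for each stage and the KO/WT pair.

    Organ-specific peaks carry ``signal_fold`` in their organ at every
    stage; temporally gained peaks carry it only in their organ's late
    sample.  KO-gained peaks carry it in KO, KO-lost in WT.  Library sizes
    vary per sample so depth normalization is exercised downstream.
    Returns ``{stage_label: frame, ..., "ko": frame}`` with columns named
    ``{organ}_rep{r}`` (stages) or ``{KO,WT}_rep{r}``.
    """
    rng = _rng(config, 6)
    organs = list(config.organs)
    n_peaks = len(peaks)
    name_to_idx = {n: i for i, n in enumerate(peaks.df["name"])}
    base = rng.lognormal(mean=np.log(30.0), sigma=0.6, size=n_peaks)

    spec_fold = np.ones((n_peaks, len(organs)))
    gain_fold = np.ones((n_peaks, len(organs)))
    for oi, organ in enumerate(organs):
        for n in truth.organ_specific_peaks.get(organ, []):
            spec_fold[name_to_idx[n], oi] = config.signal_fold
        for n in truth.temporal_gained_peaks.get(organ, []):
            gain_fold[name_to_idx[n], oi] = config.signal_fold

    out: dict[str, pd.DataFrame] = {}
    for early, late in config.stage_pairs:
        for stage, is_late in ((early, False), (late, True)):
            cols = {}
            for oi, organ in enumerate(organs):
                mu = base * spec_fold[:, oi]
                if is_late:
                    mu = mu * gain_fold[:, oi]
                for r in range(config.n_bulk_replicates):
                    lib = rng.lognormal(mean=0.0, sigma=0.3)
                    cols[f"{organ}_rep{r + 1}"] = _nb_sample(
                        rng, mu * lib, config.noise_dispersion
                    )
            out[stage] = pd.DataFrame(cols, index=peaks.df["name"].to_list())

    ko_fold = np.ones(n_peaks)
    wt_fold = np.ones(n_peaks)
    for n in truth.ko_gained:
        ko_fold[name_to_idx[n]] = config.signal_fold
    for n in truth.ko_lost:
        wt_fold[name_to_idx[n]] = config.signal_fold
    cols = {}
    for cond, fold in (("KO", ko_fold), ("WT", wt_fold)):
        for r in range(config.n_bulk_replicates):
            lib = rng.lognormal(mean=0.0, sigma=0.3)
            cols[f"{cond}_rep{r + 1}"] = _nb_sample(
                rng, base * fold * lib, config.noise_dispersion
            )
    out["ko"] = pd.DataFrame(cols, index=peaks.df["name"].to_list())
    return out


# ---------------------------------------------------------------------------
# Expression

def simulate_expression_tables(
    config: SimConfig, genes: pd.DataFrame, truth: PlantedTruth
) -> tuple[dict[str, pd.DataFrame], dict[str, list[str]]]:
    """FPKM-like gene x organ expression per stage plus per-organ DE lists.

    Planted up-genes of organ *o* are elevated ``signal_fold``-fold in
    organ *o* at the late stage.  Multiplicative log-normal noise with
    sigma = ``noise_dispersion`` (exact planted ranks at dispersion 0).
    """
    rng = _rng(config, 7)
    organs = list(config.organs)
    n_genes = len(genes)
    gene_names = genes["name"].to_list()
    name_to_idx = {n: i for i, n in enumerate(gene_names)}
    base = rng.lognormal(mean=np.log(20.0), sigma=1.0, size=n_genes)

    up_fold = np.ones((n_genes, len(organs)))
    for oi, organ in enumerate(organs):
        for g in truth.temporal_up_genes.get(organ, []):
            up_fold[name_to_idx[g], oi] = config.signal_fold

    tables: dict[str, pd.DataFrame] = {}
    for early, late in config.stage_pairs:
        for stage, is_late in ((early, False), (late, True)):
            cols = {}
            for oi, organ in enumerate(organs):
                mu = base * (up_fold[:, oi] if is_late else 1.0)
                noise = (
                    np.exp(rng.normal(0.0, config.noise_dispersion, size=n_genes))
                    if config.noise_dispersion > 0
                    else 1.0
                )
                cols[organ] = mu * noise
            tables[stage] = pd.DataFrame(cols, index=gene_names)
    de_lists = {organ: list(truth.temporal_up_genes.get(organ, [])) for organ in organs}
    return tables, de_lists


# ---------------------------------------------------------------------------
# Full emission

def simulate_to_dir(config: SimConfig, outdir: str | Path) -> PlantedTruth:
    """Run every generator stage and emit all artifacts to ``outdir``.

    Emits genome FASTA, genes BED6 (score column = gene length class),
    fragments TSV, peaks BED, bulk/KO count matrices and expression tables
    (MatrixMarket + TSV), DE gene lists, PWM file, and the planted-truth
    JSON.  Byte-identical under identical config.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    genome, genes = generate_reference(config)
    peaks, truth = plant_truth(config, genes)
    motifs = make_motifs(config)
    genome = plant_motif_sites(config, genome, peaks, truth, motifs)
    frags, cells = simulate_scatac_fragments(config, genes, peaks, truth)
    bulk = simulate_bulk_counts(config, peaks, truth)
    expr, de_lists = simulate_expression_tables(config, genes, truth)

    write_fasta(genome, outdir / "genome.fa")
    gene_bed = genes.rename(columns={"length_class": "score"})[
        ["contig", "start", "end", "name", "score", "strand"]
    ]
    gene_bed.to_csv(outdir / "genes.bed", sep="\t", header=False, index=False)
    frags.to_csv(outdir / "fragments.tsv", sep="\t", header=False, index=False)
    write_bed(peaks, outdir / "peaks.bed")
    cells.to_csv(outdir / "cells.tsv", sep="\t", index=False)
    for stage, frame in bulk.items():
        write_labeled_matrix(
            frame.to_numpy(), list(frame.index), list(frame.columns),
            outdir / f"bulk_atac_{stage.replace('.', '_')}",
        )
    for stage, frame in expr.items():
        frame.to_csv(outdir / f"expression_{stage.replace('.', '_')}.tsv", sep="\t")
    for organ, names in de_lists.items():
        (outdir / f"de_up_{organ}.tsv").write_text("\n".join(names) + ("\n" if names else ""))
    write_pwm(motifs, outdir / "motifs.pwm")
    truth.to_json(outdir / "truth.json")
    return truth
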