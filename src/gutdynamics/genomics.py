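"""Genomic interval containers, standard-format readers/writers, and the
1 bp overlap arithmetic used throughout the pipeline.

All coordinates are 0-based half-open (BED convention), internally and on
disk.  Two intervals overlap iff their intersection is at least 1 bp under
half-open semantics, i.e. ``a.start < b.end and b.start < a.end``.
"""

from __future__ import annotations

import gzip
import io as _io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

__all__ = [
    "GenomicInterval",
    "PeakSet",
    "MotifModel",
    "BedFormatError",
    "parse_bed",
    "write_bed",
    "parse_fragments",
    "fragment_totals",
    "overlaps_1bp",
    "overlap_pairs",
    "merge_iterative_overlap",
    "parse_pwm",
    "write_pwm",
    "read_labeled_matrix",
    "write_labeled_matrix",
    "read_fasta",
    "write_fasta",
]

_BASES = "ACGT"


class BedFormatError(ValueError):
    """Malformed record in a BED-like file; carries the offending line number."""


@dataclass(frozen=True)
class GenomicInterval:
    """A half-open genomic interval with optional BED6 annotations."""

    contig: str
    start: int
    end: int
    name: str = "."
    score: float = 0.0
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.contig:
            raise ValueError("contig must be nonempty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval [{self.start}, {self.end}): need 0 <= start < end"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.contig == other.contig
            and self.start < other.end
            and other.start < self.end
        )


class PeakSet:
    """An ordered, named collection of genomic intervals.

    Backed by a DataFrame with columns (contig, start, end, name, score,
    strand), sorted by (contig, start, end).  An optional ``signal`` frame
    (indexed by peak name, one column per sample) carries normalized read
    counts.
    """

    COLUMNS = ["contig", "start", "end", "name", "score", "strand"]

    def __init__(
        self,
        intervals: pd.DataFrame | Sequence[GenomicInterval],
        signal: pd.DataFrame | None = None,
        provenance: str = "",
    ) -> None:
        if isinstance(intervals, pd.DataFrame):
            df = intervals.copy()
        else:
            df = pd.DataFrame(
                [
                    (iv.contig, iv.start, iv.end, iv.name, iv.score, iv.strand)
                    for iv in intervals
                ],
                columns=self.COLUMNS,
            )
        for col, default in (("name", "."), ("score", 0.0), ("strand", ".")):
            if col not in df.columns:
                df[col] = default
        df = df[self.COLUMNS].reset_index(drop=True)
        if len(df):
            if (df["start"] < 0).any() or (df["start"] >= df["end"]).any():
                raise ValueError("all intervals must satisfy 0 <= start < end")
            df = df.sort_values(["contig", "start", "end"], kind="mergesort")
            df = df.reset_index(drop=True)
            # auto-name unnamed peaks so identifiers are unique
            if (df["name"] == ".").all():
                df["name"] = [f"peak_{i}" for i in range(len(df))]
            if df["name"].duplicated().any():
                dup = df.loc[df["name"].duplicated(), "name"].iloc[0]
                raise ValueError(f"duplicate peak identifier {dup!r}")
        self.df = df
        self.signal = signal
        self.provenance = provenance
        if signal is not None and len(df):
            missing = set(df["name"]) - set(signal.index)
            if missing:
                raise ValueError(f"signal missing {len(missing)} peak rows")

    def __len__(self) -> int:
        return len(self.df)

    def __iter__(self) -> Iterator[GenomicInterval]:
        for row in self.df.itertuples(index=False):
            yield GenomicInterval(
                row.contig, int(row.start), int(row.end), row.name, float(row.score), row.strand
            )

    @property
    def names(self) -> pd.Index:
        return pd.Index(self.df["name"])

    def subset(self, names: Iterable[str]) -> "PeakSet":
        keep = self.df["name"].isin(set(names))
        sig = self.signal.loc[self.df.loc[keep, "name"]] if self.signal is not None else None
        return PeakSet(self.df.loc[keep], signal=sig, provenance=self.provenance)


# ---------------------------------------------------------------------------
# BED

def parse_bed(path: str | Path) -> PeakSet:
    """Read a BED3/BED6 file into a sorted, validated :class:`PeakSet`."""
    path = Path(path)
    rows = []
    with _open_maybe_gzip(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise BedFormatError(f"{path}:{lineno}: fewer than 3 columns")
            contig = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise BedFormatError(f"{path}:{lineno}: non-integer coordinates") from exc
            if start >= end:
                raise BedFormatError(
                    f"{path}:{lineno}: empty or inverted interval [{start}, {end})"
                )
            if start < 0:
                raise BedFormatError(f"{path}:{lineno}: negative start {start}")
            name = fields[3] if len(fields) > 3 else "."
            score = float(fields[4]) if len(fields) > 4 and fields[4] != "." else 0.0
            strand = fields[5] if len(fields) > 5 else "."
            rows.append((contig, start, end, name, score, strand))
    df = pd.DataFrame(rows, columns=PeakSet.COLUMNS)
    return PeakSet(df, provenance=str(path))


def write_bed(peaks: PeakSet, path: str | Path) -> None:
    """Write BED6; bit-stable given identical input."""
    df = peaks.df.copy()
    df["score"] = df["score"].map(lambda s: format(float(s), "g"))
    df.to_csv(path, sep="\t", header=False, index=False)


def _open_maybe_gzip(path: Path):
    if str(path).endswith(".gz"):
        return _io.TextIOWrapper(gzip.open(path, "rb"))
    return open(path)


# ---------------------------------------------------------------------------
# Fragments

def parse_fragments(path: str | Path) -> Iterator[tuple[GenomicInterval, str, int]]:
    """Stream a scATAC fragments file: (interval, barcode, count) per record.

    Accepts the 4-column (chrom, start, end, barcode) and 5-column
    (..., count) dialects; a missing count column defaults to 1.
    """
    path = Path(path)
    with _open_maybe_gzip(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise BedFormatError(f"{path}:{lineno}: fewer than 4 columns")
            contig, start, end, barcode = fields[0], int(fields[1]), int(fields[2]), fields[3]
            count = int(fields[4]) if len(fields) > 4 else 1
            if count < 0:
                raise BedFormatError(f"{path}:{lineno}: negative count {count}")
            yield GenomicInterval(contig, start, end), barcode, count


def fragment_totals(path: str | Path) -> pd.Series:
    """Per-barcode fragment totals in a single pass."""
    totals: dict[str, int] = {}
    for _, barcode, count in parse_fragments(path):
        totals[barcode] = totals.get(barcode, 0) + count
    return pd.Series(totals, dtype=int).sort_index()


def read_fragments_frame(path: str | Path) -> pd.DataFrame:
    """Load a whole fragments file as a DataFrame (vectorized path for large files)."""
    # no comment= here: '#' legitimately appears inside barcodes
    df = pd.read_csv(
        path, sep="\t", header=None,
        names=["contig", "start", "end", "barcode", "count"],
        dtype={"contig": str, "start": np.int64, "end": np.int64, "barcode": str},
    )
    if df["count"].isna().all():
        df["count"] = 1
    df["count"] = df["count"].fillna(1).astype(np.int64)
    if (df["count"] < 0).any():
        raise BedFormatError(f"{path}: negative fragment count")
    return df


# ---------------------------------------------------------------------------
# Overlap arithmetic

def overlap_pairs(a: PeakSet, b: PeakSet) -> list[tuple[int, int]]:
    """All index pairs (i, j) with a[i] and b[j] intersecting by >= 1 bp.

    Indices refer to row positions in the sorted frames.
    """
    pairs: list[tuple[int, int]] = []
    adf, bdf = a.df, b.df
    for contig in adf["contig"].unique():
        ai = np.flatnonzero(adf["contig"].to_numpy() == contig)
        bi = np.flatnonzero(bdf["contig"].to_numpy() == contig)
        if len(ai) == 0 or len(bi) == 0:
            continue
        a_start = adf["start"].to_numpy()[ai]
        a_end = adf["end"].to_numpy()[ai]
        b_start = bdf["start"].to_numpy()[bi]
        b_end = bdf["end"].to_numpy()[bi]
        # b sorted by start; running max of ends bounds the candidate window
        cummax_end = np.maximum.accumulate(b_end)
        for k in range(len(ai)):
            hi = np.searchsorted(b_start, a_end[k], side="left")
            lo = np.searchsorted(cummax_end, a_start[k], side="right")
            if lo >= hi:
                continue
            cand = np.arange(lo, hi)
            cand = cand[b_end[cand] > a_start[k]]
            pairs.extend((int(ai[k]), int(bi[j])) for j in cand)
    return sorted(pairs)


def overlaps_1bp(a: PeakSet, b: PeakSet) -> tuple[list[tuple[int, int]], np.ndarray, np.ndarray]:
    """Overlap pairs plus per-peak boolean flags for both sets."""
    pairs = overlap_pairs(a, b)
    flag_a = np.zeros(len(a), dtype=bool)
    flag_b = np.zeros(len(b), dtype=bool)
    for i, j in pairs:
        flag_a[i] = True
        flag_b[j] = True
    return pairs, flag_a, flag_b


def merge_iterative_overlap(peak_sets: Sequence[PeakSet]) -> PeakSet:
    """Reduce several scored peak sets to one non-overlapping set.

    Iteratively retains the highest-scoring remaining peak and discards
    every peak overlapping it by >= 1 bp, until none remain.  Equal scores
    are broken by (contig, start) so the result is deterministic.
    """
    frames = []
    for k, ps in enumerate(peak_sets):
        if len(ps) and not np.isfinite(ps.df["score"]).all():
            raise ValueError("iterative merge requires a finite score on every peak")
        df = ps.df.copy()
        df["_src"] = k
        frames.append(df)
    allp = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(columns=PeakSet.COLUMNS)
    if len(allp) == 0:
        return PeakSet(pd.DataFrame(columns=PeakSet.COLUMNS))
    allp = allp.sort_values(
        ["score", "contig", "start", "end"],
        ascending=[False, True, True, True],
        kind="mergesort",
    ).reset_index(drop=True)
    kept: dict[str, list[tuple[int, int]]] = {}
    keep_rows = []
    for row in allp.itertuples():
        ivs = kept.setdefault(row.contig, [])
        if any(row.start < e and s < row.end for s, e in ivs):
            continue
        ivs.append((row.start, row.end))
        keep_rows.append(row.Index)
    out = allp.loc[keep_rows, PeakSet.COLUMNS].copy()
    out["name"] = [f"mpeak_{i}" for i in range(len(out))]
    return PeakSet(out, provenance="merge_iterative_overlap")


# ---------------------------------------------------------------------------
# PWMs

@dataclass
class MotifModel:
    """A position weight matrix over ACGT with a background model.

    ``matrix`` is 4 x width, columns summing to 1; row order A, C, G, T.
    """

    id: str
    matrix: np.ndarray
    background: np.ndarray = field(default_factory=lambda: np.full(4, 0.25))
    pseudo: float = 1.0

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.matrix.shape[0] != 4:
            raise ValueError("PWM must have 4 rows (A, C, G, T)")
        if self.matrix.shape[1] < 1:
            raise ValueError("PWM width must be >= 1")
        colsums = self.matrix.sum(axis=0)
        if not np.allclose(colsums, 1.0, atol=1e-9):
            raise ValueError("PWM columns must each sum to 1")

    @property
    def width(self) -> int:
        return int(self.matrix.shape[1])

    def reverse_complement(self) -> "MotifModel":
        return MotifModel(self.id, self.matrix[::-1, ::-1], self.background, self.pseudo)

    @classmethod
    def from_counts(
        cls, motif_id: str, counts: np.ndarray, pseudo: float = 1.0,
        background: np.ndarray | None = None,
    ) -> "MotifModel":
        counts = np.asarray(counts, dtype=float)
        probs = (counts + pseudo) / (counts.sum(axis=0) + 4.0 * pseudo)
        bg = np.full(4, 0.25) if background is None else background
        return cls(motif_id, probs, bg, pseudo)


def parse_pwm(path: str | Path, pseudo: float = 1.0) -> list[MotifModel]:
    """Parse a JASPAR-style PWM text file into probability matrices.

    Count matrices are converted to probabilities as
    (count + pseudo) / (column_total + 4 * pseudo).
    """
    motifs: list[MotifModel] = []
    current_id: str | None = None
    rows: list[list[float]] = []

    def _flush() -> None:
        nonlocal rows, current_id
        if current_id is None:
            return
        if len(rows) != 4:
            raise ValueError(f"motif {current_id!r}: expected 4 rows, got {len(rows)}")
        counts = np.asarray(rows, dtype=float)
        motifs.append(MotifModel.from_counts(current_id, counts, pseudo=pseudo))
        rows = []
        current_id = None

    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                _flush()
                current_id = line[1:].split()[0]
            else:
                body = line
                if body[0] in "ACGT" and ("[" in body or body[1:2].isspace()):
                    body = body[1:]
                body = body.replace("[", " ").replace("]", " ")
                rows.append([float(x) for x in body.split()])
    _flush()
    return motifs


def write_pwm(motifs: Sequence[MotifModel], path: str | Path, as_counts_scale: int = 1000) -> None:
    """Write motifs in JASPAR-style count layout (probabilities x scale)."""
    with open(path, "w") as fh:
        for m in motifs:
            fh.write(f">{m.id}\n")
            for base, row in zip(_BASES, np.round(m.matrix * as_counts_scale).astype(int)):
                fh.write(f"{base} [ " + " ".join(str(v) for v in row) + " ]\n")


# ---------------------------------------------------------------------------
# Labeled sparse matrices (MatrixMarket triplet + row/column sidecars)

def write_labeled_matrix(
    matrix: scipy.sparse.spmatrix | np.ndarray,
    row_labels: Sequence[str],
    col_labels: Sequence[str],
    prefix: str | Path,
) -> None:
    """Write <prefix>.mtx with <prefix>.rows / <prefix>.cols label sidecars."""
    prefix = Path(prefix)
    sp = scipy.sparse.coo_matrix(matrix)
    scipy.io.mmwrite(str(prefix.with_suffix(".mtx")), sp)
    prefix.with_suffix(".rows").write_text("\n".join(row_labels) + ("\n" if len(row_labels) else ""))
    prefix.with_suffix(".cols").write_text("\n".join(col_labels) + ("\n" if len(col_labels) else ""))


def read_labeled_matrix(prefix: str | Path) -> pd.DataFrame:
    """Read a labeled MatrixMarket triplet back into a dense DataFrame."""
    prefix = Path(prefix)
    sp = scipy.io.mmread(str(prefix.with_suffix(".mtx")))
    rows = prefix.with_suffix(".rows").read_text().splitlines()
    cols = prefix.with_suffix(".cols").read_text().splitlines()
    return pd.DataFrame(np.asarray(sp.todense()), index=rows, columns=cols)


# ---------------------------------------------------------------------------
# FASTA

def write_fasta(sequences: dict[str, str], path: str | Path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_fasta(path: str | Path) -> dict[str, str]:
    sequences: dict[str, str] = {}
    name = None
    chunks: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith(">"):
                if name is not None:
                    sequences[name] = "".join(chunks)
                name = line[1:].split()[0]
                chunks = []
            else:
                chunks.append(line)
    if name is not None:
        sequences[name] = "".join(chunks)
    return sequences
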