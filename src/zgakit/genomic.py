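"""Core genomic containers and text-format I/O.

All interval arithmetic in this package is 0-based, half-open
(``[start, end)``), the native convention of BED and bedGraph.  Converting
a 1-based inclusive record therefore shifts its start by −1.

Containers
----------
GenomicInterval / PeakSet
    Peaks and other genomic features, optionally carrying GC content.
GeneRecord
    A gene reduced to what the analyses need: TSS, strand and body end.
SignalTrack
    Fixed-bin coverage per chromosome in signal units per bp.
CountMatrix
    Sparse non-negative integer counts, features × cells.
CellTable
    Per-cell metadata (germ layer, genotype, replicate) as a DataFrame.
"""

from __future__ import annotations

import gzip
import io
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd
from scipy import sparse

__all__ = [
    "GenomicInterval",
    "PeakSet",
    "GeneRecord",
    "SignalTrack",
    "CountMatrix",
    "CellTable",
    "read_bed",
    "write_bed",
    "read_bedgraph",
    "write_bedgraph",
    "read_counts",
    "write_counts",
    "filter_peak_widths",
]

GERM_LAYER_VOCAB = (
    "mesoderm",
    "ectoderm",
    "endoderm",
    "yolk",
    "undifferentiated",
)
GENOTYPE_VOCAB = ("WT", "EzKD", "CBPKD")


def _open_text(path, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


@dataclass(frozen=True)
class GenomicInterval:
    """A half-open genomic interval ``[start, end)`` with an identifier.

    ``gc`` is the GC fraction of the underlying sequence when known (used
    by peak-to-gene linkage for background matching); ``extra`` preserves
    any trailing BED columns as opaque payload.
    """

    chrom: str
    start: int
    end: int
    id: str = ""
    gc: float | None = None
    extra: tuple = ()

    def __post_init__(self):
        if self.end <= self.start:
            raise ValueError(
                f"interval end must exceed start: {self.chrom}:{self.start}-{self.end}"
            )
        if self.start < 0:
            raise ValueError(f"negative start: {self.start}")
        if self.gc is not None and not (0.0 <= self.gc <= 1.0):
            raise ValueError(f"gc must be in [0, 1], got {self.gc}")

    @property
    def width(self) -> int:
        return self.end - self.start

    @property
    def center(self) -> int:
        return (self.start + self.end) // 2

    def overlaps(self, other: "GenomicInterval") -> bool:
        """True iff the two intervals share at least one base."""
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def distance_to_point(self, chrom: str, pos: int) -> int | None:
        """Distance (bp) from this interval to a point; 0 if inside, None off-chromosome."""
        if chrom != self.chrom:
            return None
        if self.start <= pos < self.end:
            return 0
        return self.start - pos if pos < self.start else pos - (self.end - 1)


class PeakSet:
    """An ordered collection of :class:`GenomicInterval`.

    Order is preserved from construction; ``sorted()`` returns a new set
    in (chrom, start, end) order.  Identifiers need not be unique but
    downstream tables key on them, so generators should keep them unique.
    """

    def __init__(self, intervals: Iterable[GenomicInterval] = ()):
        self.intervals: list[GenomicInterval] = list(intervals)

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self) -> Iterator[GenomicInterval]:
        return iter(self.intervals)

    def __getitem__(self, i) -> GenomicInterval:
        return self.intervals[i]

    def __eq__(self, other) -> bool:
        return isinstance(other, PeakSet) and self.intervals == other.intervals

    def ids(self) -> list[str]:
        return [iv.id for iv in self.intervals]

    def by_chrom(self) -> dict[str, list[GenomicInterval]]:
        out: dict[str, list[GenomicInterval]] = {}
        for iv in self.intervals:
            out.setdefault(iv.chrom, []).append(iv)
        return out

    def sorted(self) -> "PeakSet":
        return PeakSet(
            sorted(self.intervals, key=lambda iv: (iv.chrom, iv.start, iv.end))
        )

    def get(self, peak_id: str) -> GenomicInterval:
        for iv in self.intervals:
            if iv.id == peak_id:
                return iv
        raise KeyError(peak_id)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chrom": [iv.chrom for iv in self.intervals],
                "start": [iv.start for iv in self.intervals],
                "end": [iv.end for iv in self.intervals],
                "id": [iv.id for iv in self.intervals],
                "gc": [iv.gc for iv in self.intervals],
            }
        )


@dataclass(frozen=True)
class GeneRecord:
    """A gene as TSS + strand + body extent.

    ``tss`` is 0-based.  On the plus strand the body runs from ``tss``
    to ``body_end`` in increasing coordinates; on the minus strand
    ``body_end`` lies upstream in genome coordinates (``body_end < tss``).
    """

    gene_id: str
    chrom: str
    tss: int
    strand: str
    body_end: int

    def __post_init__(self):
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if self.strand == "+" and self.body_end <= self.tss:
            raise ValueError(f"{self.gene_id}: plus-strand body_end must exceed tss")
        if self.strand == "-" and self.body_end >= self.tss:
            raise ValueError(f"{self.gene_id}: minus-strand body_end must precede tss")

    @property
    def length(self) -> int:
        return abs(self.body_end - self.tss)


@dataclass
class SignalTrack:
    """Fixed-bin coverage: ``data[chrom][i]`` is the mean signal per bp
    over ``[i * bin_size, (i + 1) * bin_size)``."""

    data: dict[str, np.ndarray]
    bin_size: int = 10

    def __post_init__(self):
        if self.bin_size < 1:
            raise ValueError("bin_size must be >= 1")
        self.data = {c: np.asarray(v, dtype=float) for c, v in self.data.items()}
        for c, v in self.data.items():
            if not np.all(np.isfinite(v)):
                raise ValueError(f"non-finite signal on {c}")

    def chrom_length(self, chrom: str) -> int:
        return len(self.data[chrom]) * self.bin_size

    def window_sum(self, chrom: str, start: int, end: int) -> float:
        """Integrated signal (value × bp) over ``[start, end)``.

        Partial bins contribute proportionally to their overlap; the
        window is truncated at chromosome bounds.
        """
        if chrom not in self.data:
            raise KeyError(chrom)
        arr = self.data[chrom]
        b = self.bin_size
        start = max(start, 0)
        end = min(end, len(arr) * b)
        if end <= start:
            return 0.0
        first, last = start // b, (end - 1) // b
        if first == last:
            return float(arr[first]) * (end - start)
        total = float(arr[first]) * ((first + 1) * b - start)
        total += float(arr[last]) * (end - last * b)
        if last > first + 1:
            total += float(arr[first + 1 : last].sum()) * b
        return total

    def window_mean(self, chrom: str, start: int, end: int) -> float:
        """Length-weighted mean signal density over the clipped window."""
        if chrom not in self.data:
            raise KeyError(chrom)
        lo = max(start, 0)
        hi = min(end, self.chrom_length(chrom))
        if hi <= lo:
            return float("nan")
        return self.window_sum(chrom, lo, hi) / (hi - lo)

    def scaled(self, factor: float) -> "SignalTrack":
        return SignalTrack(
            {c: v * factor for c, v in self.data.items()}, self.bin_size
        )


@dataclass
class CountMatrix:
    """Sparse features × cells matrix of non-negative integer counts."""

    features: list[str]
    cells: list[str]
    X: sparse.csr_matrix

    def __post_init__(self):
        self.X = sparse.csr_matrix(self.X)
        if self.X.shape != (len(self.features), len(self.cells)):
            raise ValueError(
                f"matrix shape {self.X.shape} inconsistent with "
                f"{len(self.features)} features x {len(self.cells)} cells"
            )
        if self.X.nnz and self.X.data.min() < 0:
            raise ValueError("counts must be non-negative")

    @property
    def shape(self) -> tuple[int, int]:
        return self.X.shape

    def cell_totals(self) -> np.ndarray:
        return np.asarray(self.X.sum(axis=0)).ravel()

    def genes_per_cell(self) -> np.ndarray:
        return np.asarray((self.X > 0).sum(axis=0)).ravel()

    def feature_index(self, ids: Sequence[str]) -> np.ndarray:
        lookup = {f: i for i, f in enumerate(self.features)}
        missing = [g for g in ids if g not in lookup]
        if missing:
            raise KeyError(f"features not found: {missing[:5]}")
        return np.array([lookup[g] for g in ids], dtype=int)

    def subset_cells(self, mask: np.ndarray) -> "CountMatrix":
        idx = np.flatnonzero(mask)
        return CountMatrix(
            self.features,
            [self.cells[i] for i in idx],
            self.X[:, idx],
        )


class CellTable:
    """Per-cell metadata with a declared label vocabulary.

    Wraps a DataFrame with columns ``cell_id``, ``germ_layer``,
    ``genotype`` and ``replicate``; cell ids must be unique.
    """

    REQUIRED = ("cell_id", "germ_layer", "genotype", "replicate")

    def __init__(self, df: pd.DataFrame):
        missing = [c for c in self.REQUIRED if c not in df.columns]
        if missing:
            raise ValueError(f"cell table missing columns: {missing}")
        if df["cell_id"].duplicated().any():
            raise ValueError("duplicate cell ids")
        bad = set(df["genotype"]) - set(GENOTYPE_VOCAB)
        if bad:
            raise ValueError(f"unknown genotypes: {sorted(bad)}")
        self.df = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    @property
    def cell_ids(self) -> list[str]:
        return list(self.df["cell_id"])

    @property
    def germ_layer(self) -> np.ndarray:
        return self.df["germ_layer"].to_numpy()

    @property
    def genotype(self) -> np.ndarray:
        return self.df["genotype"].to_numpy()

    def subset(self, mask: np.ndarray) -> "CellTable":
        return CellTable(self.df.loc[np.asarray(mask)].reset_index(drop=True))

    def aligned_to(self, cells: Sequence[str]) -> "CellTable":
        """Reorder rows to match a cell-id sequence (e.g. matrix columns)."""
        indexed = self.df.set_index("cell_id")
        return CellTable(indexed.loc[list(cells)].reset_index())


# ---------------------------------------------------------------------------
# BED


def read_bed(path) -> PeakSet:
    """Read a BED3+/BED6 file into a :class:`PeakSet`.

    Column 4 becomes the interval id when present; remaining columns are
    kept verbatim in ``extra``.  Malformed lines raise with the line
    number; ``start >= end`` is rejected.
    """
    intervals = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: expected >=3 tab-separated columns")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer coordinates") from exc
            if end <= start:
                raise ValueError(f"{path}:{lineno}: start >= end ({start} >= {end})")
            name = fields[3] if len(fields) > 3 else f"peak_{lineno}"
            intervals.append(
                GenomicInterval(
                    fields[0], start, end, id=name, extra=tuple(fields[4:])
                )
            )
    return PeakSet(intervals)


def write_bed(peaks: PeakSet, path) -> None:
    with _open_text(path, "wt") as fh:
        for iv in peaks:
            fields = [iv.chrom, str(iv.start), str(iv.end), iv.id, *iv.extra]
            fh.write("\t".join(fields) + "\n")


# ---------------------------------------------------------------------------
# bedGraph


def read_bedgraph(path, bin_size: int = 10) -> SignalTrack:
    """Read a bedGraph onto a fixed grid by length-weighted averaging.

    Input intervals must not overlap within a chromosome.  A grid bin
    covered partially gets the covering value weighted by the covered
    fraction (uncovered bases count as zero signal).
    """
    rows = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise ValueError(f"{path}:{lineno}: expected 4 columns")
            rows.append((fields[0], int(fields[1]), int(fields[2]), float(fields[3])))

    per_chrom: dict[str, list[tuple[int, int, float]]] = {}
    for chrom, start, end, value in rows:
        if end <= start:
            raise ValueError(f"bedGraph interval start >= end on {chrom}")
        per_chrom.setdefault(chrom, []).append((start, end, value))

    data = {}
    for chrom, ivs in per_chrom.items():
        ivs.sort()
        for (s1, e1, _), (s2, _, _) in zip(ivs, ivs[1:]):
            if s2 < e1:
                raise ValueError(f"overlapping bedGraph intervals on {chrom}")
        n_bins = -(-ivs[-1][1] // bin_size)
        arr = np.zeros(n_bins)
        for start, end, value in ivs:
            first, last = start // bin_size, (end - 1) // bin_size
            for b in range(first, last + 1):
                lo = max(start, b * bin_size)
                hi = min(end, (b + 1) * bin_size)
                arr[b] += value * (hi - lo) / bin_size
        data[chrom] = arr
    return SignalTrack(data, bin_size)


def write_bedgraph(track: SignalTrack, path) -> None:
    """Write a track as bedGraph, merging runs of equal-valued bins."""
    with _open_text(path, "wt") as fh:
        for chrom in sorted(track.data):
            arr = track.data[chrom]
            b = track.bin_size
            i = 0
            while i < len(arr):
                j = i
                while j + 1 < len(arr) and arr[j + 1] == arr[i]:
                    j += 1
                if arr[i] != 0.0:
                    fh.write(f"{chrom}\t{i * b}\t{(j + 1) * b}\t{arr[i]:.10g}\n")
                i = j + 1


# ---------------------------------------------------------------------------
# Count matrices (triplet text) + cell metadata


def read_counts(matrix_path, features_path, cells_path) -> tuple[CountMatrix, CellTable]:
    """Read a triplet-text count matrix with its feature and cell metadata.

    The matrix file holds ``%``-prefixed comments, then a header line
    ``n_features n_cells n_entries``, then 1-based ``i j count`` triplets.
    Duplicate (feature, cell) entries, out-of-range indices and negative
    counts are rejected.
    """
    with _open_text(matrix_path) as fh:
        lines = [ln for ln in fh if ln.strip() and not ln.startswith("%")]
    header = lines[0].split()
    n_feat, n_cell, n_entries = int(header[0]), int(header[1]), int(header[2])
    if len(lines) - 1 != n_entries:
        raise ValueError(
            f"{matrix_path}: header declares {n_entries} entries, found {len(lines) - 1}"
        )
    seen = set()
    rows, cols, vals = [], [], []
    for ln in lines[1:]:
        i_s, j_s, v_s = ln.split()
        i, j, v = int(i_s), int(j_s), int(v_s)
        if not (1 <= i <= n_feat and 1 <= j <= n_cell):
            raise ValueError(f"{matrix_path}: index ({i},{j}) out of range")
        if v < 0:
            raise ValueError(f"{matrix_path}: negative count at ({i},{j})")
        if (i, j) in seen:
            raise ValueError(f"{matrix_path}: duplicate entry at ({i},{j})")
        seen.add((i, j))
        rows.append(i - 1)
        cols.append(j - 1)
        vals.append(v)
    X = sparse.csr_matrix(
        (vals, (rows, cols)), shape=(n_feat, n_cell), dtype=np.int64
    )

    with _open_text(features_path) as fh:
        features = [ln.split("\t")[0].strip() for ln in fh if ln.strip()]
    if len(features) != n_feat:
        raise ValueError("feature list length does not match matrix")

    cells_df = pd.read_csv(cells_path, sep="\t", dtype=str)
    table = CellTable(cells_df)
    if len(table) != n_cell:
        raise ValueError("cell table length does not match matrix")
    return CountMatrix(features, table.cell_ids, X), table


def write_counts(matrix: CountMatrix, cells: CellTable, matrix_path, features_path, cells_path) -> None:
    coo = matrix.X.tocoo()
    order = np.lexsort((coo.col, coo.row))
    with _open_text(matrix_path, "wt") as fh:
        fh.write("%% triplet count matrix: features x cells, 1-based indices\n")
        fh.write(f"{matrix.shape[0]} {matrix.shape[1]} {coo.nnz}\n")
        for k in order:
            fh.write(f"{coo.row[k] + 1} {coo.col[k] + 1} {int(coo.data[k])}\n")
    with _open_text(features_path, "wt") as fh:
        fh.write("\n".join(matrix.features) + "\n")
    cells.df.to_csv(cells_path, sep="\t", index=False)


# ---------------------------------------------------------------------------


def filter_peak_widths(peaks: PeakSet, min_w: int = 20, max_w: int = 10_000) -> PeakSet:
    """Retain peaks with ``min_w <= width <= max_w`` (both bounds inclusive),
    the standard low-quality-peak filter; order is preserved."""
    if min_w > max_w:
        raise ValueError("min_w must not exceed max_w")
    return PeakSet(iv for iv in peaks if min_w <= iv.width <= max_w)


def read_genes(path) -> list[GeneRecord]:
    """Read gene annotation from a BED6-style file.

    Columns: chrom, start, end, gene_id, score (ignored), strand.  The TSS
    is ``start`` on the plus strand and ``end − 1`` on the minus strand;
    the body extends to the other edge.
    """
    genes = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise ValueError(f"{path}:{lineno}: need 6 columns for genes")
            chrom, start, end, gid, _, strand = fields[:6]
            start, end = int(start), int(end)
            if strand == "+":
                genes.append(GeneRecord(gid, chrom, start, "+", end))
            else:
                genes.append(GeneRecord(gid, chrom, end - 1, "-", start - 1))
    return genes


def write_genes(genes: Sequence[GeneRecord], path) -> None:
    with _open_text(path, "wt") as fh:
        for g in genes:
            if g.strand == "+":
                start, end = g.tss, g.body_end
            else:
                start, end = g.body_end + 1, g.tss + 1
            fh.write(f"{g.chrom}\t{start}\t{end}\t{g.gene_id}\t0\t{g.strand}\n")
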