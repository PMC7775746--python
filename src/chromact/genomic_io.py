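"""Genomic formats and the coordinate contract.

Every coordinate in this package is 0-based, half-open (BED native): an
interval ``[start, end)`` covers ``end - start`` base pairs.  refGene
``txStart`` is already 0-based, so gene tables are read without any shift.
The TSS of a minus-strand gene is ``end - 1`` (its last covered base).

Supported formats: BED6, narrowPeak (10 columns), bedGraph, refGene-style
tab tables, JASPAR position frequency matrices, and FASTA (via pyfaidx).
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from pyfaidx import Fasta

BASES = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}

__all__ = [
    "GenomicInterval",
    "GeneModel",
    "Pwm",
    "BedFeature",
    "CoverageTrack",
    "read_bed",
    "write_bed",
    "read_gene_table",
    "write_gene_table",
    "read_coverage",
    "write_coverage",
    "read_jaspar",
    "write_jaspar",
    "open_fasta",
    "write_fasta",
]


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """Half-open genomic span ``[start, end)`` on a named chromosome."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("empty chromosome name")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def contains(self, pos: int) -> bool:
        return self.start <= pos < self.end

    def overlaps(self, other: "GenomicInterval") -> bool:
        """True when the two spans share at least 1 bp (same chromosome)."""
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass(frozen=True)
class GeneModel:
    """Stranded gene with transcript and CDS bounds.

    ``tss``/``tes`` are strand-aware single-base positions inside the
    transcript span.  A record with ``cds_start == cds_end`` is non-coding.
    """

    gene_id: str
    chrom: str
    strand: str
    start: int
    end: int
    cds_start: int
    cds_end: int

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: unknown strand {self.strand!r}")
        if not (0 <= self.start < self.end):
            raise ValueError(f"gene {self.gene_id}: invalid span")
        if self.cds_start != self.cds_end:
            if not (self.start <= self.cds_start < self.cds_end <= self.end):
                raise ValueError(f"gene {self.gene_id}: CDS not nested in transcript")

    @property
    def interval(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.start, self.end, self.strand)

    @property
    def tss(self) -> int:
        return self.start if self.strand == "+" else self.end - 1

    @property
    def tes(self) -> int:
        return self.end - 1 if self.strand == "+" else self.start

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def is_coding(self) -> bool:
        return self.cds_end > self.cds_start

    @property
    def cds_length(self) -> int:
        return self.cds_end - self.cds_start


@dataclass
class Pwm:
    """Position weight matrix over A,C,G,T.

    ``matrix`` holds per-position base probabilities with shape (L, 4);
    each row sums to 1.  Scores are log2 odds against ``background``.
    ``score_threshold`` (bits) is the default hit cutoff; when None the
    scanner falls back to a fraction of the maximum achievable score.
    """

    motif_id: str
    matrix: np.ndarray
    background: np.ndarray = field(
        default_factory=lambda: np.full(4, 0.25)
    )
    score_threshold: float | None = None

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != 4:
            raise ValueError(f"PWM {self.motif_id}: matrix must be (L, 4)")
        if len(self) < 4:
            raise ValueError(f"PWM {self.motif_id}: length {len(self)} < 4")
        if not np.allclose(self.matrix.sum(axis=1), 1.0, atol=1e-6):
            raise ValueError(f"PWM {self.motif_id}: columns must sum to 1")
        if not np.isclose(self.background.sum(), 1.0, atol=1e-6):
            raise ValueError(f"PWM {self.motif_id}: background must sum to 1")

    def __len__(self) -> int:
        return self.matrix.shape[0]

    @property
    def log_odds(self) -> np.ndarray:
        """(L, 4) log2(p/background), zero-probability cells at -inf."""
        with np.errstate(divide="ignore"):
            return np.log2(self.matrix) - np.log2(self.background)

    @property
    def max_score(self) -> float:
        return float(self.log_odds.max(axis=1).sum())

    @property
    def consensus(self) -> str:
        return "".join(BASES[i] for i in self.matrix.argmax(axis=1))

    @classmethod
    def from_counts(
        cls,
        motif_id: str,
        counts: np.ndarray,
        pseudocount: float = 1.0,
        background: Sequence[float] | None = None,
    ) -> "Pwm":
        """Build from a (L, 4) or (4, L) count matrix with a pseudocount
        added to every cell before normalisation."""
        counts = np.asarray(counts, dtype=float)
        if counts.ndim != 2:
            raise ValueError("count matrix must be 2-D")
        if counts.shape[0] == 4 and counts.shape[1] != 4:
            counts = counts.T
        if counts.shape[1] != 4:
            raise ValueError("count matrix must have a base axis of size 4")
        if np.any(counts < 0):
            raise ValueError("negative counts")
        probs = counts + pseudocount
        probs /= probs.sum(axis=1, keepdims=True)
        bg = np.full(4, 0.25) if background is None else np.asarray(background, float)
        return cls(motif_id, probs, bg)

    @classmethod
    def from_consensus(
        cls, motif_id: str, consensus: str, match_prob: float = 0.85
    ) -> "Pwm":
        """Synthetic PWM concentrated on a consensus string; each position
        puts ``match_prob`` on the consensus base, the rest spread evenly."""
        off = (1.0 - match_prob) / 3.0
        mat = np.full((len(consensus), 4), off)
        for i, base in enumerate(consensus.upper()):
            mat[i, BASE_INDEX[base]] = match_prob
        return cls(motif_id, mat)


@dataclass(frozen=True)
class BedFeature:
    """One BED6 / narrowPeak record.  ``summit`` is the absolute genomic
    coordinate (start + offset) for narrowPeak, None for plain BED6."""

    interval: GenomicInterval
    name: str = "."
    score: float = 0.0
    signal: float = 0.0
    p_value: float = -1.0
    q_value: float = -1.0
    summit: int | None = None


def _parse_error(path: str, lineno: int, msg: str) -> ValueError:
    return ValueError(f"{path}:{lineno}: {msg}")


def read_bed(path: str | os.PathLike, dialect: str = "bed6") -> list[BedFeature]:
    """Read a BED6 or narrowPeak file.

    narrowPeak summit offsets are converted to absolute coordinates; an
    offset of -1 (unknown) yields ``summit=None``.
    """
    if dialect not in ("bed6", "narrowPeak"):
        raise ValueError(f"unknown BED dialect {dialect!r}")
    min_cols = 3 if dialect == "bed6" else 10
    out: list[BedFeature] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            cols = line.split("\t") if "\t" in line else line.split()
            if len(cols) < min_cols:
                raise _parse_error(str(path), lineno, f"expected >= {min_cols} columns")
            try:
                chrom, start, end = cols[0], int(cols[1]), int(cols[2])
            except ValueError as exc:
                raise _parse_error(str(path), lineno, f"bad coordinates: {exc}")
            name = cols[3] if len(cols) > 3 else "."
            score = float(cols[4]) if len(cols) > 4 and cols[4] != "." else 0.0
            strand = cols[5] if len(cols) > 5 else "."
            try:
                interval = GenomicInterval(chrom, start, end, strand)
            except ValueError as exc:
                raise _parse_error(str(path), lineno, str(exc))
            signal = p = q = 0.0
            summit = None
            if dialect == "narrowPeak":
                signal, p, q = float(cols[6]), float(cols[7]), float(cols[8])
                offset = int(cols[9])
                if offset >= interval.length:
                    raise _parse_error(
                        str(path), lineno,
                        f"summit offset {offset} >= region length {interval.length}",
                    )
                summit = None if offset < 0 else start + offset
            out.append(BedFeature(interval, name, score, signal, p, q, summit))
    return out


def write_bed(
    features: Iterable[BedFeature], path: str | os.PathLike, dialect: str = "bed6"
) -> None:
    with open(path, "w") as fh:
        for f in features:
            iv = f.interval
            cols = [iv.chrom, str(iv.start), str(iv.end), f.name,
                    f"{f.score:g}", iv.strand]
            if dialect == "narrowPeak":
                offset = -1 if f.summit is None else f.summit - iv.start
                cols += [f"{f.signal:g}", f"{f.p_value:g}", f"{f.q_value:g}",
                         str(offset)]
            fh.write("\t".join(cols) + "\n")


_GENE_COLS = ("name", "chrom", "strand", "txStart", "txEnd", "cdsStart", "cdsEnd")


def read_gene_table(path: str | os.PathLike) -> list[GeneModel]:
    """Read a refGene-style tab table.

    Columns name/chrom/strand/txStart/txEnd/cdsStart/cdsEnd, with an
    optional header line.  Duplicate gene ids (isoforms with distinct
    TSSs) are kept as separate records.
    """
    genes: list[GeneModel] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if cols[0] in ("name", "gene_id"):  # header
                continue
            if len(cols) < 7:
                raise _parse_error(str(path), lineno, "expected >= 7 columns")
            name, chrom, strand = cols[0], cols[1], cols[2]
            try:
                tx_start, tx_end = int(cols[3]), int(cols[4])
                cds_start, cds_end = int(cols[5]), int(cols[6])
            except ValueError as exc:
                raise _parse_error(str(path), lineno, f"bad coordinates: {exc}")
            try:
                genes.append(
                    GeneModel(name, chrom, strand, tx_start, tx_end,
                              cds_start, cds_end)
                )
            except ValueError as exc:
                raise _parse_error(str(path), lineno, str(exc))
    return genes


def write_gene_table(genes: Iterable[GeneModel], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(_GENE_COLS) + "\n")
        for g in genes:
            fh.write(
                f"{g.gene_id}\t{g.chrom}\t{g.strand}\t{g.start}\t{g.end}"
                f"\t{g.cds_start}\t{g.cds_end}\n"
            )


class CoverageTrack:
    """Per-base read-start counts for one sample.

    Thin wrapper over one integer numpy array per chromosome, with cached
    prefix sums for O(1) region counting.
    """

    def __init__(self, counts: dict[str, np.ndarray]):
        self.counts = {
            chrom: np.asarray(arr, dtype=np.int64) for chrom, arr in counts.items()
        }
        for chrom, arr in self.counts.items():
            if arr.ndim != 1:
                raise ValueError(f"{chrom}: counts must be 1-D")
            if np.any(arr < 0):
                raise ValueError(f"{chrom}: negative counts")
        self._cumsum: dict[str, np.ndarray] = {}

    @property
    def chrom_lengths(self) -> dict[str, int]:
        return {chrom: len(arr) for chrom, arr in self.counts.items()}

    @property
    def depth(self) -> int:
        """Total reads in the track."""
        return int(sum(arr.sum() for arr in self.counts.values()))

    def _cs(self, chrom: str) -> np.ndarray:
        cs = self._cumsum.get(chrom)
        if cs is None:
            cs = np.concatenate([[0], np.cumsum(self.counts[chrom])])
            self._cumsum[chrom] = cs
        return cs

    def region_count(self, chrom: str, start: int, end: int) -> int:
        """Reads with start position in [start, end), clipped to the chromosome."""
        arr = self.counts[chrom]
        start, end = max(0, start), min(len(arr), end)
        if start >= end:
            return 0
        cs = self._cs(chrom)
        return int(cs[end] - cs[start])

    def interval_count(self, interval: GenomicInterval) -> int:
        return self.region_count(interval.chrom, interval.start, interval.end)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CoverageTrack):
            return NotImplemented
        return self.counts.keys() == other.counts.keys() and all(
            np.array_equal(self.counts[c], other.counts[c]) for c in self.counts
        )

    def scaled(self, factor: float) -> "CoverageTrack":
        """Integer-scaled copy (used only in scale-invariance checks)."""
        return CoverageTrack(
            {c: (arr * factor).astype(np.int64) for c, arr in self.counts.items()}
        )


def write_coverage(track: CoverageTrack, path: str | os.PathLike) -> None:
    """Write a track as bedGraph in canonical form: run-length encoded,
    adjacent equal-value spans merged, zero spans omitted.  Chromosome
    lengths go into a comment header so a round trip is exact."""
    with open(path, "w") as fh:
        lengths = ",".join(f"{c}={n}" for c, n in sorted(track.chrom_lengths.items()))
        fh.write(f"#chrom_lengths\t{lengths}\n")
        for chrom in sorted(track.counts):
            arr = track.counts[chrom]
            if len(arr) == 0:
                continue
            # run-length boundaries
            change = np.flatnonzero(np.diff(arr)) + 1
            starts = np.concatenate([[0], change])
            ends = np.concatenate([change, [len(arr)]])
            for s, e in zip(starts, ends):
                v = arr[s]
                if v != 0:
                    fh.write(f"{chrom}\t{s}\t{e}\t{v}\n")


def read_coverage(
    path: str | os.PathLike, chrom_lengths: dict[str, int] | None = None
) -> CoverageTrack:
    """Read a bedGraph into a CoverageTrack.

    Spans must not overlap.  Lengths come from the ``#chrom_lengths``
    header when present, from ``chrom_lengths``, else from the maximum
    end seen per chromosome.
    """
    spans: dict[str, list[tuple[int, int, int]]] = {}
    lengths = dict(chrom_lengths or {})
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line:
                continue
            if line.startswith("#chrom_lengths"):
                for item in line.split("\t", 1)[1].split(","):
                    c, n = item.split("=")
                    lengths[c] = int(n)
                continue
            if line.startswith(("#", "track", "browser")):
                continue
            cols = line.split()
            if len(cols) != 4:
                raise _parse_error(str(path), lineno, "expected 4 columns")
            chrom, start, end = cols[0], int(cols[1]), int(cols[2])
            value = float(cols[3])
            if value < 0:
                raise _parse_error(str(path), lineno, f"negative value {value}")
            if end <= start:
                raise _parse_error(str(path), lineno, "end <= start")
            spans.setdefault(chrom, []).append((start, end, int(round(value))))
    counts: dict[str, np.ndarray] = {}
    for chrom, chrom_spans in spans.items():
        chrom_spans.sort()
        for (s1, e1, _), (s2, _, _) in zip(chrom_spans, chrom_spans[1:]):
            if s2 < e1:
                raise ValueError(
                    f"{path}: overlapping bedGraph spans on {chrom} at {s2}"
                )
        n = lengths.get(chrom, max(e for _, e, _ in chrom_spans))
        arr = np.zeros(n, dtype=np.int64)
        for s, e, v in chrom_spans:
            arr[s:e] = v
        counts[chrom] = arr
    for chrom, n in lengths.items():
        counts.setdefault(chrom, np.zeros(n, dtype=np.int64))
    return CoverageTrack(counts)


def read_jaspar(
    path: str | os.PathLike, pseudocount: float = 1.0
) -> list[Pwm]:
    """Read JASPAR-format position frequency matrices.

    Accepts the bracketed 4-row layout::

        >MA0000.1 NAME
        A [ 10  0  3 ]
        C [  0 12  1 ]
        ...

    Counts become probabilities with ``pseudocount`` added per cell.
    """
    pwms: list[Pwm] = []
    motif_id: str | None = None
    rows: dict[str, list[float]] = {}

    def _flush() -> None:
        nonlocal rows, motif_id
        if motif_id is None:
            return
        if set(rows) != set(BASES):
            raise ValueError(f"PWM {motif_id}: need exactly rows A,C,G,T")
        lens = {len(v) for v in rows.values()}
        if len(lens) != 1:
            raise ValueError(f"PWM {motif_id}: rows of unequal length")
        counts = np.array([rows[b] for b in BASES])  # (4, L)
        pwms.append(Pwm.from_counts(motif_id, counts, pseudocount=pseudocount))
        rows = {}
        motif_id = None

    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                _flush()
                motif_id = line[1:].split()[0]
                continue
            if motif_id is None:
                raise ValueError(f"{path}: matrix row before any header")
            base = line[0].upper()
            if base not in BASE_INDEX:
                raise ValueError(f"{path}: unknown base row {line[0]!r}")
            body = line[1:].replace("[", " ").replace("]", " ")
            rows[base] = [float(x) for x in body.split()]
    _flush()
    return pwms


def write_jaspar(pwms: Iterable[Pwm], path: str | os.PathLike, scale: int = 100) -> None:
    """Write PWMs as JASPAR count matrices (probabilities scaled to counts)."""
    with open(path, "w") as fh:
        for pwm in pwms:
            fh.write(f">{pwm.motif_id}\n")
            counts = np.round(pwm.matrix * scale).astype(int)
            for bi, base in enumerate(BASES):
                body = " ".join(f"{c:4d}" for c in counts[:, bi])
                fh.write(f"{base} [ {body} ]\n")


def open_fasta(path: str | os.PathLike) -> Fasta:
    return Fasta(str(path))


def write_fasta(
    sequences: dict[str, str], path: str | os.PathLike, width: int = 80
) -> None:
    with open(path, "w") as fh:
        for name in sequences:
            fh.write(f">{name}\n")
            seq = sequences[name]
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")
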