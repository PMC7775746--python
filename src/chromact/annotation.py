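"""Chromatin-state classification and peak-to-gene target mapping.

A peak is classified by the histone marks overlapping its *summit*,
with precedence promoter (H3K4me3) > enhancer (H3K4me1 or H3K27ac) >
repressed (H3K9me3 or H3K27me3) > uncharacterized.  Promoter peaks map
to the nearest TSS within a strand-aware window 1500 bp upstream to
250 bp downstream, with a downstream summit additionally required to
lie within 5% of the gene length of the TSS; enhancer peaks map to all
genes whose TSS is within 50 kb of the summit or whose body contains
the summit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from ._stats import ContingencyResult, fisher_exact_2x2
from .genomic_io import GeneModel, GenomicInterval
from .peaks import Peak

PROMOTER_MARKS = ("H3K4me3",)
ENHANCER_MARKS = ("H3K4me1", "H3K27ac")
REPRESSED_MARKS = ("H3K9me3", "H3K27me3")
CLASSES = ("promoter", "enhancer", "repressed", "uncharacterized")

__all__ = [
    "ChromatinStateMap",
    "classify_peak",
    "classify_peaks",
    "assign_promoter_targets",
    "assign_enhancer_targets",
    "gene_target_classes",
    "class_enrichment",
    "CLASSES",
]


class ChromatinStateMap:
    """Labeled region sets per histone mark with point-overlap queries."""

    def __init__(self, regions: Mapping[str, Iterable[GenomicInterval]]):
        self._index: dict[str, dict[str, tuple[np.ndarray, np.ndarray]]] = {}
        self.regions = {mark: list(ivs) for mark, ivs in regions.items()}
        for mark, ivs in self.regions.items():
            by_chrom: dict[str, list[tuple[int, int]]] = {}
            for iv in ivs:
                by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end))
            self._index[mark] = {}
            for chrom, spans in by_chrom.items():
                spans.sort()
                starts = np.array([s for s, _ in spans])
                ends = np.maximum.accumulate(np.array([e for _, e in spans]))
                self._index[mark][chrom] = (starts, ends)

    def mark_at(self, mark: str, chrom: str, pos: int) -> bool:
        entry = self._index.get(mark, {}).get(chrom)
        if entry is None:
            return False
        starts, ends = entry
        i = np.searchsorted(starts, pos, side="right")
        return i > 0 and ends[i - 1] > pos

    def classify_position(
        self,
        chrom: str,
        pos: int,
        precedence: Sequence[tuple[str, tuple[str, ...]]] = (
            ("promoter", PROMOTER_MARKS),
            ("enhancer", ENHANCER_MARKS),
            ("repressed", REPRESSED_MARKS),
        ),
    ) -> str:
        for label, marks in precedence:
            if any(self.mark_at(m, chrom, pos) for m in marks):
                return label
        return "uncharacterized"


def classify_peak(peak: Peak, states: ChromatinStateMap, **kw) -> str:
    """Chromatin class of a single peak, decided at its summit."""
    return states.classify_position(peak.interval.chrom, peak.summit, **kw)


def classify_peaks(peaks: Sequence[Peak], states: ChromatinStateMap, **kw) -> list[str]:
    return [classify_peak(p, states, **kw) for p in peaks]


@dataclass
class GeneTargetAssignment:
    """Per-gene target call: Pr (promoter sites only), Eh (enhancer sites
    only) or Pr+Eh, with the supporting peaks and summit-to-TSS distances."""

    gene_id: str
    target_class: str
    promoter_peaks: list[int] = field(default_factory=list)
    enhancer_peaks: list[int] = field(default_factory=list)
    distances: list[int] = field(default_factory=list)


def assign_promoter_targets(
    peaks: Sequence[Peak],
    genes: Sequence[GeneModel],
    upstream: int = 1500,
    downstream: int = 250,
    max_gene_fraction: float = 0.05,
) -> pd.DataFrame:
    """Map promoter-classified peaks to the nearest qualifying TSS.

    A TSS qualifies when the summit lies within ``upstream`` bp upstream
    to ``downstream`` bp downstream of it (strand-aware, bounds
    inclusive).  When the summit is downstream of the TSS (toward the
    gene body) the summit-to-TSS distance must additionally be strictly
    less than ``max_gene_fraction`` of the gene length.  Among
    qualifying TSSs the nearest wins (ties -> lexicographically smaller
    gene id).  Returns one row per assigned peak:
    peak_index, gene_id, distance (signed, + downstream of TSS).
    """
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    rows = []
    for idx, peak in enumerate(peaks):
        summit = peak.summit
        best: tuple[int, str, int] | None = None  # (|dist|, gene_id, signed)
        for gene in by_chrom.get(peak.interval.chrom, ()):
            tss = gene.tss
            # signed offset in gene orientation: + means downstream of TSS
            offset = summit - tss if gene.strand == "+" else tss - summit
            if not (-upstream <= offset <= downstream):
                continue
            if offset > 0 and not (offset < max_gene_fraction * gene.length):
                continue
            key = (abs(offset), gene.gene_id, offset)
            if best is None or key[:2] < best[:2]:
                best = key
        if best is not None:
            rows.append((idx, best[1], best[2]))
    return pd.DataFrame(rows, columns=["peak_index", "gene_id", "distance"])


def assign_enhancer_targets(
    peaks: Sequence[Peak],
    genes: Sequence[GeneModel],
    max_dist: int = 50_000,
) -> pd.DataFrame:
    """Map enhancer-classified peaks to genes.

    A gene is a target of a peak when |TSS - summit| <= ``max_dist``
    (inclusive) or the summit falls inside the gene body.  Many-to-many:
    one peak may target several genes and vice versa.
    """
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    rows = []
    for idx, peak in enumerate(peaks):
        summit = peak.summit
        for gene in by_chrom.get(peak.interval.chrom, ()):
            dist = abs(gene.tss - summit)
            if dist <= max_dist or gene.interval.contains(summit):
                rows.append((idx, gene.gene_id, dist))
    return pd.DataFrame(rows, columns=["peak_index", "gene_id", "distance"])


def gene_target_classes(
    promoter_assignments: pd.DataFrame, enhancer_assignments: pd.DataFrame
) -> dict[str, GeneTargetAssignment]:
    """Partition target genes into Pr / Eh / Pr+Eh."""
    out: dict[str, GeneTargetAssignment] = {}
    for row in promoter_assignments.itertuples(index=False):
        a = out.setdefault(row.gene_id, GeneTargetAssignment(row.gene_id, "Pr"))
        a.promoter_peaks.append(int(row.peak_index))
        a.distances.append(int(row.distance))
    for row in enhancer_assignments.itertuples(index=False):
        a = out.setdefault(row.gene_id, GeneTargetAssignment(row.gene_id, "Eh"))
        a.enhancer_peaks.append(int(row.peak_index))
        a.distances.append(int(row.distance))
    for a in out.values():
        if a.promoter_peaks and a.enhancer_peaks:
            a.target_class = "Pr+Eh"
        elif a.promoter_peaks:
            a.target_class = "Pr"
        else:
            a.target_class = "Eh"
    return out


def class_enrichment(
    peak_classes: Sequence[str], background_classes: Sequence[str]
) -> pd.DataFrame:
    """Per-class 2x2 Fisher exact test of peaks against a background
    region set (e.g. DNase hypersensitive sites).

    Rows: class, n_peaks, n_background, peak_fraction,
    background_fraction, odds_ratio, p_value.
    """
    if len(background_classes) == 0:
        raise ValueError("empty background classification")
    pc = pd.Series(peak_classes)
    bc = pd.Series(background_classes)
    rows = []
    for cls in CLASSES:
        a = int((pc == cls).sum())
        b = len(pc) - a
        c = int((bc == cls).sum())
        d = len(bc) - c
        res: ContingencyResult = fisher_exact_2x2([[a, b], [c, d]])
        rows.append(
            (cls, a, c, a / len(pc) if len(pc) else np.nan, c / len(bc),
             res.odds_ratio, res.p_value)
        )
    return pd.DataFrame(
        rows,
        columns=[
            "class", "n_peaks", "n_background", "peak_fraction",
            "background_fraction", "odds_ratio", "p_value",
        ],
    )
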