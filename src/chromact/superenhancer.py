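"""ROSE-style super-enhancer identification.

H3K27ac enhancer peaks (lacking H3K4me3) are stitched when their gap is
at most 12.5 kb; each stitched region is scored by the sum of
input-corrected H3K27ac signal over its constituents; regions are
ranked by signal and the super-enhancer cutoff is the tangent point
where the slope of the rescaled signal-vs-rank curve reaches 1,
scanning down from the top rank.  Genes are assigned to a region when
their TSS is within 50 kb of the region boundary or their body overlaps
the region.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .genomic_io import GeneModel, GenomicInterval

STITCH_DISTANCE = 12_500
GENE_WINDOW = 50_000

__all__ = ["StitchedEnhancer", "stitch", "call_super", "assign_se_genes"]


@dataclass
class StitchedEnhancer:
    interval: GenomicInterval
    constituent_ids: list[int]
    signal: float
    rank: int | None = None  # 1 = highest signal
    is_super: bool = False
    genes: list[str] = field(default_factory=list)


def input_corrected_signal(
    chip_rpm: np.ndarray, input_rpm: np.ndarray
) -> np.ndarray:
    """Per-peak enhancer signal: ChIP RPM minus depth-scaled input RPM,
    floored at zero."""
    return np.maximum(np.asarray(chip_rpm, float) - np.asarray(input_rpm, float), 0.0)


def stitch(
    intervals: Sequence[GenomicInterval],
    signals: Sequence[float],
    distance: int = STITCH_DISTANCE,
) -> list[StitchedEnhancer]:
    """Transitively stitch enhancer peaks whose gap is <= ``distance``
    on the same chromosome; the stitched signal is the sum over
    constituents.  Indices into the input order are kept as
    constituent ids.  Order-independent and idempotent."""
    if len(intervals) != len(signals):
        raise ValueError("need one signal per interval")
    order = sorted(
        range(len(intervals)),
        key=lambda i: (intervals[i].chrom, intervals[i].start, intervals[i].end),
    )
    out: list[StitchedEnhancer] = []
    group: list[int] = []
    group_end = 0
    for i in order:
        iv = intervals[i]
        if group and iv.chrom == intervals[group[0]].chrom and iv.start - group_end <= distance:
            group.append(i)
            group_end = max(group_end, iv.end)
        else:
            if group:
                out.append(_emit_group(intervals, signals, group, group_end))
            group = [i]
            group_end = iv.end
    if group:
        out.append(_emit_group(intervals, signals, group, group_end))
    return out


def _emit_group(intervals, signals, group, end) -> StitchedEnhancer:
    first = intervals[group[0]]
    return StitchedEnhancer(
        GenomicInterval(first.chrom, first.start, end),
        list(group),
        float(sum(signals[i] for i in group)),
    )


def call_super(stitched: Sequence[StitchedEnhancer]) -> tuple[list[StitchedEnhancer], float]:
    """Flag super-enhancers by the discrete tangent criterion.

    Signals are sorted ascending and both rank and signal rescaled to
    [0, 1]; the cutoff sits at the smallest signal whose local two-point
    slope of the signal-vs-rank curve exceeds 1 — on the rescaled convex
    curve this is where the tangent reaches unit slope — and every
    region from there up is super.  The cutoff returned is that raw
    signal (inf when no slope exceeds 1).  Requires >= 3 regions; with
    all-equal signals no region is super.  Ranks (1 = strongest) are
    written onto the input objects.
    """
    if len(stitched) < 3:
        raise ValueError("need >= 3 stitched regions to place a cutoff")
    regions = sorted(stitched, key=lambda r: r.signal)
    n = len(regions)
    sig = np.array([r.signal for r in regions], dtype=float)
    span = sig[-1] - sig[0]
    for i, r in enumerate(regions):
        r.rank = n - i
        r.is_super = False
    if span == 0:
        return list(stitched), float("inf")
    y = (sig - sig[0]) / span
    x = np.arange(n) / (n - 1)
    cutoff_idx = n  # first index NOT super
    for i in range(1, n):
        slope = (y[i] - y[i - 1]) / (x[i] - x[i - 1])
        if slope > 1.0:
            cutoff_idx = i
            break
    for r in regions[cutoff_idx:]:
        r.is_super = True
    cutoff = sig[cutoff_idx] if cutoff_idx < n else float("inf")
    return list(stitched), float(cutoff)


def assign_se_genes(
    stitched: Sequence[StitchedEnhancer],
    genes: Sequence[GeneModel],
    max_dist: int = GENE_WINDOW,
) -> list[StitchedEnhancer]:
    """Attach target genes: TSS within ``max_dist`` of the region edge
    (inclusive) or gene body overlapping the region."""
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    for region in stitched:
        iv = region.interval
        hits = []
        for gene in by_chrom.get(iv.chrom, ()):
            # distance from the TSS to the nearest region coordinate
            # (half-open convention: a TSS at start - d or end + d is d away)
            dist = max(iv.start - gene.tss, gene.tss - iv.end, 0)
            if dist <= max_dist or gene.interval.overlaps(iv):
                hits.append(gene.gene_id)
        region.genes = sorted(set(hits))
    return list(stitched)
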