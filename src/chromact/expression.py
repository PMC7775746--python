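"""Expression quantification and cancer-gene enrichment.

Ribosome-footprint (or RNA) signal is quantified as RPKM over a trimmed
ORF: the CDS minus the first 15 codons after the start, the last 5
codons before the stop, and any supplied upstream-ORF mask.  Genes with
fewer than 5 raw reads in a condition are filtered from fold-change
comparisons; differential expression calls use an inclusive twofold
cutoff.  Cancer-gene catalogs are consolidated by role union (genes
annotated as both oncogene and tumor suppressor become OncoTSG), and
every enrichment claim is a two-sided Fisher exact test.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from ._stats import (
    ContingencyResult,
    RankTestResult,
    fisher_exact_2x2,
    rank_sum_test,
)
from .genomic_io import CoverageTrack, GeneModel, GenomicInterval

START_TRIM_BP = 15 * 3  # 15 codons after the start codon
STOP_TRIM_BP = 5 * 3  # 5 codons before the stop codon
MIN_RAW_READS = 5
CATALOG_LABELS = ("NonCancer", "ONG", "TSG", "OncoTSG")

__all__ = [
    "trimmed_orf_region",
    "trimmed_orf_rpkm",
    "expression_table",
    "call_de",
    "bound_vs_unbound",
    "consolidate_catalogs",
    "cancer_enrichment",
]


def trimmed_orf_region(
    gene: GeneModel, uorf_mask: Sequence[GenomicInterval] = ()
) -> list[tuple[int, int]]:
    """Quantification segments of a gene's ORF after trimming.

    Removes ``START_TRIM_BP`` from the start-codon end and
    ``STOP_TRIM_BP`` from the stop-codon end (strand-aware), then
    subtracts any overlap with ``uorf_mask``.  Returns half-open
    (start, end) segments; empty when the gene is non-coding or the CDS
    is too short to survive trimming.
    """
    if not gene.is_coding:
        return []
    if gene.cds_length <= START_TRIM_BP + STOP_TRIM_BP:
        return []
    if gene.strand == "+":
        lo, hi = gene.cds_start + START_TRIM_BP, gene.cds_end - STOP_TRIM_BP
    else:
        lo, hi = gene.cds_start + STOP_TRIM_BP, gene.cds_end - START_TRIM_BP
    segments = [(lo, hi)]
    for mask in uorf_mask:
        if mask.chrom != gene.chrom:
            continue
        next_segments = []
        for s, e in segments:
            if mask.end <= s or mask.start >= e:
                next_segments.append((s, e))
                continue
            if s < mask.start:
                next_segments.append((s, mask.start))
            if mask.end < e:
                next_segments.append((mask.end, e))
        segments = next_segments
    return segments


@dataclass(frozen=True)
class ExpressionRecord:
    gene_id: str
    region_bp: int
    reads: int
    rpkm: float
    filtered: bool  # fewer than MIN_RAW_READS raw reads


def trimmed_orf_rpkm(
    track: CoverageTrack,
    gene: GeneModel,
    uorf_mask: Sequence[GenomicInterval] = (),
    min_reads: int = MIN_RAW_READS,
) -> ExpressionRecord:
    """RPKM of one gene over its trimmed ORF from a footprint track."""
    segments = trimmed_orf_region(gene, uorf_mask)
    region_bp = sum(e - s for s, e in segments)
    if region_bp == 0:
        return ExpressionRecord(gene.gene_id, 0, 0, np.nan, True)
    reads = sum(track.region_count(gene.chrom, s, e) for s, e in segments)
    depth = track.depth
    if depth == 0:
        raise ValueError("zero-depth track")
    rpkm = reads * 1e9 / (depth * region_bp)
    return ExpressionRecord(gene.gene_id, region_bp, reads, rpkm, reads < min_reads)


def expression_table(
    counts: pd.DataFrame,
    genes: Sequence[GeneModel],
    depths: Mapping[str, int],
    uorf_mask: Sequence[GenomicInterval] = (),
    conditions: tuple[str, str] = ("etoh", "tam"),
    min_reads: int = MIN_RAW_READS,
) -> pd.DataFrame:
    """Build the per-gene expression table from a raw count table.

    ``counts`` needs columns gene_id and reads_<cond> per condition;
    ``depths`` maps condition -> total mapped reads.  RPKM uses the
    trimmed-ORF length of each gene.  A gene is filtered for
    fold-change purposes when it has fewer than ``min_reads`` raw reads
    in either condition, or no quantifiable trimmed ORF.
    """
    ref, alt = conditions
    by_id: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_id.setdefault(g.gene_id, []).append(g)
    rows = []
    for row in counts.itertuples(index=False):
        models = by_id.get(row.gene_id)
        if not models:
            continue
        region_bp = sum(
            e - s for s, e in trimmed_orf_region(models[0], uorf_mask)
        )
        k_ref = int(getattr(row, f"reads_{ref}"))
        k_alt = int(getattr(row, f"reads_{alt}"))
        if region_bp == 0:
            rows.append((row.gene_id, region_bp, k_ref, k_alt, np.nan, np.nan,
                         np.nan, True))
            continue
        rpkm_ref = k_ref * 1e9 / (depths[ref] * region_bp)
        rpkm_alt = k_alt * 1e9 / (depths[alt] * region_bp)
        filtered = k_ref < min_reads or k_alt < min_reads
        fc = rpkm_alt / rpkm_ref if rpkm_ref > 0 else np.nan
        rows.append(
            (row.gene_id, region_bp, k_ref, k_alt, rpkm_ref, rpkm_alt, fc, filtered)
        )
    return pd.DataFrame(
        rows,
        columns=[
            "gene_id", "region_bp", f"reads_{ref}", f"reads_{alt}",
            f"rpkm_{ref}", f"rpkm_{alt}", "fold_change", "filtered",
        ],
    )


def call_de(records: pd.DataFrame, fold: float = 2.0) -> pd.DataFrame:
    """Label genes up/down/unchanged/filtered at an inclusive
    ``fold``-change cutoff (TAM:EtOH >= fold is up, <= 1/fold is down)."""
    out = records.copy()
    fc = out["fold_change"]
    status = np.where(
        out["filtered"] | fc.isna(),
        "filtered",
        np.where(fc >= fold, "up", np.where(fc <= 1.0 / fold, "down", "unchanged")),
    )
    out["de_status"] = status
    return out


def bound_vs_unbound(
    records: pd.DataFrame,
    bound_genes: Iterable[str],
    conditions: tuple[str, str] = ("etoh", "tam"),
) -> dict[str, RankTestResult]:
    """Compare expression of bound versus unbound genes.

    Two-sided Wilcoxon rank-sum tests on log2 RPKM per condition and on
    log2 fold change (filtered genes excluded from the fold-change
    comparison, never imputed).  Returns results keyed
    'level_<cond>' and 'fold_change'.
    """
    bound = set(bound_genes)
    is_bound = records["gene_id"].isin(bound)
    results: dict[str, RankTestResult] = {}
    for cond in conditions:
        col = f"rpkm_{cond}"
        ok = records[col].notna()
        x = np.log2(records.loc[ok & is_bound, col] + 0.5)
        y = np.log2(records.loc[ok & ~is_bound, col] + 0.5)
        if x.empty or y.empty:
            raise ValueError(f"empty group for condition {cond!r}")
        results[f"level_{cond}"] = rank_sum_test(x, y)
    ok = ~records["filtered"] & records["fold_change"].notna()
    x = np.log2(records.loc[ok & is_bound, "fold_change"])
    y = np.log2(records.loc[ok & ~is_bound, "fold_change"])
    if x.empty or y.empty:
        raise ValueError("empty group in fold-change comparison")
    results["fold_change"] = rank_sum_test(x, y)
    return results


def consolidate_catalogs(
    sources: Sequence[tuple[Iterable[str], str]],
    universe: Iterable[str] | None = None,
) -> pd.Series:
    """Consolidate cancer-gene catalogs into one exclusive labelling.

    ``sources`` is a list of (gene set, role) with role ONG or TSG.
    Roles are unioned over sources; a gene in both unions is OncoTSG.
    With a ``universe`` the remaining genes get NonCancer.  Idempotent
    and order-independent.
    """
    ong: set[str] = set()
    tsg: set[str] = set()
    for genes, role in sources:
        if role == "ONG":
            ong.update(genes)
        elif role == "TSG":
            tsg.update(genes)
        else:
            raise ValueError(f"unknown catalog role {role!r}")
    labels: dict[str, str] = {}
    for g in ong | tsg:
        if g in ong and g in tsg:
            labels[g] = "OncoTSG"
        elif g in ong:
            labels[g] = "ONG"
        else:
            labels[g] = "TSG"
    if universe is not None:
        for g in universe:
            labels.setdefault(g, "NonCancer")
    return pd.Series(labels, name="label").sort_index()


def cancer_enrichment(
    catalog: pd.Series | Mapping[str, str],
    target_genes: Iterable[str],
    universe: Iterable[str],
) -> pd.DataFrame:
    """Enrichment of cancer-gene classes among target genes.

    For each label (and for all cancer labels combined) builds the 2x2
    table target/non-target x label/not over the universe and runs a
    two-sided Fisher exact test.  Also reports the fraction of target
    genes in the label and the fraction of label genes that are targets.
    """
    catalog = pd.Series(dict(catalog)) if not isinstance(catalog, pd.Series) else catalog
    universe = set(universe)
    targets = set(target_genes)
    if not targets <= universe:
        raise ValueError("target genes must be a subset of the universe")
    labels = {g: catalog.get(g, "NonCancer") for g in universe}
    rows = []
    groups = [(lab, {g for g, l in labels.items() if l == lab})
              for lab in ("ONG", "TSG", "OncoTSG")]
    cancer_all = set().union(*(s for _, s in groups))
    groups.append(("AnyCancer", cancer_all))
    for lab, members in groups:
        a = len(targets & members)
        b = len(targets - members)
        c = len(members - targets)
        d = len(universe) - a - b - c
        res: ContingencyResult = fisher_exact_2x2([[a, b], [c, d]])
        rows.append(
            (
                lab, a, len(members),
                a / len(targets) if targets else np.nan,
                a / len(members) if members else np.nan,
                res.odds_ratio, res.p_value,
            )
        )
    return pd.DataFrame(
        rows,
        columns=[
            "label", "n_target_in_label", "n_label", "fraction_of_targets",
            "fraction_of_label_targeted", "odds_ratio", "p_value",
        ],
    )
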