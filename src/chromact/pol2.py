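"""RNA polymerase II density, pausing index and meta-gene profiles.

Pol II density is reads per million per kilobase (RPM/kb) in the
promoter-proximal window (TSS +/- 250 bp) and in the gene body (the
remaining gene length, i.e. the gene minus the downstream 250 bp of the
promoter window, strand-aware).  The pausing index (traveling ratio) is
the promoter/body density ratio, computed for genes longer than 251 bp
and reported as missing when the body has zero signal.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ._stats import pearson_log
from .genomic_io import CoverageTrack, GeneModel

PROMOTER_FLANK = 250
MIN_GENE_LENGTH = 251  # genes must be strictly longer

__all__ = [
    "Pol2GeneMetrics",
    "pol2_gene_metrics",
    "pol2_metrics_table",
    "metagene_profile",
    "binding_expression_correlation",
]


@dataclass(frozen=True)
class Pol2GeneMetrics:
    gene_id: str
    promoter_reads: int
    body_reads: int
    promoter_density: float  # RPM/kb
    body_density: float
    pausing_index: float | None  # None when body density is 0


def _gene_windows(gene: GeneModel, flank: int = PROMOTER_FLANK):
    """(promoter_window, body_segments) in absolute coordinates.

    The promoter window is TSS +/- flank.  The body is the gene interval
    minus its intersection with the promoter window; for a + strand gene
    that removes [TSS, TSS+flank), mirrored for - strand.
    """
    tss = gene.tss
    prom = (tss - flank, tss + flank + 1)  # inclusive +/-flank around the base
    if gene.strand == "+":
        body = (min(gene.end, max(gene.start, prom[1])), gene.end)
    else:
        body = (gene.start, max(gene.start, min(gene.end, prom[0])))
    return prom, body


def pol2_gene_metrics(
    track: CoverageTrack, gene: GeneModel, flank: int = PROMOTER_FLANK
) -> Pol2GeneMetrics | None:
    """Densities and pausing index for one gene; None when the gene is
    too short (<= 251 bp) or its promoter window leaves the chromosome."""
    if gene.length <= MIN_GENE_LENGTH:
        return None
    chrom_len = track.chrom_lengths.get(gene.chrom)
    if chrom_len is None:
        return None
    prom, body = _gene_windows(gene, flank)
    if prom[0] < 0 or prom[1] > chrom_len:
        return None
    depth = track.depth
    if depth == 0:
        raise ValueError("zero-depth track")
    k_prom = track.region_count(gene.chrom, *prom)
    k_body = track.region_count(gene.chrom, *body) if body[1] > body[0] else 0
    prom_kb = (prom[1] - prom[0]) / 1000.0
    body_kb = (body[1] - body[0]) / 1000.0
    d_prom = k_prom * 1e6 / depth / prom_kb
    d_body = k_body * 1e6 / depth / body_kb if body_kb > 0 else 0.0
    pi = d_prom / d_body if d_body > 0 else None
    return Pol2GeneMetrics(gene.gene_id, k_prom, k_body, d_prom, d_body, pi)


def pol2_metrics_table(
    track: CoverageTrack, genes: Sequence[GeneModel], flank: int = PROMOTER_FLANK
) -> pd.DataFrame:
    """Per-gene metrics table; excluded genes get status != 'ok' and NaN
    metrics, undefined pausing indices are NaN (never 0 or inf)."""
    rows = []
    for gene in genes:
        m = pol2_gene_metrics(track, gene, flank)
        if m is None:
            reason = (
                "short_gene" if gene.length <= MIN_GENE_LENGTH else "edge_clipped"
            )
            rows.append((gene.gene_id, np.nan, np.nan, np.nan, reason))
        else:
            rows.append(
                (
                    gene.gene_id,
                    m.promoter_density,
                    m.body_density,
                    m.pausing_index if m.pausing_index is not None else np.nan,
                    "ok" if m.pausing_index is not None else "zero_body",
                )
            )
    return pd.DataFrame(
        rows,
        columns=["gene_id", "promoter_density", "body_density", "pausing_index",
                 "status"],
    )


def metagene_profile(
    track: CoverageTrack,
    genes: Sequence[GeneModel],
    group_labels: Mapping[str, str] | Sequence[str],
    body_bins: int = 100,
    upstream_bp: int = 1000,
    downstream_bp: int = 2000,
    flank_bin_bp: int = 50,
) -> pd.DataFrame:
    """Meta-gene profile: fixed 1 kb upstream flank, length-scaled gene
    body, fixed 2 kb downstream flank; per-group mean of per-gene RPM
    per bp.  Minus-strand genes are reversed so bins run TSS -> TES.

    ``group_labels`` maps gene_id -> group (or is a parallel sequence).
    Genes shorter than ``body_bins`` bp or extending past chromosome
    bounds are excluded.  Returns a (bin x group) DataFrame.
    """
    if isinstance(group_labels, Mapping):
        labels = {g.gene_id: group_labels.get(g.gene_id) for g in genes}
    else:
        labels = {g.gene_id: lab for g, lab in zip(genes, group_labels)}
    groups = sorted({v for v in labels.values() if v is not None})
    if not groups:
        raise ValueError("no non-empty gene groups")
    n_up = upstream_bp // flank_bin_bp
    n_down = downstream_bp // flank_bin_bp
    n_bins = n_up + body_bins + n_down
    sums = {g: np.zeros(n_bins) for g in groups}
    counts = {g: 0 for g in groups}
    depth = track.depth
    if depth == 0:
        raise ValueError("zero-depth track")
    for gene in genes:
        grp = labels.get(gene.gene_id)
        if grp is None or gene.length < body_bins:
            continue
        arr = track.counts.get(gene.chrom)
        if arr is None:
            continue
        lo = gene.start - (upstream_bp if gene.strand == "+" else downstream_bp)
        hi = gene.end + (downstream_bp if gene.strand == "+" else upstream_bp)
        if lo < 0 or hi > len(arr):
            continue
        prof = np.empty(n_bins)
        if gene.strand == "+":
            up = arr[gene.start - upstream_bp : gene.start]
            body = arr[gene.start : gene.end]
            down = arr[gene.end : gene.end + downstream_bp]
        else:
            up = arr[gene.end : gene.end + upstream_bp][::-1]
            body = arr[gene.start : gene.end][::-1]
            down = arr[gene.start - downstream_bp : gene.start][::-1]
        prof[:n_up] = up.reshape(n_up, flank_bin_bp).mean(axis=1)
        edges = np.linspace(0, len(body), body_bins + 1).round().astype(int)
        cs = np.concatenate([[0], np.cumsum(body)])
        widths = np.maximum(np.diff(edges), 1)
        prof[n_up : n_up + body_bins] = (cs[edges[1:]] - cs[edges[:-1]]) / widths
        prof[n_up + body_bins :] = down.reshape(n_down, flank_bin_bp).mean(axis=1)
        sums[grp] += prof * 1e6 / depth  # RPM per bp
        counts[grp] += 1
    data = {}
    for g in groups:
        if counts[g] == 0:
            raise ValueError(f"group {g!r} has no usable genes")
        data[g] = sums[g] / counts[g]
    idx = np.arange(n_bins)
    return pd.DataFrame(data, index=pd.Index(idx, name="bin"))


def binding_expression_correlation(
    binding: Sequence[float],
    response: Sequence[float],
    pseudocount: float = 0.5,
    n_permutations: int | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[float, float]:
    """Pearson correlation between per-gene binding and Pol II occupancy
    or expression, on log2(value + pseudocount).

    Returns (r, p) with p from the t-distribution; when
    ``n_permutations`` is given the p-value is instead estimated by
    permutation (useful as a small-n cross-check).
    """
    r, p = pearson_log(binding, response, pseudocount)
    if n_permutations:
        rng = rng or np.random.default_rng(0)
        y = np.asarray(response, dtype=float)
        hits = 0
        for _ in range(n_permutations):
            r_perm, _ = pearson_log(binding, rng.permutation(y), pseudocount)
            if abs(r_perm) >= abs(r) - 1e-12:
                hits += 1
        p = (hits + 1) / (n_permutations + 1)
    return r, p
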