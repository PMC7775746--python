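"""Seeded miniature transformation study with recorded ground truth.

Generates everything the pipeline consumes: a small genome with
non-overlapping genes, histone-mark segmentations, two-factor ChIP
coverage in two conditions (nontransformed "etoh" / transformed "tam")
with planted condition-dependent enrichment, matched inputs, Pol II
tracks with planted promoter pausing, motif-bearing summit sequences,
a ribosome-footprint count table coupled to binding, and a cancer-gene
catalog enriched among bound genes.

Defaults are the study conditions used throughout the tests: 3
chromosomes x 2 Mb, 300 genes, 400 binding sites (class mix close to
the 30/45/6/19 promoter/enhancer/repressed/uncharacterized split seen
in real segmentations), 2 replicates per condition, ~1 M reads per
ChIP sample, a 300 bp site footprint, and a mean twofold binding gain
upon transformation.  Everything is a function of the seed alone.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .genomic_io import (
    BASES,
    CoverageTrack,
    GeneModel,
    GenomicInterval,
    Pwm,
    write_bed,
    write_coverage,
    write_fasta,
    write_gene_table,
    write_jaspar,
    BedFeature,
)

FACTORS = ("S100A8", "S100A9")
CONDITIONS = ("etoh", "tam")
SITE_CLASSES = ("promoter", "enhancer", "repressed", "null")

# Consensus strings for the motif families named in the analysis.
# These are synthetic, consensus-derived matrices (not JASPAR data).
PROMOTER_MOTIF_CONSENSUS = {
    "ETS": "ACAGGAAGTG",
    "KLF_SP1": "GGGGCGGGGC",
    "THAP11": "GGCAACTGCG",
    "CREB": "TGACGTCA",
    "ZBTB33": "TCCTGCGA",
}
ENHANCER_MOTIF_CONSENSUS = {
    "AP1": "TGACTCA",
    "CEBP": "ATTGCGCAAT",
    "STAT3": "TTCCCGGAAT",
    "CTCF": "CCACCAGGTGGCAG",
}
ALL_MOTIF_CONSENSUS = {**PROMOTER_MOTIF_CONSENSUS, **ENHANCER_MOTIF_CONSENSUS}

__all__ = [
    "SimulationConfig",
    "SyntheticStudy",
    "default_pwms",
    "simulate_genome",
    "simulate_chip",
    "simulate_pol2_and_expression",
    "simulate_study",
    "simulate_enhancer_landscape",
    "write_study",
]


def default_pwms(match_prob: float = 0.85) -> list[Pwm]:
    """Synthetic consensus-derived PWMs for the named motif families."""
    return [
        Pwm.from_consensus(name, cons, match_prob)
        for name, cons in ALL_MOTIF_CONSENSUS.items()
    ]


@dataclass
class SimulationConfig:
    """All dials of the miniature study; see module docstring for the
    rationale behind the defaults."""

    seed: int = 0
    n_chroms: int = 3
    chrom_length: int = 2_000_000
    n_genes: int = 300
    gene_length_range: tuple[int, int] = (2_000, 15_000)
    short_gene_fraction: float = 0.03  # genes too short for Pol II metrics
    noncoding_fraction: float = 0.05
    n_sites: dict = field(
        default_factory=lambda: {
            "promoter": 120, "enhancer": 180, "repressed": 25, "null": 75,
        }
    )
    site_width: int = 300
    min_site_gap: int = 2_500
    site_free_chroms: int = 1  # last chromosomes carry no sites (unbound pool)
    replicates: int = 2
    chip_depth: int = 1_000_000
    input_depth: int = 1_000_000
    base_enrichment: float = 20.0  # EtOH fold enrichment at a typical site
    amplitude_log2_sd: float = 0.7  # site-to-site spread, shared by factors
    factor_log2_sd: float = 0.2  # factor-specific spread (sets the A8/A9 r)
    tam_log2fc_mean: float = 1.0  # planted TAM:EtOH binding change
    tam_log2fc_sd: float = 0.6
    motif_prob: float = 0.35  # placement probability per summit per PWM
    motif_offset_sd: float = 10.0  # bp spread of planted motifs around summit
    ap1_boost_log2: float = 0.75  # extra TAM gain at AP-1-bearing sites
    pol2_depth: int = 2_000_000
    pol2_background_fraction: float = 0.02
    pausing_log2_mean: float = 2.0  # median planted pausing index = 4
    pausing_log2_sd: float = 1.0
    footprint_depth: int = 2_000_000
    base_log2_rpkm_mean: float = 3.0
    base_log2_rpkm_sd: float = 1.0
    bound_level_log2: float = 0.7  # expression offset per bound regulatory class
    expression_coupling: float = 0.35  # log2 expression change per planted
    expression_noise_sd: float = 0.35  # unit of summed site log2 binding change
    cancer_fractions: dict = field(
        default_factory=lambda: {"ONG": 0.05, "TSG": 0.08, "OncoTSG": 0.015}
    )
    cancer_bound_odds: float = 2.5  # odds multiplier for bound genes
    n_background_regions: dict = field(
        default_factory=lambda: {
            "promoter": 100, "enhancer": 100, "repressed": 50,
            "uncharacterized": 100,
        }
    )

    def __post_init__(self) -> None:
        if self.replicates < 2:
            raise ValueError("replicates must be >= 2 (the confidence filter "
                             "requires at least two biological replicates)")
        for k, v in self.n_sites.items():
            if k not in SITE_CLASSES or v < 0:
                raise ValueError(f"bad site class spec {k}={v}")
        for p in (self.motif_prob, self.short_gene_fraction,
                  self.noncoding_fraction):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        if min(self.n_chroms, self.n_genes + 1, self.chrom_length) < 1:
            raise ValueError("counts must be >= 1")


@dataclass
class SyntheticStudy:
    """In-memory study bundle plus its ground truth."""

    config: SimulationConfig
    sequences: dict[str, str]
    genes: list[GeneModel]
    states: dict[str, list[GenomicInterval]]
    background_positions: list[tuple[str, int, str]]  # chrom, pos, class
    sites: pd.DataFrame  # ground-truth site table
    pwms: list[Pwm]
    chip: dict[tuple[str, str, int], CoverageTrack] = field(default_factory=dict)
    inputs: dict[tuple[str, int], CoverageTrack] = field(default_factory=dict)
    pol2: dict[str, CoverageTrack] = field(default_factory=dict)
    footprints: pd.DataFrame | None = None
    gene_truth: pd.DataFrame | None = None
    catalog: pd.Series | None = None

    @property
    def chrom_lengths(self) -> dict[str, int]:
        return {c: len(s) for c, s in self.sequences.items()}


def _place_genes(config: SimulationConfig, rng: np.random.Generator) -> list[GeneModel]:
    chroms = [f"chr{i + 1}" for i in range(config.n_chroms)]
    margin = 25_000
    genes: list[GeneModel] = []
    per_chrom = [config.n_genes // config.n_chroms] * config.n_chroms
    for i in range(config.n_genes % config.n_chroms):
        per_chrom[i] += 1
    gi = 0
    lo, hi = config.gene_length_range
    for chrom, n in zip(chroms, per_chrom):
        pos = margin
        for _ in range(n):
            if rng.random() < config.short_gene_fraction:
                length = int(rng.integers(150, 450))
            else:
                length = int(rng.integers(lo, hi))
            gap = int(rng.integers(3_000, 12_000))
            start = pos + gap
            end = start + length
            if end > config.chrom_length - margin:
                deficit = end - (config.chrom_length - margin)
                raise ValueError(
                    f"genome too small to place {config.n_genes} genes: "
                    f"short by {deficit} bp on {chrom}"
                )
            strand = "+" if rng.random() < 0.5 else "-"
            if length > 1_200 and rng.random() > config.noncoding_fraction:
                cds_start = start + int(rng.integers(100, 300))
                cds_end = end - int(rng.integers(100, 300))
            else:
                cds_start = cds_end = start
            gi += 1
            genes.append(
                GeneModel(f"G{gi:04d}", chrom, strand, start, end, cds_start, cds_end)
            )
            pos = end
    return genes


def _sample_intergenic(
    rng: np.random.Generator,
    chrom_lengths: dict[str, int],
    genes: list[GeneModel],
    occupied: dict[str, list[int]],
    n: int,
    min_gap: int,
    gene_margin: int = 2_000,
    edge_margin: int = 25_000,
    max_tries: int = 400,
) -> list[tuple[str, int]]:
    """Sample intergenic positions keeping min_gap to previous picks."""
    gene_spans: dict[str, list[tuple[int, int]]] = {}
    for g in genes:
        gene_spans.setdefault(g.chrom, []).append(
            (g.start - gene_margin, g.end + gene_margin)
        )
    for spans in gene_spans.values():
        spans.sort()
    chroms = sorted(chrom_lengths)
    out: list[tuple[str, int]] = []
    for _ in range(n):
        placed = False
        for _try in range(max_tries):
            chrom = chroms[int(rng.integers(len(chroms)))]
            pos = int(rng.integers(edge_margin, chrom_lengths[chrom] - edge_margin))
            spans = gene_spans.get(chrom, [])
            inside_gene = any(s <= pos < e for s, e in spans)
            if inside_gene:
                continue
            occ = occupied.setdefault(chrom, [])
            if any(abs(pos - o) < min_gap for o in occ):
                continue
            occ.append(pos)
            out.append((chrom, pos))
            placed = True
            break
        if not placed:
            raise ValueError(
                f"genome too small to place {n} intergenic features "
                f"with gap {min_gap}: placed only {len(out)}"
            )
    return out


def _plant_motifs(
    seq: np.ndarray,
    summit: int,
    consensi: dict[str, str],
    config: SimulationConfig,
    rng: np.random.Generator,
) -> list[str]:
    """Write motif consensus strings near a summit; returns planted ids."""
    planted: list[str] = []
    used: list[tuple[int, int]] = []
    comp = {0: 3, 1: 2, 2: 1, 3: 0}
    for name, cons in consensi.items():
        if rng.random() >= config.motif_prob:
            continue
        enc = [BASES.index(b) for b in cons]
        if rng.random() < 0.5:  # minus strand
            enc = [comp[b] for b in enc[::-1]]
        ok = False
        for _ in range(8):
            off = int(round(rng.normal(0.0, config.motif_offset_sd)))
            off = int(np.clip(off, -40, 40))
            start = summit + off - len(enc) // 2
            end = start + len(enc)
            if start < 0 or end > len(seq):
                continue
            if any(s < end and start < e for s, e in used):
                continue
            seq[start:end] = enc
            used.append((start, end))
            planted.append(name)
            ok = True
            break
        if not ok:
            continue
    return planted


def simulate_genome(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> SyntheticStudy:
    """Genome, genes, chromatin-state maps, binding sites and planted
    motifs.  Deterministic given the config seed."""
    rng = rng or np.random.default_rng(config.seed)
    chrom_lengths = {
        f"chr{i + 1}": config.chrom_length for i in range(config.n_chroms)
    }
    seqs = {
        chrom: rng.integers(0, 4, size=n, dtype=np.int8)
        for chrom, n in chrom_lengths.items()
    }
    genes = _place_genes(config, rng)

    states: dict[str, list[GenomicInterval]] = {
        m: [] for m in ("H3K4me3", "H3K4me1", "H3K27ac", "H3K9me3", "H3K27me3",
                        "DNase")
    }
    occupied: dict[str, list[int]] = {}
    site_rows = []

    # sites are confined to the first chromosomes; the remaining ones
    # supply the unbound gene pool
    n_site_chroms = max(1, config.n_chroms - config.site_free_chroms)
    site_chroms = {f"chr{i + 1}" for i in range(n_site_chroms)}
    site_chrom_lengths = {c: n for c, n in chrom_lengths.items() if c in site_chroms}

    # promoter sites sit at TSSs of a random subset of eligible genes
    eligible = [g for g in genes if g.length >= 2_000 and g.chrom in site_chroms]
    n_prom = config.n_sites.get("promoter", 0)
    if n_prom > len(eligible):
        raise ValueError(
            f"genome too small: {n_prom} promoter sites requested but only "
            f"{len(eligible)} eligible genes"
        )
    prom_gene_idx = rng.choice(len(eligible), size=n_prom, replace=False)
    prom_genes = {eligible[i].gene_id for i in prom_gene_idx}
    for i in prom_gene_idx:
        g = eligible[i]
        offset = int(rng.integers(-300, 100))  # gene-oriented summit offset
        summit = g.tss + offset if g.strand == "+" else g.tss - offset
        occupied.setdefault(g.chrom, []).append(summit)
        planted = _plant_motifs(
            seqs[g.chrom], summit, PROMOTER_MOTIF_CONSENSUS, config, rng
        )
        site_rows.append((g.chrom, summit, "promoter", g.gene_id, planted))
        states["H3K4me3"].append(GenomicInterval(g.chrom, g.tss - 500, g.tss + 501))
        states["H3K27ac"].append(GenomicInterval(g.chrom, g.tss - 500, g.tss + 501))

    # promoter marks at unbound genes too (background promoters)
    for g in genes:
        if g.gene_id not in prom_genes and rng.random() < 0.5:
            states["H3K4me3"].append(
                GenomicInterval(g.chrom, max(0, g.tss - 500), g.tss + 501)
            )

    half_mark = 600
    for chrom, pos in _sample_intergenic(
        rng, site_chrom_lengths, genes, occupied,
        config.n_sites.get("enhancer", 0), config.min_site_gap,
    ):
        planted = _plant_motifs(
            seqs[chrom], pos, ENHANCER_MOTIF_CONSENSUS, config, rng
        )
        # ground-truth functional target: nearest TSS
        near = min(
            (g for g in genes if g.chrom == chrom),
            key=lambda g: abs(g.tss - pos),
            default=None,
        )
        target = near.gene_id if near and abs(near.tss - pos) <= 50_000 else ""
        site_rows.append((chrom, pos, "enhancer", target, planted))
        states["H3K4me1"].append(GenomicInterval(chrom, pos - half_mark, pos + half_mark))
        states["H3K27ac"].append(GenomicInterval(chrom, pos - half_mark, pos + half_mark))

    for chrom, pos in _sample_intergenic(
        rng, site_chrom_lengths, genes, occupied,
        config.n_sites.get("repressed", 0), config.min_site_gap,
    ):
        mark = "H3K9me3" if rng.random() < 0.5 else "H3K27me3"
        site_rows.append((chrom, pos, "repressed", "", []))
        states[mark].append(GenomicInterval(chrom, pos - 1_000, pos + 1_000))

    for chrom, pos in _sample_intergenic(
        rng, site_chrom_lengths, genes, occupied,
        config.n_sites.get("null", 0), config.min_site_gap,
    ):
        site_rows.append((chrom, pos, "null", "", []))

    # background regions (the DNase universe for enrichment tests)
    background: list[tuple[str, int, str]] = []
    bg = config.n_background_regions
    bg_prom_genes = [g for g in genes if g.gene_id not in prom_genes]
    n_bg_prom = min(bg.get("promoter", 0), len(bg_prom_genes))
    for i in rng.choice(len(bg_prom_genes), size=n_bg_prom, replace=False):
        g = bg_prom_genes[i]
        background.append((g.chrom, g.tss, "promoter"))
        states["H3K4me3"].append(
            GenomicInterval(g.chrom, max(0, g.tss - 500), g.tss + 501)
        )
    for chrom, pos in _sample_intergenic(
        rng, chrom_lengths, genes, occupied, bg.get("enhancer", 0),
        config.min_site_gap,
    ):
        background.append((chrom, pos, "enhancer"))
        states["H3K4me1"].append(GenomicInterval(chrom, pos - half_mark, pos + half_mark))
        states["H3K27ac"].append(GenomicInterval(chrom, pos - half_mark, pos + half_mark))
    for chrom, pos in _sample_intergenic(
        rng, chrom_lengths, genes, occupied, bg.get("repressed", 0),
        config.min_site_gap,
    ):
        background.append((chrom, pos, "repressed"))
        mark = "H3K9me3" if rng.random() < 0.5 else "H3K27me3"
        states[mark].append(GenomicInterval(chrom, pos - 1_000, pos + 1_000))
    for chrom, pos in _sample_intergenic(
        rng, chrom_lengths, genes, occupied, bg.get("uncharacterized", 0),
        config.min_site_gap,
    ):
        background.append((chrom, pos, "uncharacterized"))
    states["DNase"] = [
        GenomicInterval(chrom, max(0, pos - 150), pos + 150)
        for chrom, pos, _ in background
    ] + [
        GenomicInterval(chrom, max(0, summit - 150), summit + 150)
        for chrom, summit, *_ in site_rows
    ]

    # planted binding amplitudes and condition fold changes
    n_sites = len(site_rows)
    amp = rng.normal(0.0, config.amplitude_log2_sd, size=n_sites)
    factor_off = {
        f: rng.normal(0.0, config.factor_log2_sd, size=n_sites) for f in FACTORS
    }
    log2fc = rng.normal(config.tam_log2fc_mean, config.tam_log2fc_sd, size=n_sites)
    half = config.site_width // 2
    rows = []
    for i, (chrom, summit, cls, target, planted) in enumerate(site_rows):
        boost = config.ap1_boost_log2 if "AP1" in planted else 0.0
        rows.append(
            {
                "site_id": f"S{i + 1:04d}",
                "chrom": chrom,
                "start": summit - half,
                "end": summit + half,
                "summit": summit,
                "site_class": cls,
                "target_gene": target,
                "motifs": ",".join(planted),
                "amp_log2": amp[i],
                "log2fc": log2fc[i] + boost,
                "etoh_enrich_S100A8": config.base_enrichment
                * 2.0 ** (amp[i] + factor_off["S100A8"][i]),
                "etoh_enrich_S100A9": config.base_enrichment
                * 2.0 ** (amp[i] + factor_off["S100A9"][i]),
            }
        )
    sites = pd.DataFrame(rows)
    return SyntheticStudy(
        config=config,
        sequences={c: _indices_to_str(a) for c, a in seqs.items()},
        genes=genes,
        states=states,
        background_positions=background,
        sites=sites,
        pwms=default_pwms(),
    )


def _indices_to_str(arr: np.ndarray) -> str:
    lookup = np.frombuffer("ACGT".encode(), dtype=np.uint8)
    return lookup[arr].tobytes().decode()


def _triangular_profile(width: int) -> np.ndarray:
    half = width // 2
    x = np.arange(width)
    return 1.0 - np.abs(x - half) / (half + 1.0)


def simulate_chip(
    study: SyntheticStudy, rng: np.random.Generator
) -> None:
    """ChIP coverage for both factors x conditions x replicates plus
    matched inputs, written into the study in place.

    Read starts are Poisson; inside a site the rate is the flat
    background times a triangular enrichment profile peaking at the
    planted fold over the summit.
    """
    cfg = study.config
    lengths = study.chrom_lengths
    genome = sum(lengths.values())
    lam_bg = cfg.chip_depth / genome
    profile = _triangular_profile(cfg.site_width)
    for factor in FACTORS:
        for cond in CONDITIONS:
            base_rate = {c: np.full(n, lam_bg) for c, n in lengths.items()}
            for row in study.sites.itertuples(index=False):
                enrich = getattr(row, f"etoh_enrich_{factor}")
                if cond == "tam":
                    enrich *= 2.0 ** row.log2fc
                s = max(0, row.start)
                e = min(lengths[row.chrom], row.end)
                seg = profile[s - row.start : e - row.start]
                base_rate[row.chrom][s:e] += lam_bg * (enrich - 1.0) * seg
            for rep in range(1, cfg.replicates + 1):
                counts = {
                    c: rng.poisson(r).astype(np.int64)
                    for c, r in base_rate.items()
                }
                study.chip[(factor, cond, rep)] = CoverageTrack(counts)
    lam_in = cfg.input_depth / genome
    for cond in CONDITIONS:
        for rep in range(1, cfg.replicates + 1):
            counts = {
                c: rng.poisson(lam_in, size=n).astype(np.int64)
                for c, n in lengths.items()
            }
            study.inputs[(cond, rep)] = CoverageTrack(counts)


def simulate_pol2_and_expression(
    study: SyntheticStudy, rng: np.random.Generator
) -> None:
    """Pol II tracks per condition and the footprint count table.

    Per gene the promoter-proximal rate (TSS +/- 250 bp) is the body
    rate times the planted pausing index; footprint counts over the
    trimmed ORF follow the planted expression level, whose TAM:EtOH
    log2 change is the coupling coefficient times the summed planted
    binding change of the sites targeting the gene, plus noise.
    """
    from .expression import trimmed_orf_region
    from .pol2 import PROMOTER_FLANK

    cfg = study.config
    genes = study.genes
    n = len(genes)
    site_fc: dict[str, float] = {}
    bound_classes: dict[str, set[str]] = {}
    for row in study.sites.itertuples(index=False):
        if row.target_gene:
            site_fc[row.target_gene] = site_fc.get(row.target_gene, 0.0) + max(
                row.log2fc, 0.0
            )
            bound_classes.setdefault(row.target_gene, set()).add(row.site_class)

    # regulatory target domain: gene with any site summit within 50 kb of
    # its TSS or inside its body (the definition target mapping recovers)
    summits_by_chrom: dict[str, np.ndarray] = {
        chrom: np.sort(grp["summit"].to_numpy())
        for chrom, grp in study.sites.groupby("chrom")
    }

    def _in_domain(g: GeneModel) -> bool:
        summits = summits_by_chrom.get(g.chrom)
        if summits is None or summits.size == 0:
            return False
        i = np.searchsorted(summits, g.tss)
        near_tss = min(
            abs(int(summits[j]) - g.tss)
            for j in (max(i - 1, 0), min(i, summits.size - 1))
        ) <= 50_000
        j0, j1 = np.searchsorted(summits, [g.start, g.end])
        return near_tss or j1 > j0

    base = rng.normal(cfg.base_log2_rpkm_mean, cfg.base_log2_rpkm_sd, size=n)
    pausing = 2.0 ** rng.normal(cfg.pausing_log2_mean, cfg.pausing_log2_sd, size=n)
    noise = rng.normal(0.0, cfg.expression_noise_sd, size=n)
    rows = []
    rpkm = {c: np.zeros(n) for c in CONDITIONS}
    for i, g in enumerate(genes):
        classes = bound_classes.get(g.gene_id, set())
        n_classes = len(classes & {"promoter", "enhancer"})
        level = base[i] + cfg.bound_level_log2 * n_classes
        fc = cfg.expression_coupling * site_fc.get(g.gene_id, 0.0) + noise[i]
        rpkm["etoh"][i] = 2.0 ** level
        rpkm["tam"][i] = 2.0 ** (level + fc)
        rows.append(
            {
                "gene_id": g.gene_id,
                "bound": n_classes > 0,
                "in_target_domain": _in_domain(g),
                "bound_classes": "+".join(sorted(classes)),
                "binding_log2fc_sum": site_fc.get(g.gene_id, 0.0),
                "pausing_index": pausing[i],
                "expr_log2fc": fc,
            }
        )
    study.gene_truth = pd.DataFrame(rows)

    # Pol II tracks: rate proportional to expression, pausing in the
    # promoter window, then rescaled to the requested depth.
    lengths = study.chrom_lengths
    for cond in CONDITIONS:
        rate = {c: np.zeros(lgt) for c, lgt in lengths.items()}
        for i, g in enumerate(genes):
            body_rate = rpkm[cond][i]
            arr = rate[g.chrom]
            arr[g.start : g.end] += body_rate
            lo = max(0, g.tss - PROMOTER_FLANK)
            hi = min(len(arr), g.tss + PROMOTER_FLANK + 1)
            arr[lo:hi] = body_rate * pausing[i]
        total = sum(a.sum() for a in rate.values())
        signal_budget = cfg.pol2_depth * (1.0 - cfg.pol2_background_fraction)
        bg = cfg.pol2_depth * cfg.pol2_background_fraction / sum(lengths.values())
        scale = signal_budget / total
        counts = {
            c: rng.poisson(a * scale + bg).astype(np.int64)
            for c, a in rate.items()
        }
        study.pol2[cond] = CoverageTrack(counts)

    # footprint counts over trimmed ORFs
    fp_rows = []
    for i, g in enumerate(genes):
        region = sum(e - s for s, e in trimmed_orf_region(g))
        k = {}
        for cond in CONDITIONS:
            mean = rpkm[cond][i] * cfg.footprint_depth * region / 1e9
            k[cond] = int(rng.poisson(mean)) if region else 0
        fp_rows.append(
            {"gene_id": g.gene_id, "reads_etoh": k["etoh"], "reads_tam": k["tam"]}
        )
    study.footprints = pd.DataFrame(fp_rows)

    # cancer-gene catalog, enriched among genes in the binding domain
    labels = []
    fr = cfg.cancer_fractions
    for row in study.gene_truth.itertuples(index=False):
        odds = cfg.cancer_bound_odds if row.in_target_domain else 1.0
        probs = {}
        for lab in ("OncoTSG", "ONG", "TSG"):
            p = fr[lab]
            probs[lab] = p * odds / (1.0 - p + p * odds)
        u = rng.random()
        cum = 0.0
        label = "NonCancer"
        for lab in ("OncoTSG", "ONG", "TSG"):
            cum += probs[lab]
            if u < cum:
                label = lab
                break
        labels.append(label)
    study.gene_truth["catalog_label"] = labels
    study.catalog = pd.Series(
        {g.gene_id: lab for g, lab in zip(genes, labels)}, name="label"
    ).sort_index()


def simulate_study(config: SimulationConfig) -> SyntheticStudy:
    """Full miniature study: genome + ChIP + Pol II + expression."""
    rng = np.random.default_rng(config.seed)
    study = simulate_genome(config, rng)
    simulate_chip(study, rng)
    simulate_pol2_and_expression(study, rng)
    return study


def simulate_enhancer_landscape(
    seed: int,
    n_background: int = 200,
    n_super: int = 10,
    constituents_per_super: tuple[int, int] = (3, 5),
    background_signal_mean: float = 2.0,
    super_constituent_signal: float = 25.0,
    chrom: str = "chrE",
) -> tuple[list[GenomicInterval], np.ndarray, pd.DataFrame]:
    """Signal-level enhancer landscape for super-enhancer calling.

    Background enhancer peaks carry exponential signal; planted
    super-enhancers are clusters of 3-5 strong constituents within
    stitching range of each other and far from everything else.
    Returns (intervals, input-corrected signals, truth) where truth
    marks for each interval whether it belongs to a planted super.
    """
    rng = np.random.default_rng(seed)
    intervals: list[GenomicInterval] = []
    signals: list[float] = []
    truth_rows = []
    pos = 50_000
    width = 1_000
    for i in range(n_background):
        pos += int(rng.integers(30_000, 60_000))
        intervals.append(GenomicInterval(chrom, pos, pos + width))
        signals.append(float(rng.exponential(background_signal_mean)))
        truth_rows.append({"index": len(intervals) - 1, "super_id": -1})
        pos += width
    for s in range(n_super):
        pos += int(rng.integers(60_000, 100_000))
        k = int(rng.integers(constituents_per_super[0], constituents_per_super[1] + 1))
        for _ in range(k):
            intervals.append(GenomicInterval(chrom, pos, pos + width))
            signals.append(
                float(super_constituent_signal * rng.lognormal(0.0, 0.25))
            )
            truth_rows.append({"index": len(intervals) - 1, "super_id": s})
            pos += width + int(rng.integers(2_000, 10_000))
    return intervals, np.array(signals), pd.DataFrame(truth_rows)


def write_study(study: SyntheticStudy, outdir: str | Path) -> dict[str, str]:
    """Write every artifact of the study in the package's text formats;
    returns {artifact name: path}.  Byte-deterministic given the seed."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, str] = {}

    def _p(name: str, rel: str) -> Path:
        paths[name] = str(out / rel)
        return out / rel

    write_fasta(study.sequences, _p("genome_fasta", "genome.fa"))
    write_gene_table(study.genes, _p("gene_table", "genes.tsv"))
    (out / "states").mkdir(exist_ok=True)
    for mark, ivs in study.states.items():
        write_bed(
            [BedFeature(iv) for iv in ivs],
            _p(f"state_{mark}", f"states/{mark}.bed"),
        )
    (out / "tracks").mkdir(exist_ok=True)
    for (factor, cond, rep), track in study.chip.items():
        write_coverage(
            track, _p(f"chip_{factor}_{cond}_r{rep}",
                      f"tracks/{factor}_{cond}_rep{rep}.bedgraph")
        )
    for (cond, rep), track in study.inputs.items():
        write_coverage(
            track, _p(f"input_{cond}_r{rep}", f"tracks/input_{cond}_rep{rep}.bedgraph")
        )
    for cond, track in study.pol2.items():
        write_coverage(track, _p(f"pol2_{cond}", f"tracks/pol2_{cond}.bedgraph"))
    if study.footprints is not None:
        study.footprints.to_csv(
            _p("footprints", "footprints.tsv"), sep="\t", index=False
        )
    study.sites.to_csv(_p("truth_sites", "truth_sites.tsv"), sep="\t", index=False)
    if study.gene_truth is not None:
        study.gene_truth.to_csv(
            _p("truth_genes", "truth_genes.tsv"), sep="\t", index=False
        )
    if study.catalog is not None:
        study.catalog.rename_axis("gene_id").to_csv(
            _p("catalog", "catalog.tsv"), sep="\t"
        )
    write_jaspar(study.pwms, _p("pwms", "motifs.jaspar"))
    return paths
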