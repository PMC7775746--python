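"""End-to-end orchestration of the synthetic study analysis.

``run`` executes the stages in dependency order on a freshly simulated
study and writes every stage's tables plus a machine-readable manifest
(config hash, seed, per-stage row counts) to the output directory.
Reruns with the same config produce byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import annotation, expression, motifs, peaks, pol2, superenhancer
from .synthetic import (
    CONDITIONS,
    FACTORS,
    SimulationConfig,
    SyntheticStudy,
    simulate_enhancer_landscape,
    simulate_study,
    write_study,
)

log = logging.getLogger("chromact")

STAGES = (
    "simulate", "callpeaks", "classify", "targets", "pol2",
    "superenhancer", "motifs", "integrate",
)


@dataclass
class RunConfig:
    """Thresholds and paths for a full pipeline run.

    The defaults are the analysis constants used throughout: q <= 1e-7,
    >= 5 reads, >= 2 replicates for confident peaks; 12.5 kb stitching;
    50 kb enhancer window; promoter window (-1500, +250); +/-250 bp
    promoter-proximal; motif windows 100/200/50 bp; twofold DE.
    """

    seed: int = 0
    outdir: str = "chromact_run"
    q_max: float = 1e-7
    min_reads: int = 5
    min_replicates: int = 2
    candidate_q: float = 0.05
    window_bp: int = 300
    step_bp: int = 50
    stitch_distance: int = 12_500
    enhancer_window: int = 50_000
    promoter_upstream: int = 1_500
    promoter_downstream: int = 250
    pol2_flank: int = 250
    motif_scan_half_window: int = 100
    motif_density_half_window: int = 200
    motif_stratify_window: int = 50
    de_fold: float = 2.0
    simulation: SimulationConfig = field(default_factory=SimulationConfig)

    def __post_init__(self) -> None:
        positive = (
            self.min_reads, self.min_replicates, self.window_bp, self.step_bp,
            self.stitch_distance, self.enhancer_window, self.promoter_upstream,
            self.promoter_downstream, self.pol2_flank, self.de_fold,
        )
        if any(v <= 0 for v in positive):
            raise ValueError("all thresholds must be positive")
        if self.min_replicates < 2:
            raise ValueError("min_replicates must be >= 2")
        if not (0 < self.q_max <= 1):
            raise ValueError("q_max must lie in (0, 1]")
        self.simulation.seed = self.seed

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        data.update(overrides)
        sim = data.pop("simulation", {})
        cfg = cls(**data)
        for k, v in sim.items():
            setattr(cfg.simulation, k, v)
        cfg.simulation.seed = cfg.seed
        return cfg

    def to_dict(self) -> dict:
        return asdict(self)

    def digest(self) -> str:
        """Hash of the analysis parameters (output location excluded)."""
        params = self.to_dict()
        params.pop("outdir", None)
        return hashlib.sha256(
            json.dumps(params, sort_keys=True).encode()
        ).hexdigest()[:16]


@dataclass
class RunResult:
    config: RunConfig
    study: SyntheticStudy
    artifacts: dict[str, object] = field(default_factory=dict)
    manifest: dict = field(default_factory=dict)


def _call_factor_condition(study, cfg: RunConfig, factor: str, cond: str):
    """Candidate calls per replicate, pooled call, confident filter."""
    reps = range(1, study.config.replicates + 1)
    inputs = [study.inputs[(cond, r)] for r in reps]
    pooled_input = _pool([study.inputs[(cond, r)] for r in reps])
    rep_candidates = [
        peaks.call_candidate_peaks(
            study.chip[(factor, cond, r)], study.inputs[(cond, r)],
            cfg.window_bp, cfg.step_bp, cfg.candidate_q,
        )
        for r in reps
    ]
    pooled_chip = _pool([study.chip[(factor, cond, r)] for r in reps])
    pooled_candidates = peaks.call_candidate_peaks(
        pooled_chip, pooled_input, cfg.window_bp, cfg.step_bp, cfg.candidate_q
    )
    confident = peaks.confident_peaks(
        pooled_candidates, rep_candidates, cfg.q_max, cfg.min_replicates,
        cfg.min_reads,
    )
    return confident, rep_candidates


def _pool(tracks) -> "peaks.CoverageTrack":
    from .genomic_io import CoverageTrack

    counts = {}
    for t in tracks:
        for c, arr in t.counts.items():
            counts[c] = counts.get(c, 0) + arr
    return CoverageTrack(counts)


def run(
    config: RunConfig,
    stages: str | list[str] = "all",
    write_outputs: bool = True,
) -> RunResult:
    """Run the pipeline stages in dependency order.

    ``stages`` is "all" or a prefix-closed list; requesting a stage
    whose prerequisites are not included raises with the name of the
    stage to run first.
    """
    wanted = list(STAGES) if stages == "all" else list(stages)
    for s in wanted:
        if s not in STAGES:
            raise ValueError(f"unknown stage {s!r}")
        upstream = STAGES[: STAGES.index(s)]
        missing = [u for u in upstream if u not in wanted]
        if missing:
            raise ValueError(
                f"stage {s!r} needs upstream artifacts; run {missing[0]!r} first"
            )
    outdir = Path(config.outdir)
    if write_outputs:
        outdir.mkdir(parents=True, exist_ok=True)
    result = RunResult(config, study=None)  # type: ignore[arg-type]
    manifest: dict = {
        "config_digest": config.digest(),
        "seed": config.seed,
        "stages": {},
    }
    t_all = time.time()

    def _stage_done(name: str, **counts) -> None:
        manifest["stages"][name] = counts
        log.info("stage %-13s done in %5.1fs %s", name, time.time() - t0, counts)

    # --- simulate -----------------------------------------------------
    t0 = time.time()
    study = simulate_study(config.simulation)
    result.study = study
    if write_outputs and "simulate" in wanted:
        write_study(study, outdir / "simulated")
    _stage_done("simulate", genes=len(study.genes), sites=len(study.sites))
    if wanted == ["simulate"]:
        _finish(manifest, result, outdir, write_outputs, t_all)
        return result

    # --- callpeaks ----------------------------------------------------
    t0 = time.time()
    confident: dict[tuple[str, str], list] = {}
    for factor in FACTORS:
        for cond in CONDITIONS:
            confident[(factor, cond)], _ = _call_factor_condition(
                study, config, factor, cond
            )
    universe = peaks.merge_peak_sets(*confident.values())
    chip_by_factor = {
        f: [study.chip[(f, c, r)] for c in CONDITIONS
            for r in range(1, study.config.replicates + 1)]
        for f in FACTORS
    }
    rpm = {f: peaks.pooled_rpm(chip_by_factor[f], universe) for f in FACTORS}
    combined = peaks.combined_signal(rpm["S100A8"], rpm["S100A9"])
    r_factors, _ = peaks.signal_correlation(rpm["S100A8"], rpm["S100A9"])
    tam_tracks = [
        study.chip[(f, "tam", r)]
        for f in FACTORS for r in range(1, study.config.replicates + 1)
    ]
    etoh_tracks = [
        study.chip[(f, "etoh", r)]
        for f in FACTORS for r in range(1, study.config.replicates + 1)
    ]
    diff = peaks.differential_binding(universe, tam_tracks, etoh_tracks)
    result.artifacts.update(
        confident_peaks=confident, universe=universe, rpm=rpm,
        combined_signal=combined, factor_correlation=r_factors,
        differential=diff,
    )
    if write_outputs:
        diff.to_csv(outdir / "differential_binding.tsv", sep="\t", index=False)
        _write_universe(universe, outdir / "confident_peaks.narrowPeak")
    _stage_done(
        "callpeaks", universe=len(universe),
        confident={f"{f}_{c}": len(v) for (f, c), v in confident.items()},
        factor_r=round(r_factors, 4),
    )
    if "classify" not in wanted:
        _finish(manifest, result, outdir, write_outputs, t_all)
        return result

    # --- classify -----------------------------------------------------
    t0 = time.time()
    states = annotation.ChromatinStateMap(study.states)
    classes = annotation.classify_peaks(universe, states)
    background_classes = [cls for _, _, cls in study.background_positions]
    enrich = annotation.class_enrichment(classes, background_classes)
    result.artifacts.update(peak_classes=classes, class_enrichment=enrich)
    if write_outputs:
        enrich.to_csv(outdir / "class_enrichment.tsv", sep="\t", index=False)
    _stage_done("classify", **pd.Series(classes).value_counts().to_dict())
    if "targets" not in wanted:
        _finish(manifest, result, outdir, write_outputs, t_all)
        return result

    # --- targets ------------------------------------------------------
    t0 = time.time()
    prom_idx = [i for i, c in enumerate(classes) if c == "promoter"]
    enh_idx = [i for i, c in enumerate(classes) if c == "enhancer"]
    prom_peaks = [universe[i] for i in prom_idx]
    enh_peaks = [universe[i] for i in enh_idx]
    prom_assign = annotation.assign_promoter_targets(
        prom_peaks, study.genes, config.promoter_upstream,
        config.promoter_downstream,
    )
    enh_assign = annotation.assign_enhancer_targets(
        enh_peaks, study.genes, config.enhancer_window
    )
    # map local indices back into the universe
    prom_assign = prom_assign.assign(
        peak_index=[prom_idx[i] for i in prom_assign["peak_index"]]
    )
    enh_assign = enh_assign.assign(
        peak_index=[enh_idx[i] for i in enh_assign["peak_index"]]
    )
    targets = annotation.gene_target_classes(prom_assign, enh_assign)
    result.artifacts.update(
        promoter_assignments=prom_assign, enhancer_assignments=enh_assign,
        gene_targets=targets,
    )
    if write_outputs:
        pd.DataFrame(
            [(a.gene_id, a.target_class) for a in targets.values()],
            columns=["gene_id", "target_class"],
        ).to_csv(outdir / "gene_targets.tsv", sep="\t", index=False)
    _stage_done(
        "targets",
        **pd.Series([a.target_class for a in targets.values()])
        .value_counts().to_dict(),
    )
    if "pol2" not in wanted:
        _finish(manifest, result, outdir, write_outputs, t_all)
        return result

    # --- pol2 ---------------------------------------------------------
    t0 = time.time()
    pol2_tables = {
        cond: pol2.pol2_metrics_table(study.pol2[cond], study.genes,
                                      config.pol2_flank)
        for cond in CONDITIONS
    }
    group_of = {
        a.gene_id: a.target_class for a in result.artifacts["gene_targets"].values()
    }
    labels = {
        g.gene_id: group_of.get(g.gene_id, "unbound") for g in study.genes
    }
    profiles = {
        cond: pol2.metagene_profile(study.pol2[cond], study.genes, labels)
        for cond in CONDITIONS
    }
    result.artifacts.update(pol2_metrics=pol2_tables, metagene=profiles)
    if write_outputs:
        for cond in CONDITIONS:
            pol2_tables[cond].to_csv(
                outdir / f"pol2_metrics_{cond}.tsv", sep="\t", index=False
            )
            profiles[cond].to_csv(outdir / f"metagene_{cond}.tsv", sep="\t")
    _stage_done(
        "pol2",
        genes_ok=int((pol2_tables["etoh"]["status"] == "ok").sum()),
    )
    if "superenhancer" not in wanted:
        _finish(manifest, result, outdir, write_outputs, t_all)
        return result

    # --- superenhancer ------------------------------------------------
    t0 = time.time()
    se_intervals, se_signals, se_truth = simulate_enhancer_landscape(
        seed=config.seed + 104_729
    )
    stitched = superenhancer.stitch(
        se_intervals, se_signals, config.stitch_distance
    )
    stitched, cutoff = superenhancer.call_super(stitched)
    stitched = superenhancer.assign_se_genes(
        stitched, study.genes, config.enhancer_window
    )
    result.artifacts.update(
        stitched_enhancers=stitched, se_cutoff=cutoff, se_truth=se_truth
    )
    if write_outputs:
        pd.DataFrame(
            [
                (
                    s.interval.chrom, s.interval.start, s.interval.end,
                    len(s.constituent_ids), s.signal, s.rank, s.is_super,
                    ",".join(s.genes),
                )
                for s in stitched
            ],
            columns=["chrom", "start", "end", "n_constituents", "signal",
                     "rank", "is_super", "genes"],
        ).to_csv(outdir / "superenhancers.tsv", sep="\t", index=False)
    _stage_done(
        "superenhancer", stitched=len(stitched),
        supers=sum(s.is_super for s in stitched),
    )
    if "motifs" not in wanted:
        _finish(manifest, result, outdir, write_outputs, t_all)
        return result

    # --- motifs -------------------------------------------------------
    t0 = time.time()
    summits = [(p.interval.chrom, p.summit) for p in universe]
    hits = motifs.hits_near_summits(
        study.sequences, summits, study.pwms, config.motif_scan_half_window
    )
    density = {
        pwm.motif_id: motifs.motif_density_profile(
            study.sequences, summits, pwm, config.motif_density_half_window
        )
        for pwm in study.pwms
    }
    enh_fc = diff.loc[enh_idx, "log2fc"].to_numpy()
    enh_hits = {j: hits[i] for j, i in enumerate(enh_idx) if i in hits}
    strat = motifs.stratify_fold_changes(
        enh_fc, enh_hits,
        combos=[["AP1"], ["CEBP"], ["STAT3"], ["AP1", "CEBP"]],
        window=config.motif_stratify_window,
    )
    result.artifacts.update(
        motif_hits=hits, motif_density=density, motif_stratification=strat
    )
    if write_outputs:
        pd.DataFrame(density).to_csv(outdir / "motif_density.tsv", sep="\t")
        strat.to_csv(outdir / "motif_stratification.tsv", sep="\t", index=False)
    _stage_done("motifs", peaks_with_hits=len(hits))
    if "integrate" not in wanted:
        _finish(manifest, result, outdir, write_outputs, t_all)
        return result

    # --- integrate ----------------------------------------------------
    t0 = time.time()
    depths = {
        "etoh": int(study.footprints["reads_etoh"].sum()),
        "tam": int(study.footprints["reads_tam"].sum()),
    }
    records = expression.expression_table(
        study.footprints, study.genes, depths
    )
    records = expression.call_de(records, config.de_fold)
    bound = {a.gene_id for a in result.artifacts["gene_targets"].values()}
    rank_results = expression.bound_vs_unbound(records, bound)
    universe_genes = {g.gene_id for g in study.genes}
    enrich_cancer = expression.cancer_enrichment(
        study.catalog, bound & universe_genes, universe_genes
    )
    result.artifacts.update(
        expression=records, bound_vs_unbound=rank_results,
        cancer_enrichment=enrich_cancer,
    )
    if write_outputs:
        records.to_csv(outdir / "expression.tsv", sep="\t", index=False)
        enrich_cancer.to_csv(outdir / "cancer_enrichment.tsv", sep="\t",
                             index=False)
    _stage_done(
        "integrate",
        **records["de_status"].value_counts().to_dict(),
    )
    _finish(manifest, result, outdir, write_outputs, t_all)
    return result


def _write_universe(universe, path: Path) -> None:
    from .genomic_io import BedFeature, write_bed

    feats = []
    for i, p in enumerate(universe):
        q = max(p.q_value, 1e-300)
        feats.append(
            BedFeature(
                p.interval, name=f"peak{i + 1}",
                score=min(1000.0, round(-10 * np.log10(q), 1)),
                signal=p.signal, p_value=-np.log10(max(p.p_value, 1e-300)),
                q_value=-np.log10(q), summit=p.summit,
            )
        )
    write_bed(feats, path, dialect="narrowPeak")


def _finish(manifest, result, outdir: Path, write_outputs: bool, t_all) -> None:
    manifest["elapsed_s"] = round(time.time() - t_all, 2)
    result.manifest = manifest
    if write_outputs:
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True, default=str)


def configure_logging(verbose: bool = True) -> None:
    logging.basicConfig(
        stream=sys.stderr,
        level=logging.INFO if verbose else logging.WARNING,
        format="%(asctime)s %(name)s %(message)s",
    )
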