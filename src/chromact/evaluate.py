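"""Recovery of planted ground truth from pipeline output.

Because every synthetic study records what was planted, the package can
score itself: how well estimated binding fold changes, pausing indices,
super-enhancers and motif placement are recovered, and how the callers
behave on null data.  These routines define the evaluation conditions
(problem sizes, seed handling) in one place so that tests and the
reproduction script measure the same thing.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from . import peaks as peaks_mod
from .genomic_io import CoverageTrack
from .motifs import motif_density_profile
from .pipeline import RunConfig, _pool, run
from .superenhancer import call_super, stitch
from .synthetic import (
    SimulationConfig,
    simulate_chip,
    simulate_enhancer_landscape,
    simulate_genome,
    simulate_study,
)

__all__ = [
    "match_sites_to_peaks",
    "binding_recovery",
    "pausing_recovery",
    "superenhancer_recovery",
    "motif_density_peak_offset",
    "ap1_stratification_rate",
    "null_confident_peak_rate",
    "null_window_pvalue_rate",
    "null_expression_pvalues",
]


def match_sites_to_peaks(
    sites: pd.DataFrame, universe, max_dist: int = 300
) -> list[int | None]:
    """For each planted site, the index of the universe peak whose
    region covers a position within ``max_dist`` of the planted summit
    (None when unrecovered)."""
    out: list[int | None] = []
    for row in sites.itertuples(index=False):
        best = None
        for i, p in enumerate(universe):
            if p.interval.chrom != row.chrom:
                continue
            if abs(p.summit - row.summit) <= max_dist or p.interval.contains(
                row.summit
            ):
                best = i
                break
        out.append(best)
    return out


def binding_recovery(study, universe, diff: pd.DataFrame) -> dict:
    """Planted vs estimated binding log2 fold change and summit accuracy."""
    matches = match_sites_to_peaks(study.sites, universe)
    idx = [i for i, m in enumerate(matches) if m is not None]
    planted = study.sites["log2fc"].to_numpy()[idx]
    estimated = diff["log2fc"].to_numpy()[[matches[i] for i in idx]]
    r = float(stats.pearsonr(planted, estimated)[0]) if len(idx) >= 3 else np.nan
    summit_err = np.array(
        [abs(universe[matches[i]].summit - study.sites["summit"].iloc[i])
         for i in idx]
    )
    return {
        "n_sites": len(study.sites),
        "n_recovered": len(idx),
        "log2fc_pearson_r": r,
        "summit_within_25bp_fraction": float(np.mean(summit_err <= 25))
        if len(idx) else np.nan,
    }


def pausing_recovery(study, pol2_metrics: pd.DataFrame) -> dict:
    """Median relative error of estimated vs planted pausing index."""
    truth = study.gene_truth[["gene_id", "pausing_index"]].rename(
        columns={"pausing_index": "true_pi"}
    )
    m = pol2_metrics.merge(truth, on="gene_id")
    ok = m[m["status"] == "ok"]
    rel = (ok["pausing_index"] - ok["true_pi"]).abs() / ok["true_pi"]
    return {"n_genes": int(len(ok)), "median_relative_error": float(rel.median())}


def superenhancer_recovery(n_seeds: int = 20, base_seed: int = 0) -> dict:
    """Fraction of planted super-enhancers flagged as super, per seed."""
    recovered = []
    for s in range(n_seeds):
        intervals, signals, truth = simulate_enhancer_landscape(base_seed + s)
        stitched, _ = call_super(stitch(intervals, signals))
        found: set[int] = set()
        super_of = dict(zip(truth["index"], truth["super_id"]))
        for region in stitched:
            if region.is_super:
                found |= {
                    super_of[c] for c in region.constituent_ids if super_of[c] >= 0
                }
        n_planted = int(truth.loc[truth["super_id"] >= 0, "super_id"].nunique())
        recovered.append(len(found) / n_planted)
    return {
        "n_seeds": n_seeds,
        "mean_recovered_fraction": float(np.mean(recovered)),
        "min_recovered_fraction": float(np.min(recovered)),
    }


def motif_density_peak_offset(
    study, universe, classes, motif_id: str = "AP1", smooth_bp: int = 21
) -> dict:
    """Offset of the maximal (smoothed) motif density from the summit,
    over the enhancer peaks of the universe."""
    pwm = next(p for p in study.pwms if p.motif_id == motif_id)
    summits = [
        (p.interval.chrom, p.summit)
        for p, c in zip(universe, classes)
        if c == "enhancer"
    ]
    profile = motif_density_profile(study.sequences, summits, pwm)
    smooth = (
        profile.rolling(smooth_bp, center=True, min_periods=1).mean()
    )
    peak_offset = int(smooth.idxmax())
    center = profile.loc[-25:25].mean()
    flank = pd.concat([profile.loc[:-150], profile.loc[150:]]).mean()
    return {
        "n_peaks": len(summits),
        "peak_offset_bp": peak_offset,
        "central_to_flank_density_ratio": float(center / flank) if flank > 0
        else float("inf"),
    }


def _stratification_config(seed: int) -> SimulationConfig:
    # enhancer-heavy miniature study sized so the AP-1 group holds ~50 peaks
    return SimulationConfig(
        seed=seed,
        n_chroms=2,
        chrom_length=1_500_000,
        site_free_chroms=0,
        n_genes=60,
        n_sites={"promoter": 20, "enhancer": 150, "repressed": 0, "null": 0},
        n_background_regions={
            "promoter": 10, "enhancer": 10, "repressed": 5, "uncharacterized": 10,
        },
    )


def ap1_stratification_rate(
    n_seeds: int = 20, base_seed: int = 0, alpha: float = 0.05
) -> dict:
    """Fraction of seeds in which the planted AP-1 binding boost is
    detected (AP-1 group median above Other and rank-sum p < alpha).

    Each seed runs the ChIP arm of the pipeline for one factor on an
    enhancer-heavy miniature study and stratifies the TAM:EtOH fold
    changes of enhancer peaks by AP-1 presence within 50 bp of the
    summit.
    """
    from .annotation import ChromatinStateMap, classify_peaks
    from .motifs import hits_near_summits, stratify_fold_changes

    detected = 0
    group_sizes = []
    for s in range(n_seeds):
        cfg = _stratification_config(base_seed + s)
        study = simulate_study(cfg)
        universe, diff = _single_factor_differential(study)
        states = ChromatinStateMap(study.states)
        classes = classify_peaks(universe, states)
        enh_idx = [i for i, c in enumerate(classes) if c == "enhancer"]
        summits = [(universe[i].interval.chrom, universe[i].summit)
                   for i in enh_idx]
        hits = hits_near_summits(study.sequences, summits, study.pwms)
        strat = stratify_fold_changes(
            diff["log2fc"].to_numpy()[enh_idx], hits, combos=[["AP1"]]
        )
        ap1 = strat[strat["group"] == "AP1"].iloc[0]
        other = strat[strat["group"] == "Other"].iloc[0]
        group_sizes.append(int(ap1["n"]))
        if (
            ap1["n"] > 0
            and ap1["median_log2fc"] > other["median_log2fc"]
            and ap1["p_value"] < alpha
        ):
            detected += 1
    return {
        "n_seeds": n_seeds,
        "detection_rate": detected / n_seeds,
        "median_group_size": float(np.median(group_sizes)),
    }


def _single_factor_differential(study, factor: str = "S100A8"):
    """Confident-peak universe and TAM:EtOH differential table using one
    factor's tracks (the cheap arm used in multi-seed loops)."""
    cfg = RunConfig(seed=study.config.seed)
    confident = {}
    for cond in ("etoh", "tam"):
        reps = range(1, study.config.replicates + 1)
        rep_cand = [
            peaks_mod.call_candidate_peaks(
                study.chip[(factor, cond, r)], study.inputs[(cond, r)],
                cfg.window_bp, cfg.step_bp, cfg.candidate_q,
            )
            for r in reps
        ]
        pooled = _pool([study.chip[(factor, cond, r)] for r in reps])
        pooled_in = _pool([study.inputs[(cond, r)] for r in reps])
        pooled_cand = peaks_mod.call_candidate_peaks(
            pooled, pooled_in, cfg.window_bp, cfg.step_bp, cfg.candidate_q
        )
        confident[cond] = peaks_mod.confident_peaks(
            pooled_cand, rep_cand, cfg.q_max, cfg.min_replicates, cfg.min_reads
        )
    universe = peaks_mod.merge_peak_sets(*confident.values())
    reps = range(1, study.config.replicates + 1)
    diff = peaks_mod.differential_binding(
        universe,
        [study.chip[(factor, "tam", r)] for r in reps],
        [study.chip[(factor, "etoh", r)] for r in reps],
    )
    return universe, diff


def _null_config(seed: int) -> SimulationConfig:
    return SimulationConfig(
        seed=seed,
        n_chroms=1,
        chrom_length=500_000,
        n_genes=20,
        n_sites={"promoter": 0, "enhancer": 0, "repressed": 0, "null": 0},
        n_background_regions={
            "promoter": 5, "enhancer": 5, "repressed": 3, "uncharacterized": 5,
        },
    )


def null_confident_peak_rate(n_seeds: int = 30, base_seed: int = 0) -> dict:
    """Fraction of null-simulation seeds (no planted sites) that yield
    zero confident peaks at q <= 1e-7."""
    clean = 0
    for s in range(n_seeds):
        cfg = _null_config(base_seed + s)
        rng = np.random.default_rng(cfg.seed)
        study = simulate_genome(cfg, rng)
        simulate_chip(study, rng)
        universe, _ = _single_factor_differential(study)
        if len(universe) == 0:
            clean += 1
    return {"n_seeds": n_seeds, "zero_confident_fraction": clean / n_seeds}


def null_window_pvalue_rate(
    alpha: float = 0.05,
    n_bp: int = 300_000,
    rate: float = 0.2,
    seed: int = 0,
) -> dict:
    """Fraction of windows significant at alpha when ChIP equals the
    scaled input everywhere (uniform null); expected to sit at or just
    below alpha because the Poisson tail is discrete."""
    rng = np.random.default_rng(seed)
    chip = CoverageTrack({"chrN": rng.poisson(rate, size=n_bp)})
    input_track = CoverageTrack(
        {"chrN": np.ones(n_bp, dtype=np.int64)}
    )
    # compute raw window p-values via the caller's own model
    from ._stats import poisson_upper_tail

    window, step = 300, 50
    cs = np.concatenate([[0], np.cumsum(chip.counts["chrN"])])
    starts = np.arange(0, n_bp - window + 1, step)
    k = cs[starts + window] - cs[starts]
    lam = window * chip.depth / n_bp  # scaled uniform input
    p = poisson_upper_tail(k, lam)
    return {
        "n_windows": int(len(starts)),
        "alpha": alpha,
        "fraction_significant": float(np.mean(p < alpha)),
    }


def null_expression_pvalues(n_seeds: int = 40, base_seed: int = 0) -> np.ndarray:
    """Bound-vs-unbound fold-change rank-sum p-values under zero
    binding-expression coupling; uniform when the test is calibrated."""
    from .expression import bound_vs_unbound, call_de, expression_table

    out = []
    for s in range(n_seeds):
        cfg = SimulationConfig(
            seed=base_seed + s,
            n_chroms=1,
            chrom_length=800_000,
            n_genes=40,
            site_free_chroms=0,
            n_sites={"promoter": 10, "enhancer": 10, "repressed": 0, "null": 0},
            n_background_regions={
                "promoter": 5, "enhancer": 5, "repressed": 3,
                "uncharacterized": 5,
            },
            expression_coupling=0.0,
            bound_level_log2=0.0,
        )
        rng = np.random.default_rng(cfg.seed)
        study = simulate_genome(cfg, rng)
        from .synthetic import simulate_pol2_and_expression

        simulate_pol2_and_expression(study, rng)
        depths = {
            "etoh": int(study.footprints["reads_etoh"].sum()),
            "tam": int(study.footprints["reads_tam"].sum()),
        }
        records = call_de(
            expression_table(study.footprints, study.genes, depths)
        )
        bound = set(study.gene_truth.loc[study.gene_truth["bound"], "gene_id"])
        res = bound_vs_unbound(records, bound)
        out.append(res["fold_change"].p_value)
    return np.array(out)


def full_run_summary(seed: int = 0) -> dict:
    """One default-scale pipeline run plus every recovery metric that
    can be read off it."""
    from .annotation import ChromatinStateMap, classify_peaks  # noqa: F401

    result = run(RunConfig(seed=seed), "all", write_outputs=False)
    study = result.study
    universe = result.artifacts["universe"]
    diff = result.artifacts["differential"]
    classes = result.artifacts["peak_classes"]
    out = {
        "binding": binding_recovery(study, universe, diff),
        "pausing": pausing_recovery(
            study, result.artifacts["pol2_metrics"]["etoh"]
        ),
        "motif": motif_density_peak_offset(study, universe, classes),
        "factor_r": result.artifacts["factor_correlation"],
        "classes": pd.Series(classes).value_counts(normalize=True).to_dict(),
        "result": result,
    }
    return out
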