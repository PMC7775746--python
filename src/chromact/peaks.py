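"""Peak calling, filtering, merging and differential binding.

The candidate caller is a windowed Poisson scan against a depth-scaled
input background (a deliberately simple, fully testable stand-in for a
model-based caller).  The confident-peak filter is the conjunctive
triple used throughout the analysis: q <= 1e-7 versus input, support in
at least two biological replicates, and at least five raw reads in the
peak region.  Peak sets from different samples are merged whenever they
overlap by at least 1 bp.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd

from ._stats import bh_adjust, poisson_two_sample, poisson_upper_tail, pearson_log
from .genomic_io import CoverageTrack, GenomicInterval

__all__ = [
    "Peak",
    "call_candidate_peaks",
    "confident_peaks",
    "merge_peak_sets",
    "count_matrix",
    "pooled_rpm",
    "combined_signal",
    "signal_correlation",
    "differential_binding",
]


@dataclass(frozen=True)
class Peak:
    """Called peak: region, summit, raw counts and significance."""

    interval: GenomicInterval
    summit: int
    chip_count: int = 0
    input_count: int = 0
    p_value: float = 1.0
    q_value: float = 1.0
    signal: float = 0.0  # RPM in the region
    n_replicates_supporting: int = 0

    def __post_init__(self) -> None:
        if not self.interval.contains(self.summit):
            raise ValueError(
                f"summit {self.summit} outside {self.interval.chrom}:"
                f"{self.interval.start}-{self.interval.end}"
            )
        if self.chip_count < 0 or self.input_count < 0:
            raise ValueError("negative read counts")
        if not (0.0 <= self.q_value <= 1.0):
            raise ValueError(f"q value {self.q_value} outside [0, 1]")


def _window_counts(arr_cumsum: np.ndarray, starts: np.ndarray, width: int) -> np.ndarray:
    ends = np.minimum(starts + width, len(arr_cumsum) - 1)
    return arr_cumsum[ends] - arr_cumsum[starts]


def _smoothed_argmax(arr: np.ndarray, half: int = 25) -> int:
    """Leftmost position of maximal moving-window coverage."""
    if len(arr) == 1:
        return 0
    kernel = np.ones(2 * half + 1)
    smooth = np.convolve(arr, kernel, mode="same")
    return int(np.argmax(smooth))


def call_candidate_peaks(
    chip: CoverageTrack,
    input_track: CoverageTrack,
    window_bp: int = 300,
    step_bp: int = 50,
    q_threshold: float = 0.05,
) -> list[Peak]:
    """Sliding-window Poisson caller against a scaled input background.

    For every window the ChIP count is tested against
    ``lambda = max(scale * input_count, genome-wide expected count)``
    with a Poisson upper tail; BH correction runs over all tested
    windows, significant windows overlapping by >= 1 bp are merged, and
    the summit is the (leftmost) position of maximal smoothed ChIP
    coverage inside the merged region.
    """
    if window_bp < 50:
        raise ValueError("window_bp must be >= 50")
    input_depth = input_track.depth
    if input_depth == 0:
        raise ValueError("input track has zero depth; background undefined")
    chip_depth = chip.depth
    if chip_depth == 0:
        return []
    scale = chip_depth / input_depth
    genome_size = sum(chip.chrom_lengths.values())
    lam_floor = chip_depth / genome_size * window_bp

    window_rows: list[tuple[str, int, int, int]] = []  # chrom, start, k_chip, k_input
    p_values: list[np.ndarray] = []
    for chrom, arr in chip.counts.items():
        length = len(arr)
        starts = np.arange(0, max(length - window_bp, 0) + 1, step_bp)
        cs_chip = np.concatenate([[0], np.cumsum(arr)])
        cs_in = np.concatenate(
            [[0], np.cumsum(input_track.counts[chrom])]
        )
        k_chip = _window_counts(cs_chip, starts, window_bp)
        k_in = _window_counts(cs_in, starts, window_bp)
        lam = np.maximum(k_in * scale, lam_floor)
        p = poisson_upper_tail(k_chip, lam)
        p = np.where(k_chip == 0, 1.0, p)
        p_values.append(p)
        window_rows.extend(
            (chrom, int(s), int(kc), int(ki))
            for s, kc, ki in zip(starts, k_chip, k_in)
        )
    if not window_rows:
        return []
    p_all = np.concatenate(p_values)
    q_all = bh_adjust(p_all)

    # merge significant windows into peaks
    sig = np.flatnonzero(q_all <= q_threshold)
    regions: dict[str, list[tuple[int, int, float, float]]] = {}
    for idx in sig:
        chrom, start, _, _ = window_rows[idx]
        regions.setdefault(chrom, []).append(
            (start, start + window_bp, p_all[idx], q_all[idx])
        )
    peaks: list[Peak] = []
    for chrom in sorted(regions):
        spans = sorted(regions[chrom])
        cur_s, cur_e, cur_p, cur_q = spans[0]
        merged = []
        for s, e, p, q in spans[1:]:
            if s < cur_e:
                cur_e = max(cur_e, e)
                cur_p = min(cur_p, p)
                cur_q = min(cur_q, q)
            else:
                merged.append((cur_s, cur_e, cur_p, cur_q))
                cur_s, cur_e, cur_p, cur_q = s, e, p, q
        merged.append((cur_s, cur_e, cur_p, cur_q))
        chrom_len = chip.chrom_lengths[chrom]
        for s, e, p, q in merged:
            e = min(e, chrom_len)
            region = chip.counts[chrom][s:e]
            summit = s + _smoothed_argmax(region)
            k_chip = chip.region_count(chrom, s, e)
            k_in = input_track.region_count(chrom, s, e)
            peaks.append(
                Peak(
                    GenomicInterval(chrom, s, e),
                    summit,
                    chip_count=k_chip,
                    input_count=k_in,
                    p_value=float(p),
                    q_value=float(q),
                    signal=k_chip * 1e6 / chip_depth,
                )
            )
    return peaks


def _overlap_index(peaks: Sequence[Peak]) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for p in peaks:
        by_chrom.setdefault(p.interval.chrom, []).append(
            (p.interval.start, p.interval.end)
        )
    out = {}
    for chrom, spans in by_chrom.items():
        spans.sort()
        starts = np.array([s for s, _ in spans])
        # running max of ends lets a single bisect answer "any overlap?"
        ends = np.maximum.accumulate(np.array([e for _, e in spans]))
        out[chrom] = (starts, ends)
    return out


def _any_overlap(index, interval: GenomicInterval) -> bool:
    entry = index.get(interval.chrom)
    if entry is None:
        return False
    starts, ends = entry
    i = np.searchsorted(starts, interval.end, side="left")
    return i > 0 and ends[i - 1] > interval.start


def confident_peaks(
    pooled: Sequence[Peak],
    replicate_candidates: Sequence[Sequence[Peak]],
    q_max: float = 1e-7,
    min_replicates: int = 2,
    min_reads: int = 5,
) -> list[Peak]:
    """Apply the conjunctive confident-peak filter triple.

    Keeps pooled peaks with (i) q <= ``q_max``, (ii) >= 1 bp overlap
    with a candidate peak in at least ``min_replicates`` replicates, and
    (iii) at least ``min_reads`` pooled raw reads in the region.
    """
    if len(replicate_candidates) < min_replicates:
        raise ValueError(
            f"need candidate sets from >= {min_replicates} replicates, "
            f"got {len(replicate_candidates)}"
        )
    indexes = [_overlap_index(reps) for reps in replicate_candidates]
    out = []
    for peak in pooled:
        if peak.q_value > q_max:
            continue
        if peak.chip_count < min_reads:
            continue
        support = sum(_any_overlap(ix, peak.interval) for ix in indexes)
        if support < min_replicates:
            continue
        out.append(replace(peak, n_replicates_supporting=support))
    return out


def merge_peak_sets(*peak_sets: Sequence[Peak]) -> list[Peak]:
    """Merge peaks across sets by transitive >= 1 bp overlap.

    The merged interval is the union span; the merged summit is the
    summit of the constituent with maximal signal (ties -> leftmost
    summit).  Raw counts are summed over constituents.  Half-open
    abutting peaks ([a,b) and [b,c)) do not merge.
    """
    peaks = [p for ps in peak_sets for p in ps]
    if not peaks:
        return []
    peaks.sort(key=lambda p: (p.interval.chrom, p.interval.start, p.interval.end))
    merged: list[Peak] = []
    group: list[Peak] = [peaks[0]]
    group_end = peaks[0].interval.end

    def _emit(group: list[Peak], end: int) -> Peak:
        best = max(group, key=lambda p: (p.signal, -p.summit))
        return Peak(
            GenomicInterval(group[0].interval.chrom, group[0].interval.start, end),
            best.summit,
            chip_count=sum(p.chip_count for p in group),
            input_count=sum(p.input_count for p in group),
            p_value=min(p.p_value for p in group),
            q_value=min(p.q_value for p in group),
            signal=max(p.signal for p in group),
            n_replicates_supporting=max(p.n_replicates_supporting for p in group),
        )

    for p in peaks[1:]:
        if p.interval.chrom == group[0].interval.chrom and p.interval.start < group_end:
            group.append(p)
            group_end = max(group_end, p.interval.end)
        else:
            merged.append(_emit(group, group_end))
            group = [p]
            group_end = p.interval.end
    merged.append(_emit(group, group_end))
    return merged


def count_matrix(tracks: Sequence[CoverageTrack], universe: Sequence[Peak]) -> np.ndarray:
    """(n_peaks, n_tracks) raw read counts over the peak universe."""
    out = np.zeros((len(universe), len(tracks)), dtype=np.int64)
    for j, track in enumerate(tracks):
        for i, peak in enumerate(universe):
            out[i, j] = track.interval_count(peak.interval)
    return out


def pooled_rpm(tracks: Sequence[CoverageTrack], universe: Sequence[Peak]) -> np.ndarray:
    """Replicate-pooled reads-per-million signal per peak."""
    counts = count_matrix(tracks, universe).sum(axis=1)
    depth = sum(t.depth for t in tracks)
    if depth == 0:
        raise ValueError("zero pooled depth")
    return counts * 1e6 / depth


def combined_signal(a8_rpm: np.ndarray, a9_rpm: np.ndarray) -> np.ndarray:
    """Combined two-factor signal: arithmetic mean of the factors'
    replicate-pooled RPM over a common peak universe."""
    a8 = np.asarray(a8_rpm, dtype=float)
    a9 = np.asarray(a9_rpm, dtype=float)
    if a8.size == 0 or a8.shape != a9.shape:
        raise ValueError("need equal-length non-empty signal vectors")
    return (a8 + a9) / 2.0


def signal_correlation(
    a8_rpm: np.ndarray, a9_rpm: np.ndarray, pseudocount: float = 0.5
) -> tuple[float, float]:
    """Pearson r (and p) between two factors on log2(RPM + pseudocount)."""
    return pearson_log(a8_rpm, a9_rpm, pseudocount)


def differential_binding(
    universe: Sequence[Peak],
    tam_tracks: Sequence[CoverageTrack],
    etoh_tracks: Sequence[CoverageTrack],
    pseudocount_rpm: float = 0.5,
    q_significant: float = 0.05,
) -> pd.DataFrame:
    """Pooled TAM:EtOH binding fold change per peak of the merged universe.

    Fold change is the ratio of pseudocounted pooled RPMs; significance
    is an exact two-sample Poisson (conditional binomial) test on the
    pooled counts, BH-corrected.  The flag column is named after the
    test so the departure from dispersion-modelling tools is explicit.
    """
    if not tam_tracks or not etoh_tracks:
        raise ValueError("need >= 1 replicate track per condition")
    k_tam = count_matrix(tam_tracks, universe).sum(axis=1)
    k_etoh = count_matrix(etoh_tracks, universe).sum(axis=1)
    d_tam = sum(t.depth for t in tam_tracks)
    d_etoh = sum(t.depth for t in etoh_tracks)
    rpm_tam = k_tam * 1e6 / d_tam
    rpm_etoh = k_etoh * 1e6 / d_etoh
    fc = (rpm_tam + pseudocount_rpm) / (rpm_etoh + pseudocount_rpm)
    ratio = d_tam / d_etoh
    p = np.array(
        [poisson_two_sample(int(a), int(b), ratio) for a, b in zip(k_tam, k_etoh)]
    )
    q = bh_adjust(p)
    return pd.DataFrame(
        {
            "chrom": [pk.interval.chrom for pk in universe],
            "start": [pk.interval.start for pk in universe],
            "end": [pk.interval.end for pk in universe],
            "summit": [pk.summit for pk in universe],
            "count_etoh": k_etoh,
            "count_tam": k_tam,
            "rpm_etoh": rpm_etoh,
            "rpm_tam": rpm_tam,
            "fold_change": fc,
            "log2fc": np.log2(fc),
            "p_value": p,
            "q_value": q,
            "sig_exact_poisson": q <= q_significant,
        }
    )
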