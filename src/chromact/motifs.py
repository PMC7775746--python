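"""PWM scanning around peak summits and motif-stratified binding.

Given position weight matrices are scored as log2-odds against the
background on both strands; a hit requires a score of at least the
PWM's threshold (default 80% of the maximum achievable score).  Hit
positions are the center of the match, which drives the summit-distance
logic: motif-density profiles over +/-200 bp of summits, and the
stratification of TAM:EtOH binding fold changes by motif presence
within +/-50 bp of the summit (inclusive group semantics, compared to
the peaks carrying none of the listed motifs).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ._stats import bh_adjust, rank_sum_test
from .genomic_io import BASES, Pwm

DEFAULT_THRESHOLD_FRACTION = 0.8
COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

__all__ = [
    "MotifHit",
    "scan_pwm",
    "hits_near_summits",
    "motif_density_profile",
    "stratify_fold_changes",
]


@dataclass(frozen=True)
class MotifHit:
    motif_id: str
    position: int  # center of the match, in the scanned window's coordinates
    strand: str
    score: float


def _encode(seq: str) -> np.ndarray:
    """Map a sequence to base indices; anything that is not ACGT -> 4."""
    idx = np.full(len(seq), 4, dtype=np.int8)
    for i, b in enumerate(BASES):
        idx[np.frombuffer(seq.upper().encode(), dtype=np.uint8) == ord(b)] = i
    return idx


def _score_positions(idx: np.ndarray, log_odds: np.ndarray) -> np.ndarray:
    """Log-odds score at every offset; ambiguous bases contribute 0
    (i.e. score with the background probability)."""
    L = log_odds.shape[0]
    n = len(idx) - L + 1
    if n <= 0:
        return np.empty(0)
    lo = np.hstack([log_odds, np.zeros((L, 1))])  # column 4: N -> 0 bits
    scores = np.zeros(n)
    for j in range(L):
        scores += lo[j, idx[j : j + n]]
    return scores


def reverse_complement(seq: str) -> str:
    return seq.upper().translate(COMPLEMENT)[::-1]


def scan_pwm(sequence: str, pwm: Pwm, threshold: float | None = None) -> list[MotifHit]:
    """Scan both strands of ``sequence`` with one PWM.

    ``threshold`` (bits) defaults to the PWM's own threshold, else 80%
    of the maximum achievable score.  Hit positions are match centers
    (offset + L//2).  On the minus strand the score at center c equals
    the plus-strand score of the reverse complement at the mirrored
    center — strand symmetry is exact.
    """
    L = len(pwm)
    if len(sequence) < L:
        raise ValueError(f"window shorter than PWM ({len(sequence)} < {L})")
    if threshold is None:
        threshold = (
            pwm.score_threshold
            if pwm.score_threshold is not None
            else DEFAULT_THRESHOLD_FRACTION * pwm.max_score
        )
    lo = pwm.log_odds
    hits: list[MotifHit] = []
    fwd = _score_positions(_encode(sequence), lo)
    rev_seq = reverse_complement(sequence)
    rev = _score_positions(_encode(rev_seq), lo)
    n = len(fwd)
    for off in range(n):
        if fwd[off] >= threshold:
            hits.append(MotifHit(pwm.motif_id, off + L // 2, "+", float(fwd[off])))
    for off in range(n):
        if rev[off] >= threshold:
            # mirror the match back onto the forward coordinates
            start = len(sequence) - off - L
            hits.append(MotifHit(pwm.motif_id, start + L // 2, "-", float(rev[off])))
    hits.sort(key=lambda h: (h.position, h.strand))
    return hits


def _summit_window(fasta, chrom: str, summit: int, half_window: int) -> tuple[str, int]:
    """Sequence around a summit, clipped at chromosome bounds; returns
    (sequence, start_offset_from_summit)."""
    chrom_len = len(fasta[chrom])
    lo = max(0, summit - half_window)
    hi = min(chrom_len, summit + half_window + 1)
    return str(fasta[chrom][lo:hi]), lo - summit


def hits_near_summits(
    fasta,
    summits: Sequence[tuple[str, int]],
    pwms: Sequence[Pwm],
    half_window: int = 100,
) -> dict[int, dict[str, list[int]]]:
    """Scan every PWM in windows around peak summits.

    Returns ``{peak_index: {motif_id: [offset, ...]}}`` with offsets
    relative to the summit (hit center minus summit position).
    """
    out: dict[int, dict[str, list[int]]] = {}
    for i, (chrom, summit) in enumerate(summits):
        seq, base = _summit_window(fasta, chrom, summit, half_window)
        per_motif: dict[str, list[int]] = {}
        for pwm in pwms:
            if len(seq) < len(pwm):
                continue
            for hit in scan_pwm(seq, pwm):
                per_motif.setdefault(pwm.motif_id, []).append(hit.position + base)
        if per_motif:
            out[i] = per_motif
    return out


def motif_density_profile(
    fasta,
    summits: Sequence[tuple[str, int]],
    pwm: Pwm,
    half_window: int = 200,
) -> pd.Series:
    """Per-bp motif hit density at offsets -half_window..+half_window
    from peak summits, averaged over peaks.

    Windows clipped at chromosome edges contribute only to the offsets
    they cover; each offset is normalised by the number of peaks whose
    window covers it.
    """
    offsets = np.arange(-half_window, half_window + 1)
    counts = np.zeros(offsets.size)
    covered = np.zeros(offsets.size)
    for chrom, summit in summits:
        seq, base = _summit_window(fasta, chrom, summit, half_window)
        lo_off, hi_off = base, base + len(seq)
        covered[(offsets >= lo_off) & (offsets < hi_off)] += 1
        if len(seq) < len(pwm):
            continue
        for hit in scan_pwm(seq, pwm):
            off = hit.position + base
            if -half_window <= off <= half_window:
                counts[off + half_window] += 1
    with np.errstate(invalid="ignore", divide="ignore"):
        density = np.where(covered > 0, counts / np.maximum(covered, 1), 0.0)
    return pd.Series(density, index=pd.Index(offsets, name="offset"), name=pwm.motif_id)


def stratify_fold_changes(
    log2fc: Sequence[float],
    peak_motifs: Mapping[int, dict[str, list[int]]] | Sequence[set],
    combos: Sequence[Sequence[str]],
    window: int = 50,
) -> pd.DataFrame:
    """Stratify per-peak binding fold changes by motif presence near the
    summit.

    A peak belongs to a combination group when *every* motif of the set
    has at least one hit within +/-``window`` bp of the summit
    (inclusive semantics: extra motifs do not exclude it).  "Other"
    collects the peaks carrying none of the motifs listed in any combo
    and is the reference group for two-sided Wilcoxon rank-sum tests.

    ``peak_motifs`` is either the output of :func:`hits_near_summits`
    (offsets relative to summits) or a per-peak sequence of motif-id
    sets already restricted to the window.
    Returns a table: group, n, median_log2fc, p_value, q_value.
    """
    fc = np.asarray(log2fc, dtype=float)
    n_peaks = fc.size
    if isinstance(peak_motifs, Mapping):
        near: list[set[str]] = []
        for i in range(n_peaks):
            motifs = peak_motifs.get(i, {})
            near.append(
                {
                    m
                    for m, offs in motifs.items()
                    if any(abs(o) <= window for o in offs)
                }
            )
    else:
        near = [set(s) for s in peak_motifs]
        if len(near) != n_peaks:
            raise ValueError("peak_motifs length != number of fold changes")
    listed = {m for combo in combos for m in combo}
    other_idx = [i for i in range(n_peaks) if not (near[i] & listed)]
    if not other_idx:
        raise ValueError("no reference peaks: every peak carries a listed motif")
    other_fc = fc[other_idx]
    rows = []
    for combo in combos:
        cset = set(combo)
        members = [i for i in range(n_peaks) if cset <= near[i]]
        label = "+".join(combo)
        if members:
            res = rank_sum_test(fc[members], other_fc)
            rows.append((label, len(members), float(np.median(fc[members])), res.p_value))
        else:
            rows.append((label, 0, np.nan, np.nan))
    df = pd.DataFrame(rows, columns=["group", "n", "median_log2fc", "p_value"])
    valid = df["p_value"].notna()
    q = np.full(len(df), np.nan)
    q[valid.to_numpy()] = bh_adjust(df.loc[valid, "p_value"].to_numpy())
    df["q_value"] = q
    df.loc[len(df)] = (
        "Other", len(other_idx), float(np.median(other_fc)), np.nan, np.nan,
    )
    return df
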