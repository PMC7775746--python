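"""Peak caller, confident-peak filter, merging and differential binding."""

import math

import numpy as np
import pytest

from chromact._stats import poisson_two_sample, poisson_upper_tail
from chromact.genomic_io import CoverageTrack, GenomicInterval
from chromact.peaks import (
    Peak,
    call_candidate_peaks,
    combined_signal,
    confident_peaks,
    differential_binding,
    merge_peak_sets,
    signal_correlation,
)


def _peak(chrom, start, end, summit=None, q=1e-9, reads=100, signal=1.0):
    return Peak(
        GenomicInterval(chrom, start, end),
        summit if summit is not None else (start + end) // 2,
        chip_count=reads,
        q_value=q,
        signal=signal,
    )


def brute_poisson_tail(k: int, lam: float, terms: int = 400) -> float:
    """Independent oracle: term-wise pmf summation of P(X >= k)."""
    total = 0.0
    for j in range(k, k + terms):
        total += math.exp(j * math.log(lam) - lam - math.lgamma(j + 1))
    return total


class TestPoissonTail:
    def test_zero_count_never_significant(self):
        assert poisson_upper_tail(0, 5.0) == 1.0

    @pytest.mark.parametrize("k,lam", [(50, 5.0), (10, 5.0), (3, 0.5), (100, 80.0)])
    def test_matches_termwise_summation(self, k, lam):
        assert poisson_upper_tail(k, lam) == pytest.approx(
            brute_poisson_tail(k, lam), rel=1e-10
        )


class TestCandidateCaller:
    def test_null_uniform_alpha_calibration(self, rng):
        """ChIP drawn at exactly the scaled-input rate: the fraction of
        windows with p < alpha approximates alpha from below."""
        n = 200_000
        chip = CoverageTrack({"c": rng.poisson(0.2, size=n)})
        cs = np.concatenate([[0], np.cumsum(chip.counts["c"])])
        starts = np.arange(0, n - 300 + 1, 50)
        k = cs[starts + 300] - cs[starts]
        lam = 300 * chip.depth / n
        p = poisson_upper_tail(k, lam)
        frac = np.mean(p < 0.05)
        assert 0.01 <= frac <= 0.065

    def test_recovers_strong_site(self, rng):
        n = 100_000
        lam = np.full(n, 0.2)
        lam[50_000:50_300] = 0.2 * 50
        chip = CoverageTrack({"c": rng.poisson(lam)})
        inp = CoverageTrack({"c": rng.poisson(0.2, size=n)})
        called = call_candidate_peaks(chip, inp)
        assert len(called) == 1
        assert called[0].interval.start <= 50_000 < called[0].interval.end
        # rectangular planted site: the summit lies on its plateau
        assert 50_000 <= called[0].summit < 50_300
        assert called[0].q_value < 1e-7

    def test_zero_depth_input_rejected(self):
        chip = CoverageTrack({"c": np.ones(1000, dtype=int)})
        empty = CoverageTrack({"c": np.zeros(1000, dtype=int)})
        with pytest.raises(ValueError, match="zero depth"):
            call_candidate_peaks(chip, empty)


class TestConfidentFilter:
    def _reps(self):
        hit = [_peak("chr1", 90, 210)]
        return [hit, hit]

    def test_read_filter(self):
        pooled = [_peak("chr1", 100, 200, reads=4, q=1e-8)]
        assert confident_peaks(pooled, self._reps()) == []

    def test_replicate_filter(self):
        pooled = [_peak("chr1", 100, 200, reads=100, q=1e-8)]
        reps = [[_peak("chr1", 90, 210)], [_peak("chr1", 5000, 5100)]]
        assert confident_peaks(pooled, reps) == []

    def test_q_boundary_inclusive(self):
        kept = confident_peaks([_peak("chr1", 100, 200, q=1e-7)], self._reps())
        assert len(kept) == 1 and kept[0].n_replicates_supporting == 2
        assert confident_peaks([_peak("chr1", 100, 200, q=1e-6)], self._reps()) == []

    def test_single_replicate_rejected(self):
        with pytest.raises(ValueError, match="2 replicates"):
            confident_peaks([], [[_peak("chr1", 0, 10)]])

    def test_monotone_in_thresholds(self, rng):
        """Relaxing any threshold never removes a confident peak."""
        pooled = [
            _peak("chr1", int(s), int(s) + 150,
                  reads=int(rng.integers(0, 20)),
                  q=float(10 ** -rng.uniform(0, 10)))
            for s in range(0, 5000, 300)
        ]
        reps = [
            [_peak("chr1", int(s) + 40, int(s) + 120) for s in range(0, 5000, 600)],
            [_peak("chr1", int(s), int(s) + 100) for s in range(0, 5000, 300)],
        ]
        strict = {
            p.interval for p in confident_peaks(pooled, reps, 1e-7, 2, 5)
        }
        relaxed = {
            p.interval for p in confident_peaks(pooled, reps, 1e-5, 2, 3)
        }
        assert strict <= relaxed


def brute_merge(spans):
    """O(n^2) transitive-closure merge oracle."""
    parent = list(range(len(spans)))

    def find(i):
        while parent[i] != i:
            i = parent[i]
        return i

    for i in range(len(spans)):
        for j in range(i + 1, len(spans)):
            (c1, s1, e1), (c2, s2, e2) = spans[i], spans[j]
            if c1 == c2 and s1 < e2 and s2 < e1:
                parent[find(i)] = find(j)
    groups = {}
    for i, (c, s, e) in enumerate(spans):
        groups.setdefault(find(i), []).append((c, s, e))
    return sorted(
        (g[0][0], min(s for _, s, _ in g), max(e for _, _, e in g))
        for g in groups.values()
    )


class TestMerge:
    def test_one_bp_overlap_merges(self):
        merged = merge_peak_sets([_peak("chr1", 100, 200), _peak("chr1", 199, 300)])
        assert len(merged) == 1
        assert (merged[0].interval.start, merged[0].interval.end) == (100, 300)

    def test_abutting_half_open_stays_separate(self):
        merged = merge_peak_sets([_peak("chr1", 100, 200), _peak("chr1", 200, 300)])
        assert len(merged) == 2

    def test_transitive_chain(self):
        merged = merge_peak_sets(
            [_peak("chr1", 0, 120), _peak("chr1", 100, 260), _peak("chr1", 250, 400)]
        )
        assert len(merged) == 1
        assert merged[0].interval.end == 400

    def test_summit_from_strongest_constituent(self):
        a = _peak("chr1", 100, 200, summit=150, signal=1.0)
        b = _peak("chr1", 150, 300, summit=220, signal=9.0)
        merged = merge_peak_sets([a, b])
        assert merged[0].summit == 220

    def test_matches_brute_force_and_is_idempotent(self, rng):
        for _ in range(10):
            peaks = []
            for _ in range(60):
                chrom = f"chr{int(rng.integers(1, 3))}"
                s = int(rng.integers(0, 3000))
                peaks.append(_peak(chrom, s, s + int(rng.integers(10, 400))))
            merged = merge_peak_sets(peaks)
            got = sorted(
                (p.interval.chrom, p.interval.start, p.interval.end) for p in merged
            )
            spans = [(p.interval.chrom, p.interval.start, p.interval.end)
                     for p in peaks]
            assert got == brute_merge(spans)
            again = merge_peak_sets(merged)
            assert got == sorted(
                (p.interval.chrom, p.interval.start, p.interval.end) for p in again
            )
            rng.shuffle(peaks)
            assert got == sorted(
                (p.interval.chrom, p.interval.start, p.interval.end)
                for p in merge_peak_sets(peaks)
            )


class TestCombinedSignal:
    def test_identical_signals_correlate_perfectly(self):
        x = np.array([1.0, 5.0, 2.0, 9.0, 4.0])
        np.testing.assert_allclose(combined_signal(x, x), x)
        r, _ = signal_correlation(x, x)
        assert r == pytest.approx(1.0)

    def test_empty_universe_rejected(self):
        with pytest.raises(ValueError):
            combined_signal(np.array([]), np.array([]))


def brute_two_sided_binomial(k: int, n: int, p0: float) -> float:
    """Exact enumeration: sum of P(X=j) over j with pmf <= pmf(k)."""
    from scipy.stats import binom

    pk = binom.pmf(k, n, p0)
    return float(
        sum(binom.pmf(j, n, p0) for j in range(n + 1)
            if binom.pmf(j, n, p0) <= pk * (1 + 1e-9))
    )


class TestDifferentialBinding:
    def _tracks(self, counts, n=2000):
        """One-track condition with reads placed in the peak regions."""
        arr = np.zeros(n, dtype=int)
        for (s, e), k in counts.items():
            arr[s:e] = k // (e - s)
        return [CoverageTrack({"c": arr})]

    def test_equal_counts_equal_depth_fold_one(self):
        universe = [_peak("c", 100, 200)]
        tam = self._tracks({(100, 200): 100})
        etoh = self._tracks({(100, 200): 100})
        df = differential_binding(universe, tam, etoh)
        assert df["fold_change"].iloc[0] == pytest.approx(1.0)
        assert df["p_value"].iloc[0] == pytest.approx(1.0)

    def test_exact_conditional_binomial_p(self):
        # 40 TAM vs 10 EtOH reads at equal depth: k=40 of n=50 at p0=0.5
        assert poisson_two_sample(40, 10) == pytest.approx(
            brute_two_sided_binomial(40, 50, 0.5), rel=1e-9
        )

    def test_fold_change_recovery_on_planted_sites(self, rng):
        """Planted 4x vs 1x sites at high enrichment: median estimated
        log2 fold change within +/-0.3 of planted."""
        n = 400_000
        lam_bg = 0.2
        sites4 = [(i, i + 300) for i in range(20_000, 200_000, 12_000)]
        sites1 = [(i, i + 300) for i in range(220_000, 390_000, 12_000)]
        enrich = 50
        etoh = np.full(n, lam_bg)
        tam = np.full(n, lam_bg)
        for s, e in sites4 + sites1:
            etoh[s:e] += lam_bg * enrich
        for s, e in sites4:
            tam[s:e] += lam_bg * enrich * 4
        for s, e in sites1:
            tam[s:e] += lam_bg * enrich
        tam_tracks = [CoverageTrack({"c": rng.poisson(tam)})]
        etoh_tracks = [CoverageTrack({"c": rng.poisson(etoh)})]
        universe = [_peak("c", s, e) for s, e in sites4 + sites1]
        df = differential_binding(universe, tam_tracks, etoh_tracks)
        # fold changes are relative to library size; compare the planted
        # 4x group against the planted 1x group
        est4 = df["log2fc"].iloc[: len(sites4)].median()
        est1 = df["log2fc"].iloc[len(sites4):].median()
        assert est4 - est1 == pytest.approx(2.0, abs=0.3)
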