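"""Chromatin-state classification, target mapping and class enrichment."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import hypergeom

from chromact._stats import fisher_exact_2x2
from chromact.annotation import (
    ChromatinStateMap,
    assign_enhancer_targets,
    assign_promoter_targets,
    class_enrichment,
    classify_peak,
    gene_target_classes,
)
from chromact.genomic_io import GeneModel, GenomicInterval
from chromact.peaks import Peak


def _peak(chrom, summit, half=150):
    return Peak(GenomicInterval(chrom, summit - half, summit + half), summit)


class TestClassification:
    def _states(self):
        return ChromatinStateMap(
            {
                "H3K4me3": [GenomicInterval("chr1", 1000, 2000)],
                "H3K27ac": [GenomicInterval("chr1", 1000, 2000),
                            GenomicInterval("chr1", 5000, 6000)],
                "H3K4me1": [GenomicInterval("chr1", 5000, 6000)],
                "H3K9me3": [GenomicInterval("chr1", 9000, 10000)],
            }
        )

    def test_promoter_precedence_over_enhancer_marks(self):
        assert classify_peak(_peak("chr1", 1500), self._states()) == "promoter"

    def test_enhancer_and_repressed_and_uncharacterized(self):
        states = self._states()
        assert classify_peak(_peak("chr1", 5500), states) == "enhancer"
        assert classify_peak(_peak("chr1", 9500), states) == "repressed"
        assert classify_peak(_peak("chr1", 20_000), states) == "uncharacterized"

    def test_summit_decides_not_region(self):
        # peak region overlaps the promoter mark but its summit does not
        p = Peak(GenomicInterval("chr1", 1900, 2600), 2500)
        assert classify_peak(p, self._states()) == "uncharacterized"

    def test_planted_labels_recovered_exactly(self, tiny_study, full_run):
        """On synthetic data every recovered peak carries the planted
        chromatin class ('null' sites are in uncharacterized chromatin)."""
        from chromact.evaluate import match_sites_to_peaks

        res = full_run
        universe = res.artifacts["universe"]
        classes = res.artifacts["peak_classes"]
        matches = match_sites_to_peaks(res.study.sites, universe)
        for site_class, m in zip(res.study.sites["site_class"], matches):
            if m is None:
                continue
            expected = "uncharacterized" if site_class == "null" else site_class
            assert classes[m] == expected


class TestPromoterTargets:
    def _gene(self, gene_id="g1", strand="+", start=10_000, end=20_000):
        return GeneModel(gene_id, "chr1", strand, start, end, start, start)

    def test_downstream_summit_within_gene_fraction(self):
        gene = self._gene()  # length 10 kb -> 5% = 500
        df = assign_promoter_targets([_peak("chr1", 10_200)], [gene])
        assert list(df["gene_id"]) == ["g1"]
        assert list(df["distance"]) == [200]

    def test_downstream_summit_beyond_gene_fraction_rejected(self):
        gene = self._gene(end=13_000)  # length 3 kb -> 5% = 150 <= 200
        df = assign_promoter_targets([_peak("chr1", 10_200)], [gene])
        assert df.empty

    def test_upstream_bound_inclusive(self):
        gene = self._gene()
        df = assign_promoter_targets([_peak("chr1", 10_000 - 1500)], [gene])
        assert list(df["gene_id"]) == ["g1"]
        df = assign_promoter_targets([_peak("chr1", 10_000 - 1501)], [gene])
        assert df.empty

    def test_minus_strand_window_flipped(self):
        gene = self._gene(strand="-")  # tss = 19_999
        # 200 bp upstream of a minus-strand TSS is at tss + 200
        df = assign_promoter_targets([_peak("chr1", 19_999 + 200)], [gene])
        assert list(df["gene_id"]) == ["g1"]
        # 200 bp downstream (into the body) passes the 5% rule (500)
        df = assign_promoter_targets([_peak("chr1", 19_999 - 200)], [gene])
        assert list(df["gene_id"]) == ["g1"]

    def test_nearest_tss_wins_ties_lexicographic(self):
        g1 = self._gene("a", start=10_000, end=20_000)
        g2 = self._gene("b", start=10_000, end=20_000)
        df = assign_promoter_targets([_peak("chr1", 9_900)], [g2, g1])
        assert list(df["gene_id"]) == ["a"]

    def test_matches_all_pairs_brute_force(self, rng):
        genes = []
        for i in range(50):
            start = int(rng.integers(0, 490_000))
            length = int(rng.integers(1_000, 20_000))
            strand = "+" if rng.random() < 0.5 else "-"
            genes.append(
                GeneModel(f"g{i:02d}", "chr1", strand, start, start + length,
                          start, start)
            )
        peaks = [_peak("chr1", int(rng.integers(500, 499_500))) for _ in range(100)]
        got = assign_promoter_targets(peaks, genes)
        expected_rows = []
        for pi, p in enumerate(peaks):
            candidates = []
            for g in genes:
                off = p.summit - g.tss if g.strand == "+" else g.tss - p.summit
                if not (-1500 <= off <= 250):
                    continue
                if off > 0 and not (off < 0.05 * g.length):
                    continue
                candidates.append((abs(off), g.gene_id, off))
            if candidates:
                d, gid, off = min(candidates)
                expected_rows.append((pi, gid, off))
        expected = pd.DataFrame(
            expected_rows, columns=["peak_index", "gene_id", "distance"]
        )
        pd.testing.assert_frame_equal(
            got.reset_index(drop=True), expected, check_dtype=False
        )


class TestEnhancerTargets:
    def _gene(self, gene_id="g1", start=100_000, end=120_000):
        return GeneModel(gene_id, "chr1", "+", start, end, start, start)

    def test_distance_boundary_inclusive(self):
        gene = self._gene()  # TSS at 100 kb
        # summit 49,999 bp from the TSS -> assigned
        assert not assign_enhancer_targets([_peak("chr1", 50_001)], [gene]).empty
        # exactly 50 kb -> still assigned (inclusive)
        assert not assign_enhancer_targets([_peak("chr1", 50_000)], [gene]).empty
        # 50,001 bp -> out of range
        assert assign_enhancer_targets([_peak("chr1", 49_999)], [gene]).empty

    def test_gene_body_overlap_clause(self):
        gene = self._gene(end=200_000)  # TSS 100 kb from the summit below
        df = assign_enhancer_targets([_peak("chr1", 180_000)], [gene])
        assert list(df["gene_id"]) == ["g1"]

    def test_matches_all_pairs_brute_force(self, rng):
        genes = [
            GeneModel(f"g{i}", "chr1", "+" if rng.random() < 0.5 else "-",
                      s := int(rng.integers(0, 800_000)),
                      s + int(rng.integers(1_000, 30_000)), s, s)
            for i in range(40)
        ]
        peaks = [_peak("chr1", int(rng.integers(500, 799_000))) for _ in range(80)]
        got = set(
            map(tuple, assign_enhancer_targets(peaks, genes)[
                ["peak_index", "gene_id"]
            ].itertuples(index=False))
        )
        expected = {
            (pi, g.gene_id)
            for pi, p in enumerate(peaks)
            for g in genes
            if abs(g.tss - p.summit) <= 50_000 or g.interval.contains(p.summit)
        }
        assert got == expected


class TestGeneTargetClasses:
    def test_pr_eh_partition(self):
        prom = pd.DataFrame(
            [(0, "a", 10), (1, "b", 20)],
            columns=["peak_index", "gene_id", "distance"],
        )
        enh = pd.DataFrame(
            [(2, "b", 100), (3, "c", 200)],
            columns=["peak_index", "gene_id", "distance"],
        )
        out = gene_target_classes(prom, enh)
        assert {g: a.target_class for g, a in out.items()} == {
            "a": "Pr", "b": "Pr+Eh", "c": "Eh",
        }


def brute_fisher_two_sided(a, b, c, d):
    """Oracle: full hypergeometric enumeration of tables with the
    observed margins, summing probabilities <= the observed one."""
    n = a + b + c + d
    row1, col1 = a + b, a + c
    p_obs = hypergeom.pmf(a, n, col1, row1)
    total = 0.0
    for x in range(max(0, row1 + col1 - n), min(row1, col1) + 1):
        p = hypergeom.pmf(x, n, col1, row1)
        if p <= p_obs * (1 + 1e-7):
            total += p
    return total


class TestClassEnrichment:
    def test_identical_distributions_null(self):
        classes = ["promoter"] * 30 + ["enhancer"] * 70
        df = class_enrichment(classes, classes)
        assert (df["odds_ratio"].loc[df["n_peaks"] > 0] == 1.0).all()
        assert (df["p_value"] == 1.0).all()

    def test_fisher_matches_enumeration_oracle(self, rng):
        assert fisher_exact_2x2([[30, 70], [10, 90]]).p_value == pytest.approx(
            brute_fisher_two_sided(30, 70, 10, 90), rel=1e-9
        )
        for _ in range(40):
            a, b, c, d = (int(x) for x in rng.integers(0, 50, size=4))
            if (a + b) == 0 or (c + d) == 0:
                continue
            assert fisher_exact_2x2([[a, b], [c, d]]).p_value == pytest.approx(
                brute_fisher_two_sided(a, b, c, d), rel=1e-8
            ), (a, b, c, d)

    def test_empty_background_rejected(self):
        with pytest.raises(ValueError, match="background"):
            class_enrichment(["promoter"], [])

    def test_planted_promoter_bias_detected(self, rng):
        """Promoter-biased peaks against a uniform background give
        OR > 1 at small p."""
        detected = 0
        for seed in range(10):
            r = np.random.default_rng(seed)
            classes = ["promoter", "enhancer", "repressed", "uncharacterized"]
            peak_cls = r.choice(classes, p=[0.55, 0.25, 0.05, 0.15], size=400)
            bg_cls = r.choice(classes, p=[0.25] * 4, size=400)
            row = class_enrichment(peak_cls, bg_cls).set_index("class").loc["promoter"]
            if row["odds_ratio"] > 1 and row["p_value"] < 0.01:
                detected += 1
        assert detected >= 10 * 0.95
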