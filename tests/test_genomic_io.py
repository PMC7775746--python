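"""I/O round trips, coordinate conventions and format validation."""

import numpy as np
import pytest

from chromact.genomic_io import (
    CoverageTrack,
    GeneModel,
    GenomicInterval,
    Pwm,
    read_bed,
    read_coverage,
    read_gene_table,
    read_jaspar,
    write_bed,
    write_coverage,
    write_gene_table,
    write_jaspar,
)
from chromact.genomic_io import BedFeature


class TestIntervals:
    def test_invariants(self):
        iv = GenomicInterval("chr1", 100, 200)
        assert iv.length == 100
        assert iv.contains(100) and not iv.contains(200)

    @pytest.mark.parametrize("start,end", [(200, 100), (100, 100), (-1, 50)])
    def test_invalid_span_rejected(self, start, end):
        with pytest.raises(ValueError):
            GenomicInterval("chr1", start, end)

    def test_half_open_overlap(self):
        a = GenomicInterval("chr1", 100, 200)
        assert a.overlaps(GenomicInterval("chr1", 199, 300))
        assert not a.overlaps(GenomicInterval("chr1", 200, 300))
        assert not a.overlaps(GenomicInterval("chr2", 100, 200))


class TestBed:
    def test_narrowpeak_summit_is_absolute(self, tmp_path):
        path = tmp_path / "a.narrowPeak"
        path.write_text("chr1\t100\t200\tp1\t0\t.\t5.0\t3.2\t2.1\t50\n")
        (feat,) = read_bed(path, "narrowPeak")
        assert feat.interval == GenomicInterval("chr1", 100, 200)
        assert feat.summit == 150

    def test_empty_file(self, tmp_path):
        path = tmp_path / "e.bed"
        path.write_text("")
        assert read_bed(path) == []

    def test_end_before_start_names_line(self, tmp_path):
        path = tmp_path / "bad.bed"
        path.write_text("chr1\t10\t20\tok\t0\t.\nchr1\t300\t200\tbad\t0\t.\n")
        with pytest.raises(ValueError, match=":2:"):
            read_bed(path)

    def test_summit_offset_past_end_rejected(self, tmp_path):
        path = tmp_path / "bad.narrowPeak"
        path.write_text("chr1\t100\t200\tp\t0\t.\t1\t1\t1\t100\n")
        with pytest.raises(ValueError, match="summit offset"):
            read_bed(path, "narrowPeak")

    def test_round_trip(self, tmp_path, rng):
        feats = []
        for i in range(30):
            start = int(rng.integers(0, 10_000))
            length = int(rng.integers(1, 500))
            iv = GenomicInterval("chr1", start, start + length)
            feats.append(
                BedFeature(iv, f"p{i}", float(i), 1.0, 2.0, 3.0,
                           start + int(rng.integers(0, length)))
            )
        path = tmp_path / "rt.narrowPeak"
        write_bed(feats, path, "narrowPeak")
        back = read_bed(path, "narrowPeak")
        assert [(f.interval, f.summit) for f in back] == [
            (f.interval, f.summit) for f in feats
        ]


class TestGeneTable:
    def test_strand_aware_tss_tes(self, tmp_path):
        path = tmp_path / "genes.tsv"
        path.write_text(
            "name\tchrom\tstrand\ttxStart\ttxEnd\tcdsStart\tcdsEnd\n"
            "gp\tchr1\t+\t1000\t5000\t1200\t4800\n"
            "gm\tchr1\t-\t1000\t5000\t1200\t4800\n"
            "nc\tchr1\t+\t1000\t5000\t1000\t1000\n"
        )
        gp, gm, nc = read_gene_table(path)
        assert (gp.tss, gp.tes) == (1000, 4999)
        assert (gm.tss, gm.tes) == (4999, 1000)
        assert not nc.is_coding and gp.is_coding

    def test_unknown_strand_rejected(self, tmp_path):
        path = tmp_path / "genes.tsv"
        path.write_text("g\tchr1\t*\t0\t100\t0\t0\n")
        with pytest.raises(ValueError, match="strand"):
            read_gene_table(path)

    def test_round_trip(self, tmp_path):
        genes = [
            GeneModel("a", "chr1", "+", 10, 500, 50, 400),
            GeneModel("a", "chr2", "-", 1000, 3000, 1000, 1000),
        ]
        path = tmp_path / "rt.tsv"
        write_gene_table(genes, path)
        assert read_gene_table(path) == genes


class TestCoverage:
    def test_round_trip_random_tracks(self, tmp_path, rng):
        for trial in range(5):
            track = CoverageTrack(
                {
                    "chrA": rng.poisson(0.5, size=int(rng.integers(50, 400))),
                    "chrB": rng.poisson(2.0, size=int(rng.integers(50, 400))),
                }
            )
            path = tmp_path / f"t{trial}.bedgraph"
            write_coverage(track, path)
            assert read_coverage(path) == track

    def test_adjacent_equal_spans_merged_on_write(self, tmp_path):
        track = CoverageTrack({"chrS": np.array([0, 3, 3, 3, 0, 0])})
        path = tmp_path / "m.bedgraph"
        write_coverage(track, path)
        lines = [l for l in path.read_text().splitlines() if not l.startswith("#")]
        assert lines == ["chrS\t1\t4\t3"]
        assert read_coverage(path) == track

    def test_overlapping_spans_rejected(self, tmp_path):
        path = tmp_path / "o.bedgraph"
        path.write_text("chr1\t0\t10\t3\nchr1\t5\t15\t2\n")
        with pytest.raises(ValueError, match="overlap"):
            read_coverage(path)

    def test_negative_value_rejected(self, tmp_path):
        path = tmp_path / "n.bedgraph"
        path.write_text("chr1\t0\t10\t-3\n")
        with pytest.raises(ValueError, match="negative"):
            read_coverage(path)

    def test_region_count_matches_slice_sum(self, rng):
        arr = rng.poisson(1.0, size=1000)
        track = CoverageTrack({"c": arr})
        for _ in range(20):
            s, e = sorted(rng.integers(0, 1000, size=2))
            assert track.region_count("c", s, e) == arr[s:e].sum()


class TestJaspar:
    def test_pseudocount_normalisation(self, tmp_path):
        path = tmp_path / "m.jaspar"
        path.write_text(
            ">M1\n"
            "A [ 10 0 0 0 ]\nC [ 0 10 0 10 ]\nG [ 0 0 10 0 ]\nT [ 0 0 0 0 ]\n"
        )
        (pwm,) = read_jaspar(path, pseudocount=1.0)
        np.testing.assert_allclose(
            pwm.matrix[0], [11 / 14, 1 / 14, 1 / 14, 1 / 14]
        )

    def test_all_equal_column_is_uniform(self, tmp_path):
        path = tmp_path / "m.jaspar"
        path.write_text(">M1\nA [ 5 5 5 5 ]\nC [ 5 5 5 5 ]\nG [ 5 5 5 5 ]\nT [ 5 5 5 5 ]\n")
        (pwm,) = read_jaspar(path)
        np.testing.assert_allclose(pwm.matrix, 0.25)

    def test_unequal_rows_rejected(self, tmp_path):
        path = tmp_path / "m.jaspar"
        path.write_text(">M1\nA [ 1 2 3 4 ]\nC [ 1 2 3 ]\nG [ 1 2 3 4 ]\nT [ 1 2 3 4 ]\n")
        with pytest.raises(ValueError, match="unequal"):
            read_jaspar(path)

    def test_missing_row_rejected(self, tmp_path):
        path = tmp_path / "m.jaspar"
        path.write_text(">M1\nA [ 1 2 3 4 ]\nC [ 1 2 3 4 ]\nG [ 1 2 3 4 ]\n")
        with pytest.raises(ValueError, match="A,C,G,T"):
            read_jaspar(path)

    def test_write_read_round_trip(self, tmp_path):
        pwm = Pwm.from_consensus("TEST", "TGACTCA", 0.85)
        path = tmp_path / "rt.jaspar"
        write_jaspar([pwm], path)
        (back,) = read_jaspar(path, pseudocount=0.0)
        assert back.consensus == pwm.consensus


class TestPwm:
    def test_short_matrix_rejected(self):
        with pytest.raises(ValueError, match="length"):
            Pwm("x", np.full((3, 4), 0.25))

    def test_columns_must_normalise(self):
        bad = np.full((6, 4), 0.3)
        with pytest.raises(ValueError, match="sum to 1"):
            Pwm("x", bad)

    def test_max_score_and_consensus(self):
        pwm = Pwm.from_consensus("x", "ACGT", 0.85)
        assert pwm.consensus == "ACGT"
        assert pwm.max_score == pytest.approx(4 * np.log2(0.85 / 0.25))
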