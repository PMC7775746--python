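"""ORF-trimmed quantification, DE calls and catalog enrichment."""

import itertools

import numpy as np
import pandas as pd
import pytest

from chromact._stats import rank_sum_test
from chromact.expression import (
    bound_vs_unbound,
    call_de,
    cancer_enrichment,
    consolidate_catalogs,
    expression_table,
    trimmed_orf_region,
    trimmed_orf_rpkm,
)
from chromact.genomic_io import CoverageTrack, GeneModel, GenomicInterval


def _gene(gene_id="g", strand="+", start=1_000, end=9_000, cds=None):
    cds_start, cds_end = cds if cds else (start + 100, end - 100)
    return GeneModel(gene_id, "chr1", strand, start, end, cds_start, cds_end)


class TestTrimming:
    def test_300bp_cds_leaves_240(self):
        g = _gene(cds=(2_000, 2_300))
        ((s, e),) = trimmed_orf_region(g)
        assert (s, e) == (2_045, 2_285)
        assert e - s == 240

    def test_minus_strand_trims_opposite_ends(self):
        g = _gene(strand="-", cds=(2_000, 2_300))
        ((s, e),) = trimmed_orf_region(g)
        # start codon sits at the high end for a minus-strand gene
        assert (s, e) == (2_015, 2_255)

    def test_cds_too_short_after_trimming_is_empty(self):
        assert trimmed_orf_region(_gene(cds=(2_000, 2_060))) == []

    def test_noncoding_gene_is_empty(self):
        assert trimmed_orf_region(_gene(cds=(1_000, 1_000))) == []

    def test_uorf_mask_subtracted(self):
        g = _gene(cds=(2_000, 3_000))
        mask = [GenomicInterval("chr1", 2_100, 2_200)]
        segments = trimmed_orf_region(g, mask)
        assert segments == [(2_045, 2_100), (2_200, 2_985)]
        assert sum(e - s for s, e in segments) == (2_985 - 2_045) - 100


class TestRpkm:
    def test_unit_definition(self):
        # 10 reads, depth 1e6, quantified region 1 kb -> RPKM = 10
        g = _gene(cds=(2_000, 3_060))  # trimmed region exactly 1000 bp
        assert sum(
            e - s for s, e in trimmed_orf_region(g)
        ) == 1_000
        arr = np.zeros(1_000_000, dtype=int)
        arr[2_500] = 10
        arr[500_000] = 1_000_000 - 10  # pad depth elsewhere
        rec = trimmed_orf_rpkm(CoverageTrack({"chr1": arr}), g)
        assert rec.rpkm == pytest.approx(10.0)
        assert not rec.filtered

    def test_fewer_than_five_reads_filtered(self):
        g = _gene(cds=(2_000, 3_060))
        arr = np.zeros(10_000, dtype=int)
        arr[2_500] = 4
        rec = trimmed_orf_rpkm(CoverageTrack({"chr1": arr}), g)
        assert rec.filtered and rec.reads == 4


class TestDeCalls:
    def _records(self, folds):
        return pd.DataFrame(
            {
                "gene_id": [f"g{i}" for i in range(len(folds))],
                "rpkm_etoh": 10.0,
                "rpkm_tam": [10 * f if f == f else np.nan for f in folds],
                "fold_change": folds,
                "filtered": [f != f for f in folds],
            }
        )

    def test_twofold_boundary_inclusive(self):
        out = call_de(self._records([2.0, 1.99, 0.5, 0.51, np.nan]))
        assert list(out["de_status"]) == [
            "up", "unchanged", "down", "unchanged", "filtered",
        ]

    def test_status_partition_exhaustive(self, rng):
        folds = rng.lognormal(0, 1, size=200)
        folds[rng.integers(0, 200, size=20)] = np.nan
        out = call_de(self._records(list(folds)))
        counts = out["de_status"].value_counts()
        assert counts.sum() == 200
        assert set(counts.index) <= {"up", "down", "unchanged", "filtered"}


class TestBoundVsUnbound:
    def test_exact_small_sample_p(self):
        res = rank_sum_test([1, 2, 3], [4, 5, 6])
        assert res.p_value == pytest.approx(0.1)

    def test_identical_distributions_near_one(self):
        res = rank_sum_test(np.arange(30), np.arange(30) + 0.5)
        assert res.p_value > 0.5

    def test_empty_group_rejected(self):
        records = pd.DataFrame(
            {
                "gene_id": ["a", "b"],
                "rpkm_etoh": [1.0, 2.0],
                "rpkm_tam": [1.0, 2.0],
                "fold_change": [1.0, 1.0],
                "filtered": [False, False],
            }
        )
        with pytest.raises(ValueError, match="empty"):
            bound_vs_unbound(records, {"a", "b"})

    def test_enumeration_oracle_random_cases(self, rng):
        """Rank-sum p equals full-split enumeration for n <= 12."""
        for _ in range(10):
            nx, ny = int(rng.integers(3, 7)), int(rng.integers(3, 7))
            vals = rng.permutation(np.arange(1.0, nx + ny + 1))
            x, y = list(vals[:nx]), list(vals[nx:])
            pooled = sorted(x + y)
            ranks = {v: i + 1 for i, v in enumerate(pooled)}
            obs = sum(ranks[v] for v in x)
            mean = nx * (nx + ny + 1) / 2
            stats_all = [
                sum(c)
                for c in itertools.combinations(range(1, nx + ny + 1), nx)
            ]
            exact = sum(
                1 for s in stats_all if abs(s - mean) >= abs(obs - mean) - 1e-9
            ) / len(stats_all)
            assert rank_sum_test(x, y).p_value == pytest.approx(exact)


class TestCatalogs:
    def test_both_roles_become_oncotsg(self):
        out = consolidate_catalogs([({"g1"}, "ONG"), ({"g1"}, "TSG")])
        assert out["g1"] == "OncoTSG"

    def test_disjoint_sources_keep_sizes(self):
        out = consolidate_catalogs(
            [({"a", "b"}, "ONG"), ({"c"}, "TSG")], universe={"a", "b", "c", "d"}
        )
        assert out.value_counts().to_dict() == {
            "ONG": 2, "TSG": 1, "NonCancer": 1,
        }

    def test_matches_set_algebra_oracle_and_idempotent(self, rng):
        genes = [f"g{i}" for i in range(60)]
        sources = []
        for _ in range(5):
            members = {g for g in genes if rng.random() < 0.3}
            sources.append((members, "ONG" if rng.random() < 0.5 else "TSG"))
        out = consolidate_catalogs(sources)
        ong = set().union(*(m for m, r in sources if r == "ONG"), set())
        tsg = set().union(*(m for m, r in sources if r == "TSG"), set())
        for g in ong | tsg:
            expected = (
                "OncoTSG" if g in ong and g in tsg
                else "ONG" if g in ong else "TSG"
            )
            assert out[g] == expected
        rng.shuffle(sources)
        assert consolidate_catalogs(sources).equals(out)


class TestCancerEnrichment:
    def test_targets_equal_universe_is_null(self):
        catalog = pd.Series({"a": "ONG", "b": "TSG"})
        universe = {"a", "b", "c", "d"}
        df = cancer_enrichment(catalog, universe, universe).set_index("label")
        assert (df["p_value"] == 1.0).all()
        assert df.loc["ONG", "fraction_of_targets"] == 0.25

    def test_targets_outside_universe_rejected(self):
        with pytest.raises(ValueError, match="subset"):
            cancer_enrichment(pd.Series(dtype=object), {"x"}, {"a"})


class TestExpressionTable:
    def test_from_counts(self):
        genes = [_gene("g1", cds=(2_000, 3_060)), _gene("g2", cds=(2_000, 3_060))]
        counts = pd.DataFrame(
            {"gene_id": ["g1", "g2"], "reads_etoh": [100, 4], "reads_tam": [400, 50]}
        )
        out = expression_table(
            counts, genes, {"etoh": 1_000_000, "tam": 2_000_000}
        )
        assert out.loc[0, "rpkm_etoh"] == pytest.approx(100.0)
        assert out.loc[0, "rpkm_tam"] == pytest.approx(200.0)
        assert out.loc[0, "fold_change"] == pytest.approx(2.0)
        assert bool(out.loc[1, "filtered"])  # 4 raw reads in EtOH
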