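import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from deepsav.gts import (
    GeneVariantSet,
    count_deleterious,
    gene_tolerance_table,
    gts_score,
    maf_category,
    percentile_and_decile,
    spectrum_shares,
    summarize_maf_spectrum,
)


class TestMafCategory:
    @pytest.mark.parametrize(
        "maf,label",
        [
            (0.05, "common"),
            (0.00005, "rare"),
            (0.0001, "low"),  # left-closed boundary
            (0.001, "medium"),
            (0.01, "common"),
            (0.00999, "medium"),
            (1.0, "common"),
        ],
    )
    def test_boundaries(self, maf, label):
        assert maf_category(maf) == label

    @pytest.mark.parametrize("maf", [0.0, -0.1, 1.5])
    def test_out_of_range(self, maf):
        with pytest.raises(ValueError):
            maf_category(maf)

    @given(st.floats(1e-9, 1.0))
    @settings(max_examples=100, deadline=None)
    def test_partition(self, maf):
        # every valid MAF maps to exactly one category
        assert maf_category(maf) in {"rare", "low", "medium", "common"}


class TestSpectrum:
    def test_printed_counts_reproduce_published_shares(self):
        # gnomAD-scale worked example: 27,813 common and 4,588,805 rare
        # of 4,885,239 total SAVs
        counts = {"rare": 4_588_805, "low": 215_132, "medium": 53_489, "common": 27_813}
        shares = spectrum_shares(counts).set_index("category")["percent"]
        assert shares["common"] == pytest.approx(0.57, abs=0.005)
        assert shares["rare"] == pytest.approx(94.0, abs=0.1)
        assert shares.sum() == pytest.approx(100.0, abs=1e-9)

    def test_single_variant_catalog(self):
        table = summarize_maf_spectrum([0.5])
        assert table.set_index("category").loc["common", "percent"] == 100.0
        assert table["count"].sum() == 1


class TestGTS:
    def test_no_rare_savs_is_zero(self):
        gvs = GeneVariantSet("G", 100, [0.9, 0.8], [0.5, 0.01])
        assert gts_score(gvs) == 0.0

    def test_single_rare_sav_formula(self):
        gvs = GeneVariantSet("G", 100, [0.8], [5e-5])
        assert gts_score(gvs) == pytest.approx(0.8 * 5e-5 / 100)

    def test_matches_bruteforce_sum(self):
        rng = np.random.default_rng(3)
        scores = rng.random(30)
        mafs = 10 ** rng.uniform(-6, -1, 30)
        gvs = GeneVariantSet("G", 250, scores, mafs)
        expected = sum(s * m for s, m in zip(scores, mafs) if m < 1e-4) / 250
        assert gts_score(gvs) == pytest.approx(expected, abs=1e-15)

    def test_removing_rare_sav_never_increases(self):
        rng = np.random.default_rng(4)
        scores = rng.random(10)
        mafs = 10 ** rng.uniform(-6, -4.1, 10)
        full = gts_score(GeneVariantSet("G", 100, scores, mafs))
        for k in range(10):
            reduced = gts_score(
                GeneVariantSet("G", 100, np.delete(scores, k), np.delete(mafs, k))
            )
            assert reduced <= full + 1e-18

    def test_invariant_to_common_variants(self):
        base = GeneVariantSet("G", 50, [0.9], [1e-5])
        extended = GeneVariantSet("G", 50, [0.9, 1.0, 1.0], [1e-5, 0.2, 1e-4])
        assert gts_score(base) == gts_score(extended)

    def test_invalid_protein_len(self):
        with pytest.raises(ValueError):
            GeneVariantSet("G", 0, [], [])


class TestCountDeleterious:
    def test_strict_threshold(self):
        gvs = GeneVariantSet("G", 10, [0.75, 0.76], [1e-5, 1e-5])
        assert count_deleterious(gvs) == 1

    def test_empty(self):
        assert count_deleterious(GeneVariantSet("G", 10, [], [])) == 0

    def test_rare_filter(self):
        gvs = GeneVariantSet("G", 10, [0.9], [0.5])
        assert count_deleterious(gvs, rare_only=True) == 0
        assert count_deleterious(gvs, rare_only=False) == 1


class TestPercentileDecile:
    def test_endpoints(self):
        gts = np.array([5.0, 1.0, 3.0, 2.0, 4.0])
        pct, dec = percentile_and_decile(gts)
        assert pct[1] == 0.0 and dec[1] == 0
        assert pct[0] == 1.0 and dec[0] == 9

    def test_ties_share_first_occurrence_percentile(self):
        gts = np.array([1.0, 2.0, 2.0, 3.0])
        pct, _ = percentile_and_decile(gts)
        # sort-and-scan oracle: count of strictly smaller / (n-1)
        for x, p in zip(gts, pct):
            assert p == pytest.approx(sum(v < x for v in gts) / 3)
        assert pct[1] == pct[2]

    def test_matches_sort_and_scan_oracle(self):
        rng = np.random.default_rng(11)
        gts = rng.integers(0, 40, size=100).astype(float)  # many ties
        pct, dec = percentile_and_decile(gts)
        n = len(gts)
        for x, p, d in zip(gts, pct, dec):
            expected = sum(v < x for v in gts) / (n - 1)
            assert p == pytest.approx(expected)
            assert d == min(int(expected * 10 + 1e-12), 9)

    def test_decile_histogram_near_uniform(self):
        rng = np.random.default_rng(12)
        gts = rng.random(1000)
        _, dec = percentile_and_decile(gts)
        counts = np.bincount(dec, minlength=10)
        assert counts.min() >= 99 and counts.max() <= 101

    def test_single_gene_rejected(self):
        with pytest.raises(ValueError):
            percentile_and_decile(np.array([1.0]))


class TestGeneToleranceTable:
    def test_pipeline_table(self):
        scored = pd.DataFrame(
            {
                "gene": ["A", "A", "B"],
                "position": [1, 2, 1],
                "wt": ["A", "C", "D"],
                "mut": ["C", "D", "E"],
                "maf": [1e-5, 0.5, 2e-5],
                "deepsav_score": [0.9, 0.9, 0.1],
            }
        )
        table = gene_tolerance_table(scored, {"A": 100, "B": 200, "C": 50})
        assert list(table.columns) == [
            "gene", "gts", "percentile", "decile", "n_rare_savs", "n_deleterious",
        ]
        by_gene = table.set_index("gene")
        assert by_gene.loc["A", "gts"] == pytest.approx(0.9 * 1e-5 / 100)
        assert by_gene.loc["C", "gts"] == 0.0  # no variants
        assert by_gene.loc["A", "n_deleterious"] == 1
        assert (table["gts"].diff().dropna() >= 0).all()  # ascending order

    def test_duplicates_keep_max_maf(self):
        scored = pd.DataFrame(
            {
                "gene": ["A", "A"],
                "position": [1, 1],
                "wt": ["A", "A"],
                "mut": ["C", "C"],
                "maf": [1e-5, 3e-5],
                "deepsav_score": [0.5, 0.5],
            }
        )
        table = gene_tolerance_table(scored, {"A": 10, "B": 10})
        assert table.set_index("gene").loc["A", "n_rare_savs"] == 1
        assert table.set_index("gene").loc["A", "gts"] == pytest.approx(0.5 * 3e-5 / 10)
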