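"""Normalization, decrease bins, and the hit-calling cascade."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import adhescreen as a
from tests.conftest import make_quant_table


class TestPercentNeg:
    def test_neg_median_maps_to_exactly_100(self, quant_table_factory):
        df = quant_table_factory([1.0, 3.0], neg_ratios=(1.8, 2.0, 2.2, 2.4))
        norm = a.normalize_percent_neg(df)
        neg = norm[norm.content_class == "neg_ctrl_scrambled"]
        assert float(neg["normalized"].median()) == 100.0

    def test_well_at_neg_median_normalizes_to_100(self, quant_table_factory):
        df = quant_table_factory([2.0], neg_ratios=(2.0, 2.0, 2.0, 2.0))
        norm = a.normalize_percent_neg(df)
        row = norm[norm.content_class == "gene_pool"].iloc[0]
        assert row["normalized"] == 100.0
        assert row["decrease_pct"] == 0.0

    def test_zero_ratio_full_decrease(self, quant_table_factory):
        df = quant_table_factory([0.0])
        row = a.normalize_percent_neg(df).query("content_class == 'gene_pool'").iloc[0]
        assert row["normalized"] == 0.0
        assert row["decrease_pct"] == 100.0

    def test_plate_effect_cancels(self, quant_table_factory):
        d1 = quant_table_factory([1.0, 2.5], plate_id="P001")
        d2 = quant_table_factory([1.0, 2.5], plate_id="P002")
        for col in ("bac_nuc_ratio",):
            d2[col] = d2[col] * 2.0
        norm = a.normalize_percent_neg(pd.concat([d1, d2], ignore_index=True))
        v1 = norm[norm.plate_id == "P001"].sort_values("well")["normalized"].to_numpy()
        v2 = norm[norm.plate_id == "P002"].sort_values("well")["normalized"].to_numpy()
        assert np.allclose(v1, v2)

    @settings(derandomize=True, max_examples=30)
    @given(g=st.floats(min_value=1e-6, max_value=1e6, allow_nan=False))
    def test_positive_scalar_invariance(self, g):
        df = make_quant_table([0.5, 1.0, 3.3], neg_ratios=(1.7, 2.1, 2.3, 2.9))
        base = a.normalize_percent_neg(df)["normalized"].to_numpy()
        scaled_df = df.copy()
        scaled_df["bac_nuc_ratio"] = scaled_df["bac_nuc_ratio"] * g
        scaled = a.normalize_percent_neg(scaled_df)["normalized"].to_numpy()
        assert np.max(np.abs(base - scaled)) < 1e-9 * np.max(np.abs(base))

    def test_flagged_wells_dropped_before_median(self, quant_table_factory):
        df = quant_table_factory([2.0], neg_ratios=(2.0, 2.0, 50.0))
        df.loc[df.bac_nuc_ratio == 50.0, "flags"] = "zero_nuclei"
        norm = a.normalize_percent_neg(df)
        assert norm.query("content_class == 'gene_pool'").iloc[0]["normalized"] == 100.0
        assert 50.0 not in norm["bac_nuc_ratio"].values

    def test_no_usable_negatives_is_plate_error(self, quant_table_factory):
        df = quant_table_factory([1.0], neg_ratios=())
        with pytest.raises(a.NormalizationError):
            a.normalize_percent_neg(df)

    def test_zero_median_is_plate_error(self, quant_table_factory):
        df = quant_table_factory([1.0], neg_ratios=(0.0, 0.0, 0.0))
        with pytest.raises(a.NormalizationError):
            a.normalize_percent_neg(df)


class TestFoldAbBlock:
    def test_abblock_median_maps_to_exactly_1(self, quant_table_factory):
        df = quant_table_factory([1.0], ab_ratios=(0.08, 0.1, 0.12, 0.14))
        norm = a.normalize_fold_abblock(df)
        ab = norm[norm.content_class == "ab_block"]
        assert float(ab["normalized"].median()) == 1.0

    def test_zero_ratio_maps_to_zero_fold(self, quant_table_factory):
        df = quant_table_factory([0.0])
        row = a.normalize_fold_abblock(df).query("content_class == 'gene_pool'").iloc[0]
        assert row["normalized"] == 0.0

    def test_negatives_sit_far_above_block_floor(self, small_library):
        truth = a.sample_ground_truth(small_library, receptor_fraction=0.0, seed=8)
        plates = a.layout_plates(small_library, pooled=False, controls_per_plate=32)
        df = a.simulate_screen_counts(plates, truth, a.RenderSpec(), seed=8)
        norm = a.normalize_fold_abblock(df)
        neg_fold = norm.query("content_class == 'neg_ctrl_scrambled'")["normalized"]
        assert neg_fold.median() >= 0.5 / truth.abblock_residual

    def test_decreases_referenced_to_neg_controls(self, quant_table_factory):
        df = quant_table_factory([1.0, 2.0], neg_ratios=(2.0, 2.0, 2.0, 2.0))
        norm = a.normalize_fold_abblock(df)
        samples = norm[norm.content_class == "gene_pool"].sort_values("well")
        assert samples["decrease_pct"].tolist() == pytest.approx([50.0, 0.0])


class TestBins:
    def test_hand_binned_example(self, quant_table_factory):
        # decreases 80, 60, 30, 10 -> one well per bin plus remainder
        df = quant_table_factory([0.4, 0.8, 1.4, 1.8], neg_ratios=(2.0,) * 4)
        bins = a.bin_decreases(a.normalize_percent_neg(df))
        assert (bins.gt70, bins.b50_70, bins.b25_50, bins.remainder) == (1, 1, 1, 1)

    def test_no_decrease_all_remainder(self, quant_table_factory):
        df = quant_table_factory([2.0, 2.0], neg_ratios=(2.0,) * 4)
        bins = a.bin_decreases(a.normalize_percent_neg(df))
        assert (bins.gt70, bins.b50_70, bins.b25_50) == (0, 0, 0)
        assert bins.remainder == 2

    def test_boundary_70_goes_to_middle_bin(self, quant_table_factory):
        df = quant_table_factory([0.6], neg_ratios=(2.0,) * 4)  # decrease exactly 70
        bins = a.bin_decreases(a.normalize_percent_neg(df))
        assert bins.b50_70 == 1 and bins.gt70 == 0

    def test_wrong_mode_rejected(self, quant_table_factory):
        norm = a.normalize_fold_abblock(quant_table_factory([1.0]))
        with pytest.raises(ValueError):
            a.bin_decreases(norm)

    @settings(derandomize=True, max_examples=25)
    @given(
        ratios=st.lists(
            st.floats(min_value=0.0, max_value=6.0, allow_nan=False), min_size=1, max_size=30
        )
    )
    def test_bins_partition_all_wells(self, ratios):
        df = make_quant_table(list(ratios))
        bins = a.bin_decreases(a.normalize_percent_neg(df))
        assert bins.total == len(ratios)


class TestPrimaryHits:
    def test_decrease_above_threshold_is_hit(self, quant_table_factory):
        # normalized 66 -> decrease 34 -> hit at the 30% rule
        df = quant_table_factory({"GENEA": 1.32}, neg_ratios=(2.0,) * 4)
        res = a.call_primary_hits(a.normalize_percent_neg(df), a.DEFAULT_ROUNDS[0])
        assert res.iloc[0]["hit"] and res.iloc[0]["mean_decrease_pct"] == pytest.approx(34.0)

    def test_boundary_decrease_is_not_hit(self, quant_table_factory):
        df = quant_table_factory({"GENEA": 1.4}, neg_ratios=(2.0,) * 4)  # exactly 30
        res = a.call_primary_hits(a.normalize_percent_neg(df), a.DEFAULT_ROUNDS[0])
        assert not res.iloc[0]["hit"]

    def test_increased_adhesion_is_not_hit(self, quant_table_factory):
        df = quant_table_factory({"GENEA": 2.6}, neg_ratios=(2.0,) * 4)  # normalized 130
        res = a.call_primary_hits(a.normalize_percent_neg(df), a.DEFAULT_ROUNDS[0])
        assert not res.iloc[0]["hit"]

    def test_sorted_by_decrease_with_gene_tiebreak(self, quant_table_factory):
        df = quant_table_factory(
            {"GB": 1.0, "GA": 1.0, "GC": 0.5}, neg_ratios=(2.0,) * 4
        )
        res = a.call_primary_hits(a.normalize_percent_neg(df), a.DEFAULT_ROUNDS[0])
        assert res["gene_id"].tolist() == ["GC", "GA", "GB"]

    def test_duplicate_gene_rows_rejected(self, quant_table_factory):
        df = quant_table_factory([1.0, 1.0])
        df.loc[df.content_class == "gene_pool", "gene_id"] = "GENEA"
        with pytest.raises(ValueError):
            a.call_primary_hits(a.normalize_percent_neg(df), a.DEFAULT_ROUNDS[0])


class TestConcordanceHits:
    def _norm(self, per_sirna, factory):
        df = factory(
            {g: v for g, v in per_sirna.items()},
            neg_ratios=(2.0,) * 4,
            content_class="gene_single",
        )
        return a.normalize_percent_neg(df)

    def test_two_of_three_is_hit(self, quant_table_factory):
        norm = self._norm({"GENEA": [1.3, 1.2, 1.9]}, quant_table_factory)  # 35, 40, 5
        res = a.call_concordance_hits(norm, a.DEFAULT_ROUNDS[1])
        assert res.iloc[0]["support"] == 2 and res.iloc[0]["hit"]

    def test_one_of_three_is_not_hit(self, quant_table_factory):
        norm = self._norm({"GENEA": [1.3, 1.9, 1.9]}, quant_table_factory)  # 35, 5, 5
        res = a.call_concordance_hits(norm, a.DEFAULT_ROUNDS[1])
        assert res.iloc[0]["support"] == 1 and not res.iloc[0]["hit"]

    def test_zero_decrease_zero_support(self, quant_table_factory):
        norm = self._norm({"GENEA": [2.0, 2.0, 2.0]}, quant_table_factory)
        res = a.call_concordance_hits(norm, a.DEFAULT_ROUNDS[1])
        assert res.iloc[0]["support"] == 0 and not res.iloc[0]["hit"]

    def test_more_wells_than_duplexes_rejected(self, quant_table_factory):
        norm = self._norm({"GENEA": [1.0, 1.0, 1.0, 1.0]}, quant_table_factory)
        with pytest.raises(ValueError):
            a.call_concordance_hits(norm, a.DEFAULT_ROUNDS[1])

    @pytest.mark.parametrize(
        "threshold,min_support", [(30.0, 2), (20.0, 2), (30.0, 1), (10.0, 1)]
    )
    def test_relaxing_never_removes_hits(self, quant_table_factory, threshold, min_support):
        norm = self._norm(
            {"GA": [1.3, 1.2, 1.9], "GB": [1.5, 1.9, 1.9], "GC": [0.4, 0.6, 1.9]},
            quant_table_factory,
        )
        strict = a.call_concordance_hits(norm, a.RoundSpec(2, "percent_neg", 30.0, 2, 3))
        relaxed = a.call_concordance_hits(
            norm, a.RoundSpec(2, "percent_neg", threshold, min_support, 3)
        )
        strict_hits = set(strict.loc[strict.hit, "gene_id"])
        relaxed_hits = set(relaxed.loc[relaxed.hit, "gene_id"])
        assert strict_hits <= relaxed_hits


class TestCascade:
    def _tables(self, factory, round3_ratios):
        r1 = a.normalize_percent_neg(factory({"GA": 0.5}, neg_ratios=(2.0,) * 4))
        r2 = a.normalize_percent_neg(
            factory(
                {"GA": [1.0, 1.1, 1.9]}, neg_ratios=(2.0,) * 4, content_class="gene_single"
            )
        )
        r3 = a.normalize_fold_abblock(
            factory(
                {"GA": round3_ratios},
                neg_ratios=(2.0,) * 4,
                ab_ratios=(0.1,) * 4,
                content_class="gene_single",
            )
        )
        return [r1, r2, r3]

    def test_full_support_survives_to_candidate(self, quant_table_factory):
        res = a.run_cascade(self._tables(quant_table_factory, [1.0, 1.1, 1.9, 1.9, 1.9]))
        assert res.candidates == ["GA"]
        assert res.funnel == [1, 1, 1]

    def test_round3_attrition_drops_gene(self, quant_table_factory):
        # hit in rounds 1-2 but only 1/5 concordant duplexes in round 3
        res = a.run_cascade(self._tables(quant_table_factory, [1.0, 1.9, 1.9, 1.9, 1.9]))
        assert res.candidates == []
        assert res.funnel == [1, 1, 0]

    def test_empty_first_round_empty_cascade(self, quant_table_factory):
        r1 = a.normalize_percent_neg(quant_table_factory({"GA": 2.0}))  # no hits
        empty = r1[r1.content_class == "missing"]
        res = a.run_cascade([r1, empty, empty])
        assert res.candidates == []
        assert res.funnel == [0, 0, 0]

    def test_foreign_gene_in_later_round_rejected(self, quant_table_factory):
        tables = self._tables(quant_table_factory, [1.0] * 5)
        rogue = a.normalize_percent_neg(
            quant_table_factory(
                {"GZ": [1.0, 1.0, 1.9]}, neg_ratios=(2.0,) * 4, content_class="gene_single"
            )
        )
        with pytest.raises(ValueError):
            a.run_cascade([tables[0], rogue, tables[2]])

    def test_funnel_monotone_on_synthetic_screen(self):
        rep = a.run_all(a.RunConfig(seed=21))
        assert rep.funnel[0] >= rep.funnel[1] >= rep.funnel[2]
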