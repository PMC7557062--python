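import numpy as np
import pandas as pd
import pytest

from savbind import data_model as dm
from savbind import enrichment_analysis as ea
from savbind import synthetic_data as sd
from savbind.enrichment_analysis import GroupKey


class TestBackground19:
    def test_pool_size_is_19_per_position(self):
        positions = pd.DataFrame({"protein_id": ["P1", "P1"], "position": [1, 2]})
        scores = pd.DataFrame(
            {
                "protein_id": ["P1"] * 38,
                "position": [1] * 19 + [2] * 19,
                "alt_aa": list("CDEFGHIKLMNPQRSTVWY") + list("ADEFGHIKLMNPQRSTVWY"),
                "snap2_score": list(range(19)) * 2,
            }
        )
        pooled = ea.build_background_19(positions, scores)
        assert len(pooled) == 38

    def test_duplicate_substitution_rejected(self):
        positions = pd.DataFrame({"protein_id": ["P1"], "position": [1]})
        scores = pd.DataFrame(
            {
                "protein_id": ["P1"] * 19,
                "position": [1] * 19,
                "alt_aa": ["C"] * 2 + list("DEFGHIKLMNPQRSTVW"),
                "snap2_score": range(19),
            }
        )
        with pytest.raises(ValueError, match="P1:1"):
            ea.build_background_19(positions, scores)

    def test_wrong_count_rejected(self):
        positions = pd.DataFrame({"protein_id": ["P1"], "position": [1]})
        scores = pd.DataFrame(
            {"protein_id": ["P1"] * 5, "position": [1] * 5,
             "alt_aa": list("CDEFG"), "snap2_score": range(5)}
        )
        with pytest.raises(ValueError, match="expected 19"):
            ea.build_background_19(positions, scores)

    def test_pooled_mean_matches_generator(self, bundle, joined):
        pooled = ea.build_background_19(
            joined, bundle["background_scores"], bundle["residue_annotations"]
        )
        expected = bundle["bookkeeping"]["expected_background_mean"]
        se = pooled["snap2_score"].std() / np.sqrt(len(pooled))
        assert abs(pooled["snap2_score"].mean() - expected) < 3 * se + 0.5  # +discretization

    def test_positions_weight_equally_regardless_of_sav_multiplicity(self, bundle, joined):
        pooled = ea.build_background_19(
            joined, bundle["background_scores"], bundle["residue_annotations"]
        )
        n_positions = joined[["protein_id", "position"]].drop_duplicates().shape[0]
        assert len(pooled) == 19 * n_positions


class TestContingency:
    def test_four_savs_unit_table(self, tiny_table):
        t = ea.build_contingency(tiny_table, "protein")
        assert t.as_tuple() == (1, 1, 1, 1)

    def test_unknown_status_excluded(self, tiny_table):
        t2 = tiny_table.copy()
        extra = t2.iloc[[0]].assign(position=9, protein_status="unknown",
                                    dna_status="unknown", rna_status="unknown")
        t = ea.build_contingency(pd.concat([t2, extra], ignore_index=True), "any")
        assert t.total == 4

    def test_cells_sum_to_filtered_size(self, joined):
        t = ea.build_contingency(joined, "any")
        assert t.total == len(joined)

    def test_effect_filter_applied_before_counting(self, tiny_table):
        t = ea.build_contingency(tiny_table, "protein", effect_min=0)
        assert t.as_tuple() == (1, 0, 1, 0)

    def test_degenerate_empty_class_rejected(self, tiny_table):
        only_common = tiny_table[tiny_table["freq_class"] == "common"]
        with pytest.raises(ValueError, match="degenerate"):
            ea.build_contingency(only_common, "protein")

    def test_reliability_filter_keeps_confident_calls_of_both_signs(self):
        t = pd.DataFrame(
            {
                "freq_class": ["common", "common", "rare", "rare"],
                "snap2_score": [10, 10, 10, 10],
                "protein_score": [80, 20, -70, -10],  # confident: rows 0 and 2
                "protein_status": ["binding", "binding", "other", "other"],
                "dna_status": ["other"] * 4,
                "rna_status": ["other"] * 4,
            }
        )
        tab = ea.build_contingency(t, "protein", binding_reliability_min=50)
        assert tab.as_tuple() == (1, 0, 0, 1)


class TestCumulativeCurve:
    def test_one_at_lower_bound(self, rng):
        scores = rng.integers(-100, 101, 500)
        c = ea.cumulative_curve(scores)
        assert c.fraction_at_or_above[0] == 1.0

    def test_all_zero_scores(self):
        c = ea.cumulative_curve([0, 0, 0])
        assert c.fraction_at_or_above[c.thresholds.tolist().index(1)] == 0.0
        assert c.fraction_at_or_above[c.thresholds.tolist().index(0)] == 1.0

    def test_half_at_median_threshold(self):
        c = ea.cumulative_curve([-50, 0, 50, 100])
        assert c.fraction_at_or_above[c.thresholds.tolist().index(50)] == 0.5

    def test_non_increasing(self, rng):
        c = ea.cumulative_curve(rng.integers(-100, 101, 1000))
        assert (np.diff(c.fraction_at_or_above) <= 1e-15).all()

    def test_exclusive_variant_differs_only_at_grid_hits(self):
        c_in = ea.cumulative_curve([0, 50], inclusive=True)
        c_ex = ea.cumulative_curve([0, 50], inclusive=False)
        i = c_in.thresholds.tolist().index(50)
        assert c_in.fraction_at_or_above[i] == 0.5
        assert c_ex.fraction_at_or_above[i] == 0.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            ea.cumulative_curve([])


class TestBindingFraction:
    def test_point_estimate(self, tiny_table):
        t = pd.concat([tiny_table] * 5, ignore_index=True)
        t["position"] = range(len(t))
        est = ea.binding_fraction(t, "protein", n_replicates=50, seed=0)
        assert est.point == pytest.approx(0.5)

    def test_all_binding_zero_se(self, tiny_table):
        t = tiny_table[tiny_table["protein_status"] == "binding"]
        t = pd.concat([t] * 5, ignore_index=True)
        est = ea.binding_fraction(t, "protein", n_replicates=50, seed=0)
        assert est.point == 1.0 and est.std_error == 0.0

    def test_recovers_planted_rate(self, bundle, joined):
        est = ea.binding_fraction(joined, "any", n_replicates=200, seed=3)
        planted = bundle["bookkeeping"]["binding_fraction_positions"]
        assert abs(est.point - planted) < 4 * max(est.std_error, 1e-3)


class TestCompareGroups:
    def test_identical_groups(self, joined):
        key = GroupKey("rare", "any")
        ks, ca, cb = ea.compare_groups(joined, key, key)
        assert ks.d_statistic == 0.0

    def test_empty_group_error_names_group(self, tiny_table):
        with pytest.raises(ValueError, match="common"):
            ea.compare_groups(
                tiny_table, GroupKey("common", "any", effect_min=99),
                GroupKey("rare", "any"),
            )

    def test_background_group_requires_pool(self, tiny_table):
        with pytest.raises(ValueError, match="19-non-native"):
            ea.extract_group_scores(tiny_table, GroupKey("background", "any"))

    def test_planted_shift_detected_with_correct_sign(self, joined):
        # generator plants binding scores above non-binding scores
        ks, _, _ = ea.compare_groups(
            joined, GroupKey("rare", "any"), GroupKey("rare", "non_binding")
        )
        assert ks.p_value < 1e-6
        assert ks.d_signed < 0  # binding group shifted toward higher scores


class TestMultiBindingPartition:
    def test_exclusive_and_complete(self, joined):
        parts = ea.multi_binding_partition(joined)
        n_binding = int(joined["any_binding"].sum())
        combo_total = sum(
            len(v) for k, v in parts.items() if k != "non_binding"
        )
        assert combo_total == n_binding
        assert combo_total + len(parts["non_binding"]) == len(joined)

    def test_triple_binder_only_in_triple_cell(self):
        t = pd.DataFrame(
            {
                "snap2_score": [10],
                "protein_status": ["binding"],
                "dna_status": ["binding"],
                "rna_status": ["binding"],
            }
        )
        parts = ea.multi_binding_partition(t)
        assert len(parts["protein+dna+rna"]) == 1
        assert all(len(v) == 0 for k, v in parts.items() if k != "protein+dna+rna")

    def test_planted_multi_binding_shift_recovered(self):
        sm = sd.ScoreModel(multi_binding_bonus=25.0)
        cfg = sd.GeneratorConfig(n_savs=30_000, score_model=sm, seed=11)
        v, _ = sd.generate_variants(cfg)
        eff, _, ann, _ = sd.generate_scores(cfg, v)
        table, _ = dm.join_annotations(v, eff, ann)
        parts = ea.multi_binding_partition(table)
        triple = parts["protein+dna+rna"].mean()
        singles = [parts[c].mean() for c in ("protein", "dna", "rna")]
        assert all(triple > s for s in singles)
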