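"""Single-cell aggregation, outlier removal, thresholds and the rule
engine, checked against brute-force loops and planted truth."""

import numpy as np
import pandas as pd
import pytest

from mifpipe.errors import ConfigurationError
from mifpipe.phenotypes import PhenotypeRule, default_rules
from mifpipe.profiling import (SingleCellTable, aggregate_cell_signals,
                               assign_phenotypes, call_positivity,
                               concat_tables, log_transform,
                               positivity_thresholds, remove_outliers_mad,
                               zscore_matrix)


def table_from_values(values, markers=None):
    values = np.asarray(values, dtype=float)
    if values.ndim == 1:
        values = values[:, None]
    markers = markers or [f"m{i}" for i in range(values.shape[1])]
    n = len(values)
    df = pd.DataFrame({"cell_id": np.arange(1, n + 1), "fov": 0,
                       "area": 10, "centroid_r": 0.0, "centroid_c": 0.0})
    for i, m in enumerate(markers):
        df[m] = values[:, i]
    return SingleCellTable(df, markers)


class TestAggregation:
    def test_uniform_cell_mean(self):
        inst = np.zeros((8, 8), dtype=np.int32)
        inst[2:5, 2:5] = 1
        img = np.where(inst == 1, 7.0, 99.0)
        t = aggregate_cell_signals(inst, {"m": img})
        assert t.data.loc[0, "m"] == pytest.approx(7.0)
        assert t.data.loc[0, "area"] == 9

    def test_matches_explicit_pixel_loop(self, rng):
        inst = np.zeros((32, 32), dtype=np.int32)
        inst[3:10, 3:10] = 1
        inst[15:28, 12:20] = 2
        inst[25:30, 25:31] = 3
        img = rng.random((32, 32)) * 100
        t = aggregate_cell_signals(inst, {"m": img})
        for k in (1, 2, 3):
            expected = img[inst == k].mean()
            assert t.data.loc[k - 1, "m"] == pytest.approx(expected,
                                                           abs=1e-9)

    def test_mask_additivity_of_means(self, rng):
        """Splitting a cell's pixel set in two and area-weight-averaging
        the two means reproduces the whole-cell mean."""
        inst_whole = np.zeros((16, 16), dtype=np.int32)
        inst_whole[4:12, 4:12] = 1
        inst_split = inst_whole.copy()
        inst_split[4:12, 8:12] = 2
        img = rng.random((16, 16))
        whole = aggregate_cell_signals(inst_whole, {"m": img}).data
        split = aggregate_cell_signals(inst_split, {"m": img}).data
        a1, a2 = split["area"]
        recombined = (split.loc[0, "m"] * a1 + split.loc[1, "m"] * a2) \
            / (a1 + a2)
        assert recombined == pytest.approx(whole.loc[0, "m"], abs=1e-9)

    def test_empty_instance_map_gives_empty_table(self):
        t = aggregate_cell_signals(np.zeros((4, 4), dtype=np.int32),
                                   {"m": np.zeros((4, 4))})
        assert len(t) == 0

    def test_shape_mismatch_raises(self):
        with pytest.raises(ValueError, match="match"):
            aggregate_cell_signals(np.zeros((4, 4), dtype=np.int32),
                                   {"m": np.zeros((4, 5))})


class TestMadOutlierRemoval:
    def test_hand_computed_example(self):
        # median 3, MAD 1 -> cutoff 3 + 5*1 = 8; 100 removed
        t, removed = remove_outliers_mad(table_from_values([1, 2, 3, 4, 100]),
                                         k=5)
        assert removed == [5]
        assert len(t) == 4

    def test_mad_zero_with_planted_outlier(self):
        t, removed = remove_outliers_mad(table_from_values([1, 1, 1, 1, 100]),
                                         k=5)
        assert removed == [5]

    def test_all_equal_column_removes_nothing(self):
        t, removed = remove_outliers_mad(table_from_values([3, 3, 3, 3]), k=5)
        assert removed == []

    def test_symmetric_data_untouched(self):
        t, removed = remove_outliers_mad(
            table_from_values([1, 2, 3, 4, 5, 6, 7]), k=5)
        assert removed == []

    def test_low_side_never_removed(self):
        t, removed = remove_outliers_mad(
            table_from_values([-100, 1, 2, 3, 4]), k=5)
        assert removed == []

    def test_removal_count_monotone_in_k(self, rng):
        values = rng.lognormal(0, 1, 200)
        counts = [len(remove_outliers_mad(table_from_values(values), k=k)[1])
                  for k in (1, 2, 3, 5, 8)]
        assert counts == sorted(counts, reverse=True)

    def test_requires_three_cells(self):
        with pytest.raises(ValueError):
            remove_outliers_mad(table_from_values([1, 2]))


class TestLogTransform:
    def test_ln_e_is_one(self):
        t = log_transform(table_from_values([np.e - 1e-6]))
        assert t.data["m0"].iloc[0] == pytest.approx(1.0)

    def test_zero_maps_to_log_pseudocount(self):
        t = log_transform(table_from_values([0.0]))
        assert t.data["m0"].iloc[0] == pytest.approx(np.log(1e-6))

    def test_double_transform_rejected(self):
        t = log_transform(table_from_values([1.0, 2.0]))
        with pytest.raises(ValueError, match="raw"):
            log_transform(t)

    def test_monotone(self, rng):
        v = rng.random(50) * 100
        t = log_transform(table_from_values(v))
        assert np.array_equal(np.argsort(v), np.argsort(t.data["m0"]))


class TestPositivity:
    def test_mean_minus_3sd_formula(self):
        # mean 2.0, sd 0.5 -> threshold 0.5
        v = np.array([1.5, 2.5, 1.5, 2.5])
        t = table_from_values(v)
        t.transform_state = "log"
        thr = positivity_thresholds(t)
        assert thr["m0"] == pytest.approx(2.0 - 3 * 0.5)

    def test_constant_marker_all_negative_by_strict_comparison(self):
        t = table_from_values([2.0, 2.0, 2.0])
        t.transform_state = "log"
        thr = positivity_thresholds(t)
        pos = call_positivity(t, thr)
        assert not pos["m0"].any()

    def test_translation_invariance(self, rng):
        v = rng.normal(0, 1, 100)
        t1 = table_from_values(v)
        t1.transform_state = "log"
        t2 = table_from_values(v + 7.5)
        t2.transform_state = "log"
        thr1 = positivity_thresholds(t1)
        thr2 = positivity_thresholds(t2)
        assert thr2["m0"] - thr1["m0"] == pytest.approx(7.5)
        assert call_positivity(t1, thr1).equals(call_positivity(t2, thr2))

    def test_single_cell_table_rejected(self):
        t = table_from_values([1.0])
        t.transform_state = "log"
        with pytest.raises(ValueError):
            positivity_thresholds(t)

    def test_guarded_otsu_separates_planted_mixture(self, rng):
        on = rng.normal(8.0, 0.3, 40)
        off = rng.normal(4.0, 0.3, 160)
        t = table_from_values(np.concatenate([on, off]))
        t.transform_state = "log"
        thr = positivity_thresholds(t, method="otsu")
        pos = call_positivity(t, thr)["m0"].to_numpy()
        assert pos[:40].all() and not pos[40:].any()


class TestPhenotypeRules:
    def _table(self, positive_sets):
        markers = ["CD45", "CK56", "CD3", "CD4", "CD8", "CD56", "CD20",
                   "CD11b", "CD66b", "CD68", "CD11c"]
        n = len(positive_sets)
        t = table_from_values(np.zeros((n, len(markers))), markers)
        t.transform_state = "log"
        t.positivity = pd.DataFrame(
            [{m: m in s for m in markers} for s in positive_sets])
        return t

    def test_cd4_t_cell_combination(self):
        t = self._table([{"CD45", "CD3", "CD4"}])
        assert assign_phenotypes(t).iloc[0] == "CD4+ T cells"

    def test_neutrophil_combination(self):
        t = self._table([{"CD45", "CD11b", "CD66b"}])
        assert assign_phenotypes(t).iloc[0] == "Neutrophils"

    def test_cd45_negative_is_unassigned(self):
        t = self._table([{"CD3", "CD4", "CD20", "CD68"}])
        assert assign_phenotypes(t).iloc[0] == "unassigned"

    def test_first_match_wins_for_ambiguous_cells(self):
        # CD68+ and CD66b+ cell: neutrophil rule precedes macrophage
        t = self._table([{"CD45", "CD11b", "CD66b", "CD68"}])
        assert assign_phenotypes(t).iloc[0] == "Neutrophils"

    def test_generic_immune_fallback(self):
        t = self._table([{"CD45"}])
        assert assign_phenotypes(t).iloc[0] == "Immune cells"

    def test_rule_with_unknown_marker_rejected(self):
        t = self._table([{"CD45"}])
        bad = [PhenotypeRule("X cells", {"CD45", "CD999"}, set())]
        with pytest.raises(ConfigurationError, match="CD999"):
            assign_phenotypes(t, bad)


class TestZScore:
    def test_columns_standardized(self, rng):
        t = table_from_values(rng.random((30, 2)) * 50)
        t.transform_state = "log"
        z = zscore_matrix(t)
        assert np.allclose(z.mean(axis=0), 0.0, atol=1e-12)
        assert np.allclose(z.std(axis=0, ddof=0), 1.0, atol=1e-12)

    def test_constant_column_is_zero(self):
        t = table_from_values(np.full((5, 1), 3.0))
        t.transform_state = "log"
        assert (zscore_matrix(t)["m0"] == 0).all()

    def test_three_cell_hand_example(self):
        t = table_from_values([1.0, 2.0, 3.0])
        t.transform_state = "log"
        z = zscore_matrix(t)["m0"].to_numpy()
        sd = np.sqrt(2.0 / 3.0)
        assert z == pytest.approx([-1 / sd, 0.0, 1 / sd])


class TestPlantedPhenotypeRecovery:
    def test_rule_engine_recovers_planted_phenotypes(self):
        """End to end with ground-truth masks: aggregate true images,
        threshold, gate — planted phenotypes come back."""
        from mifpipe.preprocess import preprocess_dataset
        from mifpipe.profiling import profile_cells
        from mifpipe.synth import SyntheticConfig, generate_dataset

        cfg = SyntheticConfig(n_cycles=4, n_fovs=1, n_channels_per_cycle=4,
                              image_shape=(512, 512), n_cells=200,
                              max_shift=0, seed=17)
        ds, gt = generate_dataset(cfg)
        quant = preprocess_dataset(ds, normalize=False)
        stacks = {0: {quant.marker(j, c):
                      np.asarray(quant.pair(0, j, c).stain.pixels)
                      for j in range(4) for c in range(4)}}
        table = profile_cells(gt.instance_maps, stacks, mad_k=None,
                              threshold_method="otsu")
        merged = table.data.assign(phenotype=table.phenotypes.values).merge(
            gt.cell_tables[0], on="cell_id", suffixes=("", "_gt"))
        agree = (merged["phenotype"] == merged["phenotype_gt"]).mean()
        assert agree >= 0.99
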