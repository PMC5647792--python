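import itertools

import numpy as np
import pandas as pd
import pytest

from lipidq import qcfilter
from lipidq.qcfilter import FilterReport
from lipidq.simcohort import SimConfig, generate_cohort

from conftest import make_table


class TestFeatureQcStats:
    def test_hand_computed_qc_stats(self):
        # QC values [100, 110, 90] -> mean 100, sd 10, rsd 10%
        table, samples = make_table(
            [[100.0, 110.0, 90.0, 50.0, 60.0, 70.0]], qc_cols=[0, 1, 2]
        )
        stats = qcfilter.compute_feature_qc(table, samples)
        assert stats.loc["F0", "mean_qc"] == pytest.approx(100.0)
        assert stats.loc["F0", "sd_qc"] == pytest.approx(10.0)
        assert stats.loc["F0", "rsd_qc"] == pytest.approx(10.0)

    def test_snr_definition(self):
        # sd_study/sd_qc: study [50,60,70] sd=10 vs qc sd 10 -> 1; scale study x0.5
        table, samples = make_table(
            [[100.0, 110.0, 90.0, 55.0, 60.0, 65.0]], qc_cols=[0, 1, 2]
        )
        stats = qcfilter.compute_feature_qc(table, samples)
        assert stats.loc["F0", "snr"] == pytest.approx(5.0 / 10.0)

    def test_all_qc_missing_flagged_undefined(self):
        table, samples = make_table(
            [[np.nan, np.nan, np.nan, 50.0, 60.0, 70.0]], qc_cols=[0, 1, 2]
        )
        stats = qcfilter.compute_feature_qc(table, samples)
        assert stats.loc["F0", "undefined"]
        assert np.isnan(stats.loc["F0", "rsd_qc"])

    def test_missing_cells_excluded(self):
        table, samples = make_table(
            [[100.0, np.nan, 110.0, 90.0, 1.0, 2.0, 3.0]], qc_cols=[0, 1, 2, 3]
        )
        stats = qcfilter.compute_feature_qc(table, samples)
        assert stats.loc["F0", "det_rate_qc"] == pytest.approx(3 / 4)
        assert stats.loc["F0", "mean_qc"] == pytest.approx(100.0)


class TestDetectionFilter:
    def _table(self, qc_missing, study_missing):
        vals = np.full((1, 10), 100.0)
        for j in qc_missing:
            vals[0, j] = np.nan
        for j in study_missing:
            vals[0, j] = np.nan
        return make_table(vals, qc_cols=[0, 1, 2, 3])

    def test_below_qc_threshold_removed(self):
        # 2/4 QCs missing -> det_rate_qc = 0.5 retained; 3/4 -> 0.25 removed
        table, samples = self._table([0, 1, 2], [])
        _, rep = qcfilter.filter_by_detection(table, samples)
        assert rep.n_removed == 1

    def test_boundary_rates_retained(self):
        # det_rate_qc exactly 0.5 and study rate well above 0.2: retained
        table, samples = self._table([0, 1], [])
        out, rep = qcfilter.filter_by_detection(table, samples)
        assert rep.n_removed == 0 and out.n_features == 1

    def test_fully_observed_all_retained(self, small_cohort):
        _, table, samples, _ = small_cohort
        full = table.with_values(table.intensities.fillna(1000.0))
        _, rep = qcfilter.filter_by_detection(full, samples)
        assert rep.n_removed == 0


class TestKnnImputation:
    def test_complete_table_identity(self):
        table, _ = make_table(np.random.default_rng(0).uniform(10, 20, (5, 6)))
        out = qcfilter.impute_knn(table, k=2)
        pd.testing.assert_frame_equal(out.intensities, table.intensities)

    def test_single_neighbor_copies_value(self):
        vals = np.array([[10.0, 20.0, np.nan], [10.0, 20.0, 30.0]])
        table, _ = make_table(vals)
        out = qcfilter.impute_knn(table, k=1)
        assert out.intensities.loc["F0", "I2"] == pytest.approx(30.0)

    def test_brute_force_neighbor_oracle(self):
        """Imputed cell equals the mean over the k nearest rows found by
        exhaustive mutual-overlap distance search."""
        rng = np.random.default_rng(4)
        vals = rng.uniform(100, 10000, (12, 8))
        holes = [(0, 3), (5, 1), (9, 7), (2, 0)]
        for i, j in holes:
            vals[i, j] = np.nan
        table, _ = make_table(vals)
        k = 3
        out = qcfilter.impute_knn(table, k=k)

        log_vals = np.log2(vals)
        for i, j in holes:
            dists = []
            for other in range(12):
                if other == i:
                    continue
                both = ~np.isnan(log_vals[i]) & ~np.isnan(log_vals[other])
                if not both.any() or np.isnan(vals[other, j]):
                    continue
                d = np.sqrt(np.sum((log_vals[i, both] - log_vals[other, both]) ** 2))
                dists.append((d, other))
            expected = np.mean([vals[o, j] for _, o in sorted(dists)[:k]])
            assert out.intensities.iloc[i, j] == pytest.approx(expected, rel=1e-12)

    def test_imputed_value_within_neighbor_range(self, small_cohort):
        _, table, samples, _ = small_cohort
        filtered, _ = qcfilter.filter_by_detection(table, samples)
        out = qcfilter.impute_knn(filtered, samples, k=10)
        assert not out.intensities.isna().any().any()
        missing = filtered.intensities.isna()
        col_max = filtered.intensities.max(axis=0)
        col_min = filtered.intensities.min(axis=0)
        filled = out.intensities[missing]
        assert ((filled.le(col_max, axis=1) | filled.isna()).all().all())
        assert ((filled.ge(col_min, axis=1) | filled.isna()).all().all())

    def test_all_missing_feature_errors(self):
        vals = np.array([[np.nan, np.nan], [1.0, 2.0], [3.0, 4.0]])
        table, _ = make_table(vals)
        with pytest.raises(ValueError, match="no observed values"):
            qcfilter.impute_knn(table, k=1)


class TestRetentionAndCleanRules:
    def _one_feature(self, qc, study):
        vals = np.array([list(qc) + list(study)], dtype=float)
        return make_table(vals, qc_cols=list(range(len(qc))))

    @pytest.mark.parametrize(
        "scale, kept",
        [(0.299, True), (0.300, False), (0.0, True)],
        ids=["rsd 29.9 retained", "rsd 30.0 removed", "constant qc retained"],
    )
    def test_rsd_boundary_is_strict(self, scale, kept):
        # symmetric QC triple {100-d, 100, 100+d}: mean 100, sample sd d
        d = scale * 100.0
        qc = [100.0 - d, 100.0, 100.0 + d]
        table, samples = self._one_feature(qc, [1.0, 2.0, 3.0])
        out, rep = qcfilter.filter_by_qc_rsd(table, samples)
        assert (rep.n_removed == 0) is kept

    def test_snr_below_one_removed(self):
        # study sd 5 vs qc sd 10
        table, samples = self._one_feature([90.0, 100.0, 110.0], [95.0, 100.0, 105.0])
        _, rep = qcfilter.clean_snr(table, samples)
        assert rep.n_removed == 1 and "SNR" in list(rep.removed.values())[0]

    def test_snr_boundary_equal_sds_retained(self):
        table, samples = self._one_feature([90.0, 100.0, 110.0], [90.0, 100.0, 110.0])
        _, rep = qcfilter.clean_snr(table, samples)
        assert rep.n_removed == 0

    def test_mean_shift_removed(self):
        # mean_qc 200 vs mean_study 100, sd_study 30 -> 100 > 90 removed
        table, samples = self._one_feature([200.0, 200.0, 200.0], [70.0, 100.0, 130.0])
        _, rep = qcfilter.clean_mean_shift(table, samples)
        assert rep.n_removed == 1

    def test_mean_shift_boundary_exact_retained(self):
        # |diff| exactly 3 x sd_study -> retained (strict greater-than)
        study = [70.0, 100.0, 130.0]  # mean 100, sd 30
        table, samples = self._one_feature([190.0, 190.0, 190.0], study)
        _, rep = qcfilter.clean_mean_shift(table, samples)
        assert rep.n_removed == 0

    def test_snr_clean_removes_constructed_noise_features(self):
        cfg = SimConfig(n_features=60, seed=13, drift_amplitude=0.0, n_batches=1,
                        mcar_rate=0.0, mnar_strength=0.0, frac_noise_features=0.2)
        table, samples, truth = generate_cohort(cfg)
        out, rep = qcfilter.clean_snr(table, samples)
        noise_ids = set(truth.features.index[truth.features["is_noise"]])
        assert noise_ids <= set(rep.removed)


class TestFilterAccounting:
    def test_report_conservation_enforced(self):
        with pytest.raises(ValueError):
            FilterReport(stage="x", n_input=10, n_removed=3, n_retained=6)

    def test_chained_summary(self):
        r1 = FilterReport("a", 100, 10, 90, {f"f{i}": "r" for i in range(10)})
        r2 = FilterReport("b", 90, 5, 85, {f"g{i}": "r" for i in range(5)})
        total = qcfilter.summarize_filters([r1, r2])
        assert total.n_input == 100 and total.n_removed == 15 and total.n_retained == 85
        assert total.pct_removed == 15.0

    def test_inconsistent_chaining_errors(self):
        r1 = FilterReport("a", 100, 10, 90)
        r2 = FilterReport("b", 80, 5, 75)
        with pytest.raises(ValueError, match="inconsistent chaining"):
            qcfilter.summarize_filters([r1, r2])

    def test_single_stage_identity(self):
        r1 = FilterReport("a", 50, 2, 48)
        total = qcfilter.summarize_filters([r1])
        assert (total.n_input, total.n_removed, total.n_retained) == (50, 2, 48)
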