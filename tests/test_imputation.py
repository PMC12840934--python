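"""Gap segmentation, the three imputation protocols, and test purity."""

import numpy as np
import pandas as pd
import pytest

import basalwatch as bw
from basalwatch.imputation import ImputationError, imputable_mask


def _series(observed_days, n_days=12, rid="R0", channel="TEMP", values=None):
    """One resident-channel daily series with nulls outside observed_days."""
    dates = pd.date_range("2018-01-01", periods=n_days)
    vals = {d: (values or {}).get(d, 36.5 + 0.01 * d) for d in observed_days}
    return pd.DataFrame(
        {
            "resident_id": rid,
            "date": dates,
            "channel": channel,
            "value": [vals.get(i, np.nan) for i in range(n_days)],
            "observed": [i in observed_days for i in range(n_days)],
            "imputed": False,
        }
    )


class TestSegmentGaps:
    @pytest.mark.parametrize(
        "observed,expected_segments",
        [
            ({0, 1, 2, 8, 9}, 2),   # 5-day gap > 4 splits
            ({0, 1, 2, 7, 8}, 1),   # 4-day gap <= 4 stays whole
            (set(range(12)), 1),     # fully observed
        ],
    )
    def test_split_rule(self, observed, expected_segments):
        segments = bw.segment_gaps(_series(observed), max_gap=4)
        assert len(segments) == expected_segments

    def test_segment_bounds_are_observed_days(self):
        segments = bw.segment_gaps(_series({0, 1, 2, 8, 9}), max_gap=4)
        spans = {(s.start_date.day, s.end_date.day) for s in segments}
        assert spans == {(1, 3), (9, 10)}  # calendar days of Jan

    def test_long_gap_days_never_imputable(self):
        vitals = _series({0, 1, 2, 8, 9})
        mask = imputable_mask(vitals, max_gap=4)
        assert not mask.any()  # the only gap is 5 days long

    def test_short_gap_days_imputable(self):
        vitals = _series({0, 1, 5})
        mask = imputable_mask(vitals, max_gap=4)
        assert list(vitals.loc[mask, "date"].dt.day) == [3, 4, 5]


class TestMeanImputation:
    def test_fills_with_training_mean(self):
        vitals = _series({0, 2}, n_days=3, values={0: 5.0, 2: 7.0})
        out = bw.impute(vitals, bw.ImputationConfig(method="MEAN"))
        assert out.loc[1, "value"] == 6.0
        assert bool(out.loc[1, "imputed"]) is True

    def test_observed_cells_bitwise_unchanged(self, small_cohort):
        out = bw.impute(small_cohort.vitals, bw.ImputationConfig(method="MEAN"))
        obs = small_cohort.vitals["observed"]
        assert (
            out.loc[obs, "value"].to_numpy()
            == small_cohort.vitals.loc[obs, "value"].to_numpy()
        ).all()

    def test_long_gaps_stay_null(self, small_cohort):
        out = bw.impute(small_cohort.vitals, bw.ImputationConfig(method="MEAN"))
        eligible = imputable_mask(small_cohort.vitals, 4)
        originally_null = small_cohort.vitals["value"].isna()
        assert out.loc[originally_null & ~eligible, "value"].isna().all()
        assert not out.loc[originally_null & ~eligible, "imputed"].any()

    def test_training_mean_preserved(self, small_cohort):
        cfg = bw.ImputationConfig(method="MEAN")
        out = bw.impute(small_cohort.vitals, cfg)
        for ch in bw.CHANNELS:
            pre = small_cohort.vitals.query("channel == @ch")["value"].mean()
            filled = out.query("channel == @ch and imputed")["value"]
            if len(filled):
                assert filled.to_numpy() == pytest.approx(pre)

    def test_no_training_data_for_channel_errors(self):
        vitals = _series({0, 1, 5})
        train = pd.Series(False, index=vitals.index)  # nothing to fit on
        with pytest.raises(ImputationError, match="TEMP"):
            bw.impute(vitals, bw.ImputationConfig(method="MEAN"), train_mask=train)


class TestKnnImputation:
    def test_identical_donor_with_k1(self):
        # target day: TEMP missing, other channels match the donor day exactly
        rows = []
        day = pd.Timestamp("2018-01-02")
        donor_day = pd.Timestamp("2018-01-01")
        anchor_day = pd.Timestamp("2018-01-03")  # anchors the gap so it is fillable
        for ch, donor_val, target_val, anchor_val in [
            ("TEMP", 37.5, np.nan, 36.0),
            ("SPO2", 95.0, 95.0, 99.0),
            ("BPM", 70.0, 70.0, 95.0),
            ("EDA", 2.0, 2.0, 4.0),
        ]:
            rows.append({"resident_id": "R0", "date": donor_day, "channel": ch,
                         "value": donor_val, "observed": True, "imputed": False})
            rows.append({"resident_id": "R0", "date": day, "channel": ch,
                         "value": target_val, "observed": not np.isnan(target_val),
                         "imputed": False})
            rows.append({"resident_id": "R0", "date": anchor_day, "channel": ch,
                         "value": anchor_val, "observed": True, "imputed": False})
        vitals = pd.DataFrame(rows)
        out = bw.impute(vitals, bw.ImputationConfig(method="KNN", knn_k=1))
        got = out.query("channel == 'TEMP' and date == @day")["value"].iloc[0]
        assert got == pytest.approx(37.5)


class TestMiceImputation:
    def test_recovers_linear_relation(self):
        """Chained equations on channels generated with an exact y=2x relation
        fill the missing y values within 5% relative error."""
        rng = np.random.default_rng(42)
        n = 120
        dates = pd.date_range("2018-01-01", periods=n)
        x = rng.uniform(1, 3, n)
        y = 2 * x
        missing_y = rng.random(n) < 0.2
        missing_y[:2] = False  # keep anchors so every gap is short
        rows = []
        for i, d in enumerate(dates):
            rows.append({"resident_id": "R0", "date": d, "channel": "EDA",
                         "value": x[i], "observed": True, "imputed": False})
            rows.append({"resident_id": "R0", "date": d, "channel": "BPM",
                         "value": np.nan if missing_y[i] else y[i],
                         "observed": not missing_y[i], "imputed": False})
        vitals = pd.DataFrame(rows)
        out = bw.impute(
            vitals, bw.ImputationConfig(method="MICE", mice_draws=5, seed=1)
        )
        filled = out.query("channel == 'BPM' and imputed")
        assert len(filled) > 10
        expect = 2 * out.query("channel == 'EDA'").set_index("date")["value"]
        rel_err = (
            (filled.set_index("date")["value"] - expect.loc[filled["date"]])
            .abs() / expect.loc[filled["date"]]
        )
        assert (rel_err < 0.05).all()


class TestLeakageGuard:
    @pytest.mark.parametrize("method", ["MEAN", "KNN", "MICE"])
    def test_nontrain_corruption_cannot_change_train_fills(self, method, small_cohort):
        vitals = small_cohort.vitals.reset_index(drop=True)
        residents = sorted(vitals["resident_id"].unique())
        train_res = set(residents[: len(residents) // 2])
        train_mask = vitals["resident_id"].isin(train_res)
        cfg = bw.ImputationConfig(method=method, seed=3)
        base = bw.impute(vitals, cfg, small_cohort.profiles, train_mask)
        corrupted = vitals.copy()
        bad = ~train_mask & corrupted["value"].notna()
        corrupted.loc[bad, "value"] = corrupted.loc[bad, "value"] + 500.0
        redo = bw.impute(corrupted, cfg, small_cohort.profiles, train_mask)
        fills = base["imputed"] & train_mask
        assert np.allclose(
            base.loc[fills, "value"].to_numpy(),
            redo.loc[fills, "value"].to_numpy(),
        )


class TestPurity:
    def _samples(self, n_imputed_counts):
        return pd.DataFrame(
            {
                "sample_id": [f"s{i}" for i in range(len(n_imputed_counts))],
                "resident_id": "R0",
                "n_imputed": n_imputed_counts,
            }
        )

    def test_all_observed_passes(self):
        report = bw.assert_test_purity(self._samples([0, 0, 0]))
        assert report.passed and report.violations == []

    def test_planted_imputed_cell_is_flagged(self):
        report = bw.assert_test_purity(self._samples([0, 3, 0]))
        assert not report.passed
        assert report.violations == ["s1"]

    def test_empty_test_fold_vacuous_pass(self):
        samples = self._samples([5, 5])
        folds = pd.Series(dtype=float)  # nobody assigned to a test fold
        report = bw.assert_test_purity(samples, folds)
        assert report.passed and report.n_tested == 0
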