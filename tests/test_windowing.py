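"""Event segmentation, lead/lag windows, causal integrity, balancing."""

import numpy as np
import pandas as pd
import pytest

import basalwatch as bw
from basalwatch.windowing import WindowSpec


def _diagnoses(infected_spans, n_days=60, rid="R0"):
    """infected_spans: list of (start_day, end_day, category) inclusive."""
    dates = pd.date_range("2018-01-01", periods=n_days)
    rows = []
    for i, d in enumerate(dates):
        status, cat = "HEALTHY", None
        for lo, hi, c in infected_spans:
            if lo <= i <= hi:
                status, cat = "INFECTED", c
        rows.append({"resident_id": rid, "date": d, "status": status, "category": cat})
    return pd.DataFrame(rows)


class TestSegmentEvents:
    def test_short_gap_merges_into_one_event(self):
        diag = _diagnoses([(10, 12, "ARI"), (21, 22, "ARI")])  # gap 9 < 15
        events = bw.segment_events(diag, washout=15)
        assert len(events) == 1
        assert events.iloc[0]["t0"] == pd.Timestamp("2018-01-11")  # day index 10

    def test_long_gap_separates_two_events(self):
        diag = _diagnoses([(10, 12, "ARI"), (28, 29, "UTI")])  # gap 16 >= 15
        events = bw.segment_events(diag, washout=15)
        assert len(events) == 2
        assert list(events["category"]) == ["ARI", "UTI"]

    def test_overlapping_day_excluded(self):
        diag = _diagnoses([(10, 15, "ARI")])
        extra = _diagnoses([(15, 15, "UTI")])
        both = pd.concat([diag[diag["status"] == "INFECTED"], extra[extra["status"] == "INFECTED"]])
        events = bw.segment_events(both, washout=15)
        assert len(events) == 1
        assert events.iloc[0]["end"] == pd.Timestamp("2018-01-15")  # day 14, not 15

    def test_post_segmentation_spacing_invariant(self, small_cohort):
        events = bw.segment_events(small_cohort.diagnoses, washout=15)
        for _, group in events.groupby("resident_id"):
            g = group.sort_values("start")
            gaps = (g["start"] - g["end"].shift()).dropna().dt.days
            assert (gaps >= 15).all()


class TestLagExternal:
    def _signals(self, n=10):
        return pd.DataFrame(
            {
                "date": pd.date_range("2018-01-01", periods=n),
                "signal_name": "kw_resp_1",
                "value": np.arange(n, dtype=float),
                "source": "SOCIAL",
            }
        )

    def test_zero_shift_is_identity(self):
        signals = self._signals()
        pd.testing.assert_frame_equal(bw.lag_external(signals, 0), signals)

    def test_value_moves_forward_by_shift(self):
        signals = self._signals()
        shifted = bw.lag_external(signals, 2).set_index("date")["value"]
        # source value at day 5 (index 4, value 4.0) lands on day 7
        assert shifted[pd.Timestamp("2018-01-07")] == 4.0

    def test_leading_days_are_null(self):
        shifted = bw.lag_external(self._signals(), 3).sort_values("date")
        assert shifted["value"].iloc[:3].isna().all()
        assert shifted["value"].iloc[3:].notna().all()


@pytest.fixture(scope="module")
def dense_samples(dense_cohort):
    events = bw.segment_events(dense_cohort.diagnoses)
    q = bw.quantize_cohort(dense_cohort.vitals, dense_cohort.diagnoses)
    samples, skip = bw.build_samples(
        dense_cohort, events, WindowSpec(lead=5, lag=3), "SOCIAL",
        quantized=q, seed=9,
    )
    return events, q, samples, skip


class TestBuildSamples:
    def test_accounting_identity(self, dense_samples):
        _, _, samples, skip = dense_samples
        assert skip["emitted"] + skip["skipped_boundary"] + skip["skipped_sparse"] == skip["attempted"]
        assert skip["emitted"] == len(samples)

    def test_causal_integrity_perturbing_excluded_interval(self, dense_cohort):
        """Corrupting every vital in (T_t, T0] leaves event feature vectors
        bit-identical — the central causal guarantee."""
        events = bw.segment_events(dense_cohort.diagnoses)
        q = bw.quantize_cohort(dense_cohort.vitals, dense_cohort.diagnoses)
        spec = WindowSpec(lead=5, lag=3)
        base, _ = bw.build_samples(dense_cohort, events, spec, "BASIC", quantized=q, seed=1)

        corrupted = dense_cohort.copy()
        vit = corrupted.vitals
        for _, ev in events.iterrows():
            t_pred = ev["t0"] - pd.Timedelta(days=spec.lag)
            mask = (
                (vit["resident_id"] == ev["resident_id"])
                & (vit["date"] > t_pred)
                & (vit["date"] <= ev["t0"])
            )
            vit.loc[mask, "value"] = 12345.0
        redo, _ = bw.build_samples(corrupted, events, spec, "BASIC", quantized=q, seed=1)
        ev_base = base[base["kind"] == "event"].reset_index(drop=True)
        ev_redo = redo[redo["kind"] == "event"].reset_index(drop=True)
        feature_cols = bw.feature_columns(base)
        pd.testing.assert_frame_equal(ev_base[feature_cols], ev_redo[feature_cols])

    def test_boundary_event_skipped(self):
        spec = bw.CohortSpec(n_residents=2, n_days=40, seed=2, missing_rate=0.0,
                             infection_rate=0.0)
        cohort = bw.generate_cohort(spec)
        dates = spec.dates
        events = pd.DataFrame([
            {"resident_id": "R000", "t0": dates[4], "category": "ARI",
             "start": dates[4], "end": dates[6]},
        ])
        samples, skip = bw.build_samples(
            cohort, events, WindowSpec(lead=5, lag=3), "BASIC",
            seed=0, max_healthy_per_resident=0,
        )
        assert skip["skipped_boundary"] == 1 and len(samples) == 0

    def test_healthy_windows_avoid_event_washout(self, dense_samples):
        events, _, samples, _ = dense_samples
        healthy = samples[samples["kind"] == "healthy"]
        for _, s in healthy.iterrows():
            w_lo = s["prediction_date"] - pd.Timedelta(days=5)
            w_hi = s["prediction_date"]
            for _, ev in events[events["resident_id"] == s["resident_id"]].iterrows():
                b_lo = ev["start"] - pd.Timedelta(days=15)
                b_hi = ev["end"] + pd.Timedelta(days=15)
                assert w_hi < b_lo or w_lo > b_hi

    def test_event_samples_anchor_at_t0_minus_lag(self, dense_samples):
        events, _, samples, _ = dense_samples
        ev_samples = samples[samples["kind"] == "event"]
        anchors = set(zip(ev_samples["resident_id"], ev_samples["prediction_date"]))
        expected = set(
            zip(events["resident_id"], events["t0"] - pd.Timedelta(days=3))
        )
        assert anchors <= expected

    def test_scenario_controls_external_features(self, dense_cohort):
        events = bw.segment_events(dense_cohort.diagnoses)
        basic, _ = bw.build_samples(dense_cohort, events, WindowSpec(5, 2), "BASIC", seed=0)
        social, _ = bw.build_samples(dense_cohort, events, WindowSpec(5, 2), "SOCIAL", seed=0)
        pollution, _ = bw.build_samples(dense_cohort, events, WindowSpec(5, 2), "POLLUTION", seed=0)
        assert not any(c.startswith("kw_") for c in basic.columns)
        assert any(c.startswith("kw_") for c in social.columns)
        assert any(c.startswith("NO2") for c in pollution.columns)
        assert not any(c.startswith("kw_") for c in pollution.columns)

    def test_observed_only_build_ignores_imputed_cells(self, small_cohort):
        vitals = bw.impute(small_cohort.vitals, bw.ImputationConfig(method="MEAN"))
        cohort = small_cohort.copy()
        cohort.vitals = vitals
        events = bw.segment_events(cohort.diagnoses)
        obs, _ = bw.build_samples(cohort, events, WindowSpec(5, 2), "BASIC",
                                  seed=3, use="observed")
        assert (obs["n_imputed"] == 0).all()


class TestUndersample:
    def _samples(self, n_healthy, n_infected):
        return pd.DataFrame(
            {
                "sample_id": [f"s{i}" for i in range(n_healthy + n_infected)],
                "label_binary": ["HEALTHY"] * n_healthy + ["INFECTED"] * n_infected,
            }
        )

    def test_downsamples_majority_to_minority(self):
        out = bw.undersample(self._samples(120, 45), seed=1)
        assert out["label_binary"].value_counts().to_dict() == {
            "HEALTHY": 45, "INFECTED": 45,
        }

    def test_balanced_input_unchanged_membership(self):
        samples = self._samples(30, 30)
        out = bw.undersample(samples, seed=2)
        assert set(out["sample_id"]) == set(samples["sample_id"])

    def test_deterministic_per_seed(self):
        samples = self._samples(100, 20)
        a = bw.undersample(samples, seed=7)
        b = bw.undersample(samples, seed=7)
        pd.testing.assert_frame_equal(a, b)

    def test_single_class_errors(self):
        with pytest.raises(ValueError, match="classes"):
            bw.undersample(self._samples(10, 0), seed=0)
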