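"""Causally valid sample construction on the resident timeline.

Each labeled sample is anchored at a prediction point ``T_t``. For an
infection event diagnosed at ``T0``, ``T_t = T0 - lag`` (the anticipation
horizon) and the feature vector is derived exclusively from the closed
window ``[T_t - lead, T_t]``: everything in ``(T_t, T0]`` — the overt
deterioration immediately preceding diagnosis — is strictly excluded, so
the classifier can only react to early prodromal variation. Consecutive
infected-day runs of one resident count as distinct events only when
separated by a washout period (15 days by default); days carrying two
simultaneous diagnoses are dropped as noisy labels. Healthy samples are
drawn from days whose windows stay at least a washout away from every
event of that resident.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .synthetic import CHANNELS, SyntheticCohort

DEFAULT_WASHOUT = 15
MULTICLASS_CODES = {"HEALTHY": 0, "ARI": 1, "UTI": 2, "OTHER": 3}

SCENARIOS = ("BASIC", "POLLUTION", "SOCIAL")
_SCENARIO_SOURCES = {
    "BASIC": (),
    "POLLUTION": ("POLLUTION", "METEO"),
    "SOCIAL": ("SOCIAL",),
}


@dataclass(frozen=True)
class WindowSpec:
    """Lead (historical observation window) and lag (anticipation horizon)."""

    lead: int
    lag: int

    def __post_init__(self) -> None:
        if self.lead < 1:
            raise ValueError(f"lead must be >= 1, got {self.lead}")
        if self.lag < 0:
            raise ValueError(f"lag must be >= 0, got {self.lag}")


def segment_events(
    diagnoses: pd.DataFrame, washout: int = DEFAULT_WASHOUT
) -> pd.DataFrame:
    """Merge infected-day runs into distinct infection events.

    Days labeled with more than one category simultaneously are excluded
    before segmentation. Runs of one resident separated by fewer than
    ``washout`` days are merged into a single event whose ``t0`` is the
    first diagnosis day and whose category is that of the first run.
    Returns one row per event: resident_id, t0, category, start, end.
    """
    infected = diagnoses[diagnoses["status"] == "INFECTED"].copy()
    if len(infected) == 0:
        return pd.DataFrame(columns=["resident_id", "t0", "category", "start", "end"])
    infected["date"] = pd.to_datetime(infected["date"])
    # Overlap rule: same resident-day with >1 distinct category is dropped.
    ncat = infected.groupby(["resident_id", "date"])["category"].nunique()
    overlapping = set(ncat[ncat > 1].index)
    if overlapping:
        key = pd.MultiIndex.from_frame(infected[["resident_id", "date"]])
        infected = infected[~key.isin(overlapping)]
    infected = infected.drop_duplicates(["resident_id", "date"]).sort_values(
        ["resident_id", "date"]
    )

    events = []
    for rid, group in infected.groupby("resident_id"):
        dates = group["date"].to_numpy()
        cats = group["category"].to_numpy()
        runs = []  # (start, end, category)
        start = prev = dates[0]
        cat = cats[0]
        for d, c in zip(dates[1:], cats[1:]):
            if (d - prev) / np.timedelta64(1, "D") == 1:
                prev = d
            else:
                runs.append((start, prev, cat))
                start = prev = d
                cat = c
        runs.append((start, prev, cat))
        # washout merge
        merged = [list(runs[0])]
        for start, end, cat in runs[1:]:
            gap = (start - merged[-1][1]) / np.timedelta64(1, "D")
            if gap < washout:
                merged[-1][1] = end
            else:
                merged.append([start, end, cat])
        for start, end, cat in merged:
            events.append(
                {
                    "resident_id": rid,
                    "t0": pd.Timestamp(start),
                    "category": cat,
                    "start": pd.Timestamp(start),
                    "end": pd.Timestamp(end),
                }
            )
    return pd.DataFrame(events)


def lag_external(signals: pd.DataFrame, shift: int) -> pd.DataFrame:
    """Attribute each signal value to a date ``shift`` days later.

    The value reported for date ``t`` is the source value at ``t - shift``;
    the first ``shift`` days of each series have no source and become null.
    """
    if shift < 0:
        raise ValueError("shift must be >= 0")
    if shift == 0 or len(signals) == 0:
        return signals.copy()
    out = signals.copy()
    out["date"] = pd.to_datetime(out["date"]) + pd.Timedelta(days=shift)
    horizon = pd.to_datetime(signals["date"])
    keep = (out["date"] >= horizon.min()) & (out["date"] <= horizon.max())
    out = out[keep]
    # reinstate the uncovered leading dates as nulls
    lead_dates = pd.date_range(horizon.min(), periods=shift, freq="D")
    pads = []
    for name, group in signals.groupby("signal_name"):
        pads.append(
            pd.DataFrame(
                {
                    "date": lead_dates,
                    "signal_name": name,
                    "value": np.nan,
                    "source": group["source"].iloc[0],
                }
            )
        )
    return pd.concat([out] + pads, ignore_index=True).sort_values(
        ["signal_name", "date"], ignore_index=True
    )


def _sample_id(rid: str, date: pd.Timestamp, kind: str) -> str:
    raw = f"{rid}|{date.date()}|{kind}"
    return hashlib.md5(raw.encode()).hexdigest()[:12]


class _CohortArrays:
    """Per-resident dense day-indexed arrays for fast window slicing."""

    def __init__(
        self,
        cohort: SyntheticCohort,
        quantized: Optional[pd.DataFrame],
        scenario: str,
    ):
        vit = cohort.vitals
        dates = pd.to_datetime(vit["date"])
        self.day0 = dates.min()
        self.n_days = int((dates.max() - self.day0).days) + 1
        day = ((dates - self.day0).dt.days).to_numpy()
        self.values: dict = {}
        self.imputed: dict = {}
        self.observed: dict = {}
        rids = vit["resident_id"].to_numpy()
        chans = vit["channel"].to_numpy()
        vals = vit["value"].to_numpy(dtype=float)
        imp = vit["imputed"].to_numpy(dtype=bool)
        obs = vit["observed"].to_numpy(dtype=bool)
        for rid in np.unique(rids):
            rmask = rids == rid
            for ch in CHANNELS:
                m = rmask & (chans == ch)
                v = np.full(self.n_days, np.nan)
                fi = np.zeros(self.n_days, dtype=bool)
                fo = np.zeros(self.n_days, dtype=bool)
                v[day[m]] = vals[m]
                fi[day[m]] = imp[m]
                fo[day[m]] = obs[m]
                self.values[(rid, ch)] = v
                self.imputed[(rid, ch)] = fi
                self.observed[(rid, ch)] = fo

        self.q: dict = {}
        self.dq: dict = {}
        if quantized is not None and len(quantized):
            qday = (pd.to_datetime(quantized["date"]) - self.day0).dt.days.to_numpy()
            qr = quantized["resident_id"].to_numpy()
            qc = quantized["channel"].to_numpy()
            qv = quantized["Q"].to_numpy(dtype=float, na_value=np.nan)
            dv = quantized["delta_Q"].to_numpy(dtype=float, na_value=np.nan)
            for rid in np.unique(qr):
                rmask = qr == rid
                for ch in CHANNELS:
                    m = rmask & (qc == ch)
                    q = np.full(self.n_days, np.nan)
                    dq = np.full(self.n_days, np.nan)
                    q[qday[m]] = qv[m]
                    dq[qday[m]] = dv[m]
                    self.q[(rid, ch)] = q
                    self.dq[(rid, ch)] = dq

        self.external: dict = {}
        sources = _SCENARIO_SOURCES[scenario]
        ext = cohort.externals
        if sources and ext is not None and len(ext):
            ext = ext[ext["source"].isin(sources)]
            eday = (pd.to_datetime(ext["date"]) - self.day0).dt.days.to_numpy()
            for name, group in ext.groupby("signal_name"):
                v = np.full(self.n_days, np.nan)
                gday = (pd.to_datetime(group["date"]) - self.day0).dt.days.to_numpy()
                ok = (gday >= 0) & (gday < self.n_days)
                v[gday[ok]] = group["value"].to_numpy(dtype=float)[ok]
                self.external[str(name)] = v

        self.profiles = cohort.profiles.set_index("resident_id")


def _window_features(
    arrays: _CohortArrays, rid: str, lo: int, hi: int, observed_only: bool = False
) -> tuple[Optional[dict], int, int]:
    """Aggregate features over day-index window [lo, hi] (closed).

    Returns (features, n_nonnull_days, n_imputed_cells); features is None
    when the resident has no vitals arrays. With ``observed_only`` imputed
    cells are excluded from every aggregate (n_imputed is then 0 by
    construction) — the variant used for test-fold feature vectors.
    """
    feats: dict = {}
    sl = slice(lo, hi + 1)
    nonnull_days = np.zeros(hi - lo + 1, dtype=bool)
    n_imputed = 0
    for ch in CHANNELS:
        key = (rid, ch)
        if key not in arrays.values:
            return None, 0, 0
        v = arrays.values[key][sl]
        finite = np.isfinite(v)
        if observed_only:
            finite &= arrays.observed[key][sl]
        else:
            n_imputed += int(arrays.imputed[key][sl][finite].sum())
        nonnull_days |= finite
        if finite.any():
            vv = v[finite]
            feats[f"{ch}_mean"] = float(vv.mean())
            feats[f"{ch}_min"] = float(vv.min())
            feats[f"{ch}_max"] = float(vv.max())
        else:
            feats[f"{ch}_mean"] = np.nan
            feats[f"{ch}_min"] = np.nan
            feats[f"{ch}_max"] = np.nan
        q = arrays.q.get(key)
        if q is not None:
            qw = q[sl]
            qf = np.isfinite(qw)
            dqw = arrays.dq[key][sl]
            dqf = np.isfinite(dqw)
            if observed_only:
                qf &= arrays.observed[key][sl]
                dqf &= arrays.observed[key][sl]
            feats[f"Q_{ch}_mean"] = float(qw[qf].mean()) if qf.any() else np.nan
            feats[f"dQ_{ch}_last"] = float(dqw[dqf][-1]) if dqf.any() else np.nan
        else:
            feats[f"Q_{ch}_mean"] = np.nan
            feats[f"dQ_{ch}_last"] = np.nan
    for name, series in arrays.external.items():
        w = series[sl]
        f = np.isfinite(w)
        feats[f"{name}_mean"] = float(w[f].mean()) if f.any() else np.nan
        feats[f"{name}_last"] = float(w[f][-1]) if f.any() else np.nan
    return feats, int(nonnull_days.sum()), n_imputed


def build_samples(
    cohort: SyntheticCohort,
    events: pd.DataFrame,
    spec: WindowSpec,
    scenario: str = "BASIC",
    quantized: Optional[pd.DataFrame] = None,
    seed: int = 0,
    washout: int = DEFAULT_WASHOUT,
    max_healthy_per_resident: int = 5,
    min_window_obs: int = 2,
    external_shift: int = 0,
    use: str = "all",
) -> tuple[pd.DataFrame, dict]:
    """Build labeled window samples for one (lead, lag) configuration.

    One positive sample is attempted per event at ``T_t = t0 - lag``;
    healthy prediction points are drawn uniformly (seeded) from each
    resident's eligible days, at most ``max_healthy_per_resident`` each.
    A sample is skipped when its window extends before the horizon start
    (``skipped_boundary``) or contains fewer than ``min_window_obs``
    resident-days with any non-null vital (``skipped_sparse``). Feature
    columns: per-channel window mean/min/max, mean Q and last dQ, age,
    sex, Barthel index, and — outside the BASIC scenario — window mean and
    window-end value of each external signal (optionally lagged by
    ``external_shift`` days first). Provenance: ``n_imputed`` counts
    imputed cells feeding the window; emitted + skipped = attempted.

    ``use="all"`` aggregates every non-null cell (observed and imputed, the
    training variant); ``use="observed"`` excludes imputed cells from every
    aggregate, producing the imputation-free feature vectors used for test
    folds. Window placement and the seeded healthy-day draw are identical
    in both modes, so sample ids align across the two builds.
    """
    scenario = scenario.upper()
    if scenario not in SCENARIOS:
        raise ValueError(f"unknown scenario {scenario!r}; expected one of {SCENARIOS}")
    if use not in {"all", "observed"}:
        raise ValueError(f"use must be 'all' or 'observed', got {use!r}")
    observed_only = use == "observed"
    work = cohort
    if external_shift > 0 and len(cohort.externals):
        work = cohort.copy()
        work.externals = lag_external(cohort.externals, external_shift)
    arrays = _CohortArrays(work, quantized, scenario)
    rng = np.random.default_rng(seed)

    rows = []
    skip = {"skipped_boundary": 0, "skipped_sparse": 0, "attempted": 0}

    def day_of(ts: pd.Timestamp) -> int:
        return int((pd.Timestamp(ts) - arrays.day0).days)

    events = events.sort_values(["resident_id", "t0"]) if len(events) else events
    for _, ev in events.iterrows():
        skip["attempted"] += 1
        t_pred = day_of(ev["t0"]) - spec.lag
        lo = t_pred - spec.lead
        if lo < 0 or t_pred < 0:
            skip["skipped_boundary"] += 1
            continue
        feats, n_obs_days, n_imputed = _window_features(
            arrays, ev["resident_id"], lo, t_pred, observed_only
        )
        if feats is None or n_obs_days < min_window_obs:
            skip["skipped_sparse"] += 1
            continue
        rows.append(
            _assemble_row(
                arrays, ev["resident_id"], t_pred, feats, n_imputed,
                label=ev["category"], kind="event",
            )
        )

    # healthy prediction points
    ev_by_rid = {rid: g for rid, g in events.groupby("resident_id")} if len(events) else {}
    for rid in arrays.profiles.index:
        blocked = np.zeros(arrays.n_days, dtype=bool)
        for _, ev in ev_by_rid.get(rid, pd.DataFrame()).iterrows():
            b_lo = max(0, day_of(ev["start"]) - washout)
            b_hi = min(arrays.n_days - 1, day_of(ev["end"]) + washout)
            blocked[b_lo : b_hi + 1] = True
        eligible = [
            d
            for d in range(spec.lead, arrays.n_days)
            if not blocked[d - spec.lead : d + 1].any()
        ]
        if not eligible:
            continue
        chosen = rng.choice(
            eligible,
            size=min(max_healthy_per_resident, len(eligible)),
            replace=False,
        )
        for d in sorted(int(x) for x in chosen):
            skip["attempted"] += 1
            feats, n_obs_days, n_imputed = _window_features(
                arrays, rid, d - spec.lead, d, observed_only
            )
            if feats is None or n_obs_days < min_window_obs:
                skip["skipped_sparse"] += 1
                continue
            rows.append(
                _assemble_row(arrays, rid, d, feats, n_imputed, label="HEALTHY", kind="healthy")
            )

    samples = pd.DataFrame(rows)
    skip["emitted"] = len(samples)
    if len(samples):
        samples.insert(0, "sample_id", [
            _sample_id(r, d, k)
            for r, d, k in zip(
                samples["resident_id"], samples["prediction_date"], samples["kind"]
            )
        ])
    return samples, skip


def _assemble_row(
    arrays: _CohortArrays,
    rid: str,
    t_pred: int,
    feats: dict,
    n_imputed: int,
    label: str,
    kind: str,
) -> dict:
    prof = arrays.profiles.loc[rid]
    row = {
        "resident_id": rid,
        "prediction_date": arrays.day0 + pd.Timedelta(days=t_pred),
        "kind": kind,
        "label_binary": "HEALTHY" if label == "HEALTHY" else "INFECTED",
        "label_multiclass": MULTICLASS_CODES[label],
        "n_imputed": n_imputed,
        "age": float(prof["age"]),
        "sex": 1.0 if prof["sex"] == "F" else 0.0,
        "barthel_index": float(prof["barthel_index"]),
    }
    row.update(feats)
    return row


def feature_columns(samples: pd.DataFrame) -> list[str]:
    """Names of the model-input columns of a sample table, in stable order."""
    meta = {
        "sample_id", "resident_id", "prediction_date", "kind",
        "label_binary", "label_multiclass", "n_imputed",
    }
    return [c for c in samples.columns if c not in meta]


def undersample(
    samples: pd.DataFrame, seed: int = 0, label_col: str = "label_binary"
) -> pd.DataFrame:
    """Balance classes by random undersampling to the minority count.

    Deterministic per seed; sampling without replacement. Raises on an
    empty class (every class named in the column must have >= 1 sample).
    """
    counts = samples[label_col].value_counts()
    if len(counts) < 2:
        raise ValueError(
            f"undersampling needs >= 2 classes in {label_col}, found {list(counts.index)}"
        )
    n_min = int(counts.min())
    rng = np.random.default_rng(seed)
    parts = []
    for label in sorted(counts.index, key=str):
        idx = samples.index[samples[label_col] == label].to_numpy()
        chosen = rng.choice(idx, size=n_min, replace=False)
        parts.append(samples.loc[np.sort(chosen)])
    return pd.concat(parts).sort_index()
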