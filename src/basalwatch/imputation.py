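"""Gap-limited imputation of daily vital-sign series.

Imputation is only ever allowed inside short gaps: a run of consecutive
missing days longer than ``max_gap`` (4 days by default) splits a
resident-channel series into independent discontinuous segments, and the
days of such long runs are never filled. Three protocols are supported —
per-channel mean substitution, k-nearest-neighbour estimation on same-day
feature vectors, and chained-equation multiple imputation (MICE) pooled by
mean — each fitted exclusively on rows flagged as training data so that no
statistic leaks from held-out residents. Test purity (no imputed cell ever
feeding an evaluated sample) is asserted separately.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np
import pandas as pd
from sklearn.experimental import enable_iterative_imputer  # noqa: F401
from sklearn.impute import IterativeImputer, KNNImputer

from .synthetic import CHANNELS


class ImputationError(ValueError):
    """Imputation cannot proceed (e.g., a channel with no training data)."""


@dataclass(frozen=True)
class ImputationConfig:
    method: str = "MEAN"  # MEAN | KNN | MICE
    max_gap: int = 4
    knn_k: int = 5
    mice_iterations: int = 10
    mice_draws: int = 5
    mean_scope: str = "global"  # global | per_resident
    seed: int = 0

    def __post_init__(self) -> None:
        if self.method.upper() not in {"MEAN", "KNN", "MICE"}:
            raise ImputationError(f"unknown imputation method {self.method!r}")
        if self.max_gap < 1:
            raise ImputationError("max_gap must be >= 1")
        if self.knn_k < 1:
            raise ImputationError("knn_k must be >= 1")


@dataclass(frozen=True)
class Segment:
    """A maximal resident-channel stretch whose internal gaps are all short."""

    resident_id: str
    channel: str
    start_date: pd.Timestamp
    end_date: pd.Timestamp

    @property
    def n_days(self) -> int:
        return (self.end_date - self.start_date).days + 1


def _group_series(vitals: pd.DataFrame) -> Iterable[tuple[tuple, pd.DataFrame]]:
    return vitals.sort_values("date").groupby(["resident_id", "channel"], sort=True)


def segment_gaps(vitals: pd.DataFrame, max_gap: int = 4) -> list[Segment]:
    """Split each resident-channel series into maximal short-gap segments.

    A segment runs from one non-null day to another and may contain
    internal null runs of length <= ``max_gap`` (those days are eligible
    for imputation). A null run longer than ``max_gap`` separates two
    segments; leading and trailing nulls belong to no segment.
    """
    segments: list[Segment] = []
    for (rid, channel), group in _group_series(vitals):
        obs = group.loc[group["value"].notna(), "date"].sort_values().to_numpy()
        if len(obs) == 0:
            continue
        start = obs[0]
        prev = obs[0]
        for d in obs[1:]:
            gap = (d - prev) / np.timedelta64(1, "D") - 1
            if gap > max_gap:
                segments.append(Segment(rid, channel, pd.Timestamp(start), pd.Timestamp(prev)))
                start = d
            prev = d
        segments.append(Segment(rid, channel, pd.Timestamp(start), pd.Timestamp(prev)))
    return segments


def imputable_mask(vitals: pd.DataFrame, max_gap: int = 4) -> pd.Series:
    """Boolean mask over ``vitals`` rows: null cells inside a segment.

    Exactly the cells :func:`impute` is permitted to fill — null values
    whose surrounding gap is <= ``max_gap`` days and which have an observed
    anchor on both sides.
    """
    mask = pd.Series(False, index=vitals.index)
    segments = segment_gaps(vitals, max_gap)
    by_key: dict[tuple, list[Segment]] = {}
    for seg in segments:
        by_key.setdefault((seg.resident_id, seg.channel), []).append(seg)
    for (rid, channel), group in vitals.groupby(["resident_id", "channel"], sort=False):
        segs = by_key.get((rid, channel), [])
        if not segs:
            continue
        nulls = group[group["value"].isna()]
        for seg in segs:
            inside = nulls.index[
                (nulls["date"] >= seg.start_date) & (nulls["date"] <= seg.end_date)
            ]
            mask.loc[inside] = True
    return mask


def _wide_table(vitals: pd.DataFrame, profiles: Optional[pd.DataFrame]) -> pd.DataFrame:
    # plain pivot: keeps all-null resident-days as NaN rows
    wide = vitals.pivot(index=["resident_id", "date"], columns="channel", values="value")
    wide = wide[[c for c in CHANNELS if c in wide.columns]]
    if profiles is not None and len(profiles):
        demo = profiles.set_index("resident_id")[["age", "barthel_index"]]
        wide = wide.join(demo, on="resident_id")
    return wide


def _resident_day_train_mask(
    vitals: pd.DataFrame, train_mask: Optional[pd.Series], wide_index: pd.MultiIndex
) -> np.ndarray:
    if train_mask is None:
        return np.ones(len(wide_index), dtype=bool)
    train_mask = train_mask.reindex(vitals.index, fill_value=False)
    keys = vitals.loc[train_mask.to_numpy(), ["resident_id", "date"]]
    train_keys = set(map(tuple, keys.itertuples(index=False)))
    return np.array([key in train_keys for key in wide_index], dtype=bool)


def impute(
    vitals: pd.DataFrame,
    config: ImputationConfig,
    profiles: Optional[pd.DataFrame] = None,
    train_mask: Optional[pd.Series] = None,
) -> pd.DataFrame:
    """Fill eligible nulls under the configured protocol.

    Returns a copy of ``vitals`` with eligible null cells (see
    :func:`imputable_mask`) filled and flagged ``imputed=True``. Observed
    cells are never modified, and nulls outside segments remain null. All
    imputation statistics — channel means, neighbour pools, chained
    regressions — are computed only from rows selected by ``train_mask``
    (a boolean Series over ``vitals`` rows; None means all rows).

    kNN and MICE operate on the same-day wide feature vector (the four
    channels plus age and Barthel index when ``profiles`` is given),
    z-standardised with training statistics; MICE pools ``mice_draws``
    posterior-sampled completions by their mean.
    """
    out = vitals.copy()
    fillable = imputable_mask(out, config.max_gap)
    if not fillable.any():
        return out

    if train_mask is None:
        train_rows = pd.Series(True, index=out.index)
    else:
        train_rows = train_mask.reindex(out.index, fill_value=False).astype(bool)

    for channel in out.loc[fillable, "channel"].unique():
        n_train_obs = int(
            (train_rows & (out["channel"] == channel) & out["value"].notna()).sum()
        )
        if n_train_obs == 0:
            raise ImputationError(
                f"channel {channel} has no observed training values to fit on"
            )

    method = config.method.upper()
    if method == "MEAN":
        filled_values = _fill_mean(out, fillable, train_rows, config)
    else:
        filled_values = _fill_multivariate(out, fillable, train_rows, profiles, config)

    out.loc[fillable, "value"] = filled_values
    out.loc[fillable, "imputed"] = True
    out.loc[fillable, "observed"] = False
    return out


def _fill_mean(
    vitals: pd.DataFrame,
    fillable: pd.Series,
    train_rows: pd.Series,
    config: ImputationConfig,
) -> pd.Series:
    train = vitals[train_rows & vitals["value"].notna()]
    if config.mean_scope == "per_resident":
        means = train.groupby(["resident_id", "channel"])["value"].mean()
        fallback = train.groupby("channel")["value"].mean()
        keys = list(
            vitals.loc[fillable, ["resident_id", "channel"]].itertuples(index=False)
        )
        values = means.reindex(pd.MultiIndex.from_tuples(keys))
        values = values.fillna(
            fallback.reindex(vitals.loc[fillable, "channel"]).to_numpy()
        )
        return pd.Series(values.to_numpy(), index=vitals.index[fillable])
    means = train.groupby("channel")["value"].mean()
    return pd.Series(
        means.reindex(vitals.loc[fillable, "channel"]).to_numpy(),
        index=vitals.index[fillable],
    )


def _fill_multivariate(
    vitals: pd.DataFrame,
    fillable: pd.Series,
    train_rows: pd.Series,
    profiles: Optional[pd.DataFrame],
    config: ImputationConfig,
) -> pd.Series:
    wide = _wide_table(vitals, profiles)
    is_train = _resident_day_train_mask(vitals, train_rows, wide.index)
    train_wide = wide.loc[is_train]
    # columns with no observed training values carry no information to fit on
    usable = train_wide.columns[train_wide.notna().any()]
    wide = wide[usable]
    train_wide = train_wide[usable]

    mu = train_wide.mean()
    sd = train_wide.std(ddof=0).replace(0.0, 1.0).fillna(1.0)
    z_train = (train_wide - mu) / sd
    z_all = (wide - mu) / sd

    if config.method.upper() == "KNN":
        imputer = KNNImputer(n_neighbors=config.knn_k)
        imputer.fit(z_train.to_numpy())
        completed = imputer.transform(z_all.to_numpy())
    else:  # MICE
        draws = []
        for d in range(config.mice_draws):
            imputer = IterativeImputer(
                max_iter=config.mice_iterations,
                sample_posterior=config.mice_draws > 1,
                random_state=(config.seed + d) % (2**31),
            )
            imputer.fit(z_train.to_numpy())
            draws.append(imputer.transform(z_all.to_numpy()))
        completed = np.mean(draws, axis=0)
    completed = completed * sd.to_numpy() + mu.to_numpy()
    completed = pd.DataFrame(completed, index=wide.index, columns=wide.columns)

    targets = vitals.loc[fillable, ["resident_id", "date", "channel"]]
    values = [
        completed.at[(row.resident_id, row.date), row.channel]
        for row in targets.itertuples(index=False)
    ]
    return pd.Series(values, index=vitals.index[fillable], dtype=float)


@dataclass
class PurityReport:
    """Outcome of the no-imputed-data-in-testing check."""

    passed: bool
    n_tested: int
    violations: list = field(default_factory=list)

    def __bool__(self) -> bool:  # pragma: no cover - convenience
        return self.passed


def assert_test_purity(
    samples: pd.DataFrame, fold_assignment: Optional[pd.Series] = None
) -> PurityReport:
    """Check that no evaluated sample aggregates an imputed cell.

    ``samples`` is a window-sample table carrying ``n_imputed`` provenance
    counts (see :mod:`basalwatch.windowing`). ``fold_assignment`` maps
    sample ids to their test fold; samples with a null/missing assignment
    are treated as never tested. Report-only: returns the violating sample
    ids rather than raising.
    """
    if "n_imputed" not in samples.columns:
        raise ValueError("samples table lacks 'n_imputed' provenance column")
    if fold_assignment is not None:
        tested = samples[
            samples["sample_id"].map(fold_assignment).notna()
        ]
    else:
        tested = samples
    violations = tested.loc[tested["n_imputed"] > 0, "sample_id"].tolist()
    return PurityReport(
        passed=len(violations) == 0, n_tested=len(tested), violations=violations
    )
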