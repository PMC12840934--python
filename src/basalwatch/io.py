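"""Reading, writing and descriptive summaries of cohort tables.

Tables travel as comma-separated UTF-8 CSV with a header row and ISO-8601
dates. The vitals table is long format (resident_id, date, channel, value,
observed, imputed); the planted-truth table of a synthetic cohort is written
to a separate file so that pipeline stages cannot accidentally consume it.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .synthetic import CHANNELS, CATEGORIES, SyntheticCohort

_FILES = {
    "profiles": "profiles.csv",
    "vitals": "vitals.csv",
    "diagnoses": "diagnoses.csv",
    "externals": "externals.csv",
}
_TRUTH_FILE = "truth.csv"


class CohortLoadError(ValueError):
    """A cohort table is missing, unparseable or violates an invariant."""


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Round with ties away from zero, matching printed clinical tables."""
    factor = 10.0**ndigits
    return math.floor(abs(x) * factor + 0.5) / factor * (1 if x >= 0 else -1)


def write_cohort(cohort: SyntheticCohort, dir_path: str | Path) -> None:
    """Write the four cohort tables (and truth, if present) as CSV."""
    dir_path = Path(dir_path)
    dir_path.mkdir(parents=True, exist_ok=True)
    for attr, fname in _FILES.items():
        df = getattr(cohort, attr).copy()
        for col in ("date", "t0"):
            if col in df.columns:
                df[col] = pd.to_datetime(df[col]).dt.strftime("%Y-%m-%d")
        df.to_csv(dir_path / fname, index=False)
    if cohort.truth is not None and len(cohort.truth.columns):
        truth = cohort.truth.copy()
        for col in ("t0", "episode_end", "prodrome_start", "prodrome_end"):
            if col in truth.columns:
                truth[col] = pd.to_datetime(truth[col]).dt.strftime("%Y-%m-%d")
        truth.to_csv(dir_path / _TRUTH_FILE, index=False)


def _validate_vitals(vitals: pd.DataFrame) -> None:
    unknown = set(vitals["channel"].unique()) - set(CHANNELS)
    if unknown:
        rows = vitals.index[vitals["channel"].isin(unknown)][:5].tolist()
        raise CohortLoadError(
            f"unknown channel(s) {sorted(unknown)} in vitals rows {rows}"
        )
    both = vitals["observed"] & vitals["imputed"]
    if both.any():
        raise CohortLoadError(
            "rows marked both observed and imputed: "
            f"{vitals.index[both][:5].tolist()}"
        )
    null_bad = vitals["value"].isna() & (vitals["observed"] | vitals["imputed"])
    if null_bad.any():
        raise CohortLoadError(
            "null values flagged observed or imputed at rows "
            f"{vitals.index[null_bad][:5].tolist()}"
        )


def _validate_diagnoses(diagnoses: pd.DataFrame) -> None:
    cat = diagnoses["category"].notna() & (diagnoses["category"] != "")
    infected = diagnoses["status"] == "INFECTED"
    bad = cat != infected
    if bad.any():
        raise CohortLoadError(
            "category must be set iff status is INFECTED; offending rows "
            f"{diagnoses.index[bad][:5].tolist()}"
        )
    unknown = set(diagnoses.loc[cat, "category"].unique()) - set(CATEGORIES)
    if unknown:
        raise CohortLoadError(f"unknown diagnosis categories {sorted(unknown)}")


def _validate_profiles(profiles: pd.DataFrame) -> None:
    bad = ~profiles["barthel_index"].between(0, 100)
    if bad.any():
        raise CohortLoadError(
            f"barthel_index outside [0, 100] at rows {profiles.index[bad][:5].tolist()}"
        )
    bad = profiles["age"] <= 0
    if bad.any():
        raise CohortLoadError(
            f"non-positive age at rows {profiles.index[bad][:5].tolist()}"
        )


def load_cohort(dir_path: str | Path) -> SyntheticCohort:
    """Load and validate a cohort bundle written by :func:`write_cohort`.

    The truth table is loaded when present (synthetic cohorts) and left
    empty otherwise. Malformed rows raise :class:`CohortLoadError` naming
    the offending table, rows and rule.
    """
    dir_path = Path(dir_path)
    tables = {}
    for attr, fname in _FILES.items():
        path = dir_path / fname
        if not path.exists():
            raise CohortLoadError(f"missing cohort table: {path}")
        try:
            df = pd.read_csv(path)
        except Exception as exc:  # pragma: no cover - pandas message passthrough
            raise CohortLoadError(f"cannot parse {path}: {exc}") from exc
        if "date" in df.columns and len(df):
            try:
                df["date"] = pd.to_datetime(df["date"], format="%Y-%m-%d")
            except ValueError as exc:
                raise CohortLoadError(f"unparseable date in {fname}: {exc}") from exc
        tables[attr] = df

    vitals = tables["vitals"]
    if len(vitals) == 0:
        vitals = pd.DataFrame(
            columns=["resident_id", "date", "channel", "value", "observed", "imputed"]
        )
    else:
        for col in ("observed", "imputed"):
            vitals[col] = vitals[col].astype(bool)
        _validate_vitals(vitals)
    diagnoses = tables["diagnoses"]
    if len(diagnoses):
        if "category" in diagnoses:
            diagnoses["category"] = diagnoses["category"].where(
                diagnoses["category"].notna(), None
            )
        _validate_diagnoses(diagnoses)
    if len(tables["profiles"]):
        _validate_profiles(tables["profiles"])

    truth_path = dir_path / _TRUTH_FILE
    if truth_path.exists():
        truth = pd.read_csv(truth_path)
        for col in ("t0", "episode_end", "prodrome_start", "prodrome_end"):
            if col in truth.columns:
                truth[col] = pd.to_datetime(truth[col])
    else:
        truth = pd.DataFrame()
    return SyntheticCohort(
        tables["profiles"], vitals, diagnoses, tables["externals"], truth
    )


def summarize_missingness(
    vitals: pd.DataFrame, expected_per_channel: Optional[int | dict] = None
) -> pd.DataFrame:
    """Per-channel expected/actual/missing counts and missing percentage.

    ``expected_per_channel`` may be a single count applied to every channel,
    a per-channel mapping, or None, in which case the expected count is the
    number of resident-days present in the table for that channel
    (enrollment-days). Percentages are rounded half-up to 2 decimals, the
    convention of printed clinical summary tables.
    """
    rows = []
    for channel in CHANNELS:
        sub = vitals[vitals["channel"] == channel]
        actual = int(sub["observed"].sum()) if len(sub) else 0
        if expected_per_channel is None:
            expected = len(sub)
        elif isinstance(expected_per_channel, dict):
            expected = int(expected_per_channel[channel])
        else:
            expected = int(expected_per_channel)
        if actual > expected:
            raise ValueError(
                f"channel {channel}: actual count {actual} exceeds expected {expected}"
            )
        missing = expected - actual
        pct = round_half_up(100.0 * missing / expected, 2) if expected else float("nan")
        rows.append(
            {
                "channel": channel,
                "expected": expected,
                "actual": actual,
                "missing": missing,
                "missing_pct": pct,
            }
        )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class CohortSummary:
    """Counts mirroring the standard cohort description tables."""

    residents: int
    participants: int
    infected_residents: int
    participation_rate_pct: Optional[int]
    total_infections: int
    infections_per_affected: Optional[float]
    category_counts: dict

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)


def summarize_cohort(
    profiles: pd.DataFrame,
    events: pd.DataFrame,
    total_residents: Optional[int] = None,
) -> CohortSummary:
    """Cohort participation and infection-recurrence summary.

    ``events`` is an event table (one row per infection event, with
    resident_id and category) as produced by
    :func:`basalwatch.windowing.segment_events` or a synthetic truth table.
    ``total_residents`` is the facility census against which participation
    is computed; it defaults to the number of enrolled participants.
    """
    participants = int(profiles["resident_id"].nunique())
    residents = int(total_residents) if total_residents is not None else participants
    infected_residents = int(events["resident_id"].nunique()) if len(events) else 0
    total_infections = int(len(events))
    if residents > 0:
        participation = int(round_half_up(100.0 * participants / residents, 0))
    else:
        participation = None
    if infected_residents > 0:
        per_affected = round_half_up(total_infections / infected_residents, 2)
    else:
        per_affected = None
    counts = (
        events["category"].value_counts().to_dict() if len(events) else {}
    )
    return CohortSummary(
        residents=residents,
        participants=participants,
        infected_residents=infected_residents,
        participation_rate_pct=participation,
        total_infections=total_infections,
        infections_per_affected=per_affected,
        category_counts={c: int(counts.get(c, 0)) for c in CATEGORIES},
    )
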