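"""Shapley-additive feature attribution and threshold-based selection.

Attributions are exact TreeSHAP values computed by the boosted-tree library
itself (``pred_contribs``), satisfying local accuracy: per sample, the
attributions plus the base value sum to the model's raw margin output.
Global importance is the mean absolute attribution per feature; the
Selected Feature Set keeps only features whose importance exceeds a
threshold, either absolute or as a fraction of the total attribution mass.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import xgboost as xgb


class SchemaError(ValueError):
    """Sample features do not match the fitted model's feature schema."""


def shap_values(model: xgb.XGBClassifier, X: pd.DataFrame) -> np.ndarray:
    """Exact per-sample TreeSHAP attributions, base value in the last column.

    Shape ``(n, f+1)`` for binary models, ``(n, k, f+1)`` for k-class
    models; units are the model's raw margin (log-odds).
    """
    booster = model.get_booster()
    expected = booster.feature_names
    if expected is not None and list(X.columns) != list(expected):
        missing = set(expected) - set(X.columns)
        extra = set(X.columns) - set(expected)
        raise SchemaError(
            f"feature schema mismatch; missing={sorted(missing)} extra={sorted(extra)}"
        )
    return booster.predict(xgb.DMatrix(X, feature_names=list(X.columns)), pred_contribs=True)


def compute_importances(
    model: xgb.XGBClassifier,
    X: pd.DataFrame,
    per_class: bool = False,
    class_names: Optional[Sequence[str]] = None,
) -> pd.DataFrame:
    """Mean-|SHAP| importance table over the given samples.

    One row per feature with ``mean_abs_shap`` and dense ``rank`` (1 = most
    important). For multiclass models the overall importance is the
    unweighted mean of the per-class mean absolute attributions, and
    ``per_class=True`` adds one column per class.
    """
    contribs = shap_values(model, X)
    return _table_from_contribs(contribs, list(X.columns), per_class, class_names)


def _table_from_contribs(
    contribs: np.ndarray,
    features: list,
    per_class: bool,
    class_names: Optional[Sequence[str]],
) -> pd.DataFrame:
    if contribs.ndim == 3:
        per_class_imp = np.abs(contribs[:, :, :-1]).mean(axis=0)  # (k, f)
        overall = per_class_imp.mean(axis=0)
    else:
        per_class_imp = None
        overall = np.abs(contribs[:, :-1]).mean(axis=0)
    table = pd.DataFrame({"feature": features, "mean_abs_shap": overall})
    if per_class and per_class_imp is not None:
        names = class_names or [f"class_{i}" for i in range(per_class_imp.shape[0])]
        for i, name in enumerate(names):
            table[f"shap_{name}"] = per_class_imp[i]
    order = table["mean_abs_shap"].rank(ascending=False, method="first").astype(int)
    table["rank"] = order
    return table


def compute_importances_cv(
    models_and_samples: Sequence[tuple],
    per_class: bool = False,
    class_names: Optional[Sequence[str]] = None,
) -> pd.DataFrame:
    """Pool attributions over the out-of-fold (model, X) pairs of a CV run.

    Out-of-fold attribution avoids conflating fit with signal: each fold's
    model explains only samples it never saw. Contributions are pooled over
    all samples before averaging.
    """
    if not models_and_samples:
        raise ValueError("no fitted fold models to explain")
    all_contribs = []
    features = None
    for model, X in models_and_samples:
        features = list(X.columns)
        all_contribs.append(shap_values(model, X))
    contribs = np.concatenate(all_contribs, axis=0)
    return _table_from_contribs(contribs, features, per_class, class_names)


@dataclass(frozen=True)
class SelectionRule:
    """Feature-retention rule on mean-|SHAP| importance.

    ``ABSOLUTE`` keeps features strictly above ``threshold_value`` in
    attribution units; ``FRACTION_OF_TOTAL`` resolves the threshold as
    ``threshold_value`` times the summed importance of all features (the
    default, 0.01, keeps features carrying more than 1% of total
    attribution mass — a relative rule that transfers across scenarios).
    """

    threshold_mode: str = "FRACTION_OF_TOTAL"  # ABSOLUTE | FRACTION_OF_TOTAL
    threshold_value: float = 0.01

    def __post_init__(self) -> None:
        if self.threshold_mode not in {"ABSOLUTE", "FRACTION_OF_TOTAL"}:
            raise ValueError(f"unknown threshold_mode {self.threshold_mode!r}")
        if self.threshold_value <= 0:
            raise ValueError("threshold_value must be > 0")

    def resolve(self, table: pd.DataFrame) -> float:
        if self.threshold_mode == "ABSOLUTE":
            return self.threshold_value
        return self.threshold_value * float(table["mean_abs_shap"].sum())


def select_features(table: pd.DataFrame, rule: Optional[SelectionRule] = None) -> list:
    """Features whose importance strictly exceeds the resolved threshold.

    Original table order is preserved. Raises when nothing survives, with
    the resolved threshold in the message so a caller can lower it.
    """
    if len(table) == 0:
        raise ValueError("empty importance table")
    rule = rule or SelectionRule()
    cut = rule.resolve(table)
    kept = table.loc[table["mean_abs_shap"] > cut, "feature"].tolist()
    if not kept:
        raise ValueError(
            f"no feature exceeds the resolved threshold {cut:.4g}; lower the threshold"
        )
    return kept
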