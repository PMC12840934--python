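"""Confusion-matrix metrics: per-class rates, F1 and MCC.

Rates with a zero denominator are reported as NaN with an explicit flag
rather than silently coerced to 0. The Matthews correlation coefficient is
computed from the four-quadrant formula in the binary case and from the
generalized multi-category (Gorodkin) form on the full confusion matrix
otherwise; the two coincide for two classes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd


def confusion_counts(
    y_true: Sequence, y_pred: Sequence, labels: Optional[Sequence] = None
) -> pd.DataFrame:
    """Confusion matrix as a DataFrame (rows = true, columns = predicted)."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if len(y_true) != len(y_pred):
        raise ValueError(f"length mismatch: {len(y_true)} true vs {len(y_pred)} predicted")
    if len(y_true) == 0:
        raise ValueError("empty label sequences")
    if labels is None:
        labels = sorted(set(y_true) | set(y_pred), key=str)
    labels = list(labels)
    index = {lab: i for i, lab in enumerate(labels)}
    cm = np.zeros((len(labels), len(labels)), dtype=int)
    for t, p in zip(y_true, y_pred):
        cm[index[t], index[p]] += 1
    return pd.DataFrame(cm, index=labels, columns=labels)


def mcc_from_cm(cm: pd.DataFrame) -> float:
    """Matthews correlation coefficient of a confusion matrix.

    Binary: ``(TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN))``.
    Multi-category: the Gorodkin generalization
    ``(c*s - sum_k p_k t_k) / sqrt((s^2 - sum p_k^2)(s^2 - sum t_k^2))``
    where c is the trace, s the total, and t/p the row/column sums.
    Degenerate matrices (all mass in one true or one predicted class)
    return NaN.
    """
    m = cm.to_numpy(dtype=float)
    s = m.sum()
    c = np.trace(m)
    t = m.sum(axis=1)  # true-class totals
    p = m.sum(axis=0)  # predicted totals
    denom = (s**2 - (p**2).sum()) * (s**2 - (t**2).sum())
    if denom <= 0:
        return float("nan")
    return float((c * s - (p * t).sum()) / np.sqrt(denom))


def mcc(y_true: Sequence, y_pred: Sequence) -> float:
    return mcc_from_cm(confusion_counts(y_true, y_pred))


@dataclass
class EvaluationReport:
    """Per-class precision/recall/specificity/F1 plus MCC and macro-F1.

    ``per_class`` has one row per class; undefined rates are NaN and listed
    in ``undefined_rates`` as ``(class, metric)`` pairs. ``metadata``
    carries the run context (scenario, feature set, imputation method,
    lead, lag, seed) for report assembly.
    """

    per_class: pd.DataFrame
    cm: pd.DataFrame
    mcc: float
    macro_f1: float
    undefined_rates: list = field(default_factory=list)
    metadata: dict = field(default_factory=dict)

    @property
    def n(self) -> int:
        return int(self.cm.to_numpy().sum())

    def class_f1(self, label) -> float:
        return float(self.per_class.loc[self.per_class["class"] == label, "f1"].iloc[0])

    def summary(self, ndigits: int = 2) -> str:
        """Printable table; rates rounded only at presentation."""
        df = self.per_class.copy()
        for col in ("precision", "recall", "specificity", "f1"):
            df[col] = df[col].round(ndigits)
        lines = [df.to_string(index=False)]
        lines.append(f"MCC: {self.mcc:.{ndigits + 2}f}  macro-F1: {self.macro_f1:.{ndigits + 2}f}  n: {self.n}")
        if self.metadata:
            lines.append("  ".join(f"{k}={v}" for k, v in self.metadata.items()))
        return "\n".join(lines)


def confusion_metrics(
    y_true: Sequence,
    y_pred: Sequence,
    labels: Optional[Sequence] = None,
    metadata: Optional[dict] = None,
) -> EvaluationReport:
    """One-vs-rest per-class metrics and overall MCC/macro-F1."""
    cm = confusion_counts(y_true, y_pred, labels)
    m = cm.to_numpy(dtype=float)
    total = m.sum()
    rows = []
    undefined = []
    f1s = []
    for i, label in enumerate(cm.index):
        tp = m[i, i]
        fn = m[i, :].sum() - tp
        fp = m[:, i].sum() - tp
        tn = total - tp - fn - fp

        def rate(num, den, name):
            if den == 0:
                undefined.append((label, name))
                return float("nan")
            return num / den

        precision = rate(tp, tp + fp, "precision")
        recall = rate(tp, tp + fn, "recall")
        specificity = rate(tn, tn + fp, "specificity")
        if np.isnan(precision) or np.isnan(recall) or (precision + recall) == 0:
            f1 = float("nan")
            undefined.append((label, "f1"))
        else:
            f1 = 2 * precision * recall / (precision + recall)
        f1s.append(f1)
        rows.append(
            {
                "class": label,
                "precision": precision,
                "recall": recall,
                "specificity": specificity,
                "f1": f1,
                "support": int(tp + fn),
            }
        )
    macro = float(np.nanmean(f1s)) if not all(np.isnan(f) for f in f1s) else float("nan")
    return EvaluationReport(
        per_class=pd.DataFrame(rows),
        cm=cm,
        mcc=mcc_from_cm(cm),
        macro_f1=macro,
        undefined_rates=undefined,
        metadata=metadata or {},
    )


def scenario_report(runs: Sequence[EvaluationReport]) -> pd.DataFrame:
    """Stack per-class metrics of several runs into one long comparison table.

    Keyed by (scenario, feature_set, imputation, lead, lag, class) — the
    shape of the printed scenario-comparison tables.
    """
    frames = []
    for rep in runs:
        df = rep.per_class.copy()
        for key in ("scenario", "feature_set", "imputation", "lead", "lag", "seed"):
            df[key] = rep.metadata.get(key)
        df["mcc"] = rep.mcc
        df["macro_f1"] = rep.macro_f1
        frames.append(df)
    if not frames:
        return pd.DataFrame()
    cols = [
        "scenario", "feature_set", "imputation", "lead", "lag", "seed",
        "class", "precision", "recall", "specificity", "f1", "support",
        "mcc", "macro_f1",
    ]
    out = pd.concat(frames, ignore_index=True)
    return out[[c for c in cols if c in out.columns]]


def permutation_f1_band(
    y_true: Sequence,
    y_pred: Sequence,
    positive_label,
    n_permutations: int = 500,
    quantile: float = 0.99,
    seed: int = 0,
) -> float:
    """Upper null band for a class F1 under label-prediction independence.

    Permutes the predictions against the fixed labels and returns the given
    quantile of the resulting F1 distribution for ``positive_label`` — the
    bar a classifier must clear to show signal beyond chance at this n.
    """
    rng = np.random.default_rng(seed)
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred).copy()
    scores = []
    for _ in range(n_permutations):
        rng.shuffle(y_pred)
        rep = confusion_metrics(y_true, y_pred)
        if positive_label in list(rep.per_class["class"]):
            f1 = rep.class_f1(positive_label)
            scores.append(0.0 if np.isnan(f1) else f1)
    return float(np.quantile(scores, quantile))
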