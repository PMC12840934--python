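"""Gradient-boosted classification under resident-grouped cross-validation.

Two tasks share one machinery: a binary screen (healthy vs infected) and a
multiclass triage (healthy / ARI / UTI / other). Models are XGBoost
gradient-boosted tree ensembles; hyperparameters are tuned by seeded
randomized search whose objective is the mean out-of-fold Matthews
correlation coefficient, with folds assigned by Stratified Group K-Fold on
resident identity so that no resident ever appears in both the training and
the test partition of a fold (the identity-leakage guard). Evaluation is
pooled over out-of-fold predictions, and samples whose windows contain any
imputed cell are excluded from test scoring (test purity).

The front end follows the Model/Results convention: build an
:class:`InfectionModel` from a sample table (or straight from a cohort via
``from_cohort``), call ``fit()``, and read estimates, diagnostics and the
``summary()`` table off the returned :class:`InfectionResults`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import xgboost as xgb
from sklearn.model_selection import StratifiedGroupKFold

from . import windowing
from .basal import quantize_cohort
from .metrics import EvaluationReport, confusion_metrics, mcc as mcc_score
from .synthetic import SyntheticCohort
from .windowing import WindowSpec, build_samples, feature_columns, segment_events, undersample

DEFAULT_PARAM_SPACE: Mapping[str, tuple] = {
    "max_depth": ("int", 2, 6),
    "learning_rate": ("log", 0.01, 0.3),
    "n_estimators": ("int", 50, 400),
    "subsample": ("float", 0.6, 1.0),
    "colsample_bytree": ("float", 0.6, 1.0),
}

DEFAULT_PARAMS = {
    "max_depth": 3,
    "learning_rate": 0.1,
    "n_estimators": 150,
    "subsample": 0.9,
    "colsample_bytree": 0.9,
}


@dataclass(frozen=True)
class ModelConfig:
    """Training configuration shared by both tasks."""

    task: str = "binary"  # binary | multiclass
    scenario: str = "BASIC"
    feature_set: str = "FULL"  # FULL | SELECTED
    search_iterations: int = 10
    cv_folds: int = 5
    seed: int = 0
    param_space: Mapping[str, tuple] = field(
        default_factory=lambda: dict(DEFAULT_PARAM_SPACE)
    )
    test_purity: bool = True

    def __post_init__(self) -> None:
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")
        if self.search_iterations < 0:
            raise ValueError("search_iterations must be >= 0")
        if self.task not in {"binary", "multiclass"}:
            raise ValueError(f"unknown task {self.task!r}")


def assign_folds(
    samples: pd.DataFrame,
    k: int = 5,
    seed: int = 0,
    label_col: str = "label_binary",
) -> pd.Series:
    """Resident-grouped, label-stratified fold assignment.

    All samples of one resident land in a single fold; label proportions
    are approximately stratified subject to that constraint. Returns a
    Series of fold indices aligned with ``samples``. Raises when fewer
    distinct residents than folds exist.
    """
    residents = samples["resident_id"].nunique()
    if k < 2:
        raise ValueError("k must be >= 2")
    if residents < k:
        raise ValueError(f"need >= {k} distinct residents for {k} folds, have {residents}")
    splitter = StratifiedGroupKFold(n_splits=k, shuffle=True, random_state=seed % (2**31))
    y = samples[label_col].to_numpy()
    groups = samples["resident_id"].to_numpy()
    folds = pd.Series(-1, index=samples.index, dtype=int)
    X_dummy = np.zeros((len(samples), 1))
    for fold, (_, test_idx) in enumerate(splitter.split(X_dummy, y, groups)):
        folds.iloc[test_idx] = fold
    return folds


def draw_params(rng: np.random.Generator, space: Mapping[str, tuple]) -> dict:
    params = {}
    for name, (kind, lo, hi) in space.items():
        if kind == "int":
            params[name] = int(rng.integers(lo, hi + 1))
        elif kind == "log":
            params[name] = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
        else:
            params[name] = float(rng.uniform(lo, hi))
    return params


def train(
    X: pd.DataFrame,
    y: np.ndarray,
    params: Optional[dict] = None,
    task: str = "binary",
    seed: int = 0,
) -> xgb.XGBClassifier:
    """Fit one boosted-tree classifier; deterministic per seed.

    ``y`` must be contiguous integer codes. Missing feature values are
    handled natively by the trees (default-direction splits), which is why
    sparse windows can still be classified.
    """
    classes = np.unique(y)
    if len(classes) < 2:
        raise ValueError(f"training requires >= 2 classes, got {classes}")
    params = dict(params or DEFAULT_PARAMS)
    model = xgb.XGBClassifier(
        **params,
        objective="binary:logistic" if task == "binary" else "multi:softprob",
        tree_method="hist",
        n_jobs=1,
        random_state=seed % (2**31),
        verbosity=0,
    )
    model.fit(X, y)
    return model


def _encode_labels(samples: pd.DataFrame, task: str) -> tuple[np.ndarray, list]:
    if task == "binary":
        y = (samples["label_binary"] == "INFECTED").astype(int).to_numpy()
        return y, ["HEALTHY", "INFECTED"]
    codes = samples["label_multiclass"].to_numpy(dtype=int)
    present = sorted(np.unique(codes))
    remap = {c: i for i, c in enumerate(present)}
    names = {v: k for k, v in windowing.MULTICLASS_CODES.items()}
    y = np.array([remap[c] for c in codes])
    return y, [names[c] for c in present]


def _scoring_arrays(
    samples: pd.DataFrame,
    X: pd.DataFrame,
    X_test: Optional[pd.DataFrame],
    config: ModelConfig,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Which rows may be scored, and the feature matrix to score them with.

    Test purity is enforced one of two ways: with an observed-only feature
    matrix available (built by ``build_samples(use="observed")``), every
    sample is scorable on its imputation-free features; otherwise samples
    whose windows aggregated imputed cells are dropped from scoring.
    """
    if not config.test_purity:
        return np.ones(len(samples), dtype=bool), X
    if X_test is not None:
        scorable = ~X_test.isna().all(axis=1).to_numpy()
        return scorable, X_test
    return (samples["n_imputed"] == 0).to_numpy(), X


def _oof_predictions(
    samples: pd.DataFrame,
    X: pd.DataFrame,
    y: np.ndarray,
    folds: pd.Series,
    params: dict,
    config: ModelConfig,
    X_test: Optional[pd.DataFrame] = None,
) -> tuple[pd.DataFrame, list]:
    """Pooled out-of-fold predictions with per-fold fitted models.

    Training always uses the full (possibly imputed) feature matrix;
    scoring respects test purity via :func:`_scoring_arrays`. Samples that
    cannot be scored still contribute to training folds.
    """
    records = []
    fold_models = []
    scorable, X_score = _scoring_arrays(samples, X, X_test, config)
    for fold in sorted(folds.unique()):
        test_mask = (folds == fold).to_numpy()
        train_mask = ~test_mask
        score_mask = test_mask & scorable
        if len(np.unique(y[train_mask])) < 2 or score_mask.sum() == 0:
            fold_models.append(None)
            continue
        model = train(
            X.iloc[train_mask], y[train_mask], params, config.task,
            seed=config.seed + 1000 + int(fold),
        )
        pred = model.predict(X_score.iloc[score_mask])
        records.append(
            pd.DataFrame(
                {
                    "sample_id": samples.loc[score_mask, "sample_id"].to_numpy()
                    if "sample_id" in samples
                    else samples.index[score_mask],
                    "fold": fold,
                    "y_true": y[score_mask],
                    "y_pred": pred,
                }
            )
        )
        fold_models.append((model, X_score.iloc[score_mask], y[score_mask]))
    oof = pd.concat(records, ignore_index=True) if records else pd.DataFrame(
        columns=["sample_id", "fold", "y_true", "y_pred"]
    )
    return oof, fold_models


def tune(
    samples: pd.DataFrame,
    X: pd.DataFrame,
    y: np.ndarray,
    folds: pd.Series,
    config: ModelConfig,
    X_test: Optional[pd.DataFrame] = None,
) -> tuple[dict, pd.DataFrame]:
    """Seeded randomized search maximizing mean out-of-fold MCC.

    Each of ``config.search_iterations`` draws from the hyperparameter
    space is scored by the mean MCC over folds (degenerate single-class
    folds are skipped and recorded); the arg-max draw wins. Returns
    ``(best_params, log)`` where the log holds one row per (draw, fold)
    plus the per-draw mean.
    """
    rng = np.random.default_rng(config.seed)
    scorable, X_score = _scoring_arrays(samples, X, X_test, config)
    log_rows = []
    best: tuple[float, dict] = (-np.inf, dict(DEFAULT_PARAMS))
    for it in range(config.search_iterations):
        params = draw_params(rng, config.param_space)
        fold_scores = []
        for fold in sorted(folds.unique()):
            test_mask = (folds == fold).to_numpy()
            score_mask = test_mask & scorable
            train_mask = ~test_mask
            if (
                len(np.unique(y[train_mask])) < 2
                or score_mask.sum() == 0
                or len(np.unique(y[score_mask])) < 2
            ):
                log_rows.append(
                    {"draw": it, "fold": int(fold), "mcc": np.nan,
                     "note": "degenerate fold skipped", **params}
                )
                continue
            model = train(
                X.iloc[train_mask], y[train_mask], params, config.task,
                seed=config.seed + it,
            )
            score = mcc_score(y[score_mask], model.predict(X_score.iloc[score_mask]))
            fold_scores.append(score)
            log_rows.append({"draw": it, "fold": int(fold), "mcc": score, "note": "", **params})
        mean_mcc = float(np.nanmean(fold_scores)) if fold_scores else -np.inf
        log_rows.append({"draw": it, "fold": -1, "mcc": mean_mcc, "note": "mean", **params})
        if mean_mcc > best[0]:
            best = (mean_mcc, params)
    return best[1], pd.DataFrame(log_rows)


class InfectionModel:
    """Early-infection classifier over a window-sample table.

    Parameters
    ----------
    samples : DataFrame
        Output of :func:`basalwatch.windowing.build_samples` (typically
        balanced with :func:`basalwatch.windowing.undersample` first).
    config : ModelConfig
        Task, scenario, fold count, tuning budget, seed.
    feature_cols : list of str, optional
        Restrict the model to these feature columns (e.g., a SHAP-selected
        subset); defaults to every feature column in the table.
    test_features : DataFrame, optional
        Imputation-free feature vectors indexed by sample_id (the
        ``use="observed"`` build), used for test-fold scoring. Without it,
        test purity falls back to dropping imputed-containing samples from
        scoring.
    """

    def __init__(
        self,
        samples: pd.DataFrame,
        config: Optional[ModelConfig] = None,
        feature_cols: Optional[Sequence[str]] = None,
        metadata: Optional[dict] = None,
        test_features: Optional[pd.DataFrame] = None,
    ):
        if len(samples) == 0:
            raise ValueError("empty sample table")
        self.samples = samples.reset_index(drop=True)
        self.config = config or ModelConfig()
        self.feature_cols = list(feature_cols or feature_columns(self.samples))
        self.metadata = dict(metadata or {})
        self.test_features = test_features

    @classmethod
    def from_cohort(
        cls,
        cohort: SyntheticCohort,
        lead: int,
        lag: int,
        scenario: str = "BASIC",
        config: Optional[ModelConfig] = None,
        events: Optional[pd.DataFrame] = None,
        quantized: Optional[pd.DataFrame] = None,
        washout: int = windowing.DEFAULT_WASHOUT,
        balance: bool = True,
        **build_kwargs,
    ) -> "InfectionModel":
        """Build samples from a cohort and wrap them in a model.

        Runs event segmentation and basal quantization when not supplied,
        then window construction and (by default) undersampling to class
        balance on the task's label.
        """
        config = config or ModelConfig(scenario=scenario)
        if events is None:
            events = segment_events(cohort.diagnoses, washout)
        if quantized is None:
            quantized = quantize_cohort(cohort.vitals, cohort.diagnoses)
        samples, skip = build_samples(
            cohort, events, WindowSpec(lead, lag), scenario,
            quantized=quantized, seed=config.seed, washout=washout, **build_kwargs,
        )
        if len(samples) == 0:
            raise ValueError(f"no samples could be built (skip report: {skip})")
        test_features = None
        if config.test_purity and bool(cohort.vitals["imputed"].any()):
            obs_samples, _ = build_samples(
                cohort, events, WindowSpec(lead, lag), scenario,
                quantized=quantized, seed=config.seed, washout=washout,
                use="observed", **build_kwargs,
            )
            if len(obs_samples):
                test_features = obs_samples.set_index("sample_id")[
                    feature_columns(obs_samples)
                ]
        if balance:
            label_col = "label_binary" if config.task == "binary" else "label_multiclass"
            samples = undersample(samples, seed=config.seed, label_col=label_col)
        meta = {"scenario": scenario, "lead": lead, "lag": lag, "skip_report": skip}
        return cls(samples, config=config, metadata=meta, test_features=test_features)

    def with_features(self, feature_cols: Sequence[str]) -> "InfectionModel":
        """Same samples and config, restricted to a feature subset."""
        cfg = replace(self.config, feature_set="SELECTED")
        return InfectionModel(
            self.samples, config=cfg, feature_cols=feature_cols,
            metadata=self.metadata, test_features=self.test_features,
        )

    def fit(self) -> "InfectionResults":
        """Tune (if budgeted), cross-validate out-of-fold, fit the final model."""
        config = self.config
        label_col = "label_binary" if config.task == "binary" else "label_multiclass"
        y, class_names = _encode_labels(self.samples, config.task)
        X = self.samples[self.feature_cols]
        X_test = None
        if self.test_features is not None:
            X_test = (
                self.test_features.reindex(self.samples["sample_id"])[self.feature_cols]
                .reset_index(drop=True)
            )
        folds = assign_folds(self.samples, config.cv_folds, config.seed, label_col)

        if config.search_iterations > 0:
            params, tuning_log = tune(self.samples, X, y, folds, config, X_test)
        else:
            params, tuning_log = dict(DEFAULT_PARAMS), pd.DataFrame()

        oof, fold_models = _oof_predictions(
            self.samples, X, y, folds, params, config, X_test
        )
        if len(oof) == 0:
            raise ValueError("no pure out-of-fold predictions; cannot evaluate")
        report = confusion_metrics(
            [class_names[t] for t in oof["y_true"]],
            [class_names[p] for p in oof["y_pred"]],
            labels=class_names,
            metadata={
                "task": config.task,
                "scenario": self.metadata.get("scenario", config.scenario),
                "feature_set": config.feature_set,
                "lead": self.metadata.get("lead"),
                "lag": self.metadata.get("lag"),
                "seed": config.seed,
            },
        )
        final_model = train(X, y, params, config.task, seed=config.seed)
        return InfectionResults(
            model=self,
            params=params,
            classifier=final_model,
            class_names=class_names,
            folds=folds,
            oof=oof,
            fold_models=fold_models,
            report=report,
            tuning_log=tuning_log,
        )


@dataclass
class InfectionResults:
    """Fitted classifier plus pooled out-of-fold diagnostics."""

    model: InfectionModel
    params: dict
    classifier: xgb.XGBClassifier
    class_names: list
    folds: pd.Series
    oof: pd.DataFrame
    fold_models: list
    report: EvaluationReport
    tuning_log: pd.DataFrame

    @property
    def mcc(self) -> float:
        return self.report.mcc

    @property
    def macro_f1(self) -> float:
        return self.report.macro_f1

    def infected_f1(self) -> float:
        """F1 of the positive screen: infected class (binary task)."""
        return self.report.class_f1("INFECTED")

    def importances(self, per_class: bool = False) -> pd.DataFrame:
        """Mean-|SHAP| feature importances over out-of-fold samples."""
        from .interpret import compute_importances_cv

        pairs = [(m, Xs) for item in self.fold_models if item is not None
                 for m, Xs, _ in [item]]
        return compute_importances_cv(pairs, per_class=per_class, class_names=self.class_names)

    def summary(self) -> str:
        head = (
            f"InfectionModel results — task={self.model.config.task}, "
            f"scenario={self.report.metadata.get('scenario')}, "
            f"features={len(self.model.feature_cols)} ({self.model.config.feature_set})"
        )
        param_line = "params: " + ", ".join(
            f"{k}={v:.3g}" if isinstance(v, float) else f"{k}={v}"
            for k, v in self.params.items()
        )
        return "\n".join([head, param_line, self.report.summary()])


def sweep_lead_lag(
    cohort: SyntheticCohort,
    scenario: str,
    lead_grid: Sequence[int],
    lag_grid: Sequence[int],
    config: Optional[ModelConfig] = None,
    events: Optional[pd.DataFrame] = None,
    quantized: Optional[pd.DataFrame] = None,
    min_class_samples: int = 5,
    **build_kwargs,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Max-F1-per-lag analysis over a (lead, lag) grid.

    For every lag, samples are rebuilt per lead, tuned and evaluated
    out-of-fold; the best F1 over leads (infected-class F1 for the binary
    task, macro-F1 for multiclass) and its argmax lead are recorded.
    Cells whose balanced sample table is too small (any class below
    ``min_class_samples``) or that cannot be evaluated are marked invalid
    and excluded from the max.

    Returns ``(sweep, cells)``: one row per lag, and the full per-cell
    table.
    """
    if len(lead_grid) == 0 or len(lag_grid) == 0:
        raise ValueError("lead_grid and lag_grid must be nonempty")
    config = config or ModelConfig(scenario=scenario)
    if events is None:
        events = segment_events(cohort.diagnoses, windowing.DEFAULT_WASHOUT)
    if quantized is None:
        quantized = quantize_cohort(cohort.vitals, cohort.diagnoses)
    label_col = "label_binary" if config.task == "binary" else "label_multiclass"

    cell_rows = []
    for lag in lag_grid:
        for lead in lead_grid:
            cell = {"lag": lag, "lead": lead, "f1": np.nan, "mcc": np.nan,
                    "n_samples": 0, "valid": False, "note": ""}
            try:
                model = InfectionModel.from_cohort(
                    cohort, lead, lag, scenario, config=config,
                    events=events, quantized=quantized, **build_kwargs,
                )
            except ValueError as exc:
                cell["note"] = str(exc)
                cell_rows.append(cell)
                continue
            counts = model.samples[label_col].value_counts()
            cell["n_samples"] = int(len(model.samples))
            if counts.min() < min_class_samples or model.samples[
                "resident_id"
            ].nunique() < config.cv_folds:
                cell["note"] = "too few samples"
                cell_rows.append(cell)
                continue
            try:
                res = model.fit()
            except ValueError as exc:
                cell["note"] = str(exc)
                cell_rows.append(cell)
                continue
            cell["f1"] = (
                res.infected_f1() if config.task == "binary" else res.macro_f1
            )
            cell["mcc"] = res.mcc
            cell["valid"] = True
            # pooled OOF marginals; enough to reconstruct permutation nulls
            cell["n_scored"] = int(len(res.oof))
            if config.task == "binary":
                cell["n_true_pos"] = int((res.oof["y_true"] == 1).sum())
                cell["n_pred_pos"] = int((res.oof["y_pred"] == 1).sum())
            cell_rows.append(cell)
    cells = pd.DataFrame(cell_rows)

    sweep_rows = []
    for lag in lag_grid:
        sub = cells[(cells["lag"] == lag) & cells["valid"]]
        if len(sub) == 0 or sub["f1"].isna().all():
            sweep_rows.append(
                {"lag": lag, "best_lead": None, "max_f1": np.nan, "n_samples": 0}
            )
            continue
        best = sub.loc[sub["f1"].idxmax()]
        sweep_rows.append(
            {
                "lag": lag,
                "best_lead": int(best["lead"]),
                "max_f1": float(best["f1"]),
                "n_samples": int(best["n_samples"]),
            }
        )
    return pd.DataFrame(sweep_rows), cells
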