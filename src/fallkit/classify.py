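"""Faller classification: six cross-validated models with fold-level metrics.

The positive class is the faller throughout, so sensitivity is the fraction
of fallers correctly identified and specificity the analogue for non-fallers.
Metrics are reported in percent.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .core_io import ValidationError
from .stats_screen import _labels_to_bool, ttest_from_samples

__all__ = [
    "MODEL_IDS",
    "ModelSpec",
    "ModelEvaluation",
    "make_folds",
    "evaluate_model",
    "evaluate_all_models",
    "compare_models",
]

MODEL_IDS = (
    "logistic_regression",
    "naive_bayes",
    "decision_tree",
    "boosted_tree",
    "random_forest",
    "svm",
)

# paper-silent hyperparameters; explicit, overridable defaults
DEFAULT_HYPERPARAMETERS: dict[str, dict] = {
    "logistic_regression": {"C": 1.0, "max_iter": 2000},
    "naive_bayes": {},
    "decision_tree": {"ccp_alpha": 0.02},
    "boosted_tree": {"n_estimators": 100, "max_depth": 3, "learning_rate": 0.1,
                     "min_samples_leaf": 20},
    "random_forest": {"n_estimators": 500, "max_features": "sqrt", "min_samples_leaf": 5},
    "svm": {"kernel": "rbf", "C": 1.0, "gamma": "scale"},
}


@dataclass(frozen=True)
class ModelSpec:
    model_id: str
    hyperparameters: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self):
        if self.model_id not in MODEL_IDS:
            raise ValidationError(f"unknown model_id {self.model_id!r}; choose from {MODEL_IDS}")

    def build(self):
        """Imputation + standardization + estimator pipeline.

        Preprocessing lives inside the pipeline so it is fitted on training
        folds only.
        """
        from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
        from sklearn.impute import SimpleImputer
        from sklearn.linear_model import LogisticRegression
        from sklearn.naive_bayes import GaussianNB
        from sklearn.pipeline import Pipeline
        from sklearn.preprocessing import StandardScaler
        from sklearn.svm import SVC
        from sklearn.tree import DecisionTreeClassifier

        hp = {**DEFAULT_HYPERPARAMETERS[self.model_id], **self.hyperparameters}
        seed = self.seed
        if self.model_id == "logistic_regression":
            est = LogisticRegression(random_state=seed, **hp)
        elif self.model_id == "naive_bayes":
            est = GaussianNB(**hp)
        elif self.model_id == "decision_tree":
            est = DecisionTreeClassifier(random_state=seed, **hp)
        elif self.model_id == "boosted_tree":
            est = GradientBoostingClassifier(random_state=seed, **hp)
        elif self.model_id == "random_forest":
            est = RandomForestClassifier(random_state=seed, n_jobs=1, **hp)
        else:
            est = SVC(random_state=seed, **hp)
        return Pipeline([
            ("impute", SimpleImputer(strategy="mean")),
            ("scale", StandardScaler()),
            ("model", est),
        ])


@dataclass
class ModelEvaluation:
    model_id: str
    k: int
    repeats: int
    fold_accuracy: np.ndarray   # percent, length k * repeats
    fold_sensitivity: np.ndarray
    fold_specificity: np.ndarray

    @property
    def accuracy(self) -> tuple[float, float]:
        return float(np.mean(self.fold_accuracy)), float(np.std(self.fold_accuracy, ddof=1))

    @property
    def sensitivity(self) -> tuple[float, float]:
        v = self.fold_sensitivity[np.isfinite(self.fold_sensitivity)]
        return float(np.mean(v)), float(np.std(v, ddof=1))

    @property
    def specificity(self) -> tuple[float, float]:
        v = self.fold_specificity[np.isfinite(self.fold_specificity)]
        return float(np.mean(v)), float(np.std(v, ddof=1))

    def summary(self) -> dict:
        acc, sens, spec = self.accuracy, self.sensitivity, self.specificity
        return {
            "model_id": self.model_id,
            "accuracy_mean": acc[0], "accuracy_sd": acc[1],
            "sensitivity_mean": sens[0], "sensitivity_sd": sens[1],
            "specificity_mean": spec[0], "specificity_sd": spec[1],
        }


def make_folds(labels, k: int = 10, repeat: int = 0, seed: int = 0) -> np.ndarray:
    """Stratified k-fold assignment (array of fold ids, one per subject).

    Within each class, subjects are shuffled and dealt round-robin, so class
    proportions per fold are balanced to within one subject.  Deterministic in
    (seed, repeat).  If a class is smaller than k a warning is issued and a
    plain (unstratified) partition is used.
    """
    is_faller = _labels_to_bool(labels)
    n = is_faller.size
    if n < k:
        raise ValidationError(f"need at least k={k} subjects, got {n}")
    if is_faller.sum() == 0 or (~is_faller).sum() == 0:
        raise ValidationError("both classes must be present")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), int(repeat), 0xF0]))
    folds = np.empty(n, dtype=int)
    if min(is_faller.sum(), (~is_faller).sum()) < k:
        warnings.warn("a class is smaller than k; falling back to a plain partition")
        perm = rng.permutation(n)
        folds[perm] = np.arange(n) % k
        return folds
    for mask in (is_faller, ~is_faller):
        idx = np.nonzero(mask)[0]
        perm = rng.permutation(idx.size)
        folds[idx[perm]] = np.arange(idx.size) % k
    return folds


def _fold_metrics(y_true: np.ndarray, y_pred: np.ndarray) -> tuple[float, float, float]:
    acc = 100.0 * float(np.mean(y_true == y_pred))
    n_f = int(y_true.sum())
    n_nf = y_true.size - n_f
    sens = 100.0 * float(np.mean(y_pred[y_true == 1] == 1)) if n_f else float("nan")
    spec = 100.0 * float(np.mean(y_pred[y_true == 0] == 0)) if n_nf else float("nan")
    return acc, sens, spec


def evaluate_model(
    spec: ModelSpec,
    features: pd.DataFrame,
    measure_ids: Optional[Sequence[str]] = None,
    k: int = 10,
    repeats: int = 10,
    seed: int = 0,
) -> ModelEvaluation:
    """Repeated stratified k-fold cross-validation of one model.

    Imputation and standardization are fitted on the training folds only.
    """
    if measure_ids is None:
        measure_ids = [c for c in features.columns if c not in ("fall_status", "subject_id")]
    measure_ids = list(measure_ids)
    if len(measure_ids) < 2:
        raise ValidationError("need at least 2 predictor measures")
    missing = [m for m in measure_ids if m not in features.columns]
    if missing:
        raise ValidationError(f"measures absent from feature table: {missing}")

    X = features[measure_ids].to_numpy(float)
    y = _labels_to_bool(features["fall_status"]).astype(int)

    accs, senss, specs = [], [], []
    for rep in range(repeats):
        folds = make_folds(y, k=k, repeat=rep, seed=seed)
        for f in range(k):
            train, test = folds != f, folds == f
            if len(np.unique(y[train])) < 2:
                raise ValidationError(f"fold {f} (repeat {rep}) has a single-class training set")
            model = spec.build()
            model.fit(X[train], y[train])
            pred = model.predict(X[test])
            acc, sens, sp = _fold_metrics(y[test], pred)
            accs.append(acc)
            senss.append(sens)
            specs.append(sp)
    return ModelEvaluation(
        model_id=spec.model_id, k=k, repeats=repeats,
        fold_accuracy=np.array(accs),
        fold_sensitivity=np.array(senss),
        fold_specificity=np.array(specs),
    )


def evaluate_all_models(
    features: pd.DataFrame,
    measure_ids: Optional[Sequence[str]] = None,
    k: int = 10,
    repeats: int = 10,
    seed: int = 0,
    hyperparameters: Optional[dict[str, dict]] = None,
) -> dict[str, ModelEvaluation]:
    hyperparameters = hyperparameters or {}
    out = {}
    for model_id in MODEL_IDS:
        spec = ModelSpec(model_id, hyperparameters.get(model_id, {}), seed=seed)
        out[model_id] = evaluate_model(spec, features, measure_ids, k=k, repeats=repeats, seed=seed)
    return out


def compare_models(reference: ModelEvaluation, others: Sequence[ModelEvaluation]) -> pd.DataFrame:
    """Two-sample t-tests of the reference model's per-fold accuracies against
    each other model's.  Returns mean difference (points), 95% CI and p."""
    rows = []
    ref = reference.fold_accuracy
    for other in others:
        if other.fold_accuracy.size != ref.size:
            raise ValidationError(
                f"fold counts differ: {reference.model_id} has {ref.size}, "
                f"{other.model_id} has {other.fold_accuracy.size}"
            )
        t, df, p = ttest_from_samples(ref, other.fold_accuracy)
        delta = float(ref.mean() - other.fold_accuracy.mean())
        pooled_var = (
            (ref.size - 1) * ref.var(ddof=1)
            + (other.fold_accuracy.size - 1) * other.fold_accuracy.var(ddof=1)
        ) / df
        se = float(np.sqrt(pooled_var * (1.0 / ref.size + 1.0 / other.fold_accuracy.size)))
        from scipy import stats as sp_stats

        tcrit = sp_stats.t.ppf(0.975, df)
        rows.append({
            "reference": reference.model_id,
            "other": other.model_id,
            "delta_accuracy": delta,
            "ci_lo": delta - tcrit * se,
            "ci_hi": delta + tcrit * se,
            "t": t, "df": df, "p": p,
        })
    return pd.DataFrame(rows)
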