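"""Repeated stratified cross-validation, metrics and robustness checks.

Protocol: the cohort is split into five folds (stratified by risk label);
while one fold is held out for testing, the remaining subjects are split
70/30 into a fit portion and a validation portion used for epoch/grid
selection.  Oversampling, when enabled, is fitted on and applied to the
fit portion only, so no synthetic sample ever derives from a validation
or test subject — this is asserted on every fold via the synthetic
subjects' contributor ids.  The whole procedure is repeated (50 times in
the published protocol) with fresh fold splits; per-repeat metrics are
computed on the pooled test-fold predictions, and the summary reports the
mean with a percentile (2.5th, 97.5th) confidence interval across
repeats.

Classification metrics: sensitivity and specificity of the high-risk
class at threshold 0.5, balanced accuracy (their mean), and AUC.
Regression metrics: Pearson r (with two-sided p), MAE, and the standard
deviation of the absolute errors.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
from scipy import stats

from .augment import AugmentationConfig, augment
from .connectome import Cohort, Connectome, Subject
from .models import Task

__all__ = [
    "CVConfig",
    "MetricsRecord",
    "CVResults",
    "RepeatedCV",
    "split_folds",
    "train_val_split",
    "run_repeated_cv",
    "compute_classification_metrics",
    "compute_regression_metrics",
    "permute_roi_order",
    "percentile_ci",
    "LeakageError",
]


class LeakageError(AssertionError):
    """A synthetic training sample derives from a held-out subject."""


@dataclass(frozen=True)
class CVConfig:
    folds: int = 5
    repeats: int = 50
    train_fraction: float = 0.70  # fit share of the non-test portion
    stratified: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.folds < 2:
            raise ValueError("folds must be >= 2")
        if self.repeats < 1:
            raise ValueError("repeats must be >= 1")
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train_fraction must be in (0, 1)")


def split_folds(cohort: Cohort, config: CVConfig,
                rng: np.random.Generator | None = None) -> list[np.ndarray]:
    """Disjoint fold index arrays covering the cohort, optionally stratified."""
    n = len(cohort)
    if n < config.folds:
        raise ValueError(f"cohort of {n} cannot be split into {config.folds} folds")
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    folds: list[list[int]] = [[] for _ in range(config.folds)]
    if config.stratified:
        labels = cohort.labels
        start = 0
        for cls in (1, 0):
            members = np.flatnonzero(labels == cls)
            members = members[rng.permutation(len(members))]
            for i, m in enumerate(members):
                folds[(start + i) % config.folds].append(int(m))
            start += len(members)  # continue dealing where the last class stopped
    else:
        order = rng.permutation(n)
        for i, m in enumerate(order):
            folds[i % config.folds].append(int(m))
    return [np.sort(np.array(f, dtype=int)) for f in folds]


def train_val_split(cohort: Cohort, train_fraction: float, seed: int,
                    stratified: bool = True) -> tuple[Cohort, Cohort]:
    """Split a cohort into fit/validation portions (stratified by risk)."""
    rng = np.random.default_rng(seed)
    n = len(cohort)
    fit_idx: list[int] = []
    val_idx: list[int] = []
    if stratified:
        labels = cohort.labels
        for cls in (1, 0):
            members = np.flatnonzero(labels == cls)
            members = members[rng.permutation(len(members))]
            n_fit = int(round(train_fraction * len(members)))
            n_fit = min(max(n_fit, 1), max(len(members) - 1, 1))
            fit_idx.extend(members[:n_fit])
            val_idx.extend(members[n_fit:])
    else:
        order = rng.permutation(n)
        n_fit = max(1, int(round(train_fraction * n)))
        fit_idx = list(order[:n_fit])
        val_idx = list(order[n_fit:])
    if not val_idx:  # degenerate small cohorts: fall back to no validation
        return cohort, cohort.subset([])
    return cohort.subset(sorted(fit_idx)), cohort.subset(sorted(val_idx))


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------

def compute_classification_metrics(predictions, labels, threshold: float = 0.5) -> dict:
    """Balanced accuracy / sensitivity / specificity (%, high-risk positive)
    and AUC of the predicted probabilities."""
    p = np.asarray(predictions, dtype=float)
    y = np.asarray(labels, dtype=int)
    if set(np.unique(y)) != {0, 1}:
        raise ValueError("both classes must be present to compute metrics")
    pred = (p >= threshold).astype(int)
    tp = int(np.sum((pred == 1) & (y == 1)))
    fn = int(np.sum((pred == 0) & (y == 1)))
    tn = int(np.sum((pred == 0) & (y == 0)))
    fp = int(np.sum((pred == 1) & (y == 0)))
    sensitivity = 100.0 * tp / (tp + fn)
    specificity = 100.0 * tn / (tn + fp)
    from sklearn.metrics import roc_auc_score

    return {
        "balanced_accuracy": (sensitivity + specificity) / 2.0,
        "sensitivity": sensitivity,
        "specificity": specificity,
        "auc": float(roc_auc_score(y, p)),
    }


def compute_regression_metrics(predictions, scores) -> dict:
    """Pearson r (two-sided p), MAE and SD of the absolute errors."""
    yhat = np.asarray(predictions, dtype=float)
    y = np.asarray(scores, dtype=float)
    if len(y) < 2:
        raise ValueError("need at least two subjects")
    if np.std(y) == 0 or np.std(yhat) == 0:
        raise ValueError("Pearson r undefined for zero-variance inputs")
    r, pval = stats.pearsonr(yhat, y)
    ae = np.abs(y - yhat)
    return {
        "pearson_r": float(r),
        "p_value": float(pval),
        "mae": float(ae.mean()),
        "std_ae": float(ae.std(ddof=1)),
    }


def percentile_ci(values: Sequence[float], level: float = 95.0) -> tuple[float, float]:
    v = np.asarray(values, dtype=float)
    lo = (100.0 - level) / 2.0
    return (float(np.percentile(v, lo)), float(np.percentile(v, 100.0 - lo)))


# ---------------------------------------------------------------------------
# repeated CV driver
# ---------------------------------------------------------------------------

@dataclass
class MetricsRecord:
    """Per-repeat metric values plus mean and 95% CI summaries."""

    task: Task
    per_repeat: list[dict] = field(default_factory=list)

    @property
    def metric_names(self) -> tuple[str, ...]:
        return tuple(self.per_repeat[0].keys()) if self.per_repeat else ()

    def values(self, name: str) -> np.ndarray:
        return np.array([m[name] for m in self.per_repeat])

    def mean(self, name: str) -> float:
        return float(self.values(name).mean())

    def ci(self, name: str, level: float = 95.0) -> tuple[float, float]:
        return percentile_ci(self.values(name), level)

    def as_dict(self) -> dict:
        out = {}
        for name in self.metric_names:
            lo, hi = self.ci(name)
            out[name] = {"mean": self.mean(name), "ci95": [lo, hi]}
        return out


def _audit_no_leakage(fit_cohort: Cohort, forbidden_ids: set[str]) -> None:
    for s in fit_cohort:
        if s.contributors and (set(s.contributors) & forbidden_ids):
            raise LeakageError(
                f"synthetic sample {s.id} derives from held-out subject(s) "
                f"{sorted(set(s.contributors) & forbidden_ids)}"
            )


def run_repeated_cv(
    cohort: Cohort,
    model_spec,
    cv: CVConfig,
    aug: AugmentationConfig | None = None,
    gradcam_collector: Callable | None = None,
) -> "CVResults":
    """Repeated k-fold cross-validation of a model spec on a cohort.

    ``model_spec`` is any object with ``fit(train, val) -> fitted`` where
    the fitted model has ``predict_values(cohort)`` and ``task``/``kind``
    attributes (the specs in :mod:`connectopred.models`).  When ``aug`` is
    given, the fit portion of every fold is expanded by score-binned
    convex-combination oversampling before training — never the validation
    or test portion.  ``gradcam_collector(fitted, test_cohort)`` is invoked
    once per trained fold (used to pool saliency maps over test subjects).
    """
    task: Task = model_spec.task
    record = MetricsRecord(task=task)
    rng = np.random.default_rng(cv.seed)
    all_ids = set(cohort.ids)
    predictions_frames = []
    n_models = 0
    for repeat in range(cv.repeats):
        folds = split_folds(cohort, cv, rng=rng)
        pooled_p = np.empty(len(cohort))
        for fold_idx, test_idx in enumerate(folds):
            train_idx = np.setdiff1d(np.arange(len(cohort)), test_idx)
            test_cohort = cohort.subset(test_idx)
            train_cohort = cohort.subset(train_idx)
            if task == "classification" and len(set(train_cohort.labels)) < 2:
                raise ValueError(
                    f"fold {fold_idx} training portion contains one class only; "
                    "enable stratification or enlarge the cohort"
                )
            split_seed = int(rng.integers(2**31))
            fit_c, val_c = train_val_split(
                train_cohort, cv.train_fraction, seed=split_seed,
                stratified=cv.stratified,
            )
            if len(val_c) == 0:
                val_c = None
            if aug is not None:
                aug_seed = int(rng.integers(2**31))
                fit_c = augment(fit_c, replace(aug, seed=aug_seed))
                held_out = all_ids - set(
                    s.id for s in fit_c if not s.contributors
                )
                _audit_no_leakage(fit_c, held_out)
            fitted = _refit(model_spec, repeat, fold_idx, fit_c, val_c)
            n_models += 1
            pooled_p[test_idx] = fitted.predict_values(test_cohort)
            if gradcam_collector is not None:
                gradcam_collector(fitted, test_cohort)
        if task == "classification":
            record.per_repeat.append(
                compute_classification_metrics(pooled_p, cohort.labels)
            )
        else:
            record.per_repeat.append(
                compute_regression_metrics(pooled_p, cohort.scores)
            )
        predictions_frames.append(pooled_p.copy())
    return CVResults(
        cohort=cohort,
        model_kind=model_spec.kind,
        task=task,
        cv=cv,
        aug=aug,
        record=record,
        per_repeat_predictions=np.array(predictions_frames),
        n_models_trained=n_models,
    )


def _refit(model_spec, repeat: int, fold_idx: int, fit_c: Cohort, val_c):
    """Fit a fresh model with a fold-specific training seed."""
    tc = getattr(model_spec, "train_config", None)
    if tc is not None:
        fold_seed = (tc.seed + 7919 * repeat + 13 * fold_idx) % (2**31)
        model_spec = replace(model_spec, train_config=replace(tc, seed=fold_seed))
    return model_spec.fit(fit_c, val_c)


@dataclass
class CVResults:
    """Summary of a repeated cross-validation experiment."""

    cohort: Cohort
    model_kind: str
    task: Task
    cv: CVConfig
    aug: AugmentationConfig | None
    record: MetricsRecord
    per_repeat_predictions: np.ndarray  # (repeats, n_subjects)
    n_models_trained: int

    def summary(self) -> str:
        lines = [
            "Repeated cross-validation results",
            "=" * 44,
            f"model: {self.model_kind}   task: {self.task}",
            f"subjects: {len(self.cohort)}   folds: {self.cv.folds}   "
            f"repeats: {self.cv.repeats}",
            f"augmentation: "
            + (f"{self.aug.expansion_factor}x (k={self.aug.k})" if self.aug else "off"),
            "-" * 44,
            f"{'metric':<20}{'mean':>8}   95% CI",
        ]
        for name in self.record.metric_names:
            lo, hi = self.record.ci(name)
            lines.append(
                f"{name:<20}{self.record.mean(name):>8.3f}   ({lo:.3f}, {hi:.3f})"
            )
        return "\n".join(lines)

    def as_dict(self) -> dict:
        return {
            "model": self.model_kind,
            "task": self.task,
            "n_subjects": len(self.cohort),
            "folds": self.cv.folds,
            "repeats": self.cv.repeats,
            "metrics": self.record.as_dict(),
        }

    def to_frame(self):
        """Per-repeat metric values as a pandas DataFrame."""
        import pandas as pd

        return pd.DataFrame(self.record.per_repeat).rename_axis("repeat")

    def mean_predictions(self) -> np.ndarray:
        return self.per_repeat_predictions.mean(axis=0)

    def plot_metric_distribution(self, name: str, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.hist(self.record.values(name), bins=20)
        ax.set_xlabel(name)
        ax.set_ylabel("repeats")
        return ax


class RepeatedCV:
    """Statsmodels-style front end: configure, then ``run(cohort)``."""

    def __init__(self, model_spec, cv: CVConfig = CVConfig(),
                 aug: AugmentationConfig | None = None):
        self.model_spec = model_spec
        self.cv = cv
        self.aug = aug

    def run(self, cohort: Cohort, gradcam_collector: Callable | None = None
            ) -> CVResults:
        return run_repeated_cv(cohort, self.model_spec, self.cv, self.aug,
                               gradcam_collector)


# ---------------------------------------------------------------------------
# ROI-permutation robustness experiment
# ---------------------------------------------------------------------------

def permute_roi_order(cohort: Cohort, seed: int) -> tuple[Cohort, np.ndarray]:
    """Apply one random region permutation to rows+columns of every matrix.

    Scores are unchanged.  Returns the permuted cohort and the permutation
    ``perm`` (0-based: new position i holds old region perm[i]), which
    lets edge identities be tracked through the relabelling.
    """
    rng = np.random.default_rng(seed)
    perm = rng.permutation(90)
    subjects = []
    for s in cohort:
        m = s.connectome.matrix[np.ix_(perm, perm)]
        subjects.append(
            Subject(s.id, Connectome(m, s.connectome.atlas), s.score,
                    contributors=s.contributors)
        )
    return Cohort(tuple(subjects), provenance=cohort.provenance), perm
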