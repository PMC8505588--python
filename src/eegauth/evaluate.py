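"""k-fold cross-validated identification metrics and protocol comparison.

Per fold, each enrolled class contributes a one-vs-rest confusion tally
(TP/FP/TN/FN) on the test rows, from which accuracy, precision, sensitivity,
specificity and F1 are computed and macro-averaged with equal class weight.
Reports carry per-fold values, mean and standard deviation in percent.  Note
macro accuracy from one-vs-rest counts differs from plain top-1 accuracy;
both are reported, clearly labelled.

The protocol/session comparison applies a normality gate: Shapiro-Wilk on
both paired per-fold samples, a paired t-test when both pass at alpha, and a
non-parametric alternative otherwise (rank-sum by default, signed-rank
selectable).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps_stats

from eegauth.classify import PolyKernel, predict, train
from eegauth.exceptions import InsufficientDataError
from eegauth.features import apply_normalizer, fit_normalizer

logger = logging.getLogger(__name__)

METRIC_NAMES = ("accuracy", "precision", "sensitivity", "specificity", "f1")


@dataclass(frozen=True)
class ConfusionCounts:
    """One-vs-rest confusion tallies for a single positive class."""

    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be nonnegative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def confusion(y_true, y_pred, positive_class) -> ConfusionCounts:
    """One-vs-rest confusion counts for ``positive_class``."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must have equal length")
    if positive_class not in y_true:
        raise ValueError(f"positive_class {positive_class!r} absent from y_true")
    t = y_true == positive_class
    p = y_pred == positive_class
    return ConfusionCounts(
        tp=int(np.sum(t & p)),
        fp=int(np.sum(~t & p)),
        tn=int(np.sum(~t & ~p)),
        fn=int(np.sum(t & ~p)),
    )


def _ratio(num: float, den: float, name: str) -> float:
    if den == 0:
        logger.warning("0/0 in %s; defined as 0", name)
        return 0.0
    return num / den


def metrics(counts: ConfusionCounts, f1_mode: str = "standard") -> dict[str, float]:
    """Accuracy, precision, sensitivity, specificity and F1 as proportions.

    ``f1_mode="standard"`` is the conventional harmonic mean
    2*P*S/(P+S); ``"paper_literal"`` computes P*S/(P+S), i.e. half the
    harmonic mean (so a perfect classifier scores 0.5) — kept for
    comparability with reports that use that variant.  Degenerate 0/0
    ratios are defined as 0 with a logged warning.
    """
    if f1_mode not in ("standard", "paper_literal"):
        raise ValueError("f1_mode must be 'standard' or 'paper_literal'")
    c = counts
    precision = _ratio(c.tp, c.tp + c.fp, "precision")
    sensitivity = _ratio(c.tp, c.tp + c.fn, "sensitivity")
    factor = 2.0 if f1_mode == "standard" else 1.0
    return {
        "accuracy": _ratio(c.tp + c.tn, c.total, "accuracy"),
        "precision": precision,
        "sensitivity": sensitivity,
        "specificity": _ratio(c.tn, c.tn + c.fp, "specificity"),
        "f1": factor * _ratio(precision * sensitivity,
                              precision + sensitivity, "f1"),
    }


@dataclass
class EvalReport:
    """Cross-validation outcome: per-fold macro metrics in percent."""

    per_fold: list[dict[str, float]]
    strategy: str
    task: str
    session: str
    k: int
    top1_accuracy_mean: float
    n_rows: int = 0
    config: dict = field(default_factory=dict)

    @property
    def mean(self) -> dict[str, float]:
        return {
            m: float(np.mean([f[m] for f in self.per_fold])) for m in METRIC_NAMES
        }

    @property
    def std(self) -> dict[str, float]:
        # sample standard deviation over folds (ddof=1), the dispersion a
        # "mean +/- std over k folds" table reports
        return {
            m: float(np.std([f[m] for f in self.per_fold], ddof=1))
            for m in METRIC_NAMES
        }

    def fold_samples(self, metric: str) -> np.ndarray:
        return np.array([f[metric] for f in self.per_fold])

    def summary(self) -> str:
        parts = [
            f"{m[:4]} {self.mean[m]:5.2f} +/- {self.std[m]:4.2f}"
            for m in METRIC_NAMES
        ]
        return (
            f"{self.task} {self.session} {self.strategy}: " + " | ".join(parts)
        )

    def to_dict(self) -> dict:
        return {
            "task": self.task,
            "session": self.session,
            "strategy": self.strategy,
            "k": self.k,
            "per_fold": self.per_fold,
            "mean": self.mean,
            "std": self.std,
            "top1_accuracy_mean": self.top1_accuracy_mean,
            "n_rows": self.n_rows,
            "config": self.config,
        }


def make_folds(
    n_rows: int, k: int, rng: np.random.Generator, labels: np.ndarray | None = None,
    stratify: bool = False,
) -> list[np.ndarray]:
    """Randomized, mutually exclusive fold index sets partitioning all rows."""
    if stratify:
        if labels is None:
            raise ValueError("stratified folds require labels")
        folds: list[list[int]] = [[] for _ in range(k)]
        for cls in np.unique(labels):
            idx = rng.permutation(np.flatnonzero(labels == cls))
            for f, chunk in enumerate(np.array_split(idx, k)):
                folds[f].extend(chunk.tolist())
        return [np.sort(np.array(f, dtype=int)) for f in folds]
    perm = rng.permutation(n_rows)
    return [np.sort(chunk) for chunk in np.array_split(perm, k)]


def kfold_evaluate(
    X: np.ndarray,
    labels: np.ndarray,
    strategy: str = "OVO",
    k: int = 5,
    seed: int = 0,
    kernel: PolyKernel | None = None,
    f1_mode: str = "standard",
    stratify: bool = True,
    averaging: str = "macro",
    task: str = "",
    session: str = "",
) -> EvalReport:
    """k-fold cross-validation of the full normalize/train/predict chain.

    Folds are randomized and mutually exclusive; the min-max normalizer is
    fitted on each training split only and applied to its test split, so no
    test statistics leak into training.  ``averaging="macro"`` (default)
    weights classes equally; ``"micro"`` pools the one-vs-rest counts.
    """
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels)
    classes, counts = np.unique(labels, return_counts=True)
    for cls, cnt in zip(classes, counts):
        if cnt < k:
            raise InsufficientDataError(
                f"class {cls!r} has {cnt} rows; k={k} folds require >= {k}"
            )
    if averaging not in ("macro", "micro"):
        raise ValueError("averaging must be 'macro' or 'micro'")

    rng = np.random.default_rng(seed)
    folds = make_folds(X.shape[0], k, rng, labels=labels, stratify=stratify)
    kernel = kernel or PolyKernel()

    per_fold: list[dict[str, float]] = []
    top1: list[float] = []
    for test_idx in folds:
        train_mask = np.ones(X.shape[0], dtype=bool)
        train_mask[test_idx] = False
        norm = fit_normalizer(X[train_mask])
        X_train = apply_normalizer(X[train_mask], norm)
        X_test = apply_normalizer(X[test_idx], norm)
        model = train(X_train, labels[train_mask], strategy, kernel, norm)
        y_pred = predict(model, X_test)
        y_true = labels[test_idx]
        top1.append(float(np.mean(y_pred == y_true)))

        fold_counts = [confusion(y_true, y_pred, c) for c in classes
                       if c in y_true]
        if averaging == "macro":
            per_class = [metrics(c, f1_mode) for c in fold_counts]
            fold_metrics = {
                m: 100.0 * float(np.mean([pc[m] for pc in per_class]))
                for m in METRIC_NAMES
            }
        else:
            pooled = ConfusionCounts(
                tp=sum(c.tp for c in fold_counts),
                fp=sum(c.fp for c in fold_counts),
                tn=sum(c.tn for c in fold_counts),
                fn=sum(c.fn for c in fold_counts),
            )
            fold_metrics = {
                m: 100.0 * v for m, v in metrics(pooled, f1_mode).items()
            }
        per_fold.append(fold_metrics)

    return EvalReport(
        per_fold=per_fold,
        strategy=strategy,
        task=task,
        session=session,
        k=k,
        top1_accuracy_mean=100.0 * float(np.mean(top1)),
        n_rows=int(X.shape[0]),
        config={
            "k": k, "seed": int(seed), "strategy": strategy,
            "f1_mode": f1_mode, "stratify": stratify, "averaging": averaging,
            "kernel": {
                "degree": kernel.degree, "coef0": kernel.coef0,
                "gamma": kernel.gamma, "C": kernel.C,
            },
        },
    )


@dataclass
class StatTestReport:
    """Outcome of the normality-gated paired comparison, per metric."""

    shapiro_p_a: dict[str, float]
    shapiro_p_b: dict[str, float]
    chosen_test: dict[str, str]  # "paired_t" or the non-parametric name
    comparison_p: dict[str, float]
    significant: dict[str, bool]
    alpha: float = 0.05

    def to_dict(self) -> dict:
        return {
            "alpha": self.alpha,
            "shapiro_p_a": self.shapiro_p_a,
            "shapiro_p_b": self.shapiro_p_b,
            "chosen_test": self.chosen_test,
            "comparison_p": self.comparison_p,
            "significant": self.significant,
        }


def _is_normal(sample: np.ndarray, alpha: float) -> tuple[float, bool]:
    """Shapiro-Wilk p-value; a zero-variance sample is treated as non-normal."""
    if np.ptp(sample) == 0:
        return 0.0, False
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        p = float(sps_stats.shapiro(sample).pvalue)
    return p, p > alpha


def compare_protocols(
    samples_a: dict[str, np.ndarray] | np.ndarray,
    samples_b: dict[str, np.ndarray] | np.ndarray,
    alpha: float = 0.05,
    nonparametric: str = "ranksum",
) -> StatTestReport:
    """Normality-gated paired comparison of fold-wise metric samples.

    For each metric: Shapiro-Wilk on both samples; if both look normal at
    ``alpha`` the paired t-test is used, otherwise the non-parametric
    alternative — ``"ranksum"`` (Wilcoxon rank-sum / Mann-Whitney) or
    ``"signed_rank"`` (Wilcoxon signed-rank, the strictly paired variant).
    Identical samples yield p = 1 with a warning rather than an undefined
    statistic.
    """
    if nonparametric not in ("ranksum", "signed_rank"):
        raise ValueError("nonparametric must be 'ranksum' or 'signed_rank'")
    if not isinstance(samples_a, dict):
        samples_a = {"value": np.asarray(samples_a, dtype=float)}
        samples_b = {"value": np.asarray(samples_b, dtype=float)}
    if set(samples_a) != set(samples_b):
        raise ValueError("metric sets differ between the two report groups")

    shapiro_a: dict[str, float] = {}
    shapiro_b: dict[str, float] = {}
    chosen: dict[str, str] = {}
    pvals: dict[str, float] = {}
    signif: dict[str, bool] = {}
    for name in samples_a:
        a = np.asarray(samples_a[name], dtype=float)
        b = np.asarray(samples_b[name], dtype=float)
        if a.shape != b.shape:
            raise ValueError(f"paired samples for {name!r} differ in length")
        pa, norm_a = _is_normal(a, alpha)
        pb, norm_b = _is_normal(b, alpha)
        shapiro_a[name], shapiro_b[name] = pa, pb

        if np.array_equal(a, b):
            warnings.warn(
                f"identical samples for {name!r}; comparison p set to 1",
                stacklevel=2,
            )
            chosen[name] = "paired_t" if norm_a and norm_b else nonparametric
            pvals[name] = 1.0
        elif norm_a and norm_b:
            chosen[name] = "paired_t"
            pvals[name] = float(sps_stats.ttest_rel(a, b).pvalue)
        elif nonparametric == "ranksum":
            chosen[name] = "ranksum"
            pvals[name] = float(sps_stats.ranksums(a, b).pvalue)
        else:
            chosen[name] = "signed_rank"
            pvals[name] = float(sps_stats.wilcoxon(a, b).pvalue)
        signif[name] = bool(pvals[name] < alpha)

    return StatTestReport(
        shapiro_p_a=shapiro_a,
        shapiro_p_b=shapiro_b,
        chosen_test=chosen,
        comparison_p=pvals,
        significant=signif,
        alpha=alpha,
    )
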