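"""Closed-set subject identification with polynomial-kernel SVMs.

Multi-class identification is decomposed explicitly into binary machines:

* OVO (one-vs-one): one machine per unordered class pair, n(n-1)/2 in total;
  prediction by majority vote over the pairwise winners, ties broken first
  by summed decision values, then by class order.
* OVA (one-vs-all): one machine per class (that class positive, the rest
  negative), n in total; prediction by argmax of the decision values.

The binary machine is a polynomial-kernel SVM,
K(u, v) = (gamma * <u, v> + coef0)^degree, with defaults degree 3, coef0 1,
C 1 and gamma = 1 / (d * Var(X)) ("scale").  A variance-blind gamma = 1/d
is tempting for features already normalized to [0, 1], but their variance
is far below 1, which flattens the kernel toward a constant and underfits
badly; the variance-scaled default is the established choice.  The
decomposition, model counting and aggregation rules live here so that the
number of trained binaries is a first-class, observable quantity.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from sklearn.svm import SVC

from eegauth.exceptions import InsufficientDataError

STRATEGIES = ("OVO", "OVA")


@dataclass(frozen=True)
class PolyKernel:
    """Polynomial kernel hyperparameters; gamma=None means 1/(d * Var(X))."""

    degree: int = 3
    coef0: float = 1.0
    gamma: float | None = None
    C: float = 1.0

    def __post_init__(self) -> None:
        if self.degree < 1:
            raise ValueError("degree must be >= 1")
        if self.C <= 0:
            raise ValueError("C must be > 0")

    def make_svc(self) -> SVC:
        return SVC(
            kernel="poly",
            degree=self.degree,
            coef0=self.coef0,
            gamma=self.gamma if self.gamma is not None else "scale",
            C=self.C,
        )


@dataclass
class TrainedModel:
    """A bank of binary decision functions plus the decomposition strategy."""

    strategy: str
    classes: list
    binaries: list[tuple[tuple, SVC]]  # (class pair) or (class,) -> fitted SVC
    kernel: PolyKernel
    n_features: int
    norm_params: tuple[np.ndarray, np.ndarray] | None = field(default=None)

    def __post_init__(self) -> None:
        expected = count_models(self.strategy, len(self.classes))
        if len(self.binaries) != expected:
            raise ValueError(
                f"{self.strategy} over {len(self.classes)} classes requires "
                f"{expected} binaries, got {len(self.binaries)}"
            )


def count_models(strategy: str, n_classes: int) -> int:
    """Number of binary machines the decomposition generates.

    OVO trains one machine per class pair, n(n-1)/2; OVA one per class, n.
    For n = 5 these are 10 and 5.
    """
    if strategy not in STRATEGIES:
        raise ValueError(f"strategy must be one of {STRATEGIES}")
    if n_classes < 2:
        raise ValueError("n_classes must be >= 2")
    if strategy == "OVO":
        return n_classes * (n_classes - 1) // 2
    return n_classes


def train(
    X_norm: np.ndarray,
    labels: np.ndarray,
    strategy: str = "OVO",
    kernel: PolyKernel | None = None,
    norm_params: tuple[np.ndarray, np.ndarray] | None = None,
) -> TrainedModel:
    """Fit the bank of binary polynomial SVMs for the chosen decomposition."""
    X_norm = np.asarray(X_norm, dtype=float)
    labels = np.asarray(labels)
    if X_norm.ndim != 2 or X_norm.shape[0] != labels.size:
        raise ValueError("X_norm must be 2-D with one label per row")
    kernel = kernel or PolyKernel()

    classes, counts = np.unique(labels, return_counts=True)
    if classes.size < 2:
        raise ValueError("need at least 2 classes")
    for cls, cnt in zip(classes, counts):
        if cnt < 2:
            raise InsufficientDataError(
                f"class {cls!r} has only {cnt} training row(s); need >= 2"
            )

    binaries: list[tuple[tuple, SVC]] = []
    if strategy == "OVO":
        for a, b in combinations(classes.tolist(), 2):
            mask = (labels == a) | (labels == b)
            svc = kernel.make_svc()
            # binary target +1 for class a, -1 for class b: the decision
            # value's sign picks the pairwise winner directly
            svc.fit(X_norm[mask], np.where(labels[mask] == a, 1, -1))
            binaries.append(((a, b), svc))
    elif strategy == "OVA":
        for cls in classes.tolist():
            svc = kernel.make_svc()
            svc.fit(X_norm, np.where(labels == cls, 1, -1))
            binaries.append(((cls,), svc))
    else:
        raise ValueError(f"strategy must be one of {STRATEGIES}")

    return TrainedModel(
        strategy=strategy,
        classes=classes.tolist(),
        binaries=binaries,
        kernel=kernel,
        n_features=X_norm.shape[1],
        norm_params=norm_params,
    )


def decision_matrix(model: TrainedModel, X_norm: np.ndarray) -> np.ndarray:
    """Per-class aggregate decision scores, rows x classes.

    OVO: votes per class, with summed signed decision values folded in at
    1e-9 weight purely as the documented tie-break (a full vote always
    outweighs any accumulated margin).  OVA: each class's own decision value.
    """
    X_norm = np.asarray(X_norm, dtype=float)
    if X_norm.ndim != 2 or X_norm.shape[1] != model.n_features:
        raise ValueError(
            f"feature dimension {X_norm.shape[-1]} does not match the "
            f"{model.n_features} the model was trained on"
        )
    n = X_norm.shape[0]
    class_index = {c: k for k, c in enumerate(model.classes)}
    scores = np.zeros((n, len(model.classes)))
    if model.strategy == "OVO":
        for (a, b), svc in model.binaries:
            dec = svc.decision_function(X_norm)
            ka, kb = class_index[a], class_index[b]
            scores[:, ka] += (dec > 0).astype(float) + 1e-9 * dec
            scores[:, kb] += (dec <= 0).astype(float) - 1e-9 * dec
    else:
        for (cls,), svc in model.binaries:
            scores[:, class_index[cls]] = svc.decision_function(X_norm)
    return scores


def predict(model: TrainedModel, X_norm: np.ndarray) -> np.ndarray:
    """Predict one enrolled identity per row.

    Remaining exact ties after vote + margin aggregation resolve to the
    earliest class in ``model.classes`` (argmax takes the first maximum), a
    deterministic, documented rule.
    """
    scores = decision_matrix(model, X_norm)
    winners = np.argmax(scores, axis=1)
    return np.asarray(model.classes, dtype=object)[winners]
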