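"""Least-squares SVM (binary and multiclass) and the evaluation metrics.

The LS-SVM replaces the SVM's inequality constraints with equalities, so
training reduces to one dense linear solve in the dual:

    [ 0   yᵀ ] [ b ]   [ 0 ]
    [ y   Ω+I/γ ] [ α ] = [ 1 ],    Ω_ij = y_i y_j K(x_i, x_j)

with decision value d(x) = Σ_i α_i y_i K(x, x_i) + b.  Multiclass problems
are handled by one-versus-one voting or error-correcting output codes over a
set of binary machines.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations, product
from typing import Sequence

import numpy as np


@dataclass(frozen=True)
class KernelSpec:
    """Kernel function parameters.

    gaussian_rbf: K(x, z) = exp(−‖x−z‖²/σ²); polynomial:
    K(x, z) = (x·z + offset)^degree.
    """

    kind: str = "gaussian_rbf"
    sigma: float = 1.0
    degree: int = 3
    offset: float = 1.0

    def __post_init__(self) -> None:
        if self.kind not in ("gaussian_rbf", "polynomial"):
            raise ValueError(f"unknown kernel kind {self.kind!r}")
        if self.kind == "gaussian_rbf" and self.sigma <= 0:
            raise ValueError("gaussian kernel needs sigma > 0")
        if self.kind == "polynomial" and self.degree < 1:
            raise ValueError("polynomial kernel needs degree ≥ 1")


def kernel_eval(spec: KernelSpec, x: np.ndarray, z: np.ndarray) -> np.ndarray | float:
    """Evaluate the kernel between vectors or row-stacked matrices.

    1-D inputs give a scalar; 2-D inputs give the Gram matrix K[i, j] =
    K(x_i, z_j).
    """
    x = np.asarray(x, dtype=float)
    z = np.asarray(z, dtype=float)
    scalar = x.ndim == 1 and z.ndim == 1
    X = np.atleast_2d(x)
    Z = np.atleast_2d(z)
    if X.shape[1] != Z.shape[1]:
        raise ValueError(f"dimension mismatch: {X.shape[1]} vs {Z.shape[1]}")
    if spec.kind == "gaussian_rbf":
        sq = (
            (X**2).sum(axis=1)[:, None]
            + (Z**2).sum(axis=1)[None, :]
            - 2.0 * X @ Z.T
        )
        out = np.exp(-np.maximum(sq, 0.0) / spec.sigma**2)
    else:
        out = (X @ Z.T + spec.offset) ** spec.degree
    return float(out[0, 0]) if scalar else out


@dataclass
class LSSVMModel:
    """A trained binary LS-SVM: support coefficients α (one per training
    point), bias b, and the stored training inputs."""

    alpha: np.ndarray
    bias: float
    gamma: float
    kernel: KernelSpec
    X_train: np.ndarray
    y_train: np.ndarray  # ±1

    def decision_values(self, X: np.ndarray) -> np.ndarray:
        K = kernel_eval(self.kernel, np.atleast_2d(X), self.X_train)
        return K @ (self.alpha * self.y_train) + self.bias

    def predict(self, X: np.ndarray) -> np.ndarray:
        d = self.decision_values(X)
        return np.where(d >= 0, 1, -1)


def lssvm_train(
    X: np.ndarray, y: Sequence, gamma: float, kernel: KernelSpec
) -> LSSVMModel:
    """Solve the LS-SVM dual system for ±1 labels.

    Raises a numerical error with the condition number if the regularized
    system is singular (cannot happen for finite γ > 0 and a PSD kernel, but
    checked defensively).
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    if set(np.unique(y)) - {-1.0, 1.0}:
        raise ValueError("labels must be ±1")
    if (y == 1).sum() == 0 or (y == -1).sum() == 0:
        raise ValueError("need at least one sample of each class")
    if gamma <= 0:
        raise ValueError("gamma must be positive")
    n = X.shape[0]
    K = kernel_eval(kernel, X, X)
    omega = (y[:, None] * y[None, :]) * K
    A = np.zeros((n + 1, n + 1))
    A[0, 1:] = y
    A[1:, 0] = y
    A[1:, 1:] = omega + np.eye(n) / gamma
    rhs = np.concatenate(([0.0], np.ones(n)))
    try:
        sol = np.linalg.solve(A, rhs)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            f"LS-SVM dual system is singular (cond={np.linalg.cond(A):.3e})"
        ) from exc
    return LSSVMModel(
        alpha=sol[1:], bias=float(sol[0]), gamma=gamma, kernel=kernel,
        X_train=X, y_train=y,
    )


@dataclass
class CodingScheme:
    """Multiclass wiring: OVO pair list or an ECOC code matrix.

    ``code_matrix`` has one row per class and one ±1 column per binary
    machine; rows must be pairwise distinct.  For OVO, ``pairs`` lists the
    C(k,2) class pairs.
    """

    kind: str
    classes: tuple
    pairs: list[tuple] | None = None
    code_matrix: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("OVO", "ECOC"):
            raise ValueError(f"coding kind must be OVO or ECOC, got {self.kind!r}")
        if self.kind == "ECOC":
            cm = np.asarray(self.code_matrix)
            if cm.shape[0] != len(self.classes):
                raise ValueError("code matrix needs one row per class")
            for a, b in combinations(range(cm.shape[0]), 2):
                if np.array_equal(cm[a], cm[b]):
                    raise ValueError(f"code rows {a} and {b} are identical")

    @property
    def n_machines(self) -> int:
        if self.kind == "OVO":
            return len(self.pairs)
        return self.code_matrix.shape[1]


def ovo_scheme(classes: Sequence) -> CodingScheme:
    """One-versus-one: one machine per unordered class pair."""
    classes = tuple(classes)
    return CodingScheme(kind="OVO", classes=classes,
                        pairs=list(combinations(classes, 2)))


def ecoc_scheme(classes: Sequence, seed: int = 0) -> CodingScheme:
    """Error-correcting output codes.

    k = 2 uses the single-column code (identical to one binary machine);
    3 ≤ k ≤ 6 uses the exhaustive code with 2^(k−1) − 1 columns; larger k
    falls back to seeded random dense ±1 codes with 2k columns and distinct
    rows.
    """
    classes = tuple(classes)
    k = len(classes)
    if k < 2:
        raise ValueError("need at least 2 classes")
    if k == 2:
        cm = np.array([[1], [-1]])
    elif k <= 6:
        n_cols = 2 ** (k - 1) - 1
        cm = np.ones((k, n_cols), dtype=int)
        # row i of the exhaustive code: sign patterns of all non-trivial
        # bipartitions that keep class 0 on the +1 side
        cols = [c for c in product([1, -1], repeat=k - 1) if any(v < 0 for v in c)]
        for j, col in enumerate(cols):
            cm[1:, j] = col
    else:
        rng = np.random.default_rng(seed)
        while True:
            cm = rng.choice([-1, 1], size=(k, 2 * k))
            rows = {tuple(r) for r in cm}
            if len(rows) == k and all(len(set(cm[:, j])) == 2 for j in range(2 * k)):
                break
    return CodingScheme(kind="ECOC", classes=classes, code_matrix=cm)


@dataclass
class MulticlassLSSVM:
    """OVO- or ECOC-coded LS-SVM multiclass classifier."""

    coding: CodingScheme
    kernel: KernelSpec
    gamma: float
    machines: list[LSSVMModel] = field(default_factory=list)

    def fit(self, X: np.ndarray, y: Sequence) -> "MulticlassLSSVM":
        X = np.atleast_2d(np.asarray(X, dtype=float))
        y = np.asarray(y)
        self.machines = []
        if self.coding.kind == "OVO":
            for a, b in self.coding.pairs:
                sel = (y == a) | (y == b)
                yy = np.where(y[sel] == a, 1.0, -1.0)
                self.machines.append(lssvm_train(X[sel], yy, self.gamma, self.kernel))
        else:
            cm = self.coding.code_matrix
            class_index = {c: i for i, c in enumerate(self.coding.classes)}
            rows = np.array([class_index[c] for c in y])
            for j in range(cm.shape[1]):
                yy = cm[rows, j].astype(float)
                self.machines.append(lssvm_train(X, yy, self.gamma, self.kernel))
        return self

    def decision_matrix(self, X: np.ndarray) -> np.ndarray:
        return np.column_stack([m.decision_values(X) for m in self.machines])

    def predict(self, X: np.ndarray) -> np.ndarray:
        """OVO: majority vote, ties broken by the largest summed decision
        margin; ECOC: minimum Hamming distance between the machines' sign
        vector and the class codewords, ties broken by the largest summed
        signed agreement Σ_j code_ij · d_j."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        D = self.decision_matrix(X)
        classes = self.coding.classes
        if self.coding.kind == "OVO":
            votes = np.zeros((X.shape[0], len(classes)))
            margins = np.zeros_like(votes)
            for j, (a, b) in enumerate(self.coding.pairs):
                ia, ib = classes.index(a), classes.index(b)
                pos = D[:, j] >= 0
                votes[pos, ia] += 1
                votes[~pos, ib] += 1
                margins[:, ia] += D[:, j]
                margins[:, ib] -= D[:, j]
            # lexicographic argmax on (votes, margins): margins settle ties
            score = votes + 1e-9 * np.tanh(margins)
            winner = np.argmax(score, axis=1)
        else:
            cm = self.coding.code_matrix
            signs = np.where(D >= 0, 1, -1)
            hamming = (signs[:, None, :] != cm[None, :, :]).sum(axis=2)
            agreement = np.einsum("nj,cj->nc", D, cm.astype(float))
            score = -hamming + 1e-9 * np.tanh(agreement)
            winner = np.argmax(score, axis=1)
        return np.asarray([classes[i] for i in winner])


def multiclass_train_predict(
    X_train: np.ndarray,
    y_train: Sequence,
    X_test: np.ndarray,
    coding: CodingScheme,
    kernel: KernelSpec,
    gamma: float,
) -> np.ndarray:
    """Train the coded multiclass LS-SVM and predict labels for ``X_test``."""
    return MulticlassLSSVM(coding=coding, kernel=kernel, gamma=gamma).fit(
        X_train, y_train
    ).predict(X_test)


# ---------------------------------------------------------------------------
# Metrics


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")
        if self.tp + self.tn + self.fp + self.fn == 0:
            raise ValueError("at least one sample is required")


@dataclass
class MetricsReport:
    """Sensitivity/specificity per class (one-vs-rest sense for k > 2) and
    total accuracy, all as percentages; undefined ratios are None."""

    sensitivity: dict[str, float | None]
    specificity: dict[str, float | None]
    total_accuracy: float


def compute_metrics(counts: ConfusionCounts) -> MetricsReport:
    """Binary metrics from confusion counts:
    sensitivity = TP/(TP+FN)·100, specificity = TN/(TN+FP)·100,
    total accuracy = (TP+TN)/(TP+TN+FP+FN)·100."""
    def ratio(num: int, den: int) -> float | None:
        return None if den == 0 else 100.0 * num / den

    sens = ratio(counts.tp, counts.tp + counts.fn)
    spec = ratio(counts.tn, counts.tn + counts.fp)
    acc = 100.0 * (counts.tp + counts.tn) / (
        counts.tp + counts.tn + counts.fp + counts.fn
    )
    return MetricsReport(
        sensitivity={"positive": sens}, specificity={"positive": spec},
        total_accuracy=acc,
    )


def confusion_counts(y_true: Sequence, y_pred: Sequence, positive) -> ConfusionCounts:
    """One-vs-rest confusion counts for the given positive class."""
    yt = np.asarray(y_true)
    yp = np.asarray(y_pred)
    if yt.shape != yp.shape:
        raise ValueError("y_true and y_pred must have equal length")
    pos_t, pos_p = yt == positive, yp == positive
    return ConfusionCounts(
        tp=int((pos_t & pos_p).sum()),
        tn=int((~pos_t & ~pos_p).sum()),
        fp=int((~pos_t & pos_p).sum()),
        fn=int((pos_t & ~pos_p).sum()),
    )


def metrics_report(y_true: Sequence, y_pred: Sequence,
                   classes: Sequence | None = None) -> MetricsReport:
    """Per-class one-vs-rest sensitivity/specificity plus overall accuracy
    (fraction of correct predictions, as a percentage)."""
    yt = np.asarray(y_true)
    yp = np.asarray(y_pred)
    classes = tuple(classes) if classes is not None else tuple(np.unique(yt))
    sens: dict[str, float | None] = {}
    spec: dict[str, float | None] = {}
    for c in classes:
        counts = confusion_counts(yt, yp, c)
        m = compute_metrics(counts)
        sens[str(c)] = m.sensitivity["positive"]
        spec[str(c)] = m.specificity["positive"]
    return MetricsReport(
        sensitivity=sens, specificity=spec,
        total_accuracy=100.0 * float((yt == yp).mean()),
    )


def select_hyperparameters(
    X_train: np.ndarray,
    y_train: Sequence,
    X_val: np.ndarray,
    y_val: Sequence,
    kernel_kind: str = "gaussian_rbf",
    coding: CodingScheme | None = None,
    gammas: Sequence[float] = (1.0, 10.0, 100.0, 1000.0),
    sigma_factors: Sequence[float] = (0.5, 1.0, 2.0, 5.0),
    degrees: Sequence[int] = (2, 3),
) -> tuple[float, KernelSpec, float]:
    """Grid-search γ and the kernel parameter on the validation partition.

    Gaussian bandwidths are scaled by √d (d = feature count) so the grid
    tracks dimensionality.  Returns (gamma, kernel, validation accuracy %).
    """
    coding = coding or ovo_scheme(tuple(np.unique(np.asarray(y_train))))
    d = np.atleast_2d(X_train).shape[1]
    if kernel_kind == "gaussian_rbf":
        kernels = [KernelSpec(kind="gaussian_rbf", sigma=f * np.sqrt(d))
                   for f in sigma_factors]
    else:
        kernels = [KernelSpec(kind="polynomial", degree=deg) for deg in degrees]
    best = (-1.0, None, None)
    for kernel in kernels:
        for gamma in gammas:
            pred = multiclass_train_predict(X_train, y_train, X_val, coding,
                                            kernel, gamma)
            acc = 100.0 * float((pred == np.asarray(y_val)).mean())
            if acc > best[0]:
                best = (acc, gamma, kernel)
    return best[1], best[2], best[0]
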