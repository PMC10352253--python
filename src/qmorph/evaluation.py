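"""Multiclass SVM on precomputed Grams, the CV protocol, and the benchmark grid.

The evaluation protocol: an 80/20 stratified holdout, stratified 5-fold
cross-validation on the training partition (mean, standard deviation and the
95% confidence half-width 1.96 * sd / sqrt(k) are all reported), and a
benchmark grid enumerating rescaler x reducer x algorithm cells.  Every
algorithm — the four classical kernels, the seven static quantum encodings
and the aligned quantum kernel — flows through the identical
precomputed-Gram SVM code path, so rows differ only in how the Gram was
produced.

Multiclass classification is one-vs-one: a soft-margin binary SVM per class
pair (the quadratic program is solved by scikit-learn's SVC), majority
voting at prediction time with ties broken by the lowest class index.
"""

from __future__ import annotations

import logging
import math
import time
import warnings
from dataclasses import dataclass, field

import numpy as np

from .classical_kernels import ClassicalKernelSpec, gram
from .dimensionality import Reducer, select_top_k, tree_importances
from .kernel_training import QKAConfig, qka_statevectors, train_quantum_kernel
from .preprocessing import RESCALER_METHODS, Rescaler, encode_labels
from .quantum_kernels import FeatureMapSpec, KernelMatrix, statevectors
from .synthetic import MorphometryTable

logger = logging.getLogger(__name__)

__all__ = [
    "ALGORITHMS",
    "CVReport",
    "BenchmarkRow",
    "BenchmarkGrid",
    "PrecomputedSVM",
    "svm_fit_precomputed",
    "svm_predict",
    "holdout_split",
    "crossval_precomputed",
    "run_benchmark",
    "top_n",
    "default_extraction_grid",
    "default_selection_grid",
]

CLASSICAL_ALGORITHMS = ("SVM_linear", "SVM_rbf", "SVM_poly", "SVM_sigmoid")
QUANTUM_STATIC_ALGORITHMS = (
    "q_kernel_zz",
    "q_kernel_default",
    "q_kernel_8",
    "q_kernel_9",
    "q_kernel_10",
    "q_kernel_11",
    "q_kernel_12",
)
ALGORITHMS = CLASSICAL_ALGORITHMS + QUANTUM_STATIC_ALGORITHMS + ("q_kernel_training",)

_ENCODING_OF = {
    "q_kernel_zz": "zz",
    "q_kernel_default": "default",
    "q_kernel_8": "k8",
    "q_kernel_9": "k9",
    "q_kernel_10": "k10",
    "q_kernel_11": "k11",
    "q_kernel_12": "k12",
}

#: desk-scale guardrails for exact statevector simulation
MAX_QUBITS = 10
MAX_SAMPLES = 2080


# ---------------------------------------------------------------------------
# reports


@dataclass
class CVReport:
    """Per-fold accuracies with mean, dispersion and 95% CI half-width."""

    fold_scores: list[float]
    k: int
    seed: int | None = None

    @property
    def mean(self) -> float:
        return float(np.mean(self.fold_scores))

    @property
    def std(self) -> float:
        return float(np.std(self.fold_scores))

    @property
    def ci95_halfwidth(self) -> float:
        return float(1.96 * self.std / math.sqrt(self.k))

    def __post_init__(self) -> None:
        if len(self.fold_scores) != self.k:
            raise ValueError("fold_scores length must equal k")


@dataclass
class BenchmarkRow:
    """One (rescaler, reducer, algorithm) grid cell."""

    rescaling: str
    reduction: str
    algorithm: str
    cv_mean: float | None = None
    cv_std: float | None = None
    holdout_accuracy: float | None = None
    status: str = "ok"
    error: str | None = None
    n_qubits: int | None = None
    seconds: float | None = None

    @property
    def cell_name(self) -> str:
        return f"{self.rescaling}/{self.reduction}/{self.algorithm}"


# ---------------------------------------------------------------------------
# precomputed-kernel one-vs-one SVM


@dataclass
class _PairModel:
    classes: tuple[int, int]
    support: np.ndarray  # indices into the pair's training rows
    dual_coef: np.ndarray
    intercept: float
    rows: np.ndarray  # indices of the pair's rows in the full training order
    clf: object


class PrecomputedSVM:
    """One-vs-one ensemble of soft-margin SVMs on a precomputed Gram matrix."""

    def __init__(self, C: float = 1.0):
        self.C = C
        self.classes_: np.ndarray | None = None
        self.pairs_: list[_PairModel] = []
        self._n_train: int | None = None

    def fit(self, K_train: np.ndarray, y: np.ndarray) -> "PrecomputedSVM":
        from sklearn.svm import SVC

        K = K_train.values if isinstance(K_train, KernelMatrix) else np.asarray(K_train, float)
        y = np.asarray(y)
        if K.ndim != 2 or K.shape[0] != K.shape[1]:
            raise ValueError("K_train must be square")
        if len(y) != K.shape[0]:
            raise ValueError("label count must match the Gram dimension")
        self.classes_ = np.unique(y)
        if self.classes_.size < 2:
            raise ValueError("need at least 2 classes")
        self._n_train = K.shape[0]
        self.pairs_ = []
        for a in range(self.classes_.size):
            for b in range(a + 1, self.classes_.size):
                ca, cb = self.classes_[a], self.classes_[b]
                rows = np.flatnonzero((y == ca) | (y == cb))
                clf = SVC(kernel="precomputed", C=self.C)
                clf.fit(K[np.ix_(rows, rows)], y[rows])
                self.pairs_.append(
                    _PairModel(
                        classes=(ca, cb),
                        support=clf.support_.copy(),
                        dual_coef=clf.dual_coef_[0].copy(),
                        intercept=float(clf.intercept_[0]),
                        rows=rows,
                        clf=clf,
                    )
                )
        return self

    def predict(self, K_test_train: np.ndarray) -> np.ndarray:
        """Majority vote over pair classifiers; ties go to the lowest class index.

        Columns of ``K_test_train`` must align with the training order.
        """
        if self.classes_ is None:
            raise RuntimeError("model not fitted")
        K = (
            K_test_train.values
            if isinstance(K_test_train, KernelMatrix)
            else np.asarray(K_test_train, float)
        )
        K = np.atleast_2d(K)
        if K.shape[1] != self._n_train:
            raise ValueError(
                f"K_test_train has {K.shape[1]} columns; expected {self._n_train}"
            )
        votes = np.zeros((K.shape[0], self.classes_.size), dtype=int)
        class_pos = {c: i for i, c in enumerate(self.classes_)}
        for pm in self.pairs_:
            # decision > 0 votes the upper class; a degenerate decision of
            # exactly 0 (e.g. all-zero kernel rows) votes the lower class
            d = pm.clf.decision_function(K[:, pm.rows])
            lo, hi = pm.classes
            pred = np.where(d > 0, hi, lo)
            for c in pm.classes:
                votes[pred == c, class_pos[c]] += 1
        # argmax takes the first maximum -> lowest class index wins ties
        return self.classes_[np.argmax(votes, axis=1)]


def svm_fit_precomputed(K_train, y, C: float = 1.0) -> PrecomputedSVM:
    return PrecomputedSVM(C=C).fit(K_train, y)


def svm_predict(model: PrecomputedSVM, K_test_train) -> np.ndarray:
    return model.predict(K_test_train)


# ---------------------------------------------------------------------------
# splits and cross-validation


def holdout_split(
    table_or_y, train_fraction: float = 0.8, seed: int | None = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Stratified random holdout; returns (train_idx, test_idx) positions.

    Accepts a :class:`MorphometryTable` or a label vector.  Classes with a
    single member stay in the training split (with a warning).
    """
    if not 0.0 < train_fraction < 1.0:
        raise ValueError("train_fraction must be in (0, 1)")
    y = (
        table_or_y.labels
        if isinstance(table_or_y, MorphometryTable)
        else np.asarray(table_or_y)
    )
    rng = np.random.default_rng(seed)
    train, test = [], []
    for cls in np.unique(y):
        rows = np.flatnonzero(y == cls)
        if rows.size < 2:
            warnings.warn(
                f"class {cls!r} has a single member; kept in the training split",
                stacklevel=2,
            )
            train.extend(rows)
            continue
        rows = rng.permutation(rows)
        n_tr = int(round(train_fraction * rows.size))
        n_tr = min(max(n_tr, 1), rows.size - 1)
        train.extend(rows[:n_tr])
        test.extend(rows[n_tr:])
    return np.sort(np.asarray(train, dtype=int)), np.sort(np.asarray(test, dtype=int))


def crossval_precomputed(K, y, k: int = 5, seed: int | None = 0, C: float = 1.0) -> CVReport:
    """Stratified k-fold CV of the one-vs-one SVM on a full precomputed Gram."""
    from sklearn.model_selection import StratifiedKFold

    Kv = K.values if isinstance(K, KernelMatrix) else np.asarray(K, dtype=float)
    y = np.asarray(y)
    _, counts = np.unique(y, return_counts=True)
    if k > counts.min():
        raise ValueError(
            f"k = {k} exceeds the smallest class count ({counts.min()})"
        )
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    scores = []
    for tr, te in skf.split(Kv, y):
        model = PrecomputedSVM(C=C).fit(Kv[np.ix_(tr, tr)], y[tr])
        pred = model.predict(Kv[np.ix_(te, tr)])
        scores.append(float(np.mean(pred == y[te])))
    return CVReport(scores, k=k, seed=seed)


# ---------------------------------------------------------------------------
# the benchmark grid


@dataclass
class BenchmarkGrid:
    """Declarative grid: rescalers x reducers x algorithms.

    ``reducers`` entries are ``("selection", tree_method, k)`` or
    ``("extraction", method, n_components)``.
    """

    rescalers: list[str] = field(default_factory=lambda: list(RESCALER_METHODS))
    reducers: list[tuple] = field(default_factory=list)
    algorithms: list[str] = field(default_factory=lambda: ["SVM_rbf", "q_kernel_zz"])
    cv_k: int = 5
    train_fraction: float = 0.8
    C: float = 1.0
    seed: int = 0
    shots: int | None = None  # None = exact simulation
    qka: QKAConfig | None = None

    def cells(self):
        for r in self.rescalers:
            for red in self.reducers:
                for alg in self.algorithms:
                    yield r, red, alg

    def n_cells_per_algorithm(self) -> int:
        return len(self.rescalers) * len(self.reducers)


def default_extraction_grid(**overrides) -> BenchmarkGrid:
    """All 11 rescalers x all 14 extraction methods (2 components, 2 qubits)."""
    from .dimensionality import EXTRACTION_METHODS

    kw = dict(
        rescalers=list(RESCALER_METHODS),
        reducers=[("extraction", m, 2) for m in EXTRACTION_METHODS],
    )
    kw.update(overrides)
    return BenchmarkGrid(**kw)


def default_selection_grid(k: int = 5, **overrides) -> BenchmarkGrid:
    """All 11 rescalers x the 3 tree-based selectors (top-k features)."""
    from .dimensionality import TREE_METHODS

    kw = dict(
        rescalers=list(RESCALER_METHODS),
        reducers=[("selection", m, k) for m in TREE_METHODS],
    )
    kw.update(overrides)
    return BenchmarkGrid(**kw)


def _reduction_name(red: tuple) -> str:
    mode, method, k = red
    return f"{method}_top{k}" if mode == "selection" else f"{method}_{k}c"


def _quantum_grams(
    algorithm: str,
    X_train: np.ndarray,
    X_test: np.ndarray,
    y_train: np.ndarray,
    grid: BenchmarkGrid,
) -> tuple[np.ndarray, np.ndarray, int]:
    n_qubits = X_train.shape[1]
    if n_qubits > MAX_QUBITS:
        raise MemoryError(
            f"{n_qubits} qubits exceeds the exact-simulation preset cap of "
            f"{MAX_QUBITS}; reduce the feature count"
        )
    n_total = len(X_train) + len(X_test)
    if n_total > MAX_SAMPLES:
        raise MemoryError(
            f"{n_total} samples exceeds the exact-simulation preset cap of "
            f"{MAX_SAMPLES}"
        )
    if algorithm == "q_kernel_training":
        spec = FeatureMapSpec(n_qubits=n_qubits, encoding="zz")
        config = grid.qka or QKAConfig(seed=grid.seed)
        lam, _, _ = train_quantum_kernel(X_train, y_train, spec, config)
        S_tr = qka_statevectors(X_train, spec, lam)
        S_te = qka_statevectors(X_test, spec, lam)
    else:
        spec = FeatureMapSpec(n_qubits=n_qubits, encoding=_ENCODING_OF[algorithm])
        S_tr = statevectors(X_train, spec)
        S_te = statevectors(X_test, spec)
    K_train = np.abs(S_tr @ S_tr.conj().T) ** 2
    K_test = np.abs(S_te @ S_tr.conj().T) ** 2
    iu = np.triu_indices(len(K_train), k=1)
    K_train[(iu[1], iu[0])] = K_train[iu]
    if grid.shots:
        rng = np.random.default_rng(grid.seed)
        p = np.clip(K_train[iu], 0.0, 1.0)
        K_train = np.eye(len(K_train))
        draws = rng.binomial(grid.shots, p) / grid.shots
        K_train[iu] = draws
        K_train[(iu[1], iu[0])] = draws
        K_test = rng.binomial(grid.shots, np.clip(K_test, 0.0, 1.0)) / grid.shots
        from .quantum_kernels import psd_projection

        K_train = psd_projection(K_train).values
    return K_train, K_test, n_qubits


def _classical_grams(algorithm, X_train, X_test):
    spec = ClassicalKernelSpec(kernel=algorithm.removeprefix("SVM_"))
    K_train = gram(X_train, X_train, spec).values
    K_test = gram(X_test, X_train, spec).values
    return K_train, K_test


def run_benchmark(table: MorphometryTable, grid: BenchmarkGrid) -> list[BenchmarkRow]:
    """Execute every grid cell end-to-end (rescale -> reduce -> Gram -> CV).

    Cells that fail (singular encodings, non-positive data under Box-Cox, ...)
    are recorded as error rows rather than aborting the grid.  Deterministic
    under the grid's root seed: the holdout split and all per-cell seeds
    derive from it.
    """
    cells = list(grid.cells())
    if not cells:
        raise ValueError("empty benchmark grid")
    X_all = table.features
    if np.isnan(X_all).any():
        raise ValueError("table contains missing cells; run the filters first")
    y_all, classes = encode_labels(table.labels)

    train_idx, test_idx = holdout_split(y_all, grid.train_fraction, seed=grid.seed)
    rows: list[BenchmarkRow] = []

    for rescaler_name, red, algorithm in cells:
        mode, method, k = red
        row = BenchmarkRow(rescaler_name, _reduction_name(red), algorithm)
        t0 = time.perf_counter()
        try:
            resc = Rescaler(rescaler_name)
            Xtr = resc.fit(X_all[train_idx]).transform(X_all[train_idx])
            Xte = resc.transform(X_all[test_idx])
            ytr, yte = y_all[train_idx], y_all[test_idx]

            if mode == "selection":
                imp = tree_importances(Xtr, ytr, method=method, seed=grid.seed)
                keep = select_top_k(imp, k)
                Xtr, Xte = Xtr[:, keep], Xte[:, keep]
            else:
                reducer = Reducer(method, n_components=k, seed=grid.seed)
                if reducer.transductive:
                    logger.warning(
                        "cell %s: %s is transductive; embedding is fit on the "
                        "full rescaled design matrix before splitting",
                        row.cell_name,
                        method,
                    )
                    X_full = resc.transform(X_all)
                    emb = reducer.fit_transform(X_full, y_all)
                    Xtr, Xte = emb[train_idx], emb[test_idx]
                else:
                    Xtr = reducer.fit_transform(Xtr, ytr)
                    Xte = reducer.transform(Xte)

            if algorithm in CLASSICAL_ALGORITHMS:
                K_train, K_test = _classical_grams(algorithm, Xtr, Xte)
            else:
                K_train, K_test, nq = _quantum_grams(algorithm, Xtr, Xte, ytr, grid)
                row.n_qubits = nq

            report = crossval_precomputed(K_train, ytr, k=grid.cv_k, seed=grid.seed,
                                          C=grid.C)
            model = PrecomputedSVM(C=grid.C).fit(K_train, ytr)
            pred = model.predict(K_test)
            row.cv_mean = report.mean
            row.cv_std = report.std
            row.holdout_accuracy = float(np.mean(pred == yte))
        except Exception as exc:  # noqa: BLE001 - grid cells must not abort the run
            row.status = "error"
            row.error = f"{type(exc).__name__}: {exc}"
            logger.warning("cell %s failed: %s", row.cell_name, row.error)
        row.seconds = time.perf_counter() - t0
        logger.info(
            "cell %s: status=%s cv_mean=%s (%.2fs)",
            row.cell_name, row.status, row.cv_mean, row.seconds,
        )
        rows.append(row)
    return rows


def top_n(rows: list[BenchmarkRow], n: int = 5) -> list[BenchmarkRow]:
    """Best rows by CV mean (descending); ties by lower std, then cell name."""
    if not rows:
        raise ValueError("no benchmark rows to rank")
    ok = [r for r in rows if r.status == "ok" and r.cv_mean is not None]
    ranked = sorted(ok, key=lambda r: (-r.cv_mean, r.cv_std, r.cell_name))
    return ranked[:n]


def rows_to_frame(rows: list[BenchmarkRow]):
    """Benchmark rows as a DataFrame mirroring the result-table columns."""
    import pandas as pd

    return pd.DataFrame(
        {
            "rescaling": [r.rescaling for r in rows],
            "feature_reduction": [r.reduction for r in rows],
            "algorithm": [r.algorithm for r in rows],
            "cv_mean": [r.cv_mean for r in rows],
            "cv_std": [r.cv_std for r in rows],
            "holdout_accuracy": [r.holdout_accuracy for r in rows],
            "status": [r.status for r in rows],
            "error": [r.error for r in rows],
        }
    )
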