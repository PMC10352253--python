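"""Model/Results surface over the kernel-SVM pipeline.

:class:`KernelSVMModel` is built from data (a feature matrix and labels, or
a :class:`~qmorph.synthetic.MorphometryTable`) together with one kernel
choice; :meth:`KernelSVMModel.fit` runs the holdout + cross-validation
protocol and returns a :class:`KernelSVMResults` carrying the fold scores,
their dispersion, the holdout accuracy and a ``summary()`` table.

This is a presentation layer: all computation lives in the library modules
(:mod:`~qmorph.quantum_kernels`, :mod:`~qmorph.kernel_training`,
:mod:`~qmorph.classical_kernels`, :mod:`~qmorph.evaluation`).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .evaluation import (
    ALGORITHMS,
    CLASSICAL_ALGORITHMS,
    CVReport,
    PrecomputedSVM,
    _classical_grams,
    _quantum_grams,
    BenchmarkGrid,
    crossval_precomputed,
    holdout_split,
)
from .kernel_training import QKAConfig
from .preprocessing import Rescaler, encode_labels
from .synthetic import MorphometryTable

__all__ = ["KernelSVMModel", "KernelSVMResults"]


class KernelSVMModel:
    """A multiclass SVM with a chosen (quantum or classical) kernel.

    Parameters
    ----------
    X, y
        Feature matrix (one qubit per feature for quantum kernels) and labels.
    algorithm
        One of ``SVM_linear | SVM_rbf | SVM_poly | SVM_sigmoid |
        q_kernel_zz | q_kernel_default | q_kernel_8..12 | q_kernel_training``.
    rescale
        Optional rescaling method applied inside the protocol (fit on the
        training partition only).
    C
        Soft-margin regularisation.
    """

    def __init__(self, X, y, algorithm: str = "q_kernel_zz",
                 rescale: str | None = None, C: float = 1.0,
                 qka: QKAConfig | None = None):
        if algorithm not in ALGORITHMS:
            raise ValueError(f"unknown algorithm {algorithm!r}; choose from {ALGORITHMS}")
        self.X = np.atleast_2d(np.asarray(X, dtype=float))
        self.y_raw = np.asarray(y)
        self.y, self.classes = encode_labels(self.y_raw)
        self.algorithm = algorithm
        self.rescale = rescale
        self.C = C
        self.qka = qka

    @classmethod
    def from_table(cls, table: MorphometryTable, **kwargs) -> "KernelSVMModel":
        return cls(table.features, table.labels, **kwargs)

    def fit(self, cv: int = 5, train_fraction: float = 0.8,
            seed: int = 0) -> "KernelSVMResults":
        """Run holdout + stratified k-fold CV; returns the results object."""
        train_idx, test_idx = holdout_split(self.y, train_fraction, seed=seed)
        Xtr, Xte = self.X[train_idx], self.X[test_idx]
        ytr, yte = self.y[train_idx], self.y[test_idx]
        if self.rescale:
            resc = Rescaler(self.rescale).fit(Xtr)
            Xtr, Xte = resc.transform(Xtr), resc.transform(Xte)

        if self.algorithm in CLASSICAL_ALGORITHMS:
            K_train, K_test = _classical_grams(self.algorithm, Xtr, Xte)
            n_qubits = None
        else:
            grid = BenchmarkGrid(seed=seed, C=self.C, qka=self.qka)
            K_train, K_test, n_qubits = _quantum_grams(
                self.algorithm, Xtr, Xte, ytr, grid
            )

        report = crossval_precomputed(K_train, ytr, k=cv, seed=seed, C=self.C)
        model = PrecomputedSVM(C=self.C).fit(K_train, ytr)
        holdout_acc = float(np.mean(model.predict(K_test) == yte))
        return KernelSVMResults(
            model=self,
            cv_report=report,
            holdout_accuracy=holdout_acc,
            n_train=len(train_idx),
            n_test=len(test_idx),
            n_qubits=n_qubits,
            svm=model,
            seed=seed,
        )


@dataclass
class KernelSVMResults:
    """Fitted protocol results: fold scores, holdout accuracy, support sizes."""

    model: KernelSVMModel
    cv_report: CVReport
    holdout_accuracy: float
    n_train: int
    n_test: int
    n_qubits: int | None
    svm: PrecomputedSVM
    seed: int

    @property
    def cv_mean(self) -> float:
        return self.cv_report.mean

    @property
    def cv_std(self) -> float:
        return self.cv_report.std

    def summary(self) -> str:
        m = self.model
        lines = [
            "Kernel SVM classification results",
            "=" * 49,
            f"{'algorithm':<28}{m.algorithm:>21}",
            f"{'rescaling':<28}{str(m.rescale):>21}",
            f"{'classes':<28}{len(m.classes):>21}",
            f"{'train / test rows':<28}{f'{self.n_train} / {self.n_test}':>21}",
        ]
        if self.n_qubits is not None:
            lines.append(f"{'qubits':<28}{self.n_qubits:>21}")
        lines += [
            "-" * 49,
            f"{'cv folds':<28}{self.cv_report.k:>21}",
            f"{'cv mean accuracy':<28}{self.cv_mean:>21.4f}",
            f"{'cv std':<28}{self.cv_std:>21.4f}",
            f"{'cv 95% CI half-width':<28}{self.cv_report.ci95_halfwidth:>21.4f}",
            f"{'holdout accuracy':<28}{self.holdout_accuracy:>21.4f}",
            "=" * 49,
        ]
        return "\n".join(lines)
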