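"""The four classical SVM kernels, emitted as precomputed Gram matrices.

Classical and quantum kernels flow through the same precomputed-Gram SVM
path, so a benchmark cell differs only in how its Gram matrix was produced.

Kernels (entry for samples x_i, x_j):

* linear    x_i . x_j
* rbf       exp(-||x_i - x_j||^2 / (2 sigma^2))
* poly      (x_i . x_j + a)^b
* sigmoid   tanh(a x_i . x_j - b)

Unset parameters resolve from the training data at evaluation time:
sigma such that 1/(2 sigma^2) = 1/(n_features * Var(X)); poly offset a = 1,
degree b = 3; sigmoid slope a = 1/n_features, offset b = 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.metrics.pairwise import (
    linear_kernel,
    polynomial_kernel,
    rbf_kernel,
    sigmoid_kernel,
)

from .quantum_kernels import KernelMatrix

__all__ = ["CLASSICAL_KERNELS", "ClassicalKernelSpec", "gram"]

CLASSICAL_KERNELS = ("linear", "rbf", "poly", "sigmoid")


@dataclass(frozen=True)
class ClassicalKernelSpec:
    """Kernel name plus its free parameters (None = resolve from data)."""

    kernel: str
    sigma: float | None = None  # rbf width
    a: float | None = None  # poly offset / sigmoid slope
    b: float | None = None  # poly degree / sigmoid offset

    def __post_init__(self) -> None:
        if self.kernel not in CLASSICAL_KERNELS:
            raise ValueError(
                f"unknown kernel {self.kernel!r}; choose from {CLASSICAL_KERNELS}"
            )
        if self.sigma is not None and self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if self.kernel == "poly" and self.b is not None:
            if self.b != int(self.b) or self.b < 1:
                raise ValueError("poly degree b must be a positive integer")


def gram(X: np.ndarray, Z: np.ndarray, spec: ClassicalKernelSpec) -> KernelMatrix:
    """Gram block between the rows of X and Z (X is Z for the training Gram)."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    Z = np.atleast_2d(np.asarray(Z, dtype=float))
    if X.shape[1] != Z.shape[1]:
        raise ValueError("X and Z must have the same feature count")
    d = X.shape[1]

    if spec.kernel == "linear":
        K = linear_kernel(X, Z)
    elif spec.kernel == "rbf":
        if spec.sigma is not None:
            gamma = 1.0 / (2.0 * spec.sigma**2)
        else:
            var = Z.var()
            gamma = 1.0 / (d * var) if var > 0 else 1.0 / d
        K = rbf_kernel(X, Z, gamma=gamma)
    elif spec.kernel == "poly":
        a = 1.0 if spec.a is None else spec.a
        b = 3 if spec.b is None else int(spec.b)
        K = polynomial_kernel(X, Z, degree=b, gamma=1.0, coef0=a)
    else:  # sigmoid: tanh(a x.z - b)
        a = 1.0 / d if spec.a is None else spec.a
        b = 0.0 if spec.b is None else spec.b
        K = sigmoid_kernel(X, Z, gamma=a, coef0=-b)

    return KernelMatrix(np.asarray(K, dtype=float), mode="exact",
                        meta={"classical": spec.kernel})
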