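"""Independent dense linear-algebra oracles for checking the statevector engine.

Everything here is built from explicit matrices — Kronecker products, a dense
matrix exponential of the Pauli-Z generator, dense Hadamard tensors — and
never calls the fast-transform engine it is used to verify.
"""

import numpy as np
from scipy.linalg import expm

from qmorph.quantum_kernels import FeatureMapSpec, pair_phase, singleton_phase

Z = np.diag([1.0, -1.0])
I2 = np.eye(2)
H1 = np.array([[1.0, 1.0], [1.0, -1.0]]) / np.sqrt(2.0)


def kron_at(op: np.ndarray, qubit: int, n: int) -> np.ndarray:
    """Operator acting on one qubit; qubit 0 is the least-significant bit."""
    mats = [I2] * n
    mats[n - 1 - qubit] = op
    out = mats[0]
    for m in mats[1:]:
        out = np.kron(out, m)
    return out


def dense_hadamard(n: int) -> np.ndarray:
    out = H1
    for _ in range(n - 1):
        out = np.kron(out, H1)
    return out


def dense_generator(x: np.ndarray, spec: FeatureMapSpec) -> np.ndarray:
    """The Hermitian generator sum_S phi_S(x) prod_{i in S} Z_i as a dense matrix."""
    n = spec.n_qubits
    A = np.zeros((2**n, 2**n))
    for i in range(n):
        A += singleton_phase(x[i]) * kron_at(Z, i, n)
    for i, j in spec.pairs:
        A += pair_phase(spec.encoding, x[i], x[j]) * (kron_at(Z, i, n) @ kron_at(Z, j, n))
    return A


def dense_encoding_unitary(x: np.ndarray, spec: FeatureMapSpec) -> np.ndarray:
    return expm(1j * dense_generator(x, spec))


def dense_feature_state(x: np.ndarray, spec: FeatureMapSpec) -> np.ndarray:
    """(U_Phi H^{x n})^reps |0^n> built from dense matrices."""
    n = spec.n_qubits
    U = dense_encoding_unitary(x, spec)
    Hn = dense_hadamard(n)
    psi = np.zeros(2**n, dtype=complex)
    psi[0] = 1.0
    for _ in range(spec.reps):
        psi = U @ (Hn @ psi)
    return psi


def dense_fidelity(x, y, spec: FeatureMapSpec) -> float:
    a, b = dense_feature_state(x, spec), dense_feature_state(y, spec)
    return float(abs(np.vdot(a, b)) ** 2)


def dense_ry(theta: float) -> np.ndarray:
    c, s = np.cos(theta / 2.0), np.sin(theta / 2.0)
    return np.array([[c, -s], [s, c]])


def dense_fiducial_feature_state(x, spec: FeatureMapSpec, lam) -> np.ndarray:
    """D(x) [H D(x)]^{reps-1} U_lambda |0^n> from dense matrices."""
    n = spec.n_qubits
    lam = np.atleast_1d(np.asarray(lam, dtype=float))
    if lam.size == 1:
        lam = np.repeat(lam, n)
    U_lam = kron_at(dense_ry(lam[0]), 0, n)
    for q in range(1, n):
        U_lam = kron_at(dense_ry(lam[q]), q, n) @ U_lam
    U = dense_encoding_unitary(x, spec)
    Hn = dense_hadamard(n)
    psi = np.zeros(2**n, dtype=complex)
    psi[0] = 1.0
    psi = U @ (U_lam @ psi)
    for _ in range(spec.reps - 1):
        psi = U @ (Hn @ psi)
    return psi


def brute_force_svm_dual(K: np.ndarray, y: np.ndarray, C: float, steps: int = 21) -> float:
    """Maximum of the SVM dual objective over a dense grid of alpha vectors.

    Enumerates alpha on a grid in [0, C]^n, keeps the equality-constrained
    points (sum alpha_i y_i = 0) and returns the best objective.  Only viable
    for a handful of samples; used as the independent oracle for svc_loss.
    """
    import itertools

    y = np.asarray(y, dtype=float)
    n = len(y)
    grid = np.linspace(0.0, C, steps)
    best = -np.inf
    for alpha in itertools.product(grid, repeat=n):
        alpha = np.asarray(alpha)
        if abs(alpha @ y) > 1e-12:
            continue
        obj = alpha.sum() - 0.5 * (alpha * y) @ K @ (alpha * y)
        best = max(best, obj)
    return best
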