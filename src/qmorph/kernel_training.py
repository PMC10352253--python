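"""Quantum kernel alignment (QKA).

A parametrized fiducial state U_lambda |0^n> — here a single layer of
single-qubit Y rotations R_y(lambda_q) — replaces the first Hadamard-prepared
layer of the feature map, giving the family of kernels

    K_lambda(x, x~) = |<0^n| U_lambda^+ D^+(x) D(x~) U_lambda |0^n>|^2 ,

where D is the data-encoding block of :mod:`qmorph.quantum_kernels`.  With
per-qubit lambda = pi/2, R_y(pi/2)|0> = H|0> and the base feature map is
recovered exactly, which is also the default starting point for training.

Alignment minimises the soft-margin SVM dual objective (SVCLoss)

    L(lambda) = sum_i alpha_i - 1/2 sum_ij alpha_i alpha_j y_i y_j K_lambda,ij

(alpha the attained dual optimum) over lambda with simultaneous perturbation
stochastic approximation (SPSA): two objective evaluations per iteration
along a random Rademacher direction, constant gains, 10 iterations, learning
rate 0.05 and perturbation magnitude 0.05 by default.  Minimising the dual
optimum over the kernel family maximises the achievable SVM margin.
Multiclass problems are aligned by summing the one-vs-one binary losses
under a shared lambda.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .quantum_kernels import (
    FeatureMapSpec,
    KernelMatrix,
    StateVector,
    _evolve,
    phase_table,
)

__all__ = [
    "QKAConfig",
    "SPSATrace",
    "fiducial_state",
    "qka_statevectors",
    "qka_kernel_matrix",
    "svc_loss",
    "spsa_minimize",
    "train_quantum_kernel",
    "planted_alignment_problem",
]


@dataclass(frozen=True)
class QKAConfig:
    """SPSA and SVM settings for kernel alignment."""

    maxiter: int = 10
    learning_rate: float = 0.05
    perturbation: float = 0.05
    C: float = 1.0
    seed: int = 0
    gain_decay: bool = False  # standard decaying SPSA schedules instead of constant gains
    initial_lambda: tuple[float, ...] | None = None  # default: pi/2 per qubit

    def __post_init__(self) -> None:
        if self.maxiter < 1:
            raise ValueError(f"maxiter must be >= 1, got {self.maxiter}")
        if self.learning_rate <= 0 or self.perturbation <= 0:
            raise ValueError("learning_rate and perturbation must be positive")
        if self.C <= 0:
            raise ValueError("C must be positive")
        if self.initial_lambda is not None and not np.isfinite(self.initial_lambda).all():
            raise ValueError("initial_lambda must be finite")


@dataclass
class SPSATrace:
    """Every objective evaluation made during one SPSA run."""

    iterations: list[int] = field(default_factory=list)
    kinds: list[str] = field(default_factory=list)  # init | plus | minus | final
    lambdas: list[np.ndarray] = field(default_factory=list)
    objectives: list[float] = field(default_factory=list)

    def record(self, iteration: int, kind: str, lam: np.ndarray, value: float) -> None:
        self.iterations.append(iteration)
        self.kinds.append(kind)
        self.lambdas.append(np.array(lam, dtype=float))
        self.objectives.append(float(value))

    def __len__(self) -> int:
        return len(self.objectives)

    def best(self) -> tuple[np.ndarray, float]:
        i = int(np.argmin(self.objectives))
        return self.lambdas[i], self.objectives[i]

    def to_frame(self):
        import pandas as pd

        lam = np.stack(self.lambdas)
        frame = pd.DataFrame({"iteration": self.iterations, "kind": self.kinds,
                              "objective": self.objectives})
        for q in range(lam.shape[1]):
            frame[f"lambda_{q}"] = lam[:, q]
        return frame


class SPSAError(RuntimeError):
    """Objective returned a non-finite value; carries the partial trace."""

    def __init__(self, message: str, trace: SPSATrace):
        super().__init__(message)
        self.trace = trace


# ---------------------------------------------------------------------------
# fiducial states and the aligned kernel


def _broadcast_lambda(lam, n_qubits: int) -> np.ndarray:
    lam = np.atleast_1d(np.asarray(lam, dtype=float))
    if lam.shape == (1,):
        lam = np.repeat(lam, n_qubits)
    if lam.shape != (n_qubits,):
        raise ValueError(
            f"lambda must have length 1 or n_qubits ({n_qubits}), got {lam.shape}"
        )
    if not np.isfinite(lam).all():
        raise ValueError("lambda must be finite")
    return lam


def fiducial_state(lam, n_qubits: int) -> StateVector:
    """U_lambda |0^n> for a layer of Y rotations: per qubit (cos l/2, sin l/2)."""
    lam = _broadcast_lambda(lam, n_qubits)
    amps = np.array([1.0 + 0.0j])
    for q in range(n_qubits - 1, -1, -1):
        # qubit 0 is the least-significant bit, so it is the innermost factor
        qamp = np.array([math.cos(lam[q] / 2.0), math.sin(lam[q] / 2.0)], dtype=complex)
        amps = np.kron(amps, qamp)
    return StateVector(amps, n_qubits)


def _fiducial_feature_state(x, spec: FeatureMapSpec, lam) -> np.ndarray:
    """D(x) [H D(x)]^{reps-1} U_lambda |0^n>: the fiducial replaces the first H layer."""
    a = fiducial_state(lam, spec.n_qubits).amplitudes
    phases = np.exp(1j * phase_table(x, spec))
    a = a * phases  # first encoding layer acts directly on the fiducial
    if spec.reps > 1:
        a = _evolve(a, phases, spec.reps - 1)
    return a


def qka_statevectors(X: np.ndarray, spec: FeatureMapSpec, lam) -> np.ndarray:
    X = np.atleast_2d(np.asarray(X, dtype=float))
    return np.stack([_fiducial_feature_state(x, spec, lam) for x in X])


def qka_kernel_matrix(X: np.ndarray, spec: FeatureMapSpec, lam) -> KernelMatrix:
    """Aligned Gram matrix |<psi_lambda(x_i)|psi_lambda(x_j)>|^2 (exact mode)."""
    S = qka_statevectors(X, spec, lam)
    K = np.abs(S @ S.conj().T) ** 2
    iu = np.triu_indices(len(K), k=1)
    K[(iu[1], iu[0])] = K[iu]
    lam_arr = _broadcast_lambda(lam, spec.n_qubits)
    return KernelMatrix(K, mode="exact", spec=spec, meta={"lambda": lam_arr.tolist()})


# ---------------------------------------------------------------------------
# loss and optimiser


def svc_loss(K: np.ndarray | KernelMatrix, y: np.ndarray, C: float = 1.0) -> float:
    """Attained soft-margin SVM dual objective on a precomputed binary kernel.

    The quadratic program is solved by scikit-learn's SVC; the objective
    sum alpha - 1/2 sum_ij alpha_i alpha_j y_i y_j K_ij is assembled here
    from the returned dual coefficients.
    """
    from sklearn.svm import SVC

    Kv = K.values if isinstance(K, KernelMatrix) else np.asarray(K, dtype=float)
    y = np.asarray(y)
    classes = np.unique(y)
    if classes.size != 2:
        raise ValueError(f"svc_loss requires binary labels, got {classes.size} classes")
    clf = SVC(kernel="precomputed", C=C).fit(Kv, y)
    sv = clf.support_
    signed_alpha = clf.dual_coef_[0]  # y_i * alpha_i over support vectors
    alpha = np.abs(signed_alpha)
    return float(alpha.sum() - 0.5 * signed_alpha @ Kv[np.ix_(sv, sv)] @ signed_alpha)


def spsa_minimize(objective, lam0, config: QKAConfig) -> tuple[np.ndarray, SPSATrace]:
    """Gradient-free SPSA minimisation with constant gains.

    Per iteration k: draw a Rademacher direction Delta, evaluate the
    objective at lambda +- c Delta, form the simultaneous-perturbation
    gradient estimate ((f+ - f-) / 2c) * Delta and step lambda <- lambda -
    a * g.  Records every evaluation (2 per iteration plus the initial and
    final points) and returns the best-evaluated lambda.  Deterministic
    given the config seed.
    """
    lam = np.atleast_1d(np.asarray(lam0, dtype=float)).copy()
    rng = np.random.default_rng(config.seed)
    trace = SPSATrace()

    def evaluate(iteration: int, kind: str, point: np.ndarray) -> float:
        value = float(objective(point))
        if not math.isfinite(value):
            trace.record(iteration, kind, point, value)
            raise SPSAError(
                f"objective returned non-finite value {value!r} at iteration {iteration}",
                trace,
            )
        trace.record(iteration, kind, point, value)
        return value

    evaluate(0, "init", lam)
    for k in range(1, config.maxiter + 1):
        if config.gain_decay:
            a_k = config.learning_rate / k**0.602
            c_k = config.perturbation / k**0.101
        else:
            a_k, c_k = config.learning_rate, config.perturbation
        delta = rng.choice((-1.0, 1.0), size=lam.shape)
        f_plus = evaluate(k, "plus", lam + c_k * delta)
        f_minus = evaluate(k, "minus", lam - c_k * delta)
        grad = (f_plus - f_minus) / (2.0 * c_k) * delta  # delta^-1 == delta elementwise
        lam = lam - a_k * grad
    evaluate(config.maxiter, "final", lam)

    best_lam, _ = trace.best()
    return best_lam, trace


def _ovo_alignment_loss(K: np.ndarray, y: np.ndarray, C: float) -> float:
    """Sum of one-vs-one binary SVCLosses on the restricted sub-Grams."""
    classes = np.unique(y)
    total = 0.0
    for a in range(len(classes)):
        for b in range(a + 1, len(classes)):
            mask = (y == classes[a]) | (y == classes[b])
            total += svc_loss(K[np.ix_(mask, mask)], y[mask], C)
    return total


def train_quantum_kernel(
    X: np.ndarray,
    y: np.ndarray,
    spec: FeatureMapSpec,
    config: QKAConfig | None = None,
) -> tuple[np.ndarray, KernelMatrix, SPSATrace]:
    """Align the fiducial parameters to (X, y); returns (lambda*, K_lambda*, trace)."""
    config = config or QKAConfig()
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y)
    if np.unique(y).size < 2:
        raise ValueError("kernel alignment requires at least 2 classes")

    if config.initial_lambda is not None:
        lam0 = _broadcast_lambda(np.asarray(config.initial_lambda), spec.n_qubits)
    else:
        lam0 = np.full(spec.n_qubits, math.pi / 2.0)

    def objective(lam):
        K = qka_kernel_matrix(X, spec, lam)
        return _ovo_alignment_loss(K.values, y, config.C)

    lam_star, trace = spsa_minimize(objective, lam0, config)
    return lam_star, qka_kernel_matrix(X, spec, lam_star), trace


# ---------------------------------------------------------------------------
# planted diagnostic problem


def planted_alignment_problem(
    n_samples: int = 24, seed: int = 0
) -> tuple[np.ndarray, np.ndarray, FeatureMapSpec]:
    """A synthetic 2-feature binary problem where the fiducial matters.

    A candidate pool is drawn uniformly in [0, 1]^2 and labelled by the top
    eigenvector of the double-centred kernel difference K_{pi/2} - K_0, and
    the strongest half of each side is kept: by construction the two classes
    cluster in the feature space of the Hadamard-equivalent fiducial
    (lambda = pi/2) and anti-cluster under the trivial fiducial (lambda = 0),
    so alignment over lambda has a real margin to gain.  Returns
    ``(X, y, spec)`` with labels in {-1, +1}.
    """
    spec = FeatureMapSpec(n_qubits=2, reps=2, encoding="zz")
    rng = np.random.default_rng(seed)
    n_cand = 2 * n_samples
    X = rng.uniform(0.0, 1.0, size=(n_cand, 2))
    K_h = qka_kernel_matrix(X, spec, np.full(2, math.pi / 2.0)).values
    K_0 = qka_kernel_matrix(X, spec, np.zeros(2)).values
    J = np.eye(n_cand) - np.full((n_cand, n_cand), 1.0 / n_cand)
    v = np.linalg.eigh(J @ (K_h - K_0) @ J)[1][:, -1]
    half = n_samples // 2
    hi = np.argsort(-v)[:half]
    lo = np.argsort(v)[: n_samples - half]
    keep = np.sort(np.concatenate([hi, lo]))
    y = np.where(np.isin(np.arange(n_cand), hi), 1, -1)[keep]
    return X[keep], y, spec
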