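"""Statevector engine for diagonal Pauli-Z feature maps and fidelity kernels.

A feature vector x (one entry per qubit) is encoded into an n-qubit state

    |psi(x)> = (D(x) H^{x n})^reps |0^n>,

where H^{x n} is the n-fold Hadamard and D(x) = exp(i sum_S phi_S(x) prod_{i in S} Z_i)
is diagonal in the computational basis, with phase functions phi over
singletons (phi_{i}(x) = x_i for every encoding) and entangled qubit pairs.
The fidelity kernel between two samples is the all-zero transition
probability K(x, x~) = |<psi(x)|psi(x~)>|^2, evaluated either exactly from
the statevectors or by binomial "shot" sampling that emulates repeated
circuit measurement.

Because D is diagonal, the whole map needs only a phase table over the 2^n
basis states and a fast Walsh-Hadamard transform per repetition — O(reps *
n * 2^n) per sample, no dense unitaries.

Basis ordering convention: bit i of the basis index b is the Z eigenvalue
bit of qubit i, with qubit 0 the least-significant bit.  Fidelity kernels do
not depend on this choice, but the phase tables and statevectors do, and the
dense-oracle tests pin it down.

The seven pair-phase encodings:

========  ==========================================
zz        (pi - x_i)(pi - x_j)
default   product form prod_{j in S}(pi - x_j)  (coincides with zz on pairs)
k8        pi * x_i * x_j
k9        (pi/2)(1 - x_i)(1 - x_j)
k10       exp(|x_i - x_j|^2 / (8 / ln pi))
k11       pi / (3 cos(x_i) cos(x_j))   (singular; inputs must be bounded)
k12       pi * cos(x_i) cos(x_j)
========  ==========================================
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import yaml

__all__ = [
    "ENCODINGS",
    "FeatureMapSpec",
    "StateVector",
    "KernelMatrix",
    "singleton_phase",
    "pair_phase",
    "phase_table",
    "walsh_hadamard",
    "feature_state",
    "statevectors",
    "kernel_entry_exact",
    "kernel_matrix",
    "psd_projection",
]

ENCODINGS = ("zz", "default", "k8", "k9", "k10", "k11", "k12")

_DEFAULT_MEMORY_BUDGET = 2 * 1024**3  # bytes of statevector cache

#: running count of amplitude updates, for asserting the O(reps * n * 2^n)
#: cost model by instrumentation rather than wall-clock
OPS = {"amplitude_updates": 0}


def full_entanglement(n_qubits: int) -> list[tuple[int, int]]:
    """All ordered pairs i < j."""
    return [(i, j) for i in range(n_qubits) for j in range(i + 1, n_qubits)]


@dataclass(frozen=True)
class FeatureMapSpec:
    """Shape of the feature map: qubit count, repetitions, pair graph, encoding."""

    n_qubits: int
    reps: int = 2
    entanglement: tuple[tuple[int, int], ...] | None = None
    encoding: str = "zz"

    def __post_init__(self) -> None:
        if self.n_qubits < 1:
            raise ValueError(f"n_qubits must be >= 1, got {self.n_qubits}")
        if self.reps < 1:
            raise ValueError(f"reps must be >= 1, got {self.reps}")
        if self.encoding not in ENCODINGS:
            raise ValueError(f"unknown encoding {self.encoding!r}; choose from {ENCODINGS}")
        if self.entanglement is not None:
            seen = set()
            for pair in self.entanglement:
                i, j = pair
                if not (0 <= i < self.n_qubits and 0 <= j < self.n_qubits) or i == j:
                    raise ValueError(f"invalid entanglement pair {pair!r}")
                if (i, j) in seen:
                    raise ValueError(f"duplicate entanglement pair {pair!r}")
                seen.add((i, j))

    @property
    def pairs(self) -> list[tuple[int, int]]:
        if self.entanglement is None:
            return full_entanglement(self.n_qubits)
        return [tuple(p) for p in self.entanglement]

    def to_yaml(self) -> str:
        return yaml.safe_dump(
            {
                "n_qubits": self.n_qubits,
                "reps": self.reps,
                "entanglement": None
                if self.entanglement is None
                else [list(p) for p in self.entanglement],
                "encoding": self.encoding,
            }
        )

    @classmethod
    def from_yaml(cls, text: str) -> "FeatureMapSpec":
        raw = yaml.safe_load(text)
        ent = raw.get("entanglement")
        if ent is not None:
            ent = tuple(tuple(p) for p in ent)
        return cls(raw["n_qubits"], raw.get("reps", 2), ent, raw.get("encoding", "zz"))


@dataclass
class StateVector:
    """2^n complex amplitudes with unit Euclidean norm."""

    amplitudes: np.ndarray
    n_qubits: int

    def __post_init__(self) -> None:
        self.amplitudes = np.asarray(self.amplitudes, dtype=complex)
        if self.amplitudes.shape != (2**self.n_qubits,):
            raise ValueError(
                f"expected {2**self.n_qubits} amplitudes, got {self.amplitudes.shape}"
            )
        norm = np.linalg.norm(self.amplitudes)
        if abs(norm - 1.0) > 1e-10:
            raise ValueError(f"state norm is {norm!r}, not 1 +- 1e-10")


@dataclass
class KernelMatrix:
    """Symmetric Gram matrix with provenance (mode exact|shots)."""

    values: np.ndarray
    mode: str = "exact"
    shots: int | None = None
    spec: FeatureMapSpec | None = None
    seed: int | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.mode not in ("exact", "shots"):
            raise ValueError(f"mode must be 'exact' or 'shots', got {self.mode!r}")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def min_eigenvalue(self) -> float:
        return float(np.linalg.eigvalsh(self.values).min())


# ---------------------------------------------------------------------------
# phase functions


def singleton_phase(x_i: float) -> float:
    """First-order phase phi_{i}(x) = x_i (shared by all encodings)."""
    x_i = float(x_i)
    if not math.isfinite(x_i):
        raise ValueError(f"singleton phase requires a finite input, got {x_i!r}")
    return x_i


def pair_phase(encoding: str, x_i: float, x_j: float) -> float:
    """Second-order phase phi_{i,j}(x) for an entangled qubit pair."""
    if encoding not in ENCODINGS:
        raise ValueError(f"unknown encoding {encoding!r}; choose from {ENCODINGS}")
    x_i, x_j = float(x_i), float(x_j)
    if not (math.isfinite(x_i) and math.isfinite(x_j)):
        raise ValueError("pair phase requires finite inputs")
    if encoding in ("zz", "default"):
        return (math.pi - x_i) * (math.pi - x_j)
    if encoding == "k8":
        return math.pi * x_i * x_j
    if encoding == "k9":
        return (math.pi / 2.0) * (1.0 - x_i) * (1.0 - x_j)
    if encoding == "k10":
        return math.exp(abs(x_i - x_j) ** 2 / (8.0 / math.log(math.pi)))
    if encoding == "k11":
        denom = math.cos(x_i) * math.cos(x_j)
        if abs(denom) < 1e-12:
            raise ValueError(
                "k11 pair phase is singular at cos(x_i)cos(x_j) = 0; rescale the "
                "inputs into a bounded interval away from pi/2 + k*pi"
            )
        return math.pi / (3.0 * denom)
    # k12
    return math.pi * math.cos(x_i) * math.cos(x_j)


def phase_table(x: np.ndarray, spec: FeatureMapSpec) -> np.ndarray:
    """Diagonal of the Hermitian generator of D(x) over the 2^n basis states.

    Entry for basis state b is
    ``sum_i phi_i(x) (-1)^{b_i} + sum_{(i,j)} phi_ij(x) (-1)^{b_i + b_j}``.
    """
    x = np.asarray(x, dtype=float).ravel()
    n = spec.n_qubits
    if x.shape != (n,):
        raise ValueError(f"expected {n} features for {n} qubits, got {x.shape}")
    if not np.isfinite(x).all():
        raise ValueError("feature vector must be finite")
    idx = np.arange(2**n)
    signs = 1.0 - 2.0 * ((idx[:, None] >> np.arange(n)[None, :]) & 1)  # (2^n, n)
    table = np.zeros(2**n)
    for i in range(n):
        table += singleton_phase(x[i]) * signs[:, i]
    for i, j in spec.pairs:
        table += pair_phase(spec.encoding, x[i], x[j]) * signs[:, i] * signs[:, j]
    return table


# ---------------------------------------------------------------------------
# state construction


def walsh_hadamard(amplitudes: np.ndarray) -> np.ndarray:
    """Apply H^{x n} via the fast Walsh-Hadamard transform (unitary, O(n 2^n))."""
    a = np.array(amplitudes, dtype=complex)
    m = a.shape[-1]
    if m == 0 or m & (m - 1):
        raise ValueError(f"length must be a power of 2, got {m}")
    h = 1
    inv_sqrt2 = 1.0 / math.sqrt(2.0)
    n_batch = a.size // m
    while h < m:
        a = a.reshape(-1, m // (2 * h), 2, h)
        top = a[..., 0, :] + a[..., 1, :]
        bot = a[..., 0, :] - a[..., 1, :]
        a = np.stack((top, bot), axis=-2) * inv_sqrt2
        a = a.reshape(-1, m)
        OPS["amplitude_updates"] += n_batch * m  # one butterfly stage
        h *= 2
    return a.reshape(np.shape(amplitudes))


def _evolve(amplitudes: np.ndarray, phases: np.ndarray, reps: int) -> np.ndarray:
    """(D H^{x n})^reps acting on ``amplitudes`` (phases = exp(i * phase_table))."""
    a = amplitudes
    for _ in range(reps):
        a = walsh_hadamard(a)
        a = a * phases
    return a


def feature_state(x: np.ndarray, spec: FeatureMapSpec) -> StateVector:
    """|psi(x)> = (D(x) H^{x n})^reps |0^n>."""
    n = spec.n_qubits
    a = np.zeros(2**n, dtype=complex)
    a[0] = 1.0
    phases = np.exp(1j * phase_table(x, spec))
    return StateVector(_evolve(a, phases, spec.reps), n)


def statevectors(X: np.ndarray, spec: FeatureMapSpec) -> np.ndarray:
    """Stack of feature states, one row per sample (shape (n_samples, 2^n))."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    return np.stack([feature_state(x, spec).amplitudes for x in X])


# ---------------------------------------------------------------------------
# kernels


def kernel_entry_exact(a: StateVector, b: StateVector) -> float:
    """Fidelity |<a|b>|^2 between two unit states."""
    if a.amplitudes.shape != b.amplitudes.shape:
        raise ValueError("state dimensions do not match")
    return float(abs(np.vdot(a.amplitudes, b.amplitudes)) ** 2)


def _fidelity_gram(S: np.ndarray, T: np.ndarray | None = None) -> np.ndarray:
    inner = S @ (S if T is None else T).conj().T
    return np.abs(inner) ** 2


def kernel_matrix(
    X: np.ndarray,
    spec: FeatureMapSpec,
    mode: str = "exact",
    shots: int = 1024,
    seed: int | None = None,
    block_size: int | None = None,
    memory_budget: int = _DEFAULT_MEMORY_BUDGET,
) -> KernelMatrix:
    """Fidelity Gram matrix K_ij = |<psi(x_i)|psi(x_j)>|^2 over the rows of X.

    In ``exact`` mode the upper triangle is computed from cached statevectors
    (blocked when the cache would exceed ``memory_budget`` bytes) and
    mirrored.  In ``shots`` mode every off-diagonal entry is replaced by a
    binomial draw frequency m/shots with success probability the exact
    fidelity, emulating repeated measurement of the all-zero outcome; the
    diagonal is fixed at 1.
    """
    if mode not in ("exact", "shots"):
        raise ValueError(f"mode must be 'exact' or 'shots', got {mode!r}")
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n_samples = X.shape[0]
    if X.shape[1] != spec.n_qubits:
        raise ValueError(
            f"X has {X.shape[1]} features but the feature map expects "
            f"{spec.n_qubits} (one qubit per feature)"
        )
    dim = 2**spec.n_qubits
    bytes_needed = n_samples * dim * 16

    if block_size is None:
        if bytes_needed <= memory_budget:
            block_size = n_samples
        else:
            block_size = max(1, memory_budget // (2 * dim * 16))
            if block_size < 1:
                raise MemoryError(
                    f"statevector block needs at least {2 * dim * 16} bytes; "
                    f"budget is {memory_budget}"
                )

    K = np.empty((n_samples, n_samples))
    if block_size >= n_samples:
        S = statevectors(X, spec)
        K[:] = _fidelity_gram(S)
    else:
        for i0 in range(0, n_samples, block_size):
            Si = statevectors(X[i0 : i0 + block_size], spec)
            for j0 in range(i0, n_samples, block_size):
                Sj = Si if j0 == i0 else statevectors(X[j0 : j0 + block_size], spec)
                blk = _fidelity_gram(Si, Sj)
                K[i0 : i0 + len(Si), j0 : j0 + len(Sj)] = blk
                K[j0 : j0 + len(Sj), i0 : i0 + len(Si)] = blk.T

    # mirror the upper triangle for exact symmetry
    iu = np.triu_indices(n_samples, k=1)
    K[(iu[1], iu[0])] = K[iu]

    if mode == "exact":
        return KernelMatrix(K, mode="exact", spec=spec)

    rng = np.random.default_rng(seed)
    p = np.clip(K[iu], 0.0, 1.0)
    draws = rng.binomial(shots, p) / shots
    Ks = np.eye(n_samples)
    Ks[iu] = draws
    Ks[(iu[1], iu[0])] = draws
    return KernelMatrix(Ks, mode="shots", shots=shots, spec=spec, seed=seed)


def psd_projection(K: KernelMatrix | np.ndarray, tol: float = 1e-10) -> KernelMatrix:
    """Repair shot-noise indefiniteness: clip negative eigenvalues, restore diag 1.

    Matrices already PSD within ``tol`` pass through unchanged.
    """
    if isinstance(K, KernelMatrix):
        values, template = K.values, K
    else:
        values, template = np.asarray(K, dtype=float), None
    if not np.allclose(values, values.T, atol=1e-9):
        raise ValueError("psd_projection requires a symmetric matrix")
    w, V = np.linalg.eigh(values)
    if w.min() >= -tol:
        out = values
    else:
        w = np.clip(w, 0.0, None)
        out = (V * w) @ V.T
        out = (out + out.T) / 2.0
        d = np.sqrt(np.clip(np.diag(out), 1e-30, None))
        out = out / np.outer(d, d)
        np.fill_diagonal(out, 1.0)
    if template is not None:
        return KernelMatrix(out, mode=template.mode, shots=template.shots,
                            spec=template.spec, seed=template.seed,
                            meta={**template.meta, "psd_projected": True})
    return KernelMatrix(out, mode="exact", meta={"psd_projected": True})
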