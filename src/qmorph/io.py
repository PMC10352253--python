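"""File round-tripping: feature-table CSV, Gram matrices with JSON sidecars.

The feature-table dialect is ``neuron_id,label,Soma_Surface,F01,...``,
UTF-8, "." decimal, missing cells empty.  Gram matrices are written as
whitespace-delimited text with a JSON sidecar recording provenance (mode,
shots, seed, feature-map spec), enough to re-derive the matrix bit-
identically in exact mode.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .quantum_kernels import FeatureMapSpec, KernelMatrix
from .synthetic import MorphometryTable

__all__ = [
    "read_feature_table",
    "write_feature_table",
    "write_gram",
    "read_gram",
]


def write_feature_table(table: MorphometryTable, path) -> None:
    table.frame.to_csv(path, index=False, na_rep="")


def read_feature_table(path) -> MorphometryTable:
    """Parse a feature-table CSV; empty cells become the missing mask (NaN)."""
    path = Path(path)
    frame = pd.read_csv(path, dtype={"neuron_id": str, "label": str})
    for required in ("neuron_id", "label"):
        if required not in frame.columns:
            raise ValueError(
                f"{path}: malformed header — missing required column {required!r}"
            )
    feature_cols = [c for c in frame.columns if c not in ("neuron_id", "label")]
    if not feature_cols:
        raise ValueError(f"{path}: no feature columns found")
    for col in feature_cols:
        coerced = pd.to_numeric(frame[col], errors="coerce")
        bad = frame[col].notna() & coerced.isna()
        if bad.any():
            row = int(frame.index[bad][0])
            raise ValueError(
                f"{path}: non-numeric value {frame[col][bad].iloc[0]!r} at data "
                f"row {row} (line {row + 2}), column {col!r}"
            )
        frame[col] = coerced
    return MorphometryTable(frame)


def write_gram(K: KernelMatrix, path) -> None:
    """Delimited-text Gram matrix plus a .json provenance sidecar."""
    path = Path(path)
    np.savetxt(path, K.values)
    sidecar = {
        "mode": K.mode,
        "shots": K.shots,
        "seed": K.seed,
        "n": int(K.n),
        "spec": None if K.spec is None else yaml_spec(K.spec),
        "meta": K.meta,
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=2))


def yaml_spec(spec: FeatureMapSpec) -> dict:
    return {
        "n_qubits": spec.n_qubits,
        "reps": spec.reps,
        "entanglement": None
        if spec.entanglement is None
        else [list(p) for p in spec.entanglement],
        "encoding": spec.encoding,
    }


def read_gram(path) -> KernelMatrix:
    path = Path(path)
    values = np.loadtxt(path)
    sidecar_path = path.with_suffix(path.suffix + ".json")
    if sidecar_path.exists():
        raw = json.loads(sidecar_path.read_text())
        spec = None
        if raw.get("spec"):
            s = raw["spec"]
            ent = s.get("entanglement")
            spec = FeatureMapSpec(
                s["n_qubits"],
                s.get("reps", 2),
                None if ent is None else tuple(tuple(p) for p in ent),
                s.get("encoding", "zz"),
            )
        return KernelMatrix(values, mode=raw["mode"], shots=raw.get("shots"),
                            spec=spec, seed=raw.get("seed"), meta=raw.get("meta", {}))
    return KernelMatrix(values)
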