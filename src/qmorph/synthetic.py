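"""Synthetic neuron morphometry tables.

Generates seed-reproducible feature tables that mimic the statistical shape
of L-Measure morphometrics: one row per neuron, an M-type class label, and
43 positive-valued features (lengths, surfaces, angles, counts).  A small
planted subset of "informative" features carries class signal through
class-specific log-normal location parameters; the rest are class-independent
nuisance features.  Artifact injection plants the three data pathologies the
preprocessing stage must remove — missing cells, zero soma surface, and
gross multivariate outliers — and records exactly which rows were touched,
so filter behaviour can be checked against ground truth.

The generator makes no claim of anatomical realism (no allometry between
features, no real marginals); it exists so that every downstream stage is
testable without any external download.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import median_abs_deviation

__all__ = [
    "M_TYPES",
    "SAMPLE_SIZES",
    "SyntheticSpec",
    "MorphometryTable",
    "ArtifactRecord",
    "generate_dataset",
    "inject_artifacts",
    "informative_feature_indices",
    "feature_names",
]

#: The 14 morphological neuron types used as class labels.
M_TYPES = (
    "astrocyte",
    "basket",
    "bitufted",
    "chandelier",
    "double_bouquet",
    "ganglion",
    "granule",
    "martinotti",
    "medium_spiny",
    "microglia",
    "nitrergic",
    "parachromaffin",
    "purkinje",
    "pyramidal",
)

#: Sample-size presets (samples 1-5 of the benchmark study design).
SAMPLE_SIZES = {1: 260, 2: 626, 3: 1143, 4: 2080, 5: 22691}

SOMA_SURFACE = "Soma_Surface"

# Log-space geometry of the planted class structure.  Every informative
# feature assigns each class its own log-location level, levels spaced by
# _CLASS_SPACING while the within-class log standard deviation is _LOG_SD:
# neighbouring class locations sit 5 within-class standard deviations apart,
# comfortably above the >= 1 sd margin the generator contract promises.
# The class -> level assignment is a seeded permutation drawn independently
# per feature, so informative features are not redundant copies of each other.
_CLASS_SPACING = 2.0
_LOG_SD = 0.4
_NOISE_LOG_SD = 0.6
_OUTLIER_MADS = 10.0  # displacement of planted outliers, in robust sds


def feature_names(n_features: int = 43) -> list[str]:
    """Column names: ``Soma_Surface`` then ``F01``..``F42`` (generic morphometrics)."""
    return [SOMA_SURFACE] + [f"F{i:02d}" for i in range(1, n_features)]


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of one synthetic table draw.

    ``n_informative`` features carry class signal; ``feature_scale`` sets the
    overall magnitude (think µm); the three rates control artifact injection.
    """

    n_neurons: int
    n_classes: int = 14
    n_features: int = 43
    n_informative: int = 5
    class_proportions: tuple[float, ...] | None = None
    feature_scale: float = 100.0
    outlier_rate: float = 0.0
    missing_rate: float = 0.0
    zero_soma_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_neurons <= 0:
            raise ValueError(f"n_neurons must be positive, got {self.n_neurons}")
        if self.n_classes < 1:
            raise ValueError(f"n_classes must be >= 1, got {self.n_classes}")
        if self.n_features < 1:
            raise ValueError(f"n_features must be >= 1, got {self.n_features}")
        if not 0 <= self.n_informative <= self.n_features:
            raise ValueError(
                f"n_informative must be in [0, n_features], got {self.n_informative}"
            )
        if self.feature_scale <= 0:
            raise ValueError(f"feature_scale must be positive, got {self.feature_scale}")
        for name in ("outlier_rate", "missing_rate", "zero_soma_rate"):
            rate = getattr(self, name)
            if not 0.0 <= rate <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {rate}")
        if self.class_proportions is not None:
            p = np.asarray(self.class_proportions, dtype=float)
            if p.shape != (self.n_classes,):
                raise ValueError(
                    "class_proportions must have length n_classes "
                    f"({self.n_classes}), got {p.shape}"
                )
            if (p < 0).any():
                raise ValueError("class_proportions must be non-negative")
            if abs(p.sum() - 1.0) > 1e-12:
                raise ValueError(
                    f"class_proportions must sum to 1 +- 1e-12, got {p.sum()!r}"
                )

    @property
    def proportions(self) -> np.ndarray:
        if self.class_proportions is None:
            return np.full(self.n_classes, 1.0 / self.n_classes)
        return np.asarray(self.class_proportions, dtype=float)

    def class_names(self) -> list[str]:
        if self.n_classes <= len(M_TYPES):
            return list(M_TYPES[: self.n_classes])
        extra = [f"mtype_{i:02d}" for i in range(len(M_TYPES), self.n_classes)]
        return list(M_TYPES) + extra


@dataclass
class ArtifactRecord:
    """Ground-truth positional row indices of each injected artifact kind."""

    missing_rows: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))
    zero_soma_rows: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))
    outlier_rows: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))


class MorphometryTable:
    """Labelled neuron x feature matrix.

    Thin wrapper over a :class:`pandas.DataFrame` with columns
    ``neuron_id, label, Soma_Surface, F01, ...``; missing cells are NaN.
    The DataFrame integer index is preserved through filtering so that
    removed-row reports refer to original row positions.
    """

    def __init__(self, frame: pd.DataFrame, artifacts: ArtifactRecord | None = None):
        if "neuron_id" not in frame.columns or "label" not in frame.columns:
            raise ValueError("frame must have 'neuron_id' and 'label' columns")
        self.frame = frame
        self.artifacts = artifacts

    @property
    def feature_names(self) -> list[str]:
        return [c for c in self.frame.columns if c not in ("neuron_id", "label")]

    @property
    def features(self) -> np.ndarray:
        """Feature matrix as float array; missing cells are NaN."""
        return self.frame[self.feature_names].to_numpy(dtype=float)

    @property
    def labels(self) -> np.ndarray:
        return self.frame["label"].to_numpy()

    @property
    def n_rows(self) -> int:
        return len(self.frame)

    @property
    def soma_surface_index(self) -> int:
        return self.feature_names.index(SOMA_SURFACE)

    def with_frame(self, frame: pd.DataFrame) -> "MorphometryTable":
        return MorphometryTable(frame, self.artifacts)

    def __len__(self) -> int:
        return self.n_rows

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, MorphometryTable):
            return NotImplemented
        return self.frame.equals(other.frame)


def _streams(seed: int) -> list[np.random.Generator]:
    """Independent child streams: labels, informative-choice, features, artifacts."""
    children = np.random.SeedSequence(seed).spawn(4)
    return [np.random.default_rng(c) for c in children]


def informative_feature_indices(spec: SyntheticSpec) -> np.ndarray:
    """Planted informative feature indices (sorted; stable under seed).

    The soma-surface column (index 0) is excluded when possible so that
    zero-soma artifact injection never destroys class signal.
    """
    _, rng, _, _ = _streams(spec.seed)
    if spec.n_informative == 0:
        return np.array([], dtype=int)
    if spec.n_informative < spec.n_features:
        pool = np.arange(1, spec.n_features)
        idx = rng.choice(pool, size=spec.n_informative, replace=False)
    else:
        idx = np.arange(spec.n_features)
    return np.sort(idx)


def generate_dataset(spec: SyntheticSpec) -> MorphometryTable:
    """Draw a clean synthetic table (no artifacts) for ``spec``.

    Informative features follow shifted log-normals whose log-location is a
    class-specific level; nuisance features are class-independent log-normals
    with per-feature magnitudes.  Deterministic under the spec seed.
    """
    label_rng, _, feat_rng, _ = _streams(spec.seed)
    n, d = spec.n_neurons, spec.n_features
    names = spec.class_names()

    y = label_rng.choice(spec.n_classes, size=n, p=spec.proportions)

    info = informative_feature_indices(spec)
    info_set = set(info.tolist())
    base_log = math.log(spec.feature_scale)
    shift = 0.1 * spec.feature_scale

    # per-feature magnitude of nuisance features, fixed across rows
    noise_logloc = base_log + feat_rng.normal(0.0, 1.0, size=d)
    # per-informative-feature class -> level permutation
    level_of = {
        f: feat_rng.permutation(spec.n_classes) for f in info.tolist()
    }

    X = np.empty((n, d), dtype=float)
    z = feat_rng.normal(0.0, 1.0, size=(n, d))
    for f in range(d):
        if f in info_set:
            locs = base_log + _CLASS_SPACING * level_of[f].astype(float)
            X[:, f] = shift + np.exp(locs[y] + _LOG_SD * z[:, f])
        else:
            X[:, f] = shift + np.exp(noise_logloc[f] + _NOISE_LOG_SD * z[:, f])

    frame = pd.DataFrame(X, columns=feature_names(d))
    frame.insert(0, "label", [names[c] for c in y])
    frame.insert(0, "neuron_id", [f"syn-{spec.seed}-{i:06d}" for i in range(n)])
    return MorphometryTable(frame, ArtifactRecord())


def inject_artifacts(table: MorphometryTable, spec: SyntheticSpec) -> MorphometryTable:
    """Plant missing cells, zero soma surfaces and gross outliers.

    Marks ``floor(rate * n)`` rows per artifact kind, with the three row sets
    kept disjoint so each downstream filter sees exactly its own ground truth.
    Outlier rows are rewritten to sit ``10`` robust (MAD-based) standard
    deviations from their class mean in every feature, far beyond any
    plausible chi-squared cutoff.  Returns a new table whose
    :attr:`MorphometryTable.artifacts` records the touched row positions.
    """
    for name in ("outlier_rate", "missing_rate", "zero_soma_rate"):
        rate = getattr(spec, name)
        if not 0.0 <= rate <= 1.0:
            raise ValueError(f"{name} must be in [0, 1], got {rate}")

    _, _, _, rng = _streams(spec.seed)
    n = table.n_rows
    n_miss = int(math.floor(spec.missing_rate * n))
    n_zero = int(math.floor(spec.zero_soma_rate * n))
    n_out = int(math.floor(spec.outlier_rate * n))
    if n_miss + n_zero + n_out > n:
        raise ValueError("artifact rates sum to more than one row each")

    perm = rng.permutation(n)
    miss_rows = np.sort(perm[:n_miss])
    zero_rows = np.sort(perm[n_miss : n_miss + n_zero])
    out_rows = np.sort(perm[n_miss + n_zero : n_miss + n_zero + n_out])

    frame = table.frame.copy()
    feats = table.feature_names
    d = len(feats)

    for r in miss_rows:
        col = feats[rng.integers(0, d)]
        frame.iloc[r, frame.columns.get_loc(col)] = np.nan

    if n_zero:
        frame.iloc[zero_rows, frame.columns.get_loc(SOMA_SURFACE)] = 0.0

    if n_out:
        X = table.features
        mad = median_abs_deviation(X, axis=0, scale="normal")
        # displacement unit: at least the robust sd, but never below the
        # classical sd — heavy-tailed features have sd >> MAD, and a shift
        # small relative to the fitted covariance would not register as a
        # multivariate outlier
        mad = np.maximum(np.where(mad > 0, mad, 1e-9), X.std(axis=0))
        labels = table.labels
        col_locs = [frame.columns.get_loc(c) for c in feats]
        for r in out_rows:
            cls_mask = labels == labels[r]
            cls_mean = X[cls_mask].mean(axis=0)
            signs = rng.choice((-1.0, 1.0), size=d)
            frame.iloc[r, col_locs] = cls_mean + signs * _OUTLIER_MADS * mad

    record = ArtifactRecord(miss_rows, zero_rows, out_rows)
    return MorphometryTable(frame, record)


def generate(spec: SyntheticSpec) -> MorphometryTable:
    """Convenience: :func:`generate_dataset` followed by :func:`inject_artifacts`."""
    return inject_artifacts(generate_dataset(spec), spec)
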