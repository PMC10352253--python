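"""Feature selection and extraction.

Feature selection is by tree-ensemble impurity importance: a forest (or a
single tree, or gradient-boosted trees) is fit on the labelled table and the
total Gini-impurity decrease attributed to each feature, normalised to sum
to one, ranks the features.  Feature extraction reduces the table to a small
number of components through thin, uniform adapters over the established
implementations (PCA, ICA, LDA, manifold methods, ...); methods with no
out-of-sample transform are flagged transductive and must be fit on the full
design matrix before any split, which is a documented leakage caveat.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "TREE_METHODS",
    "EXTRACTION_METHODS",
    "TRANSDUCTIVE_METHODS",
    "ImportanceVector",
    "ReducerSpec",
    "gini_index",
    "tree_importances",
    "importances_to_frame",
    "select_top_k",
    "extract_components",
    "make_reducer",
    "Reducer",
]

TREE_METHODS = ("random_forest", "decision_tree", "xgboost")

EXTRACTION_METHODS = (
    "pca",
    "ica",
    "ica_pca",
    "lda",
    "random_projection",
    "truncated_svd",
    "isomap",
    "nca",
    "tsne",
    "lle",
    "hessian_lle",
    "mlle",
    "ltsa",
    "mds",
)

#: methods with no out-of-sample transform; fit on the full design matrix
TRANSDUCTIVE_METHODS = frozenset(
    {"tsne", "mds", "lle", "hessian_lle", "mlle", "ltsa", "isomap"}
)

_SUPERVISED = frozenset({"lda", "nca"})


def gini_index(p) -> float:
    """Gini impurity ``1 - sum(p_i^2)`` of a class-probability vector.

    0 when all mass sits on one class, ``1 - 1/m`` for ``m`` equiprobable
    classes (0.5 for two).
    """
    p = np.asarray(p, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("p must be a non-empty 1-d probability vector")
    if (p < 0).any():
        raise ValueError("probabilities must be non-negative")
    if abs(p.sum() - 1.0) > 1e-9:
        raise ValueError(f"probabilities must sum to 1 +- 1e-9, got {p.sum()!r}")
    return float(1.0 - np.sum(p**2))


@dataclass
class ImportanceVector:
    """Per-feature importances normalised to sum to one."""

    values: np.ndarray
    method: str
    seed: int

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if (self.values < 0).any():
            raise ValueError("importances must be non-negative")

    def __len__(self) -> int:
        return len(self.values)


def tree_importances(X, y, method: str = "random_forest", seed: int = 0,
                     n_estimators: int = 100) -> ImportanceVector:
    """Impurity-decrease feature importances from a tree-based classifier.

    The ensemble fit is delegated to scikit-learn / XGBoost; the
    normalisation contract (entries >= 0, sum exactly 1) is enforced here.
    Deterministic given the seed.
    """
    if method not in TREE_METHODS:
        raise ValueError(f"unknown tree method {method!r}; choose from {TREE_METHODS}")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if np.unique(y).size < 2:
        raise ValueError("tree importances require at least 2 classes")

    if method == "random_forest":
        from sklearn.ensemble import RandomForestClassifier

        clf = RandomForestClassifier(
            n_estimators=n_estimators, random_state=seed, n_jobs=1
        ).fit(X, y)
        raw = clf.feature_importances_
    elif method == "decision_tree":
        from sklearn.tree import DecisionTreeClassifier

        clf = DecisionTreeClassifier(random_state=seed).fit(X, y)
        raw = clf.feature_importances_
    else:  # xgboost: gradient-boosted trees, total-gain importance
        from xgboost import XGBClassifier

        codes = np.unique(y, return_inverse=True)[1]
        clf = XGBClassifier(
            n_estimators=n_estimators,
            random_state=seed,
            n_jobs=1,
            importance_type="total_gain",
            verbosity=0,
        ).fit(X, codes)
        raw = clf.feature_importances_

    raw = np.asarray(raw, dtype=float)
    total = raw.sum()
    if total <= 0:
        warnings.warn("all importances are zero; returning zeros", stacklevel=2)
        values = raw
    else:
        values = raw / total
    return ImportanceVector(values, method, seed)


def select_top_k(imp: ImportanceVector | np.ndarray, k: int) -> np.ndarray:
    """Indices of the ``k`` largest importances.

    Output is ordered by importance descending; ties broken by ascending
    feature index.  Pure function of the importance vector.
    """
    values = imp.values if isinstance(imp, ImportanceVector) else np.asarray(imp, dtype=float)
    n = len(values)
    if not 1 <= k <= n:
        raise ValueError(f"k must be in [1, {n}], got {k}")
    order = np.lexsort((np.arange(n), -values))
    return order[:k]


class Reducer:
    """Uniform fit/transform adapter over one extraction method."""

    def __init__(self, method: str, n_components: int = 2, seed: int = 0,
                 n_neighbors: int | None = None):
        if method not in EXTRACTION_METHODS:
            raise ValueError(
                f"unknown extraction method {method!r}; choose from {EXTRACTION_METHODS}"
            )
        self.method = method
        self.n_components = n_components
        self.seed = seed
        self.n_neighbors = n_neighbors
        self.transductive = method in TRANSDUCTIVE_METHODS
        self._est = None
        self._embedding: np.ndarray | None = None

    # -- estimator construction -------------------------------------------
    def _build(self, n_samples: int, n_classes: int):
        m, k, seed = self.method, self.n_components, self.seed
        nn = self.n_neighbors
        if m == "pca":
            from sklearn.decomposition import PCA

            return PCA(n_components=k)
        if m == "ica":
            from sklearn.decomposition import FastICA

            return FastICA(n_components=k, random_state=seed, max_iter=1000)
        if m == "ica_pca":
            from sklearn.decomposition import PCA, FastICA
            from sklearn.pipeline import Pipeline

            return Pipeline(
                [
                    ("pca", PCA(whiten=True, random_state=seed)),
                    ("ica", FastICA(n_components=k, random_state=seed, max_iter=1000)),
                ]
            )
        if m == "lda":
            from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

            if k > n_classes - 1:
                raise ValueError(
                    f"lda supports at most n_classes - 1 = {n_classes - 1} components"
                )
            return LinearDiscriminantAnalysis(n_components=k)
        if m == "random_projection":
            from sklearn.random_projection import GaussianRandomProjection

            return GaussianRandomProjection(n_components=k, random_state=seed)
        if m == "truncated_svd":
            from sklearn.decomposition import TruncatedSVD

            return TruncatedSVD(n_components=k, random_state=seed)
        if m == "nca":
            from sklearn.neighbors import NeighborhoodComponentsAnalysis

            return NeighborhoodComponentsAnalysis(n_components=k, random_state=seed)
        if m == "isomap":
            from sklearn.manifold import Isomap

            return Isomap(n_components=k, n_neighbors=nn or min(10, n_samples - 1))
        if m == "tsne":
            from sklearn.manifold import TSNE

            return TSNE(
                n_components=k,
                random_state=seed,
                perplexity=min(30.0, max(2.0, (n_samples - 1) / 3.0)),
                init="pca",
            )
        if m == "mds":
            from sklearn.manifold import MDS

            return MDS(n_components=k, random_state=seed, normalized_stress="auto",
                       init="random")
        # LLE family
        from sklearn.manifold import LocallyLinearEmbedding

        variant = {"lle": "standard", "hessian_lle": "hessian",
                   "mlle": "modified", "ltsa": "ltsa"}[m]
        min_nn = {
            "standard": k + 1,
            "hessian": 1 + k * (k + 3) // 2 + 1,
            "modified": k + 1,
            "ltsa": k + 1,
        }[variant]
        return LocallyLinearEmbedding(
            n_components=k,
            n_neighbors=max(nn or 10, min_nn),
            method=variant,
            random_state=seed,
        )

    # -- fitting -----------------------------------------------------------
    def fit(self, X: np.ndarray, y: np.ndarray | None = None) -> "Reducer":
        X = np.asarray(X, dtype=float)
        n_classes = len(np.unique(y)) if y is not None else 0
        if self.method in _SUPERVISED and y is None:
            raise ValueError(f"{self.method} is supervised and requires y")
        self._est = self._build(len(X), n_classes)
        if self.transductive:
            logger.warning(
                "%s has no out-of-sample transform; fitting on the full design "
                "matrix (transductive embedding, potential leakage across splits)",
                self.method,
            )
            self._embedding = np.asarray(self._est.fit_transform(X))
        elif self.method in _SUPERVISED:
            self._est.fit(X, y)
        else:
            self._est.fit(X)
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        if self._est is None:
            raise RuntimeError("Reducer not fitted")
        if self.transductive:
            if self._embedding is None or len(X) != len(self._embedding):
                raise RuntimeError(
                    f"{self.method} is transductive: transform is only defined on "
                    "the matrix it was fit on"
                )
            return self._embedding
        return np.asarray(self._est.transform(np.asarray(X, dtype=float)))

    def fit_transform(self, X: np.ndarray, y: np.ndarray | None = None) -> np.ndarray:
        self.fit(X, y)
        if self.transductive:
            return self._embedding
        return self.transform(X)


@dataclass(frozen=True)
class ReducerSpec:
    """Declarative reduction: selection (tree method + k) or extraction."""

    mode: str  # selection | extraction
    method: str
    k: int = 2  # selected feature count, or extracted component count
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("selection", "extraction"):
            raise ValueError(f"mode must be selection|extraction, got {self.mode!r}")
        pool = TREE_METHODS if self.mode == "selection" else EXTRACTION_METHODS
        if self.method not in pool:
            raise ValueError(f"unknown {self.mode} method {self.method!r}")
        if self.k < 1:
            raise ValueError("k must be >= 1")

    def to_yaml(self) -> str:
        import yaml

        return yaml.safe_dump(
            {"mode": self.mode, "method": self.method, "k": self.k, "seed": self.seed}
        )

    @classmethod
    def from_yaml(cls, text: str) -> "ReducerSpec":
        import yaml

        raw = yaml.safe_load(text)
        return cls(raw["mode"], raw["method"], raw.get("k", 2), raw.get("seed", 0))


def importances_to_frame(imp: ImportanceVector, feature_names=None):
    """Importances as a ``feature, importance, rank`` table (rank 1 = best)."""
    import pandas as pd

    n = len(imp)
    names = list(feature_names) if feature_names is not None else [f"f{i}" for i in range(n)]
    if len(names) != n:
        raise ValueError("feature_names length must match the importance vector")
    order = select_top_k(imp, n)
    rank = np.empty(n, dtype=int)
    rank[order] = np.arange(1, n + 1)
    return pd.DataFrame({"feature": names, "importance": imp.values, "rank": rank})


def make_reducer(method: str, n_components: int = 2, seed: int = 0,
                 n_neighbors: int | None = None) -> Reducer:
    return Reducer(method, n_components=n_components, seed=seed, n_neighbors=n_neighbors)


def extract_components(X, y=None, method: str = "pca", n_components: int = 2,
                       seed: int = 0) -> np.ndarray:
    """Reduce ``X`` to ``n_components`` columns with the named method."""
    return make_reducer(method, n_components=n_components, seed=seed).fit_transform(X, y)
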