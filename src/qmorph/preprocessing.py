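"""Row filtering and feature rescaling.

Filtering happens in a fixed order — rows with missing cells, then rows whose
soma surface equals zero exactly, then multivariate outliers by Mahalanobis
distance against a chi-squared cutoff — and each step reports exactly which
original rows it removed.

Eleven rescaling transforms are provided behind a single fit/apply interface:
standard, min-max, max-abs, robust (quartile), row L2 normalisation, logistic,
lognormal CDF, Box-Cox, Yeo-Johnson, and the two nonparametric quantile maps
(to a normal and to a uniform target).  All parameterised transforms are fit
on training data only; applying them never touches test statistics.

Notes on the less common conventions used here:

* the robust scaler is ``(x - Q1) / (Q3 - Q1)`` (first quartile in the
  numerator); pass ``center="median"`` for the conventional median-centred
  variant;
* the quantile-to-normal map sends an empirical CDF value ``p`` to
  ``mu + sigma * sqrt(2) * erfinv(2p - 1)``, the exact normal quantile
  function;
* the lognormal transform is ``Phi(ln(x) / sigma)`` for ``x >= 0`` with
  ``sigma`` defaulting to 1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml
from scipy import stats
from scipy.special import erfinv

from .synthetic import SOMA_SURFACE, MorphometryTable

__all__ = [
    "RESCALER_METHODS",
    "RescalerSpec",
    "FilterReport",
    "drop_incomplete_rows",
    "drop_zero_soma",
    "mahalanobis_distances",
    "mahalanobis_filter",
    "apply_filters",
    "fit_rescaler",
    "apply_rescaler",
    "encode_labels",
]

RESCALER_METHODS = (
    "standard",
    "minmax",
    "maxabs",
    "robust",
    "l2norm",
    "logistic",
    "lognormal",
    "boxcox",
    "yeojohnson",
    "quantile_normal",
    "quantile_uniform",
)

#: methods that need no fitted statistics
_STATELESS = {"l2norm", "logistic", "lognormal"}


# ---------------------------------------------------------------------------
# filtering


@dataclass
class FilterReport:
    """Bookkeeping for one filtering step (indices are original row labels)."""

    rows_in: int
    rows_out: int
    removed_missing: list = field(default_factory=list)
    removed_zero_soma: list = field(default_factory=list)
    removed_mahalanobis: list = field(default_factory=list)
    threshold: float | None = None

    def to_dict(self) -> dict:
        return {
            "rows_in": int(self.rows_in),
            "rows_out": int(self.rows_out),
            "removed_missing": [int(i) for i in self.removed_missing],
            "removed_zero_soma": [int(i) for i in self.removed_zero_soma],
            "removed_mahalanobis": [int(i) for i in self.removed_mahalanobis],
            "threshold": None if self.threshold is None else float(self.threshold),
        }


def drop_incomplete_rows(table: MorphometryTable) -> tuple[MorphometryTable, FilterReport]:
    """Delete every row containing at least one missing feature cell."""
    frame = table.frame
    mask = frame[table.feature_names].isna().any(axis=1)
    removed = frame.index[mask].tolist()
    out = table.with_frame(frame.loc[~mask])
    if out.n_rows == 0:
        warnings.warn("all rows removed by missing-value filter", stacklevel=2)
    return out, FilterReport(len(frame), out.n_rows, removed_missing=removed)


def drop_zero_soma(table: MorphometryTable) -> tuple[MorphometryTable, FilterReport]:
    """Delete rows whose soma surface equals 0 exactly (strict equality)."""
    frame = table.frame
    if SOMA_SURFACE not in frame.columns:
        raise ValueError(f"table has no '{SOMA_SURFACE}' column")
    mask = frame[SOMA_SURFACE] == 0.0
    removed = frame.index[mask].tolist()
    out = table.with_frame(frame.loc[~mask])
    return out, FilterReport(len(frame), out.n_rows, removed_zero_soma=removed)


def mahalanobis_distances(X: np.ndarray, shrinkage: bool = True) -> np.ndarray:
    """Squared Mahalanobis distance of every row to the column mean.

    With ``shrinkage`` (default) the covariance is Ledoit-Wolf
    shrinkage-regularised — recommended when 43 features dwarf the sample
    size; otherwise the plain empirical covariance is inverted, which
    requires more rows than features.
    """
    X = np.asarray(X, dtype=float)
    n, d = X.shape
    if shrinkage:
        from sklearn.covariance import LedoitWolf

        cov = LedoitWolf().fit(X)
        mu, prec = cov.location_, cov.get_precision()
    else:
        if n <= d:
            raise ValueError(
                "empirical covariance is singular with n <= n_features; "
                "enable shrinkage"
            )
        mu = X.mean(axis=0)
        sigma = np.cov(X, rowvar=False)
        try:
            prec = np.linalg.inv(sigma)
        except np.linalg.LinAlgError as exc:
            raise ValueError(
                "covariance matrix is singular; enable shrinkage"
            ) from exc
    centred = X - mu
    return np.einsum("ij,jk,ik->i", centred, prec, centred)


def mahalanobis_filter(
    X: np.ndarray,
    alpha: float = 0.025,
    shrinkage: bool = True,
) -> tuple[np.ndarray, FilterReport]:
    """Keep rows whose squared Mahalanobis distance is below the chi2 cutoff.

    The cutoff is the chi-squared quantile at ``1 - alpha`` with
    ``n_features`` degrees of freedom.  Returns kept positional indices.
    """
    X = np.asarray(X, dtype=float)
    n, d = X.shape
    d2 = mahalanobis_distances(X, shrinkage=shrinkage)
    threshold = stats.chi2.ppf(1.0 - alpha, df=d)
    kept = np.flatnonzero(d2 <= threshold)
    removed = np.flatnonzero(d2 > threshold).tolist()
    report = FilterReport(n, len(kept), removed_mahalanobis=removed, threshold=threshold)
    return kept, report


def apply_filters(
    table: MorphometryTable,
    alpha: float = 0.025,
    shrinkage: bool = True,
) -> tuple[MorphometryTable, FilterReport]:
    """Run the full filter chain (missing -> zero-soma -> Mahalanobis).

    The combined report lists removed rows by their original positional index
    and reconciles exactly: ``rows_out = rows_in - |union of removals|``.
    """
    rows_in = table.n_rows
    t1, r1 = drop_incomplete_rows(table)
    t2, r2 = drop_zero_soma(t1)
    kept, r3 = mahalanobis_filter(t2.features, alpha=alpha, shrinkage=shrinkage)
    original = t2.frame.index.to_numpy()
    out = t2.with_frame(t2.frame.iloc[kept])
    removed_mahal = [int(original[i]) for i in r3.removed_mahalanobis]
    report = FilterReport(
        rows_in,
        out.n_rows,
        removed_missing=r1.removed_missing,
        removed_zero_soma=r2.removed_zero_soma,
        removed_mahalanobis=removed_mahal,
        threshold=r3.threshold,
    )
    return out, report


# ---------------------------------------------------------------------------
# rescaling


@dataclass
class RescalerSpec:
    """A fitted rescaling transform: method name plus per-feature parameters."""

    method: str
    params: dict = field(default_factory=dict)
    n_features: int | None = None

    def to_yaml(self) -> str:
        def clean(v):
            if isinstance(v, np.ndarray):
                return v.tolist()
            if isinstance(v, (np.floating, np.integer)):
                return v.item()
            if isinstance(v, dict):
                return {k: clean(x) for k, x in v.items()}
            if isinstance(v, (list, tuple)):
                return [clean(x) for x in v]
            return v

        return yaml.safe_dump(
            {"method": self.method, "n_features": self.n_features, "params": clean(self.params)}
        )

    @classmethod
    def from_yaml(cls, text: str) -> "RescalerSpec":
        raw = yaml.safe_load(text)
        params = {
            k: (np.asarray(v, dtype=float) if isinstance(v, list) else v)
            for k, v in raw["params"].items()
        }
        return cls(raw["method"], params, raw.get("n_features"))


def _nonconstant(scale: np.ndarray, method: str) -> np.ndarray:
    ok = scale != 0
    if not ok.all():
        warnings.warn(
            f"{method}: {np.count_nonzero(~ok)} constant feature(s) pass through unchanged",
            stacklevel=3,
        )
    return ok


def fit_rescaler(X: np.ndarray, method: str, **options) -> RescalerSpec:
    """Estimate per-feature rescaling parameters on training data.

    Box-Cox and Yeo-Johnson estimate the power parameter ``lambda`` per
    feature by maximum likelihood; the quantile maps store an empirical
    quantile table of ``min(1000, n)`` uniformly spaced probabilities.
    """
    if method not in RESCALER_METHODS:
        raise ValueError(f"unknown rescaling method {method!r}; choose from {RESCALER_METHODS}")
    X = np.asarray(X, dtype=float)
    n, d = X.shape
    params: dict = {}

    if method == "standard":
        params["mean"] = X.mean(axis=0)
        params["sd"] = X.std(axis=0)
        params["active"] = _nonconstant(params["sd"], method)
    elif method == "minmax":
        params["min"] = X.min(axis=0)
        params["max"] = X.max(axis=0)
        params["active"] = _nonconstant(params["max"] - params["min"], method)
    elif method == "maxabs":
        params["maxabs"] = np.abs(X).max(axis=0)
        params["active"] = _nonconstant(params["maxabs"], method)
    elif method == "robust":
        q1 = np.percentile(X, 25, axis=0)
        q3 = np.percentile(X, 75, axis=0)
        params["q1"], params["q3"] = q1, q3
        params["center"] = options.get("center", "q1")
        if params["center"] not in ("q1", "median"):
            raise ValueError("robust center must be 'q1' or 'median'")
        if params["center"] == "median":
            params["median"] = np.median(X, axis=0)
        params["active"] = _nonconstant(q3 - q1, method)
    elif method == "lognormal":
        params["sigma"] = float(options.get("sigma", 1.0))
        if params["sigma"] <= 0:
            raise ValueError("lognormal sigma must be positive")
    elif method == "boxcox":
        if (X <= 0).any():
            raise ValueError("boxcox requires strictly positive data")
        lam = np.empty(d)
        for j in range(d):
            if np.ptp(X[:, j]) == 0:
                lam[j] = 1.0
            else:
                _, lam[j] = stats.boxcox(X[:, j])
        params["lmbda"] = lam
    elif method == "yeojohnson":
        lam = np.empty(d)
        for j in range(d):
            if np.ptp(X[:, j]) == 0:
                lam[j] = 1.0
            else:
                _, lam[j] = stats.yeojohnson(X[:, j])
        params["lmbda"] = lam
    elif method in ("quantile_normal", "quantile_uniform"):
        m = min(int(options.get("n_quantiles", 1000)), n)
        probs = np.linspace(0.0, 1.0, m)
        params["probs"] = probs
        params["quantiles"] = np.quantile(X, probs, axis=0)  # shape (m, d)
        params["n_train"] = n
        if method == "quantile_normal":
            params["mu"] = float(options.get("mu", 0.0))
            params["sigma"] = float(options.get("sigma", 1.0))
        else:
            params["a"] = float(options.get("a", 0.0))
            params["b"] = float(options.get("b", 1.0))
    # l2norm / logistic have no parameters

    return RescalerSpec(method, params, n_features=d)


def apply_rescaler(spec: RescalerSpec, X: np.ndarray) -> np.ndarray:
    """Apply a fitted rescaler to a feature matrix."""
    X = np.asarray(X, dtype=float)
    if spec.n_features is not None and X.shape[1] != spec.n_features:
        raise ValueError(
            f"feature count mismatch: spec fitted on {spec.n_features}, got {X.shape[1]}"
        )
    method, p = spec.method, spec.params

    if method == "standard":
        out = X.copy()
        a = p["active"]
        out[:, a] = (X[:, a] - p["mean"][a]) / p["sd"][a]
        return out
    if method == "minmax":
        out = X.copy()
        a = p["active"]
        rng_ = p["max"] - p["min"]
        out[:, a] = (X[:, a] - p["min"][a]) / rng_[a]
        return out
    if method == "maxabs":
        out = X.copy()
        a = p["active"]
        out[:, a] = X[:, a] / p["maxabs"][a]
        return out
    if method == "robust":
        out = X.copy()
        a = p["active"]
        iqr = p["q3"] - p["q1"]
        center = p["median"] if p.get("center") == "median" else p["q1"]
        out[:, a] = (X[:, a] - np.asarray(center)[a]) / iqr[a]
        return out
    if method == "l2norm":
        norms = np.linalg.norm(X, axis=1, keepdims=True)
        norms[norms == 0] = 1.0
        return X / norms
    if method == "logistic":
        return 1.0 / (1.0 + np.exp(-X))
    if method == "lognormal":
        if (X < 0).any():
            raise ValueError("lognormal transform requires x >= 0")
        with np.errstate(divide="ignore"):
            logx = np.where(X > 0, np.log(np.where(X > 0, X, 1.0)), -np.inf)
        return stats.norm.cdf(logx / p["sigma"])
    if method == "boxcox":
        lam = p["lmbda"]
        if (X <= 0).any():
            raise ValueError("boxcox transform requires strictly positive data")
        out = np.empty_like(X)
        for j in range(X.shape[1]):
            out[:, j] = stats.boxcox(X[:, j], lmbda=lam[j])
        return out
    if method == "yeojohnson":
        lam = p["lmbda"]
        out = np.empty_like(X)
        for j in range(X.shape[1]):
            out[:, j] = stats.yeojohnson(X[:, j], lmbda=lam[j])
        return out
    if method in ("quantile_normal", "quantile_uniform"):
        probs, quantiles, n = p["probs"], p["quantiles"], p["n_train"]
        lo, hi = 1.0 / (2 * n), 1.0 - 1.0 / (2 * n)
        out = np.empty_like(X)
        for j in range(X.shape[1]):
            pj = np.interp(X[:, j], quantiles[:, j], probs)
            pj = np.clip(pj, lo, hi)
            if method == "quantile_normal":
                out[:, j] = p["mu"] + p["sigma"] * np.sqrt(2.0) * erfinv(2.0 * pj - 1.0)
            else:
                out[:, j] = p["a"] * (1.0 - pj) + p["b"] * pj
        return out
    raise ValueError(f"unknown rescaling method {method!r}")


class Rescaler:
    """fit/transform convenience wrapper over the functional interface."""

    def __init__(self, method: str, **options):
        self.method = method
        self.options = options
        self.spec: RescalerSpec | None = None

    def fit(self, X: np.ndarray) -> "Rescaler":
        self.spec = fit_rescaler(X, self.method, **self.options)
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        if self.spec is None:
            raise RuntimeError("Rescaler not fitted")
        return apply_rescaler(self.spec, X)

    def fit_transform(self, X: np.ndarray) -> np.ndarray:
        return self.fit(X).transform(X)


# ---------------------------------------------------------------------------
# label encoding


def encode_labels(labels) -> tuple[np.ndarray, list]:
    """Deterministic lexicographic label -> integer encoding.

    Returns ``(codes, classes)`` where ``classes[code] == original label``.
    """
    labels = np.asarray(labels)
    classes, codes = np.unique(labels, return_inverse=True)
    return codes.astype(int), classes.tolist()


def decode_labels(codes: np.ndarray, classes: list) -> np.ndarray:
    return np.asarray(classes, dtype=object)[np.asarray(codes, dtype=int)]
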