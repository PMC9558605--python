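"""Normalization and dimensionality-reduction stages, fitted on training data only.

Normalizers: per-feature Z-score, per-feature min-max to [0, 1], or an explicit
bypass.  (Mie baseline removal is the third normalization option of the
pipeline; it lives in :mod:`thzchem.mie_baseline` and is routed there by the
evaluation layer.)

Reducers wrap scikit-learn estimators — PCA, factor analysis, fastICA,
(modified) locally linear embedding, NMF, isomap — behind one fit/apply
contract with out-of-sample transforms for held-out spectra and an optional
extra column of Mie baseline coefficients appended after reduction
(``concat_xi``).  All randomized solvers are seeded; the seed is part of the
recorded state.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
from sklearn.decomposition import NMF, PCA, FactorAnalysis, FastICA
from sklearn.manifold import Isomap, LocallyLinearEmbedding

__all__ = [
    "NormalizerState",
    "ReducerSpec",
    "ReducerState",
    "fit_normalizer",
    "apply_normalizer",
    "fit_reducer",
    "apply_reducer",
]

NORMALIZER_METHODS = ("zscore", "minmax", "none")
REDUCER_METHODS = ("pca", "fa", "ica", "lle", "modified_lle", "nmf", "isomap", "none")


@dataclass(frozen=True)
class NormalizerState:
    method: str
    center: np.ndarray | None = None   # mean (zscore) or min (minmax)
    scale: np.ndarray | None = None    # sd (zscore) or range (minmax); 0 where degenerate


def fit_normalizer(train_matrix: np.ndarray, method: str) -> NormalizerState:
    """Learn per-feature statistics from the training block.

    Degenerate features (zero variance / zero range) are mapped to 0 for all
    spectra rather than dividing by zero.
    """
    if method == "mie":
        raise ValueError(
            "Mie baseline removal is handled by thzchem.mie_baseline, not here"
        )
    if method not in NORMALIZER_METHODS:
        raise ValueError(f"unknown normalizer {method!r}")
    if method == "none":
        return NormalizerState(method="none")
    X = np.asarray(train_matrix, dtype=float)
    if X.ndim != 2:
        raise ValueError("training matrix must be 2-D")
    if method == "zscore":
        if X.shape[0] < 2:
            raise ValueError("zscore needs at least two training spectra")
        mean = X.mean(axis=0)
        sd = X.std(axis=0, ddof=0)
        return NormalizerState(method="zscore", center=mean, scale=sd)
    lo = X.min(axis=0)
    rng = X.max(axis=0) - lo
    return NormalizerState(method="minmax", center=lo, scale=rng)


def apply_normalizer(state: NormalizerState, matrix: np.ndarray) -> np.ndarray:
    """Apply training statistics to any block (held-out values may leave [0,1])."""
    X = np.asarray(matrix, dtype=float)
    if state.method == "none":
        return X.copy()
    out = np.zeros_like(X)
    ok = state.scale > 0
    out[:, ok] = (X[:, ok] - state.center[ok]) / state.scale[ok]
    return out


@dataclass(frozen=True)
class ReducerSpec:
    """Declarative description of one reduction stage."""

    method: str = "none"
    n_components: int = 27
    n_neighbors: int = 30
    concat_xi: bool = False
    seed: int = 0

    def __post_init__(self):
        if self.method not in REDUCER_METHODS:
            raise ValueError(f"unknown reducer {self.method!r}")
        if self.method != "none":
            if self.n_components < 1:
                raise ValueError("n_components must be >= 1")
            if self.method in ("lle", "modified_lle", "isomap"):
                if self.n_neighbors < self.n_components + 1:
                    raise ValueError(
                        "n_neighbors must be >= n_components + 1 for "
                        "neighborhood embeddings"
                    )


@dataclass(frozen=True)
class ReducerState:
    spec: ReducerSpec
    estimator: Any = field(repr=False, default=None)


def _build_estimator(spec: ReducerSpec):
    k, seed = spec.n_components, spec.seed
    if spec.method == "pca":
        return PCA(n_components=k, random_state=seed)
    if spec.method == "fa":
        return FactorAnalysis(n_components=k, random_state=seed)
    if spec.method == "ica":
        return FastICA(n_components=k, random_state=seed, max_iter=1000, whiten="unit-variance")
    if spec.method == "lle":
        return LocallyLinearEmbedding(
            n_components=k, n_neighbors=spec.n_neighbors,
            method="standard", random_state=seed,
        )
    if spec.method == "modified_lle":
        return LocallyLinearEmbedding(
            n_components=k, n_neighbors=spec.n_neighbors,
            method="modified", random_state=seed,
        )
    if spec.method == "nmf":
        return NMF(n_components=k, init="nndsvda", random_state=seed, max_iter=500)
    if spec.method == "isomap":
        return Isomap(n_components=k, n_neighbors=spec.n_neighbors)
    raise AssertionError(spec.method)


def fit_reducer(train_matrix: np.ndarray, spec: ReducerSpec) -> ReducerState:
    """Fit the reduction stage on the training block only.

    NMF requires nonnegative input; a negative entry raises with a hint to
    apply min-max scaling or Mie baseline removal first.  Held-out blocks are
    later transformed with this state via each method's out-of-sample
    extension (neighbor-weight reconstruction for LLE, landmark/kernel
    embedding for isomap — scikit-learn's ``transform``).
    """
    X = np.asarray(train_matrix, dtype=float)
    if spec.method == "none":
        return ReducerState(spec=spec)
    if spec.n_components > min(X.shape):
        raise ValueError(
            f"n_components={spec.n_components} exceeds min(n_samples, n_features)"
            f"={min(X.shape)}"
        )
    if spec.method == "nmf" and np.any(X < 0):
        raise ValueError(
            "NMF needs nonnegative inputs; normalize with min-max scaling or "
            "Mie baseline removal first"
        )
    est = _build_estimator(spec)
    est.fit(X)
    return ReducerState(spec=spec, estimator=est)


def apply_reducer(
    state: ReducerState,
    matrix: np.ndarray,
    xi_values: np.ndarray | None = None,
) -> np.ndarray:
    """Transform a block with the training-fitted state.

    When the spec asks for ``concat_xi``, the per-spectrum Mie baseline
    coefficients are appended as one extra column after reduction.
    """
    X = np.asarray(matrix, dtype=float)
    if state.spec.method == "none":
        out = X.copy()
    else:
        out = np.asarray(state.estimator.transform(X), dtype=float)
    if state.spec.concat_xi:
        if xi_values is None:
            raise ValueError("concat_xi requested but no xi values supplied")
        xi = np.asarray(xi_values, dtype=float).reshape(-1, 1)
        if xi.shape[0] != out.shape[0]:
            raise ValueError("xi vector length does not match block size")
        out = np.hstack([out, xi])
    return out
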