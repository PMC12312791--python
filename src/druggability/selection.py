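"""SVM-weight feature selection, fitted on training folds only.

The concatenated representation is high-dimensional (embedding + GO terms),
so a single-pass filter keeps the top-k features ranked by the absolute
weights of a linear maximum-margin classifier fitted on standardized
training data.  The standardizer (per-feature center and scale, fitted on
the same training data; zero-variance features get scale 1) travels with
the mask so the identical transform is replayed at prediction time.

Interface contract: neither fitting nor applying the mask ever sees
held-out labels or features, which is what makes nested cross-validation
leak-free.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.preprocessing import StandardScaler
from sklearn.svm import LinearSVC


@dataclass
class SelectionMask:
    """The k kept feature indices plus the standardizer fitted with them."""

    kept_indices: np.ndarray  # sorted ascending, unique
    k: int
    center: np.ndarray  # per-feature mean (length p, source space)
    scale: np.ndarray  # per-feature scale (length p, zero-variance -> 1)

    def __post_init__(self) -> None:
        self.kept_indices = np.asarray(self.kept_indices, dtype=int)
        self.center = np.asarray(self.center, dtype=float)
        self.scale = np.asarray(self.scale, dtype=float)
        if self.kept_indices.size != self.k:
            raise ValueError("k must equal the number of kept indices")
        if np.unique(self.kept_indices).size != self.k:
            raise ValueError("kept indices must be unique")
        if not np.all(np.diff(self.kept_indices) > 0) and self.k > 1:
            raise ValueError("kept indices must be sorted ascending")

    @property
    def source_dim(self) -> int:
        return self.center.size

    def to_json(self, path: str | Path) -> None:
        payload = {
            "k": self.k,
            "kept_indices": self.kept_indices.tolist(),
            "center": self.center.tolist(),
            "scale": self.scale.tolist(),
        }
        Path(path).write_text(json.dumps(payload), encoding="utf-8")

    @classmethod
    def from_json(cls, path: str | Path) -> "SelectionMask":
        payload = json.loads(Path(path).read_text(encoding="utf-8"))
        return cls(
            kept_indices=np.array(payload["kept_indices"], dtype=int),
            k=payload["k"],
            center=np.array(payload["center"]),
            scale=np.array(payload["scale"]),
        )


class SVMFeatureSelector(BaseEstimator, TransformerMixin):
    """Top-k filter on absolute linear-SVM weights.

    Parameters
    ----------
    k : number of features to keep (capped at the input dimension).
    C : regularization constant of the linear margin fit.
    tol, max_iter, random_state : passed to the underlying solver.
    """

    def __init__(
        self,
        k: int = 4000,
        C: float = 1.0,
        tol: float = 1e-4,
        max_iter: int = 5000,
        random_state: int = 0,
    ) -> None:
        self.k = k
        self.C = C
        self.tol = tol
        self.max_iter = max_iter
        self.random_state = random_state

    def fit(self, X: np.ndarray, y: np.ndarray) -> "SVMFeatureSelector":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if X.ndim != 2 or X.shape[0] < 2:
            raise ValueError("X must be 2-D with at least 2 samples")
        if np.unique(y).size < 2:
            raise ValueError("both classes must be present to fit the selector")

        scaler = StandardScaler().fit(X)  # zero-variance features get scale 1
        Xs = scaler.transform(X)
        svm = LinearSVC(
            C=self.C,
            tol=self.tol,
            max_iter=self.max_iter,
            random_state=self.random_state,
            dual=(X.shape[0] <= X.shape[1]),
        )
        svm.fit(Xs, y)
        weights = np.abs(np.ravel(svm.coef_))
        p = X.shape[1]
        # rank by |weight| descending, ties broken by lower feature index
        order = np.lexsort((np.arange(p), -weights))
        k_eff = min(self.k, p)
        self.ranking_ = order
        self.mask_ = SelectionMask(
            kept_indices=np.sort(order[:k_eff]),
            k=k_eff,
            center=scaler.mean_.copy(),
            scale=scaler.scale_.copy(),
        )
        self.n_features_in_ = p
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        if not hasattr(self, "mask_"):
            raise ValueError("selector is not fitted")
        return apply_mask(X, self.mask_)

    def get_support(self) -> np.ndarray:
        support = np.zeros(self.n_features_in_, dtype=bool)
        support[self.mask_.kept_indices] = True
        return support


def fit_selector(
    X_train: np.ndarray,
    y_train: np.ndarray,
    k: int = 4000,
    C: float = 1.0,
    random_state: int = 0,
) -> SelectionMask:
    """Functional form of :class:`SVMFeatureSelector.fit`."""
    sel = SVMFeatureSelector(k=k, C=C, random_state=random_state)
    return sel.fit(X_train, y_train).mask_


def apply_mask(X: np.ndarray, mask: SelectionMask) -> np.ndarray:
    """Standardize with the mask's stored parameters, then select columns."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] != mask.source_dim:
        raise ValueError(
            f"feature dimension mismatch: X has {X.shape[-1]} columns, "
            f"mask was fitted on {mask.source_dim}"
        )
    Xs = (X - mask.center) / mask.scale
    return Xs[:, mask.kept_indices]
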