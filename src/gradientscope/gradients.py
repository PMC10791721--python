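"""Gradient extraction: row sparsification, cosine affinity, PCA, Procrustes.

The embedding follows the standard connectome-gradient recipe: each row of
the correlation matrix is thresholded so only its strongest entries survive
(sparsity 0.95 keeps the top 5%), a cosine-similarity affinity is built from
the sparsified connectivity profiles, and the affinity is decomposed with
PCA. Individual embeddings are brought into the group space by orthogonal
Procrustes alignment (rotation + reflection, no scaling or translation) to a
fixed group-average reference.

`GradientEmbedding` packages the whole recipe as a scikit-learn transformer:
``fit`` derives the reference gradients from one (typically group-average)
connectivity matrix and ``transform`` embeds further matrices into the
reference space.
"""

from __future__ import annotations

import numpy as np
from scipy.linalg import orthogonal_procrustes
from sklearn.base import BaseEstimator, TransformerMixin

from .core_io import ConnectivityMatrix, GradientSet

__all__ = [
    "sparsify_rows",
    "cosine_affinity",
    "pca_gradients",
    "variance_explained",
    "procrustes_align",
    "GradientEmbedding",
    "ProcrustesAlignment",
]


def _values(m: ConnectivityMatrix | np.ndarray) -> np.ndarray:
    return m.values if isinstance(m, ConnectivityMatrix) else np.asarray(m, dtype=float)


def sparsify_rows(m: ConnectivityMatrix | np.ndarray, sparsity: float) -> np.ndarray:
    """Zero the smallest ``floor(sparsity · P)`` entries of each row.

    Entries are ranked by signed value, so retained negatives are removed
    before weak positives; ties are broken by zeroing the lower parcel index
    first (stable sort). Survivors keep their values and the result is NOT
    re-symmetrized — the affinity step consumes rows as connectivity
    profiles.
    """
    if not 0.0 <= sparsity < 1.0:
        raise ValueError("sparsity must lie in [0, 1)")
    values = _values(m).copy()
    n_p = values.shape[1]
    n_zero = int(np.floor(sparsity * n_p))
    if n_zero == 0:
        return values
    order = np.argsort(values, axis=1, kind="stable")  # ascending; ties → lower index first
    rows = np.repeat(np.arange(values.shape[0]), n_zero)
    cols = order[:, :n_zero].ravel()
    values[rows, cols] = 0.0
    return values


def cosine_affinity(m: np.ndarray) -> np.ndarray:
    """Cosine similarity between all pairs of rows.

    ``affinity[i, j] = <row_i, row_j> / (‖row_i‖ · ‖row_j‖)``. An all-zero
    row has no direction and raises, naming the parcel.
    """
    values = _values(m)
    norms = np.linalg.norm(values, axis=1)
    if (norms == 0).any():
        bad = np.flatnonzero(norms == 0).tolist()
        raise ValueError(f"all-zero rows (no surviving connections) at parcels {bad}")
    unit = values / norms[:, None]
    aff = unit @ unit.T
    aff = np.clip((aff + aff.T) / 2.0, -1.0, 1.0)
    return aff


def _fix_signs(scores: np.ndarray) -> np.ndarray:
    """Deterministic sign convention: largest-|score| element positive."""
    for j in range(scores.shape[1]):
        i = int(np.argmax(np.abs(scores[:, j])))
        if scores[i, j] < 0:
            scores[:, j] = -scores[:, j]
    return scores


def pca_gradients(affinity: np.ndarray, n_gradients: int) -> GradientSet:
    """PCA of the affinity matrix: top ``n_gradients`` component scores.

    Columns are mean-centred, scores are the projections of the P rows onto
    the leading principal axes, and explained variance is each eigenvalue's
    fraction of the total variance. PCA signs are arbitrary; a deterministic
    convention (element of largest absolute score positive) is applied.
    """
    aff = np.asarray(affinity, dtype=float)
    if aff.ndim != 2 or aff.shape[0] != aff.shape[1]:
        raise ValueError("affinity must be square")
    if not np.isfinite(aff).all():
        raise ValueError("affinity contains non-finite values")
    n_p = aff.shape[0]
    if n_gradients > n_p:
        raise ValueError(f"n_gradients={n_gradients} exceeds {n_p} parcels")
    centred = aff - aff.mean(axis=0, keepdims=True)
    u, s, _vt = np.linalg.svd(centred, full_matrices=False)
    total = float(np.sum(s**2))
    if total <= 0:
        raise ValueError("affinity has zero variance after centring")
    rank = int(np.count_nonzero(s > s[0] * 1e-12))
    if rank < n_gradients:
        raise ValueError(
            f"affinity rank {rank} is below n_gradients={n_gradients}; "
            "request fewer gradients"
        )
    scores = _fix_signs(u[:, :n_gradients] * s[:n_gradients])
    explained = (s[:n_gradients] ** 2) / total
    return GradientSet(scores=scores, explained_variance=explained, aligned=False)


def variance_explained(gset: GradientSet, component: int = 0) -> float:
    """Fraction of total variance carried by one component (0-based)."""
    if not 0 <= component < gset.n_gradients:
        raise IndexError(
            f"component {component} out of range for {gset.n_gradients} gradients"
        )
    return float(gset.explained_variance[component])


def procrustes_align(individual: GradientSet, reference: GradientSet) -> GradientSet:
    """Orthogonally align an individual's scores to a reference embedding.

    Returns ``individual.scores @ R`` where R (rotation + reflection, no
    scaling or translation) minimizes the Frobenius distance to the
    reference. Explained-variance fractions are carried over unchanged.
    """
    x = individual.scores
    y = reference.scores
    if x.shape != y.shape:
        raise ValueError(f"shape mismatch: individual {x.shape} vs reference {y.shape}")
    rotation, _scale = orthogonal_procrustes(x, y)
    return GradientSet(
        scores=x @ rotation,
        explained_variance=individual.explained_variance,
        aligned=True,
    )


class GradientEmbedding(BaseEstimator, TransformerMixin):
    """Connectome gradient extractor with reference alignment.

    Parameters
    ----------
    n_gradients : int, default 10
        Number of components to retain.
    sparsity : float, default 0.95
        Fraction of each row's smallest entries zeroed before the affinity.
    kernel : str, default "cosine"
        Affinity kernel; only cosine similarity is implemented.
    align : bool, default True
        Whether ``transform`` Procrustes-aligns embeddings to the fitted
        reference.

    Attributes
    ----------
    gradients_ : ndarray of shape (P, n_gradients)
        Reference gradient scores from the fitted connectivity matrix.
    explained_variance_ratio_ : ndarray of shape (n_gradients,)
        Variance fraction per reference component.
    n_features_in_ : int
        Number of parcels P.
    """

    def __init__(self, n_gradients: int = 10, sparsity: float = 0.95,
                 kernel: str = "cosine", align: bool = True):
        self.n_gradients = n_gradients
        self.sparsity = sparsity
        self.kernel = kernel
        self.align = align

    def _embed(self, x: np.ndarray) -> GradientSet:
        if self.kernel != "cosine":
            raise ValueError(f"unsupported kernel {self.kernel!r}")
        sparse = sparsify_rows(x, self.sparsity)
        return pca_gradients(cosine_affinity(sparse), self.n_gradients)

    def fit(self, X: ConnectivityMatrix | np.ndarray, y=None) -> "GradientEmbedding":
        """Derive the reference gradients from one P × P connectivity matrix."""
        x = _values(X)
        if x.ndim != 2 or x.shape[0] != x.shape[1]:
            raise ValueError("X must be a square connectivity matrix")
        gset = self._embed(x)
        self.n_features_in_ = x.shape[0]
        self.reference_ = gset
        self.gradients_ = gset.scores
        self.explained_variance_ratio_ = gset.explained_variance
        return self

    def transform(self, X: ConnectivityMatrix | np.ndarray) -> np.ndarray:
        """Embed a P × P connectivity matrix into the reference space.

        Returns the P × n_gradients score matrix (aligned to the reference
        when ``align=True``).
        """
        if not hasattr(self, "reference_"):
            raise AttributeError("GradientEmbedding is not fitted yet")
        return self.transform_set(X).scores

    def transform_set(self, X: ConnectivityMatrix | np.ndarray) -> GradientSet:
        """Like :meth:`transform` but returns the full :class:`GradientSet`."""
        if not hasattr(self, "reference_"):
            raise AttributeError("GradientEmbedding is not fitted yet")
        x = _values(X)
        if x.shape != (self.n_features_in_, self.n_features_in_):
            raise ValueError(
                f"expected a {self.n_features_in_}×{self.n_features_in_} matrix, "
                f"got {x.shape}"
            )
        gset = self._embed(x)
        if self.align:
            gset = procrustes_align(gset, self.reference_)
        return gset


class ProcrustesAlignment(BaseEstimator, TransformerMixin):
    """Orthogonal Procrustes alignment to a fixed reference score matrix.

    ``fit(X)`` stores X as the reference; ``transform(Y)`` returns Y rotated
    (and possibly reflected) onto it. No scaling or translation is applied.
    """

    def fit(self, X: np.ndarray, y=None) -> "ProcrustesAlignment":
        self.reference_ = np.asarray(X, dtype=float)
        self.n_features_in_ = self.reference_.shape[1]
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        if not hasattr(self, "reference_"):
            raise AttributeError("ProcrustesAlignment is not fitted yet")
        x = np.asarray(X, dtype=float)
        if x.shape != self.reference_.shape:
            raise ValueError(
                f"shape mismatch: {x.shape} vs reference {self.reference_.shape}"
            )
        rotation, _ = orthogonal_procrustes(x, self.reference_)
        return x @ rotation
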