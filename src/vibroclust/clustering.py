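"""Spectral clustering of vibrational spectra.

Pipeline: each pair of broadened spectra is scored by Pearson's correlation
(mean-centred intensity vectors, normalized by their standard deviations),
giving a similarity graph S over compounds. From the symmetric normalized
Laplacian

    L_sym = I - D^{-1/2} S D^{-1/2},   d_i = sum_j S_ij,

the eigenvectors of the k smallest eigenvalues embed the compounds in R^k,
where cluster structure is (near) piecewise constant. Hard labels are then
obtained by the Yu–Shi discretization: alternately rotate the embedding
toward a cluster-indicator matrix (rotation updated from an SVD) and assign
each row to its largest coordinate (non-maximum suppression). The number of
clusters is chosen by the mean silhouette coefficient on the correlation
distance 1 - r. Spectral clustering makes no convexity assumption about
cluster shape, unlike k-means.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.linalg

from .labeling import Labeling
from .metrics import silhouette
from .spectra import GridSpectrum

__all__ = [
    "SimilarityMatrix",
    "Embedding",
    "ClusteringResult",
    "DegenerateSpectrumError",
    "IsolatedNodeError",
    "DegenerateClusteringError",
    "pearson_correlation",
    "pearson_similarity",
    "laplacian_sym",
    "spectral_embed",
    "discretize",
    "cluster_spectra",
    "silhouette_select_k",
]

CLIP_POLICIES = ("clip", "shift")


class DegenerateSpectrumError(ValueError):
    """A spectrum has zero variance, so Pearson correlation is undefined."""


class IsolatedNodeError(ValueError):
    """A node has zero degree after the non-negativity policy."""


class DegenerateClusteringError(RuntimeError):
    """Discretization could not produce k non-empty clusters."""


@dataclass(frozen=True)
class SimilarityMatrix:
    """Symmetric non-negative affinity matrix with unit diagonal."""

    ids: tuple
    values: np.ndarray

    def __post_init__(self):
        values = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if values.shape != (n, n):
            raise ValueError("similarity matrix shape does not match id count")
        if not np.allclose(values, values.T, atol=1e-10):
            raise ValueError("similarity matrix must be symmetric")
        if np.any(values < -1e-12) or np.any(values > 1 + 1e-12):
            raise ValueError("similarities must lie in [0, 1]")
        if not np.allclose(np.diag(values), 1.0):
            raise ValueError("similarity diagonal must equal 1")
        object.__setattr__(self, "ids", tuple(self.ids))
        object.__setattr__(self, "values", values)

    @property
    def n(self) -> int:
        return len(self.ids)

    def degrees(self) -> np.ndarray:
        return self.values.sum(axis=1)


@dataclass(frozen=True)
class Embedding:
    """Rows = compounds embedded on the k lowest Laplacian eigenvectors."""

    ids: tuple
    U: np.ndarray
    eigenvalues: np.ndarray

    def __post_init__(self):
        U = np.asarray(self.U, dtype=float)
        ev = np.asarray(self.eigenvalues, dtype=float)
        if U.ndim != 2 or U.shape[0] != len(self.ids) or U.shape[1] != ev.size:
            raise ValueError("embedding shape inconsistent with ids/eigenvalues")
        if np.any(np.diff(ev) < -1e-10):
            raise ValueError("eigenvalues must be ascending")
        gram = U.T @ U
        if not np.allclose(gram, np.eye(U.shape[1]), atol=1e-8):
            raise ValueError("embedding columns must be orthonormal")
        object.__setattr__(self, "ids", tuple(self.ids))
        object.__setattr__(self, "U", U)
        object.__setattr__(self, "eigenvalues", ev)


@dataclass(frozen=True)
class ClusteringResult:
    labeling: Labeling
    k: int
    silhouette: float
    eigenvalues: np.ndarray
    similarity: SimilarityMatrix
    seed: int

    def __post_init__(self):
        if self.labeling.n_labels != self.k:
            raise ValueError("k must equal the number of distinct labels")


def _common_grid_matrix(spectra: list[GridSpectrum]) -> tuple[tuple, np.ndarray]:
    if len(spectra) < 2:
        raise ValueError("need at least 2 spectra")
    grid = spectra[0].grid
    for s in spectra[1:]:
        if s.grid != grid:
            raise ValueError(
                f"spectra are not on a common grid ({s.compound_id} differs)"
            )
    ids = tuple(s.compound_id for s in spectra)
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate compound ids among spectra")
    X = np.stack([s.intensities for s in spectra])
    return ids, X


def pearson_correlation(spectra: list[GridSpectrum]) -> tuple[tuple, np.ndarray]:
    """Raw (unclipped) Pearson correlation matrix between spectra.

    Returns (ids, r) with r_ij in [-1, 1] and unit diagonal. Raises
    :class:`DegenerateSpectrumError` for a constant spectrum.
    """
    ids, X = _common_grid_matrix(spectra)
    sd = X.std(axis=1)
    flat = np.flatnonzero(sd == 0)
    if flat.size:
        raise DegenerateSpectrumError(
            f"constant spectrum (zero variance): {[ids[i] for i in flat]!r}"
        )
    r = np.corrcoef(X)
    r = np.clip((r + r.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(r, 1.0)
    return ids, r


def _apply_clip_policy(r: np.ndarray, clip_policy: str) -> np.ndarray:
    if clip_policy == "clip":
        s = np.maximum(r, 0.0)
    elif clip_policy == "shift":
        s = (1.0 + r) / 2.0
    else:
        raise ValueError(f"clip_policy must be one of {CLIP_POLICIES}")
    np.fill_diagonal(s, 1.0)
    return s


def pearson_similarity(
    spectra: list[GridSpectrum], clip_policy: str = "clip"
) -> SimilarityMatrix:
    """Pearson-correlation affinity between spectra on a common grid.

    Negative correlations break the non-negative-affinity interpretation of
    the similarity graph; by default they are clipped to 0
    (``clip_policy="shift"`` rescales r to (1+r)/2 instead).
    """
    ids, r = pearson_correlation(spectra)
    return SimilarityMatrix(ids, _apply_clip_policy(r, clip_policy))


def laplacian_sym(S: SimilarityMatrix) -> tuple[np.ndarray, np.ndarray]:
    """Symmetric normalized Laplacian L = I - D^{-1/2} S D^{-1/2}.

    Returns (L, d) where d is the degree vector. L is symmetric positive
    semidefinite with eigenvalues in [0, 2]; sqrt(d) spans its null space
    direction for each connected component.
    """
    d = S.degrees()
    if np.any(d <= 0):
        bad = [S.ids[i] for i in np.flatnonzero(d <= 0)]
        raise IsolatedNodeError(f"zero-degree node(s) in similarity graph: {bad!r}")
    inv_sqrt = 1.0 / np.sqrt(d)
    L = np.eye(S.n) - (inv_sqrt[:, None] * S.values * inv_sqrt[None, :])
    L = (L + L.T) / 2.0
    return L, d


def spectral_embed(L: np.ndarray, k: int, ids: tuple | None = None) -> Embedding:
    """Orthonormal eigenvectors of the k smallest eigenvalues of L_sym.

    Deterministic up to sign (fixed by making each column's largest-
    magnitude entry positive) and up to rotation within degenerate
    eigenspaces.
    """
    L = np.asarray(L, dtype=float)
    n = L.shape[0]
    if ids is None:
        ids = tuple(range(n))
    if not 2 <= k <= n - 1:
        raise ValueError(f"k must satisfy 2 <= k <= n-1 (= {n - 1}), got {k}")
    eigenvalues, U = scipy.linalg.eigh(L, subset_by_index=[0, k - 1])
    # fix sign per column for determinism
    for j in range(U.shape[1]):
        i_max = np.argmax(np.abs(U[:, j]))
        if U[i_max, j] < 0:
            U[:, j] = -U[:, j]
    return Embedding(ids, U, eigenvalues)


def _init_rotation(U: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Seed the rotation with k mutually far rows (first picked at random)."""
    n, k = U.shape
    R = np.zeros((k, k))
    R[:, 0] = U[rng.integers(n)]
    c = np.zeros(n)
    for j in range(1, k):
        c += np.abs(U @ R[:, j - 1])
        R[:, j] = U[int(c.argmin())]
    return R


def discretize(
    embedding: Embedding,
    seed: int = 0,
    row_normalize: bool = True,
    max_restarts: int = 30,
    tol: float = 1e-7,
    max_iter: int = 100,
) -> Labeling:
    """Yu–Shi discretization of a spectral embedding into hard labels.

    Rows of U are length-normalized; a k x k rotation R is initialized from
    k mutually far rows and refined by alternating (i) non-maximum
    suppression — assign each row to the argmax column of U R, ties to the
    lowest column index — and (ii) an SVD update: with X the indicator
    matrix of the assignment and X^T U = W Sigma V^T, set R = V W^T. The
    loop stops when the SVD objective (sum of singular values) changes by
    less than ``tol`` or after ``max_iter`` sweeps. An assignment with an
    empty cluster triggers a restart with a fresh random initial row, up to
    ``max_restarts`` times.
    """
    U = embedding.U.copy()
    n, k = U.shape
    if row_normalize:
        norms = np.linalg.norm(U, axis=1, keepdims=True)
        norms[norms == 0] = 1.0
        U = U / norms
    rng = np.random.default_rng(seed)
    for _restart in range(max_restarts):
        R = _init_rotation(U, rng)
        last_objective = 0.0
        labels = None
        for _it in range(max_iter):
            labels = np.argmax(U @ R, axis=1)  # argmax takes the lowest index on ties
            if np.unique(labels).size < k:
                labels = None
                break  # empty cluster: restart with a new initialization
            X = np.zeros((n, k))
            X[np.arange(n), labels] = 1.0
            W, sv, Vt = scipy.linalg.svd(X.T @ U)
            objective = sv.sum()
            if abs(objective - last_objective) < tol:
                break
            last_objective = objective
            R = Vt.T @ W.T
        if labels is not None:
            return Labeling(embedding.ids, tuple(int(v) for v in labels)).relabel_contiguous()
    raise DegenerateClusteringError(
        f"could not find {k} non-empty clusters after {max_restarts} restarts"
    )


def _cluster_similarity(
    ids: tuple,
    r: np.ndarray,
    k: int,
    seed: int,
    clip_policy: str,
) -> ClusteringResult:
    S = SimilarityMatrix(ids, _apply_clip_policy(r.copy(), clip_policy))
    L, _d = laplacian_sym(S)
    emb = spectral_embed(L, k, ids=ids)
    labeling = discretize(emb, seed=seed)
    dist = 1.0 - r  # correlation distance on the unclipped correlations
    np.fill_diagonal(dist, 0.0)
    sil = silhouette(labeling.codes(order=ids), dist)
    return ClusteringResult(
        labeling=labeling,
        k=k,
        silhouette=sil,
        eigenvalues=emb.eigenvalues,
        similarity=S,
        seed=seed,
    )


def cluster_spectra(
    spectra: list[GridSpectrum],
    k: int,
    seed: int = 0,
    clip_policy: str = "clip",
) -> ClusteringResult:
    """Full pipeline at fixed k: similarity -> Laplacian -> embed -> discretize."""
    ids, r = pearson_correlation(spectra)
    return _cluster_similarity(ids, r, k, seed, clip_policy)


def silhouette_select_k(
    spectra: list[GridSpectrum],
    k_min: int = 2,
    k_max: int = 10,
    seed: int = 0,
    clip_policy: str = "clip",
) -> ClusteringResult:
    """Run the pipeline for each k in [k_min, k_max]; keep the best silhouette.

    The silhouette is evaluated on the correlation distance 1 - r of the
    original spectra (the same similarity the clustering consumed); ties go
    to the smallest k.
    """
    ids, r = pearson_correlation(spectra)
    n = len(ids)
    if not 2 <= k_min <= k_max <= n - 1:
        raise ValueError(f"need 2 <= k_min <= k_max <= n-1 (= {n - 1})")
    best: ClusteringResult | None = None
    for k in range(k_min, k_max + 1):
        result = _cluster_similarity(ids, r, k, seed, clip_policy)
        if best is None or result.silhouette > best.silhouette + 1e-12:
            best = result
    assert best is not None
    return best
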