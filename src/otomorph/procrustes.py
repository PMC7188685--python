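"""Generalized Procrustes analysis, tangent projection and shape PCA."""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Sequence, Tuple

import numpy as np

from otomorph.types import GeometryError


def centroid_size(config: np.ndarray) -> float:
    """Square root of summed squared landmark distances from their centroid."""
    X = np.asarray(config, dtype=float)
    return float(np.sqrt(((X - X.mean(axis=0)) ** 2).sum()))


def _rotation_to(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Proper rotation R (det +1, reflections disallowed) minimizing ||A R - B||."""
    U, _, Vt = np.linalg.svd(A.T @ B)
    d = np.sign(np.linalg.det(U @ Vt))
    D = np.diag([1.0, 1.0, d])
    return U @ D @ Vt


@dataclass
class SimilarityTransform:
    """x -> scale * (x - translation) @ rotation, as applied during GPA."""

    translation: np.ndarray
    scale: float
    rotation: np.ndarray

    def apply(self, X: np.ndarray) -> np.ndarray:
        return self.scale * (np.asarray(X, float) - self.translation) @ self.rotation

    def invert(self, Y: np.ndarray) -> np.ndarray:
        return (np.asarray(Y, float) / self.scale) @ self.rotation.T + self.translation


@dataclass
class AlignedSample:
    """Procrustes-aligned configurations, their consensus and centroid sizes."""

    coordinates: np.ndarray  # n x k x 3
    consensus: np.ndarray  # k x 3
    centroid_sizes: np.ndarray  # n


def gpa_transforms(
    configs: Sequence[np.ndarray], tol: float = 1e-10, max_iter: int = 100
) -> Tuple[np.ndarray, np.ndarray, List[SimilarityTransform]]:
    """Full GPA returning aligned shapes, consensus, and per-shape transforms.

    Each configuration is centered, scaled to unit centroid size, and rotated
    (proper rotations only) to the iteratively re-estimated consensus, itself
    rescaled to unit centroid size each round.
    """
    if len(configs) < 2:
        raise GeometryError("GPA needs at least 2 configurations")
    X = [np.asarray(c, dtype=float) for c in configs]
    centroids = [x.mean(axis=0) for x in X]
    sizes = np.array([centroid_size(x) for x in X])
    for i, s in enumerate(sizes):
        if s <= 0:
            raise GeometryError(f"configuration {i} is degenerate (zero centroid size)")
    Z = [(x - c) / s for x, c, s in zip(X, centroids, sizes)]
    rotations = [np.eye(3) for _ in Z]

    consensus = Z[0].copy()
    for _ in range(max_iter):
        rotations = [_rotation_to(z, consensus) for z in Z]
        aligned = np.stack([z @ r for z, r in zip(Z, rotations)])
        new_consensus = aligned.mean(axis=0)
        new_consensus /= centroid_size(new_consensus)
        if np.linalg.norm(new_consensus - consensus) < tol:
            consensus = new_consensus
            break
        consensus = new_consensus
    rotations = [_rotation_to(z, consensus) for z in Z]
    aligned = np.stack([z @ r for z, r in zip(Z, rotations)])
    transforms = [
        SimilarityTransform(translation=c, scale=1.0 / s, rotation=r)
        for c, s, r in zip(centroids, sizes, rotations)
    ]
    return aligned, aligned.mean(axis=0), transforms


def gpa(configs: Sequence[np.ndarray], tol: float = 1e-10, max_iter: int = 100) -> AlignedSample:
    """Generalized Procrustes alignment (translation, scale, proper rotation)."""
    X = [np.asarray(c, dtype=float) for c in configs]
    sizes = np.array([centroid_size(x) for x in X])
    aligned, consensus, _ = gpa_transforms(X, tol=tol, max_iter=max_iter)
    return AlignedSample(coordinates=aligned, consensus=consensus, centroid_sizes=sizes)


@dataclass
class ShapeSpace:
    """PCA of tangent-projected aligned coordinates.

    ``scores`` are specimen coordinates in morphospace; Euclidean distances
    between score rows equal tangent-space distances between specimens.
    """

    scores: np.ndarray  # n x m
    eigenvalues: np.ndarray  # m, descending
    variance_fractions: np.ndarray  # m, sums to 1 over nonzero axes
    loadings: np.ndarray  # m x 3k
    mean: np.ndarray  # 3k tangent-space mean
    consensus: np.ndarray  # k x 3


def pca_shapes(aligned: AlignedSample, rank_tol: float = 1e-10) -> ShapeSpace:
    """Project aligned shapes into the tangent space at the consensus and
    decompose by SVD of the centered data matrix.

    Tangent projection is orthogonal: the component of each (vectorized)
    shape along the unit consensus vector is removed before PCA.
    """
    n = aligned.coordinates.shape[0]
    if n < 3:
        raise GeometryError("shape PCA needs at least 3 specimens")
    X = aligned.coordinates.reshape(n, -1)
    c = aligned.consensus.reshape(-1)
    c_hat = c / np.linalg.norm(c)
    Xt = X - np.outer(X @ c_hat, c_hat)
    mean = Xt.mean(axis=0)
    Xc = Xt - mean
    U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
    if S[0] <= rank_tol:
        raise GeometryError("all shapes identical: shape covariance has rank 0")
    m = int(np.sum(S > rank_tol * S[0]))
    U, S, Vt = U[:, :m], S[:m], Vt[:m]
    # deterministic sign: largest-magnitude loading element positive
    for j in range(m):
        i = np.argmax(np.abs(Vt[j]))
        if Vt[j, i] < 0:
            Vt[j] *= -1.0
            U[:, j] *= -1.0
    eigenvalues = S**2 / (n - 1)
    return ShapeSpace(
        scores=U * S,
        eigenvalues=eigenvalues,
        variance_fractions=eigenvalues / eigenvalues.sum(),
        loadings=Vt,
        mean=mean,
        consensus=aligned.consensus,
    )


def min_pcs_for_variance(space: ShapeSpace, threshold: float) -> int:
    """Smallest number of leading PCs whose cumulative variance >= threshold."""
    if not (0.0 < threshold <= 1.0):
        raise GeometryError(f"threshold must be in (0, 1], got {threshold}")
    cum = np.cumsum(space.variance_fractions)
    return int(np.searchsorted(cum, threshold - 1e-12) + 1)
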