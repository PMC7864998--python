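"""Metric multidimensional scaling of mean Hamming-distance matrices.

The embedding places each grading (human or model) as a point in the
plane so that pairwise Euclidean distances reproduce the mean Hamming
distances as accurately as possible.  The axes carry no unit: they are
on the Hamming scale.

Algorithm: Torgerson classical scaling (double centering of squared
distances, top-2 eigenpairs) as a deterministic initialization, refined
by SMACOF-style stress majorization, which never increases the raw
stress.  Because MDS solutions are defined only up to rigid motions, the
result is moved into a canonical frame: centroid at the origin, first id
on the non-negative x-axis, second id with non-negative y.  This makes
outputs reproducible across runs and platforms.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import ValidationError
from .metrics import MeanDistanceMatrix

__all__ = ["Embedding2D", "mds_embed", "stress"]

_MAX_ITER = 300
_REL_TOL = 1e-9


@dataclass
class Embedding2D:
    """A 2D configuration of gradings with its Kruskal stress."""

    ids: list[str]
    coords: np.ndarray  # (k, 2), centered at the origin
    stress: float
    seed: int = 0

    def point(self, grading_id: str) -> np.ndarray:
        return self.coords[self.ids.index(grading_id)]

    def pairwise_distances(self) -> np.ndarray:
        diff = self.coords[:, None, :] - self.coords[None, :, :]
        return np.sqrt((diff**2).sum(axis=-1))

    def to_csv(self, path: str | Path) -> None:
        frame = pd.DataFrame(
            {"grading_id": self.ids, "x": self.coords[:, 0], "y": self.coords[:, 1]}
        )
        with open(path, "w", encoding="utf-8") as fh:
            frame.to_csv(fh, index=False)
            fh.write(f"# stress: {self.stress!r}\n")


def _validate_matrix(d: MeanDistanceMatrix) -> np.ndarray:
    values = np.asarray(d.values, dtype=float)
    if values.ndim != 2 or values.shape[0] != values.shape[1]:
        raise ValidationError("distance matrix must be square")
    if values.shape[0] < 2:
        raise ValidationError("need at least two gradings to embed")
    if not np.allclose(values, values.T):
        raise ValidationError("distance matrix must be symmetric")
    if (values < 0).any():
        raise ValidationError("distance matrix must be non-negative")
    return values


def _raw_stress(dist: np.ndarray, coords: np.ndarray) -> float:
    diff = coords[:, None, :] - coords[None, :, :]
    edist = np.sqrt((diff**2).sum(axis=-1))
    iu = np.triu_indices_from(dist, k=1)
    return float(((dist[iu] - edist[iu]) ** 2).sum())


def _classical_init(dist: np.ndarray) -> np.ndarray:
    k = dist.shape[0]
    j = np.eye(k) - np.full((k, k), 1.0 / k)
    b = -0.5 * j @ (dist**2) @ j
    eigval, eigvec = np.linalg.eigh(b)
    order = np.argsort(eigval)[::-1][:2]
    lam = np.clip(eigval[order], 0.0, None)
    coords = eigvec[:, order] * np.sqrt(lam)[None, :]
    return coords


def _guttman_transform(dist: np.ndarray, coords: np.ndarray) -> np.ndarray:
    k = dist.shape[0]
    diff = coords[:, None, :] - coords[None, :, :]
    edist = np.sqrt((diff**2).sum(axis=-1))
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(edist > 0, dist / np.where(edist > 0, edist, 1.0), 0.0)
    b = -ratio
    np.fill_diagonal(b, 0.0)
    np.fill_diagonal(b, -b.sum(axis=1))
    return b @ coords / k


def _canonicalize(coords: np.ndarray, tol: float = 1e-12) -> np.ndarray:
    coords = coords - coords.mean(axis=0, keepdims=True)
    first = coords[0]
    norm = np.hypot(first[0], first[1])
    if norm > tol:
        c, s = first[0] / norm, first[1] / norm
        rot = np.array([[c, s], [-s, c]])  # rotates first point onto +x
        coords = coords @ rot.T
    if coords.shape[0] > 1 and coords[1, 1] < -tol:
        coords = coords * np.array([1.0, -1.0])
    # recenter exactly (rotation preserves the centroid, but be safe)
    return coords - coords.mean(axis=0, keepdims=True)


def mds_embed(d: MeanDistanceMatrix, seed: int = 0) -> Embedding2D:
    """Embed a mean-distance matrix into 2D by metric MDS.

    Deterministic: the classical-scaling initialization and majorization
    refinement involve no randomness; ``seed`` is recorded for provenance
    and API stability.
    """
    dist = _validate_matrix(d)
    coords = _classical_init(dist)
    s_prev = _raw_stress(dist, coords)
    for _ in range(_MAX_ITER):
        coords = _guttman_transform(dist, coords)
        s_new = _raw_stress(dist, coords)
        if s_prev <= 0 or abs(s_prev - s_new) <= _REL_TOL * max(s_prev, 1e-300):
            s_prev = s_new
            break
        s_prev = s_new
    coords = _canonicalize(coords)
    emb = Embedding2D(list(d.ids), coords, stress=0.0, seed=seed)
    emb.stress = stress(d, emb)
    return emb


def stress(d: MeanDistanceMatrix, e: Embedding2D) -> float:
    """Kruskal stress-1: sqrt(Σ_{i<j}(d_ij − ||x_i − x_j||)² / Σ_{i<j} d_ij²).

    Zero for an exact reproduction; defined as 0 for an all-zero matrix
    embedded at a single point.
    """
    if list(d.ids) != list(e.ids):
        raise ValidationError(
            f"id mismatch between matrix ({d.ids}) and embedding ({e.ids})"
        )
    dist = np.asarray(d.values, dtype=float)
    edist = e.pairwise_distances()
    iu = np.triu_indices_from(dist, k=1)
    num = ((dist[iu] - edist[iu]) ** 2).sum()
    den = (dist[iu] ** 2).sum()
    if den == 0:
        return 0.0 if num == 0 else float("inf")
    return float(np.sqrt(num / den))
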