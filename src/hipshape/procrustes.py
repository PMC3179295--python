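"""Generalized Procrustes analysis (GPA) of 2D landmark outlines.

Shapes are superimposed by removing translation, scale (to unit centroid
size) and rotation, iterating rotations against the evolving mean until the
mean stabilizes.  Only proper rotations are allowed — cohorts are same-side
(right) hips, so reflections would be anatomical errors.  By default the
aligned shapes are projected onto the tangent space at the mean, the
standard linearization before PCA on shape coordinates.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np


class DegenerateShapeError(ValueError):
    """Shape has no spatial extent (all landmarks coincide) or degenerate fit."""


def _as_points(shape: np.ndarray) -> np.ndarray:
    pts = np.asarray(shape, dtype=float)
    if pts.ndim == 1:
        pts = pts.reshape(-1, 2)
    return pts


def centroid_size(points: np.ndarray) -> float:
    """Square root of summed squared landmark distances from the centroid (mm)."""
    pts = _as_points(points)
    if pts.shape[0] < 2:
        raise DegenerateShapeError("need at least 2 points")
    centered = pts - pts.mean(axis=0)
    size = float(np.sqrt((centered**2).sum()))
    if size <= 0 or not np.isfinite(size):
        raise DegenerateShapeError("degenerate shape: all points identical")
    return size


def optimal_rotation(shape_a: np.ndarray, shape_b: np.ndarray) -> np.ndarray:
    """Proper 2x2 rotation R minimizing the squared distance of the rotated
    shape a (points R @ p, i.e. ``a @ R.T`` row-wise) from shape b.

    Kabsch solution restricted to det(R) = +1 (reflections forbidden —
    cohorts are same-side hips).
    """
    a = _as_points(shape_a)
    b = _as_points(shape_b)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    h = a.T @ b  # cross-covariance
    u, s, vt = np.linalg.svd(h)
    if np.min(s) <= 1e-14 * max(np.max(s), 1e-300):
        raise DegenerateShapeError("degenerate cross-covariance; rotation undefined")
    d = np.sign(np.linalg.det(vt.T @ u.T))
    r = vt.T @ np.diag([1.0, d]) @ u.T
    return r


def procrustes_distance(shape_a: np.ndarray, shape_b: np.ndarray) -> float:
    """Root-sum-square distance after optimally rotating a onto b
    (both centered and unit-size)."""
    a = _as_points(shape_a)
    b = _as_points(shape_b)
    a = (a - a.mean(axis=0)) / centroid_size(a)
    b = (b - b.mean(axis=0)) / centroid_size(b)
    r = optimal_rotation(a, b)
    return float(np.sqrt(((a @ r.T - b) ** 2).sum()))


@dataclass
class AlignedCohort:
    """GPA result: n aligned shapes as flat 2k vectors, plus provenance."""

    shapes: np.ndarray  # (n, 2k)
    mean_shape: np.ndarray  # (2k,)
    centroid_sizes: np.ndarray  # (n,), mm
    subject_ids: list[str]
    iterations_run: int
    converged: bool
    tangent: bool

    @property
    def n(self) -> int:
        return self.shapes.shape[0]

    @property
    def k(self) -> int:
        return self.shapes.shape[1] // 2

    def to_json(self, path: str | Path) -> None:
        payload = dict(
            n=self.n,
            k=self.k,
            subject_ids=self.subject_ids,
            iterations_run=self.iterations_run,
            converged=self.converged,
            tangent=self.tangent,
            centroid_sizes=self.centroid_sizes.tolist(),
            mean_shape=self.mean_shape.tolist(),
            shapes=self.shapes.tolist(),
        )
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path: str | Path) -> "AlignedCohort":
        d = json.loads(Path(path).read_text())
        return cls(
            shapes=np.asarray(d["shapes"], dtype=float),
            mean_shape=np.asarray(d["mean_shape"], dtype=float),
            centroid_sizes=np.asarray(d["centroid_sizes"], dtype=float),
            subject_ids=list(d["subject_ids"]),
            iterations_run=int(d["iterations_run"]),
            converged=bool(d["converged"]),
            tangent=bool(d["tangent"]),
        )


def tangent_project(shapes: np.ndarray, mean: np.ndarray) -> np.ndarray:
    """Project unit-size aligned shapes onto the tangent plane at the mean.

    Each shape x is rescaled by (m.m)/(x.m) so its component along the mean
    m is constant; with a unit-size mean this keeps shapes at unit scale to
    first order while removing the curvature of the pre-shape sphere.
    """
    m = mean.ravel()
    denom = shapes @ m
    if np.any(denom <= 0):
        raise DegenerateShapeError("shape orthogonal to mean; tangent projection undefined")
    return shapes * ((m @ m) / denom)[:, None]


def generalized_procrustes(
    cohort: Sequence,
    tol: float = 1e-8,
    max_iter: int = 100,
    tangent: bool = True,
) -> AlignedCohort:
    """Iteratively superimpose a cohort of outlines on their evolving mean.

    Accepts a sequence of LandmarkSet or of (k, 2) arrays.  Each shape is
    centered and scaled to unit centroid size, rotated to the current mean,
    the mean recomputed and renormalized, until the RMS change of the mean
    drops below ``tol``.  The global rotation (arbitrary for GPA) is fixed
    by rotating the final configuration so the mean best fits the first
    shape, making output reproducible.
    """
    pts_list = []
    ids = []
    for i, item in enumerate(cohort):
        if hasattr(item, "points"):
            pts_list.append(np.asarray(item.points, dtype=float))
            ids.append(item.subject_id)
        else:
            pts_list.append(_as_points(item))
            ids.append(str(i))
    n = len(pts_list)
    if n < 2:
        raise ValueError("need at least 2 shapes")
    ks = {p.shape[0] for p in pts_list}
    if len(ks) != 1:
        raise ValueError(f"mixed point counts: {sorted(ks)}")
    k = ks.pop()

    sizes = np.array([centroid_size(p) for p in pts_list])
    normed = np.stack(
        [(p - p.mean(axis=0)) / s for p, s in zip(pts_list, sizes)]
    )  # (n, k, 2)

    mean = normed.mean(axis=0)
    mean /= centroid_size(mean)
    converged = False
    iterations = 0
    for iterations in range(1, max_iter + 1):
        for i in range(n):
            normed[i] = normed[i] @ optimal_rotation(normed[i], mean).T
        new_mean = normed.mean(axis=0)
        new_mean /= centroid_size(new_mean)
        change = np.sqrt(((new_mean - mean) ** 2).mean())
        mean = new_mean
        if change < tol:
            converged = True
            break
    if not converged:
        warnings.warn(
            f"GPA did not converge in {max_iter} iterations", RuntimeWarning, stacklevel=2
        )

    # fix the global rotation against shape #1 for reproducibility
    first = (pts_list[0] - pts_list[0].mean(axis=0)) / sizes[0]
    r = optimal_rotation(mean, first)
    mean = mean @ r.T
    for i in range(n):
        normed[i] = normed[i] @ r.T

    flat = normed.reshape(n, 2 * k)
    mean_flat = mean.ravel()
    if tangent:
        flat = tangent_project(flat, mean_flat)
    return AlignedCohort(
        shapes=flat,
        mean_shape=mean_flat,
        centroid_sizes=sizes,
        subject_ids=ids,
        iterations_run=iterations,
        converged=converged,
        tangent=tangent,
    )
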