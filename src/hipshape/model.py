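"""PCA point-distribution model: modes of variation and SD-unit mode scores.

After Procrustes alignment, the cohort of flat coordinate vectors is
eigen-decomposed about its mean.  Each retained eigenvector is a "mode of
variation"; a subject's position on mode j is the projection coefficient
b_j = phi_j . (x - xbar), reported in SD units s_j = b_j / sqrt(lambda_j) so
that over the training cohort every mode has mean 0, SD 1.  The default
retains 10 modes; a variance-target rule (e.g. 0.95) is available instead.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from hipshape.procrustes import AlignedCohort


@dataclass
class ShapeModel:
    mean_shape: np.ndarray  # (2k,)
    modes: np.ndarray  # (2k, m) orthonormal columns
    eigenvalues: np.ndarray  # (m,) non-increasing
    variance_fractions: np.ndarray  # (m,) lambda_j / total variance
    total_variance: float
    m_retained: int

    @property
    def k(self) -> int:
        return self.mean_shape.size // 2

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                dict(
                    k=self.k,
                    m_retained=self.m_retained,
                    eigenvalues=self.eigenvalues.tolist(),
                    variance_fractions=self.variance_fractions.tolist(),
                    total_variance=self.total_variance,
                    mean_shape=self.mean_shape.tolist(),
                    modes=self.modes.tolist(),
                )
            )
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "ShapeModel":
        d = json.loads(Path(path).read_text())
        return cls(
            mean_shape=np.asarray(d["mean_shape"], dtype=float),
            modes=np.asarray(d["modes"], dtype=float),
            eigenvalues=np.asarray(d["eigenvalues"], dtype=float),
            variance_fractions=np.asarray(d["variance_fractions"], dtype=float),
            total_variance=float(d["total_variance"]),
            m_retained=int(d["m_retained"]),
        )


@dataclass
class ModeScores:
    """Per-subject mode coefficients: raw b and SD-unit s."""

    subject_ids: list[str]
    raw: np.ndarray  # (n, m)
    sd_units: np.ndarray  # (n, m)

    def frame(self, prefix: str = "mode") -> pd.DataFrame:
        m = self.sd_units.shape[1]
        df = pd.DataFrame(
            self.sd_units, columns=[f"{prefix}{j + 1}" for j in range(m)]
        )
        df.insert(0, "subject_id", self.subject_ids)
        return df


def _fix_signs(vecs: np.ndarray) -> np.ndarray:
    # eigenvectors are sign-ambiguous; make the largest-|entry| positive
    idx = np.argmax(np.abs(vecs), axis=0)
    signs = np.sign(vecs[idx, np.arange(vecs.shape[1])])
    signs[signs == 0] = 1.0
    return vecs * signs


def fit_shape_model(
    aligned: AlignedCohort | np.ndarray,
    m: int | None = 10,
    variance_target: float | None = None,
) -> ShapeModel:
    """Eigen-decompose the aligned-cohort covariance into modes of variation.

    Exactly one retention rule applies: a fixed mode count ``m`` (default 10)
    or the smallest count reaching ``variance_target``.  Covariance uses the
    unbiased n-1 divisor; modes are sorted by descending eigenvalue with a
    deterministic sign convention.
    """
    x = aligned.shapes if isinstance(aligned, AlignedCohort) else np.asarray(aligned, dtype=float)
    n, p = x.shape
    mean = x.mean(axis=0)
    centered = x - mean
    cov = centered.T @ centered / (n - 1)
    total_var = float(np.trace(cov))
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals, kind="stable")[::-1]
    evals = np.clip(evals[order], 0.0, None)
    evecs = _fix_signs(evecs[:, order])

    rank = int(np.sum(evals > max(total_var, 1e-300) * 1e-12))
    if variance_target is not None:
        frac = np.cumsum(evals) / total_var
        m = int(np.searchsorted(frac, variance_target) + 1)
        m = min(m, rank)
    if m is None:
        m = 10
    if m > rank:
        raise ValueError(f"requested {m} modes but cohort covariance has rank {rank}")
    return ShapeModel(
        mean_shape=mean,
        modes=evecs[:, :m],
        eigenvalues=evals[:m],
        variance_fractions=evals[:m] / total_var,
        total_variance=total_var,
        m_retained=m,
    )


def score_subjects(model: ShapeModel, aligned: AlignedCohort | np.ndarray) -> ModeScores:
    """Project shapes onto the modes; report raw and SD-unit coefficients.

    SD units divide each coefficient by sqrt(lambda_j): over the training
    cohort every mode column then has mean 0 and SD 1.
    """
    if isinstance(aligned, AlignedCohort):
        x = aligned.shapes
        ids = aligned.subject_ids
    else:
        x = np.atleast_2d(np.asarray(aligned, dtype=float))
        ids = [str(i) for i in range(x.shape[0])]
    if x.shape[1] != model.mean_shape.size:
        raise ValueError(
            f"model expects 2k={model.mean_shape.size} coordinates, got {x.shape[1]}"
        )
    b = (x - model.mean_shape) @ model.modes
    zero = model.eigenvalues <= 0
    if np.any(zero):
        if np.any(np.abs(b[:, zero]) > 1e-8):
            raise ValueError("nonzero coefficient on a zero-variance mode (out of span)")
        s = np.zeros_like(b)
        nz = ~zero
        s[:, nz] = b[:, nz] / np.sqrt(model.eigenvalues[nz])
    else:
        s = b / np.sqrt(model.eigenvalues)
    return ModeScores(subject_ids=list(ids), raw=b, sd_units=s)


def reconstruct(model: ShapeModel, sd_scores: Sequence[float]) -> np.ndarray:
    """Shape vector xbar + sum_j s_j sqrt(lambda_j) phi_j for SD-unit scores."""
    s = np.asarray(sd_scores, dtype=float)
    if s.size > model.m_retained:
        raise ValueError(f"got {s.size} scores for a {model.m_retained}-mode model")
    b = s * np.sqrt(model.eigenvalues[: s.size])
    return model.mean_shape + model.modes[:, : s.size] @ b


def mode_gallery(
    model: ShapeModel, j: int, sd_grid: Sequence[float] = (-2.0, 0.0, 2.0)
) -> list[np.ndarray]:
    """Reconstructions varying mode ``j`` (1-based) alone over an SD grid,
    e.g. the conventional -2/mean/+2 SD panels."""
    if not 1 <= j <= model.m_retained:
        raise ValueError(f"mode {j} out of range 1..{model.m_retained}")
    shapes = []
    for sd in sd_grid:
        s = np.zeros(model.m_retained)
        s[j - 1] = sd
        shapes.append(reconstruct(model, s))
    return shapes
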