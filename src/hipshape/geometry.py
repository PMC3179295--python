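"""Classical geometric measures from a proximal-femur landmark outline.

The comparator predictors: femoral head diameter, femoral neck length and
femoral neck width.  Because only the 60-point outline is available, the
measures are defined operationally on the landmarks:

* **head diameter** — twice the radius of a least-squares circle fitted to
  the articular-surface landmarks;
* **neck axis** — the line through the head-circle centre and the midpoint
  of the intertrochanteric line (the segment joining the greater- and
  lesser-trochanter landmarks);
* **neck width** — the minimal separation of the superior and inferior neck
  outline segments measured along cross-lines perpendicular to the neck
  axis;
* **neck length** — distance along the neck axis from the head-circle
  centre to its intersection with the intertrochanteric line.

All measures operate on raw landmarks in mm (never Procrustes-normalized
shapes); they are invariant to rigid motion and scale linearly with the
outline.  Which landmark indices form the head / neck / trochanter regions
is configuration; defaults follow the synthetic template's point semantics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np


class GeometryError(ValueError):
    pass


@dataclass(frozen=True)
class GeometryConfig:
    """Landmark-index semantics of an outline (half-open ranges)."""

    head_range: tuple[int, int] = (10, 36)
    inferior_neck_range: tuple[int, int] = (4, 10)
    superior_neck_range: tuple[int, int] = (36, 42)
    lesser_trochanter_index: int = 0
    greater_trochanter_index: int = 45


@dataclass
class GeometryMeasures:
    neck_length: float
    neck_width: float
    head_diameter: float
    head_fit_rms: float


def _points(landmarks) -> np.ndarray:
    pts = np.asarray(getattr(landmarks, "points", landmarks), dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise GeometryError(f"expected (k, 2) landmarks, got {pts.shape}")
    return pts


def fit_circle(points: np.ndarray) -> tuple[np.ndarray, float, float]:
    """Algebraic (Kasa) least-squares circle fit.

    Returns (centre, radius, rms) where rms is the root-mean-square radial
    residual.  Collinear points make the normal system singular -> error.
    """
    pts = _points(points)
    if pts.shape[0] < 3:
        raise GeometryError("need at least 3 points for a circle fit")
    x, y = pts[:, 0], pts[:, 1]
    a = np.column_stack([x, y, np.ones_like(x)])
    b = x**2 + y**2
    try:
        sol, *_ = np.linalg.lstsq(a, b, rcond=None)
    except np.linalg.LinAlgError as exc:  # pragma: no cover
        raise GeometryError(f"circle fit failed: {exc}") from None
    # collinearity check: the design has rank < 3 when points lie on a line
    if np.linalg.matrix_rank(a - a.mean(axis=0), tol=1e-9 * max(np.abs(pts).max(), 1.0)) < 2:
        raise GeometryError("points are collinear; circle undefined")
    cx, cy = sol[0] / 2.0, sol[1] / 2.0
    r2 = sol[2] + cx**2 + cy**2
    if r2 <= 0 or not np.isfinite(r2):
        raise GeometryError("degenerate circle fit")
    r = float(np.sqrt(r2))
    resid = np.hypot(x - cx, y - cy) - r
    return np.array([cx, cy]), r, float(np.sqrt(np.mean(resid**2)))


def head_diameter(landmarks, head_range: tuple[int, int] | None = None,
                  config: GeometryConfig | None = None) -> tuple[float, float]:
    """Femoral head diameter (mm) and circle-fit RMS residual (mm)."""
    cfg = config or GeometryConfig()
    lo, hi = head_range if head_range is not None else cfg.head_range
    pts = _points(landmarks)[lo:hi]
    if pts.shape[0] < 5:
        raise GeometryError("head range must select at least 5 points")
    _, r, rms = fit_circle(pts)
    return 2.0 * r, rms


def minimal_cross_width(
    superior: np.ndarray,
    inferior: np.ndarray,
    axis_point: np.ndarray,
    axis_dir: np.ndarray,
    n_cuts: int = 512,
) -> float:
    """Minimal separation of two landmark chains along cuts perpendicular to
    an axis.

    Each chain is parameterized by its along-axis coordinate s and
    perpendicular offset d; the width at a cut s is d_sup(s) - d_inf(s) by
    linear interpolation, minimized over a dense grid spanning the s-range
    both chains cover.
    """
    sup = _points(superior)
    inf = _points(inferior)
    if sup.shape[0] < 3 or inf.shape[0] < 3:
        raise GeometryError("each neck segment needs at least 3 points")
    u = np.asarray(axis_dir, dtype=float)
    norm = np.linalg.norm(u)
    if norm <= 0:
        raise GeometryError("zero axis direction")
    u = u / norm
    perp = np.array([-u[1], u[0]])
    p0 = np.asarray(axis_point, dtype=float)

    def chain_coords(chain):
        rel = chain - p0
        s = rel @ u
        d = rel @ perp
        order = np.argsort(s)
        return s[order], d[order]

    s_sup, d_sup = chain_coords(sup)
    s_inf, d_inf = chain_coords(inf)
    lo = max(s_sup.min(), s_inf.min())
    hi = min(s_sup.max(), s_inf.max())
    if hi <= lo:
        raise GeometryError("neck segments do not overlap along the axis")
    grid = np.linspace(lo, hi, n_cuts)
    width = np.abs(np.interp(grid, s_sup, d_sup) - np.interp(grid, s_inf, d_inf))
    return float(width.min())


def neck_axis_and_width(
    landmarks,
    superior_range: tuple[int, int] | None = None,
    inferior_range: tuple[int, int] | None = None,
    config: GeometryConfig | None = None,
) -> tuple[tuple[np.ndarray, np.ndarray], float]:
    """Neck axis (point, unit direction) and minimal neck width (mm)."""
    cfg = config or GeometryConfig()
    sup_r = superior_range if superior_range is not None else cfg.superior_neck_range
    inf_r = inferior_range if inferior_range is not None else cfg.inferior_neck_range
    if max(sup_r[0], inf_r[0]) < min(sup_r[1], inf_r[1]):
        raise GeometryError("superior and inferior neck ranges overlap")
    pts = _points(landmarks)
    sup = pts[sup_r[0] : sup_r[1]]
    inf = pts[inf_r[0] : inf_r[1]]
    if sup.shape[0] < 3 or inf.shape[0] < 3:
        raise GeometryError("neck ranges too short (< 3 points)")
    centre, _, _ = fit_circle(pts[cfg.head_range[0] : cfg.head_range[1]])
    itl_mid = 0.5 * (
        pts[cfg.lesser_trochanter_index] + pts[cfg.greater_trochanter_index]
    )
    direction = centre - itl_mid
    norm = np.linalg.norm(direction)
    if norm <= 0:
        raise GeometryError("head centre coincides with intertrochanteric midpoint")
    direction = direction / norm
    width = minimal_cross_width(sup, inf, itl_mid, direction)
    return (itl_mid, direction), width


def neck_length(landmarks, config: GeometryConfig | None = None) -> float:
    """Distance (mm) from the head-circle centre along the neck axis to its
    intersection with the intertrochanteric line."""
    cfg = config or GeometryConfig()
    pts = _points(landmarks)
    centre, _, _ = fit_circle(pts[cfg.head_range[0] : cfg.head_range[1]])
    lt = pts[cfg.lesser_trochanter_index]
    gt = pts[cfg.greater_trochanter_index]
    itl_mid = 0.5 * (lt + gt)
    axis = centre - itl_mid
    itl = gt - lt
    cross = axis[0] * itl[1] - axis[1] * itl[0]
    if abs(cross) <= 1e-12 * max(np.linalg.norm(axis) * np.linalg.norm(itl), 1e-300):
        raise GeometryError("neck axis parallel to the intertrochanteric line")
    # the axis passes through the ITL midpoint, so that midpoint IS the
    # intersection point
    return float(np.linalg.norm(centre - itl_mid))


def is_right_outline(landmarks, config: GeometryConfig | None = None) -> bool:
    """Orientation check: a right-hip outline in the mathematical convention
    has the femoral head superior-medial (up and to the left) of the shaft."""
    cfg = config or GeometryConfig()
    pts = _points(landmarks)
    head = pts[cfg.head_range[0] : cfg.head_range[1]].mean(axis=0)
    shaft = 0.5 * (pts[0] + pts[-1])
    return bool(head[0] < shaft[0] and head[1] > shaft[1])


def geometry_measures(landmarks, config: GeometryConfig | None = None) -> GeometryMeasures:
    """All geometric measures for one outline (raw mm landmarks)."""
    cfg = config or GeometryConfig()
    diam, rms = head_diameter(landmarks, config=cfg)
    _, width = neck_axis_and_width(landmarks, config=cfg)
    length = neck_length(landmarks, config=cfg)
    if width >= diam:
        warnings.warn(
            f"neck width {width:.1f} mm >= head diameter {diam:.1f} mm: "
            "anatomically implausible outline",
            RuntimeWarning,
            stacklevel=2,
        )
    if min(width, diam, length) <= 0:
        raise GeometryError("non-positive geometric measure")
    return GeometryMeasures(
        neck_length=length, neck_width=width, head_diameter=diam, head_fit_rms=rms
    )
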