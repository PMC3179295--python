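"""Synthetic femur-outline cohort generator with planted, recoverable truth.

Emulates the study inputs end to end, with no real radiographs required:

* a parametric 60-point right-proximal-femur **template** (shaft, lesser
  trochanter, inferior neck, head arc, superior neck, greater trochanter,
  shaft) whose landmark-index semantics drive the geometry defaults;
* an orthonormal 10-mode **basis** of smooth deformation fields in which the
  designated mode-4 analog is built by differencing a template with a
  longer, narrower neck and smaller head against the mean template —
  reproducing the reported "long neck / small head / narrow neck" shape
  axis;
* per-subject shapes = template + sum_j s_j sqrt(lambda_j) phi_j + isotropic
  landmark noise, pushed through random in-plane similarity transforms;
* **fracture outcomes** from a logistic model on the true SD-unit scores
  with planted per-mode log-odds (per-SD odds ratios 2.48 and 1.32 on the
  mode-4/5 analogs, protective 0.56 / 0.78 / 0.66 on modes 6/8/10), the
  intercept calibrated by bisection to the target case fraction 168/399;
* **covariates** drawn conditionally on realized case status with the
  baseline-table group means and pooled within-group SDs, so the implied
  conditional outcome model stays exactly logistic and adjusted fits
  recover the planted mode effects without bias.

All randomness flows from one master seed through named child streams.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit

from hipshape.geometry import GeometryConfig, geometry_measures, is_right_outline
from hipshape.io import LandmarkSet, write_landmarks, write_covariates

K_POINTS = 60
# points per outline segment: inferior neck incl. lesser trochanter, head
# arc incl. both neck junctions, superior neck incl. greater trochanter,
# lateral shaft incl. the end point opposite the lesser trochanter
_SEG_POINTS = (10, 26, 10, 14)


@dataclass(frozen=True)
class TemplateParams:
    """Anatomical parameters (mm / degrees) of the mean outline."""

    head_radius: float = 24.0
    neck_length: float = 50.0
    neck_width: float = 31.0
    shaft_width: float = 30.0
    neck_shaft_angle_deg: float = 130.0
    trochanter_offset: float = 24.0
    itl_angle_deg: float = 40.0
    neck_flare_s: float = 10.0

    def validate(self) -> None:
        if self.head_radius <= self.neck_width / 2:
            raise ValueError("head radius must exceed half the neck width")
        if not (0 < self.neck_flare_s < self.neck_length):
            raise ValueError("neck_flare_s must lie between 0 and neck_length")
        junction = self.neck_length - np.sqrt(
            self.head_radius**2 - (self.neck_width / 2) ** 2
        )
        if junction <= self.neck_flare_s:
            raise ValueError("neck too short: head overlaps the trochanteric flare")
        if min(self.neck_width, self.shaft_width, self.trochanter_offset) <= 0:
            raise ValueError("lengths must be positive")


# Table-1-style covariate parameters: (case mean, control mean, pooled SD).
# Within-group SDs are deliberately equal across groups (see docs/methods.md);
# the intertrochanteric SD uses 0.12 because the printed 0.01 is an SEM-scale
# value, not a plausible SD.
COVARIATE_PARAMS: dict[str, tuple[float, float, float]] = {
    "age": (71.7, 70.6, 4.5),
    "weight": (65.1, 67.3, 10.65),
    "height": (159.9, 159.2, 5.9),
    "bmi": (25.5, 26.6, 4.2),
    "bmd_th": (0.70, 0.76, 0.115),
    "bmd_fn": (0.60, 0.65, 0.09),
    "bmd_it": (0.82, 0.88, 0.12),
}

# young-adult femoral-neck BMD reference used ONLY by the generator to
# convert its BMD draws to T-scores
TSCORE_REF_MEAN = 0.85
TSCORE_REF_SD = 0.12

DEFAULT_GAMMA = np.array(
    [0.0, 0.0, 0.0, np.log(2.48), np.log(1.32), np.log(0.56), 0.0, np.log(0.78), 0.0, np.log(0.66)]
)

SITE_PROBS = {"femoral_neck": 86 / 168, "intertrochanteric": 75 / 168, "other": 7 / 168}


@dataclass(frozen=True)
class GeneratorConfig:
    n_subjects: int = 399
    seed: int = 0
    template: TemplateParams = field(default_factory=TemplateParams)
    n_modes: int = 10
    lambda1: float = 36.0  # mm^2, leading planted eigenvalue
    lambda_decay: float = 0.6
    noise_sd: float = 0.15  # mm, isotropic per-coordinate landmark noise
    rotation_range_deg: float = 15.0
    scale_range: tuple[float, float] = (0.9, 1.1)
    translation_range_mm: float = 20.0
    gamma: tuple[float, ...] = tuple(DEFAULT_GAMMA)
    target_prevalence: float = 168 / 399

    @property
    def eigenvalues(self) -> np.ndarray:
        return self.lambda1 * self.lambda_decay ** np.arange(self.n_modes)

    def config_hash(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def preset(name: str, seed: int = 0, **overrides) -> GeneratorConfig:
    """Named generator presets: 'tiny' (n=40, unit tests) and 'paper' (n=399)."""
    sizes = {"tiny": 40, "paper": 399}
    if name not in sizes:
        raise ValueError(f"unknown preset {name!r}; choose from {sorted(sizes)}")
    return GeneratorConfig(n_subjects=sizes[name], seed=seed, **overrides)


@dataclass
class SyntheticTruth:
    """Ground-truth ledger sufficient for recovery checks without rerunning
    the generator."""

    true_scores: np.ndarray  # (n, 10) SD units
    basis: np.ndarray  # (2k, 10) orthonormal, mm space
    eigenvalues: np.ndarray  # (10,) planted, mm^2
    gamma: np.ndarray  # (10,) planted per-SD log-odds
    template_points: np.ndarray  # (k, 2) mm
    template_geometry: dict  # measured neck length/width, head diameter
    alpha: float  # calibrated logistic intercept
    realized_prevalence: float
    subject_ids: list[str]
    config_hash: str
    seed: int

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                dict(
                    true_scores=self.true_scores.tolist(),
                    basis=self.basis.tolist(),
                    eigenvalues=self.eigenvalues.tolist(),
                    gamma=self.gamma.tolist(),
                    template_points=self.template_points.tolist(),
                    template_geometry=self.template_geometry,
                    alpha=self.alpha,
                    realized_prevalence=self.realized_prevalence,
                    subject_ids=self.subject_ids,
                    config_hash=self.config_hash,
                    seed=self.seed,
                )
            )
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "SyntheticTruth":
        d = json.loads(Path(path).read_text())
        return cls(
            true_scores=np.asarray(d["true_scores"], dtype=float),
            basis=np.asarray(d["basis"], dtype=float),
            eigenvalues=np.asarray(d["eigenvalues"], dtype=float),
            gamma=np.asarray(d["gamma"], dtype=float),
            template_points=np.asarray(d["template_points"], dtype=float),
            template_geometry=d["template_geometry"],
            alpha=float(d["alpha"]),
            realized_prevalence=float(d["realized_prevalence"]),
            subject_ids=list(d["subject_ids"]),
            config_hash=d["config_hash"],
            seed=int(d["seed"]),
        )


@dataclass
class SyntheticCohort:
    landmarks: list[LandmarkSet]
    covariates: pd.DataFrame
    truth: SyntheticTruth
    geometry_config: GeometryConfig


# ---------------------------------------------------------------------------
# template construction


def _sample_polyline(vertices: np.ndarray, fractions: np.ndarray) -> np.ndarray:
    """Sample points at arc-length fractions along a polyline."""
    seg = np.diff(vertices, axis=0)
    seglen = np.hypot(seg[:, 0], seg[:, 1])
    cum = np.concatenate([[0.0], np.cumsum(seglen)])
    targets = fractions * cum[-1]
    out = np.empty((fractions.size, 2))
    for i, t in enumerate(targets):
        j = min(np.searchsorted(cum, t, side="right") - 1, len(seglen) - 1)
        f = (t - cum[j]) / seglen[j] if seglen[j] > 0 else 0.0
        out[i] = vertices[j] + f * seg[j]
    return out


def make_template(params: TemplateParams | None = None) -> tuple[LandmarkSet, GeometryConfig]:
    """Build the 60-point mean outline and its landmark-index semantics.

    The outline traces: lesser trochanter -> inferior neck -> head arc ->
    superior neck -> greater trochanter -> lateral shaft, ending opposite
    the lesser trochanter.  The trochanter landmarks sit symmetrically about
    the origin on the intertrochanteric line, so the neck axis (head centre
    to ITL midpoint) recovers the neck-length parameter exactly, and the
    mid-neck borders run parallel to the axis so the minimal cross-width
    recovers the neck-width parameter exactly.
    """
    p = params or TemplateParams()
    p.validate()
    a = np.radians(p.neck_shaft_angle_deg)
    u = np.array([-np.sin(a), -np.cos(a)])  # neck axis, toward the head
    perp = np.array([u[1], -u[0]])  # superior-lateral normal
    b = np.radians(p.itl_angle_deg)
    v = np.array([np.cos(b), np.sin(b)])  # intertrochanteric line, toward GT

    gt = p.trochanter_offset * v
    lt = -p.trochanter_offset * v
    centre = p.neck_length * u
    half_w = p.neck_width / 2
    s_junction = p.neck_length - np.sqrt(p.head_radius**2 - half_w**2)

    a_inf = p.neck_flare_s * u - half_w * perp
    j_inf = s_junction * u - half_w * perp
    a_sup = p.neck_flare_s * u + half_w * perp
    j_sup = s_junction * u + half_w * perp

    n1, n2, n3, n4 = _SEG_POINTS
    seg1 = _sample_polyline(
        np.array([lt, a_inf, j_inf]), np.linspace(0.0, 1.0, n1 + 1)[:-1]
    )
    phi1 = np.arctan2(-half_w, s_junction - p.neck_length)
    phis = np.linspace(phi1, -phi1, n2)
    arc = centre + p.head_radius * (np.cos(phis)[:, None] * u + np.sin(phis)[:, None] * perp)
    seg3 = _sample_polyline(
        np.array([j_sup, a_sup, gt]), np.linspace(0.0, 1.0, n3 + 1)[1:]
    )
    shaft_corner = np.array([p.shaft_width / 2, 0.0])
    end = np.array([p.shaft_width / 2, lt[1]])
    seg4 = _sample_polyline(
        np.array([gt, shaft_corner, end]), np.linspace(0.0, 1.0, n4 + 1)[1:]
    )
    pts = np.vstack([seg1, arc, seg3, seg4])
    assert pts.shape == (K_POINTS, 2)

    cfg = GeometryConfig(
        head_range=(n1, n1 + n2),
        inferior_neck_range=(4, n1),
        superior_neck_range=(n1 + n2, n1 + n2 + 6),
        lesser_trochanter_index=0,
        greater_trochanter_index=n1 + n2 + n3 - 1,
    )
    lm = LandmarkSet("template", pts, pixel_spacing_mm=None)
    if not is_right_outline(lm, cfg):
        raise ValueError("template failed the right-hip orientation check")
    return lm, cfg


# ---------------------------------------------------------------------------
# mode basis


def _similarity_directions(template_flat: np.ndarray) -> np.ndarray:
    """Orthonormal basis of the similarity-transform directions at the
    template (x/y translation, rotation, scale) to be excluded from planted
    shape modes."""
    pts = template_flat.reshape(-1, 2)
    centered = pts - pts.mean(axis=0)
    k = pts.shape[0]
    tx = np.tile([1.0, 0.0], k)
    ty = np.tile([0.0, 1.0], k)
    rot = np.column_stack([-centered[:, 1], centered[:, 0]]).ravel()
    scale = centered.ravel()
    q, _ = np.linalg.qr(np.column_stack([tx, ty, rot, scale]))
    return q


def _project_out(vec: np.ndarray, basis_cols: np.ndarray) -> np.ndarray:
    return vec - basis_cols @ (basis_cols.T @ vec)


def _smooth_field(rng: np.random.Generator, k: int, n_harmonics: int = 4) -> np.ndarray:
    """Random smooth deformation field over the outline index, as a flat 2k
    vector: low-frequency Fourier series with 1/h amplitude decay."""
    t = 2 * np.pi * np.arange(k) / k
    field_xy = np.zeros((k, 2))
    for axis in range(2):
        for h in range(1, n_harmonics + 1):
            ah, bh = rng.standard_normal(2)
            field_xy[:, axis] += (ah * np.cos(h * t) + bh * np.sin(h * t)) / h
    return field_xy.ravel()


def make_mode_basis(
    template: LandmarkSet,
    config: GeneratorConfig | None = None,
    seed: int | np.random.SeedSequence | None = None,
) -> np.ndarray:
    """Orthonormal (2k, 10) mode basis with a designated mode-4 analog.

    The mode-4 column is the normalized difference between a template with a
    10% longer neck, 12% smaller head and 8% narrower neck and shaft and the
    mean template; the remaining columns are random smooth fields.  All
    columns have the rigid-motion and scale directions projected out (the
    planted variation must live in shape space, where Procrustes alignment
    cannot remove it) and are Gram-Schmidt orthonormalized, deterministically
    per seed.
    """
    cfg = config or GeneratorConfig()
    if seed is None:
        seed = cfg.seed
    rng = np.random.default_rng(seed)
    flat = template.points.ravel()
    k = template.k
    sim = _similarity_directions(flat)

    p = cfg.template
    perturbed = dataclasses.replace(
        p,
        neck_length=p.neck_length * 1.10,
        head_radius=p.head_radius * 0.88,
        neck_width=p.neck_width * 0.92,
        shaft_width=p.shaft_width * 0.92,
    )
    mode4 = make_template(perturbed)[0].points.ravel() - flat
    mode4 = _project_out(mode4, sim)
    norm = np.linalg.norm(mode4)
    if norm <= 1e-12:
        raise ValueError("degenerate mode-4 construction")
    mode4 /= norm

    columns: list[np.ndarray] = [mode4]
    for _ in range(cfg.n_modes - 1):
        for _attempt in range(50):
            f = _project_out(_smooth_field(rng, k), sim)
            f = _project_out(f, np.column_stack(columns))
            norm = np.linalg.norm(f)
            if norm > 1e-8:
                columns.append(f / norm)
                break
        else:
            raise ValueError("rank deficiency while orthonormalizing mode basis")
    # mode order 1..10 with the differenced analog in position 4
    ordered = columns[1:4] + [columns[0]] + columns[4:]
    basis = np.column_stack(ordered)
    assert np.allclose(basis.T @ basis, np.eye(cfg.n_modes), atol=1e-10)
    return basis


# ---------------------------------------------------------------------------
# cohort sampling


def _calibrate_intercept(linpred: np.ndarray, target: float) -> float:
    """Bisection for the logistic intercept hitting the target mean risk."""

    def f(alpha: float) -> float:
        return float(np.mean(expit(alpha + linpred))) - target

    lo, hi = -30.0, 30.0
    if f(lo) > 0 or f(hi) < 0:
        raise ValueError("target prevalence unattainable under planted effects")
    return float(brentq(f, lo, hi, xtol=1e-12))


def sample_cohort(config: GeneratorConfig | None = None) -> SyntheticCohort:
    """Draw a complete synthetic cohort: outlines, covariates, truth ledger."""
    cfg = config or GeneratorConfig()
    streams = np.random.SeedSequence(cfg.seed).spawn(5)
    rng_basis, rng_scores, rng_noise, rng_xform, rng_cov = (
        np.random.default_rng(s) for s in streams
    )

    template, geom_cfg = make_template(cfg.template)
    basis = make_mode_basis(template, cfg, seed=rng_basis.integers(2**31))
    lam = cfg.eigenvalues
    n = cfg.n_subjects
    k = template.k

    s_true = rng_scores.standard_normal((n, cfg.n_modes))
    flat = template.points.ravel()
    shapes = flat + (s_true * np.sqrt(lam)) @ basis.T
    shapes += cfg.noise_sd * rng_noise.standard_normal(shapes.shape)
    shapes = shapes.reshape(n, k, 2)

    # random in-plane similarity transforms (digitization nuisance)
    thetas = np.radians(
        rng_xform.uniform(-cfg.rotation_range_deg, cfg.rotation_range_deg, n)
    )
    scales = rng_xform.uniform(cfg.scale_range[0], cfg.scale_range[1], n)
    trans = rng_xform.uniform(-cfg.translation_range_mm, cfg.translation_range_mm, (n, 2))
    landmarks = []
    ids = [f"S{i + 1:04d}" for i in range(n)]
    for i in range(n):
        c, s = np.cos(thetas[i]), np.sin(thetas[i])
        rot = np.array([[c, -s], [s, c]])
        pts = scales[i] * shapes[i] @ rot.T + trans[i]
        landmarks.append(LandmarkSet(ids[i], pts, pixel_spacing_mm=None))

    gamma = np.asarray(cfg.gamma, dtype=float)
    linpred = s_true @ gamma
    alpha = _calibrate_intercept(linpred, cfg.target_prevalence)
    y = rng_cov.random(n) < expit(alpha + linpred)

    cov = {"subject_id": ids, "fracture": y}
    for name, (mu_case, mu_ctrl, sd) in COVARIATE_PARAMS.items():
        mu = np.where(y, mu_case, mu_ctrl)
        vals = mu + sd * rng_cov.standard_normal(n)
        if name.startswith("bmd"):
            vals = np.clip(vals, 0.05, None)
        cov[name] = vals
    cov["fn_tscore"] = (cov["bmd_fn"] - TSCORE_REF_MEAN) / TSCORE_REF_SD
    sites = np.where(y, "other", "none").astype(object)
    case_idx = np.flatnonzero(y)
    if case_idx.size:
        sites[case_idx] = rng_cov.choice(
            list(SITE_PROBS), size=case_idx.size, p=list(SITE_PROBS.values())
        )
    cov["fracture_site"] = sites
    covariates = pd.DataFrame(cov)[
        ["subject_id", "age", "bmi", "weight", "height", "bmd_fn", "bmd_it",
         "bmd_th", "fn_tscore", "fracture", "fracture_site"]
    ]

    truth = SyntheticTruth(
        true_scores=s_true,
        basis=basis,
        eigenvalues=lam,
        gamma=gamma,
        template_points=template.points,
        template_geometry=dataclasses.asdict(geometry_measures(template, geom_cfg)),
        alpha=alpha,
        realized_prevalence=float(y.mean()),
        subject_ids=ids,
        config_hash=cfg.config_hash(),
        seed=cfg.seed,
    )
    return SyntheticCohort(
        landmarks=landmarks, covariates=covariates, truth=truth, geometry_config=geom_cfg
    )


def match_modes(
    estimated_scores: np.ndarray, true_scores: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Match estimated PCA modes to planted modes by score correlation.

    PCA recovers the planted subspace only up to mode permutation and sign;
    this resolves both from the data.  Returns (perm, signs) such that
    ``signs[j] * estimated_scores[:, perm[j]]`` is the estimate of planted
    mode j (greedy best-|correlation| assignment without replacement).
    """
    est = np.asarray(estimated_scores, dtype=float)
    tru = np.asarray(true_scores, dtype=float)
    m = tru.shape[1]
    corr = np.array(
        [[np.corrcoef(est[:, i], tru[:, j])[0, 1] for j in range(m)] for i in range(est.shape[1])]
    )
    perm = np.full(m, -1)
    signs = np.ones(m)
    taken: set[int] = set()
    # assign strongest pairs first
    order = np.dstack(np.unravel_index(np.argsort(-np.abs(corr), axis=None), corr.shape))[0]
    for i, j in order:
        if perm[j] == -1 and i not in taken:
            perm[j] = i
            signs[j] = np.sign(corr[i, j]) or 1.0
            taken.add(i)
    return perm, signs


def write_cohort(out_dir: str | Path, cohort: SyntheticCohort, tps: bool = False) -> dict[str, Path]:
    """Write landmarks (CSV and optionally TPS), covariates and truth files."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "landmarks": out / "landmarks.csv",
        "covariates": out / "covariates.csv",
        "truth": out / "truth.json",
    }
    write_landmarks(paths["landmarks"], cohort.landmarks)
    write_covariates(paths["covariates"], cohort.covariates)
    cohort.truth.to_json(paths["truth"])
    if tps:
        paths["landmarks_tps"] = out / "landmarks.tps"
        write_landmarks(paths["landmarks_tps"], cohort.landmarks, format="tps")
    return paths
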