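"""Landmark-outline and covariate I/O, cohort bookkeeping and summary tables.

Outlines are ordered 2D landmark sets (default 60 points) tracing the right
proximal femur from the lesser trochanter, up the inferior neck, around the
femoral head, back along the superior neck and over the greater trochanter
to the opposite point on the femoral shaft.  Two on-disk dialects are
supported:

* **CSV** — one row per subject: ``subject_id, x1, y1, ..., xk, yk`` with a
  header; an optional ``acceptable`` column (0/1) carries the
  trochanters-visualized quality flag.
* **TPS** — the de-facto landmark interchange format: ``LM=k`` followed by k
  ``x y`` lines and an ``ID=subject`` line; an optional ``SCALE=`` line is
  read as the pixel spacing.

Coordinates use a mathematical convention (x rightward, y upward).  Files
digitized with an image-origin (row-down) convention can be flipped on
import with ``flip_y=True``.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from hipshape._util import round_half_up

FRACTURE_SITES = ("femoral_neck", "intertrochanteric", "other", "none")


class LandmarkFormatError(ValueError):
    """Raised for structurally invalid landmark files."""


@dataclass
class LandmarkSet:
    """One subject's ordered outline.

    points are in mm once ``pixel_spacing_mm`` has been applied at read time;
    the spacing is retained as provenance (``None`` means the source was
    already metric).
    """

    subject_id: str
    points: np.ndarray  # (k, 2) float array, mm
    pixel_spacing_mm: float | None = None
    side: str = "right"
    acceptable: bool = True

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 2:
            raise LandmarkFormatError(
                f"{self.subject_id}: points must be a (k, 2) array, got {pts.shape}"
            )
        if pts.shape[0] < 3:
            raise LandmarkFormatError(f"{self.subject_id}: need k >= 3 points")
        if not np.all(np.isfinite(pts)):
            raise LandmarkFormatError(f"{self.subject_id}: non-finite coordinates")
        if self.pixel_spacing_mm is not None and self.pixel_spacing_mm <= 0:
            raise LandmarkFormatError(f"{self.subject_id}: pixel_spacing_mm must be > 0")
        if self.side != "right":
            raise LandmarkFormatError(f"{self.subject_id}: only right-side outlines are supported")
        self.points = pts

    @property
    def k(self) -> int:
        return self.points.shape[0]


@dataclass
class SubjectRecord:
    """Baseline covariates, BMD and fracture outcome for one subject."""

    subject_id: str
    age: float
    bmi: float
    weight: float | None = None
    height: float | None = None
    bmd_fn: float | None = None
    bmd_it: float | None = None
    bmd_th: float | None = None
    fn_tscore: float | None = None
    fracture: bool = False
    fracture_site: str = "none"

    def __post_init__(self) -> None:
        if self.fracture_site not in FRACTURE_SITES:
            raise ValueError(f"unknown fracture_site {self.fracture_site!r}")
        if not self.fracture and self.fracture_site != "none":
            raise ValueError(f"{self.subject_id}: control with fracture_site set")
        if self.fracture and self.fracture_site == "none":
            raise ValueError(f"{self.subject_id}: case without fracture_site")
        for name in ("bmd_fn", "bmd_it", "bmd_th"):
            v = getattr(self, name)
            if v is not None and v <= 0:
                raise ValueError(f"{self.subject_id}: {name} must be > 0")
        if self.age <= 0:
            raise ValueError(f"{self.subject_id}: age must be > 0")


@dataclass
class FilterReport:
    n_total: int
    n_excluded: int

    @property
    def n_kept(self) -> int:
        return self.n_total - self.n_excluded

    @property
    def percent_excluded(self) -> float:
        return round_half_up(100.0 * self.n_excluded / self.n_total, 1)


def pixel_pitch_mm(dpi: float) -> float:
    """Physical pixel pitch (mm) of a scanner resolution, rounded to 3 dp.

    150 dpi digitization corresponds to a 0.169 mm pitch.
    """
    if dpi <= 0:
        raise ValueError("dpi must be positive")
    return round_half_up(25.4 / dpi, 3)


def case_control_ratio(n_cases: int, n_controls: int) -> float:
    """Controls-per-case ratio, rounded half-up to 2 decimals (e.g. 1:1.38)."""
    if n_cases <= 0:
        raise ValueError("n_cases must be positive")
    return round_half_up(n_controls / n_cases, 2)


def filter_acceptable(cohort: Sequence[LandmarkSet]) -> tuple[list[LandmarkSet], FilterReport]:
    """Drop outlines whose trochanters were not fully visualized.

    Returns the kept subjects and a report with the exclusion percentage
    (1 decimal, half-up).
    """
    cohort = list(cohort)
    if not cohort:
        raise ValueError("empty cohort")
    kept = [lm for lm in cohort if lm.acceptable]
    return kept, FilterReport(n_total=len(cohort), n_excluded=len(cohort) - len(kept))


# ---------------------------------------------------------------------------
# landmark file reading / writing


def _check_cohort(sets: list[LandmarkSet], source: str) -> list[LandmarkSet]:
    if not sets:
        raise LandmarkFormatError(f"{source}: no subjects found")
    ks = {lm.k for lm in sets}
    if len(ks) > 1:
        # majority point count wins; ties go to the first-encountered count
        counts = [lm.k for lm in sets]
        common = max(dict.fromkeys(counts), key=counts.count)
        bad = [lm.subject_id for lm in sets if lm.k != common]
        raise LandmarkFormatError(
            f"{source}: mixed point counts {sorted(ks)}; offending subjects: {', '.join(bad)}"
        )
    ids = [lm.subject_id for lm in sets]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise LandmarkFormatError(f"{source}: duplicate subject ids: {', '.join(dupes)}")
    return sets


def _scale_flip(pts: np.ndarray, spacing: float | None, flip_y: bool) -> np.ndarray:
    if spacing is not None:
        pts = pts * spacing
    if flip_y:
        pts = pts * np.array([1.0, -1.0])
    return pts


def read_landmarks_csv(
    path: str | Path,
    pixel_spacing_mm: float | None = None,
    flip_y: bool = False,
) -> list[LandmarkSet]:
    path = Path(path)
    out: list[LandmarkSet] = []
    with path.open(newline="") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise LandmarkFormatError(f"{path}: empty file") from None
        if not header or header[0].strip().lower() != "subject_id":
            raise LandmarkFormatError(f"{path}: first header column must be subject_id")
        has_flag = header[-1].strip().lower() == "acceptable"
        ncoord = len(header) - 1 - int(has_flag)
        if ncoord < 6 or ncoord % 2:
            raise LandmarkFormatError(f"{path}: header implies {ncoord} coordinate columns")
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) != len(header):
                raise LandmarkFormatError(
                    f"{path}:{lineno}: expected {len(header)} fields, got {len(row)}"
                )
            sid = row[0].strip()
            try:
                coords = np.array([float(v) for v in row[1 : 1 + ncoord]], dtype=float)
            except ValueError as exc:
                raise LandmarkFormatError(f"{path}:{lineno}: unparseable coordinate ({exc})") from None
            acceptable = True
            if has_flag:
                acceptable = row[-1].strip() not in ("0", "false", "False")
            pts = _scale_flip(coords.reshape(-1, 2), pixel_spacing_mm, flip_y)
            out.append(
                LandmarkSet(sid, pts, pixel_spacing_mm=pixel_spacing_mm, acceptable=acceptable)
            )
    return _check_cohort(out, str(path))


def read_landmarks_tps(
    path: str | Path,
    pixel_spacing_mm: float | None = None,
    flip_y: bool = False,
) -> list[LandmarkSet]:
    path = Path(path)
    out: list[LandmarkSet] = []
    lines = path.read_text().splitlines()
    i = 0
    while i < len(lines):
        line = lines[i].strip()
        if not line:
            i += 1
            continue
        if not line.upper().startswith("LM="):
            raise LandmarkFormatError(f"{path}:{i + 1}: expected LM= block, got {line!r}")
        try:
            k = int(line.split("=", 1)[1])
        except ValueError:
            raise LandmarkFormatError(f"{path}:{i + 1}: bad LM count") from None
        coords = []
        for j in range(k):
            try:
                x, y = lines[i + 1 + j].split()
                coords.append((float(x), float(y)))
            except (IndexError, ValueError):
                raise LandmarkFormatError(f"{path}:{i + 2 + j}: bad coordinate line") from None
        i += 1 + k
        sid = None
        scale = None
        while i < len(lines) and lines[i].strip() and "=" in lines[i] and not lines[i].upper().startswith("LM="):
            key, val = lines[i].strip().split("=", 1)
            key = key.strip().upper()
            if key == "ID":
                sid = val.strip()
            elif key == "SCALE":
                scale = float(val)
            i += 1
        if sid is None:
            raise LandmarkFormatError(f"{path}: block ending at line {i} has no ID=")
        spacing = pixel_spacing_mm if pixel_spacing_mm is not None else scale
        pts = _scale_flip(np.asarray(coords), spacing, flip_y)
        out.append(LandmarkSet(sid, pts, pixel_spacing_mm=spacing))
    return _check_cohort(out, str(path))


def read_landmarks(
    path: str | Path,
    format: str | None = None,
    pixel_spacing_mm: float | None = None,
    flip_y: bool = False,
) -> list[LandmarkSet]:
    """Read a cohort of outlines from a CSV or TPS file.

    ``format`` defaults from the file suffix.  When ``pixel_spacing_mm`` is
    given, coordinates are converted from pixels to mm on read.
    """
    if format is None:
        format = "tps" if str(path).lower().endswith(".tps") else "csv"
    if format == "csv":
        return read_landmarks_csv(path, pixel_spacing_mm, flip_y)
    if format == "tps":
        return read_landmarks_tps(path, pixel_spacing_mm, flip_y)
    raise ValueError(f"unknown landmark format {format!r}")


def write_landmarks(path: str | Path, cohort: Sequence[LandmarkSet], format: str | None = None) -> None:
    """Write outlines (always in mm) to CSV or TPS."""
    path = Path(path)
    if format is None:
        format = "tps" if path.suffix.lower() == ".tps" else "csv"
    cohort = list(cohort)
    if not cohort:
        raise ValueError("empty cohort")
    k = cohort[0].k
    if format == "csv":
        with path.open("w", newline="") as fh:
            w = csv.writer(fh)
            header = ["subject_id"]
            for i in range(1, k + 1):
                header += [f"x{i}", f"y{i}"]
            header.append("acceptable")
            w.writerow(header)
            for lm in cohort:
                row = [lm.subject_id]
                row += [f"{v:.6f}" for v in lm.points.ravel()]
                row.append("1" if lm.acceptable else "0")
                w.writerow(row)
    elif format == "tps":
        with path.open("w") as fh:
            for lm in cohort:
                fh.write(f"LM={lm.k}\n")
                for x, y in lm.points:
                    fh.write(f"{x:.6f} {y:.6f}\n")
                fh.write(f"ID={lm.subject_id}\n\n")
    else:
        raise ValueError(f"unknown landmark format {format!r}")


# ---------------------------------------------------------------------------
# covariates

_COVARIATE_COLS = [
    "subject_id",
    "age",
    "bmi",
    "weight",
    "height",
    "bmd_fn",
    "bmd_it",
    "bmd_th",
    "fn_tscore",
    "fracture",
    "fracture_site",
]


def records_to_frame(records: Iterable[SubjectRecord]) -> pd.DataFrame:
    df = pd.DataFrame([vars(r) for r in records])
    return df[_COVARIATE_COLS]


def frame_to_records(df: pd.DataFrame) -> list[SubjectRecord]:
    out = []
    for row in df.itertuples(index=False):
        d = {c: getattr(row, c) for c in _COVARIATE_COLS if hasattr(row, c)}
        d["fracture"] = bool(d["fracture"])
        d["subject_id"] = str(d["subject_id"])
        out.append(SubjectRecord(**d))
    return out


def read_covariates(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = {"subject_id", "age", "bmi", "fracture"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing covariate columns {sorted(missing)}")
    df["subject_id"] = df["subject_id"].astype(str)
    df["fracture"] = df["fracture"].astype(bool)
    if "fracture_site" not in df.columns:
        df["fracture_site"] = np.where(df["fracture"], "other", "none")
    return df


def write_covariates(path: str | Path, records: Iterable[SubjectRecord] | pd.DataFrame) -> None:
    df = records if isinstance(records, pd.DataFrame) else records_to_frame(records)
    df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# cohort summary (baseline characteristics table)

CONTINUOUS_VARS = ["age", "weight", "height", "bmi", "bmd_th", "bmd_fn", "bmd_it", "fn_tscore"]


def summarize_cohort(
    records: Sequence[SubjectRecord] | pd.DataFrame,
    continuous: Sequence[str] | None = None,
    categorical: Sequence[str] = (),
) -> pd.DataFrame:
    """Case/control baseline summary: mean +/- SD with Welch t-tests for
    continuous variables, counts (%) with chi-square tests for categorical.

    Returns a tidy table with one row per variable.  A variable constant in
    both groups gets ``p = NaN`` and test ``"n/a"`` rather than failing.
    """
    df = records if isinstance(records, pd.DataFrame) else records_to_frame(records)
    if continuous is None:
        continuous = [c for c in CONTINUOUS_VARS if c in df.columns and df[c].notna().any()]
    cases = df[df["fracture"]]
    controls = df[~df["fracture"]]
    if len(cases) < 2 or len(controls) < 2:
        raise ValueError("need at least 2 subjects per group")
    rows = []
    for var in continuous:
        a, b = cases[var].dropna(), controls[var].dropna()
        if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
            p, test = np.nan, "n/a"
        else:
            p = stats.ttest_ind(a, b, equal_var=False).pvalue
            test = "welch_t"
        rows.append(
            dict(
                variable=var,
                case_mean=a.mean(),
                case_sd=a.std(ddof=1),
                control_mean=b.mean(),
                control_sd=b.std(ddof=1),
                case_n=len(a),
                control_n=len(b),
                p_value=p,
                test=test,
            )
        )
    for var in categorical:
        a = cases[var].astype(bool)
        b = controls[var].astype(bool)
        table = np.array([[a.sum(), len(a) - a.sum()], [b.sum(), len(b) - b.sum()]])
        if (table.sum(axis=0) == 0).any():
            p, test = np.nan, "n/a"
        else:
            p = stats.chi2_contingency(table, correction=False).pvalue
            test = "chi2"
        rows.append(
            dict(
                variable=var,
                case_mean=a.sum(),
                case_sd=100.0 * a.mean(),
                control_mean=b.sum(),
                control_sd=100.0 * b.mean(),
                case_n=len(a),
                control_n=len(b),
                p_value=p,
                test=test,
            )
        )
    out = pd.DataFrame(rows)
    out.attrs["n_cases"] = len(cases)
    out.attrs["n_controls"] = len(controls)
    return out
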