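"""End-to-end orchestration: simulate/ingest -> filter -> align -> PCA ->
score -> geometry -> risk tables -> permutation check.

``run_pipeline`` executes all stages in order and writes a reproducible
report bundle (baseline-table, model-comparison, stratified and per-mode
odds-ratio CSVs, mode-gallery SVGs, a permutation summary and a structured
log).  Given the same configuration and seed the CSV outputs are
byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from hipshape import io
from hipshape.geometry import geometry_measures
from hipshape.model import fit_shape_model, mode_gallery, score_subjects
from hipshape.permutation import null_association_check
from hipshape.procrustes import generalized_procrustes
from hipshape.risk import (
    SeparationError,
    model_comparison_table,
    odds_ratio_table,
    fit_logistic,
    stratified_auroc,
)
from hipshape.simulate import GeneratorConfig, preset, sample_cohort, write_cohort

MODE_COLS = [f"mode{j}" for j in range(1, 11)]

ADJUST_BMD = ["age", "bmi", "bmd_fn"]

DEFAULT_SPECS = {
    "hip_shape_modes_1_10": MODE_COLS,
    "femoral_neck_bmd": ["bmd_fn"],
    "intertrochanteric_bmd": ["bmd_it"],
    "femoral_neck_length": ["neck_length"],
    "femoral_neck_width": ["neck_width"],
    "hip_shape_plus_fn_bmd": MODE_COLS + ["bmd_fn"],
    "hip_shape_plus_it_bmd": MODE_COLS + ["bmd_it"],
    "neck_length_plus_fn_bmd": ["neck_length", "bmd_fn"],
    "neck_length_plus_it_bmd": ["neck_length", "bmd_it"],
    "neck_width_plus_fn_bmd": ["neck_width", "bmd_fn"],
    "neck_width_plus_it_bmd": ["neck_width", "bmd_it"],
}


def planted_mode_or_recovery(n_subjects: int = 5000, seed: int = 0) -> pd.DataFrame:
    """Generate a cohort, run the full shape pipeline and refit the adjusted
    logistic model on the estimated SD-unit mode scores.

    Estimated modes are matched to the planted ones by score correlation
    (PCA order and sign are arbitrary) before fitting.  Returns the
    odds-ratio table indexed by planted mode with the planted per-SD OR
    alongside the estimate — the end-to-end parameter-recovery check.
    """
    from hipshape.simulate import GeneratorConfig, match_modes

    cohort = sample_cohort(GeneratorConfig(n_subjects=n_subjects, seed=seed))
    aligned = generalized_procrustes(cohort.landmarks)
    model = fit_shape_model(aligned, m=10)
    scores = score_subjects(model, aligned)
    perm, signs = match_modes(scores.sd_units, cohort.truth.true_scores)
    oriented = scores.sd_units[:, perm] * signs
    x = np.column_stack([cohort.covariates[ADJUST_BMD].to_numpy(), oriented])
    fit = fit_logistic(
        x, cohort.covariates["fracture"].to_numpy(int), names=ADJUST_BMD + MODE_COLS
    )
    tab = odds_ratio_table(fit)
    tab = tab[tab.predictor.isin(MODE_COLS)].reset_index(drop=True)
    tab["planted_or"] = np.exp(cohort.truth.gamma)
    return tab


@dataclass
class RunConfig:
    out_dir: str = "results/run"
    preset: str = "paper"  # 'tiny' | 'paper', ignored if landmarks_path given
    seed: int = 0
    landmarks_path: str | None = None
    covariates_path: str | None = None
    pixel_spacing_mm: float | None = None
    gpa_tol: float = 1e-8
    gpa_max_iter: int = 100
    tangent: bool = True
    n_modes: int = 10
    variance_target: float | None = None
    relabel_ratios: tuple[float, ...] = (1.38, 1.0, 2.0)
    relabel_reps: int = 50
    gallery_modes: tuple[int, ...] = (1, 4)
    generator_overrides: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("relabel_ratios", "gallery_modes"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, float_format="%.10g")


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage and write the report bundle; returns the run log."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log: dict = {"config": dataclasses.asdict(config), "stages": []}

    def stage(name):
        def wrap(fn):
            t0 = time.perf_counter()
            try:
                result = fn()
            except Exception as exc:
                log["stages"].append({"stage": name, "status": "failed", "error": str(exc)})
                (out / "run_log.json").write_text(json.dumps(log, indent=2, default=str))
                raise PipelineError(name, exc) from exc
            log["stages"].append(
                {"stage": name, "status": "ok", "seconds": round(time.perf_counter() - t0, 3)}
            )
            return result

        return wrap

    # --- inputs -----------------------------------------------------------
    if config.landmarks_path:
        def load():
            lms = io.read_landmarks(
                config.landmarks_path, pixel_spacing_mm=config.pixel_spacing_mm
            )
            cov = io.read_covariates(config.covariates_path)
            from hipshape.geometry import GeometryConfig

            return lms, cov, GeometryConfig(), None

        landmarks, covariates, geom_cfg, truth = stage("ingest")(load)
    else:
        def simulate():
            gen = preset(config.preset, seed=config.seed, **config.generator_overrides)
            cohort = sample_cohort(gen)
            write_cohort(out / "cohort", cohort)
            log["generator_config_hash"] = cohort.truth.config_hash
            return cohort.landmarks, cohort.covariates, cohort.geometry_config, cohort.truth

        landmarks, covariates, geom_cfg, truth = stage("simulate")(simulate)

    kept, report = stage("filter")(lambda: io.filter_acceptable(landmarks))
    log["filter"] = dataclasses.asdict(report) | {"percent_excluded": report.percent_excluded}

    aligned = stage("align")(
        lambda: generalized_procrustes(
            kept, tol=config.gpa_tol, max_iter=config.gpa_max_iter, tangent=config.tangent
        )
    )
    log["align"] = {"iterations": aligned.iterations_run, "converged": aligned.converged}

    model = stage("fit")(
        lambda: fit_shape_model(
            aligned,
            m=None if config.variance_target else config.n_modes,
            variance_target=config.variance_target,
        )
    )
    model.to_json(out / "shape_model.json")
    log["fit"] = {
        "m_retained": model.m_retained,
        "variance_captured": float(model.variance_fractions.sum()),
    }

    scores = stage("score")(lambda: score_subjects(model, aligned))
    scores_df = scores.frame()
    _write_csv(scores_df, out / "mode_scores.csv")

    def geometry():
        rows = []
        for lm in kept:
            g = geometry_measures(lm, geom_cfg)
            rows.append(dict(subject_id=lm.subject_id, **dataclasses.asdict(g)))
        return pd.DataFrame(rows)

    geo_df = stage("geometry")(geometry)
    _write_csv(geo_df, out / "geometry.csv")

    data = covariates.merge(scores_df, on="subject_id").merge(geo_df, on="subject_id")

    def baseline():
        return io.summarize_cohort(data)

    table1 = stage("baseline_summary")(baseline)
    _write_csv(table1, out / "table1_baseline.csv")

    def risk_tables():
        # small cohorts can perfectly separate the high-dimensional mode
        # models; cells fall back to an explicit tiny ridge and are marked
        t2 = model_comparison_table(data, DEFAULT_SPECS, on_separation="ridge")
        t3 = stratified_auroc(data, DEFAULT_SPECS, on_separation="ridge")
        x4 = data[["age", "bmi", "bmd_fn"] + MODE_COLS]
        y4 = data["fracture"].to_numpy(int)
        try:
            fit4 = fit_logistic(x4, y4)
        except SeparationError:
            fit4 = fit_logistic(x4, y4, ridge=1e-4)
            log.setdefault("notes", []).append("mode odds-ratio model penalized (separation)")
        t4 = odds_ratio_table(fit4)
        t4 = t4[t4["predictor"].isin(MODE_COLS)].reset_index(drop=True)
        return t2, t3, t4

    table2, table3, table4 = stage("risk_models")(risk_tables)
    _write_csv(table2, out / "table2_model_comparison.csv")
    _write_csv(table3, out / "table3_tscore_strata.csv")
    _write_csv(table4, out / "table4_mode_odds_ratios.csv")

    perm = stage("permutation_check")(
        lambda: null_association_check(
            data,
            MODE_COLS,
            ratios=config.relabel_ratios,
            n_reps=config.relabel_reps,
            seed=config.seed,
        )
    )
    _write_csv(perm, out / "permutation_summary.csv")
    log["permutation"] = {"consistent_with_null": perm.attrs["consistent_with_null"]}

    def gallery():
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        paths = []
        for j in config.gallery_modes:
            fig, ax = plt.subplots(figsize=(4, 4))
            for sd, style in zip((-2.0, 0.0, 2.0), ("C0--", "k-", "C3:")):
                shape = mode_gallery(model, j, (sd,))[0].reshape(-1, 2)
                closed = np.vstack([shape, shape[:1]])
                ax.plot(closed[:, 0], closed[:, 1], style, label=f"{sd:+.0f} SD" if sd else "mean")
            ax.set_aspect("equal")
            ax.legend(loc="lower right", fontsize=8)
            ax.set_title(f"Mode {j}")
            p = out / f"gallery_mode{j}.svg"
            fig.savefig(p)
            plt.close(fig)
            paths.append(str(p))
        return paths

    stage("gallery")(gallery)

    log["n_subjects"] = len(kept)
    log["seed"] = config.seed
    (out / "run_log.json").write_text(json.dumps(log, indent=2, default=str))
    return log
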