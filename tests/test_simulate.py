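import dataclasses

import numpy as np
import pytest
from shapely.geometry import LineString

from hipshape.geometry import geometry_measures, head_diameter, is_right_outline
from hipshape.model import fit_shape_model, score_subjects
from hipshape.procrustes import generalized_procrustes
from hipshape.risk import auroc, fit_logistic
from hipshape.simulate import (
    GeneratorConfig,
    SyntheticTruth,
    TemplateParams,
    make_mode_basis,
    make_template,
    match_modes,
    preset,
    sample_cohort,
)


def _is_simple(points):
    return LineString(np.vstack([points, points[:1]])).is_simple


def test_template_is_simple_polyline(template):
    lm, _ = template
    assert _is_simple(lm.points)


def test_template_head_radius_consistency(template):
    """Head-radius parameter 24 mm comes back as diameter 48 +/- 0.5 mm via
    the geometry module."""
    lm, cfg = template
    diam, rms = head_diameter(lm, config=cfg)
    assert diam == pytest.approx(48.0, abs=0.5)


def test_template_rejects_impossible_parameters():
    with pytest.raises(ValueError):
        make_template(TemplateParams(head_radius=10.0, neck_width=31.0))
    with pytest.raises(ValueError):
        make_template(TemplateParams(neck_length=20.0))


def test_mirrored_template_fails_orientation_check(template):
    lm, cfg = template
    assert not is_right_outline(lm.points * np.array([-1.0, 1.0]), cfg)


def test_basis_orthonormal_and_deterministic(template):
    lm, _ = template
    cfg = GeneratorConfig()
    b1 = make_mode_basis(lm, cfg, seed=11)
    b2 = make_mode_basis(lm, cfg, seed=11)
    b3 = make_mode_basis(lm, cfg, seed=12)
    np.testing.assert_allclose(b1.T @ b1, np.eye(10), atol=1e-10)
    np.testing.assert_array_equal(b1, b2)
    assert np.abs(b1 - b3).max() > 1e-3


def test_outlines_stay_simple_across_mode_range(template):
    """Shapes remain simple (non-self-intersecting) polylines for mode
    scores up to +/-3 SD on every planted mode."""
    lm, _ = template
    cfg = GeneratorConfig()
    basis = make_mode_basis(lm, cfg, seed=0)
    lam = cfg.eigenvalues
    flat = lm.points.ravel()
    for j in range(10):
        for sd in (-3.0, 3.0):
            pts = (flat + sd * np.sqrt(lam[j]) * basis[:, j]).reshape(-1, 2)
            assert _is_simple(pts), f"mode {j + 1} at {sd} SD self-intersects"


def test_cohort_shapes_and_files(tiny_cohort, tmp_path):
    from hipshape.simulate import write_cohort

    assert len(tiny_cohort.landmarks) == 40
    assert all(lm.k == 60 for lm in tiny_cohort.landmarks)
    assert set(tiny_cohort.covariates.columns) >= {
        "subject_id", "age", "bmi", "bmd_fn", "fn_tscore", "fracture", "fracture_site",
    }
    paths = write_cohort(tmp_path, tiny_cohort, tps=True)
    for p in paths.values():
        assert p.exists()
    back = SyntheticTruth.from_json(paths["truth"])
    np.testing.assert_allclose(back.true_scores, tiny_cohort.truth.true_scores)
    np.testing.assert_allclose(back.basis, tiny_cohort.truth.basis)


def test_fracture_sites_consistent(paper_cohort):
    df = paper_cohort.covariates
    assert (df.loc[~df.fracture, "fracture_site"] == "none").all()
    assert df.loc[df.fracture, "fracture_site"].isin(
        ["femoral_neck", "intertrochanteric", "other"]
    ).all()


def test_prevalence_calibration_across_seeds():
    """Realized case fraction stays within 3 binomial SEs of the 168/399
    target across 50 seeds."""
    target = 168 / 399
    n = 399
    tol = 3 * np.sqrt(target * (1 - target) / n)
    misses = 0
    for seed in range(50):
        c = sample_cohort(preset("paper", seed=seed))
        if abs(c.truth.realized_prevalence - target) > tol:
            misses += 1
    assert misses <= 1  # a 3-sigma bound may fail rarely by chance


def test_null_effects_give_chance_discrimination():
    """With all planted log-odds zero the 10-mode model cannot discriminate
    (in-sample AUROC near 0.5 at n = 3000)."""
    cfg = GeneratorConfig(n_subjects=3000, seed=5, gamma=tuple(np.zeros(10)))
    c = sample_cohort(cfg)
    fit = fit_logistic(c.truth.true_scores, c.covariates.fracture.to_numpy(int))
    a = auroc(fit.fitted_probs, c.covariates.fracture.to_numpy(int))
    assert abs(a - 0.5) < 0.05


def test_full_pipeline_recovers_true_scores(paper_cohort, paper_model, paper_aligned):
    """Generate -> align -> fit -> score closes the loop: estimated SD-unit
    scores correlate |r| > 0.9 with the planted ones, mode by mode."""
    scores = score_subjects(paper_model, paper_aligned)
    perm, signs = match_modes(scores.sd_units, paper_cohort.truth.true_scores)
    assert sorted(perm.tolist()) == list(range(10))
    for j in range(10):
        r = np.corrcoef(
            signs[j] * scores.sd_units[:, perm[j]], paper_cohort.truth.true_scores[:, j]
        )[0, 1]
        assert r > 0.9, f"mode {j + 1} recovery r={r:.3f}"


def test_recovery_uses_only_truth_ledger(tmp_path, tiny_cohort):
    """Recovery checks need nothing beyond the serialized truth file."""
    from hipshape.simulate import write_cohort

    paths = write_cohort(tmp_path, tiny_cohort)
    truth = SyntheticTruth.from_json(paths["truth"])
    assert truth.true_scores.shape == (40, 10)
    assert truth.gamma.shape == (10,)
    g = truth.template_geometry
    assert g["neck_length"] == pytest.approx(50.0, rel=0.02)


def test_planted_gamma_recovery_large_n():
    """At n=5000 the adjusted logistic refit on estimated modes recovers
    every nonzero planted log-OR with the right sign and <=10% relative
    error on the OR scale."""
    c = sample_cohort(GeneratorConfig(n_subjects=5000, seed=2))
    aligned = generalized_procrustes(c.landmarks)
    model = fit_shape_model(aligned, m=10)
    scores = score_subjects(model, aligned)
    perm, signs = match_modes(scores.sd_units, c.truth.true_scores)
    oriented = scores.sd_units[:, perm] * signs
    x = np.column_stack(
        [c.covariates[["age", "bmi", "bmd_fn"]].to_numpy(), oriented]
    )
    names = ["age", "bmi", "bmd_fn"] + [f"mode{j + 1}" for j in range(10)]
    fit = fit_logistic(x, c.covariates.fracture.to_numpy(int), names=names)
    for j, g in enumerate(c.truth.gamma):
        if g == 0:
            continue
        est = fit.params[fit.names.index(f"mode{j + 1}")]
        assert np.sign(est) == np.sign(g)
        assert abs(np.exp(est) - np.exp(g)) / np.exp(g) < 0.10


def test_mixture_tscore_strata_are_realistic(paper_cohort):
    """T-scores derived from the BMD mixture give non-trivial occupancy of
    all three diagnostic strata."""
    from hipshape.risk import assign_stratum

    strata = paper_cohort.covariates.fn_tscore.map(assign_stratum).value_counts()
    assert set(strata.index) == {"normal", "osteopenic", "osteoporotic"}
    assert strata["osteopenic"] > strata["normal"]
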