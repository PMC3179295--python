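import numpy as np
import pytest
from scipy.linalg import eigh, subspace_angles

from hipshape.model import (
    fit_shape_model,
    mode_gallery,
    reconstruct,
    score_subjects,
    ShapeModel,
)
from hipshape.procrustes import optimal_rotation


def _planted_cohort(n, p, n_modes, rng, noise=0.0):
    basis, _ = np.linalg.qr(rng.normal(size=(p, n_modes)))
    lam = 4.0 * 0.5 ** np.arange(n_modes)
    scores = rng.standard_normal((n, n_modes))
    x = (scores * np.sqrt(lam)) @ basis.T + noise * rng.standard_normal((n, p))
    return x, basis, lam, scores


def test_planted_rank_three_spectrum(rng):
    """Three planted modes with no noise give exactly three nonzero
    eigenvalues."""
    x, *_ = _planted_cohort(50, 16, 3, rng)
    model = fit_shape_model(x, m=3)
    assert model.variance_fractions.sum() == pytest.approx(1.0, abs=1e-12)
    full = np.linalg.eigvalsh(np.cov(x.T))
    assert np.all(np.sort(full)[:-3] < 1e-12 * full.max())


def test_eigenvalue_sum_equals_total_variance(rng):
    x, *_ = _planted_cohort(40, 12, 6, rng, noise=0.3)
    model = fit_shape_model(x, m=12)
    assert model.eigenvalues.sum() == pytest.approx(model.total_variance, rel=1e-9)
    centered = x - x.mean(axis=0)
    trace = (centered**2).sum() / (len(x) - 1)
    assert model.total_variance == pytest.approx(trace, rel=1e-12)


def test_matches_dense_eigensolver_oracle(rng):
    """Small instance agrees with an independent covariance + dense
    symmetric eigensolver to 1e-8 in eigenvalues and 1e-6 rad in span."""
    x = rng.standard_normal((20, 8))
    model = fit_shape_model(x, m=8)
    cov = np.cov(x, rowvar=False, ddof=1)
    lam_oracle, vec_oracle = eigh(cov)
    np.testing.assert_allclose(
        model.eigenvalues, np.sort(lam_oracle)[::-1], atol=1e-8
    )
    angles = subspace_angles(model.modes[:, :4], vec_oracle[:, -4:])
    assert np.max(angles) < 1e-6


def test_modes_orthonormal_and_sorted(paper_model):
    m = paper_model.modes
    np.testing.assert_allclose(m.T @ m, np.eye(m.shape[1]), atol=1e-10)
    assert np.all(np.diff(paper_model.eigenvalues) <= 1e-12)
    # deterministic sign convention: largest-|entry| coefficient positive
    idx = np.argmax(np.abs(m), axis=0)
    assert np.all(m[idx, np.arange(m.shape[1])] > 0)


def test_m_larger_than_rank_is_an_error(rng):
    x, *_ = _planted_cohort(30, 10, 2, rng)
    with pytest.raises(ValueError, match="rank"):
        fit_shape_model(x, m=5)


def test_variance_target_retention(paper_aligned):
    model = fit_shape_model(paper_aligned, m=None, variance_target=0.95)
    assert model.variance_fractions.sum() >= 0.95
    assert model.variance_fractions[:-1].sum() < 0.95  # smallest such m


def test_scores_of_mean_and_single_mode_displacement(paper_model):
    s = score_subjects(paper_model, paper_model.mean_shape[None, :])
    np.testing.assert_allclose(s.sd_units, 0.0, atol=1e-10)
    x = paper_model.mean_shape + 2.0 * np.sqrt(paper_model.eigenvalues[3]) * paper_model.modes[:, 3]
    s = score_subjects(paper_model, x[None, :]).sd_units[0]
    assert s[3] == pytest.approx(2.0, abs=1e-8)
    others = np.delete(s, 3)
    np.testing.assert_allclose(others, 0.0, atol=1e-8)


def test_training_scores_standardized(paper_model, paper_aligned):
    """Training-cohort SD-unit scores have mean 0 and SD 1 per mode."""
    s = score_subjects(paper_model, paper_aligned).sd_units
    np.testing.assert_allclose(s.mean(axis=0), 0.0, atol=1e-8)
    np.testing.assert_allclose(s.std(axis=0, ddof=1), 1.0, atol=1e-6)


def test_heldout_scores_have_unit_spread(paper_model, rng):
    """Shapes generated from the model itself score with per-mode SD close
    to 1 (binomial-style tolerance 3/sqrt(2n))."""
    n = 2000
    sd = rng.standard_normal((n, paper_model.m_retained))
    shapes = paper_model.mean_shape + (sd * np.sqrt(paper_model.eigenvalues)) @ paper_model.modes.T
    s = score_subjects(paper_model, shapes).sd_units
    np.testing.assert_allclose(s.std(axis=0, ddof=1), 1.0, atol=3 / np.sqrt(2 * n))


def test_reconstruct_mean_and_round_trip(rng):
    x, *_ = _planted_cohort(30, 12, 5, rng, noise=0.1)
    model = fit_shape_model(x, m=12)
    np.testing.assert_allclose(reconstruct(model, np.zeros(12)), model.mean_shape)
    scores = score_subjects(model, x)
    for i in (0, 7, 29):
        back = reconstruct(model, scores.sd_units[i])
        np.testing.assert_allclose(back, x[i], atol=1e-8)


def test_out_of_span_score_request_errors():
    model = ShapeModel(
        mean_shape=np.zeros(4),
        modes=np.eye(4)[:, :2],
        eigenvalues=np.array([1.0, 0.0]),
        variance_fractions=np.array([1.0, 0.0]),
        total_variance=1.0,
        m_retained=2,
    )
    ok = score_subjects(model, np.array([[0.5, 0.0, 0.0, 0.0]]))
    assert ok.sd_units[0, 1] == 0.0
    with pytest.raises(ValueError, match="span"):
        score_subjects(model, np.array([[0.0, 0.5, 0.0, 0.0]]))


def test_mode_gallery_symmetry(paper_model):
    (mean_only,) = mode_gallery(paper_model, 1, (0.0,))
    np.testing.assert_allclose(mean_only, paper_model.mean_shape)
    lo, hi = mode_gallery(paper_model, 4, (-2.0, 2.0))
    np.testing.assert_allclose(lo + hi, 2 * paper_model.mean_shape, atol=1e-10)
    with pytest.raises(ValueError):
        mode_gallery(paper_model, 11)


def _shoelace(pts):
    x, y = pts[:, 0], pts[:, 1]
    return 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))


def test_mode4_analog_trades_area_monotonically(paper_cohort):
    """The planted size-trading mode changes outline area monotonically
    along an SD grid in the generator's mm space."""
    t = paper_cohort.truth
    areas = []
    for sd in (-2.0, -1.0, 0.0, 1.0, 2.0):
        flat = t.template_points.ravel() + sd * np.sqrt(t.eigenvalues[3]) * t.basis[:, 3]
        areas.append(_shoelace(flat.reshape(-1, 2)))
    diffs = np.diff(areas)
    assert np.all(diffs > 0) or np.all(diffs < 0)


def test_planted_mode_recovery(paper_cohort, paper_model, paper_aligned):
    """The estimated 10-mode subspace matches the planted one (principal
    angle < 10 degrees after undoing the global alignment rotation) and the
    eigenvalue profile matches within 15% for well-separated modes."""
    t = paper_cohort.truth
    mean_pts = paper_model.mean_shape.reshape(-1, 2)
    r = optimal_rotation(mean_pts, t.template_points)
    k = mean_pts.shape[0]
    est_fields = paper_model.modes.T.reshape(-1, k, 2) @ r.T
    est = est_fields.reshape(-1, 2 * k).T
    angles = subspace_angles(est, t.basis)
    assert np.degrees(np.max(angles)) < 10.0
    ratio_est = paper_model.eigenvalues / paper_model.eigenvalues[0]
    ratio_true = t.eigenvalues / t.eigenvalues[0]
    np.testing.assert_allclose(ratio_est[:5], ratio_true[:5], rtol=0.15)


def test_model_json_round_trip(tmp_path, paper_model):
    paper_model.to_json(tmp_path / "m.json")
    back = ShapeModel.from_json(tmp_path / "m.json")
    np.testing.assert_allclose(back.modes, paper_model.modes)
    np.testing.assert_allclose(back.eigenvalues, paper_model.eigenvalues)
    assert back.m_retained == paper_model.m_retained
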