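"""Logistic fracture-discrimination models, AUROC machinery and strata.

Implements the analysis behind the model-comparison tables: adjusted
logistic regression (age/BMI, optionally BMD), per-predictor odds ratios
with Wald CIs, in-sample AUROC with a DeLong 95% CI, McFadden pseudo-R2,
site-specific fracture subsets, and femoral-neck T-score strata
(normal T > -1, osteopenic -2.5 <= T <= -1, osteoporotic T < -2.5).

"Adjusting for age and BMI" means the adjustment covariates enter the
logistic model whose fitted probabilities feed the ROC; AUROCs are
in-sample, matching the source analysis style.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from sklearn.metrics import roc_auc_score

from hipshape._util import round_half_up


class SeparationError(RuntimeError):
    """Perfect separation: the MLE diverges.  Consider the ridge option
    (fit_logistic(..., ridge=1e-4)), which is off by default because silent
    penalization would distort odds ratios."""


@dataclass
class RiskModelFit:
    names: list[str]
    params: np.ndarray
    cov_params: np.ndarray
    llf: float
    llnull: float
    n_cases: int
    n_controls: int
    converged: bool
    fitted_probs: np.ndarray
    outcome: np.ndarray

    @property
    def bse(self) -> np.ndarray:
        return np.sqrt(np.diag(self.cov_params))


def _design(x, names=None, add_intercept=True):
    if isinstance(x, pd.DataFrame):
        names = list(x.columns)
        x = x.to_numpy(dtype=float)
    else:
        x = np.asarray(x, dtype=float)
        if x.ndim == 1:
            x = x[:, None]
        if names is None:
            names = [f"x{i + 1}" for i in range(x.shape[1])]
        names = list(names)
    if add_intercept:
        x = np.column_stack([np.ones(x.shape[0]), x])
        names = ["intercept"] + names
    return x, names


def fit_logistic(
    x,
    y,
    names: list[str] | None = None,
    add_intercept: bool = True,
    ridge: float | None = None,
) -> RiskModelFit:
    """Maximum-likelihood logistic fit (Newton/IRLS via statsmodels).

    Raises on single-class outcomes, singular designs (naming the collinear
    columns) and perfect separation (advising the explicit ridge option).
    ``ridge`` adds an L2 penalty of the given strength to the slope terms —
    off by default.
    """
    y = np.asarray(y, dtype=float).ravel()
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ValueError("outcome must be binary 0/1")
    if y.min() == y.max():
        raise ValueError("outcome has a single class; logistic model undefined")
    xd, names = _design(x, names, add_intercept)
    n, p = xd.shape
    if n <= p + 1:
        raise ValueError(f"need n > p + 1 observations (n={n}, p={p})")
    rank = np.linalg.matrix_rank(xd)
    if rank < p:
        # name the dependent columns: those whose removal restores full rank
        bad = [
            names[j]
            for j in range(p)
            if np.linalg.matrix_rank(np.delete(xd, j, axis=1)) == rank
        ]
        raise ValueError(f"singular design; collinear columns: {', '.join(bad)}")
    const = [names[j] for j in range(p) if names[j] != "intercept" and np.ptp(xd[:, j]) == 0]
    if const:
        raise ValueError(f"constant predictor(s): {', '.join(const)}")

    if ridge is not None:
        beta = _ridge_newton(xd, y, ridge, skip_first=add_intercept)
        eta = np.clip(xd @ beta, -30.0, 30.0)
        probs = 1.0 / (1.0 + np.exp(-eta))
        w = probs * (1 - probs)
        cov = np.linalg.inv(xd.T @ (w[:, None] * xd) + ridge * np.eye(p))
        llf = float(np.sum(y * eta - np.log1p(np.exp(eta))))
        converged = True
        params = beta
    else:
        sep_warning = sm.tools.sm_exceptions.PerfectSeparationWarning
        with warnings.catch_warnings():
            warnings.simplefilter("error", category=RuntimeWarning)
            warnings.simplefilter("error", category=sep_warning)
            warnings.simplefilter("ignore", category=FutureWarning)
            try:
                res = sm.Logit(y, xd).fit(disp=0, maxiter=200, tol=1e-10)
            except (
                sm.tools.sm_exceptions.PerfectSeparationError,
                sep_warning,
                RuntimeWarning,
            ) as exc:
                raise SeparationError(
                    "perfect separation detected; refit with ridge=1e-4 if a "
                    "penalized fit is acceptable"
                ) from exc
        if np.any(~np.isfinite(res.params)) or np.any(~np.isfinite(res.bse)):
            raise SeparationError(
                "non-finite estimates (likely separation); consider ridge=1e-4"
            )
        params = np.asarray(res.params)
        cov = np.asarray(res.cov_params())
        llf = float(res.llf)
        probs = np.asarray(res.predict())
        converged = bool(res.mle_retvals.get("converged", True))

    pbar = y.mean()
    llnull = float(np.sum(y * np.log(pbar) + (1 - y) * np.log1p(-pbar)))
    return RiskModelFit(
        names=names,
        params=params,
        cov_params=cov,
        llf=llf,
        llnull=llnull,
        n_cases=int(y.sum()),
        n_controls=int((1 - y).sum()),
        converged=converged,
        fitted_probs=probs,
        outcome=y.astype(int),
    )


def _ridge_newton(xd, y, lam, skip_first, max_iter=100, tol=1e-10):
    p = xd.shape[1]
    pen = lam * np.eye(p)
    if skip_first:
        pen[0, 0] = 0.0
    beta = np.zeros(p)
    ll_old = -np.inf
    for _ in range(max_iter):
        eta = np.clip(xd @ beta, -30, 30)
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = mu * (1 - mu)
        grad = xd.T @ (y - mu) - pen @ beta
        hess = xd.T @ (w[:, None] * xd) + pen
        beta = beta + np.linalg.solve(hess, grad)
        ll = np.sum(y * eta - np.log1p(np.exp(eta))) - 0.5 * beta @ pen @ beta
        if abs(ll - ll_old) < tol:
            break
        ll_old = ll
    return beta


def odds_ratio_table(fit: RiskModelFit, z: float = 1.96) -> pd.DataFrame:
    """Per-predictor odds ratios e^beta with Wald 95% CIs and p-values
    (intercept excluded)."""
    if not fit.converged:
        raise ValueError("fit did not converge; odds ratios unreliable")
    rows = []
    for j, name in enumerate(fit.names):
        if name == "intercept":
            continue
        beta = fit.params[j]
        se = fit.bse[j]
        pval = 2 * stats.norm.sf(abs(beta / se)) if se > 0 else np.nan
        rows.append(
            dict(
                predictor=name,
                odds_ratio=np.exp(beta),
                ci_low=np.exp(beta - z * se),
                ci_high=np.exp(beta + z * se),
                p_value=pval,
            )
        )
    return pd.DataFrame(rows)


def auroc(scores, outcome) -> float:
    """Probability a random case outranks a random control (ties count 1/2)."""
    y = np.asarray(outcome, dtype=int).ravel()
    s = np.asarray(scores, dtype=float).ravel()
    if y.min() == y.max():
        raise ValueError("both classes required to compute AUROC")
    return float(roc_auc_score(y, s))


def _delong_variance(scores, outcome):
    s = np.asarray(scores, dtype=float).ravel()
    y = np.asarray(outcome, dtype=int).ravel()
    cases = s[y == 1]
    controls = s[y == 0]
    m, n = cases.size, controls.size
    # structural components: per-case / per-control placement values
    cmp_matrix = (cases[:, None] > controls[None, :]).astype(float)
    cmp_matrix += 0.5 * (cases[:, None] == controls[None, :])
    v10 = cmp_matrix.mean(axis=1)
    v01 = cmp_matrix.mean(axis=0)
    theta = float(cmp_matrix.mean())
    s10 = v10.var(ddof=1) if m > 1 else 0.0
    s01 = v01.var(ddof=1) if n > 1 else 0.0
    return theta, s10 / m + s01 / n


def auroc_ci(
    scores,
    outcome,
    z: float = 1.96,
    bootstrap_reps: int = 2000,
    seed: int = 0,
) -> tuple[float, float]:
    """DeLong normal-approximation 95% CI for the AUROC, truncated to [0, 1].

    Falls back to a seeded stratified bootstrap when the DeLong variance
    degenerates (e.g. perfectly separated scores).
    """
    y = np.asarray(outcome, dtype=int).ravel()
    s = np.asarray(scores, dtype=float).ravel()
    if (y == 1).sum() < 2 or (y == 0).sum() < 2:
        raise ValueError("need at least 2 subjects per class")
    theta, var = _delong_variance(s, y)
    if var > 0:
        half = z * np.sqrt(var)
        return max(0.0, theta - half), min(1.0, theta + half)
    rng = np.random.default_rng(seed)
    cases = s[y == 1]
    ctrls = s[y == 0]
    reps = np.empty(bootstrap_reps)
    for r in range(bootstrap_reps):
        cs = rng.choice(cases, cases.size)
        ks = rng.choice(ctrls, ctrls.size)
        gt = cs[:, None] > ks[None, :]
        eq = cs[:, None] == ks[None, :]
        reps[r] = gt.mean() + 0.5 * eq.mean()
    lo, hi = np.percentile(reps, [2.5, 97.5])
    return float(max(0.0, lo)), float(min(1.0, hi))


def mcfadden_r2(fit: RiskModelFit, null_fit: RiskModelFit | None = None) -> float:
    """McFadden pseudo-R2: 1 - llf_model / llf_null."""
    llnull = null_fit.llf if null_fit is not None else fit.llnull
    if null_fit is not None and not np.array_equal(null_fit.outcome, fit.outcome):
        raise ValueError("null fit must use the same outcome vector")
    if llnull == 0:
        raise ValueError("null log-likelihood is zero; pseudo-R2 undefined")
    return float(1.0 - fit.llf / llnull)


# ---------------------------------------------------------------------------
# model-comparison grids

DEFAULT_ADJUST = ("age", "bmi")

OUTCOME_SETS = {
    "all": None,
    "femoral_neck": "femoral_neck",
    "intertrochanteric": "intertrochanteric",
}


def _subset_for_outcome(data: pd.DataFrame, site: str | None) -> pd.DataFrame:
    if site is None:
        return data
    keep = (~data["fracture"]) | (data["fracture_site"] == site)
    return data[keep]


def _fit_cell(sub: pd.DataFrame, predictors: list[str], adjust,
              on_separation: str = "error") -> dict:
    cols = list(adjust) + [c for c in predictors if c not in adjust]
    for c in cols:
        if sub[c].nunique() <= 1:
            raise ValueError(f"predictor {c!r} is constant in this subset")
    penalized = False
    try:
        fit = fit_logistic(sub[cols], sub["fracture"].to_numpy(dtype=int))
    except SeparationError:
        if on_separation != "ridge":
            raise
        fit = fit_logistic(sub[cols], sub["fracture"].to_numpy(dtype=int), ridge=1e-4)
        penalized = True
    lo, hi = auroc_ci(fit.fitted_probs, fit.outcome)
    return dict(
        auroc=auroc(fit.fitted_probs, fit.outcome),
        ci_low=lo,
        ci_high=hi,
        pseudo_r2=mcfadden_r2(fit),
        n_cases=fit.n_cases,
        n_controls=fit.n_controls,
        penalized=penalized,
    )


def model_comparison_table(
    data: pd.DataFrame,
    specs: dict[str, list[str]],
    adjust=DEFAULT_ADJUST,
    outcome_sets=("all", "femoral_neck", "intertrochanteric"),
    on_separation: str = "error",
) -> pd.DataFrame:
    """Model-comparison grid: one row per model spec x fracture-site subset.

    ``specs`` maps a model name to its predictor columns (beyond the
    adjustment covariates).  Site-specific subsets compare cases of that
    site against all controls; cases of unclassifiable site ("other") are
    excluded from site-specific columns.  ``on_separation='ridge'`` retries
    a perfectly separated cell with an explicit small L2 penalty and marks
    the row ``penalized`` (useful for very small cohorts, where the
    unpenalized MLE does not exist).
    """
    rows = []
    for outcome_name in outcome_sets:
        site = OUTCOME_SETS[outcome_name]
        sub = _subset_for_outcome(data, site)
        if sub["fracture"].sum() == 0 or (~sub["fracture"]).sum() == 0:
            raise ValueError(f"outcome subset {outcome_name!r} has a single class")
        for spec_name, predictors in specs.items():
            cell = _fit_cell(sub, predictors, adjust, on_separation)
            rows.append(dict(model=spec_name, outcome=outcome_name, **cell))
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class StratumSpec:
    """Femoral-neck T-score stratum: t_min < or <= T < or <= t_max.

    The three defaults partition the real line with both boundaries in the
    osteopenic stratum: normal T > -1; osteopenic -2.5 <= T <= -1;
    osteoporotic T < -2.5.
    """

    name: str
    t_min: float
    t_max: float
    closed_min: bool = True
    closed_max: bool = True

    def contains(self, t: float) -> bool:
        lower = t >= self.t_min if self.closed_min else t > self.t_min
        upper = t <= self.t_max if self.closed_max else t < self.t_max
        return lower and upper


DEFAULT_STRATA = (
    StratumSpec("normal", t_min=-1.0, t_max=np.inf, closed_min=False),
    StratumSpec("osteopenic", t_min=-2.5, t_max=-1.0),
    StratumSpec("osteoporotic", t_min=-np.inf, t_max=-2.5, closed_max=False),
)


def assign_stratum(t: float, strata=DEFAULT_STRATA) -> str | None:
    for spec in strata:
        if spec.contains(t):
            return spec.name
    return None


def stratified_auroc(
    data: pd.DataFrame,
    specs: dict[str, list[str]],
    adjust=DEFAULT_ADJUST,
    strata=DEFAULT_STRATA,
    on_separation: str = "error",
) -> pd.DataFrame:
    """Per-T-score-stratum model comparison (all-fracture outcome).

    Subjects lacking a T-score are dropped.  Strata where a model cannot be
    fitted (single class, constant predictor) are reported as not estimable
    rather than failing.
    """
    rows = []
    with_t = data[data["fn_tscore"].notna()]
    for spec in strata:
        mask = with_t["fn_tscore"].map(lambda t: assign_stratum(t, strata) == spec.name)
        sub = with_t[mask]
        n = len(sub)
        n_cases = int(sub["fracture"].sum()) if n else 0
        case_pct = round_half_up(100.0 * n_cases / n, 0) if n else np.nan
        for spec_name, predictors in specs.items():
            base = dict(
                stratum=spec.name,
                model=spec_name,
                n=n,
                n_cases=n_cases,
                case_percent=case_pct,
            )
            if n == 0 or n_cases == 0 or n_cases == n:
                rows.append(dict(**base, auroc=np.nan, ci_low=np.nan, ci_high=np.nan,
                                 pseudo_r2=np.nan, note="not_estimable"))
                continue
            try:
                cell = _fit_cell(sub, predictors, adjust, on_separation)
            except (ValueError, SeparationError) as exc:
                rows.append(dict(**base, auroc=np.nan, ci_low=np.nan, ci_high=np.nan,
                                 pseudo_r2=np.nan, note=f"not_estimable: {exc}"))
                continue
            cell.pop("n_cases"), cell.pop("n_controls")
            penalized = cell.pop("penalized")
            rows.append(dict(**base, **cell, note="penalized" if penalized else ""))
    return pd.DataFrame(rows)
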