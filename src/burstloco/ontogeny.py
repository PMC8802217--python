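"""Ontogenetic statistics: quadratic performance-mass models, vertex (peak)
estimation, growth-curve age prediction, log-log allometry, repeatability,
group comparisons, Box-Cox + one-tailed correlation, and correlation power.

Performance traits that rise through the juvenile period and decline into
adulthood are modelled as quadratics in body mass. Two levels are supported:

* ``per-trial`` - every trial enters, with a random intercept per individual
  and residual sd modelled as a linear function of body mass
  (sd = s0 * (1 + c * mass)), fit by maximum likelihood;
* ``per-peak``  - one row per individual (its maximum), fit by generalized
  least squares with the same variance function.

The mass at peak performance is the parabola vertex -b1/(2 b2); its
confidence interval comes from a case-resampling bootstrap with individuals
as the resampling unit. A cubic regression of age on the cube root of body
mass maps the vertex mass to an age in days.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from scipy.optimize import minimize, minimize_scalar

from .errors import ConvergenceError, InsufficientDataError, ValidationError

__all__ = [
    "QuadraticFit", "VertexEstimate", "GrowthModel", "AllometryFit",
    "fit_quadratic", "compare_linear_quadratic", "vertex",
    "fit_growth_model", "fit_allometry", "repeatability_icc",
    "compare_groups", "cohen_d_category", "boxcox_z", "one_tailed_pearson",
    "invert_one_tailed_p", "correlation_power", "required_n",
]


# --------------------------------------------------------------------------
# quadratic (and linear) performance-mass models
# --------------------------------------------------------------------------

@dataclass
class QuadraticFit:
    """A polynomial performance-mass fit at one analysis level.

    ``coef`` is (b0, b1[, b2]) in increasing power of mass. ``var_slope`` is
    the c of the residual-sd function s0 * (1 + c * mass); ``sigma_b`` is the
    between-individual sd (per-trial level only).
    """

    level: str                  # 'per-trial' | 'per-peak'
    degree: int
    coef: np.ndarray
    sigma0: float
    var_slope: float
    sigma_b: float
    loglik: float
    aicc: float
    r2: float
    n_obs: int
    n_groups: int
    k_params: int
    data: pd.DataFrame = field(repr=False)
    mass_col: str = "body_mass_kg"
    response_col: str = "value"
    id_col: str = "rabbit_id"

    def predict(self, mass) -> np.ndarray:
        mass = np.asarray(mass, dtype=float)
        return sum(b * mass**p for p, b in enumerate(self.coef))

    @property
    def vertex_mass(self) -> float:
        if self.degree != 2:
            raise ValidationError("vertex requires a quadratic fit")
        if self.coef[2] >= 0:
            raise ValidationError("no interior maximum: curvature >= 0")
        return float(-self.coef[1] / (2.0 * self.coef[2]))


def _aicc(loglik: float, k: int, n: int) -> float:
    aic = -2.0 * loglik + 2.0 * k
    if n - k - 1 <= 0:
        return math.inf
    return aic + 2.0 * k * (k + 1) / (n - k - 1)


def _design(mass: np.ndarray, degree: int) -> np.ndarray:
    return np.column_stack([mass**p for p in range(degree + 1)])


def _gls_profile_c(mass: np.ndarray, y: np.ndarray, degree: int):
    """Single-level GLS with residual sd s0*(1+c*mass): profile ML over c."""
    X = _design(mass, degree)
    n = len(y)
    c_lo = -0.99 / mass.max()

    def negll(c: float) -> float:
        s = 1.0 + c * mass
        if np.any(s <= 0):
            return 1e12
        w = 1.0 / s**2
        XtW = X.T * w
        beta = np.linalg.solve(XtW @ X, XtW @ y)
        r = y - X @ beta
        rss_w = float(np.sum(w * r**2))
        s0_sq = rss_w / n
        ll = (-0.5 * n * math.log(2 * math.pi * s0_sq)
              - np.log(s).sum() - 0.5 * n)
        return -ll

    res = minimize_scalar(negll, bounds=(c_lo, 100.0), method="bounded",
                          options={"xatol": 1e-8})
    c = float(res.x)
    s = 1.0 + c * mass
    w = 1.0 / s**2
    XtW = X.T * w
    beta = np.linalg.solve(XtW @ X, XtW @ y)
    r = y - X @ beta
    s0 = math.sqrt(float(np.sum(w * r**2)) / n)
    ll = -negll(c)
    r2 = 1.0 - float(np.sum(r**2)) / float(np.sum((y - y.mean())**2))
    return beta, s0, c, ll, r2


def _mixed_negll(theta: np.ndarray, X: np.ndarray, y: np.ndarray,
                 mass: np.ndarray, group_slices: list[slice],
                 fit_var_slope: bool) -> tuple[float, np.ndarray]:
    """Profile negative log-likelihood of the random-intercept model with
    heteroscedastic residuals; returns (-ll, beta-hat)."""
    log_sb, log_s0 = theta[0], theta[1]
    c = theta[2] if fit_var_slope else 0.0
    sb2 = math.exp(2.0 * log_sb)
    s0 = math.exp(log_s0)
    s = s0 * (1.0 + c * mass)
    if np.any(s <= 0):
        return 1e12, np.zeros(X.shape[1])
    d = s**2

    # Woodbury per group: V^-1 = D^-1 - sb2 D^-1 1 1' D^-1 / (1 + sb2 a)
    XtVX = np.zeros((X.shape[1], X.shape[1]))
    XtVy = np.zeros(X.shape[1])
    logdet = 0.0
    quad_terms = []
    for sl in group_slices:
        Xi, yi, di = X[sl], y[sl], d[sl]
        inv_d = 1.0 / di
        a = inv_d.sum()
        k = sb2 / (1.0 + sb2 * a)
        u = inv_d  # D^-1 1
        XtVX += (Xi.T * inv_d) @ Xi - k * np.outer(Xi.T @ u, Xi.T @ u)
        XtVy += Xi.T @ (inv_d * yi) - k * (Xi.T @ u) * float(u @ yi)
        logdet += np.log(di).sum() + math.log1p(sb2 * a)
        quad_terms.append((inv_d, k, u, sl))
    try:
        beta = np.linalg.solve(XtVX, XtVy)
    except np.linalg.LinAlgError:
        return 1e12, np.zeros(X.shape[1])
    quad = 0.0
    for inv_d, k, u, sl in quad_terms:
        ri = y[sl] - X[sl] @ beta
        quad += float(ri @ (inv_d * ri)) - k * float(u @ ri) ** 2
    n = len(y)
    ll = -0.5 * (n * math.log(2 * math.pi) + logdet + quad)
    return -ll, beta


def _fit_mixed(data: pd.DataFrame, degree: int, mass_col: str,
               response_col: str, id_col: str,
               fit_var_slope: bool = True):
    df = data.sort_values(id_col, kind="stable")
    y = df[response_col].to_numpy(dtype=float)
    mass = df[mass_col].to_numpy(dtype=float)
    X = _design(mass, degree)
    codes = pd.factorize(df[id_col])[0]
    bounds = np.flatnonzero(np.diff(codes)) + 1
    starts = np.concatenate([[0], bounds, [len(codes)]])
    slices = [slice(starts[i], starts[i + 1]) for i in range(len(starts) - 1)]

    sd_y = y.std(ddof=1) or 1.0
    x0 = [math.log(0.5 * sd_y), math.log(0.7 * sd_y)]
    if fit_var_slope:
        x0.append(0.0)

    def obj(theta):
        return _mixed_negll(np.asarray(theta), X, y, mass, slices,
                            fit_var_slope)[0]

    res = minimize(obj, x0, method="Nelder-Mead",
                   options={"xatol": 1e-8, "fatol": 1e-10, "maxiter": 4000})
    if not res.success:
        raise ConvergenceError(f"mixed fit failed: {res.message}")
    negll, beta = _mixed_negll(res.x, X, y, mass, slices, fit_var_slope)
    sb = math.exp(res.x[0])
    s0 = math.exp(res.x[1])
    c = float(res.x[2]) if fit_var_slope else 0.0
    # marginal R^2: fixed-effect variance over total (fixed + random + resid)
    var_fixed = float(np.var(X @ beta))
    mean_resid_var = float(np.mean((s0 * (1.0 + c * mass))**2))
    r2 = var_fixed / (var_fixed + sb**2 + mean_resid_var)
    return beta, s0, c, sb, -negll, r2, len(slices), len(y)


def _peaks(data: pd.DataFrame, mass_col: str, response_col: str,
           id_col: str) -> pd.DataFrame:
    """One row per individual: its maximum response."""
    idx = data.groupby(id_col)[response_col].idxmax()
    return data.loc[idx, [id_col, mass_col, response_col]].reset_index(drop=True)


def fit_quadratic(data: pd.DataFrame, level: str = "per-peak",
                  degree: int = 2, mass_col: str = "body_mass_kg",
                  response_col: str = "value",
                  id_col: str = "rabbit_id") -> QuadraticFit:
    """Fit a performance-mass polynomial at the requested level.

    ``degree=1`` gives the linear alternative used for model comparison.
    """
    if degree not in (1, 2):
        raise ValidationError("degree must be 1 or 2")
    if data[mass_col].nunique() < degree + 1:
        raise InsufficientDataError("too few distinct masses")
    if level == "per-peak":
        peaks = _peaks(data, mass_col, response_col, id_col)
        mass = peaks[mass_col].to_numpy(dtype=float)
        y = peaks[response_col].to_numpy(dtype=float)
        beta, s0, c, ll, r2 = _gls_profile_c(mass, y, degree)
        n = len(y)
        k = (degree + 1) + 2
        return QuadraticFit(level=level, degree=degree, coef=beta, sigma0=s0,
                            var_slope=c, sigma_b=0.0, loglik=ll,
                            aicc=_aicc(ll, k, n), r2=r2, n_obs=n, n_groups=n,
                            k_params=k, data=data, mass_col=mass_col,
                            response_col=response_col, id_col=id_col)
    if level == "per-trial":
        counts = data.groupby(id_col).size()
        if (counts >= 2).sum() < 2:
            raise InsufficientDataError(
                "per-trial level needs >= 2 individuals with >= 2 trials")
        beta, s0, c, sb, ll, r2, n_groups, n_obs = _fit_mixed(
            data, degree, mass_col, response_col, id_col)
        k = (degree + 1) + 3
        return QuadraticFit(level=level, degree=degree, coef=beta, sigma0=s0,
                            var_slope=c, sigma_b=sb, loglik=ll,
                            aicc=_aicc(ll, k, n_obs), r2=r2, n_obs=n_obs,
                            n_groups=n_groups, k_params=k, data=data,
                            mass_col=mass_col, response_col=response_col,
                            id_col=id_col)
    raise ValidationError(f"unknown level '{level}'")


def compare_linear_quadratic(data: pd.DataFrame, level: str = "per-peak",
                             **kw) -> tuple[QuadraticFit, QuadraticFit]:
    """Fit both polynomial degrees for AICc model comparison."""
    return (fit_quadratic(data, level=level, degree=1, **kw),
            fit_quadratic(data, level=level, degree=2, **kw))


# --------------------------------------------------------------------------
# vertex (peak performance) estimation
# --------------------------------------------------------------------------

@dataclass
class VertexEstimate:
    """Mass (and optionally age) at peak performance with bootstrap CIs."""

    peak_mass_kg: float
    ci_mass_kg: tuple[float, float]
    peak_age_days: float | None
    ci_age_days: tuple[float, float] | None
    n_boot_valid: int
    boot_masses: np.ndarray = field(repr=False)


def vertex(fit: QuadraticFit, growth: "GrowthModel | None" = None,
           n_boot: int = 2000, seed: int = 0) -> VertexEstimate:
    """Vertex mass -b1/(2 b2) with a case-resampling bootstrap CI.

    Individuals are the resampling unit; each bootstrap cohort is refit at
    the same level and its vertex recorded; the CI is the 2.5-97.5 percentile
    interval. Draws whose refit lacks an interior maximum are discarded
    (counted in ``n_boot_valid``).
    """
    point = fit.vertex_mass
    rng = np.random.default_rng(seed)
    boot = []
    if fit.level == "per-peak":
        # fast path: one row per individual, resample rows directly
        peaks = _peaks(fit.data, fit.mass_col, fit.response_col, fit.id_col)
        mass = peaks[fit.mass_col].to_numpy(dtype=float)
        y = peaks[fit.response_col].to_numpy(dtype=float)
        n = len(y)
        for _ in range(n_boot):
            pick = rng.integers(0, n, n)
            try:
                beta = _gls_profile_c(mass[pick], y[pick], 2)[0]
            except np.linalg.LinAlgError:
                continue
            if beta[2] < 0:
                boot.append(float(-beta[1] / (2.0 * beta[2])))
    else:
        ids = fit.data[fit.id_col].unique()
        blocks = {rid: fit.data[fit.data[fit.id_col] == rid] for rid in ids}
        for _ in range(n_boot):
            pick = rng.choice(ids, size=len(ids), replace=True)
            parts = []
            for j, rid in enumerate(pick):
                block = blocks[rid].copy()
                block[fit.id_col] = f"b{j}"
                parts.append(block)
            bdata = pd.concat(parts, ignore_index=True)
            try:
                bfit = fit_quadratic(bdata, level=fit.level, degree=2,
                                     mass_col=fit.mass_col,
                                     response_col=fit.response_col,
                                     id_col=fit.id_col)
                if bfit.coef[2] < 0:
                    boot.append(bfit.vertex_mass)
            except (ValidationError, InsufficientDataError, ConvergenceError):
                continue
    boot = np.asarray(boot)
    if boot.size < max(20, n_boot // 10):
        warnings.warn("fewer than 10% of bootstrap refits had an interior "
                      "maximum; CI unreliable", stacklevel=2)
    ci = (float(np.percentile(boot, 2.5)), float(np.percentile(boot, 97.5)))
    age = ages_ci = None
    if growth is not None:
        age = float(growth.predict_age(point))
        boot_ages = growth.predict_age(boot)
        ages_ci = (float(np.percentile(boot_ages, 2.5)),
                   float(np.percentile(boot_ages, 97.5)))
    return VertexEstimate(peak_mass_kg=point, ci_mass_kg=ci,
                          peak_age_days=age, ci_age_days=ages_ci,
                          n_boot_valid=int(boot.size), boot_masses=boot)


# --------------------------------------------------------------------------
# growth model: age from body mass
# --------------------------------------------------------------------------

@dataclass
class GrowthModel:
    """Cubic regression of age (days) on the cube root of body mass (kg)."""

    coef: np.ndarray          # order 0..3 in u = mass^(1/3)
    mae: float
    rmse: float
    mass_range_kg: tuple[float, float]
    monotone: bool
    _ols: object = field(repr=False, default=None)

    def predict_age(self, mass_kg) -> np.ndarray:
        mass_kg = np.asarray(mass_kg, dtype=float)
        lo, hi = self.mass_range_kg
        if np.any(mass_kg < lo) or np.any(mass_kg > hi):
            warnings.warn("predicting age outside the reference mass range",
                          stacklevel=2)
        u = np.cbrt(mass_kg)
        return sum(b * u**p for p, b in enumerate(self.coef))

    def prediction_interval(self, mass_kg, alpha: float = 0.05):
        u = np.cbrt(np.atleast_1d(np.asarray(mass_kg, dtype=float)))
        Xn = np.column_stack([u**p for p in range(4)])
        pred = self._ols.get_prediction(Xn)
        return pred.conf_int(obs=True, alpha=alpha)


def fit_growth_model(reference: pd.DataFrame, age_col: str = "age_days",
                     mass_col: str = "body_mass_kg") -> GrowthModel:
    """Least-squares cubic of age on mass^(1/3) from a reference table."""
    if len(reference) < 5:
        raise InsufficientDataError("need >= 5 reference points")
    u = np.cbrt(reference[mass_col].to_numpy(dtype=float))
    age = reference[age_col].to_numpy(dtype=float)
    X = np.column_stack([u**p for p in range(4)])
    ols = sm.OLS(age, X).fit()
    pred = ols.fittedvalues
    resid = age - pred
    # monotonicity of the fitted cubic over the reference range
    ugrid = np.linspace(u.min(), u.max(), 200)
    dage = ols.params[1] + 2 * ols.params[2] * ugrid + 3 * ols.params[3] * ugrid**2
    monotone = bool(np.all(dage > 0))
    if not monotone:
        warnings.warn("fitted growth curve is not monotone over the "
                      "reference range; age predictions may be ambiguous",
                      stacklevel=2)
    return GrowthModel(
        coef=np.asarray(ols.params), mae=float(np.mean(np.abs(resid))),
        rmse=float(np.sqrt(np.mean(resid**2))),
        mass_range_kg=(float(reference[mass_col].min()),
                       float(reference[mass_col].max())),
        monotone=monotone, _ols=ols)


# --------------------------------------------------------------------------
# allometry
# --------------------------------------------------------------------------

GEOMETRIC_SIMILARITY_EXPONENT = 1.00
MECHANICAL_SIMILARITY_EXPONENT = 4.0 / 3.0


@dataclass
class AllometryFit:
    """Log-log power-law fit y = coefficient * mass^exponent."""

    coefficient: float
    exponent: float
    exponent_ci: tuple[float, float]
    r2: float
    n: int
    infinite_ci: bool
    verdicts: dict[str, str]


def fit_allometry(values, masses) -> AllometryFit:
    """OLS of log10(value) on log10(mass) with similarity verdicts.

    Verdicts state whether the 95% CI of the exponent contains the
    geometric-similarity (1.00) and mechanical-similarity (1.33) nulls.
    """
    y = np.asarray(values, dtype=float)
    m = np.asarray(masses, dtype=float)
    if np.any(y <= 0) or np.any(m <= 0):
        raise ValidationError("allometry requires strictly positive values")
    if len(y) < 2:
        raise InsufficientDataError("need >= 2 points")
    X = sm.add_constant(np.log10(m))
    ols = sm.OLS(np.log10(y), X).fit()
    exponent = float(ols.params[1])
    infinite = ols.df_resid < 1
    if infinite:
        ci = (-math.inf, math.inf)
    else:
        ci_arr = ols.conf_int(alpha=0.05)
        ci = (float(ci_arr[1, 0]), float(ci_arr[1, 1]))
    verdicts = {}
    for label, null in (("geometric_1.00", GEOMETRIC_SIMILARITY_EXPONENT),
                        ("mechanical_1.33", MECHANICAL_SIMILARITY_EXPONENT)):
        verdicts[label] = ("consistent" if ci[0] <= null <= ci[1]
                           else "excluded")
    if len(y) <= 2 or np.var(np.log10(y)) == 0:
        r2 = 1.0 if float(ols.ssr) < 1e-20 else 0.0
    else:
        r2 = float(ols.rsquared)
    return AllometryFit(coefficient=float(10.0**ols.params[0]),
                        exponent=exponent, exponent_ci=ci,
                        r2=r2, n=len(y), infinite_ci=bool(infinite),
                        verdicts=verdicts)


# --------------------------------------------------------------------------
# repeatability (ICC)
# --------------------------------------------------------------------------

def _icc_ml(y: np.ndarray, codes: np.ndarray) -> tuple[float, float, float]:
    """ML variance components of the intercept-only random-intercept model.

    Profiles the within-group variance and the grand mean; optimizes the
    variance ratio sb^2/sw^2 on a log grid refined by bounded search.
    Returns (icc, sb2, sw2).
    """
    n = len(y)
    groups = [y[codes == g] for g in np.unique(codes)]
    n_i = np.array([len(g) for g in groups])
    sums = np.array([g.sum() for g in groups])
    ss = float(sum((g**2).sum() for g in groups))

    def negll(log_lam: float) -> float:
        lam = math.exp(log_lam)
        w = 1.0 / (1.0 + n_i * lam)
        denom = float((n_i * w).sum())
        mu = float((sums * w).sum()) / denom
        # quadratic form y'V^-1 y with V = sw2 (I + lam J) per group
        quad = ss - 2 * mu * float(sums.sum()) + n * mu**2 \
            - float((lam * w * (sums - n_i * mu)**2).sum())
        sw2 = quad / n
        if sw2 <= 0:
            return 1e12
        ll = -0.5 * (n * math.log(2 * math.pi * sw2)
                     + float(np.log(1.0 + n_i * lam).sum()) + n)
        return -ll

    res = minimize_scalar(negll, bounds=(-12.0, 8.0), method="bounded",
                          options={"xatol": 1e-9})
    lam = math.exp(float(res.x))
    # recover sw2 at the optimum
    w = 1.0 / (1.0 + n_i * lam)
    denom = float((n_i * w).sum())
    mu = float((sums * w).sum()) / denom
    quad = ss - 2 * mu * float(sums.sum()) + n * mu**2 \
        - float((lam * w * (sums - n_i * mu)**2).sum())
    sw2 = quad / n
    sb2 = lam * sw2
    return sb2 / (sb2 + sw2), sb2, sw2


def repeatability_icc(trials: pd.DataFrame, n_boot: int = 500, seed: int = 0,
                      value_col: str = "value",
                      id_col: str = "rabbit_id"):
    """Intraclass correlation from a random-intercept model, with a
    parametric-bootstrap percentile CI.

    ICC = between-individual variance / total variance; the bootstrap
    simulates new datasets from the fitted variance components on the
    observed design and refits each.
    Returns (icc, (lo, hi)).
    """
    codes, uniques = pd.factorize(trials[id_col])
    counts = np.bincount(codes)
    if (counts >= 2).sum() < 2:
        raise InsufficientDataError(
            "repeatability needs >= 2 individuals with >= 2 trials")
    y = trials[value_col].to_numpy(dtype=float)
    icc, sb2, sw2 = _icc_ml(y, codes)
    if n_boot <= 0:
        return icc, (math.nan, math.nan)
    rng = np.random.default_rng(seed)
    n_groups = len(uniques)
    boot = np.empty(n_boot)
    for b in range(n_boot):
        intercepts = rng.normal(0.0, math.sqrt(sb2), n_groups)
        y_sim = intercepts[codes] + rng.normal(0.0, math.sqrt(sw2), len(y))
        boot[b] = _icc_ml(y_sim, codes)[0]
    ci = (float(np.percentile(boot, 2.5)), float(np.percentile(boot, 97.5)))
    return icc, ci


# --------------------------------------------------------------------------
# group comparison, transforms, correlation, power
# --------------------------------------------------------------------------

#: effect-size categories (lower bound of |d| -> label)
COHEN_D_CATEGORIES = [
    (2.0, "huge"), (1.2, "very large"), (0.8, "large"),
    (0.5, "moderate"), (0.2, "small"), (0.0, "very small"),
]


def cohen_d_category(d: float) -> str:
    for bound, label in COHEN_D_CATEGORIES:
        if abs(d) >= bound:
            return label
    return "very small"


def compare_groups(a, b):
    """Welch's t-test plus Cohen's d (pooled sd) with its category.

    Returns (t, p, d, category).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise InsufficientDataError("each group needs n >= 2")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0 and vb == 0:
        if a.mean() == b.mean():
            return 0.0, 1.0, 0.0, "very small"
        raise ValidationError("zero variance in both groups: d undefined")
    t, p = stats.ttest_ind(a, b, equal_var=False)
    pooled = math.sqrt(((len(a) - 1) * va + (len(b) - 1) * vb)
                       / (len(a) + len(b) - 2))
    d = float((a.mean() - b.mean()) / pooled)
    return float(t), float(p), d, cohen_d_category(d)


def boxcox_z(values, lambda_grid=None):
    """Box-Cox transform (grid profile ML) followed by z-scoring.

    The transform parameter is chosen on a fixed grid from -2 to 2 in steps
    of 0.01 by profile log-likelihood; the transformed values are
    standardized to mean 0 and sd 1 (n-1 denominator).
    Returns (z, lambda).
    """
    x = np.asarray(values, dtype=float)
    if np.any(x <= 0):
        raise ValidationError("Box-Cox requires strictly positive values")
    if x.std(ddof=1) == 0 or len(x) < 3:
        raise ValidationError("degenerate input: no variance to transform")
    grid = (np.arange(-200, 201) / 100.0 if lambda_grid is None
            else np.asarray(lambda_grid, dtype=float))
    llf = np.array([stats.boxcox_llf(lam, x) for lam in grid])
    lam = float(grid[np.argmax(llf)])
    y = stats.boxcox(x, lmbda=lam)
    z = (y - y.mean()) / y.std(ddof=1)
    return z, lam


def one_tailed_pearson(x, y):
    """Pearson r with a one-tailed p for a positive association.

    Returns (r, p) with p = P(T >= t), t = r sqrt((n-2)/(1-r^2)), df = n-2.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 4:
        raise InsufficientDataError("need n >= 4 pairs")
    if x.std() == 0 or y.std() == 0:
        raise ValidationError("zero variance: correlation undefined")
    res = stats.pearsonr(x, y, alternative="greater")
    return float(res.statistic), float(res.pvalue)


def invert_one_tailed_p(p: float, n: int) -> float:
    """The positive r whose one-tailed test at sample size n yields p."""
    if not 0 < p < 1:
        raise ValidationError("p must be in (0, 1)")
    if n < 4:
        raise InsufficientDataError("need n >= 4")
    t = stats.t.isf(p, n - 2)
    return float(t / math.sqrt(t**2 + n - 2))


def correlation_power(r: float, n: int, alpha: float = 0.05) -> float:
    """Power of the one-tailed Pearson test via the Fisher-z approximation:
    power = Phi(atanh(r) sqrt(n-3) - z_{1-alpha})."""
    if not abs(r) < 1:
        raise ValidationError("|r| must be < 1")
    if n < 4:
        raise InsufficientDataError("need n >= 4")
    zr = math.atanh(r)
    return float(stats.norm.cdf(zr * math.sqrt(n - 3)
                                - stats.norm.isf(alpha)))


def required_n(r: float, power_target: float = 0.8,
               alpha: float = 0.05) -> int:
    """Smallest n whose Fisher-z power reaches ``power_target``."""
    if r == 0 and power_target > alpha:
        raise ValidationError("power target unreachable at r = 0")
    if not 0 < power_target < 1:
        raise ValidationError("power target must be in (0, 1)")
    zr = abs(math.atanh(r))
    za = stats.norm.isf(alpha)
    zb = stats.norm.isf(1.0 - power_target)
    n = math.ceil(((za + zb) / zr) ** 2 + 3)
    while correlation_power(abs(r), n, alpha) < power_target:  # ceiling guard
        n += 1
    return int(n)
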