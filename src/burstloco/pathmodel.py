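"""Recursive path analysis: standardized coefficients, fit indices, pruning.

The model of interest is the determinants-of-acceleration structure: body
mass and hindlimb muscle power capacity (correlated exogenous variables)
drive COM mechanical power, which together with body mass drives mean
acceleration. All variables are z-scored, so single-headed coefficients are
beta-weights and double-headed ones correlations.

Fitting minimizes the normal-theory ML discrepancy

    F(theta) = log|Sigma(theta)| + tr(S Sigma^-1) - log|S| - p

between the sample covariance S (n-1 denominator) and the model-implied
covariance Sigma = (I-B)^-1 Psi (I-B)^-T. For recursive (acyclic) models the
optimum coincides with per-equation least squares, which is used both for
starting values and as an internal cross-check. chi^2 = (n-1) F_min is
referred against the saturated model; CFI uses the independence baseline;
RMSEA = sqrt(max(chi^2 - df, 0) / (df (n-1))).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import minimize

from .errors import ConvergenceError, ValidationError

__all__ = ["PathSpec", "PathFit", "standardize", "fit_path", "prune",
           "acceleration_path_spec"]


@dataclass(frozen=True)
class PathSpec:
    """A recursive path model: directed edges plus exogenous covariances."""

    variables: tuple[str, ...]
    edges: tuple[tuple[str, str], ...]              # (from, to)
    covariances: tuple[tuple[str, str], ...] = ()   # among exogenous vars

    def __post_init__(self) -> None:
        for a, b in self.edges:
            if a not in self.variables or b not in self.variables:
                raise ValidationError(f"edge ({a}, {b}) uses unknown variable")
        if self._has_cycle():
            raise ValidationError("path model must be recursive (acyclic)")
        endo = self.endogenous
        for a, b in self.covariances:
            if a in endo or b in endo:
                raise ValidationError(
                    f"covariance ({a}, {b}) involves an endogenous variable")

    @property
    def endogenous(self) -> tuple[str, ...]:
        targets = {b for _, b in self.edges}
        return tuple(v for v in self.variables if v in targets)

    @property
    def exogenous(self) -> tuple[str, ...]:
        endo = set(self.endogenous)
        return tuple(v for v in self.variables if v not in endo)

    def _has_cycle(self) -> bool:
        adj: dict[str, list[str]] = {v: [] for v in self.variables}
        for a, b in self.edges:
            adj[a].append(b)
        state: dict[str, int] = {}

        def visit(v: str) -> bool:
            state[v] = 1
            for w in adj[v]:
                if state.get(w) == 1 or (state.get(w) is None and visit(w)):
                    return True
            state[v] = 2
            return False

        return any(state.get(v) is None and visit(v) for v in self.variables)

    @property
    def n_free(self) -> int:
        """Free parameters: edges + endogenous residual variances +
        exogenous variances + listed exogenous covariances."""
        return (len(self.edges) + len(self.endogenous)
                + len(self.exogenous) + len(self.covariances))


def acceleration_path_spec(power_var: str = "p_com") -> PathSpec:
    """The determinants-of-acceleration model: M_b, P_musc -> P_COM;
    P_COM, M_b -> a_COM; M_b correlated with P_musc."""
    return PathSpec(
        variables=("body_mass", "p_musc", power_var, "a_com"),
        edges=(("body_mass", power_var), ("p_musc", power_var),
               (power_var, "a_com"), ("body_mass", "a_com")),
        covariances=(("body_mass", "p_musc"),),
    )


def standardize(data: pd.DataFrame) -> pd.DataFrame:
    """z-score every column (n-1 denominator)."""
    out = {}
    for col in data.columns:
        x = data[col].to_numpy(dtype=float)
        sd = x.std(ddof=1)
        if not sd > 0:
            raise ValidationError(f"column '{col}' has no variance")
        out[col] = (x - x.mean()) / sd
    return pd.DataFrame(out, index=data.index)


@dataclass
class PathFit:
    """Fitted path model: standardized estimates and global fit indices."""

    spec: PathSpec
    coefficients: dict[tuple[str, str], float]
    std_errors: dict[tuple[str, str], float]
    p_values: dict[tuple[str, str], float]
    residual_variances: dict[str, float]
    exo_params: dict[tuple[str, str], float]
    r2: dict[str, float]
    chi2: float
    df: int
    p_value: float
    rmsea: float
    cfi: float
    implied: pd.DataFrame
    n: int
    f_min: float
    loglik_converged: bool = True


def _implied_cov(spec: PathSpec, order: list[str], coef: np.ndarray,
                 psi_diag: np.ndarray, exo_cov: np.ndarray) -> np.ndarray:
    p = len(order)
    idx = {v: i for i, v in enumerate(order)}
    B = np.zeros((p, p))
    for (a, b), val in zip(spec.edges, coef):
        B[idx[b], idx[a]] = val
    Psi = np.zeros((p, p))
    exo = list(spec.exogenous)
    for i, v in enumerate(exo):
        Psi[idx[v], idx[v]] = exo_cov[i, i]
    for i, a in enumerate(exo):
        for j, b in enumerate(exo):
            if i != j:
                Psi[idx[a], idx[b]] = exo_cov[i, j]
    for v, val in zip(spec.endogenous, psi_diag):
        Psi[idx[v], idx[v]] = val
    inv = np.linalg.inv(np.eye(p) - B)
    return inv @ Psi @ inv.T


def _pack(spec: PathSpec):
    """Parameter layout: edges, endo residual vars, exo vars, exo covs."""
    n_e = len(spec.edges)
    n_d = len(spec.endogenous)
    n_x = len(spec.exogenous)
    n_c = len(spec.covariances)
    exo_index = {v: i for i, v in enumerate(spec.exogenous)}

    def unpack(theta: np.ndarray):
        coef = theta[:n_e]
        psi = theta[n_e:n_e + n_d]
        exo_var = theta[n_e + n_d:n_e + n_d + n_x]
        covs = theta[n_e + n_d + n_x:]
        exo_cov = np.diag(exo_var.astype(float))
        for (a, b), val in zip(spec.covariances, covs):
            exo_cov[exo_index[a], exo_index[b]] = val
            exo_cov[exo_index[b], exo_index[a]] = val
        return coef, psi, exo_cov

    return n_e + n_d + n_x + n_c, unpack


def _ols_start(spec: PathSpec, S: pd.DataFrame) -> np.ndarray:
    """Per-equation least squares from the sample covariance matrix."""
    theta = []
    for a, b in spec.edges:
        preds = [x for x, y in spec.edges if y == b]
        Sxx = S.loc[preds, preds].to_numpy()
        sxy = S.loc[preds, b].to_numpy()
        beta = np.linalg.solve(Sxx, sxy)
        theta.append(beta[preds.index(a)])
    for v in spec.endogenous:
        preds = [x for x, y in spec.edges if y == v]
        Sxx = S.loc[preds, preds].to_numpy()
        sxy = S.loc[preds, v].to_numpy()
        beta = np.linalg.solve(Sxx, sxy)
        theta.append(float(S.loc[v, v] - sxy @ beta))
    for v in spec.exogenous:
        theta.append(float(S.loc[v, v]))
    for a, b in spec.covariances:
        theta.append(float(S.loc[a, b]))
    return np.asarray(theta)


def fit_path(spec: PathSpec, data: pd.DataFrame) -> PathFit:
    """Fit a recursive path model by ML to (preferably z-scored) data."""
    order = list(spec.variables)
    missing = [v for v in order if v not in data.columns]
    if missing:
        raise ValidationError(f"data missing variables {missing}")
    n = len(data)
    if n <= spec.n_free:
        raise ValidationError("need n > number of free parameters")
    X = data[order].to_numpy(dtype=float)
    S = np.cov(X, rowvar=False, ddof=1)
    eigmin = np.linalg.eigvalsh(S).min()
    if eigmin <= 0:
        raise ValidationError("sample covariance not positive definite")
    S_df = pd.DataFrame(S, index=order, columns=order)
    p = len(order)
    sign, logdet_S = np.linalg.slogdet(S)

    n_theta, unpack = _pack(spec)

    def discrepancy(theta: np.ndarray) -> float:
        coef, psi, exo_cov = unpack(theta)
        if np.any(psi <= 0) or np.any(np.diag(exo_cov) <= 0):
            return 1e10
        Sigma = _implied_cov(spec, order, coef, psi, exo_cov)
        s, logdet = np.linalg.slogdet(Sigma)
        if s <= 0:
            return 1e10
        try:
            trace = float(np.trace(S @ np.linalg.inv(Sigma)))
        except np.linalg.LinAlgError:
            return 1e10
        return logdet + trace - logdet_S - p

    theta0 = _ols_start(spec, S_df)
    res = minimize(discrepancy, theta0, method="BFGS",
                   options={"gtol": 1e-12, "maxiter": 2000})
    # BFGS may report line-search failure at an already-optimal start
    theta = res.x if res.fun <= discrepancy(theta0) else theta0
    f_min = float(min(res.fun, discrepancy(theta0)))
    if f_min >= 1e9:
        raise ConvergenceError(
            f"path fit failed; last gradient norm "
            f"{np.linalg.norm(getattr(res, 'jac', np.nan)):.3g}")

    coef, psi, exo_cov = unpack(theta)

    # asymptotic SEs from the numerical Hessian of the discrepancy:
    # acov(theta) = (2 / (n-1)) H^-1
    eps = 1e-5
    H = np.zeros((n_theta, n_theta))
    f0 = discrepancy(theta)
    for i in range(n_theta):
        for j in range(i, n_theta):
            ei = np.zeros(n_theta); ei[i] = eps
            ej = np.zeros(n_theta); ej[j] = eps
            fij = discrepancy(theta + ei + ej)
            fi = discrepancy(theta + ei)
            fj = discrepancy(theta + ej)
            H[i, j] = H[j, i] = (fij - fi - fj + f0) / eps**2
    try:
        acov = 2.0 / (n - 1) * np.linalg.inv(H)
        ses = np.sqrt(np.clip(np.diag(acov), 0.0, None))
    except np.linalg.LinAlgError:
        ses = np.full(n_theta, np.nan)

    coefficients, std_errors, p_values = {}, {}, {}
    for k, edge in enumerate(spec.edges):
        coefficients[edge] = float(coef[k])
        std_errors[edge] = float(ses[k])
        z = coef[k] / ses[k] if ses[k] > 0 else math.inf
        p_values[edge] = float(2.0 * stats.norm.sf(abs(z)))

    residual_variances = {v: float(psi[i])
                          for i, v in enumerate(spec.endogenous)}
    exo_params = {}
    for i, v in enumerate(spec.exogenous):
        exo_params[(v, v)] = float(exo_cov[i, i])
    exo_idx = {v: i for i, v in enumerate(spec.exogenous)}
    for a, b in spec.covariances:
        exo_params[(a, b)] = float(exo_cov[exo_idx[a], exo_idx[b]])

    Sigma = _implied_cov(spec, order, coef, psi, exo_cov)
    implied = pd.DataFrame(Sigma, index=order, columns=order)
    r2 = {v: float(1.0 - residual_variances[v] / Sigma[order.index(v),
                                                       order.index(v)])
          for v in spec.endogenous}

    df_model = p * (p + 1) // 2 - spec.n_free
    chi2 = max((n - 1) * f_min, 0.0)
    p_chi2 = float(stats.chi2.sf(chi2, df_model)) if df_model > 0 else 1.0
    rmsea = (math.sqrt(max(chi2 - df_model, 0.0) / (df_model * (n - 1)))
             if df_model > 0 else 0.0)

    # independence baseline: diagonal Sigma with sample variances
    f_base = float(np.log(np.diag(S)).sum() - logdet_S)
    chi2_base = max((n - 1) * f_base, 0.0)
    df_base = p * (p - 1) // 2
    denom = max(chi2_base - df_base, chi2 - df_model, 0.0)
    cfi = 1.0 if denom == 0 else 1.0 - max(chi2 - df_model, 0.0) / denom
    cfi = float(min(max(cfi, 0.0), 1.0))

    return PathFit(spec=spec, coefficients=coefficients,
                   std_errors=std_errors, p_values=p_values,
                   residual_variances=residual_variances,
                   exo_params=exo_params, r2=r2, chi2=float(chi2),
                   df=int(df_model), p_value=p_chi2, rmsea=float(rmsea),
                   cfi=cfi, implied=implied, n=n, f_min=f_min,
                   loglik_converged=bool(res.success or f_min < 1e9))


def prune(spec: PathSpec, data: pd.DataFrame,
          alpha: float = 0.05) -> tuple[PathSpec, PathFit, list]:
    """Iteratively drop the least-significant edge with p > alpha and refit.

    One edge is removed per iteration (determinism); if an endogenous
    variable loses its last incoming edge it is dropped from the model with
    a warning. Returns (pruned spec, final fit, removal log).
    """
    removed: list[tuple[str, str, float]] = []
    current = spec
    while True:
        fit = fit_path(current, data)
        weak = {e: p for e, p in fit.p_values.items() if p > alpha}
        if not weak:
            return current, fit, removed
        edge = max(weak, key=weak.get)
        removed.append((edge[0], edge[1], weak[edge]))
        new_edges = tuple(e for e in current.edges if e != edge)
        orphan = {b for _, b in current.edges} - {b for _, b in new_edges}
        variables = current.variables
        covariances = current.covariances
        if orphan:
            warnings.warn(f"variable(s) {sorted(orphan)} lost all incoming "
                          "paths and were dropped from the model",
                          stacklevel=2)
            variables = tuple(v for v in variables if v not in orphan)
            new_edges = tuple((a, b) for a, b in new_edges
                              if a not in orphan and b not in orphan)
            covariances = tuple((a, b) for a, b in covariances
                                if a not in orphan and b not in orphan)
        current = PathSpec(variables=variables, edges=new_edges,
                           covariances=covariances)
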