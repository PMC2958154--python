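"""Binomial logit mixed models with an area random intercept.

The marginal likelihood of the logistic model with independent Gaussian
area intercepts (and optionally independent Gaussian area slopes on a
centred year trend) is maximised under the Laplace approximation.  The
inner problem — the conditional mode of the random effects — factorises by
area and is solved by a vectorised Newton iteration; the outer problem
optimises (log sigma, beta) by L-BFGS with an analytic gradient in the
random-intercept case.

Conventions:

* age, race and (fixed) year enter as treatment contrasts against the
  configured reference levels (earliest training year for year);
* area-level covariates are standardised internally for optimizer
  conditioning and all estimates are reported on the original scale;
* model fitting is unweighted — poststratification weights are used only
  by the direct estimator.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import expit

from .schema import (
    DEFAULT_SCHEMA,
    CountyTable,
    DemographicSchema,
    EstimationError,
    SeparationError,
    SchemaError,
)

__all__ = ["ModelSpec", "FittedModel", "fit", "predict_linear", "cell_design"]

logger = logging.getLogger("saeval")

FAMILIES = ("naive", "geospatial", "covariate", "full")

_PHI_LO, _PHI_HI = np.log(1e-4), np.log(10.0)
_SEPARATION_LIMIT = 12.0  # |standardised coefficient| beyond which we flag separation


@dataclass(frozen=True)
class ModelSpec:
    """One of the four model families plus its specification switches."""

    family: str = "naive"
    include_race: bool = True
    year_effect: str = "fixed"
    sex: str | None = None

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}")
        if self.year_effect not in ("fixed", "random"):
            raise ValueError(f"unknown year_effect {self.year_effect!r}")

    @property
    def uses_covariates(self) -> bool:
        return self.family in ("covariate", "full")

    @property
    def uses_spatial(self) -> bool:
        return self.family in ("geospatial", "full")

    def label(self) -> str:
        race = "race" if self.include_race else "norace"
        return f"{self.family}-{race}-{self.year_effect}year"


@dataclass
class _DesignInfo:
    names: list[str]
    ref_year: int
    train_years: tuple[int, ...]
    year_center: float
    z_names: list[str]
    include_race: bool
    year_effect: str
    schema: DemographicSchema


@dataclass
class FittedModel:
    """Result of a Laplace fit: fixed effects, random-effect posteriors, diagnostics."""

    spec: ModelSpec
    fixed_effects: pd.Series
    fixed_cov: pd.DataFrame
    sigma_delta: float
    ranef_mean: pd.Series
    ranef_var: pd.Series
    loglik: float
    converged: bool
    n_used: int
    design: _DesignInfo
    sigma_year: float | None = None
    ranef_year_mean: pd.Series | None = None
    ranef_year_var: pd.Series | None = None
    ranef_cross_cov: pd.Series | None = None
    spatial_base: str | None = None  # which family produced the spatial covariate
    log_sigma_se: float = float("nan")  # SE of log sigma_delta (Wald, delta method)

    def sigma_delta_ci(self, level: float = 0.95) -> tuple[float, float]:
        """Wald interval for sigma_delta on the log scale."""
        from scipy.stats import norm

        z = norm.ppf(0.5 + level / 2.0)
        if not np.isfinite(self.log_sigma_se):
            return (float("nan"), float("nan"))
        lo = self.sigma_delta * np.exp(-z * self.log_sigma_se)
        hi = self.sigma_delta * np.exp(z * self.log_sigma_se)
        return (float(lo), float(hi))

    def wald_ci(self, term: str, level: float = 0.95) -> tuple[float, float]:
        """Wald interval for one fixed effect."""
        from scipy.stats import norm

        z = norm.ppf(0.5 + level / 2.0)
        est = float(self.fixed_effects[term])
        se = float(np.sqrt(self.fixed_cov.loc[term, term]))
        return (est - z * se, est + z * se)

    def summary(self) -> pd.DataFrame:
        se = pd.Series(
            np.sqrt(np.diag(self.fixed_cov.to_numpy())), index=self.fixed_effects.index
        )
        return pd.DataFrame(
            {"coef": self.fixed_effects, "se": se, "z": self.fixed_effects / se}
        )


# ---------------------------------------------------------------------------
# design construction
# ---------------------------------------------------------------------------

def _build_design(
    records: pd.DataFrame,
    spec: ModelSpec,
    counties: CountyTable | None,
    spatial_covariate: Mapping[str, float] | None,
    schema: DemographicSchema,
) -> tuple[np.ndarray, np.ndarray, _DesignInfo]:
    """Raw-scale fixed-effect design matrix, year-trend values, and metadata."""
    n = len(records)
    train_years = tuple(sorted(records["survey_year"].unique()))
    ref_year = train_years[0]
    year_center = float(np.mean(train_years))
    year_effect = spec.year_effect if len(train_years) > 1 else "fixed"

    cols: list[np.ndarray] = [np.ones(n)]
    names: list[str] = ["intercept"]

    age = records["age_group"].to_numpy()
    for g in schema.nonref_ages:
        cols.append((age == g).astype(float))
        names.append(f"age:{g}")
    if spec.include_race:
        race = records["race_group"].to_numpy()
        for g in schema.nonref_races:
            cols.append((race == g).astype(float))
            names.append(f"race:{g}")

    yr = records["survey_year"].to_numpy()
    t = yr - year_center
    if year_effect == "fixed":
        for y in train_years[1:]:
            cols.append((yr == y).astype(float))
            names.append(f"year:{y}")
    else:
        cols.append(t.astype(float))
        names.append("year_trend")

    z_names: list[str] = []
    if spec.uses_covariates:
        if counties is None:
            raise EstimationError(f"{spec.family} model requires a county table")
        zdf = counties.Z.reindex(records["area_id"])
        if zdf.isna().any().any():
            missing = sorted(set(records["area_id"]) - set(counties.Z.index))
            raise SchemaError(f"areas missing from county table: {missing[:5]}")
        for name in counties.Z.columns:
            cols.append(zdf[name].to_numpy(dtype=float))
            names.append(f"z:{name}")
            z_names.append(f"z:{name}")
    if spec.uses_spatial:
        if spatial_covariate is None:
            raise EstimationError(f"{spec.family} model requires a spatial covariate")
        vals = records["area_id"].map(lambda a: float(spatial_covariate.get(a, 0.0)))
        cols.append(vals.to_numpy(dtype=float))
        names.append("spatial")

    X = np.column_stack(cols)
    info = _DesignInfo(
        names=names,
        ref_year=ref_year,
        train_years=train_years,
        year_center=year_center,
        z_names=z_names,
        include_race=spec.include_race,
        year_effect=year_effect,
        schema=schema,
    )
    return X, t.astype(float), info


def _check_separation(beta_std: np.ndarray, names: list[str]) -> None:
    worst = int(np.argmax(np.abs(beta_std)))
    if abs(beta_std[worst]) > _SEPARATION_LIMIT:
        raise SeparationError(names[worst])


# ---------------------------------------------------------------------------
# inner problem: conditional modes of the random effects
# ---------------------------------------------------------------------------

def _bernoulli_loglik(y: np.ndarray, eta: np.ndarray) -> float:
    return float(np.dot(y, eta) - np.logaddexp(0.0, eta).sum())


def _inner_mode_k1(
    y: np.ndarray,
    eta_fix: np.ndarray,
    a: np.ndarray,
    q: int,
    sig2: float,
    delta0: np.ndarray,
    tol: float = 1e-11,
    max_iter: int = 100,
):
    """Per-area Newton for the conditional mode of the random intercepts."""
    delta = delta0.copy()

    def pll(d: np.ndarray) -> float:
        return _bernoulli_loglik(y, eta_fix + d[a]) - 0.5 * float(d @ d) / sig2

    f = pll(delta)
    f_tol = 1e-13 * (1.0 + abs(f))  # descent check at float resolution of f
    for _ in range(max_iter):
        p = expit(eta_fix + delta[a])
        g = np.bincount(a, weights=y - p, minlength=q) - delta / sig2
        if np.max(np.abs(g)) < tol:
            break
        W = np.bincount(a, weights=p * (1 - p), minlength=q)
        H = W + 1.0 / sig2
        step = g / H
        if np.max(np.abs(step)) < 1e-12 * (1.0 + np.max(np.abs(delta))):
            delta = delta + step
            break
        new = delta + step
        f_new = pll(new)
        shrink = 0
        while f_new < f - f_tol and shrink < 30:
            step *= 0.5
            new = delta + step
            f_new = pll(new)
            shrink += 1
        if shrink == 30 and f_new < f - f_tol:
            break  # no further float-resolvable improvement
        delta, f = new, f_new
    p = expit(eta_fix + delta[a])
    W = np.bincount(a, weights=p * (1 - p), minlength=q)
    return delta, p, W


def _inner_mode_k2(
    y: np.ndarray,
    eta_fix: np.ndarray,
    t: np.ndarray,
    a: np.ndarray,
    q: int,
    sig2_0: float,
    sig2_1: float,
    d0_init: np.ndarray,
    d1_init: np.ndarray,
    tol: float = 1e-11,
    max_iter: int = 100,
):
    """Per-area Newton for (intercept, year-slope) random effects."""
    d0, d1 = d0_init.copy(), d1_init.copy()

    def pll(u0: np.ndarray, u1: np.ndarray) -> float:
        eta = eta_fix + u0[a] + u1[a] * t
        return (
            _bernoulli_loglik(y, eta)
            - 0.5 * float(u0 @ u0) / sig2_0
            - 0.5 * float(u1 @ u1) / sig2_1
        )

    f = pll(d0, d1)
    f_tol = 1e-13 * (1.0 + abs(f))
    for _ in range(max_iter):
        eta = eta_fix + d0[a] + d1[a] * t
        p = expit(eta)
        r = y - p
        g0 = np.bincount(a, weights=r, minlength=q) - d0 / sig2_0
        g1 = np.bincount(a, weights=r * t, minlength=q) - d1 / sig2_1
        if max(np.max(np.abs(g0)), np.max(np.abs(g1))) < tol:
            break
        w = p * (1 - p)
        H00 = np.bincount(a, weights=w, minlength=q) + 1.0 / sig2_0
        H01 = np.bincount(a, weights=w * t, minlength=q)
        H11 = np.bincount(a, weights=w * t * t, minlength=q) + 1.0 / sig2_1
        det = H00 * H11 - H01 * H01
        s0 = (H11 * g0 - H01 * g1) / det
        s1 = (H00 * g1 - H01 * g0) / det
        scale = max(np.max(np.abs(d0)), np.max(np.abs(d1)))
        if max(np.max(np.abs(s0)), np.max(np.abs(s1))) < 1e-12 * (1.0 + scale):
            d0, d1 = d0 + s0, d1 + s1
            break
        n0, n1 = d0 + s0, d1 + s1
        f_new = pll(n0, n1)
        shrink = 0
        while f_new < f - f_tol and shrink < 30:
            s0 *= 0.5
            s1 *= 0.5
            n0, n1 = d0 + s0, d1 + s1
            f_new = pll(n0, n1)
            shrink += 1
        if shrink == 30 and f_new < f - f_tol:
            break
        d0, d1, f = n0, n1, f_new
    eta = eta_fix + d0[a] + d1[a] * t
    p = expit(eta)
    w = p * (1 - p)
    H00 = np.bincount(a, weights=w, minlength=q) + 1.0 / sig2_0
    H01 = np.bincount(a, weights=w * t, minlength=q)
    H11 = np.bincount(a, weights=w * t * t, minlength=q) + 1.0 / sig2_1
    return d0, d1, p, (H00, H01, H11)


# ---------------------------------------------------------------------------
# outer problem: Laplace marginal likelihood
# ---------------------------------------------------------------------------

def _laplace_k1(theta, X, y, a, q, state):
    """Negative Laplace log-likelihood and its analytic gradient (intercept only)."""
    phi, beta = theta[0], theta[1:]
    sig2 = np.exp(2.0 * phi)
    eta_fix = X @ beta
    delta, p, W = _inner_mode_k1(y, eta_fix, a, q, sig2, state["delta"])
    state["delta"] = delta
    H = W + 1.0 / sig2
    eta = eta_fix + delta[a]
    ll = (
        _bernoulli_loglik(y, eta)
        - 0.5 * float(delta @ delta) / sig2
        - 0.5 * float(np.log(sig2 * H).sum())
    )

    r = y - p
    w = p * (1 - p)
    v = w * (1 - 2 * p)
    V = np.bincount(a, weights=v, minlength=q)
    c = -0.5 * V / H  # d loglik / d delta_hat (from the log-det term)

    # S_i = sum_j w_j x_j ;   d delta_hat / d beta = -S_i / H_i
    S = np.zeros((q, X.shape[1]))
    np.add.at(S, a, w[:, None] * X)
    grad_beta = X.T @ (r - 0.5 * v / H[a]) - S.T @ (c / H)

    ddelta_dphi = 2.0 * delta / (sig2 * H)
    grad_phi = float(
        np.sum((delta * delta) / sig2 - 1.0 + 1.0 / (sig2 * H) + c * ddelta_dphi)
    )
    grad = np.concatenate(([grad_phi], grad_beta))
    return -ll, -grad


def _laplace_k2(theta, X, y, t, a, q, state):
    """Negative Laplace log-likelihood for intercept + year-slope random effects."""
    phi0, phi1, beta = theta[0], theta[1], theta[2:]
    s2_0, s2_1 = np.exp(2.0 * phi0), np.exp(2.0 * phi1)
    eta_fix = X @ beta
    d0, d1, p, (H00, H01, H11) = _inner_mode_k2(
        y, eta_fix, t, a, q, s2_0, s2_1, state["d0"], state["d1"]
    )
    state["d0"], state["d1"] = d0, d1
    eta = eta_fix + d0[a] + d1[a] * t
    logdet = np.log(H00 * H11 - H01 * H01)
    ll = (
        _bernoulli_loglik(y, eta)
        - 0.5 * float(d0 @ d0) / s2_0
        - 0.5 * float(d1 @ d1) / s2_1
        - 0.5 * float((logdet + np.log(s2_0) + np.log(s2_1)).sum())
    )
    return -ll


def _logistic_start(X: np.ndarray, y: np.ndarray, ridge: float = 1e-6) -> np.ndarray:
    """Plain (ridge-stabilised) logistic regression for starting values."""
    beta = np.zeros(X.shape[1])
    beta[0] = np.log((y.mean() + 1e-6) / (1 - y.mean() + 1e-6))
    for _ in range(25):
        eta = X @ beta
        p = expit(eta)
        w = p * (1 - p) + 1e-10
        g = X.T @ (y - p) - ridge * beta
        Hm = (X * w[:, None]).T @ X + ridge * np.eye(X.shape[1])
        try:
            step = np.linalg.solve(Hm, g)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(Hm, g, rcond=None)[0]
        beta = beta + step
        if np.max(np.abs(step)) < 1e-8:
            break
    return beta


def _hessian_from_grad(fun_grad, x: np.ndarray) -> np.ndarray:
    """Central-difference Hessian from an analytic gradient."""
    d = len(x)
    H = np.zeros((d, d))
    for k in range(d):
        h = 1e-5 * max(1.0, abs(x[k]))
        xp, xm = x.copy(), x.copy()
        xp[k] += h
        xm[k] -= h
        gp = fun_grad(xp)[1]
        gm = fun_grad(xm)[1]
        H[:, k] = (gp - gm) / (2 * h)
    return 0.5 * (H + H.T)


def _hessian_from_fun(fun, x: np.ndarray) -> np.ndarray:
    """Central-difference Hessian from objective values only."""
    d = len(x)
    h = np.array([1e-4 * max(1.0, abs(v)) for v in x])
    H = np.zeros((d, d))
    f0 = fun(x)
    for i in range(d):
        ei = np.zeros(d)
        ei[i] = h[i]
        fpp = fun(x + ei)
        fmm = fun(x - ei)
        H[i, i] = (fpp - 2 * f0 + fmm) / (h[i] ** 2)
        for j in range(i + 1, d):
            ej = np.zeros(d)
            ej[j] = h[j]
            H[i, j] = H[j, i] = (
                fun(x + ei + ej) - fun(x + ei - ej) - fun(x - ei + ej) + fun(x - ei - ej)
            ) / (4 * h[i] * h[j])
    return H


# ---------------------------------------------------------------------------
# public fitting interface
# ---------------------------------------------------------------------------

def fit(
    records: pd.DataFrame,
    spec: ModelSpec,
    counties: CountyTable | None = None,
    spatial_covariate: Mapping[str, float] | None = None,
    schema: DemographicSchema = DEFAULT_SCHEMA,
    compute_cov: bool = True,
) -> FittedModel:
    """Maximise the Laplace-approximated marginal likelihood.

    ``records`` is filtered to ``spec.sex`` when that is set.  Raises
    :class:`EstimationError` for non-identifiable inputs (a single area, a
    constant outcome) and :class:`SeparationError` when a fixed effect runs
    away to the boundary.
    """
    if spec.sex is not None:
        records = records[records["sex"] == spec.sex]
    records = records.reset_index(drop=True)
    if len(records) == 0:
        raise EstimationError("no records to fit")

    areas = np.asarray(sorted(records["area_id"].unique()))
    q = len(areas)
    if q < 2:
        raise EstimationError(
            "random-intercept variance is not identifiable from a single area"
        )
    y = records["outcome"].to_numpy(dtype=float)
    if y.min() == y.max():
        raise EstimationError("outcome is constant; model is not identifiable")

    X_raw, t, info = _build_design(records, spec, counties, spatial_covariate, schema)
    a = pd.Categorical(records["area_id"], categories=areas).codes.astype(np.int64)

    # standardise the area-level covariate columns (and the spatial covariate,
    # whose natural scale can be arbitrarily small) for conditioning
    names = info.names
    means = np.zeros(X_raw.shape[1])
    sds = np.ones(X_raw.shape[1])
    X = X_raw.copy()
    for j, name in enumerate(names):
        if name in info.z_names or name == "spatial":
            mu, sd = X_raw[:, j].mean(), X_raw[:, j].std()
            if sd <= 0:
                if name == "spatial":
                    continue  # degenerate (e.g. all-zero) spatial column: leave raw
                raise EstimationError(f"covariate {name!r} is constant")
            means[j], sds[j] = mu, sd
            X[:, j] = (X_raw[:, j] - mu) / sd

    beta0 = _logistic_start(X, y)
    phi0 = np.log(0.2)
    k2 = info.year_effect == "random"

    if not k2:
        state = {"delta": np.zeros(q)}
        theta0 = np.concatenate(([phi0], beta0))
        bounds = [(_PHI_LO, _PHI_HI)] + [(None, None)] * len(beta0)
        res = minimize(
            _laplace_k1,
            theta0,
            args=(X, y, a, q, state),
            jac=True,
            method="L-BFGS-B",
            bounds=bounds,
            options={"maxiter": 200, "ftol": 1e-12, "gtol": 1e-6},
        )
        phi_hat, beta_std = res.x[0], res.x[1:]
        _check_separation(beta_std, names)
        sig2 = np.exp(2 * phi_hat)
        delta, p, W = _inner_mode_k1(y, X @ beta_std, a, q, sig2, state["delta"])
        H = W + 1.0 / sig2
        ranef_mean = pd.Series(delta, index=areas)
        ranef_var = pd.Series(1.0 / H, index=areas)
        sigma_year = None
        ry_mean = ry_var = ry_cov = None
        if compute_cov:
            hess = _hessian_from_grad(
                lambda th: _laplace_k1(th, X, y, a, q, dict(state, delta=state["delta"].copy())),
                res.x,
            )
        loglik = -res.fun
    else:
        state = {"d0": np.zeros(q), "d1": np.zeros(q)}
        theta0 = np.concatenate(([phi0, np.log(0.05)], beta0))
        bounds = [(_PHI_LO, _PHI_HI)] * 2 + [(None, None)] * len(beta0)
        res = minimize(
            _laplace_k2,
            theta0,
            args=(X, y, t, a, q, state),
            method="L-BFGS-B",
            bounds=bounds,
            options={"maxiter": 200, "ftol": 1e-12},
        )
        phi_hat, phi1_hat, beta_std = res.x[0], res.x[1], res.x[2:]
        _check_separation(beta_std, names)
        s2_0, s2_1 = np.exp(2 * phi_hat), np.exp(2 * phi1_hat)
        d0, d1, p, (H00, H01, H11) = _inner_mode_k2(
            y, X @ beta_std, t, a, q, s2_0, s2_1, state["d0"], state["d1"]
        )
        det = H00 * H11 - H01 * H01
        ranef_mean = pd.Series(d0, index=areas)
        ranef_var = pd.Series(H11 / det, index=areas)
        ry_mean = pd.Series(d1, index=areas)
        ry_var = pd.Series(H00 / det, index=areas)
        ry_cov = pd.Series(-H01 / det, index=areas)
        sigma_year = float(np.exp(phi1_hat))
        if compute_cov:
            hess = _hessian_from_fun(
                lambda th: _laplace_k2(
                    th, X, y, t, a, q,
                    {"d0": state["d0"].copy(), "d1": state["d1"].copy()},
                ),
                res.x,
            )
        loglik = -res.fun

    n_var = 1 if not k2 else 2
    log_sigma_se = float("nan")
    if compute_cov:
        try:
            cov_all = np.linalg.inv(hess)
            cov_std = cov_all[n_var:, n_var:]
            if cov_all[0, 0] > 0:
                log_sigma_se = float(np.sqrt(cov_all[0, 0]))
        except np.linalg.LinAlgError:
            cov_std = None
        if cov_std is None or not np.isfinite(cov_std).all() or (
            np.diag(cov_std) <= 0
        ).any():
            # variance parameter at the boundary makes the joint Hessian
            # singular; condition on it and invert the beta block alone
            beta_block = hess[n_var:, n_var:]
            try:
                cov_std = np.linalg.inv(beta_block)
            except np.linalg.LinAlgError:
                cov_std = np.linalg.pinv(beta_block)
    else:
        cov_std = np.full((len(beta_std), len(beta_std)), np.nan)

    # report on the original covariate scale
    p_dim = len(beta_std)
    A = np.eye(p_dim)
    for j in range(p_dim):
        if sds[j] != 1.0 or means[j] != 0.0:
            A[j, j] = 1.0 / sds[j]
            A[0, j] = -means[j] / sds[j]
    beta_raw = A @ beta_std
    cov_raw = A @ cov_std @ A.T
    cov_raw = 0.5 * (cov_raw + cov_raw.T)

    converged = bool(res.success) or res.status == 0
    if not converged:
        logger.warning("GLMM fit did not converge: %s", res.message)

    return FittedModel(
        spec=spec,
        fixed_effects=pd.Series(beta_raw, index=names),
        fixed_cov=pd.DataFrame(cov_raw, index=names, columns=names),
        sigma_delta=float(np.exp(phi_hat)),
        ranef_mean=ranef_mean,
        ranef_var=ranef_var,
        loglik=float(loglik),
        converged=converged,
        n_used=len(records),
        design=info,
        sigma_year=sigma_year,
        ranef_year_mean=ry_mean,
        ranef_year_var=ry_var,
        ranef_cross_cov=ry_cov,
        log_sigma_se=log_sigma_se,
    )


# ---------------------------------------------------------------------------
# prediction
# ---------------------------------------------------------------------------

def _fixed_row(
    model: FittedModel,
    age_group: str,
    race_group: str,
    year: int,
    z_row: pd.Series | None,
    spatial_value: float,
) -> np.ndarray:
    info = model.design
    schema = info.schema
    if age_group not in schema.age_groups:
        raise SchemaError(f"unknown age group {age_group!r}")
    if race_group not in schema.race_groups:
        raise SchemaError(f"unknown race group {race_group!r}")
    row = np.zeros(len(info.names))
    for j, name in enumerate(info.names):
        if name == "intercept":
            row[j] = 1.0
        elif name == f"age:{age_group}":
            row[j] = 1.0
        elif name == f"race:{race_group}":
            row[j] = 1.0
        elif name == f"year:{year}":
            row[j] = 1.0
        elif name == "year_trend":
            row[j] = year - info.year_center
        elif name.startswith("z:"):
            if z_row is None:
                raise EstimationError("prediction requires county covariates")
            row[j] = float(z_row[name[2:]])
        elif name == "spatial":
            row[j] = spatial_value
    if (
        info.year_effect == "fixed"
        and year != info.ref_year
        and f"year:{year}" not in info.names
    ):
        raise EstimationError(
            f"year {year} was not in the training data (fixed year contrasts)"
        )
    return row


def predict_linear(
    model: FittedModel,
    area: str,
    age_group: str,
    race_group: str,
    year: int,
    counties: CountyTable | None = None,
    spatial_covariate: Mapping[str, float] | None = None,
) -> float:
    """Linear predictor (log-odds) for one demographic cell in one area.

    Areas unseen at fit time contribute a random effect of 0 (the prior
    mean).
    """
    z_row = None
    if model.design.z_names:
        if counties is None:
            raise EstimationError("prediction requires county covariates")
        z_row = counties.Z.loc[area]
    spat = 0.0
    if "spatial" in model.design.names and spatial_covariate is not None:
        spat = float(spatial_covariate.get(area, 0.0))
    row = _fixed_row(model, age_group, race_group, year, z_row, spat)
    eta = float(row @ model.fixed_effects.to_numpy())
    eta += float(model.ranef_mean.get(area, 0.0))
    if model.ranef_year_mean is not None:
        eta += float(model.ranef_year_mean.get(area, 0.0)) * (
            year - model.design.year_center
        )
    return eta


def cell_design(
    model: FittedModel,
    area: str,
    year: int,
    counties: CountyTable | None = None,
    spatial_covariate: Mapping[str, float] | None = None,
) -> tuple[np.ndarray, pd.MultiIndex]:
    """Fixed-effect design rows for every age x race cell of one area.

    Returns (C x p matrix, cell MultiIndex).  Used by the aggregation and
    credibility-region machinery; rows are on the original covariate scale
    to match ``fixed_effects``.
    """
    schema = model.design.schema
    z_row = None
    if model.design.z_names:
        if counties is None:
            raise EstimationError("prediction requires county covariates")
        z_row = counties.Z.loc[area]
    spat = 0.0
    if "spatial" in model.design.names and spatial_covariate is not None:
        spat = float(spatial_covariate.get(area, 0.0))
    cells = pd.MultiIndex.from_product(
        [schema.age_groups, schema.race_groups], names=["age_group", "race_group"]
    )
    rows = np.vstack(
        [
            _fixed_row(model, ag, rg, year, z_row, spat)
            for ag, rg in cells
        ]
    )
    return rows, cells
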