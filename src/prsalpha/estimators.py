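"""Estimation of the PRS calibration parameter alpha.

Three procedures are provided, all targeting the same quantity: alpha, the
square root of the proportion of the age-dependent polygenic variance
sigma_P^2(t) = gamma + theta*t that a given PRS explains.

1. ``estimate_alpha_glm`` — logistic regression of case/control status on the
   age-transformed covariate S' = sqrt(gamma + theta*t) * x_K, whose
   coefficient is alpha under the rare-disease approximation.  This marginal
   approach ignores the unmeasured residual polygene: early-onset selection
   induces a negative correlation between the PRS and the residual component
   at later ages (a form of index-event bias), so it systematically
   underestimates alpha.
2. ``estimate_alpha_rl`` — a retrospective likelihood of the observed PRS
   conditional on phenotype (status and age), integrating over the residual
   polygene.  This is the preferred estimator; profile-likelihood confidence
   intervals come from a grid with the chi-square(1) threshold.
3. ``calibrate_alpha_app`` — proportionality calibration alpha ~= c * eta
   against a reference PRS with known (eta0, alpha0), c = alpha0/eta0.

``residualize_prs`` removes country and principal-component structure from
the PRS (adjusting for status so the case/control signal is retained) before
likelihood analyses.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.optimize import minimize_scalar
from scipy.stats import norm

from .core_model import (
    DEFAULT_QUADRATURE_ORDER,
    AlphaEstimate,
    BaselineHazard,
    IncidenceTable,
    VarianceParams,
    constrain_baseline,
    gauss_hermite_normal,
)
from .errors import DomainError, EstimationError, NumericalError
from .prs_io import _append_covariates

__all__ = [
    "Cohort",
    "transform_prs_for_glm",
    "estimate_alpha_glm",
    "residualize_prs",
    "retrospective_loglik",
    "estimate_alpha_rl",
    "calibrate_alpha_app",
]

#: Profile-likelihood drop for a 95% CI: chi2_1(0.95) / 2.
PROFILE_CI_DROP = 1.92

_REQUIRED_COLUMNS = ("status", "age", "prs_raw")


@dataclass
class Cohort:
    """A case-control sample: status, age, PRS and adjustment covariates.

    ``age`` is the age at diagnosis for cases and at last observation for
    controls; analyses are restricted to ages below 80.  ``prs_std`` holds
    the standardized (and possibly residualized) PRS consumed by the
    estimators; ``pc1..pcK`` and ``country`` are optional adjustment columns.
    """

    df: pd.DataFrame

    def __post_init__(self):
        df = self.df
        for col in _REQUIRED_COLUMNS:
            if col not in df.columns:
                raise DomainError(f"cohort lacks required column {col!r}")
        if df["age"].isna().any():
            raise DomainError("cohort contains missing ages")
        if not set(np.unique(df["status"])) <= {0, 1}:
            raise DomainError("status must be binary 0/1")
        ages = df["age"].to_numpy()
        if np.any(ages >= 80) or np.any(ages < 0):
            raise DomainError("ages must satisfy 0 <= age < 80")
        self.df = df.reset_index(drop=True)

    @classmethod
    def from_csv(cls, path) -> "Cohort":
        return cls(pd.read_csv(path, comment="#"))

    def to_csv(self, path, **kwargs) -> None:
        self.df.to_csv(path, index=False, **kwargs)

    @property
    def n_cases(self) -> int:
        return int((self.df["status"] == 1).sum())

    @property
    def n_controls(self) -> int:
        return int((self.df["status"] == 0).sum())

    @property
    def pc_columns(self) -> list[str]:
        return [c for c in self.df.columns if c.startswith("pc") and c[2:].isdigit()]

    def with_standardized_prs(self, ref: str = "controls") -> "Cohort":
        """Attach ``prs_std``, standardizing against the control group by default."""
        df = self.df.copy()
        if ref == "controls":
            refvals = df.loc[df["status"] == 0, "prs_raw"]
        elif ref == "all":
            refvals = df["prs_raw"]
        else:
            raise DomainError(f"unknown standardization reference {ref!r}")
        sd = float(refvals.std(ddof=1))
        if sd <= 0:
            raise DomainError("reference SD is zero; cannot standardize")
        df["prs_std"] = (df["prs_raw"] - float(refvals.mean())) / sd
        return Cohort(df)


def _as_cohort(cohort) -> Cohort:
    return cohort if isinstance(cohort, Cohort) else Cohort(cohort)


def transform_prs_for_glm(x_K, t, params: VarianceParams):
    """Age-scaled PRS covariate S' = sqrt(gamma + theta*t) * x_K.

    The age-specific log-OR per unit SD of the PRS is sigma_K(t) =
    alpha * sqrt(gamma + theta*t); scaling the standardized PRS by the
    age-dependent polygenic SD makes the regression coefficient of S' equal
    alpha itself.
    """
    v = params.variance(t)
    if np.any(np.asarray(v) <= 0):
        raise DomainError(f"non-positive polygenic variance at age {t}")
    return np.sqrt(v) * np.asarray(x_K, dtype=float)


def estimate_alpha_glm(
    cohort,
    params: VarianceParams,
    covariates: Sequence[str] = (),
) -> AlphaEstimate:
    """Estimate alpha by logistic regression on the transformed covariate.

    Fits status ~ S' + covariates (country categorical, PCs continuous); the
    coefficient of S' is alpha_GLM with its Wald 95% CI.
    """
    coh = _as_cohort(cohort)
    df = coh.df
    z = _prs_values(df)
    sprime = transform_prs_for_glm(z, df["age"].to_numpy(), params)
    X = pd.DataFrame({"s_prime": sprime}, index=df.index)
    X = _append_covariates(X, df, covariates)
    X = sm.add_constant(X, has_constant="add")
    y = df["status"].to_numpy()
    if not (np.any(y == 1) and np.any(y == 0)):
        raise EstimationError("cohort must contain both cases and controls")
    try:
        fit = sm.Logit(y, X.astype(float)).fit(disp=0)
        if not fit.mle_retvals.get("converged", True):
            raise EstimationError(f"logistic regression did not converge: {fit.mle_retvals}")
    except EstimationError:
        raise
    except Exception as exc:
        raise EstimationError(f"logistic regression failed: {exc}") from exc
    ci = fit.conf_int().loc["s_prime"]
    return AlphaEstimate(
        alpha=float(fit.params["s_prime"]),
        method="glm",
        ci_low=float(ci[0]),
        ci_high=float(ci[1]),
        loglik=float(fit.llf),
        se=float(fit.bse["s_prime"]),
        n_cases=coh.n_cases,
        n_controls=coh.n_controls,
        settings={"covariates": list(covariates)},
    )


def residualize_prs(cohort, covariates: Sequence[str] = ("country",)) -> Cohort:
    """Remove country/PC structure from the standardized PRS.

    Regresses ``prs_std`` on the covariates plus a case/control indicator,
    then subtracts only the covariate (and intercept) contributions — the
    fitted status effect stays in the residual, since removing it would erase
    the signal being estimated.  The result is centered at 0 overall.
    """
    coh = _as_cohort(cohort)
    df = coh.df.copy()
    z = _prs_values(df)
    X = pd.DataFrame(index=df.index)
    X = _append_covariates(X, df, covariates)
    X["status"] = df["status"].to_numpy(dtype=float)
    X = sm.add_constant(X, has_constant="add")
    Xv = X.astype(float)
    if np.linalg.matrix_rank(Xv.to_numpy()) < Xv.shape[1]:
        raise EstimationError("rank-deficient design in PRS residualization")
    fit = sm.OLS(z, Xv).fit()
    nuisance = [c for c in Xv.columns if c != "status"]
    resid = z - Xv[nuisance].to_numpy() @ fit.params[nuisance].to_numpy()
    resid = resid - resid.mean()
    df["prs_std"] = resid
    return Cohort(df)


def _prs_values(df: pd.DataFrame) -> np.ndarray:
    if "prs_std" in df.columns:
        return df["prs_std"].to_numpy(dtype=float)
    return df["prs_raw"].to_numpy(dtype=float)


# ---------------------------------------------------------------------------
# Retrospective likelihood


def _model_arrays(baseline: BaselineHazard, params: VarianceParams):
    ages = baseline.ages
    sigma = np.sqrt(params.gamma + params.theta * ages)
    return sigma, baseline.lambda0


def _phenotype_prob_many(
    status: np.ndarray,
    t_idx: np.ndarray,
    scores: np.ndarray,
    sigma: np.ndarray,
    lam0: np.ndarray,
    weights: np.ndarray,
) -> np.ndarray:
    """P(phenotype_i | scores_i) for rows of quadrature scores, chunk-vectorized.

    ``scores`` has shape (n, Q): per individual, the effective polygenic
    scores alpha*z_i + sqrt(1-alpha^2)*r_k at the quadrature nodes.
    ``t_idx`` counts completed exposure years (age - age_min).
    """
    n, _ = scores.shape
    out = np.empty(n)
    order = np.argsort(t_idx, kind="stable")
    chunk = 4096
    for start in range(0, n, chunk):
        rows = order[start : start + chunk]
        ti = t_idx[rows]
        m = int(ti.max())
        sc = scores[rows]
        if m > 0:
            # hazard terms lambda0(u) * exp(sigma_u * s) for ages below each t
            e = np.exp(sc[:, :, None] * sigma[:m][None, None, :])
            cum = np.cumsum(e * lam0[:m][None, None, :], axis=2)
            lam_cum = np.zeros_like(sc)
            pos = ti > 0
            lam_cum[pos] = np.take_along_axis(
                cum[pos], (ti[pos] - 1)[:, None, None], axis=2
            )[:, :, 0]
        else:
            lam_cum = np.zeros_like(sc)
        integrand = np.exp(-lam_cum)
        is_case = status[rows] == 1
        if np.any(is_case):
            crow = np.where(is_case)[0]
            tc = ti[crow]
            integrand[crow] *= lam0[tc][:, None] * np.exp(sigma[tc][:, None] * sc[crow])
        out[rows] = integrand @ weights
    return out


def retrospective_loglik(
    alpha: float,
    cohort,
    baseline: BaselineHazard,
    params: VarianceParams,
    quadrature_order: int = DEFAULT_QUADRATURE_ORDER,
) -> float:
    """Log-likelihood of the observed PRS conditional on phenotypes.

    Each individual contributes

        log [ P(pheno_i | x_K = z_i) phi(z_i) / Int P(pheno_i | u) phi(u) du ],

    with the phenotype probability integrating the residual polygene out by
    Gauss-Hermite quadrature, and the denominator integral over the PRS by
    the same rule.  Conditioning on phenotype makes the likelihood immune to
    case-control ascertainment (the sampling fractions cancel in the ratio).
    """
    if not 0.0 <= alpha < 1.0:
        raise DomainError(f"alpha must lie in [0, 1), got {alpha}")
    coh = _as_cohort(cohort)
    df = coh.df
    z = _prs_values(df)
    status = df["status"].to_numpy()
    ages = df["age"].to_numpy(dtype=int)
    if ages.min() < baseline.age_min or ages.max() > baseline.age_max:
        raise DomainError(
            f"cohort ages [{ages.min()}, {ages.max()}] exceed baseline range "
            f"[{baseline.age_min}, {baseline.age_max}]"
        )
    sigma, lam0 = _model_arrays(baseline, params)
    r, w = gauss_hermite_normal(quadrature_order)
    beta = np.sqrt(1.0 - alpha**2)
    t_idx = ages - baseline.age_min

    # numerator: P(pheno_i | z_i)
    scores = alpha * z[:, None] + beta * r[None, :]
    p_num = _phenotype_prob_many(status, t_idx, scores, sigma, lam0, w)

    # denominator: Int P(pheno | u) phi(u) du, shared within (status, age) groups
    groups = {}
    for s_val in (0, 1):
        for ti in np.unique(t_idx[status == s_val]):
            groups[(s_val, int(ti))] = None
    u = r  # same nodes for the outer integral over the PRS
    den_scores = alpha * u[:, None] + beta * r[None, :]
    for s_val, ti in groups:
        st = np.full(u.size, s_val)
        tis = np.full(u.size, ti)
        p_u = _phenotype_prob_many(st, tis, den_scores, sigma, lam0, w)
        groups[(s_val, ti)] = float(p_u @ w)
    p_den = np.array([groups[(int(s), int(ti))] for s, ti in zip(status, t_idx)])

    if np.any(p_num <= 0) or np.any(p_den <= 0):
        bad = int(np.argmax((p_num <= 0) | (p_den <= 0)))
        raise NumericalError(
            f"non-positive phenotype probability for record {bad} "
            f"(status={status[bad]}, age={ages[bad]}, z={z[bad]:.3f})"
        )
    ll = float(np.sum(np.log(p_num) - np.log(p_den) + norm.logpdf(z)))
    if not np.isfinite(ll):
        raise NumericalError(f"non-finite retrospective log-likelihood at alpha={alpha}")
    return ll


def estimate_alpha_rl(
    cohort,
    incidence: IncidenceTable,
    params: VarianceParams,
    bounds: tuple[float, float] = (0.0, 0.99),
    grid_step: float = 0.001,
    quadrature_order: int = DEFAULT_QUADRATURE_ORDER,
    baseline: Optional[BaselineHazard] = None,
) -> AlphaEstimate:
    """Maximize the retrospective likelihood over alpha with a profile-grid CI.

    The baseline hazard is constrained to the supplied incidence first (or a
    pre-constrained baseline may be passed).  The 95% CI comprises the
    outermost grid points whose log-likelihood is within 1.92 of the maximum,
    walking outward from the MLE (the profile is unimodal in practice).
    """
    lo, hi = bounds
    if not (0.0 <= lo < hi <= 0.99):
        raise DomainError(f"bounds must satisfy 0 <= lo < hi <= 0.99, got {bounds}")
    if baseline is None:
        baseline = constrain_baseline(incidence, params, quadrature_order)
    coh = _as_cohort(cohort)

    cache: dict[float, float] = {}

    def ll(a: float) -> float:
        key = round(float(a), 12)
        if key not in cache:
            cache[key] = retrospective_loglik(
                key, coh, baseline, params, quadrature_order
            )
        return cache[key]

    res = minimize_scalar(
        lambda a: -ll(a), bounds=(lo, hi), method="bounded", options={"xatol": 1e-5}
    )
    if not res.success:
        raise EstimationError(f"likelihood maximization failed: {res.message}")
    alpha_hat = float(res.x)
    llmax = float(-res.fun)
    at_bound = alpha_hat - lo < 1e-4 or hi - alpha_hat < 1e-4

    grid = np.round(np.arange(lo, hi + grid_step / 2, grid_step), 10)
    threshold = llmax - PROFILE_CI_DROP
    center = int(np.clip(np.round((alpha_hat - lo) / grid_step), 0, grid.size - 1))
    ci_low_idx = center
    while ci_low_idx > 0 and ll(grid[ci_low_idx - 1]) >= threshold:
        ci_low_idx -= 1
    ci_high_idx = center
    while ci_high_idx < grid.size - 1 and ll(grid[ci_high_idx + 1]) >= threshold:
        ci_high_idx += 1
    ci_low = min(float(grid[ci_low_idx]), alpha_hat)
    ci_high = max(float(grid[ci_high_idx]), alpha_hat)

    return AlphaEstimate(
        alpha=alpha_hat,
        method="rl",
        ci_low=ci_low,
        ci_high=ci_high,
        loglik=llmax,
        at_bound=at_bound,
        n_cases=coh.n_cases,
        n_controls=coh.n_controls,
        settings={
            "bounds": [lo, hi],
            "grid_step": grid_step,
            "quadrature_order": quadrature_order,
        },
    )


def calibrate_alpha_app(
    eta: float,
    eta0: float,
    alpha0: float,
    round_constant: Optional[int] = None,
) -> AlphaEstimate:
    """Proportionality calibration alpha_APP = (eta / eta0) * alpha0.

    ``eta`` is the log-OR per 1 SD of the target PRS; ``eta0`` and ``alpha0``
    are the log-OR per SD and calibrated alpha of the reference PRS.  If
    ``round_constant`` is given, the constant alpha0/eta0 is rounded to that
    many decimals before scaling (matching published constants such as
    0.887 for the PRS313 standard).
    """
    if eta0 <= 0:
        raise DomainError(f"reference log-OR eta0 must be positive, got {eta0}")
    if not 0.0 < alpha0 < 1.0:
        raise DomainError(f"reference alpha0 must lie in (0, 1), got {alpha0}")
    c = alpha0 / eta0
    if round_constant is not None:
        c = round(c, round_constant)
    return AlphaEstimate(
        alpha=float(c * eta),
        method="app",
        settings={"eta": eta, "eta0": eta0, "alpha0": alpha0, "constant": c},
    )
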