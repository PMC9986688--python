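"""Age-dependent polygenic hazard model.

BOADICEA models breast-cancer incidence for individual *i* as a proportional
hazard on a latent standard-normal polygenotype ``x_P``::

    lambda(t) = lambda0(t) * exp(sigma_P(t) * x_P)

where the polygenic variance is linear in age, ``sigma_P^2(t) = gamma +
theta * t``.  A polygenic risk score (PRS) measures a component ``x_K`` of
the polygenotype; the remainder ``x_R`` is unmeasured, and a priori the two
are independent standard normals combined as ``x_P = alpha * x_K +
sqrt(1 - alpha^2) * x_R``.  The calibration parameter ``alpha^2`` is the
proportion of the polygenic variance explained by the PRS.

This module provides the variance functions, the baseline hazard
``lambda0(t)`` constrained so that the population-marginal incidence matches
an observed incidence table, and the phenotype probabilities (case at age t /
unaffected to age t) conditional on the measured component, integrating the
unmeasured component out by Gauss-Hermite quadrature.

Ages are treated on a yearly grid with piecewise-constant hazards; the
cumulative hazard is a yearly sum.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from functools import lru_cache
from typing import Optional

import numpy as np
import pandas as pd

from .errors import DomainError, FormatError, NumericalError

__all__ = [
    "DEFAULT_GAMMA",
    "DEFAULT_THETA",
    "DEFAULT_AGE_MIN",
    "DEFAULT_AGE_MAX",
    "DEFAULT_QUADRATURE_ORDER",
    "VarianceParams",
    "IncidenceTable",
    "BaselineHazard",
    "AlphaEstimate",
    "gauss_hermite_normal",
    "polygenic_variance",
    "known_variance",
    "constrain_baseline",
    "marginal_incidence",
    "cumulative_hazard",
    "phenotype_prob_given_prs",
]

#: Polygenic variance at age 0 (log-hazard-ratio squared), from segregation
#: analysis of breast-cancer families.
DEFAULT_GAMMA = 4.86
#: Change in polygenic variance per year of age.
DEFAULT_THETA = -0.06
#: Supported age range; the upper bound honours both the positivity of
#: gamma + theta * t and the restriction of analyses to ages below 80.
DEFAULT_AGE_MIN = 20
DEFAULT_AGE_MAX = 79
#: Gauss-Hermite order for all latent-variable integrals.
DEFAULT_QUADRATURE_ORDER = 30

_VARIANCE_FLOOR = 1e-10


@dataclass(frozen=True)
class VarianceParams:
    """Linear age-dependence of the polygenic variance, sigma_P^2(t) = gamma + theta*t.

    Parameters
    ----------
    gamma
        Polygenic variance at age 0.  Must be positive (an exactly-zero
        variance with ``theta == 0`` is accepted as the degenerate
        no-polygene limit).
    theta
        Change in polygenic variance per year of age.
    age_min, age_max
        Inclusive integer bounds of the supported age range; the variance
        must stay positive across the whole range.
    """

    gamma: float = DEFAULT_GAMMA
    theta: float = DEFAULT_THETA
    age_min: int = DEFAULT_AGE_MIN
    age_max: int = DEFAULT_AGE_MAX

    def __post_init__(self) -> None:
        if self.age_min >= self.age_max:
            raise DomainError(f"age_min ({self.age_min}) must be < age_max ({self.age_max})")
        degenerate = self.gamma == 0.0 and self.theta == 0.0
        if self.gamma < 0:
            raise DomainError(f"gamma must be non-negative, got {self.gamma}")
        if not degenerate:
            v = self.gamma + self.theta * self.ages
            bad = self.ages[v <= _VARIANCE_FLOOR]
            if bad.size:
                raise DomainError(
                    f"polygenic variance gamma + theta*t is not positive at ages "
                    f"{bad.tolist()}; supported range requires gamma + theta*t > {_VARIANCE_FLOOR}"
                )

    @property
    def ages(self) -> np.ndarray:
        """Integer age grid [age_min, age_max]."""
        return np.arange(self.age_min, self.age_max + 1)

    def variance(self, t) -> np.ndarray | float:
        """sigma_P^2(t) = gamma + theta * t for t inside the supported range."""
        t_arr = np.asarray(t)
        if np.any(t_arr < self.age_min) or np.any(t_arr > self.age_max):
            raise DomainError(
                f"age {t} outside supported range [{self.age_min}, {self.age_max}]"
            )
        out = self.gamma + self.theta * t_arr
        return float(out) if np.isscalar(t) else out

    def sd(self, t) -> np.ndarray | float:
        """sigma_P(t), the polygenic standard deviation at age t."""
        return np.sqrt(self.variance(t))


def polygenic_variance(t, params: VarianceParams) -> float:
    """Total polygenic variance sigma_P^2(t) = gamma + theta*t at age ``t``."""
    return params.variance(t)


def known_variance(t, alpha: float, params: VarianceParams) -> float:
    """Variance of the PRS-measured component, sigma_K^2(t) = alpha^2 (gamma + theta*t)."""
    if not 0.0 <= alpha <= 1.0:
        raise DomainError(f"alpha must lie in [0, 1], got {alpha}")
    return alpha**2 * params.variance(t)


class IncidenceTable:
    """Population age-specific incidence on a yearly grid.

    Rates are per person-year.  Tables supplied in integer age bands (e.g.
    5-year bands, half-open ``[age_low, age_high)``) are expanded to yearly
    resolution by constant interpolation within bands.
    """

    def __init__(self, ages, rate):
        ages = np.asarray(ages, dtype=int)
        rate = np.asarray(rate, dtype=float)
        if ages.size == 0:
            raise FormatError("incidence table is empty")
        if ages.size != rate.size:
            raise FormatError("ages and rate must have equal length")
        order = np.argsort(ages)
        ages, rate = ages[order], rate[order]
        if np.any(np.diff(ages) != 1):
            raise FormatError("incidence ages must be contiguous yearly values")
        if np.any(rate < 0) or not np.all(np.isfinite(rate)):
            raise FormatError("incidence rates must be finite and non-negative")
        self.ages = ages
        self.rate = rate

    @classmethod
    def from_bands(cls, age_low, age_high, rate_per_100000) -> "IncidenceTable":
        """Expand half-open integer bands [age_low, age_high) to yearly rows."""
        ages: list[int] = []
        rates: list[float] = []
        for lo, hi, r in zip(age_low, age_high, rate_per_100000):
            lo, hi = int(lo), int(hi)
            if hi <= lo:
                raise FormatError(f"band [{lo}, {hi}) is empty")
            ages.extend(range(lo, hi))
            rates.extend([float(r) / 1e5] * (hi - lo))
        return cls(ages, rates)

    @classmethod
    def from_csv(cls, path) -> "IncidenceTable":
        """Read a band CSV with columns ``age_low, age_high, rate_per_100000``."""
        df = pd.read_csv(path)
        required = {"age_low", "age_high", "rate_per_100000"}
        missing = required - set(df.columns)
        if missing:
            raise FormatError(f"incidence CSV {path} lacks columns {sorted(missing)}")
        return cls.from_bands(df["age_low"], df["age_high"], df["rate_per_100000"])

    def restrict(self, age_min: int, age_max: int) -> "IncidenceTable":
        """Slice to the inclusive age range [age_min, age_max]."""
        mask = (self.ages >= age_min) & (self.ages <= age_max)
        sub = IncidenceTable(self.ages[mask], self.rate[mask])
        if sub.ages[0] != age_min or sub.ages[-1] != age_max:
            raise FormatError(
                f"incidence table covers [{self.ages[0]}, {self.ages[-1]}], "
                f"cannot cover requested [{age_min}, {age_max}]"
            )
        return sub

    def rate_at(self, t: int) -> float:
        idx = int(t) - int(self.ages[0])
        if idx < 0 or idx >= self.ages.size:
            raise DomainError(f"age {t} outside incidence table range")
        return float(self.rate[idx])

    def __len__(self) -> int:
        return int(self.ages.size)


@dataclass(frozen=True)
class BaselineHazard:
    """Baseline hazard lambda0(t) on a yearly age grid."""

    ages: np.ndarray
    lambda0: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "ages", np.asarray(self.ages, dtype=int))
        object.__setattr__(self, "lambda0", np.asarray(self.lambda0, dtype=float))
        if self.ages.size != self.lambda0.size:
            raise FormatError("ages and lambda0 must have equal length")
        if np.any(np.diff(self.ages) != 1):
            raise FormatError("baseline hazard ages must be contiguous")
        if np.any(self.lambda0 < 0) or not np.all(np.isfinite(self.lambda0)):
            raise NumericalError("baseline hazard must be finite and non-negative")

    @property
    def age_min(self) -> int:
        return int(self.ages[0])

    @property
    def age_max(self) -> int:
        return int(self.ages[-1])

    def to_csv(self, path) -> None:
        pd.DataFrame({"age": self.ages, "lambda0": self.lambda0}).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "BaselineHazard":
        df = pd.read_csv(path)
        return cls(df["age"].to_numpy(), df["lambda0"].to_numpy())


@dataclass
class AlphaEstimate:
    """An estimate of the calibration parameter alpha.

    ``method`` tags the procedure: ``glm`` (transformed-covariate logistic
    regression), ``rl`` (retrospective likelihood) or ``app`` (proportionality
    calibration).  Point estimates from finite samples may fall marginally
    outside [0, 1); ``in_range`` reports whether the estimate respects the
    model-parameter domain.
    """

    alpha: float
    method: str
    ci_low: Optional[float] = None
    ci_high: Optional[float] = None
    loglik: Optional[float] = None
    se: Optional[float] = None
    at_bound: bool = False
    n_cases: Optional[int] = None
    n_controls: Optional[int] = None
    settings: dict = dataclasses.field(default_factory=dict)

    def __post_init__(self):
        if self.method not in {"glm", "rl", "app"}:
            raise DomainError(f"unknown estimation method tag {self.method!r}")
        if self.ci_low is not None and self.ci_high is not None:
            if not (self.ci_low <= self.alpha <= self.ci_high):
                raise DomainError(
                    f"confidence interval [{self.ci_low}, {self.ci_high}] "
                    f"does not bracket alpha={self.alpha}"
                )

    @property
    def in_range(self) -> bool:
        return 0.0 <= self.alpha < 1.0

    def to_dict(self) -> dict:
        ci = None
        if self.ci_low is not None and self.ci_high is not None:
            ci = [self.ci_low, self.ci_high]
        return {
            "method": self.method,
            "alpha": self.alpha,
            "ci": ci,
            "loglik": self.loglik,
            "n_cases": self.n_cases,
            "n_controls": self.n_controls,
            "settings": dict(self.settings),
        }


@lru_cache(maxsize=None)
def gauss_hermite_normal(order: int) -> tuple[np.ndarray, np.ndarray]:
    """Nodes and weights for E[f(X)], X ~ N(0,1), by Gauss-Hermite quadrature.

    Physicists' nodes are rescaled by sqrt(2); weights are normalised to sum
    to exactly 1 so that a constant integrand is reproduced without error.
    """
    if order < 2:
        raise DomainError(f"quadrature order must be >= 2, got {order}")
    nodes, weights = np.polynomial.hermite.hermgauss(order)
    x = nodes * np.sqrt(2.0)
    w = weights / weights.sum()
    return x, w


def constrain_baseline(
    incidence: IncidenceTable,
    params: VarianceParams,
    quadrature_order: int = DEFAULT_QUADRATURE_ORDER,
) -> BaselineHazard:
    """Solve for the baseline hazard that reproduces population incidence.

    Under the polygenic model the population incidence at age t among
    disease-free women is the frailty-weighted average hazard

        mu(t) = lambda0(t) * E[exp(sigma_P(t) X) S(t|X)] / E[S(t|X)],

    with X ~ N(0,1) and S(t|x) = exp(-sum_{u<t} lambda0(u) exp(sigma_P(u) x)).
    Because lambda0(t) factors out of the numerator, the constraint is solved
    in closed form age by age, ascending, using the already-solved younger
    ages inside S.
    """
    if quadrature_order < 8:
        raise DomainError(f"quadrature_order must be >= 8, got {quadrature_order}")
    inc = incidence.restrict(params.age_min, params.age_max)
    ages = inc.ages
    sigma = np.sqrt(params.gamma + params.theta * ages)
    x, w = gauss_hermite_normal(quadrature_order)

    lam0 = np.empty(ages.size)
    cumhaz = np.zeros_like(x)  # cumulative hazard at each quadrature node
    for i in range(ages.size):
        relrisk = np.exp(sigma[i] * x)
        surv = np.exp(-cumhaz)
        denom = float(np.dot(w, relrisk * surv))
        numer = float(np.dot(w, surv))
        lam0_i = inc.rate[i] * numer / denom
        if not np.isfinite(lam0_i) or lam0_i < 0:
            raise NumericalError(
                f"baseline solve failed at age {ages[i]}: lambda0={lam0_i}"
            )
        lam0[i] = lam0_i
        cumhaz = cumhaz + lam0_i * relrisk
    return BaselineHazard(ages=ages, lambda0=lam0)


def marginal_incidence(
    baseline: BaselineHazard,
    params: VarianceParams,
    quadrature_order: int = DEFAULT_QUADRATURE_ORDER,
) -> IncidenceTable:
    """Population incidence implied by a baseline hazard under the model.

    Inverse of :func:`constrain_baseline`; used to verify incidence
    conservation.
    """
    ages = baseline.ages
    sigma = np.sqrt(params.gamma + params.theta * ages)
    x, w = gauss_hermite_normal(quadrature_order)
    rate = np.empty(ages.size)
    cumhaz = np.zeros_like(x)
    for i in range(ages.size):
        relrisk = np.exp(sigma[i] * x)
        surv = np.exp(-cumhaz)
        rate[i] = baseline.lambda0[i] * np.dot(w, relrisk * surv) / np.dot(w, surv)
        cumhaz = cumhaz + baseline.lambda0[i] * relrisk
    return IncidenceTable(ages, rate)


def _check_alpha(alpha: float) -> float:
    if not 0.0 <= alpha <= 1.0:
        raise DomainError(f"alpha must lie in [0, 1], got {alpha}")
    return float(alpha)


def _effective_score(x_K, x_R, alpha: float):
    """Combine measured and residual components: x_P = alpha x_K + sqrt(1-alpha^2) x_R."""
    return alpha * np.asarray(x_K, dtype=float) + np.sqrt(1.0 - alpha**2) * np.asarray(
        x_R, dtype=float
    )


def cumulative_hazard(
    t: int,
    x_K,
    x_R,
    alpha: float,
    baseline: BaselineHazard,
    params: VarianceParams,
):
    """Cumulative hazard to age ``t`` for given polygenic components.

    Yearly sum over ages ``u`` in ``[age_min, t-1]`` of
    ``lambda0(u) * exp(sigma_P(u) * (alpha x_K + sqrt(1-alpha^2) x_R))``.
    Returns 0 at ``t == age_min``.  Broadcasts over array-valued components.
    """
    _check_alpha(alpha)
    t = int(t)
    if t < params.age_min or t > params.age_max:
        raise DomainError(f"age {t} outside supported range [{params.age_min}, {params.age_max}]")
    score = _effective_score(x_K, x_R, alpha)
    n = t - baseline.age_min  # number of completed years of exposure
    if n <= 0:
        return np.zeros_like(score) if score.ndim else 0.0
    ages = baseline.ages[:n]
    sigma = np.sqrt(params.gamma + params.theta * ages)
    terms = baseline.lambda0[:n] * np.exp(np.multiply.outer(score, sigma))
    out = terms.sum(axis=-1)
    return float(out) if np.ndim(score) == 0 else out


def _hazard_at(t, score, baseline: BaselineHazard, params: VarianceParams):
    i = int(t) - baseline.age_min
    sigma_t = np.sqrt(params.gamma + params.theta * int(t))
    return baseline.lambda0[i] * np.exp(sigma_t * score)


def phenotype_prob_given_prs(
    status,
    t: int,
    x_K,
    alpha: float,
    baseline: BaselineHazard,
    params: VarianceParams,
    quadrature_order: int = DEFAULT_QUADRATURE_ORDER,
):
    """Probability of the observed phenotype given the measured PRS component.

    For a control censored at age t, the probability of remaining unaffected,

        P(unaffected to t | x_K) = E_{x_R}[ exp(-Lambda(t | x_K, x_R)) ],

    and for a case diagnosed at age t, the density-style contribution

        P(case at t | x_K) = E_{x_R}[ exp(-Lambda(t)) * lambda(t | x_K, x_R) ],

    with the unmeasured residual polygene integrated out by Gauss-Hermite
    quadrature.  ``status`` may be ``"case"``/``"control"`` or ``1``/``0``.
    Accepts scalar or array ``x_K``.
    """
    status = _normalize_status(status)
    a = _check_alpha(alpha)
    xk = np.asarray(x_K, dtype=float)
    scalar = xk.ndim == 0
    r, w = gauss_hermite_normal(quadrature_order)
    # effective scores: shape (n_xK, order)
    scores = a * xk.reshape(-1, 1) + np.sqrt(1.0 - a**2) * r.reshape(1, -1)
    lam_cum = _cumhaz_matrix(int(t), scores, baseline, params)
    surv = np.exp(-lam_cum)
    if status == "case":
        integrand = surv * _hazard_at(t, scores, baseline, params)
    else:
        integrand = surv
    out = integrand @ w
    if not np.all(np.isfinite(out)):
        raise NumericalError(
            f"non-finite phenotype probability at t={t}, alpha={alpha}, x_K={x_K}"
        )
    return float(out[0]) if scalar else out


def _cumhaz_matrix(t: int, scores: np.ndarray, baseline: BaselineHazard, params: VarianceParams):
    """Lambda(t | s) for an array of effective scores s (sum over ages < t)."""
    if t < params.age_min or t > params.age_max:
        raise DomainError(f"age {t} outside supported range [{params.age_min}, {params.age_max}]")
    n = int(t) - baseline.age_min
    if n <= 0:
        return np.zeros_like(scores)
    ages = baseline.ages[:n]
    sigma = np.sqrt(params.gamma + params.theta * ages)
    return np.exp(np.multiply.outer(scores, sigma)) @ (baseline.lambda0[:n])


def _normalize_status(status) -> str:
    if isinstance(status, str):
        s = status.lower()
        if s in {"case", "control"}:
            return s
    elif status in (0, 1):
        return "case" if status == 1 else "control"
    raise DomainError(f"status must be 'case'/'control' or 0/1, got {status!r}")
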