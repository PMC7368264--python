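"""Parametric vital rates over age and maternal age.

Survival follows a Weibull survivorship curve whose scale and shape depend
log-linearly on maternal age; fertility follows a natural-fertility-times-
controlled-reduction model in the Coale–Trussell tradition, with maternal
age acting as the control covariate.  Both are evaluated on a discrete
daily grid into a :class:`VitalRates` table that feeds the block
projection-matrix machinery.

Conventions
-----------
Ages and maternal ages are integer days ``1..omega`` and ``1..s``.  The
daily survival probability ``p[i, j]`` is the conditional probability of
surviving the day-``j`` interval, ``S_i(j) / S_i(j-1)``, the standard
cohort life-table discretisation.  Tables are stored as ``s x omega``
arrays indexed ``[i-1, j-1]``.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict, field
from pathlib import Path

import numpy as np
import yaml

__all__ = [
    "WeibullParams",
    "CoaleTrussellParams",
    "VitalRates",
    "weibull_survivorship",
    "survival_probabilities",
    "natural_fertility",
    "fertility_schedule",
    "build_vital_rates",
]


class InvalidParameterError(ValueError):
    """Raised when model parameters are non-finite or out of domain."""


@dataclass(frozen=True)
class WeibullParams:
    """Coefficients of the maternal-age-dependent Weibull survivorship.

    Scale and shape for maternal age ``i`` are obtained through
    exponential links::

        b_i = exp(log_scale_intercept + log_scale_slope * i)
        k_i = exp(log_shape_intercept + log_shape_slope * i)

    so both are positive for any real coefficients.  Survivorship is
    ``S_i(t) = exp(-(t / b_i) ** k_i)``.
    """

    log_scale_intercept: float
    log_scale_slope: float
    log_shape_intercept: float
    log_shape_slope: float

    def __post_init__(self) -> None:
        vals = [self.log_scale_intercept, self.log_scale_slope,
                self.log_shape_intercept, self.log_shape_slope]
        if not np.all(np.isfinite(vals)):
            raise InvalidParameterError(f"non-finite Weibull coefficients: {vals}")

    def scale(self, maternal_age) -> np.ndarray | float:
        return np.exp(self.log_scale_intercept
                      + self.log_scale_slope * np.asarray(maternal_age, dtype=float))

    def shape(self, maternal_age) -> np.ndarray | float:
        return np.exp(self.log_shape_intercept
                      + self.log_shape_slope * np.asarray(maternal_age, dtype=float))


@dataclass(frozen=True)
class CoaleTrussellParams:
    """Fertility = natural fertility n(j) times a controlled reduction.

    ``n(j) = exp(c0 + c1*j + c2*j**2)`` for ``j >= min_reproductive_age``
    and 0 below it — a smooth unimodal curve on the log scale.  The
    deviation schedule is a linear ramp ``nu(j) = -deviation_slope *
    (j - control_threshold_age)`` for ages past the threshold and zero
    before it, and the maternal-age control level is ``m_i =
    control_intercept + control_slope * i``.  The daily fertility is::

        f[i, j] = n(j) * exp(m_i * nu(j))

    With ``m_i >= 0`` and ``nu <= 0`` the factor only ever reduces
    natural fertility, and older maternal ages (larger ``m_i``) decline
    earlier and faster.
    """

    natural_fertility_coeffs: tuple[float, float, float]
    control_threshold_age: int = 4
    deviation_slope: float = 0.25
    control_intercept: float = 0.0
    control_slope: float = 0.0
    min_reproductive_age: int = 2

    def __post_init__(self) -> None:
        vals = [*self.natural_fertility_coeffs, self.control_threshold_age,
                self.deviation_slope, self.control_intercept, self.control_slope]
        if not np.all(np.isfinite(vals)):
            raise InvalidParameterError(f"non-finite fertility coefficients: {vals}")
        if len(self.natural_fertility_coeffs) != 3:
            raise InvalidParameterError("natural_fertility_coeffs must have 3 entries")
        if self.deviation_slope < 0:
            raise InvalidParameterError("deviation_slope must be >= 0 (nu = -slope * ramp)")

    def control_level(self, maternal_age) -> np.ndarray | float:
        return self.control_intercept + self.control_slope * np.asarray(maternal_age, dtype=float)

    def deviation(self, age) -> np.ndarray | float:
        """nu(j): zero up to the threshold age, declining linearly after."""
        j = np.asarray(age, dtype=float)
        return -self.deviation_slope * np.maximum(j - self.control_threshold_age, 0.0)


@dataclass(frozen=True)
class VitalRates:
    """Daily survival and fertility tables over maternal age and age.

    ``p[i-1, j-1]`` is the probability of surviving from age class ``j``
    to ``j+1`` given maternal age ``i``; ``f[i-1, j-1]`` the expected
    daughters per day.  ``p[:, omega-1]`` is stored as 0: no age class
    lies beyond ``omega``.
    """

    s: int
    omega: int
    p: np.ndarray = field(repr=False)
    f: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        p = np.asarray(self.p, dtype=float)
        f = np.asarray(self.f, dtype=float)
        if p.shape != (self.s, self.omega) or f.shape != (self.s, self.omega):
            raise ValueError(
                f"p and f must be {self.s}x{self.omega}; got {p.shape} and {f.shape}")
        if np.any(p < 0) or np.any(p > 1):
            raise ValueError("survival probabilities must lie in [0, 1]")
        if np.any(f < 0):
            raise ValueError("fertilities must be nonnegative")
        if np.any(p[:, -1] != 0):
            raise ValueError("p[:, omega] must be 0 (no age class beyond omega)")
        object.__setattr__(self, "p", p)
        object.__setattr__(self, "f", f)


def weibull_survivorship(params: WeibullParams, maternal_age: int, age) -> np.ndarray | float:
    """Weibull survivorship S_i(t) = exp(-(t / b_i) ** k_i).

    ``age`` may be a scalar or array of nonnegative values; S_i(0) = 1
    and S_i is nonincreasing.
    """
    t = np.asarray(age, dtype=float)
    if np.any(t < 0):
        raise ValueError("age must be nonnegative")
    b = params.scale(maternal_age)
    k = params.shape(maternal_age)  # k > 0, so (t/b)**k is 0 at t = 0
    out = np.exp(-((t / b) ** k))
    return out if out.ndim else float(out)


def survival_probabilities(params: WeibullParams, s: int, omega: int) -> np.ndarray:
    """Daily conditional survival p[i, j] = S_i(j) / S_i(j-1), as s x omega.

    The last column (age ``omega``) is 0 by convention.  Strata where the
    survivorship has underflowed to zero are treated as dead (p = 0).
    """
    if s < 1 or omega < 1:
        raise ValueError("s and omega must be >= 1")
    ages = np.arange(0, omega + 1, dtype=float)
    p = np.zeros((s, omega))
    for idx, i in enumerate(range(1, s + 1)):
        surv = weibull_survivorship(params, i, ages)
        denom = surv[:-1]
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(denom > 0, surv[1:] / denom, 0.0)
        p[idx, : omega - 1] = ratio[: omega - 1]
    return np.clip(p, 0.0, 1.0)


def natural_fertility(params: CoaleTrussellParams, age) -> np.ndarray:
    """Age-only natural fertility n(j), clamped to 0 before reproduction begins."""
    j = np.asarray(age, dtype=float)
    c0, c1, c2 = params.natural_fertility_coeffs
    n = np.exp(c0 + c1 * j + c2 * j * j)
    return np.where(j >= params.min_reproductive_age, n, 0.0)


def fertility_schedule(params: CoaleTrussellParams, s: int, omega: int) -> np.ndarray:
    """Daily fertility table f[i, j] = n(j) * exp(m_i * nu(j)), as s x omega."""
    if s < 1 or omega < 1:
        raise ValueError("s and omega must be >= 1")
    ages = np.arange(1, omega + 1, dtype=float)
    n = natural_fertility(params, ages)
    nu = params.deviation(ages)
    m = params.control_level(np.arange(1, s + 1, dtype=float))
    return n[None, :] * np.exp(np.outer(m, nu))


def build_vital_rates(weibull: WeibullParams, fertility: CoaleTrussellParams,
                      s: int = 16, omega: int = 16) -> VitalRates:
    """Evaluate both parametric models into a VitalRates table."""
    return VitalRates(s=s, omega=omega,
                      p=survival_probabilities(weibull, s, omega),
                      f=fertility_schedule(fertility, s, omega))


# ---------------------------------------------------------------------------
# flat key-value (de)serialisation

def params_to_dict(weibull: WeibullParams, fertility: CoaleTrussellParams) -> dict:
    d = asdict(weibull)
    fd = asdict(fertility)
    coeffs = fd.pop("natural_fertility_coeffs")
    for k, v in zip(("c0", "c1", "c2"), coeffs):
        fd[f"natural_fertility_{k}"] = float(v)
    d.update(fd)
    return {k: (v if isinstance(v, int) else float(v)) for k, v in d.items()}


def params_from_dict(d: dict) -> tuple[WeibullParams, CoaleTrussellParams]:
    w = WeibullParams(
        log_scale_intercept=d["log_scale_intercept"],
        log_scale_slope=d["log_scale_slope"],
        log_shape_intercept=d["log_shape_intercept"],
        log_shape_slope=d["log_shape_slope"],
    )
    ct = CoaleTrussellParams(
        natural_fertility_coeffs=(
            d["natural_fertility_c0"], d["natural_fertility_c1"], d["natural_fertility_c2"]),
        control_threshold_age=int(d.get("control_threshold_age", 4)),
        deviation_slope=d.get("deviation_slope", 0.25),
        control_intercept=d.get("control_intercept", 0.0),
        control_slope=d.get("control_slope", 0.0),
        min_reproductive_age=int(d.get("min_reproductive_age", 2)),
    )
    return w, ct


def save_params(path, weibull: WeibullParams, fertility: CoaleTrussellParams) -> None:
    Path(path).write_text(yaml.safe_dump(params_to_dict(weibull, fertility), sort_keys=True))


def load_params(path) -> tuple[WeibullParams, CoaleTrussellParams]:
    return params_from_dict(yaml.safe_load(Path(path).read_text()))
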