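"""Maximum-likelihood estimation of vital-rate parameters from daily life tables.

Survival: interval-censored Weibull likelihood.  Deaths are only known
to the day (the 24-h observation cycle), so a death on day ``T``
contributes ``log(S_i(T-1) - S_i(T))``; an individual lost during day
``T`` was last seen alive at the end of day ``T-1`` and contributes
``log S_i(T-1)``; an individual alive at the end of observation on day
``T`` contributes ``log S_i(T)``.  Scale and shape depend log-linearly
on maternal age; the four coefficients are estimated by multi-start
quasi-local optimisation from moment-based initial guesses.

Fertility: daily daughter counts are modelled as Poisson with mean
``f[i, j] = n(j) * exp(m_i * nu(j))``.  With the deviation schedule
``nu`` held fixed (as in the classical formulation, where it is an
empirical standard), the log mean is linear in the remaining
coefficients and the fit is an ordinary Poisson regression, done through
statsmodels GLM.

A nonparametric layer (:func:`empirical_rates`) provides per-cell
survival fractions and mean counts for cross-checking the parametric
fits.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.optimize
import scipy.special
import statsmodels.api as sm

from .vital_rates import CoaleTrussellParams, VitalRates, WeibullParams

__all__ = ["WeibullFit", "CoaleTrussellFit", "EmpiricalRates",
           "fit_weibull", "fit_coale_trussell", "empirical_rates",
           "NonIdentifiableError", "DegenerateFitError", "ConvergenceError"]


class NonIdentifiableError(ValueError):
    """The data cannot pin down the parameters (e.g. no observed deaths)."""


class DegenerateFitError(ValueError):
    """The likelihood is degenerate (e.g. all offspring counts zero)."""


class ConvergenceError(RuntimeError):
    """The optimizer failed to converge; carries the optimizer diagnostics."""

    def __init__(self, message: str, diagnostics=None):
        super().__init__(message)
        self.diagnostics = diagnostics


@dataclass(frozen=True)
class WeibullFit:
    params: WeibullParams
    log_likelihood: float
    log_likelihood_at_init: float
    n_starts: int
    n_individuals: int
    n_deaths: int
    converged: bool


@dataclass(frozen=True)
class CoaleTrussellFit:
    params: CoaleTrussellParams
    log_likelihood: float
    standard_errors: dict[str, float] = field(default_factory=dict)
    n_observation_days: int = 0
    converged: bool = True


# ---------------------------------------------------------------------------
# life-table digestion

def _validate_life_table(data: pd.DataFrame) -> pd.DataFrame:
    required = {"individual_id", "maternal_age", "day", "alive", "censored", "offspring"}
    missing = required - set(data.columns)
    if missing:
        raise ValueError(f"life table is missing columns: {sorted(missing)}")
    if len(data) == 0:
        raise NonIdentifiableError("empty life table")
    return data


def _terminal_events(data: pd.DataFrame) -> pd.DataFrame:
    """One row per individual: maternal_age, last day, and event type.

    event: 'death' (final row alive = 0), 'lost' (final row censored = 1)
    or 'open' (alive at end of observation).
    """
    last = data.sort_values("day").groupby("individual_id").tail(1)
    event = np.where(last["alive"].to_numpy() == 0, "death",
                     np.where(last["censored"].to_numpy() == 1, "lost", "open"))
    return pd.DataFrame({
        "maternal_age": last["maternal_age"].to_numpy(),
        "day": last["day"].to_numpy(),
        "event": event,
    })


# ---------------------------------------------------------------------------
# Weibull survival fit

def _log_survivorship(theta: np.ndarray, i: np.ndarray, t: np.ndarray) -> np.ndarray:
    """log S_i(t) = -(t / b_i)^{k_i} with log-linear links, vectorised."""
    b = np.exp(theta[0] + theta[1] * i)
    k = np.exp(theta[2] + theta[3] * i)
    out = np.zeros_like(t, dtype=float)
    pos = t > 0
    out[pos] = -np.power(t[pos] / b[pos], k[pos])
    return out


def _weibull_negloglik(theta: np.ndarray, events: pd.DataFrame) -> float:
    i = events["maternal_age"].to_numpy(dtype=float)
    T = events["day"].to_numpy(dtype=float)
    ev = events["event"].to_numpy()
    total = 0.0
    death = ev == "death"
    if np.any(death):
        ls_prev = _log_survivorship(theta, i[death], T[death] - 1.0)
        ls_now = _log_survivorship(theta, i[death], T[death])
        # log(S(T-1) - S(T)) = log S(T-1) + log(1 - exp(log S(T) - log S(T-1)))
        diff = ls_now - ls_prev
        with np.errstate(divide="ignore"):
            term = ls_prev + np.log(-np.expm1(np.minimum(diff, -1e-300)))
        if not np.all(np.isfinite(term)):
            return np.inf
        total += term.sum()
    lost = ev == "lost"
    if np.any(lost):
        total += _log_survivorship(theta, i[lost], T[lost] - 1.0).sum()
    open_ = ev == "open"
    if np.any(open_):
        total += _log_survivorship(theta, i[open_], T[open_]).sum()
    return -total if np.isfinite(total) else np.inf


def _moment_init(events: pd.DataFrame) -> np.ndarray:
    """Per-cohort Weibull moments, then linear links across cohorts."""
    rows = []
    for i, grp in events.groupby("maternal_age"):
        T = grp["day"].to_numpy(dtype=float)
        mean, sd = T.mean(), T.std()
        if mean <= 0:
            continue
        cv = sd / mean if mean > 0 else 0.5
        cv = min(max(cv, 0.05), 1.5)
        k0 = cv ** -1.086  # standard moment approximation for Weibull shape
        b0 = mean / scipy.special.gamma(1.0 + 1.0 / k0)
        rows.append((float(i), math.log(b0), math.log(k0)))
    if not rows:
        raise NonIdentifiableError("no usable lifetimes for initialisation")
    arr = np.array(rows)
    if len(rows) >= 2:
        ls = np.polyfit(arr[:, 0], arr[:, 1], 1)
        lk = np.polyfit(arr[:, 0], arr[:, 2], 1)
        return np.array([ls[1], ls[0], lk[1], lk[0]])
    return np.array([arr[0, 1], 0.0, arr[0, 2], 0.0])


def fit_weibull(data: pd.DataFrame, n_starts: int = 5, seed: int = 0,
                fix_slopes: bool = False, tol: float = 1e-8) -> WeibullFit:
    """Fit the maternal-age-dependent Weibull survivorship by MLE.

    ``fix_slopes`` pins both maternal-age slopes at 0, reducing to an
    ordinary censored Weibull fit (useful for single-cohort data).
    Optimisation restarts from ``n_starts`` perturbed moment-based
    initial points and keeps the best optimum.
    """
    data = _validate_life_table(data)
    events = _terminal_events(data)
    n_deaths = int((events["event"] == "death").sum())
    if n_deaths == 0:
        raise NonIdentifiableError("no observed deaths; survival parameters not identifiable")
    n_classes = events["maternal_age"].nunique()
    if n_classes < 2 and not fix_slopes:
        raise NonIdentifiableError(
            "need >= 2 maternal age classes to estimate maternal-age slopes "
            "(or pass fix_slopes=True)")

    theta0 = _moment_init(events)
    if fix_slopes:
        free = np.array([0, 2])
    else:
        free = np.arange(4)

    def objective(x: np.ndarray) -> float:
        theta = theta0.copy()
        theta[free] = x
        if fix_slopes:
            theta[[1, 3]] = 0.0
        return _weibull_negloglik(theta, events)

    if fix_slopes:
        theta0 = theta0.copy()
        theta0[[1, 3]] = 0.0
    loglik_init = -objective(theta0[free])

    rng = np.random.default_rng(seed)
    best = None
    for start in range(max(1, n_starts)):
        x0 = theta0[free] if start == 0 else theta0[free] + rng.normal(0, 0.15, size=free.size)
        res = scipy.optimize.minimize(
            objective, x0, method="Nelder-Mead",
            options={"xatol": 1e-9, "fatol": tol, "maxiter": 20000, "maxfev": 40000})
        if best is None or res.fun < best.fun:
            best = res
    if best is None or not np.isfinite(best.fun):
        raise ConvergenceError("Weibull likelihood optimisation failed", best)
    theta = theta0.copy()
    theta[free] = best.x
    if fix_slopes:
        theta[[1, 3]] = 0.0
    params = WeibullParams(*theta)
    return WeibullFit(params=params, log_likelihood=float(-best.fun),
                      log_likelihood_at_init=float(loglik_init),
                      n_starts=max(1, n_starts),
                      n_individuals=len(events), n_deaths=n_deaths,
                      converged=bool(best.success))


# ---------------------------------------------------------------------------
# Coale-Trussell-style fertility fit

def fit_coale_trussell(data: pd.DataFrame, control_threshold_age: int = 4,
                       deviation_slope: float = 0.25,
                       min_reproductive_age: int | None = None) -> CoaleTrussellFit:
    """Fit the fertility model by Poisson regression on daily counts.

    The deviation schedule nu(j) = -deviation_slope * max(j - j*, 0) is
    held fixed; the natural-fertility coefficients and the control
    level's intercept and maternal-age slope are then linear in the log
    mean and estimated by Poisson GLM.  Only uncensored observation days
    at or past the minimum reproductive age contribute; days before the
    onset of reproduction are structural zeros, not model draws, so by
    default the onset is inferred as the first day with any recorded
    offspring.
    """
    data = _validate_life_table(data)
    alive_days = data[data["censored"] == 0]
    if alive_days["offspring"].sum() == 0:
        raise DegenerateFitError("all offspring counts are zero; fertility fit degenerate")
    if min_reproductive_age is None:
        min_reproductive_age = int(
            alive_days.loc[alive_days["offspring"] > 0, "day"].min())
    obs = alive_days[alive_days["day"] >= min_reproductive_age]
    if len(obs) == 0:
        raise DegenerateFitError("no uncensored reproductive-age observation days")
    if obs["maternal_age"].nunique() < 2:
        raise NonIdentifiableError(
            "need >= 2 maternal age classes to estimate the control slope")
    j = obs["day"].to_numpy(dtype=float)
    i = obs["maternal_age"].to_numpy(dtype=float)
    y = obs["offspring"].to_numpy(dtype=float)
    nu = -deviation_slope * np.maximum(j - control_threshold_age, 0.0)
    X = np.column_stack([np.ones_like(j), j, j * j, nu, i * nu])
    model = sm.GLM(y, X, family=sm.families.Poisson())
    res = model.fit()
    beta = res.params
    params = CoaleTrussellParams(
        natural_fertility_coeffs=(float(beta[0]), float(beta[1]), float(beta[2])),
        control_threshold_age=control_threshold_age,
        deviation_slope=deviation_slope,
        control_intercept=float(beta[3]),
        control_slope=float(beta[4]),
        min_reproductive_age=min_reproductive_age,
    )
    se = res.bse
    return CoaleTrussellFit(
        params=params,
        log_likelihood=float(res.llf),
        standard_errors={
            "natural_fertility_c0": float(se[0]),
            "natural_fertility_c1": float(se[1]),
            "natural_fertility_c2": float(se[2]),
            "control_intercept": float(se[3]),
            "control_slope": float(se[4]),
        },
        n_observation_days=len(obs),
        converged=bool(res.converged),
    )


# ---------------------------------------------------------------------------
# nonparametric rates

@dataclass(frozen=True)
class EmpiricalRates:
    """Cell-wise survival fractions and mean counts with at-risk sizes.

    Cells never observed (zero at-risk) hold NaN in ``p_hat``/``f_hat``
    and 0 in the corresponding at-risk count.
    """

    s: int
    omega: int
    p_hat: np.ndarray = field(repr=False)
    f_hat: np.ndarray = field(repr=False)
    at_risk_p: np.ndarray = field(repr=False)
    at_risk_f: np.ndarray = field(repr=False)


def empirical_rates(data: pd.DataFrame, s: int = 16, omega: int = 16) -> EmpiricalRates:
    """Nonparametric p-hat and f-hat by maternal age and age.

    For each cohort ``i`` and day ``j``: the at-risk set for survival is
    every individual with an uncensored day-``j`` record (it entered the
    day alive and was followed through it); the survival fraction is
    those still alive at the day's end.  The fertility estimate is the
    mean daughter count over the same records.
    """
    data = _validate_life_table(data)
    p_hat = np.full((s, omega), np.nan)
    f_hat = np.full((s, omega), np.nan)
    at_risk = np.zeros((s, omega), dtype=int)
    obs = data[data["censored"] == 0]
    grouped = obs.groupby(["maternal_age", "day"])
    for (i, j), grp in grouped:
        i, j = int(i), int(j)
        if not (1 <= i <= s and 1 <= j <= omega):
            continue
        n = len(grp)
        at_risk[i - 1, j - 1] = n
        p_hat[i - 1, j - 1] = grp["alive"].mean()
        f_hat[i - 1, j - 1] = grp["offspring"].mean()
    return EmpiricalRates(s=s, omega=omega, p_hat=p_hat, f_hat=f_hat,
                          at_risk_p=at_risk, at_risk_f=at_risk.copy())
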