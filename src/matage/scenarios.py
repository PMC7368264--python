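"""Stationary and maternal-effect-removal life-history variants.

Starting from a fitted high-growth model A, two stationary variants are
constructed: B divides every fertility by the net reproductive rate R0
(resource limitation; lambda and R0 both become 1), and C multiplies
every survival probability by a constant c found so that lambda = 1
(extra mortality hazard; multiplying survival by c adds -log c to the
cumulative hazard, so the multiplicative rule is an additive hazard in
disguise).  For each of A, B, C a removal variant gives every maternal
age class the schedules of a reference maternal age (default 3 d),
erasing maternal effect senescence.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.optimize

from . import block_model as bm
from .block_model import BlockModel
from .eigen_demography import eigen, net_reproductive_rate
from .vital_rates import VitalRates

__all__ = ["ScenarioSet", "normalize_fertility", "impose_hazard",
           "remove_maternal_effects", "build_scenarios"]

_LAMBDA_TOL = 1e-10


@dataclass(frozen=True)
class ScenarioSet:
    """The six labelled life histories and the constants that made them."""

    A: BlockModel
    B: BlockModel
    C: BlockModel
    A_r: BlockModel
    B_r: BlockModel
    C_r: BlockModel
    R0: float                    # divisor used for B
    hazard_multiplier: float     # survival multiplier used for C
    reference_maternal_age: int  # schedules copied in the removal variants

    def models(self) -> dict[str, BlockModel]:
        return {"A": self.A, "B": self.B, "C": self.C,
                "A_r": self.A_r, "B_r": self.B_r, "C_r": self.C_r}


def normalize_fertility(model: BlockModel) -> tuple[BlockModel, float]:
    """Divide all fertilities by R0, yielding a stationary population.

    Dividing F by R0 makes the next-generation matrix F(I-U)^{-1} have
    dominant eigenvalue 1, which forces lambda = 1 while leaving
    survival and the shape and timing of reproduction unchanged.
    Returns (new model, R0 of the input).
    """
    R0 = net_reproductive_rate(model)
    if R0 <= 0:
        raise ValueError("R0 is zero; cannot normalise fertility")
    out = BlockModel(s=model.s, omega=model.omega, U=model.U, F=model.F / R0)
    return out, R0


def scale_fertility_to_lambda(model: BlockModel, target: float) -> tuple[BlockModel, float]:
    """Multiply F by the scalar q that makes lambda(U + qF) = target.

    Generalises fertility normalisation to targets other than 1 (for
    target 1 the root is exactly 1/R0).  Requires lambda(U alone) <
    target, which holds whenever target >= 1 since U is substochastic.
    """
    s, omega = model.s, model.omega

    def g(q: float) -> float:
        return _lam(model.U, q * model.F, s, omega) - target

    hi = 1.0
    while g(hi) < 0:
        hi *= 2.0
        if hi > 1e9:
            raise ValueError("cannot bracket fertility multiplier")
    q = scipy.optimize.brentq(g, 1e-12, hi, xtol=1e-14, rtol=8.9e-16)
    return BlockModel(s=s, omega=omega, U=model.U, F=q * model.F), float(q)


def _lam(U: np.ndarray, F: np.ndarray, s: int, omega: int) -> float:
    return eigen(BlockModel(s=s, omega=omega, U=U, F=F)).lam


def impose_hazard(model: BlockModel, target: float = 1.0) -> tuple[BlockModel, float]:
    """Multiply all survival probabilities by a constant c so lambda = target.

    lambda(c U + F) is strictly increasing in c, so the root is bracketed
    in (0, 1] whenever lambda(F alone) < target < lambda(model); it is
    found by bracketed root search (bisection with inverse interpolation)
    and polished to |lambda - target| < 1e-10.
    """
    s, omega = model.s, model.omega
    lam_full = _lam(model.U, model.F, s, omega)
    if abs(lam_full - target) <= _LAMBDA_TOL:
        return model, 1.0
    if lam_full < target:
        raise ValueError(f"already subcritical: lambda = {lam_full:.6g} < {target}")
    try:
        lam_f_only = _lam(np.zeros_like(model.U), model.F, s, omega)
    except ValueError:  # F identically zero
        lam_f_only = 0.0
    if lam_f_only >= target:
        raise ValueError(
            f"no feasible multiplier: lambda of F alone is {lam_f_only:.6g} >= {target}")

    def g(c: float) -> float:
        return _lam(c * model.U, model.F, s, omega) - target

    lo = 1e-6
    if g(lo) > 0:
        lo = 1e-12
    c = scipy.optimize.brentq(g, lo, 1.0, xtol=1e-14, rtol=8.9e-16)
    achieved = g(c)
    if abs(achieved) > _LAMBDA_TOL:
        raise RuntimeError(
            f"root search failed to reach tolerance: |lambda - {target}| = {abs(achieved):.3g}")
    return BlockModel(s=s, omega=omega, U=c * model.U, F=model.F), float(c)


def remove_maternal_effects(vital: VitalRates, reference_maternal_age: int = 3) -> VitalRates:
    """Give every maternal age class the reference class's schedules.

    The output has p[i, j] = p[ref, j] and f[i, j] = f[ref, j] for all i:
    offspring quality no longer depends on maternal age.
    """
    if not 1 <= reference_maternal_age <= vital.s:
        raise ValueError(
            f"reference maternal age {reference_maternal_age} outside 1..{vital.s}")
    r = reference_maternal_age - 1
    p = np.tile(vital.p[r], (vital.s, 1))
    f = np.tile(vital.f[r], (vital.s, 1))
    return VitalRates(s=vital.s, omega=vital.omega, p=p, f=f)


def _removed(model: BlockModel, ref: int) -> BlockModel:
    return bm.build(remove_maternal_effects(bm.extract_vital_rates(model), ref))


def build_scenarios(vital: VitalRates, reference_maternal_age: int = 3,
                    target_lambda: float = 1.0) -> ScenarioSet:
    """Construct all six life histories from one fitted VitalRates table.

    A is the fitted model; B and C are its fertility-normalised and
    hazard-multiplied stationary variants (lambda = target_lambda); the
    removal variants A_r, B_r, C_r replace every maternal age class's
    schedules with those of the reference class in A, B and C
    respectively.
    """
    A = bm.build(vital)
    if target_lambda == 1.0:
        B, R0 = normalize_fertility(A)
    else:
        B, _ = scale_fertility_to_lambda(A, target_lambda)
        R0 = net_reproductive_rate(A)
    C, c = impose_hazard(A, target=target_lambda)
    return ScenarioSet(
        A=A, B=B, C=C,
        A_r=_removed(A, reference_maternal_age),
        B_r=_removed(B, reference_maternal_age),
        C_r=_removed(C, reference_maternal_age),
        R0=R0, hazard_multiplier=c,
        reference_maternal_age=reference_maternal_age,
    )
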