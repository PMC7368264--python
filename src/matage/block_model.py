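"""Block-structured projection matrices over age and maternal age.

The population vector collects maternal ages within age classes: state
``(i, j)`` (maternal age ``i``, age ``j``, both 1-based days) sits at flat
position ``(j - 1) * s + i`` (1-based).  The survival matrix ``U`` moves
individuals down the block subdiagonal (age ``j`` to ``j + 1``, maternal
age unchanged); the fertility matrix ``F`` occupies the first block row,
and within its age-``j`` block only row ``j`` is nonzero, because the
offspring of an age-``j`` mother start life in age class 1 with maternal
age ``j``.  The projection matrix is ``A = U + F``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .vital_rates import VitalRates

__all__ = ["BlockModel", "build", "project", "extract_vital_rates", "flat_index"]


def flat_index(i: int, j: int, s: int) -> int:
    """0-based flat position of state (maternal age i, age j), both 1-based."""
    return (j - 1) * s + (i - 1)


@dataclass(frozen=True)
class BlockModel:
    """Survival (U), fertility (F) and projection (A = U + F) matrices.

    All three are dense ``s*omega`` square arrays in the
    maternal-age-within-age ordering.
    """

    s: int
    omega: int
    U: np.ndarray = field(repr=False)
    F: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        dim = self.s * self.omega
        U = np.asarray(self.U, dtype=float)
        F = np.asarray(self.F, dtype=float)
        if U.shape != (dim, dim) or F.shape != (dim, dim):
            raise ValueError(f"U and F must be {dim}x{dim}")
        object.__setattr__(self, "U", U)
        object.__setattr__(self, "F", F)

    @property
    def A(self) -> np.ndarray:
        return self.U + self.F

    @property
    def dim(self) -> int:
        return self.s * self.omega


def build(vital: VitalRates) -> BlockModel:
    """Assemble U, F from a VitalRates table.

    Each survival probability ``p[i, j]`` (``j < omega``) lands at
    ``U[(i, j+1), (i, j)]`` and each fertility ``f[i, j]`` at
    ``F[(j, 1), (i, j)]`` in state coordinates; every rate appears in
    exactly one entry.
    """
    s, omega = vital.s, vital.omega
    dim = s * omega
    U = np.zeros((dim, dim))
    F = np.zeros((dim, dim))
    for j in range(1, omega + 1):
        for i in range(1, s + 1):
            col = flat_index(i, j, s)
            if j < omega:
                U[flat_index(i, j + 1, s), col] = vital.p[i - 1, j - 1]
            # offspring of an age-j mother acquire maternal age j, clamped to
            # the last maternal age class when mothers outlive it (s < omega)
            F[flat_index(min(j, s), 1, s), col] = vital.f[i - 1, j - 1]
    return BlockModel(s=s, omega=omega, U=U, F=F)


def extract_vital_rates(model: BlockModel) -> VitalRates:
    """Read the p and f tables back out of a BlockModel (inverse of build)."""
    s, omega = model.s, model.omega
    p = np.zeros((s, omega))
    f = np.zeros((s, omega))
    for j in range(1, omega + 1):
        for i in range(1, s + 1):
            col = flat_index(i, j, s)
            if j < omega:
                p[i - 1, j - 1] = model.U[flat_index(i, j + 1, s), col]
            f[i - 1, j - 1] = model.F[flat_index(min(j, s), 1, s), col]
    return VitalRates(s=s, omega=omega, p=p, f=f)


def validate_structure(model: BlockModel) -> None:
    """Reject nonzeros outside the permitted block positions.

    U may only be nonzero on the block subdiagonal diagonal entries;
    F only in block row 1, within block j only on row j.  Raises
    ``ValueError`` listing offending (row, col) 1-based positions.
    """
    s, omega = model.s, model.omega
    mask_u = np.zeros_like(model.U, dtype=bool)
    mask_f = np.zeros_like(model.F, dtype=bool)
    for j in range(1, omega):
        for i in range(1, s + 1):
            mask_u[flat_index(i, j + 1, s), flat_index(i, j, s)] = True
    for j in range(1, omega + 1):
        for i in range(1, s + 1):
            mask_f[flat_index(min(j, s), 1, s), flat_index(i, j, s)] = True
    bad_u = np.argwhere((model.U != 0) & ~mask_u)
    bad_f = np.argwhere((model.F != 0) & ~mask_f)
    msgs = []
    if bad_u.size:
        msgs.append(f"U has nonzeros off the block subdiagonal at {(bad_u + 1).tolist()}")
    if bad_f.size:
        msgs.append(f"F has nonzeros outside block row 1 / offspring rows at {(bad_f + 1).tolist()}")
    if np.any(model.U < 0) or np.any(model.U > 1):
        msgs.append("U entries outside [0, 1]")
    if np.any(model.F < 0):
        msgs.append("F has negative entries")
    if msgs:
        raise ValueError("; ".join(msgs))


def project(model: BlockModel, n0: np.ndarray, t: int) -> np.ndarray:
    """Iterate n(t+1) = A n(t); returns array of shape (t+1, s*omega).

    The initial vector must be nonnegative; every iterate then is.
    """
    n0 = np.asarray(n0, dtype=float)
    if n0.shape != (model.dim,):
        raise ValueError(f"n0 must have length {model.dim}")
    if np.any(n0 < 0):
        raise ValueError("initial population vector must be nonnegative")
    A = model.A
    out = np.empty((t + 1, model.dim))
    out[0] = n0
    for step in range(t):
        out[step + 1] = A @ out[step]
    return out
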