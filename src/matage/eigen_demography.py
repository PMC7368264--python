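"""Asymptotic demography of a block projection matrix.

Computes the dominant eigenvalue lambda (the fitness measure: the
population ultimately grows by the factor lambda each day), the stable
age-by-maternal-age distribution w (right eigenvector, normalised to sum
to 1), reproductive values v (left eigenvector, scaled so v'w = 1), and
the net reproductive rate R0 — the expected lifetime offspring of a
newborn, the dominant eigenvalue of the next-generation matrix
F (I - U)^{-1}.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import scipy.linalg

from .block_model import BlockModel, flat_index

__all__ = ["EigenAnalysis", "eigen", "net_reproductive_rate", "structure_summary"]

_IMAG_TOL = 1e-10


class ImprimitiveMatrixError(ValueError):
    """Dominant eigenvalue is genuinely complex (imprimitive rotational input)."""


@dataclass(frozen=True)
class EigenAnalysis:
    lam: float
    w: np.ndarray = field(repr=False)
    v: np.ndarray = field(repr=False)
    R0: float
    s: int
    omega: int
    residual: float  # max of the two eigen-equation residuals, infinity norm

    @property
    def log_lam(self) -> float:
        return float(np.log(self.lam))


def _dominant_pair(M: np.ndarray) -> tuple[float, np.ndarray]:
    """Perron eigenvalue of a nonnegative matrix and its right eigenvector.

    Among eigenvalues tied in modulus (an imprimitive matrix carries a
    full ring of them) the real nonnegative Perron root is selected; a
    genuinely complex dominant pair with no real root of equal modulus
    is an error, never silently truncated.
    """
    vals, vecs = scipy.linalg.eig(M)
    mod = np.abs(vals)
    top = float(mod.max())
    scale = max(1.0, top)
    ties = np.flatnonzero(mod >= top - _IMAG_TOL * scale)
    k = int(ties[np.argmax(vals[ties].real)])
    lam = vals[k]
    if abs(lam.imag) > _IMAG_TOL * scale or lam.real < 0:
        raise ImprimitiveMatrixError(
            f"dominant eigenvalue is complex ({lam:.6g}); no real Perron root found")
    vec = vecs[:, k].real
    if vec.sum() < 0:
        vec = -vec
    return float(lam.real), vec


def eigen(model: BlockModel) -> EigenAnalysis:
    """Dominant eigen-triple (lambda, w, v) plus R0 of a BlockModel.

    Raises on an identically zero matrix (lambda = 0 leaves the stable
    structure undefined) and on complex dominant pairs.
    """
    A = model.A
    if not np.any(A):
        raise ValueError("projection matrix is identically zero; lambda = 0, w undefined")
    lam, w = _dominant_pair(A)
    _, v = _dominant_pair(A.T)
    w = np.abs(w)
    v = np.abs(v)
    w = w / w.sum()
    vw = float(v @ w)
    if vw <= 0:
        raise ValueError("degenerate eigenvectors: v'w = 0")
    v = v / vw
    scale = max(lam, 1.0)
    residual = max(
        float(np.max(np.abs(A @ w - lam * w))),
        float(np.max(np.abs(v @ A - lam * v))),
    ) / scale
    return EigenAnalysis(lam=lam, w=w, v=v, R0=net_reproductive_rate(model),
                         s=model.s, omega=model.omega, residual=residual)


def net_reproductive_rate(model: BlockModel) -> float:
    """R0: dominant eigenvalue of the next-generation matrix F (I - U)^{-1}.

    U is nilpotent (nobody outlives the last age class), so I - U is
    always invertible.
    """
    dim = model.dim
    N = scipy.linalg.solve(np.eye(dim) - model.U.T, model.F.T).T  # F (I-U)^{-1}
    if not np.any(N):
        return 0.0
    vals = scipy.linalg.eigvals(N)
    return float(np.max(np.abs(vals)))


def structure_summary(e: EigenAnalysis, max_age: int, max_maternal_age: int) -> float:
    """Fraction of the stable population with age <= max_age and maternal
    age <= max_maternal_age (both bounds inclusive)."""
    if not (0 <= max_age <= e.omega) or not (0 <= max_maternal_age <= e.s):
        raise ValueError(
            f"bounds must lie in 0..{e.omega} (age) and 0..{e.s} (maternal age)")
    total = 0.0
    for j in range(1, max_age + 1):
        for i in range(1, max_maternal_age + 1):
            total += e.w[flat_index(i, j, e.s)]
    return float(total)


def structure_grid(e: EigenAnalysis) -> np.ndarray:
    """Stable structure reshaped to an s x omega grid, [i-1, j-1]."""
    return e.w.reshape(e.omega, e.s).T.copy()


def to_report(e: EigenAnalysis, summaries: dict[str, tuple[int, int]] | None = None) -> dict:
    """Machine-readable analysis report (JSON-serialisable)."""
    rep = {
        "lambda": e.lam,
        "log_lambda": e.log_lam,
        "R0": e.R0,
        "s": e.s,
        "omega": e.omega,
        "residual": e.residual,
        "w": e.w.tolist(),
        "v": e.v.tolist(),
    }
    if summaries:
        rep["structure_summaries"] = {
            name: {"max_age": a, "max_maternal_age": i,
                   "fraction": structure_summary(e, a, i)}
            for name, (a, i) in summaries.items()
        }
    return rep


def save_report(path, e: EigenAnalysis, summaries=None) -> None:
    Path(path).write_text(json.dumps(to_report(e, summaries), indent=2))
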