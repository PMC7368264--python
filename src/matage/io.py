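"""File formats: life-table CSV, dense matrix CSV, MatrixMarket, reports.

Matrix files carry a metadata header recording ``s``, ``omega``, the
block kind (``U``, ``F``, or a per-age block ``U_j``/``F_j``) and the
state ordering (maternal ages grouped within age classes), so a file is
never interpreted under the wrong convention.  Whole-matrix and
per-age-block layouts are both accepted on read; structural invariants
(U on the block subdiagonal, F in block row 1) are enforced, and a
violation is rejected with the offending positions listed.
"""

from __future__ import annotations

import io as _io
import re
from pathlib import Path

import numpy as np
import scipy.io
import scipy.sparse
import yaml

from .block_model import BlockModel, flat_index, validate_structure

__all__ = ["write_matrix", "read_matrix", "write_block_model", "read_block_model",
           "load_config", "save_config"]

_ORDERING = "maternal-age-within-age"
_FLOAT_FMT = "%.17g"


# ---------------------------------------------------------------------------
# single matrices

def _header(s: int, omega: int, kind: str, block_age: int | None) -> str:
    h = f"s={s} omega={omega} kind={kind} ordering={_ORDERING}"
    if block_age is not None:
        h += f" block_age={block_age}"
    return h


def _parse_header(text: str) -> dict:
    meta = {}
    for m in re.finditer(r"(\w+)=([\w.-]+)", text):
        meta[m.group(1)] = m.group(2)
    for key in ("s", "omega"):
        if key not in meta:
            raise ValueError(f"matrix header is missing '{key}='")
        meta[key] = int(meta[key])
    if "kind" not in meta:
        raise ValueError("matrix header is missing 'kind='")
    if "block_age" in meta:
        meta["block_age"] = int(meta["block_age"])
    return meta


def write_matrix(path, M: np.ndarray, s: int, omega: int, kind: str,
                 block_age: int | None = None) -> None:
    """Write a dense matrix as CSV (.csv) or MatrixMarket (.mtx).

    ``kind`` is ``"U"``, ``"F"`` or ``"A"``; ``block_age`` marks a
    per-age s x s block.  Metadata goes in a leading comment line.
    """
    path = Path(path)
    header = _header(s, omega, kind, block_age)
    if path.suffix == ".mtx":
        buf = _io.BytesIO()
        scipy.io.mmwrite(buf, scipy.sparse.coo_matrix(M), comment=header,
                         precision=17)
        path.write_bytes(buf.getvalue())
    else:
        with path.open("w") as fh:
            fh.write(f"# {header}\n")
            np.savetxt(fh, np.asarray(M, dtype=float), delimiter=",", fmt=_FLOAT_FMT)


def read_matrix(path) -> tuple[np.ndarray, dict]:
    """Read a matrix written by :func:`write_matrix`; returns (array, metadata)."""
    path = Path(path)
    if path.suffix == ".mtx":
        comment_text = ""
        with path.open() as fh:
            fh.readline()  # banner
            for line in fh:
                if line.startswith("%"):
                    comment_text += line.lstrip("% ")
                else:
                    break
        meta = _parse_header(comment_text)
        M = scipy.io.mmread(str(path))
        if scipy.sparse.issparse(M):
            M = M.toarray()
        M = np.asarray(M, dtype=float)
    else:
        with path.open() as fh:
            first = fh.readline()
            if not first.startswith("#"):
                raise ValueError(f"{path}: missing metadata header line")
            meta = _parse_header(first)
            M = np.loadtxt(fh, delimiter=",", ndmin=2)
    return M, meta


# ---------------------------------------------------------------------------
# block models

def write_block_model(directory, model: BlockModel, fmt: str = "csv",
                      per_age_blocks: bool = False) -> list[Path]:
    """Write U and F under ``directory`` as whole matrices or per-age blocks."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    ext = {"csv": ".csv", "mm": ".mtx", "mtx": ".mtx"}[fmt]
    s, omega = model.s, model.omega
    written = []
    if not per_age_blocks:
        for kind, M in (("U", model.U), ("F", model.F)):
            p = directory / f"{kind}{ext}"
            write_matrix(p, M, s, omega, kind)
            written.append(p)
        return written
    for j in range(1, omega):  # U_j blocks: survival out of age j
        block = model.U[j * s:(j + 1) * s, (j - 1) * s:j * s]
        p = directory / f"U_{j:02d}{ext}"
        write_matrix(p, block, s, omega, "U", block_age=j)
        written.append(p)
    for j in range(1, omega + 1):
        block = model.F[0:s, (j - 1) * s:j * s]
        p = directory / f"F_{j:02d}{ext}"
        write_matrix(p, block, s, omega, "F", block_age=j)
        written.append(p)
    return written


def _assemble_from_blocks(files: list[Path]) -> BlockModel:
    metas = []
    for f in files:
        M, meta = read_matrix(f)
        metas.append((M, meta))
    s = metas[0][1]["s"]
    omega = metas[0][1]["omega"]
    dim = s * omega
    U = np.zeros((dim, dim))
    F = np.zeros((dim, dim))
    for M, meta in metas:
        if (meta["s"], meta["omega"]) != (s, omega):
            raise ValueError("inconsistent s/omega across block files")
        j = meta["block_age"]
        if M.shape != (s, s):
            raise ValueError(f"block {meta['kind']}_{j} must be {s}x{s}, got {M.shape}")
        if meta["kind"] == "U":
            U[j * s:(j + 1) * s, (j - 1) * s:j * s] = M
        elif meta["kind"] == "F":
            F[0:s, (j - 1) * s:j * s] = M
        else:
            raise ValueError(f"unknown block kind {meta['kind']!r}")
    return BlockModel(s=s, omega=omega, U=U, F=F)


def read_block_model(directory) -> BlockModel:
    """Read U and F from ``directory`` (whole-matrix or per-age-block files).

    Accepts ``U.csv``/``F.csv`` (or ``.mtx``), else per-age files
    ``U_01..``/``F_01..``.  The assembled model is checked against the
    structural invariants and rejected on any out-of-place nonzero.
    """
    directory = Path(directory)
    whole = {}
    for ext in (".csv", ".mtx"):
        for kind in ("U", "F"):
            p = directory / f"{kind}{ext}"
            if p.exists():
                whole[kind] = p
        if len(whole) == 2:
            break
        whole = {}
    if whole:
        U, mu = read_matrix(whole["U"])
        F, mf = read_matrix(whole["F"])
        if (mu["s"], mu["omega"]) != (mf["s"], mf["omega"]):
            raise ValueError("U and F headers disagree on s/omega")
        model = BlockModel(s=mu["s"], omega=mu["omega"], U=U, F=F)
    else:
        blocks = sorted(directory.glob("U_*")) + sorted(directory.glob("F_*"))
        blocks = [b for b in blocks if b.suffix in (".csv", ".mtx")]
        if not blocks:
            raise FileNotFoundError(
                f"no U/F matrix files (whole or per-age-block) found in {directory}")
        model = _assemble_from_blocks(blocks)
    validate_structure(model)
    return model


# ---------------------------------------------------------------------------
# config

def load_config(path) -> dict:
    cfg = yaml.safe_load(Path(path).read_text())
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: config must be a mapping")
    return cfg


def save_config(path, cfg: dict) -> None:
    Path(path).write_text(yaml.safe_dump(cfg, sort_keys=True))
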