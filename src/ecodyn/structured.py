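"""Age-structured population growth via Leslie matrix projection.

A Leslie matrix has per-capita fecundities on its top row and survival
probabilities on the subdiagonal (pre-breeding census, birth-pulse
convention).  Its dominant eigenvalue is the asymptotic growth rate
lambda, and the matching right eigenvector, normalised to sum one, is the
stable age distribution the population converges to.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import Trajectory

__all__ = [
    "LeslieMatrix",
    "project_structured",
    "leslie_summary",
    "leslie_edges",
    "leslie_from_csv",
]

#: imaginary parts below this are treated as zero when picking the real
#: dominant eigenvalue
_REAL_TOL = 1e-12


@dataclass(frozen=True)
class LeslieMatrix:
    """Validated nonnegative projection matrix with Leslie structure."""

    matrix: np.ndarray

    def __post_init__(self):
        A = np.atleast_2d(np.asarray(self.matrix, dtype=float))
        if A.ndim != 2 or A.shape[0] != A.shape[1]:
            raise ValueError("Leslie matrix must be square")
        if np.any(A < 0):
            raise ValueError("Leslie matrix entries must be nonnegative")
        n = A.shape[0]
        surv = np.diag(A, k=-1) if n > 1 else np.array([])
        if np.any(surv > 1.0):
            raise ValueError("survival probabilities must be in [0, 1]")
        mask = np.ones_like(A, dtype=bool)
        mask[0, :] = False
        if n > 1:
            mask[np.arange(1, n), np.arange(n - 1)] = False
        if np.any(A[mask] != 0):
            raise ValueError("entries off the top row and subdiagonal must be zero")
        object.__setattr__(self, "matrix", A)

    @property
    def size(self) -> int:
        return self.matrix.shape[0]

    @property
    def fecundity(self) -> np.ndarray:
        return self.matrix[0, :].copy()

    @property
    def survival(self) -> np.ndarray:
        return np.diag(self.matrix, k=-1).copy()


def leslie_from_csv(path) -> LeslieMatrix:
    """Read a Leslie matrix from a headerless square numeric CSV grid."""
    grid = pd.read_csv(path, header=None).to_numpy(dtype=float)
    return LeslieMatrix(grid)


def project_structured(L: LeslieMatrix, n0, T: int) -> Trajectory:
    """Project an initial age vector forward: row t = L^t · n0.

    ``n0`` may be a sequence or a mapping keyed ``age1..ageN``.  A total
    population column is appended.
    """
    if isinstance(n0, dict):
        n0 = [n0[f"age{i + 1}"] for i in range(L.size)]
    v = np.asarray(list(n0), dtype=float)
    if v.shape != (L.size,):
        raise ValueError(f"initial vector length {v.size} != {L.size} age classes")
    if T < 0:
        raise ValueError("T must be >= 0")
    rows = np.empty((T + 1, L.size), dtype=float)
    rows[0] = v
    for t in range(T):
        rows[t + 1] = L.matrix @ rows[t]
    states = np.column_stack([rows, rows.sum(axis=1)])
    names = [f"age{i + 1}" for i in range(L.size)] + ["total"]
    return Trajectory(
        time=np.arange(T + 1, dtype=float),
        states=states,
        state_names=names,
        meta={"model": "structured-population", "leslie": L.matrix.tolist(), "n_steps": T},
    )


def leslie_summary(L: LeslieMatrix, T: int = 100) -> dict:
    """Asymptotic growth rate, stable age distribution, and achieved-lambda series.

    ``lambda`` is the dominant eigenvalue (largest modulus, ties broken by
    largest real part); ``stable_age_dist`` its right eigenvector normalised
    to sum 1.  ``achieved_lambda_series`` is total(t+1)/total(t) from a
    default projection started at a uniform age vector; for primitive
    matrices it converges to lambda.
    """
    A = L.matrix
    if not np.any(A):
        raise ValueError("degenerate all-zero Leslie matrix")
    vals, vecs = np.linalg.eig(A)
    order = np.lexsort((-vals.real, -np.abs(vals)))
    k = order[0]
    lam_c, w = vals[k], vecs[:, k]
    if abs(lam_c.imag) > _REAL_TOL * max(1.0, abs(lam_c.real)):
        lam = float(abs(lam_c))
    else:
        lam = float(lam_c.real)
    w = np.real_if_close(w, tol=1e6)
    w = np.abs(w.real)
    sad = w / w.sum()

    proj = project_structured(L, np.ones(L.size), T)
    total = proj["total"]
    with np.errstate(divide="ignore", invalid="ignore"):
        achieved = total[1:] / total[:-1]
    return {
        "lambda": lam,
        "stable_age_dist": sad,
        "achieved_lambda_series": achieved,
        "eigenvalues": vals,
    }


def leslie_edges(L: LeslieMatrix) -> list[tuple[int, int, float]]:
    """Life-cycle graph edges, one per nonzero matrix entry.

    Survival entries give ``i -> i+1`` edges; fecundities give ``i -> 1``.
    Classes are numbered from 1 for diagram rendering.
    """
    edges = []
    for j, f in enumerate(L.fecundity):
        if f != 0:
            edges.append((j + 1, 1, float(f)))
    for i, s in enumerate(L.survival):
        if s != 0:
            edges.append((i + 1, i + 2, float(s)))
    return edges
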