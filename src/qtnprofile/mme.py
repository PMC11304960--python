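"""Mixed-model equations for the single-trait animal model.

Model: ``y = 1μ + W u + e`` with ``Var(u) = H σ²_u`` and ``Var(e) = I σ²_e``.
Variance components are treated as known (the simulation truth), entering
only through the ratio ``λ = σ²_e / σ²_u``.  The coefficient matrix is

    [ 1'1      1'W            ]
    [ W'1      W'W + H⁻¹ λ    ]

Animals without records are carried by the H⁻¹ block alone.  Solutions come
from a dense symmetric factorization; the prediction-error (co)variance of
the genotyped animals is the corresponding block of ``σ²_e · C⁻¹`` with C
the coefficient matrix, obtained by solving for unit right-hand sides rather
than forming the full inverse.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg

__all__ = ["MmeSystem", "SsgblupFit", "build_mme", "solve_mme", "pev_block",
           "fit_ssgblup", "reliability"]


@dataclass
class MmeSystem:
    """Assembled left-hand side and right-hand side of the equations."""

    lhs: np.ndarray        # (n+1, n+1): overall mean then one equation per animal
    rhs: np.ndarray        # (n+1,)
    n_animals: int
    n_records: int
    lambda_ratio: float


@dataclass
class SsgblupFit:
    """Solution container: fixed effect, GEBVs, PEV block for genotyped animals."""

    mu_hat: float
    u_hat: np.ndarray             # (n_animals,)
    genotyped_idx: np.ndarray
    c_u2u2: np.ndarray | None     # (n_gen, n_gen) PEV block, trait units²
    sigma2_u: float
    sigma2_e: float

    @property
    def pev(self) -> np.ndarray:
        if self.c_u2u2 is None:
            raise ValueError("PEV block was not computed")
        return np.diag(self.c_u2u2)


def build_mme(y: np.ndarray, record_idx: np.ndarray, hinv: np.ndarray,
              lambda_ratio: float = 1.0) -> MmeSystem:
    """Assemble the equations.

    ``record_idx`` maps each record in ``y`` to a 0-based animal index; an
    animal may have zero or several records.  Requires at least one record
    (otherwise the mean equation is singular).
    """
    y = np.asarray(y, dtype=float)
    record_idx = np.asarray(record_idx, dtype=int)
    if y.shape != record_idx.shape:
        raise ValueError("y and record_idx must have matching shapes")
    if y.size == 0:
        raise ValueError("no phenotypic records: the mean equation is singular")
    n = hinv.shape[0]
    if hinv.shape != (n, n):
        raise ValueError("hinv must be square")
    if record_idx.min() < 0 or record_idx.max() >= n:
        raise ValueError("record_idx out of range")
    if lambda_ratio <= 0:
        raise ValueError("lambda_ratio must be > 0")

    counts = np.bincount(record_idx, minlength=n).astype(float)
    lhs = np.empty((n + 1, n + 1))
    lhs[0, 0] = y.size
    lhs[0, 1:] = counts
    lhs[1:, 0] = counts
    lhs[1:, 1:] = lambda_ratio * hinv
    lhs[np.arange(1, n + 1), np.arange(1, n + 1)] += counts
    rhs = np.empty(n + 1)
    rhs[0] = y.sum()
    rhs[1:] = np.bincount(record_idx, weights=y, minlength=n)
    return MmeSystem(lhs=lhs, rhs=rhs, n_animals=n, n_records=y.size,
                     lambda_ratio=lambda_ratio)


def solve_mme(mme: MmeSystem, rtol: float = 1e-8) -> tuple[float, np.ndarray]:
    """Solve for ``(μ̂, û)`` by dense symmetric factorization.

    Verifies the residual of the normal equations against ``rtol`` relative
    to the right-hand-side norm.
    """
    sol = scipy.linalg.solve(mme.lhs, mme.rhs, assume_a="sym")
    resid = np.linalg.norm(mme.lhs @ sol - mme.rhs)
    scale = max(np.linalg.norm(mme.rhs), 1.0)
    if resid > rtol * scale:
        raise np.linalg.LinAlgError(
            f"MME solution residual {resid:.3e} exceeds tolerance; the "
            f"coefficient matrix may be singular"
        )
    return float(sol[0]), sol[1:]


def pev_block(mme: MmeSystem, genotyped_idx: np.ndarray,
              sigma2_e: float) -> np.ndarray:
    """Prediction-error (co)variance block ``C^{u2,u2}`` for genotyped animals.

    The genotyped-animal block of ``σ²_e · C⁻¹`` restricted to animal
    equations, computed by Cholesky solves against unit columns.  Symmetric
    with non-negative diagonal.
    """
    g_idx = np.asarray(genotyped_idx, dtype=int)
    try:
        c, low = scipy.linalg.cho_factor(mme.lhs)
    except scipy.linalg.LinAlgError as err:
        raise np.linalg.LinAlgError("MME coefficient matrix is singular") from err
    rhs = np.zeros((mme.n_animals + 1, g_idx.size))
    rhs[1 + g_idx, np.arange(g_idx.size)] = 1.0
    cols = scipy.linalg.cho_solve((c, low), rhs)
    block = sigma2_e * cols[1 + g_idx, :]
    return 0.5 * (block + block.T)


def fit_ssgblup(y: np.ndarray, record_idx: np.ndarray, hinv: np.ndarray,
                genotyped_idx: np.ndarray, sigma2_u: float = 1.0,
                sigma2_e: float = 1.0, compute_pev: bool = True) -> SsgblupFit:
    """Assemble, solve, and extract the PEV block.

    Factorizes the coefficient matrix once (in place) and reuses the factor
    for both the solution and the PEV columns, so large systems pay for a
    single Cholesky decomposition.
    """
    mme = build_mme(y, record_idx, hinv, lambda_ratio=sigma2_e / sigma2_u)
    g_idx = np.asarray(genotyped_idx, dtype=int)
    rhs = mme.rhs.copy()
    try:
        factor = scipy.linalg.cho_factor(mme.lhs, overwrite_a=True)
    except scipy.linalg.LinAlgError as err:
        raise np.linalg.LinAlgError("MME coefficient matrix is singular") from err
    sol = scipy.linalg.cho_solve(factor, rhs)
    c22 = None
    if compute_pev and g_idx.size:
        unit = np.zeros((mme.n_animals + 1, g_idx.size))
        unit[1 + g_idx, np.arange(g_idx.size)] = 1.0
        cols = scipy.linalg.cho_solve(factor, unit)
        block = sigma2_e * cols[1 + g_idx, :]
        c22 = 0.5 * (block + block.T)
    return SsgblupFit(mu_hat=float(sol[0]), u_hat=sol[1:],
                      genotyped_idx=g_idx, c_u2u2=c22,
                      sigma2_u=sigma2_u, sigma2_e=sigma2_e)


def reliability(pev: np.ndarray, h_diag: np.ndarray, sigma2_u: float) -> np.ndarray:
    """Individual reliabilities ``1 − PEV_i / (σ²_u · H_ii)``, in [0, 1]."""
    rel = 1.0 - np.asarray(pev, float) / (sigma2_u * np.asarray(h_diag, float))
    return np.clip(rel, 0.0, 1.0)
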