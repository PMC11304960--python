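"""Pedigree and genomic relationship machinery.

Dense implementations of the standard single-step ingredients: the numerator
relationship matrix A (tabular method), its direct inverse with inbreeding
(Henderson rules), the VanRaden genomic relationship matrix G, blending of G
with the pedigree submatrix A22, the tuning statistics (ρ, δ) aligning the
genetic base of G to A22, and the Aguilar-form H⁻¹.

Dense algebra throughout — the intended scale is a few thousand genotyped
animals.  Individuals are referenced by 0-based row index; pedigrees must
list parents before offspring.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import scipy.linalg

__all__ = [
    "pedigree_arrays",
    "numerator_relationship",
    "a_inverse",
    "inbreeding",
    "vanraden_g",
    "blend_and_tune",
    "h_inverse",
    "h_matrix",
]


def pedigree_arrays(ped: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    """0-based (sire, dam) index arrays from an id/sire/dam frame.

    Ids must be 1-based and consecutive in row order; 0 marks an unknown
    parent and maps to -1.  Raises if any parent does not precede its
    offspring (which also rules out an individual being its own ancestor).
    """
    ids = ped["id"].to_numpy()
    n = len(ids)
    if not np.array_equal(ids, np.arange(1, n + 1)):
        raise ValueError("pedigree ids must be 1..n in row order")
    sire = ped["sire"].to_numpy(dtype=np.int64) - 1
    dam = ped["dam"].to_numpy(dtype=np.int64) - 1
    rows = np.arange(n)
    if np.any(sire >= rows) or np.any(dam >= rows):
        raise ValueError("parents must precede offspring in the pedigree")
    return sire, dam


def numerator_relationship(ped: pd.DataFrame) -> np.ndarray:
    """Pedigree numerator relationship matrix A by the tabular method.

    ``A_ii = 1 + F_i`` with F the inbreeding coefficient; symmetric.
    """
    sire, dam = pedigree_arrays(ped)
    n = len(sire)
    a = np.zeros((n, n))
    for i in range(n):
        s, d = sire[i], dam[i]
        if s >= 0 and d >= 0:
            a[i, :i] = 0.5 * (a[s, :i] + a[d, :i])
            a[i, i] = 1.0 + 0.5 * a[s, d]
        elif s >= 0 or d >= 0:
            p = s if s >= 0 else d
            a[i, :i] = 0.5 * a[p, :i]
            a[i, i] = 1.0
        else:
            a[i, i] = 1.0
        a[:i, i] = a[i, :i]
    return a


def inbreeding(ped: pd.DataFrame) -> np.ndarray:
    """Inbreeding coefficients F (diagonal of A minus one)."""
    return np.diag(numerator_relationship(ped)) - 1.0


def a_inverse(ped: pd.DataFrame, f: np.ndarray | None = None) -> np.ndarray:
    """Direct construction of A⁻¹ with inbreeding (Henderson rules).

    The Mendelian-sampling variance of individual i is
    ``0.5 − 0.25·(F_s + F_d)`` with both parents known, ``0.75 − 0.25·F_p``
    with one, and 1 with none; its reciprocal is scattered over the
    individual/parent equations with coefficients (1, −1/2, 1/4).
    """
    sire, dam = pedigree_arrays(ped)
    if f is None:
        f = inbreeding(ped)
    n = len(sire)
    ainv = np.zeros((n, n))
    for i in range(n):
        s, d = sire[i], dam[i]
        if s >= 0 and d >= 0:
            m = 0.5 - 0.25 * (f[s] + f[d])
        elif s >= 0 or d >= 0:
            m = 0.75 - 0.25 * f[s if s >= 0 else d]
        else:
            m = 1.0
        w = 1.0 / m
        ainv[i, i] += w
        for p in (s, d):
            if p >= 0:
                ainv[i, p] -= 0.5 * w
                ainv[p, i] -= 0.5 * w
        for p in (s, d):
            for q in (s, d):
                if p >= 0 and q >= 0:
                    ainv[p, q] += 0.25 * w
    return ainv


def vanraden_g(genotypes: np.ndarray, p: np.ndarray | None = None,
               weights: np.ndarray | None = None) -> tuple[np.ndarray, np.ndarray]:
    """VanRaden genomic relationship matrix ``G = Z D Z' / (2·Σ p(1−p))``.

    ``Z`` is the 0/1/2 allele-content matrix centred by ``2·p_j``; ``p``
    defaults to frequencies observed in the supplied (current genotyped)
    individuals.  Monomorphic SNP contribute zero to both numerator and
    denominator but keep their column so SNP coordinates never shift.
    Returns ``(G, p)``.
    """
    m = np.asarray(genotypes, dtype=float)
    if m.ndim != 2:
        raise ValueError("genotypes must be a 2-D (individuals x SNP) matrix")
    if p is None:
        p = m.mean(axis=0) / 2.0
    p = np.asarray(p, dtype=float)
    het = p * (1.0 - p)
    if weights is not None:
        het = het * np.asarray(weights, dtype=float)
    denom = 2.0 * het.sum()
    if denom <= 0.0:
        raise ValueError("all SNP are monomorphic; G is undefined")
    z = m - 2.0 * p
    if weights is not None:
        g = (z * np.asarray(weights, dtype=float)) @ z.T / denom
    else:
        g = z @ z.T / denom
    return 0.5 * (g + g.T), p


def blend_and_tune(g: np.ndarray, a22: np.ndarray, alpha: float = 0.95,
                   include_diagonal: bool = True) -> tuple[np.ndarray, float, float]:
    """Blend G towards A22 and compute the base-alignment statistics.

    ``Gb = α·G + (1−α)·A22`` guarantees invertibility for α < 1;
    ``ρ = mean(G − A22)`` over all n² elements (set
    ``include_diagonal=False`` for the off-diagonal-only variant) and
    ``δ = 1 − ρ/2`` adjusts the genetic base of G to that of A22.
    Returns ``(Gb, rho, delta)``.
    """
    if not 0.0 < alpha <= 1.0:
        raise ValueError("alpha must be in (0, 1]")
    if g.shape != a22.shape:
        raise ValueError("G and A22 must be conformable")
    diff = g - a22
    if include_diagonal:
        rho = float(diff.mean())
    else:
        n = g.shape[0]
        rho = float((diff.sum() - np.trace(diff)) / (n * (n - 1)))
    delta = 1.0 - rho / 2.0
    gb = alpha * g + (1.0 - alpha) * a22
    return gb, rho, delta


def _pd_inverse(mat: np.ndarray, name: str) -> np.ndarray:
    try:
        c, low = scipy.linalg.cho_factor(mat)
    except scipy.linalg.LinAlgError as err:
        raise np.linalg.LinAlgError(
            f"{name} is not positive definite; lower the blending weight "
            f"alpha (more pedigree) or check the pedigree/genotype inputs"
        ) from err
    return scipy.linalg.cho_solve((c, low), np.eye(mat.shape[0]))


def h_inverse(ainv: np.ndarray, a22: np.ndarray, gb: np.ndarray,
              genotyped_idx: np.ndarray) -> np.ndarray:
    """Single-step relationship inverse (Aguilar form).

    ``H⁻¹ = A⁻¹`` plus ``Gb⁻¹ − A22⁻¹`` added into the genotyped block.
    With no genotyped animals, or with ``Gb = A22``, this is exactly A⁻¹.
    """
    genotyped_idx = np.asarray(genotyped_idx, dtype=int)
    hinv = ainv.copy()
    if genotyped_idx.size == 0:
        return hinv
    if gb.shape[0] != genotyped_idx.size or a22.shape[0] != genotyped_idx.size:
        raise ValueError("Gb/A22 dimension must match the genotyped index set")
    correction = _pd_inverse(gb, "Gb") - _pd_inverse(a22, "A22")
    hinv[np.ix_(genotyped_idx, genotyped_idx)] += correction
    return hinv


def h_matrix(a: np.ndarray, gb: np.ndarray, genotyped_idx: np.ndarray) -> np.ndarray:
    """Dense joint relationship matrix H (Legarra form), for small problems.

    Conditional on the genotyped block being replaced by Gb:
    ``H11 = A11 + A12 A22⁻¹ (Gb − A22) A22⁻¹ A21``, ``H12 = A12 A22⁻¹ Gb``,
    ``H22 = Gb``.  Useful as an independent cross-check of
    :func:`h_inverse` via direct inversion.
    """
    n = a.shape[0]
    g_idx = np.asarray(genotyped_idx, dtype=int)
    if g_idx.size == 0:
        return a.copy()
    ng_idx = np.setdiff1d(np.arange(n), g_idx)
    a22 = a[np.ix_(g_idx, g_idx)]
    a12 = a[np.ix_(ng_idx, g_idx)]
    a22_inv = _pd_inverse(a22, "A22")
    k = a12 @ a22_inv
    h = np.empty_like(a)
    h[np.ix_(g_idx, g_idx)] = gb
    h[np.ix_(ng_idx, g_idx)] = k @ gb
    h[np.ix_(g_idx, ng_idx)] = (k @ gb).T
    h[np.ix_(ng_idx, ng_idx)] = (
        a[np.ix_(ng_idx, ng_idx)] + k @ (gb - a22) @ k.T
    )
    return h
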