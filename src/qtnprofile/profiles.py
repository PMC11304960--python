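"""QTN profiles: pooled SNP effects around causal positions and their fit
to the expected pairwise-LD decay curve.

Because every QTN is simulated with the same effect, the noisy per-SNP
signals can be pooled: for each signed offset in SNP units from a QTN, the
absolute estimated effects are averaged across all QTNs.  The resulting
"QTN profile" has the QTN itself at offset 0 and, by hypothesis, decays on
either side like the Sved curve ``E(r²) = 1/(4cNe + 1)``.

``fit_pld_curve`` performs the corresponding least-squares fit over a
window of ±``window_segments`` Stam segments around the QTN, excluding the
QTN point itself from both the fit and its R² (the peak is direct signal,
not linkage).  The fit has two free parameters, an amplitude mapping
``E(r²)`` to effect units and an intercept absorbing the noise floor; an
amplitude-only variant is available.

``window_variance`` converts a scan into the percentage of total
SNP-explained variance ``Σ 2p(1−p)â²`` per genomic window, the moving-window
display recommended for Manhattan plots in small-Ne populations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .sim import GenomeSpec
from .theory import expected_r2, stam_segment_size

__all__ = ["QtnProfile", "PldFit", "pool_profile", "fit_pld_curve",
           "window_variance", "profile_width"]


@dataclass
class QtnProfile:
    """Pooled effect profile at signed SNP offsets around the QTNs."""

    offsets: np.ndarray            # -flank..+flank, SNP units
    mean_abs_effect: np.ndarray
    sd_band: np.ndarray            # per-offset dispersion across QTNs
    n_qtn: int
    spacing_morgan: float          # distance between adjacent SNP

    @property
    def flank(self) -> int:
        return int(self.offsets.max())

    @property
    def offsets_cm(self) -> np.ndarray:
        return self.offsets * self.spacing_morgan * 100.0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "offset_snp": self.offsets,
                "offset_cm": self.offsets_cm,
                "mean_abs_effect": self.mean_abs_effect,
                "sd_band": self.sd_band,
                "n_qtn": self.n_qtn,
            }
        )


@dataclass
class PldFit:
    """Least-squares fit of the profile to the expected LD-decay curve."""

    amplitude: float
    intercept: float
    r_squared: float
    window_segments: float
    n_points: int
    ne: float


def pool_profile(a_hat: np.ndarray, qtn_indices: np.ndarray, spec: GenomeSpec,
                 flank: int = 50, signed: bool = False,
                 qtn_maf: np.ndarray | None = None,
                 top_k: int | None = None) -> QtnProfile:
    """Average SNP effects at each signed offset within ±``flank`` SNP of
    every QTN.

    By default absolute effects are pooled (profiles are magnitude
    patterns); ``signed=True`` averages raw effects.  ``top_k`` with
    ``qtn_maf`` restricts pooling to the k QTNs with the highest minor
    allele frequency, the filter used to check that near-fixed QTNs are not
    driving the profile.
    """
    a_hat = np.asarray(a_hat, dtype=float)
    qtn = np.asarray(qtn_indices, dtype=int)
    if a_hat.size != spec.n_snp:
        raise ValueError("effect vector length does not match the genome spec")
    if flank < 1:
        raise ValueError("flank must be >= 1")
    m = spec.snps_per_chrom
    within = qtn % m
    if np.any(within < flank) or np.any(within > m - 1 - flank):
        raise ValueError(
            f"flank {flank} exceeds chromosome bounds for at least one QTN"
        )
    if top_k is not None:
        if qtn_maf is None:
            raise ValueError("top_k filtering requires qtn_maf")
        if not 1 <= top_k <= qtn.size:
            raise ValueError("top_k out of range")
        order = np.argsort(np.asarray(qtn_maf, dtype=float))[::-1]
        qtn = qtn[np.sort(order[:top_k])]

    offsets = np.arange(-flank, flank + 1)
    vals = a_hat[qtn[:, None] + offsets[None, :]]
    if not signed:
        vals = np.abs(vals)
    sd = vals.std(axis=0, ddof=1) if qtn.size > 1 else np.zeros(offsets.size)
    return QtnProfile(offsets=offsets, mean_abs_effect=vals.mean(axis=0),
                      sd_band=sd, n_qtn=int(qtn.size),
                      spacing_morgan=spec.spacing)


def fit_pld_curve(profile: QtnProfile, ne: float,
                  window_segments: float = 2.0, exclude_qtn: bool = True,
                  intercept: bool = True) -> PldFit:
    """Fit ``mean_abs_effect(offset) ≈ amplitude·E(r²)(|offset|·spacing) + b``
    by least squares over offsets within ±``window_segments`` Stam segments.

    The QTN point (offset 0) is excluded by default.  ``R² = 1 − SSres/SStot``
    over the fitted points; a constant profile is reported as R² = 0 (the
    fit is then no better than the mean).
    """
    if ne <= 0:
        raise ValueError("ne must be > 0")
    half_window_morgan = window_segments * stam_segment_size(ne)
    w_snp = int(round(half_window_morgan / profile.spacing_morgan))
    w_snp = min(w_snp, profile.flank)
    keep = np.abs(profile.offsets) <= w_snp
    if exclude_qtn:
        keep &= profile.offsets != 0
    if keep.sum() < 3:
        raise ValueError(
            f"only {int(keep.sum())} points inside ±{window_segments} Stam "
            f"segments; increase SNP density or the window"
        )
    y = profile.mean_abs_effect[keep]
    dist = np.abs(profile.offsets[keep]) * profile.spacing_morgan
    x = expected_r2(dist, ne)
    design = np.column_stack([x, np.ones_like(x)]) if intercept else x[:, None]
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    pred = design @ coef
    ss_res = float(((y - pred) ** 2).sum())
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 0.0 if ss_tot <= np.finfo(float).eps * y.size else 1.0 - ss_res / ss_tot
    return PldFit(amplitude=float(coef[0]),
                  intercept=float(coef[1]) if intercept else 0.0,
                  r_squared=r2, window_segments=float(window_segments),
                  n_points=int(keep.sum()), ne=float(ne))


def window_variance(a_hat: np.ndarray, p_freq: np.ndarray, spec: GenomeSpec,
                    window_snp: int, mode: str = "disjoint") -> pd.DataFrame:
    """Percentage of total SNP-explained variance per genomic window.

    Each SNP contributes ``2·p(1−p)·â²``; windows never span chromosome
    boundaries.  ``mode="disjoint"`` tiles each chromosome (percentages sum
    to 100); ``mode="sliding"`` moves one SNP at a time.
    """
    a_hat = np.asarray(a_hat, dtype=float)
    p = np.asarray(p_freq, dtype=float)
    if a_hat.size != spec.n_snp or p.size != spec.n_snp:
        raise ValueError("a_hat / p_freq length does not match the genome spec")
    if window_snp < 1:
        raise ValueError("window_snp must be >= 1")
    contrib = 2.0 * p * (1.0 - p) * a_hat**2
    total = contrib.sum()
    rows = []
    m = spec.snps_per_chrom
    for k in range(spec.n_chrom):
        c = contrib[spec.chrom_slice(k)]
        if mode == "disjoint":
            starts = range(0, m, window_snp)
        elif mode == "sliding":
            starts = range(0, m - window_snp + 1)
        else:
            raise ValueError(f"unknown mode {mode!r}")
        for s in starts:
            e = min(s + window_snp, m)
            val = c[s:e].sum()
            rows.append(
                {
                    "chrom": k + 1,
                    "start_snp": k * m + s,
                    "end_snp": k * m + e - 1,
                    "pct_variance": 100.0 * val / total if total > 0 else 0.0,
                }
            )
    return pd.DataFrame(rows)


def profile_width(profile: QtnProfile, threshold: float | None = None,
                  a_hat: np.ndarray | None = None,
                  qtn_indices: np.ndarray | None = None) -> dict:
    """Width of the contiguous span around the QTN exceeding a threshold.

    The default threshold is ``mean + 1·SD`` of |â| over all non-QTN SNP
    (computed from ``a_hat``/``qtn_indices``), so the peak does not inflate
    its own cutoff.  Returns width in SNP and cM plus a ``capped`` flag set
    when the whole profile exceeds the threshold.
    """
    if threshold is None:
        if a_hat is None or qtn_indices is None:
            raise ValueError("default threshold requires a_hat and qtn_indices")
        mask = np.ones(np.asarray(a_hat).size, dtype=bool)
        mask[np.asarray(qtn_indices, dtype=int)] = False
        bg = np.abs(np.asarray(a_hat, dtype=float)[mask])
        threshold = float(bg.mean() + bg.std(ddof=1))
    vals = profile.mean_abs_effect
    center = int(np.flatnonzero(profile.offsets == 0)[0])
    if vals[center] <= threshold:
        return {"width_snp": 0, "width_cm": 0.0, "threshold": threshold,
                "capped": False}
    left = right = 0
    while center - left - 1 >= 0 and vals[center - left - 1] > threshold:
        left += 1
    while center + right + 1 < vals.size and vals[center + right + 1] > threshold:
        right += 1
    width = left + right + 1
    capped = width == vals.size
    return {
        "width_snp": int(width),
        "width_cm": float(width * profile.spacing_morgan * 100.0),
        "threshold": float(threshold),
        "capped": capped,
    }
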