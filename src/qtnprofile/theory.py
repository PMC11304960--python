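"""Closed-form chromosome-segment and linkage-disequilibrium decay theory.

A randomly mating population of effective size ``Ne`` inherits its genome as
a mosaic of founder segments separated by junctions.  Two classical results
describe that mosaic:

* the expected number of segments over a genome of length ``L`` Morgan is
  ``4·Ne·L``, so the mean segment ("Stam segment") is ``s = 1/(4·Ne)`` Morgan;
* the expected pairwise linkage disequilibrium between two loci separated by
  ``c`` Morgan is the Sved curve ``E(r²) = 1/(4·c·Ne + 1)``.

Everything in this module is a deterministic function of ``Ne`` and distance.
Distances are Morgans internally; "Stam segment" units are provided because
they make the decay curve universal across ``Ne``: at a distance of ``k``
segments, ``E(r²) = 1/(k + 1)`` regardless of ``Ne``.

The variance-fraction relation treats the Sved curve as the expected profile
of a causal variant (QTN): the fraction of the QTN's additive variance
captured inside a symmetric interval of total width ``w`` centred on it is
``1 − E(r²)`` evaluated at the half-interval ``w/2``.  This closed relation
reproduces the standard 50%/66%/80% figures for 2/4/8-segment intervals; it
is a numerically consistent summary, not a derivation from first principles.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "expected_r2",
    "expected_r2_segments",
    "stam_segment_size",
    "n_segments",
    "variance_fraction_in_interval",
    "variance_fraction_morgan",
    "interval_physical_size",
    "decay_table",
    "species_window_table",
    "SPECIES_PRESETS",
]


def _validate_positive(name: str, value) -> None:
    if not np.all(np.asarray(value) > 0):
        raise ValueError(f"{name} must be > 0, got {value!r}")


def _validate_nonnegative(name: str, value) -> None:
    if not np.all(np.asarray(value) >= 0):
        raise ValueError(f"{name} must be >= 0, got {value!r}")


def _as_result(arr: np.ndarray, scalar: bool) -> float | np.ndarray:
    return float(arr) if scalar else arr


def expected_r2(c, ne) -> float | np.ndarray:
    """Sved expectation of pairwise LD, ``E(r²) = 1/(4·c·Ne + 1)``.

    Parameters
    ----------
    c : float or array-like
        Genetic distance between the two loci, in Morgan (``c >= 0``).
    ne : float
        Effective population size (``Ne > 0``).
    """
    c_arr = np.asarray(c, dtype=float)
    scalar = c_arr.ndim == 0
    _validate_nonnegative("distance c (Morgan)", c_arr)
    _validate_positive("Ne", ne)
    return _as_result(1.0 / (4.0 * c_arr * ne + 1.0), scalar)


def expected_r2_segments(distance_segments) -> float | np.ndarray:
    """``E(r²)`` at a distance given in Stam segments: ``1/(k + 1)``.

    With distance expressed in units of ``s = 1/(4·Ne)`` Morgan, ``Ne``
    cancels from the Sved curve, so ``k`` segments give ``1/(k + 1)``.
    """
    k = np.asarray(distance_segments, dtype=float)
    scalar = k.ndim == 0
    _validate_nonnegative("distance (Stam segments)", k)
    return _as_result(1.0 / (k + 1.0), scalar)


def stam_segment_size(ne) -> float:
    """Mean chromosome-segment length ``s = 1/(4·Ne)`` in Morgan."""
    _validate_positive("Ne", ne)
    return 1.0 / (4.0 * float(ne))


def n_segments(ne, genome_length) -> float:
    """Expected genome-wide segment count ``4·Ne·L`` (L in Morgan)."""
    _validate_positive("Ne", ne)
    _validate_nonnegative("genome length L (Morgan)", genome_length)
    return 4.0 * float(ne) * float(genome_length)


def variance_fraction_in_interval(width_segments) -> float | np.ndarray:
    """Fraction of a QTN's variance inside a symmetric ``w``-segment interval.

    ``f = 1 − E(r²)(w/2 segments) = w / (w + 2)``; in [0, 1), increasing in
    ``w``, independent of ``Ne`` when the width is expressed in segments.
    """
    w = np.asarray(width_segments, dtype=float)
    scalar = w.ndim == 0
    _validate_nonnegative("interval width (Stam segments)", w)
    return _as_result(w / (w + 2.0), scalar)


def variance_fraction_morgan(width_morgan, ne) -> float | np.ndarray:
    """Same fraction for an interval width given in Morgan.

    ``f = 4·c·Ne / (4·c·Ne + 1)`` with ``c = width/2`` the half-interval.
    An interval of ``±1/Ne`` Morgan (total width ``2/Ne``, i.e. 8 Stam
    segments) gives 0.80.
    """
    w = np.asarray(width_morgan, dtype=float)
    scalar = w.ndim == 0
    _validate_nonnegative("interval width (Morgan)", w)
    _validate_positive("Ne", ne)
    x = 4.0 * (w / 2.0) * ne
    return _as_result(x / (x + 1.0), scalar)


def interval_physical_size(ne, width_segments, genome_morgans, genome_bp) -> float:
    """Physical size (bp) of a ``width_segments``-segment interval.

    The genetic width ``width_segments/(4·Ne)`` Morgan is converted at the
    genome-average rate ``genome_bp / genome_morgans`` bp per Morgan.  Linear
    in ``width_segments`` and in ``genome_bp``.
    """
    _validate_positive("Ne", ne)
    _validate_positive("width (segments)", width_segments)
    _validate_positive("genome length (Morgan)", genome_morgans)
    _validate_positive("genome length (bp)", genome_bp)
    width_morgan = float(width_segments) / (4.0 * float(ne))
    return width_morgan * float(genome_bp) / float(genome_morgans)


#: Reference (Ne, genome Morgan, genome bp) triples used for window-size
#: illustrations: cattle-like, pig/chicken-like, human-like.
SPECIES_PRESETS: dict[str, dict[str, float]] = {
    "cattle": {"ne": 100, "genome_morgans": 30.0, "genome_bp": 3.0e9},
    "pig_chicken": {"ne": 40, "genome_morgans": 30.0, "genome_bp": 3.0e9},
    "human": {"ne": 10_000, "genome_morgans": 30.0, "genome_bp": 3.0e9},
}


def decay_table(ne, interval_segments=(0.5, 1, 2, 4, 8, 18)) -> pd.DataFrame:
    """LD decay and variance fractions for symmetric intervals around a QTN.

    One row per interval width (in Stam segments): the half-interval distance
    in Morgan, ``E(r²)`` at that distance, and the captured variance fraction.
    """
    _validate_positive("Ne", ne)
    widths = np.asarray(interval_segments, dtype=float)
    half_morgan = widths / 2.0 * stam_segment_size(ne)
    return pd.DataFrame(
        {
            "interval_segments": widths,
            "half_distance_morgan": half_morgan,
            "expected_r2": expected_r2(half_morgan, ne),
            "variance_fraction": variance_fraction_in_interval(widths),
        }
    )


def species_window_table(width_segments=8, presets=None) -> pd.DataFrame:
    """Physical window sizes holding a fixed variance fraction, per species."""
    presets = SPECIES_PRESETS if presets is None else presets
    rows = []
    for name, p in presets.items():
        rows.append(
            {
                "species": name,
                "ne": p["ne"],
                "window_segments": float(width_segments),
                "variance_fraction": variance_fraction_in_interval(width_segments),
                "window_bp": interval_physical_size(
                    p["ne"], width_segments, p["genome_morgans"], p["genome_bp"]
                ),
            }
        )
    return pd.DataFrame(rows)
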