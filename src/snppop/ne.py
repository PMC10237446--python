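"""LD-based effective population size trajectories.

Under drift-recombination equilibrium the expected squared correlation
between loci at recombination distance ``c`` (Morgans) is approximately
``E[r²] = 1 / (4 c Ne + 1)``; inverting it at the binned, sample-size
corrected mean r² gives ``Ne = (1/r²_adj − α) / (4 c)``, referring to the
population roughly ``t = 1/(2 c)`` generations ago.  The mutation correction
α defaults to 1 (no-mutation inversion); 2.2 is the common mutation-aware
alternative.  Physical distance converts to map distance at 1 Mb = 1 cM by
default.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .ld import LDDecaySummary

__all__ = [
    "NE_BIN_EDGES_CM",
    "ne_bin_edges_bp",
    "expected_r2",
    "ne_point",
    "ne_trajectory",
]

logger = logging.getLogger(__name__)

#: recombination-distance bin edges in cM for the trajectory
NE_BIN_EDGES_CM = (0.0, 0.01, 0.02, 0.05, 0.1, 0.2, 0.5, 1.0, 2.0, 5.0, 10.0, 20.0)


def ne_bin_edges_bp(mb_per_cm: float = 1.0, edges_cm=NE_BIN_EDGES_CM) -> np.ndarray:
    """Physical bin edges (bp) matching the cM trajectory bins."""
    return np.asarray(edges_cm, dtype=float) * mb_per_cm * 1e6


def expected_r2(ne: float, c: float) -> float:
    """Equilibrium expectation ``1 / (4 c Ne + 1)``."""
    if ne <= 0 or c <= 0:
        raise ValueError("ne and c must be positive")
    return 1.0 / (4.0 * c * ne + 1.0)


def ne_point(mean_r2: float, c: float, alpha: float = 1.0) -> tuple[float, float]:
    """Invert the equilibrium expectation at one (r², c) point.

    Returns ``(Ne, t)`` with ``Ne = (1/r² − alpha) / (4c)`` and
    ``t = 1/(2c)`` generations ago.  A non-positive Ne (r² at or below the
    chance level the formula can explain) is returned as-is for the caller
    to flag.
    """
    if not 0.0 < mean_r2 <= 1.0:
        raise ValueError("mean_r2 must be in (0, 1]")
    if c <= 0:
        raise ValueError("c must be positive")
    return (1.0 / mean_r2 - alpha) / (4.0 * c), 1.0 / (2.0 * c)


def ne_trajectory(
    decay: LDDecaySummary,
    mb_per_cm: float = 1.0,
    alpha: float = 1.0,
    representative: str = "midpoint",
) -> pd.DataFrame:
    """Ne per distance bin of an LD-decay summary.

    ``decay`` should have been computed with the cM bin edges converted to bp
    (:func:`ne_bin_edges_bp`).  The representative recombination distance per
    bin is the arithmetic midpoint (default) or the harmonic mean of the bin
    edges; bins with no pairs, undefined r² or non-positive Ne are dropped
    with a log notice.

    Returns columns: c_lo_cM, c_hi_cM, c_rep_M, t_generations, mean_r2_adj,
    n_pairs, Ne — ordered by increasing distance, i.e. decreasing t.
    """
    if representative not in ("midpoint", "harmonic"):
        raise ValueError("representative must be 'midpoint' or 'harmonic'")
    rows = []
    for _, rec in decay.pooled.iterrows():
        lo_m = rec["bin_lo_bp"] / (mb_per_cm * 1e8)  # bp -> Morgans
        hi_m = rec["bin_hi_bp"] / (mb_per_cm * 1e8)
        if representative == "harmonic" and lo_m > 0:
            c_rep = 2.0 / (1.0 / lo_m + 1.0 / hi_m)
        else:
            c_rep = (lo_m + hi_m) / 2.0
        r2 = rec["mean_r2"]
        if rec["n_pairs"] < 1 or not np.isfinite(r2) or not 0.0 < r2 <= 1.0:
            logger.info("bin [%g, %g) cM dropped: no usable mean r²",
                        lo_m * 100, hi_m * 100)
            continue
        ne, t = ne_point(float(r2), c_rep, alpha)
        if ne <= 0:
            logger.info("bin [%g, %g) cM dropped: non-positive Ne estimate",
                        lo_m * 100, hi_m * 100)
            continue
        rows.append(
            (lo_m * 100, hi_m * 100, c_rep, t, float(r2), int(rec["n_pairs"]), ne)
        )
    return pd.DataFrame(
        rows,
        columns=["c_lo_cM", "c_hi_cM", "c_rep_M", "t_generations", "mean_r2_adj", "n_pairs", "Ne"],
    )
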