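"""Persistence of LD phase between two populations.

For each marker pair (i, j) within a short physical distance, the signed LD
correlation r is computed in each population under one shared allele
orientation.  Within distance bins the Pearson correlation of the matched
signed-r vectors measures how well gametic phase is conserved between the
populations — the quantity that determines whether marker effects estimated
in one population carry over to another in multi-population genomic
selection.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .genotype_io import GenotypeMatrix, HaplotypeMatrix
from .ld import haplotype_freqs_em, haplotype_freqs_phased, ld_statistics

__all__ = ["signed_r_table", "phase_persistence", "default_phase_bins_bp"]


def default_phase_bins_bp(bin_width_bp: int = 10_000, max_distance_bp: int = 100_000) -> np.ndarray:
    """Half-open [lo, hi) distance bin edges covering 0..max_distance_bp."""
    return np.arange(0, max_distance_bp + bin_width_bp, bin_width_bp, dtype=float)


def signed_r_table(
    source: HaplotypeMatrix | GenotypeMatrix,
    max_distance_bp: float = 100_000.0,
) -> pd.DataFrame:
    """Signed r for every intra-chromosomal marker pair within ``max_distance_bp``.

    Columns: chromosome, marker_i, marker_j, distance_bp, r.  Pairs with a
    monomorphic member are omitted (r undefined).  Signs follow the shared
    lexicographic allele orientation, so tables from different populations
    genotyped on the same map are directly comparable.
    """
    phased = isinstance(source, HaplotypeMatrix)
    marker_ids = [m.id for m in source.markers]
    pos_all = source.positions
    rows: list[tuple] = []
    for chrom, idx in source.chromosome_groups():
        pos = pos_all[idx]
        m = len(idx)
        for a in range(m - 1):
            hi = int(np.searchsorted(pos, pos[a] + max_distance_bp, side="right"))
            for b in range(a + 1, hi):
                try:
                    if phased:
                        f = haplotype_freqs_phased(source, int(idx[a]), int(idx[b]))
                    else:
                        f = haplotype_freqs_em(source, int(idx[a]), int(idx[b]), max_iter=50_000)
                    r, _, _ = ld_statistics(f)
                except ValueError:
                    continue
                rows.append(
                    (
                        chrom,
                        marker_ids[idx[a]],
                        marker_ids[idx[b]],
                        int(pos[b] - pos[a]),
                        r,
                    )
                )
    return pd.DataFrame(
        rows, columns=["chromosome", "marker_i", "marker_j", "distance_bp", "r"]
    )


def phase_persistence(
    table_a: pd.DataFrame,
    table_b: pd.DataFrame,
    bins: np.ndarray | None = None,
) -> pd.DataFrame:
    """Correlation of signed r between two populations per distance bin.

    Marker pairs are matched by (marker_i, marker_j) identity, restricting
    the comparison to pairs segregating in both populations.  Within each
    half-open bin the Pearson correlation uses the bin's own means and
    standard deviations; bins with fewer than two shared pairs, or with zero
    variance in either vector, report NaN.

    Returns columns: bin_lo_bp, bin_hi_bp, n_pairs, R.
    """
    edges = default_phase_bins_bp() if bins is None else np.asarray(bins, dtype=float)
    if np.any(np.diff(edges) <= 0):
        raise ValueError("bin edges must be strictly increasing")
    merged = table_a.merge(
        table_b, on=["marker_i", "marker_j"], suffixes=("_a", "_b"), how="inner"
    )
    dist = merged["distance_bp_a"].to_numpy(dtype=float)
    ra = merged["r_a"].to_numpy()
    rb = merged["r_b"].to_numpy()

    rows = []
    which = np.digitize(dist, edges) - 1
    in_range = (dist >= edges[0]) & (dist < edges[-1])
    for k in range(len(edges) - 1):
        sel = in_range & (which == k)
        n = int(sel.sum())
        if n < 2 or np.std(ra[sel]) == 0 or np.std(rb[sel]) == 0:
            corr = np.nan
        else:
            a = ra[sel] - ra[sel].mean()
            b = rb[sel] - rb[sel].mean()
            corr = float((a * b).sum() / np.sqrt((a**2).sum() * (b**2).sum()))
        rows.append((edges[k], edges[k + 1], n, corr))
    return pd.DataFrame(rows, columns=["bin_lo_bp", "bin_hi_bp", "n_pairs", "R"])
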