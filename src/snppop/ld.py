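"""Pairwise linkage disequilibrium statistics and LD-decay summaries.

Two estimation routes share one statistic layer:

* **phased** — haplotype frequencies by direct counting over haplotype rows;
* **unphased** — maximum-likelihood two-locus haplotype frequencies by the
  standard EM over double-heterozygote phase ambiguity.

From the two-locus frequencies, ``D = fAB·fab − fAb·faB``, signed
``r = D / sqrt(pA pa pB pb)``, ``r² = r²`` and ``D' = |D| / Dmax``.  Every
reported r² is also adjusted for the chance level implied by the number of
haplotypes sampled: ``r²_corr = (r² − 1/n) / (1 − 1/n)``.

Throughout, the "A"/"B" letters of the classical two-locus notation refer to
the counted (``alleleB``-coded) allele at the first and second locus, so the
sign of r matches the Pearson correlation of the allele-dosage columns under
the shared orientation table.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genotype_io import MISSING, GenotypeMatrix, HaplotypeMatrix

__all__ = [
    "DEFAULT_DISTANCE_BIN_EDGES_MB",
    "TwoLocusFreqs",
    "LDDecaySummary",
    "distance_bins_bp",
    "haplotype_freqs_phased",
    "haplotype_freqs_em",
    "ld_statistics",
    "correct_r2",
    "ld_decay",
]

logger = logging.getLogger(__name__)

#: physical-distance bin edges (Mb) used for decay summaries
DEFAULT_DISTANCE_BIN_EDGES_MB = (
    0.0, 0.01, 0.02, 0.04, 0.06, 0.08, 0.1, 0.2, 0.5, 1.0, 2.0, 5.0, 10.0, 20.0,
)


def distance_bins_bp(edges_mb=DEFAULT_DISTANCE_BIN_EDGES_MB) -> np.ndarray:
    """Convert Mb bin edges to bp (half-open [lo, hi) bins, 1 Mb = 1e6 bp)."""
    edges = np.asarray(edges_mb, dtype=float) * 1e6
    if np.any(np.diff(edges) <= 0):
        raise ValueError("bin edges must be strictly increasing")
    return edges


@dataclass(frozen=True)
class TwoLocusFreqs:
    """Haplotype frequencies at two loci; allele margins are derived exactly."""

    freqAB: float
    freqAb: float
    freqaB: float
    freqab: float
    n_haplotypes: int

    def __post_init__(self) -> None:
        total = self.freqAB + self.freqAb + self.freqaB + self.freqab
        if not math.isclose(total, 1.0, abs_tol=1e-9):
            raise ValueError(f"haplotype frequencies sum to {total}, not 1")
        for f in (self.freqAB, self.freqAb, self.freqaB, self.freqab):
            if not -1e-12 <= f <= 1.0 + 1e-12:
                raise ValueError("haplotype frequency outside [0, 1]")

    @property
    def freqA(self) -> float:
        return self.freqAB + self.freqAb

    @property
    def freqa(self) -> float:
        return self.freqaB + self.freqab

    @property
    def freqB(self) -> float:
        return self.freqAB + self.freqaB

    @property
    def freqb(self) -> float:
        return self.freqAb + self.freqab


def haplotype_freqs_phased(h: HaplotypeMatrix, i: int, j: int) -> TwoLocusFreqs:
    """Two-locus haplotype frequencies by direct counting of haplotype rows."""
    if i == j:
        raise ValueError("need two distinct markers")
    a = h.haplotypes[:, i].astype(bool)
    b = h.haplotypes[:, j].astype(bool)
    n = a.size
    if n == 0:
        raise ValueError("no haplotypes to count")
    n_ab = int((a & b).sum())
    n_aB = int((~a & b).sum())
    n_Ab = int((a & ~b).sum())
    return TwoLocusFreqs(
        freqAB=n_ab / n,
        freqAb=n_Ab / n,
        freqaB=n_aB / n,
        freqab=(n - n_ab - n_aB - n_Ab) / n,
        n_haplotypes=n,
    )


def haplotype_freqs_em(
    g: GenotypeMatrix,
    i: int,
    j: int,
    tol: float = 1e-10,
    max_iter: int = 1000,
) -> TwoLocusFreqs:
    """ML two-locus haplotype frequencies from unphased genotypes (EM).

    Only the double-heterozygote class has ambiguous phase; the EM splits its
    gametes between coupling (AB/ab) and repulsion (Ab/aB) in proportion to
    the current frequency estimates.  Initialization is at linkage
    equilibrium, which is deterministic and lies in the interior.
    """
    gi = g.calls[:, i]
    gj = g.calls[:, j]
    use = (gi != MISSING) & (gj != MISSING)
    gi, gj = gi[use].astype(int), gj[use].astype(int)
    n_ind = gi.size
    if n_ind == 0:
        raise ValueError("no samples called at both markers")
    if len(set(gi.tolist())) == 1 or len(set(gj.tolist())) == 1:
        raise ValueError("marker monomorphic among jointly called samples")
    counts = np.zeros((3, 3))
    np.add.at(counts, (gi, gj), 1)
    n_hap = 2 * n_ind

    # unambiguous gamete counts (AB, Ab, aB, ab); A/B = counted allele
    c_ab = counts[1, 1]  # double heterozygotes, phase unknown
    base = np.array(
        [
            2 * counts[2, 2] + counts[2, 1] + counts[1, 2],  # AB
            2 * counts[2, 0] + counts[2, 1] + counts[1, 0],  # Ab
            2 * counts[0, 2] + counts[0, 1] + counts[1, 2],  # aB
            2 * counts[0, 0] + counts[0, 1] + counts[1, 0],  # ab
        ],
        dtype=float,
    )

    p_a = (2 * counts[2, :].sum() + counts[1, :].sum()) / n_hap
    p_b = (2 * counts[:, 2].sum() + counts[:, 1].sum()) / n_hap
    f = np.array(
        [p_a * p_b, p_a * (1 - p_b), (1 - p_a) * p_b, (1 - p_a) * (1 - p_b)]
    )
    for _ in range(max_iter):
        denom = f[0] * f[3] + f[1] * f[2]
        coupling = 0.5 if denom == 0 else f[0] * f[3] / denom
        expected = base + c_ab * np.array(
            [coupling, 1 - coupling, 1 - coupling, coupling]
        )
        f_new = expected / n_hap
        if np.max(np.abs(f_new - f)) < tol:
            f = f_new
            break
        f = f_new
    else:
        raise RuntimeError(
            f"two-locus EM did not converge in {max_iter} iterations; last iterate {f}"
        )
    f = f / f.sum()
    return TwoLocusFreqs(
        freqAB=float(f[0]),
        freqAb=float(f[1]),
        freqaB=float(f[2]),
        freqab=float(f[3]),
        n_haplotypes=n_hap,
    )


def ld_statistics(f: TwoLocusFreqs) -> tuple[float, float, float]:
    """(signed r, r², D') from two-locus frequencies.

    ``D' = |D| / Dmax`` with ``Dmax = min(pA pb, pa pB)`` for D > 0 and
    ``min(pA pB, pa pb)`` for D < 0; D = 0 gives D' = 0.
    """
    pA, pa, pB, pb = f.freqA, f.freqa, f.freqB, f.freqb
    if min(pA, pa, pB, pb) <= 0:
        raise ValueError("LD undefined for a monomorphic margin")
    d = f.freqAB * f.freqab - f.freqAb * f.freqaB
    r = d / math.sqrt(pA * pa * pB * pb)
    if d > 0:
        dmax = min(pA * pb, pa * pB)
    elif d < 0:
        dmax = min(pA * pB, pa * pb)
    else:
        return 0.0, 0.0, 0.0
    return r, r * r, min(abs(d) / dmax, 1.0)


def correct_r2(r2_computed: float, n_haplotypes: int) -> float:
    """Sample-size adjustment ``(r² − 1/n) / (1 − 1/n)``.

    Negative adjusted values (r² below the chance level 1/n) are retained.
    """
    if n_haplotypes < 2:
        raise ValueError("need at least 2 haplotypes")
    inv = 1.0 / n_haplotypes
    return (r2_computed - inv) / (1.0 - inv)


# ---------------------------------------------------------------------------
# decay over distance bins
# ---------------------------------------------------------------------------


@dataclass
class LDDecaySummary:
    """Binned LD decay plus the headline short-range statistics.

    ``pooled`` / ``per_chromosome`` columns: bin_lo_bp, bin_hi_bp, n_pairs,
    mean_r2, sd_r2 (of the sample-size-corrected r²), mean_r2_raw.
    """

    bin_edges_bp: np.ndarray
    pooled: pd.DataFrame
    per_chromosome: pd.DataFrame
    n_haplotypes: int
    n_pairs_total: int
    adjacent_mean_r2: float
    adjacent_sd_r2: float
    n_adjacent_pairs: int
    adjacent_mean_r2_within_10kb: float
    n_adjacent_pairs_within_10kb: int
    frac_pairs_10kb_r2_above_030: float

    def distance_at_threshold(self, threshold: float = 0.2) -> float:
        """Distance (bp) at which the binned mean r² first drops below ``threshold``.

        Linear interpolation between the midpoints of the two bracketing bins;
        NaN when the curve never crosses within the binned range.
        """
        t = self.pooled[self.pooled["n_pairs"] > 0]
        mids = ((t["bin_lo_bp"] + t["bin_hi_bp"]) / 2.0).to_numpy()
        means = t["mean_r2"].to_numpy()
        if means.size == 0 or means[0] < threshold:
            return float("nan")
        for k in range(1, means.size):
            if means[k] < threshold <= means[k - 1]:
                x0, x1 = mids[k - 1], mids[k]
                y0, y1 = means[k - 1], means[k]
                return float(x0 + (y0 - threshold) * (x1 - x0) / (y0 - y1))
        return float("nan")


def _pair_stream_phased(h: HaplotypeMatrix, max_pair_distance: float):
    """Yield (chrom, dist, r2_raw, n_hap, adjacent) arrays per chromosome block."""
    n_hap = h.haplotypes.shape[0]
    for chrom, idx in h.chromosome_groups():
        x = h.haplotypes[:, idx].astype(float)
        mu = x.mean(axis=0)
        xc = x - mu
        norm = np.sqrt((xc**2).sum(axis=0))
        ok = norm > 0
        z = np.zeros_like(xc)
        z[:, ok] = xc[:, ok] / norm[ok]
        pos = h.positions[idx]
        m = len(idx)
        for a in range(m - 1):
            hi = int(np.searchsorted(pos, pos[a] + max_pair_distance, side="left"))
            if hi <= a + 1:
                continue
            js = np.arange(a + 1, hi)
            r = z[:, a] @ z[:, js]
            valid = ok[a] & ok[js]
            if not np.any(valid):
                continue
            js = js[valid]
            yield (
                chrom,
                (pos[js] - pos[a]).astype(float),
                (r[valid] ** 2),
                np.full(js.size, n_hap),
                js == a + 1,
            )


def _pair_stream_em(
    g: GenotypeMatrix, max_pair_distance: float, min_call_fraction: float = 0.5
):
    n = g.n_samples
    called_frac = (g.calls != MISSING).mean(axis=0)
    for chrom, idx in g.chromosome_groups():
        pos = g.positions[idx]
        m = len(idx)
        for a in range(m - 1):
            ja = idx[a]
            if called_frac[ja] < min_call_fraction:
                continue
            hi = int(np.searchsorted(pos, pos[a] + max_pair_distance, side="left"))
            dists, r2s, ns, adjs = [], [], [], []
            for b in range(a + 1, hi):
                jb = idx[b]
                if called_frac[jb] < min_call_fraction:
                    continue
                try:
                    f = haplotype_freqs_em(g, ja, jb, max_iter=50_000)
                    _, r2, _ = ld_statistics(f)
                except ValueError:
                    continue
                dists.append(float(pos[b] - pos[a]))
                r2s.append(r2)
                ns.append(f.n_haplotypes)
                adjs.append(b == a + 1)
            if dists:
                yield (
                    chrom,
                    np.array(dists),
                    np.array(r2s),
                    np.array(ns),
                    np.array(adjs),
                )


def ld_decay(
    source: HaplotypeMatrix | GenotypeMatrix,
    bins: np.ndarray | None = None,
    max_pair_distance: float = 20e6,
    adjacent_window_bp: float = 10_000.0,
) -> LDDecaySummary:
    """Binned mean corrected r² over all intra-chromosomal pairs.

    ``source`` may be phased (direct counting; fast vectorized path) or
    unphased genotypes (per-pair EM).  Pairs are assigned to half-open
    [lo, hi) distance bins; the adjacent-pair statistic uses consecutive
    markers in post-QC order, both unrestricted and restricted to pairs
    closer than ``adjacent_window_bp``.
    """
    edges = distance_bins_bp() if bins is None else np.asarray(bins, dtype=float)
    if np.any(np.diff(edges) <= 0):
        raise ValueError("bin edges must be strictly increasing")
    stream = (
        _pair_stream_phased(source, max_pair_distance)
        if isinstance(source, HaplotypeMatrix)
        else _pair_stream_em(source, max_pair_distance)
    )

    chroms, dists, r2c, r2raw, adj = [], [], [], [], []
    n_hap_seen = 0
    for chrom, d, r2, n, is_adj in stream:
        inv = 1.0 / n
        chroms.append(np.full(d.size, chrom))
        dists.append(d)
        r2raw.append(r2)
        r2c.append((r2 - inv) / (1.0 - inv))
        adj.append(is_adj)
        n_hap_seen = max(n_hap_seen, int(n.max()))
    if dists:
        chrom_arr = np.concatenate(chroms)
        dist = np.concatenate(dists)
        r2_corr = np.concatenate(r2c)
        r2_raw = np.concatenate(r2raw)
        adjacent = np.concatenate(adj)
    else:
        chrom_arr = dist = r2_corr = r2_raw = adjacent = np.array([])

    def _bin_table(sel: np.ndarray) -> pd.DataFrame:
        rows = []
        which = np.digitize(dist[sel], edges) - 1 if sel.any() else np.array([])
        for k in range(len(edges) - 1):
            vals = r2_corr[sel][which == k] if sel.any() else np.array([])
            raw = r2_raw[sel][which == k] if sel.any() else np.array([])
            rows.append(
                (
                    edges[k],
                    edges[k + 1],
                    vals.size,
                    vals.mean() if vals.size else np.nan,
                    vals.std(ddof=1) if vals.size > 1 else np.nan,
                    raw.mean() if raw.size else np.nan,
                )
            )
        return pd.DataFrame(
            rows,
            columns=["bin_lo_bp", "bin_hi_bp", "n_pairs", "mean_r2", "sd_r2", "mean_r2_raw"],
        )

    in_range = (
        (dist >= edges[0]) & (dist < edges[-1]) if dist.size else np.array([], bool)
    )
    pooled = _bin_table(in_range)
    per_chrom_frames = []
    for c in np.unique(chrom_arr):
        tbl = _bin_table(in_range & (chrom_arr == c))
        tbl.insert(0, "chromosome", int(c))
        per_chrom_frames.append(tbl)
    per_chrom = (
        pd.concat(per_chrom_frames, ignore_index=True)
        if per_chrom_frames
        else pd.DataFrame(
            columns=["chromosome", "bin_lo_bp", "bin_hi_bp", "n_pairs", "mean_r2", "sd_r2", "mean_r2_raw"]
        )
    )

    adj_vals = r2_corr[adjacent] if dist.size else np.array([])
    adj_near = (
        r2_corr[adjacent & (dist <= adjacent_window_bp)] if dist.size else np.array([])
    )
    near = r2_corr[dist <= adjacent_window_bp] if dist.size else np.array([])

    return LDDecaySummary(
        bin_edges_bp=edges,
        pooled=pooled,
        per_chromosome=per_chrom,
        n_haplotypes=n_hap_seen,
        n_pairs_total=int(dist.size),
        adjacent_mean_r2=float(adj_vals.mean()) if adj_vals.size else np.nan,
        adjacent_sd_r2=float(adj_vals.std(ddof=1)) if adj_vals.size > 1 else np.nan,
        n_adjacent_pairs=int(adj_vals.size),
        adjacent_mean_r2_within_10kb=float(adj_near.mean()) if adj_near.size else np.nan,
        n_adjacent_pairs_within_10kb=int(adj_near.size),
        frac_pairs_10kb_r2_above_030=float((near > 0.3).mean()) if near.size else np.nan,
    )
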