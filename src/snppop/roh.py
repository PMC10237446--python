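"""Runs of homozygosity and genomic inbreeding estimators.

ROH are detected with a sliding-window scan in the style of the standard
whole-genome tools: windows of ``window_snp`` SNPs tolerate up to
``window_het_max`` heterozygous and ``window_missing_max`` missing calls;
SNPs covered by a sufficient fraction of passing windows become eligible,
and maximal eligible runs are refined into homozygous segments.  Segment
acceptance applies a minimum SNP count (the false-positive-calibrated
minimum, see :func:`min_roh_snps`), minimum length, maximum inter-SNP gap
and a density requirement.

Genomic inbreeding comes from four estimators: F_ROH (fraction of the
autosomal genome in ROH of at least ``min_segment_mb``) and the three
GRM-family coefficients Fhat1 (additive-genotype variance), Fhat2 (excess
homozygosity) and Fhat3 (correlation between uniting gametes).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genotype_io import MISSING, GenotypeMatrix

__all__ = [
    "ROHParams",
    "ROHSegment",
    "min_roh_snps",
    "detect_roh",
    "f_roh",
    "f_roh_per_chromosome",
    "grm_inbreeding",
    "roh_length_classes",
    "DEFAULT_LENGTH_CLASSES_MB",
]

logger = logging.getLogger(__name__)

#: ROH length class edges in Mb; segments shorter than the first edge are ignored
DEFAULT_LENGTH_CLASSES_MB = (1.0, 5.0, 10.0, 15.0, 20.0, math.inf)


@dataclass
class ROHParams:
    """Sliding-window scan parameters (kb units follow the scanning tools)."""

    window_snp: int = 20
    window_het_max: int = 1
    window_missing_max: int = 5
    density_kb_per_snp: float = 1000.0
    min_length_kb: float = 10.0
    max_gap_kb: float = 1000.0
    window_hit_threshold: float = 0.05
    #: minimum SNPs per segment; supply the value from :func:`min_roh_snps`
    min_snp_count: int = 0

    def __post_init__(self) -> None:
        if self.window_snp < 1 or self.window_het_max < 0:
            raise ValueError("invalid window parameters")
        if not 0.0 < self.window_hit_threshold <= 1.0:
            raise ValueError("window_hit_threshold must be in (0, 1]")


@dataclass(frozen=True)
class ROHSegment:
    sample_id: str
    chromosome: int
    start_bp: int
    end_bp: int
    n_snps: int
    n_het: int

    @property
    def length_bp(self) -> int:
        return self.end_bp - self.start_bp + 1

    @property
    def length_kb(self) -> float:
        return self.length_bp / 1000.0


def min_roh_snps(
    n_snps: int, n_individuals: int, alpha: float = 0.05, mean_het: float = 0.38
) -> int:
    """Minimum SNP count for an ROH to control false positives.

    ``l = ceil( ln(alpha / (n_snps * n_individuals)) / ln(1 - mean_het) )``:
    the shortest run of homozygous genotypes unlikely to occur by chance
    anywhere among ``n_snps * n_individuals`` genotype calls when the mean
    per-SNP heterozygosity is ``mean_het``.
    """
    if not 0.0 < mean_het < 1.0:
        raise ValueError("mean_het must be in (0, 1)")
    if n_snps < 1 or n_individuals < 1:
        raise ValueError("counts must be >= 1")
    l = math.log(alpha / (n_snps * n_individuals)) / math.log(1.0 - mean_het)
    return max(1, math.ceil(l))


def _sliding_sum(x: np.ndarray, w: int) -> np.ndarray:
    c = np.concatenate([[0], np.cumsum(x)])
    return c[w:] - c[:-w]


def _segments_for_chromosome(
    het: np.ndarray, miss: np.ndarray, pos: np.ndarray, p: ROHParams
) -> list[tuple[int, int]]:
    """Return (start, end) marker-index pairs of accepted segments."""
    m = het.size
    w = p.window_snp
    if m < w:
        return []
    hits = (_sliding_sum(het, w) <= p.window_het_max) & (
        _sliding_sum(miss, w) <= p.window_missing_max
    )
    # per-SNP: fraction of covering windows that hit
    n_win = m - w + 1
    csum = np.concatenate([[0], np.cumsum(hits)])
    starts_lo = np.maximum(np.arange(m) - w + 1, 0)
    starts_hi = np.minimum(np.arange(m), n_win - 1)
    n_hit = csum[starts_hi + 1] - csum[starts_lo]
    n_cov = starts_hi - starts_lo + 1
    eligible = n_hit / n_cov >= p.window_hit_threshold

    hom = ~het & ~miss
    segments: list[tuple[int, int]] = []
    # maximal runs of eligible SNPs, split at over-long physical gaps
    run_edges = np.flatnonzero(np.diff(np.concatenate([[0], eligible.view(np.int8), [0]])))
    max_gap_bp = p.max_gap_kb * 1000.0
    for k in range(0, run_edges.size, 2):
        lo, hi = int(run_edges[k]), int(run_edges[k + 1])  # [lo, hi)
        pieces = [lo]
        gaps = np.flatnonzero(np.diff(pos[lo:hi]) > max_gap_bp)
        for gidx in gaps:
            pieces.extend([lo + int(gidx) + 1])
        bounds = pieces + [hi]
        for b in range(len(bounds) - 1):
            segments.extend(
                _best_subsegments(hom, het, bounds[b], bounds[b + 1] - 1, p.window_het_max)
            )

    # final acceptance filters
    out = []
    for s, e in segments:
        n_snps = e - s + 1
        if n_snps < max(p.min_snp_count, 2):
            continue
        length_kb = (pos[e] - pos[s] + 1) / 1000.0
        if length_kb < p.min_length_kb:
            continue
        if length_kb / n_snps > p.density_kb_per_snp:
            continue
        out.append((s, e))
    return out


def _best_subsegments(
    hom: np.ndarray, het: np.ndarray, lo: int, hi: int, het_budget: int
) -> list[tuple[int, int]]:
    """Greedy longest-first, non-overlapping sub-segments with at most
    ``het_budget`` heterozygotes, trimmed to homozygous endpoints."""
    hpos = [i for i in range(lo, hi + 1) if het[i]]
    if len(hpos) <= het_budget:
        cands = [(lo, hi)]
    else:
        cands = []
        # maximal windows containing exactly het_budget hets
        anchors = [lo - 1] + hpos + [hi + 1]
        for k in range(len(hpos) - het_budget + 1):
            s = anchors[k] + 1  # just past the previous het
            e = anchors[k + het_budget + 1] - 1  # just before the next het
            if s <= e:
                cands.append((s, e))
    trimmed = []
    for s, e in cands:
        while s <= e and not hom[s]:
            s += 1
        while e >= s and not hom[e]:
            e -= 1
        if s < e:
            trimmed.append((s, e))
    trimmed.sort(key=lambda t: (t[0] - t[1], t[0]))  # longest first, then leftmost
    chosen: list[tuple[int, int]] = []
    for s, e in trimmed:
        if all(e < cs or s > ce for cs, ce in chosen):
            chosen.append((s, e))
    chosen.sort()
    return chosen


def detect_roh(g: GenotypeMatrix, params: ROHParams | None = None) -> list[ROHSegment]:
    """Sliding-window ROH detection for every sample and autosome.

    Chromosomes with fewer SNPs than the window size are skipped with a log
    notice.  Output is sorted by (sample order, chromosome, start) and is
    invariant to sample and chromosome processing order.
    """
    params = params or ROHParams()
    segments: list[ROHSegment] = []
    pos_all = g.positions
    groups = list(g.chromosome_groups())
    for chrom, idx in groups:
        if len(idx) < params.window_snp:
            logger.info(
                "chromosome %s has %d < %d SNPs; skipped for ROH",
                chrom, len(idx), params.window_snp,
            )
    for i, sid in enumerate(g.sample_ids):
        row = g.calls[i]
        for chrom, idx in groups:
            if len(idx) < params.window_snp:
                continue
            sub = row[idx]
            het = sub == 1
            miss = sub == MISSING
            pos = pos_all[idx]
            for s, e in _segments_for_chromosome(het, miss, pos, params):
                segments.append(
                    ROHSegment(
                        sample_id=sid,
                        chromosome=chrom,
                        start_bp=int(pos[s]),
                        end_bp=int(pos[e]),
                        n_snps=e - s + 1,
                        n_het=int(het[s : e + 1].sum()),
                    )
                )
    return segments


def f_roh(
    segments: list[ROHSegment],
    sample_ids: list[str],
    l_auto_bp: float,
    min_segment_mb: float = 1.0,
) -> pd.Series:
    """F_ROH per sample: summed ROH length (segments >= ``min_segment_mb``)
    over the total autosomal length."""
    if l_auto_bp <= 0:
        raise ValueError("l_auto_bp must be positive")
    floor_bp = min_segment_mb * 1e6
    total = {sid: 0.0 for sid in sample_ids}
    for seg in segments:
        if seg.length_bp >= floor_bp and seg.sample_id in total:
            total[seg.sample_id] += seg.length_bp
    return pd.Series({sid: v / l_auto_bp for sid, v in total.items()}, name="f_roh")


def f_roh_per_chromosome(
    segments: list[ROHSegment],
    sample_ids: list[str],
    chrom_lengths_bp: dict[int, float],
    min_segment_mb: float = 1.0,
) -> pd.DataFrame:
    """Per-chromosome F_ROH (chromosome span as denominator)."""
    floor_bp = min_segment_mb * 1e6
    out = pd.DataFrame(
        0.0, index=pd.Index(sample_ids, name="sample_id"), columns=sorted(chrom_lengths_bp)
    )
    for seg in segments:
        if seg.length_bp >= floor_bp and seg.chromosome in chrom_lengths_bp:
            out.loc[seg.sample_id, seg.chromosome] += seg.length_bp
    for c, length in chrom_lengths_bp.items():
        out[c] = out[c] / length
    return out


def grm_inbreeding(g: GenotypeMatrix) -> pd.DataFrame:
    """Per-sample Fhat1 (GRM diagonal), Fhat2 (excess homozygosity) and
    Fhat3 (uniting-gamete correlation).

    Allele frequencies are computed within the supplied matrix, so pass one
    population at a time.  Fixed loci are skipped; missing calls are ignored
    per individual.  Samples with no usable locus get NaN.
    """
    calls = g.calls.astype(float)
    called = g.calls != MISSING
    n_called = called.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(called, calls, 0).sum(axis=0) / (2.0 * np.maximum(n_called, 1))
    usable = (n_called > 0) & (p > 0.0) & (p < 1.0)
    x = calls[:, usable]
    ok = called[:, usable]
    p = p[usable]
    het_exp = 2.0 * p * (1.0 - p)

    with np.errstate(invalid="ignore"):
        t1 = np.where(ok, (x - 2.0 * p) ** 2 / het_exp, 0.0)
        t3 = np.where(ok, (x**2 - (1.0 + 2.0 * p) * x + 2.0 * p**2) / het_exp, 0.0)
        obs_het = np.where(ok, x * (2.0 - x), 0.0)
    n_ok = ok.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        fhat1 = t1.sum(axis=1) / n_ok - 1.0
        fhat3 = t3.sum(axis=1) / n_ok
        fhat2 = 1.0 - obs_het.sum(axis=1) / (ok * het_exp).sum(axis=1)
    bad = n_ok == 0
    for arr in (fhat1, fhat2, fhat3):
        arr[bad] = np.nan
    return pd.DataFrame(
        {"fhat1": fhat1, "fhat2": fhat2, "fhat3": fhat3},
        index=pd.Index(g.sample_ids, name="sample_id"),
    )


def roh_length_classes(
    segments: list[ROHSegment],
    sample_ids: list[str],
    populations: list[str],
    classes_mb: tuple[float, ...] = DEFAULT_LENGTH_CLASSES_MB,
) -> pd.DataFrame:
    """Mean per-individual ROH count and total length per length class.

    Classes are half-open [lo, hi) in Mb; segments shorter than the first
    edge are excluded.  Returns one row per (population, class).
    """
    edges = np.asarray(classes_mb, dtype=float)
    pop_of = dict(zip(sample_ids, populations))
    pop_sizes = pd.Series(populations).value_counts().to_dict()
    labels = [
        f"[{edges[k]:g}, {edges[k + 1]:g}) Mb" if np.isfinite(edges[k + 1]) else f">={edges[k]:g} Mb"
        for k in range(len(edges) - 1)
    ]
    counts: dict[tuple[str, str], float] = {}
    lengths: dict[tuple[str, str], float] = {}
    for seg in segments:
        mb = seg.length_bp / 1e6
        if mb < edges[0] or seg.sample_id not in pop_of:
            continue
        k = int(np.searchsorted(edges, mb, side="right")) - 1
        k = min(k, len(labels) - 1)
        key = (pop_of[seg.sample_id], labels[k])
        counts[key] = counts.get(key, 0) + 1
        lengths[key] = lengths.get(key, 0.0) + mb
    rows = []
    for pop in dict.fromkeys(populations):
        for lab in labels:
            n = pop_sizes[pop]
            rows.append(
                (
                    pop,
                    lab,
                    counts.get((pop, lab), 0) / n,
                    lengths.get((pop, lab), 0.0) / n,
                )
            )
    return pd.DataFrame(
        rows, columns=["population", "length_class", "mean_count", "mean_total_mb"]
    )
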