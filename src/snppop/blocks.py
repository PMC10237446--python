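"""Haplotype-block detection from confidence bounds on D'.

Implements the confidence-interval block definition used by association-era
haplotype maps: a marker pair is in *strong LD* when the one-sided 95%
confidence bounds on |D'| are high (upper >= 0.98, lower >= 0.7) and shows
*strong recombination* when the upper bound is below 0.9.  A block is a run
of consecutive markers whose outermost pair is in strong LD and in which at
least 95% of the informative pairs are in strong LD; overlapping candidates
are resolved greedily, longest span first.

The D' confidence bounds come from the likelihood of the haplotype counts
evaluated on a grid of D' in [0, 1] (allele frequencies held at their
observed values), taking the 5th and 95th percentiles of the normalized
likelihood mass.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np
import pandas as pd

from .genotype_io import GenotypeMatrix, HaplotypeMatrix
from .ld import TwoLocusFreqs, haplotype_freqs_em, haplotype_freqs_phased

__all__ = [
    "PairClass",
    "DPrimeCI",
    "Block",
    "BlockConfig",
    "BlockSummary",
    "dprime_ci",
    "classify_pair",
    "pair_classes",
    "find_blocks",
    "block_summary",
]


class PairClass(Enum):
    STRONG_LD = "strong_ld"
    STRONG_RECOMBINATION = "strong_recombination"
    UNINFORMATIVE = "uninformative"


@dataclass(frozen=True)
class DPrimeCI:
    """One-sided 95% confidence bounds on |D'|."""

    lower: float
    upper: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.lower <= self.upper <= 1.0:
            raise ValueError(f"invalid CI ({self.lower}, {self.upper})")


@dataclass
class BlockConfig:
    """Thresholds of the block definition, all exposed for sensitivity work."""

    strong_ld_upper: float = 0.98
    strong_ld_lower: float = 0.70
    recomb_upper: float = 0.90
    min_strong_fraction: float = 0.95
    max_span_bp: int = 500_000
    min_informative_pairs: int = 1
    grid_step: float = 0.001


@dataclass(frozen=True)
class Block:
    chromosome: int
    start_index: int  # first marker index (within the input matrix)
    end_index: int
    start_bp: int
    end_bp: int
    n_snps: int

    @property
    def length_bp(self) -> int:
        # inclusive of both endpoint SNP positions
        return self.end_bp - self.start_bp + 1

    @property
    def length_kb(self) -> float:
        return self.length_bp / 1000.0


def dprime_ci(f: TwoLocusFreqs, grid_step: float = 0.001) -> DPrimeCI:
    """Grid-likelihood confidence bounds on |D'|.

    The likelihood of the (possibly expected) haplotype counts is evaluated
    for D' on {0, grid_step, ..., 1}, with allele frequencies fixed at their
    observed values and D oriented to the observed sign; bounds are the 5th
    and 95th percentiles of the normalized likelihood mass.
    """
    counts = np.array([f.freqAB, f.freqAb, f.freqaB, f.freqab]) * f.n_haplotypes
    p_a, p_b = f.freqA, f.freqB
    d_obs = f.freqAB * f.freqab - f.freqAb * f.freqaB
    if d_obs < 0:
        # relabel the second locus so the likelihood grid runs over D >= 0
        counts = counts[[1, 0, 3, 2]]
        p_b = 1.0 - p_b
    dmax = min(p_a * (1.0 - p_b), (1.0 - p_a) * p_b)
    if dmax <= 0:
        return DPrimeCI(0.0, 1.0)  # monomorphic margin: no information on D'
    grid = np.arange(0.0, 1.0 + grid_step / 2, grid_step)
    d = grid * dmax
    freqs = np.stack(
        [
            p_a * p_b + d,
            p_a * (1.0 - p_b) - d,
            (1.0 - p_a) * p_b - d,
            (1.0 - p_a) * (1.0 - p_b) + d,
        ]
    )
    loglik = (counts[:, None] * np.log(np.clip(freqs, 1e-12, None))).sum(axis=0)
    w = np.exp(loglik - loglik.max())
    cdf = np.cumsum(w)
    cdf /= cdf[-1]
    lower = grid[int(np.searchsorted(cdf, 0.05))]
    upper = grid[int(np.searchsorted(cdf, 0.95))]
    return DPrimeCI(float(lower), float(upper))


def classify_pair(ci: DPrimeCI, cfg: BlockConfig | None = None) -> PairClass:
    cfg = cfg or BlockConfig()
    if ci.upper >= cfg.strong_ld_upper and ci.lower >= cfg.strong_ld_lower:
        return PairClass.STRONG_LD
    if ci.upper < cfg.recomb_upper:
        return PairClass.STRONG_RECOMBINATION
    return PairClass.UNINFORMATIVE


def pair_classes(
    source: HaplotypeMatrix | GenotypeMatrix,
    cfg: BlockConfig | None = None,
) -> dict[tuple[int, int], PairClass]:
    """Classify every intra-chromosomal pair within the block search span."""
    cfg = cfg or BlockConfig()
    phased = isinstance(source, HaplotypeMatrix)
    pos_all = source.positions
    out: dict[tuple[int, int], PairClass] = {}
    for _, idx in source.chromosome_groups():
        pos = pos_all[idx]
        m = len(idx)
        for a in range(m - 1):
            hi = int(np.searchsorted(pos, pos[a] + cfg.max_span_bp, side="right"))
            for b in range(a + 1, hi):
                try:
                    if phased:
                        f = haplotype_freqs_phased(source, int(idx[a]), int(idx[b]))
                    else:
                        f = haplotype_freqs_em(source, int(idx[a]), int(idx[b]), max_iter=50_000)
                    ci = dprime_ci(f, cfg.grid_step)
                    cls = classify_pair(ci, cfg)
                except ValueError:
                    cls = PairClass.UNINFORMATIVE
                out[(int(idx[a]), int(idx[b]))] = cls
    return out


def find_blocks(
    source: HaplotypeMatrix | GenotypeMatrix,
    cfg: BlockConfig | None = None,
    classes: dict[tuple[int, int], PairClass] | None = None,
) -> list[Block]:
    """Non-overlapping blocks, accepted greedily by decreasing span length.

    A candidate span [i, j] requires the outermost pair (i, j) to be in
    strong LD and at least ``min_strong_fraction`` of the informative pairs
    inside the span to be in strong LD; ties in span length break to the
    leftmost start.
    """
    cfg = cfg or BlockConfig()
    if classes is None:
        classes = pair_classes(source, cfg)
    pos_all = source.positions
    chrom_all = source.chromosomes
    candidates: list[tuple[int, int, int]] = []  # (length_bp, start, end)
    for _, idx in source.chromosome_groups():
        pos = pos_all[idx]
        m = len(idx)
        for a in range(m - 1):
            hi = int(np.searchsorted(pos, pos[a] + cfg.max_span_bp, side="right"))
            for b in range(a + 1, hi):
                key = (int(idx[a]), int(idx[b]))
                if classes.get(key) is not PairClass.STRONG_LD:
                    continue
                n_strong = n_inf = 0
                for x in range(a, b + 1):
                    for y in range(x + 1, b + 1):
                        cls = classes.get((int(idx[x]), int(idx[y])))
                        if cls is PairClass.STRONG_LD:
                            n_strong += 1
                            n_inf += 1
                        elif cls is PairClass.STRONG_RECOMBINATION:
                            n_inf += 1
                if n_inf < cfg.min_informative_pairs:
                    continue
                if n_strong / n_inf >= cfg.min_strong_fraction:
                    candidates.append(
                        (int(pos[b] - pos[a]) + 1, int(idx[a]), int(idx[b]))
                    )
    candidates.sort(key=lambda t: (-t[0], t[1]))
    used = np.zeros(len(pos_all), dtype=bool)
    blocks: list[Block] = []
    for length_bp, i, j in candidates:
        if used[i : j + 1].any():
            continue
        used[i : j + 1] = True
        blocks.append(
            Block(
                chromosome=int(chrom_all[i]),
                start_index=i,
                end_index=j,
                start_bp=int(pos_all[i]),
                end_bp=int(pos_all[j]),
                n_snps=j - i + 1,
            )
        )
    blocks.sort(key=lambda b: (b.chromosome, b.start_bp))
    return blocks


@dataclass
class BlockSummary:
    per_chromosome: pd.DataFrame  # chromosome, n_blocks, pct_length, block_kb, pct_snps
    totals: pd.Series

    def to_frame(self) -> pd.DataFrame:
        tot = self.totals.to_frame().T
        tot.insert(0, "chromosome", "total")
        per = self.per_chromosome.copy()
        per["chromosome"] = per["chromosome"].astype(str)
        return pd.concat([per, tot], ignore_index=True)


def block_summary(blocks: list[Block], g: GenotypeMatrix | HaplotypeMatrix) -> BlockSummary:
    """Per-chromosome block counts, coverage length/percent and SNP percent.

    Chromosome length is the span from the first to the last post-QC marker
    (both endpoints included).
    """
    pos = g.positions
    rows = []
    tot_len = tot_block = tot_snp = tot_snp_in = tot_blocks = 0
    for chrom, idx in g.chromosome_groups():
        span = int(pos[idx].max() - pos[idx].min()) + 1
        cblocks = [b for b in blocks if b.chromosome == chrom]
        blk_bp = sum(b.length_bp for b in cblocks)
        snps_in = sum(b.n_snps for b in cblocks)
        rows.append(
            (
                chrom,
                len(cblocks),
                100.0 * blk_bp / span,
                blk_bp / 1000.0,
                100.0 * snps_in / len(idx),
            )
        )
        tot_len += span
        tot_block += blk_bp
        tot_snp += len(idx)
        tot_snp_in += snps_in
        tot_blocks += len(cblocks)
    per = pd.DataFrame(
        rows,
        columns=["chromosome", "n_blocks", "pct_length_in_blocks", "block_kb", "pct_snps_in_blocks"],
    )
    totals = pd.Series(
        {
            "n_blocks": tot_blocks,
            "pct_length_in_blocks": 100.0 * tot_block / tot_len if tot_len else 0.0,
            "block_kb": tot_block / 1000.0,
            "pct_snps_in_blocks": 100.0 * tot_snp_in / tot_snp if tot_snp else 0.0,
        }
    )
    return BlockSummary(per_chromosome=per, totals=totals)
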