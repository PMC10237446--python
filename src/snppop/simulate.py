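"""Synthetic genotype generators with known ground truth.

The workhorse is a discrete-generation Wright-Fisher forward simulator of
``2·Ne`` haplotypes over an array-like marker map: each offspring gamete is
a recombinant mosaic of one random parent's haplotype pair, with crossovers
between adjacent markers at the map-implied frequency and free recombination
between chromosomes.  After a burn-in long enough to reach
drift-recombination equilibrium (default ``6·Ne`` generations) a diploid
sample is drawn, so ``Ne`` is literally the parameter that the LD-based
estimators downstream should recover.

Also provided: an independent-locus Hardy-Weinberg genotype generator (for
calibration fixtures without LD), autozygosity-tract injection with exact
coverage bookkeeping (ground truth for F_ROH), population splits with a
shared map and allele orientation (ground truth for phase persistence), and
deterministic QC-violation planting (ground truth for the QC accounting).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from .genotype_io import (
    MISSING,
    GenotypeMatrix,
    HaplotypeMatrix,
    MarkerRecord,
    UNKNOWN_CHROMOSOME,
    X_CHROMOSOME,
)

__all__ = [
    "SimConfig",
    "TractTruth",
    "QCViolationPlan",
    "QCViolationTruth",
    "simulate_population",
    "simulate_hwe_population",
    "inject_autozygosity",
    "split_populations",
    "plant_qc_violations",
]


@dataclass
class SimConfig:
    """Wright-Fisher simulation settings.

    Defaults emulate a medium-density ovine array study: 26 autosomes at
    ~58 kb marker spacing (the post-QC mean spacing of such arrays), 1 cM/Mb,
    and an output MAF floor mimicking array ascertainment plus QC.
    """

    ne: int = 100
    #: burn-in generations; None = 6 * ne (drift-recombination equilibrium)
    n_generations: int | None = None
    n_chromosomes: int = 26
    chrom_length_bp: int = 95_000_000
    marker_spacing_bp: int = 58_000
    recomb_rate_per_bp: float = 1e-8  # Morgans/bp, i.e. 1 cM/Mb
    mutation_rate: float = 0.0  # per site per gamete per generation
    sample_size: int = 45
    seed: int = 0
    min_maf_at_output: float = 0.05
    #: simulate this many times more loci than the output map, so that after
    #: drift fixes a share of them the common SNPs can be thinned back to the
    #: requested spacing (array-ascertainment emulation)
    ascertainment_factor: int = 8
    population_label: str = "pop1"

    def __post_init__(self) -> None:
        if min(self.ne, self.n_chromosomes, self.chrom_length_bp,
               self.marker_spacing_bp, self.sample_size) < 1:
            raise ValueError("SimConfig sizes must be positive")
        if self.sample_size > self.ne:
            raise ValueError("sample_size cannot exceed ne")

    @property
    def burn_in(self) -> int:
        return 6 * self.ne if self.n_generations is None else self.n_generations


def _make_markers(cfg: SimConfig) -> tuple[list[MarkerRecord], np.ndarray]:
    """Dense candidate-locus grid: ``ascertainment_factor`` x the output density."""
    markers: list[MarkerRecord] = []
    spacing = max(1, cfg.marker_spacing_bp // cfg.ascertainment_factor)
    per_chrom = cfg.chrom_length_bp // spacing
    if per_chrom < 1:
        raise ValueError("chromosome shorter than marker spacing")
    for c in range(1, cfg.n_chromosomes + 1):
        for k in range(per_chrom):
            pos = (k + 1) * spacing
            markers.append(
                MarkerRecord(
                    id=f"snp_{c}_{k + 1}",
                    chromosome=c,
                    position_bp=pos,
                    alleleA="A",
                    alleleB="B",
                    position_cm=pos * cfg.recomb_rate_per_bp * 100,
                )
            )
    # inter-marker recombination fractions, 0.5 across chromosome boundaries
    probs = []
    for i in range(1, len(markers)):
        if markers[i].chromosome == markers[i - 1].chromosome:
            d = markers[i].position_bp - markers[i - 1].position_bp
            probs.append(min(0.5, d * cfg.recomb_rate_per_bp))
        else:
            probs.append(0.5)
    return markers, np.asarray(probs)


def _thin(chroms: np.ndarray, keep: np.ndarray, target_per_chrom: int) -> np.ndarray:
    """Thin a candidate mask to at most ``target_per_chrom`` evenly spread
    markers per chromosome."""
    out = np.zeros_like(keep)
    for c in np.unique(chroms):
        idx = np.flatnonzero((chroms == c) & keep)
        if idx.size > target_per_chrom:
            sel = np.unique(np.linspace(0, idx.size - 1, target_per_chrom).round().astype(int))
            idx = idx[sel]
        out[idx] = True
    return out


def _ascertain(h: HaplotypeMatrix, cfg: SimConfig) -> np.ndarray:
    """Array-style marker ascertainment on the sampled haplotypes.

    Keep loci at or above the output MAF floor, then thin each chromosome to
    at most ``chrom_length_bp // marker_spacing_bp`` evenly spread markers,
    so the output map has roughly the requested mean spacing.
    """
    keep = _maf_mask(h, cfg.min_maf_at_output)
    target = max(1, cfg.chrom_length_bp // cfg.marker_spacing_bp)
    return _thin(h.chromosomes, keep, target)


def _wf_generation(pop: np.ndarray, rp: np.ndarray, ne: int,
                   mutation_rate: float, rng: np.random.Generator) -> np.ndarray:
    """One Wright-Fisher generation: 2*ne recombinant gametes from ne diploids."""
    n_gametes, m = 2 * ne, pop.shape[1]
    parents = rng.integers(0, ne, n_gametes)
    hap_a = pop[2 * parents]
    hap_b = pop[2 * parents + 1]
    start = rng.integers(0, 2, (n_gametes, 1))
    switch = rng.random((n_gametes, m - 1)) < rp if m > 1 else np.zeros((n_gametes, 0), bool)
    which = (start + np.concatenate(
        [np.zeros((n_gametes, 1), dtype=np.int64), np.cumsum(switch, axis=1)], axis=1
    )) % 2
    new = np.where(which == 0, hap_a, hap_b).astype(np.uint8)
    if mutation_rate > 0:
        flips = rng.random(new.shape) < mutation_rate
        new ^= flips.astype(np.uint8)
    return new


def _sample_population(
    pop: np.ndarray, markers: list[MarkerRecord], cfg: SimConfig,
    rng: np.random.Generator, label: str, individuals: np.ndarray | None = None,
) -> tuple[HaplotypeMatrix, GenotypeMatrix]:
    if individuals is None:
        individuals = rng.choice(cfg.ne, cfg.sample_size, replace=False)
    rows = np.stack([2 * individuals, 2 * individuals + 1], axis=1).ravel()
    haps = pop[rows].copy()
    ids = [f"{label}_{k + 1:03d}" for k in range(len(individuals))]
    h = HaplotypeMatrix(ids, [label] * len(ids), list(markers), haps)
    return h, h.to_genotypes()


def _maf_mask(h: HaplotypeMatrix, floor: float) -> np.ndarray:
    p = h.haplotypes.mean(axis=0)
    maf = np.minimum(p, 1.0 - p)
    return maf >= floor


def simulate_population(cfg: SimConfig) -> tuple[HaplotypeMatrix, GenotypeMatrix]:
    """Forward Wright-Fisher simulation of one equilibrium population.

    Initial haplotypes are drawn site-wise with allele frequencies uniform on
    [0.05, 0.95]; after ``cfg.burn_in`` generations, ``cfg.sample_size``
    diploids are drawn without replacement and markers below the output MAF
    floor are dropped.  Fully reproducible from ``cfg.seed``.
    """
    rng = np.random.default_rng(cfg.seed)
    markers, rp = _make_markers(cfg)
    m = len(markers)
    p0 = rng.uniform(0.05, 0.95, m)
    pop = (rng.random((2 * cfg.ne, m)) < p0).astype(np.uint8)
    for _ in range(cfg.burn_in):
        pop = _wf_generation(pop, rp, cfg.ne, cfg.mutation_rate, rng)
    h, g = _sample_population(pop, markers, cfg, rng, cfg.population_label)
    h = h.subset(marker_mask=_ascertain(h, cfg))
    return h, h.to_genotypes()


def split_populations(
    cfg: SimConfig, divergence_generations: int
) -> tuple[tuple[HaplotypeMatrix, GenotypeMatrix], tuple[HaplotypeMatrix, GenotypeMatrix]]:
    """One ancestral population split into two, evolved independently.

    With ``divergence_generations == 0`` the two outputs are disjoint samples
    of the same final generation (requires ``2*sample_size <= ne``).  The two
    populations share the marker map and allele orientation; the output MAF
    floor is applied jointly (a marker must pass in both samples).
    """
    rng = np.random.default_rng(cfg.seed)
    markers, rp = _make_markers(cfg)
    m = len(markers)
    p0 = rng.uniform(0.05, 0.95, m)
    pop = (rng.random((2 * cfg.ne, m)) < p0).astype(np.uint8)
    for _ in range(cfg.burn_in):
        pop = _wf_generation(pop, rp, cfg.ne, cfg.mutation_rate, rng)

    if divergence_generations == 0:
        if 2 * cfg.sample_size > cfg.ne:
            raise ValueError("divergence 0 needs 2*sample_size <= ne for disjoint samples")
        pick = rng.choice(cfg.ne, 2 * cfg.sample_size, replace=False)
        h1, _ = _sample_population(pop, markers, cfg, rng, "popA",
                                   individuals=pick[: cfg.sample_size])
        h2, _ = _sample_population(pop, markers, cfg, rng, "popB",
                                   individuals=pick[cfg.sample_size:])
    else:
        pop_a = pop.copy()
        pop_b = pop.copy()
        for _ in range(divergence_generations):
            pop_a = _wf_generation(pop_a, rp, cfg.ne, cfg.mutation_rate, rng)
        for _ in range(divergence_generations):
            pop_b = _wf_generation(pop_b, rp, cfg.ne, cfg.mutation_rate, rng)
        h1, _ = _sample_population(pop_a, markers, cfg, rng, "popA")
        h2, _ = _sample_population(pop_b, markers, cfg, rng, "popB")

    # joint ascertainment: a marker must be common in both samples
    keep_common = _maf_mask(h1, cfg.min_maf_at_output) & _maf_mask(h2, cfg.min_maf_at_output)
    target = max(1, cfg.chrom_length_bp // cfg.marker_spacing_bp)
    keep = _thin(h1.chromosomes, keep_common, target)
    h1 = h1.subset(marker_mask=keep)
    h2 = h2.subset(marker_mask=keep)
    return (h1, h1.to_genotypes()), (h2, h2.to_genotypes())


def simulate_hwe_population(
    n_samples: int,
    n_chromosomes: int = 26,
    markers_per_chromosome: int = 100,
    marker_spacing_bp: int = 58_000,
    p_range: tuple[float, float] = (0.05, 0.95),
    seed: int = 0,
    population_label: str = "pop1",
) -> GenotypeMatrix:
    """Independent-locus genotypes drawn at Hardy-Weinberg proportions.

    No LD and no autozygosity: a null fixture for estimator calibration and
    ROH false-positive control.
    """
    rng = np.random.default_rng(seed)
    markers = [
        MarkerRecord(
            id=f"snp_{c}_{k + 1}",
            chromosome=c,
            position_bp=(k + 1) * marker_spacing_bp,
            alleleA="A",
            alleleB="B",
        )
        for c in range(1, n_chromosomes + 1)
        for k in range(markers_per_chromosome)
    ]
    p = rng.uniform(*p_range, len(markers))
    calls = rng.binomial(2, p, size=(n_samples, len(markers))).astype(np.int8)
    ids = [f"{population_label}_{k + 1:03d}" for k in range(n_samples)]
    return GenotypeMatrix(ids, [population_label] * n_samples, markers, calls)


@dataclass
class TractTruth:
    """Ground truth of injected autozygous tracts."""

    phi_target: float
    genome_bp: int
    #: sample_id -> list of (chromosome, start_bp, end_bp), non-overlapping
    tracts: dict[str, list[tuple[int, int, int]]]

    def phi_realized(self, sample_id: str) -> float:
        return sum(e - s + 1 for _, s, e in self.tracts[sample_id]) / self.genome_bp


def inject_autozygosity(
    g: GenotypeMatrix,
    phi: float,
    tract_length_mb: float = 5.0,
    seed: int = 0,
) -> tuple[GenotypeMatrix, TractTruth]:
    """Overwrite one haplotype with the other inside random tracts.

    Per sample, non-overlapping intervals with exponentially distributed
    lengths (mean ``tract_length_mb``) are placed uniformly over the marker
    span of the autosomes until the covered fraction reaches ``phi`` (the
    final tract is truncated so realized coverage matches the target up to
    marker discreteness).  Within a tract every heterozygous call becomes
    homozygous for a random one of its two alleles; missing calls stay
    missing.
    """
    if not 0.0 <= phi < 1.0:
        raise ValueError("phi must be in [0, 1)")
    rng = np.random.default_rng(seed)
    chroms = g.chromosomes
    pos = g.positions
    spans: list[tuple[int, int, int]] = []  # (chromosome, lo_bp, hi_bp)
    for c, idx in g.chromosome_groups():
        if 1 <= c <= 26:
            spans.append((c, int(pos[idx].min()), int(pos[idx].max())))
    genome_bp = sum(hi - lo + 1 for _, lo, hi in spans)
    weights = np.array([hi - lo + 1 for _, lo, hi in spans], dtype=float)
    weights /= weights.sum()
    mean_bp = tract_length_mb * 1e6

    calls = g.calls.copy()
    truth: dict[str, list[tuple[int, int, int]]] = {}
    for i, sid in enumerate(g.sample_ids):
        target = phi * genome_bp
        covered = 0.0
        placed: list[tuple[int, int, int]] = []
        attempts = 0
        while covered < target:
            attempts += 1
            if attempts > 100_000:
                raise RuntimeError(f"cannot place tracts to phi={phi}: genome too full")
            which = rng.choice(len(spans), p=weights)
            c, lo, hi = spans[which]
            length = max(1.0, rng.exponential(mean_bp))
            length = min(length, target - covered)  # truncate the last tract
            start = int(rng.integers(lo, hi + 1))
            end = min(int(start + length), hi)
            if end <= start:
                continue
            if any(cc == c and not (end < s or start > e) for cc, s, e in placed):
                continue
            placed.append((c, start, end))
            covered += end - start + 1
        placed.sort()
        truth[sid] = placed
        for c, s, e in placed:
            in_tract = (chroms == c) & (pos >= s) & (pos <= e)
            het = in_tract & (calls[i] == 1)
            n_het = int(het.sum())
            if n_het:
                calls[i, het] = 2 * rng.integers(0, 2, n_het).astype(np.int8)
    out = GenotypeMatrix(
        list(g.sample_ids), list(g.populations), list(g.markers), calls
    )
    return out, TractTruth(phi_target=phi, genome_bp=genome_bp, tracts=truth)


# ---------------------------------------------------------------------------
# planted QC violations
# ---------------------------------------------------------------------------


@dataclass
class QCViolationPlan:
    n_low_maf: int = 0
    n_low_call_rate: int = 0
    n_hwe: int = 0
    n_high_missing_samples: int = 0
    n_unplaced: int = 0
    n_x_linked: int = 0


@dataclass
class QCViolationTruth:
    low_maf_markers: list[str]
    low_call_rate_markers: list[str]
    hwe_markers: list[str]
    high_missing_samples: list[str]
    unplaced_markers: list[str]
    x_linked_markers: list[str]


def plant_qc_violations(
    g: GenotypeMatrix, plan: QCViolationPlan, seed: int = 0
) -> tuple[GenotypeMatrix, QCViolationTruth]:
    """Deterministically inject QC violations into a clean genotype matrix.

    The planted patterns are arranged so each victim is removed at exactly
    one step of the QC cascade: low-MAF and HWE markers keep full call rate,
    the low-call-rate markers keep healthy MAF, relabelled markers pass the
    genotype filters, and sample-level missingness is spread over untouched
    markers only.  Patterns are written on the samples that survive step 1,
    since marker statistics are recomputed after sample removal.
    """
    rng = np.random.default_rng(seed)
    n, m = g.n_samples, g.n_markers
    total_markers = plan.n_low_maf + plan.n_low_call_rate + plan.n_hwe + plan.n_unplaced + plan.n_x_linked
    if total_markers > m or plan.n_high_missing_samples > n:
        raise ValueError("plan exceeds matrix dimensions")
    if plan.n_low_maf and n - plan.n_high_missing_samples < 11:
        raise ValueError("need >= 11 surviving samples for a MAF < 0.05 pattern")

    calls = g.calls.copy()
    markers = list(g.markers)

    bad_samples = sorted(rng.choice(n, plan.n_high_missing_samples, replace=False).tolist())
    survivors = np.array([i for i in range(n) if i not in bad_samples])

    # X-linked victims must stay position-ordered: take a contiguous block
    # from the chromosome with the most markers.
    chrom_arr = g.chromosomes
    counts = {c: int((chrom_arr == c).sum()) for c in np.unique(chrom_arr) if c >= 1}
    avail = np.ones(m, dtype=bool)
    x_idx: list[int] = []
    if plan.n_x_linked:
        c_big = max(counts, key=lambda c: counts[c])
        if counts[c_big] < plan.n_x_linked:
            raise ValueError("no chromosome long enough for the X-linked block")
        block = np.flatnonzero(chrom_arr == c_big)[-plan.n_x_linked:]
        x_idx = block.tolist()
        avail[block] = False

    def _draw(k: int) -> list[int]:
        pool = np.flatnonzero(avail)
        if k > pool.size:
            raise ValueError("not enough clean markers for the requested plan")
        pick = rng.choice(pool, k, replace=False)
        avail[pick] = False
        return sorted(pick.tolist())

    maf_idx = _draw(plan.n_low_maf)
    cr_idx = _draw(plan.n_low_call_rate)
    hwe_idx = _draw(plan.n_hwe)
    unk_idx = _draw(plan.n_unplaced)

    for j in maf_idx:  # one heterozygote among survivors -> MAF = 1/(2n) < 0.05
        calls[:, j] = 0
        calls[survivors[0], j] = 1
    for j in cr_idx:  # >5% of survivors missing, healthy HWE genotypes elsewhere
        calls[:, j] = rng.binomial(2, 0.3, n).astype(np.int8)
        n_missing = math.floor(0.05 * survivors.size) + 1
        calls[survivors[:n_missing], j] = MISSING
    for j in hwe_idx:  # all homozygotes, balanced: extreme heterozygote deficit
        calls[:, j] = 0
        half = survivors.size // 2
        calls[survivors[:half], j] = 0
        calls[survivors[half:], j] = 2
    for j in unk_idx:
        markers[j] = replace(markers[j], chromosome=UNKNOWN_CHROMOSOME)
    for j in x_idx:
        markers[j] = replace(markers[j], chromosome=X_CHROMOSOME)

    # sample-level missingness on untouched markers only
    clean = np.flatnonzero(avail)
    n_miss = math.floor(0.15 * m)
    if bad_samples and clean.size < n_miss:
        raise ValueError("too few clean markers to exceed the sample missingness threshold")
    for i in bad_samples:
        hit = rng.choice(clean, n_miss, replace=False)
        calls[i, hit] = MISSING

    out = GenotypeMatrix(list(g.sample_ids), list(g.populations), markers, calls)
    truth = QCViolationTruth(
        low_maf_markers=[g.markers[j].id for j in maf_idx],
        low_call_rate_markers=[g.markers[j].id for j in cr_idx],
        hwe_markers=[g.markers[j].id for j in hwe_idx],
        high_missing_samples=[g.sample_ids[i] for i in bad_samples],
        unplaced_markers=[g.markers[j].id for j in unk_idx],
        x_linked_markers=[g.markers[j].id for j in x_idx],
    )
    return out, truth
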