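"""Quality control cascade, allele frequencies, heterozygosity, HWE and PCA.

The QC filter order mirrors the standard array-QC accounting: (1) samples by
missingness, then — with per-marker statistics recomputed on the surviving
samples — (2) MAF, (3) marker call rate, (4) Hardy-Weinberg exact test at a
Bonferroni-corrected threshold, (5) unknown placement, (6) sex chromosomes.
Removal counts are sequential (each marker is counted at the first step that
removes it), so the report rows sum to initial minus remaining.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln
from scipy.stats import chi2

from .genotype_io import (
    MISSING,
    N_AUTOSOMES,
    GenotypeMatrix,
    UNKNOWN_CHROMOSOME,
)

__all__ = [
    "QCConfig",
    "QCReport",
    "DiversitySummary",
    "PCAResult",
    "allele_frequency",
    "hwe_exact_test",
    "hwe_chisq_test",
    "bonferroni_threshold",
    "run_qc",
    "heterozygosity",
    "pca",
]

logger = logging.getLogger(__name__)


@dataclass
class QCConfig:
    """Thresholds of the QC cascade (all fractions in [0, 1])."""

    max_sample_missing: float = 0.10
    min_maf: float = 0.05
    min_snp_call_rate: float = 0.95
    experimentwise_alpha: float = 0.05
    #: number of tests for the Bonferroni correction; None = SNPs pre-QC
    n_tests_for_bonferroni: int | None = None
    drop_unknown_position: bool = True
    drop_sex_chromosomes: bool = True
    hwe_method: str = "exact"  # or "chisq"

    def __post_init__(self) -> None:
        for name in ("max_sample_missing", "min_maf", "min_snp_call_rate", "experimentwise_alpha"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.hwe_method not in ("exact", "chisq"):
            raise ValueError(f"unknown hwe_method {self.hwe_method!r}")


@dataclass
class QCReport:
    """Per-step sequential removal counts, in filter order."""

    n_animals_initial: int
    n_snps_initial: int
    animals_low_call_rate: int
    snps_low_maf: int
    snps_low_call_rate: int
    snps_hwe: int
    snps_unknown_position: int
    snps_sex_chromosomes: int
    n_animals_remaining: int
    n_snps_remaining: int

    def __post_init__(self) -> None:
        removed = (
            self.snps_low_maf
            + self.snps_low_call_rate
            + self.snps_hwe
            + self.snps_unknown_position
            + self.snps_sex_chromosomes
        )
        assert self.n_snps_remaining == self.n_snps_initial - removed
        assert self.n_animals_remaining == self.n_animals_initial - self.animals_low_call_rate

    def to_frame(self) -> pd.DataFrame:
        rows = [
            ("Total animals before QC", self.n_animals_initial),
            ("Total SNPs before QC", self.n_snps_initial),
            ("Excluded animals by call rate", self.animals_low_call_rate),
            ("Excluded SNPs by MAF", self.snps_low_maf),
            ("Excluded SNPs by call rate", self.snps_low_call_rate),
            ("Excluded SNPs out of HWE", self.snps_hwe),
            ("Excluded SNPs with unknown position", self.snps_unknown_position),
            ("Excluded SNPs on sex chromosomes", self.snps_sex_chromosomes),
            ("Remaining animals after QC", self.n_animals_remaining),
            ("Remaining SNPs after QC", self.n_snps_remaining),
        ]
        return pd.DataFrame(rows, columns=["step", "count"])


def allele_frequency(g: GenotypeMatrix) -> pd.DataFrame:
    """Per-marker frequency of alleleB, MAF and call counts.

    Markers with no non-missing call get ``freq = MAF = NaN`` (they are
    removed by the call-rate filter regardless).
    """
    calls = g.calls
    called = calls != MISSING
    n_called = called.sum(axis=0)
    b_copies = np.where(called, calls, 0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        freq = np.where(n_called > 0, b_copies / (2.0 * np.maximum(n_called, 1)), np.nan)
    maf = np.minimum(freq, 1.0 - freq)
    return pd.DataFrame(
        {
            "marker_id": g.marker_ids,
            "freq_b": freq,
            "maf": maf,
            "n_called": n_called,
        }
    )


def _hwe_het_distribution(n_a: int, n_b: int):
    """Conditional distribution of the heterozygote count given allele counts.

    Returns (possible het counts, probabilities) for ``n_a + n_b`` alleles in
    ``(n_a + n_b) / 2`` diploids.
    """
    n = (n_a + n_b) // 2
    rare = min(n_a, n_b)
    hets = np.arange(rare % 2, rare + 1, 2)
    logp = (
        gammaln(n + 1)
        - gammaln((n_a - hets) / 2 + 1)
        - gammaln(hets + 1)
        - gammaln((n_b - hets) / 2 + 1)
        + hets * np.log(2.0)
        + gammaln(n_a + 1)
        + gammaln(n_b + 1)
        - gammaln(2 * n + 1)
    )
    logp -= logp.max()
    p = np.exp(logp)
    return hets, p / p.sum()


def hwe_exact_test(n_AA: int, n_AB: int, n_BB: int) -> float:
    """Two-sided exact Hardy-Weinberg test.

    Sums the probabilities of all heterozygote counts no more likely than the
    observed one, under the conditional distribution of heterozygote number
    given the allele counts.  Monomorphic markers return p = 1.
    """
    n = n_AA + n_AB + n_BB
    if n < 1:
        raise ValueError("hwe_exact_test requires at least one individual")
    n_a = 2 * n_AA + n_AB
    n_b = 2 * n_BB + n_AB
    if n_a == 0 or n_b == 0:
        return 1.0
    hets, p = _hwe_het_distribution(n_a, n_b)
    p_obs = p[hets == n_AB][0]
    return float(min(1.0, p[p <= p_obs * (1.0 + 1e-12)].sum()))


def hwe_chisq_test(n_AA: int, n_AB: int, n_BB: int) -> float:
    """One-degree-of-freedom chi-square HWE test (optional alternative)."""
    n = n_AA + n_AB + n_BB
    if n < 1:
        raise ValueError("hwe_chisq_test requires at least one individual")
    p = (2 * n_AA + n_AB) / (2.0 * n)
    if p in (0.0, 1.0):
        return 1.0
    exp = np.array([n * p * p, 2 * n * p * (1 - p), n * (1 - p) ** 2])
    obs = np.array([n_AA, n_AB, n_BB], dtype=float)
    stat = ((obs - exp) ** 2 / exp).sum()
    return float(chi2.sf(stat, df=1))


def bonferroni_threshold(alpha: float, n_tests: int) -> float:
    """Per-test significance threshold alpha / n for an experiment-wise alpha."""
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    return alpha / n_tests


def run_qc(g: GenotypeMatrix, cfg: QCConfig | None = None) -> tuple[GenotypeMatrix, QCReport]:
    """Apply the QC cascade and return the filtered matrix plus its accounting.

    Intended for a single population at a time (the HWE test assumes random
    mating within the genotyped group).
    """
    cfg = cfg or QCConfig()
    n0, m0 = g.n_samples, g.n_markers

    # step 1: samples by missingness
    miss_frac = (g.calls == MISSING).mean(axis=1) if m0 else np.zeros(n0)
    keep_samples = miss_frac <= cfg.max_sample_missing
    n_bad_samples = int((~keep_samples).sum())
    g1 = g.subset(sample_mask=keep_samples)

    freq = allele_frequency(g1)
    maf = freq["maf"].to_numpy()
    n_called = freq["n_called"].to_numpy()
    alive = np.ones(m0, dtype=bool)

    # step 2: MAF (NaN MAF — all-missing markers — is left for the call-rate step)
    drop_maf = alive & (maf < cfg.min_maf)
    n_maf = int(drop_maf.sum())
    alive &= ~drop_maf

    # step 3: call rate
    call_rate = n_called / max(g1.n_samples, 1)
    drop_cr = alive & (call_rate < cfg.min_snp_call_rate)
    n_cr = int(drop_cr.sum())
    alive &= ~drop_cr

    # step 4: HWE at the Bonferroni threshold
    n_tests = cfg.n_tests_for_bonferroni if cfg.n_tests_for_bonferroni else m0
    threshold = bonferroni_threshold(cfg.experimentwise_alpha, max(n_tests, 1))
    test = hwe_exact_test if cfg.hwe_method == "exact" else hwe_chisq_test
    drop_hwe = np.zeros(m0, dtype=bool)
    calls1 = g1.calls
    for j in np.flatnonzero(alive):
        col = calls1[:, j]
        n_het = int((col == 1).sum())
        n_homb = int((col == 2).sum())
        n_homa = int((col == 0).sum())
        if n_homa + n_het + n_homb == 0:
            continue
        if test(n_homa, n_het, n_homb) < threshold:
            drop_hwe[j] = True
    n_hwe = int(drop_hwe.sum())
    alive &= ~drop_hwe

    chroms = g1.chromosomes
    # step 5: unknown placement
    n_unknown = 0
    if cfg.drop_unknown_position:
        drop_unk = alive & (chroms == UNKNOWN_CHROMOSOME)
        n_unknown = int(drop_unk.sum())
        alive &= ~drop_unk
    # step 6: sex chromosomes
    n_sex = 0
    if cfg.drop_sex_chromosomes:
        drop_sex = alive & (chroms > N_AUTOSOMES)
        n_sex = int(drop_sex.sum())
        alive &= ~drop_sex

    out = g1.subset(marker_mask=alive)
    report = QCReport(
        n_animals_initial=n0,
        n_snps_initial=m0,
        animals_low_call_rate=n_bad_samples,
        snps_low_maf=n_maf,
        snps_low_call_rate=n_cr,
        snps_hwe=n_hwe,
        snps_unknown_position=n_unknown,
        snps_sex_chromosomes=n_sex,
        n_animals_remaining=out.n_samples,
        n_snps_remaining=out.n_markers,
    )
    if out.n_markers == 0 or out.n_samples == 0:
        logger.warning("QC produced an empty matrix (%d samples, %d markers)",
                       out.n_samples, out.n_markers)
    return out, report


@dataclass
class DiversitySummary:
    """Per-SNP heterozygosity/MAF plus genome-wide and spacing summaries."""

    marker_ids: list[str]
    ho: np.ndarray
    he: np.ndarray
    maf: np.ndarray
    mean_ho: float
    sd_ho: float
    mean_he: float
    sd_he: float
    mean_maf: float
    spacing_kb_by_chromosome: pd.DataFrame  # columns: chromosome, n_snps, mean_spacing_kb
    mean_spacing_kb: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"marker_id": self.marker_ids, "ho": self.ho, "he": self.he, "maf": self.maf}
        )


def heterozygosity(g: GenotypeMatrix) -> DiversitySummary:
    """Observed/expected heterozygosity per SNP and unweighted genome means.

    Ho = het calls / non-missing calls; He = 2 p (1 - p) with p the alleleB
    frequency.  Adjacent-marker spacing is the mean successive position
    difference within each chromosome, in kb.
    """
    freq = allele_frequency(g)
    p = freq["freq_b"].to_numpy()
    called = (g.calls != MISSING).sum(axis=0)
    het = (g.calls == 1).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        ho = np.where(called > 0, het / np.maximum(called, 1), np.nan)
    he = 2.0 * p * (1.0 - p)

    rows = []
    gaps_all = []
    pos = g.positions
    for c, idx in g.chromosome_groups():
        gaps = np.diff(pos[idx]) / 1000.0
        rows.append((c, len(idx), gaps.mean() if gaps.size else np.nan))
        gaps_all.append(gaps)
    spacing = pd.DataFrame(rows, columns=["chromosome", "n_snps", "mean_spacing_kb"])
    pooled = np.concatenate(gaps_all) if gaps_all else np.array([])

    return DiversitySummary(
        marker_ids=g.marker_ids,
        ho=ho,
        he=he,
        maf=freq["maf"].to_numpy(),
        mean_ho=float(np.nanmean(ho)) if len(ho) else np.nan,
        sd_ho=float(np.nanstd(ho, ddof=1)) if len(ho) > 1 else np.nan,
        mean_he=float(np.nanmean(he)) if len(he) else np.nan,
        sd_he=float(np.nanstd(he, ddof=1)) if len(he) > 1 else np.nan,
        mean_maf=float(np.nanmean(freq["maf"])) if len(freq) else np.nan,
        spacing_kb_by_chromosome=spacing,
        mean_spacing_kb=float(pooled.mean()) if pooled.size else np.nan,
    )


@dataclass
class PCAResult:
    sample_ids: list[str]
    coordinates: np.ndarray  # (n_samples, n_axes)
    explained_variance_ratio: np.ndarray  # (n_axes,), descending

    def to_frame(self) -> pd.DataFrame:
        k = self.coordinates.shape[1]
        df = pd.DataFrame(self.coordinates, columns=[f"PC{i + 1}" for i in range(k)])
        df.insert(0, "sample_id", self.sample_ids)
        return df


def pca(g: GenotypeMatrix, n_components: int = 10) -> PCAResult:
    """Genotype PCA on markers standardized by allele frequency.

    Each marker is centred by 2p and scaled by sqrt(2 p (1 - p)); missing
    calls are mean-imputed and monomorphic markers dropped.  Axes are the
    eigenvectors of the sample covariance of the standardized matrix.
    """
    if g.n_samples < 2 or g.n_markers < 2:
        raise ValueError("pca requires at least 2 samples and 2 markers")
    freq = allele_frequency(g)
    p = freq["freq_b"].to_numpy()
    keep = np.isfinite(p) & (p > 0.0) & (p < 1.0)
    if keep.sum() < 1:
        raise ValueError("no polymorphic markers for PCA")
    calls = g.calls[:, keep].astype(float)
    p = p[keep]
    calls[calls == MISSING] = np.nan
    mu = 2.0 * p
    sd = np.sqrt(2.0 * p * (1.0 - p))
    x = (np.where(np.isnan(calls), mu, calls) - mu) / sd
    u, s, _ = np.linalg.svd(x, full_matrices=False)
    total = (s**2).sum()
    if total <= 0:
        raise ValueError("no genotypic variation among samples")
    k = int(min(n_components, (s > s[0] * 1e-9).sum()))
    return PCAResult(
        sample_ids=list(g.sample_ids),
        coordinates=u[:, :k] * s[:k],
        explained_variance_ratio=(s[:k] ** 2) / total,
    )
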