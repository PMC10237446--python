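"""Allele frequencies, HWE exact test, the QC cascade and genotype PCA."""

import math
from fractions import Fraction

import numpy as np
import pytest

from snppop.genotype_io import MISSING
from snppop.qc import (
    QCConfig,
    allele_frequency,
    bonferroni_threshold,
    heterozygosity,
    hwe_exact_test,
    pca,
    run_qc,
)
from snppop.simulate import QCViolationPlan, plant_qc_violations, simulate_hwe_population

from conftest import make_genotypes


@pytest.mark.parametrize(
    "calls, freq, maf",
    [
        ([0, 0, 1, 2], 0.375, 0.375),
        ([2, 2, 2], 1.0, 0.0),
        ([1, 1, 1, 1], 0.5, 0.5),
    ],
)
def test_allele_frequency_direct_counts(calls, freq, maf):
    g = make_genotypes(np.array(calls)[:, None])
    out = allele_frequency(g)
    assert out["freq_b"][0] == pytest.approx(freq)
    assert out["maf"][0] == pytest.approx(maf)


def test_allele_frequency_all_missing_is_flagged():
    g = make_genotypes(np.full((3, 1), MISSING))
    out = allele_frequency(g)
    assert np.isnan(out["freq_b"][0]) and out["n_called"][0] == 0


def hwe_oracle(n_aa, n_ab, n_bb):
    """Exact-rational enumeration of the conditional heterozygote distribution."""
    n = n_aa + n_ab + n_bb
    n_a, n_b = 2 * n_aa + n_ab, 2 * n_bb + n_ab
    if n_a == 0 or n_b == 0:
        return 1.0
    rare = min(n_a, n_b)

    def prob(h):
        na, nb = (n_a - h) // 2, (n_b - h) // 2
        return (
            Fraction(math.factorial(n), math.factorial(na) * math.factorial(h) * math.factorial(nb))
            * Fraction(2**h)
            * Fraction(math.factorial(n_a) * math.factorial(n_b), math.factorial(2 * n))
        )

    probs = {h: prob(h) for h in range(rare % 2, rare + 1, 2)}
    p_obs = probs[n_ab]
    return float(min(1, sum(p for p in probs.values() if p <= p_obs)))


@pytest.mark.parametrize(
    "table, expected",
    [((25, 50, 25), 1.0), ((1, 0, 0), 1.0), ((0, 0, 7), 1.0)],
)
def test_hwe_exact_modal_and_monomorphic_cases(table, expected):
    assert hwe_exact_test(*table) == pytest.approx(expected)


def test_hwe_extreme_homozygote_split_is_rejected():
    """50/0/50 in 100 diploids falls far below the 1e-6 array threshold."""
    p = hwe_exact_test(50, 0, 50)
    assert p < 1e-6
    assert p == pytest.approx(hwe_oracle(50, 0, 50), rel=1e-9)


def test_hwe_exact_matches_enumeration_small_tables():
    for n in range(1, 16):
        for n_aa in range(n + 1):
            for n_ab in range(n - n_aa + 1):
                n_bb = n - n_aa - n_ab
                assert hwe_exact_test(n_aa, n_ab, n_bb) == pytest.approx(
                    hwe_oracle(n_aa, n_ab, n_bb), abs=1e-10
                ), (n_aa, n_ab, n_bb)


@pytest.mark.parametrize(
    "alpha, n, expected", [(0.05, 50_000, 1e-6), (0.05, 1, 0.05), (1.0, 4, 0.25)]
)
def test_bonferroni_threshold(alpha, n, expected):
    assert bonferroni_threshold(alpha, n) == pytest.approx(expected)
    with pytest.raises(ValueError):
        bonferroni_threshold(0.05, 0)


def test_qc_cascade_order_and_sequential_counts():
    """A low-MAF marker is removed (and counted) at the MAF step; a sample
    missing 3/10 markers is removed first."""
    rng = np.random.default_rng(0)
    calls = rng.binomial(2, 0.4, (20, 10)).astype(np.int8)
    calls[:, 0] = 0
    calls[0, 0] = 1  # MAF 1/40 < 0.05
    calls[5, :3] = MISSING  # 30% missing sample
    g = make_genotypes(calls)
    out, rep = run_qc(g, QCConfig(n_tests_for_bonferroni=50_000))
    assert rep.animals_low_call_rate == 1
    assert rep.snps_low_maf == 1
    assert rep.n_snps_remaining == 9 and rep.n_animals_remaining == 19
    assert out.n_markers == 9


def test_qc_planted_violation_accounting_and_idempotence():
    """Each planted violation is counted once, at its own cascade step."""
    base = simulate_hwe_population(
        50, n_chromosomes=5, markers_per_chromosome=100, p_range=(0.15, 0.5), seed=7
    )
    plan = QCViolationPlan(
        n_low_maf=5, n_low_call_rate=3, n_hwe=1,
        n_high_missing_samples=2, n_unplaced=2, n_x_linked=4,
    )
    g, truth = plant_qc_violations(base, plan, seed=11)
    cfg = QCConfig(n_tests_for_bonferroni=50_000)
    out, rep = run_qc(g, cfg)
    assert rep.animals_low_call_rate == 2
    assert rep.snps_low_maf == 5
    assert rep.snps_low_call_rate == 3
    assert rep.snps_hwe == 1
    assert rep.snps_unknown_position == 2
    assert rep.snps_sex_chromosomes == 4
    assert rep.n_snps_remaining == 500 - 15
    surviving = set(out.marker_ids)
    for lst in (truth.low_maf_markers, truth.hwe_markers, truth.x_linked_markers):
        assert surviving.isdisjoint(lst)

    # idempotence: a second pass removes nothing
    out2, rep2 = run_qc(out, cfg)
    assert np.array_equal(out2.calls, out.calls)
    assert (
        rep2.animals_low_call_rate == rep2.snps_low_maf == rep2.snps_low_call_rate
        == rep2.snps_hwe == rep2.snps_unknown_position == rep2.snps_sex_chromosomes == 0
    )


def test_heterozygosity_values_and_hwe_agreement():
    g = make_genotypes(np.array([[1], [1], [0], [2]]))
    div = heterozygosity(g)
    assert div.ho[0] == pytest.approx(0.5)
    assert div.he[0] == pytest.approx(0.5)  # p = 0.5 maximizes He

    # HWE draws at p=0.3: mean Ho within 3 binomial SEs of 2*0.3*0.7
    rng = np.random.default_rng(3)
    n, m = 500, 40
    calls = rng.binomial(2, 0.3, (n, m)).astype(np.int8)
    div = heterozygosity(make_genotypes(calls))
    se = math.sqrt(0.42 * 0.58 / (n * m))
    assert abs(div.mean_ho - 0.42) < 3 * se


def test_heterozygosity_spacing_summary():
    g = make_genotypes(
        np.zeros((2, 4), np.int8) + 1,
        positions=[10_000, 30_000, 10_000, 20_000],
        chromosomes=[1, 1, 2, 2],
    )
    div = heterozygosity(g)
    by_chrom = div.spacing_kb_by_chromosome.set_index("chromosome")["mean_spacing_kb"]
    assert by_chrom[1] == pytest.approx(20.0)
    assert by_chrom[2] == pytest.approx(10.0)
    assert div.mean_spacing_kb == pytest.approx(15.0)


def test_pca_separates_divergent_clusters_and_is_order_invariant():
    rng = np.random.default_rng(2)
    p0 = rng.uniform(0.2, 0.8, 300)
    a_shape = p0 * 9.0  # Balding-Nichols with Fst = 0.1
    b_shape = (1 - p0) * 9.0
    p1, p2 = rng.beta(a_shape, b_shape), rng.beta(a_shape, b_shape)
    calls = np.vstack(
        [rng.binomial(2, p1, (50, 300)), rng.binomial(2, p2, (50, 300))]
    ).astype(np.int8)
    g = make_genotypes(calls, positions=[(j + 1) * 1000 for j in range(300)])
    res = pca(g)
    pc1 = res.coordinates[:, 0]
    assert (pc1[:50].max() < pc1[50:].min()) or (pc1[:50].min() > pc1[50:].max())
    assert np.all(np.diff(res.explained_variance_ratio) <= 1e-12)
    assert res.explained_variance_ratio.sum() <= 1 + 1e-9

    perm = rng.permutation(100)
    res_perm = pca(g.subset(sample_mask=perm))
    np.testing.assert_allclose(
        res_perm.explained_variance_ratio, res.explained_variance_ratio, rtol=1e-8
    )


def test_pca_duplicate_samples_and_degenerate_input():
    rng = np.random.default_rng(4)
    calls = rng.integers(0, 3, (5, 30)).astype(np.int8)
    calls[1] = calls[0]
    res = pca(make_genotypes(calls))
    np.testing.assert_allclose(res.coordinates[0], res.coordinates[1], atol=1e-9)

    constant = np.tile(np.array([0, 1, 2, 1], np.int8), (4, 1))
    with pytest.raises(ValueError):
        pca(make_genotypes(constant))
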