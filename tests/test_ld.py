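"""Two-locus LD statistics, the EM estimator and binned decay summaries."""

import itertools

import numpy as np
import pytest
from hypothesis import given, strategies as st

from snppop.genotype_io import MISSING
from snppop.ld import (
    TwoLocusFreqs,
    correct_r2,
    haplotype_freqs_em,
    haplotype_freqs_phased,
    ld_decay,
    ld_statistics,
)

from conftest import make_genotypes, make_haplotypes


def freqs_from_counts(n_ab, n_Ab, n_aB, n_abab, n=None):
    n = n or (n_ab + n_Ab + n_aB + n_abab)
    return TwoLocusFreqs(n_ab / n, n_Ab / n, n_aB / n, n_abab / n, n)


def test_phased_counting_direct():
    cols = np.repeat([[1, 1], [0, 0], [1, 0], [0, 1]], [40, 40, 10, 10], axis=0)
    h = make_haplotypes(cols)
    f = haplotype_freqs_phased(h, 0, 1)
    assert (f.freqA, f.freqB, f.freqAB) == (0.5, 0.5, 0.4)
    assert f.n_haplotypes == 100

    uniform = make_haplotypes(np.repeat([[1, 1], [0, 0], [1, 0], [0, 1]], 25, axis=0))
    fu = haplotype_freqs_phased(uniform, 0, 1)
    assert fu.freqAB == fu.freqab == fu.freqAb == fu.freqaB == 0.25

    mono = make_haplotypes(np.tile([[1, 1]], (6, 1)))
    fm = haplotype_freqs_phased(mono, 0, 1)
    assert fm.freqAB == 1.0 and fm.freqa == 0.0


def test_ld_statistics_hand_example_and_edges():
    r, r2, dp = ld_statistics(freqs_from_counts(40, 10, 10, 40))
    assert r == pytest.approx(0.6)  # D = 0.15, denominator 0.25
    assert r2 == pytest.approx(0.36)
    assert dp == pytest.approx(0.6)  # Dmax = 0.25

    # independence
    f = TwoLocusFreqs(0.12, 0.18, 0.28, 0.42, 100)  # pA=0.3, pB=0.4, D=0
    r, r2, dp = ld_statistics(f)
    assert r2 == pytest.approx(0.0, abs=1e-12)
    assert dp == pytest.approx(0.0, abs=1e-12)

    # perfect coupling
    r, r2, dp = ld_statistics(TwoLocusFreqs(0.5, 0.0, 0.0, 0.5, 100))
    assert (r2, dp) == (pytest.approx(1.0), pytest.approx(1.0))

    with pytest.raises(ValueError):
        ld_statistics(TwoLocusFreqs(0.7, 0.3, 0.0, 0.0, 10))  # monomorphic B margin


def test_ld_statistics_equals_pearson_exhaustively():
    """Brute-force oracle: r from the haplotype-count table equals the Pearson
    correlation of the two binary columns, for every table with <= 12 rows."""
    checked = 0
    for n in range(2, 13):
        for n_ab, n_Ab, n_aB in itertools.product(range(n + 1), repeat=3):
            n_abab = n - n_ab - n_Ab - n_aB
            if n_abab < 0:
                continue
            a = np.array([1] * (n_ab + n_Ab) + [0] * (n_aB + n_abab))
            b = np.array([1] * n_ab + [0] * n_Ab + [1] * n_aB + [0] * n_abab)
            if a.std() == 0 or b.std() == 0:
                continue
            r, r2, dp = ld_statistics(freqs_from_counts(n_ab, n_Ab, n_aB, n_abab))
            assert r == pytest.approx(np.corrcoef(a, b)[0, 1], abs=1e-12)
            assert r2 == pytest.approx(r * r, abs=1e-12)
            assert 0.0 <= dp <= 1.0
            checked += 1
    assert checked > 400


@given(st.integers(1, 50), st.integers(1, 50), st.integers(1, 50), st.integers(1, 50))
def test_label_swap_invariance(n_ab, n_Ab, n_aB, n_abab):
    """r² and D' are invariant to swapping allele labels at one locus;
    signed r flips sign."""
    f = freqs_from_counts(n_ab, n_Ab, n_aB, n_abab)
    swapped = freqs_from_counts(n_Ab, n_ab, n_abab, n_aB)  # swap locus-2 labels
    try:
        r, r2, dp = ld_statistics(f)
    except ValueError:
        return
    rs, r2s, dps = ld_statistics(swapped)
    assert rs == pytest.approx(-r, abs=1e-12)
    assert r2s == pytest.approx(r2, abs=1e-12)
    assert dps == pytest.approx(dp, abs=1e-12)


def test_correct_r2_values_and_monotonicity():
    assert correct_r2(0.01, 100) == pytest.approx(0.0)  # r² = 1/n zeroes out
    assert correct_r2(1.0, 7) == pytest.approx(1.0)  # fixed point
    assert correct_r2(0.36, 100) == pytest.approx(0.35354, abs=5e-6)
    assert correct_r2(0.005, 100) < 0  # retained, not clipped
    grid = np.linspace(0, 1, 11)
    vals = [correct_r2(x, 50) for x in grid]
    assert np.all(np.diff(vals) > 0)
    assert correct_r2(0.36, 10**9) == pytest.approx(0.36, abs=1e-8)
    with pytest.raises(ValueError):
        correct_r2(0.5, 1)


def test_em_equals_counting_without_double_heterozygotes():
    # genotypes with no double hets: phase is unambiguous
    calls = np.array([[2, 2], [0, 0], [2, 0], [0, 2], [1, 0], [0, 1]], np.int8)
    g = make_genotypes(calls)
    f = haplotype_freqs_em(g, 0, 1)
    # direct gamete counting: AB=2, Ab=3, aB=3, ab=4 of 12
    assert f.freqAB == pytest.approx(2 / 12, abs=1e-9)
    assert f.freqAb == pytest.approx(3 / 12, abs=1e-9)
    assert f.freqab == pytest.approx(4 / 12, abs=1e-9)
    assert f.n_haplotypes == 12


def test_em_recovers_phased_frequencies_and_truth():
    """Phase-erased genotypes give back the phased-counting haplotype
    frequencies when the MLE is unique, and multinomial-sampled data stay
    within 3 SEs of the generating frequencies."""
    rng = np.random.default_rng(10)
    truth = np.array([0.4, 0.1, 0.1, 0.4])
    draws = rng.choice(4, size=(200, 2), p=truth)
    # haplotype pair -> genotype codes (allele 1 = "A" of the first locus)
    hap_a = (draws < 2).astype(np.uint8)  # carries A at locus 1
    hap_b = ((draws == 0) | (draws == 2)).astype(np.uint8)
    calls = np.column_stack([hap_a.sum(1), hap_b.sum(1)]).astype(np.int8)
    g = make_genotypes(calls)
    f = haplotype_freqs_em(g, 0, 1)
    est = np.array([f.freqAB, f.freqAb, f.freqaB, f.freqab])
    se = np.sqrt(truth * (1 - truth) / 400)
    assert np.all(np.abs(est - truth) < 3 * se + 0.02)

    haps = np.empty((400, 2), np.uint8)
    haps[0::2] = np.column_stack([hap_a[:, 0], hap_b[:, 0]])
    haps[1::2] = np.column_stack([hap_a[:, 1], hap_b[:, 1]])
    h = make_haplotypes(haps)
    fp = haplotype_freqs_phased(h, 0, 1)
    assert abs(ld_statistics(f)[1] - ld_statistics(fp)[1]) < 0.02


def test_em_errors():
    with pytest.raises(ValueError, match="monomorphic"):
        haplotype_freqs_em(make_genotypes(np.array([[2, 1], [2, 0]], np.int8)), 0, 1)
    with pytest.raises(RuntimeError, match="did not converge"):
        haplotype_freqs_em(
            make_genotypes(np.array([[1, 1], [1, 1], [0, 2], [2, 0]], np.int8)),
            0, 1, tol=0.0, max_iter=3,
        )


def test_decay_bin_edges_and_single_pair():
    # two-marker chromosome: one pair, assigned to the upper half-open bin
    h = make_haplotypes(
        np.repeat([[1, 1], [0, 0], [1, 0], [0, 1]], [40, 40, 10, 10], axis=0),
        positions=[10_000, 30_000],
    )
    d = ld_decay(h, bins=np.array([0.0, 20_000.0, 40_000.0]))
    assert d.pooled["n_pairs"].tolist() == [0, 1]  # distance 20 kb -> [20k, 40k)
    assert d.pooled["mean_r2"].iloc[1] == pytest.approx(correct_r2(0.36, 100))
    assert d.n_pairs_total == 1
    assert d.adjacent_mean_r2 == pytest.approx(correct_r2(0.36, 100))


def test_decay_is_nonincreasing_on_equilibrium_population(wf_population):
    """Mean corrected r² decays with distance (drift-recombination balance)."""
    h, g = wf_population
    d = ld_decay(h, max_pair_distance=5e6)
    t = d.pooled[d.pooled["n_pairs"] >= 30]
    means = t["mean_r2"].to_numpy()
    assert means.size >= 5
    # allow small Monte-Carlo wiggle, require overall decay
    assert np.all(np.diff(means) < 0.05)
    assert means[-1] < means[0] / 3


def test_decay_em_and_phased_paths_agree_on_binned_means(wf_population):
    h, g = wf_population
    one_chrom = np.flatnonzero(h.chromosomes == 1)
    hs = h.subset(marker_mask=one_chrom)
    gs = hs.to_genotypes()
    dp = ld_decay(hs, max_pair_distance=1e6)
    de = ld_decay(gs, max_pair_distance=1e6)
    sel = dp.pooled["n_pairs"] > 10
    np.testing.assert_allclose(
        dp.pooled.loc[sel, "mean_r2"], de.pooled.loc[sel, "mean_r2"], atol=0.03
    )


def test_distance_at_threshold_interpolation():
    import pandas as pd
    from snppop.ld import LDDecaySummary

    pooled = pd.DataFrame(
        {
            "bin_lo_bp": [0, 10_000, 20_000],
            "bin_hi_bp": [10_000, 20_000, 30_000],
            "n_pairs": [5, 5, 5],
            "mean_r2": [0.5, 0.3, 0.1],
            "sd_r2": [0.1] * 3,
            "mean_r2_raw": [0.5, 0.3, 0.1],
        }
    )
    s = LDDecaySummary(
        bin_edges_bp=np.array([0.0, 10_000.0, 20_000.0, 30_000.0]),
        pooled=pooled, per_chromosome=pooled, n_haplotypes=100, n_pairs_total=15,
        adjacent_mean_r2=np.nan, adjacent_sd_r2=np.nan, n_adjacent_pairs=0,
        adjacent_mean_r2_within_10kb=np.nan, n_adjacent_pairs_within_10kb=0,
        frac_pairs_10kb_r2_above_030=np.nan,
    )
    # linear interpolation between midpoints 15 kb (0.3) and 25 kb (0.1)
    assert s.distance_at_threshold(0.2) == pytest.approx(20_000.0)
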