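"""Properties of the synthetic-data generators."""

import numpy as np
import pytest

from snppop.genotype_io import MISSING, read_ped_map, write_ped_map
from snppop.ld import haplotype_freqs_phased, ld_statistics
from snppop.qc import allele_frequency
from snppop.simulate import (
    QCViolationPlan,
    SimConfig,
    inject_autozygosity,
    plant_qc_violations,
    simulate_hwe_population,
    simulate_population,
    split_populations,
)


def small_cfg(**kw):
    base = dict(
        ne=50, n_generations=100, n_chromosomes=3, chrom_length_bp=2_000_000,
        marker_spacing_bp=50_000, sample_size=25, seed=123,
    )
    base.update(kw)
    return SimConfig(**base)


def test_same_seed_is_bit_identical():
    h1, g1 = simulate_population(small_cfg())
    h2, g2 = simulate_population(small_cfg())
    assert np.array_equal(h1.haplotypes, h2.haplotypes)
    assert g1.markers == g2.markers
    h3, _ = simulate_population(small_cfg(seed=124))
    assert h3.markers != h1.markers or not np.array_equal(h3.haplotypes, h1.haplotypes)


def test_output_respects_invariants_and_round_trips(tmp_path):
    h, g = simulate_population(small_cfg())
    g.validate()
    h.check_consistency(g)
    maf = allele_frequency(g)["maf"]
    assert (maf >= 0.05 - 1e-9).all()
    write_ped_map(g, tmp_path / "s.ped", tmp_path / "s.map")
    back = read_ped_map(tmp_path / "s.ped", tmp_path / "s.map")
    assert np.array_equal(back.calls, g.calls)


def test_sample_size_cannot_exceed_ne():
    with pytest.raises(ValueError):
        SimConfig(ne=10, sample_size=11, seed=1)


def test_no_recombination_leaves_founder_haplotypes():
    """With c = 0 every chromosome is inherited whole: within a chromosome
    at most a handful of founder haplotypes survive and pairwise D' = 1
    whenever a gamete class is absent (the generic case)."""
    h, g = simulate_population(small_cfg(recomb_rate_per_bp=0.0, seed=5))
    dprimes = []
    for c in np.unique(h.chromosomes):
        idx = np.flatnonzero(h.chromosomes == c)
        rows = h.haplotypes[:, idx]
        # few distinct whole-chromosome haplotypes survive the burn-in
        assert len(np.unique(rows, axis=0)) <= 6
        for a in range(len(idx) - 1):
            for b in range(a + 1, len(idx)):
                try:
                    dprimes.append(ld_statistics(haplotype_freqs_phased(h, int(idx[a]), int(idx[b])))[2])
                except ValueError:
                    pass
    assert dprimes and np.mean(np.asarray(dprimes) > 0.999) > 0.8


def test_hwe_population_heterozygosity_matches_expectation():
    g = simulate_hwe_population(400, n_chromosomes=2, markers_per_chromosome=100, seed=9)
    freq = allele_frequency(g)
    p = freq["freq_b"].to_numpy()
    ho = (g.calls == 1).mean(axis=0)
    he = 2 * p * (1 - p)
    se = np.sqrt(he * (1 - he) / 400)
    assert (np.abs(ho - he) < 4 * se + 1e-9).mean() > 0.99


def test_inject_autozygosity_coverage_and_edge_cases():
    g = simulate_hwe_population(12, n_chromosomes=6, markers_per_chromosome=120, seed=2)
    out, truth = inject_autozygosity(g, 0.10, tract_length_mb=5.0, seed=3)
    for sid in out.sample_ids:
        assert truth.phi_realized(sid) == pytest.approx(0.10, abs=0.03)
        tracts = truth.tracts[sid]
        by_chrom = {}
        for c, s, e in tracts:
            assert s <= e
            for s2, e2 in by_chrom.get(c, []):
                assert e < s2 or s > e2  # non-overlapping
            by_chrom.setdefault(c, []).append((s, e))
    # genotypes inside tracts are homozygous (or missing)
    pos, chroms = out.positions, out.chromosomes
    for i, sid in enumerate(out.sample_ids):
        for c, s, e in truth.tracts[sid]:
            inside = (chroms == c) & (pos >= s) & (pos <= e)
            assert not np.any(out.calls[i, inside] == 1)

    same, t0 = inject_autozygosity(g, 0.0, seed=3)
    assert np.array_equal(same.calls, g.calls) and all(not v for v in t0.tracts.values())
    with pytest.raises(ValueError):
        inject_autozygosity(g, 1.0)


def test_split_populations_determinism_and_shared_map():
    cfg = small_cfg(sample_size=20)
    (h1, g1), (h2, g2) = split_populations(cfg, 10)
    (h1b, _), (h2b, _) = split_populations(cfg, 10)
    assert np.array_equal(h1.haplotypes, h1b.haplotypes)
    assert np.array_equal(h2.haplotypes, h2b.haplotypes)
    assert g1.markers == g2.markers
    assert g1.populations[0] != g2.populations[0]
    maf1 = allele_frequency(g1)["maf"]
    maf2 = allele_frequency(g2)["maf"]
    assert (maf1 >= 0.05 - 1e-9).all() and (maf2 >= 0.05 - 1e-9).all()

    with pytest.raises(ValueError):
        split_populations(small_cfg(ne=30, sample_size=20), 0)


def test_plant_qc_violations_truth_record():
    base = simulate_hwe_population(40, n_chromosomes=4, markers_per_chromosome=50,
                                   p_range=(0.2, 0.5), seed=1)
    plan = QCViolationPlan(n_low_maf=3, n_low_call_rate=2, n_hwe=1,
                           n_high_missing_samples=1, n_unplaced=1, n_x_linked=2)
    g, truth = plant_qc_violations(base, plan, seed=4)
    assert len(truth.low_maf_markers) == 3
    assert len(truth.x_linked_markers) == 2
    ids = g.marker_ids
    chroms = dict(zip(ids, g.chromosomes))
    assert all(chroms[m] == 27 for m in truth.x_linked_markers)
    assert all(chroms[m] == 0 for m in truth.unplaced_markers)
    # missingness of flagged samples exceeds the 10% threshold
    i = g.sample_ids.index(truth.high_missing_samples[0])
    assert (g.calls[i] == MISSING).mean() > 0.10

    g0, t0 = plant_qc_violations(base, QCViolationPlan(), seed=4)
    assert np.array_equal(g0.calls, base.calls)
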