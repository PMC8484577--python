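"""Meiosis simulator: mosaic invariants, Haldane behaviour, pedigree expectations."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import mabc
from mabc.simpop import (
    CrossScheme,
    cross,
    founder_individual,
    genotype_panel,
    simulate_gamete,
    simulate_population,
    true_parent_fraction,
)


@pytest.fixture(scope="module")
def small_genome():
    return mabc.default_genome_model(n_chromosomes=3)


def test_homozygous_founder_gamete_is_pure(small_genome):
    rng = np.random.default_rng(0)
    p = founder_individual("P", small_genome)
    gam = simulate_gamete(p, small_genome, rng)
    gam.validate(small_genome)
    assert gam.founders() == {"P"}


def test_f1_gamete_with_no_crossovers_is_single_founder():
    genome = mabc.default_genome_model(cm_lengths=[1e-9])  # ~0 Morgans: no crossovers
    rng = np.random.default_rng(1)
    f1 = cross(founder_individual("P", genome), founder_individual("D", genome), genome, rng)
    for _ in range(20):
        gam = simulate_gamete(f1, genome, rng)
        segs = gam.segments["A01"]
        assert len(segs) == 1 and segs[0][2] in {"P", "D"}


def test_haldane_recombination_fraction_across_100cm():
    """Ends of a 100 cM chromosome recombine at r = 0.5(1 - e^-2) ~ 0.432."""
    genome = mabc.default_genome_model(cm_lengths=[100.0])
    rng = np.random.default_rng(1900)
    f1 = cross(founder_individual("P", genome), founder_individual("D", genome), genome, rng)
    L = 100.0
    n = 4000
    diff = 0
    for _ in range(n):
        gam = simulate_gamete(f1, genome, rng)
        if gam.founder_at("A01", 0.0) != gam.founder_at("A01", L):
            diff += 1
    r_expected = 0.5 * (1 - np.exp(-2.0))
    assert diff / n == pytest.approx(r_expected, abs=0.025)


@settings(max_examples=25, derandomize=True, deadline=None)
@given(seed=st.integers(0, 2**31 - 1))
def test_gamete_mosaics_tile_chromosomes_for_all_seeds(seed):
    genome = mabc.default_genome_model(n_chromosomes=2, cm_lengths=[120.0, 80.0])
    rng = np.random.default_rng(seed)
    p = founder_individual("P", genome)
    d = founder_individual("D", genome)
    f1 = cross(d, p, genome, rng)
    bc1 = cross(f1, p, genome, rng)
    for ind in (f1, bc1, cross(bc1, p, genome, rng)):
        ind.maternal.validate(genome)
        ind.paternal.validate(genome)


def test_cross_structure(small_genome):
    rng = np.random.default_rng(2)
    p = founder_individual("P", small_genome)
    d = founder_individual("D", small_genome)
    f1 = cross(p, d, small_genome, rng)
    assert f1.maternal.founders() == {"P"} and f1.paternal.founders() == {"D"}
    selfed = cross(p, p, small_genome, rng)
    assert selfed.maternal.founders() == selfed.paternal.founders() == {"P"}
    bc1 = cross(f1, p, small_genome, rng)
    assert bc1.paternal.founders() == {"P"}
    assert bc1.maternal.founders() <= {"P", "D"}


def test_cross_rejects_mismatched_genomes(small_genome):
    other = mabc.default_genome_model(n_chromosomes=2)
    rng = np.random.default_rng(3)
    with pytest.raises(ValueError):
        cross(founder_individual("P", small_genome), founder_individual("D", other), small_genome, rng)
    with pytest.raises(ValueError):
        simulate_gamete(founder_individual("P", other), small_genome, rng)


def test_true_parent_fraction_identities(small_genome):
    rng = np.random.default_rng(4)
    p = founder_individual("P", small_genome)
    d = founder_individual("D", small_genome)
    assert true_parent_fraction(p, "P", small_genome) == 100.0
    f1 = cross(p, d, small_genome, rng)
    assert true_parent_fraction(f1, "P", small_genome) == 50.0
    with pytest.raises(ValueError, match="unknown|not present"):
        true_parent_fraction(p, "X", small_genome)


def test_neutral_bc1_true_fraction_means_75(genome19, bc1_large):
    truth = np.array(
        [bc1_large.ds.true_recurrent_share[s] for s in bc1_large.ds.sheet.progeny_ids]
    )
    assert truth.mean() == pytest.approx(75.0, abs=0.5)


def test_neutral_f1xf1_true_fraction_means_50(f1xf1_large):
    truth = np.array(
        [f1xf1_large.ds.true_recurrent_share[s] for s in f1xf1_large.ds.sheet.progeny_ids]
    )
    assert truth.mean() == pytest.approx(50.0, abs=0.5)


def test_bc2_true_fraction_means_87_5(genome19):
    rng = np.random.default_rng(190_010)
    p = founder_individual("P", genome19)
    d = founder_individual("D", genome19)
    f1 = cross(d, p, genome19, rng)
    vals = []
    for i in range(1500):
        bc1 = cross(f1, p, genome19, rng)
        bc2 = cross(bc1, p, genome19, rng, id=f"BC2_{i}", pedigree_class="BC2")
        vals.append(true_parent_fraction(bc2, "P", genome19))
    assert np.mean(vals) == pytest.approx(87.5, abs=0.5)


def test_share_variance_shrinks_with_map_length():
    """More independently segregating map: tighter BC1 share distribution."""
    out = {}
    for n_chrom in (5, 19):
        genome = mabc.default_genome_model(n_chromosomes=n_chrom)
        rng = np.random.default_rng(190_011)
        inds = simulate_population(CrossScheme("BC1"), 800, genome, rng)
        out[n_chrom] = np.var([true_parent_fraction(i, "RP", genome) for i in inds])
    assert out[19] < out[5]


def test_conditioning_guarantees_het_and_drags_linked_markers(genome19):
    rng = np.random.default_rng(190_012)
    scheme = CrossScheme("BC1", target_loci=[("A01", 50.0)], conditioning=True)
    inds = simulate_population(scheme, 600, genome19, rng)
    assert all(ind.is_het_at("A01", 50.0) for ind in inds)
    mean_share = np.mean([true_parent_fraction(i, "RP", genome19) for i in inds])
    # donor allele forced at the target locus drags linked territory: mean < 75
    assert mean_share < 74.75
    assert mean_share > 70.0


def test_f1xf1_single_locus_segregates_1_2_1(f1xf1_large):
    from mabc.foreground import TargetLocus, chi_square_ratio_test, resolve_marker

    ds = f1xf1_large.ds
    col = resolve_marker(ds.panel, TargetLocus("L", "A01", 50.0))
    prog = ds.matrix.subset_samples(ds.sheet.progeny_ids)
    calls = prog.calls[:, col]
    counts = [(calls == c).sum() for c in (0, 1, 2)]
    res = chi_square_ratio_test(counts, (1, 2, 1))
    assert res.pvalue > 1e-3


def test_conditioning_requires_target_loci(genome19):
    with pytest.raises(ValueError):
        CrossScheme("BC1", target_loci=[], conditioning=True)
    with pytest.raises(ValueError):
        CrossScheme("F1xF1", target_loci=[("A01", 50.0)], conditioning=True)


def test_genotype_panel_boundaries(small_genome):
    rng = np.random.default_rng(6)
    panel = mabc.random_marker_panel(small_genome, 40, rng)
    p = founder_individual("P", small_genome)
    d = founder_individual("D", small_genome)
    m = genotype_panel([p, d], panel, founder_alleles={"P": 0, "D": 1}, genome=small_genome)
    assert (m.row("P") == 0).all() and (m.row("D") == 2).all()
    m_miss = genotype_panel([p], panel, missing_rate=1.0, rng=rng,
                            founder_alleles={"P": 0, "D": 1}, genome=small_genome)
    assert (m_miss.calls == -1).all()


def test_genotype_panel_rejects_out_of_range_marker(small_genome):
    import pandas as pd

    table = pd.DataFrame(
        {"id": ["m1"], "chromosome": "A01", "cm": [150.0], "bp": [100], "ref": "A", "alt": "G"}
    )
    panel = mabc.MarkerPanel(table)
    p = founder_individual("P", small_genome)
    with pytest.raises(ValueError, match="outside"):
        genotype_panel([p], panel, genome=small_genome, founder_alleles={"P": 0})


def test_identical_seed_reproduces_population_and_genotypes(small_genome):
    panel = mabc.random_marker_panel(small_genome, 100, np.random.default_rng(9))
    runs = []
    for _ in range(2):
        rng = np.random.default_rng(190_013)
        scheme = CrossScheme("BC1", target_loci=[("A01", 10.0)], conditioning=True)
        ds = mabc.simulate_dataset(scheme, 25, small_genome, panel, rng,
                                   error_rate=0.01, missing_rate=0.02)
        runs.append(ds)
    a, b = runs
    assert a.matrix.equals(b.matrix)
    for ia, ib in zip(a.individuals, b.individuals):
        assert ia.maternal.segments == ib.maternal.segments
        assert ia.paternal.segments == ib.paternal.segments
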