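"""Diplotype solver tests: oracle equivalence, heuristic admissibility,
tie-breaking and block post-splitting."""

import random

import pytest

from phasekit.core import (
    AMBIGUOUS,
    CondensedRead,
    Diplotype,
    PhaseBlock,
    diplotype_cost,
    make_observation,
)
from phasekit.solver import (
    brute_force,
    heuristic_chain,
    post_split,
    solve_astar,
    _restrict_reads,
)

from conftest import biallelic_sites, random_wmec_instance, read_from


def test_error_free_reads_recover_truth():
    sites = biallelic_sites(5)
    h1 = (0, 1, 1, 0, 1)
    h2 = tuple(1 - a for a in h1)
    reads = []
    for i in range(20):
        hap = h1 if i % 2 else h2
        reads.append(read_from({j: hap[j] for j in range(5)}, name=f"r{i}"))
    d = solve_astar(reads, sites)
    assert d.cost == 0
    assert {d.h1, d.h2} == {h1, h2}


def test_astar_matches_brute_force_on_random_instances():
    rng = random.Random(7)
    for _ in range(150):
        reads, sites, _, _ = random_wmec_instance(rng, max_sites=8, max_reads=12)
        bf = brute_force(reads, sites)
        az = solve_astar(reads, sites, chunk_size=3)
        assert az.cost == bf.cost
        assert diplotype_cost(reads, az) == az.cost  # reported cost is genuine


def test_opposing_cohorts_pay_the_cheaper_cohort():
    """Two equal-size cohorts supporting opposite phases at one junction:
    the optimum pays the cheaper cohort's total weight, and repeated solves
    return the same (deterministically tie-broken) optimum."""
    cohort_a = [read_from({0: 0, 1: 0}, weight=5, name=f"a{i}") for i in range(2)]
    cohort_b = [read_from({0: 0, 1: 1}, weight=3, name=f"b{i}") for i in range(2)]
    sites = biallelic_sites(2)
    reads = cohort_a + cohort_b
    d = solve_astar(reads, sites)
    assert d.cost == 2 * 3  # each cheaper-cohort read pays one site's weight
    assert d.cost == brute_force(reads, sites).cost
    assert solve_astar(reads, sites) == d


def test_multiallelic_haplotypes_respect_genotype():
    from phasekit.core import VariantClass, VariantSite

    sites = [VariantSite("chr1", 0, "G", ("A", "C"), (1, 2), VariantClass.SMALL, 0),
             VariantSite("chr1", 10, "G", ("A",), (0, 1), VariantClass.SMALL, 1)]
    reads = [read_from({0: 1, 1: 0}, name="x"), read_from({0: 2, 1: 1}, name="y")]
    for solverfn in (brute_force, solve_astar):
        d = solverfn(reads, sites)
        assert {d.h1[0], d.h2[0]} == {1, 2}
        assert 0 not in (d.h1[0], d.h2[0])


def test_single_site_block():
    sites = biallelic_sites(1)
    reads = [read_from({0: 0}, weight=4, name="a"),
             read_from({0: 1}, weight=9, name="b")]
    d = brute_force(reads, sites)
    assert (d.h1, d.h2, d.cost) == ((0,), (1,), 0)
    assert solve_astar(reads, sites).cost == 0


def test_brute_force_refuses_large_instances():
    sites = biallelic_sites(17)
    with pytest.raises(ValueError):
        brute_force([], sites)
    with pytest.raises(ValueError):
        solve_astar([], [])


def test_heuristic_empty_remainder_and_perfect_single_chunk():
    rng = random.Random(3)
    reads, sites, _, _ = random_wmec_instance(rng, max_sites=6)
    n = len(sites)
    assert heuristic_chain(reads, sites, 3, n) == 0
    assert heuristic_chain(reads, sites, n, 0) == brute_force(reads, sites).cost


def test_heuristic_admissible_at_every_depth():
    rng = random.Random(11)
    for _ in range(100):
        reads, sites, _, _ = random_wmec_instance(rng, max_sites=8, max_reads=10)
        n = len(sites)
        for j in range(n + 1):
            h = heuristic_chain(reads, sites, 3, j)
            sub = _restrict_reads(reads, j, n)
            completion = brute_force(sub, sites[j:]).cost if (sub and j < n) else 0
            assert h <= completion


def _solved_block(sites, h1, h2, reads):
    cost = diplotype_cost(reads, Diplotype(h1, h2, 0))
    b = PhaseBlock(0, "chr1", list(range(len(sites))), sites[0].pos + 1,
                   Diplotype(h1, h2, cost))
    return b, Diplotype(h1, h2, cost)


def test_post_split_keeps_supported_block():
    sites = biallelic_sites(4)
    reads = [read_from({0: 0, 1: 1, 2: 0, 3: 1}, name=f"r{i}") for i in range(3)]
    b, d = _solved_block(sites, (0, 1, 0, 1), (1, 0, 1, 0), reads)
    assert post_split(b, d, reads, sites) == [b]


def test_post_split_cuts_ambiguous_junction():
    """A junction whose only spanning reads collapsed to ambiguous calls
    starts a new phase set; within-piece assignments are untouched."""
    sites = biallelic_sites(4)
    left = [read_from({0: 0, 1: 1}, name=f"l{i}") for i in range(2)]
    right = [read_from({2: 0, 3: 1}, name=f"r{i}") for i in range(2)]
    bridge = CondensedRead("amb", (
        make_observation(1, 1, 8), make_observation(2, AMBIGUOUS, 0)))
    reads = left + right + [bridge]
    b, d = _solved_block(sites, (0, 1, 0, 1), (1, 0, 1, 0), reads)
    pieces = post_split(b, d, reads, sites)
    assert [p.site_indices for p in pieces] == [[0, 1], [2, 3]]
    assert pieces[0].diplotype.h1 == (0, 1)
    assert pieces[1].diplotype.h1 == (0, 1)
    assert pieces[1].phase_set == sites[2].pos + 1
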