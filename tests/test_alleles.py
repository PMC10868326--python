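"""Allele assignment: windowed local re-alignment, the alt-aware graph,
exact graph alignment (with a path-enumeration oracle), dual-mode fallback
and mapping collapsing."""

import random

import edlib
import pytest

from phasekit import synth
from phasekit.alleles import (
    AMBIGUOUS,
    UNKNOWN,
    assign_block,
    assign_global,
    assign_local,
    build_graph,
    collapse_mappings,
    graph_alignment_cost,
    query_window,
)
from phasekit.core import VariantClass, VariantSite, make_observation
from phasekit.io_formats import AlignmentRecord

RNG = random.Random(99)
_REF = "".join(RNG.choice("ACGT") for _ in range(400))


def _ref_read(start, end, name="r", qual=30, sup=False):
    seq = _REF[start:end]
    return AlignmentRecord(name, "chr1", start, end, 60, is_supplementary=sup,
                           cigar=((0, end - start),), query_sequence=seq,
                           base_qualities=tuple([qual] * len(seq)))


def _snv(pos, i, alt=None):
    ref = _REF[pos]
    alt = alt or ("A" if ref != "A" else "C")
    return VariantSite("chr1", pos, ref, (alt,), (0, 1), VariantClass.SMALL, i)


def test_query_window_projection_with_indels():
    # 20M 5I 20M 10D 20M starting at ref 100
    seq = _REF[100:120] + "TTTTT" + _REF[120:140] + _REF[150:170]
    m = AlignmentRecord("r", "chr1", 100, 170, 60,
                        cigar=((0, 20), (1, 5), (0, 20), (2, 10), (0, 20)),
                        query_sequence=seq,
                        base_qualities=tuple([30] * len(seq)))
    assert query_window(m, 100, 110) == (0, 10)
    assert query_window(m, 110, 130) == (10, 35)   # includes the insertion
    assert query_window(m, 140, 160) == (45, 55)   # deletion consumes no query
    assert query_window(m, 90, 110) is None        # window not covered


def test_local_assignment_calls_ref_alt_and_unknown():
    sites = [_snv(150, 0), _snv(300, 1)]
    m = _ref_read(100, 220)
    obs = assign_local(m, sites, _REF)
    assert (obs[0].allele, obs[0].weight) == (0, 30)
    assert obs[1].allele == UNKNOWN and obs[1].weight == 0
    # read carrying the alt base
    alt_seq = _REF[100:150] + sites[0].alt_alleles[0] + _REF[151:220]
    m2 = AlignmentRecord("r2", "chr1", 100, 220, 60, cigar=((0, 120),),
                         query_sequence=alt_seq,
                         base_qualities=tuple([30] * 120))
    assert assign_local(m2, sites, _REF)[0].allele == 1


def test_local_assignment_tie_is_ambiguous():
    # ref and alt windows equidistant from the read: delete the variant base
    pos = 200
    site = _snv(pos, 0)
    seq = _REF[150:pos] + _REF[pos + 1:260]
    m = AlignmentRecord("r", "chr1", 150, 260, 60,
                        cigar=((0, 50), (2, 1), (0, 59)),
                        query_sequence=seq, base_qualities=tuple([30] * len(seq)))
    obs = assign_local(m, [site], _REF)
    assert obs[0].allele == AMBIGUOUS and obs[0].weight == 0


def test_missing_sequence_degrades_to_unknown():
    m = AlignmentRecord("r", "chr1", 100, 200, 60)
    obs = assign_local(m, [_snv(150, 0)], _REF)
    assert obs[0].allele == UNKNOWN
    g = build_graph(_REF, [_snv(150, 0)])
    assert all(o.allele == UNKNOWN for o in assign_global(m, g))


def test_graph_with_no_sites_spells_reference():
    g = build_graph(_REF, [])
    paths = list(g.enumerate_paths())
    assert len(paths) == 1
    assert paths[0][1] == g.reference_segment()


def test_graph_single_snv_two_branches():
    g = build_graph(_REF, [_snv(150, 0)])
    (cluster,) = g.clusters
    assert len(cluster.branches) == 2
    spelled = {als[0]: seq for als, seq in g.enumerate_paths()}
    assert spelled[0] == g.reference_segment()
    alt = spelled[1]
    assert alt[150 - g.start] == _snv(150, 0).alt_alleles[0]


def test_overlapping_deletions_merge_into_joint_branch_set():
    """Two overlapping deletions form one cluster whose branches spell the
    consistent joint haplotypes; the colliding both-deleted combination is
    excluded."""
    d1 = VariantSite("chr1", 100, _REF[100:111], (_REF[100],), (0, 1),
                     VariantClass.SMALL, 0)
    d2 = VariantSite("chr1", 105, _REF[105:116], (_REF[105],), (0, 1),
                     VariantClass.SMALL, 1)
    g = build_graph(_REF, [d1, d2])
    (cluster,) = g.clusters
    combos = {als for als, _ in cluster.branches}
    assert combos == {(0, 0), (1, 0), (0, 1)}  # (1,1) collides
    spell = {als: seq for als, seq in cluster.branches}
    assert spell[(0, 0)] == _REF[100:116]
    assert spell[(1, 0)] == _REF[100] + _REF[111:116]  # d1 removes 105-110 too
    assert spell[(0, 1)] == _REF[100:105] + _REF[105] + _REF[116:116]


def test_graph_rejects_reference_mismatch():
    bad = VariantSite("chr1", 150, "NNN", ("A",), (0, 1), VariantClass.SMALL, 0)
    with pytest.raises(ValueError):
        build_graph(_REF, [bad])


def _random_graph(rng, n_sites):
    """A small graph over _REF with random SNV/indel/insertion sites."""
    positions = sorted(rng.sample(range(60, 340, 12), n_sites))
    sites, i = [], 0
    for pos in positions:
        kind = rng.random()
        if kind < 0.5:
            sites.append(_snv(pos, i))
        elif kind < 0.75:
            ln = rng.randint(2, 8)
            sites.append(VariantSite("chr1", pos, _REF[pos:pos + ln + 1],
                                     (_REF[pos],), (0, 1), VariantClass.SMALL, i))
        else:
            ins = _REF[pos] + "".join(rng.choice("ACGT") for _ in range(rng.randint(2, 30)))
            sites.append(VariantSite("chr1", pos, _REF[pos], (ins,), (0, 1),
                                     VariantClass.SMALL, i))
        i += 1
    return build_graph(_REF, sites)


def test_graph_alignment_cost_matches_path_enumeration_oracle():
    """On graphs with <= 4 sites, the DAG alignment cost equals the
    brute-force minimum edit distance over every enumerated allele path."""
    rng = random.Random(5)
    for _ in range(100):
        g = _random_graph(rng, rng.randint(1, 4))
        alleles, base = rng.choice(list(g.enumerate_paths()))
        # corrupt the spelled haplotype a little
        chars = list(base)
        for _ in range(rng.randint(0, 4)):
            op = rng.random()
            k = rng.randrange(len(chars))
            if op < 0.4:
                chars[k] = rng.choice("ACGT")
            elif op < 0.7:
                chars.insert(k, rng.choice("ACGT"))
            else:
                chars.pop(k)
        query = "".join(chars)
        oracle = min(
            edlib.align(query, seq, task="distance")["editDistance"]
            for _, seq in g.enumerate_paths())
        assert graph_alignment_cost(query, g) == oracle


def test_global_assignment_recovers_path_alleles():
    """Error-free reads spelling a 100 bp-insertion haplotype get the alt
    allele with a positive margin weight; reference reads get allele 0."""
    rng = random.Random(17)
    pos = 200
    ins = _REF[pos] + "".join(rng.choice("ACGT") for _ in range(100))
    site = VariantSite("chr1", pos, _REF[pos], (ins,), (0, 1),
                       VariantClass.SV, 0)
    snv = _snv(120, 1)
    g = build_graph(_REF, [site, snv])
    # read spelling the insertion haplotype (alt at both sites)
    seq = (_REF[g.start:120] + snv.alt_alleles[0] + _REF[121:pos] + ins
           + _REF[pos + 1:g.end])
    m = AlignmentRecord("hap", "chr1", g.start, g.end, 60,
                        cigar=((0, pos - g.start + 1), (1, 100),
                               (0, g.end - pos - 1)),
                        query_sequence=seq,
                        base_qualities=tuple([30] * len(seq)))
    obs = {o.site_index: o for o in assign_global(m, g)}
    assert obs[0].allele == 1 and obs[0].weight > 0
    assert obs[1].allele == 1
    # margin through the 100 bp insertion is capped at the weight ceiling
    assert obs[0].weight == 60
    ref_read = _ref_read(g.start, g.end)
    assert [o.allele for o in assign_global(ref_read, g)] == [0, 0]


def test_global_assignment_sites_beyond_read_are_unknown():
    sites = [_snv(100, 0), _snv(300, 1)]
    g = build_graph(_REF, sites)
    m = _ref_read(g.start, 200)
    obs = assign_global(m, g)
    assert obs[0].allele == 0
    assert obs[1].allele == UNKNOWN


def test_mismapped_read_is_all_unknown():
    site = _snv(200, 0)
    g = build_graph(_REF, [site])
    garbage = "".join(random.Random(1).choice("ACGT")
                      for _ in range(g.end - g.start))
    m = AlignmentRecord("junk", "chr1", g.start, g.end, 60,
                        cigar=((0, len(garbage)),), query_sequence=garbage,
                        base_qualities=tuple([30] * len(garbage)))
    assert all(o.allele == UNKNOWN for o in assign_global(m, g))


def test_dual_mode_budget_contract():
    sites = [_snv(150, 0), _snv(250, 1)]
    mappings = [_ref_read(100, 300, name=f"r{i}") for i in range(3)]
    by_mode = {}
    for mode, budget in (("global", 0), ("local", 0), ("dual", 0),
                         ("dual", 10 ** 9)):
        obs, fb = assign_block(sites, mappings, _REF, mode=mode, budget=budget)
        by_mode[(mode, budget)] = (obs, fb)
    assert by_mode[("dual", 10 ** 9)][0] == by_mode[("global", 0)][0]
    assert by_mode[("dual", 10 ** 9)][1] is False
    assert by_mode[("dual", 0)][0] == by_mode[("local", 0)][0]
    assert by_mode[("dual", 0)][1] is True  # forced fallback is flagged


def test_collapse_rules_and_order_independence():
    a = [make_observation(0, 0, 10), make_observation(1, 1, 5)]
    b = [make_observation(1, 1, 20), make_observation(2, 0, 10),
         make_observation(3, UNKNOWN, 0)]
    c = [make_observation(2, 1, 15)]
    fwd = collapse_mappings([("x", a), ("x", b), ("x", c)])
    rev = collapse_mappings([("x", c), ("x", b), ("x", a)])
    assert fwd == rev
    (read,) = fwd
    by_site = {o.site_index: o for o in read.observations}
    assert (by_site[0].allele, by_site[0].weight) == (0, 10)
    assert (by_site[1].allele, by_site[1].weight) == (1, 20)  # agree: max w
    assert (by_site[2].allele, by_site[2].weight) == (AMBIGUOUS, 0)  # conflict
    assert 3 not in by_site  # UNKNOWN dropped


def test_collapse_bridges_disjoint_supplementary_pieces():
    primary = [make_observation(i, 1, 10) for i in range(0, 3)]
    supp = [make_observation(i, 0, 10) for i in range(8, 11)]
    (read,) = collapse_mappings([("x", primary), ("x", supp)])
    assert [o.site_index for o in read.observations] == [0, 1, 2, 8, 9, 10]


def test_global_mode_reproduces_source_haplotypes_on_clean_reads(small_truth):
    """Error-free simulated reads re-aligned against the graph reproduce
    their source haplotype's alleles at every covered het site."""
    truth = small_truth
    sims = [s for s in synth.simulate_reads(truth, 4, 2000, seed=31)
            if s.observed]
    het = truth.het_sites
    g = build_graph(truth.reference, het)
    for s in sims[:25]:
        rec = synth.render_alignment(truth, s)
        obs = assign_global(rec, g)
        hap = truth.truth_h1 if s.source_hap == 1 else truth.truth_h2
        for vi, allele in s.observed.items():
            v = truth.variants[vi]
            if not v.is_het:
                continue
            o = obs[v.site_index]
            if o.allele >= 0:
                assert o.allele == hap[v.site_index]
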