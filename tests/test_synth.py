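"""Synthetic-data generator tests: determinism, construction guarantees,
coverage statistics and read splitting at homozygous deletions."""

import math

import pytest

from phasekit import synth
from phasekit.core import VariantClass


def test_seeded_determinism():
    a = synth.simulate_truth(50_000, snv_rate=0.001, seed=7)
    b = synth.simulate_truth(50_000, snv_rate=0.001, seed=7)
    assert a.reference == b.reference
    assert a.variants == b.variants
    assert (a.truth_h1, a.truth_h2) == (b.truth_h1, b.truth_h2)
    ra = synth.simulate_reads(a, 10, 2000, seed=3)
    rb = synth.simulate_reads(b, 10, 2000, seed=3)
    assert ra == rb


def test_sv_count_and_size_by_construction(small_truth):
    svs = [v for v in small_truth.variants if v.source == VariantClass.SV]
    assert len(svs) == 1
    for v in svs:
        assert max(abs(len(a) - len(v.ref_allele)) for a in v.alt_alleles) >= 50
    trs = [v for v in small_truth.variants
           if v.source == VariantClass.TANDEM_REPEAT]
    assert len(trs) == 2 and all(v.is_het for v in trs)


def test_zero_rates_give_zero_variants():
    t = synth.simulate_truth(20_000, snv_rate=0, indel_rate=0, sv_count=0,
                             tr_count=0, seed=1)
    assert t.variants == []
    assert t.truth_h1 == []


def test_truth_haplotypes_differ_at_every_het_site(small_truth):
    assert len(small_truth.truth_h1) == len(small_truth.het_sites)
    for a, b in zip(small_truth.truth_h1, small_truth.truth_h2):
        assert a != b


def test_variants_are_sorted_and_non_overlapping(small_truth):
    vs = small_truth.variants
    for a, b in zip(vs, vs[1:]):
        assert a.pos <= b.pos
        assert a.end <= b.pos  # strictly separated spans


def test_read_count_is_poisson_around_expectation():
    t = synth.simulate_truth(50_000, snv_rate=0.0005, sv_count=0, tr_count=0,
                             seed=5)
    sims = synth.simulate_reads(t, coverage=20, read_length=2000, seed=6)
    primaries = {s.read_name for s in sims}
    lam = 20 * 50_000 / 2000
    assert abs(len(primaries) - lam) <= 3 * math.sqrt(lam)


def test_error_free_reads_match_source_haplotype(small_truth):
    sims = synth.simulate_reads(small_truth, 10, 2000,
                                allele_error_rate=0.0, seed=9)
    for s in sims:
        hap = (small_truth.truth_h1 if s.source_hap == 1
               else small_truth.truth_h2)
        for vi, allele in s.observed.items():
            v = small_truth.variants[vi]
            expected = hap[v.site_index] if v.is_het else v.genotype[0]
            assert allele == expected


def test_hom_deletion_splits_crossing_reads():
    t = synth.simulate_truth(40_000, snv_rate=0.001, sv_count=0, tr_count=0,
                             seed=11, hom_deletion_count=1,
                             hom_deletion_length=10_000)
    (d0, d1), = t.deletion_intervals
    sims = synth.simulate_reads(t, coverage=15, read_length=3000, seed=12)
    by_name = {}
    for s in sims:
        by_name.setdefault(s.read_name, []).append(s)
    crossing = 0
    for name, segs in by_name.items():
        for s in segs:
            # no segment may intrude into the deleted interval
            assert s.end <= d0 or s.start >= d1
        if any(s.end <= d0 for s in segs) and any(s.start >= d1 for s in segs):
            crossing += 1
            assert len(segs) >= 2
            assert sum(not s.is_supplementary for s in segs) == 1
    assert crossing > 0  # the deletion is shorter than the sampling range


def test_rendered_alignment_spells_observed_alleles(small_truth):
    """Rendered sequence/CIGAR round-trips: query length matches the CIGAR
    and alt alleles appear verbatim in the spliced sequence."""
    sims = [s for s in synth.simulate_reads(small_truth, 5, 2000, seed=13)
            if s.observed]
    for s in sims[:20]:
        rec = synth.render_alignment(small_truth, s)
        qlen = sum(ln for op, ln in rec.cigar if op in (0, 1))
        rlen = sum(ln for op, ln in rec.cigar if op in (0, 2))
        assert qlen == len(rec.query_sequence)
        assert rlen == rec.end - rec.start
        for vi, allele in s.observed.items():
            if allele > 0:
                alt = small_truth.variants[vi].alt_alleles[allele - 1]
                assert alt in rec.query_sequence


def test_parameter_validation():
    with pytest.raises(ValueError):
        synth.simulate_truth(5_000, sv_count=1, seed=0)
    with pytest.raises(ValueError):
        synth.simulate_truth(20_000, snv_rate=1.5, seed=0)
    t = synth.simulate_truth(20_000, sv_count=0, seed=0)
    with pytest.raises(ValueError):
        synth.simulate_reads(t, coverage=0, read_length=2000)
    with pytest.raises(ValueError):
        synth.simulate_reads(t, coverage=10, read_length=500)
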