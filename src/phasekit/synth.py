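"""Synthetic diploid truth sets and simulated long-read alignments.

The simulator produces everything the phasing pipeline consumes — a
reference segment, variant calls of all three classes (small, structural,
tandem repeat), truth haplotypes, and aligned reads — so the full pipeline
is testable without any external download.

Reads are simulated at the allele level: each read is drawn from one truth
haplotype and records which allele it shows at every variant site it fully
overlaps, with optional per-site corruption.  For re-alignment tests the
same records can be rendered into raw sequence + CIGAR
(:func:`render_alignment`), splicing the observed alleles into the reference
segment, so local and global re-alignment see realistic query sequences.
Reads crossing a homozygous deletion are emitted as a primary +
supplementary pair sharing a read name, split at the deletion — the
coverage-gap structure that phase-block generation must bridge.

Deliberately not modelled: realistic base-level sequencing-error profiles
and reference-bias mapping artefacts.  Read starts are uniform and lengths
fixed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .core import VariantClass, VariantSite
from .io_formats import AlignmentRecord

_BASES = np.array(list("ACGT"))

DEFAULT_MAPQ = 60
DEFAULT_BASEQ = 30


@dataclass
class TruthSet:
    """A diploid truth: reference, variants, and per-site haplotype alleles."""

    chrom: str
    reference: str
    variants: List[VariantSite]
    truth_h1: List[int]  # allele per heterozygous site, dense het order
    truth_h2: List[int]
    deletion_intervals: List[Tuple[int, int]] = field(default_factory=list)

    @property
    def het_sites(self) -> List[VariantSite]:
        return [v for v in self.variants if v.is_het]

    def truth_phase(self) -> Dict[int, int]:
        """Map dense het site index -> truth h1 allele (for switch/flip)."""
        return {i: a for i, a in enumerate(self.truth_h1)}


@dataclass
class SimulatedAlignment:
    """One mapped segment of a simulated read (allele-level representation).

    ``observed`` maps indices into ``TruthSet.variants`` (not the dense het
    ordering) to the allele the read shows there; only sites whose reference
    span lies entirely within ``[start, end)`` are observed.  ``source_hap``
    (1 or 2) records which truth haplotype the read was drawn from — an
    oracle label for haplotagging tests, never visible to the pipeline.
    """

    read_name: str
    chrom: str
    start: int
    end: int
    mapq: int
    is_supplementary: bool
    observed: Dict[int, int]
    base_quality: int = DEFAULT_BASEQ
    source_hap: int = 1


def _random_seq(rng, length: int) -> str:
    return "".join(rng.choice(_BASES, size=length))


def _place(rng, occupied: List[Tuple[int, int]], length: int, ref_length: int,
           margin: int = 10, attempts: int = 200) -> Optional[int]:
    """Find a start so [start, start+length) clears every occupied interval."""
    for _ in range(attempts):
        pos = int(rng.integers(1, max(2, ref_length - length - 1)))
        lo, hi = pos - margin, pos + length + margin
        if all(hi <= s or lo >= e for s, e in occupied):
            occupied.append((pos, pos + length))
            return pos
    return None


def simulate_truth(
    ref_length: int,
    snv_rate: float = 0.001,
    indel_rate: float = 0.0002,
    sv_count: int = 2,
    tr_count: int = 5,
    seed: int = 0,
    hom_deletion_count: int = 0,
    hom_deletion_length: int = 10_000,
    chrom: str = "chr1",
) -> TruthSet:
    """Generate a seeded diploid truth set.

    SNVs and short indels arrive at per-base rates (mostly heterozygous,
    with a minority of homozygous-alt and multi-allelic 1/2 calls);
    ``sv_count`` structural insertions/deletions of >= 50 bp and
    ``tr_count`` tandem-repeat copy-number sites are always heterozygous.
    ``hom_deletion_count`` adds large homozygous deletions whose spans are
    recorded in ``deletion_intervals`` and split simulated reads into
    primary + supplementary pairs.

    Raises ``ValueError`` if the requested density cannot be placed without
    overlaps.
    """
    if not (0 <= snv_rate <= 1 and 0 <= indel_rate <= 1):
        raise ValueError("rates must be in [0, 1]")
    if sv_count > 0 and ref_length < 10_000:
        raise ValueError("ref_length must be >= 10 kb when sv_count > 0")
    rng = np.random.default_rng(seed)
    ref = np.array(list(_random_seq(rng, ref_length)))
    occupied: List[Tuple[int, int]] = []
    variants: List[VariantSite] = []
    deletion_intervals: List[Tuple[int, int]] = []

    def fail(kind):
        raise ValueError(f"could not place {kind}: variant density infeasible")

    # Tandem repeats first: they overwrite the reference with a motif array.
    for _ in range(tr_count):
        motif = _random_seq(rng, int(rng.integers(2, 5)))
        while len(set(motif)) == 1:  # avoid pure homopolymers
            motif = _random_seq(rng, int(rng.integers(2, 5)))
        copies = int(rng.integers(8, 14))
        region = motif * copies
        pos = _place(rng, occupied, len(region), ref_length)
        if pos is None:
            fail("tandem repeat")
        ref[pos:pos + len(region)] = list(region)
        deltas = rng.choice([-3, -2, -1, 1, 2, 3], size=2, replace=False)
        if rng.random() < 0.5:
            alts = (motif * (copies + int(deltas[0])),)
            gt = (0, 1)
        else:
            alts = (motif * (copies + int(deltas[0])), motif * (copies + int(deltas[1])))
            gt = (1, 2)
        variants.append(VariantSite(chrom, pos, region, alts, gt,
                                    VariantClass.TANDEM_REPEAT))

    # Structural insertions/deletions >= 50 bp, heterozygous.
    for _ in range(sv_count):
        if rng.random() < 0.5:  # deletion
            length = int(rng.integers(50, 200))
            pos = _place(rng, occupied, length + 1, ref_length)
            if pos is None:
                fail("SV")
            ref_allele = "".join(ref[pos:pos + length + 1])
            variants.append(VariantSite(chrom, pos, ref_allele, (ref_allele[0],),
                                        (0, 1), VariantClass.SV))
        else:  # insertion
            pos = _place(rng, occupied, 1, ref_length)
            if pos is None:
                fail("SV")
            anchor = str(ref[pos])
            ins = anchor + _random_seq(rng, int(rng.integers(50, 200)))
            variants.append(VariantSite(chrom, pos, anchor, (ins,),
                                        (0, 1), VariantClass.SV))

    # Large homozygous deletions (coverage gaps for the supplementary logic).
    for _ in range(hom_deletion_count):
        pos = _place(rng, occupied, hom_deletion_length + 1, ref_length)
        if pos is None:
            fail("homozygous deletion")
        ref_allele = "".join(ref[pos:pos + hom_deletion_length + 1])
        variants.append(VariantSite(chrom, pos, ref_allele, (ref_allele[0],),
                                    (1, 1), VariantClass.SV))
        deletion_intervals.append((pos + 1, pos + 1 + hom_deletion_length))

    # SNVs.
    n_snv = rng.binomial(ref_length, snv_rate) if snv_rate > 0 else 0
    for _ in range(n_snv):
        pos = _place(rng, occupied, 1, ref_length, margin=3)
        if pos is None:
            continue  # saturated; remaining SNVs are dropped silently
        r = str(ref[pos])
        others = [b for b in "ACGT" if b != r]
        u = rng.random()
        if u < 0.75:
            variants.append(VariantSite(chrom, pos, r, (str(rng.choice(others)),),
                                        (0, 1), VariantClass.SMALL))
        elif u < 0.90:
            variants.append(VariantSite(chrom, pos, r, (str(rng.choice(others)),),
                                        (1, 1), VariantClass.SMALL))
        else:
            a1, a2 = rng.choice(others, size=2, replace=False)
            variants.append(VariantSite(chrom, pos, r, (str(a1), str(a2)),
                                        (1, 2), VariantClass.SMALL))

    # Short indels (1-10 bp).
    n_indel = rng.binomial(ref_length, indel_rate) if indel_rate > 0 else 0
    for _ in range(n_indel):
        length = int(rng.integers(1, 11))
        gt = (0, 1) if rng.random() < 0.8 else (1, 1)
        if rng.random() < 0.5:  # deletion
            pos = _place(rng, occupied, length + 1, ref_length, margin=5)
            if pos is None:
                continue
            ref_allele = "".join(ref[pos:pos + length + 1])
            variants.append(VariantSite(chrom, pos, ref_allele, (ref_allele[0],),
                                        gt, VariantClass.SMALL))
        else:  # insertion
            pos = _place(rng, occupied, 1, ref_length, margin=5)
            if pos is None:
                continue
            anchor = str(ref[pos])
            variants.append(VariantSite(chrom, pos, anchor,
                                        (anchor + _random_seq(rng, length),),
                                        gt, VariantClass.SMALL))

    variants.sort(key=lambda v: (v.pos, v.ref_allele, v.alt_alleles[0]))
    # Dense heterozygous indexing + truth phase.
    truth_h1, truth_h2 = [], []
    indexed: List[VariantSite] = []
    het_i = 0
    for v in variants:
        if v.is_het:
            g1, g2 = v.genotype
            if rng.random() < 0.5:
                g1, g2 = g2, g1
            truth_h1.append(g1)
            truth_h2.append(g2)
            indexed.append(VariantSite(v.chrom, v.pos, v.ref_allele, v.alt_alleles,
                                       v.genotype, v.source, het_i))
            het_i += 1
        else:
            indexed.append(v)
    return TruthSet(chrom, "".join(ref), indexed, truth_h1, truth_h2,
                    deletion_intervals)


def _read_segments(start: int, read_length: int, ref_length: int,
                   deletions: Sequence) -> List[Tuple[int, int]]:
    """Reference spans covered by a read of ``read_length`` consumed bases.

    Homozygous deletions consume no read bases, so a read crossing one
    continues on the far side — producing multiple segments.
    """
    segs = []
    remaining = read_length
    cur = start
    for d0, d1 in sorted(deletions):
        if d1 <= cur:
            continue
        if d0 <= cur:
            cur = d1
            continue
        take = min(d0 - cur, remaining)
        if take > 0:
            segs.append((cur, cur + take))
            remaining -= take
        if remaining <= 0 or cur + take < d0:
            remaining = 0
            break
        cur = d1
    if remaining > 0:
        end = min(cur + remaining, ref_length)
        if end > cur:
            segs.append((cur, end))
    return [(s, e) for s, e in segs if e > s and s < ref_length]


def simulate_reads(
    truth: TruthSet,
    coverage: float,
    read_length: int,
    allele_error_rate: float = 0.0,
    seed: int = 0,
) -> List[SimulatedAlignment]:
    """Draw reads uniformly from the two truth haplotypes.

    The read count is Poisson with mean ``coverage * ref_length /
    read_length``; starts are uniform.  Each fully-overlapped variant site is
    observed with the source haplotype's allele, corrupted to a uniformly
    chosen different allele with probability ``allele_error_rate``.  Reads
    crossing a homozygous deletion are split into primary + supplementary
    records sharing a read name.
    """
    if coverage <= 0:
        raise ValueError("coverage must be positive")
    if read_length < 1000:
        raise ValueError("read_length must be >= 1 kb")
    rng = np.random.default_rng(seed)
    L = len(truth.reference)
    n_reads = int(rng.poisson(coverage * L / read_length))
    out: List[SimulatedAlignment] = []
    for i in range(n_reads):
        start = int(rng.integers(0, L))
        hap = int(rng.integers(1, 3))
        segs = _read_segments(start, read_length, L, truth.deletion_intervals)
        name = f"read_{i:06d}"
        for si, (s, e) in enumerate(segs):
            observed: Dict[int, int] = {}
            for vi, v in enumerate(truth.variants):
                if v.pos < s:
                    continue
                if v.pos >= e:
                    break
                if v.end > e:
                    continue
                if v.is_het:
                    allele = (truth.truth_h1 if hap == 1 else truth.truth_h2)[v.site_index]
                else:
                    allele = v.genotype[0]
                if allele_error_rate > 0 and rng.random() < allele_error_rate:
                    allele = int(rng.choice(
                        [a for a in range(v.n_alleles) if a != allele]))
                observed[vi] = allele
            out.append(SimulatedAlignment(
                read_name=name, chrom=truth.chrom, start=s, end=e,
                mapq=DEFAULT_MAPQ, is_supplementary=(si > 0),
                observed=observed, source_hap=hap))
    return out


def render_alignment(truth: TruthSet, sim: SimulatedAlignment) -> AlignmentRecord:
    """Render an allele-level segment into sequence + CIGAR.

    Splices each observed allele into the reference over ``[start, end)``;
    SNVs stay inside match ops, insertions/deletions emit I/D ops.  Base
    qualities are flat at the simulator's default.
    """
    ref = truth.reference
    seq_parts: List[str] = []
    cig: List[Tuple[int, int]] = []  # pysam op codes: 0=M, 1=I, 2=D

    def add(op, ln):
        if ln <= 0:
            return
        if cig and cig[-1][0] == op:
            cig[-1] = (op, cig[-1][1] + ln)
        else:
            cig.append((op, ln))

    cur = sim.start
    for vi in sorted(sim.observed):
        v = truth.variants[vi]
        allele = sim.observed[vi]
        if allele == 0:
            continue
        alt = v.allele_seq(allele)
        seq_parts.append(ref[cur:v.pos])
        add(0, v.pos - cur)
        common = min(len(v.ref_allele), len(alt))
        seq_parts.append(alt)
        add(0, common)
        if len(alt) > common:
            add(1, len(alt) - common)
        elif len(v.ref_allele) > common:
            add(2, len(v.ref_allele) - common)
        cur = v.end
    seq_parts.append(ref[cur:sim.end])
    add(0, sim.end - cur)
    seq = "".join(seq_parts)
    return AlignmentRecord(
        read_name=sim.read_name,
        chrom=sim.chrom,
        start=sim.start,
        end=sim.end,
        mapq=sim.mapq,
        is_supplementary=sim.is_supplementary,
        cigar=tuple(cig),
        query_sequence=seq,
        base_qualities=tuple([sim.base_quality] * len(seq)),
    )


def render_all(truth: TruthSet, sims: Sequence) -> List[AlignmentRecord]:
    """Render every simulated segment, sorted by (start, name) like a BAM."""
    recs = [render_alignment(truth, s) for s in sims]
    recs.sort(key=lambda r: (r.start, r.read_name, r.is_supplementary))
    return recs


# ---------------------------------------------------------------------------
# File writers: FASTA / SAM / VCF triad + phased truth VCF + genes BED.
# ---------------------------------------------------------------------------

def write_reference_fasta(truth: TruthSet, path: str) -> str:
    with open(path, "w") as fh:
        fh.write(f">{truth.chrom}\n")
        for i in range(0, len(truth.reference), 60):
            fh.write(truth.reference[i:i + 60] + "\n")
    return path


def write_reads_sam(truth: TruthSet, sims: Sequence, path: str) -> str:
    """Write rendered alignments as coordinate-sorted SAM."""
    import pysam

    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": truth.chrom, "LN": len(truth.reference)}],
    }
    recs = render_all(truth, sims)
    with pysam.AlignmentFile(path, "w", header=header) as out:
        for r in recs:
            a = pysam.AlignedSegment(out.header)
            a.query_name = r.read_name
            a.reference_name = r.chrom
            a.reference_start = r.start
            a.mapping_quality = r.mapq
            a.cigartuples = list(r.cigar)
            a.query_sequence = r.query_sequence
            a.query_qualities = pysam.qualitystring_to_array(
                "".join(chr(q + 33) for q in r.base_qualities))
            a.flag = 2048 if r.is_supplementary else 0
            out.write(a)
    return path


def _vcf_header(truth: TruthSet, sample: str, phased: bool):
    import pysam

    header = pysam.VariantHeader()
    header.add_line(f"##contig=<ID={truth.chrom},length={len(truth.reference)}>")
    header.add_line('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    if phased:
        header.add_line('##FORMAT=<ID=PS,Number=1,Type=Integer,Description="Phase set">')
    header.add_sample(sample)
    return header


def _write_vcf(truth: TruthSet, variants: Sequence, path: str, sample: str,
               phased: bool = False) -> str:
    import pysam

    header = _vcf_header(truth, sample, phased)
    with pysam.VariantFile(path, "w", header=header) as out:
        for v in variants:
            rec = out.new_record(
                contig=v.chrom, start=v.pos,
                alleles=(v.ref_allele, *v.alt_alleles), filter="PASS")
            if phased and v.is_het:
                g1 = truth.truth_h1[v.site_index]
                g2 = truth.truth_h2[v.site_index]
                rec.samples[sample]["GT"] = (g1, g2)
                rec.samples[sample].phased = True
                rec.samples[sample]["PS"] = 1
            else:
                rec.samples[sample]["GT"] = tuple(v.genotype)
                rec.samples[sample].phased = not v.is_het and phased
            out.write(rec)
    return path


def write_variant_vcfs(truth: TruthSet, prefix: str, sample: str = "SAMPLE"):
    """Write one unphased VCF per variant class (small / sv / tandem repeat).

    Returns ``{VariantClass: path}`` for classes that have any calls.
    """
    paths = {}
    for cls, tag in ((VariantClass.SMALL, "small"), (VariantClass.SV, "sv"),
                     (VariantClass.TANDEM_REPEAT, "tr")):
        vs = [v for v in truth.variants if v.source == cls]
        if vs:
            paths[cls] = _write_vcf(truth, vs, f"{prefix}.{tag}.vcf", sample)
    return paths


def write_truth_vcf(truth: TruthSet, path: str, sample: str = "SAMPLE") -> str:
    """Write the fully phased truth VCF (GT with '|', PS=1) for evaluation."""
    return _write_vcf(truth, truth.variants, path, sample, phased=True)


def make_gene_intervals(truth: TruthSet, n_genes: int = 20, gene_length: int = 5000,
                        seed: int = 0) -> List[Tuple[str, int, int]]:
    """Evenly spaced synthetic gene intervals for the gene-phasing metric."""
    L = len(truth.reference)
    step = max(gene_length + 1, L // max(1, n_genes))
    return [(truth.chrom, s, min(s + gene_length, L))
            for s in range(0, L - gene_length, step)][:n_genes]


def write_genes_bed(genes: Sequence, path: str) -> str:
    with open(path, "w") as fh:
        for i, (chrom, s, e) in enumerate(genes):
            fh.write(f"{chrom}\t{s}\t{e}\tgene_{i:04d}\n")
    return path
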