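"""VCF / SAM / TSV input and output.

Reading goes through pysam; this module converts between file records and
the in-memory types in :mod:`phasekit.core`.  All internal coordinates are
0-based half-open; VCF's 1-based convention exists only inside pysam
records.

Conventions follow the prevailing read-backed-phaser practice:

* phased genotypes use the ``|`` separator ordered (h1, h2) with a
  ``FORMAT/PS`` integer equal to the 1-based position of the block's first
  heterozygous variant;
* haplotagged alignments carry ``HP:i`` (1 or 2) and ``PC:i`` (phase set).

Single-variant blocks are reported in statistics but their site is left
unphased in the VCF — a one-site block carries no phase information.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import pysam

from .core import PhaseBlock, VariantClass, VariantSite

_DEFAULT_SOURCES = (VariantClass.SMALL, VariantClass.SV, VariantClass.TANDEM_REPEAT)

# source preference for deduplicating identical records across input files
_SOURCE_RANK = {VariantClass.SMALL: 0, VariantClass.SV: 1, VariantClass.TANDEM_REPEAT: 2}


@dataclass(frozen=True)
class AlignmentRecord:
    """One mapped read segment (SAM semantics, 0-based half-open span)."""

    read_name: str
    chrom: str
    start: int
    end: int
    mapq: int
    is_supplementary: bool = False
    cigar: Optional[tuple] = None  # pysam-style (op, length) tuples
    query_sequence: Optional[str] = None
    base_qualities: Optional[tuple] = None

    def __post_init__(self):
        if self.end <= self.start:
            raise ValueError("alignment span must be non-empty")

    def covers(self, span: tuple) -> bool:
        """True iff the mapping fully contains the half-open span."""
        return self.start <= span[0] and self.end >= span[1]


def read_reference(path: str) -> Dict[str, str]:
    """Load a FASTA into {chrom: sequence}, building the index if needed."""
    if not os.path.exists(path + ".fai"):
        pysam.faidx(path)
    out = {}
    with pysam.FastaFile(path) as fa:
        for name in fa.references:
            out[name] = fa.fetch(name)
    return out


def read_alignments(path: str, chrom: Optional[str] = None) -> List[AlignmentRecord]:
    """Read mapped records from SAM/BAM in file order (no index required)."""
    out = []
    with pysam.AlignmentFile(path, check_sq=False) as fh:
        for seg in fh:
            if seg.is_unmapped or seg.is_secondary:
                continue
            if chrom is not None and seg.reference_name != chrom:
                continue
            quals = seg.query_qualities
            out.append(AlignmentRecord(
                read_name=seg.query_name,
                chrom=seg.reference_name,
                start=seg.reference_start,
                end=seg.reference_end,
                mapq=seg.mapping_quality,
                is_supplementary=seg.is_supplementary,
                cigar=tuple(seg.cigartuples) if seg.cigartuples else None,
                query_sequence=seg.query_sequence,
                base_qualities=tuple(quals) if quals is not None else None,
            ))
    return out


def _record_passes(rec) -> bool:
    keys = list(rec.filter.keys())
    return not keys or keys == ["PASS"]


def read_variant_files(
    paths: Sequence,
    sample: Optional[str] = None,
    chrom: Optional[str] = None,
    sources: Optional[Sequence] = None,
) -> List[VariantSite]:
    """Merge one or more VCFs into a position-sorted, source-tagged site list.

    ``sources`` labels each file's calls (defaults to small, sv,
    tandem_repeat in path order, mirroring the small-variant / SV /
    tandem-repeat caller triad).  Records identical in (pos, ref, alts)
    across files are deduplicated preferring the small-variant file.  Only
    diploid genotypes with both alleles called are admitted; by default only
    PASS / unfiltered records are kept.  Heterozygous sites receive a dense
    per-chromosome ``site_index``.

    Raises ``ValueError`` for a missing sample or an unsorted file.
    """
    if sources is None:
        sources = _DEFAULT_SOURCES[: len(paths)]
    if len(sources) != len(paths):
        raise ValueError("sources must parallel paths")

    best: Dict[tuple, VariantSite] = {}
    for path, source in zip(paths, sources):
        with pysam.VariantFile(path) as vf:
            samples = list(vf.header.samples)
            use = sample if sample is not None else (samples[0] if samples else None)
            if use is None or use not in samples:
                raise ValueError(f"sample {sample!r} not found in {path}")
            last = {}
            for rec in vf:
                if chrom is not None and rec.chrom != chrom:
                    continue
                if rec.start < last.get(rec.chrom, 0):
                    raise ValueError(f"{path} is not coordinate-sorted")
                last[rec.chrom] = rec.start
                if not _record_passes(rec):
                    continue
                gt = rec.samples[use].get("GT")
                if gt is None or len(gt) != 2 or any(a is None for a in gt):
                    continue
                if rec.alts is None:
                    continue
                site = VariantSite(
                    chrom=rec.chrom,
                    pos=rec.start,
                    ref_allele=rec.ref,
                    alt_alleles=tuple(rec.alts),
                    genotype=(int(gt[0]), int(gt[1])),
                    source=VariantClass(source),
                )
                key = (site.chrom, site.pos, site.ref_allele, site.alt_alleles)
                prev = best.get(key)
                if prev is None or _SOURCE_RANK[site.source] < _SOURCE_RANK[prev.source]:
                    best[key] = site

    merged = sorted(best.values(),
                    key=lambda v: (v.chrom, v.pos, v.ref_allele, v.alt_alleles[0]))
    out: List[VariantSite] = []
    het_counter: Dict[str, int] = {}
    for v in merged:
        if v.is_het:
            i = het_counter.get(v.chrom, 0)
            het_counter[v.chrom] = i + 1
            out.append(VariantSite(v.chrom, v.pos, v.ref_allele, v.alt_alleles,
                                   v.genotype, v.source, i))
        else:
            out.append(v)
    return out


def _phase_map(blocks: Sequence, het_sites_by_chrom: Dict[str, Sequence]) -> Dict[tuple, tuple]:
    """Map (chrom, pos, ref, alts) -> (h1 allele, h2 allele, phase set)."""
    out = {}
    for b in blocks:
        if not b.solved or b.n_sites < 2:
            continue
        het = het_sites_by_chrom[b.chrom]
        for local, gi in enumerate(b.site_indices):
            v = het[gi]
            key = (v.chrom, v.pos, v.ref_allele, v.alt_alleles)
            out[key] = (b.diplotype.h1[local], b.diplotype.h2[local], b.phase_set)
    return out


def write_phased_vcf(
    in_path: str,
    blocks: Sequence,
    het_sites_by_chrom: Dict[str, Sequence],
    out_path: str,
    sample: Optional[str] = None,
) -> str:
    """Rewrite a VCF with phased genotypes and PS for solved-block sites.

    Heterozygous records inside a solved multi-site block get a phased
    genotype ordered (h1, h2) plus ``FORMAT/PS``; every other record passes
    through unmodified, so the record count is conserved.
    """
    phase = _phase_map(blocks, het_sites_by_chrom)
    with pysam.VariantFile(in_path) as vf:
        header = vf.header.copy()
        if "PS" not in header.formats:
            header.add_line(
                '##FORMAT=<ID=PS,Number=1,Type=Integer,Description="Phase set">')
        samples = list(vf.header.samples)
        use = sample if sample is not None else samples[0]
        with pysam.VariantFile(out_path, "w", header=header) as out:
            for rec in vf:
                nrec = rec.copy()
                nrec.translate(header)
                key = (rec.chrom, rec.start, rec.ref,
                       tuple(rec.alts) if rec.alts else ())
                hit = phase.get(key)
                if hit is not None:
                    h1, h2, ps = hit
                    nrec.samples[use]["GT"] = (h1, h2)
                    nrec.samples[use].phased = True
                    nrec.samples[use]["PS"] = ps
                out.write(nrec)
    return out_path


def read_phased_vcf(path: str, sample: Optional[str] = None):
    """Read phased het genotypes: {(chrom,pos,ref,alts): (h1, h2, ps)}.

    Used both for truth sets (fully phased VCFs) and for evaluating a
    phaser's output.  Unphased or homozygous records are skipped.
    """
    out = {}
    with pysam.VariantFile(path) as vf:
        samples = list(vf.header.samples)
        use = sample if sample is not None else samples[0]
        for rec in vf:
            sd = rec.samples[use]
            gt = sd.get("GT")
            if gt is None or len(gt) != 2 or any(a is None for a in gt):
                continue
            if gt[0] == gt[1] or not sd.phased:
                continue
            ps = sd.get("PS")
            key = (rec.chrom, rec.start, rec.ref,
                   tuple(rec.alts) if rec.alts else ())
            out[key] = (int(gt[0]), int(gt[1]), ps if ps is not None else 0)
    return out


def write_haplotagged_alignments(
    in_path: str,
    tag_map: Dict[str, tuple],
    out_path: str,
) -> str:
    """Copy alignments, adding HP/PC tags for reads in ``tag_map``.

    ``tag_map`` maps read name -> (haplotype 1|2, phase set).  Untagged
    reads pass through untouched; record order and count are preserved.
    """
    with pysam.AlignmentFile(in_path, check_sq=False) as fh:
        with pysam.AlignmentFile(out_path, "w", template=fh) as out:
            for seg in fh:
                hit = tag_map.get(seg.query_name)
                if hit is not None:
                    hp, ps = hit
                    seg.set_tag("HP", int(hp), "i")
                    seg.set_tag("PC", int(ps), "i")
                out.write(seg)
    return out_path


STATS_COLUMNS = ["block_id", "chrom", "start", "end", "n_sites", "n_small",
                 "n_sv", "n_tandem_repeat", "solved", "cost", "fallback",
                 "phase_set"]


def write_block_stats(
    blocks: Sequence,
    het_sites_by_chrom: Dict[str, Sequence],
    out_path: str,
) -> str:
    """One TSV row per phase block (span, per-source counts, solve result)."""
    import pandas as pd

    rows = []
    for b in blocks:
        het = het_sites_by_chrom[b.chrom]
        sites = [het[i] for i in b.site_indices]
        counts = {c: 0 for c in VariantClass}
        for s in sites:
            counts[s.source] += 1
        rows.append({
            "block_id": b.block_id,
            "chrom": b.chrom,
            "start": min(s.pos for s in sites),
            "end": max(s.end for s in sites),
            "n_sites": b.n_sites,
            "n_small": counts[VariantClass.SMALL],
            "n_sv": counts[VariantClass.SV],
            "n_tandem_repeat": counts[VariantClass.TANDEM_REPEAT],
            "solved": b.solved,
            "cost": b.diplotype.cost if b.solved else "",
            "fallback": b.fallback,
            "phase_set": b.phase_set,
        })
    pd.DataFrame(rows, columns=STATS_COLUMNS).to_csv(out_path, sep="\t", index=False)
    return out_path
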