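"""End-to-end orchestration: files in, phased files + statistics out.

The unit of parallel work is the putative phase block: blocks are
independent sub-problems, so allele assignment and diplotype solving run per
block (optionally on a thread pool) and results are collected in genomic
order before anything is written.  Output bytes are therefore identical for
any worker count.
"""

from __future__ import annotations

import json
import logging
from concurrent.futures import ThreadPoolExecutor
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

from . import alleles, blocks as blocks_mod, io_formats, metrics, solver
from .core import AMBIGUOUS, CondensedRead, PhaseBlock, row_cost

logger = logging.getLogger("phasekit")


@dataclass
class PhaseConfig:
    """Inputs, outputs and tuning knobs for one phasing run."""

    vcf: str
    alignments: str
    reference: str
    output_prefix: str
    sv_vcf: Optional[str] = None
    tr_vcf: Optional[str] = None
    sample: Optional[str] = None
    mode: str = "dual"
    global_budget: int = alleles.DEFAULT_GLOBAL_BUDGET
    min_mapq: int = blocks_mod.DEFAULT_MIN_MAPQ
    window_pad: int = alleles.DEFAULT_WINDOW_PAD
    chunk_size: int = solver.DEFAULT_CHUNK_SIZE
    threads: int = 1
    haplotag: bool = False
    genes_bed: Optional[str] = None
    truth_vcf: Optional[str] = None
    reference_length: Optional[int] = None  # NG50 denominator; FASTA total if unset

    def variant_paths(self) -> List[str]:
        return [p for p in (self.vcf, self.sv_vcf, self.tr_vcf) if p is not None]

    def variant_sources(self):
        out = [io_formats.VariantClass.SMALL]
        if self.sv_vcf is not None:
            out.append(io_formats.VariantClass.SV)
        if self.tr_vcf is not None:
            out.append(io_formats.VariantClass.TANDEM_REPEAT)
        return out


@dataclass
class BlockResult:
    """One finished (post-split) block plus its block-local condensed reads."""

    block: PhaseBlock
    sites: list
    condensed: list
    n_ambiguous: int = 0
    n_unknown: int = 0


@dataclass
class RunResult:
    blocks: List[PhaseBlock]
    block_results: List[BlockResult]
    het_sites_by_chrom: Dict[str, list]
    tag_map: Dict[str, tuple]
    summary: dict
    outputs: Dict[str, str] = field(default_factory=dict)


def _restrict(read: CondensedRead, lo: int, hi: int) -> Optional[CondensedRead]:
    obs = tuple(o._replace(site_index=o.site_index - lo)
                for o in read.observations if lo <= o.site_index < hi)
    return CondensedRead(read.read_name, obs) if obs else None


def _process_block(
    putative: PhaseBlock,
    het_sites: Sequence,
    alignments: Sequence,
    reference: str,
    cfg: PhaseConfig,
) -> List[BlockResult]:
    sites = [het_sites[i] for i in putative.site_indices]
    mappings = [m for m in alignments
                if m.mapq >= cfg.min_mapq
                and any(m.covers(s.span) for s in sites)]
    obs_lists, fallback = alleles.assign_block(
        sites, mappings, reference, mode=cfg.mode,
        budget=cfg.global_budget, window_pad=cfg.window_pad)
    n_amb = sum(1 for ol in obs_lists for o in ol if o.allele == AMBIGUOUS)
    n_unk = sum(1 for ol in obs_lists for o in ol if o.allele == alleles.UNKNOWN)
    condensed = alleles.collapse_mappings(
        [(m.read_name, ol) for m, ol in zip(mappings, obs_lists)])
    putative.fallback = fallback

    if len(sites) < 2:
        return [BlockResult(putative, sites, condensed, n_amb, n_unk)]

    solvable = [r for r in condensed if r.weighted_sites]
    d = solver.solve_astar(solvable, sites, chunk_size=cfg.chunk_size)
    putative.diplotype = d
    pieces = solver.post_split(putative, d, condensed, sites)

    out = []
    offset = 0
    for piece in pieces:
        lo = offset
        hi = offset + piece.n_sites
        offset = hi
        sub_sites = [het_sites[i] for i in piece.site_indices]
        sub_condensed = [r for r in (_restrict(c, lo, hi) for c in condensed)
                         if r is not None]
        out.append(BlockResult(piece, sub_sites, sub_condensed, n_amb, n_unk))
        n_amb = n_unk = 0  # attribute assignment stats to the first piece
    return out


def haplotag_assign(block_results: Sequence) -> Dict[str, tuple]:
    """Assign each read to the haplotype with strictly smaller row cost.

    Equal costs leave the read untagged.  A read condensed into several
    final blocks keeps the assignment with the largest cost margin (first
    block in genomic order on ties).
    """
    best: Dict[str, tuple] = {}
    for br in block_results:
        b = br.block
        if not b.solved:
            continue
        for read in br.condensed:
            c1 = row_cost(read, b.diplotype.h1)
            c2 = row_cost(read, b.diplotype.h2)
            if c1 == c2:
                continue
            hp = 1 if c1 < c2 else 2
            margin = abs(c1 - c2)
            prev = best.get(read.read_name)
            if prev is None or margin > prev[2]:
                best[read.read_name] = (hp, b.phase_set, margin)
    return {name: (hp, ps) for name, (hp, ps, _) in best.items()}


def phase_chromosome(
    het_sites: Sequence,
    alignments: Sequence,
    reference: str,
    cfg: PhaseConfig,
) -> List[BlockResult]:
    """Run block generation, allele assignment and solving for one chromosome.

    Returns finished block results in genomic order, identical for any
    ``cfg.threads``.
    """
    putative = blocks_mod.generate_blocks(het_sites, alignments, cfg.min_mapq)
    if not putative:
        return []
    if cfg.threads > 1:
        with ThreadPoolExecutor(max_workers=cfg.threads) as pool:
            futures = [pool.submit(_process_block, b, het_sites, alignments,
                                   reference, cfg) for b in putative]
            nested = [f.result() for f in futures]
    else:
        nested = [_process_block(b, het_sites, alignments, reference, cfg)
                  for b in putative]
    out: List[BlockResult] = []
    for group in nested:
        for br in group:
            logger.info(
                "block chrom=%s sites=%d ps=%d solved=%s cost=%s fallback=%s",
                br.block.chrom, br.block.n_sites, br.block.phase_set,
                br.block.solved,
                br.block.diplotype.cost if br.block.solved else "-",
                br.block.fallback)
            out.append(br)
    return out


def run(cfg: PhaseConfig) -> RunResult:
    """Execute the full pipeline described by ``cfg``.

    Reads variants and alignments, phases every chromosome, and writes: one
    phased VCF per input VCF, a block statistics TSV, a JSON summary, and
    (optionally) haplotagged alignments.
    """
    reference = io_formats.read_reference(cfg.reference)
    sites = io_formats.read_variant_files(
        cfg.variant_paths(), sample=cfg.sample, sources=cfg.variant_sources())
    all_alignments = io_formats.read_alignments(cfg.alignments)

    het_by_chrom: Dict[str, list] = {}
    for v in sites:
        if v.is_het:
            het_by_chrom.setdefault(v.chrom, []).append(v)
    aln_by_chrom: Dict[str, list] = {}
    for a in all_alignments:
        aln_by_chrom.setdefault(a.chrom, []).append(a)

    block_results: List[BlockResult] = []
    for chrom in reference:
        het = het_by_chrom.get(chrom, [])
        if not het:
            logger.info("chromosome %s: no heterozygous sites, skipped", chrom)
            continue
        aln = sorted(aln_by_chrom.get(chrom, []), key=lambda m: (m.start, m.read_name))
        block_results.extend(phase_chromosome(het, aln, reference[chrom], cfg))

    for i, br in enumerate(block_results):
        br.block.block_id = i
    final_blocks = [br.block for br in block_results]
    tag_map = haplotag_assign(block_results) if cfg.haplotag else {}

    outputs: Dict[str, str] = {}
    for path, tag in zip(cfg.variant_paths(),
                         ("small", "sv", "tr")[: len(cfg.variant_paths())]):
        out = f"{cfg.output_prefix}.{tag}.phased.vcf"
        io_formats.write_phased_vcf(path, final_blocks, het_by_chrom, out,
                                    sample=cfg.sample)
        outputs[f"phased_vcf_{tag}"] = out
    stats_path = f"{cfg.output_prefix}.blocks.tsv"
    io_formats.write_block_stats(final_blocks, het_by_chrom, stats_path)
    outputs["block_stats"] = stats_path
    if cfg.haplotag:
        tagged = f"{cfg.output_prefix}.haplotagged.sam"
        io_formats.write_haplotagged_alignments(cfg.alignments, tag_map, tagged)
        outputs["haplotagged"] = tagged

    ref_len = cfg.reference_length or sum(len(s) for s in reference.values())
    counts = metrics.phased_counts(final_blocks, het_by_chrom)
    summary = {
        "n_het_sites": sum(len(v) for v in het_by_chrom.values()),
        "n_blocks": len(final_blocks),
        "n_solved_blocks": sum(1 for b in final_blocks if b.solved),
        "n_fallback_blocks": sum(1 for b in final_blocks if b.fallback),
        "ng50": metrics.ng50(metrics.block_spans(final_blocks, het_by_chrom),
                             ref_len),
        "phased_small": counts[io_formats.VariantClass.SMALL],
        "phased_sv": counts[io_formats.VariantClass.SV],
        "phased_tandem_repeat": counts[io_formats.VariantClass.TANDEM_REPEAT],
        "total_cost": sum(b.diplotype.cost for b in final_blocks if b.solved),
        "n_ambiguous_obs": sum(br.n_ambiguous for br in block_results),
        "n_unknown_obs": sum(br.n_unknown for br in block_results),
        "n_haplotagged_reads": len(tag_map),
    }
    if cfg.genes_bed:
        genes = metrics.read_genes_bed(cfg.genes_bed)
        summary["fully_phased_gene_fraction"] = metrics.gene_phasing(
            genes, final_blocks, het_by_chrom)
    if cfg.truth_vcf:
        truth = io_formats.read_phased_vcf(cfg.truth_vcf, sample=cfg.sample)
        pred = {}
        for key in outputs:
            if key.startswith("phased_vcf_"):
                pred.update(io_formats.read_phased_vcf(outputs[key],
                                                       sample=cfg.sample))
        s, f, n = metrics.compare_phased_vcfs(pred, truth)
        summary["switches"] = s
        summary["flips"] = f
        summary["n_compared_sites"] = n

    summary_path = f"{cfg.output_prefix}.summary.json"
    with open(summary_path, "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    outputs["summary"] = summary_path

    return RunResult(final_blocks, block_results, het_by_chrom, tag_map,
                     summary, outputs)
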