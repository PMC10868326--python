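"""Phasing evaluation and summary statistics.

Switch/flip accounting follows the read-backed-phasing convention: within
each predicted block, compare the predicted h1 allele against the truth h1
allele site by site, forming an agreement sequence.  Each transition in that
sequence is a phase discordance; an isolated single-site disagreement
bounded by two transitions is one *flip* (consuming both transitions), and
every remaining transition is one *switch*.  Because complementing the
agreement sequence leaves its transitions unchanged, the per-block
orientation (which truth haplotype is "h1") does not affect the totals.

NG50 is the largest block length L such that blocks of length >= L cover at
least half of the *reference* length — the denominator is the genome, not
the phased portion.
"""

from __future__ import annotations

from typing import Dict, List, Sequence, Tuple

from .core import PhaseBlock, VariantClass, VariantSite


def _classify_transitions(agreement: Sequence) -> Tuple[int, int]:
    """Greedy left-to-right switch/flip classification of one block."""
    t = [i for i in range(len(agreement) - 1) if agreement[i] != agreement[i + 1]]
    switches = flips = 0
    i = 0
    while i < len(t):
        if i + 1 < len(t) and t[i + 1] == t[i] + 1:
            flips += 1
            i += 2
        else:
            switches += 1
            i += 1
    return switches, flips


def switch_flip(
    truth_h1: Dict[int, int],
    blocks: Sequence,
) -> Tuple[int, int]:
    """Count switch and flip errors of predicted blocks against a truth phase.

    ``truth_h1`` maps dense heterozygous site index -> truth h1 allele;
    comparison happens only at sites phased in both (inside solved
    multi-site predicted blocks and present in the truth).  Totals are
    summed over blocks; the per-block orientation minimising the error count
    is implicit (transition counts are orientation-invariant).
    """
    switches = flips = 0
    for b in blocks:
        if not b.solved or b.n_sites < 2:
            continue
        agreement = [
            1 if b.diplotype.h1[local] == truth_h1[gi] else 0
            for local, gi in enumerate(b.site_indices)
            if gi in truth_h1
        ]
        s, f = _classify_transitions(agreement)
        switches += s
        flips += f
    return switches, flips


def ng50(block_spans: Sequence, reference_length: int) -> int:
    """NG50 of phase block spans against a fixed reference length.

    ``block_spans`` holds (chrom, start, end) triples; returns 0 when the
    sorted cumulative block length never reaches half the reference.
    """
    if reference_length <= 0:
        raise ValueError("reference_length must be positive")
    lengths = sorted((e - s for _, s, e in block_spans), reverse=True)
    half = reference_length / 2
    acc = 0
    for ln in lengths:
        acc += ln
        if acc >= half:
            return ln
    return 0


def block_spans(blocks: Sequence, het_sites_by_chrom: Dict[str, Sequence]) -> List[tuple]:
    """(chrom, start, end) for each solved multi-site block."""
    out = []
    for b in blocks:
        if not b.solved or b.n_sites < 2:
            continue
        het = het_sites_by_chrom[b.chrom]
        sites = [het[i] for i in b.site_indices]
        out.append((b.chrom, min(s.pos for s in sites), max(s.end for s in sites)))
    return out


def phased_counts(blocks: Sequence, het_sites_by_chrom: Dict[str, Sequence]) -> Dict:
    """Number of phased het sites per variant class.

    A site counts as phased when it lies inside a solved block of at least
    two sites.
    """
    counts = {c: 0 for c in VariantClass}
    for b in blocks:
        if not b.solved or b.n_sites < 2:
            continue
        het = het_sites_by_chrom[b.chrom]
        for gi in b.site_indices:
            counts[het[gi].source] += 1
    return counts


def gene_phasing(
    genes: Sequence,
    blocks: Sequence,
    het_sites_by_chrom: Dict[str, Sequence],
    require_span: bool = False,
) -> float:
    """Fraction of gene intervals that are fully phased.

    A gene is fully phased iff every heterozygous site inside its (0-based,
    half-open) interval belongs to one single solved multi-site block; genes
    with no het sites count as fully phased (vacuously).  With
    ``require_span`` the block must additionally cover the whole gene
    interval.
    """
    if not genes:
        return 0.0
    # site (chrom, dense het index) -> (block id, block span)
    owner = {}
    for b in blocks:
        if not b.solved or b.n_sites < 2:
            continue
        het = het_sites_by_chrom[b.chrom]
        span = (min(het[i].pos for i in b.site_indices),
                max(het[i].end for i in b.site_indices))
        for gi in b.site_indices:
            owner[(b.chrom, gi)] = (b.chrom, b.block_id, b.phase_set, span)
    phased = 0
    for chrom, gstart, gend in genes:
        het = het_sites_by_chrom.get(chrom, [])
        inside = [v for v in het if gstart <= v.pos < gend]
        if not inside:
            phased += 1
            continue
        owners = {owner.get((chrom, v.site_index)) for v in inside}
        if len(owners) == 1 and None not in owners:
            (_, _, _, span) = next(iter(owners))
            if not require_span or (span[0] <= gstart and span[1] >= gend):
                phased += 1
    return phased / len(genes)


def read_genes_bed(path: str) -> List[tuple]:
    """Parse a BED3+ file into (chrom, start, end) triples."""
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            out.append((f[0], int(f[1]), int(f[2])))
    return out


def compare_phased_vcfs(pred: Dict, truth: Dict) -> Tuple[int, int, int]:
    """Switch/flip between two phased VCFs read by ``read_phased_vcf``.

    Both arguments map (chrom, pos, ref, alts) -> (h1, h2, ps).  Sites
    present and heterozygous in both are grouped by the prediction's phase
    set and ordered by position.  Returns (switches, flips, n_compared).
    """
    groups: Dict[tuple, list] = {}
    n = 0
    for key in sorted(pred.keys() & truth.keys()):
        chrom = key[0]
        h1p, _, ps = pred[key]
        h1t, _, _ = truth[key]
        groups.setdefault((chrom, ps), []).append(1 if h1p == h1t else 0)
        n += 1
    switches = flips = 0
    for seq in groups.values():
        s, f = _classify_transitions(seq)
        switches += s
        flips += f
    return switches, flips, n
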