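"""Phase block generation from read-mapping connectivity.

A chromosome's heterozygous sites are swept left to right.  The current
block is extended to the next site when (a) at least one mapping of adequate
mapping quality fully covers both the new site and some site already in the
block, or (b) a split read bridges them: two distinct same-name mappings,
at least one flagged supplementary, cover the new site and a block site
respectively.  The supplementary check is what lets blocks span coverage
gaps at homozygous deletions and reference gaps.  When neither holds the
block is closed and a new single-site block starts.

Putative blocks are a lower bound on the final block count: the solver may
later split a block whose internal junctions lost read support during
allele assignment, but blocks are never merged.
"""

from __future__ import annotations

from typing import List, Sequence

from .core import PhaseBlock, VariantSite
from .io_formats import AlignmentRecord

DEFAULT_MIN_MAPQ = 5


def spans_block(mapping: AlignmentRecord, block_sites: Sequence,
                new_site: VariantSite) -> bool:
    """True iff ``mapping`` fully covers the new site and >= 1 block site.

    A variant's span is ``[pos, pos + len(ref))`` (a 1-base anchor for
    insertions); coverage is full containment, so a site starting exactly at
    the mapping's half-open end does not count.
    """
    if not mapping.covers(new_site.span):
        return False
    return any(mapping.covers(s.span) for s in block_sites)


def generate_blocks(
    sites: Sequence,
    alignments: Sequence,
    min_mapq: int = DEFAULT_MIN_MAPQ,
) -> List[PhaseBlock]:
    """Partition a chromosome's het sites into putative phase blocks.

    ``sites`` must be the chromosome's heterozygous sites in order;
    ``alignments`` must be sorted by start.  Returns contiguous, disjoint
    blocks covering every site.  A single spanning (or bridging
    supplementary) mapping suffices to extend a block.
    """
    for a, b in zip(sites, sites[1:]):
        if (b.pos, b.ref_allele) < (a.pos, a.ref_allele):
            raise ValueError("sites are not sorted")
    if any(b.start < a.start for a, b in zip(alignments, alignments[1:])):
        raise ValueError("alignments are not sorted by start")

    usable = [m for m in alignments if m.mapq >= min_mapq]

    # For each site, the ids of mappings fully covering it.
    cover: List[List[int]] = []
    lo = 0
    active: List[int] = []
    for s in sites:
        while lo < len(usable) and usable[lo].start <= s.pos:
            active.append(lo)
            lo += 1
        active = [i for i in active if usable[i].end > s.pos]
        cover.append([i for i in active if usable[i].covers(s.span)])

    blocks: List[PhaseBlock] = []
    cur: List[int] = []          # site indices of current block
    cur_ids: set = set()         # mapping ids covering any current-block site
    cur_names: set = set()       # read names covering any current-block site

    def close():
        if cur:
            blocks.append(PhaseBlock(
                block_id=len(blocks),
                chrom=sites[cur[0]].chrom,
                site_indices=list(cur),
                phase_set=sites[cur[0]].pos + 1,
            ))

    for si, s in enumerate(sites):
        ids = cover[si]
        extend = False
        if cur:
            if any(i in cur_ids for i in ids):
                extend = True  # one mapping spans both
            else:
                # supplementary bridge: distinct same-name mappings, one
                # covering the new site and one covering the block, with a
                # supplementary record in the pair
                for i in ids:
                    m = usable[i]
                    if m.read_name not in cur_names:
                        continue
                    for j in cur_ids:
                        o = usable[j]
                        if j != i and o.read_name == m.read_name and (
                                m.is_supplementary or o.is_supplementary):
                            extend = True
                            break
                    if extend:
                        break
        if cur and not extend:
            close()
            cur, cur_ids, cur_names = [], set(), set()
        cur.append(si)
        cur_ids.update(ids)
        cur_names.update(usable[i].read_name for i in ids)
    close()
    return blocks
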