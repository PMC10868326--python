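"""Exact diplotype solving for a phase block's wMEC instance.

Given the condensed reads of a block (rows of a weighted matrix over the
block's heterozygous sites), the goal is two haplotypes h1/h2 minimising the
total weight of allele edits needed to make every read consistent with one
of them.  The search runs best-first (A*) over partial diplotypes, assigning
sites left to right.  The admissible heuristic chains exact solutions of
small column chunks: per read, the minimum edit cost over disjoint column
subsets can only underestimate the minimum over all remaining columns, and
each chunk optimum ignores cross-chunk consistency, so the chained sum never
exceeds the true completion cost.  The heuristic is also consistent (the cost
accrued while traversing a chunk is at least that chunk's optimum), so the
first goal popped is optimal and no node needs reopening.

A brute-force enumerator over all ``2^(n-1)`` biallelic-style orientations is
provided as an independent oracle for testing; it is never used by the search
itself except to solve the small heuristic chunks exactly.

Haplotypes carry allele *indices*, not bits: a multi-allelic heterozygous
site with genotype 1/2 contributes the choice of which of alleles 1 and 2
goes to h1.  Homozygous sites never enter a block.
"""

from __future__ import annotations

import heapq
from itertools import count, product
from typing import Dict, List, Optional, Sequence, Tuple

from .core import (
    CondensedRead,
    Diplotype,
    PhaseBlock,
    canonicalize,
    diplotype_cost,
    row_cost,
)

#: Hard guard for the exhaustive enumerator.
BRUTE_FORCE_MAX_SITES = 16

#: Default chunk width for the chained heuristic; chunks are solved
#: exhaustively (2^(w-1) orientations), so 8 keeps that trivial while making
#: the heuristic perfect on blocks of up to 8 sites.
DEFAULT_CHUNK_SIZE = 8


def _genotype_pairs(sites: Sequence) -> List[Tuple[int, int]]:
    pairs = []
    for s in sites:
        if not s.is_het:
            raise ValueError("solver blocks must contain heterozygous sites only")
        a, b = sorted(s.genotype)
        pairs.append((a, b))
    return pairs


def _enumerate_diplotypes(sites: Sequence):
    """Yield (h1, h2) over all orientations, h1-lexicographic order.

    Site 0 is symmetry-fixed: its smaller genotype allele goes to h1.
    """
    pairs = _genotype_pairs(sites)
    n = len(pairs)
    if n == 0:
        return
    for flips in product((0, 1), repeat=n - 1):
        h1 = [pairs[0][0]]
        h2 = [pairs[0][1]]
        for (a, b), f in zip(pairs[1:], flips):
            h1.append(b if f else a)
            h2.append(a if f else b)
        yield tuple(h1), tuple(h2)


def brute_force(reads: Sequence, sites: Sequence) -> Diplotype:
    """Exhaustively solve a small wMEC instance (independent test oracle).

    Enumerates every allele-to-haplotype assignment after fixing the first
    site's orientation and returns the minimum-cost diplotype; ties break to
    the lexicographically smallest h1.  Refuses more than
    :data:`BRUTE_FORCE_MAX_SITES` sites.
    """
    n = len(sites)
    if n == 0:
        raise ValueError("cannot solve an empty site list")
    if n > BRUTE_FORCE_MAX_SITES:
        raise ValueError(f"brute force refuses {n} > {BRUTE_FORCE_MAX_SITES} sites")
    best = None
    for h1, h2 in _enumerate_diplotypes(sites):
        c = diplotype_cost(reads, Diplotype(h1, h2, 0))
        if best is None or c < best.cost or (c == best.cost and h1 < best.h1):
            best = Diplotype(h1, h2, c)
    return canonicalize(best)


def _restrict_reads(reads: Sequence, lo: int, hi: int) -> List[CondensedRead]:
    """Project reads onto columns [lo, hi), reindexed to start at 0."""
    out = []
    for r in reads:
        obs = tuple(
            o._replace(site_index=o.site_index - lo)
            for o in r.observations
            if lo <= o.site_index < hi and o.allele >= 0 and o.weight > 0
        )
        if obs:
            out.append(CondensedRead(r.read_name, obs))
    return out


def _chunk_bounds(n_sites: int, chunk_size: int) -> List[Tuple[int, int]]:
    if chunk_size < 1:
        raise ValueError("chunk_size must be positive")
    return [(s, min(s + chunk_size, n_sites)) for s in range(0, n_sites, chunk_size)]


def heuristic_chain(reads: Sequence, sites: Sequence, chunk_size: int, j: int) -> int:
    """Admissible completion-cost estimate for a partial diplotype at depth j.

    Sites ``>= j`` are partitioned into consecutive chunks of at most
    ``chunk_size`` columns (the partition is anchored at column 0 so it is
    identical for every depth); each chunk whose first column is ``>= j`` is
    solved exactly on the reads restricted to its columns, and the chunk
    optima are summed.  Chunks straddling ``j`` contribute nothing.
    """
    n = len(sites)
    if not 0 <= j <= n:
        raise ValueError("depth out of range")
    total = 0
    for lo, hi in _chunk_bounds(n, chunk_size):
        if lo < j:
            continue
        sub_reads = _restrict_reads(reads, lo, hi)
        if sub_reads:
            total += brute_force(sub_reads, sites[lo:hi]).cost
    return total


def solve_astar(
    reads: Sequence,
    sites: Sequence,
    chunk_size: int = DEFAULT_CHUNK_SIZE,
) -> Diplotype:
    """Find a minimum-cost diplotype for a block by A* search.

    Nodes are partial diplotypes over a prefix of the block's sites; children
    of a depth-``j`` node assign site ``j`` (two orientations of the called
    genotype; one at site 0, where symmetry is broken by placing the smaller
    allele on h1).  Nodes pop in ascending ``f = g + h`` with deterministic
    tie-breaking on (f, deeper-first, lexicographic partial h1).  Frontier
    states identical on the "active" sites (assigned sites still covered by
    a read that extends past the frontier) have identical completion costs,
    so duplicates are pruned keeping the cheapest.

    Every read is consumed — there is no down-sampling and no node budget.
    """
    n = len(sites)
    if n == 0:
        raise ValueError("cannot solve an empty site list")
    pairs = _genotype_pairs(sites)

    # Keep only reads that can influence the objective.
    active_reads = [r for r in reads if r.weighted_sites]
    n_reads = len(active_reads)

    # Per-column weighted observations: col[j] = [(read_id, allele, weight)].
    col: List[List[Tuple[int, int, int]]] = [[] for _ in range(n)]
    last_site = [-1] * n_reads
    for rid, r in enumerate(active_reads):
        for o in r.observations:
            if o.allele >= 0 and o.weight > 0:
                col[o.site_index].append((rid, o.allele, o.weight))
                last_site[rid] = max(last_site[rid], o.site_index)

    # Active-site sets for dominance pruning: site i is active at depth j>i
    # iff some read observes i and extends to a site >= j.
    max_reach = [0] * n  # furthest last_site over reads observing column i
    for j in range(n):
        for rid, _, _ in col[j]:
            max_reach[j] = max(max_reach[j], last_site[rid])
    active_at: List[Tuple[int, ...]] = [()] * (n + 1)
    for j in range(1, n + 1):
        active_at[j] = tuple(i for i in range(j) if max_reach[i] >= j)

    # Precompute the chained heuristic as suffix sums of chunk optima.
    bounds = _chunk_bounds(n, chunk_size)
    chunk_opt = []
    for lo, hi in bounds:
        sub = _restrict_reads(active_reads, lo, hi)
        chunk_opt.append(brute_force(sub, sites[lo:hi]).cost if sub else 0)
    # h_of[j] = sum of optima of chunks starting at or after column j.
    h_of = [
        sum(c for (lo, _), c in zip(bounds, chunk_opt) if lo >= j)
        for j in range(n + 1)
    ]

    # Node payload: (h1 list, per-read (c1, c2) dict for straddling reads,
    # folded cost of finished reads, running sum of straddling minima).
    tick = count()
    heap = []
    root = ([], {}, 0, 0)
    heapq.heappush(heap, (h_of[0], 0, (), next(tick), root))
    seen: Dict[Tuple[int, Tuple[int, ...]], int] = {}

    while heap:
        f, neg_depth, h1_key, _, payload = heapq.heappop(heap)
        j = -neg_depth
        h1, partial, g_fold, g_open = payload
        g = g_fold + g_open
        key = (j, tuple(h1[i] for i in active_at[j]))
        if seen.get(key, g) < g:
            continue
        if j == n:
            h2 = tuple(
                pairs[i][1] if h1[i] == pairs[i][0] else pairs[i][0] for i in range(n)
            )
            return canonicalize(Diplotype(tuple(h1), h2, g))

        a, b = pairs[j]
        orientations = ((a, b),) if j == 0 else ((a, b), (b, a))
        for x, _y in orientations:
            new_partial = dict(partial)
            new_fold = g_fold
            new_open = g_open
            for rid, allele, w in col[j]:
                c1, c2 = new_partial.get(rid, (0, 0))
                old_min = min(c1, c2)
                if allele != x:
                    c1 += w
                other = a if x == b else b
                if allele != other:
                    c2 += w
                new_min = min(c1, c2)
                new_open += new_min - old_min
                if last_site[rid] == j:
                    new_fold += new_min
                    new_open -= new_min
                    new_partial.pop(rid, None)
                else:
                    new_partial[rid] = (c1, c2)
            new_h1 = h1 + [x]
            ng = new_fold + new_open
            nkey = (j + 1, tuple(new_h1[i] for i in active_at[j + 1]))
            if seen.get(nkey, ng + 1) <= ng:
                continue
            seen[nkey] = ng
            nf = ng + h_of[j + 1]
            heapq.heappush(
                heap,
                (nf, -(j + 1), tuple(new_h1), next(tick),
                 (new_h1, new_partial, new_fold, new_open)),
            )
    raise RuntimeError("search exhausted without reaching a goal")  # pragma: no cover


def post_split(
    block: PhaseBlock,
    diplotype: Diplotype,
    reads: Sequence,
    sites: Sequence,
) -> List[PhaseBlock]:
    """Split a solved block at junctions with no read support.

    Putative blocks are a lower bound on the final block count: after allele
    assignment some connecting reads may have become ambiguous, leaving a
    junction between consecutive sites that no collapsed read with concrete
    alleles on both sides supports.  Each such junction starts a new phase
    set.  Within-block phase assignments are untouched; only boundaries (and
    therefore PS values and per-block costs) change.

    ``reads`` and ``sites`` are block-local (observation site_index 0..n-1).
    """
    n = block.n_sites
    if diplotype is None or n <= 1:
        return [block]

    supported = [False] * (n - 1)
    for r in reads:
        concrete = [(o.site_index, o.allele) for o in r.observations if o.allele >= 0]
        if len(concrete) < 2:
            continue
        for hap in (diplotype.h1, diplotype.h2):
            left = [i for i, a in concrete if hap[i] == a]
            if not left:
                continue
            lo, hi = min(left), max(left)
            for j in range(lo, hi):
                supported[j] = True

    if all(supported):
        return [block]

    pieces = []
    start = 0
    for j in range(n - 1):
        if not supported[j]:
            pieces.append((start, j + 1))
            start = j + 1
    pieces.append((start, n))

    out = []
    for lo, hi in pieces:
        sub_sites = block.site_indices[lo:hi]
        sub_reads = _restrict_reads(reads, lo, hi)
        d = canonicalize(
            Diplotype(
                diplotype.h1[lo:hi],
                diplotype.h2[lo:hi],
                diplotype_cost(
                    sub_reads,
                    Diplotype(diplotype.h1[lo:hi], diplotype.h2[lo:hi], 0),
                ),
            )
        )
        if hi - lo == 1:
            d = None  # single-site pieces carry no phase information
        out.append(
            PhaseBlock(
                block_id=block.block_id,
                chrom=block.chrom,
                site_indices=sub_sites,
                phase_set=sites[lo].pos + 1,
                diplotype=d,
                fallback=block.fallback,
            )
        )
    return out
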