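"""Allele assignment: converting read mappings into weighted allele calls.

Two re-alignment strategies are provided.

*Local* assignment scores, for each variant site a mapping fully covers, the
query subsequence projected onto a small window around the site against each
allele's windowed sequence by edit distance; the closest allele wins, ties
are ambiguous, and the weight is the minimum base quality inside the window
(capped).  It is fast and accurate for SNVs and isolated short indels but
unreliable around structural and tandem-repeat alleles.

*Global* assignment re-aligns the whole mapped segment against an alt-aware
reference graph: a DAG over the block's reference segment with one branch
per allele at each site (overlapping sites are merged into a single branch
set enumerating their joint local haplotypes).  The optimal edit-distance
path through the graph picks the alleles; a site's weight is the margin by
which forcing the alignment through a different allele worsens the optimal
cost.  The alignment is an exact dynamic program over the DAG — any
acceleration (e.g. wavefront-style pruning) would have to preserve exactly
these optima.

*Dual mode* runs global assignment unless the block's projected alignment
work (in DP cells, a machine-independent proxy for run time) exceeds a
budget, in which case the whole block falls back to local assignment and is
flagged; the decision is always per-block, never per-read.

Finally, same-name mappings (primary + supplementary pieces of one read)
are collapsed into a single condensed read per name; conflicting concrete
alleles at a shared site become ambiguous, agreeing duplicates keep the
larger weight.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product
from typing import Dict, List, Optional, Sequence, Tuple

import edlib
import numpy as np

from .core import (
    AMBIGUOUS,
    UNKNOWN,
    WEIGHT_CAP,
    AlleleObservation,
    CondensedRead,
    VariantSite,
    make_observation,
)
from .io_formats import AlignmentRecord

DEFAULT_WINDOW_PAD = 25
#: Graph reference padding beyond the outermost site spans.
GRAPH_PAD = 50
#: Per-base optimal-cost ceiling above which a read is considered mismapped.
MAX_EDIT_RATE = 0.3
#: Default per-block DP-cell budget for dual mode.
DEFAULT_GLOBAL_BUDGET = 10 ** 9


# ---------------------------------------------------------------------------
# CIGAR projection
# ---------------------------------------------------------------------------

_REF_OPS = {0, 2, 3, 7, 8}   # consume reference: M, D, N, =, X
_QRY_OPS = {0, 1, 4, 7, 8}   # consume query: M, I, S, =, X


def query_window(mapping: AlignmentRecord, ws: int, we: int):
    """Project the reference window [ws, we) onto the query.

    Returns ``(query_start, query_end)`` offsets into the mapping's query
    sequence, or ``None`` when the mapping does not fully cover the window
    or has no CIGAR.  Insertions strictly inside the window are included;
    insertions at the window boundary fall outside it.
    """
    if mapping.cigar is None or not mapping.covers((ws, we)):
        return None
    qpos, rpos = 0, mapping.start
    qs = qe = None
    for op, ln in mapping.cigar:
        r_adv = ln if op in _REF_OPS else 0
        q_adv = ln if op in _QRY_OPS else 0
        if qs is None and r_adv and rpos + r_adv > ws:
            qs = qpos + (max(0, ws - rpos) if op in (0, 7, 8) else 0)
        if r_adv and rpos + r_adv >= we:
            qe = qpos + (min(ln, we - rpos) if op in (0, 7, 8) else 0)
            return (qs if qs is not None else qpos, qe)
        qpos += q_adv
        rpos += r_adv
    return None  # pragma: no cover - covers() guards this


# ---------------------------------------------------------------------------
# Local re-alignment
# ---------------------------------------------------------------------------

def _edit_distance(a: str, b: str) -> int:
    if not a or not b:
        return max(len(a), len(b))
    return edlib.align(a, b, task="distance")["editDistance"]


def assign_local(
    mapping: AlignmentRecord,
    sites: Sequence,
    reference: str,
    window_pad: int = DEFAULT_WINDOW_PAD,
    cap: int = WEIGHT_CAP,
) -> List[AlleleObservation]:
    """Windowed edit-distance allele assignment for each covered site.

    Returns one observation per site (block-local ``site_index`` equal to
    the position in ``sites``): UNKNOWN for sites the mapping does not fully
    cover or when the mapping carries no sequence/CIGAR, AMBIGUOUS on an
    edit-distance tie between the best alleles.
    """
    out = []
    degraded = mapping.query_sequence is None or mapping.cigar is None
    for li, v in enumerate(sites):
        if degraded or not mapping.covers(v.span):
            out.append(make_observation(li, UNKNOWN, 0))
            continue
        ws = max(mapping.start, v.pos - window_pad)
        we = min(mapping.end, v.end + window_pad)
        win = query_window(mapping, ws, we)
        if win is None:
            out.append(make_observation(li, UNKNOWN, 0))
            continue
        qs, qe = win
        qsub = mapping.query_sequence[qs:qe]
        left = reference[ws:v.pos]
        right = reference[v.end:we]
        dists = [_edit_distance(qsub, left + v.allele_seq(a) + right)
                 for a in range(v.n_alleles)]
        best = min(dists)
        winners = [a for a, d in enumerate(dists) if d == best]
        if len(winners) > 1:
            out.append(make_observation(li, AMBIGUOUS, 0))
            continue
        if mapping.base_qualities is not None and qe > qs:
            weight = min(mapping.base_qualities[qs:qe])
        else:
            weight = cap
        out.append(make_observation(li, winners[0], min(weight, cap)))
    return out


# ---------------------------------------------------------------------------
# Alt-aware reference graph
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GraphCluster:
    """A merged set of (possibly overlapping) sites with joint branches.

    Each branch is ``(alleles, sequence)``: one allele index per site in the
    cluster and the local haplotype those choices spell over
    ``[start, end)``.  Combinations whose edits collide (a non-reference
    allele starting inside a region consumed by an earlier deletion) are
    excluded.
    """

    start: int
    end: int
    site_indices: tuple  # positions within the graph's site list
    branches: tuple      # ((allele per site, spelled str), ...)


@dataclass(frozen=True)
class VariantGraph:
    """Alt-aware DAG: reference segments interleaved with branch clusters.

    Every source-to-sink path spells the local haplotype for exactly one
    allele choice per site; the all-reference path spells the reference
    segment itself.
    """

    chrom: str
    start: int
    end: int
    reference: str  # full chromosome sequence (not just the segment)
    sites: tuple
    clusters: tuple

    def reference_segment(self) -> str:
        return self.reference[self.start:self.end]

    def enumerate_paths(self):
        """Yield (alleles per site, spelled sequence) over all full paths.

        Exponential in the number of sites — a test oracle, not a fast path.
        """
        per_cluster = [c.branches for c in self.clusters]
        for combo in product(*per_cluster):
            alleles = [0] * len(self.sites)
            parts = []
            cur = self.start
            for cluster, (als, seq) in zip(self.clusters, combo):
                parts.append(self.reference[cur:cluster.start])
                parts.append(seq)
                for si, a in zip(cluster.site_indices, als):
                    alleles[si] = a
                cur = cluster.end
            parts.append(self.reference[cur:self.end])
            yield tuple(alleles), "".join(parts)


def _spell(reference: str, sites: Sequence, alleles: Sequence,
           start: int, end: int) -> Optional[str]:
    """Apply allele choices over [start, end); None if the combo collides."""
    parts = []
    cur = start
    for v, a in zip(sites, alleles):
        if a == 0:
            continue
        if v.pos < cur:
            return None
        parts.append(reference[cur:v.pos])
        parts.append(v.allele_seq(a))
        cur = v.end
    if cur > end:
        return None
    parts.append(reference[cur:end])
    return "".join(parts)


def build_graph(reference: str, sites: Sequence, pad: int = GRAPH_PAD) -> VariantGraph:
    """Build the alt-aware graph over a block's reference segment.

    Sites whose reference spans overlap are merged into one cluster whose
    branch set enumerates every consistent joint allele combination.
    Raises ``ValueError`` if a site's reference allele disagrees with the
    reference sequence.
    """
    for v in sites:
        if reference[v.pos:v.end] != v.ref_allele:
            raise ValueError(
                f"ref allele mismatch at {v.chrom}:{v.pos}: "
                f"{v.ref_allele!r} vs {reference[v.pos:v.end]!r}")
    if sites:
        gstart = max(0, min(v.pos for v in sites) - pad)
        gend = min(len(reference), max(v.end for v in sites) + pad)
    else:
        gstart, gend = 0, min(len(reference), 2 * pad)

    clusters = []
    i = 0
    order = sorted(range(len(sites)), key=lambda k: (sites[k].pos, sites[k].end))
    while i < len(order):
        members = [order[i]]
        cend = sites[order[i]].end
        j = i + 1
        while j < len(order) and sites[order[j]].pos < cend:
            members.append(order[j])
            cend = max(cend, sites[order[j]].end)
            j += 1
        cstart = sites[members[0]].pos
        msites = [sites[k] for k in members]
        branches = []
        for combo in product(*(range(s.n_alleles) for s in msites)):
            seq = _spell(reference, msites, combo, cstart, cend)
            if seq is not None:
                branches.append((combo, seq))
        clusters.append(GraphCluster(cstart, cend, tuple(members), tuple(branches)))
        i = j
    return VariantGraph(sites[0].chrom if sites else "", gstart, gend,
                        reference, tuple(sites), tuple(clusters))


# ---------------------------------------------------------------------------
# Exact edit-distance alignment over the graph
# ---------------------------------------------------------------------------

def _propagate(v: np.ndarray, seq: str, q: np.ndarray) -> np.ndarray:
    """Advance an edit-distance DP column vector through sequence ``seq``.

    ``v[i]`` is the cost of aligning the query prefix of length ``i`` to the
    graph prefix consumed so far; returns the vector after also consuming
    ``seq``.  Vectorised over the query with a prefix-min scan for the
    insertion chain.
    """
    m = len(q)
    ar = np.arange(m + 1, dtype=np.int32)
    for ch in seq.encode():
        cand = np.empty(m + 1, dtype=np.int32)
        cand[0] = v[0] + 1
        cand[1:] = np.minimum(v[1:] + 1, v[:-1] + (q != ch))
        v = np.minimum.accumulate(cand - ar) + ar
    return v


def _graph_pieces(graph: VariantGraph, s: int, e: int):
    """Linearise the graph clipped to [s, e): ('ref', seq) / ('cluster', c).

    Only clusters entirely inside the clip participate; a partially clipped
    cluster's region is spelled as plain reference (its sites are reported
    UNKNOWN by the caller).
    """
    pieces = []
    cur = s
    inside = []
    for c in graph.clusters:
        if c.start >= cur and c.end <= e:
            pieces.append(("ref", graph.reference[cur:c.start]))
            pieces.append(("cluster", c))
            inside.append(c)
            cur = c.end
    pieces.append(("ref", graph.reference[cur:e]))
    return pieces, inside


def graph_alignment_cost(query: str, graph: VariantGraph) -> int:
    """Minimum edit cost of aligning ``query`` end-to-end against the graph.

    Equals the minimum over every allele path of the global edit distance
    between ``query`` and the path's spelled sequence (checked against path
    enumeration in the test suite).
    """
    q = np.frombuffer(query.encode(), dtype=np.uint8)
    m = len(q)
    pieces, _ = _graph_pieces(graph, graph.start, graph.end)
    v = np.arange(m + 1, dtype=np.int32)
    for kind, item in pieces:
        if kind == "ref":
            v = _propagate(v, item, q)
        else:
            v = np.min([_propagate(v, seq, q) for _, seq in item.branches], axis=0)
    return int(v[m])


def assign_global(
    mapping: AlignmentRecord,
    graph: VariantGraph,
    cap: int = WEIGHT_CAP,
    max_edit_rate: float = MAX_EDIT_RATE,
) -> List[AlleleObservation]:
    """Graph re-alignment allele assignment for one mapping.

    The mapping's query segment over its intersection with the graph span is
    aligned against every allele path simultaneously (forward/backward DP
    with per-branch rescoring), giving for each site the optimal cost
    attainable with each allele.  The chosen allele minimises that cost; the
    weight is the capped margin to the best alternative, and a zero margin
    is AMBIGUOUS.  Sites outside the mapping (or in partially covered
    clusters) are UNKNOWN; a mapping whose optimal cost exceeds
    ``max_edit_rate`` per query base is reported all-UNKNOWN as likely
    mismapped.
    """
    n = len(graph.sites)
    unknown = [make_observation(i, UNKNOWN, 0) for i in range(n)]
    if mapping.query_sequence is None or mapping.cigar is None:
        return unknown
    s = max(graph.start, mapping.start)
    e = min(graph.end, mapping.end)
    if e <= s:
        return unknown
    win = query_window(mapping, s, e)
    if win is None:
        return unknown
    query = mapping.query_sequence[win[0]:win[1]]
    m = len(query)
    if m == 0:
        return unknown
    q = np.frombuffer(query.encode(), dtype=np.uint8)

    pieces, inside = _graph_pieces(graph, s, e)

    # Forward pass, recording the DP vector entering each cluster.
    fwd_at: Dict[int, np.ndarray] = {}
    v = np.arange(m + 1, dtype=np.int32)
    for kind, item in pieces:
        if kind == "ref":
            v = _propagate(v, item, q)
        else:
            fwd_at[id(item)] = v
            v = np.min(
                [_propagate(v, seq, q) for _, seq in item.branches], axis=0)
    best = int(v[m])

    if best > max_edit_rate * m:
        return unknown

    # Backward pass on reversed query/graph, recording vectors at cluster ends.
    qr = q[::-1]
    bwd_at: Dict[int, np.ndarray] = {}
    v = np.arange(m + 1, dtype=np.int32)
    for kind, item in reversed(pieces):
        if kind == "ref":
            v = _propagate(v, item[::-1], qr)
        else:
            bwd_at[id(item)] = v
            v = np.min(
                [_propagate(v, seq[::-1], qr) for _, seq in item.branches], axis=0)

    obs: List[Optional[AlleleObservation]] = list(unknown)
    for c in inside:
        f0 = fwd_at[id(c)]
        b0 = bwd_at[id(c)][::-1]  # b0[i]: cost of query[i:] vs graph suffix
        totals = []
        for alleles, seq in c.branches:
            fb = _propagate(f0, seq, q)
            totals.append((alleles, int(np.min(fb + b0))))
        for k, si in enumerate(c.site_indices):
            site = graph.sites[si]
            per_allele = {}
            for alleles, t in totals:
                a = alleles[k]
                per_allele[a] = min(per_allele.get(a, t), t)
            ordered = sorted(per_allele.items(), key=lambda kv: (kv[1], kv[0]))
            if len(ordered) == 1:
                obs[si] = make_observation(si, ordered[0][0], cap)
                continue
            (a_best, c_best), (_, c_second) = ordered[0], ordered[1]
            margin = c_second - c_best
            if margin == 0:
                obs[si] = make_observation(si, AMBIGUOUS, 0)
            else:
                obs[si] = make_observation(si, a_best, min(margin, cap))
    return obs


# ---------------------------------------------------------------------------
# Block-level assignment with dual-mode fallback
# ---------------------------------------------------------------------------

def estimate_cells(mappings: Sequence, graph: VariantGraph) -> int:
    """Projected DP work for global alignment of a block, in matrix cells.

    Approximates each mapping's query-segment length by its reference
    overlap with the graph span; deterministic and implementation-free, so
    the dual-mode fallback decision does not depend on the machine.
    """
    total = 0
    for mp in mappings:
        ov = min(graph.end, mp.end) - max(graph.start, mp.start)
        if ov > 0:
            total += ov * ov
    return total


def assign_block(
    sites: Sequence,
    mappings: Sequence,
    reference: str,
    mode: str = "dual",
    budget: int = DEFAULT_GLOBAL_BUDGET,
    window_pad: int = DEFAULT_WINDOW_PAD,
    cap: int = WEIGHT_CAP,
) -> Tuple[List[List[AlleleObservation]], bool]:
    """Assign alleles for every mapping of a block.

    Returns ``(observation lists, fallback)``.  ``mode`` is ``local``,
    ``global`` or ``dual``; dual uses global alignment unless the block's
    projected DP work exceeds ``budget``, in which case the whole block is
    assigned locally and flagged.  The fallback decision is per-block.
    """
    if mode not in ("local", "global", "dual"):
        raise ValueError(f"unknown mode {mode!r}")
    fallback = False
    use_global = mode == "global"
    graph = None
    if mode in ("global", "dual"):
        graph = build_graph(reference, sites)
        if mode == "dual":
            if estimate_cells(mappings, graph) <= budget:
                use_global = True
            else:
                fallback = True
    if use_global:
        out = [assign_global(mp, graph, cap=cap) for mp in mappings]
    else:
        out = [assign_local(mp, sites, reference, window_pad=window_pad, cap=cap)
               for mp in mappings]
    return out, fallback


def collapse_mappings(
    per_mapping: Sequence,
) -> List[CondensedRead]:
    """Collapse same-name mappings into one condensed read per name.

    ``per_mapping`` is a sequence of ``(read_name, observations)`` pairs.
    Per site: conflicting concrete alleles (or any ambiguous call) give
    AMBIGUOUS with weight 0; agreeing concrete duplicates keep the maximum
    weight; UNKNOWN entries are dropped.  The result is order-independent
    and sorted by read name, then site index.
    """
    merged: Dict[str, Dict[int, Tuple[int, int]]] = {}
    for name, observations in per_mapping:
        slot = merged.setdefault(name, {})
        for o in observations:
            if o.allele == UNKNOWN:
                continue
            prev = slot.get(o.site_index)
            if prev is None:
                slot[o.site_index] = (o.allele, o.weight)
            else:
                pa, pw = prev
                if pa == AMBIGUOUS or o.allele == AMBIGUOUS or pa != o.allele:
                    slot[o.site_index] = (AMBIGUOUS, 0)
                else:
                    slot[o.site_index] = (pa, max(pw, o.weight))
    out = []
    for name in sorted(merged):
        slot = merged[name]
        if not slot:
            continue
        obs = tuple(make_observation(i, a, w)
                    for i, (a, w) in sorted(slot.items()))
        out.append(CondensedRead(name, obs))
    return out
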