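"""Shared domain types and elementary cost operations.

Everything downstream of variant/alignment parsing speaks in terms of these
types: a :class:`VariantSite` is one called variant, a :class:`CondensedRead`
is one row of the weighted minimum-error-correction (wMEC) matrix for a phase
block, and a :class:`Diplotype` is the pair of haplotypes the solver returns
for a block.

Coordinates are 0-based, half-open throughout the library; conversion to and
from VCF's 1-based convention happens only at the file boundary.

Observation weights are integers on a phred-like scale, capped at
:data:`WEIGHT_CAP`.  Integer arithmetic keeps solver costs exact so that
independent oracles (brute-force enumeration) can be compared bit-stably.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, NamedTuple, Optional, Sequence

#: Maximum weight any single allele observation may carry.
WEIGHT_CAP = 60

#: Sentinel allele: conflicting evidence for this site (costs nothing to flip).
AMBIGUOUS = -1
#: Sentinel allele: no evidence for this site.
UNKNOWN = -2


class VariantClass(str, Enum):
    """Provenance class of a variant call (which caller/file it came from)."""

    SMALL = "small"
    SV = "sv"
    TANDEM_REPEAT = "tandem_repeat"


@dataclass(frozen=True)
class VariantSite:
    """One called variant for the sample, possibly multi-allelic.

    Parameters
    ----------
    chrom : str
        Chromosome name.
    pos : int
        0-based reference start of ``ref_allele``.
    ref_allele : str
        Reference bases replaced by the variant.
    alt_alleles : tuple of str
        Ordered alternate alleles (1..k).
    genotype : (int, int)
        Pair of allele indices; 0 is the reference allele.  The site is
        heterozygous iff the two indices differ.
    source : VariantClass
        Which variant class/file the call came from.
    site_index : int
        Dense index of this site within its chromosome's ordering of
        heterozygous sites; ``-1`` for homozygous sites, which are carried
        only as re-alignment context.
    """

    chrom: str
    pos: int
    ref_allele: str
    alt_alleles: tuple
    genotype: tuple
    source: VariantClass = VariantClass.SMALL
    site_index: int = -1

    def __post_init__(self):
        if not self.alt_alleles:
            raise ValueError("alt_alleles must be non-empty")
        k = len(self.alt_alleles)
        if any(g < 0 or g > k for g in self.genotype):
            raise ValueError(f"genotype {self.genotype} out of range for {k} alts")

    @property
    def is_het(self) -> bool:
        return self.genotype[0] != self.genotype[1]

    @property
    def end(self) -> int:
        """Exclusive end of the reference span (insertion anchors are 1 bp)."""
        return self.pos + len(self.ref_allele)

    @property
    def span(self) -> tuple:
        return (self.pos, self.end)

    @property
    def n_alleles(self) -> int:
        """Total number of alleles including the reference."""
        return 1 + len(self.alt_alleles)

    def allele_seq(self, allele: int) -> str:
        return self.ref_allele if allele == 0 else self.alt_alleles[allele - 1]


class AlleleObservation(NamedTuple):
    """One read mapping's allele call at one site — a wMEC matrix entry.

    ``weight`` is the cost of altering or ignoring this allele when fitting
    the read onto a haplotype; sentinel alleles always carry weight 0.
    """

    site_index: int
    allele: int
    weight: int


def make_observation(site_index: int, allele: int, weight: int) -> AlleleObservation:
    """Build an observation, enforcing sentinel/weight invariants."""
    if allele in (AMBIGUOUS, UNKNOWN):
        weight = 0
    if weight < 0:
        raise ValueError("weight must be non-negative")
    return AlleleObservation(site_index, allele, min(weight, WEIGHT_CAP))


@dataclass(frozen=True)
class CondensedRead:
    """Per-read chain of allele observations over a block's sites.

    One matrix row of the block's wMEC instance.  Observations are sorted by
    ``site_index`` with at most one entry per site: mappings sharing a read
    name have already been collapsed.
    """

    read_name: str
    observations: tuple

    def __post_init__(self):
        idx = [o.site_index for o in self.observations]
        if any(b <= a for a, b in zip(idx, idx[1:])):
            raise ValueError(f"observations of {self.read_name} not strictly sorted")

    @property
    def weighted_sites(self) -> list:
        """Site indices at which this read carries a concrete, weighted call."""
        return [o.site_index for o in self.observations if o.allele >= 0 and o.weight > 0]


@dataclass(frozen=True)
class Diplotype:
    """The two solved haplotypes over a block's sites, plus total wMEC cost."""

    h1: tuple
    h2: tuple
    cost: int

    def __post_init__(self):
        if len(self.h1) != len(self.h2):
            raise ValueError("haplotypes must have equal length")
        if self.cost < 0:
            raise ValueError("cost must be non-negative")


@dataclass
class PhaseBlock:
    """A maximal run of connected heterozygous sites and its solving result.

    ``site_indices`` are positions within the chromosome's dense heterozygous
    ordering and are contiguous.  ``phase_set`` follows the read-backed
    phasing convention: the 1-based position of the block's first site.
    ``diplotype`` is ``None`` while the block is unsolved (and stays ``None``
    for single-site blocks, which carry no phase information).
    """

    block_id: int
    chrom: str
    site_indices: list
    phase_set: int
    diplotype: Optional[Diplotype] = None
    fallback: bool = False

    @property
    def n_sites(self) -> int:
        return len(self.site_indices)

    @property
    def solved(self) -> bool:
        return self.diplotype is not None


def row_cost(read: CondensedRead, haplotype: Sequence) -> int:
    """Cost of editing ``read`` to exactly match ``haplotype``.

    Sums the weights of concrete observations whose allele differs from the
    haplotype's allele at that site; AMBIGUOUS/UNKNOWN observations are free.
    ``haplotype`` is indexed directly by each observation's ``site_index``.
    """
    n = len(haplotype)
    total = 0
    for obs in read.observations:
        if obs.site_index < 0 or obs.site_index >= n:
            raise IndexError(
                f"observation site {obs.site_index} outside haplotype of length {n}"
            )
        if obs.allele >= 0 and obs.allele != haplotype[obs.site_index]:
            total += obs.weight
    return total


def diplotype_cost(reads: Iterable, d: Diplotype) -> int:
    """wMEC objective: each read pays the cheaper of its two row costs."""
    return sum(min(row_cost(r, d.h1), row_cost(r, d.h2)) for r in reads)


def canonicalize(d: Diplotype) -> Diplotype:
    """Return the orientation with ``h1[0] <= h2[0]``; cost is unchanged."""
    if d.h1 and d.h1[0] > d.h2[0]:
        return Diplotype(d.h2, d.h1, d.cost)
    return d
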