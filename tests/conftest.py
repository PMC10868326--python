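"""Shared fixtures and instance generators for the test suite."""

from __future__ import annotations

import random

import pytest

from phasekit.core import (
    CondensedRead,
    VariantClass,
    VariantSite,
    make_observation,
)


def random_wmec_instance(rng: random.Random, max_sites: int = 10,
                         max_reads: int = 15, p_multiallelic: float = 0.15,
                         corruption: float = 0.15):
    """A random small wMEC instance with a known generating diplotype.

    Reads are drawn from one of two random haplotypes over 1..max_sites
    heterozygous sites (a fraction multi-allelic with genotype 1/2), with
    random integer weights in 1..60 and each observed allele corrupted with
    probability ``corruption``.  Returns (reads, sites, truth_h1, truth_h2).
    """
    n = rng.randint(1, max_sites)
    sites = []
    for i in range(n):
        if rng.random() < p_multiallelic:
            gt, alts = (1, 2), ("A", "C")
        else:
            gt, alts = (0, 1), ("A",)
        sites.append(VariantSite("chr1", 10 * i, "G", alts, gt,
                                 VariantClass.SMALL, i))
    h1, h2 = [], []
    for s in sites:
        a, b = s.genotype
        if rng.random() < 0.5:
            a, b = b, a
        h1.append(a)
        h2.append(b)
    reads = []
    n_reads = rng.randint(1, max_reads)
    for r in range(n_reads):
        if n == 1:
            lo, hi = 0, 1
        else:
            lo = rng.randrange(n)
            hi = rng.randint(lo + 1, n)
        hap = h1 if rng.random() < 0.5 else h2
        obs = []
        for i in range(lo, hi):
            allele = hap[i]
            if rng.random() < corruption:
                allele = rng.choice(
                    [a for a in range(sites[i].n_alleles) if a != allele])
            obs.append(make_observation(i, allele, rng.randint(1, 60)))
        if obs:
            reads.append(CondensedRead(f"r{r}", tuple(obs)))
    return reads, sites, tuple(h1), tuple(h2)


def biallelic_sites(n: int, spacing: int = 10):
    """n heterozygous 0/1 SNV sites with dense indices."""
    return [VariantSite("chr1", spacing * i, "G", ("A",), (0, 1),
                        VariantClass.SMALL, i) for i in range(n)]


def read_from(alleles_by_site: dict, weight: int = 10, name: str = "r"):
    obs = tuple(make_observation(i, a, weight)
                for i, a in sorted(alleles_by_site.items()))
    return CondensedRead(name, obs)


@pytest.fixture(scope="session")
def small_truth():
    """A 30 kb truth set with all three variant classes, fixed seed."""
    from phasekit import synth

    return synth.simulate_truth(30_000, snv_rate=0.0012, indel_rate=0.0003,
                                sv_count=1, tr_count=2, seed=101)


@pytest.fixture(scope="session")
def small_dataset(small_truth, tmp_path_factory):
    """The small truth rendered to files plus simulated error-free reads."""
    from phasekit import synth
    from phasekit.core import VariantClass

    d = tmp_path_factory.mktemp("small_ds")
    truth = small_truth
    sims = synth.simulate_reads(truth, coverage=25, read_length=3000, seed=102)
    prefix = str(d / "syn")
    vcfs = synth.write_variant_vcfs(truth, prefix)
    return {
        "truth": truth,
        "sims": sims,
        "prefix": prefix,
        "reference": synth.write_reference_fasta(truth, prefix + ".ref.fa"),
        "sam": synth.write_reads_sam(truth, sims, prefix + ".reads.sam"),
        "vcf": vcfs[VariantClass.SMALL],
        "sv_vcf": vcfs.get(VariantClass.SV),
        "tr_vcf": vcfs.get(VariantClass.TANDEM_REPEAT),
        "truth_vcf": synth.write_truth_vcf(truth, prefix + ".truth.vcf"),
        "genes_bed": synth.write_genes_bed(
            synth.make_gene_intervals(truth, n_genes=6, gene_length=4000),
            prefix + ".genes.bed"),
    }
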