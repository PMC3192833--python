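"""Shared-haplotype core extraction inside significant sweep regions.

Within each significant S_i region, a breed's *homozygous cores* are the
maximal runs of consecutive SNPs at which the breed carries a single
allele and no heterozygous call.  Cores from different breeds are grouped
by physical overlap (single linkage), and each multi-breed cluster is
narrowed to the longest interval over which every member breed is fixed
for the *identical* allele at every SNP -- the identity-by-state (IBS)
core that best localizes a sweep shared through common ancestry.

Complete homozygosity is evaluated on genotypes, so unphased input
suffices: fixation makes phase irrelevant.  Missing genotypes inside an
otherwise fixed run are treated as compatible (array missingness would
otherwise shatter cores arbitrarily); the per-core missing fraction is
reported.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .genotype_model import MISSING, GenotypePanel
from .sweep_scan import CandidateRegion


@dataclass
class HomozygousCore:
    breed: str
    chrom: str
    start: int
    end: int           # half-open; last member SNP position + 1
    snp_indices: np.ndarray
    missing_frac: float = 0.0

    @property
    def n_snps(self) -> int:
        return len(self.snp_indices)

    def overlaps(self, other: "HomozygousCore") -> bool:
        return self.chrom == other.chrom and self.start < other.end and other.start < self.end


@dataclass
class SharedCore:
    cluster_id: int
    breeds: list[str]
    chrom: str
    ibs_start: int
    ibs_end: int
    snp_indices: np.ndarray

    @property
    def length_bp(self) -> int:
        return self.ibs_end - self.ibs_start

    @property
    def n_snps(self) -> int:
        return len(self.snp_indices)


def _fixed_state(geno_block: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-locus fixation over a breed's genotype block.

    Returns (fixed, allele, missing_frac): ``fixed`` where no heterozygote
    is called and at most one homozygous class appears; ``allele`` is 0/1
    for the fixed B-dosage (or -1 where nothing is called, a wildcard).
    """
    called = geno_block != MISSING
    any_het = ((geno_block == 1) & called).any(axis=0)
    has0 = ((geno_block == 0) & called).any(axis=0)
    has2 = ((geno_block == 2) & called).any(axis=0)
    fixed = ~any_het & ~(has0 & has2)
    allele = np.where(has2, 1, np.where(has0, 0, -1))
    missing_frac = 1.0 - called.mean(axis=0)
    return fixed, allele, missing_frac


def homozygous_cores(
    panel: GenotypePanel, regions: list[CandidateRegion]
) -> list[HomozygousCore]:
    """Maximal fully-homozygous SNP runs per breed inside each region."""
    cores: list[HomozygousCore] = []
    pos = panel.loci["pos"].to_numpy()
    chrom = panel.loci["chrom"].to_numpy()
    for region in regions:
        in_region = np.flatnonzero(
            (chrom == region.chrom) & (pos >= region.start) & (pos < region.end)
        )
        if len(in_region) == 0:
            continue
        rows = panel.breed_mask(region.breed)
        block = panel.genotypes[np.ix_(rows, in_region)]
        fixed, _, miss = _fixed_state(block)
        for lo, hi in _runs(fixed):
            idx = in_region[lo:hi]
            cores.append(
                HomozygousCore(
                    breed=region.breed,
                    chrom=region.chrom,
                    start=int(pos[idx[0]]),
                    end=int(pos[idx[-1]]) + 1,
                    snp_indices=idx,
                    missing_frac=float(miss[lo:hi].mean()),
                )
            )
    return cores


def _runs(mask: np.ndarray):
    """Yield (lo, hi) bounds of maximal True runs."""
    mask = np.asarray(mask, dtype=bool)
    padded = np.concatenate(([False], mask, [False])).astype(np.int8)
    d = np.diff(padded)
    starts = np.flatnonzero(d == 1)
    ends = np.flatnonzero(d == -1)
    yield from zip(starts, ends)


def cluster_cores(cores: list[HomozygousCore]) -> list[list[HomozygousCore]]:
    """Single-linkage clusters of cores overlapping by >=1 bp (per chromosome)."""
    clusters: list[list[HomozygousCore]] = []
    by_chrom: dict[str, list[HomozygousCore]] = {}
    for c in cores:
        by_chrom.setdefault(c.chrom, []).append(c)
    for chrom in by_chrom:
        group = sorted(by_chrom[chrom], key=lambda c: (c.start, c.end))
        current = [group[0]]
        reach = group[0].end
        for c in group[1:]:
            if c.start < reach:
                current.append(c)
                reach = max(reach, c.end)
            else:
                clusters.append(current)
                current, reach = [c], c.end
        clusters.append(current)
    return clusters


def maximal_ibs(
    cluster: list[HomozygousCore], panel: GenotypePanel, cluster_id: int = 0
) -> SharedCore | None:
    """Longest interval where all cluster breeds are fixed for one haplotype.

    Within the intersection of the cluster's cores, finds the longest
    contiguous SNP run at which every breed is fixed and the fixed alleles
    agree; breeds with no called genotype at a SNP are wildcards there.
    Returns ``None`` when the cluster spans < 2 breeds or no SNP qualifies.
    Among equal-bp runs the leftmost is returned.
    """
    breeds = sorted({c.breed for c in cluster})
    if len(breeds) < 2:
        return None
    chrom = cluster[0].chrom
    lo = max(c.start for c in cluster)
    hi = min(c.end for c in cluster)
    if lo >= hi:
        return None
    pos = panel.loci["pos"].to_numpy()
    idx = np.flatnonzero(
        (panel.loci["chrom"].to_numpy() == chrom) & (pos >= lo) & (pos < hi)
    )
    if len(idx) == 0:
        return None

    ok = np.ones(len(idx), dtype=bool)
    consensus = np.full(len(idx), -1, dtype=np.int8)
    for breed in breeds:
        block = panel.genotypes[np.ix_(panel.breed_mask(breed), idx)]
        fixed, allele, _ = _fixed_state(block)
        ok &= fixed
        clash = (consensus >= 0) & (allele >= 0) & (consensus != allele)
        ok &= ~clash
        consensus = np.where((consensus < 0) & (allele >= 0), allele, consensus)

    best = None
    best_span = -1
    for a, b in _runs(ok):
        span = int(pos[idx[b - 1]]) + 1 - int(pos[idx[a]])
        if span > best_span:
            best_span = span
            best = (a, b)
    if best is None:
        return None
    a, b = best
    return SharedCore(
        cluster_id=cluster_id,
        breeds=breeds,
        chrom=chrom,
        ibs_start=int(pos[idx[a]]),
        ibs_end=int(pos[idx[b - 1]]) + 1,
        snp_indices=idx[a:b],
    )


def shared_cores(
    panel: GenotypePanel,
    regions: list[CandidateRegion],
    min_breeds: int = 2,
) -> list[SharedCore]:
    """Full pipeline: cores -> overlap clusters -> maximal IBS intervals."""
    cores = homozygous_cores(panel, regions)
    out: list[SharedCore] = []
    cid = 0
    for cluster in cluster_cores(cores):
        if len({c.breed for c in cluster}) < min_breeds:
            continue
        shared = maximal_ibs(cluster, panel, cluster_id=cid)
        if shared is not None:
            out.append(shared)
            cid += 1
    return out
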