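"""Across-breed GWAS with genome-wide significance from breed-label permutation.

Every dog carries its breed's phenotype value, so the sample-level test is
confounded by breed structure; significance therefore comes from a max-T
permutation that shuffles the phenotype *values among breeds* (never
samples among breeds), re-assigning an identical value to every sample of
a breed.  The genome-wide maximum statistic of each permutation forms the
reference distribution, which corrects for the extreme population
substructure of breed panels.

The single-SNP test is an ordinary least-squares trend test (phenotype on
B-allele dosage, statistic = squared t).  Dichotomous traits run through
the same regression on a 0/1 phenotype, which is equivalent up to a
monotone transform to the allelic trend test and keeps one code path.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .genotype_model import MISSING, GenotypePanel

logger = logging.getLogger("sweepscan")

QUANTITATIVE = "quantitative"
DICHOTOMOUS = "dichotomous"
N_PERM_DEFAULT = 1000


@dataclass
class TraitTable:
    """A breed-level phenotype: one value per included breed."""

    name: str
    coding: str
    values: dict[str, float]

    def __post_init__(self) -> None:
        if self.coding not in (QUANTITATIVE, DICHOTOMOUS):
            raise ValueError(f"unknown coding {self.coding!r}")
        if len(self.values) == 0:
            raise ValueError("empty trait table")
        if len(set(self.values.values())) < 2:
            raise ValueError("trait requires >=2 distinct values across breeds")
        if self.coding == DICHOTOMOUS and not set(self.values.values()) <= {0.0, 1.0, 0, 1}:
            raise ValueError("dichotomous trait values must be 0/1")

    @classmethod
    def from_tsv(cls, path, name: str | None = None, coding: str = QUANTITATIVE) -> "TraitTable":
        df = pd.read_csv(path, sep="\t")
        trait_col = name or df.columns[1]
        sub = df[["breed", trait_col]].dropna()
        return cls(name=trait_col, coding=coding,
                   values=dict(zip(sub["breed"], sub[trait_col].astype(float))))


@dataclass
class GwasResult:
    loci: pd.DataFrame
    statistic: np.ndarray
    raw_p: np.ndarray
    p_genome: np.ndarray
    n_perm: int
    seed: int | None
    exhaustive: bool = False
    sample_filter: str = "none"

    def to_frame(self) -> pd.DataFrame:
        out = self.loci[["chrom", "pos"]].copy()
        out["stat"] = self.statistic
        out["raw_p"] = self.raw_p
        out["p_genome"] = self.p_genome
        return out


def assign_phenotypes(panel: GenotypePanel, trait: TraitTable) -> tuple[GenotypePanel, np.ndarray]:
    """Give every sample its breed's trait value; drop breeds not in the table."""
    keep = panel.samples["breed"].isin(trait.values).to_numpy()
    if not keep.any():
        raise ValueError("no panel breed appears in the trait table")
    sub = panel.subset_samples(keep)
    pheno = sub.samples["breed"].map(trait.values).to_numpy(dtype=float)
    return sub, pheno


def _xtab(genotypes: np.ndarray) -> tuple[np.ndarray, ...]:
    """Permutation-invariant genotype-side sums for the per-SNP regression."""
    called = (genotypes != MISSING)
    x = np.where(called, genotypes, 0).astype(float)
    m = called.astype(float)
    n = m.sum(axis=0)
    sx = x.sum(axis=0)
    sxx = (x * x).sum(axis=0)
    return x, m, n, sx, sxx


def _stat_from_sums(x, m, n, sx, sxx, y) -> np.ndarray:
    """Squared t of the dosage slope, per locus, with per-locus missingness.

    Monomorphic or degenerate loci get statistic 0; all-missing loci NaN
    (excluded from permutation maxima).
    """
    sy = m.T @ y
    sxy = x.T @ y
    syy = m.T @ (y * y)
    with np.errstate(invalid="ignore", divide="ignore"):
        cov = sxy - sx * sy / n
        varx = sxx - sx * sx / n
        vary = syy - sy * sy / n
        r2 = cov * cov / (varx * vary)
        t2 = r2 * (n - 2) / (1 - r2)
    stat = np.where((varx > 0) & (vary > 0), t2, 0.0)
    stat = np.where(np.isnan(stat) & (varx > 0) & (vary > 0), np.inf, stat)
    stat[n == 0] = np.nan
    # r2 numerically >= 1 -> perfect fit, analytic maximum
    stat[(varx > 0) & (vary > 0) & (r2 >= 1 - 1e-12)] = np.inf
    return stat


def snp_association(
    genotypes: np.ndarray, phenotype: np.ndarray, coding: str = QUANTITATIVE
) -> tuple[np.ndarray, np.ndarray]:
    """Per-locus trend statistic (squared t) and its raw F(1, n-2) p-value."""
    phenotype = np.asarray(phenotype, dtype=float)
    if np.var(phenotype) == 0:
        raise ValueError("phenotype has zero variance")
    x, m, n, sx, sxx = _xtab(genotypes)
    stat = _stat_from_sums(x, m, n, sx, sxx, phenotype)
    with np.errstate(invalid="ignore"):
        raw_p = stats.f.sf(stat, 1, np.maximum(n - 2, 1))
    raw_p = np.where(np.isnan(stat), np.nan, raw_p)
    return stat, raw_p


def genomewide_permutation(
    panel: GenotypePanel,
    trait: TraitTable,
    n_perm: int = N_PERM_DEFAULT,
    seed: int | None = None,
    females_only: bool = False,
) -> GwasResult:
    """Max-T breed-permutation GWAS.

    P_genome(snp) = (1 + #permutations whose genome-wide maximum statistic
    >= the observed statistic) / (1 + n_perm); the floor at 1000
    permutations is 1/1001.  When the permutation space (all orderings of
    the breed values, duplicates counted) is no larger than ``n_perm`` it
    is enumerated exhaustively and P_genome becomes the exact proportion.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    filt = "none"
    if females_only:
        panel = panel.subset_samples((panel.samples["sex"] == "F").to_numpy())
        filt = "females_only"
    sub, pheno = assign_phenotypes(panel, trait)
    breeds = sub.breeds
    if len(breeds) < 3:
        raise ValueError("breed permutation requires >=3 breeds")
    values = np.array([trait.values[b] for b in breeds], dtype=float)
    breed_of = pd.Categorical(sub.samples["breed"], categories=breeds).codes

    x, m, n, sx, sxx = _xtab(sub.genotypes)
    obs = _stat_from_sums(x, m, n, sx, sxx, pheno)
    with np.errstate(invalid="ignore"):
        raw_p = stats.f.sf(obs, 1, np.maximum(n - 2, 1))
    raw_p = np.where(np.isnan(obs), np.nan, raw_p)

    # permutations swapping breeds with equal dosage sums tie the observed
    # statistic exactly in theory; count such ties as >= despite float noise
    tie_tol = 1e-9 * (1.0 + np.where(np.isfinite(obs), np.abs(obs), 0.0))

    n_space = math.factorial(len(breeds))
    exhaustive = n_space <= n_perm
    if exhaustive:
        logger.info("permutation space %d <= n_perm %d: exhaustive enumeration", n_space, n_perm)
        perms = itertools.permutations(values)
        maxima = np.array(
            [np.nanmax(_stat_from_sums(x, m, n, sx, sxx, np.asarray(p)[breed_of]))
             for p in perms]
        )
        ge = maxima[:, None] >= (obs - tie_tol)[None, :]
        p_genome = ge.sum(axis=0) / n_space
        n_used = n_space
    else:
        rng = np.random.default_rng(seed)
        maxima = np.empty(n_perm)
        for k in range(n_perm):
            y = rng.permutation(values)[breed_of]
            maxima[k] = np.nanmax(_stat_from_sums(x, m, n, sx, sxx, y))
        ge = maxima[:, None] >= (obs - tie_tol)[None, :]
        p_genome = (1 + ge.sum(axis=0)) / (1 + n_perm)
        n_used = n_perm
    p_genome = np.where(np.isnan(obs), np.nan, p_genome)
    return GwasResult(
        loci=sub.loci, statistic=obs, raw_p=raw_p, p_genome=p_genome,
        n_perm=n_used, seed=seed, exhaustive=exhaustive, sample_filter=filt,
    )
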