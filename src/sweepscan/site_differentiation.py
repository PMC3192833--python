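"""Per-SNP differentiation statistics across breeds and high-F_ST region calls.

F_ST uses the Weir & Cockerham (1984) theta estimator computed from
allele counts (each called allele treated as a haploid observation), which
carries the unequal-sample-size correction needed when breeds differ in
size.  A Hudson-style estimator is available behind ``estimator="hudson"``
for sensitivity checks.  Negative theta estimates are kept internally
(clipping would bias the moments used by downstream standardization) and
clipped to [0, 1] only for reporting and thresholding.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genotype_model import BreedFrequencies, GenotypePanel

FST_MIN_DEFAULT = 0.55
MAF_MIN_DEFAULT = 0.15
MERGE_BP_DEFAULT = 500_000
FIX_THRESHOLD_DEFAULT = 0.95


@dataclass
class SnpFstTable:
    """Per-locus multi-breed F_ST, pooled MAF and pairwise fixation index."""

    loci: pd.DataFrame
    fst_multi: np.ndarray       # unclipped Weir-Cockerham theta, NaN undefined
    maf_overall: np.ndarray
    pq_index: np.ndarray        # int, 0 where undefined

    @property
    def fst_clipped(self) -> np.ndarray:
        return np.clip(self.fst_multi, 0.0, 1.0)

    def to_frame(self) -> pd.DataFrame:
        out = self.loci[["chrom", "pos"]].copy()
        out["fst_multi"] = self.fst_clipped
        out["maf"] = self.maf_overall
        out["pq"] = self.pq_index
        return out


@dataclass
class HighFstRegion:
    chrom: str
    start: int
    end: int
    n_snps: int
    max_fst: float


def _wc_theta(freq: np.ndarray, n: np.ndarray) -> np.ndarray:
    """Weir-Cockerham theta per locus from allele frequencies and counts.

    ``freq``/``n`` are (n_pops, n_loci); entries with NaN frequency or
    fewer than 2 called alleles are excluded per locus.  The estimator is
    the ratio of mean squares ANOVA form for haploid (allele-level)
    observations:

        MSP = sum_i n_i (p_i - p_bar)^2 / (r - 1)
        MSG = sum_i n_i p_i (1 - p_i) / sum_i (n_i - 1)
        theta = (MSP - MSG) / (MSP + (n_c - 1) MSG)

    with n_c the Weir-Cockerham effective sample-size correction.  Loci
    where all contributing breeds are monomorphic for the same allele (or
    <2 breeds contribute) return NaN.
    """
    freq = np.asarray(freq, dtype=float)
    n = np.asarray(n, dtype=float)
    use = ~np.isnan(freq) & (n >= 2)
    n = np.where(use, n, 0.0)
    p = np.where(use, freq, 0.0)

    r = use.sum(axis=0).astype(float)             # breeds contributing per locus
    n_tot = n.sum(axis=0)
    out = np.full(freq.shape[1], np.nan)
    ok = r >= 2
    if not ok.any():
        return out

    with np.errstate(invalid="ignore", divide="ignore"):
        p_bar = (n * p).sum(axis=0) / n_tot
        msp = (n * (p - p_bar) ** 2).sum(axis=0) / (r - 1)
        denom_g = (n - use).sum(axis=0)           # sum (n_i - 1) over contributing
        msg = (n * p * (1 - p)).sum(axis=0) / denom_g
        n_c = (n_tot - (n ** 2).sum(axis=0) / n_tot) / (r - 1)
        num = msp - msg
        den = msp + (n_c - 1) * msg
        theta = num / den

    monomorphic = ok & np.isclose(msp, 0.0) & np.isclose(msg, 0.0)
    out[ok] = theta[ok]
    out[monomorphic] = np.nan
    return out


def _hudson_fst(freq: np.ndarray, n: np.ndarray) -> np.ndarray:
    """Hudson estimator averaged over contributing breed pairs (2-pop form)."""
    n_pops = freq.shape[0]
    num = np.zeros(freq.shape[1])
    den = np.zeros(freq.shape[1])
    cnt = np.zeros(freq.shape[1])
    for i in range(n_pops):
        for j in range(i + 1, n_pops):
            pi, pj = freq[i], freq[j]
            ni, nj = n[i], n[j]
            use = ~np.isnan(pi) & ~np.isnan(pj) & (ni >= 2) & (nj >= 2)
            with np.errstate(invalid="ignore", divide="ignore"):
                nm = (pi - pj) ** 2 - pi * (1 - pi) / (ni - 1) - pj * (1 - pj) / (nj - 1)
                dn = pi * (1 - pj) + pj * (1 - pi)
            num[use] += nm[use]
            den[use] += dn[use]
            cnt[use] += 1
    out = np.full(freq.shape[1], np.nan)
    ok = (cnt > 0) & (den > 0)
    out[ok] = num[ok] / den[ok]
    return out


def fst_multi(
    freqs: BreedFrequencies,
    breeds: list[str] | None = None,
    estimator: str = "wc",
) -> np.ndarray:
    """All-breed F_ST per locus (unclipped; clip for reporting)."""
    idx = [freqs.breed_index(b) for b in breeds] if breeds is not None else slice(None)
    freq = freqs.freq_b[idx]
    n = freqs.n_called[idx]
    if estimator == "wc":
        return _wc_theta(freq, n)
    if estimator == "hudson":
        return _hudson_fst(freq, n)
    raise ValueError(f"unknown estimator {estimator!r}")


def fst_pair(
    freqs: BreedFrequencies, breed_i: str, breed_j: str, estimator: str = "wc"
) -> np.ndarray:
    """Two-breed F_ST per locus; symmetric in its breed arguments."""
    return fst_multi(freqs, [breed_i, breed_j], estimator=estimator)


def pairwise_fixation_index(
    freqs: BreedFrequencies, fix_threshold: float = FIX_THRESHOLD_DEFAULT
) -> np.ndarray:
    """p*q where p (q) counts breeds with allele A (B) above ``fix_threshold``.

    A SNP scores > 0 exactly when at least one breed is near-fixed for each
    allele, flagging between-breed fixed differences.
    """
    with np.errstate(invalid="ignore"):
        p = np.nansum(freqs.freq_b < (1 - fix_threshold), axis=0)
        q = np.nansum(freqs.freq_b > fix_threshold, axis=0)
    return (p * q).astype(np.int64)


def overall_maf(panel: GenotypePanel) -> np.ndarray:
    """Minor-allele frequency pooled over all samples (missing excluded)."""
    geno = panel.genotypes
    called = geno != -1
    x_mask = (panel.loci["chrom_class"] == "X_nonrec").to_numpy()
    b = np.where(called, geno, 0).astype(float)
    n = np.where(called, 2, 0).astype(float)
    if x_mask.any():
        male = (panel.samples["sex"] == "M").to_numpy()
        if male.any():
            sub = np.ix_(male, x_mask)
            het = geno[sub] == 1
            b[sub] = np.where(het, 0, geno[sub] // 2)
            n[sub] = np.where(het | ~called[sub], 0, 1)
    with np.errstate(invalid="ignore", divide="ignore"):
        f = b.sum(axis=0) / n.sum(axis=0)
    return np.minimum(f, 1 - f)


def snp_fst_table(
    panel: GenotypePanel,
    freqs: BreedFrequencies | None = None,
    breeds: list[str] | None = None,
    estimator: str = "wc",
) -> SnpFstTable:
    from .genotype_model import breed_frequencies

    if freqs is None:
        freqs = breed_frequencies(panel)
    return SnpFstTable(
        loci=panel.loci,
        fst_multi=fst_multi(freqs, breeds, estimator=estimator),
        maf_overall=overall_maf(panel),
        pq_index=pairwise_fixation_index(freqs),
    )


def high_fst_regions(
    table: SnpFstTable,
    fst_min: float = FST_MIN_DEFAULT,
    maf_min: float = MAF_MIN_DEFAULT,
    merge_bp: int = MERGE_BP_DEFAULT,
) -> list[HighFstRegion]:
    """Chain SNPs passing both thresholds into regions.

    Consecutive passing SNPs on one chromosome at most ``merge_bp`` apart
    join one region; region bounds are the first/last member positions.
    """
    with np.errstate(invalid="ignore"):
        passing = (table.fst_clipped > fst_min) & (table.maf_overall > maf_min)
    regions: list[HighFstRegion] = []
    df = table.loci.loc[passing, ["chrom", "pos"]].copy()
    df["fst"] = table.fst_clipped[passing]
    for chrom, sub in df.groupby("chrom", sort=False):
        pos = sub["pos"].to_numpy()
        fst = sub["fst"].to_numpy()
        start = 0
        for k in range(1, len(pos) + 1):
            if k == len(pos) or pos[k] - pos[k - 1] > merge_bp:
                regions.append(
                    HighFstRegion(
                        chrom=str(chrom),
                        start=int(pos[start]),
                        end=int(pos[k - 1]),
                        n_snps=k - start,
                        max_fst=float(fst[start:k].max()),
                    )
                )
                start = k
    return regions


def regions_to_frame(regions: list[HighFstRegion]) -> pd.DataFrame:
    return pd.DataFrame(
        [(r.chrom, r.start, r.end, r.n_snps, r.max_fst) for r in regions],
        columns=["chrom", "start", "end", "n_snps", "max_fst"],
    )
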