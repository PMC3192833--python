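"""Cross-population extended haplotype homozygosity (XP-EHH) validation.

EHH over an interval [a, b] is the probability that two distinct
haplotypes drawn at random from a pool are identical at every SNP in the
closed interval.  SNP pairs are chosen where the *pooled* (all-breeds)
EHH has decayed into a fixed band (0.03-0.05 by default): at that point
the pooled haplotype pool is highly fragmented, so a breed that still
carries one long fixed haplotype stands out maximally.

For each retained pair and breed, the breed's EHH is integrated from the
anchor to the partner over the SNP grid (trapezoid rule, physical bp
abscissa) to give iHH; the raw cross-population statistic is the log
ratio of the breed's iHH to the mean iHH of all other breeds.  Scores are
normalized to mean 0, sd 1 within each breed x chromosome, then globally
sign-flipped so that breeds carrying a long fixed haplotype (candidate
sweeps) score *negative* -- the orientation under which sweep-region means
are negative while the genome-wide mean stays 0.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genotype_model import GenotypePanel
from .site_differentiation import overall_maf
from .sweep_scan import CandidateRegion

logger = logging.getLogger("sweepscan")

EHH_LO_DEFAULT = 0.03
EHH_HI_DEFAULT = 0.05
MAF_MIN_DEFAULT = 0.05


@dataclass(frozen=True)
class EhhPair:
    """Anchor/partner SNP pair (global locus indices) with its pooled EHH."""

    anchor: int
    partner: int
    ehh: float

    @property
    def lo(self) -> int:
        return min(self.anchor, self.partner)

    @property
    def hi(self) -> int:
        return max(self.anchor, self.partner)


def _homozygosity(group_sizes: np.ndarray, n: int) -> float:
    """sum C(n_k, 2) / C(N, 2) over haplotype classes."""
    if n < 2:
        return float("nan")
    return float((group_sizes * (group_sizes - 1)).sum() / (n * (n - 1)))


def ehh_between(haplotypes: np.ndarray, a: int, b: int) -> float:
    """EHH of the closed SNP interval [a, b] over the given haplotypes."""
    lo, hi = (a, b) if a <= b else (b, a)
    block = np.ascontiguousarray(haplotypes[:, lo: hi + 1])
    _, counts = np.unique(block, axis=0, return_counts=True)
    return _homozygosity(counts, haplotypes.shape[0])


def _ehh_walk(hap: np.ndarray, start: int, stop: int, step: int):
    """Yield (column, ehh) extending from ``start`` towards ``stop`` (exclusive).

    Incremental partition refinement: identical-haplotype classes can only
    split as SNPs are added, so EHH is non-increasing along the walk.
    """
    n = hap.shape[0]
    ids = np.zeros(n, dtype=np.int64)
    col = start
    while True:
        ids = ids * 2 + hap[:, col]
        _, ids, counts = np.unique(ids, return_inverse=True, return_counts=True)
        yield col, _homozygosity(counts, n)
        col += step
        if (step > 0 and col >= stop) or (step < 0 and col <= stop):
            return


def select_pairs(
    panel: GenotypePanel,
    ehh_lo: float = EHH_LO_DEFAULT,
    ehh_hi: float = EHH_HI_DEFAULT,
    maf_min: float = MAF_MIN_DEFAULT,
) -> list[EhhPair]:
    """Anchor/partner pairs whose pooled EHH falls inside [ehh_lo, ehh_hi].

    SNPs with pooled MAF < ``maf_min`` are removed first (neither anchor
    nor partner).  For each anchor the walk extends SNP by SNP in each
    direction; the first partner at which EHH drops to <= ehh_hi is
    retained if EHH is still >= ehh_lo (nearest-in-band), otherwise the
    decay skipped the band and no pair is kept in that direction.
    """
    if not panel.phased or panel.haplotypes is None:
        raise ValueError("XP-EHH requires a phased panel")
    maf = overall_maf(panel)
    keep = np.flatnonzero(maf >= maf_min)
    pairs: list[EhhPair] = []
    chrom = panel.loci["chrom"].to_numpy()
    hap = panel.haplotypes
    for c in pd.unique(chrom):
        cidx = keep[chrom[keep] == c]
        if len(cidx) < 2:
            continue
        sub = np.ascontiguousarray(hap[:, cidx])
        m = len(cidx)
        for ai in range(m):
            for step, stop in ((1, m), (-1, -1)):
                if ai + step == stop:
                    continue
                walk = _ehh_walk(sub, ai, stop, step)
                next(walk)  # anchor alone, EHH = 1
                for bi, e in walk:
                    if e <= ehh_hi:
                        if e >= ehh_lo:
                            pairs.append(EhhPair(int(cidx[ai]), int(cidx[bi]), e))
                        break
    return pairs


def xpehh_scores(
    pairs: list[EhhPair],
    panel: GenotypePanel,
    breeds: list[str] | None = None,
) -> pd.DataFrame:
    """Per-breed XP-EHH score for every SNP pair.

    Returns a DataFrame with columns ``breed, chrom, anchor, partner,
    anchor_pos, raw, score``; ``score`` is normalized (mean 0, sd 1) within
    breed x chromosome and sign-oriented so fixed-haplotype breeds score
    negative.  Pairs with an undefined log ratio for a breed are dropped
    with a logged count.
    """
    if panel.haplotypes is None:
        raise ValueError("XP-EHH requires a phased panel")
    breeds = breeds or panel.breeds
    if len(breeds) < 2:
        raise ValueError("XP-EHH requires >=2 breeds")
    pos = panel.loci["pos"].to_numpy()
    chrom = panel.loci["chrom"].to_numpy()
    hap_rows = {}
    for b in breeds:
        rows = np.flatnonzero(panel.breed_mask(b))
        hap_rows[b] = np.column_stack([2 * rows, 2 * rows + 1]).ravel()
        if len(hap_rows[b]) < 2:
            raise ValueError(f"breed {b} has <2 haplotypes")

    records = []
    n_dropped = 0
    for pair in pairs:
        step = 1 if pair.partner >= pair.anchor else -1
        ihh = np.empty(len(breeds))
        for k, b in enumerate(breeds):
            sub = panel.haplotypes[hap_rows[b]]
            xs = [0.0]
            ys = [1.0]
            for col, e in _ehh_walk(sub, pair.anchor, pair.partner + step, step):
                if col == pair.anchor:
                    continue
                xs.append(abs(float(pos[col] - pos[pair.anchor])))
                ys.append(e)
            ihh[k] = np.trapezoid(ys, xs)
        for k, b in enumerate(breeds):
            others = np.delete(ihh, k).mean()
            if ihh[k] <= 0 or others <= 0:
                n_dropped += 1
                continue
            records.append(
                (b, chrom[pair.anchor], pair.anchor, pair.partner,
                 int(pos[pair.anchor]), float(np.log(ihh[k] / others)))
            )
    if n_dropped:
        logger.info("dropped %d breed-pair scores with zero iHH", n_dropped)
    df = pd.DataFrame(
        records, columns=["breed", "chrom", "anchor", "partner", "anchor_pos", "raw"]
    )
    if df.empty:
        df["score"] = []
        return df
    df["score"] = np.nan
    for (b, c), sub in df.groupby(["breed", "chrom"], sort=False):
        vals = sub["raw"].to_numpy()
        sd = vals.std(ddof=1) if len(vals) > 1 else 0.0
        if sd > 0:
            # global sign flip: long fixed haplotypes -> negative scores
            df.loc[sub.index, "score"] = -(vals - vals.mean()) / sd
    return df


def region_mean_xpehh(
    scores: pd.DataFrame, regions: list[CandidateRegion]
) -> pd.DataFrame:
    """Mean normalized score over pairs anchored inside each region's breed.

    Regions containing no anchors for their breed report NaN.
    """
    rows = []
    for r in regions:
        sub = scores[
            (scores["breed"] == r.breed)
            & (scores["chrom"] == r.chrom)
            & (scores["anchor_pos"] >= r.start)
            & (scores["anchor_pos"] < r.end)
        ]
        mean = float(sub["score"].mean()) if len(sub) else float("nan")
        rows.append((r.breed, r.statistic, r.chrom, r.start, r.end, len(sub), mean))
    return pd.DataFrame(
        rows, columns=["breed", "statistic", "chrom", "start", "end",
                       "n_pairs", "mean_xpehh"],
    )
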