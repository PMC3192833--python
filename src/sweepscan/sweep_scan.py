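"""Windowed S_i / d_i selective-sweep scans with a simulation-based length null.

S_i sums, over all breed pairs involving breed *i*, the standardized window
relative heterozygosity theta_ij = h_i / (h_i + h_j), where h is the count
of SNPs segregating in a breed within the window.  Strongly negative S_i
marks windows where breed *i* has lost variation relative to the rest of
the panel.  d_i sums standardized per-SNP pairwise F_ST involving breed
*i*; large positive values mark breed-specific allele-frequency divergence.

Windows in the extreme 1% tail (bottom for S_i, top for d_i) are merged
into candidate regions; each region receives a marginal p-value equal to
the (add-one adjusted) proportion of regions from a neutral simulated panel
of the same breed that are longer, followed by Benjamini-Hochberg FDR
control across all regions of the statistic.

Autosomes plus PAR and the non-recombining X are standardized separately:
the two chromosome classes have different effective sizes and hence
different theta/F_ST baselines.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .genotype_model import BreedFrequencies, Window, X_NONREC
from .site_differentiation import fst_pair

logger = logging.getLogger("sweepscan")

S_I = "S_i"
D_I = "d_i"
TAIL_FRAC_DEFAULT = 0.01
ALPHA_DEFAULT = 0.05

AUTO_PAR = "auto_par"


def _class_group(chrom_class: str) -> str:
    return X_NONREC if chrom_class == X_NONREC else AUTO_PAR


@dataclass
class PairMoments:
    """Genome-wide moments used for standardization, per chromosome-class group.

    ``e_theta[i, j]`` is the expected relative heterozygosity of the ordered
    pair (i, j) from pooled genome-wide polymorphic-SNP counts,
    H_i / (H_i + H_j); ``sd_theta[i, j]`` the standard deviation of that
    pair's per-window theta values.  ``e_fst``/``sd_fst`` are the per-SNP
    pairwise F_ST moments (symmetric).
    """

    breeds: list[str]
    group: str
    e_theta: np.ndarray
    sd_theta: np.ndarray
    e_fst: np.ndarray
    sd_fst: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, bi in enumerate(self.breeds):
            for j, bj in enumerate(self.breeds):
                if i == j:
                    continue
                rows.append(
                    (self.group, bi, bj, self.e_theta[i, j], self.sd_theta[i, j],
                     self.e_fst[i, j], self.sd_fst[i, j])
                )
        return pd.DataFrame(
            rows, columns=["group", "breed_i", "breed_j",
                           "e_theta", "sd_theta", "e_fst", "sd_fst"]
        )


@dataclass
class WindowStatTrack:
    """Per-breed per-window values of one scan statistic."""

    breed: str
    statistic: str
    windows: list[Window]
    values: np.ndarray
    defined_pairs: np.ndarray  # count of breed pairs contributing per window

    def groups(self) -> np.ndarray:
        return np.array([_class_group(w.chrom_class) for w in self.windows])


@dataclass
class CandidateRegion:
    breed: str
    statistic: str
    chrom: str
    start: int
    end: int
    n_windows: int
    marginal_p: float | None = None
    fdr_q: float | None = None
    significant: bool | None = None

    @property
    def length_bp(self) -> int:
        return self.end - self.start

    def overlaps(self, chrom: str, start: int, end: int) -> bool:
        return self.chrom == chrom and self.start < end and start < self.end


@dataclass
class NullLengthDistribution:
    """Region lengths from scanning neutral simulated panels, per breed x statistic."""

    lengths: dict[tuple[str, str], np.ndarray]
    descriptor: dict = field(default_factory=dict)

    def get(self, breed: str, statistic: str) -> np.ndarray:
        key = (breed, statistic)
        if key not in self.lengths or len(self.lengths[key]) == 0:
            raise KeyError(f"null length distribution empty for {key}")
        return self.lengths[key]

    @classmethod
    def from_regions(cls, regions: list[CandidateRegion], **descriptor) -> "NullLengthDistribution":
        lengths: dict[tuple[str, str], list[int]] = {}
        for r in regions:
            lengths.setdefault((r.breed, r.statistic), []).append(r.length_bp)
        return cls(
            lengths={k: np.asarray(v) for k, v in lengths.items()},
            descriptor=descriptor,
        )


# ---------------------------------------------------------------------------
# relative heterozygosity and S_i
# ---------------------------------------------------------------------------


def window_polymorphic_counts(
    freqs: BreedFrequencies, windows: list[Window]
) -> np.ndarray:
    """h[k, w] = number of SNPs segregating in breed k within window w."""
    poly = freqs.polymorphic()
    h = np.empty((poly.shape[0], len(windows)), dtype=np.int64)
    for w, win in enumerate(windows):
        idx = win.snp_indices
        h[:, w] = poly[:, idx[0]: idx[-1] + 1].sum(axis=1) if len(idx) else 0
    return h


def relative_heterozygosity(
    freqs: BreedFrequencies, window: Window, breed_i: str, breed_j: str
) -> float:
    """theta_ij = h_i / (h_i + h_j) for one window; NaN when h_i + h_j = 0."""
    poly = freqs.polymorphic()[:, window.snp_indices]
    hi = int(poly[freqs.breed_index(breed_i)].sum())
    hj = int(poly[freqs.breed_index(breed_j)].sum())
    if hi + hj == 0:
        return math.nan
    return hi / (hi + hj)


def _theta_matrix(h: np.ndarray) -> np.ndarray:
    """theta[i, j, w] from per-window polymorphic counts; NaN where h_i+h_j=0."""
    n_b, n_w = h.shape
    hi = h[:, None, :].astype(float)
    hj = h[None, :, :].astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        theta = np.where(hi + hj > 0, hi / (hi + hj), np.nan)
    return theta


def s_i_scan(
    freqs: BreedFrequencies,
    windows: list[Window],
    breeds: list[str] | None = None,
    e_theta_mode: str = "pooled",
) -> tuple[dict[str, WindowStatTrack], list[PairMoments]]:
    """Compute S_i for every breed over the retained windows.

    ``e_theta_mode``: "pooled" uses genome-wide polymorphic-site totals
    H_i/(H_i+H_j) as E[theta_ij]; "window_mean" uses the mean of per-window
    theta values instead.
    """
    breeds = breeds or freqs.breeds
    if len(breeds) < 2:
        raise ValueError("S_i requires at least 2 breeds")
    bidx = np.array([freqs.breed_index(b) for b in breeds])
    n_b = len(breeds)

    groups = np.array([_class_group(w.chrom_class) for w in windows])
    locus_groups = freqs.loci["chrom_class"].map(_class_group).to_numpy()
    poly_all = freqs.polymorphic()[bidx]
    h_all = window_polymorphic_counts(freqs, windows)[bidx]

    values = np.zeros((n_b, len(windows)))
    defined = np.zeros((n_b, len(windows)), dtype=np.int64)
    moments: list[PairMoments] = []
    for group in pd.unique(groups):
        gw = groups == group
        h = h_all[:, gw]
        theta = _theta_matrix(h)

        if e_theta_mode == "pooled":
            H = poly_all[:, locus_groups == group].sum(axis=1).astype(float)
            with np.errstate(invalid="ignore", divide="ignore"):
                e_theta = H[:, None] / (H[:, None] + H[None, :])
        elif e_theta_mode == "window_mean":
            with np.errstate(invalid="ignore"):
                e_theta = np.nanmean(theta, axis=2)
        else:
            raise ValueError(f"unknown e_theta_mode {e_theta_mode!r}")
        with np.errstate(invalid="ignore"):
            sd_theta = _nanstd(theta, axis=2)
        np.fill_diagonal(e_theta, np.nan)
        np.fill_diagonal(sd_theta, np.nan)

        bad = (sd_theta <= 0) | np.isnan(sd_theta)
        np.fill_diagonal(bad, False)
        if bad.any():
            logger.warning(
                "%d breed pairs excluded from S_i (%s): zero/undefined sd",
                int(bad.sum()), group,
            )
        with np.errstate(invalid="ignore"):
            z = (theta - e_theta[:, :, None]) / sd_theta[:, :, None]
        z[bad] = np.nan
        ok = ~np.isnan(z)
        values[:, gw] = np.where(ok, z, 0.0).sum(axis=1)
        defined[:, gw] = ok.sum(axis=1)

        # F_ST moments filled in by d_i_scan; keep placeholders here
        moments.append(
            PairMoments(
                breeds=list(breeds), group=str(group),
                e_theta=e_theta, sd_theta=sd_theta,
                e_fst=np.full((n_b, n_b), np.nan),
                sd_fst=np.full((n_b, n_b), np.nan),
            )
        )

    tracks = {
        b: WindowStatTrack(
            breed=b, statistic=S_I, windows=list(windows),
            values=values[k], defined_pairs=defined[k],
        )
        for k, b in enumerate(breeds)
    }
    return tracks, moments


def _nanstd(a: np.ndarray, axis: int) -> np.ndarray:
    """Sample standard deviation (ddof=1) ignoring NaNs; NaN when n < 2."""
    cnt = np.sum(~np.isnan(a), axis=axis)
    with np.errstate(invalid="ignore", divide="ignore"):
        sd = np.nanstd(a, axis=axis, ddof=1)
    return np.where(cnt >= 2, sd, np.nan)


# ---------------------------------------------------------------------------
# d_i
# ---------------------------------------------------------------------------


def per_snp_di(
    freqs: BreedFrequencies,
    breeds: list[str] | None = None,
    estimator: str = "wc",
) -> tuple[np.ndarray, list[PairMoments]]:
    """Per-SNP d_i for every breed: sum of standardized pairwise F_ST.

    F_ST moments (mean and sample sd over all SNPs of the chromosome-class
    group) use unclipped estimates; clipping would bias the moments.
    Returns ``(d, moments)`` with ``d`` of shape (n_breeds, n_loci); entries
    are sums over the pairs defined at that SNP.
    """
    breeds = breeds or freqs.breeds
    if len(breeds) < 2:
        raise ValueError("d_i requires at least 2 breeds")
    n_b = len(breeds)
    n_loci = len(freqs.loci)
    locus_groups = freqs.loci["chrom_class"].map(_class_group).to_numpy()

    pair_fst = {}
    for i in range(n_b):
        for j in range(i + 1, n_b):
            pair_fst[(i, j)] = fst_pair(freqs, breeds[i], breeds[j], estimator=estimator)

    d = np.zeros((n_b, n_loci))
    moments: list[PairMoments] = []
    for group in pd.unique(locus_groups):
        gmask = locus_groups == group
        e_fst = np.full((n_b, n_b), np.nan)
        sd_fst = np.full((n_b, n_b), np.nan)
        for (i, j), fst in pair_fst.items():
            vals = fst[gmask]
            cnt = np.sum(~np.isnan(vals))
            if cnt >= 2:
                e_fst[i, j] = e_fst[j, i] = np.nanmean(vals)
                sd = np.nanstd(vals, ddof=1)
                sd_fst[i, j] = sd_fst[j, i] = sd
        bad = ~(sd_fst > 0)
        np.fill_diagonal(bad, False)
        if bad.any():
            logger.warning(
                "%d breed pairs excluded from d_i (%s): zero/undefined sd",
                int(bad.sum() // 2), group,
            )
        for (i, j), fst in pair_fst.items():
            if bad[i, j]:
                continue
            with np.errstate(invalid="ignore"):
                z = (fst[gmask] - e_fst[i, j]) / sd_fst[i, j]
            z = np.where(np.isnan(z), 0.0, z)
            d[i, gmask] += z
            d[j, gmask] += z
        moments.append(
            PairMoments(
                breeds=list(breeds), group=str(group),
                e_theta=np.full((n_b, n_b), np.nan),
                sd_theta=np.full((n_b, n_b), np.nan),
                e_fst=e_fst, sd_fst=sd_fst,
            )
        )
    return d, moments


def d_i_scan(
    freqs: BreedFrequencies,
    windows: list[Window],
    breeds: list[str] | None = None,
    estimator: str = "wc",
) -> tuple[dict[str, WindowStatTrack], list[PairMoments]]:
    """Window-averaged d_i per breed: mean of member-SNP d_i values."""
    breeds = breeds or freqs.breeds
    d, moments = per_snp_di(freqs, breeds, estimator=estimator)
    values = np.empty((len(breeds), len(windows)))
    for w, win in enumerate(windows):
        values[:, w] = d[:, win.snp_indices].mean(axis=1)
    n_pairs = np.full(len(windows), len(breeds) - 1, dtype=np.int64)
    tracks = {
        b: WindowStatTrack(
            breed=b, statistic=D_I, windows=list(windows),
            values=values[k], defined_pairs=n_pairs,
        )
        for k, b in enumerate(breeds)
    }
    return tracks, moments


# ---------------------------------------------------------------------------
# tails, regions, significance
# ---------------------------------------------------------------------------


def tail_windows(
    track: WindowStatTrack,
    tail_frac: float = TAIL_FRAC_DEFAULT,
    by_class: bool = True,
) -> list[Window]:
    """Flag the extreme-tail windows of a track (low tail for S_i, high for d_i).

    The ceil(tail_frac * N) most extreme windows are flagged; windows tied
    with the threshold value are all included.  With ``by_class`` the tail
    is taken separately within autosome+PAR and X_nonrec windows, matching
    the separate standardization.
    """
    n = len(track.windows)
    if n < int(round(1 / tail_frac)):
        raise ValueError(
            f"too few windows ({n}) for a {tail_frac:g} tail; need >= {int(round(1 / tail_frac))}"
        )
    low = track.statistic == S_I
    groups = track.groups() if by_class else np.array(["all"] * n)
    flagged: list[Window] = []
    for group in pd.unique(groups):
        gmask = groups == group
        vals = track.values[gmask]
        wins = [w for w, m in zip(track.windows, gmask) if m]
        k = math.ceil(tail_frac * len(vals))
        srt = np.sort(vals)
        thresh = srt[k - 1] if low else srt[len(vals) - k]
        sel = vals <= thresh if low else vals >= thresh
        if sel.all() and len(vals) > k:
            logger.warning(
                "all %d windows tied at the %s tail threshold for breed %s",
                len(vals), track.statistic, track.breed,
            )
        flagged.extend(w for w, m in zip(wins, sel) if m)
    return flagged


def merge_to_regions(
    flagged: list[Window], breed: str, statistic: str
) -> list[CandidateRegion]:
    """Collapse overlapping or exactly abutting flagged windows into regions."""
    regions: list[CandidateRegion] = []
    by_chrom: dict[str, list[Window]] = {}
    for w in flagged:
        by_chrom.setdefault(w.chrom, []).append(w)
    for chrom in by_chrom:
        wins = sorted(by_chrom[chrom], key=lambda w: w.start)
        cur_start, cur_end, cur_n = wins[0].start, wins[0].end, 1
        for w in wins[1:]:
            if w.start <= cur_end:
                cur_end = max(cur_end, w.end)
                cur_n += 1
            else:
                regions.append(CandidateRegion(breed, statistic, chrom, cur_start, cur_end, cur_n))
                cur_start, cur_end, cur_n = w.start, w.end, 1
        regions.append(CandidateRegion(breed, statistic, chrom, cur_start, cur_end, cur_n))
    regions.sort(key=lambda r: (r.chrom, r.start))
    return regions


def marginal_p(length_bp: int, null_lengths: np.ndarray, add_one: bool = True) -> float:
    """Proportion of null regions strictly longer; add-one adjusted by default."""
    null_lengths = np.asarray(null_lengths)
    longer = int(np.sum(null_lengths > length_bp))
    if add_one:
        return (1 + longer) / (1 + len(null_lengths))
    return longer / len(null_lengths)


def region_significance(
    regions: list[CandidateRegion],
    null: NullLengthDistribution,
    alpha: float = ALPHA_DEFAULT,
    add_one: bool = True,
) -> list[CandidateRegion]:
    """Attach marginal p-values and Benjamini-Hochberg q-values in place.

    The BH correction is applied jointly over all regions of one statistic
    across breeds.  Ties with the null ("as long as") count as not longer.
    """
    by_stat: dict[str, list[CandidateRegion]] = {}
    for r in regions:
        r.marginal_p = marginal_p(r.length_bp, null.get(r.breed, r.statistic), add_one)
        by_stat.setdefault(r.statistic, []).append(r)
    for stat_regions in by_stat.values():
        pvals = np.array([r.marginal_p for r in stat_regions])
        reject, qvals, _, _ = multipletests(pvals, alpha=alpha, method="fdr_bh")
        for r, q, rej in zip(stat_regions, qvals, reject):
            r.fdr_q = float(q)
            r.significant = bool(rej)
    return regions


def regions_to_frame(regions: list[CandidateRegion]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (r.breed, r.statistic, r.chrom, r.start, r.end, r.length_bp,
             r.n_windows, r.marginal_p, r.fdr_q, r.significant)
            for r in regions
        ],
        columns=["breed", "statistic", "chrom", "start", "end", "length_bp",
                 "n_windows", "marginal_p", "fdr_q", "significant"],
    )


def scan_regions(
    freqs: BreedFrequencies,
    windows: list[Window],
    statistic: str = S_I,
    breeds: list[str] | None = None,
    tail_frac: float = TAIL_FRAC_DEFAULT,
) -> list[CandidateRegion]:
    """Convenience pipeline: scan -> tail -> merge, for one statistic."""
    if statistic == S_I:
        tracks, _ = s_i_scan(freqs, windows, breeds)
    elif statistic == D_I:
        tracks, _ = d_i_scan(freqs, windows, breeds)
    else:
        raise ValueError(f"unknown statistic {statistic!r}")
    regions: list[CandidateRegion] = []
    for breed, track in tracks.items():
        flagged = tail_windows(track, tail_frac)
        regions.extend(merge_to_regions(flagged, breed, statistic))
    return regions
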