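"""Neutral and sweep-planted breed panels under a dog-domestication model.

The demographic program models an ancestral wolf population (diploid
Ne 22,600) that shrinks instantaneously to a domesticated-dog population
(Ne 5,650) 5,000 generations ago, then splits simultaneously 100
generations ago into isolated breed populations whose sizes are a
fraction f of the wolf size (f in roughly [0.001, 0.03] -- the breed
bottleneck grid), sampled at present.  Mutation rate 1e-8 /bp/generation;
recombination defaults to a uniform 1e-8 /bp/generation (~1 cM/Mb, the
canine genome-average scale); generation time 3 years.

msprime is the coalescent engine; the demographic program, SNP-array
ascertainment matching (frequency-histogram rejection sampling followed
by density thinning to one marker per ~13 kb), LD-decay curves,
grid-search bottleneck fitting, sweep planting and the neutral
region-length null builder are provided here so that every pipeline stage
is testable without any real genotype download.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import msprime
import numpy as np
import pandas as pd

from . import sweep_scan
from .breed_gwas import QUANTITATIVE, TraitTable
from .genotype_model import (
    X_NONREC,
    GenotypePanel,
    breed_frequencies,
    make_windows,
)

logger = logging.getLogger("sweepscan")

SPACING_BP_DEFAULT = 13_046
GRID_F = np.round(np.arange(0.001, 0.03 + 1e-9, 0.0005), 6)  # 59 bottleneck sizes


@dataclass(frozen=True)
class DemographicModel:
    """Wolf -> domestication bottleneck -> simultaneous breed-split model."""

    ne_wolf: float = 22_600.0
    ne_dog: float = 5_650.0
    t_dom: float = 5_000.0     # generations ago
    t_breed: float = 100.0     # generations ago
    mu: float = 1e-8           # per bp per generation
    recomb_rate: float = 1e-8  # per bp per generation (uniform default)
    generation_years: float = 3.0
    x_ne_ratio: float = 9134.0 / 7752.0  # X vs autosomal dog Ne estimates

    def __post_init__(self) -> None:
        if not (0 < self.t_breed < self.t_dom):
            raise ValueError("need 0 < t_breed < t_dom")
        for r in (self.ne_wolf, self.ne_dog, self.mu, self.recomb_rate):
            if r <= 0:
                raise ValueError("all rates and sizes must be positive")

    def size_scale(self, chrom_class: str) -> float:
        """Population-size multiplier for a chromosome class.

        The non-recombining X carries 3/4 as many copies as an autosome and
        the dog X/autosome Ne ratio is applied on top.
        """
        if chrom_class == X_NONREC:
            return 0.75 * self.x_ne_ratio
        return 1.0


@dataclass
class LdDecayCurve:
    """Mean haplotype r^2 in distance bins."""

    bin_edges: np.ndarray   # len n_bins + 1, bp
    mean_r2: np.ndarray     # NaN for unpopulated bins
    counts: np.ndarray

    @property
    def bin_mid(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])


def _demography(
    model: DemographicModel, breeds: list[tuple[str, int, float]], scale: float
) -> msprime.Demography:
    dem = msprime.Demography()
    for name, _n, f in breeds:
        if f <= 0:
            raise ValueError(f"bottleneck fraction must be positive for {name}")
        dem.add_population(name=name, initial_size=f * model.ne_wolf * scale)
    dem.add_population(name="dog_ancestral", initial_size=model.ne_dog * scale)
    dem.add_population_split(
        time=model.t_breed, derived=[b[0] for b in breeds], ancestral="dog_ancestral"
    )
    dem.add_population_parameters_change(
        time=model.t_dom, population="dog_ancestral", initial_size=model.ne_wolf * scale
    )
    return dem


def simulate_neutral_panel(
    model: DemographicModel,
    breeds: list[tuple[str, int, float]],
    segments: list[tuple[str, int]],
    seed: int,
) -> GenotypePanel:
    """Simulate a phased, missingness-free neutral panel.

    ``breeds`` holds (name, n_diploid_samples, bottleneck fraction f);
    ``segments`` holds (chrom_class, length_bp) -- each segment becomes an
    independently simulated chromosome named seg1, seg2, ...
    """
    if not segments:
        raise ValueError("at least one segment required")
    rng = np.random.default_rng(seed)
    seg_seeds = rng.integers(1, 2**31 - 1, size=2 * len(segments))

    sample_rows = []
    for name, n, _f in breeds:
        for k in range(n):
            sample_rows.append((f"{name}_{k}", name, "F"))
    samples_df = pd.DataFrame(sample_rows, columns=["sample_id", "breed", "sex"])

    loci_frames = []
    hap_blocks = []
    for s, (chrom_class, length_bp) in enumerate(segments):
        scale = model.size_scale(chrom_class)
        dem = _demography(model, breeds, scale)
        sample_sets = [
            msprime.SampleSet(n, population=name, ploidy=2) for name, n, _f in breeds
        ]
        ts = msprime.sim_ancestry(
            samples=sample_sets,
            demography=dem,
            sequence_length=length_bp,
            recombination_rate=model.recomb_rate,
            random_seed=int(seg_seeds[2 * s]),
        )
        ts = msprime.sim_mutations(
            ts,
            rate=model.mu,
            random_seed=int(seg_seeds[2 * s + 1]),
            model=msprime.BinaryMutationModel(),
        )
        if ts.num_sites == 0:
            raise RuntimeError(
                f"no segregating sites in segment {s + 1} "
                f"(length={length_bp}, breeds={len(breeds)}); model: {model}"
            )
        geno = ts.genotype_matrix()           # (n_sites, n_haps), 0/1
        seg = geno.sum(axis=1)
        poly = (seg > 0) & (seg < geno.shape[1])
        geno = geno[poly]
        positions = np.array([int(site.position) for site in ts.sites()])[poly]
        # discrete-genome mutations can stack at one bp; keep the first
        uniq = np.concatenate(([True], np.diff(positions) > 0))
        geno = geno[uniq]
        positions = positions[uniq]
        loci_frames.append(
            pd.DataFrame(
                {
                    "chrom": f"seg{s + 1}",
                    "pos": positions,
                    "allele_a": "A",
                    "allele_b": "B",
                    "chrom_class": chrom_class,
                }
            )
        )
        hap_blocks.append(geno.T.astype(np.int8))  # (n_haps, n_sites)

    loci = pd.concat(loci_frames, ignore_index=True)
    haplotypes = np.concatenate(hap_blocks, axis=1)
    genotypes = (haplotypes[0::2] + haplotypes[1::2]).astype(np.int8)
    panel = GenotypePanel(
        loci=loci, samples=samples_df, genotypes=genotypes,
        haplotypes=haplotypes, phased=True,
    )
    panel.validate()
    return panel


# ---------------------------------------------------------------------------
# ascertainment matching
# ---------------------------------------------------------------------------


def array_like_maf_target(n_bins: int = 10) -> np.ndarray:
    """Default target MAF spectrum emulating SNP-array ascertainment.

    Genotyping arrays are designed around SNPs already seen in a small
    discovery panel, which flattens the neutral 1/x spectrum towards
    common variants; a uniform mass over equal MAF bins on (0, 0.5] is the
    simplest spectrum with that character and is the default target.
    """
    return np.full(n_bins, 1.0 / n_bins)


def ascertainment_match(
    panel: GenotypePanel,
    target_freq_hist: np.ndarray | None = None,
    spacing_bp: int = SPACING_BP_DEFAULT,
    seed: int = 0,
) -> GenotypePanel:
    """Rejection-sample sites towards a pooled-MAF target, then thin by density.

    The retained pooled-MAF histogram approaches ``target_freq_hist``
    (equal-width bins over (0, 0.5]); empty donor bins are reported as a
    best-effort deficit.  Thinning then reduces the panel to one marker
    per ``spacing_bp`` on average.  Positions keep their order and phasing
    is preserved.
    """
    from .site_differentiation import overall_maf

    rng = np.random.default_rng(seed)
    target = array_like_maf_target() if target_freq_hist is None else np.asarray(
        target_freq_hist, dtype=float
    )
    target = target / target.sum()
    n_bins = len(target)

    maf = overall_maf(panel.subset_loci(np.arange(panel.n_loci)))
    # bin (0, 0.5] into n_bins; MAF == 0 sites are never retained
    bins = np.clip(np.ceil(maf * 2 * n_bins).astype(int) - 1, -1, n_bins - 1)
    bins[maf <= 0] = -1
    donor = np.bincount(bins[bins >= 0], minlength=n_bins).astype(float)
    empty = (donor == 0) & (target > 0)
    if empty.any():
        logger.warning(
            "ascertainment target has %d infeasible bins (no donor sites); best effort",
            int(empty.sum()),
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        weight = np.where(donor > 0, target / donor, 0.0)
    if weight.max() <= 0:
        raise ValueError("no usable donor sites for ascertainment matching")
    accept_p = weight / weight.max()
    u = rng.random(panel.n_loci)
    keep = (bins >= 0) & (u < accept_p[np.clip(bins, 0, None)])

    # thin to the requested mean marker spacing
    span = sum(
        int(sub["pos"].max() - sub["pos"].min()) + 1
        for _, sub in panel.loci.groupby("chrom", sort=False)
    )
    n_target = max(2, int(round(span / spacing_bp)))
    kept_idx = np.flatnonzero(keep)
    if len(kept_idx) > n_target:
        kept_idx = np.sort(rng.choice(kept_idx, size=n_target, replace=False))
    else:
        logger.warning(
            "only %d sites survive frequency matching (target density %d)",
            len(kept_idx), n_target,
        )
    return panel.subset_loci(kept_idx)


# ---------------------------------------------------------------------------
# LD decay and bottleneck fitting
# ---------------------------------------------------------------------------


def ld_decay(
    panel: GenotypePanel,
    max_bp: int = 500_000,
    bin_bp: int = 10_000,
    within: str = "pooled",
) -> LdDecayCurve:
    """Haplotype r^2 for marker pairs within ``max_bp``, binned by distance.

    ``within`` is "pooled" or a breed name.  Pairs involving a marker
    monomorphic in the chosen haplotype set are skipped.
    """
    if panel.haplotypes is None:
        raise ValueError("LD decay requires a phased panel")
    if within == "pooled":
        hap = panel.haplotypes
    else:
        rows = np.flatnonzero(panel.breed_mask(within))
        hap = panel.haplotypes[np.column_stack([2 * rows, 2 * rows + 1]).ravel()]
    n_bins = int(np.ceil(max_bp / bin_bp))
    sums = np.zeros(n_bins)
    counts = np.zeros(n_bins, dtype=np.int64)
    chrom = panel.loci["chrom"].to_numpy()
    pos_all = panel.loci["pos"].to_numpy()
    n_hap = hap.shape[0]
    for c in pd.unique(chrom):
        cidx = np.flatnonzero(chrom == c)
        h = hap[:, cidx].astype(float)
        mean = h.mean(axis=0)
        sd = h.std(axis=0)
        poly = sd > 0
        z = np.zeros_like(h)
        z[:, poly] = (h[:, poly] - mean[poly]) / sd[poly]
        pos = pos_all[cidx]
        for i in range(len(cidx) - 1):
            if not poly[i]:
                continue
            hi = int(np.searchsorted(pos, pos[i] + max_bp, side="right"))
            js = np.arange(i + 1, hi)
            js = js[poly[js]]
            if len(js) == 0:
                continue
            r = z[:, js].T @ z[:, i] / n_hap
            b = np.minimum(((pos[js] - pos[i] - 1) // bin_bp), n_bins - 1)
            np.add.at(sums, b, r * r)
            np.add.at(counts, b, 1)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean_r2 = np.where(counts > 0, sums / counts, np.nan)
    edges = np.arange(n_bins + 1) * bin_bp
    return LdDecayCurve(bin_edges=edges, mean_r2=mean_r2, counts=counts)


def simulate_breed_ld_curve(
    model: DemographicModel,
    f: float,
    n_samples: int,
    segments: list[tuple[str, int]],
    seed: int,
    max_bp: int = 500_000,
    bin_bp: int = 10_000,
    maf_min: float = 0.05,
) -> LdDecayCurve:
    """Single-breed simulation -> MAF filter -> within-breed LD curve.

    This is the shared curve protocol used on both the observed and the
    grid-simulated side of :func:`fit_bottleneck`.
    """
    panel = simulate_neutral_panel(model, [("b", n_samples, f)], segments, seed)
    from .site_differentiation import overall_maf

    keep = overall_maf(panel) >= maf_min
    panel = panel.subset_loci(keep)
    return ld_decay(panel, max_bp=max_bp, bin_bp=bin_bp, within="pooled")


def fit_bottleneck(
    observed: LdDecayCurve,
    model: DemographicModel,
    n_samples: int,
    segments: list[tuple[str, int]],
    seed: int,
    grid: np.ndarray = GRID_F,
) -> tuple[float, pd.DataFrame]:
    """Grid-search the breed bottleneck fraction f by LD-decay least squares.

    Simulates the curve protocol at every grid f and returns the argmin of
    the summed squared bin differences (ties towards smaller f) plus the
    per-grid score table.
    """
    grid = np.asarray(grid, dtype=float)
    if len(grid) == 0:
        raise ValueError("empty bottleneck grid")
    pops = np.flatnonzero(observed.counts >= 1)
    if len(pops) < 10:
        raise ValueError("observed LD curve needs >=10 populated bins")
    rng = np.random.default_rng(seed)
    grid_seeds = rng.integers(1, 2**31 - 1, size=len(grid))
    scores = np.empty(len(grid))
    for g, f in enumerate(grid):
        curve = simulate_breed_ld_curve(
            model, float(f), n_samples, segments, int(grid_seeds[g]),
            max_bp=int(observed.bin_edges[-1]),
            bin_bp=int(observed.bin_edges[1] - observed.bin_edges[0]),
        )
        both = pops[np.isfinite(curve.mean_r2[pops])]
        scores[g] = np.sum((observed.mean_r2[both] - curve.mean_r2[both]) ** 2)
    best = int(np.argmin(scores))  # argmin returns the first (smallest f) tie
    table = pd.DataFrame({"f": grid, "sse": scores})
    return float(grid[best]), table


# ---------------------------------------------------------------------------
# sweep planting and trait simulation
# ---------------------------------------------------------------------------


def plant_sweep(
    panel: GenotypePanel,
    breed: str,
    chrom: str,
    start: int,
    end: int,
    seed: int = 0,
) -> GenotypePanel:
    """Fix one randomly chosen haplotype of ``breed`` across [start, end).

    Emulates a completed hard sweep: every haplotype of every sample of
    the breed is overwritten with the chosen donor haplotype inside the
    region; everything outside, and every other breed, is untouched.
    """
    pos = panel.loci["pos"].to_numpy()
    in_region = np.flatnonzero(
        (panel.loci["chrom"].to_numpy() == chrom) & (pos >= start) & (pos < end)
    )
    if len(in_region) == 0:
        raise ValueError(f"no SNPs in {chrom}:{start}-{end}")
    rows = np.flatnonzero(panel.breed_mask(breed))
    if len(rows) == 0:
        raise ValueError(f"breed {breed!r} not in panel")
    if panel.haplotypes is None:
        raise ValueError("plant_sweep requires haplotypes")
    rng = np.random.default_rng(seed)
    hap_rows = np.column_stack([2 * rows, 2 * rows + 1]).ravel()
    donor = int(rng.choice(hap_rows))
    haplotypes = panel.haplotypes.copy()
    haplotypes[np.ix_(hap_rows, in_region)] = haplotypes[donor, in_region]
    genotypes = panel.genotypes.copy()
    genotypes[np.ix_(rows, in_region)] = (
        haplotypes[hap_rows[0::2]][:, in_region] + haplotypes[hap_rows[1::2]][:, in_region]
    )
    return replace(panel, genotypes=genotypes, haplotypes=haplotypes)


def simulate_trait_panel(
    panel: GenotypePanel,
    causal_locus: int,
    effect: float,
    noise_sd: float,
    seed: int = 0,
    name: str = "synthetic_trait",
) -> TraitTable:
    """Breed phenotype = effect x breed B-allele frequency + Gaussian noise."""
    freqs = breed_frequencies(panel)
    rng = np.random.default_rng(seed)
    values = {}
    for k, b in enumerate(freqs.breeds):
        values[b] = float(
            effect * freqs.freq_b[k, causal_locus] + rng.normal(0.0, noise_sd)
        )
    if len(set(values.values())) < 2:  # degenerate draw; nudge deterministically
        first = next(iter(values))
        values[first] += 1e-9
    return TraitTable(name=name, coding=QUANTITATIVE, values=values)


# ---------------------------------------------------------------------------
# null region-length distributions
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ScanParams:
    window_bp: int = 150_000
    step_bp: int = 25_000
    min_snps: int = 5
    tail_frac: float = 0.01
    statistics: tuple[str, ...] = (sweep_scan.S_I, sweep_scan.D_I)


def scan_panel_regions(
    panel: GenotypePanel, params: ScanParams
) -> list[sweep_scan.CandidateRegion]:
    """Windows -> S_i/d_i scans -> tails -> merged regions for one panel."""
    freqs = breed_frequencies(panel)
    windows = make_windows(panel.loci, params.window_bp, params.step_bp, params.min_snps)
    regions: list[sweep_scan.CandidateRegion] = []
    for stat in params.statistics:
        regions.extend(
            sweep_scan.scan_regions(freqs, windows, statistic=stat, tail_frac=params.tail_frac)
        )
    return regions


def null_region_lengths(
    model: DemographicModel,
    breeds: list[tuple[str, int, float]],
    segments: list[tuple[str, int]],
    params: ScanParams,
    n_replicates: int,
    seed: int,
    target_freq_hist: np.ndarray | None = None,
    spacing_bp: int = SPACING_BP_DEFAULT,
) -> sweep_scan.NullLengthDistribution:
    """Scan neutral replicates and pool region lengths per breed x statistic.

    Runs simulate -> ascertainment-match -> scan with the given parameters
    for every replicate; a failed replicate is skipped with a logged count.
    """
    rng = np.random.default_rng(seed)
    rep_seeds = rng.integers(1, 2**31 - 1, size=(n_replicates, 2))
    lengths: dict[tuple[str, str], list[int]] = {
        (b[0], stat): [] for b in breeds for stat in params.statistics
    }
    n_failed = 0
    for rep in range(n_replicates):
        try:
            panel = simulate_neutral_panel(model, breeds, segments, int(rep_seeds[rep, 0]))
            panel = ascertainment_match(
                panel, target_freq_hist, spacing_bp, int(rep_seeds[rep, 1])
            )
            for r in scan_panel_regions(panel, params):
                lengths[(r.breed, r.statistic)].append(r.length_bp)
        except Exception as exc:  # pragma: no cover - defensive
            n_failed += 1
            logger.warning("null replicate %d failed: %s", rep, exc)
    if n_failed:
        logger.warning("%d of %d null replicates failed", n_failed, n_replicates)
    return sweep_scan.NullLengthDistribution(
        lengths={k: np.asarray(v) for k, v in lengths.items()},
        descriptor={
            "model": repr(DemographicModel()) if model is None else repr(model),
            "seed": seed,
            "n_replicates": n_replicates,
            "n_failed": n_failed,
            "segments": list(segments),
        },
    )


def within_breed_heterozygosity(panel: GenotypePanel, breed: str) -> float:
    """Per-bp expected heterozygosity of a breed: sum of 2p(1-p) over span.

    Normalizing by sequence span (not by segregating-site count) makes the
    measure sensitive to variant loss: conditioning on segregation would
    paradoxically rise under stronger drift as rare variants disappear.
    """
    freqs = breed_frequencies(panel)
    p = freqs.freq_b[freqs.breed_index(breed)]
    p = p[~np.isnan(p)]
    span = sum(
        int(sub["pos"].max() - sub["pos"].min()) + 1
        for _, sub in panel.loci.groupby("chrom", sort=False)
    )
    return float(np.sum(2 * p * (1 - p)) / span)
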