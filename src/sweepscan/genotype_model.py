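"""Genotype panel data model, readers/writers, and sliding-window construction.

The central container is :class:`GenotypePanel`: a breed-labelled biallelic
genotype (and optionally phased haplotype) matrix over an ordered SNP map.
All coordinates are 0-based half-open internally; 1-based coordinates appear
only at I/O boundaries (VCF and PLINK transposed text in, BED out).

Chromosomes carry a class label (``autosome``, ``PAR`` or ``X_nonrec``)
because downstream scan statistics standardize the autosomes-plus-PAR and
the non-recombining X separately.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("sweepscan")

MISSING = -1

AUTOSOME = "autosome"
PAR = "PAR"
X_NONREC = "X_nonrec"
CHROM_CLASSES = (AUTOSOME, PAR, X_NONREC)

LOCI_COLUMNS = ["chrom", "pos", "allele_a", "allele_b", "chrom_class"]
SAMPLE_COLUMNS = ["sample_id", "breed", "sex"]


class PanelFormatError(ValueError):
    """Raised for malformed input files (message carries the offending line)."""


@dataclass(frozen=True)
class Locus:
    """A single biallelic site.

    ``pos`` is stored 0-based.  ``allele_a`` plays the REF-like role and
    ``allele_b`` the ALT-like role; genotype dosages count B alleles.
    """

    chrom: str
    pos: int
    allele_a: str
    allele_b: str
    chrom_class: str = AUTOSOME

    def __post_init__(self) -> None:
        if self.pos < 0:
            raise ValueError(f"negative position {self.pos}")
        if self.chrom_class not in CHROM_CLASSES:
            raise ValueError(f"unknown chromosome class {self.chrom_class!r}")


@dataclass
class GenotypePanel:
    """Breed-labelled genotype/haplotype matrix with an ordered SNP map.

    Attributes
    ----------
    loci : pandas.DataFrame
        Columns ``chrom, pos, allele_a, allele_b, chrom_class``; sorted by
        chromosome then position, strictly increasing within a chromosome.
    samples : pandas.DataFrame
        Columns ``sample_id, breed, sex`` (sex in {"M", "F", "U"}).
    genotypes : numpy.ndarray
        ``(n_samples, n_loci)`` int8 count of B alleles in {0, 1, 2} with
        ``-1`` for missing.
    haplotypes : numpy.ndarray or None
        ``(2 * n_samples, n_loci)`` int8 binary matrix when phased; sample
        ``i`` owns rows ``2i`` and ``2i + 1``.
    """

    loci: pd.DataFrame
    samples: pd.DataFrame
    genotypes: np.ndarray
    haplotypes: np.ndarray | None = None
    phased: bool = False

    # -- basic introspection -------------------------------------------------

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    @property
    def breeds(self) -> list[str]:
        """Breed labels in first-appearance order."""
        return list(dict.fromkeys(self.samples["breed"]))

    def breed_mask(self, breed: str) -> np.ndarray:
        return (self.samples["breed"] == breed).to_numpy()

    def validate(self) -> None:
        """Check the container invariants; raise ``ValueError`` on violation."""
        if self.genotypes.shape != (self.n_samples, self.n_loci):
            raise ValueError("genotype matrix shape mismatch")
        if self.samples["breed"].eq("").any() or self.samples["breed"].isna().any():
            raise ValueError("every sample requires a non-empty breed label")
        if self.samples["sample_id"].duplicated().any():
            dup = self.samples["sample_id"][self.samples["sample_id"].duplicated()].iloc[0]
            raise ValueError(f"duplicated sample id {dup!r}")
        for chrom, sub in self.loci.groupby("chrom", sort=False):
            pos = sub["pos"].to_numpy()
            if np.any(np.diff(pos) <= 0):
                raise ValueError(f"loci not strictly increasing on {chrom}")
        if (self.loci["pos"] < 0).any():
            raise ValueError("negative locus position")
        ok = np.isin(self.genotypes, (MISSING, 0, 1, 2))
        if not ok.all():
            raise ValueError("genotype dosages must be in {missing, 0, 1, 2}")
        if self.phased:
            if self.haplotypes is None:
                raise ValueError("phased panel without haplotypes")
            if self.haplotypes.shape != (2 * self.n_samples, self.n_loci):
                raise ValueError("haplotype matrix shape mismatch")
            hap_sum = self.haplotypes[0::2] + self.haplotypes[1::2]
            called = self.genotypes != MISSING
            if not np.array_equal(hap_sum[called], self.genotypes[called]):
                raise ValueError("haplotype pair sums disagree with genotypes")

    # -- subsetting ----------------------------------------------------------

    def subset_samples(self, mask: np.ndarray) -> "GenotypePanel":
        mask = np.asarray(mask)
        if mask.dtype == bool:
            idx = np.flatnonzero(mask)
        else:
            idx = mask
        hap = None
        if self.haplotypes is not None:
            hap_idx = np.column_stack([2 * idx, 2 * idx + 1]).ravel()
            hap = self.haplotypes[hap_idx]
        return replace(
            self,
            samples=self.samples.iloc[idx].reset_index(drop=True),
            genotypes=self.genotypes[idx],
            haplotypes=hap,
        )

    def subset_loci(self, idx: np.ndarray) -> "GenotypePanel":
        idx = np.asarray(idx)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return replace(
            self,
            loci=self.loci.iloc[idx].reset_index(drop=True),
            genotypes=self.genotypes[:, idx],
            haplotypes=None if self.haplotypes is None else self.haplotypes[:, idx],
        )

    def restrict_breeds(self, breeds: Sequence[str]) -> "GenotypePanel":
        return self.subset_samples(self.samples["breed"].isin(list(breeds)).to_numpy())


@dataclass
class BreedFrequencies:
    """Per-breed B-allele frequencies and called-allele counts.

    ``freq_b[k, l]`` is NaN where breed ``k`` has zero called alleles at
    locus ``l`` (the undefined flag); such entries are excluded from every
    cross-breed statistic.
    """

    breeds: list[str]
    freq_b: np.ndarray  # (n_breeds, n_loci) float64, NaN = undefined
    n_called: np.ndarray  # (n_breeds, n_loci) int64 called-allele counts
    loci: pd.DataFrame

    def defined(self) -> np.ndarray:
        return ~np.isnan(self.freq_b)

    def breed_index(self, breed: str) -> int:
        return self.breeds.index(breed)

    def polymorphic(self) -> np.ndarray:
        """Boolean (n_breeds, n_loci): 0 < freq_b < 1."""
        with np.errstate(invalid="ignore"):
            return (self.freq_b > 0.0) & (self.freq_b < 1.0)


@dataclass(frozen=True)
class Window:
    """A half-open genomic interval with the indices of contained loci."""

    chrom: str
    start: int
    end: int
    snp_indices: np.ndarray
    chrom_class: str = AUTOSOME

    @property
    def n_snps(self) -> int:
        return len(self.snp_indices)


# ---------------------------------------------------------------------------
# allele frequencies
# ---------------------------------------------------------------------------


def breed_frequencies(panel: GenotypePanel) -> BreedFrequencies:
    """Tally per-breed B-allele frequencies from genotype dosages.

    Missing genotypes are excluded from the counts.  On the non-recombining
    X, male samples are treated as haploid: a male dosage of 0 or 2
    contributes one allele (heterozygous male calls there are counted as
    missing).
    """
    breeds = panel.breeds
    n_loci = panel.n_loci
    geno = panel.genotypes
    called = geno != MISSING

    b_count = np.where(called, geno, 0).astype(np.int64)
    allele_n = np.where(called, 2, 0).astype(np.int64)

    x_mask = (panel.loci["chrom_class"] == X_NONREC).to_numpy()
    if x_mask.any():
        male = (panel.samples["sex"] == "M").to_numpy()
        if male.any():
            sub = np.ix_(male, x_mask)
            het = geno[sub] == 1
            b_count[sub] = np.where(het, 0, geno[sub] // 2)
            allele_n[sub] = np.where(het | ~called[sub], 0, 1)

    freq = np.full((len(breeds), n_loci), np.nan)
    n_called = np.zeros((len(breeds), n_loci), dtype=np.int64)
    for k, breed in enumerate(breeds):
        rows = panel.breed_mask(breed)
        n_called[k] = allele_n[rows].sum(axis=0)
        b = b_count[rows].sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            freq[k] = np.where(n_called[k] > 0, b / n_called[k], np.nan)
    return BreedFrequencies(breeds=breeds, freq_b=freq, n_called=n_called, loci=panel.loci)


# ---------------------------------------------------------------------------
# windows
# ---------------------------------------------------------------------------


def make_windows(
    loci: pd.DataFrame,
    window_bp: int = 150_000,
    step_bp: int = 25_000,
    min_snps: int = 5,
) -> list[Window]:
    """Tile each chromosome with sliding windows anchored at position 0.

    Windows are ``[start, start + window_bp)`` with starts every ``step_bp``
    from 0; a window keeps the loci whose position falls inside it and is
    retained only when it holds at least ``min_snps`` loci.  The SNP count
    is taken over all array loci present in the map, before any per-breed
    restriction.
    """
    if window_bp <= 0 or step_bp <= 0:
        raise ValueError("window_bp and step_bp must be positive")
    windows: list[Window] = []
    offset = 0
    for chrom, sub in loci.groupby("chrom", sort=False):
        pos = sub["pos"].to_numpy()
        cclass = sub["chrom_class"].iloc[0]
        idx0 = offset
        offset += len(sub)
        if len(pos) == 0:
            continue
        last = int(pos[-1])
        for start in range(0, last + 1, step_bp):
            end = start + window_bp
            lo = int(np.searchsorted(pos, start, side="left"))
            hi = int(np.searchsorted(pos, end, side="left"))
            if hi - lo >= min_snps:
                windows.append(
                    Window(
                        chrom=str(chrom),
                        start=start,
                        end=end,
                        snp_indices=np.arange(idx0 + lo, idx0 + hi),
                        chrom_class=cclass,
                    )
                )
    return windows


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------


def read_panel(
    path: str | Path,
    format: str = "vcf",
    sample_meta: str | Path | None = None,
    chrom_class_map: dict[str, str] | None = None,
) -> GenotypePanel:
    """Read a genotype panel from VCF or PLINK transposed text.

    Parameters
    ----------
    path
        The VCF file, or the ``.tped`` file (its ``.tfam`` sibling is
        located by extension swap).
    sample_meta
        TSV with columns ``sample_id, breed, sex``; required for VCF
        (VCF has no breed field), optional for tped where breed is the
        family-ID column.
    chrom_class_map
        Mapping chromosome name -> class; unlisted chromosomes are
        autosomes.
    """
    if format == "vcf":
        return _read_vcf(Path(path), sample_meta, chrom_class_map or {})
    if format == "tped":
        return _read_tped(Path(path), sample_meta, chrom_class_map or {})
    raise ValueError(f"unknown panel format {format!r}")


def _finalize_loci(records: list[tuple], chrom_class_map: dict[str, str]) -> pd.DataFrame:
    df = pd.DataFrame(records, columns=["chrom", "pos", "allele_a", "allele_b"])
    df["chrom_class"] = df["chrom"].map(lambda c: chrom_class_map.get(c, AUTOSOME))
    return df


def _read_sample_meta(sample_meta: str | Path) -> pd.DataFrame:
    meta = pd.read_csv(sample_meta, sep="\t", dtype=str)
    missing = set(SAMPLE_COLUMNS) - set(meta.columns)
    if missing:
        raise PanelFormatError(f"sample metadata lacks columns {sorted(missing)}")
    return meta[SAMPLE_COLUMNS]


def _read_vcf(path: Path, sample_meta, chrom_class_map) -> GenotypePanel:
    from cyvcf2 import VCF

    if sample_meta is None:
        raise ValueError("VCF input requires a sample-metadata TSV (sample_id, breed, sex)")
    meta = _read_sample_meta(sample_meta)

    vcf = VCF(str(path))
    ids = list(vcf.samples)
    if len(set(ids)) != len(ids):
        raise PanelFormatError("duplicated sample id in VCF header")
    meta = meta.set_index("sample_id").reindex(ids)
    if meta["breed"].isna().any():
        absent = [s for s in ids if s not in set(meta.index[meta["breed"].notna()])]
        raise PanelFormatError(f"samples missing from metadata: {absent[:5]}")
    samples = meta.reset_index()[SAMPLE_COLUMNS]

    loci_records: list[tuple] = []
    geno_cols: list[np.ndarray] = []
    hap_cols: list[np.ndarray] = []
    n_multi = n_allmissing = 0
    any_unphased = False
    for var in vcf:
        if len(var.ALT) != 1:
            n_multi += 1
            continue
        gts = np.array(var.genotypes, dtype=object)
        a0 = np.array([g[0] for g in gts], dtype=np.int8)
        a1 = np.array([g[1] for g in gts], dtype=np.int8)
        phased_flags = np.array([bool(g[2]) for g in gts])
        miss = (a0 < 0) | (a1 < 0)
        if miss.all():
            n_allmissing += 1
            continue
        dose = np.where(miss, MISSING, a0 + a1).astype(np.int8)
        geno_cols.append(dose)
        hap = np.empty(2 * len(dose), dtype=np.int8)
        hap[0::2] = np.where(miss, 0, np.maximum(a0, 0))
        hap[1::2] = np.where(miss, 0, np.maximum(a1, 0))
        hap_cols.append(hap)
        if not phased_flags[~miss].all():
            any_unphased = True
        loci_records.append((var.CHROM, var.POS - 1, var.REF, var.ALT[0]))
    if n_multi or n_allmissing:
        logger.warning(
            "dropped %d multiallelic and %d all-missing sites from %s",
            n_multi, n_allmissing, path,
        )
    loci = _finalize_loci(loci_records, chrom_class_map)
    genotypes = (
        np.column_stack(geno_cols) if geno_cols else np.empty((len(samples), 0), np.int8)
    )
    phased = bool(geno_cols) and not any_unphased and not (genotypes == MISSING).any()
    haplotypes = np.column_stack(hap_cols) if (phased and hap_cols) else None
    panel = GenotypePanel(
        loci=loci, samples=samples, genotypes=genotypes,
        haplotypes=haplotypes, phased=phased,
    )
    panel = _sort_loci(panel)
    panel.validate()
    return panel


def _read_tped(path: Path, sample_meta, chrom_class_map) -> GenotypePanel:
    tfam = path.with_suffix(".tfam")
    fam_rows = []
    for ln, line in enumerate(tfam.read_text().splitlines(), 1):
        parts = line.split()
        if not parts:
            continue
        if len(parts) < 6:
            raise PanelFormatError(f"{tfam}:{ln}: expected 6 fields, got {len(parts)}")
        sex = {"1": "M", "2": "F"}.get(parts[4], "U")
        fam_rows.append((parts[1], parts[0], sex))
    samples = pd.DataFrame(fam_rows, columns=SAMPLE_COLUMNS)
    if sample_meta is not None:
        meta = _read_sample_meta(sample_meta).set_index("sample_id")
        samples = samples.set_index("sample_id")
        samples.update(meta)
        samples = samples.reset_index()
    if samples["sample_id"].duplicated().any():
        raise PanelFormatError(f"{tfam}: duplicated sample id")
    n = len(samples)

    loci_records: list[tuple] = []
    geno_cols: list[np.ndarray] = []
    n_multi = n_allmissing = 0
    for ln, line in enumerate(Path(path).read_text().splitlines(), 1):
        parts = line.split()
        if not parts:
            continue
        if len(parts) != 4 + 2 * n:
            raise PanelFormatError(
                f"{path}:{ln}: expected {4 + 2 * n} fields, got {len(parts)}"
            )
        chrom, snp_id, _cm, pos1 = parts[:4]
        alleles = np.array(parts[4:], dtype=object)
        obs = sorted(set(alleles) - {"0"})
        if len(obs) > 2:
            n_multi += 1
            continue
        if len(obs) == 0:
            n_allmissing += 1
            continue
        if len(obs) == 1:
            a_ref, a_alt = obs[0], _other_allele(obs[0])
        else:
            # tped carries no REF designation; orient the minor allele as
            # the counted B allele (PLINK A1 convention), ties by sort order
            c0 = int(np.sum(alleles == obs[0]))
            c1 = int(np.sum(alleles == obs[1]))
            a_ref, a_alt = (obs[0], obs[1]) if c1 <= c0 else (obs[1], obs[0])
        a0 = alleles[0::2]
        a1 = alleles[1::2]
        miss = (a0 == "0") | (a1 == "0")
        dose = ((a0 == a_alt).astype(np.int8) + (a1 == a_alt).astype(np.int8))
        dose[miss] = MISSING
        geno_cols.append(dose)
        loci_records.append((chrom, int(pos1) - 1, a_ref, a_alt))
    if n_multi or n_allmissing:
        logger.warning(
            "dropped %d multiallelic and %d all-missing sites from %s",
            n_multi, n_allmissing, path,
        )
    loci = _finalize_loci(loci_records, chrom_class_map)
    genotypes = np.column_stack(geno_cols) if geno_cols else np.empty((n, 0), np.int8)
    panel = GenotypePanel(loci=loci, samples=samples, genotypes=genotypes, phased=False)
    panel = _sort_loci(panel)
    panel.validate()
    return panel


def _other_allele(a: str) -> str:
    return "A" if a != "A" else "B"


def _sort_loci(panel: GenotypePanel) -> GenotypePanel:
    order = np.lexsort(
        (panel.loci["pos"].to_numpy(),
         pd.factorize(panel.loci["chrom"], sort=False)[0])
    )
    if np.array_equal(order, np.arange(len(order))):
        return panel
    return panel.subset_loci(order)


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------


def write_panel(panel: GenotypePanel, path: str | Path, format: str = "vcf") -> None:
    """Write a panel as VCF (plus ``<path>.samples.tsv``) or .tped/.tfam."""
    path = Path(path)
    if format == "vcf":
        _write_vcf(panel, path)
        panel.samples.to_csv(str(path) + ".samples.tsv", sep="\t", index=False)
    elif format == "tped":
        _write_tped(panel, path)
    else:
        raise ValueError(f"unknown panel format {format!r}")


def _write_vcf(panel: GenotypePanel, path: Path) -> None:
    sep = "|" if panel.phased else "/"
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom, sub in panel.loci.groupby("chrom", sort=False):
            fh.write(f"##contig=<ID={chrom},length={int(sub['pos'].max()) + 2}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(panel.samples["sample_id"]) + "\n"
        )
        hap = panel.haplotypes
        for l in range(panel.n_loci):
            row = panel.loci.iloc[l]
            if panel.phased and hap is not None:
                gts = [f"{hap[2 * s, l]}{sep}{hap[2 * s + 1, l]}" for s in range(panel.n_samples)]
            else:
                lut = {0: f"0{sep}0", 1: f"0{sep}1", 2: f"1{sep}1", MISSING: f".{sep}."}
                gts = [lut[int(g)] for g in panel.genotypes[:, l]]
            fh.write(
                f"{row.chrom}\t{row.pos + 1}\tsnp{l}\t{row.allele_a}\t{row.allele_b}"
                f"\t.\tPASS\t.\tGT\t" + "\t".join(gts) + "\n"
            )


def _write_tped(panel: GenotypePanel, path: Path) -> None:
    path = Path(path)
    sexcode = {"M": "1", "F": "2"}
    with open(path.with_suffix(".tfam"), "w") as fh:
        for _, s in panel.samples.iterrows():
            fh.write(f"{s.breed} {s.sample_id} 0 0 {sexcode.get(s.sex, '0')} -9\n")
    with open(path, "w") as fh:
        for l in range(panel.n_loci):
            row = panel.loci.iloc[l]
            fields = [str(row.chrom), f"snp{l}", "0", str(row.pos + 1)]
            for g in panel.genotypes[:, l]:
                if g == MISSING:
                    fields += ["0", "0"]
                elif g == 0:
                    fields += [row.allele_a, row.allele_a]
                elif g == 1:
                    fields += [row.allele_a, row.allele_b]
                else:
                    fields += [row.allele_b, row.allele_b]
            fh.write(" ".join(fields) + "\n")


def panel_from_arrays(
    loci: pd.DataFrame | Iterable[Locus],
    samples: pd.DataFrame | Iterable[tuple],
    genotypes: np.ndarray,
    haplotypes: np.ndarray | None = None,
    phased: bool = False,
) -> GenotypePanel:
    """Convenience constructor accepting plain sequences; validates."""
    if not isinstance(loci, pd.DataFrame):
        loci = pd.DataFrame(
            [(l.chrom, l.pos, l.allele_a, l.allele_b, l.chrom_class) for l in loci],
            columns=LOCI_COLUMNS,
        )
    if not isinstance(samples, pd.DataFrame):
        samples = pd.DataFrame(list(samples), columns=SAMPLE_COLUMNS)
    panel = GenotypePanel(
        loci=loci.reset_index(drop=True),
        samples=samples.reset_index(drop=True),
        genotypes=np.asarray(genotypes, dtype=np.int8),
        haplotypes=None if haplotypes is None else np.asarray(haplotypes, dtype=np.int8),
        phased=phased,
    )
    panel.validate()
    return panel
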