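import numpy as np
import pandas as pd
import pytest

import sweepscan as ss


def build_panel(genotypes, breeds, positions=None, chrom="chr1", haplotypes=None,
                phased=False, sexes=None, chrom_class="autosome"):
    """Small-panel constructor for hand-built fixtures."""
    genotypes = np.asarray(genotypes, dtype=np.int8)
    n_samples, n_loci = genotypes.shape
    positions = list(range(0, 10 * n_loci, 10)) if positions is None else positions
    loci = pd.DataFrame(
        {
            "chrom": chrom if isinstance(chrom, str) else list(chrom),
            "pos": positions,
            "allele_a": "A",
            "allele_b": "B",
            "chrom_class": chrom_class if isinstance(chrom_class, str) else list(chrom_class),
        }
    )
    sexes = ["F"] * n_samples if sexes is None else sexes
    samples = pd.DataFrame(
        {
            "sample_id": [f"s{i}" for i in range(n_samples)],
            "breed": list(breeds),
            "sex": sexes,
        }
    )
    return ss.panel_from_arrays(loci, samples, genotypes,
                                haplotypes=haplotypes, phased=phased)


def random_panel(rng, n_breeds=4, n_per_breed=6, n_loci=60, missing_rate=0.0,
                 n_chroms=2):
    """Random unstructured diploid panel (uniform allele frequencies)."""
    n = n_breeds * n_per_breed
    freqs = rng.uniform(0.05, 0.95, size=n_loci)
    geno = (rng.random((n, n_loci)) < freqs).astype(np.int8) + (
        rng.random((n, n_loci)) < freqs
    ).astype(np.int8)
    if missing_rate:
        geno[rng.random((n, n_loci)) < missing_rate] = -1
    breeds = [f"b{k}" for k in range(n_breeds) for _ in range(n_per_breed)]
    per = n_loci // n_chroms
    chroms = [f"chr{c + 1}" for c in range(n_chroms) for _ in range(per)]
    chroms += [f"chr{n_chroms}"] * (n_loci - len(chroms))
    pos = []
    start = 0
    cur = chroms[0]
    p = 0
    for c in chroms:
        if c != cur:
            cur = c
            p = 0
        pos.append(p)
        p += int(rng.integers(5_000, 40_000))
    return build_panel(geno, breeds, positions=pos, chrom=chroms)


@pytest.fixture(scope="session")
def sim_panel():
    """A small ascertained neutral panel under the default demographic model."""
    model = ss.DemographicModel()
    breeds = [(f"b{i}", 8, 0.01) for i in range(4)]
    panel = ss.simulate_neutral_panel(
        model, breeds, [("autosome", 2_500_000)] * 2, seed=42
    )
    return ss.ascertainment_match(panel, seed=43)
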