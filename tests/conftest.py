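"""Shared fixtures: small simulated populations reused across test modules."""

import numpy as np
import pandas as pd
import pytest

from gpsel import (
    GenotypePanel,
    SimConfig,
    TraitArchitecture,
    simulate_genotypes,
    simulate_traits,
)


@pytest.fixture(scope="session")
def small_panel():
    """300 individuals x (3 x 300) SNPs with LD and sib families."""
    cfg = SimConfig(n_individuals=300, n_chromosomes=3, snps_per_chromosome=300,
                    chip_fraction=0.2, seed=11)
    return simulate_genotypes(cfg)


@pytest.fixture(scope="session")
def small_traits(small_panel):
    pheno, truth = simulate_traits(small_panel, TraitArchitecture(), seed=12)
    return pheno, truth


def manual_panel(dosages, chrom=None, pos=None, dr2=None, ids=None, tag="wgs"):
    """Construct a panel from an explicit dosage matrix (test helper)."""
    dosages = np.asarray(dosages, float)
    n, m = dosages.shape
    chrom = ["1"] * m if chrom is None else [str(c) for c in chrom]
    if pos is None:
        pos, counters = [], {}
        for c in chrom:
            counters[c] = counters.get(c, 0) + 100
            pos.append(counters[c])
    snp_map = pd.DataFrame({
        "id": [f"s{j}" for j in range(m)],
        "chrom": chrom,
        "pos": pos,
        "a1": "B",
        "a2": "A",
        "dr2": 1.0 if dr2 is None else dr2,
    })
    return GenotypePanel(
        ids=np.array([f"i{i}" for i in range(n)], dtype=object) if ids is None else np.asarray(ids, dtype=object),
        dosages=dosages,
        snp_map=snp_map,
        tag=tag,
    )


@pytest.fixture
def make_panel():
    return manual_panel
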