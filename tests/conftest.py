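import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # makes _oracles importable

from introscan.genotype_io import MISSING, GenotypeMatrix


def make_random_matrix(rng: np.random.Generator, n_sites: int, n_samples: int,
                       missing_rate: float = 0.1, n_chroms: int = 2) -> GenotypeMatrix:
    """Random valid GenotypeMatrix (sorted sites, biallelic SNPs, missing data)."""
    bases = np.array(list("ACGT"), dtype=object)
    chrom_labels = [f"chr{i + 1}" for i in range(n_chroms)]
    per_chrom = np.sort(rng.choice(n_chroms, size=n_sites))
    pos = np.empty(n_sites, dtype=np.int64)
    for c in range(n_chroms):
        mask = per_chrom == c
        k = int(mask.sum())
        pos[mask] = np.sort(rng.choice(np.arange(1, 10 * n_sites + 2), size=k, replace=False))
    ref_idx = rng.integers(0, 4, size=n_sites)
    alt_idx = (ref_idx + rng.integers(1, 4, size=n_sites)) % 4
    dos = rng.integers(0, 3, size=(n_sites, n_samples)).astype(np.int8)
    dos[rng.random((n_sites, n_samples)) < missing_rate] = MISSING
    return GenotypeMatrix(
        chrom=np.array([chrom_labels[c] for c in per_chrom], dtype=object),
        pos=pos,
        ref=bases[ref_idx],
        alt=bases[alt_idx],
        dosages=dos,
        sample_ids=tuple(f"s{i:02d}" for i in range(n_samples)),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20260926)


@pytest.fixture(scope="session")
def small_fixture(tmp_path_factory):
    """On-disk synthetic fixture: 2000 sites, 5 marine + 5 freshwater."""
    from introscan.simulate import SimParams, write_fixture

    out = tmp_path_factory.mktemp("fixture")
    params = SimParams(seed=7)
    paths = write_fixture(params, out)
    return params, paths
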