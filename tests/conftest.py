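import numpy as np
import pytest

from feralscan.core_io import GenotypeMatrix
from feralscan.simdata import ScenarioConfig, emit_cohort


def small_config(seed: int = 11) -> ScenarioConfig:
    """Default study conditions on a reduced genome (fast unit tests)."""
    return ScenarioConfig(
        contig_lengths={"chr1": 1_000_000, "chr2": 1_000_000},
        sweep_intervals=[("chr1", 350_000, 650_000, "weed_dedom")],
        seed=seed,
    )


def random_gm(rng, n_samples=6, n_sites=40, miss_frac=0.1,
              chroms=("1",)) -> GenotypeMatrix:
    """Random valid genotype matrix for oracle comparisons."""
    per = n_sites // len(chroms)
    chrom, pos = [], []
    for c in chroms:
        p = np.sort(rng.choice(np.arange(1, 10 * per + 1), size=per, replace=False))
        chrom.extend([c] * per)
        pos.extend(p.tolist())
    n_sites = len(pos)
    geno = rng.integers(0, 3, size=(n_samples, n_sites)).astype(np.int8)
    miss = rng.random((n_samples, n_sites)) < miss_frac
    geno[miss] = -1
    bases = np.array(list("ACGT"), dtype=object)
    ref = bases[rng.integers(0, 4, size=n_sites)]
    alt = np.array(
        ["ACGT"[("ACGT".index(r) + int(s)) % 4]
         for r, s in zip(ref, rng.integers(1, 4, size=n_sites))],
        dtype=object,
    )
    samples = [f"s{i}" for i in range(n_samples)]
    return GenotypeMatrix(samples, np.array(chrom, dtype=object),
                          np.array(pos), ref, alt, geno)


@pytest.fixture(scope="session")
def small_cohort():
    return emit_cohort(small_config())


@pytest.fixture(scope="session")
def default_cohort():
    return emit_cohort(ScenarioConfig(seed=17))


@pytest.fixture(scope="session")
def replicate_cohorts():
    """Ten replicate cohorts at the default study conditions."""
    return [emit_cohort(ScenarioConfig(seed=100 + i)) for i in range(10)]
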