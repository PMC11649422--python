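import numpy as np
import pytest

from snppanel import GenotypeMatrix, LocusInfo, SimConfig, simulate


def random_matrix(seed: int, n_varieties: int = 12, n_loci: int = 25) -> GenotypeMatrix:
    """A small random but valid genotype matrix (with some missing calls)."""
    rng = np.random.default_rng(seed)
    bases = "ACGT"
    loci = []
    pos_used: set[tuple[str, int]] = set()
    for j in range(n_loci):
        chrom = f"chr{rng.integers(1, 13)}"
        pos = int(rng.integers(1, 10_000))
        while (chrom, pos) in pos_used:
            pos = int(rng.integers(1, 10_000))
        pos_used.add((chrom, pos))
        ref = bases[rng.integers(0, 4)]
        alt = bases[(bases.index(ref) + int(rng.integers(1, 4))) % 4]
        loci.append(LocusInfo(id=f"s{seed}_m{j}", chrom=chrom, pos=pos,
                              ref_allele=ref, alt_allele=alt))
    calls = rng.integers(-1, 3, size=(n_varieties, n_loci)).astype(np.int8)
    varieties = [f"v{i}" for i in range(n_varieties)]
    return GenotypeMatrix(varieties=varieties, loci=loci, calls=calls)


@pytest.fixture(scope="session")
def small_sim():
    """A 40-variety simulated panel with planted duplicates, no missingness."""
    config = SimConfig(
        n_varieties=40, n_loci=120, k_subpops=3, missing_rate=0.0,
        n_duplicates=2, n_near_duplicates=1, seed=11,
    )
    return simulate(config)
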