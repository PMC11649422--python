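"""Synthetic genotype panels with known truth.

Emulates the data shape of a crop germplasm fingerprinting study: N
diploid varieties (default 418) genotyped at L biallelic loci spread over
12 chromosomes, with K subpopulations (default 6). Per-locus ancestral
allele frequencies are drawn uniformly from ``maf_range``; subpopulation
frequencies follow the Balding-Nichols model with differentiation ``fst``;
each variety draws an admixture vector (Dirichlet) and its genotypes are
sampled under Hardy-Weinberg equilibrium from the admixture-weighted
frequency. Planted exact and near duplicates, uniform missingness, and
position clusters violating the 100-bp flank rule exercise every
downstream stage.

Each concern (frequencies, positions, genotypes, duplicates, missingness,
reference sequence) draws from its own child stream of the master seed, so
changing one dimension of the configuration does not perturb the others.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .model import (
    DEFAULT_CHROMOSOMES,
    GenotypeMatrix,
    HET,
    HOM_ALT,
    HOM_REF,
    LocusInfo,
    MISSING,
)


class SimConfigError(ValueError):
    """Infeasible simulation configuration."""


@dataclass
class SimConfig:
    """Generator parameters; defaults mirror the study conditions."""

    n_varieties: int = 418
    n_loci: int = 1000
    n_chrom: int = 12
    k_subpops: int = 6
    fst: float = 0.1
    maf_range: tuple[float, float] = (0.05, 0.5)
    missing_rate: float = 0.01
    n_duplicates: int = 0
    n_near_duplicates: int = 0
    cluster_fraction: float = 0.1
    admixture_alpha: float = 0.1
    flank_bp: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.fst < 1:
            raise SimConfigError("fst must lie in [0, 1)")
        if not 0 <= self.missing_rate <= 1 or not 0 <= self.cluster_fraction <= 1:
            raise SimConfigError("rates must lie in [0, 1]")
        lo, hi = self.maf_range
        if not 0 < lo <= hi <= 0.5:
            raise SimConfigError("maf_range must satisfy 0 < low <= high <= 0.5")
        if 2 * (self.n_duplicates + self.n_near_duplicates) > self.n_varieties:
            raise SimConfigError("too many planted duplicate pairs for n_varieties")
        if self.n_chrom < 1 or self.k_subpops < 1:
            raise SimConfigError("n_chrom and k_subpops must be positive")
        per_chrom = self.n_loci // self.n_chrom
        if self.cluster_fraction > 0 and per_chrom < 2:
            raise SimConfigError("cluster_fraction needs >= 2 loci per chromosome")


@dataclass
class SyntheticTruth:
    """Ground truth recorded by the generator for recovery tests."""

    config: SimConfig
    ancestral_freqs: np.ndarray
    subpop_freqs: np.ndarray
    admixture: np.ndarray
    duplicate_pairs: list[tuple[str, str]] = field(default_factory=list)
    near_duplicate_pairs: list[tuple[str, str]] = field(default_factory=list)


def _positions(
    rng: np.random.Generator, m: int, cluster_fraction: float, flank_bp: int
) -> np.ndarray:
    """1-based positions for one chromosome.

    Anchor sites are spaced > 2*flank_bp apart; a fraction of loci is
    planted as close pairs (second member within flank_bp of its anchor),
    so roughly ``cluster_fraction * m`` loci violate the flank rule while
    the rest pass it.
    """
    n_pairs = int(round(cluster_fraction * m / 2))
    n_anchor = m - n_pairs
    gaps = rng.integers(2 * flank_bp + 2, 20 * flank_bp, size=n_anchor)
    anchors = np.cumsum(gaps)
    partners = anchors[:n_pairs] + rng.integers(1, flank_bp + 1, size=n_pairs)
    return np.sort(np.concatenate([anchors, partners]))


def simulate(
    config: SimConfig,
) -> tuple[GenotypeMatrix, SyntheticTruth, dict[str, str]]:
    """Generate a genotype matrix, its truth record, and a reference.

    Returns ``(matrix, truth, reference)`` where ``reference`` maps each
    chromosome name to an i.i.d.-uniform ACGT sequence with the catalogued
    reference alleles substituted at their positions. Fully reproducible
    from ``config.seed``.
    """
    streams = np.random.SeedSequence(config.seed).spawn(6)
    rng_freq, rng_pos, rng_geno, rng_dup, rng_miss, rng_ref = (
        np.random.default_rng(s) for s in streams
    )
    N, L, K = config.n_varieties, config.n_loci, config.k_subpops

    # Variant catalogue: positions, alleles, ids.
    chroms = (
        DEFAULT_CHROMOSOMES[: config.n_chrom]
        if config.n_chrom <= len(DEFAULT_CHROMOSOMES)
        else tuple(f"chr{i}" for i in range(1, config.n_chrom + 1))
    )
    per_chrom = [L // config.n_chrom] * config.n_chrom
    for i in range(L % config.n_chrom):
        per_chrom[i] += 1
    loci: list[LocusInfo] = []
    bases = np.array(list("ACGT"))
    for c, chrom in enumerate(chroms):
        positions = _positions(rng_pos, per_chrom[c], config.cluster_fraction, config.flank_bp)
        ref_idx = rng_pos.integers(0, 4, size=per_chrom[c])
        alt_shift = rng_pos.integers(1, 4, size=per_chrom[c])
        for j, pos in enumerate(positions):
            loci.append(
                LocusInfo(
                    id=f"{chrom}_m{j + 1}",
                    chrom=chrom,
                    pos=int(pos),
                    ref_allele=str(bases[ref_idx[j]]),
                    alt_allele=str(bases[(ref_idx[j] + alt_shift[j]) % 4]),
                )
            )

    # Allele frequencies: ancestral ~ U(maf_range), subpops ~ Balding-Nichols.
    ancestral = rng_freq.uniform(config.maf_range[0], config.maf_range[1], size=L)
    if config.fst > 0:
        theta = (1.0 - config.fst) / config.fst
        subpop = rng_freq.beta(
            np.broadcast_to(ancestral * theta, (K, L)),
            np.broadcast_to((1.0 - ancestral) * theta, (K, L)),
        )
        subpop = np.clip(subpop, 1e-12, 1 - 1e-12)
    else:
        subpop = np.broadcast_to(ancestral, (K, L)).copy()

    # Admixture: each variety leans on a home subpopulation (round-robin),
    # with Dirichlet noise controlled by admixture_alpha.
    alpha = np.full(K, config.admixture_alpha)
    home = np.arange(N) % K
    admixture = np.empty((N, K))
    for i in range(N):
        a = alpha.copy()
        a[home[i]] += 1.0
        admixture[i] = rng_geno.dirichlet(a)

    # Genotypes under HWE at each variety's admixture-weighted frequency.
    freq = admixture @ subpop  # (N, L) alt-allele frequency per variety
    calls = rng_geno.binomial(2, freq).astype(np.int8)

    varieties = [f"V{i + 1:04d}" for i in range(N)]

    # Planted duplicates: copy rows before missingness is applied.
    dup_pairs: list[tuple[str, str]] = []
    near_pairs: list[tuple[str, str]] = []
    cursor = N - 2 * (config.n_duplicates + config.n_near_duplicates)
    for _ in range(config.n_duplicates):
        a, b = cursor, cursor + 1
        calls[b] = calls[a]
        dup_pairs.append((varieties[a], varieties[b]))
        cursor += 2
    for _ in range(config.n_near_duplicates):
        a, b = cursor, cursor + 1
        calls[b] = calls[a]
        j = int(rng_dup.integers(0, L))
        calls[b, j] = (calls[a, j] + 1 + int(rng_dup.integers(0, 2))) % 3
        near_pairs.append((varieties[a], varieties[b]))
        cursor += 2

    if config.missing_rate > 0:
        mask = rng_miss.random((N, L)) < config.missing_rate
        calls[mask] = MISSING

    matrix = GenotypeMatrix(
        varieties=varieties, loci=loci, calls=calls, chrom_order=chroms
    )
    truth = SyntheticTruth(
        config=config,
        ancestral_freqs=ancestral,
        subpop_freqs=subpop,
        admixture=admixture,
        duplicate_pairs=dup_pairs,
        near_duplicate_pairs=near_pairs,
    )

    reference: dict[str, str] = {}
    for chrom in chroms:
        chrom_loci = [l for l in loci if l.chrom == chrom]
        length = max(l.pos for l in chrom_loci) + config.flank_bp + 50
        seq = rng_ref.integers(0, 4, size=length)
        seq_arr = bases[seq].copy()
        for l in chrom_loci:
            seq_arr[l.pos - 1] = l.ref_allele
        reference[chrom] = "".join(seq_arr)
    return matrix, truth, reference


def toy_fixture() -> tuple[GenotypeMatrix, list[str], list[str]]:
    """A small deterministic matrix with hand-checkable screening outcomes.

    Returns ``(matrix, expected_survivors, expected_minimal_panel)``:
    a 16-variety x 12-locus matrix on 2 chromosomes where loci are planted
    to fail specific screening criteria, leaving a known survivor list, and
    the greedy minimal panel over the survivors is pinned. Regenerating the
    fixture is byte-identical (pure construction, no randomness).
    """
    chroms = ("chr1", "chr2")
    N = 16

    def locus(i: int, chrom: str, pos: int, ref="A", alt="G") -> LocusInfo:
        return LocusInfo(id=f"L{i:02d}", chrom=chrom, pos=pos, ref_allele=ref, alt_allele=alt)

    loci = [
        locus(1, "chr1", 1_000),          # survivor
        locus(2, "chr1", 2_000),          # survivor
        locus(3, "chr1", 3_000),          # fails MAF (mostly ref)
        locus(4, "chr1", 4_000),          # fails HWE (no hets)
        locus(5, "chr1", 5_000),          # fails missingness
        locus(6, "chr1", 6_050),          # fails flank: 50 bp from L07
        locus(7, "chr1", 6_100),          # fails flank
        locus(8, "chr2", 1_000),          # survivor
        locus(9, "chr2", 2_000),          # survivor
        locus(10, "chr2", 3_000),         # fails MAF (monomorphic)
        locus(11, "chr2", 4_000),         # fails HWE
        locus(12, "chr2", 5_000),         # survivor (redundant with L01)
    ]
    cols = {
        # Survivors: MAF 0.5, HWE-exact proportions (4, 8, 4) over 16.
        "L01": [0] * 4 + [1] * 8 + [2] * 4,
        "L02": [0] * 2 + [1] * 4 + [2] * 2 + [0] * 2 + [1] * 4 + [2] * 2,
        "L03": [0] * 15 + [2],
        "L04": [0] * 8 + [2] * 8,
        "L05": [-1] + [0] * 3 + [1] * 8 + [2] * 4,
        "L06": [0] * 4 + [1] * 8 + [2] * 4,
        "L07": [2] * 4 + [1] * 8 + [0] * 4,
        "L08": [1] * 8 + [0] * 4 + [2] * 4,
        "L09": [0, 1, 2, 1] * 4,
        "L10": [0] * 16,
        "L11": [2] * 8 + [0] * 8,
        "L12": [0] * 4 + [1] * 8 + [2] * 4,
    }
    calls = np.array([cols[l.id] for l in loci], dtype=np.int8).T
    matrix = GenotypeMatrix(
        varieties=[f"T{i + 1:02d}" for i in range(N)],
        loci=loci,
        calls=calls,
        chrom_order=chroms,
    )
    expected_survivors = ["L01", "L02", "L08", "L09", "L12"]
    # Greedy selection order over the survivors; verified against the
    # exhaustive search in the tests (same size, full coverage).
    expected_panel = ["L01", "L09", "L02", "L08"]
    return matrix, expected_survivors, expected_panel
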