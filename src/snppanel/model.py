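"""Shared data model for diploid biallelic SNP genotype panels.

Genotypes are stored as an N varieties x L loci ``int8`` matrix of codes:
``0`` = homozygous reference, ``1`` = heterozygous, ``2`` = homozygous
alternate, ``-1`` = missing. Calls are unordered and unphased; phase is
discarded on input. Coordinates are 1-based inclusive throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

MISSING: int = -1
HOM_REF: int = 0
HET: int = 1
HOM_ALT: int = 2

NUCLEOTIDES = frozenset("ACGT")

#: Default declared chromosome order (tomato has 12 chromosomes).
DEFAULT_CHROMOSOMES: tuple[str, ...] = tuple(f"chr{i}" for i in range(1, 13))


class GenotypeDataError(ValueError):
    """Invalid genotype data, locus catalogue, or file contents."""


@dataclass(frozen=True)
class LocusInfo:
    """A catalogued biallelic SNP: identifier, position, and allele pair."""

    id: str
    chrom: str
    pos: int
    ref_allele: str
    alt_allele: str

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise GenotypeDataError(f"locus {self.id}: pos must be >= 1, got {self.pos}")
        for name, allele in (("ref", self.ref_allele), ("alt", self.alt_allele)):
            if allele not in NUCLEOTIDES:
                raise GenotypeDataError(
                    f"locus {self.id}: {name} allele {allele!r} is not a single nucleotide"
                )
        if self.ref_allele == self.alt_allele:
            raise GenotypeDataError(f"locus {self.id}: ref and alt alleles are identical")

    def genotype_string(self, code: int) -> str:
        """Render a genotype code as an unordered allele pair, e.g. ``"A/G"``.

        Alleles within a heterozygous call are sorted alphabetically; a
        missing call renders as ``"NA"``.
        """
        if code == MISSING:
            return "NA"
        if code == HOM_REF:
            return f"{self.ref_allele}/{self.ref_allele}"
        if code == HOM_ALT:
            return f"{self.alt_allele}/{self.alt_allele}"
        if code == HET:
            a, b = sorted((self.ref_allele, self.alt_allele))
            return f"{a}/{b}"
        raise GenotypeDataError(f"invalid genotype code {code}")

    def parse_genotype(self, cell: str) -> int:
        """Parse an ``"A/G"``-style cell (order-insensitive) into a code."""
        cell = cell.strip()
        if cell in ("NA", "N/N", "NN", "./.", ".", ""):
            return MISSING
        parts = cell.split("/")
        if len(parts) != 2:
            raise GenotypeDataError(f"locus {self.id}: malformed genotype cell {cell!r}")
        alleles = frozenset(parts)
        valid = {self.ref_allele, self.alt_allele}
        if not alleles <= valid:
            raise GenotypeDataError(
                f"locus {self.id}: alleles {cell!r} not in locus alleles "
                f"{self.ref_allele}/{self.alt_allele}"
            )
        if len(alleles) == 2:
            return HET
        return HOM_REF if parts[0] == self.ref_allele else HOM_ALT


def _chrom_rank(chrom_order: Sequence[str]) -> dict[str, int]:
    return {c: i for i, c in enumerate(chrom_order)}


def sort_loci(
    loci: Sequence[LocusInfo], chrom_order: Sequence[str]
) -> list[int]:
    """Indices that sort loci by declared chromosome order, then position."""
    rank = _chrom_rank(chrom_order)
    return sorted(range(len(loci)), key=lambda i: (rank[loci[i].chrom], loci[i].pos))


@dataclass
class GenotypeMatrix:
    """N diploid varieties genotyped at L biallelic loci.

    Parameters
    ----------
    varieties : ordered unique variety labels (length N).
    loci : ordered :class:`LocusInfo` list (length L); (chrom, pos) unique.
    calls : int8 array of shape (N, L) with codes in {-1, 0, 1, 2}.
    chrom_order : declared ordered chromosome labels. Defaults to
        ``chr1``..``chr12``; if any locus uses another label the order of
        first appearance in ``loci`` is declared instead. Labels are opaque
        strings — no numeric parsing.
    """

    varieties: list[str]
    loci: list[LocusInfo]
    calls: np.ndarray
    chrom_order: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        self.varieties = list(self.varieties)
        self.loci = list(self.loci)
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if len(set(self.varieties)) != len(self.varieties):
            raise GenotypeDataError("variety labels are not unique")
        keys = {(l.chrom, l.pos) for l in self.loci}
        if len(keys) != len(self.loci):
            raise GenotypeDataError("(chrom, pos) pairs are not unique in the catalogue")
        if self.calls.shape != (len(self.varieties), len(self.loci)):
            raise GenotypeDataError(
                f"calls shape {self.calls.shape} does not match "
                f"{len(self.varieties)} varieties x {len(self.loci)} loci"
            )
        bad = ~np.isin(self.calls, (MISSING, HOM_REF, HET, HOM_ALT))
        if bad.any():
            raise GenotypeDataError("calls contain invalid genotype codes")
        if not self.chrom_order:
            present = {l.chrom for l in self.loci}
            if present <= set(DEFAULT_CHROMOSOMES):
                self.chrom_order = DEFAULT_CHROMOSOMES
            else:
                seen: list[str] = []
                for l in self.loci:
                    if l.chrom not in seen:
                        seen.append(l.chrom)
                self.chrom_order = tuple(seen)
        else:
            self.chrom_order = tuple(self.chrom_order)
            missing = {l.chrom for l in self.loci} - set(self.chrom_order)
            if missing:
                raise GenotypeDataError(
                    f"loci use chromosomes outside the declared order: {sorted(missing)}"
                )

    @property
    def n_varieties(self) -> int:
        return len(self.varieties)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    @property
    def locus_ids(self) -> list[str]:
        return [l.id for l in self.loci]

    def locus_index(self, locus_ids: Sequence[str]) -> np.ndarray:
        """Column indices for the given locus ids (order preserved)."""
        lookup = {l.id: i for i, l in enumerate(self.loci)}
        try:
            return np.array([lookup[i] for i in locus_ids], dtype=np.intp)
        except KeyError as exc:
            raise GenotypeDataError(f"unknown locus id {exc.args[0]!r}") from None

    def subset_loci(self, locus_ids: Sequence[str]) -> "GenotypeMatrix":
        """A new matrix restricted to the given loci, in the given order."""
        idx = self.locus_index(locus_ids)
        return GenotypeMatrix(
            varieties=list(self.varieties),
            loci=[self.loci[i] for i in idx],
            calls=self.calls[:, idx].copy(),
            chrom_order=self.chrom_order,
        )

    def sorted_by_position(self) -> "GenotypeMatrix":
        """Loci reordered by (declared chromosome order, position)."""
        order = sort_loci(self.loci, self.chrom_order)
        return GenotypeMatrix(
            varieties=list(self.varieties),
            loci=[self.loci[i] for i in order],
            calls=self.calls[:, order].copy(),
            chrom_order=self.chrom_order,
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenotypeMatrix):
            return NotImplemented
        return (
            self.varieties == other.varieties
            and self.loci == other.loci
            and np.array_equal(self.calls, other.calls)
        )
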