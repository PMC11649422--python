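"""KASP submission-sheet preparation.

For each panel SNP, the flanking sequence on each side of the variant is
taken from the reference (trimmed to ``flank_bp`` bases, 100 by default)
and the site is written in the conventional bracketed-allele submission
format ``LEFT[REF/ALT]RIGHT``, always on the reference forward strand.
Each record also carries a flank-uniqueness verdict against the full
variant catalogue, since assays with a second polymorphism inside the
flank genotype unreliably.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

from pyfaidx import Fasta

from .filtering import flank_unique
from .model import GenotypeDataError, LocusInfo


@dataclass
class KaspRecord:
    """One SNP's bracketed flanking sequence and QC flags."""

    locus_id: str
    chrom: str
    pos: int
    sequence: str
    flank_clean: bool
    truncated: bool = False
    error: str | None = None


def _load_reference(reference) -> Mapping[str, str]:
    if isinstance(reference, (str, bytes)):
        fasta = Fasta(str(reference), as_raw=True, sequence_always_upper=True)
        return {name: str(fasta[name][:]) for name in fasta.keys()}
    return {k: v.upper() for k, v in reference.items()}


def extract_flanks(
    reference,
    loci: Sequence[LocusInfo],
    catalogue: Sequence[LocusInfo] | None = None,
    flank_bp: int = 100,
) -> list[KaspRecord]:
    """Build KASP records for each locus from a reference.

    Parameters
    ----------
    reference : FASTA path or mapping of chromosome name -> sequence.
    loci : panel loci to prepare.
    catalogue : full pre-filter variant list for the flank-clean verdict;
        defaults to ``loci`` itself.
    flank_bp : bases kept on each side; flanks are truncated (and flagged)
        at contig ends.

    A reference base disagreeing with the locus's reference allele yields a
    per-locus error record rather than aborting; an absent chromosome
    raises.
    """
    seqs = _load_reference(reference)
    catalogue = list(catalogue) if catalogue is not None else list(loci)
    clean = flank_unique(catalogue, flank_bp)
    records: list[KaspRecord] = []
    for locus in loci:
        if locus.chrom not in seqs:
            raise GenotypeDataError(f"chromosome {locus.chrom!r} absent from reference")
        seq = seqs[locus.chrom]
        if locus.pos > len(seq):
            raise GenotypeDataError(
                f"locus {locus.id}: pos {locus.pos} beyond contig end ({len(seq)} bp)"
            )
        ref_base = seq[locus.pos - 1]
        if ref_base != locus.ref_allele:
            records.append(
                KaspRecord(
                    locus_id=locus.id, chrom=locus.chrom, pos=locus.pos, sequence="",
                    flank_clean=locus.id in clean,
                    error=f"reference base {ref_base} != ref allele {locus.ref_allele}",
                )
            )
            continue
        left = seq[max(0, locus.pos - 1 - flank_bp) : locus.pos - 1]
        right = seq[locus.pos : locus.pos + flank_bp]
        records.append(
            KaspRecord(
                locus_id=locus.id,
                chrom=locus.chrom,
                pos=locus.pos,
                sequence=f"{left}[{locus.ref_allele}/{locus.alt_allele}]{right}",
                flank_clean=locus.id in clean,
                truncated=len(left) < flank_bp or len(right) < flank_bp,
            )
        )
    return records


def write_kasp_sheet(records: Sequence[KaspRecord], path: str) -> None:
    """Tab-delimited KASP submission sheet."""
    with open(path, "w") as fh:
        fh.write("locus_id\tchrom\tpos\tsequence\tflank_clean\ttruncated\terror\n")
        for r in records:
            fh.write(
                f"{r.locus_id}\t{r.chrom}\t{r.pos}\t{r.sequence}\t"
                f"{r.flank_clean}\t{r.truncated}\t{r.error or ''}\n"
            )
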