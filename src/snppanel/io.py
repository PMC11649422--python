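"""Genotype I/O: VCF v4.2 (via pysam) and a delimited genotype-table dialect.

The genotype table is lossless: one row per variety, one column per marker,
cells like ``A/G`` (unordered) or ``NA``. Column headers carry the locus
catalogue as ``id:chrom:pos:ref:alt`` so a table round-trips without a
sidecar file.
"""

from __future__ import annotations

import logging
from typing import Sequence

import numpy as np
import pysam

from .model import (
    GenotypeDataError,
    GenotypeMatrix,
    HET,
    HOM_ALT,
    HOM_REF,
    LocusInfo,
    MISSING,
    sort_loci,
)

logger = logging.getLogger(__name__)


def read_vcf(path: str, *, on_multiallelic: str = "drop") -> GenotypeMatrix:
    """Read a multi-sample VCF into a :class:`GenotypeMatrix`.

    Only biallelic SNP records are retained; indels are skipped and counted.
    ``./.`` and ``.`` genotypes map to missing; phased separators are read
    as unphased.

    Parameters
    ----------
    path : VCF file path (plain text or bgzipped).
    on_multiallelic : ``"drop"`` (default, logged) or ``"error"``.
    """
    if on_multiallelic not in ("drop", "error"):
        raise ValueError("on_multiallelic must be 'drop' or 'error'")
    try:
        vcf = pysam.VariantFile(path)
    except (ValueError, OSError) as exc:
        raise GenotypeDataError(f"malformed or unreadable VCF {path}: {exc}") from exc
    with vcf:
        samples = list(vcf.header.samples)
        if not samples:
            raise GenotypeDataError(f"VCF {path} declares no samples")
        loci: list[LocusInfo] = []
        columns: list[np.ndarray] = []
        n_skipped_indel = 0
        n_skipped_multi = 0
        for rec in vcf:
            alts = rec.alts or ()
            if len(alts) > 1:
                if on_multiallelic == "error":
                    raise GenotypeDataError(
                        f"multiallelic record at {rec.chrom}:{rec.pos}"
                    )
                n_skipped_multi += 1
                continue
            if len(alts) == 0 or len(rec.ref) != 1 or len(alts[0]) != 1:
                n_skipped_indel += 1
                continue
            if rec.ref not in "ACGT" or alts[0] not in "ACGT":
                n_skipped_indel += 1
                continue
            col = np.empty(len(samples), dtype=np.int8)
            for i, sample in enumerate(samples):
                gt = rec.samples[sample].get("GT", (None, None))
                if gt is None or None in gt or len(gt) != 2:
                    col[i] = MISSING
                else:
                    col[i] = int(gt[0]) + int(gt[1])
            locus_id = rec.id if rec.id not in (None, ".") else f"{rec.chrom}_{rec.pos}"
            loci.append(
                LocusInfo(
                    id=locus_id,
                    chrom=rec.chrom,
                    pos=rec.pos,
                    ref_allele=rec.ref,
                    alt_allele=alts[0],
                )
            )
            columns.append(col)
    if n_skipped_indel:
        logger.info("read_vcf: skipped %d non-SNP records", n_skipped_indel)
    if n_skipped_multi:
        logger.warning("read_vcf: dropped %d multiallelic records", n_skipped_multi)
    calls = (
        np.stack(columns, axis=1)
        if columns
        else np.empty((len(samples), 0), dtype=np.int8)
    )
    return GenotypeMatrix(varieties=samples, loci=loci, calls=calls)


_GT_CODES = {HOM_REF: (0, 0), HET: (0, 1), HOM_ALT: (1, 1), MISSING: (None, None)}


def write_vcf(matrix: GenotypeMatrix, path: str) -> None:
    """Write a GT-only VCF v4.2, loci sorted by (chromosome order, position)."""
    m = matrix.sorted_by_position()
    header = pysam.VariantHeader()
    header.add_line('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    chrom_max: dict[str, int] = {}
    for locus in m.loci:
        chrom_max[locus.chrom] = max(chrom_max.get(locus.chrom, 0), locus.pos)
    for chrom in m.chrom_order:
        if chrom in chrom_max:
            header.contigs.add(chrom, length=chrom_max[chrom] + 1000)
    for v in m.varieties:
        header.add_sample(v)
    with pysam.VariantFile(path, "w", header=header) as out:
        for j, locus in enumerate(m.loci):
            rec = out.new_record(
                contig=locus.chrom,
                start=locus.pos - 1,
                stop=locus.pos,
                alleles=(locus.ref_allele, locus.alt_allele),
                id=locus.id,
            )
            for i, v in enumerate(m.varieties):
                rec.samples[v]["GT"] = _GT_CODES[int(m.calls[i, j])]
                rec.samples[v].phased = False
            out.write(rec)


def _detect_sep(header_line: str) -> str:
    return "\t" if "\t" in header_line else ","


def write_genotype_table(matrix: GenotypeMatrix, path: str, *, sep: str = "\t") -> None:
    """Write the delimited genotype-table dialect (header carries the catalogue)."""
    m = matrix.sorted_by_position()
    with open(path, "w") as fh:
        headers = ["variety"] + [
            f"{l.id}:{l.chrom}:{l.pos}:{l.ref_allele}:{l.alt_allele}" for l in m.loci
        ]
        fh.write(sep.join(headers) + "\n")
        for i, v in enumerate(m.varieties):
            cells = [m.loci[j].genotype_string(int(m.calls[i, j])) for j in range(m.n_loci)]
            fh.write(sep.join([v] + cells) + "\n")


def read_genotype_table(path: str, *, sep: str | None = None) -> GenotypeMatrix:
    """Read the genotype-table dialect written by :func:`write_genotype_table`.

    Raises a validation error naming the offending row and column when a
    cell uses alleles outside its locus's allele pair.
    """
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    if not lines:
        raise GenotypeDataError(f"empty genotype table {path}")
    if sep is None:
        sep = _detect_sep(lines[0])
    header = lines[0].split(sep)
    if header[0] != "variety":
        raise GenotypeDataError(f"genotype table {path}: first column must be 'variety'")
    loci: list[LocusInfo] = []
    for col in header[1:]:
        parts = col.split(":")
        if len(parts) != 5:
            raise GenotypeDataError(
                f"genotype table {path}: column header {col!r} is not id:chrom:pos:ref:alt"
            )
        loci.append(
            LocusInfo(
                id=parts[0], chrom=parts[1], pos=int(parts[2]),
                ref_allele=parts[3], alt_allele=parts[4],
            )
        )
    varieties: list[str] = []
    rows: list[list[int]] = []
    for ln in lines[1:]:
        cells = ln.split(sep)
        if len(cells) != len(loci) + 1:
            raise GenotypeDataError(
                f"genotype table {path}: row {cells[0]!r} has {len(cells) - 1} cells, "
                f"expected {len(loci)}"
            )
        varieties.append(cells[0])
        row: list[int] = []
        for j, cell in enumerate(cells[1:]):
            try:
                row.append(loci[j].parse_genotype(cell))
            except GenotypeDataError as exc:
                raise GenotypeDataError(
                    f"genotype table {path}: row {cells[0]!r}, column {loci[j].id!r}: {exc}"
                ) from None
        rows.append(row)
    calls = (
        np.array(rows, dtype=np.int8)
        if rows
        else np.empty((0, len(loci)), dtype=np.int8)
    )
    return GenotypeMatrix(varieties=varieties, loci=loci, calls=calls)


def write_fasta(sequences: dict[str, str], path: str, *, width: int = 70) -> None:
    """Write chromosome sequences as an uncompressed FASTA file."""
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")
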