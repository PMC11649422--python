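"""Per-locus marker statistics for biallelic SNPs.

Implements the screening statistics used in core-panel design: minor allele
frequency (MAF), polymorphic information content (PIC, Botstein biallelic
form), observed heterozygosity (Ho), gene diversity / expected
heterozygosity (He = 2p(1-p)), missingness, and a Hardy-Weinberg
equilibrium test (chi-square goodness of fit by default, exact enumeration
optionally).

All statistics are per-locus complete-case: missing calls are excluded
from every denominator.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import chi2

from .model import GenotypeMatrix, HET, HOM_ALT, HOM_REF, MISSING


class AllMissingError(ValueError):
    """A statistic was requested for a column with no non-missing calls."""


def genotype_counts(calls: np.ndarray) -> tuple[int, int, int]:
    """Counts (n_refref, n_het, n_altalt) for one locus column."""
    calls = np.asarray(calls)
    return (
        int(np.sum(calls == HOM_REF)),
        int(np.sum(calls == HET)),
        int(np.sum(calls == HOM_ALT)),
    )


def allele_freq(calls: np.ndarray) -> tuple[float, tuple[int, int, int]]:
    """Alternate-allele frequency and genotype-class counts for a column.

    Returns ``(p_alt, (n_refref, n_het, n_altalt))`` with missing calls
    excluded from the denominator. Raises :class:`AllMissingError` when the
    column holds no calls.
    """
    n_rr, n_het, n_aa = genotype_counts(calls)
    n_called = n_rr + n_het + n_aa
    if n_called == 0:
        raise AllMissingError("all calls missing: allele frequency undefined")
    p = (2 * n_aa + n_het) / (2 * n_called)
    return p, (n_rr, n_het, n_aa)


def maf(p: float) -> float:
    """Minor allele frequency from an allele frequency."""
    return min(p, 1.0 - p)


def pic(p):
    """Polymorphic information content of a biallelic locus.

    Botstein's PIC restricted to two alleles::

        PIC = 1 - (p^2 + q^2) - 2 p^2 q^2,   q = 1 - p

    Symmetric in p <-> q, strictly increasing in MAF, maximum 0.375 at
    p = 0.5. Accepts a scalar or array in [0, 1].
    """
    p = np.asarray(p, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("allele frequency must lie in [0, 1]")
    q = 1.0 - p
    out = 1.0 - (p**2 + q**2) - 2.0 * p**2 * q**2
    return float(out) if out.ndim == 0 else out


def heterozygosity(counts: tuple[int, int, int]) -> tuple[float, float]:
    """Observed heterozygosity and gene diversity from genotype counts.

    ``ho = n_het / n_called``; ``he = 2 p (1 - p)`` with p the alternate
    allele frequency implied by the counts.
    """
    n_rr, n_het, n_aa = counts
    n_called = n_rr + n_het + n_aa
    if n_called == 0:
        raise AllMissingError("all calls missing: heterozygosity undefined")
    p = (2 * n_aa + n_het) / (2 * n_called)
    return n_het / n_called, 2.0 * p * (1.0 - p)


def hwe_test(counts: tuple[int, int, int], *, method: str = "chisq") -> float:
    """Hardy-Weinberg equilibrium p-value from genotype-class counts.

    ``method="chisq"`` (default): chi-square goodness of fit against the
    expected classes ``(n p^2, 2 n p q, n q^2)`` on 1 df, no continuity
    correction. ``method="exact"``: full enumeration of the conditional
    distribution of heterozygote counts given allele counts, summing the
    probabilities of all outcomes no more probable than the observed one.
    Monomorphic loci return p = 1.
    """
    n_rr, n_het, n_aa = counts
    n = n_rr + n_het + n_aa
    if n == 0:
        raise AllMissingError("all calls missing: HWE test undefined")
    n_alt = 2 * n_aa + n_het
    if n_alt == 0 or n_alt == 2 * n:
        return 1.0
    if method == "chisq":
        p = n_alt / (2 * n)
        q = 1.0 - p
        expected = np.array([n * q * q, 2 * n * p * q, n * p * p])
        observed = np.array([n_rr, n_het, n_aa], dtype=float)
        stat = float(np.sum((observed - expected) ** 2 / expected))
        return float(chi2.sf(stat, df=1))
    if method == "exact":
        return _hwe_exact(n_het, min(n_alt, 2 * n - n_alt), n)
    raise ValueError(f"unknown HWE method {method!r}")


def _hwe_exact(n_het_obs: int, n_rare: int, n: int) -> float:
    """Exact HWE p-value by enumerating heterozygote counts.

    Conditional on ``n_rare`` copies of the rarer allele among ``2n``
    alleles, the heterozygote count ranges over values of matching parity;
    probabilities follow the standard recurrence, and the p-value sums all
    outcomes with probability <= that of the observed count.
    """
    het_values = list(range(n_rare % 2, n_rare + 1, 2))
    probs = np.zeros(len(het_values))
    # Unnormalised recurrence upward from the smallest heterozygote count.
    probs[0] = 1.0
    for k in range(1, len(het_values)):
        h = het_values[k - 1]
        n_hom_rare = (n_rare - h) // 2
        n_hom_common = n - h - n_hom_rare
        probs[k] = probs[k - 1] * 4.0 * n_hom_rare * n_hom_common / ((h + 1.0) * (h + 2.0))
        if probs[k] > 1e250:  # rescale to avoid overflow on large n
            probs /= probs[k]
    probs /= probs.sum()
    p_obs = probs[het_values.index(n_het_obs)]
    return float(min(1.0, probs[probs <= p_obs * (1 + 1e-12)].sum()))


def stats_table(
    matrix: GenotypeMatrix, *, hwe_method: str = "chisq"
) -> pd.DataFrame:
    """Per-locus statistics table for every locus in the matrix.

    Columns: ``locus_id, chrom, pos, n_called, n_missing, maf, pic, ho,
    he, hwe_p``, one row per locus in matrix order. Loci with no calls get
    NaN statistics.
    """
    calls = matrix.calls
    n = matrix.n_varieties
    n_rr = np.sum(calls == HOM_REF, axis=0)
    n_het = np.sum(calls == HET, axis=0)
    n_aa = np.sum(calls == HOM_ALT, axis=0)
    n_called = n_rr + n_het + n_aa
    with np.errstate(divide="ignore", invalid="ignore"):
        p = np.where(n_called > 0, (2 * n_aa + n_het) / (2 * np.maximum(n_called, 1)), np.nan)
    maf_col = np.minimum(p, 1.0 - p)
    pic_col = np.where(np.isnan(p), np.nan, pic(np.nan_to_num(p)))
    ho = np.where(n_called > 0, n_het / np.maximum(n_called, 1), np.nan)
    he = 2.0 * p * (1.0 - p)
    hwe_p = np.array(
        [
            hwe_test((int(n_rr[j]), int(n_het[j]), int(n_aa[j])), method=hwe_method)
            if n_called[j] > 0
            else np.nan
            for j in range(matrix.n_loci)
        ]
    )
    return pd.DataFrame(
        {
            "locus_id": matrix.locus_ids,
            "chrom": [l.chrom for l in matrix.loci],
            "pos": [l.pos for l in matrix.loci],
            "n_called": n_called.astype(int),
            "n_missing": (n - n_called).astype(int),
            "maf": maf_col,
            "pic": pic_col,
            "ho": ho,
            "he": he,
            "hwe_p": hwe_p,
        }
    )


def summarize_stats(table: pd.DataFrame) -> pd.DataFrame:
    """Min/max/mean summary of maf, pic, ho, he across loci."""
    cols = ["maf", "pic", "ho", "he"]
    return table[cols].agg(["min", "max", "mean"])


def snv_ratio(n_nonsyn: int, n_syn: int) -> float:
    """Ratio of non-synonymous to synonymous SNVs, rounded to 2 decimals."""
    if n_syn <= 0:
        raise ValueError("synonymous count must be positive")
    return round(n_nonsyn / n_syn, 2)
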