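"""Six-criterion screening cascade for core-marker candidates.

A locus survives when, conjunctively:

1. (panel-level, handled at selection time, not here) markers are evenly
   distributed across chromosomes;
2. its number of missing genotypes is <= ``max_missing`` (default 0);
3. its number of unmeasured varieties is < ``max_unmeasured`` (default 20)
   and MAF >= ``min_maf`` (default 0.34, inclusive);
4. PIC > ``min_pic`` (default 0.35, exclusive);
5. the HWE-test p-value >= ``min_hwe_p`` (default 0.01, inclusive);
6. no other catalogued variant lies within ``flank_bp`` (default 100,
   inclusive: a neighbour exactly 100 bp away fails the locus) on the same
   chromosome — judged against the FULL pre-filter catalogue.

Criteria 2 and 3 both bound missingness; they are kept as independent
thresholds so either convention can be enforced alone.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .model import GenotypeDataError, GenotypeMatrix, LocusInfo
from .stats import stats_table

logger = logging.getLogger(__name__)


@dataclass
class FilterConfig:
    """Thresholds for the screening cascade (see module docstring)."""

    max_missing: int = 0
    max_unmeasured: int = 20
    min_maf: float = 0.34
    min_pic: float = 0.35
    min_hwe_p: float = 0.01
    flank_bp: int = 100

    def __post_init__(self) -> None:
        if min(self.max_missing, self.max_unmeasured, self.flank_bp) < 0:
            raise ValueError("thresholds must be non-negative")
        if not 0 <= self.min_maf <= 0.5:
            raise ValueError("min_maf must lie in [0, 0.5]")


@dataclass
class FilterStep:
    criterion: str
    n_in: int
    n_out: int


@dataclass
class FilterReport:
    """Per-criterion attrition and the surviving locus ids."""

    steps: list[FilterStep] = field(default_factory=list)
    survivors: list[str] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(s.criterion, s.n_in, s.n_out) for s in self.steps],
            columns=["criterion", "n_in", "n_out"],
        )


def flank_unique(
    catalogue: Sequence[LocusInfo], flank_bp: int = 100
) -> set[str]:
    """Ids of loci with no other catalogued variant within ``flank_bp``.

    A locus fails when any other variant on the same chromosome sits at an
    absolute distance <= ``flank_bp`` (the boundary counts as "within").
    Implemented as a sorted nearest-neighbour sweep per chromosome,
    contract-equivalent to the all-pairs comparison.
    """
    by_chrom: dict[str, list[LocusInfo]] = {}
    for locus in catalogue:
        by_chrom.setdefault(locus.chrom, []).append(locus)
    passing: set[str] = set()
    for loci in by_chrom.values():
        loci = sorted(loci, key=lambda l: l.pos)
        for i in range(1, len(loci)):
            if loci[i].pos == loci[i - 1].pos:
                raise GenotypeDataError(
                    f"duplicate position {loci[i].chrom}:{loci[i].pos} in catalogue"
                )
        for i, locus in enumerate(loci):
            left_ok = i == 0 or locus.pos - loci[i - 1].pos > flank_bp
            right_ok = i == len(loci) - 1 or loci[i + 1].pos - locus.pos > flank_bp
            if left_ok and right_ok:
                passing.add(locus.id)
    return passing


def apply_cascade(
    matrix: GenotypeMatrix,
    catalogue: Sequence[LocusInfo] | None = None,
    config: FilterConfig | None = None,
    *,
    stats: pd.DataFrame | None = None,
    hwe_method: str = "chisq",
) -> FilterReport:
    """Run the screening cascade over the matrix loci.

    ``catalogue`` is the full pre-filter variant list used for the flank
    criterion; it defaults to the matrix's own loci and must contain them.
    Criteria are applied in the order missingness -> unmeasured/MAF -> PIC
    -> HWE -> flank; the survivor SET is order-invariant (criteria are
    conjunctive) while the attrition trace reflects this order.
    """
    config = config or FilterConfig()
    if catalogue is None:
        catalogue = matrix.loci
    else:
        cat_keys = {(l.chrom, l.pos) for l in catalogue}
        missing = [(l.chrom, l.pos) for l in matrix.loci if (l.chrom, l.pos) not in cat_keys]
        if missing:
            raise GenotypeDataError(
                f"matrix loci absent from catalogue, e.g. {missing[0]}"
            )
    if stats is None:
        stats = stats_table(matrix, hwe_method=hwe_method)
    report = FilterReport()
    alive = stats.copy()

    def step(criterion: str, mask: pd.Series) -> None:
        nonlocal alive
        n_in = len(alive)
        alive = alive[mask.loc[alive.index]]
        report.steps.append(FilterStep(criterion, n_in, len(alive)))

    step("missing<=%d" % config.max_missing, stats["n_missing"] <= config.max_missing)
    step("unmeasured<%d" % config.max_unmeasured, stats["n_missing"] < config.max_unmeasured)
    step("maf>=%.3g" % config.min_maf, stats["maf"] >= config.min_maf)
    step("pic>%.3g" % config.min_pic, stats["pic"] > config.min_pic)
    step("hwe_p>=%.3g" % config.min_hwe_p, stats["hwe_p"] >= config.min_hwe_p)
    clean = flank_unique(catalogue, config.flank_bp)
    step("flank>%dbp" % config.flank_bp, stats["locus_id"].isin(clean))

    report.survivors = alive["locus_id"].tolist()
    if not report.survivors:
        logger.warning("filter cascade left no surviving loci")
    return report


class MarkerFilter(TransformerMixin, BaseEstimator):
    """Locus screener exposing the cascade as a scikit-learn transformer.

    ``fit`` computes per-locus statistics and the cascade verdicts;
    ``transform`` restricts a :class:`GenotypeMatrix` to the survivors.

    Parameters mirror :class:`FilterConfig`. After ``fit``:

    Attributes
    ----------
    stats_ : per-locus statistics table.
    report_ : :class:`FilterReport` with attrition per criterion.
    survivor_ids_ : surviving locus ids, matrix order.
    support_ : boolean mask over the fitted matrix's loci.
    """

    def __init__(
        self,
        max_missing: int = 0,
        max_unmeasured: int = 20,
        min_maf: float = 0.34,
        min_pic: float = 0.35,
        min_hwe_p: float = 0.01,
        flank_bp: int = 100,
        hwe_method: str = "chisq",
    ) -> None:
        self.max_missing = max_missing
        self.max_unmeasured = max_unmeasured
        self.min_maf = min_maf
        self.min_pic = min_pic
        self.min_hwe_p = min_hwe_p
        self.flank_bp = flank_bp
        self.hwe_method = hwe_method

    def _config(self) -> FilterConfig:
        return FilterConfig(
            max_missing=self.max_missing,
            max_unmeasured=self.max_unmeasured,
            min_maf=self.min_maf,
            min_pic=self.min_pic,
            min_hwe_p=self.min_hwe_p,
            flank_bp=self.flank_bp,
        )

    def fit(self, X: GenotypeMatrix, y=None, *, catalogue: Sequence[LocusInfo] | None = None):
        if not isinstance(X, GenotypeMatrix):
            raise TypeError("MarkerFilter expects a GenotypeMatrix")
        self.stats_ = stats_table(X, hwe_method=self.hwe_method)
        self.report_ = apply_cascade(
            X, catalogue, self._config(), stats=self.stats_, hwe_method=self.hwe_method
        )
        self.survivor_ids_ = list(self.report_.survivors)
        surviving = set(self.survivor_ids_)
        self.support_ = np.array([l.id in surviving for l in X.loci])
        return self

    def transform(self, X: GenotypeMatrix) -> GenotypeMatrix:
        if not hasattr(self, "survivor_ids_"):
            raise RuntimeError("MarkerFilter is not fitted")
        keep = [i for i in self.survivor_ids_ if i in set(X.locus_ids)]
        return X.subset_loci(keep)

    def get_support(self) -> np.ndarray:
        return self.support_
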