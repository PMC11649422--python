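"""Core-panel selection, minimal discriminating sets, and fingerprints.

The core panel is a chromosome-balanced subset of high-PIC screened loci
(the study design targets ~50 markers over 12 chromosomes). The minimal
discriminating set is a greedy set cover over the C(N,2) variety pairs:
each marker "covers" the pairs it distinguishes, and markers are added by
descending coverage gain until no marker resolves an additional pair.

A pair of varieties is distinguished at a locus only when both calls are
non-missing and their unordered allele pairs differ; comparisons against a
missing call never count, so missingness cannot inflate discrimination.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .model import GenotypeDataError, GenotypeMatrix, MISSING, sort_loci
from .stats import stats_table

logger = logging.getLogger(__name__)

VERDICT_SIMILAR = "identical-or-highly-similar"
VERDICT_DISTINCT = "distinct"


@dataclass
class PanelSelection:
    """An ordered marker subset with its pairwise-resolution accounting."""

    marker_ids: list[str]
    per_chrom_counts: dict[str, int]
    resolved_pairs: int
    unresolved_pairs: list[tuple[str, str]] = field(default_factory=list)


@dataclass
class Fingerprint:
    """A variety's ordered genotype string over the panel markers."""

    variety: str
    genotype: str


def pair_distinguished(call_a: int, call_b: int) -> bool:
    """True iff two codes at one locus differ and neither is missing."""
    return call_a != MISSING and call_b != MISSING and call_a != call_b


def difference_matrix(matrix: GenotypeMatrix, panel: Sequence[str]) -> np.ndarray:
    """N x N counts of panel loci at which each variety pair is distinguished.

    Symmetric with a zero diagonal; missing-vs-anything never counts.
    """
    if len(panel) == 0:
        raise GenotypeDataError("panel is empty")
    G = matrix.calls[:, matrix.locus_index(panel)]
    valid = G != MISSING
    n = matrix.n_varieties
    out = np.zeros((n, n), dtype=np.int32)
    for i in range(n):
        diff = (G[i] != G) & valid[i] & valid
        out[i] = diff.sum(axis=1)
    np.fill_diagonal(out, 0)
    return out


def _pair_index(n: int) -> tuple[np.ndarray, np.ndarray]:
    iu = np.triu_indices(n, k=1)
    return iu[0], iu[1]


def _resolution_matrix(matrix: GenotypeMatrix, candidates: Sequence[str]) -> np.ndarray:
    """Boolean (n_candidates, n_pairs) matrix of pairwise distinguishability."""
    G = matrix.calls[:, matrix.locus_index(candidates)]
    valid = G != MISSING
    rows, cols = _pair_index(matrix.n_varieties)
    res = np.empty((len(candidates), len(rows)), dtype=bool)
    for m in range(len(candidates)):
        g, v = G[:, m], valid[:, m]
        res[m] = (g[rows] != g[cols]) & v[rows] & v[cols]
    return res


def _selection(
    matrix: GenotypeMatrix,
    marker_ids: Sequence[str],
    covered: np.ndarray | None = None,
) -> PanelSelection:
    """Assemble a PanelSelection, computing coverage if not supplied."""
    rows, cols = _pair_index(matrix.n_varieties)
    if covered is None:
        if marker_ids:
            covered = _resolution_matrix(matrix, marker_ids).any(axis=0)
        else:
            covered = np.zeros(len(rows), dtype=bool)
    per_chrom: dict[str, int] = {}
    by_id = {l.id: l for l in matrix.loci}
    for mid in marker_ids:
        chrom = by_id[mid].chrom
        per_chrom[chrom] = per_chrom.get(chrom, 0) + 1
    unresolved = [
        (matrix.varieties[rows[k]], matrix.varieties[cols[k]])
        for k in np.flatnonzero(~covered)
    ]
    return PanelSelection(
        marker_ids=list(marker_ids),
        per_chrom_counts=per_chrom,
        resolved_pairs=int(covered.sum()),
        unresolved_pairs=unresolved,
    )


def select_core(
    matrix: GenotypeMatrix,
    survivors: Sequence[str],
    k: int,
    *,
    flank_bp: int = 100,
    stats: pd.DataFrame | None = None,
) -> PanelSelection:
    """Pick a chromosome-balanced core panel of ``k`` markers.

    Each chromosome gets a quota of ``floor(k / n_chrom)`` markers, with the
    remainder going to the chromosomes holding the most candidates. Within
    a chromosome, loci are taken by descending PIC (ties: smaller position)
    subject to a mutual distance > ``flank_bp``. Quotas a chromosome cannot
    fill are redistributed to the chromosomes with the most remaining
    candidates. Fully deterministic given its input.
    """
    survivors = list(survivors)
    if k > len(survivors):
        raise GenotypeDataError(f"k={k} exceeds {len(survivors)} surviving loci")
    if stats is None:
        stats = stats_table(matrix)
    pic_by_id = dict(zip(stats["locus_id"], stats["pic"]))
    by_id = {l.id: l for l in matrix.loci}
    chrom_rank = {c: i for i, c in enumerate(matrix.chrom_order)}

    # Candidate queues per chromosome: descending PIC, then ascending position.
    queues: dict[str, list[str]] = {}
    for mid in survivors:
        queues.setdefault(by_id[mid].chrom, []).append(mid)
    for chrom in queues:
        queues[chrom].sort(key=lambda m: (-pic_by_id[m], by_id[m].pos))

    n_chrom = len(matrix.chrom_order)
    base, rem = divmod(k, n_chrom)
    quota = {c: base for c in matrix.chrom_order}
    richest = sorted(
        matrix.chrom_order, key=lambda c: (-len(queues.get(c, [])), chrom_rank[c])
    )
    for c in richest[:rem]:
        quota[c] += 1

    chosen: dict[str, list[str]] = {c: [] for c in matrix.chrom_order}

    def try_pick(chrom: str) -> bool:
        """Take the next queue entry compatible with the flank spacing."""
        taken_pos = [by_id[m].pos for m in chosen[chrom]]
        queue = queues.get(chrom, [])
        for idx, mid in enumerate(queue):
            pos = by_id[mid].pos
            if all(abs(pos - t) > flank_bp for t in taken_pos):
                chosen[chrom].append(mid)
                queue.pop(idx)
                return True
        return False

    for chrom in matrix.chrom_order:
        while len(chosen[chrom]) < quota[chrom] and try_pick(chrom):
            pass
        if len(chosen[chrom]) < quota[chrom] and not queues.get(chrom):
            logger.warning(
                "chromosome %s has only %d pickable candidates (quota %d); "
                "redistributing", chrom, len(chosen[chrom]), quota[chrom]
            )
    # Redistribute unfilled quota to the chromosomes with most candidates left.
    total = sum(len(v) for v in chosen.values())
    while total < k:
        order = sorted(
            (c for c in matrix.chrom_order if queues.get(c)),
            key=lambda c: (-len(queues[c]), chrom_rank[c]),
        )
        picked_any = False
        for chrom in order:
            if try_pick(chrom):
                total += 1
                picked_any = True
                break
        if not picked_any:
            logger.warning("could only select %d of the requested %d markers", total, k)
            break

    marker_ids = [m for c in matrix.chrom_order for m in chosen[c]]
    order = sort_loci([by_id[m] for m in marker_ids], matrix.chrom_order)
    marker_ids = [marker_ids[i] for i in order]
    return _selection(matrix, marker_ids)


def minimal_discriminating_set(
    matrix: GenotypeMatrix,
    candidates: Sequence[str],
    *,
    stats: pd.DataFrame | None = None,
) -> PanelSelection:
    """Greedy set cover: smallest marker set distinguishing all variety pairs.

    Repeatedly adds the candidate resolving the most still-unresolved pairs
    (ties broken by higher PIC, then chromosome order and position) and
    stops when no candidate adds coverage. Pairs indistinguishable even by
    all candidates jointly are returned as ``unresolved_pairs``.
    """
    candidates = list(candidates)
    if not candidates:
        raise GenotypeDataError("candidate set is empty")
    if stats is None:
        stats = stats_table(matrix.subset_loci(candidates))
    pic_by_id = dict(zip(stats["locus_id"], stats["pic"]))
    by_id = {l.id: l for l in matrix.loci}
    chrom_rank = {c: i for i, c in enumerate(matrix.chrom_order)}

    res = _resolution_matrix(matrix, candidates)
    n_pairs = res.shape[1]
    covered = np.zeros(n_pairs, dtype=bool)
    selected: list[str] = []
    remaining = list(range(len(candidates)))
    while True:
        gains = res[remaining][:, ~covered].sum(axis=1) if n_pairs else np.array([])
        if len(gains) == 0 or gains.max() == 0:
            break
        best_gain = gains.max()

        def tie_key(pos_in_remaining: int) -> tuple:
            mid = candidates[remaining[pos_in_remaining]]
            locus = by_id[mid]
            return (-pic_by_id[mid], chrom_rank[locus.chrom], locus.pos)

        best = min(
            (i for i in range(len(remaining)) if gains[i] == best_gain), key=tie_key
        )
        m = remaining.pop(best)
        selected.append(candidates[m])
        covered |= res[m]
        if covered.all():
            break
    return _selection(matrix, selected, covered=covered)


def exhaustive_minimum_set(
    matrix: GenotypeMatrix, candidates: Sequence[str]
) -> PanelSelection:
    """Provably minimum-cardinality panel with maximum coverage.

    Exhaustive subset enumeration by increasing size; intended as an
    independent check on the greedy search for small instances only
    (<= ~12 candidates).
    """
    candidates = list(candidates)
    if len(candidates) > 16:
        raise GenotypeDataError("exhaustive search limited to <= 16 candidates")
    res = _resolution_matrix(matrix, candidates)
    achievable = res.any(axis=0)
    target = int(achievable.sum())
    if target == 0:
        return _selection(matrix, [], covered=achievable & False)
    for size in range(1, len(candidates) + 1):
        for combo in combinations(range(len(candidates)), size):
            covered = res[list(combo)].any(axis=0)
            if int(covered.sum()) == target:
                return _selection(matrix, [candidates[i] for i in combo], covered=covered)
    raise AssertionError("unreachable: full candidate set attains its own coverage")


def build_fingerprints(
    matrix: GenotypeMatrix, panel: Sequence[str]
) -> list[Fingerprint]:
    """One fingerprint per variety over the panel loci in (chrom, pos) order.

    Genotypes are rendered with alleles sorted alphabetically and joined
    with ``|``; missing calls appear as ``NN``.
    """
    if len(panel) == 0:
        raise GenotypeDataError("panel is empty")
    sub = matrix.subset_loci(panel).sorted_by_position()
    prints = []
    for i, variety in enumerate(sub.varieties):
        codes = [
            "NN" if sub.calls[i, j] == MISSING else sub.loci[j].genotype_string(int(sub.calls[i, j]))
            for j in range(sub.n_loci)
        ]
        prints.append(Fingerprint(variety=variety, genotype="|".join(codes)))
    return prints


def similarity_verdict(diff_count: int, threshold: int = 1) -> str:
    """Classify a pair from its differing-locus count.

    Pairs differing at <= ``threshold`` panel loci (default 1) are called
    identical or highly similar; anything above is distinct.
    """
    if diff_count < 0:
        raise ValueError("difference count must be non-negative")
    return VERDICT_SIMILAR if diff_count <= threshold else VERDICT_DISTINCT


@dataclass
class ConcordanceResult:
    rate: float
    n_compared: int
    n_concordant: int
    n_excluded_missing: int


def concordance_rate(
    fingerprints_a: Sequence[Fingerprint],
    fingerprints_b: Sequence[Fingerprint],
) -> ConcordanceResult:
    """Cell-level concordance between two fingerprint sets of one panel.

    Both sides must cover the same varieties and panel length. Cells missing
    (``NN``) on either side are excluded from the denominator and counted
    separately. With no comparable cells the rate is NaN (with a warning).
    """
    a_by_var = {f.variety: f.genotype.split("|") for f in fingerprints_a}
    b_by_var = {f.variety: f.genotype.split("|") for f in fingerprints_b}
    if set(a_by_var) != set(b_by_var):
        raise GenotypeDataError("fingerprint sets cover different varieties")
    n_comp = n_conc = n_miss = 0
    for variety, cells_a in a_by_var.items():
        cells_b = b_by_var[variety]
        if len(cells_a) != len(cells_b):
            raise GenotypeDataError(f"panel length mismatch for variety {variety!r}")
        for ca, cb in zip(cells_a, cells_b):
            if ca == "NN" or cb == "NN":
                n_miss += 1
            else:
                n_comp += 1
                n_conc += ca == cb
    if n_comp == 0:
        warnings.warn("no comparable cells: concordance undefined", stacklevel=2)
        return ConcordanceResult(float("nan"), 0, 0, n_miss)
    return ConcordanceResult(n_conc / n_comp, n_comp, n_conc, n_miss)


class CorePanelSelector(TransformerMixin, BaseEstimator):
    """Chromosome-balanced core-panel selection as a transformer.

    ``fit(X, survivors=...)`` selects ``k`` markers from the survivor ids
    (default: all loci of X); ``transform`` restricts a matrix to the panel.

    Attributes after fit: ``panel_`` (:class:`PanelSelection`),
    ``marker_ids_``, ``per_chrom_counts_``.
    """

    def __init__(self, k: int = 50, flank_bp: int = 100) -> None:
        self.k = k
        self.flank_bp = flank_bp

    def fit(self, X: GenotypeMatrix, y=None, *, survivors: Sequence[str] | None = None):
        if not isinstance(X, GenotypeMatrix):
            raise TypeError("CorePanelSelector expects a GenotypeMatrix")
        survivors = list(survivors) if survivors is not None else X.locus_ids
        self.panel_ = select_core(X, survivors, self.k, flank_bp=self.flank_bp)
        self.marker_ids_ = list(self.panel_.marker_ids)
        self.per_chrom_counts_ = dict(self.panel_.per_chrom_counts)
        return self

    def transform(self, X: GenotypeMatrix) -> GenotypeMatrix:
        return X.subset_loci(self.marker_ids_)


class MinimalPanelSelector(TransformerMixin, BaseEstimator):
    """Greedy minimal discriminating subset as a transformer.

    Attributes after fit: ``panel_``, ``marker_ids_``, ``resolved_pairs_``,
    ``unresolved_pairs_``.
    """

    def __init__(self) -> None:
        pass

    def fit(self, X: GenotypeMatrix, y=None, *, candidates: Sequence[str] | None = None):
        if not isinstance(X, GenotypeMatrix):
            raise TypeError("MinimalPanelSelector expects a GenotypeMatrix")
        candidates = list(candidates) if candidates is not None else X.locus_ids
        self.panel_ = minimal_discriminating_set(X, candidates)
        self.marker_ids_ = list(self.panel_.marker_ids)
        self.resolved_pairs_ = self.panel_.resolved_pairs
        self.unresolved_pairs_ = list(self.panel_.unresolved_pairs)
        return self

    def transform(self, X: GenotypeMatrix) -> GenotypeMatrix:
        return X.subset_loci(self.marker_ids_)


class Fingerprinter(TransformerMixin, BaseEstimator):
    """Render varieties as fingerprint strings over a fixed panel."""

    def __init__(self, panel: Sequence[str] | None = None) -> None:
        self.panel = panel

    def fit(self, X: GenotypeMatrix, y=None):
        self.panel_ = list(self.panel) if self.panel is not None else X.locus_ids
        return self

    def transform(self, X: GenotypeMatrix) -> pd.DataFrame:
        prints = build_fingerprints(X, self.panel_)
        return pd.DataFrame(
            {"variety": [f.variety for f in prints], "fingerprint": [f.genotype for f in prints]}
        )
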