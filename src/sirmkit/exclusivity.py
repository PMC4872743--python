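"""Gene-pair co-occurrence / mutual-exclusivity screen.

Expression is binarized to high-expressor calls per sample (either mean +
1 SD, suited to large tumor panels, or positive deviation from the median
gene profile, suited to cell-line panels); gene pairs are then scored with
hypergeometric tail probabilities on the joint-high count, odds ratios with
Haldane-Anscombe continuity handling, Venn partitions for triplets, and a
z-score / euclidean-distance hierarchical clustering with Pearson
correlation tests.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

logger = logging.getLogger(__name__)

RULES = ("above_mean_plus_sd", "above_median_profile")


@dataclass
class BinaryCallMatrix:
    """Boolean high-expression calls with the thresholds that produced them."""

    calls: pd.DataFrame  # genes x samples, bool
    rule: str
    thresholds: pd.Series  # per-gene threshold on the expression scale


def binarize(matrix: pd.DataFrame, rule: str = "above_mean_plus_sd") -> BinaryCallMatrix:
    """Call each (gene, sample) high or not under the chosen rule.

    ``above_mean_plus_sd``: expression strictly above mean + 1 sample SD
    (n-1 denominator) of the gene across samples.  ``above_median_profile``:
    expression strictly above the gene's median across samples.  Boundary
    values are never high.
    """
    if rule not in RULES:
        raise ValueError(f"unknown binarization rule {rule!r}; choose from {RULES}")
    if matrix.shape[1] < 2:
        raise ValueError("binarization needs at least two samples")
    if rule == "above_mean_plus_sd":
        thresholds = matrix.mean(axis=1) + matrix.std(axis=1, ddof=1)
        constant = matrix.std(axis=1, ddof=1) == 0
        if constant.any():
            logger.warning(
                "constant gene(s) under mean+sd rule produce all-false calls: %s",
                list(matrix.index[constant])[:10],
            )
    else:
        thresholds = matrix.median(axis=1)
    calls = matrix.gt(thresholds, axis=0)
    return BinaryCallMatrix(calls, rule, thresholds)


@dataclass(frozen=True)
class PairAssociation:
    """2x2 association between two genes' high-expression calls.

    ``p_cooccurrence`` is the upper hypergeometric tail P[X >= k] of the
    joint-high count with both margins fixed; ``p_exclusivity`` the lower
    tail P[X <= k].  The odds ratio uses the Haldane-Anscombe 0.5-per-cell
    correction only when a zero cell exists.
    """

    gene_a: str
    gene_b: str
    n11: int
    n10: int
    n01: int
    n00: int
    odds_ratio: float
    p_cooccurrence: float
    p_exclusivity: float

    @property
    def n_samples(self) -> int:
        return self.n11 + self.n10 + self.n01 + self.n00


def pair_test(calls_a, calls_b, names: tuple[str, str] = ("A", "B")) -> PairAssociation:
    """Hypergeometric co-occurrence / exclusivity test for one gene pair."""
    a = np.asarray(calls_a, dtype=bool)
    b = np.asarray(calls_b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError(f"call vectors differ in length: {a.shape} vs {b.shape}")
    if a.size == 0:
        raise ValueError("empty call vectors")
    n = a.size
    n11 = int(np.sum(a & b))
    n10 = int(np.sum(a & ~b))
    n01 = int(np.sum(~a & b))
    n00 = int(np.sum(~a & ~b))
    n_a, n_b = n11 + n10, n11 + n01
    # X ~ Hypergeom(population n, successes n_a, draws n_b)
    p_co = float(stats.hypergeom.sf(n11 - 1, n, n_a, n_b))
    p_ex = float(stats.hypergeom.cdf(n11, n, n_a, n_b))
    cells = np.array([n11, n10, n01, n00], dtype=float)
    if np.any(cells == 0):
        cells = cells + 0.5
    odds = (cells[0] * cells[3]) / (cells[1] * cells[2])
    return PairAssociation(names[0], names[1], n11, n10, n01, n00, float(odds), p_co, p_ex)


def all_pair_tests(calls: BinaryCallMatrix | pd.DataFrame) -> list[PairAssociation]:
    """Pairwise tests over every gene pair of a call matrix."""
    frame = calls.calls if isinstance(calls, BinaryCallMatrix) else calls
    return [
        pair_test(frame.loc[ga], frame.loc[gb], (ga, gb))
        for ga, gb in itertools.combinations(frame.index, 2)
    ]


def classify_pair(assoc: PairAssociation, or_bounds: tuple[float, float] = (0.1, 2.0)) -> str:
    """'mutually_exclusive' | 'co_occurring' | 'neither' by odds-ratio bands."""
    low, high = or_bounds
    if assoc.odds_ratio < low:
        return "mutually_exclusive"
    if assoc.odds_ratio > high:
        return "co_occurring"
    return "neither"


@dataclass(frozen=True)
class VennPartition:
    """Region counts for 2-3 genes' expressor calls.

    ``regions`` maps membership tuples (one bool per gene, in input order)
    to sample counts; ``none_count`` is the all-false region.  For the
    designated pair, ``pair_union`` counts samples high for either gene and
    ``pair_exactly_one`` those high for exactly one — their ratio is the
    mutual-exclusivity fraction.
    """

    genes: tuple[str, ...]
    regions: dict[tuple[bool, ...], int]
    none_count: int
    pair: tuple[str, str]
    pair_union: int
    pair_exactly_one: int

    @property
    def exclusivity_fraction(self) -> float | None:
        if self.pair_union == 0:
            return None
        return self.pair_exactly_one / self.pair_union

    def union_count(self, genes: Sequence[str]) -> int:
        idx = [self.genes.index(g) for g in genes]
        return sum(c for member, c in self.regions.items() if any(member[i] for i in idx))


def expressor_venn(calls: pd.DataFrame, pair: tuple[str, str] | None = None) -> VennPartition:
    """Partition samples by which of 2-3 genes call them high."""
    genes = tuple(calls.index)
    if len(genes) not in (2, 3):
        raise ValueError("expressor_venn takes 2 or 3 gene call vectors")
    arr = calls.to_numpy(dtype=bool)
    regions: dict[tuple[bool, ...], int] = {}
    none_count = 0
    for member in itertools.product([True, False], repeat=len(genes)):
        mask = np.ones(arr.shape[1], dtype=bool)
        for i, m in enumerate(member):
            mask &= arr[i] == m
        count = int(mask.sum())
        if any(member):
            regions[member] = count
        else:
            none_count = count
    if pair is None:
        pair = (genes[0], genes[1])
    ia, ib = genes.index(pair[0]), genes.index(pair[1])
    union = arr[ia] | arr[ib]
    exactly_one = arr[ia] ^ arr[ib]
    return VennPartition(genes, regions, none_count, pair, int(union.sum()), int(exactly_one.sum()))


@dataclass
class ClusterResult:
    """Hierarchical-clustering order plus pairwise Pearson correlations."""

    order: list[str]  # genes in dendrogram leaf order
    linkage_matrix: np.ndarray
    correlations: pd.DataFrame  # gene_a, gene_b, r, p_value (NaN if undefined)
    linkage_method: str = "average"


def cluster_and_correlate(matrix: pd.DataFrame, linkage_method: str = "average") -> ClusterResult:
    """Z-score genes across samples, cluster on euclidean distance, correlate.

    Pearson r per gene pair with the two-sided t-based test of r = 0;
    pairs involving a constant gene are reported with NaN r and p.
    """
    if matrix.shape[1] < 3:
        raise ValueError("need at least 3 samples")
    if linkage_method not in ("average", "single", "complete", "ward"):
        raise ValueError(f"unsupported linkage method {linkage_method!r}")
    sd = matrix.std(axis=1, ddof=1)
    centered = matrix.sub(matrix.mean(axis=1), axis=0)
    zed = centered.div(sd.replace(0.0, np.nan), axis=0).fillna(0.0)
    Z = hierarchy.linkage(pdist(zed.to_numpy(), metric="euclidean"), method=linkage_method)
    order = [matrix.index[i] for i in hierarchy.leaves_list(Z)]
    records = []
    for ga, gb in itertools.combinations(matrix.index, 2):
        if sd[ga] == 0 or sd[gb] == 0:
            r, p = np.nan, np.nan
        else:
            r, p = stats.pearsonr(matrix.loc[ga], matrix.loc[gb])
        records.append({"gene_a": ga, "gene_b": gb, "r": float(r), "p_value": float(p)})
    return ClusterResult(order, Z, pd.DataFrame.from_records(records), linkage_method)
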