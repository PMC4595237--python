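"""Quartile rate categories and the gene-gene co-evolution proportion test.

Per gene, species' omega-lineage values are classified as accelerated
(above the 0.75 quantile), conserved (below the 0.25 quantile) or
neutral.  Two genes co-evolve when species match categories (AA, CC or
NN) more often than the 6/16 = 0.375 expected under independence
(0.25^2 + 0.25^2 + 0.5^2); a one-sided proportion test per gene pair with
Bonferroni control over the tests actually run gives the verdicts.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import OmegaLineageTable

logger = logging.getLogger("opsinevol")

__all__ = ["CategorizedTable", "AssociationResult", "NULL_MATCH_PROBABILITY",
           "categorize_omegas", "match_count", "proportion_test",
           "coevolution_matrix"]

NULL_MATCH_PROBABILITY = 6.0 / 16.0  # 0.25^2 + 0.25^2 + 0.5^2


@dataclass
class CategorizedTable:
    """Genes x species matrix over {A, C, N} with NaN for missing."""

    data: pd.DataFrame
    thresholds: pd.DataFrame  # per-gene q_low / q_high used

    @property
    def genes(self) -> list[str]:
        return list(self.data.index)


def categorize_omegas(table: OmegaLineageTable, q_low: float = 0.25,
                      q_high: float = 0.75, pooled: bool = False
                      ) -> CategorizedTable:
    """Classify omega-lineage values into accelerated/conserved/neutral.

    Quantiles use the linear-interpolation convention (numpy default) and
    are taken per gene unless ``pooled=True``.  Inequalities are strict,
    so values on a threshold are neutral and a constant gene is all
    neutral.  Genes with fewer than 4 non-missing values are dropped.
    """
    if not 0.0 <= q_low < q_high <= 1.0:
        raise ValueError("need 0 <= q_low < q_high <= 1")
    df = table.data
    counts = df.notna().sum(axis=1)
    dropped = counts[counts < 4].index
    for gene in dropped:
        logger.warning("categorize_omegas: gene %r has %d < 4 values, dropped",
                       gene, int(counts[gene]))
    df = df.drop(index=dropped)
    if df.empty:
        raise ValueError("no gene has >= 4 non-missing omega values")

    if pooled:
        pool = df.to_numpy().ravel()
        lo = hi = None
        lo = float(np.nanquantile(pool, q_low))
        hi = float(np.nanquantile(pool, q_high))
        lo_s = pd.Series(lo, index=df.index)
        hi_s = pd.Series(hi, index=df.index)
    else:
        lo_s = df.quantile(q_low, axis=1)
        hi_s = df.quantile(q_high, axis=1)

    cats = pd.DataFrame(index=df.index, columns=df.columns, dtype=object)
    vals = df.to_numpy()
    lo_v = lo_s.to_numpy()[:, None]
    hi_v = hi_s.to_numpy()[:, None]
    cats[:] = np.where(np.isnan(vals), None,
                       np.where(vals > hi_v, "A",
                                np.where(vals < lo_v, "C", "N")))
    thresholds = pd.DataFrame({"q_low": lo_s, "q_high": hi_s})
    return CategorizedTable(data=cats, thresholds=thresholds)


def match_count(cats_a: pd.Series, cats_b: pd.Series) -> tuple[int, int]:
    """(n, k): species non-missing in both, and matching categories (AA/CC/NN)."""
    joined = pd.DataFrame({"a": cats_a, "b": cats_b}).dropna()
    n = len(joined)
    k = int((joined["a"] == joined["b"]).sum())
    return n, k


def proportion_test(k: int, n: int, p0: float = NULL_MATCH_PROBABILITY,
                    alternative: str = "greater",
                    method: str = "exact") -> float:
    """One-sided test of a matching proportion against the null p0.

    ``exact`` is the binomial tail P(Bin(n, p0) >= k) (default,
    conservative); ``normal`` uses the normal approximation with
    continuity correction.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if k < 0 or k > n:
        raise ValueError(f"k={k} outside [0, {n}]")
    if alternative != "greater":
        raise ValueError("only the upper-tail alternative is supported")
    if method == "exact":
        return float(stats.binomtest(k, n, p0, alternative="greater").pvalue)
    if method == "normal":
        sd = np.sqrt(n * p0 * (1 - p0))
        z = (k - 0.5 - n * p0) / sd
        return float(stats.norm.sf(z))
    raise ValueError(f"unknown method {method!r}")


@dataclass(frozen=True)
class AssociationResult:
    gene_a: str
    gene_b: str
    n: int
    k: int
    proportion: float
    p_value: float
    significant: bool   # Bonferroni: p < alpha / m
    strong: bool        # uncorrected: p < alpha
    m: int              # number of tests actually run

    def __post_init__(self) -> None:
        if not 0 <= self.k <= self.n:
            raise ValueError("need 0 <= k <= n")


def coevolution_matrix(cats_a: CategorizedTable, cats_b: CategorizedTable,
                       min_n: int = 15, alpha: float = 0.05,
                       p0: float = NULL_MATCH_PROBABILITY,
                       method: str = "exact") -> list[AssociationResult]:
    """Pairwise co-evolution tests between two categorized gene sets.

    Every cross pair with at least ``min_n`` jointly observed lineages is
    tested; pairs below the floor are excluded as false-positive prone.
    The Bonferroni divisor m is the count of tests actually run.  Results
    carry both the corrected verdict (p < alpha/m) and the uncorrected
    "strong" tier (p < alpha).
    """
    candidates = []
    for ga, gb in itertools.product(cats_a.genes, cats_b.genes):
        if ga == gb:
            continue
        n, k = match_count(cats_a.data.loc[ga], cats_b.data.loc[gb])
        if n < min_n:
            logger.info("coevolution_matrix: %s-%s excluded (n=%d < %d)",
                        ga, gb, n, min_n)
            continue
        candidates.append((ga, gb, n, k))
    if not candidates:
        logger.warning("coevolution_matrix: no testable gene pair")
        return []
    m = len(candidates)
    results = []
    for ga, gb, n, k in candidates:
        p = proportion_test(k, n, p0=p0, method=method)
        results.append(AssociationResult(
            gene_a=ga, gene_b=gb, n=n, k=k, proportion=k / n, p_value=p,
            significant=p < alpha / m, strong=p < alpha, m=m))
    logger.info("coevolution_matrix: %d tests, Bonferroni threshold %.3g",
                m, alpha / m)
    return results
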