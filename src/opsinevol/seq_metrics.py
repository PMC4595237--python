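"""GC dinucleotide-ratio screening and alignment column filtering.

The GC ratio is the observed/expected odds of the GC dinucleotide,
f(GC) / (f(G) * f(C)), with f(GC) counted over overlapping windows.
GC-rich loci (microchromosomal genes such as the sw1/sw2/lw cone opsins)
are harder to sequence and assemble, so a one-way ANOVA on the log ratio
across genes screens for systematically GC-rich gene families.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .io_formats import CodonAlignment

logger = logging.getLogger("opsinevol")

__all__ = ["GcRatioRecord", "AnovaResult", "gc_ratio", "anova_log_gc",
           "posthoc_pairwise", "filter_gap_rich_columns"]


@dataclass(frozen=True)
class GcRatioRecord:
    gene: str
    taxon: str
    f_gc: float        # overlapping GC dinucleotide frequency, over L-1 windows
    f_g: float
    f_c: float
    ratio: float | None       # None when f(G)*f(C) == 0
    log_ratio: float | None   # natural log; None when ratio is 0 or undefined

    @property
    def usable(self) -> bool:
        return self.log_ratio is not None


def gc_ratio(sequence: str, gene: str = "", taxon: str = "",
             stride: int = 1) -> GcRatioRecord:
    """GC dinucleotide odds ratio of one sequence.

    Gaps and Ns are removed before counting; case is ignored.  With the
    default stride of 1 the GC count uses all L-1 overlapping windows
    (the standard dinucleotide-odds definition); ``stride=3`` restricts
    to codon-aligned windows.  Sequences lacking G or C yield a flagged
    record with an undefined ratio.
    """
    clean = "".join(ch for ch in sequence.upper() if ch in "ACGT")
    if len(clean) < 2:
        raise ValueError("need at least 2 unambiguous nucleotides")
    starts = range(0, len(clean) - 1, stride)
    f_gc = sum(clean[i:i + 2] == "GC" for i in starts) / len(starts)
    f_g = clean.count("G") / len(clean)
    f_c = clean.count("C") / len(clean)
    if f_g * f_c == 0:
        ratio = log_ratio = None
    else:
        ratio = f_gc / (f_g * f_c)
        log_ratio = math.log(ratio) if ratio > 0 else None
    return GcRatioRecord(gene=gene, taxon=taxon, f_gc=f_gc, f_g=f_g, f_c=f_c,
                         ratio=ratio, log_ratio=log_ratio)


@dataclass(frozen=True)
class AnovaResult:
    f_statistic: float
    df_num: int
    df_den: int
    p_value: float
    group_means: dict[str, float]


def _usable_groups(records: Iterable[GcRatioRecord]) -> dict[str, list[float]]:
    groups: dict[str, list[float]] = {}
    dropped = 0
    for rec in records:
        if rec.usable:
            groups.setdefault(rec.gene, []).append(rec.log_ratio)
        else:
            dropped += 1
    small = [g for g, v in groups.items() if len(v) < 2]
    for g in small:
        logger.warning("anova_log_gc: gene %r has <2 usable records, excluded", g)
        del groups[g]
    if dropped:
        logger.info("anova_log_gc: %d flagged records excluded", dropped)
    return groups


def anova_log_gc(records: Iterable[GcRatioRecord]) -> AnovaResult:
    """One-way fixed-effects ANOVA of log GC ratio across genes.

    Flagged records and genes with fewer than two usable records are
    excluded; degrees of freedom are (k - 1, N - k).
    """
    groups = _usable_groups(records)
    if len(groups) < 2:
        raise ValueError("need at least 2 gene groups with >= 2 records each")
    names = sorted(groups)
    values = [groups[g] for g in names]
    flat = [v for vals in values for v in vals]
    if len(set(flat)) == 1:
        # all observations identical: no variance anywhere, F = 0
        f_stat, p = 0.0, 1.0
    else:
        f_stat, p = stats.f_oneway(*values)
    k = len(values)
    n_total = sum(len(v) for v in values)
    return AnovaResult(f_statistic=float(f_stat), df_num=k - 1,
                       df_den=n_total - k, p_value=float(p),
                       group_means={g: float(np.mean(groups[g])) for g in names})


def posthoc_pairwise(records: Iterable[GcRatioRecord],
                     method: str = "tukey") -> pd.DataFrame:
    """All gene-pair post-hoc comparisons of log GC ratio.

    ``tukey`` runs Tukey's HSD; ``bonferroni-t`` runs Welch t-tests with
    Bonferroni-adjusted (capped at 1) p-values.
    """
    groups = _usable_groups(records)
    if len(groups) < 2:
        raise ValueError("need at least 2 gene groups")
    names = sorted(groups)
    if method == "tukey":
        data = np.concatenate([groups[g] for g in names])
        labels = np.concatenate([[g] * len(groups[g]) for g in names])
        res = pairwise_tukeyhsd(data, labels)
        frame = pd.DataFrame(res.summary().data[1:],
                             columns=res.summary().data[0])
        return frame.rename(columns={"group1": "gene_a", "group2": "gene_b",
                                     "p-adj": "p_adjusted"})
    if method == "bonferroni-t":
        m = len(names) * (len(names) - 1) // 2
        rows = []
        for a, b in itertools.combinations(names, 2):
            t, p = stats.ttest_ind(groups[a], groups[b], equal_var=False)
            rows.append({"gene_a": a, "gene_b": b, "t": float(t),
                         "p_raw": float(p), "p_adjusted": min(1.0, float(p) * m)})
        return pd.DataFrame(rows)
    raise ValueError(f"unknown post-hoc method {method!r}")


def filter_gap_rich_columns(alignment: CodonAlignment,
                            max_gap_fraction: float) -> CodonAlignment:
    """Drop whole codon columns whose gap fraction exceeds the threshold.

    A codon column is removed when any of its three nucleotide positions
    has a gap fraction strictly above ``max_gap_fraction``; the reading
    frame is preserved.
    """
    if not 0.0 <= max_gap_fraction <= 1.0:
        raise ValueError("max_gap_fraction must lie in [0, 1]")
    n_seq = len(alignment.taxa)
    keep: list[int] = []
    for col in range(alignment.n_codons):
        worst = max(
            sum(s[3 * col + k] == "-" for s in alignment.sequences) / n_seq
            for k in range(3))
        if worst <= max_gap_fraction:
            keep.append(col)
    if not keep:
        raise ValueError("no codon columns survive the gap filter")
    seqs = tuple("".join(s[3 * c: 3 * c + 3] for c in keep)
                 for s in alignment.sequences)
    logger.info("filter_gap_rich_columns: kept %d/%d codon columns",
                len(keep), alignment.n_codons)
    return CodonAlignment(taxa=alignment.taxa, sequences=seqs)
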