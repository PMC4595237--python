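"""Selection-model utilities.

The heavy lifting of codon-model maximum likelihood belongs to codeml and
is consumed through :mod:`opsinevol.io_formats`.  This module provides the
surrounding machinery: site-class summaries and beta discretization,
likelihood-ratio tests, a Nei–Gojobori (1986) counting dN/dS estimator
with Jukes–Cantor correction that serves as a self-contained stand-in for
branch models on synthetic data, root-to-tip foreground omega
("omega-lineage") estimation, pseudogene screening, reference-numbered
site maps, and single-site Fitch ancestral reconstruction.
"""

from __future__ import annotations

import itertools
import logging
import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import special, stats

from ._codons import (GENETIC_CODE, SENSE_CODONS, STOP_CODONS, is_stop,
                      single_nt_neighbors, translate_codon)
from .io_formats import (CodonAlignment, OmegaLineageTable, PhyloTree,
                         SequenceAlignment, SiteClassDistribution)

logger = logging.getLogger("opsinevol")

__all__ = [
    "SiteClassDistribution", "LrtResult", "NG86Result", "PseudogeneReport",
    "AncestralSiteReconstruction", "ReferenceSiteMap",
    "mean_omega_from_categories", "discretize_beta", "lrt", "ng86_dnds",
    "root_to_tip_omega", "omega_lineage_table", "pseudogene_screen",
    "reference_site_map", "fitch_ancestral_site",
]


# ---------------------------------------------------------------------------
# site-class summaries
# ---------------------------------------------------------------------------

def mean_omega_from_categories(dist: SiteClassDistribution) -> float:
    """Proportion-weighted mean omega over the site categories.

    This is the single-number summary used to compare selective regimes of
    a gene between clades: sum_i proportion_i * omega_i.
    """
    return float(np.dot(dist.proportions, dist.omegas))


def discretize_beta(p: float, q: float, k: int = 10) -> SiteClassDistribution:
    """Discretize Beta(p, q) into ``k`` equal-probability omega classes.

    Class omega values are the conditional means of the beta over each
    quantile interval (the common codeml discretization), so the weighted
    mean equals p/(p+q) exactly for every ``k``.
    """
    if p <= 0 or q <= 0:
        raise ValueError("beta shape parameters must be > 0")
    if k < 1:
        raise ValueError("k must be >= 1")
    edges = stats.beta.ppf(np.linspace(0, 1, k + 1), p, q)
    mean = p / (p + q)
    # E[X; a<X<b] = mean * (I_b(p+1,q) - I_a(p+1,q)); each bin has mass 1/k
    partial = special.betainc(p + 1, q, edges)
    class_means = mean * np.diff(partial) * k
    return SiteClassDistribution(tuple(float(w) for w in class_means),
                                 tuple([1.0 / k] * k))


# ---------------------------------------------------------------------------
# likelihood-ratio tests
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LrtResult:
    statistic: float  # 2 * (lnL_alt - lnL_null), clamped at 0
    df: int
    p_value: float
    winner: str

    def __post_init__(self) -> None:
        if self.statistic < 0:
            raise ValueError("LRT statistic must be >= 0")


def lrt(lnl_null: float, lnl_alt: float, df: int = 1, *,
        null_label: str = "null", alt_label: str = "alt",
        alpha: float = 0.05, mixture: bool = False) -> LrtResult:
    """Likelihood-ratio test of nested codon models.

    ``2 * (lnL_alt - lnL_null)`` against chi-square(df).  For the
    boundary comparison of M8a vs M8 (the extra class pinned at omega=1),
    ``mixture=True`` uses the 50:50 chi0:chi1 mixture null instead of the
    plain (conservative) chi-square.  A negative statistic signals an
    optimizer artefact upstream; it is clamped to zero with a warning.
    """
    if df < 1:
        raise ValueError("df must be >= 1")
    stat = 2.0 * (lnl_alt - lnl_null)
    if stat < 0:
        warnings.warn(
            f"lnL_alt < lnL_null (2*dlnL = {stat:.4g}); clamping statistic to 0",
            stacklevel=2)
        stat = 0.0
    if mixture:
        p = 0.5 * stats.chi2.sf(stat, df) if stat > 0 else 1.0
    else:
        p = float(stats.chi2.sf(stat, df))
    winner = alt_label if p < alpha else null_label
    return LrtResult(statistic=stat, df=df, p_value=float(p), winner=winner)


# ---------------------------------------------------------------------------
# NG86 counting dN/dS
# ---------------------------------------------------------------------------

class NG86Result(NamedTuple):
    dn: float
    ds: float
    omega: float  # inf when ds == 0 < dn; nan when both are 0 or undefined


def _codon_sites(codon: str) -> tuple[float, float]:
    """(synonymous, nonsynonymous) site counts of one sense codon.

    Each position contributes syn_changes/3 synonymous sites; changes that
    create a stop codon count as nonsynonymous.
    """
    syn = 0.0
    aa = translate_codon(codon)
    for _, _, mutant in single_nt_neighbors(codon):
        if not is_stop(mutant) and translate_codon(mutant) == aa:
            syn += 1.0 / 3.0
    return syn, 3.0 - syn


def _pathway_counts(a: str, b: str) -> tuple[float, float]:
    """Average (syn, nonsyn) difference counts over mutational pathways.

    All orderings of the differing positions are enumerated; pathways that
    pass through a stop codon are discarded.  If every pathway is blocked
    (possible only for artificial codon pairs), all pathways are kept and
    steps into or out of a stop count as nonsynonymous.
    """
    diff = [i for i in range(3) if a[i] != b[i]]
    if not diff:
        return 0.0, 0.0
    kept: list[tuple[float, float]] = []
    blocked: list[tuple[float, float]] = []
    for order in itertools.permutations(diff):
        cur = a
        syn = nonsyn = 0.0
        through_stop = False
        for pos in order:
            nxt = cur[:pos] + b[pos] + cur[pos + 1:]
            if is_stop(nxt) and nxt != b:
                through_stop = True
            if (not is_stop(cur) and not is_stop(nxt)
                    and translate_codon(cur) == translate_codon(nxt)):
                syn += 1
            else:
                nonsyn += 1
            cur = nxt
        (blocked if through_stop else kept).append((syn, nonsyn))
    use = kept if kept else blocked
    return (sum(s for s, _ in use) / len(use),
            sum(n for _, n in use) / len(use))


def _jc_correct(p: float) -> float:
    """Jukes–Cantor multiple-hit correction of a proportion of differences."""
    if p >= 0.75:
        return math.nan
    return -0.75 * math.log1p(-4.0 * p / 3.0)


def ng86_dnds(seq_a: str, seq_b: str) -> NG86Result:
    """Nei–Gojobori (1986) counting estimate of (dN, dS, omega).

    Sequences must be equal-length and in frame.  Codon pairs containing
    gaps, ambiguity codes or stop codons are skipped pairwise.  Site and
    difference counts are averaged over both sequences and over all
    mutational pathway orderings; Jukes–Cantor correction is applied to
    the proportions.  pS >= 3/4 makes dS undefined (NaN).  The estimator
    is exactly symmetric in its arguments.
    """
    seq_a, seq_b = seq_a.upper(), seq_b.upper()
    if len(seq_a) != len(seq_b):
        raise ValueError("sequences differ in length")
    if len(seq_a) % 3:
        raise ValueError("sequence length not divisible by 3")
    s_sites = n_sites = 0.0
    s_diff = n_diff = 0.0
    n_codons = 0
    for i in range(0, len(seq_a), 3):
        ca, cb = seq_a[i:i + 3], seq_b[i:i + 3]
        if (set(ca) | set(cb)) - set("ACGT"):
            continue
        if is_stop(ca) or is_stop(cb):
            continue
        n_codons += 1
        sa, na = _codon_sites(ca)
        sb, nb = _codon_sites(cb)
        s_sites += (sa + sb) / 2.0
        n_sites += (na + nb) / 2.0
        sd, nd = _pathway_counts(ca, cb)
        s_diff += sd
        n_diff += nd
    if n_codons == 0:
        raise ValueError("no comparable codons between sequences")
    ps = s_diff / s_sites
    pn = n_diff / n_sites
    ds = _jc_correct(ps)
    dn = _jc_correct(pn)
    if math.isnan(dn) or math.isnan(ds):
        omega = math.nan
    elif ds == 0.0:
        omega = math.inf if dn > 0 else math.nan
    else:
        omega = dn / ds
    return NG86Result(dn=dn, ds=ds, omega=omega)


# ---------------------------------------------------------------------------
# root-to-tip omega (omega-lineage)
# ---------------------------------------------------------------------------

def _fitch_root_codons(alignment: CodonAlignment, tree: PhyloTree) -> str:
    """Most-parsimonious root sequence, one Fitch pass per codon column.

    Ties at the root are broken toward the codon most frequent among the
    tips at that column, then lexicographically, so the reconstruction is
    deterministic.  Columns with no usable tip codon become gap codons.
    """
    tip_codons = {t: alignment.codons(t) for t in alignment.taxa
                  if t in {l.taxon.label for l in tree.leaf_node_iter()}}
    if not tip_codons:
        raise ValueError("no overlap between alignment taxa and tree tips")
    root_parts: list[str] = []
    for col in range(alignment.n_codons):
        observed = [cods[col] for cods in tip_codons.values()
                    if not (set(cods[col]) - set("ACGT")) and not is_stop(cods[col])]
        if not observed:
            root_parts.append("---")
            continue
        alphabet = frozenset(observed)
        sets: dict[object, frozenset] = {}
        for node in tree.postorder_node_iter():
            if node.is_leaf():
                taxon = node.taxon.label
                cods = tip_codons.get(taxon)
                state = cods[col] if cods is not None else None
                sets[node] = (frozenset([state]) if state in alphabet
                              else alphabet)  # missing/ambiguous tip: wildcard
            else:
                child_sets = [sets[c] for c in node.child_nodes()]
                inter = frozenset.intersection(*child_sets)
                sets[node] = inter if inter else frozenset.union(*child_sets)
        root_set = sets[tree.seed_node]
        freq = {s: observed.count(s) for s in root_set}
        root_parts.append(min(root_set, key=lambda s: (-freq[s], s)))
    return "".join(root_parts)


def root_to_tip_omega(alignment: CodonAlignment, tree: PhyloTree,
                      species: str) -> float:
    """Foreground omega of one species' root-to-tip path (omega-lineage).

    The root sequence is reconstructed by Fitch parsimony per codon column
    and the NG86 estimate between root and tip approximates the
    foreground omega a two-ratio branch model would assign to the path
    from the root through all intermediate branches to the tip.  Returns
    NaN (a missing table entry) when omega is undefined on the path (no
    synonymous or no substitutions at all).
    """
    if species not in alignment:
        raise KeyError(f"species {species!r} not in alignment")
    root_seq = _fitch_root_codons(alignment, tree)
    result = ng86_dnds(root_seq, alignment.sequence(species))
    if not math.isfinite(result.omega):
        logger.info("root_to_tip_omega: omega undefined for %s (dN=%.4g dS=%.4g)",
                    species, result.dn, result.ds)
        return math.nan
    return result.omega


def omega_lineage_table(alignments: Mapping[str, CodonAlignment],
                        tree: PhyloTree) -> OmegaLineageTable:
    """Root-to-tip omega for every gene and species present in the tree."""
    tips = [l.taxon.label for l in tree.leaf_node_iter()]
    rows = {}
    for gene, aln in alignments.items():
        root_seq = _fitch_root_codons(aln, tree)
        row = {}
        for sp in tips:
            if sp not in aln:
                row[sp] = math.nan
                continue
            res = ng86_dnds(root_seq, aln.sequence(sp))
            row[sp] = res.omega if math.isfinite(res.omega) else math.nan
        rows[gene] = row
    return OmegaLineageTable(pd.DataFrame.from_dict(rows, orient="index",
                                                    columns=tips))


# ---------------------------------------------------------------------------
# pseudogene screening
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class IndelRecord:
    start_column: int   # 1-based alignment nucleotide column
    length: int         # nucleotides
    kind: str           # "deletion" | "insertion"
    ref_start: int | None = None  # 1-based reference aa position, if mapped

    @property
    def frameshift(self) -> bool:
        return self.length % 3 != 0


@dataclass(frozen=True)
class StopRecord:
    codon_index: int          # 1-based codon column in the alignment
    ref_position: int | None  # 1-based reference aa numbering, if mapped
    codon: str


@dataclass(frozen=True)
class PseudogeneReport:
    """Loss-of-function evidence for one taxon's coding sequence."""

    taxon: str
    internal_stops: tuple[StopRecord, ...]
    frameshifts: tuple[IndelRecord, ...]
    inframe_indels: tuple[IndelRecord, ...]

    @property
    def is_clean(self) -> bool:
        return not (self.internal_stops or self.frameshifts or self.inframe_indels)


def _ref_codon_positions(alignment: CodonAlignment, reference_taxon: str
                         ) -> list[int | None]:
    """1-based reference codon numbering per alignment codon column."""
    ref = alignment.sequence(reference_taxon)
    positions: list[int | None] = []
    count = 0
    for i in range(alignment.n_codons):
        codon = ref[3 * i: 3 * i + 3]
        if "-" in codon:
            positions.append(None)
        else:
            count += 1
            positions.append(count)
    return positions


def pseudogene_screen(alignment: CodonAlignment, taxon: str,
                      reference_taxon: str | None = None) -> PseudogeneReport:
    """Screen one sequence for premature stops and disruptive indels.

    Internal stop codons are any TAA/TAG/TGA strictly before the final
    codon column.  Indels are called from the gap pattern relative to the
    reference row: a gap run whose length is not a multiple of three is a
    frameshift, otherwise an in-frame indel.  Reference-numbered positions
    (e.g. bovine-rhodopsin-style numbering via a chosen reference row) are
    attached when a reference taxon is given.
    """
    if taxon not in alignment:
        raise KeyError(f"taxon {taxon!r} not in alignment")
    seq = alignment.sequence(taxon)
    ref_pos = (_ref_codon_positions(alignment, reference_taxon)
               if reference_taxon is not None else [None] * alignment.n_codons)

    stops = []
    for i in range(alignment.n_codons - 1):  # final codon excluded
        codon = seq[3 * i: 3 * i + 3]
        if codon in STOP_CODONS:
            stops.append(StopRecord(codon_index=i + 1, ref_position=ref_pos[i],
                                    codon=codon))

    frameshifts: list[IndelRecord] = []
    inframe: list[IndelRecord] = []
    if reference_taxon is not None:
        ref = alignment.sequence(reference_taxon)
        i = 0
        while i < len(seq):
            if seq[i] == "-" and ref[i] != "-":
                kind = "deletion"
            elif seq[i] != "-" and ref[i] == "-":
                kind = "insertion"
            else:
                i += 1
                continue
            start = i
            while i < len(seq) and ((seq[i] == "-") != (ref[i] == "-")):
                # a run may switch kind only at a column where the roles flip
                if kind == "deletion" and not (seq[i] == "-" and ref[i] != "-"):
                    break
                if kind == "insertion" and not (seq[i] != "-" and ref[i] == "-"):
                    break
                i += 1
            rec = IndelRecord(start_column=start + 1, length=i - start, kind=kind,
                              ref_start=ref_pos[start // 3])
            (frameshifts if rec.frameshift else inframe).append(rec)
    report = PseudogeneReport(taxon=taxon, internal_stops=tuple(stops),
                              frameshifts=tuple(frameshifts),
                              inframe_indels=tuple(inframe))
    logger.info("pseudogene_screen %s: %d stops, %d frameshifts, %d in-frame indels",
                taxon, len(stops), len(frameshifts), len(inframe))
    return report


# ---------------------------------------------------------------------------
# reference site map
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ReferenceSiteMap:
    """Bidirectional alignment-column <-> ungapped-reference-position map.

    Both sides are 1-based.  Columns where the reference has a gap map to
    nothing.  Works at whichever residue granularity the alignment uses
    (nucleotides for codon alignments, amino acids for protein ones).
    """

    reference_taxon: str
    column_to_position: Mapping[int, int]
    position_to_column: Mapping[int, int]

    def position_of(self, column: int) -> int | None:
        return self.column_to_position.get(column)

    def column_of(self, position: int) -> int:
        try:
            return self.position_to_column[position]
        except KeyError:
            raise KeyError(f"reference position {position} out of range") from None


def reference_site_map(alignment: SequenceAlignment,
                       reference_taxon: str) -> ReferenceSiteMap:
    ref = alignment.sequence(reference_taxon)
    col_to_pos: dict[int, int] = {}
    pos = 0
    for col, ch in enumerate(ref, start=1):
        if ch != "-":
            pos += 1
            col_to_pos[col] = pos
    return ReferenceSiteMap(
        reference_taxon=reference_taxon,
        column_to_position=col_to_pos,
        position_to_column={p: c for c, p in col_to_pos.items()})


# ---------------------------------------------------------------------------
# single-site ancestral reconstruction (Fitch)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AncestralSiteReconstruction:
    node_sets: Mapping[str, frozenset]
    min_changes: int
    assignment: Mapping[str, str]
    root_label: str

    @property
    def root_states(self) -> frozenset:
        return self.node_sets[self.root_label]


def fitch_ancestral_site(tree: PhyloTree, tip_states: Mapping[str, str], *,
                         missing: str = "wildcard") -> AncestralSiteReconstruction:
    """Fitch parsimony for one categorical character (e.g. an amino acid).

    Bottom-up pass builds candidate state sets and counts the minimum
    number of changes; a deterministic top-down pass (lexicographically
    smallest admissible state) yields one most-parsimonious assignment.
    Tips absent from ``tip_states`` are treated as wildcards by default,
    or rejected with ``missing="error"``.
    """
    if missing not in ("wildcard", "error"):
        raise ValueError("missing must be 'wildcard' or 'error'")
    alphabet = frozenset(tip_states.values())
    if not alphabet:
        raise ValueError("no tip states supplied")

    labels: dict[object, str] = {}
    counter = 0
    for node in tree.preorder_node_iter():
        if node.is_leaf():
            labels[node] = node.taxon.label
        else:
            labels[node] = node.label or f"node{counter}"
            counter += 1

    sets: dict[object, frozenset] = {}
    changes = 0
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            name = node.taxon.label
            if name in tip_states:
                sets[node] = frozenset([tip_states[name]])
            elif missing == "wildcard":
                sets[node] = alphabet
            else:
                raise ValueError(f"tip {name!r} has no state")
        else:
            child_sets = [sets[c] for c in node.child_nodes()]
            inter = frozenset.intersection(*child_sets)
            if inter:
                sets[node] = inter
            else:
                sets[node] = frozenset.union(*child_sets)
                changes += 1

    assignment: dict[str, str] = {}
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            assignment[labels[node]] = min(sets[node])
        else:
            parent_state = assignment[labels[node.parent_node]]
            assignment[labels[node]] = (parent_state if parent_state in sets[node]
                                        else min(sets[node]))
    return AncestralSiteReconstruction(
        node_sets={labels[n]: s for n, s in sets.items()},
        min_changes=changes,
        assignment=assignment,
        root_label=labels[tree.seed_node])
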