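"""Synthetic data with controlled ground truth for every pipeline stage.

Emulates the shape of a comparative avian-genomics dataset: a rooted
species tree, in-frame codon alignments evolved under a chosen selection
regime (omega), transition bias (kappa) and GC content, planted
pseudogenization features, gene-by-species omega-lineage tables with a
tunable pairwise co-evolution strength, binary VS/UVS spectral traits
generated from a logistic model on omega, and site-class distribution
pairs with exactly computable exceedance probabilities.

All generators are deterministic under their seed, and every generator
returns (or records) the ground truth a test harness needs.
"""

from __future__ import annotations

import logging
import math
import random
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd
from dendropy.simulate import treesim
from scipy.special import expit

from ._codons import NT, SENSE_CODONS, is_transition
from .io_formats import (CodonAlignment, OmegaLineageTable, PhyloTree,
                         SiteClassDistribution, TraitTable)

logger = logging.getLogger("opsinevol")

__all__ = [
    "SimulationConfig", "PlantedFeatures", "OmegaTableTruth",
    "simulate_tree", "simulate_codon_alignment", "inject_pseudogene",
    "simulate_omega_table", "simulate_traits", "simulate_siteclass_pair",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for a full synthetic dataset.

    Defaults mirror the comparative setting the pipeline targets: 48
    species (the avian phylogenomics panel size), a Yule species tree
    rescaled to a realistic root-to-tip divergence of 0.3 substitutions
    per site, codon alignments of 500 codons (opsins are ~350-500 codons)
    with transition bias kappa=4 and balanced GC, purifying selection
    omega=0.2 as the typical gene-wide regime, and the logistic
    trait model at (beta0, beta1) = (4.44, -79.91).
    """

    seed: int = 0
    n_taxa: int = 48
    birth_rate: float = 1.0
    tree_height: float = 0.3        # root-to-tip, substitutions/site
    n_codons: int = 500
    omega: float = 0.2
    kappa: float = 4.0
    gc: float = 0.5
    rho: float = 0.0                # co-evolution strength in [0, 1]
    beta0: float = 4.44
    beta1: float = -79.91
    missingness: float = 0.1

    def __post_init__(self) -> None:
        for name in ("rho", "gc", "missingness"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.n_taxa < 2:
            raise ValueError("need at least 2 taxa")
        if self.n_codons < 1 or self.tree_height <= 0:
            raise ValueError("lengths must be positive")
        if self.omega < 0 or self.kappa <= 0:
            raise ValueError("omega must be >= 0 and kappa > 0")


# ---------------------------------------------------------------------------
# species tree
# ---------------------------------------------------------------------------

def simulate_tree(n_taxa: int, birth_rate: float = 1.0, seed: int = 0,
                  tree_height: float | None = None) -> PhyloTree:
    """Rooted Yule (pure-birth) species tree with ``n_taxa`` tips.

    Tips are relabelled ``sp01..spNN`` in leaf order so downstream inputs
    are predictable.  When ``tree_height`` is given, branch lengths are
    rescaled so the maximum root-to-tip path equals it (units:
    substitutions per site, matching the codon simulator).
    """
    if n_taxa < 2:
        raise ValueError("need at least 2 taxa")
    rng = random.Random(seed)
    tree = treesim.birth_death_tree(
        birth_rate=birth_rate, death_rate=0.0,
        num_extant_tips=n_taxa, rng=rng)
    width = max(2, len(str(n_taxa)))
    for i, leaf in enumerate(tree.leaf_node_iter(), start=1):
        leaf.taxon.label = f"sp{i:0{width}d}"
    if tree_height is not None:
        height = max(leaf.distance_from_root() for leaf in tree.leaf_node_iter())
        factor = tree_height / height
        for edge in tree.preorder_edge_iter():
            if edge.length is not None:
                edge.length *= factor
    logger.info("simulate_tree: %d tips, seed=%d", n_taxa, seed)
    return tree


# ---------------------------------------------------------------------------
# codon alignment simulation (M0-style, Gillespie per branch)
# ---------------------------------------------------------------------------

def _codon_rates(omega: float, kappa: float, gc: float
                 ) -> tuple[np.ndarray, list[list[int]], list[np.ndarray], np.ndarray]:
    """Precompute the M0 rate structure over the 61 sense codons.

    Rate of a single-nucleotide change is pi(target) * kappa^[transition]
    * omega^[nonsynonymous]; stop codons are unreachable.  Rates are
    rescaled so one unit of branch length is one expected substitution
    per nucleotide site at stationarity.
    """
    from ._codons import single_nt_neighbors, translate_codon

    pi_nt = {"A": (1 - gc) / 2, "T": (1 - gc) / 2,
             "C": gc / 2, "G": gc / 2}
    index = {c: i for i, c in enumerate(SENSE_CODONS)}
    pi = np.array([pi_nt[c[0]] * pi_nt[c[1]] * pi_nt[c[2]] for c in SENSE_CODONS])
    pi /= pi.sum()

    targets: list[list[int]] = []
    rates: list[np.ndarray] = []
    for codon in SENSE_CODONS:
        t_idx, t_rate = [], []
        for pos, nt, mutant in single_nt_neighbors(codon):
            if mutant not in index:
                continue  # stop codons masked out of the state space
            r = pi_nt[nt]
            if is_transition(codon[pos], nt):
                r *= kappa
            if translate_codon(codon) != translate_codon(mutant):
                r *= omega
            t_idx.append(index[mutant])
            t_rate.append(r)
        targets.append(t_idx)
        rates.append(np.asarray(t_rate))
    exit_rates = np.array([r.sum() for r in rates])
    mean_rate_per_site = float(pi @ exit_rates) / 3.0
    if mean_rate_per_site > 0:
        rates = [r / mean_rate_per_site for r in rates]
        exit_rates = exit_rates / mean_rate_per_site
    return pi, targets, rates, exit_rates


def _evolve_site(state: int, brlen: float, targets, rates, exit_rates,
                 rng: np.random.Generator) -> int:
    t = 0.0
    while True:
        rate = exit_rates[state]
        if rate <= 0:
            return state
        t += rng.exponential(1.0 / rate)
        if t > brlen:
            return state
        r = rates[state]
        state = targets[state][rng.choice(len(r), p=r / r.sum())]


def simulate_codon_alignment(tree: PhyloTree, omega: float, kappa: float,
                             gc: float, length: int, seed: int
                             ) -> CodonAlignment:
    """Evolve a stop-free in-frame codon alignment on ``tree``.

    An M0-style codon substitution process (single-nucleotide steps,
    transition bias kappa, nonsynonymous penalty/bonus omega, nucleotide
    frequencies set by the target GC fraction) is simulated site by site
    and branch by branch with a Gillespie scheme, starting from a root
    sequence drawn from the stationary codon frequencies.  Branch lengths
    are expected substitutions per nucleotide site.
    """
    if omega < 0 or kappa <= 0 or not 0 < gc < 1 or length < 1:
        raise ValueError("require omega >= 0, kappa > 0, gc in (0,1), length >= 1")
    rng = np.random.default_rng(seed)
    pi, targets, rates, exit_rates = _codon_rates(omega, kappa, gc)
    root = rng.choice(len(SENSE_CODONS), size=length, p=pi)

    states: dict[object, np.ndarray] = {tree.seed_node: root}
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        parent = states[node.parent_node]
        brlen = node.edge.length or 0.0
        if brlen == 0.0:
            states[node] = parent.copy()
            continue
        seq = parent.copy()
        for site in range(length):
            seq[site] = _evolve_site(int(seq[site]), brlen, targets, rates,
                                     exit_rates, rng)
        states[node] = seq
    taxa, seqs = [], []
    for leaf in tree.leaf_node_iter():
        taxa.append(leaf.taxon.label)
        seqs.append("".join(SENSE_CODONS[i] for i in states[leaf]))
    logger.info("simulate_codon_alignment: %d taxa x %d codons "
                "(omega=%.3g kappa=%.3g gc=%.2f seed=%d)",
                len(taxa), length, omega, kappa, gc, seed)
    return CodonAlignment(taxa=tuple(taxa), sequences=tuple(seqs))


# ---------------------------------------------------------------------------
# pseudogene planting
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PlantedFeatures:
    """Ground truth of features injected into one taxon's sequence."""

    taxon: str
    stop_codon_positions: tuple[int, ...]          # 1-based codon indices
    deletions: tuple[tuple[int, int], ...]          # (1-based nt start, nt length)


def inject_pseudogene(alignment: CodonAlignment, taxon: str,
                      stop_codon_positions: Sequence[int] = (),
                      deletions: Sequence[tuple[int, int]] = (),
                      stop_codon: str = "TAA"
                      ) -> tuple[CodonAlignment, PlantedFeatures]:
    """Plant premature stops and/or deletions into one taxon's row.

    ``stop_codon_positions`` are 1-based codon indices; ``deletions`` are
    (1-based nucleotide start, length in nucleotides) pairs realised as
    gap runs in the focal row (lengths not divisible by 3 therefore plant
    frameshifts).  Returns the modified alignment together with the
    planted ground truth.
    """
    seq = list(alignment.sequence(taxon))
    n = len(seq)
    for pos in stop_codon_positions:
        if not 1 <= pos <= n // 3:
            raise ValueError(f"codon position {pos} beyond sequence ({n // 3} codons)")
        seq[3 * (pos - 1): 3 * pos] = list(stop_codon)
    for start, length in deletions:
        if not 1 <= start <= n or start - 1 + length > n:
            raise ValueError(f"deletion ({start}, {length}) beyond sequence length {n}")
        for i in range(start - 1, start - 1 + length):
            seq[i] = "-"
    new_seqs = tuple("".join(seq) if t == taxon else s
                     for t, s in zip(alignment.taxa, alignment.sequences))
    truth = PlantedFeatures(taxon=taxon,
                            stop_codon_positions=tuple(stop_codon_positions),
                            deletions=tuple((s, l) for s, l in deletions))
    return CodonAlignment(taxa=alignment.taxa, sequences=new_seqs), truth


# ---------------------------------------------------------------------------
# omega-lineage tables with co-evolution
# ---------------------------------------------------------------------------

_CATEGORIES = np.array(["A", "C", "N"])
_CATEGORY_P = np.array([0.25, 0.25, 0.5])


@dataclass(frozen=True)
class OmegaTableTruth:
    """Ground truth behind a simulated omega-lineage table."""

    categories: pd.DataFrame       # genes x species, before missingness
    missing_mask: pd.DataFrame     # genes x species, True where masked
    rho: pd.DataFrame              # gene x gene co-evolution strengths used
    seed: int


def _rho_frame(genes: Sequence[str], rho) -> pd.DataFrame:
    frame = pd.DataFrame(0.0, index=list(genes), columns=list(genes))
    if isinstance(rho, (int, float)):
        # scalar: couple consecutive gene pairs (g0,g1), (g2,g3), ...
        for i in range(0, len(genes) - 1, 2):
            frame.iloc[i, i + 1] = frame.iloc[i + 1, i] = float(rho)
    elif isinstance(rho, Mapping):
        for (ga, gb), r in rho.items():
            frame.loc[ga, gb] = frame.loc[gb, ga] = float(r)
    else:
        arr = np.asarray(rho, dtype=float)
        if arr.shape != (len(genes), len(genes)):
            raise ValueError("rho matrix shape mismatch")
        frame.iloc[:, :] = arr
    if ((frame.to_numpy() < 0) | (frame.to_numpy() > 1)).any():
        raise ValueError("co-evolution strengths must lie in [0, 1]")
    return frame


def simulate_omega_table(genes: Sequence[str], species: Sequence[str],
                         rho=0.0, seed: int = 0, missingness: float = 0.0,
                         gene_scales: Mapping[str, float] | None = None
                         ) -> tuple[OmegaLineageTable, OmegaTableTruth]:
    """Gene-by-species omega-lineage table with pairwise co-evolution.

    Each species draws a latent rate category per gene — accelerated,
    conserved or neutral with probabilities (0.25, 0.25, 0.5).  For a
    gene pair coupled at strength rho, the later gene copies the earlier
    gene's category with probability rho and draws independently
    otherwise, so at rho=0 two genes share a category with probability
    0.25^2 + 0.25^2 + 0.5^2 = 6/16 and at rho=1 they always match.
    Omega values are then drawn uniformly inside the per-gene band of the
    category (conserved below the 0.25 population quantile, accelerated
    above the 0.75 quantile, neutral between), so quartile categorization
    of the table recovers the latent categories up to sampling noise.
    """
    rng = np.random.default_rng(seed)
    genes, species = list(genes), list(species)
    rho_frame = _rho_frame(genes, rho)
    # per-gene omega scales spread over a realistic purifying range
    scales = {g: (gene_scales or {}).get(g, 0.1 + 0.3 * i / max(1, len(genes) - 1))
              for i, g in enumerate(genes)}

    cats = pd.DataFrame(index=genes, columns=species, dtype=object)
    for j, gene in enumerate(genes):
        partners = rho_frame.iloc[j, :j]
        own = rng.choice(_CATEGORIES, size=len(species), p=_CATEGORY_P)
        if len(partners) and partners.max() > 0:
            src = partners.idxmax()
            copy = rng.random(len(species)) < partners.max()
            own = np.where(copy, cats.loc[src].to_numpy(), own)
        cats.loc[gene] = own

    values = pd.DataFrame(index=genes, columns=species, dtype=float)
    for gene in genes:
        s = scales[gene]
        u = rng.random(len(species))
        row = cats.loc[gene].to_numpy()
        lo = np.where(row == "C", 0.0, np.where(row == "N", 0.25, 0.75)) * s
        hi = np.where(row == "C", 0.25, np.where(row == "N", 0.75, 1.0)) * s
        values.loc[gene] = lo + u * (hi - lo)

    mask = pd.DataFrame(rng.random((len(genes), len(species))) < missingness,
                        index=genes, columns=species)
    values = values.mask(mask)
    truth = OmegaTableTruth(categories=cats, missing_mask=mask,
                            rho=rho_frame, seed=seed)
    logger.info("simulate_omega_table: %d genes x %d species, seed=%d, "
                "%d masked", len(genes), len(species), seed,
                int(mask.to_numpy().sum()))
    return OmegaLineageTable(values), truth


# ---------------------------------------------------------------------------
# traits and site-class pairs
# ---------------------------------------------------------------------------

def simulate_traits(omegas: Mapping[str, float] | pd.Series, beta0: float,
                    beta1: float, seed: int = 0) -> TraitTable:
    """Binary VS/UVS trait per species from a logistic model on omega.

    Each species is VS (coded 1) with probability
    inverse-logit(beta0 + beta1 * omega).
    """
    if not (math.isfinite(beta0) and math.isfinite(beta1)):
        raise ValueError("logistic coefficients must be finite")
    series = pd.Series(dict(omegas), dtype=float)
    rng = np.random.default_rng(seed)
    probs = expit(beta0 + beta1 * series.to_numpy())
    draws = (rng.random(len(series)) < probs).astype(int)
    return TraitTable(pd.Series(draws, index=series.index))


def simulate_siteclass_pair(spec_b, spec_m, seed: int = 0
                            ) -> tuple[SiteClassDistribution, SiteClassDistribution]:
    """A pair of site-class distributions with enumerable P(wB > wM).

    Each spec is either an explicit mapping ``{omega: proportion}``
    (passed through) or an integer class count, in which case omega
    values are drawn uniformly on (0, 1.5) and proportions from a flat
    Dirichlet.
    """
    rng = np.random.default_rng(seed)

    def build(spec) -> SiteClassDistribution:
        if isinstance(spec, SiteClassDistribution):
            return spec
        if isinstance(spec, Mapping):
            return SiteClassDistribution.from_pairs(spec)
        k = int(spec)
        omegas = rng.uniform(0.0, 1.5, size=k)
        props = rng.dirichlet(np.ones(k))
        return SiteClassDistribution(tuple(omegas), tuple(props))

    return build(spec_b), build(spec_m)
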