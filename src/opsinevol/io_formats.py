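"""Readers, writers and domain containers for the opsin-evolution pipeline.

External formats handled here: FASTA codon / protein alignments, rooted
Newick trees, TSV gene-by-species omega tables, TSV binary trait tables,
TSV site-class distributions, YAML run configuration, and the text output
of PAML codeml site/branch model runs.

Conventions: all coordinates in files are 1-based; in-memory indices are
0-based half-open.  Missing cells in TSV are written empty; both empty and
"NA" are accepted on read.  Malformed input raises, it is never coerced.
"""

from __future__ import annotations

import logging
import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger("opsinevol")

NUCLEOTIDES = set("ACGTN-")
STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


class FrameError(FormatError):
    """Raised when a coding sequence is not a whole number of codons."""


# ---------------------------------------------------------------------------
# alignments
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SequenceAlignment:
    """Equal-length named sequences; base container for aligned data."""

    taxa: tuple[str, ...]
    sequences: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.taxa) != len(self.sequences):
            raise FormatError("taxa and sequences differ in number")
        if len(set(self.taxa)) != len(self.taxa):
            dupes = {t for t in self.taxa if self.taxa.count(t) > 1}
            raise FormatError(f"duplicate taxon identifiers: {sorted(dupes)}")
        lengths = {len(s) for s in self.sequences}
        if len(lengths) > 1:
            raise FormatError(f"ragged alignment: sequence lengths {sorted(lengths)}")

    def __len__(self) -> int:
        return len(self.sequences[0]) if self.sequences else 0

    def sequence(self, taxon: str) -> str:
        try:
            return self.sequences[self.taxa.index(taxon)]
        except ValueError:
            raise KeyError(f"taxon {taxon!r} not in alignment") from None

    def __contains__(self, taxon: str) -> bool:
        return taxon in self.taxa


@dataclass(frozen=True)
class CodonAlignment(SequenceAlignment):
    """In-frame aligned coding sequences, frame anchored at column 0.

    Sequences are uppercase strings over ``{A,C,G,T,N,-}`` whose common
    length is divisible by three.  Substrate for the GC-ratio screen, the
    NG86 dN/dS estimator and the pseudogene screen.
    """

    def __post_init__(self) -> None:
        object.__setattr__(self, "sequences",
                           tuple(s.upper() for s in self.sequences))
        super().__post_init__()
        if self.sequences and len(self) % 3 != 0:
            raise FrameError(
                f"alignment length {len(self)} is not divisible by 3; "
                "coding alignments must be whole codons")
        for taxon, seq in zip(self.taxa, self.sequences):
            bad = set(seq) - NUCLEOTIDES
            if bad:
                raise FormatError(
                    f"sequence {taxon!r} contains non-nucleotide symbols {sorted(bad)}")

    @property
    def n_codons(self) -> int:
        return len(self) // 3

    def codon(self, taxon: str, index: int) -> str:
        """Codon at 0-based codon ``index`` for ``taxon``."""
        return self.sequence(taxon)[3 * index: 3 * index + 3]

    def codons(self, taxon: str) -> list[str]:
        s = self.sequence(taxon)
        return [s[i:i + 3] for i in range(0, len(s), 3)]


def read_fasta(path: str | Path) -> CodonAlignment:
    """Read an in-frame codon alignment from FASTA.

    Rejects ragged records, duplicate taxa and lengths not divisible by 3.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise FormatError(f"{path}: no FASTA records found")
    aln = CodonAlignment(
        taxa=tuple(r.id for r in records),
        sequences=tuple(str(r.seq) for r in records),
    )
    logger.info("read_fasta: %s -> %d taxa x %d codons", path, len(aln.taxa), aln.n_codons)
    return aln


def read_protein_fasta(path: str | Path) -> SequenceAlignment:
    """Read an aligned amino-acid FASTA (no frame constraint)."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise FormatError(f"{path}: no FASTA records found")
    return SequenceAlignment(
        taxa=tuple(r.id for r in records),
        sequences=tuple(str(r.seq).upper() for r in records),
    )


def write_fasta(alignment: SequenceAlignment, path: str | Path) -> None:
    records = [SeqRecord(Seq(s), id=t, description="")
               for t, s in zip(alignment.taxa, alignment.sequences)]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# trees
# ---------------------------------------------------------------------------

PhyloTree = dendropy.Tree


def read_newick(path_or_string: str | Path) -> PhyloTree:
    """Read a rooted Newick tree; tips must be uniquely labelled.

    A basal trifurcation (or worse) is rejected: analyses here trace gene
    evolution inside a rooted species framework, so the user must root the
    tree first (e.g. with an outgroup).
    """
    text = str(path_or_string)
    if "(" not in text:  # a path, not a Newick literal
        text = Path(path_or_string).read_text()
    tree = dendropy.Tree.get(data=text, schema="newick",
                             preserve_underscores=True)
    nchild = len(tree.seed_node.child_nodes())
    if nchild > 2:
        raise FormatError(
            f"tree root has {nchild} children: the tree is unrooted; "
            "root it (e.g. on an outgroup) before analysis")
    labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    if len(set(labels)) != len(labels):
        raise FormatError("duplicate tip labels in tree")
    for edge in tree.preorder_edge_iter():
        if edge.length is not None and edge.length < 0:
            raise FormatError(f"negative branch length {edge.length}")
    return tree


def write_newick(tree: PhyloTree, path: str | Path) -> None:
    tree.write(path=str(path), schema="newick",
               suppress_rooting=True, unquoted_underscores=True)


# ---------------------------------------------------------------------------
# site-class distributions and codeml summaries
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SiteClassDistribution:
    """Discrete site categories for one gene: (omega value, proportion) pairs.

    These are the mixture categories of codeml-style site models (M7 beta
    classes, the M8 positive class, ...).  Proportions must sum to one.
    """

    omegas: tuple[float, ...]
    proportions: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.omegas) != len(self.proportions):
            raise ValueError("omegas and proportions differ in length")
        if not self.omegas:
            raise ValueError("empty site-class distribution")
        if any((not math.isfinite(w)) or w < 0 for w in self.omegas):
            raise ValueError("omega values must be finite and >= 0")
        if any(p < 0 or p > 1 for p in self.proportions):
            raise ValueError("proportions must lie in [0, 1]")
        total = math.fsum(self.proportions)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"proportions sum to {total!r}, not 1")

    @classmethod
    def from_pairs(cls, pairs: Mapping[float, float] | Iterable[tuple[float, float]]
                   ) -> "SiteClassDistribution":
        items = list(pairs.items()) if isinstance(pairs, Mapping) else list(pairs)
        return cls(tuple(float(w) for w, _ in items),
                   tuple(float(p) for _, p in items))

    def __len__(self) -> int:
        return len(self.omegas)


@dataclass(frozen=True)
class SiteModelSummary:
    """Parsed summary of one codeml site- or branch-model run."""

    gene: str
    model: str  # M7 | M8 | M8a | one-ratio | two-ratio
    lnl: float
    site_classes: SiteClassDistribution | None = None
    omega_background: float | None = None
    omega_foreground: float | None = None

    def __post_init__(self) -> None:
        for w in (self.omega_background, self.omega_foreground):
            if w is not None and w < 0:
                raise ValueError("omega must be >= 0")


SITE_MODELS = {"M7", "M8", "M8a"}
BRANCH_MODELS = {"one-ratio", "two-ratio"}

_LNL_RE = re.compile(r"lnL\s*(?:\([^)]*\))?\s*[:=]\s*(-?\d+(?:\.\d+)?)")
_CLASS_BLOCK_RE = re.compile(
    r"dN/dS\s*\(w\)\s*for site classes.*?\n\s*\n?"
    r"p:\s*((?:[\d.eE+-]+\s+)*[\d.eE+-]+)\s*\n"
    r"w:\s*((?:[\d.eE+-]+\s+)*[\d.eE+-]+)", re.S)
_BRANCH_W_RE = re.compile(r"w \(dN/dS\) for branches:\s*((?:[\d.eE+-]+\s*)+)")
_ONE_RATIO_W_RE = re.compile(r"omega \(dN/dS\)\s*=\s*([\d.eE+-]+)")


def parse_codeml_output(path: str | Path, model: str, gene: str = "") -> SiteModelSummary:
    """Parse a PAML 4.x codeml result file for one model.

    Only the PAML 4.x "NSsites" site-class block and the branch-model
    ``w (dN/dS) for branches`` line are recognised; anything else fails
    loudly rather than guessing at a dialect.
    """
    if model not in SITE_MODELS | BRANCH_MODELS:
        raise ValueError(f"unknown model label {model!r}")
    text = Path(path).read_text()
    gene = gene or Path(path).stem
    m = _LNL_RE.search(text)
    if m is None:
        raise FormatError(f"{path}: no 'lnL' line found")
    lnl = float(m.group(1))

    if model in SITE_MODELS:
        m = _CLASS_BLOCK_RE.search(text)
        if m is None:
            raise FormatError(
                f"{path}: no 'dN/dS (w) for site classes' block found for {model}")
        props = tuple(float(x) for x in m.group(1).split())
        omegas = tuple(float(x) for x in m.group(2).split())
        dist = SiteClassDistribution(omegas, props)
        return SiteModelSummary(gene=gene, model=model, lnl=lnl, site_classes=dist)

    if model == "two-ratio":
        m = _BRANCH_W_RE.search(text)
        if m is None:
            raise FormatError(f"{path}: no 'w (dN/dS) for branches' line found")
        ws = [float(x) for x in m.group(1).split()]
        if len(ws) < 2:
            raise FormatError(f"{path}: expected two branch omegas, got {ws}")
        return SiteModelSummary(gene=gene, model=model, lnl=lnl,
                                omega_background=ws[0], omega_foreground=ws[1])

    m = _ONE_RATIO_W_RE.search(text)
    if m is None:
        raise FormatError(f"{path}: no 'omega (dN/dS) =' line found")
    w = float(m.group(1))
    return SiteModelSummary(gene=gene, model=model, lnl=lnl,
                            omega_background=w, omega_foreground=w)


def read_siteclass_tsv(path: str | Path) -> SiteClassDistribution:
    """TSV with columns ``omega`` and ``proportion``, one class per row."""
    df = pd.read_csv(path, sep="\t")
    for col in ("omega", "proportion"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing column {col!r}")
    return SiteClassDistribution(tuple(df["omega"].astype(float)),
                                 tuple(df["proportion"].astype(float)))


def write_siteclass_tsv(dist: SiteClassDistribution, path: str | Path) -> None:
    pd.DataFrame({"omega": dist.omegas, "proportion": dist.proportions}
                 ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# omega-lineage tables and trait tables
# ---------------------------------------------------------------------------

@dataclass
class OmegaLineageTable:
    """Genes x species matrix of root-to-tip foreground omega estimates.

    ``data`` has gene rows and species columns; NaN marks a missing
    estimate (gene absent or omega undefined in that species).
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        self.data = self.data.astype(float)
        if self.data.index.has_duplicates or self.data.columns.has_duplicates:
            raise FormatError("duplicate gene or species names in omega table")
        if (self.data.to_numpy() < 0).any():
            raise FormatError("omega-lineage values must be >= 0")

    @property
    def genes(self) -> list[str]:
        return list(self.data.index)

    @property
    def species(self) -> list[str]:
        return list(self.data.columns)


def read_omega_table(path: str | Path) -> OmegaLineageTable:
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=["", "NA"],
                     keep_default_na=False)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    table = OmegaLineageTable(df)
    logger.info("read_omega_table: %s -> %d genes x %d species, %d missing",
                path, len(table.genes), len(table.species),
                int(df.isna().to_numpy().sum()))
    return table


def write_omega_table(table: OmegaLineageTable, path: str | Path) -> None:
    table.data.to_csv(path, sep="\t", na_rep="", index_label="gene")


@dataclass
class TraitTable:
    """Binary spectral class per species: VS = 1, UVS = 0."""

    data: pd.Series  # index: species, values in {0, 1}

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates:
            raise FormatError("duplicate species in trait table")
        vals = set(self.data.dropna().astype(int))
        if not vals <= {0, 1}:
            raise FormatError(f"trait values must be 0/1, got {sorted(vals)}")
        self.data = self.data.astype(float).astype("Int64")

    @property
    def species(self) -> list[str]:
        return list(self.data.index)


def read_trait_table(path: str | Path) -> TraitTable:
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=["", "NA"],
                     keep_default_na=False)
    return TraitTable(df.iloc[:, 0])


def write_trait_table(table: TraitTable, path: str | Path) -> None:
    table.data.rename("vs").to_csv(path, sep="\t", na_rep="", index_label="species")


# ---------------------------------------------------------------------------
# config + logging
# ---------------------------------------------------------------------------

def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise FormatError(f"{path}: config must be a YAML mapping")
    return cfg


def setup_logging(level: str = "INFO") -> None:
    logging.basicConfig(
        level=getattr(logging, level.upper()),
        format="%(asctime)s %(name)s %(levelname)s %(message)s")
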