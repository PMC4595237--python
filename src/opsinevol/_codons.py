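"""Genetic-code tables shared by the simulator and the dN/dS estimator.

Standard (vertebrate nuclear) code.  The table is spelled out rather than
pulled from Biopython so that neighbour/synonymy lookups can be
precomputed once into plain dicts.
"""

from __future__ import annotations

from functools import lru_cache

GENETIC_CODE: dict[str, str] = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}

STOP_CODONS = frozenset(c for c, aa in GENETIC_CODE.items() if aa == "*")
SENSE_CODONS = tuple(sorted(c for c in GENETIC_CODE if c not in STOP_CODONS))
NT = "ACGT"
PURINES = frozenset("AG")


def is_stop(codon: str) -> bool:
    return codon in STOP_CODONS


def translate_codon(codon: str) -> str:
    return GENETIC_CODE[codon]


def is_transition(a: str, b: str) -> bool:
    """A<->G or C<->T single-nucleotide change."""
    return (a in PURINES) == (b in PURINES) and a != b


@lru_cache(maxsize=None)
def single_nt_neighbors(codon: str) -> tuple[tuple[int, str, str], ...]:
    """All (position, new_nt, new_codon) one mutation away, stops included."""
    out = []
    for pos in range(3):
        for nt in NT:
            if nt != codon[pos]:
                out.append((pos, nt, codon[:pos] + nt + codon[pos + 1:]))
    return tuple(out)
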