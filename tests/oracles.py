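"""Independent reference implementations used only to check the library.

These are deliberately written with different algorithms/structures than
the package code: recursive pathway enumeration for NG86, a double loop
for the exceedance probability, Sankoff dynamic programming and full
labelling enumeration for parsimony, and raw sums of squares for the
one-way ANOVA.
"""

from __future__ import annotations

import itertools
import math

GENETIC_CODE = {
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
STOPS = {c for c, a in GENETIC_CODE.items() if a == "*"}


def brute_sites(codon: str) -> tuple[float, float]:
    syn = 0.0
    for pos in range(3):
        for nt in "ACGT":
            if nt == codon[pos]:
                continue
            mut = codon[:pos] + nt + codon[pos + 1:]
            if mut not in STOPS and GENETIC_CODE[mut] == GENETIC_CODE[codon]:
                syn += 1 / 3
    return syn, 3 - syn


def brute_pathways(a: str, b: str) -> tuple[float, float]:
    """Recursive enumeration of mutational pathways between two codons."""

    def walk(cur, remaining):
        if not remaining:
            return [[]]
        paths = []
        for pos in remaining:
            nxt = cur[:pos] + b[pos] + cur[pos + 1:]
            for tail in walk(nxt, [r for r in remaining if r != pos]):
                paths.append([(cur, nxt)] + tail)
        return paths

    diff = [i for i in range(3) if a[i] != b[i]]
    if not diff:
        return 0.0, 0.0
    all_paths = walk(a, diff)
    ok, bad = [], []
    for path in all_paths:
        has_stop = any(y in STOPS and y != b for _, y in path)
        syn = sum(1 for x, y in path
                  if x not in STOPS and y not in STOPS
                  and GENETIC_CODE[x] == GENETIC_CODE[y])
        (bad if has_stop else ok).append((syn, len(path) - syn))
    use = ok or bad
    return (sum(s for s, _ in use) / len(use),
            sum(n for _, n in use) / len(use))


def brute_ng86(seq_a: str, seq_b: str) -> tuple[float, float, float]:
    S = N = Sd = Nd = 0.0
    for i in range(0, len(seq_a), 3):
        ca, cb = seq_a[i:i + 3], seq_b[i:i + 3]
        if set(ca + cb) - set("ACGT") or ca in STOPS or cb in STOPS:
            continue
        for s, n in (brute_sites(ca), brute_sites(cb)):
            S += s / 2
            N += n / 2
        sd, nd = brute_pathways(ca, cb)
        Sd += sd
        Nd += nd

    def jc(p):
        return math.nan if p >= 0.75 else -0.75 * math.log(1 - 4 * p / 3)

    ds, dn = jc(Sd / S), jc(Nd / N)
    if math.isnan(dn) or math.isnan(ds):
        omega = math.nan
    elif ds == 0:
        omega = math.inf if dn > 0 else math.nan
    else:
        omega = dn / ds
    return dn, ds, omega


def brute_prob_exceed(dist_b, dist_m) -> float:
    total = 0.0
    for wb, pb in zip(dist_b.omegas, dist_b.proportions):
        for wm, pm in zip(dist_m.omegas, dist_m.proportions):
            if wb > wm:
                total += pb * pm
    return total


def sankoff_min_changes(tree, tip_states: dict) -> int:
    """Minimum parsimony changes by Sankoff DP with unit costs."""
    alphabet = sorted(set(tip_states.values()))
    inf = float("inf")
    cost = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            state = tip_states.get(node.taxon.label)
            cost[node] = {a: (0 if state in (None, a) else inf) for a in alphabet}
        else:
            cost[node] = {}
            for a in alphabet:
                total = 0.0
                for child in node.child_nodes():
                    total += min(cost[child][b] + (a != b) for b in alphabet)
                cost[node][a] = total
    return int(min(cost[tree.seed_node].values()))


def exhaustive_min_changes(tree, tip_states: dict) -> int:
    """Minimum changes by enumerating every internal labelling."""
    alphabet = sorted(set(tip_states.values()))
    internals = [n for n in tree.preorder_node_iter() if not n.is_leaf()]
    best = None
    for labels in itertools.product(alphabet, repeat=len(internals)):
        assign = dict(zip(internals, labels))

        def state(node):
            return (tip_states[node.taxon.label] if node.is_leaf()
                    else assign[node])

        changes = sum(state(n) != state(n.parent_node)
                      for n in tree.preorder_node_iter()
                      if n.parent_node is not None)
        best = changes if best is None else min(best, changes)
    return best


def anova_f_sums_of_squares(groups: list[list[float]]) -> float:
    """One-way ANOVA F from raw between/within sums of squares."""
    all_vals = [v for g in groups for v in g]
    grand = sum(all_vals) / len(all_vals)
    ss_between = sum(len(g) * (sum(g) / len(g) - grand) ** 2 for g in groups)
    ss_within = sum((v - sum(g) / len(g)) ** 2 for g in groups for v in g)
    df_b = len(groups) - 1
    df_w = len(all_vals) - len(groups)
    return (ss_between / df_b) / (ss_within / df_w)
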