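"""Independent brute-force oracles used by the test suite.

Everything here is deliberately naive — exhaustive enumeration or direct
definition-chasing — and shares no code with the implementation it checks.
"""

from __future__ import annotations

import itertools
from fractions import Fraction
from math import comb

from Bio.Phylo.BaseTree import Clade, Tree

# ---------------------------------------------------------------- trees

def all_rooted_trees(leaves: list[str]):
    """Every rooted bifurcating tree topology over the given leaves, as
    nested tuples; (2n-3)!! of them."""
    if len(leaves) == 1:
        yield leaves[0]
        return
    first, rest = leaves[0], leaves[1:]
    for sub in all_rooted_trees(rest):
        for t in _insert_on_every_edge(sub, first):
            yield t


def _insert_on_every_edge(tree, leaf):
    yield (leaf, tree)  # new root above the old one
    if isinstance(tree, tuple):
        a, b = tree
        for t in _insert_on_every_edge(a, leaf):
            yield (t, b)
        for t in _insert_on_every_edge(b, leaf):
            yield (a, t)


def tuple_to_clade(tree) -> Clade:
    if isinstance(tree, tuple):
        return Clade(clades=[tuple_to_clade(c) for c in tree])
    return Clade(name=tree)


def tuple_to_phylo(tree) -> Tree:
    return Tree(root=tuple_to_clade(tree), rooted=True)


def brute_force_parsimony(tree, leaf_states: dict[str, frozenset]) -> int:
    """Minimum substitution count over ALL ancestral (and missing-leaf)
    state assignments, by exhaustive enumeration."""
    alphabet = sorted(set().union(*leaf_states.values()))
    nodes, edges = [], []

    def collect(t):
        idx = len(nodes)
        nodes.append(t)
        if isinstance(t, tuple):
            for child in t:
                cidx = collect(child)
                edges.append((idx, cidx))
        return idx

    collect(tree)
    free = [
        i for i, t in enumerate(nodes)
        if isinstance(t, tuple) or len(leaf_states[t]) > 1
    ]
    fixed = {
        i: next(iter(leaf_states[t]))
        for i, t in enumerate(nodes)
        if not isinstance(t, tuple) and len(leaf_states[t]) == 1
    }
    best = None
    for combo in itertools.product(alphabet, repeat=len(free)):
        assign = dict(fixed)
        for i, st in zip(free, combo):
            t = nodes[i]
            if not isinstance(t, tuple) and st not in leaf_states[t]:
                break
            assign[i] = st
        else:
            cost = sum(assign[p] != assign[c] for p, c in edges)
            if best is None or cost < best:
                best = cost
    return best


def splits(tree: Tree) -> set[frozenset]:
    """Non-trivial leaf bipartition halves of an (un)rooted tree."""
    all_leaves = frozenset(t.name for t in tree.get_terminals())
    out = set()
    for cl in tree.get_nonterminals():
        side = frozenset(t.name for t in cl.get_terminals())
        if 1 < len(side) < len(all_leaves) - 1:
            out.add(min(side, all_leaves - side, key=sorted))
    return out


# ---------------------------------------------------------------- motifs

IUPAC_SETS = {
    "A": "A", "C": "C", "G": "G", "T": "T", "R": "AG", "Y": "CT", "S": "CG",
    "W": "AT", "K": "GT", "M": "AC", "B": "CGT", "D": "AGT", "H": "ACT",
    "V": "ACG", "N": "ACGT",
}
_RC = str.maketrans("ACGT", "TGCA")


def naive_motif_hits(seq: str, motif: str, both_strands: bool = True) -> list[tuple[int, str]]:
    """Expand the motif to every concrete sequence and str-search each."""
    def concrete(m):
        return ["".join(p) for p in itertools.product(*(IUPAC_SETS[c] for c in m))]

    hits = set()
    for word in concrete(motif):
        start = seq.find(word)
        while start != -1:
            hits.add((start + 1, "+"))
            start = seq.find(word, start + 1)
    if both_strands:
        rc_motif = motif.translate(str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN"))[::-1]
        if rc_motif != motif:
            for word in concrete(rc_motif):
                start = seq.find(word)
                while start != -1:
                    hits.add((start + 1, "-"))
                    start = seq.find(word, start + 1)
    return sorted(hits)


# ---------------------------------------------------------------- fisher

def fisher_two_sided_exact(a: int, b: int, c: int, d: int) -> Fraction:
    """Two-sided Fisher p by exact rational hypergeometric enumeration."""
    n, r1, c1 = a + b + c + d, a + b, a + c
    lo, hi = max(0, r1 + c1 - n), min(r1, c1)
    denom = comb(n, c1)
    pmf = {k: Fraction(comb(r1, k) * comb(n - r1, c1 - k), denom) for k in range(lo, hi + 1)}
    p_obs = pmf[a]
    return sum((q for q in pmf.values() if q <= p_obs), Fraction(0))
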