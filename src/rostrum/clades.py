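"""Clade structure: PCA assignment, genealogy, substitution counts, clock.

The two mitochondrial clades are recovered from the SNP matrix by principal
component analysis in the smartPCA style (missing genotypes imputed to the
column mean, columns centred, optional sqrt(p(1-p)) scaling) and specimens
are split by the sign of their first-component score.  The clade containing
a user-designated anchor specimen (a Svalbard-type control) is named
"eastern".  A neighbour-joining tree rooted on the outgroup carries Fitch
parsimony substitution counts per branch, from which the number of
substitutions separating each clade from the ingroup MRCA is read off and
converted to time under a strict molecular clock.

TMRCA values here are deterministic point estimates, not comparable to
Bayesian posterior (HPD) intervals.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from Bio.Phylo.BaseTree import Clade, Tree

from .seqio import MISSING, SnpMatrix

RATE_FAST = 0.75e-7   # subs/site/year, control-region-calibrated (fast) rate
RATE_SLOW = 0.7e-8    # subs/site/year, cytochrome-b-calibrated (slow) rate


class NoStructureError(ValueError):
    """First principal component carries no variance: no clade structure."""


@dataclass
class PcaResult:
    sample_scores: np.ndarray     # specimens x components, component 1 first
    snp_loadings: np.ndarray      # sites x components, unit-norm columns
    eigenvalues: np.ndarray       # descending, nonnegative
    specimen_ids: list[str]
    positions: np.ndarray


@dataclass
class CladeAssignment:
    labels: dict[str, str]                       # id -> "western" | "eastern"
    diagnostic_sites: list[int]                  # positions fixed between clades
    diagnostic_alleles: dict[int, tuple[str, str]]  # pos -> (allele_west, allele_east)
    loadings_by_site: dict[int, float]           # pos -> component-1 loading
    pc1_scores: dict[str, float]
    flagged: list[str] = field(default_factory=list)  # tie cases


@dataclass
class ClockConfig:
    rate_fast: float = RATE_FAST
    rate_slow: float = RATE_SLOW
    genome_length: int = 16565

    def __post_init__(self) -> None:
        if self.rate_fast <= 0 or self.rate_slow <= 0 or self.genome_length <= 0:
            raise ValueError("rates and genome length must be positive")


@dataclass
class Genealogy:
    tree: Tree
    branch_substitutions: dict[str, int]   # node name -> count on branch above it
    mrca_to_clade: dict[str, int]
    total_score: int


def _imputed(m: SnpMatrix) -> np.ndarray:
    g = m.genotypes.astype(float)
    g[m.genotypes == MISSING] = np.nan
    if np.isnan(g).all(axis=0).any():
        raise ValueError("all-missing site in matrix (should have been filtered)")
    col_mean = np.nanmean(g, axis=0)
    idx = np.where(np.isnan(g))
    g[idx] = col_mean[idx[1]]
    return g


def pca(m: SnpMatrix, scale: bool = False) -> PcaResult:
    """Principal components of the genotype matrix.

    Missing genotypes are imputed to the column mean before centring.  With
    ``scale=True`` each column is divided by sqrt(p(1-p)) where p is its
    non-missing alternate-allele frequency (sites treated as haploid
    biallelic 0/1; monomorphic-after-imputation columns are left unscaled).
    Component signs are canonicalized so the largest-magnitude loading on
    each component is positive.
    """
    if m.n_specimens < 2 or m.n_sites < 1:
        raise ValueError("need at least 2 specimens and 1 site")
    g = _imputed(m)
    center = g.mean(axis=0)
    x = g - center
    if scale:
        p = center.clip(0.0, None)
        denom = np.sqrt(p * (1.0 - p.clip(None, 1.0)))
        denom[denom <= 0] = 1.0
        x = x / denom
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    scores = u * s
    loadings = vt.T
    eig = s**2 / max(m.n_specimens - 1, 1)
    for c in range(loadings.shape[1]):
        k = int(np.argmax(np.abs(loadings[:, c])))
        if loadings[k, c] < 0:
            loadings[:, c] *= -1
            scores[:, c] *= -1
    return PcaResult(
        sample_scores=scores, snp_loadings=loadings, eigenvalues=eig,
        specimen_ids=list(m.specimen_ids), positions=m.positions.copy(),
    )


def assign_clades(m: SnpMatrix, pc: PcaResult, anchor_id: str) -> CladeAssignment:
    """Two-clade labels from the sign of component-1 scores.

    The group containing ``anchor_id`` is named "eastern".  Specimens whose
    component-1 score is (numerically) zero are assigned to the anchor's
    clade and flagged.  Diagnostic sites are those whose non-missing allele
    sets are non-empty and disjoint between the two label groups.
    """
    if anchor_id not in pc.specimen_ids:
        raise ValueError(f"anchor specimen {anchor_id!r} not in matrix")
    s1 = pc.sample_scores[:, 0]
    if pc.eigenvalues[0] <= 1e-12:
        raise NoStructureError("component-1 eigenvalue is zero")
    tol = 1e-12 * max(np.abs(s1).max(), 1.0)
    sign = np.where(s1 > tol, 1, np.where(s1 < -tol, -1, 0))
    anchor_ix = pc.specimen_ids.index(anchor_id)
    anchor_sign = sign[anchor_ix] if sign[anchor_ix] != 0 else 1

    labels, flagged = {}, []
    for i, rid in enumerate(pc.specimen_ids):
        s = sign[i]
        if s == 0:
            flagged.append(rid)
            s = anchor_sign
        labels[rid] = "eastern" if s == anchor_sign else "western"

    east = [i for i, rid in enumerate(pc.specimen_ids) if labels[rid] == "eastern"]
    west = [i for i, rid in enumerate(pc.specimen_ids) if labels[rid] == "western"]
    diagnostic, alleles = [], {}
    for j, pos in enumerate(m.positions):
        col = m.genotypes[:, j]
        a_e = {m.alleles[j][g] for g in col[east] if g != MISSING}
        a_w = {m.alleles[j][g] for g in col[west] if g != MISSING}
        if a_e and a_w and not (a_e & a_w):
            diagnostic.append(int(pos))
            alleles[int(pos)] = (",".join(sorted(a_w)), ",".join(sorted(a_e)))
    loadings = {int(p): float(l) for p, l in zip(m.positions, pc.snp_loadings[:, 0])}
    scores = {rid: float(s1[i]) for i, rid in enumerate(pc.specimen_ids)}
    return CladeAssignment(
        labels=labels, diagnostic_sites=diagnostic, diagnostic_alleles=alleles,
        loadings_by_site=loadings, pc1_scores=scores, flagged=flagged,
    )


def pairwise_distances(m: SnpMatrix) -> tuple[list[str], np.ndarray]:
    """Missing-data-corrected Hamming distances including the outgroup.

    d(i,j) = (# differing jointly non-missing sites) / (fraction of sites
    jointly non-missing); pairs with no jointly called site get the maximal
    distance n_sites.  No multiple-hit correction is applied.
    """
    names = list(m.specimen_ids) + [m.outgroup_id]
    geno = np.vstack([m.genotypes, m.outgroup_row])
    n = len(names)
    d = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        gi, gj = geno[i], geno[j]
        joint = (gi != MISSING) & (gj != MISSING)
        nj = int(joint.sum())
        if nj == 0:
            dij = float(m.n_sites)
        else:
            ndiff = int((gi[joint] != gj[joint]).sum())
            dij = ndiff * m.n_sites / nj
        d[i, j] = d[j, i] = dij
    return names, d


def nj_tree(m: SnpMatrix) -> Tree:
    """Neighbour-joining tree over specimens + outgroup, rooted on the outgroup.

    Ties on the Q-criterion are broken by the lexicographically smallest pair
    of cluster labels (a cluster is labelled by its smallest member id), so
    the topology is reproducible.
    """
    names, d = pairwise_distances(m)
    if len(names) < 3:
        raise ValueError("neighbour joining needs at least 3 records")
    tree = neighbor_joining(names, d)
    tree.root_with_outgroup(m.outgroup_id)
    return tree


def neighbor_joining(names: list[str], dist: np.ndarray) -> Tree:
    """Plain neighbour joining from a symmetric distance matrix (unrooted)."""
    nodes: dict[str, Clade] = {nm: Clade(name=nm) for nm in names}
    labels: dict[str, str] = {nm: nm for nm in names}   # cluster -> smallest leaf id
    d: dict[frozenset, float] = {}
    for i, j in itertools.combinations(range(len(names)), 2):
        d[frozenset((names[i], names[j]))] = float(dist[i, j])
    active = list(names)
    counter = 0
    while len(active) > 2:
        n = len(active)
        r = {a: sum(d[frozenset((a, b))] for b in active if b != a) for a in active}
        best, best_pair = None, None
        for a, b in itertools.combinations(active, 2):
            q = (n - 2) * d[frozenset((a, b))] - r[a] - r[b]
            key = tuple(sorted((labels[a], labels[b])))
            if best is None or q < best[0] - 1e-12 or (abs(q - best[0]) <= 1e-12 and key < best[1]):
                best, best_pair = (q, key), (a, b)
        a, b = best_pair
        dab = d[frozenset((a, b))]
        la = 0.5 * dab + (r[a] - r[b]) / (2 * (n - 2))
        lb = dab - la
        nodes[a].branch_length = max(la, 0.0)
        nodes[b].branch_length = max(lb, 0.0)
        counter += 1
        new = f"__nj{counter}"
        nodes[new] = Clade(clades=[nodes[a], nodes[b]])
        labels[new] = min(labels[a], labels[b])
        for c in active:
            if c in (a, b):
                continue
            d[frozenset((new, c))] = 0.5 * (
                d[frozenset((a, c))] + d[frozenset((b, c))] - dab
            )
        active = [c for c in active if c not in (a, b)] + [new]
    a, b = sorted(active, key=lambda c: labels[c])
    dab = d[frozenset((a, b))]
    nodes[a].branch_length = 0.5 * dab
    nodes[b].branch_length = 0.5 * dab
    root = Clade(clades=[nodes[a], nodes[b]])
    return Tree(root=root, rooted=False)


def _leaf_state_sets(m: SnpMatrix, j: int) -> dict[str, frozenset]:
    full = frozenset(range(len(m.alleles[j])))
    states = {}
    for i, rid in enumerate(m.specimen_ids):
        g = m.genotypes[i, j]
        states[rid] = full if g == MISSING else frozenset((int(g),))
    og = m.outgroup_row[j]
    states[m.outgroup_id] = full if og == MISSING else frozenset((int(og),))
    return states


def fitch_site(root: Clade, leaf_states: dict[str, frozenset]) -> tuple[int, dict]:
    """Fitch parsimony for one site on a rooted tree.

    Returns ``(minimal substitution count, per-branch count map)`` where the
    map is keyed by child clade (object identity) and holds 0/1 counts of one
    most-parsimonious labelling obtained by the standard top-down refinement.
    Leaves with a full state set (missing data) never force a substitution.
    """
    sets: dict[int, frozenset] = {}
    count = 0
    for node in reversed(list(root.find_clades(order="level"))):
        if node.is_terminal():
            sets[id(node)] = leaf_states[node.name]
        else:
            # pairwise left fold: exact for bifurcations, the standard
            # generalization for multifurcating nodes
            s = sets[id(node.clades[0])]
            for ch in node.clades[1:]:
                t = s & sets[id(ch)]
                if t:
                    s = t
                else:
                    s = s | sets[id(ch)]
                    count += 1
            sets[id(node)] = s
    branch: dict[int, int] = {}
    assigned: dict[int, int] = {id(root): min(sets[id(root)])}
    for node in root.find_clades(order="preorder"):
        st = assigned[id(node)]
        for ch in node.clades:
            if st in sets[id(ch)]:
                assigned[id(ch)] = st
                branch[id(ch)] = branch.get(id(ch), 0)
            else:
                assigned[id(ch)] = min(sets[id(ch)])
                branch[id(ch)] = branch.get(id(ch), 0) + 1
    return count, branch


def fitch_counts(
    tree: Tree, m: SnpMatrix, clade_members: dict[str, list[str]] | None = None
) -> Genealogy:
    """Per-branch minimal substitution counts summed over all sites.

    ``clade_members`` maps clade name -> specimen ids; for each clade the
    substitutions on the path from the ingroup root (the non-outgroup child
    of the root) down to that clade's ancestral node are reported as
    ``mrca_to_clade``.  Branch lengths on the returned tree are replaced by
    the substitution counts.
    """
    leaves = {t.name for t in tree.get_terminals()}
    expect = set(m.specimen_ids) | {m.outgroup_id}
    if leaves != expect:
        raise ValueError("tree leaves do not match matrix specimens + outgroup")

    root = tree.root
    totals: dict[int, int] = {}
    score = 0
    for j in range(m.n_sites):
        c, branch = fitch_site(root, _leaf_state_sets(m, j))
        score += c
        for k, v in branch.items():
            totals[k] = totals.get(k, 0) + v

    counter = 0
    names: dict[int, str] = {}
    for node in tree.find_clades():
        if node.name is None:
            counter += 1
            node.name = f"node{counter}"
        names[id(node)] = node.name
        if node is not root:
            node.branch_length = float(totals.get(id(node), 0))
    branch_subs = {
        names[k]: int(v) for k, v in totals.items() if k in names and k != id(root)
    }

    mrca: dict[str, int] = {}
    if clade_members:
        og_leaf = next(t for t in tree.get_terminals() if t.name == m.outgroup_id)
        ingroup_root = root
        kids = [c for c in root.clades if c is not og_leaf]
        if len(kids) == 1:
            ingroup_root = kids[0]
        for cname, members in clade_members.items():
            node = (
                tree.common_ancestor(members) if len(members) > 1
                else next(t for t in tree.get_terminals() if t.name == members[0])
            )
            if node is ingroup_root:
                mrca[cname] = 0
                continue
            path = ingroup_root.get_path(node)
            if path is None:
                raise ValueError(f"clade {cname!r} not below the ingroup root")
            mrca[cname] = int(sum(totals.get(id(p), 0) for p in path))
    return Genealogy(
        tree=tree, branch_substitutions=branch_subs,
        mrca_to_clade=mrca, total_score=score,
    )


def clock_tmrca(
    substitutions: float, cfg: ClockConfig, rate: str = "fast"
) -> float:
    """Strict-clock point estimate: years = (substitutions / L) / rate."""
    if substitutions < 0:
        raise ValueError("substitution count must be nonnegative")
    r = {"fast": cfg.rate_fast, "slow": cfg.rate_slow}.get(rate)
    if r is None:
        raise ValueError(f"rate must be 'fast' or 'slow', got {rate!r}")
    return substitutions / cfg.genome_length / r
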