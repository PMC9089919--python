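"""Distance-based phylogenetics for trans-species polymorphism (TSP)
detection: Kimura two-parameter (K80) distances, neighbor-joining tree
construction, identical-allele sharing across species, and species-monophyly
tests on unrooted trees.

Allelic lineages of the MHC predate speciation events under long-term
balancing selection; the signature is identical or phylogenetically
interleaved alleles across species.  This module asks exactly those two
questions of a multi-species allele panel: (i) which alleles are identical
across species, and (ii) which species fail to be monophyletic on the
allele tree.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import dendropy
import numpy as np

_PURINES = {"A", "G"}
_PYRIMIDINES = {"C", "T"}
_VALID = {"A", "C", "G", "T"}


# ---------------------------------------------------------------------------
# distances
# ---------------------------------------------------------------------------

def transition_transversion_proportions(seq_a: str, seq_b: str) -> tuple[float, float, int]:
    """P (transition) and Q (transversion) proportions over comparable sites.

    Columns containing gaps or ambiguity codes in either sequence are
    excluded pairwise.
    """
    if len(seq_a) != len(seq_b):
        raise ValueError("sequences must be aligned to equal length")
    n = ti = tv = 0
    for a, b in zip(seq_a.upper(), seq_b.upper()):
        if a not in _VALID or b not in _VALID:
            continue
        n += 1
        if a == b:
            continue
        if (a in _PURINES) == (b in _PURINES):
            ti += 1
        else:
            tv += 1
    if n == 0:
        raise ValueError("no comparable (gap-free, unambiguous) columns")
    return ti / n, tv / n, n


def k80_distance(seq_a: str, seq_b: str, gamma_alpha: float | None = None) -> tuple[float, float, float]:
    """Kimura two-parameter distance d = −½·ln((1−2P−Q)·√(1−2Q)).

    With ``gamma_alpha`` the K80+Γ rate-heterogeneity correction is applied
    instead.  Saturated pairs (non-positive log argument) get d = inf.
    Returns (d, P, Q).
    """
    P, Q, _ = transition_transversion_proportions(seq_a, seq_b)
    w1 = 1.0 - 2.0 * P - Q
    w2 = 1.0 - 2.0 * Q
    if w1 <= 0.0 or w2 <= 0.0:
        return math.inf, P, Q
    if gamma_alpha is None:
        d = -0.5 * math.log(w1 * math.sqrt(w2))
    else:
        a = gamma_alpha
        d = (a / 2.0) * (w1 ** (-1.0 / a) + 0.5 * w2 ** (-1.0 / a) - 1.5)
    return d, P, Q


@dataclass
class DistanceMatrix:
    taxa: list[str]
    d: np.ndarray
    P: np.ndarray | None = None
    Q: np.ndarray | None = None

    def __post_init__(self):
        self.d = np.asarray(self.d, dtype=float)
        if self.d.shape != (len(self.taxa), len(self.taxa)):
            raise ValueError("distance matrix shape does not match taxa")
        if not np.allclose(self.d, self.d.T):
            raise ValueError("distance matrix must be symmetric")
        if np.any(np.diag(self.d) != 0):
            raise ValueError("diagonal must be zero")

    @classmethod
    def from_sequences(
        cls, sequences: dict[str, str], gamma_alpha: float | None = None
    ) -> "DistanceMatrix":
        taxa = list(sequences)
        n = len(taxa)
        d = np.zeros((n, n))
        P = np.zeros((n, n))
        Q = np.zeros((n, n))
        for i, j in itertools.combinations(range(n), 2):
            dij, pij, qij = k80_distance(sequences[taxa[i]], sequences[taxa[j]], gamma_alpha)
            d[i, j] = d[j, i] = dij
            P[i, j] = P[j, i] = pij
            Q[i, j] = Q[j, i] = qij
        return cls(taxa=taxa, d=d, P=P, Q=Q)


# ---------------------------------------------------------------------------
# trees
# ---------------------------------------------------------------------------

@dataclass
class Node:
    name: str | None = None
    length: float = 0.0
    children: list["Node"] = field(default_factory=list)

    def is_tip(self) -> bool:
        return not self.children


class PhyloTree:
    """An unrooted tree stored with an arbitrary root node.

    Tip labels are unique; branch lengths live on child edges.
    """

    def __init__(self, root: Node):
        self.root = root
        names = [t.name for t in self.tips()]
        if len(set(names)) != len(names):
            raise ValueError("tip labels must be unique")

    def tips(self) -> list[Node]:
        return [n for n in self.postorder() if n.is_tip()]

    def tip_names(self) -> list[str]:
        return [t.name for t in self.tips()]

    def postorder(self) -> list[Node]:
        out: list[Node] = []
        stack = [(self.root, False)]
        while stack:
            node, seen = stack.pop()
            if seen:
                out.append(node)
            else:
                stack.append((node, True))
                for ch in node.children:
                    stack.append((ch, False))
        return out

    # -- newick via dendropy ------------------------------------------------
    def newick(self) -> str:
        def fmt(node: Node) -> str:
            if node.is_tip():
                body = node.name or ""
            else:
                body = "(" + ",".join(fmt(c) for c in node.children) + ")"
            return body if node is self.root else f"{body}:{node.length:.10g}"

        return fmt(self.root) + ";"

    @classmethod
    def from_newick(cls, newick: str) -> "PhyloTree":
        dt = dendropy.Tree.get(data=newick, schema="newick")

        def convert(dnode) -> Node:
            node = Node(
                name=dnode.taxon.label if dnode.taxon else dnode.label,
                length=dnode.edge.length or 0.0,
                children=[convert(c) for c in dnode.child_nodes()],
            )
            return node

        return cls(convert(dt.seed_node))

    # -- metrics ------------------------------------------------------------
    def patristic_distances(self) -> tuple[list[str], np.ndarray]:
        """Tip-to-tip path-length matrix."""
        tips = self.tips()
        names = [t.name for t in tips]
        # distance from every node to each tip via postorder accumulation
        dist_to_root: dict[int, float] = {}

        def walk(node: Node, acc: float):
            dist_to_root[id(node)] = acc
            for ch in node.children:
                walk(ch, acc + ch.length)

        walk(self.root, 0.0)
        parent: dict[int, Node] = {}
        for n in self.postorder():
            for ch in n.children:
                parent[id(ch)] = n

        def path(a: Node, b: Node) -> float:
            # lowest common ancestor by ancestor sets
            anc = {}
            x = a
            while True:
                anc[id(x)] = x
                if id(x) not in parent:
                    break
                x = parent[id(x)]
            y = b
            while id(y) not in anc:
                y = parent[id(y)]
            return dist_to_root[id(a)] + dist_to_root[id(b)] - 2 * dist_to_root[id(y)]

        n = len(tips)
        out = np.zeros((n, n))
        for i, j in itertools.combinations(range(n), 2):
            out[i, j] = out[j, i] = path(tips[i], tips[j])
        return names, out

    def bipartitions(self) -> list[frozenset[str]]:
        """For every edge, the set of tip names on the child side."""
        all_tips = frozenset(self.tip_names())
        below: dict[int, frozenset[str]] = {}
        out = []
        for node in self.postorder():
            if node.is_tip():
                below[id(node)] = frozenset([node.name])
            else:
                below[id(node)] = frozenset().union(*(below[id(c)] for c in node.children))
            if node is not self.root:
                out.append(below[id(node)])
        # root side sets are complements; include them so callers need not
        out.extend(all_tips - s for s in list(out))
        return out


def neighbor_joining(dm: DistanceMatrix) -> PhyloTree:
    """Saitou–Nei neighbor joining.

    Negative branch-length estimates are clamped to zero with the deficit
    moved to the sibling branch (total kept), the usual practical fix.
    The final tree is unrooted, represented with a trifurcating root.
    """
    n = len(dm.taxa)
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    nodes: list[Node] = [Node(name=t) for t in dm.taxa]
    D = dm.d.astype(float).copy()
    active = list(range(n))
    while len(active) > 3:
        m = len(active)
        r = {i: sum(D[i, j] for j in active if j != i) for i in active}
        best, bi, bj = None, None, None
        for ii, i in enumerate(active):
            for j in active[ii + 1 :]:
                q = (m - 2) * D[i, j] - r[i] - r[j]
                if best is None or q < best - 1e-15:
                    best, bi, bj = q, i, j
        i, j = bi, bj
        li = 0.5 * D[i, j] + (r[i] - r[j]) / (2 * (m - 2))
        lj = D[i, j] - li
        if li < 0:
            lj += li  # move deficit to the sibling
            li = 0.0
        if lj < 0:
            li += lj
            lj = 0.0
        nodes[i].length = li
        nodes[j].length = max(lj, 0.0)
        new = Node(children=[nodes[i], nodes[j]])
        # distances from the new node
        newD = np.zeros(D.shape[0] + 1)
        for k in active:
            if k in (i, j):
                continue
            newD[k] = 0.5 * (D[i, k] + D[j, k] - D[i, j])
        D = np.pad(D, ((0, 1), (0, 1)))
        D[-1, : len(newD) - 1] = newD[:-1]
        D[: len(newD) - 1, -1] = newD[:-1]
        nodes.append(new)
        active = [k for k in active if k not in (i, j)] + [len(nodes) - 1]
    # join the last three around a trifurcating root
    i, j, k = active
    li = 0.5 * (D[i, j] + D[i, k] - D[j, k])
    lj = 0.5 * (D[i, j] + D[j, k] - D[i, k])
    lk = 0.5 * (D[i, k] + D[j, k] - D[i, j])
    for idx, ln in ((i, li), (j, lj), (k, lk)):
        nodes[idx].length = max(ln, 0.0)
    root = Node(children=[nodes[i], nodes[j], nodes[k]])
    return PhyloTree(root)


# ---------------------------------------------------------------------------
# trans-species polymorphism
# ---------------------------------------------------------------------------

def identical_allele_groups(
    alleles: dict[str, str],
    species_of: dict[str, str],
    overlap_rule: str = "full",
) -> list[dict]:
    """Partition alleles into groups sharing one nucleotide sequence.

    ``overlap_rule='full'`` groups exact full-length matches only;
    ``'trimmed'`` also merges records where the shorter sequence occurs as a
    contiguous window of the longer (records of different lengths compared
    over their overlap), taking the transitive closure.  Groups spanning two
    or more species are flagged as TSP evidence.
    """
    if not alleles:
        raise ValueError("empty allele collection")
    if overlap_rule not in ("full", "trimmed"):
        raise ValueError(f"unknown overlap rule {overlap_rule!r}")
    names = list(alleles)
    parent = {n: n for n in names}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(a, b):
        parent[find(a)] = find(b)

    for a, b in itertools.combinations(names, 2):
        sa, sb = alleles[a], alleles[b]
        if sa == sb:
            union(a, b)
        elif overlap_rule == "trimmed":
            short, long_ = (sa, sb) if len(sa) <= len(sb) else (sb, sa)
            if short in long_:
                union(a, b)
    groups: dict[str, list[str]] = {}
    for nm in names:
        groups.setdefault(find(nm), []).append(nm)
    out = []
    for members in groups.values():
        sp = sorted({species_of[m] for m in members})
        out.append(
            {
                "members": sorted(members),
                "species": sp,
                "cross_species": len(sp) >= 2,
            }
        )
    out.sort(key=lambda g: (-len(g["members"]), g["members"][0]))
    return out


def species_monophyly(tree: PhyloTree, species_of: dict[str, str]) -> dict:
    """Test, per species, whether its tips form a clade on the unrooted tree.

    A species is monophyletic iff some bipartition of the tree separates
    exactly its tips from the rest.  Species with one tip are vacuously
    monophyletic (noted).  TSP is reported when any species with ≥ 2 tips is
    non-monophyletic.
    """
    tips = set(tree.tip_names())
    missing = tips - set(species_of)
    if missing:
        raise ValueError(f"tips without species assignment: {sorted(missing)}")
    species = sorted({species_of[t] for t in tips})
    if len(species) < 2:
        raise ValueError("need at least 2 species")
    biparts = set(tree.bipartitions())
    per_species = {}
    for sp in species:
        sp_tips = frozenset(t for t in tips if species_of[t] == sp)
        if len(sp_tips) == 1:
            per_species[sp] = {"n_tips": 1, "monophyletic": True, "vacuous": True}
        else:
            mono = sp_tips in biparts or sp_tips == frozenset(tips)
            per_species[sp] = {"n_tips": len(sp_tips), "monophyletic": mono, "vacuous": False}
    tsp = any(
        not v["monophyletic"] for v in per_species.values() if not v["vacuous"]
    )
    return {"per_species": per_species, "tsp_detected": tsp}
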