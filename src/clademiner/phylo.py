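"""Pairwise protein identity, neighbor-joining trees, subfamily partitioning,
one-to-one orthology and bootstrapped species trees.

Identity between two proteins is computed from a Needleman-Wunsch global
alignment (BLOSUM62, gap open 10 / extend 1, terminal gaps free) as the
fraction of identical aligned pairs among alignment columns, excluding
columns that fall inside a terminal gap run. This denominator is tolerant
of length differences while still penalizing internal indels.

Subfamilies are defined by a dual criterion: members must form a
monophyletic clade of the all-member neighbor-joining tree (built from
distance = 1 - identity) *and* every pair of members must exceed an
identity threshold tau (default 0.55, strict). The partition is found by a
root-to-tip traversal that accepts the first (i.e. maximal) clade whose
leaves pass the all-pairs test; leaves that pass with no neighbor become
singleton subfamilies.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

__all__ = [
    "AMINO_ACIDS",
    "Node",
    "IdentityMatrix",
    "SubfamilyAssignment",
    "pairwise_identity",
    "alignment_score",
    "build_identity_matrix",
    "neighbor_joining",
    "leaf_distance_matrix",
    "partition_subfamilies",
    "subfamily_tree",
    "rbh_one_to_one",
    "species_tree_bootstrap",
]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_AA_SET = frozenset(AMINO_ACIDS)

# Alignment scoring is fixed for reproducibility and echoed in metadata.
ALIGNMENT_PARAMS = {
    "matrix": "BLOSUM62",
    "gap_open": 10,
    "gap_extend": 1,
    "end_gaps": "free",
}


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.mode = "global"
    aligner.open_internal_gap_score = -10.0
    aligner.extend_internal_gap_score = -1.0
    aligner.end_gap_score = 0.0
    return aligner


_ALIGNER = _make_aligner()


def _check_protein(seq: str) -> str:
    seq = seq.upper()
    bad = set(seq) - _AA_SET
    if bad:
        raise ValueError(f"non-amino-acid characters in sequence: {sorted(bad)!r}")
    if not seq:
        raise ValueError("empty sequence")
    return seq


# ---------------------------------------------------------------------------
# Trees
# ---------------------------------------------------------------------------


@dataclass
class Node:
    """A rooted tree node; branch ``length`` is the edge above this node.

    ``support`` holds an integer bootstrap percentage in [0, 100] for
    internal nodes, or None.
    """

    name: str | None = None
    length: float = 0.0
    support: int | None = None
    children: list["Node"] = field(default_factory=list)

    def is_leaf(self) -> bool:
        return not self.children

    def preorder(self):
        stack = [self]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def leaves(self) -> list["Node"]:
        return [n for n in self.preorder() if n.is_leaf()]

    def leaf_names(self) -> list[str]:
        return [n.name for n in self.leaves()]

    def find_clade(self, names: set[str]) -> "Node | None":
        """Return the node whose leaf set equals ``names``, if any."""
        for node in self.preorder():
            if set(node.leaf_names()) == set(names):
                return node
        return None

    def bipartitions(self) -> set[frozenset[str]]:
        """Unrooted internal bipartitions, each encoded by one side's leaves."""
        all_leaves = frozenset(self.leaf_names())
        splits: set[frozenset[str]] = set()
        for node in self.preorder():
            if node is self or node.is_leaf():
                continue
            side = frozenset(node.leaf_names())
            if 1 < len(side) < len(all_leaves) - 1:
                # canonical orientation: lexicographically smaller side
                other = all_leaves - side
                splits.add(min(side, other, key=lambda s: sorted(s)))
        return splits

    def to_newick(self) -> str:
        return f"{self._newick()};"

    def _newick(self) -> str:
        if self.is_leaf():
            return f"{self.name}:{self.length:.10g}"
        inner = ",".join(c._newick() for c in self.children)
        label = "" if self.support is None else str(self.support)
        return f"({inner}){label}:{self.length:.10g}"


# ---------------------------------------------------------------------------
# Identity
# ---------------------------------------------------------------------------


def pairwise_identity(a: str, b: str) -> float:
    """Global-alignment identity between two protein sequences, in [0, 1].

    Identical aligned pairs divided by the number of alignment columns,
    excluding terminal-gap columns. Symmetric in its arguments: when
    several alignments are co-optimal the reported identity depends on
    which one the aligner enumerates first, so the argument pair is
    canonically ordered before aligning.
    """
    a = _check_protein(a)
    b = _check_protein(b)
    if b < a:
        a, b = b, a
    aln = _ALIGNER.align(a, b)[0]
    g1, g2 = str(aln[0]), str(aln[1])
    head = max(_leading_gaps(g1), _leading_gaps(g2))
    tail = max(_trailing_gaps(g1), _trailing_gaps(g2))
    ncols = len(g1) - head - tail
    if ncols <= 0:
        return 0.0
    stop = len(g1) - tail
    matches = sum(
        1 for i in range(head, stop) if g1[i] == g2[i] and g1[i] != "-"
    )
    return matches / ncols


def _leading_gaps(s: str) -> int:
    return len(s) - len(s.lstrip("-"))


def _trailing_gaps(s: str) -> int:
    return len(s) - len(s.rstrip("-"))


def alignment_score(a: str, b: str) -> float:
    """Raw global-alignment score under the fixed scoring scheme."""
    return float(_ALIGNER.score(_check_protein(a), _check_protein(b)))


@dataclass
class IdentityMatrix:
    """Symmetric matrix of pairwise identity fractions with unit diagonal."""

    ids: list[str]
    values: np.ndarray
    params: dict = field(default_factory=lambda: dict(ALIGNMENT_PARAMS))

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.ids), len(self.ids)):
            raise ValueError("matrix shape does not match id count")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValueError("identity matrix not symmetric")
        self.values = v

    def __getitem__(self, pair: tuple[str, str]) -> float:
        i = self.ids.index(pair[0])
        j = self.ids.index(pair[1])
        return float(self.values[i, j])

    def distances(self) -> np.ndarray:
        """1 - identity, zero diagonal."""
        d = 1.0 - self.values
        np.fill_diagonal(d, 0.0)
        return d


def build_identity_matrix(proteins) -> IdentityMatrix:
    """All-pairs identity over a list of ProteinRecord-like objects.

    Each object needs ``gene`` and ``sequence`` attributes. All n(n-1)/2
    pairs are aligned once.
    """
    ids = [p.gene for p in proteins]
    if len(ids) != len(set(ids)):
        raise ValueError("duplicate gene ids in input")
    if len(ids) < 2:
        raise ValueError("need at least 2 proteins")
    n = len(ids)
    mat = np.eye(n)
    seqs = [p.sequence for p in proteins]
    for i in range(n):
        for j in range(i + 1, n):
            mat[i, j] = mat[j, i] = pairwise_identity(seqs[i], seqs[j])
    np.fill_diagonal(mat, 1.0)
    return IdentityMatrix(ids=ids, values=mat)


# ---------------------------------------------------------------------------
# Neighbor joining
# ---------------------------------------------------------------------------


def neighbor_joining(distances: np.ndarray, labels: list[str]) -> Node:
    """Saitou-Nei neighbor joining.

    Negative branch-length estimates are clamped to zero with the deficit
    transferred to the sibling edge, preserving path lengths through the
    joined pair. For an additive input matrix the realized leaf-to-leaf
    path lengths reproduce the input exactly. The returned tree is rooted
    at the final join (trifurcating root for >= 3 taxa).
    """
    D = np.array(distances, dtype=float)
    n = D.shape[0]
    if D.shape != (n, n) or n != len(labels):
        raise ValueError("distance matrix shape does not match labels")
    if n < 2:
        raise ValueError("need at least 2 taxa")
    if not np.allclose(D, D.T, atol=1e-8):
        raise ValueError("distance matrix not symmetric")
    if not np.allclose(np.diag(D), 0.0, atol=1e-8):
        raise ValueError("distance matrix diagonal not zero")

    nodes: list[Node] = [Node(name=lbl) for lbl in labels]
    if n == 2:
        half = D[0, 1] / 2.0
        nodes[0].length = nodes[1].length = half
        return Node(children=nodes)

    active = list(range(n))
    work = D.copy()
    while len(active) > 3:
        m = len(active)
        sub = work[np.ix_(active, active)]
        r = sub.sum(axis=1)
        q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        # deterministic tie-break: smallest flat index
        i_loc, j_loc = divmod(int(np.argmin(q)), m)
        if i_loc > j_loc:
            i_loc, j_loc = j_loc, i_loc
        d_ij = sub[i_loc, j_loc]
        li = 0.5 * d_ij + (r[i_loc] - r[j_loc]) / (2.0 * (m - 2))
        lj = d_ij - li
        li, lj = _clamp_pair(li, lj)
        gi, gj = active[i_loc], active[j_loc]
        nodes[gi].length = li
        nodes[gj].length = lj
        parent = Node(children=[nodes[gi], nodes[gj]])
        # distances from the new node to the remaining taxa
        new_row = 0.5 * (work[gi, :] + work[gj, :] - d_ij)
        work = np.vstack([work, new_row])
        new_col = np.append(new_row, 0.0)
        work = np.column_stack([work, new_col])
        nodes.append(parent)
        active = [a for a in active if a not in (gi, gj)] + [len(nodes) - 1]

    a, b, c = active
    d_ab, d_ac, d_bc = work[a, b], work[a, c], work[b, c]
    la = 0.5 * (d_ab + d_ac - d_bc)
    lb = 0.5 * (d_ab + d_bc - d_ac)
    lc = 0.5 * (d_ac + d_bc - d_ab)
    nodes[a].length = max(la, 0.0)
    nodes[b].length = max(lb, 0.0)
    nodes[c].length = max(lc, 0.0)
    return Node(children=[nodes[a], nodes[b], nodes[c]])


def _clamp_pair(li: float, lj: float) -> tuple[float, float]:
    if li < 0.0:
        lj += li
        li = 0.0
    if lj < 0.0:
        li += lj
        lj = 0.0
    return max(li, 0.0), max(lj, 0.0)


def _tree_graph(tree: Node) -> tuple[nx.Graph, dict[int, str]]:
    """Unrooted edge graph of a tree; returns (graph, leaf-id -> name)."""
    g = nx.Graph()
    counter = itertools.count()
    names: dict[int, str] = {}

    def walk(node: Node, uid: int) -> None:
        if node.is_leaf():
            names[uid] = node.name
        for child in node.children:
            cid = next(counter)
            g.add_edge(uid, cid, weight=child.length)
            walk(child, cid)

    root_id = next(counter)
    g.add_node(root_id)
    walk(tree, root_id)
    return g, names


def leaf_distance_matrix(tree: Node) -> tuple[np.ndarray, list[str]]:
    """Path-length distances between all leaf pairs of a tree."""
    g, names = _tree_graph(tree)
    leaf_ids = sorted(names, key=lambda u: names[u])
    labels = [names[u] for u in leaf_ids]
    n = len(labels)
    mat = np.zeros((n, n))
    lengths = dict(nx.all_pairs_dijkstra_path_length(g))
    for i, u in enumerate(leaf_ids):
        for j, v in enumerate(leaf_ids):
            if i < j:
                mat[i, j] = mat[j, i] = lengths[u][v]
    return mat, labels


def midpoint_root(tree: Node) -> Node:
    """Re-root a tree at the midpoint of its longest leaf-to-leaf path.

    Neighbor joining yields an unrooted topology; its trifurcating "root"
    is an artifact of the final agglomeration step and can land inside a
    genuine cluster. Midpoint rooting places the root on the longest path
    — in a superfamily tree, an edge between the most divergent clusters —
    so clusters remain clades for the root-to-tip traversal.
    """
    g, names = _tree_graph(tree)
    if len(names) < 2:
        return tree
    lengths = dict(nx.all_pairs_dijkstra_path_length(g))
    leaf_ids = sorted(names, key=lambda u: names[u])
    best = max(
        (
            (lengths[u][v], u, v)
            for i, u in enumerate(leaf_ids)
            for v in leaf_ids[i + 1 :]
        ),
        key=lambda t: t[0],
    )
    total, u, v = best
    half = total / 2.0
    path = nx.shortest_path(g, u, v, weight="weight")
    acc = 0.0
    for a, b in zip(path, path[1:]):
        w = g[a][b]["weight"]
        if acc + w >= half - 1e-12:
            offset = half - acc  # distance from a along edge (a, b)
            root_id = ("midpoint-root",)
            g.remove_edge(a, b)
            g.add_edge(a, root_id, weight=offset)
            g.add_edge(root_id, b, weight=w - offset)
            break
        acc += w
    else:  # numerically degenerate: root at the last node of the path
        root_id = path[-1]

    def build(uid, parent, length) -> Node:
        children = [
            build(n, uid, g[uid][n]["weight"]) for n in g.neighbors(uid) if n != parent
        ]
        return Node(name=names.get(uid), length=length, children=children)

    return build(root_id, None, 0.0)


# ---------------------------------------------------------------------------
# Subfamily partitioning
# ---------------------------------------------------------------------------


@dataclass
class SubfamilyAssignment:
    """A partition of superfamily members into subfamilies."""

    members: dict[str, list[str]]  # subfamily_id -> gene list
    gene_to_subfamily: dict[str, str]
    species_of: dict[str, str]  # gene -> species label

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for sf, genes in self.members.items():
            for g in genes:
                if g in seen:
                    raise ValueError(f"gene {g!r} in more than one subfamily")
                seen.add(g)
                if self.gene_to_subfamily.get(g) != sf:
                    raise ValueError(f"inconsistent assignment for gene {g!r}")
        if seen != set(self.gene_to_subfamily):
            raise ValueError("members and gene_to_subfamily disagree")

    def species_multiset(self, subfamily_id: str) -> list[str]:
        return [self.species_of[g] for g in self.members[subfamily_id]]

    @property
    def subfamily_ids(self) -> list[str]:
        return list(self.members)


def subfamily_tree(idmat: IdentityMatrix) -> Node:
    """Midpoint-rooted neighbor-joining tree of superfamily members from
    distance = 1 - identity."""
    return midpoint_root(neighbor_joining(idmat.distances(), idmat.ids))


def partition_subfamilies(
    tree: Node,
    idmat: IdentityMatrix,
    species_of: dict[str, str],
    tau: float = 0.55,
) -> SubfamilyAssignment:
    """Partition tree leaves into subfamilies by the dual criterion.

    A subfamily is a maximal clade of ``tree`` in which every leaf pair has
    identity strictly greater than ``tau``. Leaves that satisfy the test
    with no clade partner become singletons.
    """
    leaf_set = set(tree.leaf_names())
    if leaf_set != set(idmat.ids):
        raise ValueError("tree leaves and identity-matrix ids differ")
    index = {g: i for i, g in enumerate(idmat.ids)}
    vals = idmat.values

    members: dict[str, list[str]] = {}
    gene_to_sf: dict[str, str] = {}
    counter = itertools.count(1)
    stack = [tree]
    while stack:
        node = stack.pop(0)
        leaves = node.leaf_names()
        if len(leaves) == 1 or _all_pairs_above(leaves, index, vals, tau):
            sf_id = f"SF{next(counter):04d}"
            ordered = sorted(leaves)
            members[sf_id] = ordered
            for g in ordered:
                gene_to_sf[g] = sf_id
        else:
            stack = list(node.children) + stack
    return SubfamilyAssignment(
        members=members,
        gene_to_subfamily=gene_to_sf,
        species_of={g: species_of[g] for g in gene_to_sf},
    )


def _all_pairs_above(leaves, index, vals, tau) -> bool:
    idx = [index[g] for g in leaves]
    sub = vals[np.ix_(idx, idx)]
    off = sub[np.triu_indices(len(idx), k=1)]
    return bool(np.all(off > tau))


# ---------------------------------------------------------------------------
# Orthology and the species tree
# ---------------------------------------------------------------------------


def rbh_one_to_one(proteomes: dict[str, list]) -> list[dict[str, str]]:
    """One-to-one ortholog groups by reciprocal best hits.

    ``proteomes`` maps species label -> list of ProteinRecord-like objects.
    For every species pair, the best hit of each gene is determined by
    global-alignment score (ties keep all co-optimal partners). A pair of
    genes is an RBH if each is among the other's best hits. Ortholog groups
    are connected components of the RBH graph that contain exactly one gene
    per species across *all* species and in which every cross-species pair
    is itself an RBH edge; all other components are discarded.

    Returns a list of ``{species: gene}`` mappings, deterministically
    ordered by their sorted gene ids.
    """
    species = sorted(proteomes)
    if len(species) < 2:
        raise ValueError("need at least 2 species")
    for sp in species:
        if not proteomes[sp]:
            raise ValueError(f"species {sp!r} has an empty proteome")

    seqs = {p.gene: p.sequence for sp in species for p in proteomes[sp]}
    sp_of = {p.gene: sp for sp in species for p in proteomes[sp]}
    best: dict[tuple[str, str], set[str]] = {}
    for sa, sb in itertools.combinations(species, 2):
        genes_a = [p.gene for p in proteomes[sa]]
        genes_b = [p.gene for p in proteomes[sb]]
        scores = np.array(
            [[alignment_score(seqs[ga], seqs[gb]) for gb in genes_b] for ga in genes_a]
        )
        for i, ga in enumerate(genes_a):
            top = scores[i].max()
            best[(ga, sb)] = {genes_b[j] for j in np.flatnonzero(scores[i] == top)}
        for j, gb in enumerate(genes_b):
            top = scores[:, j].max()
            best[(gb, sa)] = {genes_a[i] for i in np.flatnonzero(scores[:, j] == top)}

    graph = nx.Graph()
    graph.add_nodes_from(seqs)
    for (ga, sb), partners in best.items():
        for gb in partners:
            if ga in best.get((gb, sp_of[ga]), set()):
                graph.add_edge(ga, gb)

    groups: list[dict[str, str]] = []
    for comp in nx.connected_components(graph):
        comp_species = [sp_of[g] for g in comp]
        if sorted(comp_species) != species:
            continue  # not exactly one gene per species across all species
        if not all(
            graph.has_edge(a, b)
            for a, b in itertools.combinations(comp, 2)
            if sp_of[a] != sp_of[b]
        ):
            continue  # mutually inconsistent component
        groups.append({sp_of[g]: g for g in comp})
    groups.sort(key=lambda grp: sorted(grp.values()))
    return groups


def species_tree_bootstrap(
    orthosets: list[dict[str, str]],
    sequences: dict[str, str],
    n_boot: int = 100,
    seed: int = 0,
) -> Node:
    """Distance species tree with gene-resampling bootstrap supports.

    The distance between two species is the mean of (1 - identity) over
    one-to-one ortholog groups. Bootstrap replicates resample ortholog
    groups with replacement ``n_boot`` times; each internal bipartition of
    the point-estimate tree is annotated with the percentage of replicates
    containing it.
    """
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    if not orthosets:
        raise ValueError("need at least one ortholog group")
    species = sorted(orthosets[0])
    if len(species) < 3:
        raise ValueError("need at least 3 species")

    n_sp = len(species)
    per_group = np.zeros((len(orthosets), n_sp, n_sp))
    for g, grp in enumerate(orthosets):
        for i, j in itertools.combinations(range(n_sp), 2):
            d = 1.0 - pairwise_identity(
                sequences[grp[species[i]]], sequences[grp[species[j]]]
            )
            per_group[g, i, j] = per_group[g, j, i] = d

    tree = neighbor_joining(per_group.mean(axis=0), species)

    rng = np.random.default_rng(seed)
    counts: dict[frozenset[str], int] = {bp: 0 for bp in tree.bipartitions()}
    for _ in range(n_boot):
        take = rng.integers(0, len(orthosets), size=len(orthosets))
        rep = neighbor_joining(per_group[take].mean(axis=0), species)
        rep_bps = rep.bipartitions()
        for bp in counts:
            if bp in rep_bps:
                counts[bp] += 1

    for node in tree.preorder():
        if node is tree or node.is_leaf():
            continue
        side = frozenset(node.leaf_names())
        other = frozenset(species) - side
        key = min(side, other, key=lambda s: sorted(s))
        if key in counts:
            node.support = round(100.0 * counts[key] / n_boot)
    return tree
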