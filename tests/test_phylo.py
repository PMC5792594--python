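"""Identity, neighbor joining, subfamily partitioning, orthology and the
bootstrapped species tree."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from clademiner.phylo import (
    IdentityMatrix,
    Node,
    build_identity_matrix,
    leaf_distance_matrix,
    midpoint_root,
    neighbor_joining,
    pairwise_identity,
    partition_subfamilies,
    rbh_one_to_one,
    species_tree_bootstrap,
    subfamily_tree,
)
from clademiner.simulate import (
    FamilySpec,
    ProteinRecord,
    default_design,
    simulate_gene_families,
)

AA = "ACDEFGHIKLMNPQRSTVWY"


# --- pairwise identity ----------------------------------------------------


@pytest.mark.parametrize(
    "a, b, expected",
    [
        ("MKVLAW", "MKVLAW", 1.0),  # self-identity
        ("AAAA", "AATA", 0.75),  # hand alignment: 3 matches / 4 columns
        ("AAAA", "CCCC", 0.0),  # disjoint residue alphabets
    ],
)
def test_pairwise_identity_examples(a, b, expected):
    assert pairwise_identity(a, b) == pytest.approx(expected)


def test_pairwise_identity_rejects_non_amino_acids():
    with pytest.raises(ValueError):
        pairwise_identity("ACDX1", "ACD")


@settings(max_examples=40, derandomize=True)
@given(
    st.text(alphabet=AA, min_size=3, max_size=25),
    st.text(alphabet=AA, min_size=3, max_size=25),
)
def test_pairwise_identity_symmetric(a, b):
    assert pairwise_identity(a, b) == pytest.approx(pairwise_identity(b, a))
    assert 0.0 <= pairwise_identity(a, b) <= 1.0


def test_identity_matrix_consistency():
    rng = np.random.default_rng(5)
    prots = [
        ProteinRecord(f"g{i}", "sp", "".join(rng.choice(list(AA), 30)))
        for i in range(4)
    ]
    mat = build_identity_matrix(prots)
    assert np.allclose(mat.values, mat.values.T)
    assert np.all(np.diag(mat.values) == 1.0)
    for i, j in itertools.combinations(range(4), 2):
        assert mat.values[i, j] == pytest.approx(
            pairwise_identity(prots[i].sequence, prots[j].sequence)
        )


def test_identity_matrix_rejects_duplicate_ids():
    prots = [ProteinRecord("g1", "sp", "ACDE"), ProteinRecord("g1", "sp", "ACDF")]
    with pytest.raises(ValueError, match="duplicate"):
        build_identity_matrix(prots)


# --- neighbor joining -----------------------------------------------------


def test_nj_two_taxa_splits_distance_in_half():
    tree = neighbor_joining(np.array([[0.0, 0.8], [0.8, 0.0]]), ["a", "b"])
    lengths = {n.name: n.length for n in tree.leaves()}
    assert lengths == {"a": 0.4, "b": 0.4}


def test_nj_three_taxon_closed_form():
    d = np.array([[0.0, 0.3, 0.5], [0.3, 0.0, 0.6], [0.5, 0.6, 0.0]])
    tree = neighbor_joining(d, ["a", "b", "c"])
    lengths = {n.name: n.length for n in tree.leaves()}
    assert lengths["a"] == pytest.approx((0.3 + 0.5 - 0.6) / 2)
    assert lengths["b"] == pytest.approx((0.3 + 0.6 - 0.5) / 2)
    assert lengths["c"] == pytest.approx((0.5 + 0.6 - 0.3) / 2)


def test_nj_rejects_asymmetric_matrix():
    with pytest.raises(ValueError):
        neighbor_joining(np.array([[0.0, 1.0], [2.0, 0.0]]), ["a", "b"])


def _random_tree(n_leaves: int, rng) -> Node:
    nodes = [Node(name=f"t{i}", length=rng.uniform(0.05, 1.0)) for i in range(n_leaves)]
    while len(nodes) > 2:
        i, j = sorted(rng.choice(len(nodes), 2, replace=False))
        merged = Node(
            length=rng.uniform(0.05, 1.0), children=[nodes[i], nodes[j]]
        )
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)] + [merged]
    root = Node(children=nodes)
    for child in root.children:
        child.length = rng.uniform(0.05, 1.0)
    return root


def test_nj_recovers_known_six_leaf_tree():
    rng = np.random.default_rng(123)
    source = _random_tree(6, rng)
    dist, labels = leaf_distance_matrix(source)
    tree = neighbor_joining(dist, labels)
    # topology: same unrooted bipartitions
    assert tree.bipartitions() == source.bipartitions()
    # branch lengths: realized path lengths reproduce the input exactly
    realized, labels2 = leaf_distance_matrix(tree)
    assert labels2 == labels
    np.testing.assert_allclose(realized, dist, atol=1e-9)


def test_nj_topology_agrees_with_skbio_on_additive_matrix():
    skbio = pytest.importorskip("skbio")
    from skbio import DistanceMatrix
    from skbio.tree import nj as skbio_nj

    rng = np.random.default_rng(7)
    source = _random_tree(7, rng)
    dist, labels = leaf_distance_matrix(source)
    mine = neighbor_joining(dist, labels)
    ref = skbio_nj(DistanceMatrix(dist, ids=labels))
    ref_bps = set()
    for node in ref.non_tips():
        side = frozenset(t.name for t in node.tips())
        if 1 < len(side) < len(labels) - 1:
            other = frozenset(labels) - side
            ref_bps.add(min(side, other, key=lambda s: sorted(s)))
    assert mine.bipartitions() == ref_bps


def test_midpoint_root_preserves_path_lengths():
    rng = np.random.default_rng(11)
    source = _random_tree(8, rng)
    dist, labels = leaf_distance_matrix(source)
    rerooted = midpoint_root(source)
    dist2, labels2 = leaf_distance_matrix(rerooted)
    assert labels2 == labels
    np.testing.assert_allclose(dist2, dist, atol=1e-9)


# --- subfamily partitioning ----------------------------------------------


def _identity_matrix(ids, fill):
    n = len(ids)
    vals = np.full((n, n), fill, dtype=float)
    np.fill_diagonal(vals, 1.0)
    return IdentityMatrix(ids=ids, values=vals)


def test_partition_all_above_tau_single_subfamily():
    ids = ["a", "b", "c", "d"]
    idmat = _identity_matrix(ids, 0.8)
    tree = subfamily_tree(idmat)
    asg = partition_subfamilies(tree, idmat, {g: "sp" for g in ids}, tau=0.55)
    assert len(asg.subfamily_ids) == 1
    assert sorted(asg.members[asg.subfamily_ids[0]]) == ids


def test_partition_all_below_tau_all_singletons():
    ids = ["a", "b", "c", "d"]
    idmat = _identity_matrix(ids, 0.2)
    tree = subfamily_tree(idmat)
    asg = partition_subfamilies(tree, idmat, {g: "sp" for g in ids}, tau=0.55)
    assert len(asg.subfamily_ids) == 4
    assert all(len(v) == 1 for v in asg.members.values())


def test_partition_is_a_partition_and_recovers_truth(small_bundle):
    from sklearn.metrics import adjusted_rand_score

    truth = small_bundle.truth
    members = [
        p for p in small_bundle.all_proteins()
        if truth.genes[p.gene].is_domain_bearing
    ]
    idmat = build_identity_matrix(members)
    tree = subfamily_tree(idmat)
    asg = partition_subfamilies(
        tree, idmat, {p.gene: p.species for p in members}, tau=0.55
    )
    # partition property
    all_members = sorted(g for v in asg.members.values() for g in v)
    assert all_members == sorted(p.gene for p in members)
    # exact recovery of the planted partition
    genes = [p.gene for p in members]
    ari = adjusted_rand_score(
        [truth.genes[g].subfamily_id for g in genes],
        [asg.gene_to_subfamily[g] for g in genes],
    )
    assert ari == 1.0


def test_partition_leaf_matrix_mismatch_raises():
    idmat = _identity_matrix(["a", "b", "c"], 0.8)
    tree = subfamily_tree(idmat)
    bad = IdentityMatrix(ids=["a", "b", "x"], values=idmat.values)
    with pytest.raises(ValueError):
        partition_subfamilies(tree, bad, {g: "sp" for g in "abx"}, tau=0.55)


# --- orthology ------------------------------------------------------------

_SEQ1 = "MKVLAWERTYIPASDFGHKLCVNMQWERTYIP"
_SEQ2 = "GGHHIIKKLLMMNNPPQQRRSSTTVVWWYYAA"


def _perturb(seq, positions, to="A"):
    out = list(seq)
    for p in positions:
        out[p] = to
    return "".join(out)


def test_rbh_unique_reciprocal_bests():
    proteomes = {
        "spA": [ProteinRecord("a1", "spA", _SEQ1), ProteinRecord("a2", "spA", _SEQ2)],
        "spB": [
            ProteinRecord("b1", "spB", _perturb(_SEQ1, [3])),
            ProteinRecord("b2", "spB", _perturb(_SEQ2, [5], to="C")),
        ],
    }
    groups = rbh_one_to_one(proteomes)
    assert {frozenset(g.values()) for g in groups} == {
        frozenset({"a1", "b1"}),
        frozenset({"a2", "b2"}),
    }


def test_rbh_equal_score_duplicates_discarded():
    # two identical copies in spB tie as best hits of a1 -> the component
    # holds two spB genes and is dropped from the one-to-one set
    proteomes = {
        "spA": [ProteinRecord("a1", "spA", _SEQ1), ProteinRecord("a2", "spA", _SEQ2)],
        "spB": [
            ProteinRecord("b1x", "spB", _SEQ1),
            ProteinRecord("b1y", "spB", _SEQ1),
            ProteinRecord("b2", "spB", _SEQ2),
        ],
    }
    groups = rbh_one_to_one(proteomes)
    assert {frozenset(g.values()) for g in groups} == {frozenset({"a2", "b2"})}


def test_rbh_rejects_empty_proteome():
    with pytest.raises(ValueError, match="empty"):
        rbh_one_to_one({"spA": [ProteinRecord("a", "spA", _SEQ1)], "spB": []})


def _ortholog_world(n_families=12, seed=21):
    design = default_design(n_ingroup=3, n_outgroup=3)
    specs = [
        FamilySpec(
            f"f{i}", n_subfamilies=1, within_identity=0.75, between_identity=0.1,
            domain_length=150,
        )
        for i in range(n_families)
    ]
    proteomes, truth = simulate_gene_families(design, specs, 0, seed=seed)
    return design, proteomes, truth


def test_rbh_recovers_single_copy_families():
    design, proteomes, truth = _ortholog_world()
    groups = rbh_one_to_one(proteomes)
    assert len(groups) == 12
    for grp in groups:
        families = {truth.genes[g].family_id for g in grp.values()}
        assert len(families) == 1  # each group is one planted family


def test_species_tree_single_ortholog_all_supports_100():
    design, proteomes, truth = _ortholog_world(n_families=1)
    groups = rbh_one_to_one(proteomes)
    seqs = {p.gene: p.sequence for ps in proteomes.values() for p in ps}
    tree = species_tree_bootstrap(groups[:1], seqs, n_boot=20, seed=0)
    supports = [n.support for n in tree.preorder() if n.support is not None]
    assert supports and all(s == 100 for s in supports)


def test_species_tree_ingroup_clade_recovered_with_full_support():
    design, proteomes, truth = _ortholog_world()
    groups = rbh_one_to_one(proteomes)
    seqs = {p.gene: p.sequence for ps in proteomes.values() for p in ps}
    tree = species_tree_bootstrap(groups, seqs, n_boot=100, seed=3)
    ingroup = set(design.ingroup_ids)
    clade = tree.find_clade(ingroup)
    if clade is None:  # rooting may place the ingroup as the complement
        clade = tree.find_clade(set(design.species_ids) - ingroup)
    assert clade is not None
    assert clade.support == 100
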