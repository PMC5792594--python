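"""Generator contracts: identity targets, clade specificity by
construction, expression structure, kinetics closed forms, fixture IO."""

import itertools

import numpy as np
import pytest
from pydantic import ValidationError

from clademiner.phylo import pairwise_identity
from clademiner.simulate import (
    ExpressionTable,
    FamilySpec,
    KineticDataset,
    SpeciesDesign,
    TruthTable,
    default_design,
    parse_fasta_header,
    read_fixture,
    simulate_expression,
    simulate_gene_families,
    simulate_kinetics,
    write_fixture,
)
from clademiner.phylo import Node


def test_default_design_has_thirteen_species():
    design = default_design()
    assert len(design.species_ids) == 13
    assert len(design.ingroup_ids) == 5
    assert len(design.outgroup_ids) == 8
    assert design.guide_tree.find_clade(set(design.ingroup_ids)) is not None


def test_ingroup_must_be_monophyletic():
    # a guide tree where the "ingroup" straddles the root is rejected
    tree = Node(
        children=[
            Node(children=[Node(name="a", length=0.1), Node(name="b", length=0.1)], length=0.1),
            Node(children=[Node(name="c", length=0.1), Node(name="d", length=0.1)], length=0.1),
        ]
    )
    with pytest.raises(ValueError, match="monophyletic"):
        SpeciesDesign(species_ids=list("abcd"), ingroup_ids=["a", "c"], guide_tree=tree)


def test_family_spec_rejects_inverted_identity_targets():
    with pytest.raises(ValueError):
        FamilySpec("bad", within_identity=0.5, between_identity=0.6)


def test_zero_divergence_family_is_identical():
    """within_identity = 1.0 forces a substitution rate of zero: every
    member of the family is the same sequence (pairwise identity 1.0)."""
    design = default_design(3, 3)
    proteomes, truth = simulate_gene_families(
        design, [FamilySpec("f", within_identity=1.0, n_subfamilies=1)], 0, seed=3
    )
    seqs = [p.sequence for sp in proteomes.values() for p in sp]
    assert len(set(seqs)) == 1
    assert pairwise_identity(seqs[0], seqs[1]) == 1.0


def test_identity_targets_verified_by_alignment_oracle(small_bundle):
    """Realized identities, re-measured by exhaustive pairwise global
    alignment (independent of the generator's internal Hamming check),
    respect the within/between targets."""
    truth = small_bundle.truth
    seqs = {p.gene: p.sequence for p in small_bundle.all_proteins()}
    planted = truth.domain_bearing()
    sf = {g: truth.genes[g].subfamily_id for g in planted}
    fam = {g: truth.genes[g].family_id for g in planted}
    within, between = [], []
    for a, b in itertools.combinations(planted, 2):
        ident = pairwise_identity(seqs[a], seqs[b])
        if sf[a] == sf[b]:
            within.append(ident)
        elif fam[a] == fam[b]:
            between.append(ident)
    assert min(within) >= 0.90
    assert max(between) <= 0.30


def test_clade_specific_families_absent_from_outgroup(small_bundle):
    truth = small_bundle.truth
    outgroup = {"out1", "out2", "out3"}
    for gene, t in truth.genes.items():
        if t.subfamily_id and truth.subfamily_specific[t.subfamily_id]:
            assert t.species not in outgroup


def test_generation_is_deterministic():
    design = default_design(3, 3)
    spec = [FamilySpec("f", n_subfamilies=2, domain_length=200)]
    p1, t1 = simulate_gene_families(design, spec, 5, seed=42)
    p2, t2 = simulate_gene_families(design, spec, 5, seed=42)
    assert t1 == t2
    assert p1 == p2


# --- expression -----------------------------------------------------------


def test_expression_default_sample_layout(small_bundle):
    table = small_bundle.expression
    groups = list(table.groups.values())
    assert groups.count("wild") == 5
    assert groups.count("cultivated") == 6
    assert (table.values.to_numpy() >= 0).all()


def test_expression_determinism_byte_identical(small_bundle):
    t1 = simulate_expression(small_bundle.truth, seed=9)
    t2 = simulate_expression(small_bundle.truth, seed=9)
    assert t1.values.to_csv() == t2.values.to_csv()
    assert t1.groups == t2.groups


def test_expression_rejects_empty_groups(small_bundle):
    with pytest.raises(ValueError):
        simulate_expression(small_bundle.truth, n_wild=0, n_cultivated=6, seed=0)


def test_pathway_genes_exceed_median_across_seeds(small_bundle):
    """Planted pathway genes sit above the global median expression in
    both groups in at least 95% of seeds (Monte Carlo over 200 seeds)."""
    truth = small_bundle.truth
    assert truth.pathway_genes
    hits = 0
    for seed in range(200):
        table = simulate_expression(truth, seed=seed)
        wild = [c for c, g in table.groups.items() if g == "wild"]
        cult = [c for c, g in table.groups.items() if g == "cultivated"]
        wmeans = table.values[wild].mean(axis=1)
        cmeans = table.values[cult].mean(axis=1)
        ok = all(
            wmeans[g] > wmeans.median() and cmeans[g] > cmeans.median()
            for g in truth.pathway_genes
        )
        hits += ok
    assert hits >= 190


def test_expression_table_rejects_negative_values():
    import pandas as pd

    frame = pd.DataFrame({"s1": [1.0, -0.5]}, index=["g1", "g2"])
    with pytest.raises(ValueError):
        ExpressionTable(values=frame, groups={"s1": "wild"})


# --- kinetics -------------------------------------------------------------


def test_kinetics_half_saturation_identity():
    data = simulate_kinetics(km=5.0, kcat=2.0, enzyme_conc=0.1, concs=[5.0, 1.0, 50.0])
    # at S = Km the rate is exactly kcat*E0/2
    assert data.rates[0] == pytest.approx(2.0 * 0.1 / 2.0, abs=1e-15)


def test_kinetics_noise_free_matches_closed_form():
    s = np.array([0.5, 2.0, 8.0, 32.0])
    data = simulate_kinetics(km=9.24, kcat=0.57, enzyme_conc=0.01, concs=s)
    expected = 0.57 * 0.01 * s / (9.24 + s)
    np.testing.assert_allclose(data.rates, expected, rtol=1e-15)


def test_kinetics_parameter_errors():
    with pytest.raises(ValueError):
        simulate_kinetics(km=-1, kcat=0.5, enzyme_conc=0.1, concs=[1.0])
    with pytest.raises(ValueError):
        simulate_kinetics(km=1, kcat=0.5, enzyme_conc=0.1, concs=[0.0, 1.0])
    with pytest.raises(ValueError):
        KineticDataset(substrate_concs=[1.0, 1.0], rates=[0.1, 0.1], enzyme_conc=0.1)


# --- fixture IO -----------------------------------------------------------


def test_fixture_round_trip(small_bundle, tmp_path):
    bundle = small_bundle
    bundle.kinetics = {
        "apigenin": simulate_kinetics(
            km=9.24, kcat=0.57, enzyme_conc=0.01,
            concs=np.geomspace(0.1, 20, 8), noise_sd=0.05, seed=4,
        )
    }
    write_fixture(bundle, tmp_path)
    back = read_fixture(tmp_path)
    assert back.proteomes == bundle.proteomes
    assert back.truth == bundle.truth
    assert back.seed_alignments == bundle.seed_alignments
    assert back.expression.groups == bundle.expression.groups
    assert back.expression.values.equals(bundle.expression.values)
    kin, orig = back.kinetics["apigenin"], bundle.kinetics["apigenin"]
    np.testing.assert_array_equal(kin.substrate_concs, orig.substrate_concs)
    np.testing.assert_array_equal(kin.rates, orig.rates)
    assert kin.enzyme_conc == orig.enzyme_conc


def test_fasta_header_contract():
    assert parse_fasta_header("speciesA|g0001") == ("speciesA", "g0001")
    with pytest.raises(ValueError):
        parse_fasta_header("no-separator")


def test_truth_json_validates_against_schema(small_bundle, tmp_path):
    import json

    write_fixture(small_bundle, tmp_path)
    payload = json.loads((tmp_path / "truth.json").read_text())
    TruthTable.model_validate(payload["truth"])  # passes
    broken = dict(payload["truth"])
    broken["genes"] = {"g1": {"species": "x"}}  # missing required fields
    with pytest.raises(ValidationError):
        TruthTable.model_validate(broken)
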