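"""Orthogroup delimitation, naming grammar and categories."""

import itertools

import numpy as np
import pytest

from _oracles import enumerate_topologies, random_tree, reconcile_bruteforce, tree_leaves, tuple_to_newick
from v1r_clade_evo.io import parse_newick
from v1r_clade_evo.mining import BestHit, ReferenceGene
from v1r_clade_evo.orthology import (
    GeneTreeLeaf,
    Orthogroup,
    annotate_transcripts,
    categorize_orthogroup,
    collapse_low_support,
    delimit_orthogroups,
    name_orthogroup,
)

SP3 = ("alpha", "beta", "gamma")


def _meta_for(tree):
    meta = {}
    for lf in tree.leaf_node_iter():
        label = lf.taxon.label
        species = label.rsplit("_", 1)[0]
        meta[label] = GeneTreeLeaf(leaf_id=label, species=species)
    return meta


def _partition(groups):
    return sorted(frozenset(og.members) for og in groups)


# ---------------------------------------------------------------------------
# annotation grammar
# ---------------------------------------------------------------------------


def test_annotation_suffixes_by_score_then_id():
    hits = [
        BestHit("txB", "Vmn1r30", score=90, identity=88),
        BestHit("txA", "Vmn1r30", score=95, identity=90),
        BestHit("txC", "Vmn1r7", score=80, identity=85),
    ]
    species = {"txA": "sp1", "txB": "sp1", "txC": "sp1"}
    ann = annotate_transcripts(hits, species)
    assert ann == {"txA": "Vmn1r30.1", "txB": "Vmn1r30.2", "txC": "Vmn1r7"}


def test_annotation_equal_scores_stable_by_id():
    hits = [BestHit(f"tx{c}", "Vmn1r5", score=50, identity=70) for c in "cab"]
    ann = annotate_transcripts(hits, {h.query_id: "sp" for h in hits})
    assert ann == {"txa": "Vmn1r5.1", "txb": "Vmn1r5.2", "txc": "Vmn1r5.3"}


def test_same_gene_different_species_no_cross_suffix():
    hits = [
        BestHit("a1", "Vmn1r3", score=10, identity=50),
        BestHit("b1", "Vmn1r3", score=10, identity=50),
    ]
    ann = annotate_transcripts(hits, {"a1": "sp1", "b1": "sp2"})
    assert ann == {"a1": "Vmn1r3", "b1": "Vmn1r3"}


# ---------------------------------------------------------------------------
# delimitation
# ---------------------------------------------------------------------------


def test_congruent_tree_single_orthogroup():
    tree = parse_newick("((((alpha_1:1,beta_1:1):1,gamma_1:1):1,delta_1:1):1,eps_1:1);")
    groups = delimit_orthogroups(tree, _meta_for(tree), collapse_below=None)
    assert len(groups) == 1
    assert groups[0].species_set == {"alpha", "beta", "gamma", "delta", "eps"}


def test_local_duplication_stays_inside_group():
    tree = parse_newick("((alpha_1:1,alpha_2:1):1,beta_1:1);")
    groups = delimit_orthogroups(tree, _meta_for(tree), collapse_below=None)
    assert len(groups) == 1
    assert sorted(groups[0].members) == ["alpha_1", "alpha_2", "beta_1"]


def test_nonlocal_duplication_splits_groups():
    # two cross-species clades each with both species: ancient duplication
    tree = parse_newick("((alpha_1:1,beta_1:1):1,(alpha_2:1,beta_2:1):1);")
    groups = delimit_orthogroups(tree, _meta_for(tree), collapse_below=None)
    assert _partition(groups) == sorted(
        [frozenset({"alpha_1", "beta_1"}), frozenset({"alpha_2", "beta_2"})]
    )


def test_delimitation_equals_bruteforce_on_enumerated_trees():
    """All topologies ≤ 4 leaves × all 3-species labelings match the oracle."""
    for n in (2, 3, 4):
        for shape in enumerate_topologies(n):
            for assignment in itertools.product(range(3), repeat=n):
                species = {i: SP3[assignment[i]] for i in range(n)}
                newick = tuple_to_newick(shape, species)
                tree = parse_newick(newick)
                meta = {}
                for lf in tree.leaf_node_iter():
                    label = lf.taxon.label
                    idx = int(label.rsplit("_", 1)[1])
                    meta[label] = GeneTreeLeaf(leaf_id=label, species=species[idx])
                groups = delimit_orthogroups(tree, meta, collapse_below=None)
                got = {
                    frozenset(int(m.rsplit("_", 1)[1]) for m in og.members) for og in groups
                }
                expected = set(reconcile_bruteforce(shape, species))
                assert got == expected, f"tree {newick}"


def test_delimitation_equals_bruteforce_on_random_trees():
    rng = np.random.default_rng(7)
    import random

    pyrng = random.Random(7)
    for _ in range(200):
        n = pyrng.randint(5, 8)
        shape = random_tree(pyrng, n)
        species = {i: SP3[pyrng.randrange(3)] for i in range(n)}
        tree = parse_newick(tuple_to_newick(shape, species))
        meta = {}
        for lf in tree.leaf_node_iter():
            label = lf.taxon.label
            idx = int(label.rsplit("_", 1)[1])
            meta[label] = GeneTreeLeaf(leaf_id=label, species=species[idx])
        groups = delimit_orthogroups(tree, meta, collapse_below=None)
        got = {frozenset(int(m.rsplit("_", 1)[1]) for m in og.members) for og in groups}
        assert got == set(reconcile_bruteforce(shape, species))


def test_every_leaf_in_exactly_one_group():
    tree = parse_newick("(((alpha_1:1,beta_1:1):1,(alpha_2:1,gamma_1:1):1):1,beta_2:1);")
    meta = _meta_for(tree)
    groups = delimit_orthogroups(tree, meta, collapse_below=None)
    members = [m for og in groups for m in og.members]
    assert sorted(members) == sorted(meta)


def test_low_support_collapse_prevents_duplication_call():
    # weak edge (support 20) separating the two alpha leaves: collapsed to a
    # polytomy, conservatively not a duplication -> one orthogroup
    tree = parse_newick("((alpha_1:1,beta_1:1)20:1,(alpha_2:1,gamma_1:1)80:1);")
    groups = delimit_orthogroups(tree, _meta_for(tree), collapse_below=50)
    assert len(groups) == 1


# ---------------------------------------------------------------------------
# naming
# ---------------------------------------------------------------------------


def _group_with_refs(refs):
    return Orthogroup(
        name="", members=["x"], species_set={"domesticus"}, reference_genes=set(refs)
    )


def test_combination_id_two_genes():
    og = _group_with_refs({"Vmn1r25", "Vmn1r30"})
    assert name_orthogroup(og, None, {}) == "Vmn1r25/30"


def test_single_reference_gene_keeps_id():
    og = _group_with_refs({"Vmn1r42"})
    assert name_orthogroup(og, None, {}) == "Vmn1r42"


def test_combination_id_order_invariant():
    for perm in itertools.permutations(["Vmn1r90", "Vmn1r168", "Vmn1r177"]):
        og = _group_with_refs(set(perm))
        assert name_orthogroup(og, None, {}) == "Vmn1r90/168/177"


def _basal_meta(ref_ids):
    meta = {
        "spretus_1": GeneTreeLeaf("spretus_1", "spretus"),
        "caroli_1": GeneTreeLeaf("caroli_1", "caroli"),
    }
    for i, rid in enumerate(ref_ids, 1):
        meta[f"dom_{i}"] = GeneTreeLeaf(
            f"dom_{i}", "domesticus", reference_gene=rid, is_reference=True
        )
        meta[f"pahari_{i}"] = GeneTreeLeaf(f"pahari_{i}", "pahari")
    return meta


def test_basal_naming_from_tree_context():
    # the (spretus, caroli) pair sits basal to three reference orthogroups
    # that are separated by non-local duplications
    tree = parse_newick(
        "((spretus_1:1,caroli_1:1):1,"
        "(((dom_1:1,pahari_1:1):1,(dom_2:1,pahari_2:1):1):1,(dom_3:1,pahari_3:1):1):1);"
    )
    meta = _basal_meta(["Vmn1r90", "Vmn1r168", "Vmn1r177"])
    groups = delimit_orthogroups(tree, meta, collapse_below=None)
    basal = [og for og in groups if not og.reference_genes and len(og.members) == 2]
    assert len(basal) == 1
    assert name_orthogroup(basal[0], tree, meta) == "Vmn1r90/168/177"


def test_basal_naming_past_three_uses_lowest_id():
    tree = parse_newick(
        "((spretus_1:1,caroli_1:1):1,"
        "((((dom_1:1,pahari_1:1):1,(dom_2:1,pahari_2:1):1):1,"
        "((dom_3:1,pahari_3:1):1,(dom_4:1,pahari_4:1):1):1):1,(dom_5:1,pahari_5:1):1):1);"
    )
    meta = _basal_meta(["Vmn1r12", "Vmn1r40", "Vmn1r55", "Vmn1r60", "Vmn1r77"])
    groups = delimit_orthogroups(tree, meta, collapse_below=None)
    basal = [og for og in groups if not og.reference_genes and len(og.members) == 2]
    assert len(basal) == 1
    assert name_orthogroup(basal[0], tree, meta) == "basalVmn1r12"


# ---------------------------------------------------------------------------
# categories
# ---------------------------------------------------------------------------


def _og(species):
    return Orthogroup(name="", members=["m"], species_set=set(species), reference_genes=set())


@pytest.mark.parametrize(
    "species,expected",
    [
        ({"domesticus"}, "reference_only"),
        ({"spretus"}, "non_orthologous"),
        ({"domesticus", "spicilegus"}, "low_orthology"),  # the two-species pattern
        ({"domesticus", "spicilegus", "macedonicus"}, "low_orthology"),
        ({"domesticus", "spicilegus", "macedonicus", "spretus"}, "high_orthology"),  # lacks basal taxa
        (set(("domesticus", "spicilegus", "macedonicus", "spretus", "caroli", "pahari")), "high_orthology"),
    ],
)
def test_category_rules(species, expected):
    assert categorize_orthogroup(_og(species), "domesticus") == expected


def test_categories_partition_and_monotone():
    rank = {"reference_only": 0, "non_orthologous": 0, "low_orthology": 1, "high_orthology": 2}
    species_pool = ["domesticus", "spicilegus", "macedonicus", "spretus", "caroli", "pahari"]
    for r in range(1, 7):
        for combo in itertools.combinations(species_pool, r):
            cat = categorize_orthogroup(_og(combo), "domesticus")
            assert cat in rank
            # adding any species never lowers the rank
            for extra in species_pool:
                if extra in combo:
                    continue
                cat2 = categorize_orthogroup(_og(set(combo) | {extra}), "domesticus")
                assert rank[cat2] >= rank[cat]


def test_empty_species_set_rejected():
    with pytest.raises(ValueError):
        categorize_orthogroup(_og(set()), "domesticus")
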