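"""Simulator ground-truth properties: birth-death limits, codon model, emission."""

import math

import dendropy
import numpy as np
import pytest
from Bio.Seq import Seq

from v1r_clade_evo.io import parse_newick
from v1r_clade_evo.simulate import (
    SimParams,
    emit_transcripts,
    evolve_sequences,
    simulate_family,
)
from v1r_clade_evo.selection import branch_dnds_screen


def single_branch_tree(length: float) -> dendropy.Tree:
    return parse_newick(f"tip:{length};")


def test_no_event_limit(species_tree):
    p = SimParams(seed=5, n_root_genes=5, dup_rate=0.0, loss_rate=0.0, p_variant=0.0)
    truth = simulate_family(species_tree, p)
    assert len(set(truth.true_orthogroups.values())) == 5
    assert truth.events == []
    for sp, copies in truth.copies_by_species.items():
        assert len(copies) == 5
    # each orthogroup spans all 6 species exactly once
    by_og = {}
    for copy, og in truth.true_orthogroups.items():
        by_og.setdefault(og, []).append(copy.split("|")[0])
    for og, sps in by_og.items():
        assert sorted(sps) == sorted({s for s in sps}) and len(sps) == 6


def test_pure_birth_mean_copy_number():
    """Mean tip copy number of a pure-birth process is e^(λt)."""
    lam, t, reps = 0.5, 1.0, 2000
    counts = []
    for seed in range(reps):
        p = SimParams(seed=seed, n_root_genes=1, dup_rate=lam, loss_rate=0.0, p_variant=0.0)
        truth = simulate_family(single_branch_tree(t), p)
        counts.append(len(truth.copies_by_species.get("tip", [])))
    mean = np.mean(counts)
    se = np.std(counts, ddof=1) / math.sqrt(reps)
    assert abs(mean - math.exp(lam * t)) <= 3 * se


def test_pure_death_never_gains(species_tree):
    p = SimParams(seed=9, n_root_genes=10, dup_rate=0.0, loss_rate=3.0, p_variant=0.0)
    truth = simulate_family(species_tree, p)
    all_species = {lf.taxon.label for lf in species_tree.leaf_node_iter()}
    by_og: dict[str, set[str]] = {}
    for copy, og in truth.true_orthogroups.items():
        by_og.setdefault(og, set()).add(copy.split("|")[0])
    for sps in by_og.values():
        assert sps <= all_species
    # no orthogroup has two copies of one species (no duplications possible)
    per_sp: dict[tuple[str, str], int] = {}
    for copy, og in truth.true_orthogroups.items():
        key = (og, copy.split("|")[0])
        per_sp[key] = per_sp.get(key, 0) + 1
    assert all(v == 1 for v in per_sp.values())
    assert all(e.kind in ("loss", "pseudogenization") for e in truth.events)


def test_negative_rate_rejected():
    with pytest.raises(ValueError):
        SimParams(seed=1, dup_rate=-0.1)


def test_zero_length_tree_with_positive_rates_is_valid():
    p = SimParams(seed=2, n_root_genes=3, dup_rate=5.0, loss_rate=5.0, p_variant=0.0)
    truth = simulate_family(single_branch_tree(0.0), p)
    assert truth.events == []
    assert len(truth.copies_by_species["tip"]) == 3


def test_determinism_same_seed_byte_identical(species_tree):
    outs = []
    for _ in range(2):
        p = SimParams(seed=42, n_root_genes=4)
        truth = simulate_family(species_tree, p)
        seqs = evolve_sequences(truth, p)
        fastas, labels = emit_transcripts(truth, seqs, p)
        outs.append((fastas, labels, [(e.branch, e.kind) for e in truth.events]))
    assert outs[0] == outs[1]


def test_gene_tree_embeds_in_species_tree(species_tree):
    """Every gene-tree edge is tagged with a species-tree branch or the root ladder."""
    p = SimParams(seed=13, n_root_genes=4, dup_rate=1.0, loss_rate=0.5)
    truth = simulate_family(species_tree, p)
    valid = {lf.taxon.label for lf in species_tree.leaf_node_iter()}
    valid |= {n.label for n in species_tree.preorder_node_iter() if n.label}
    valid.add("default")
    for node in truth.gene_tree.preorder_node_iter():
        if node is truth.gene_tree.seed_node:
            continue
        assert getattr(node, "branch_class", "default") in valid
    for e in truth.events:
        assert e.branch in valid


def test_event_branches_exist_and_kinds_known(species_tree):
    p = SimParams(seed=3, n_root_genes=10, dup_rate=1.0, loss_rate=1.0)
    truth = simulate_family(species_tree, p)
    assert truth.events, "expected events at these rates"
    assert {e.kind for e in truth.events} <= {"duplication", "loss", "pseudogenization"}


# ---------------------------------------------------------------------------
# sequence evolution
# ---------------------------------------------------------------------------


def test_zero_branch_length_identical_sequences():
    p = SimParams(seed=4, n_root_genes=1, dup_rate=0.0, loss_rate=0.0, root_divergence=0.0)
    truth = simulate_family(single_branch_tree(0.0), p)
    seqs = evolve_sequences(truth, p)
    # single copy; with no branch length and no root divergence the sequence
    # is exactly the family ancestor, so re-running with the same seed and a
    # longer branch must differ
    p2 = SimParams(seed=4, n_root_genes=1, dup_rate=0.0, loss_rate=0.0, root_divergence=0.0)
    truth2 = simulate_family(single_branch_tree(2.0), p2)
    seqs2 = evolve_sequences(truth2, p2)
    (a,) = seqs.values()
    (b,) = seqs2.values()
    assert len(a) == len(b) and a != b


def test_omega_zero_forbids_nonsynonymous_change(species_tree):
    p = SimParams(
        seed=6, n_root_genes=3, dup_rate=0.0, loss_rate=0.0,
        omega_map={"default": 0.0}, root_divergence=0.5, p_variant=0.0,
    )
    truth = simulate_family(species_tree, p)
    seqs = evolve_sequences(truth, p)
    peptides = {str(Seq(s).translate()) for s in seqs.values()}
    by_og: dict[str, set[str]] = {}
    for copy, og in truth.true_orthogroups.items():
        by_og.setdefault(og, set()).add(str(Seq(seqs[copy]).translate()))
    # all copies within AND across orthogroups descend from one ancestor
    # under omega=0, so every peptide is identical
    assert len(peptides) == 1
    # but DNA did change somewhere (synonymous drift)
    assert len(set(seqs.values())) > 1


def test_neutral_omega_counting_dnds_near_one():
    """ω=1 parent/child pairs give a counting dN/dS of ≈ 1 (κ=1: unbiased)."""
    reps, t = 200, 1.0
    ratios = []
    for seed in range(reps):
        p = SimParams(
            seed=seed, n_root_genes=1, dup_rate=0.0, loss_rate=0.0,
            omega_map={"default": 1.0}, kappa=1.0, gene_length=300,
            root_divergence=0.0, p_variant=0.0,
        )
        truth = simulate_family(single_branch_tree(t), p)
        seqs = evolve_sequences(truth, p)
        # two-taxon framing: ancestor is the root; use the screen's counter
        # on the 1-branch tree (parent = reconstructed root = the child set,
        # so instead compare against an explicit second child)
        p2 = SimParams(
            seed=seed, n_root_genes=1, dup_rate=0.0, loss_rate=0.0,
            omega_map={"default": 1.0}, kappa=1.0, gene_length=300,
            root_divergence=0.0, p_variant=0.0,
        )
        two = parse_newick(f"(tipa:{t},tipb:{t});")
        truth2 = simulate_family(two, p2)
        seqs2 = evolve_sequences(truth2, p2)
        aln = {k: v for k, v in seqs2.items()}
        tree = truth2.gene_tree.extract_tree_with_taxa_labels(list(aln))
        tests = branch_dnds_screen(aln, tree, orthogroup="fam")
        for bt in tests:
            if bt.ds and bt.ds > 0:
                ratios.append(bt.dn / bt.ds)
    mean = np.mean(ratios)
    se = np.std(ratios, ddof=1) / math.sqrt(len(ratios))
    assert abs(mean - 1.0) <= 3 * se


# ---------------------------------------------------------------------------
# transcript emission
# ---------------------------------------------------------------------------


def test_emission_counts_and_labels(species_tree):
    p = SimParams(seed=8, n_root_genes=5, dup_rate=0.0, loss_rate=0.0, p_variant=0.0)
    truth = simulate_family(species_tree, p)
    seqs = evolve_sequences(truth, p)
    fastas, labels = emit_transcripts(truth, seqs, p)
    n_tx = sum(len(d) for d in fastas.values())
    n_genes = sum(len(v) for v in truth.copies_by_species.values())
    assert n_tx == n_genes
    assert set(labels.values()) == {"primary"}


def test_variant_classes(species_tree):
    p = SimParams(seed=10, n_root_genes=20, dup_rate=0.0, loss_rate=0.0, p_variant=1.0)
    truth = simulate_family(species_tree, p)
    seqs = evolve_sequences(truth, p)
    fastas, labels = emit_transcripts(truth, seqs, p)
    variants = {t: l for t, l in labels.items() if l != "primary"}
    assert variants, "p_variant=1 must emit variants"
    by_sp = {sp: d for sp, d in fastas.items()}

    def cds_of(tid):
        raw = by_sp[tid.split("|")[0]][tid]
        # strip the fixed-length UTRs and the stop codon
        return raw[30:-33]

    for tid, label in variants.items():
        primary = tid.rsplit("|", 1)[0] + "|t1"
        pep_p = str(Seq(cds_of(primary)).translate())
        pep_v = str(Seq(cds_of(tid)).translate())
        if label == "same_peptide_variant":
            assert pep_v == pep_p and cds_of(tid) != cds_of(primary)
        elif label == "truncated_variant":
            assert len(pep_v) == round(len(pep_p) * (1 - p.variant_truncation_frac))
        elif label == "end_modified_variant":
            assert len(pep_v) == len(pep_p) and pep_v != pep_p
            # differences confined to the C-terminal window
            diffs = [i for i, (x, y) in enumerate(zip(pep_p, pep_v)) if x != y]
            assert diffs and all(i >= len(pep_p) - 8 for i in diffs)


def test_truncation_arithmetic():
    from v1r_clade_evo.simulate import _truncated_variant

    rng = np.random.default_rng(0)
    cds = "ATG" + "GGA" * 299  # 300 codons
    var = _truncated_variant(cds, 0.4, rng)
    assert len(var) // 3 == 180


def test_pseudogenized_copies_not_emitted(species_tree):
    p = SimParams(seed=77, n_root_genes=10, dup_rate=0.0, loss_rate=2.0, pseudo_prob=1.0, p_variant=0.0)
    truth = simulate_family(species_tree, p)
    seqs = evolve_sequences(truth, p)
    fastas, _ = emit_transcripts(truth, seqs, p)
    emitted = {tid.rsplit("|", 1)[0] for d in fastas.values() for tid in d}
    surviving = {c for copies in truth.copies_by_species.values() for c in copies}
    assert emitted == surviving
    n_pseudo = sum(1 for e in truth.events if e.kind == "pseudogenization")
    assert n_pseudo > 0  # losses occurred but none were emitted


def test_missing_seed_rejected():
    with pytest.raises(ValueError, match="seed"):
        SimParams()
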