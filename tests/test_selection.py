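"""Branch screen, BH correction and clade summaries."""

import numpy as np
import pandas as pd
import pytest

from _oracles import bh_adjust
from v1r_clade_evo.io import parse_newick
from v1r_clade_evo.selection import (
    BranchTest,
    branch_dnds_screen,
    eligible_orthogroups,
    fdr_correct,
    headline_fractions,
    ingest_external_tests,
    round_half_up,
    summarize_selection,
)


def test_eligible_orthogroups_threshold():
    groups = {"small": ["a", "b", "c"], "paralogs": ["a1", "a2", "b1", "b2"], "big": list("abcdef")}
    out = eligible_orthogroups(groups)
    assert set(out) == {"paralogs", "big"}


# ---------------------------------------------------------------------------
# internal screen
# ---------------------------------------------------------------------------


def test_zero_length_branch_untested():
    aln = {"a": "ATGGCT", "b": "ATGGCT"}
    tree = parse_newick("(a:0,b:0);")
    assert branch_dnds_screen(aln, tree) == []


def test_synonymous_only_branch_never_significant():
    # GGA->GGG is synonymous; one change on the 2-leaf tree
    aln = {"a": "ATGGGA", "b": "ATGGGG"}
    tree = parse_newick("(a:1,b:1);")
    tests = branch_dnds_screen(aln, tree)
    assert tests, "one change must be tested"
    for t in tests:
        assert t.p_raw >= 0.5


def test_stop_codon_in_alignment_rejected():
    with pytest.raises(ValueError, match="stop"):
        branch_dnds_screen({"a": "ATGTAA", "b": "ATGTAA"}, parse_newick("(a:1,b:1);"))


def test_leaf_mismatch_rejected():
    with pytest.raises(ValueError, match="leaves"):
        branch_dnds_screen({"a": "ATG", "x": "ATG"}, parse_newick("(a:1,b:1);"))


def test_fitch_reconstruction_deterministic():
    aln = {"a": "ATGGCT", "b": "ATGGCA", "c": "ATGGCG"}
    tree = parse_newick("((a:1,b:1):1,c:1);")
    t1 = branch_dnds_screen(aln, tree, orthogroup="og")
    t2 = branch_dnds_screen(aln, parse_newick("((a:1,b:1):1,c:1);"), orthogroup="og")
    assert [(x.branch_id, x.p_raw) for x in t1] == [(x.branch_id, x.p_raw) for x in t2]


# ---------------------------------------------------------------------------
# external ingestion
# ---------------------------------------------------------------------------


def _table(rows):
    return pd.DataFrame(rows, columns=["orthogroup", "branch", "branch_kind", "p_raw"])


def test_ingest_well_formed():
    tests = ingest_external_tests(
        _table([("og1", "b1", "terminal", "0.01"), ("og1", "n2", "internal", "0.5"),
                ("og2", "b1", "terminal", "1.0")])
    )
    assert len(tests) == 3
    assert all(t.source == "external" and t.p_adj is None for t in tests)


def test_ingest_rejects_bad_p_keeps_rest(caplog):
    tests = ingest_external_tests(
        _table([("og1", "b1", "terminal", "1.5"), ("og1", "b2", "terminal", "0.2")])
    )
    assert [t.branch_id for t in tests] == ["b2"]


def test_ingest_empty_table():
    assert ingest_external_tests(_table([])) == []


# ---------------------------------------------------------------------------
# FDR
# ---------------------------------------------------------------------------


def _tests_from_p(pvals):
    return [
        BranchTest(orthogroup=f"og{i % 3}", branch_id=f"b{i}", branch_kind="terminal", p_raw=p)
        for i, p in enumerate(pvals)
    ]


def test_bh_matches_hand_computed_four_values():
    # sorted p*(m/rank), cumulative min from the top:
    # 0.001*4=0.004; 0.02*2=0.04; 0.03*4/3=0.04; 0.9 -> adj (0.004, 0.04, 0.04, 0.9)
    tests = fdr_correct(_tests_from_p([0.001, 0.02, 0.03, 0.9]))
    assert [t.p_adj for t in tests] == pytest.approx([0.004, 0.04, 0.04, 0.9])
    assert [t.significant for t in tests] == [True, True, True, False]


def test_bh_matches_textbook_oracle_random(rng):
    for _ in range(20):
        pvals = list(np.round(rng.random(int(rng.integers(1, 12))), 4))
        tests = fdr_correct(_tests_from_p(pvals))
        assert [t.p_adj for t in tests] == pytest.approx(bh_adjust(pvals))


def test_bh_all_ones_none_significant():
    tests = fdr_correct(_tests_from_p([1.0] * 5))
    assert not any(t.significant for t in tests)


def test_bh_single_p_is_raw():
    (t,) = fdr_correct(_tests_from_p([0.04]))
    assert t.p_adj == pytest.approx(0.04) and t.significant


def test_bh_monotone_in_q(rng):
    pvals = list(rng.random(40) * 0.2)
    sig_01 = {t.branch_id for t in fdr_correct(_tests_from_p(pvals), q=0.01) if t.significant}
    sig_05 = {t.branch_id for t in fdr_correct(_tests_from_p(pvals), q=0.05) if t.significant}
    assert sig_01 <= sig_05


def test_per_orthogroup_scope():
    tests = _tests_from_p([0.04, 0.9, 0.9, 0.04, 0.9, 0.9])
    fdr_correct(tests, scope="per_orthogroup")
    # og0 family = (0.04, 0.04): step-up gives 0.04*2/2 = 0.04 at the top rank,
    # and the cumulative minimum carries it down -> both adjusted to 0.04
    fam0 = [t for t in tests if t.orthogroup == "og0"]
    assert all(t.p_adj == pytest.approx(0.04) and t.significant for t in fam0)
    # og1/og2 families are (0.9, 0.9): never significant
    rest = [t for t in tests if t.orthogroup != "og0"]
    assert not any(t.significant for t in rest)


# ---------------------------------------------------------------------------
# summaries
# ---------------------------------------------------------------------------


def _clade_tests(clade_spec):
    """clade_spec: clade -> (term_sig, int_sig, tested, n_ogs, n_sig_ogs)."""
    tests = []
    clade_of = {}
    tested_ogs = {}
    for clade, (term, intl, tested, n_ogs, n_sig) in clade_spec.items():
        tested_ogs[clade] = n_ogs
        ogs = [f"{clade}_og{k}" for k in range(n_ogs)]
        for og in ogs:
            clade_of[og] = clade
        sig = [("terminal", k) for k in range(term)] + [("internal", k) for k in range(intl)]
        n = 0
        for kind, k in sig:
            og = ogs[min(k % max(n_sig, 1), n_ogs - 1)] if n_sig else ogs[0]
            tests.append(BranchTest(og, f"{clade}s{n}", kind, p_raw=1e-9))
            n += 1
        for j in range(tested - len(sig)):
            tests.append(BranchTest(ogs[j % n_ogs], f"{clade}n{j}", "terminal", p_raw=1.0))
    return tests, clade_of, tested_ogs


def test_summary_clade_percentages():
    # 101 tested branches with 8 significant over 13 orthogroups, 5 with hits
    tests, clade_of, tested_ogs = _clade_tests({"G": (6, 2, 101, 13, 5)})
    fdr_correct(tests)
    df = summarize_selection(tests, clade_of, tested_ogs)
    row = df[df["clade"] == "G"].iloc[0]
    assert row["pct_branches"] == pytest.approx(7.92)
    assert row["pct_orthogroups"] == pytest.approx(38.46)


def test_summary_zero_significant():
    tests, clade_of, tested_ogs = _clade_tests({"L": (0, 0, 7, 1, 0)})
    fdr_correct(tests)
    df = summarize_selection(tests, clade_of, tested_ogs)
    row = df[df["clade"] == "L"].iloc[0]
    assert row["pct_branches"] == 0.0 and row["orthogroup_ids"] == "-"


def test_summary_all_significant_toy():
    tests, clade_of, tested_ogs = _clade_tests({"X": (5, 0, 5, 2, 2)})
    fdr_correct(tests)
    df = summarize_selection(tests, clade_of, tested_ogs)
    row = df[df["clade"] == "X"].iloc[0]
    assert row["pct_branches"] == 100.0 and row["pct_orthogroups"] == 100.0


def test_summary_total_row_is_columnwise_sum():
    tests, clade_of, tested_ogs = _clade_tests({"A": (2, 1, 30, 4, 2), "B": (0, 1, 20, 3, 1)})
    fdr_correct(tests)
    df = summarize_selection(tests, clade_of, tested_ogs)
    total = df[df["clade"] == "Total"].iloc[0]
    clades = df[df["clade"] != "Total"]
    for col in ("terminal_sig", "internal_sig", "total_sig", "tested_branches", "tested_orthogroups"):
        assert total[col] == clades[col].sum()


def test_summary_permutation_invariant(rng):
    tests, clade_of, tested_ogs = _clade_tests({"A": (2, 1, 30, 4, 2), "B": (0, 1, 20, 3, 1)})
    fdr_correct(tests)
    df1 = summarize_selection(list(tests), clade_of, tested_ogs)
    shuffled = list(tests)
    rng.shuffle(shuffled)
    df2 = summarize_selection(shuffled, clade_of, tested_ogs)
    pd.testing.assert_frame_equal(df1, df2)


def test_headline_fractions_split():
    tests = []
    for i in range(685):
        tests.append(BranchTest("og", f"t{i}", "terminal", p_raw=1e-9 if i < 24 else 1.0))
    for i in range(1034 - 685):
        tests.append(BranchTest("og", f"i{i}", "internal", p_raw=1e-9 if i < 8 else 1.0))
    fdr_correct(tests)
    term, intl = headline_fractions(tests)
    assert term == pytest.approx(3.5)
    assert intl == pytest.approx(2.3)


def test_round_half_up():
    assert round_half_up(2.125) == 2.13
    assert round_half_up(2.124) == 2.12
    assert round_half_up(94.339622, 0) == 94.0
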