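"""Built-in study fixtures.

* the 6-taxon Mus species tree used throughout (house mouse *M. m.
  domesticus* plus five sequenced congeners; rat is available as an outgroup
  label only), ultrametric with root-to-tip depth 0.07 expected
  substitutions per codon site — genus-level divergence at desk scale;
* the published per-clade branch-level selection screen counts (significant
  and tested branches, terminal/internal split, tested orthogroups and
  orthogroups with at least one significant branch).  These counts are
  *inputs*: the package recomputes every percentage and headline fraction
  from them.
"""

from __future__ import annotations

import dendropy
import pandas as pd

SPECIES = ("domesticus", "spicilegus", "macedonicus", "spretus", "caroli", "pahari")
REFERENCE_SPECIES = "domesticus"
OUTGROUP = "rattus"

CLADES = ("A/B", "C", "D", "E", "F", "G", "H", "I", "J/K", "L", "N")

_SPECIES_TREE_NEWICK = (
    "((((domesticus:0.015,(spicilegus:0.010,macedonicus:0.010)spi_mac:0.005)"
    "dom_spi_mac:0.005,spretus:0.025)crown:0.020,caroli:0.045)derived:0.025,pahari:0.070)root;"
)


def default_species_tree() -> dendropy.Tree:
    """The default Mus species tree (rooted, ultrametric, depth 0.07)."""
    tree = dendropy.Tree.get(
        data=_SPECIES_TREE_NEWICK,
        schema="newick",
        preserve_underscores=True,
        suppress_internal_node_taxa=True,
    )
    return tree


# Published branch-level selection screen outcome counts per receptor clade.
# Columns: clade, significant terminal branches, significant internal
# branches, tested branches (all), tested orthogroups, orthogroups with >= 1
# significant branch.  The terminal/internal split of *tested* branches is
# published only as totals (685 terminal / 1034 overall), so per-clade tested
# branches are carried as a single column and the terminal total separately.
_SELECTION_COUNT_ROWS = [
    # clade, term_sig, int_sig, tested_branches, tested_orthogroups, sig_orthogroups
    ("A/B", 3, 2, 119, 11, 3),
    ("C", 3, 2, 235, 35, 4),
    ("D", 5, 0, 119, 13, 4),
    ("E", 0, 1, 122, 16, 1),
    ("F", 2, 0, 45, 5, 1),
    ("G", 6, 2, 101, 13, 5),
    ("H", 3, 0, 125, 15, 3),
    ("I", 2, 0, 100, 13, 2),
    ("J/K", 0, 1, 57, 4, 1),
    ("L", 0, 0, 7, 1, 0),
    ("N", 0, 0, 5, 1, 0),
]

TOTAL_TERMINAL_TESTED = 685
TOTAL_TESTED = 1034  # printed total; the per-clade column sums to 1035


def published_branch_tests():
    """Expand the published per-clade counts into per-branch test records.

    Returns (tests, clade_of, tested_orthogroups): significant branches get a
    vanishing raw p, the rest p = 1, so the package's own FDR correction and
    aggregation recompute every percentage from the counts.  Tested branches
    are split terminal/internal so the totals match the published 685
    terminal / 1034 overall; the per-clade split of non-significant branches
    is not published and any allocation leaves the per-clade percentages
    unchanged (they are kind-agnostic).
    """
    from v1r_clade_evo.selection import BranchTest

    counts = published_selection_counts()
    tests: list[BranchTest] = []
    clade_of: dict[str, str] = {}
    tested_orthogroups: dict[str, int] = {}
    term_remaining = TOTAL_TERMINAL_TESTED - int(counts["terminal_sig"].sum())
    for _, row in counts.iterrows():
        clade = row["clade"]
        tag = clade.replace("/", "")
        n_ogs = int(row["tested_orthogroups"])
        n_sig_ogs = int(row["sig_orthogroups"])
        ogs = [f"{tag}_og{k + 1}" for k in range(n_ogs)]
        for og in ogs:
            clade_of[og] = clade
        tested_orthogroups[clade] = n_ogs
        sig = [("terminal", k) for k in range(int(row["terminal_sig"]))]
        sig += [("internal", k) for k in range(int(row["internal_sig"]))]
        for i, (kind, _k) in enumerate(sig):
            og = ogs[i % n_sig_ogs] if n_sig_ogs else ogs[0]
            tests.append(BranchTest(og, f"{tag}_sig{i + 1}", kind, p_raw=1e-9))
        n_rest = int(row["tested_branches"]) - len(sig)
        for j in range(n_rest):
            kind = "terminal" if term_remaining > 0 else "internal"
            if kind == "terminal":
                term_remaining -= 1
            tests.append(BranchTest(ogs[j % n_ogs], f"{tag}_ns{j + 1}", kind, p_raw=1.0))
    return tests, clade_of, tested_orthogroups


def published_selection_counts() -> pd.DataFrame:
    """Per-clade counts of the published branch-selection screen, as inputs."""
    return pd.DataFrame(
        _SELECTION_COUNT_ROWS,
        columns=[
            "clade",
            "terminal_sig",
            "internal_sig",
            "tested_branches",
            "tested_orthogroups",
            "sig_orthogroups",
        ],
    )
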