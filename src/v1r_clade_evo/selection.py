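"""Branch-level positive-selection screening, FDR control and clade summaries.

Two sources of per-branch evidence are supported:

* an *internal counting screen* (clearly labelled ``internal_screen`` in all
  outputs): ancestral codons are reconstructed by Fitch parsimony
  (lexicographically smallest codon on ties), per-branch synonymous and
  nonsynonymous sites and differences are counted in the Nei–Gojobori
  unweighted-pathway style, and the one-sided binomial tail probability of
  seeing at least the observed number of nonsynonymous changes under the
  neutral expectation N/(N+S) is the raw p-value.  This is a screen, not a
  likelihood branch-site model — published branch-test results enter through
  the external ingestion path instead.
* *external per-branch p-values* (e.g. from a random-effects likelihood
  branch test) as a tab-delimited table.

Multiple testing is controlled by Benjamini–Hochberg at q = 0.05; a branch
is significant iff its adjusted p ≤ 0.05.  Summaries aggregate per receptor
clade: counts of significant terminal (gene) and internal (deeper) branches,
percentages of tested branches and of tested orthogroups with at least one
significant branch, with half-up rounding to two decimals.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import dendropy
import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from v1r_clade_evo._codon import (
    CODON_INDEX,
    STOP_CODONS,
    sequence_diff_counts,
    sequence_site_counts,
    split_codons,
)

Q_DEFAULT = 0.05

SUMMARY_COLUMNS = [
    "clade", "terminal_sig", "internal_sig", "total_sig", "tested_branches",
    "pct_branches", "tested_orthogroups", "pct_orthogroups", "orthogroup_ids",
]


@dataclass
class BranchTest:
    orthogroup: str
    branch_id: str
    branch_kind: str  # terminal | internal
    dn: float | None = None
    ds: float | None = None
    p_raw: float | None = None
    p_adj: float | None = None
    significant: bool = False
    source: str = "internal_screen"  # internal_screen | external
    clade: str | None = field(default=None)


def eligible_orthogroups(groups: dict[str, list[str]], min_members: int = 4) -> dict[str, list[str]]:
    """Orthogroups with at least ``min_members`` sequences (orthologs + paralogs)."""
    return {name: members for name, members in groups.items() if len(members) >= min_members}


def round_half_up(x: float, ndigits: int = 2) -> float:
    return float(Decimal(repr(x)).quantize(Decimal("1." + "0" * ndigits if ndigits else "1"), rounding=ROUND_HALF_UP))


# ---------------------------------------------------------------------------
# internal counting screen
# ---------------------------------------------------------------------------


def _fitch_ancestral(tree: dendropy.Tree, leaf_codons: dict[str, list[str]]) -> dict[int, list[str]]:
    """Fitch parsimony codon states for every node, ties to the smallest codon.

    Gap or stop-containing codons at leaves are treated as missing data
    (ignored in set intersection).
    """
    ncol = len(next(iter(leaf_codons.values())))
    sets: dict[int, list[frozenset[str] | None]] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            codons = leaf_codons[node.taxon.label]
            sets[id(node)] = [
                frozenset([c]) if c in CODON_INDEX else None for c in codons
            ]
        else:
            child_sets = [sets[id(c)] for c in node.child_nodes()]
            merged: list[frozenset[str] | None] = []
            for col in range(ncol):
                avail = [cs[col] for cs in child_sets if cs[col] is not None]
                if not avail:
                    merged.append(None)
                    continue
                inter = frozenset.intersection(*avail)
                merged.append(inter if inter else frozenset.union(*avail))
            sets[id(node)] = merged
    states: dict[int, list[str]] = {}
    for node in tree.preorder_node_iter():
        own = sets[id(node)]
        if node.parent_node is None:
            states[id(node)] = [min(s) if s else "---" for s in own]
        else:
            parent = states[id(node.parent_node)]
            assigned = []
            for col in range(ncol):
                s = own[col]
                if s is None:
                    assigned.append(parent[col])
                elif parent[col] in s:
                    assigned.append(parent[col])
                else:
                    assigned.append(min(s))
            states[id(node)] = assigned
    return states


def branch_dnds_screen(
    codon_alignment: dict[str, str],
    gene_tree: dendropy.Tree,
    orthogroup: str = "",
) -> list[BranchTest]:
    """Counting-based per-branch dN/dS screen on one orthogroup alignment.

    Branch ids are the child taxon label for terminal branches and a stable
    ``node<k>`` preorder index for internal ones.  Branches with no inferred
    change are untested and omitted.
    """
    leaf_codons: dict[str, list[str]] = {}
    for sid, seq in codon_alignment.items():
        codons = split_codons(seq.upper().replace(".", "-"))
        for c in codons:
            if c in STOP_CODONS:
                raise ValueError(f"stop codon in alignment row {sid}")
        leaf_codons[sid] = codons
    labels = {lf.taxon.label for lf in gene_tree.leaf_node_iter()}
    if labels != set(leaf_codons):
        raise ValueError("tree leaves do not match alignment rows")
    states = _fitch_ancestral(gene_tree, leaf_codons)
    tests: list[BranchTest] = []
    k = 0
    for node in gene_tree.preorder_node_iter():
        if node.parent_node is None:
            continue
        k += 1
        parent_codons = states[id(node.parent_node)]
        child_codons = leaf_codons[node.taxon.label] if node.is_leaf() else states[id(node)]
        s_p, n_p = sequence_site_counts(parent_codons)
        s_c, n_c = sequence_site_counts(child_codons)
        S = (s_p + s_c) / 2.0
        N = (n_p + n_c) / 2.0
        sd, nd = sequence_diff_counts(parent_codons, child_codons)
        total = sd + nd
        if total <= 0 or (N + S) <= 0:
            continue
        p_neutral = N / (N + S)
        n_int = int(round(total))
        k_int = int(round(nd))
        if n_int == 0:
            continue
        k_int = min(k_int, n_int)
        p_raw = float(stats.binom.sf(k_int - 1, n_int, p_neutral))
        tests.append(
            BranchTest(
                orthogroup=orthogroup,
                branch_id=node.taxon.label if node.is_leaf() else f"node{k}",
                branch_kind="terminal" if node.is_leaf() else "internal",
                dn=nd / N if N else None,
                ds=sd / S if S else None,
                p_raw=p_raw,
                source="internal_screen",
            )
        )
    return tests


# ---------------------------------------------------------------------------
# external ingestion, FDR, summaries
# ---------------------------------------------------------------------------


def ingest_external_tests(table: pd.DataFrame) -> list[BranchTest]:
    """Parse external per-branch tests (orthogroup, branch, branch_kind, p_raw).

    Rows with p outside [0, 1] are rejected with a logged error; the rest are
    kept.  Adjusted p-values are left unset until :func:`fdr_correct`.
    """
    import logging

    log = logging.getLogger(__name__)
    tests: list[BranchTest] = []
    for _, row in table.iterrows():
        try:
            p = float(row["p_raw"])
        except (TypeError, ValueError):
            log.error("rejecting row with unparsable p: %r", dict(row))
            continue
        if not (0.0 <= p <= 1.0):
            log.error("rejecting row with p outside [0,1]: %r", dict(row))
            continue
        kind = str(row["branch_kind"])
        if kind not in ("terminal", "internal"):
            log.error("rejecting row with unknown branch_kind: %r", dict(row))
            continue
        tests.append(
            BranchTest(
                orthogroup=str(row["orthogroup"]),
                branch_id=str(row["branch"]),
                branch_kind=kind,
                p_raw=p,
                source="external",
            )
        )
    return tests


def fdr_correct(
    tests: list[BranchTest], q: float = Q_DEFAULT, scope: str = "pooled"
) -> list[BranchTest]:
    """Benjamini–Hochberg step-up; significant iff adjusted p ≤ q.

    ``scope='pooled'`` corrects over all tested branches together (default);
    ``scope='per_orthogroup'`` corrects within each orthogroup's test family
    separately.
    """
    if scope not in ("pooled", "per_orthogroup"):
        raise ValueError("scope must be 'pooled' or 'per_orthogroup'")
    tested = [t for t in tests if t.p_raw is not None]
    if not tested:
        return tests
    if scope == "pooled":
        families = {"all": tested}
    else:
        families = {}
        for t in tested:
            families.setdefault(t.orthogroup, []).append(t)
    for fam in families.values():
        pvals = np.array([t.p_raw for t in fam])
        _, p_adj, _, _ = multipletests(pvals, alpha=q, method="fdr_bh")
        for t, pa in zip(fam, p_adj):
            t.p_adj = float(pa)
            t.significant = bool(pa <= q)
    return tests


def summarize_selection(
    tests: list[BranchTest],
    clade_of: dict[str, str],
    tested_orthogroups: dict[str, int] | None = None,
) -> pd.DataFrame:
    """Per-clade selection summary plus a Total row.

    ``clade_of`` maps orthogroup name -> clade.  ``tested_orthogroups``
    optionally supplies the number of tested orthogroups per clade (otherwise
    the distinct orthogroups present among the tests are counted).  An
    orthogroup counts as under selection iff ≥ 1 of its branches is
    significant.  Percentages are rounded half-up to 2 decimals; a clade with
    zero tested branches reports 0.00.
    """
    tested = [t for t in tests if t.p_raw is not None]
    for t in tested:
        t.clade = clade_of.get(t.orthogroup, "unplaced")
    clades = sorted({t.clade for t in tested} | (set(tested_orthogroups) if tested_orthogroups else set()))
    rows = []
    for clade in clades:
        ct = [t for t in tested if t.clade == clade]
        term = sum(1 for t in ct if t.significant and t.branch_kind == "terminal")
        intl = sum(1 for t in ct if t.significant and t.branch_kind == "internal")
        ogs = sorted({t.orthogroup for t in ct})
        sig_ogs = sorted({t.orthogroup for t in ct if t.significant})
        n_ogs = tested_orthogroups.get(clade, len(ogs)) if tested_orthogroups else len(ogs)
        n_branches = len(ct)
        total_sig = term + intl
        rows.append(
            {
                "clade": clade,
                "terminal_sig": term,
                "internal_sig": intl,
                "total_sig": total_sig,
                "tested_branches": n_branches,
                "pct_branches": round_half_up(100.0 * total_sig / n_branches) if n_branches else 0.0,
                "tested_orthogroups": n_ogs,
                "pct_orthogroups": round_half_up(100.0 * len(sig_ogs) / n_ogs) if n_ogs else 0.0,
                "orthogroup_ids": ", ".join(sig_ogs) if sig_ogs else "-",
            }
        )
    total = {
        "clade": "Total",
        "terminal_sig": sum(r["terminal_sig"] for r in rows),
        "internal_sig": sum(r["internal_sig"] for r in rows),
        "total_sig": sum(r["total_sig"] for r in rows),
        "tested_branches": sum(r["tested_branches"] for r in rows),
        "tested_orthogroups": sum(r["tested_orthogroups"] for r in rows),
        "orthogroup_ids": "NA",
    }
    total["pct_branches"] = (
        round_half_up(100.0 * total["total_sig"] / total["tested_branches"]) if total["tested_branches"] else 0.0
    )
    n_sig_ogs = sum(len([x for x in r["orthogroup_ids"].split(", ") if x not in ("-", "NA")]) for r in rows)
    total["pct_orthogroups"] = (
        round_half_up(100.0 * n_sig_ogs / total["tested_orthogroups"]) if total["tested_orthogroups"] else 0.0
    )
    df = pd.DataFrame(rows + [total], columns=SUMMARY_COLUMNS)
    return df


def headline_fractions(tests: list[BranchTest]) -> tuple[float, float]:
    """Percent of tested terminal (gene) and internal branches under selection.

    Returned at headline precision (one decimal, half-up), matching how
    genome-wide branch-test results are usually quoted.
    """
    tested = [t for t in tests if t.p_raw is not None]
    term = [t for t in tested if t.branch_kind == "terminal"]
    intl = [t for t in tested if t.branch_kind == "internal"]
    pct_term = round_half_up(100.0 * sum(t.significant for t in term) / len(term), 1) if term else 0.0
    pct_int = round_half_up(100.0 * sum(t.significant for t in intl) / len(intl), 1) if intl else 0.0
    return pct_term, pct_int


def tests_to_frame(tests: list[BranchTest]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "orthogroup": t.orthogroup,
                "branch": t.branch_id,
                "branch_kind": t.branch_kind,
                "dN": t.dn,
                "dS": t.ds,
                "p_raw": t.p_raw,
                "p_adj": t.p_adj,
                "significant": t.significant,
                "source": t.source,
            }
            for t in tests
        ]
    )
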