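"""Independent brute-force oracles used by the test suite.

Everything here deliberately re-derives results from first principles with
the dumbest correct algorithm available, sharing no code path with the
package implementation it checks.
"""

from __future__ import annotations

import itertools
from functools import lru_cache

_STOPS = {"TAA", "TAG", "TGA"}
_COMP = str.maketrans("ACGT", "TGCA")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


# ---------------------------------------------------------------------------
# six-frame ORF scanner
# ---------------------------------------------------------------------------


def orfs_six_frame(seq: str, min_len: int, max_len: int) -> set[tuple[str, int, int]]:
    """Every ATG→stop ORF on both strands; (strand, start, end) on the input strand."""
    out: set[tuple[str, int, int]] = set()
    for strand in "+-":
        s = seq if strand == "+" else revcomp(seq)
        n = len(s)
        for i in range(n - 2):
            if s[i:i + 3] != "ATG":
                continue
            for j in range(i + 3, n - 2, 3):
                if s[j:j + 3] in _STOPS:
                    length = (j - i) // 3
                    if min_len <= length <= max_len:
                        if strand == "+":
                            out.add((strand, i, j))
                        else:
                            out.add((strand, n - j, n - i))
                    break
    return out


# ---------------------------------------------------------------------------
# quadratic dedupe
# ---------------------------------------------------------------------------


def dedupe_bruteforce(seqs: dict[str, str]) -> set[str]:
    """Keep ids whose sequence is not contained in any other retained sequence.

    Mirrors the containment-chain rule: longest kept, ties by smallest id;
    a sequence is dropped if it (or its reverse complement) is a substring of
    a kept longer-or-equal sequence.
    """
    order = sorted(seqs, key=lambda i: (-len(seqs[i]), i))
    kept: list[str] = []
    for i in order:
        s, rc = seqs[i], revcomp(seqs[i])
        if not any(s in seqs[k] or rc in seqs[k] for k in kept):
            kept.append(i)
    return set(kept)


# ---------------------------------------------------------------------------
# exhaustive global-alignment enumeration (tiny sequences only)
# ---------------------------------------------------------------------------


def best_global_score_enum(a: str, b: str, score, gap_open: float, gap_extend: float) -> float:
    """Maximum global alignment score by enumerating every alignment path."""

    best = float("-inf")

    def rec(i: int, j: int, acc: float, prev: str) -> None:
        nonlocal best
        if i == len(a) and j == len(b):
            best = max(best, acc)
            return
        if i < len(a) and j < len(b):
            rec(i + 1, j + 1, acc + score(a[i], b[j]), "M")
        if j < len(b):
            cost = gap_extend if prev == "X" else gap_open
            rec(i, j + 1, acc - cost, "X")
        if i < len(a):
            cost = gap_extend if prev == "Y" else gap_open
            rec(i + 1, j, acc - cost, "Y")

    rec(0, 0, 0.0, "")
    return best


# ---------------------------------------------------------------------------
# rooted-tree enumeration and reconciliation oracle
# ---------------------------------------------------------------------------
# trees are nested tuples; a leaf is an int index into a species assignment


def enumerate_topologies(n: int):
    """All rooted binary tree shapes over leaves 0..n-1 (labelled)."""

    @lru_cache(maxsize=None)
    def build(leafset: frozenset) -> tuple:
        leaves = sorted(leafset)
        if len(leaves) == 1:
            return ((leaves[0]),)
        out = []
        rest = leaves[1:]
        first = leaves[0]
        # split: first goes left with any subset of rest (proper, non-empty right)
        for r in range(len(rest) + 1):
            for combo in itertools.combinations(rest, r):
                left = frozenset([first, *combo])
                right = leafset - left
                if not right:
                    continue
                for lt in build(left):
                    for rt in build(right):
                        out.append((lt, rt))
        return tuple(out)

    return build(frozenset(range(n)))


def tree_leaves(t) -> list[int]:
    if isinstance(t, int):
        return [t]
    return tree_leaves(t[0]) + tree_leaves(t[1])


def reconcile_bruteforce(t, species: dict[int, str]) -> list[frozenset[int]]:
    """Minimal partition of leaves into clean subtrees (direct definition).

    A subtree is *clean* when none of its internal nodes is a non-local
    duplication: children's species sets intersect while the node's subtree
    spans more than one species.  Enumerates every way to cut the tree into
    rooted subtrees and returns the (unique) coarsest all-clean partition.
    """

    def span(t) -> set[str]:
        return {species[l] for l in tree_leaves(t)}

    def clean(t) -> bool:
        if isinstance(t, int):
            return True
        a, b = t
        if span(a) & span(b) and len(span(t)) > 1:
            return False
        return clean(a) and clean(b)

    def partitions(t) -> list[list[frozenset[int]]]:
        opts: list[list[frozenset[int]]] = []
        if clean(t):
            opts.append([frozenset(tree_leaves(t))])
        if not isinstance(t, int):
            for pa in partitions(t[0]):
                for pb in partitions(t[1]):
                    opts.append(pa + pb)
        return opts

    best = min(partitions(t), key=len)
    # uniqueness of the coarsest partition is asserted by the caller's test
    return sorted(best, key=lambda s: sorted(s))


def random_tree(rng, n_leaves: int):
    """Random rooted binary topology by sequential attachment."""
    nodes = list(range(n_leaves))
    rng.shuffle(nodes)
    t = nodes[0]
    for leaf in nodes[1:]:
        t = _attach(t, leaf, rng)
    return t


def _attach(t, leaf, rng):
    # choose uniformly among edges by recursing with probability by subtree size
    def count(t):
        return 1 if isinstance(t, int) else 1 + count(t[0]) + count(t[1])

    if rng.random() < 1.0 / count(t) or isinstance(t, int):
        return (t, leaf)
    a, b = t
    if rng.random() < count(a) / (count(a) + count(b)):
        return (_attach(a, leaf, rng), b)
    return (a, _attach(b, leaf, rng))


def tuple_to_newick(t, species: dict[int, str]) -> str:
    def fmt(t):
        if isinstance(t, int):
            return f"{species[t]}_{t}:1"
        return f"({fmt(t[0])},{fmt(t[1])}):1"

    return fmt(t) + ";"


# ---------------------------------------------------------------------------
# Benjamini–Hochberg by hand (frozen example values live in the tests)
# ---------------------------------------------------------------------------


def bh_adjust(pvals: list[float]) -> list[float]:
    """Textbook step-up: p(i) * m / i, cumulative minimum from the largest."""
    m = len(pvals)
    order = sorted(range(m), key=lambda i: pvals[i])
    adj = [0.0] * m
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, pvals[i] * m / rank)
        adj[i] = running
    return adj
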