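"""Protein alignment primitives.

Three layers:

* :func:`gotoh_global` — an affine-gap Needleman–Wunsch (Gotoh) aligner with
  fully specified tie-breaking (substitution preferred over gap, then gap in
  the first sequence), so classification rules that inspect alignment columns
  are deterministic.  Defaults mirror EMBOSS Needle: BLOSUM62, gap open 10,
  gap extend 0.5 (a gap of length L costs open + (L-1)*extend); end gaps are
  penalized like internal gaps.
* local best-hit scoring via Bio.Align.PairwiseAligner (Smith–Waterman),
  used for reference annotation.
* :func:`center_star_msa` — a center-star progressive multiple aligner for
  the desk-scale identity filter; external alignments can be supplied
  instead wherever an MSA is consumed.
"""

from __future__ import annotations

from dataclasses import dataclass

from Bio import Align
from Bio.Align import substitution_matrices

GAP = "-"

_BLOSUM62 = substitution_matrices.load("BLOSUM62")
_B62: dict[tuple[str, str], float] = {}
for _a in _BLOSUM62.alphabet:
    for _b in _BLOSUM62.alphabet:
        _B62[(_a, _b)] = float(_BLOSUM62[_a, _b])


def substitution_score(a: str, b: str) -> float:
    try:
        return _B62[(a, b)]
    except KeyError:
        return _B62[("X", "X")]


@dataclass(frozen=True)
class GlobalAlignment:
    """A scored global alignment of two peptides (gap character '-')."""

    score: float
    aligned_a: str
    aligned_b: str


def gotoh_global(
    a: str,
    b: str,
    gap_open: float = 10.0,
    gap_extend: float = 0.5,
) -> GlobalAlignment:
    """Optimal global alignment under BLOSUM62 with affine gaps.

    Ties are broken by preferring a substitution column over a gap column,
    and a gap in ``a`` over a gap in ``b``; within each gap state, extension
    is preferred over opening.  Raises ``ValueError`` on empty input.
    """
    if not a or not b:
        raise ValueError("cannot align an empty sequence")
    n, m = len(a), len(b)
    NEG = float("-inf")
    # state 0 = M (a[i-1]~b[j-1]), 1 = X (gap in a, consumes b), 2 = Y (gap in b, consumes a)
    M = [[NEG] * (m + 1) for _ in range(n + 1)]
    X = [[NEG] * (m + 1) for _ in range(n + 1)]
    Y = [[NEG] * (m + 1) for _ in range(n + 1)]
    M[0][0] = 0.0
    for j in range(1, m + 1):
        X[0][j] = -gap_open - gap_extend * (j - 1)
    for i in range(1, n + 1):
        Y[i][0] = -gap_open - gap_extend * (i - 1)
    # backpointers: state entered FROM, per (state, i, j)
    bpM = [[0] * (m + 1) for _ in range(n + 1)]
    bpX = [[0] * (m + 1) for _ in range(n + 1)]
    bpY = [[0] * (m + 1) for _ in range(n + 1)]
    for i in range(1, n + 1):
        ai = a[i - 1]
        Mi1, Xi1, Yi1 = M[i - 1], X[i - 1], Y[i - 1]
        Mi, Xi, Yi = M[i], X[i], Y[i]
        bMi, bXi, bYi = bpM[i], bpX[i], bpY[i]
        for j in range(1, m + 1):
            s = substitution_score(ai, b[j - 1])
            # M: from any state at (i-1, j-1); prefer M > X > Y on ties
            best, frm = Mi1[j - 1], 0
            if Xi1[j - 1] > best:
                best, frm = Xi1[j - 1], 1
            if Yi1[j - 1] > best:
                best, frm = Yi1[j - 1], 2
            Mi[j] = best + s
            bMi[j] = frm
            # X: gap in a; open from M/Y at (i, j-1) or extend X
            ext = Xi[j - 1] - gap_extend
            opn_m = Mi[j - 1] - gap_open
            opn_y = Yi[j - 1] - gap_open
            best, frm = ext, 1
            if opn_m > best:
                best, frm = opn_m, 0
            if opn_y > best:
                best, frm = opn_y, 2
            Xi[j] = best
            bXi[j] = frm
            # Y: gap in b; open from M/X at (i-1, j) or extend Y
            ext = Yi1[j] - gap_extend
            opn_m = Mi1[j] - gap_open
            opn_x = Xi1[j] - gap_open
            best, frm = ext, 2
            if opn_m > best:
                best, frm = opn_m, 0
            if opn_x > best:
                best, frm = opn_x, 1
            Yi[j] = best
            bYi[j] = frm
    # terminal state: prefer M > X > Y
    state = 0
    score = M[n][m]
    if X[n][m] > score:
        score, state = X[n][m], 1
    if Y[n][m] > score:
        score, state = Y[n][m], 2
    out_a: list[str] = []
    out_b: list[str] = []
    i, j = n, m
    while i > 0 or j > 0:
        if state == 0:
            out_a.append(a[i - 1])
            out_b.append(b[j - 1])
            state = bpM[i][j]
            i -= 1
            j -= 1
        elif state == 1:
            if i == 0:
                out_a.append(GAP)
                out_b.append(b[j - 1])
                j -= 1
                continue
            out_a.append(GAP)
            out_b.append(b[j - 1])
            state = bpX[i][j]
            j -= 1
        else:
            if j == 0:
                out_a.append(a[i - 1])
                out_b.append(GAP)
                i -= 1
                continue
            out_a.append(a[i - 1])
            out_b.append(GAP)
            state = bpY[i][j]
            i -= 1
    return GlobalAlignment(score=score, aligned_a="".join(reversed(out_a)), aligned_b="".join(reversed(out_b)))


def _make_aligner(mode: str, gap_open: float, gap_extend: float) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = mode
    aligner.substitution_matrix = _BLOSUM62
    aligner.open_gap_score = -gap_open
    aligner.extend_gap_score = -gap_extend
    return aligner


def global_score(a: str, b: str, gap_open: float = 10.0, gap_extend: float = 0.5) -> float:
    """Optimal global affine score (fast C path, no traceback guarantees)."""
    return float(_make_aligner("global", gap_open, gap_extend).score(a, b))


@dataclass(frozen=True)
class LocalHit:
    score: float
    identity: float  # percent over aligned columns
    aligned_columns: int


def local_hit(query: str, subject: str, gap_open: float = 11.0, gap_extend: float = 1.0) -> LocalHit:
    """Best Smith–Waterman hit of two peptides with BLAST-like gap costs."""
    aligner = _make_aligner("local", gap_open, gap_extend)
    alignments = aligner.align(query, subject)
    score = float(alignments.score)
    aln = alignments[0]
    qrow, srow = str(aln[0]), str(aln[1])
    cols = matches = 0
    for x, y in zip(qrow, srow):
        if x == GAP and y == GAP:
            continue
        cols += 1
        if x == y and x != GAP:
            matches += 1
    ident = 100.0 * matches / cols if cols else 0.0
    return LocalHit(score=score, identity=ident, aligned_columns=cols)


def pairwise_identity(aligned_a: str, aligned_b: str, exclude_terminal_gaps: bool = True) -> float:
    """Percent identity of two aligned rows.

    Denominator: columns where at least one row has a residue; columns that
    fall inside either row's terminal-gap overhang are excluded when
    ``exclude_terminal_gaps`` (set False for a full-length denominator).
    """
    L = len(aligned_a)
    if L != len(aligned_b):
        raise ValueError("aligned rows differ in length")
    lo, hi = 0, L
    if exclude_terminal_gaps:
        def core(row: str) -> tuple[int, int]:
            start = next((i for i, c in enumerate(row) if c != GAP), L)
            end = next((i for i in range(L, 0, -1) if row[i - 1] != GAP), 0)
            return start, end

        sa, ea = core(aligned_a)
        sb, eb = core(aligned_b)
        lo, hi = max(sa, sb), min(ea, eb)
    cols = matches = 0
    for i in range(lo, hi):
        x, y = aligned_a[i], aligned_b[i]
        if x == GAP and y == GAP:
            continue
        cols += 1
        if x == y:
            matches += 1
    return 100.0 * matches / cols if cols else 0.0


def center_star_msa(seqs: dict[str, str], gap_open: float = 10.0, gap_extend: float = 0.5) -> dict[str, str]:
    """Multiple alignment by the center-star heuristic.

    The center is the sequence maximizing the sum of pairwise global scores
    (ties by id); every other sequence is aligned to the center and the
    pairwise alignments are merged under "once a gap, always a gap".
    """
    ids = sorted(seqs)
    if len(ids) == 1:
        return {ids[0]: seqs[ids[0]]}
    totals = {i: 0.0 for i in ids}
    for i_pos, i in enumerate(ids):
        for j in ids[i_pos + 1:]:
            s = global_score(seqs[i], seqs[j], gap_open, gap_extend)
            totals[i] += s
            totals[j] += s
    center = max(ids, key=lambda i: (totals[i], i))
    center_seq = seqs[center]
    L = len(center_seq)
    aligner = _make_aligner("global", gap_open, gap_extend)
    # per sequence: blocks[k] = residues of that sequence emitted before center residue k
    blocks: dict[str, list[str]] = {}
    for sid in ids:
        if sid == center:
            continue
        aln = aligner.align(center_seq, seqs[sid])[0]
        blocks[sid] = _split_blocks(str(aln[0]), str(aln[1]), L)
    gap_before = [0] * (L + 1)
    for sid, (before, _paired) in blocks.items():
        for k in range(L + 1):
            gap_before[k] = max(gap_before[k], len(before[k]))
    out: dict[str, str] = {}
    center_row = []
    for k in range(L):
        center_row.append(GAP * gap_before[k])
        center_row.append(center_seq[k])
    center_row.append(GAP * gap_before[L])
    out[center] = "".join(center_row)
    for sid in ids:
        if sid == center:
            continue
        before, paired = blocks[sid]
        row = []
        for k in range(L):
            row.append(before[k].ljust(gap_before[k], GAP))
            row.append(paired[k])
        row.append(before[L].ljust(gap_before[L], GAP))
        out[sid] = "".join(row)
    return out


def _split_blocks(center_row: str, seq_row: str, L: int) -> tuple[list[str], list[str]]:
    """Split a pairwise alignment against the center into insertion blocks.

    Returns (before, paired): ``before[k]`` are seq residues inserted before
    center residue k (k = L means trailing), ``paired[k]`` is the seq
    character aligned to center residue k (residue or gap).
    """
    before = ["" for _ in range(L + 1)]
    paired = [GAP for _ in range(L)]
    k = 0
    for cc, sc in zip(center_row, seq_row):
        if cc == GAP:
            if sc != GAP:
                before[k] += sc
        else:
            paired[k] = sc
            k += 1
    return before, paired
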