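"""Transcript-variant vs gene-duplicate classification.

Same-annotation transcripts within one species are compared by global
pairwise alignment and run through a four-rule variant screen, checked in
order: (1) identical peptides; (2) truncation — one sequence's ungapped
length is at most ``truncation_frac`` of the other's (a one-exon fragment of
a multi-exon transcript); (3) end variation — every mismatch lies within
``end_window`` columns of an alignment terminus; (4) gap-adjacent variation —
every remaining mismatch lies within ``gap_window`` columns of a gap.  A pair
escalates to *gene duplicate* only when at least one amino-acid change is
central: more than ``end_window`` columns from both termini and more than
``gap_window`` columns from every gap column.

The end/gap windows are not canonical values; they default to E=10 and G=5
and every call records the windows used.
"""

from __future__ import annotations

from dataclasses import dataclass

from v1r_clade_evo.align import GAP, GlobalAlignment, gotoh_global

RULES = ("same_peptide", "truncation", "end_variation", "gap_adjacent", "central_change")


@dataclass(frozen=True)
class PairAlignment:
    aligned_a: str
    aligned_b: str
    score: float
    identity: float  # percent over non-dual-gap columns
    gap_columns: tuple[int, ...]
    matrix: str = "BLOSUM62"
    gap_open: float = 10.0
    gap_extend: float = 0.5


@dataclass(frozen=True)
class DupVarCall:
    transcript_id: str
    partner_id: str
    verdict: str  # transcript_variant | gene_duplicate
    rule_fired: str
    end_window: int
    gap_window: int


def pairwise_align(a: str, b: str, gap_open: float = 10.0, gap_extend: float = 0.5) -> PairAlignment:
    """Optimal global alignment (Needle-compatible defaults, deterministic ties)."""
    if not a or not b:
        raise ValueError("cannot align an empty peptide")
    aln: GlobalAlignment = gotoh_global(a, b, gap_open, gap_extend)
    gaps = tuple(i for i, (x, y) in enumerate(zip(aln.aligned_a, aln.aligned_b)) if x == GAP or y == GAP)
    cols = matches = 0
    for x, y in zip(aln.aligned_a, aln.aligned_b):
        if x == GAP and y == GAP:
            continue
        cols += 1
        if x == y:
            matches += 1
    ident = 100.0 * matches / cols if cols else 0.0
    return PairAlignment(
        aligned_a=aln.aligned_a,
        aligned_b=aln.aligned_b,
        score=aln.score,
        identity=ident,
        gap_columns=gaps,
        gap_open=gap_open,
        gap_extend=gap_extend,
    )


def _mismatch_columns(aln: PairAlignment) -> list[int]:
    return [
        i
        for i, (x, y) in enumerate(zip(aln.aligned_a, aln.aligned_b))
        if x != GAP and y != GAP and x != y
    ]


def central_mismatches(aln: PairAlignment, end_window: int, gap_window: int) -> list[int]:
    """Mismatch columns > E from both termini and > G from every gap column."""
    L = len(aln.aligned_a)
    out = []
    for i in _mismatch_columns(aln):
        if i < end_window or (L - 1 - i) < end_window:
            continue
        if any(abs(i - g) <= gap_window for g in aln.gap_columns):
            continue
        out.append(i)
    return out


def classify_pair(
    aln: PairAlignment,
    transcript_id: str,
    partner_id: str,
    end_window: int = 10,
    gap_window: int = 5,
    truncation_frac: float = 0.75,
) -> DupVarCall:
    """Apply the four variant rules in order; escalate on a central change.

    The verdict is symmetric in the two sequences.  A pair whose variation is
    purely indels (no mismatch columns) is a variant: truncation when the
    length ratio crosses ``truncation_frac``, otherwise end or gap-adjacent
    variation depending on where the gaps fall.
    """
    a = aln.aligned_a.replace(GAP, "")
    b = aln.aligned_b.replace(GAP, "")
    centrals = central_mismatches(aln, end_window, gap_window)

    def call(verdict: str, rule: str) -> DupVarCall:
        return DupVarCall(
            transcript_id=transcript_id,
            partner_id=partner_id,
            verdict=verdict,
            rule_fired=rule,
            end_window=end_window,
            gap_window=gap_window,
        )

    # rule 1: same peptide
    if a == b:
        return call("transcript_variant", "same_peptide")
    # rule 2: truncation
    if min(len(a), len(b)) <= truncation_frac * max(len(a), len(b)):
        return call("transcript_variant", "truncation")
    mismatches = _mismatch_columns(aln)
    L = len(aln.aligned_a)
    end_mm = [i for i in mismatches if i < end_window or (L - 1 - i) < end_window]
    # rule 3: all variation at the ends
    if not centrals and len(end_mm) == len(mismatches) and not _internal_gaps(aln, end_window):
        return call("transcript_variant", "end_variation")
    # rule 4: remaining variation near gaps
    if not centrals:
        return call("transcript_variant", "gap_adjacent")
    return call("gene_duplicate", "central_change")


def _internal_gaps(aln: PairAlignment, end_window: int) -> bool:
    L = len(aln.aligned_a)
    return any(end_window <= g <= L - 1 - end_window for g in aln.gap_columns)


def classify_species_set(
    peptides: dict[str, str],
    end_window: int = 10,
    gap_window: int = 5,
    truncation_frac: float = 0.75,
    gap_open: float = 10.0,
    gap_extend: float = 0.5,
) -> list[DupVarCall]:
    """Classify same-species, same-annotation transcripts within an orthogroup.

    The first member (by id) is the unclassified primary; every further
    member is classified against its highest-scoring partner among the other
    members (score ties broken by partner id).  Singletons yield no calls.
    """
    ids = sorted(peptides)
    if len(ids) < 2:
        return []
    alns: dict[tuple[str, str], PairAlignment] = {}
    for i, x in enumerate(ids):
        for y in ids[i + 1:]:
            alns[(x, y)] = pairwise_align(peptides[x], peptides[y], gap_open, gap_extend)

    def get(x: str, y: str) -> PairAlignment:
        return alns[(x, y)] if (x, y) in alns else alns[(y, x)]

    calls: list[DupVarCall] = []
    for t in ids[1:]:
        partners = [p for p in ids if p != t]
        best = max(partners, key=lambda p: (get(t, p).score, p))
        calls.append(
            classify_pair(get(t, best), t, best, end_window, gap_window, truncation_frac)
        )
    return calls


def count_calls(calls: list[DupVarCall]) -> dict[str, int]:
    counts = {"transcript_variant": 0, "gene_duplicate": 0}
    for c in calls:
        counts[c.verdict] += 1
    return counts
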