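"""Codon-level utilities: genetic code, sense codons, Nei–Gojobori counting.

Everything here is on the standard nuclear genetic code.  Site and
difference counts follow the unweighted-pathway convention: synonymous site
fractions per codon position, and for multi-step codon differences the
average over all orderings of single-nucleotide steps, skipping pathways
that pass through a stop codon.
"""

from __future__ import annotations

import itertools
from functools import lru_cache

from Bio.Data.CodonTable import standard_dna_table

NUCLEOTIDES = "ACGT"
CODON_TABLE: dict[str, str] = dict(standard_dna_table.forward_table)
STOP_CODONS: frozenset[str] = frozenset(standard_dna_table.stop_codons)
SENSE_CODONS: tuple[str, ...] = tuple(
    sorted(c for c in ("".join(p) for p in itertools.product(NUCLEOTIDES, repeat=3)) if c not in STOP_CODONS)
)
CODON_INDEX: dict[str, int] = {c: i for i, c in enumerate(SENSE_CODONS)}

TRANSITIONS = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}


def translate_codon(codon: str) -> str:
    return CODON_TABLE[codon]


def is_transition(a: str, b: str) -> bool:
    return (a, b) in TRANSITIONS


@lru_cache(maxsize=None)
def codon_site_counts(codon: str) -> tuple[float, float]:
    """Synonymous and nonsynonymous site counts (S_c, N_c) of one sense codon.

    Each of the 3 positions contributes the fraction of its single-nucleotide
    changes that are synonymous; changes to stop codons are excluded from the
    denominator.
    """
    aa = CODON_TABLE[codon]
    s = 0.0
    for pos in range(3):
        syn = 0
        valid = 0
        for nt in NUCLEOTIDES:
            if nt == codon[pos]:
                continue
            mut = codon[:pos] + nt + codon[pos + 1:]
            if mut in STOP_CODONS:
                continue
            valid += 1
            if CODON_TABLE[mut] == aa:
                syn += 1
        if valid:
            s += syn / valid
    return s, 3.0 - s


@lru_cache(maxsize=None)
def codon_diff_counts(a: str, b: str) -> tuple[float, float]:
    """Synonymous and nonsynonymous difference counts (Sd, Nd) between codons.

    Multi-step differences are averaged over all mutation-order pathways that
    avoid stop codons; if every pathway hits a stop, all orderings are used.
    """
    if a == b:
        return 0.0, 0.0
    positions = [i for i in range(3) if a[i] != b[i]]
    pathways = []
    for order in itertools.permutations(positions):
        cur = a
        sd = nd = 0.0
        through_stop = False
        for pos in order:
            nxt = cur[:pos] + b[pos] + cur[pos + 1:]
            if nxt in STOP_CODONS:
                through_stop = True
            if CODON_TABLE.get(cur, "*") == CODON_TABLE.get(nxt, "*"):
                sd += 1
            else:
                nd += 1
            cur = nxt
        pathways.append((through_stop, sd, nd))
    clean = [(sd, nd) for stop, sd, nd in pathways if not stop]
    if not clean:
        clean = [(sd, nd) for _, sd, nd in pathways]
    sd = sum(x for x, _ in clean) / len(clean)
    nd = sum(y for _, y in clean) / len(clean)
    return sd, nd


def sequence_site_counts(codons: list[str]) -> tuple[float, float]:
    """Total (S, N) sites over a codon sequence, ignoring gaps/ambiguity."""
    s = n = 0.0
    for c in codons:
        if c in CODON_INDEX:
            cs, cn = codon_site_counts(c)
            s += cs
            n += cn
    return s, n


def sequence_diff_counts(a: list[str], b: list[str]) -> tuple[float, float]:
    """Total (Sd, Nd) differences between two aligned codon sequences."""
    sd = nd = 0.0
    for ca, cb in zip(a, b):
        if ca in CODON_INDEX and cb in CODON_INDEX:
            s, n = codon_diff_counts(ca, cb)
            sd += s
            nd += n
    return sd, nd


def split_codons(seq: str) -> list[str]:
    if len(seq) % 3:
        raise ValueError(f"sequence length {len(seq)} is not a multiple of 3")
    return [seq[i:i + 3] for i in range(0, len(seq), 3)]
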