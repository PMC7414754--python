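"""Receptor mining: ORF extraction, reference annotation, deduplication,
and the within-species group-identity filter.

The stage order is fixed: ORF extraction under the receptor gene model →
DNA-level dedupe (exact and containment, both strands) → translation →
multiple alignment → identity filter.  Candidates sharing less than the
identity threshold (default 30%) with the rest of the species' receptor
group are discarded as non-members.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import pandas as pd
from Bio.Seq import Seq

from v1r_clade_evo import align

log = logging.getLogger(__name__)

BLAST_TABULAR_COLUMNS = [
    "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
]


@dataclass
class GeneModel:
    """Length/start/stop constraints an ORF must satisfy to count as a receptor.

    Defaults bracket a ~300-codon single-exon 7-transmembrane receptor; the
    bounds are configurable because no canonical values exist.
    """

    min_len: int = 270  # codons, excluding the stop
    max_len: int = 400
    require_start: bool = True
    require_stop: bool = True

    def __post_init__(self) -> None:
        if not (0 < self.min_len <= self.max_len):
            raise ValueError("need 0 < min_len <= max_len")


@dataclass
class Transcript:
    """One coding sequence from one species, with its translation."""

    id: str
    species: str
    cds: str
    peptide: str
    source: str = "assembled"  # assembled | reference | synthetic
    strand: str = "+"
    frame: int = 0
    coords: tuple[int, int] = (0, 0)  # 0-based half-open on the input strand


@dataclass
class ReferenceGene:
    id: str
    clade: str
    peptide: str
    pseudogene: bool = False


@dataclass
class BestHit:
    query_id: str
    reference_id: str
    score: float
    identity: float
    source: str = "internal"  # internal | external


_STOPS = {"TAA", "TAG", "TGA"}


def _revcomp(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


def _scan_orfs(seq: str, model: GeneModel) -> list[tuple[int, int, int]]:
    """All qualifying ORFs on the forward strand of ``seq``.

    An ORF runs from a start codon (every ATG when starts are required,
    otherwise from the frame start or the codon after the previous stop) to
    the next in-frame stop.  Returns (start, end, frame) with 0-based
    half-open coordinates over the coding part; the stop codon is excluded.
    """
    n = len(seq)
    out = []
    for frame in range(3):
        positions = range(frame, n - 2, 3)
        stops = [i for i in positions if seq[i:i + 3] in _STOPS]
        if model.require_start:
            starts = [i for i in positions if seq[i:i + 3] == "ATG"]
        else:
            starts = [frame] + [s + 3 for s in stops]
        for s in starts:
            stop = next((e for e in stops if e > s), None)
            if stop is not None:
                length = (stop - s) // 3
                end = stop
            elif not model.require_stop:
                length = (n - s) // 3
                end = s + 3 * length
            else:
                continue
            if model.min_len <= length <= model.max_len:
                out.append((s, end, frame))
    return out


def extract_orfs(
    raw_transcripts: dict[str, str],
    model: GeneModel,
    species: str = "unknown",
    longest_only: bool = True,
    source: str = "assembled",
) -> list[Transcript]:
    """Extract receptor-model ORFs from raw transcripts (both strands, 3 frames).

    With ``longest_only`` (default) the single longest qualifying ORF per raw
    transcript is kept; ties prefer the forward strand, then the smallest
    start coordinate.  Sequences too short for the model simply yield nothing.
    """
    out: list[Transcript] = []
    for tid in sorted(raw_transcripts):
        seq = raw_transcripts[tid].upper()
        candidates: list[tuple[int, int, str, int, int]] = []
        # (-length, strand_rank, strand, start, end) for deterministic best-pick
        for strand, s in (("+", seq), ("-", _revcomp(seq))):
            for start, end, frame in _scan_orfs(s, model):
                candidates.append((end - start, 0 if strand == "+" else 1, strand, start, end, frame))
        if not candidates:
            continue
        candidates.sort(key=lambda c: (-c[0], c[1], c[3]))
        chosen = candidates[:1] if longest_only else candidates
        for k, (_ln, _rank, strand, start, end, frame) in enumerate(chosen, 1):
            s = seq if strand == "+" else _revcomp(seq)
            cds = s[start:end]
            peptide = str(Seq(cds).translate())
            if "*" in peptide:
                continue  # internal stop cannot occur by construction; guard anyway
            if strand == "-":
                start, end = len(seq) - end, len(seq) - start
            oid = tid if longest_only else f"{tid}.orf{k}"
            out.append(
                Transcript(
                    id=oid, species=species, cds=cds, peptide=peptide,
                    source=source, strand=strand, frame=frame, coords=(start, end),
                )
            )
    return out


def best_reference_hit(
    query: Transcript,
    reference: list[ReferenceGene],
    gap_open: float = 11.0,
    gap_extend: float = 1.0,
) -> BestHit:
    """Best local-alignment hit of the query peptide against the reference set.

    Ties are broken by higher identity, then lexicographically smaller
    reference id.
    """
    if not reference:
        raise ValueError("reference repertoire is empty")
    best: tuple[float, float, str] | None = None
    best_hit: align.LocalHit | None = None
    for ref in sorted(reference, key=lambda r: r.id):
        hit = align.local_hit(query.peptide, ref.peptide, gap_open, gap_extend)
        key = (hit.score, hit.identity)
        if best is None or key > (best[0], best[1]):
            best = (hit.score, hit.identity, ref.id)
            best_hit = hit
    assert best is not None and best_hit is not None
    return BestHit(query_id=query.id, reference_id=best[2], score=best[0], identity=best[1])


def read_blast_tabular(path: str) -> pd.DataFrame:
    """Read 12-column blast tabular (outfmt 6 dialect) hits."""
    df = pd.read_csv(path, sep="\t", names=BLAST_TABULAR_COLUMNS, comment="#")
    return df


def best_hits_from_tabular(df: pd.DataFrame) -> list[BestHit]:
    """Reduce external tabular hits to one best hit per query.

    Maximizes bitscore, ties by pident then lexicographically smaller subject.
    """
    hits: list[BestHit] = []
    for qid, grp in df.groupby("qseqid", sort=True):
        grp = grp.sort_values(["bitscore", "pident", "sseqid"], ascending=[False, False, True])
        row = grp.iloc[0]
        hits.append(
            BestHit(
                query_id=str(qid),
                reference_id=str(row["sseqid"]),
                score=float(row["bitscore"]),
                identity=float(row["pident"]),
                source="external",
            )
        )
    return hits


def dedupe(transcripts: list[Transcript]) -> list[Transcript]:
    """Remove exact-duplicate and contained CDSes (forward or reverse strand).

    The longest member of every containment chain is kept; ties keep the
    lexicographically smallest id.  Idempotent.
    """
    order = sorted(transcripts, key=lambda t: (-len(t.cds), t.id))
    kept: list[Transcript] = []
    for t in order:
        contained = False
        rc = _revcomp(t.cds)
        for k in kept:
            if t.cds in k.cds or rc in k.cds:
                contained = True
                break
        if not contained:
            kept.append(t)
    kept.sort(key=lambda t: t.id)
    return kept


def identity_filter(
    transcripts: list[Transcript],
    threshold: float = 30.0,
    use_min: bool = False,
    msa: dict[str, str] | None = None,
) -> tuple[list[Transcript], pd.DataFrame]:
    """Drop candidates with < ``threshold``% identity to the species' group.

    A multiple alignment of the candidate peptides is computed internally
    (center-star) unless an external ``msa`` over the same ids is supplied.
    For each sequence the mean (or, with ``use_min``, minimum) pairwise
    identity against all others is computed over aligned columns, excluding
    dual-gap columns and terminal-gap overhangs.  Single pass: all decisions
    are taken against the full input alignment.

    Returns (retained transcripts, report table).
    """
    if len(transcripts) < 2:
        warnings.warn("identity filter needs >= 2 transcripts; returning input unchanged")
        report = pd.DataFrame(
            {"id": [t.id for t in transcripts], "group_identity": [float("nan")] * len(transcripts),
             "retained": [True] * len(transcripts)}
        )
        return list(transcripts), report
    if msa is None:
        msa = align.center_star_msa({t.id: t.peptide for t in transcripts})
    ids = sorted(msa)
    stats: dict[str, float] = {}
    for i in ids:
        vals = [
            align.pairwise_identity(msa[i], msa[j]) for j in ids if j != i
        ]
        stats[i] = min(vals) if use_min else sum(vals) / len(vals)
    retained = [t for t in transcripts if stats[t.id] >= threshold]
    report = pd.DataFrame(
        {
            "id": [t.id for t in transcripts],
            "group_identity": [round(stats[t.id], 2) for t in transcripts],
            "retained": [stats[t.id] >= threshold for t in transcripts],
        }
    )
    return retained, report


def mine_species(
    raw_transcripts: dict[str, str],
    reference: list[ReferenceGene],
    model: GeneModel | None = None,
    species: str = "unknown",
    identity_threshold: float = 30.0,
    external_hits: pd.DataFrame | None = None,
) -> tuple[list[Transcript], list[BestHit], pd.DataFrame]:
    """Full mining pipeline for one species: ORF → dedupe → align → filter → hits."""
    model = model or GeneModel()
    orfs = extract_orfs(raw_transcripts, model, species=species)
    orfs = dedupe(orfs)
    retained, report = identity_filter(orfs, threshold=identity_threshold)
    if external_hits is not None:
        by_query = {h.query_id: h for h in best_hits_from_tabular(external_hits)}
        hits = [by_query[t.id] for t in retained if t.id in by_query]
    else:
        hits = [best_reference_hit(t, reference) for t in retained]
    return retained, hits, report
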