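"""Repertoire-level turnover statistics.

Clade sizes per species, orthology-category fractions (over unique gene
annotations and over total transcripts), reference-only clade concentration,
and focal-species gene-loss calls (an orthogroup lacking the focal species
but carried by enough of the other sequenced species).
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import pandas as pd

from v1r_clade_evo.orthology import Orthogroup
from v1r_clade_evo.selection import round_half_up

CATEGORY_ORDER = ("reference_only", "non_orthologous", "low_orthology", "high_orthology")


@dataclass(frozen=True)
class LossCall:
    new_gene_id: str
    orthogroup: str
    clade: str
    supporting_species: tuple[str, ...]
    pseudogene_id: str | None = None


def _unique_annotation(annotation: str) -> str:
    """Collapse transcript suffixes: Vmn1r30.2 -> Vmn1r30 (combination-IDs kept once)."""
    return re.sub(r"\.\d+$", "", annotation)


def clade_sizes(
    groups: list[Orthogroup],
    species_of: dict[str, str],
    annotation_of: dict[str, str],
    with_duplicates: bool = False,
) -> pd.DataFrame:
    """Species × clade repertoire-size matrix.

    Counts unique gene annotations per species per clade by default (the
    conservative basis); ``with_duplicates`` counts every transcript.
    Groups without a clade are tallied under ``unplaced``, never dropped.
    """
    cells: dict[tuple[str, str], set[str] | int] = {}
    for og in groups:
        clade = og.clade or "unplaced"
        for member in og.members:
            sp = species_of[member]
            key = (sp, clade)
            ann = _unique_annotation(annotation_of.get(member, member))
            if with_duplicates:
                cells[key] = cells.get(key, 0) + 1
            else:
                cells.setdefault(key, set()).add(ann)  # type: ignore[union-attr]
    species = sorted({k[0] for k in cells})
    clades = sorted({k[1] for k in cells})
    data = {
        clade: [
            (cells.get((sp, clade), 0) if with_duplicates else len(cells.get((sp, clade), set())))
            for sp in species
        ]
        for clade in clades
    }
    return pd.DataFrame(data, index=pd.Index(species, name="species"))


def category_fractions(
    groups: list[Orthogroup],
    annotation_of: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Percent of receptors in each orthology category, on two bases.

    ``unique`` counts each distinct (collapsed) annotation once per
    orthogroup; ``total`` counts every transcript.  Each basis sums to 100.
    """
    counts = {cat: {"unique": 0, "total": 0} for cat in CATEGORY_ORDER}
    for og in groups:
        cat = og.category
        if cat not in counts:
            continue
        counts[cat]["total"] += len(og.members)
        if annotation_of:
            uniq = {_unique_annotation(annotation_of.get(m, m)) for m in og.members}
        else:
            uniq = set(og.members)
        counts[cat]["unique"] += len(uniq)
    rows = []
    for basis in ("unique", "total"):
        denom = sum(counts[cat][basis] for cat in CATEGORY_ORDER)
        for cat in CATEGORY_ORDER:
            pct = round_half_up(100.0 * counts[cat][basis] / denom) if denom else 0.0
            rows.append({"basis": basis, "category": cat, "count": counts[cat][basis], "percent": pct})
    return pd.DataFrame(rows)


def call_losses(
    groups: list[Orthogroup],
    focal_species: str,
    all_species: list[str],
    min_support: int = 3,
    pseudogene_table: dict[str, str] | None = None,
    existing_gene_ids: list[str] | None = None,
) -> list[LossCall]:
    """Call focal-species gene losses.

    A loss is an orthogroup with no focal-species member that is present in
    at least ``min_support`` of the other sequenced species.  New ids are
    allocated upward from the highest numeric id in use, so they can never
    collide with existing gene numbers.  ``pseudogene_table`` maps orthogroup
    name -> pseudogene id for cross-referencing.
    """
    if focal_species not in all_species:
        raise ValueError(f"focal species {focal_species!r} is not in the species list")
    max_num = 0
    pattern = re.compile(r"(\d+)$")
    for gid in existing_gene_ids or []:
        m = pattern.search(gid)
        if m:
            max_num = max(max_num, int(m.group(1)))
    for og in groups:
        for rid in og.reference_genes:
            m = pattern.search(rid)
            if m:
                max_num = max(max_num, int(m.group(1)))
    calls: list[LossCall] = []
    nxt = max_num + 1
    for og in sorted(groups, key=lambda g: g.name):
        if focal_species in og.species_set:
            continue
        support = tuple(sorted(og.species_set - {focal_species}))
        if len(support) < min_support:
            continue
        pseudo = (pseudogene_table or {}).get(og.name)
        calls.append(
            LossCall(
                new_gene_id=f"Vmn1r{nxt}",
                orthogroup=og.name,
                clade=og.clade or "unplaced",
                supporting_species=support,
                pseudogene_id=pseudo,
            )
        )
        nxt += 1
    return calls


def reference_only_concentration(groups: list[Orthogroup]) -> tuple[int, int, float | None]:
    """(total reference-only, count in the modal clade, rounded percent).

    Percent is rounded half-up to the nearest integer; ``None`` when there
    are no reference-only orthogroups.
    """
    ref_only = [og for og in groups if og.category == "reference_only"]
    if not ref_only:
        return 0, 0, None
    by_clade: dict[str, int] = {}
    for og in ref_only:
        by_clade[og.clade or "unplaced"] = by_clade.get(og.clade or "unplaced", 0) + 1
    modal = max(sorted(by_clade), key=lambda c: by_clade[c])
    pct = round_half_up(100.0 * by_clade[modal] / len(ref_only), 0)
    return len(ref_only), by_clade[modal], pct


def losses_to_frame(calls: list[LossCall], all_species: list[str], focal_species: str) -> pd.DataFrame:
    others = [sp for sp in all_species if sp != focal_species]
    rows = []
    for c in calls:
        row = {"new_gene_id": c.new_gene_id, "orthogroup": c.orthogroup, "clade": c.clade}
        for sp in others:
            row[sp] = "+" if sp in c.supporting_species else "-"
        row["pseudogene"] = c.pseudogene_id or ""
        rows.append(row)
    return pd.DataFrame(rows, columns=["new_gene_id", "orthogroup", "clade", *others, "pseudogene"])
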