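"""Amino-acid site-change categories and membrane-region summaries.

Variable alignment columns across species orthologs are classified by the
number of species deviating from the column consensus (k) and the number of
distinct deviant residues (d):

* ``single_species``      — k = 1 (one species differs);
* ``two_species_distinct``— k = 2 with two different deviant residues;
* ``shared_2_3``          — the same deviant residue shared by 2–3 species;
* ``highly_variable``     — k ≥ 4 or d ≥ 3 (dynamism across the phylogeny).

The (k, d) map is total and disjoint over every 2–6-species column; the rule
used is recorded in all outputs.  Membrane regions come from an external
per-residue table when available, otherwise from a Kyte–Doolittle hydropathy
stand-in (window 19, threshold 1.6, segments ≥ 15 residues) threaded from an
extracellular N-terminus as in 7-transmembrane receptors.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

GAP = "-"

CATEGORY_RULE = "single_species: k=1; two_species_distinct: k=2,d=2; shared_2_3: 2<=k<=3,d=1; highly_variable: k>=4 or d>=3"

REGIONS = ("extracellular", "transmembrane", "intracellular")

KYTE_DOOLITTLE = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5, "Q": -3.5, "E": -3.5,
    "G": -0.4, "H": -3.2, "I": 4.5, "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8,
    "P": -1.6, "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
}


@dataclass(frozen=True)
class SiteCategory:
    column: int  # 0-based in the (all-gap-free) alignment
    category: str
    consensus: str
    residues: dict[str, str]

    def __hash__(self) -> int:  # residues dict is informational only
        return hash((self.column, self.category, self.consensus))


@dataclass(frozen=True)
class TopologyAnnotation:
    regions: tuple[str, ...]  # per residue
    source: str  # external_table | hydropathy_standin


def categorize_column(k: int, d: int) -> str | None:
    """Total, disjoint category map over deviant-count k and residue diversity d."""
    if k == 0:
        return None
    if k >= 4 or d >= 3:
        return "highly_variable"
    if k == 1:
        return "single_species"
    if d == 1:  # 2 <= k <= 3 here
        return "shared_2_3"
    return "two_species_distinct"  # k = 2, d = 2


def representative_rows(
    msa: dict[str, str],
    species_map: dict[str, str],
    short_len_frac: float = 0.8,
) -> dict[str, str]:
    """One row per species, in a shared all-gap-free coordinate frame.

    The representative is the longest ungapped sequence per species (ties by
    id); representatives shorter than ``short_len_frac`` × the median length
    are excluded (short transcriptional variants).  Columns gapped in every
    kept row are removed, defining the coordinate frame all site analyses
    share.
    """
    by_species: dict[str, tuple[str, str]] = {}
    for sid in sorted(msa):
        sp = species_map[sid]
        cur = by_species.get(sp)
        if cur is None or len(msa[sid].replace(GAP, "")) > len(cur[1].replace(GAP, "")):
            by_species[sp] = (sid, msa[sid])
    if len(by_species) < 2:
        raise ValueError("need representatives from at least 2 species")
    lengths = sorted(len(row.replace(GAP, "")) for _, row in by_species.values())
    median = lengths[len(lengths) // 2]
    kept = {
        sp: row for sp, (sid, row) in by_species.items()
        if len(row.replace(GAP, "")) >= short_len_frac * median
    }
    if len(kept) < 2:
        raise ValueError("fewer than 2 species remain after short-variant exclusion")
    ncol = {len(r) for r in kept.values()}
    if len(ncol) != 1:
        raise ValueError("alignment rows differ in length")
    keep_cols = [
        c for c in range(ncol.pop()) if any(row[c] != GAP for row in kept.values())
    ]
    return {sp: "".join(row[c] for c in keep_cols) for sp, row in kept.items()}


def classify_sites(
    msa: dict[str, str],
    species_map: dict[str, str],
    reference_species: str | None = None,
    short_len_frac: float = 0.8,
) -> list[SiteCategory]:
    """Classify variable columns of a cross-species ortholog alignment.

    Representatives and the coordinate frame come from
    :func:`representative_rows`.  Consensus is the majority residue, ties
    resolved toward the reference species' residue, then alphabetically.
    Gapped cells do not count as deviations.
    """
    kept = representative_rows(msa, species_map, short_len_frac)
    species = sorted(kept)
    ncol = len(kept[species[0]])
    out: list[SiteCategory] = []
    for col in range(ncol):
        column = {sp: kept[sp][col] for sp in species}
        residues = {sp: r for sp, r in column.items() if r != GAP}
        counts: dict[str, int] = {}
        for r in residues.values():
            counts[r] = counts.get(r, 0) + 1
        top = max(counts.values())
        candidates = sorted(r for r, c in counts.items() if c == top)
        if (
            reference_species in residues
            and residues[reference_species] in candidates
        ):
            consensus = residues[reference_species]
        else:
            consensus = candidates[0]
        deviants = {sp: r for sp, r in residues.items() if r != consensus}
        k = len(deviants)
        d = len(set(deviants.values()))
        cat = categorize_column(k, d)
        if cat is not None:
            out.append(SiteCategory(column=col, category=cat, consensus=consensus, residues=column))
    return out


def assign_regions(
    peptide: str,
    external: dict[int, str] | None = None,
    window: int = 19,
    threshold: float = 1.6,
    min_segment: int = 15,
) -> TopologyAnnotation:
    """Per-residue membrane regions.

    ``external`` maps 1-based residue positions to region labels and must
    cover every residue.  Without it, Kyte–Doolittle window means above the
    threshold define transmembrane segments (segments shorter than
    ``min_segment`` are discarded); loops alternate starting extracellular at
    the N-terminus.
    """
    n = len(peptide)
    if external is not None:
        missing = [i for i in range(1, n + 1) if i not in external]
        if missing:
            raise ValueError(f"external topology table misses residues {missing[:5]}…")
        bad = sorted({r for r in external.values()} - set(REGIONS))
        if bad:
            raise ValueError(f"unknown region labels: {bad}")
        return TopologyAnnotation(regions=tuple(external[i] for i in range(1, n + 1)), source="external_table")
    scores = [KYTE_DOOLITTLE.get(aa, 0.0) for aa in peptide]
    half = window // 2
    is_tm = [False] * n
    for i in range(n):
        lo, hi = max(0, i - half), min(n, i + half + 1)
        if (hi - lo) and sum(scores[lo:hi]) / (hi - lo) > threshold:
            is_tm[i] = True
    # collect segments, drop those below the minimum helix length
    regions = ["" for _ in range(n)]
    segments: list[tuple[int, int]] = []
    i = 0
    while i < n:
        if is_tm[i]:
            j = i
            while j < n and is_tm[j]:
                j += 1
            if j - i >= min_segment:
                segments.append((i, j))
            i = j
        else:
            i += 1
    loop = "extracellular"  # short N-terminal extracellular region
    pos = 0
    for start, end in segments:
        for p in range(pos, start):
            regions[p] = loop
        for p in range(start, end):
            regions[p] = "transmembrane"
        loop = "intracellular" if loop == "extracellular" else "extracellular"
        pos = end
    for p in range(pos, n):
        regions[p] = loop
    return TopologyAnnotation(regions=tuple(regions), source="hydropathy_standin")


def region_change_summary(
    site_categories: list[SiteCategory],
    reference_row: str,
    reference_topology: TopologyAnnotation,
) -> pd.DataFrame:
    """Variable-site counts per membrane region per category, plus densities.

    The region of an alignment column is the region of the reference
    residue in that column; columns where the reference is gapped use the
    nearest ungapped reference residue to the left (or the first residue when
    none exists).  Densities are counts per region length.
    """
    # map alignment column -> reference residue index
    col_to_res: list[int] = []
    res = -1
    for ch in reference_row:
        if ch != GAP:
            res += 1
        col_to_res.append(max(res, 0))
    region_len = {r: reference_topology.regions.count(r) for r in REGIONS}
    rows: dict[tuple[str, str], int] = {}
    for site in site_categories:
        if site.column >= len(col_to_res):
            raise ValueError("site column outside the reference coordinate frame")
        region = reference_topology.regions[col_to_res[site.column]]
        rows[(region, site.category)] = rows.get((region, site.category), 0) + 1
    records = []
    total = sum(rows.values())
    for region in REGIONS:
        for (reg, cat), count in sorted(rows.items()):
            if reg != region:
                continue
            records.append(
                {
                    "region": region,
                    "category": cat,
                    "count": count,
                    "fraction_of_changes": round(count / total, 4) if total else 0.0,
                    "density_per_residue": round(count / region_len[region], 4) if region_len[region] else 0.0,
                }
            )
    return pd.DataFrame(records, columns=["region", "category", "count", "fraction_of_changes", "density_per_residue"])
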