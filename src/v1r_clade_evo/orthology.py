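"""Orthogroup delimitation and annotation on a receptor gene tree.

The guiding rule is that the receptor phylogeny should recapitulate the
species phylogeny.  Its deterministic formalization is species-overlap
reconciliation: an internal node is a *duplication* node iff its children's
descendant species sets intersect; a duplication is *local* iff its whole
subtree spans a single species (a within-species tandem/duplicate cluster,
which stays inside an orthogroup).  Orthogroups are the maximal subtrees
containing no non-local duplication node, so every leaf belongs to exactly
one orthogroup.

Annotation grammar follows house-mouse reference ids: transcripts sharing a
best-hit gene within a species get ``.1, .2, …`` suffixes; orthogroups
containing several reference genes get combination-IDs (``Vmn1r25/30``);
groups with no reference member are named for the reference genes they are
basal to, or ``basal<lowest id>`` past three.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

import dendropy

from v1r_clade_evo.mining import BestHit, ReferenceGene

log = logging.getLogger(__name__)

CATEGORIES = ("reference_only", "non_orthologous", "low_orthology", "high_orthology")


@dataclass
class GeneTreeLeaf:
    """Metadata for one gene-tree leaf."""

    leaf_id: str
    species: str
    annotation: str | None = None  # annotated id, e.g. Vmn1r30.2
    reference_gene: str | None = None  # best-hit or own reference gene id
    is_reference: bool = False


@dataclass
class Orthogroup:
    name: str
    members: list[str]  # leaf ids
    species_set: set[str]
    reference_genes: set[str]
    clade: str | None = None
    category: str | None = None
    node: dendropy.Node | None = field(default=None, repr=False, compare=False)


def annotate_transcripts(hits: list[BestHit], species_of: dict[str, str]) -> dict[str, str]:
    """Assign reference-gene annotations with per-species ``.n`` suffixes.

    Transcripts of one species sharing a best-hit gene are suffixed ``.1,
    .2, …`` in descending alignment-score order (ties by transcript id); a
    lone transcript keeps the bare gene id.
    """
    groups: dict[tuple[str, str], list[BestHit]] = {}
    for h in hits:
        groups.setdefault((species_of[h.query_id], h.reference_id), []).append(h)
    out: dict[str, str] = {}
    for (_species, gene), grp in sorted(groups.items()):
        grp.sort(key=lambda h: (-h.score, h.query_id))
        if len(grp) == 1:
            out[grp[0].query_id] = gene
        else:
            for i, h in enumerate(grp, 1):
                out[h.query_id] = f"{gene}.{i}"
    return out


def root_gene_tree(
    tree: dendropy.Tree, outgroup: str | None = None
) -> dendropy.Tree:
    """Root at the outgroup leaf if given, else at the midpoint (logged)."""
    if outgroup is not None:
        node = tree.find_node_with_taxon_label(outgroup)
        if node is None:
            raise ValueError(f"outgroup leaf {outgroup!r} not in tree")
        tree.to_outgroup_position(node, update_bipartitions=False)
    else:
        log.warning("no outgroup supplied; midpoint-rooting the gene tree")
        tree.reroot_at_midpoint(update_bipartitions=False)
    return tree


def collapse_low_support(tree: dendropy.Tree, min_support: float = 50.0) -> dendropy.Tree:
    """Collapse internal edges with bootstrap support below ``min_support``.

    Support is read from internal node labels when numeric.  The resulting
    polytomies are treated conservatively downstream: no duplication is
    inferred across a polytomy.
    """
    to_collapse = []
    for edge in tree.preorder_edge_iter():
        head = edge.head_node
        if head.is_leaf() or head is tree.seed_node:
            continue
        label = head.label
        if label is None:
            continue
        try:
            support = float(label)
        except ValueError:
            continue
        if support < min_support:
            to_collapse.append(edge)
    for edge in to_collapse:
        edge.collapse()
    return tree


def delimit_orthogroups(
    tree: dendropy.Tree,
    leaf_meta: dict[str, GeneTreeLeaf],
    collapse_below: float | None = 50.0,
) -> list[Orthogroup]:
    """Cut the gene tree into maximal subtrees free of non-local duplications."""
    if collapse_below is not None:
        collapse_low_support(tree, collapse_below)

    species_at: dict[int, set[str]] = {}
    is_dup: dict[int, bool] = {}
    clean: dict[int, bool] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            label = node.taxon.label
            if label not in leaf_meta:
                raise ValueError(f"gene-tree leaf {label!r} has no species metadata")
            species_at[id(node)] = {leaf_meta[label].species}
            is_dup[id(node)] = False
            clean[id(node)] = True
            continue
        children = node.child_nodes()
        span: set[str] = set()
        overlap = False
        if len(children) == 2:  # binary: duplication iff child spans intersect
            a, b = (species_at[id(c)] for c in children)
            overlap = bool(a & b)
            span = a | b
        else:  # polytomy: conservative, never a duplication
            for c in children:
                span |= species_at[id(c)]
        species_at[id(node)] = span
        local = len(span) == 1
        is_dup[id(node)] = overlap and not local
        clean[id(node)] = not is_dup[id(node)] and all(clean[id(c)] for c in children)

    groups: list[Orthogroup] = []

    def emit(node: dendropy.Node) -> None:
        members = sorted(lf.taxon.label for lf in node.leaf_iter())
        metas = [leaf_meta[m] for m in members]
        refs = {m.reference_gene for m in metas if m.is_reference and m.reference_gene}
        groups.append(
            Orthogroup(
                name="",
                members=members,
                species_set={m.species for m in metas},
                reference_genes=refs,
                node=node,
            )
        )

    def walk(node: dendropy.Node) -> None:
        if clean[id(node)]:
            emit(node)
            return
        for child in node.child_nodes():
            walk(child)

    walk(tree.seed_node)
    return groups


_NUM = re.compile(r"(\d+)$")


def _id_parts(gene_id: str) -> tuple[str, int | None]:
    m = _NUM.search(gene_id)
    if m:
        return gene_id[: m.start()], int(m.group(1))
    return gene_id, None


def _combination_id(gene_ids: set[str]) -> str:
    """Join reference ids ascending by numeric part: {Vmn1r25, Vmn1r30} -> Vmn1r25/30."""
    parsed = sorted(
        ((_id_parts(g), g) for g in gene_ids),
        key=lambda x: (x[0][0], x[0][1] if x[0][1] is not None else -1),
    )
    prefixes = {p[0][0] for p in parsed}
    if len(prefixes) == 1 and all(p[0][1] is not None for p in parsed):
        prefix = parsed[0][0][0]
        return prefix + "/".join(str(p[0][1]) for p in parsed)
    return "/".join(p[1] for p in parsed)


def _lowest_id(gene_ids: set[str]) -> str:
    parsed = sorted(
        gene_ids,
        key=lambda g: (_id_parts(g)[1] if _id_parts(g)[1] is not None else 10 ** 9, g),
    )
    return parsed[0]


def name_orthogroup(
    og: Orthogroup,
    tree: dendropy.Tree,
    leaf_meta: dict[str, GeneTreeLeaf],
) -> str:
    """Name per the annotation grammar.

    One reference gene → its id.  Several → a combination-ID.  None → the
    reference genes of the nearest enclosing subtree the group is basal to:
    a combination-ID up to three ids, ``basal<lowest id>`` past that.
    """
    if len(og.reference_genes) == 1:
        return next(iter(og.reference_genes))
    if len(og.reference_genes) >= 2:
        return _combination_id(og.reference_genes)
    basal_refs = _nearest_reference_context(og, leaf_meta)
    if not basal_refs:
        return "unplaced_" + og.members[0]
    if len(basal_refs) <= 3:
        return _combination_id(basal_refs)
    return "basal" + _lowest_id(basal_refs)


def _nearest_reference_context(og: Orthogroup, leaf_meta: dict[str, GeneTreeLeaf]) -> set[str]:
    """Reference gene ids under the nearest ancestor that contains any."""
    node = og.node
    if node is None:
        return set()
    anc = node.parent_node
    own = set(og.members)
    while anc is not None:
        refs = {
            leaf_meta[lf.taxon.label].reference_gene
            for lf in anc.leaf_iter()
            if lf.taxon.label not in own
            and leaf_meta[lf.taxon.label].is_reference
            and leaf_meta[lf.taxon.label].reference_gene
        }
        if refs:
            return refs
        anc = anc.parent_node
    return set()


def categorize_orthogroup(og: Orthogroup, reference_species: str) -> str:
    """Partition rule over the species set (reference counts as one species)."""
    n = len(og.species_set)
    if n == 0:
        raise ValueError("orthogroup has an empty species set")
    if og.species_set == {reference_species}:
        return "reference_only"
    if n == 1:
        return "non_orthologous"
    if n <= 3:
        return "low_orthology"
    return "high_orthology"


def assign_clades(
    groups: list[Orthogroup],
    reference: dict[str, ReferenceGene],
    leaf_meta: dict[str, GeneTreeLeaf],
) -> None:
    """Clade from member reference genes; else nearest reference context."""
    for og in groups:
        clades = {reference[r].clade for r in og.reference_genes if r in reference}
        if not clades:
            ctx = _nearest_reference_context(og, leaf_meta)
            clades = {reference[r].clade for r in ctx if r in reference}
        og.clade = sorted(clades)[0] if clades else "unplaced"


def build_orthogroups(
    tree: dendropy.Tree,
    leaf_meta: dict[str, GeneTreeLeaf],
    reference: dict[str, ReferenceGene],
    reference_species: str,
    outgroup: str | None = None,
    collapse_below: float | None = 50.0,
    manual_names: dict[str, str] | None = None,
) -> list[Orthogroup]:
    """Delimit, name, categorize and clade-assign orthogroups on one tree.

    ``manual_names`` maps an automatically derived name to a curated override
    (the hook for hand-adjusted annotations).
    """
    if outgroup is not None or _needs_rooting(tree):
        root_gene_tree(tree, outgroup)
    groups = delimit_orthogroups(tree, leaf_meta, collapse_below)
    for og in groups:
        og.name = name_orthogroup(og, tree, leaf_meta)
        if manual_names and og.name in manual_names:
            og.name = manual_names[og.name]
        og.category = categorize_orthogroup(og, reference_species)
    assign_clades(groups, reference, leaf_meta)
    _disambiguate_names(groups)
    return groups


def _needs_rooting(tree: dendropy.Tree) -> bool:
    return len(tree.seed_node.child_nodes()) > 2


def _disambiguate_names(groups: list[Orthogroup]) -> None:
    seen: dict[str, int] = {}
    for og in sorted(groups, key=lambda g: g.members[0]):
        if og.name in seen:
            seen[og.name] += 1
            og.name = f"{og.name}~{seen[og.name]}"
        else:
            seen[og.name] = 1
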