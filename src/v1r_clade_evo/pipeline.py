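"""End-to-end orchestration over a run directory.

Stages mirror the analysis order: simulate (or ingest) → mine → orthogroups
→ dupvar → select → summarize → sites.  Every stage reads its inputs from
the run directory and writes plain-text artifacts (TSV / FASTA / newick)
there, so each stage is runnable in isolation on the previous stage's
outputs; ``run_pipeline`` simply chains them and writes a manifest.  All
user-facing tables use 1-based inclusive coordinates; internal arithmetic is
0-based half-open.
"""

from __future__ import annotations

import os
import shutil

import dendropy
import numpy as np
import pandas as pd
from Bio.Seq import Seq

from v1r_clade_evo import align, io, mining, orthology, selection, sites, turnover
from v1r_clade_evo.config import PipelineConfig, write_manifest
from v1r_clade_evo.datasets import CLADES, default_species_tree
from v1r_clade_evo.dupvar import classify_species_set
from v1r_clade_evo.simulate import SimParams, emit_transcripts, evolve_sequences, simulate_family


class PipelineError(RuntimeError):
    pass


def _species_tree(cfg: PipelineConfig) -> dendropy.Tree:
    if cfg.species_tree:
        return io.read_newick(cfg.species_tree)
    return default_species_tree()


def _species_list(cfg: PipelineConfig) -> list[str]:
    return sorted(lf.taxon.label for lf in _species_tree(cfg).leaf_node_iter())


def _path(cfg: PipelineConfig, name: str) -> str:
    return os.path.join(cfg.out_dir, name)


def _require(path: str) -> str:
    if not os.path.exists(path):
        raise PipelineError(f"missing input: {path}")
    return path


def _species_of(tid: str) -> str:
    return tid.split("|", 1)[0]


def _root_gene_clade(root_gene: str, cfg: PipelineConfig) -> str:
    if cfg.clade_assignment.startswith("single:"):
        return cfg.clade_assignment.split(":", 1)[1]
    idx = int(root_gene.removeprefix("rg")) - 1
    return CLADES[idx % len(CLADES)]


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------


def stage_simulate(cfg: PipelineConfig) -> None:
    """Simulate repertoires; write transcripts, truth tables and the reference."""
    if cfg.seed is None:
        raise PipelineError("simulation requires an explicit seed")
    os.makedirs(cfg.out_dir, exist_ok=True)
    params = SimParams(seed=cfg.seed, **cfg.simulate)
    tree = _species_tree(cfg)
    truth = simulate_family(tree, params)
    seqs = evolve_sequences(truth, params)
    fastas, labels = emit_transcripts(truth, seqs, params)

    for sp in sorted(fastas):
        io.write_fasta(dict(sorted(fastas[sp].items())), _path(cfg, f"transcripts_{sp}.fasta"))
    io.write_newick(truth.gene_tree, _path(cfg, "gene_tree_true.nwk"))
    io.write_tsv(
        pd.DataFrame(
            sorted(truth.true_orthogroups.items()), columns=["gene_copy", "orthogroup"]
        ),
        _path(cfg, "truth_orthogroups.tsv"),
    )
    io.write_tsv(
        pd.DataFrame([(e.branch, e.kind) for e in truth.events], columns=["branch", "event"]),
        _path(cfg, "truth_events.tsv"),
    )
    io.write_tsv(
        pd.DataFrame(sorted(labels.items()), columns=["transcript", "label"]),
        _path(cfg, "truth_variants.tsv"),
    )
    io.write_tsv(
        pd.DataFrame(
            sorted(truth.root_gene_of.items()), columns=["gene_copy", "root_gene"]
        ),
        _path(cfg, "truth_root_genes.tsv"),
    )

    # The reference repertoire emulates the annotated genome of the reference
    # species: one entry per reference-species gene copy.
    ref_sp = cfg.reference_species
    copies = truth.copies_by_species.get(ref_sp, [])
    ref_rows = []
    ref_peps: dict[str, str] = {}
    for i, copy in enumerate(copies, 1):
        rid = f"Vmn1r{i}"
        clade = _root_gene_clade(truth.root_gene_of[copy], cfg)
        ref_rows.append({"id": rid, "clade": clade, "pseudogene": "0", "gene_copy": copy})
        ref_peps[rid] = str(Seq(seqs[copy]).translate())
    io.write_tsv(pd.DataFrame(ref_rows), _path(cfg, "reference_clades.tsv"))
    io.write_fasta(ref_peps, _path(cfg, "reference_peptides.fasta"))


def _load_reference(cfg: PipelineConfig) -> list[mining.ReferenceGene]:
    peps = io.read_fasta(_require(_path(cfg, "reference_peptides.fasta")))
    clades = io.read_tsv(_require(_path(cfg, "reference_clades.tsv")))
    clade_of = dict(zip(clades["id"], clades["clade"]))
    pseudo = dict(zip(clades["id"], clades["pseudogene"]))
    return [
        mining.ReferenceGene(id=rid, clade=clade_of.get(rid, "unplaced"), peptide=pep,
                             pseudogene=pseudo.get(rid, "0") == "1")
        for rid, pep in sorted(peps.items())
    ]


def stage_mine(cfg: PipelineConfig) -> None:
    """ORF extraction, dedupe, identity filter and reference best hits."""
    reference = _load_reference(cfg)
    model = mining.GeneModel(**cfg.gene_model)
    external = None
    if cfg.external_hits:
        external = mining.read_blast_tabular(_require(cfg.external_hits))
    all_hits = []
    annotations: dict[str, str] = {}
    species_of: dict[str, str] = {}
    for sp in _species_list(cfg):
        path = _require(_path(cfg, f"transcripts_{sp}.fasta"))
        raw = io.read_fasta(path)
        kept, hits, report = mining.mine_species(
            raw, reference, model=model, species=sp,
            identity_threshold=cfg.identity_threshold, external_hits=external,
        )
        io.write_fasta({t.id: t.cds for t in kept}, _path(cfg, f"mined_cds_{sp}.fasta"))
        io.write_tsv(report, _path(cfg, f"identity_report_{sp}.tsv"))
        all_hits.extend(hits)
        for t in kept:
            species_of[t.id] = sp
    io.write_tsv(
        pd.DataFrame(
            [
                {"query": h.query_id, "reference": h.reference_id,
                 "score": h.score, "identity": round(h.identity, 2), "source": h.source}
                for h in sorted(all_hits, key=lambda h: h.query_id)
            ]
        ),
        _path(cfg, "hits.tsv"),
    )
    annotations = orthology.annotate_transcripts(all_hits, species_of)
    io.write_tsv(
        pd.DataFrame(sorted(annotations.items()), columns=["transcript", "annotation"]),
        _path(cfg, "annotations.tsv"),
    )


def _load_mined(cfg: PipelineConfig) -> dict[str, mining.Transcript]:
    out: dict[str, mining.Transcript] = {}
    for sp in _species_list(cfg):
        path = _path(cfg, f"mined_cds_{sp}.fasta")
        if not os.path.exists(path):
            continue
        for tid, cds in io.read_fasta(path).items():
            out[tid] = mining.Transcript(
                id=tid, species=sp, cds=cds, peptide=str(Seq(cds).translate()), source="assembled"
            )
    if not out:
        raise PipelineError(f"no mined transcripts found under {cfg.out_dir}")
    return out


def _gene_tree_from_truth(cfg: PipelineConfig, mined: dict[str, mining.Transcript]) -> dendropy.Tree:
    """Graft mined transcripts onto the true gene tree as zero-length tips."""
    tree = io.read_newick(_require(_path(cfg, "gene_tree_true.nwk")))
    by_copy: dict[str, list[str]] = {}
    for tid in mined:
        copy = tid.rsplit("|", 1)[0]
        by_copy.setdefault(copy, []).append(tid)
    ns = tree.taxon_namespace
    for leaf in list(tree.leaf_node_iter()):
        copy = leaf.taxon.label
        tids = sorted(by_copy.get(copy, []))
        if not tids:
            leaf.taxon = None  # pruned below
        elif len(tids) == 1:
            leaf.taxon = ns.new_taxon(tids[0])
        else:
            leaf.taxon = None
            for tid in tids:
                child = dendropy.Node()
                child.edge.length = 0.0
                child.taxon = ns.new_taxon(tid)
                leaf.add_child(child)
    # prune leaves that lost their taxon
    changed = True
    while changed:
        changed = False
        for node in list(tree.leaf_node_iter()):
            if node.taxon is None and node is not tree.seed_node:
                node.parent_node.remove_child(node)
                changed = True
    tree.suppress_unifurcations()
    return tree


def _gene_tree_nj(mined: dict[str, mining.Transcript]) -> dendropy.Tree:
    """Distance-based builder (p-distance + neighbor joining); synthetic-scale only."""
    from skbio import DistanceMatrix
    from skbio.tree import nj

    ids = sorted(mined)
    msa = align.center_star_msa({t: mined[t].peptide for t in ids})
    n = len(ids)
    dm = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            ident = align.pairwise_identity(msa[ids[i]], msa[ids[j]])
            dm[i, j] = dm[j, i] = 1.0 - ident / 100.0
    njt = nj(DistanceMatrix(dm, ids))
    tree = io.parse_newick(str(njt))
    tree.reroot_at_midpoint(update_bipartitions=False)
    return tree


def stage_orthogroups(cfg: PipelineConfig) -> None:
    """Delimit, name and categorize orthogroups on the gene tree."""
    mined = _load_mined(cfg)
    hits = io.read_tsv(_require(_path(cfg, "hits.tsv")))
    hit_of = dict(zip(hits["query"], hits["reference"]))
    annotations = io.read_tsv(_require(_path(cfg, "annotations.tsv")))
    ann_of = dict(zip(annotations["transcript"], annotations["annotation"]))
    reference = {r.id: r for r in _load_reference(cfg)}

    if cfg.gene_tree == "truth":
        tree = _gene_tree_from_truth(cfg, mined)
    elif cfg.gene_tree == "nj":
        tree = _gene_tree_nj(mined)
    else:
        tree = io.read_newick(_require(cfg.gene_tree))
    io.write_newick(tree, _path(cfg, "gene_tree_used.nwk"))

    leaf_meta = {}
    for tid, t in mined.items():
        is_ref = t.species == cfg.reference_species
        leaf_meta[tid] = orthology.GeneTreeLeaf(
            leaf_id=tid,
            species=t.species,
            annotation=ann_of.get(tid),
            reference_gene=hit_of.get(tid),
            is_reference=is_ref,
        )
    # drop tree leaves without metadata (e.g. outgroup placeholders)
    known = {lf.taxon.label for lf in tree.leaf_node_iter()} & set(leaf_meta)
    if known != {lf.taxon.label for lf in tree.leaf_node_iter()}:
        tree.retain_taxa_with_labels(sorted(known))
    groups = orthology.build_orthogroups(
        tree, leaf_meta, reference, cfg.reference_species,
        outgroup=cfg.outgroup, collapse_below=cfg.collapse_support,
        manual_names=cfg.manual_names or None,
    )
    io.write_tsv(
        pd.DataFrame(
            [
                {
                    "name": og.name,
                    "members": ";".join(og.members),
                    "species_set": ";".join(sorted(og.species_set)),
                    "n_species": len(og.species_set),
                    "category": og.category,
                    "clade": og.clade,
                }
                for og in sorted(groups, key=lambda g: g.name)
            ]
        ),
        _path(cfg, "orthogroups.tsv"),
    )


def _load_orthogroups(cfg: PipelineConfig) -> pd.DataFrame:
    return io.read_tsv(_require(_path(cfg, "orthogroups.tsv")))


def stage_dupvar(cfg: PipelineConfig) -> None:
    """Classify same-species orthogroup members as variants or duplicates."""
    mined = _load_mined(cfg)
    ogs = _load_orthogroups(cfg)
    calls_rows = []
    for _, row in ogs.iterrows():
        members = row["members"].split(";")
        by_sp: dict[str, dict[str, str]] = {}
        for m in members:
            if m in mined:
                by_sp.setdefault(_species_of(m), {})[m] = mined[m].peptide
        for sp in sorted(by_sp):
            calls = classify_species_set(
                by_sp[sp], cfg.end_window, cfg.gap_window, cfg.truncation_frac
            )
            for c in calls:
                calls_rows.append(
                    {
                        "orthogroup": row["name"],
                        "species": sp,
                        "transcript": c.transcript_id,
                        "partner": c.partner_id,
                        "verdict": c.verdict,
                        "rule": c.rule_fired,
                        "end_window": c.end_window,
                        "gap_window": c.gap_window,
                        "clade": row["clade"],
                    }
                )
    calls_df = pd.DataFrame(
        calls_rows,
        columns=["orthogroup", "species", "transcript", "partner", "verdict", "rule",
                 "end_window", "gap_window", "clade"],
    )
    io.write_tsv(calls_df, _path(cfg, "dupvar_calls.tsv"))
    for key, out_name in (("species", "dupvar_by_species.tsv"), ("clade", "dupvar_by_clade.tsv")):
        if calls_df.empty:
            summary = pd.DataFrame(columns=[key, "transcript_variant", "gene_duplicate"])
        else:
            summary = (
                calls_df.groupby([key, "verdict"]).size().unstack(fill_value=0).reset_index()
            )
            for col in ("transcript_variant", "gene_duplicate"):
                if col not in summary:
                    summary[col] = 0
            summary = summary[[key, "transcript_variant", "gene_duplicate"]]
        io.write_tsv(summary, _path(cfg, out_name))


def _codon_alignment(members: list[str], mined: dict[str, mining.Transcript]) -> dict[str, str]:
    """In-frame codon alignment via the peptide MSA (gaps become codon gaps)."""
    msa = align.center_star_msa({m: mined[m].peptide for m in members})
    out = {}
    for m in members:
        cds = mined[m].cds
        row = []
        k = 0
        for aa in msa[m]:
            if aa == align.GAP:
                row.append("---")
            else:
                row.append(cds[3 * k: 3 * k + 3])
                k += 1
        out[m] = "".join(row)
    return out


def stage_select(cfg: PipelineConfig) -> None:
    """Branch selection tests (internal screen or external), FDR and summary."""
    ogs = _load_orthogroups(cfg)
    clade_of = dict(zip(ogs["name"], ogs["clade"]))
    if cfg.external_tests:
        table = io.read_tsv(_require(cfg.external_tests))
        tests = selection.ingest_external_tests(table)
        tested_per_clade = None
    else:
        mined = _load_mined(cfg)
        tree = io.read_newick(_require(_path(cfg, "gene_tree_used.nwk")))
        groups = {row["name"]: row["members"].split(";") for _, row in ogs.iterrows()}
        eligible = selection.eligible_orthogroups(groups, cfg.min_orthogroup_size)
        tests = []
        tested_per_clade = {}
        for name in sorted(eligible):
            members = [m for m in eligible[name] if m in mined]
            if len(members) < cfg.min_orthogroup_size:
                continue
            sub = tree.extract_tree_with_taxa_labels(members)
            aln = _codon_alignment(members, mined)
            tests.extend(selection.branch_dnds_screen(aln, sub, orthogroup=name))
            clade = clade_of.get(name, "unplaced")
            tested_per_clade[clade] = tested_per_clade.get(clade, 0) + 1
    selection.fdr_correct(tests, q=cfg.fdr_q, scope=cfg.fdr_scope)
    io.write_tsv(selection.tests_to_frame(tests), _path(cfg, "selection_branches.tsv"))
    summary = selection.summarize_selection(tests, clade_of, tested_per_clade)
    io.write_tsv(summary, _path(cfg, "selection_summary.tsv"))


def stage_summarize(cfg: PipelineConfig) -> None:
    """Repertoire turnover tables: categories, clade sizes, losses, concentration."""
    ogs = _load_orthogroups(cfg)
    annotations = io.read_tsv(_require(_path(cfg, "annotations.tsv")))
    ann_of = dict(zip(annotations["transcript"], annotations["annotation"]))
    groups = []
    for _, row in ogs.iterrows():
        members = row["members"].split(";")
        groups.append(
            orthology.Orthogroup(
                name=row["name"],
                members=members,
                species_set=set(row["species_set"].split(";")),
                reference_genes=set(),
                clade=row["clade"],
                category=row["category"],
            )
        )
    species_of = {m: _species_of(m) for og in groups for m in og.members}
    io.write_tsv(
        turnover.category_fractions(groups, ann_of), _path(cfg, "category_fractions.tsv")
    )
    sizes = turnover.clade_sizes(groups, species_of, ann_of)
    sizes.reset_index().to_csv(_path(cfg, "clade_sizes.tsv"), sep="\t", index=False)
    pseudo = None
    if cfg.pseudogene_table:
        tbl = io.read_tsv(_require(cfg.pseudogene_table))
        pseudo = dict(zip(tbl["orthogroup"], tbl["pseudogene"]))
    reference = {r.id for r in _load_reference(cfg)}
    calls = turnover.call_losses(
        groups, cfg.focal_species, _species_list(cfg),
        min_support=cfg.min_support, pseudogene_table=pseudo,
        existing_gene_ids=sorted(reference),
    )
    io.write_tsv(
        turnover.losses_to_frame(calls, _species_list(cfg), cfg.focal_species),
        _path(cfg, "losses.tsv"),
    )
    total, modal, pct = turnover.reference_only_concentration(groups)
    io.write_tsv(
        pd.DataFrame(
            [{"reference_only_total": total, "modal_clade_count": modal,
              "modal_percent": "NA" if pct is None else pct}]
        ),
        _path(cfg, "reference_only.tsv"),
    )


def stage_sites(cfg: PipelineConfig) -> None:
    """Site categories and membrane-region summary for the widest orthogroup."""
    ogs = _load_orthogroups(cfg)
    mined = _load_mined(cfg)
    ogs = ogs.assign(n_species=ogs["n_species"].astype(int))
    ogs = ogs.sort_values(["n_species", "name"], ascending=[False, True])
    target = None
    for _, row in ogs.iterrows():
        members = [m for m in row["members"].split(";") if m in mined]
        if len({_species_of(m) for m in members}) >= 2:
            target = (row["name"], members)
            break
    if target is None:
        raise PipelineError("no orthogroup spans at least 2 species")
    name, members = target
    msa = align.center_star_msa({m: mined[m].peptide for m in members})
    species_map = {m: _species_of(m) for m in members}
    cats = sites.classify_sites(msa, species_map, cfg.reference_species, cfg.short_len_frac)
    rows = sites.representative_rows(msa, species_map, cfg.short_len_frac)
    ref_sp = cfg.reference_species if cfg.reference_species in rows else sorted(rows)[0]
    external = None
    if cfg.topology_table:
        tbl = io.read_tsv(_require(cfg.topology_table))
        external = {
            int(r["position"]): r["region"]
            for _, r in tbl.iterrows()
            if r["seq_id"] == ref_sp
        } or None
    topo = sites.assign_regions(rows[ref_sp].replace("-", ""), external)
    io.write_tsv(
        pd.DataFrame(
            [
                {"orthogroup": name, "column_1based": c.column + 1, "category": c.category,
                 "consensus": c.consensus, "rule": sites.CATEGORY_RULE}
                for c in cats
            ]
        ),
        _path(cfg, "site_categories.tsv"),
    )
    summary = sites.region_change_summary(cats, rows[ref_sp], topo)
    io.write_tsv(summary, _path(cfg, "region_summary.tsv"))


STAGES = {
    "simulate": stage_simulate,
    "mine": stage_mine,
    "orthogroups": stage_orthogroups,
    "dupvar": stage_dupvar,
    "select": stage_select,
    "summarize": stage_summarize,
    "sites": stage_sites,
}

STAGE_ORDER = ["simulate", "mine", "orthogroups", "dupvar", "select", "summarize", "sites"]


def run_pipeline(cfg: PipelineConfig) -> str:
    """Run all stages into ``cfg.out_dir``; deterministic given the config.

    On failure partial outputs are removed (unless the directory pre-existed
    with other content).  Returns the run directory.
    """
    created = not os.path.exists(cfg.out_dir)
    os.makedirs(cfg.out_dir, exist_ok=True)
    try:
        for name in STAGE_ORDER:
            STAGES[name](cfg)
        inputs = {
            k: v
            for k, v in {
                "species_tree": cfg.species_tree,
                "external_hits": cfg.external_hits,
                "external_tests": cfg.external_tests,
            }.items()
            if v
        }
        write_manifest(cfg, cfg.out_dir, inputs, STAGE_ORDER)
    except Exception:
        if created:
            shutil.rmtree(cfg.out_dir, ignore_errors=True)
        raise
    return cfg.out_dir
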