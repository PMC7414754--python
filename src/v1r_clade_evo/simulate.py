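"""Gene-family evolution simulator with full ground truth.

Receptor repertoires evolve along a species tree by a linear birth–death
process (duplication rate λ, loss rate μ per gene per unit branch length,
simulated exactly with a per-branch Gillespie scheme).  A loss is recorded
as a pseudogenization with probability ``pseudo_prob``, otherwise as a
deletion; either way the lineage stops and is never transcribed, mirroring
transcriptome-based detection.  Sequences evolve under a codon model with a
K80-style nucleotide kernel (transition/transversion ratio κ), a dN/dS
multiplier ω on nonsynonymous changes, stop codons forbidden and uniform
codon frequencies; ω is set per species-tree branch class so selection
regimes can be injected.  Each surviving gene emits one primary transcript
and, with probability ``p_variant``, one extra transcript drawn from the
variant classes observed in real repertoires: same-peptide (synonymous
changes only), truncated (C-terminal fraction missing, as when only one
exon is recovered) or end-modified (nonsynonymous changes confined to the
termini).

Everything is deterministic given the seed; the TruthRecord retains the gene
tree, the true orthogroup partition, every event and every variant label so
downstream inferences can be scored exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np
from scipy.linalg import expm

from v1r_clade_evo._codon import (
    CODON_INDEX,
    NUCLEOTIDES,
    SENSE_CODONS,
    STOP_CODONS,
    CODON_TABLE,
    is_transition,
    split_codons,
    translate_codon,
)

PRIMARY = "primary"
VARIANT_CLASSES = ("same_peptide", "truncated", "end_modified")


@dataclass
class SimParams:
    """Simulation parameters; rates are per gene per unit branch length."""

    n_root_genes: int = 20
    dup_rate: float = 0.4
    loss_rate: float = 0.2
    pseudo_prob: float = 0.5
    omega_map: dict[str, float] = field(default_factory=lambda: {"default": 0.3})
    kappa: float = 2.0
    gene_length: int = 300
    p_variant: float = 0.15
    variant_class_weights: dict[str, float] = field(
        default_factory=lambda: {"same_peptide": 0.6, "truncated": 0.2, "end_modified": 0.2}
    )
    variant_truncation_frac: float = 0.4
    # expected substitutions per codon site between the family ancestor and
    # each root gene: receptors form one superfamily, so root genes are
    # diverged paralogs of a single ancestor, not independent random sequences
    root_divergence: float = 0.3
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.dup_rate < 0 or self.loss_rate < 0:
            raise ValueError("duplication and loss rates must be nonnegative")
        if not (0.0 <= self.pseudo_prob <= 1.0 and 0.0 <= self.p_variant <= 1.0):
            raise ValueError("probabilities must lie in [0, 1]")
        if self.gene_length < 100:
            raise ValueError("gene_length must be at least 100 codons")
        if self.kappa < 0:
            raise ValueError("kappa must be nonnegative")
        if "default" not in self.omega_map:
            raise ValueError("omega_map must define a 'default' class")
        if any(w < 0 for w in self.omega_map.values()):
            raise ValueError("omega values must be nonnegative")
        total = sum(self.variant_class_weights.get(k, 0.0) for k in VARIANT_CLASSES)
        if abs(total - 1.0) > 1e-9:
            raise ValueError("variant_class_weights must sum to 1 over the known classes")
        if not (0.0 < self.variant_truncation_frac < 1.0):
            raise ValueError("variant_truncation_frac must be in (0, 1)")
        if self.root_divergence < 0:
            raise ValueError("root_divergence must be nonnegative")
        if self.seed is None:
            raise ValueError("an explicit seed is required; there is no wall-clock fallback")


@dataclass
class GeneEvent:
    branch: str  # species-tree edge, named by its child node
    kind: str  # duplication | loss | pseudogenization


@dataclass
class TruthRecord:
    """Ground truth of one simulated family set."""

    species_tree: dendropy.Tree
    gene_tree: dendropy.Tree  # super-root joining one subtree per root gene
    true_orthogroups: dict[str, str]  # extant gene-copy id -> orthogroup label
    events: list[GeneEvent]
    variant_labels: dict[str, str]  # transcript id -> primary / *_variant
    copies_by_species: dict[str, list[str]]  # species -> extant gene-copy ids
    root_gene_of: dict[str, str]  # gene-copy id -> root gene label
    params: SimParams


def _validate_species_tree(tree: dendropy.Tree) -> None:
    leaves = [lf.taxon.label for lf in tree.leaf_node_iter()]
    if len(leaves) != len(set(leaves)):
        raise ValueError("species tree leaf names must be unique")
    for edge in tree.preorder_edge_iter():
        if edge.length is not None and edge.length < 0:
            raise ValueError("species tree branch lengths must be nonnegative")


def _edge_name(node: dendropy.Node) -> str:
    if node.is_leaf():
        return node.taxon.label
    return node.label or f"node{id(node)}"


def branch_class(node: dendropy.Node, omega_map: dict[str, float]) -> str:
    name = _edge_name(node)
    return name if name in omega_map else "default"


def simulate_family(species_tree: dendropy.Tree, params: SimParams) -> TruthRecord:
    """Simulate gene birth-and-death along the species tree.

    Every gene lineage follows exactly one species lineage; duplications
    split a lineage in place, losses terminate it, and surviving lineages are
    transmitted to both daughter species at each speciation.
    """
    _validate_species_tree(species_tree)
    rng = np.random.default_rng([int(params.seed), 0])
    lam, mu = params.dup_rate, params.loss_rate

    gene_tree = dendropy.Tree()
    gene_ns = gene_tree.taxon_namespace
    root = gene_tree.seed_node
    root.edge.length = 0.0
    events: list[GeneEvent] = []
    dup_nodes: set[int] = set()

    sp_root = species_tree.seed_node

    def make_child(parent: dendropy.Node, length: float, branch: str) -> dendropy.Node:
        child = dendropy.Node()
        child.edge.length = length
        child.branch_class = branch
        parent.add_child(child)
        return child

    root_genes = [f"rg{i + 1}" for i in range(params.n_root_genes)]
    leaf_records: list[tuple[str, dendropy.Node, str]] = []  # (species, node, root gene)

    def evolve_edge(sp_node: dendropy.Node, entering: list[tuple[dendropy.Node, str]]) -> None:
        """Run the birth–death process over one species-tree edge, then recurse.

        A lineage is (attachment node, root gene, start time on this edge);
        lineages in a linear birth–death process are independent, so each is
        followed with its own exponential waiting times (per-branch Gillespie).
        """
        t_total = sp_node.edge.length or 0.0
        branch = _edge_name(sp_node)
        survivors: list[tuple[dendropy.Node, str]] = []
        stack: list[tuple[dendropy.Node, str, float]] = [(node, rg, 0.0) for node, rg in entering]
        rate = lam + mu
        while stack:
            node, rg, t0 = stack.pop()
            t = t0
            alive = True
            while alive:
                wait = rng.exponential(1.0 / rate) if rate > 0.0 else float("inf")
                if t + wait >= t_total:
                    break
                t += wait
                if rng.random() < lam / rate:
                    ev = make_child(node, t - t0, branch)
                    dup_nodes.add(id(ev))
                    events.append(GeneEvent(branch=branch, kind="duplication"))
                    stack.append((ev, rg, t))
                    node, t0 = ev, t
                else:
                    kind = "pseudogenization" if rng.random() < params.pseudo_prob else "loss"
                    events.append(GeneEvent(branch=branch, kind=kind))
                    alive = False
            if alive:
                end = make_child(node, t_total - t0, branch)
                survivors.append((end, rg))
        if sp_node.is_leaf():
            species = sp_node.taxon.label
            for node, rg in survivors:
                leaf_records.append((species, node, rg))
        else:
            for child in sp_node.child_nodes():
                evolve_edge(child, survivors)

    # The family radiation: root genes are ancient paralogs, joined by a
    # zero-length binary ladder of duplication nodes; each root-gene edge
    # carries the ancestor-to-root-gene divergence.
    start_lineages = []
    cur = root
    n_rg = len(root_genes)
    for i, rg in enumerate(root_genes):
        if i < n_rg - 1:
            dup_nodes.add(id(cur))
            n = make_child(cur, params.root_divergence, "default")
            if i < n_rg - 2:
                cur = make_child(cur, 0.0, "default")
        else:
            n = make_child(cur, params.root_divergence, "default")
        start_lineages.append((n, rg))
    if sp_root.is_leaf():
        # degenerate single-branch tree: the whole tree is one edge
        evolve_edge(sp_root, start_lineages)
    else:
        for child in sp_root.child_nodes():
            evolve_edge(child, start_lineages)

    # name extant copies per species, deterministically by traversal order
    copies_by_species: dict[str, list[str]] = {}
    root_gene_of: dict[str, str] = {}
    counters: dict[str, int] = {}
    for species, node, rg in leaf_records:
        counters[species] = counters.get(species, 0) + 1
        cid = f"{species}|g{counters[species]}"
        taxon = gene_ns.new_taxon(cid)
        node.taxon = taxon
        copies_by_species.setdefault(species, []).append(cid)
        root_gene_of[cid] = rg

    _prune_dead(gene_tree)
    true_orthogroups = _true_orthogroups(gene_tree, dup_nodes, root_gene_of)
    return TruthRecord(
        species_tree=species_tree,
        gene_tree=gene_tree,
        true_orthogroups=true_orthogroups,
        events=events,
        variant_labels={},
        copies_by_species=copies_by_species,
        root_gene_of=root_gene_of,
        params=params,
    )


def family_leaves(truth: TruthRecord) -> dict[str, list[str]]:
    """Extant gene-copy ids grouped by root gene (one gene family each)."""
    out: dict[str, list[str]] = {}
    for copy, rg in truth.root_gene_of.items():
        out.setdefault(rg, []).append(copy)
    return {rg: sorted(copies) for rg, copies in sorted(out.items())}


def _prune_dead(gene_tree: dendropy.Tree) -> None:
    """Drop lost lineages and suppress the resulting unary nodes."""
    changed = True
    while changed:
        changed = False
        for node in list(gene_tree.postorder_node_iter()):
            if node is gene_tree.seed_node:
                continue
            if node.is_leaf() and node.taxon is None:
                node.parent_node.remove_child(node)
                changed = True
        gene_tree.suppress_unifurcations()


def _species_of(copy_id: str) -> str:
    return copy_id.split("|", 1)[0]


def _true_orthogroups(
    gene_tree: dendropy.Tree, dup_nodes: set[int], root_gene_of: dict[str, str]
) -> dict[str, str]:
    """Partition extant copies into maximal subtrees free of non-local duplications.

    A duplication node is local when its whole (surviving) subtree spans a
    single species; local duplications stay within an orthogroup, matching
    how within-species tandem copies are grouped by the inference side.
    """
    labels: dict[str, str] = {}
    counter = [0]

    def species_span(node: dendropy.Node) -> set[str]:
        return {_species_of(lf.taxon.label) for lf in node.leaf_iter()}

    def clean(node: dendropy.Node) -> bool:
        for nd in node.preorder_iter():
            if id(nd) in dup_nodes and len(species_span(nd)) > 1:
                return False
        return True

    def assign(node: dendropy.Node) -> None:
        if node is not gene_tree.seed_node and clean(node):
            counter[0] += 1
            label = f"og{counter[0]}"
            for lf in node.leaf_iter():
                labels[lf.taxon.label] = label
            return
        for child in node.child_nodes():
            assign(child)

    assign(gene_tree.seed_node)
    return labels


# ---------------------------------------------------------------------------
# sequence evolution
# ---------------------------------------------------------------------------

_N_CODONS = len(SENSE_CODONS)


def _raw_codon_matrix(kappa: float, omega: float) -> np.ndarray:
    q = np.zeros((_N_CODONS, _N_CODONS))
    for i, ci in enumerate(SENSE_CODONS):
        for j, cj in enumerate(SENSE_CODONS):
            if i == j:
                continue
            diffs = [(a, b) for a, b in zip(ci, cj) if a != b]
            if len(diffs) != 1:
                continue
            rate = kappa if is_transition(*diffs[0]) else 1.0
            if translate_codon(ci) != translate_codon(cj):
                rate *= omega
            q[i, j] = rate
    np.fill_diagonal(q, -q.sum(axis=1))
    return q


def _codon_rate_matrix(kappa: float, omega: float) -> np.ndarray:
    """Codon substitution matrix, normalized on the neutral clock.

    The scaling factor comes from the ω = 1 matrix at the same κ, so branch
    lengths are expected substitutions per codon site *at neutrality*: the
    synonymous clock is fixed and selection (ω > 1) genuinely accelerates a
    branch rather than being renormalized away, while purifying regimes
    (ω < 1) slow it.  Uniform codon frequencies.
    """
    q = _raw_codon_matrix(kappa, omega)
    neutral = q if omega == 1.0 else _raw_codon_matrix(kappa, 1.0)
    mean_rate = -neutral.diagonal().mean()
    if mean_rate > 0:
        q = q / mean_rate
    return q


def random_root_sequence(gene_length: int, rng: np.random.Generator) -> str:
    """Random coding sequence: fixed ATG start, then random sense codons."""
    idx = rng.integers(0, _N_CODONS, size=gene_length - 1)
    return "ATG" + "".join(SENSE_CODONS[i] for i in idx)


def evolve_sequences(truth: TruthRecord, params: SimParams) -> dict[str, str]:
    """Evolve codon sequences down the true gene tree.

    Returns extant gene-copy id -> CDS (no stop codon; initiator ATG held
    fixed).  Each gene-tree edge uses the ω class of the species branch it is
    embedded in; here the class is resolved per root gene via ``omega_map``
    (a map branch-class -> ω with a mandatory 'default').
    """
    rng = np.random.default_rng([int(params.seed), 1])
    qmats: dict[float, np.ndarray] = {}
    pmats: dict[tuple[float, float], np.ndarray] = {}

    def pmat(omega: float, t: float) -> np.ndarray:
        key = (omega, round(t, 12))
        if key not in pmats:
            if omega not in qmats:
                qmats[omega] = _codon_rate_matrix(params.kappa, omega)
            p = expm(qmats[omega] * t)
            np.clip(p, 0.0, None, out=p)
            p /= p.sum(axis=1, keepdims=True)
            pmats[key] = np.cumsum(p, axis=1)
        return pmats[key]

    seqs: dict[str, str] = {}

    def omega_for(node: dendropy.Node) -> float:
        cls = getattr(node, "branch_class", "default")
        return params.omega_map.get(cls, params.omega_map["default"])

    # one family ancestor at the super-root; root genes are its diverged
    # paralogs (their edges carry the root divergence)
    ancestor = np.array(
        [CODON_INDEX["ATG"]] + list(rng.integers(0, _N_CODONS, size=params.gene_length - 1))
    )
    _check_no_stop(ancestor)

    def walk(node: dendropy.Node, codons: np.ndarray) -> None:
        t = node.edge.length or 0.0
        if t > 0:
            cum = pmat(omega_for(node), t)
            u = rng.random(len(codons) - 1)
            new = codons.copy()
            # position 0 (the initiator ATG) is held fixed
            for k, site in enumerate(range(1, len(codons))):
                idx = int(np.searchsorted(cum[codons[site]], u[k], side="right"))
                new[site] = min(idx, _N_CODONS - 1)
            codons = new
        if node.is_leaf() and node.taxon is not None:
            seqs[node.taxon.label] = "".join(SENSE_CODONS[i] for i in codons)
        for child in node.child_nodes():
            walk(child, codons)

    walk(truth.gene_tree.seed_node, ancestor)
    return seqs


def _check_no_stop(codons: np.ndarray) -> None:
    for i in codons:
        if SENSE_CODONS[i] in STOP_CODONS:
            raise ValueError("root sequence contains a stop codon")


# ---------------------------------------------------------------------------
# transcript emission
# ---------------------------------------------------------------------------

_UTR_LEN = 30


def _random_utr(rng: np.random.Generator, length: int = _UTR_LEN) -> str:
    """UTR with no ATG anywhere, so it can never extend or seed an ORF."""
    nts = [NUCLEOTIDES[i] for i in rng.integers(0, 4, size=length)]
    s = "".join(nts)
    while "ATG" in s:
        s = s.replace("ATG", "ACG", 1)
    return s


def _synonymous_variant(cds: str, rng: np.random.Generator) -> str:
    codons = split_codons(cds)
    editable = [
        i
        for i, c in enumerate(codons)
        if i > 0 and any(CODON_TABLE[x] == CODON_TABLE[c] and x != c for x in SENSE_CODONS)
    ]
    k = max(1, len(editable) // 10)
    chosen = rng.choice(len(editable), size=min(k, len(editable)), replace=False)
    for idx in sorted(int(x) for x in chosen):
        i = editable[idx]
        alts = [x for x in SENSE_CODONS if CODON_TABLE[x] == CODON_TABLE[codons[i]] and x != codons[i]]
        codons[i] = alts[int(rng.integers(0, len(alts)))]
    return "".join(codons)


def _truncated_variant(cds: str, frac_removed: float, rng: np.random.Generator) -> str:
    """First (1 - frac_removed) of the codons, plus one synonymous change.

    The synonymous change mirrors how real one-exon variants differ slightly
    from the full transcript; without it the variant would be an exact prefix
    and the DNA-level containment dedupe would (correctly) collapse it.
    """
    codons = split_codons(cds)
    keep = int(round(len(codons) * (1.0 - frac_removed)))
    trunc = codons[:max(keep, 1)]
    editable = [
        i for i, c in enumerate(trunc)
        if i > 0 and any(CODON_TABLE[x] == CODON_TABLE[c] and x != c for x in SENSE_CODONS)
    ]
    if editable:
        i = editable[int(rng.integers(0, len(editable)))]
        alts = [x for x in SENSE_CODONS if CODON_TABLE[x] == CODON_TABLE[trunc[i]] and x != trunc[i]]
        trunc[i] = alts[int(rng.integers(0, len(alts)))]
    return "".join(trunc)


def _end_modified_variant(cds: str, rng: np.random.Generator, window: int = 8) -> str:
    codons = split_codons(cds)
    tail = range(max(1, len(codons) - window), len(codons))
    n_changes = min(3, len(list(tail)))
    picks = rng.choice(list(tail), size=n_changes, replace=False)
    for i in sorted(int(x) for x in picks):
        aa = CODON_TABLE[codons[i]]
        alts = [x for x in SENSE_CODONS if CODON_TABLE[x] != aa]
        codons[i] = alts[int(rng.integers(0, len(alts)))]
    return "".join(codons)


def emit_transcripts(
    truth: TruthRecord, sequences: dict[str, str], params: SimParams
) -> tuple[dict[str, dict[str, str]], dict[str, str]]:
    """Emit per-species transcript sets (id grammar ``<species>|g<n>|t<k>``).

    Each surviving gene emits one primary transcript; with probability
    ``p_variant`` an extra transcript of a sampled class is emitted and
    recorded in the returned variant-label table.  Transcripts carry short
    ATG-free UTRs and a stop codon so the mining stage sees realistic input.
    Pseudogenized/lost copies are never emitted.
    """
    rng = np.random.default_rng([int(params.seed), 2])
    class_names = list(VARIANT_CLASSES)
    weights = np.array([params.variant_class_weights[c] for c in class_names])
    fastas: dict[str, dict[str, str]] = {sp: {} for sp in truth.copies_by_species}
    labels: dict[str, str] = {}

    for species in sorted(truth.copies_by_species):
        for copy_id in truth.copies_by_species[species]:
            cds = sequences[copy_id]
            tid = f"{copy_id}|t1"
            fastas[species][tid] = _random_utr(rng) + cds + "TAA" + _random_utr(rng)
            labels[tid] = PRIMARY
            if rng.random() < params.p_variant:
                cls = class_names[int(rng.choice(len(class_names), p=weights))]
                if cls == "same_peptide":
                    var = _synonymous_variant(cds, rng)
                elif cls == "truncated":
                    var = _truncated_variant(cds, params.variant_truncation_frac, rng)
                else:
                    var = _end_modified_variant(cds, rng)
                vid = f"{copy_id}|t2"
                fastas[species][vid] = _random_utr(rng) + var + "TAA" + _random_utr(rng)
                labels[vid] = f"{cls}_variant"
    truth.variant_labels = labels
    return fastas, labels
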