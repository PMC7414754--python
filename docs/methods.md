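# Methods

This package analyses the evolution of a vomeronasal type-1 receptor (V1R)
repertoire across six *Mus* species (*M. m. domesticus* — the annotated
reference — plus *M. spicilegus*, *M. macedonicus*, *M. spretus*,
*M. caroli* and *M. pahari*). The pipeline mines receptor coding sequences
from transcript sets, delimits orthologous receptor groups on a gene tree,
separates transcript variants from gene duplicates, screens branches for
positive selection under FDR control, and summarizes repertoire turnover and
amino-acid site changes by membrane region. A codon-level gene-family
simulator with complete ground truth makes every stage testable without
sequencing data.

## The generative model (synthetic data)

Gene families evolve along a rooted species tree by a linear birth–death
process: each gene lineage duplicates at rate λ and dies at rate μ, per gene
per unit branch length, simulated exactly with per-branch Gillespie waiting
times (lineages in a linear birth–death process are independent). A death is
recorded as a pseudogenization with probability `pseudo_prob`, otherwise as a
deletion; either way the lineage is never transcribed, mirroring detection
from transcriptome data. At speciation, every surviving lineage is passed to
both daughter branches.

Defaults (one per-unit-branch-length event scale, chosen once):

| parameter | default | meaning |
|---|---|---|
| `n_root_genes` | 20 | ancestral repertoire size (desk scale) |
| `dup_rate` λ | 0.4 | duplications / gene / unit branch length |
| `loss_rate` μ | 0.2 | losses / gene / unit branch length |
| `pseudo_prob` | 0.5 | losses recorded as pseudogenes |
| `omega_map` ω | `{default: 0.3}` | dN/dS per branch class |
| `kappa` κ | 2.0 | transition/transversion ratio |
| `gene_length` | 300 codons | ~typical single-exon 7-TM receptor |
| `p_variant` | 0.15 | extra transcript per gene |
| `root_divergence` | 0.3 | ancestor → root-gene divergence (see below) |

The default species tree is the six-taxon *Mus* topology
`((((domesticus,(spicilegus,macedonicus)),spretus),caroli),pahari)`,
ultrametric with root-to-tip depth 0.07 neutral substitutions per codon
site — genus-level divergence at desk scale. No duplication/loss rate
estimates exist for *Mus* V1Rs; λ = 0.4, μ = 0.2 give a mild, realistic
amount of turnover (a few percent event probability per gene per root-to-tip
path) and are illustrative, not inferred.

**Root genes are paralogs, not strangers.** Receptors form one superfamily,
so the simulator draws a single family ancestor and evolves each root gene
from it over `root_divergence` expected neutral substitutions per codon
site, joining the families with a zero-length binary ladder of ancient
duplication nodes above the species root. This keeps within-species group
identity far above the 30% mining filter (as for real repertoires) while
leaving families phylogenetically separable.

**Codon model.** A K80-style nucleotide kernel (κ on transitions) acts on
the 61 sense codons with uniform frequencies; stop codons are forbidden; the
nonsynonymous rate is multiplied by ω, set per species-tree branch class.
Matrices are normalized on the *neutral clock*: the scaling factor comes
from the ω = 1 matrix at the same κ, so branch lengths are expected
substitutions per codon site at neutrality. Selection (ω > 1) therefore
genuinely accelerates a branch instead of being renormalized away, and
purifying regimes slow it — the semantics under which a counting screen can
detect selection at all. The initiator ATG is held fixed.

**Transcript emission.** Every surviving gene emits one primary transcript
(short ATG-free UTRs, a stop codon, id grammar `<species>|g<n>|t<k>`); with
probability `p_variant` one extra transcript is emitted and labelled:
`same_peptide` (synonymous changes only), `truncated` (the trailing
`variant_truncation_frac` = 0.4 of codons removed, plus one synonymous
change so the variant is not an exact prefix that DNA dedupe would
collapse), or `end_modified` (nonsynonymous changes in the last ~8 codons).
Pseudogenized copies are never emitted.

What the simulator does **not** emulate: read-level sequencing and assembly
error, expression levels, within-species polymorphism, intron structure, or
GC/codon-usage bias. Passing recovery tests therefore show the inference
logic is correct under the stated generative model, not that real
assemblies are error-free.

## Receptor mining

Fixed stage order: ORF extraction → DNA dedupe → translation → alignment →
group-identity filter.

* **ORFs**: every ATG to its next in-frame stop, both strands, three frames,
  filtered by a gene model (length window, start/stop requirements). The
  canonical receptor model is 270–400 codons; the simulation-driven pipeline
  defaults to 150–400 so the one-exon truncated variants it injects remain
  visible to the classifier, as they were in real data. Longest ORF per raw
  transcript is kept by default. Coordinates are 0-based half-open
  internally, 1-based inclusive in user-facing tables.
* **Dedupe** removes exact-duplicate and contained CDSes (either strand);
  the longest member of a containment chain is kept, ties to the smallest
  id. Idempotent by construction.
* **Best-hit annotation**: Smith–Waterman peptide alignment (BLOSUM62, gap
  open 11 / extend 1) against the reference repertoire; ties broken by
  identity then id. A 12-column blast tabular ingestion path replaces the
  internal scorer when external hits are supplied.
* **Identity filter**: a center-star progressive multiple alignment (or an
  external alignment) of the species' candidates; any sequence with mean
  pairwise identity below 30% against the rest of the group is dropped in a
  single pass. Identity excludes dual-gap columns and terminal-gap
  overhangs (a full-length denominator and a minimum-identity mode are
  flags; the mean is the default because "identity with the entire group"
  most naturally reads as an average).

## Orthogroup delimitation and annotation

"The receptor phylogeny should recapitulate the species phylogeny" is
formalized as species-overlap reconciliation: an internal gene-tree node is
a duplication node iff its children's species sets intersect; it is *local*
iff its subtree spans one species. Orthogroups are the maximal subtrees
containing no non-local duplication node — local (within-species) duplicate
clusters stay inside their group, which is exactly where the
variant/duplicate classifier expects them. Rooting uses the supplied
outgroup, else the midpoint (logged). Internal edges with bootstrap support
below 50 are collapsed first; a polytomy is conservatively never a
duplication node, so noisy edges cannot fragment orthogroups.

Naming follows the reference-genome grammar: a group with one reference gene
takes its id; several reference genes give a combination-ID
(`Vmn1r25/30`, numeric parts ascending); a group with none is named for the
reference genes of the nearest enclosing subtree (combination-ID up to three
ids, `basal<lowest id>` past that). Within a species, transcripts sharing a
best-hit gene get `.1, .2, …` suffixes in descending score order.

Categories partition the orthogroups by species span: `reference_only`
(reference species alone), `non_orthologous` (one non-reference species),
`low_orthology` (2–3 species), `high_orthology` (4–6); the reference counts
as one of the six species.

## Transcript variants vs gene duplicates

Same-species members of an orthogroup are compared by global alignment
(Needleman–Wunsch/Gotoh, BLOSUM62, gap open 10 / extend 0.5 — the cited
aligner's documented defaults; end gaps are penalized like internal gaps,
and tie-breaking is fixed: substitution over gap, then gap in the first
sequence, so column-based rules are deterministic). Four variant rules are
checked in order: (1) identical peptides; (2) truncation — ungapped-length
ratio ≤ 0.75; (3) end variation — all mismatches within E = 10 columns of a
terminus; (4) gap-adjacent variation — remaining mismatches within G = 5
columns of a gap. A pair is a *gene duplicate* only if at least one
mismatch is central: further than E from both termini and further than G
from every gap column. E and G are not canonical values; they are config
keys and every call records the windows used. Each member beyond the first
is classified against its highest-scoring same-species partner, and
duplications are tallied independently per species.

## Selection screen

Orthogroups with ≥ 4 members (orthologs plus paralogs) are eligible. The
internal screen — labelled `internal_screen` in every output — is a
counting method, not a likelihood branch-site model: ancestral codons by
Fitch parsimony (ties to the lexicographically smallest codon), per-branch
synonymous/nonsynonymous sites and differences in the Nei–Gojobori
unweighted-pathway style, and a one-sided binomial tail probability of the
observed nonsynonymous excess under the neutral expectation N/(N+S).
Branches with no inferred change are untested. Published branch-test
results (e.g. from a random-effects likelihood model) enter through the
external ingestion path and flow through the same FDR and aggregation code.

Benjamini–Hochberg at q = 0.05 is applied over all tested branches pooled
(default) or per orthogroup (flag); a branch is significant iff adjusted
p ≤ 0.05. Clade summaries report significant terminal (gene) and internal
(deeper) branches, percentages of tested branches, and of tested
orthogroups with ≥ 1 significant branch, rounded half-up to two decimals; a
Total row is the column-wise sum. Headline fractions (percent of tested
terminal/internal branches under selection) are reported at one decimal.

Numerical notes. Nei–Gojobori counting is κ-blind, so at κ = 2 the screen is
conservative (neutral dN/dS ≈ 0.83, fewer false flags); calibration tests
run at κ = 1 where the counting is unbiased (neutral dN/dS ≈ 1.02 over 200
replicates). At the calibration scale (50 families × 6 species × 300
codons), a ω = 8 foreground branch on the longest lineage is flagged in
≥ 90% of cases after FDR while neutral data yield no flags; parsimony
reconstruction can smear part of a very strong foreground signal onto the
adjacent internal branch — a known limitation of counting screens.

## Turnover summaries

Clade sizes are counted per species per clade over unique gene annotations
(suffixes collapsed, combination-IDs counted once; a with-duplicates basis
is available); groups without a clade count under `unplaced`. Category
fractions are reported on both the unique-annotation and total-transcript
bases, each summing to 100%. A focal-species gene loss is an orthogroup
lacking the focal species but present in at least `min_support = 3` of the
other sequenced species; new ids are allocated above the highest existing
gene number so they can never collide, and a user-supplied pseudogene table
is cross-referenced when present. Reference-only concentration reports the
share of reference-only groups in their modal clade, rounded to whole
percent.

## Site categories and membrane regions

One representative peptide per species (longest; sequences below 0.8 × the
median length excluded as short transcriptional variants) defines a shared
all-gap-free alignment frame. For each variable column, with consensus =
majority residue (ties toward the reference species, then alphabetical),
k = deviating species and d = distinct deviant residues give the category:
`single_species` (k = 1), `two_species_distinct` (k = 2, d = 2),
`shared_2_3` (2 ≤ k ≤ 3, d = 1), `highly_variable` (k ≥ 4 or d ≥ 3). The
(k, d) map is total and disjoint (checked exhaustively over all 6-species
column patterns); the k ≥ 4 ∨ d ≥ 3 boundary is this package's declared
formalization of "highly variable" and is configurable, with the rule
recorded in every output.

Membrane regions come from an external per-residue table when given,
otherwise from a Kyte–Doolittle hydropathy stand-in (window 19, threshold
1.6, segments ≥ 15 residues) threaded from an extracellular N-terminus as
in 7-transmembrane receptors — a deliberate approximation of an HMM
predictor, labelled `hydropathy_standin` in outputs. The region of an
alignment column is the region of the reference residue there; columns
gapped in the reference inherit the nearest ungapped reference residue to
the left.

## Determinism, scales and limitations

Every stochastic stage requires an explicit seed (no wall-clock fallback);
reruns with the same config are byte-identical, and all summary tables are
invariant to input row order. Test and acceptance scales — 2,000 replicates
for the pure-birth mean, 200 for the neutral dN/dS limit, 50 families for
screen calibration, exhaustive tree enumeration to 5 leaves over 3 species
plus 300 seeded 6–8-leaf trees — are the package's chosen desk scales; the
exhaustive-cut reconciliation oracle grows super-exponentially with leaf
count, so larger trees are covered by seeded sampling rather than full
enumeration.

Known limitations: the internal selection screen is a stand-in with the
biases of parsimony reconstruction and κ-blind counting described above;
the center-star aligner is a heuristic (adequate at receptor-family
identity levels, not a general MSA replacement); the hydropathy topology
stand-in has no evolutionary model of helix boundaries; gene-loss calls
depend on detection, so incomplete repertoires inflate apparent losses —
on real data the supporting-species threshold is what guards against this.
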