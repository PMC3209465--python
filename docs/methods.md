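# Methods

This note records the models, rules and numerical choices implemented in
`classtrace`, the parameters that matter, and what the synthetic-data
generators do and do not emulate.

## The trace model

The Evolutionary Trace here is the categorical (rank-free) variant: given an
alignment and a partition of its rows into classes, each column receives one
of four statuses, applied in this order:

1. **gapped** — gap fraction over the whole column exceeds
   `max_gap_fraction` (default 0.5).  Such columns are set aside because
   insertions present in only one subfamily would otherwise be reported as
   class-specific signal.
2. **conserved** — one residue type reaches `within_class_conservation`
   (default 1.0) over the column's *non-gap* residues.  Counting gaps
   against conservation would make any column with a single gap
   non-conserved at the strict threshold, which contradicts the purpose of
   the separate gapped status; conservation is therefore evaluated among
   observed residues only.
3. **class_specific** — every class individually reaches the conservation
   fraction on some residue type (gaps excluded within the class; a class
   that is all-gap at the column blocks the status) and at least two class
   consensuses differ.
4. **variable** — everything else.

The default conservation threshold of 1.0 is the strict reading of
"invariant within, different between": a single deviant sequence vetoes a
column.  Real alignments with misannotated members need the relaxed
threshold (`within_class_conservation < 1`), which is exposed but not the
default.  `min_class_size` (default 2) refuses singleton classes, for which
class-specificity is vacuous.

Class-specific positions are reported in reference numbering: 1-based over
the ungapped reference row, plus a user-supplied offset so that output can
be quoted in a published structure's author numbering (motor-domain
positions are conventionally cited in the numbering of a crystallised
homologue rather than of the aligned sequence).

## Distances and trees

Pairwise distances are p-distances (fraction of differing residues over
columns not gapped in both rows; a column gapped in exactly one row counts
as a difference).  A Poisson-corrected variant (−ln(1−p)) is available
behind a separate function.  The distance measure is a package choice; the
classification step only needs distances monotone in divergence.

Neighbour joining is the Saitou–Nei agglomeration with two determinism
rules: ties in the Q criterion (within 1e-12) are broken by the
lexicographically smallest pair of cluster keys, a cluster's key being the
smallest leaf label it contains; and negative branch lengths are clamped to
zero after the usual length formulas.  On additive matrices the clamping
never triggers and NJ provably recovers the generating topology with exact
path lengths — the property the test suite and acceptance script measure.
`skbio.tree.nj` serves as an independent cross-check in tests; the
in-package implementation is authoritative because its tie-breaking is
specified.

Class annotation roots the tree on the outgroup split (midpoint of the
attachment edge; with several outgroups, the edge above the ingroup MRCA
after provisional rooting at one outgroup leaf).  Each query is assigned by
walking rootward to the first ancestral clade containing any reference
leaves: all one class assigns that class with the reference count as
support; mixed classes, or a query stranded among outgroups, yield
`unclassified`.  This is deterministic given the tree.

`partition_from_tree` cuts a rooted tree into at least n monophyletic
groups at the minimal depth, with depth measured in edge counts from the
root (the metric is a package choice; branch-length depth would be equally
defensible but is less stable on trees with near-zero edges).  Leaves
shallower than the cut stand as singletons.

## Structure mapping and contact typing

Columns are mapped to a template chain by global alignment (BLOSUM62, gap
open −11 / extend −1) of the ungapped reference row against the structure's
observed sequence; residues unobserved in the structure stay unmapped, and
residue-type disagreements are reported but do not invalidate the mapping.
A 30% identity guard aborts mappings that almost certainly pair the wrong
reference with the wrong chain.

Contact types use conventional distance cutoffs, all configurable:

| type        | rule                                                    | default |
|-------------|---------------------------------------------------------|---------|
| salt_bridge | side-chain O of Asp/Glu vs side-chain N of Lys/Arg/His  | 4.0 Å   |
| hbond       | any N/O vs N/O, backbone included, distance only        | 3.5 Å   |
| hydrophobic | side-chain C vs side-chain C of two apolar residues     | 4.5 Å   |
| proximity   | Cα–Cα (also the single-linkage cluster cutoff)          | 8.0 Å   |

Hydrogen bonds carry no donor–acceptor angle term because the template
structures carry no hydrogens; a distance-only rule overcalls slightly but
symmetrically across the compared classes.  In whole-structure scans,
sequence-adjacent residue pairs (|i−j| < 2 in chain order) are skipped so
peptide-bond geometry does not register as bonding; explicitly listed pairs
are always evaluated.  A pair may carry several types (a 3.0 Å Asp-O/Lys-N
pair is both salt bridge and hydrogen bond).

Spatial clusters of mapped positions are connected components of the
Cα-distance threshold graph (single linkage), ordered by lowest residue
number — deterministic and order-invariant.

The substitution report freezes geometry: for each contact touching a
substituted residue, the interaction types *eligible* under the new residue
types are recomputed using the observed contact distance against each
type's own cutoff, with backbone N/O surviving any substitution and
side-chain polarity following the new type.  Status is `retained` if the
original type remains eligible, `type_changed` if only other types are
(e.g. a lysine–backbone hydrogen bond replaced by hydrophobic eligibility
when K→V), `abolished` if none is.  This mirrors qualitative mechanistic
inference, not energetics: no remodelling, rotamers or electrostatics.

## Genome-scan validation

The pipeline consumes tabular outputs of external tools (sequence search,
domain servers); it never runs them.  Stages and defaults:

* hit filter: E-value ≤ 1e-5 AND query coverage ≥ 0.25 — deliberately
  permissive, to keep distant family members;
* triage: case-insensitive keyword match (default {"myosin"}) → category 1;
  otherwise best surviving identity ≥ 35% → category 2; otherwise rejected
  (`low_identity_unannotated`).  Candidates with no surviving hit are
  rejected as `no_significant_hit`;
* domain consensus: same-name calls overlapping ≥ 50% of the shorter span
  are unified across sources (span = union); a domain is kept when ≥ 2
  sources report it, when COILS reports a coiled-coil (sole authority for
  that domain type), or when a single source is uncontradicted over its
  span.  Cross-name conflicts over the same span resolve to the
  better-supported (then higher-scoring) call, with a warning.  The ≥ 2
  sources / sole-authority rule is this package's operationalisation of
  "consensus architecture" — domain databases do not agree often enough for
  unanimity to be workable;
* architecture classes: no motor head → `not_myosin`; DIL cargo domain
  present → `XI`; no DIL but ≥ 5 IQ motifs or an SH3-like N-terminal
  domain → `XI_DIL_minus`; otherwise a coiled coil → `VIII`; a bare head →
  `not_myosin`;
* surviving candidates are typed by NJ co-clustering of their pre-aligned
  motor-domain rows with labelled references and outgroups; an
  `unclassified` placement rejects with reason `phylogeny`.

Every rejected record carries exactly one reason code, and kept + rejected
counts equal the input size.

## Synthetic generators: what they emulate and what they do not

The generators exist to make ground truth unambiguous, not to imitate
evolution.  `gen_planted_msa` defaults encode the study conditions of a
two-subfamily motor-domain trace: 2 classes × 15 sequences (a 30-sequence
set), 300 columns of which 40% are planted conserved, 7% class-specific
(21 columns), 50% variable, the remainder gapped (gap fraction 0.6, above
the tracing cutoff).  Residues are drawn uniformly over the 20 amino acids;
class-specific columns always use distinct residues per class.  Noise is
applied cell-wise after planting (substitution first, then gaps).  Absent
are: phylogenetic correlation between rows, indel processes, rate
heterogeneity, and natural residue frequencies — so perfect recovery at
zero noise demonstrates the correctness of the rule, not performance on
real alignments, and the noise-monotonicity checks characterise robustness
only against i.i.d. corruption.

`gen_labeled_tree` builds class-monophyletic random binary trees (branch
lengths uniform 0.05–0.5 within clades, longer stems for class and outgroup
attachment) and returns exact path-length matrices, so NJ recovery is the
mathematically guaranteed case; it says nothing about estimated distances.
`gen_toy_structure` lays residue clusters out as Cα chains at 5 Å spacing
with ≥ 30 Å between groups (beyond 3× the 8 Å linkage cutoff) and realises
planted contact atom pairs at exact distances (verified post-hoc to
0.01 Å); the chains are geometrically valid but not protein-like.
`gen_candidate_table` plants XI/VIII candidates with jittered multi-source
domain architectures and three decoy modes keyed to the three rejection
reasons, plus a profile-based pre-aligned motor-domain block (70 shared +
50 class-distinct columns, 5% per-site member noise) for the co-clustering
stage.

## Problem sizes

The test suite and acceptance script use: 200 random alignments (≤ 10×50)
for the trace oracle; 20 seeds of the 30×300 planted alignment; 100 random
additive matrices with 4–8 leaves for NJ; 50 labelled trees for
co-clustering; 10 toy structures of 8 residues; 10 cohort seeds of
9 XI + 1 VIII + 5 decoys.  These sizes give exact, enumerable oracles while
keeping a full run in seconds on one core.

## Known limitations

* The trace is categorical; rank-based real-valued trace scores, entropy
  weighting and cluster significance statistics are out of scope.
* Identity conventions differ across the literature; both denominators
  (non-dual-gap columns, shorter ungapped length) are exposed because
  published percentages rarely state which was used.
* Contact typing is distance-only and the substitution report is
  eligibility logic on frozen geometry — a screening tool whose positive
  calls warrant structural follow-up, not predictions of energetics.
* PDB parsing keeps the first model and the highest-occupancy altloc and
  drops HETATM records; ligand-mediated interactions are invisible.
* The domain-consensus rule resolves conflicts heuristically (support, then
  score); pathological overlap patterns from real servers may need manual
  curation.
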