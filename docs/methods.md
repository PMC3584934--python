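# Methods

This note records the model assumptions, parameter choices and numerical
conventions behind the package, and what the synthetic fixtures do and do
not demonstrate.

## Scope of the model

The package partitions one domain superfamily at a time. Domains are
linked to whole-protein GO annotations through their parent proteins, which
is the central modelling compromise: GO annotates proteins, not domains, so
a domain's term set mixes the functions of all domains of its parent. The
coherence protocol is built to tolerate exactly this — incomplete
annotations, mixed specificity (a protein annotated with a general parent
term while another carries specific children), ancillary terms implied by
the main activity, and foreign-domain terms.

Only `is_a` edges define ancestry in the ontology. This is the
conservative reading; `part_of` and other relationship types are ignored at
parse time (with a logged warning), and reasoning over regulates/has-part
is out of scope. Obsolete terms are dropped at parse time; annotations to
them are remapped through `replaced_by` chains when available, else
discarded.

## Annotation quality filter

A record is kept iff its evidence code is not IEA, or it is IEA on a
SwissProt protein with a Keyword2GO/EC2GO mapping reference. GAF files do
not carry UniProtKB review status, so the SwissProt/TrEMBL split comes from
a sidecar TSV; unknown status is treated as TrEMBL, i.e. the filter errs
toward dropping electronically inferred annotations. The accepted GO_REF
identifiers are configurable (`DEFAULT_CURATED_IEA_REFS`) because different
GOA releases used different reference ids for the two mappings. Per
protein, term sets are reduced to the most specific terms; reduction is
applied jointly over the whole set, which is safe because is-a ancestry
never crosses namespaces.

## Clustering

Starting clusters use greedy incremental clustering at 90% identity
(longest sequence founds the first cluster; each sequence joins the
earliest representative at or above the threshold). Identity is defined as
identical aligned pairs over alignment columns of a global alignment
(BLOSUM62, gap open 11, extend 1); terminal gaps therefore count against
identity. The 0.9 threshold is the protocol's standard redundancy level,
not a tuned parameter.

Agglomeration merges the highest-similarity pair until one root remains.
The default cluster-pair similarity is the average pairwise identity
between the members of the two clusters. Because the score of a merged
cluster against any third cluster is a convex combination of its parts'
scores, no future pair can score above the current maximum, so merge scores
are non-increasing from leaves to root by construction. The similarity is
a pluggable callable: the profile–profile scoring used by the original
sampling protocol can be substituted without touching the selection step,
which is the part of the method this package exists for. Ties everywhere
break lexicographically on identifiers; internal node ids are assigned in
merge order, making trees byte-identical across runs.

## Coherence assessment

Per cluster, with `m` the minimum size over *non-empty* sequence MF term
sets (ignoring empty sets; otherwise any cluster with one unannotated
member would have `m = 0`):

1. initial core = union of the sequence MF sets of size `m`;
2. every term of a larger set that is an is-a descendant of an initial
   core term is added ("children" read transitively — a direct-child mode
   exists behind `CoherenceConfig(transitive_children=False)`);
3. ancestors of other members are removed, leaving the final core — the
   most specific putatively essential terms.

Annotation editing then runs a fixed-point iteration: the core terms and
all their ancestors start as core-associated; any larger-than-minimum
sequence MF set containing a core-associated term donates its remaining
terms, each of which becomes core-associated together with all its
ancestors and descendants. Termination is guaranteed because the
core-associated set grows monotonically inside a finite DAG. The final
filter set is *every core-associated term except the final core terms
themselves* — including the core's own ancestors, which were
core-associated from initialisation. This reading is what makes the
package's two reference scenarios (see `funfams.examples`) come out
coherent: a member annotated only with a general parent term contributes
that parent to the cluster set, and no sequence could cover it otherwise.
The iteration at which each non-core term was identified is recorded for
inspection.

The coverage test is plain set containment on edited term identifiers,
namespace order MF → BP → CC (editing touches MF only; BP/CC sets are used
unfiltered when MF is absent). An ancestor-aware mode, in which a sequence
term also covers its own ancestors, is available but off by default: term
sets are most-specific-reduced, so containment on identifiers is the
faithful reading.

Pruning emits the maximal coherent nodes (no coherent proper ancestor),
which guarantees the selected families partition the annotated starting
clusters. A starting cluster that itself fails assessment cannot be split
further; it is kept as a singleton family flagged `incoherent_leaf` rather
than discarded, preserving the partition property. Assessing leaves at all
is configurable (`assess_leaves=False` retains them axiomatically).

## Family models and probabilities

Profile HMMs are built and scanned with HMMER3 through pyhmmer, so model
construction (including Henikoff position-based sequence weighting) and
bit-score semantics are those of `hmmbuild`/`hmmscan`; scanning uses the
default reporting threshold (E = 10) and an optional bit-score floor to
separate "no hit at all" from "hit too weakly for an assignment". The
multiple alignment behind a model defaults to a deterministic center-star
aligner (pairwise global alignments to the longest member, gap columns
merged on the center's coordinates); this is adequate for the closely
related members of a family and keeps the package self-contained, while a
MAFFT adapter with high-quality settings (`--amino --localpair
--maxiterate 1000`) is available where the external tool is installed.
Model scores are used only to *rank* candidate families.

Term probabilities are `p = T/N` with T the number of distinct member
domains supporting the term (directly or via a descendant, after
up-propagation) and N the total family size, unannotated members included.
Counting distinct sequences rather than annotations bounds `p` at 1; the
map is deliberately not normalised into a distribution. Whole-protein
integration is the per-term maximum over domains — an idempotent,
commutative, associative operation, so domain order is irrelevant. CAFA-
style output rounds to 2 decimals. Bit-score ties in scanning are broken
lexicographically by family id (whether the original broke them by E-value
is unrecorded; the lexicographic rule at least makes runs reproducible).

## EC benchmark

Diversity is averaged over families with at least one EC4-labelled member;
families without labels carry no information about purity and are excluded
rather than treated as pure. Partial EC numbers (`1.1.1.-`) are ignored.
A superfamily qualifies only with ≥ 2 distinct EC4s. The published
full-corpus average-performance figures are not reproducible without the
historical Gene3D/GOA snapshots; the scorer itself is exercised on
constructed partitionings with known answers.

## Synthetic fixtures

The generator emulates, at desk scale, the conditions the protocol is
meant to survive: ground-truth families of point-mutated sequences (a
10-residue family motif is never mutated, guaranteeing within-family
identity exceeds between-family identity even for short sequences),
annotation missingness (`annotation_completeness`), specificity loss
(family leaf replaced by a random proper ancestor), ancillary terms and
foreign-domain terms at configurable rates, and one EC4 per family.
Defaults are 4 families × 6 sequences of length 120, 5% within-family
mutation, 50% between-family divergence, complete noise-free annotation,
and a depth-3 binary ontology per namespace — sizes chosen so the full
chain, including alignments, runs in seconds. Only substitutions are
simulated; no indels, no rate heterogeneity, no phylogenetic structure,
and one parent protein per domain. Passing the recovery tests therefore
shows the selection logic is correct under controlled noise, not that the
pipeline handles real superfamilies' alignment difficulty or the full
messiness of GOA.

All randomness flows through one integer-seeded numpy generator; there is
no hash-order dependence, so fixtures are identical across platforms.

## Known limitations

- The annotation-editing heuristic inherits the documented failure mode of
  multi-domain GO terms: a term describing the joint function of several
  domains is a parent of domain-specific children and can pull them into
  the core set of the wrong domain's cluster.
- Minimum-size seeding assumes proteins with the fewest MF terms are the
  ones with the fewest domains; a domain-count-aware seeding would be
  safer but requires whole-proteome domain assignments, which are outside
  this package's inputs.
- The built-in center-star aligner is not a progressive aligner; for
  deeply diverged families configure the MAFFT backend.
- Greedy identity clustering reproduces the *style* of CD-HIT, not its
  exact cluster boundaries (word filters and length rules differ).
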