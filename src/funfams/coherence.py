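"""Functional-coherence assessment of dendrogram clusters, and pruning.

For each cluster of domain sequences the protocol decides whether the
sequences plausibly share function, tolerating the incomplete and
mixed-specificity nature of GO annotation:

1.  Each member sequence carries the (most-specific, high-quality) GO terms
    of its parent protein; the cluster term set is the union.
2.  A *core* set of putatively essential molecular-function terms is seeded
    from the smallest non-empty sequence MF term sets, extended with more
    specific descendants of core terms seen in larger sequence sets, and
    reduced to its most specific members.
3.  *Annotation editing* finds terms that merely co-occur with core terms
    (ancillary activities, terms contributed by other domains of
    multi-domain parents) by a fixed-point iteration, and collects them —
    together with the core terms' own ancestors — into a *filter set*,
    which is subtracted from the MF term sets.
4.  The cluster is judged *coherent* if at least one sequence's term set of
    the assessment namespace (MF, falling back to BP then CC when absent)
    covers the whole edited cluster set of that namespace.

Pruning keeps the maximal coherent nodes of the dendrogram — coherent nodes
with no coherent proper ancestor — which partition the annotated starting
clusters into functional families.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

from funfams.annotations import AnnotationStore
from funfams.clustering import Cluster, Dendrogram, DendrogramNode, DomainSequence
from funfams.ontology import GoDag, most_specific

NAMESPACE_ORDER = ("MF", "BP", "CC")


class NoAnnotatedMembersError(ValueError):
    """The cluster contains no sequence with a post-filter annotation."""


class NoMfTermsError(ValueError):
    """Every sequence MF term set of the cluster is empty."""


@dataclass(frozen=True)
class CoherenceConfig:
    """Switches for the deliberately configurable readings of the protocol.

    transitive_children:
        Core-set extension admits all is-a descendants of core terms
        (default); ``False`` restricts to direct children.
    ancestor_aware_coverage:
        A sequence term also covers its own ancestors in the coverage test;
        off by default since term sets are most-specific-reduced.
    assess_leaves:
        Run the coherence assessment on starting clusters too (default);
        ``False`` retains leaves axiomatically.
    """

    transitive_children: bool = True
    ancestor_aware_coverage: bool = False
    assess_leaves: bool = True


@dataclass
class TermSets:
    """Per-sequence and cluster-level GO term sets, split by namespace."""

    sequence_terms: dict[str, frozenset[str]]
    sequence_ns: dict[str, dict[str, frozenset[str]]]  # seq -> ns -> terms

    @property
    def cluster_terms(self) -> frozenset[str]:
        out: set[str] = set()
        for terms in self.sequence_terms.values():
            out |= terms
        return frozenset(out)

    def cluster_subset(self, namespace: str) -> frozenset[str]:
        out: set[str] = set()
        for per_ns in self.sequence_ns.values():
            out |= per_ns.get(namespace, frozenset())
        return frozenset(out)

    @property
    def cluster_mf(self) -> frozenset[str]:
        return self.cluster_subset("MF")

    def sequence_mf(self, seq_id: str) -> frozenset[str]:
        return self.sequence_ns[seq_id].get("MF", frozenset())


@dataclass
class CoreSets:
    """Core, core-associated and filter term sets of one cluster."""

    initial_core: frozenset[str] = frozenset()
    final_core: frozenset[str] = frozenset()
    core_associated: frozenset[str] = frozenset()
    filter_set: frozenset[str] = frozenset()
    #: iteration (1-based) at which each non-core term was newly identified
    #: as core-associated during annotation editing
    found_in_iteration: dict[str, int] = field(default_factory=dict)


@dataclass
class CoherenceVerdict:
    assessment_type: str  # "MF" | "BP" | "CC"
    cluster_ta_set: frozenset[str]
    coherent: bool
    witness_sequence: str | None = None


# ---------------------------------------------------------------------------
# term-set compilation
# ---------------------------------------------------------------------------

def collect_term_sets(
    cluster: Cluster,
    seqs_by_id: Mapping[str, DomainSequence],
    store: AnnotationStore,
    dag: GoDag,
) -> TermSets:
    """Attach each member sequence's parent-protein term set, split by namespace.

    Unannotated members carry empty sets; raises
    :class:`NoAnnotatedMembersError` if no member is annotated.
    """
    sequence_terms: dict[str, frozenset[str]] = {}
    sequence_ns: dict[str, dict[str, frozenset[str]]] = {}
    for seq_id in sorted(cluster.members):
        terms = store.terms(seqs_by_id[seq_id].parent_protein_id)
        sequence_terms[seq_id] = terms
        per_ns: dict[str, set[str]] = {}
        for t in terms:
            per_ns.setdefault(dag.namespace(t), set()).add(t)
        sequence_ns[seq_id] = {
            ns: frozenset(ts) for ns, ts in per_ns.items()
        }
    if not any(sequence_terms.values()):
        raise NoAnnotatedMembersError(
            f"cluster {cluster.cluster_id}: no annotated member sequences"
        )
    return TermSets(sequence_terms=sequence_terms, sequence_ns=sequence_ns)


# ---------------------------------------------------------------------------
# core set
# ---------------------------------------------------------------------------

def _mf_sets(term_sets: TermSets) -> dict[str, frozenset[str]]:
    return {
        sid: term_sets.sequence_mf(sid)
        for sid in term_sets.sequence_terms
        if term_sets.sequence_mf(sid)
    }


def core_term_set(
    term_sets: TermSets,
    dag: GoDag,
    config: CoherenceConfig = CoherenceConfig(),
) -> CoreSets:
    """Compile the cluster core MF term set.

    Seed: the union of the smallest non-empty sequence MF term sets (sequences
    with empty MF sets do not define the minimum).  Extension: any term of a
    larger-than-minimum sequence MF set that is a more specific child of a
    core term joins the set.  Reduction: ancestors of other members are
    removed, leaving the most specific putatively essential terms.
    """
    mf_sets = _mf_sets(term_sets)
    if not mf_sets:
        raise NoMfTermsError("no sequence MF terms in cluster")
    m = min(len(s) for s in mf_sets.values())
    initial = set()
    for s in mf_sets.values():
        if len(s) == m:
            initial |= s

    extended = set(initial)
    larger_union: set[str] = set()
    for s in mf_sets.values():
        if len(s) > m:
            larger_union |= s
    for t in sorted(larger_union):
        if t in extended:
            continue
        if config.transitive_children:
            above = dag.ancestors(t)
        else:
            above = dag.parents_of.get(t, set())
        if above & initial:
            extended.add(t)

    final = frozenset(most_specific(dag, extended))
    return CoreSets(initial_core=frozenset(initial), final_core=final)


def build_filter_set(
    core: CoreSets,
    term_sets: TermSets,
    dag: GoDag,
    config: CoherenceConfig = CoherenceConfig(),
) -> CoreSets:
    """Populate the core-associated and filter sets by fixed-point iteration.

    The core terms and all their ancestors start as core-associated.  Each
    iteration scans the larger-than-minimum sequence MF term sets: a set that
    contains at least one core-associated term donates its remaining terms,
    which become core-associated together with all their ancestors and
    descendants.  The loop stops when a scan identifies nothing new —
    guaranteed, since the set grows monotonically within the DAG.  The final
    filter set is every core-associated term except the core terms
    themselves, so the ancillary and foreign-domain terms (and the core
    terms' own ancestors) are all scheduled for removal.
    """
    if not core.final_core:
        raise ValueError("final core set is empty")
    mf_sets = _mf_sets(term_sets)
    m = min(len(s) for s in mf_sets.values())
    larger = [s for _, s in sorted(mf_sets.items()) if len(s) > m]

    core_assoc: set[str] = set(core.final_core)
    for t in core.final_core:
        core_assoc |= dag.ancestors(t)

    found: dict[str, int] = {}
    iteration = 0
    while True:
        iteration += 1
        novel: set[str] = set()
        for s in larger:
            if s & core_assoc:
                novel |= s - core_assoc
        if not novel:
            break
        for t in sorted(novel):
            found[t] = iteration
        for t in novel:
            core_assoc.add(t)
            core_assoc |= dag.ancestors(t)
            core_assoc |= dag.descendants(t)

    filter_set = frozenset(core_assoc - core.final_core)
    return replace(
        core,
        core_associated=frozenset(core_assoc),
        filter_set=filter_set,
        found_in_iteration=found,
    )


def edit_cluster_terms(term_sets: TermSets, core: CoreSets) -> TermSets:
    """Subtract the filter set from every sequence MF term set.

    Only molecular-function annotations are edited; BP and CC parts are left
    untouched.  The cluster-level sets are unions of the sequence sets, so
    they are filtered implicitly.
    """
    if not core.filter_set:
        return term_sets
    new_terms: dict[str, frozenset[str]] = {}
    new_ns: dict[str, dict[str, frozenset[str]]] = {}
    for sid, per_ns in term_sets.sequence_ns.items():
        edited = dict(per_ns)
        mf = per_ns.get("MF")
        if mf:
            edited["MF"] = mf - core.filter_set
        new_ns[sid] = edited
        new_terms[sid] = frozenset().union(*edited.values()) if edited else frozenset()
    return TermSets(sequence_terms=new_terms, sequence_ns=new_ns)


# ---------------------------------------------------------------------------
# coherence assessment
# ---------------------------------------------------------------------------

def _covers(
    seq_terms: frozenset[str],
    cluster_terms: frozenset[str],
    dag: GoDag,
    ancestor_aware: bool,
) -> bool:
    if cluster_terms <= seq_terms:
        return True
    if not ancestor_aware:
        return False
    covered = set(seq_terms)
    for t in seq_terms:
        covered |= dag.ancestors(t)
    return cluster_terms <= covered


def analyse_cluster(
    cluster: Cluster,
    seqs_by_id: Mapping[str, DomainSequence],
    store: AnnotationStore,
    dag: GoDag,
    config: CoherenceConfig = CoherenceConfig(),
) -> tuple[TermSets, CoreSets | None, TermSets, CoherenceVerdict]:
    """Run the full per-cluster pipeline; returns intermediates and verdict."""
    raw = collect_term_sets(cluster, seqs_by_id, store, dag)
    core: CoreSets | None = None
    try:
        core = core_term_set(raw, dag, config)
        core = build_filter_set(core, raw, dag, config)
        edited = edit_cluster_terms(raw, core)
    except NoMfTermsError:
        edited = raw  # BP/CC-only cluster: no editing applies

    for namespace in NAMESPACE_ORDER:
        cluster_ta = edited.cluster_subset(namespace)
        if cluster_ta:
            break
    else:
        raise NoAnnotatedMembersError(
            f"cluster {cluster.cluster_id}: no terms in any namespace "
            "after editing"
        )

    witness = None
    for sid in sorted(edited.sequence_ns):
        seq_ta = edited.sequence_ns[sid].get(namespace, frozenset())
        if not seq_ta:
            continue
        if _covers(seq_ta, cluster_ta, dag, config.ancestor_aware_coverage):
            witness = sid
            break
    verdict = CoherenceVerdict(
        assessment_type=namespace,
        cluster_ta_set=cluster_ta,
        coherent=witness is not None,
        witness_sequence=witness,
    )
    return raw, core, edited, verdict


def assess(
    cluster: Cluster,
    seqs_by_id: Mapping[str, DomainSequence],
    store: AnnotationStore,
    dag: GoDag,
    config: CoherenceConfig = CoherenceConfig(),
) -> CoherenceVerdict:
    """Judge functional coherence of one cluster.

    Coherent iff at least one member sequence's assessment-namespace term set
    covers the whole edited cluster term set of that namespace.
    """
    return analyse_cluster(cluster, seqs_by_id, store, dag, config)[3]


def assess_dendrogram(
    dendrogram: Dendrogram,
    seqs_by_id: Mapping[str, DomainSequence],
    store: AnnotationStore,
    dag: GoDag,
    config: CoherenceConfig = CoherenceConfig(),
) -> dict[str, CoherenceVerdict]:
    """Assess every dendrogram node; returns node_id -> verdict.

    With ``config.assess_leaves`` off, leaves are recorded as coherent
    without assessment.
    """
    verdicts: dict[str, CoherenceVerdict] = {}
    for node in dendrogram.nodes():
        if node.is_leaf and not config.assess_leaves:
            verdicts[node.node_id] = CoherenceVerdict(
                assessment_type="MF",
                cluster_ta_set=frozenset(),
                coherent=True,
                witness_sequence=None,
            )
            continue
        cluster = node.cluster or Cluster(
            cluster_id=node.node_id, members=node.members
        )
        verdicts[node.node_id] = assess(cluster, seqs_by_id, store, dag, config)
    return verdicts


# ---------------------------------------------------------------------------
# pruning
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PrunedFamily:
    """A functional-family root selected from the dendrogram.

    ``incoherent_leaf`` marks starting clusters that failed assessment but
    cannot be split further; they are kept as flagged singleton families so
    that the selected families always partition the annotated starting
    clusters.
    """

    node: DendrogramNode
    incoherent_leaf: bool = False

    @property
    def members(self) -> frozenset[str]:
        return self.node.members


def prune(
    dendrogram: Dendrogram,
    verdicts: Mapping[str, CoherenceVerdict],
) -> list[PrunedFamily]:
    """Select the maximal coherent nodes as functional families.

    Walks the dendrogram from the root: a coherent node is emitted as a
    family and its subtree is not descended further, so no selected family is
    an ancestor of another and the families partition the leaves.
    """
    families: list[PrunedFamily] = []
    stack = [dendrogram.root]
    while stack:
        node = stack.pop()
        verdict = verdicts[node.node_id]
        if verdict.coherent:
            families.append(PrunedFamily(node=node))
        elif node.is_leaf:
            families.append(PrunedFamily(node=node, incoherent_leaf=True))
        else:
            stack.extend(reversed(node.children))
    return families


def write_verdicts_tsv(path, verdicts: Mapping[str, CoherenceVerdict]) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("node_id\tassessment_type\tcoherent\twitness\tn_terms\n")
        for node_id in sorted(verdicts):
            v = verdicts[node_id]
            fh.write(
                f"{node_id}\t{v.assessment_type}\t{v.coherent}\t"
                f"{v.witness_sequence or '-'}\t{len(v.cluster_ta_set)}\n"
            )


def write_membership_tsv(path, families: Sequence[PrunedFamily]) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("funfam_id\tseq_id\n")
        for fam in families:
            for seq_id in sorted(fam.members):
                fh.write(f"{fam.node.node_id}\t{seq_id}\n")
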