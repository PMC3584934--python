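"""End-to-end orchestration of family identification for one superfamily."""

from __future__ import annotations

from dataclasses import dataclass, field

from funfams.annotations import (
    AnnotationStore,
    build_store,
    filter_high_quality,
    parse_gaf,
)
from funfams.clustering import (
    Cluster,
    Dendrogram,
    DomainSequence,
    SimilarityFn,
    agglomerate,
    drop_unannotated,
    read_domain_fasta,
    starting_clusters,
)
from funfams.coherence import (
    CoherenceConfig,
    CoherenceVerdict,
    PrunedFamily,
    assess_dendrogram,
    prune,
)
from funfams.families import FunFam, build_funfams
from funfams.ontology import GoDag, parse_obo


@dataclass
class SuperfamilyResult:
    """Everything produced while identifying families in one superfamily."""

    seqs_by_id: dict[str, DomainSequence]
    store: AnnotationStore
    clusters: list[Cluster]
    dendrogram: Dendrogram
    verdicts: dict[str, CoherenceVerdict]
    pruned: list[PrunedFamily]
    funfams: list[FunFam] = field(default_factory=list)

    def family_of(self) -> dict[str, str]:
        """seq_id -> funfam_id over all selected families."""
        out: dict[str, str] = {}
        for fam in self.funfams:
            for seq_id in fam.members:
                out[seq_id] = fam.funfam_id
        return out


def load_annotations(
    gaf_path, dag: GoDag, subset_of: dict[str, str] | None = None
) -> AnnotationStore:
    """Parse, quality-filter and reduce a GAF file into a store."""
    records = parse_gaf(gaf_path, subset_of=subset_of)
    return build_store(filter_high_quality(records), dag)


def identify_families(
    seqs: list[DomainSequence],
    store: AnnotationStore,
    dag: GoDag,
    identity_threshold: float = 0.9,
    coherence_config: CoherenceConfig = CoherenceConfig(),
    similarity: SimilarityFn | None = None,
    with_models: bool = True,
    aligner: str = "builtin",
) -> SuperfamilyResult:
    """Run the full identification chain for one superfamily.

    Starting clusters at *identity_threshold*, removal of unannotated
    clusters, agglomeration to a single root, per-node coherence assessment,
    pruning, and family model/term-probability construction.
    """
    if not seqs:
        raise ValueError("no input sequences")
    superfamily_ids = {s.superfamily_id for s in seqs}
    if len(superfamily_ids) != 1:
        raise ValueError(
            f"sequences span multiple superfamilies: {sorted(superfamily_ids)}"
        )
    seqs_by_id = {s.seq_id: s for s in seqs}
    clusters = starting_clusters(seqs, identity_threshold)
    clusters = drop_unannotated(clusters, store, seqs_by_id)
    dendrogram = agglomerate(clusters, seqs_by_id, similarity)
    verdicts = assess_dendrogram(
        dendrogram, seqs_by_id, store, dag, coherence_config
    )
    pruned = prune(dendrogram, verdicts)
    funfams = build_funfams(
        pruned,
        seqs_by_id,
        store,
        dag,
        superfamily_id=superfamily_ids.pop(),
        with_models=with_models,
        aligner=aligner,
    )
    return SuperfamilyResult(
        seqs_by_id=seqs_by_id,
        store=store,
        clusters=clusters,
        dendrogram=dendrogram,
        verdicts=verdicts,
        pruned=pruned,
        funfams=funfams,
    )


def identify_from_files(
    fasta_path,
    obo_path,
    gaf_path,
    subset_path=None,
    **kwargs,
) -> SuperfamilyResult:
    """File-based convenience wrapper around :func:`identify_families`."""
    from funfams.annotations import read_subset_tsv

    dag = parse_obo(obo_path)
    subset_of = read_subset_tsv(subset_path) if subset_path else None
    store = load_annotations(gaf_path, dag, subset_of)
    seqs = read_domain_fasta(fasta_path)
    return identify_families(seqs, store, dag, **kwargs)
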