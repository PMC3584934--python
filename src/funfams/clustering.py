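"""Starting clusters and the superfamily dendrogram.

Superfamily domain sequences are first pre-clustered at 90% pairwise
identity by greedy incremental clustering (CD-HIT style: longest sequence
founds the first cluster, each following sequence joins the first
representative it matches at or above the threshold).  Clusters without a
single high-quality-annotated sequence are removed; the remaining "starting
clusters" are agglomerated — always merging the most similar pair — into a
binary dendrogram whose merge scores decrease from the leaves toward the
single root.

The cluster-pair similarity is pluggable.  The default scores a pair by the
average pairwise percent identity between the members of the two clusters
(global alignment, BLOSUM62, affine gaps), which makes the agglomeration an
average-linkage scheme and guarantees non-increasing merge scores.  The
profile–profile scoring of the original sampling protocol can be supplied
through the same interface.
"""

from __future__ import annotations

import itertools
import re
from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from funfams.align import IdentityCache, percent_identity
from funfams.annotations import AnnotationStore

AA_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWYX")


@dataclass(frozen=True)
class DomainSequence:
    """A domain sequence with its parent-protein linkage.

    ``segments`` are 1-based inclusive (start, end) ranges in parent-protein
    coordinates, non-overlapping and ascending.
    """

    seq_id: str
    parent_protein_id: str
    superfamily_id: str
    residues: str
    segments: tuple[tuple[int, int], ...] = ()

    def __post_init__(self):
        if not self.residues:
            raise ValueError(f"{self.seq_id}: empty sequence")
        bad = set(self.residues.upper()) - AA_ALPHABET
        if bad:
            raise ValueError(
                f"{self.seq_id}: invalid residues {sorted(bad)}"
            )
        last_end = 0
        for start, end in self.segments:
            if start <= last_end or end < start:
                raise ValueError(
                    f"{self.seq_id}: segments must be ascending and "
                    f"non-overlapping, got {self.segments}"
                )
            last_end = end


@dataclass(frozen=True)
class Cluster:
    """A set of domain sequence ids with a stable identifier."""

    cluster_id: str
    members: frozenset[str]

    def __post_init__(self):
        if not self.members:
            raise ValueError(f"cluster {self.cluster_id} is empty")


@dataclass
class DendrogramNode:
    node_id: str
    members: frozenset[str]
    children: tuple["DendrogramNode", "DendrogramNode"] | None = None
    merge_score: float | None = None
    cluster: Cluster | None = None  # set on leaves

    @property
    def is_leaf(self) -> bool:
        return self.children is None


@dataclass
class Dendrogram:
    """Binary merge tree over starting clusters."""

    root: DendrogramNode
    leaves: tuple[DendrogramNode, ...]

    def nodes(self) -> list[DendrogramNode]:
        """All nodes, post-order (children before parents)."""
        out: list[DendrogramNode] = []
        stack: list[tuple[DendrogramNode, bool]] = [(self.root, False)]
        while stack:
            node, expanded = stack.pop()
            if expanded or node.is_leaf:
                out.append(node)
            else:
                stack.append((node, True))
                for child in reversed(node.children):
                    stack.append((child, False))
        return out

    def to_newick(self) -> str:
        """Newick string with merge scores as internal node labels."""

        def render(node: DendrogramNode) -> str:
            if node.is_leaf:
                return node.node_id
            left, right = node.children
            label = f"{node.merge_score:.6g}" if node.merge_score is not None else ""
            return f"({render(left)},{render(right)}){label}"

        return render(self.root) + ";"


# ---------------------------------------------------------------------------
# FASTA with the Gene3D-style header convention
# ---------------------------------------------------------------------------

_SEGMENT_RE = re.compile(r"^(\d+)-(\d+)$")


def read_domain_fasta(path) -> list[DomainSequence]:
    """Read domain sequences from FASTA.

    Header convention: ``>seq_id|protein_id|superfamily_id/start-end[,s-e...]``
    with 1-based inclusive coordinates; the ``/segments`` part is optional.
    """
    out: list[DomainSequence] = []
    for record in SeqIO.parse(str(path), "fasta"):
        header = record.id
        segtext = ""
        if "/" in header:
            header, segtext = header.split("/", 1)
        parts = header.split("|")
        if len(parts) != 3:
            raise ValueError(
                f"{path}: header {record.id!r} does not follow "
                "'seq_id|protein_id|superfamily_id[/segments]'"
            )
        segments: list[tuple[int, int]] = []
        if segtext:
            for chunk in segtext.split(","):
                m = _SEGMENT_RE.match(chunk)
                if not m:
                    raise ValueError(
                        f"{path}: bad segment {chunk!r} in header {record.id!r}"
                    )
                segments.append((int(m.group(1)), int(m.group(2))))
        out.append(
            DomainSequence(
                seq_id=parts[0],
                parent_protein_id=parts[1],
                superfamily_id=parts[2],
                residues=str(record.seq).upper(),
                segments=tuple(segments),
            )
        )
    return out


def write_domain_fasta(path, seqs: Iterable[DomainSequence]) -> None:
    records = []
    for s in seqs:
        header = f"{s.seq_id}|{s.parent_protein_id}|{s.superfamily_id}"
        if s.segments:
            header += "/" + ",".join(f"{a}-{b}" for a, b in s.segments)
        records.append(SeqRecord(Seq(s.residues), id=header, description=""))
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def starting_clusters(
    seqs: Sequence[DomainSequence], identity_threshold: float = 0.9
) -> list[Cluster]:
    """Greedy incremental clustering at *identity_threshold* pairwise identity.

    Sequences are processed longest first (ties by seq_id); each sequence
    joins the earliest-founded cluster whose representative it matches at or
    above the threshold, else founds a new cluster.  Deterministic.
    """
    if not seqs:
        raise ValueError("no sequences to cluster")
    ordered = sorted(seqs, key=lambda s: (-len(s.residues), s.seq_id))
    reps: list[DomainSequence] = []
    members: list[list[str]] = []
    for seq in ordered:
        for idx, rep in enumerate(reps):
            if percent_identity(rep.residues, seq.residues) >= identity_threshold:
                members[idx].append(seq.seq_id)
                break
        else:
            reps.append(seq)
            members.append([seq.seq_id])
    return [
        Cluster(cluster_id=f"SC{idx:04d}", members=frozenset(m))
        for idx, m in enumerate(members)
    ]


def drop_unannotated(
    clusters: Sequence[Cluster],
    store: AnnotationStore,
    seqs_by_id: dict[str, DomainSequence],
) -> list[Cluster]:
    """Remove clusters without any high-quality-annotated member sequence.

    A cluster is kept iff at least one member's parent protein carries a
    post-filter GO term.  Raises if nothing survives — superfamilies without
    annotated sequences have no identifiable functional families.
    """
    kept = []
    for cluster in clusters:
        if any(
            store.is_annotated(seqs_by_id[m].parent_protein_id)
            for m in cluster.members
        ):
            kept.append(cluster)
    if not kept:
        raise ValueError("no annotated starting clusters")
    return kept


SimilarityFn = Callable[
    [Sequence[DomainSequence], Sequence[DomainSequence]], float
]


class AveragePairwiseIdentity:
    """Default cluster-pair scorer: mean percent identity over member pairs."""

    def __init__(self, seqs_by_id: dict[str, DomainSequence]):
        self._cache = IdentityCache(
            {sid: s.residues for sid, s in seqs_by_id.items()}
        )

    def __call__(
        self, a: Sequence[DomainSequence], b: Sequence[DomainSequence]
    ) -> float:
        total = 0.0
        for sa, sb in itertools.product(a, b):
            total += self._cache(sa.seq_id, sb.seq_id)
        return total / (len(a) * len(b))


def agglomerate(
    clusters: Sequence[Cluster],
    seqs_by_id: dict[str, DomainSequence],
    similarity: SimilarityFn | None = None,
) -> Dendrogram:
    """Merge starting clusters bottom-up until a single root remains.

    Repeatedly merges the highest-similarity pair, recording the similarity
    as the merge score; ties are broken by the lexicographically smallest
    (node_id, node_id) pair.  Identical inputs yield identical trees,
    including node identifiers (internal nodes are numbered in merge order).
    """
    if not clusters:
        raise ValueError("no clusters to agglomerate")
    if similarity is None:
        similarity = AveragePairwiseIdentity(seqs_by_id)

    leaves = tuple(
        DendrogramNode(
            node_id=c.cluster_id, members=c.members, cluster=c
        )
        for c in sorted(clusters, key=lambda c: c.cluster_id)
    )
    active: dict[str, DendrogramNode] = {n.node_id: n for n in leaves}
    member_seqs: dict[str, list[DomainSequence]] = {
        n.node_id: [seqs_by_id[m] for m in sorted(n.members)] for n in leaves
    }
    sims: dict[tuple[str, str], float] = {}
    for id_a, id_b in itertools.combinations(sorted(active), 2):
        sims[(id_a, id_b)] = similarity(member_seqs[id_a], member_seqs[id_b])

    merge_index = 0
    while len(active) > 1:
        score = max(sims.values())
        id_a, id_b = min(pair for pair, s in sims.items() if s == score)
        merge_index += 1
        new_id = f"M{merge_index:04d}"
        node = DendrogramNode(
            node_id=new_id,
            members=active[id_a].members | active[id_b].members,
            children=(active[id_a], active[id_b]),
            merge_score=score,
        )
        del active[id_a], active[id_b]
        member_seqs[new_id] = member_seqs.pop(id_a) + member_seqs.pop(id_b)
        sims = {
            pair: s
            for pair, s in sims.items()
            if id_a not in pair and id_b not in pair
        }
        for other in sorted(active):
            key = (other, new_id) if other < new_id else (new_id, other)
            sims[key] = similarity(member_seqs[new_id], member_seqs[other])
        active[new_id] = node

    return Dendrogram(root=next(iter(active.values())), leaves=leaves)
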