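"""Alignment utilities, starting clusters and the dendrogram."""

import numpy as np
import pytest

from funfams.align import center_star_align, percent_identity
from funfams.clustering import (
    Cluster,
    DomainSequence,
    agglomerate,
    drop_unannotated,
    read_domain_fasta,
    starting_clusters,
    write_domain_fasta,
)

from conftest import make_seq, make_store, random_protein


class TestPercentIdentity:
    def test_identical_sequences(self):
        assert percent_identity("ACDEFGHIKL", "ACDEFGHIKL") == 1.0

    def test_half_identity_without_gaps(self):
        # substitutions at alternating positions; affine penalties make the
        # gapless alignment optimal, so identity is exactly 10/20
        a = "ACDEFGHIKLMNPQRSTVWY"
        b = "AGDHFAHWKAMYPVRDTMWC"
        assert percent_identity(a, b) == pytest.approx(0.5)

    def test_symmetry(self):
        rng = np.random.default_rng(0)
        x, y = random_protein(rng, 30), random_protein(rng, 25)
        assert percent_identity(x, y) == pytest.approx(percent_identity(y, x))


class TestCenterStar:
    def test_rows_degap_to_inputs(self):
        rng = np.random.default_rng(1)
        base = random_protein(rng, 40)
        seqs = {
            "a": base,
            "b": base[:20] + base[25:],  # internal deletion
            "c": base[5:],               # truncated
        }
        msa = center_star_align(seqs)
        widths = {len(row) for row in msa.values()}
        assert len(widths) == 1
        assert widths.pop() >= max(len(s) for s in seqs.values())
        for sid, row in msa.items():
            assert row.replace("-", "") == seqs[sid]

    def test_single_sequence(self):
        assert center_star_align({"x": "ACDEF"}) == {"x": "ACDEF"}


class TestStartingClusters:
    def test_single_sequence_single_cluster(self):
        clusters = starting_clusters([make_seq("s1")])
        assert len(clusters) == 1
        assert clusters[0].members == {"s1"}

    def test_identical_sequences_merge(self):
        seqs = [make_seq("s1", "ACDEFGHIKLMNPQRSTVWY"),
                make_seq("s2", "ACDEFGHIKLMNPQRSTVWY")]
        clusters = starting_clusters(seqs)
        assert len(clusters) == 1
        assert clusters[0].members == {"s1", "s2"}

    def test_distant_sequences_split(self):
        # ~50% identity, far below the 0.9 threshold
        a = "ACDEFGHIKLMNPQRSTVWY" * 2
        b = "AGDHFAHWKAMYPVRDTMWC" * 2
        clusters = starting_clusters([make_seq("s1", a), make_seq("s2", b)])
        assert len(clusters) == 2

    def test_empty_input_raises(self):
        with pytest.raises(ValueError):
            starting_clusters([])

    def test_deterministic_ids_and_membership(self):
        rng = np.random.default_rng(2)
        base = random_protein(rng, 60)
        seqs = [make_seq(f"s{i}", base) for i in range(3)]
        first = starting_clusters(seqs)
        second = starting_clusters(list(reversed(seqs)))
        assert [(c.cluster_id, c.members) for c in first] == [
            (c.cluster_id, c.members) for c in second
        ]


class TestDropUnannotated:
    def test_fully_unannotated_cluster_dropped(self):
        seqs = {s.seq_id: s for s in [make_seq("a"), make_seq("b")]}
        clusters = [
            Cluster("SC0", frozenset({"a"})),
            Cluster("SC1", frozenset({"b"})),
        ]
        store = make_store({"Pa": {"GO:1"}})
        kept = drop_unannotated(clusters, store, seqs)
        assert [c.cluster_id for c in kept] == ["SC0"]

    def test_partially_annotated_cluster_kept(self):
        seqs = {s.seq_id: s for s in [make_seq(f"m{i}") for i in range(5)]}
        cluster = Cluster("SC0", frozenset(seqs))
        store = make_store({"Pm0": {"GO:1"}})
        assert drop_unannotated([cluster], store, seqs) == [cluster]

    def test_empty_store_raises(self):
        seqs = {"a": make_seq("a")}
        with pytest.raises(ValueError, match="no annotated starting clusters"):
            drop_unannotated([Cluster("SC0", frozenset({"a"}))],
                             make_store({}), seqs)


def _three_cluster_setup():
    rng = np.random.default_rng(3)
    near = random_protein(rng, 50)
    near2 = near[:2] + "A" + near[3:]  # one substitution
    far = random_protein(rng, 50)
    seqs = {s.seq_id: s for s in [
        make_seq("a", near), make_seq("b", near2), make_seq("c", far),
    ]}
    clusters = [Cluster(cid, frozenset({sid}))
                for cid, sid in (("SCa", "a"), ("SCb", "b"), ("SCc", "c"))]
    return seqs, clusters


class TestAgglomerate:
    def test_single_cluster_is_root(self):
        seqs = {"a": make_seq("a")}
        dend = agglomerate([Cluster("SC0", frozenset({"a"}))], seqs)
        assert dend.root.is_leaf
        assert dend.root.members == {"a"}

    def test_most_similar_pair_merges_first(self):
        seqs, clusters = _three_cluster_setup()
        dend = agglomerate(clusters, seqs)
        first_merge = min(
            (n for n in dend.nodes() if not n.is_leaf),
            key=lambda n: n.node_id,
        )
        assert first_merge.members == {"a", "b"}

    def test_internal_node_count(self):
        rng = np.random.default_rng(4)
        seqs = {f"s{i}": make_seq(f"s{i}", random_protein(rng, 30))
                for i in range(5)}
        clusters = [Cluster(f"SC{i}", frozenset({f"s{i}"})) for i in range(5)]
        dend = agglomerate(clusters, seqs)
        internals = [n for n in dend.nodes() if not n.is_leaf]
        assert len(internals) == len(clusters) - 1

    def test_merge_scores_non_increasing_to_root(self):
        rng = np.random.default_rng(5)
        base = random_protein(rng, 60)
        seqs = {}
        clusters = []
        for i in range(6):
            mutated = list(base)
            for pos in rng.choice(60, size=i * 4, replace=False):
                mutated[pos] = "W" if mutated[pos] != "W" else "Y"
            seqs[f"s{i}"] = make_seq(f"s{i}", "".join(mutated))
            clusters.append(Cluster(f"SC{i}", frozenset({f"s{i}"})))
        dend = agglomerate(clusters, seqs)

        # similarity decreases toward the root: every child's merge score
        # is at least its parent's
        def check(node, parent_score):
            if node.is_leaf:
                return
            assert node.merge_score >= parent_score - 1e-12
            for child in node.children:
                check(child, node.merge_score)

        check(dend.root, float("-inf"))

    def test_leaves_equal_input_clusters(self):
        seqs, clusters = _three_cluster_setup()
        dend = agglomerate(clusters, seqs)
        assert {leaf.node_id for leaf in dend.leaves} == {
            c.cluster_id for c in clusters
        }

    def test_determinism_including_node_ids(self):
        seqs, clusters = _three_cluster_setup()
        a = agglomerate(clusters, seqs).to_newick()
        b = agglomerate(list(reversed(clusters)), seqs).to_newick()
        assert a == b


def test_fasta_round_trip(tmp_path):
    seqs = [
        DomainSequence("d1", "P1", "SF1", "ACDEF", ((3, 7),)),
        DomainSequence("d2", "P2", "SF1", "GHIKL", ((1, 3), (10, 11))),
    ]
    path = tmp_path / "domains.fa"
    write_domain_fasta(path, seqs)
    assert read_domain_fasta(path) == seqs


def test_fasta_bad_header_rejected(tmp_path):
    path = tmp_path / "bad.fa"
    path.write_text(">justoneid\nACDEF\n")
    with pytest.raises(ValueError, match="header"):
        read_domain_fasta(path)
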