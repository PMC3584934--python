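"""Core-set compilation, annotation editing, coherence and pruning."""

import numpy as np
import pytest

from funfams.clustering import Cluster, agglomerate
from funfams.coherence import (
    CoherenceConfig,
    NoAnnotatedMembersError,
    NoMfTermsError,
    analyse_cluster,
    assess,
    assess_dendrogram,
    build_filter_set,
    collect_term_sets,
    core_term_set,
    edit_cluster_terms,
    prune,
)
from funfams.examples import hydrolase_cluster, reductase_cluster

from conftest import build_dag, make_seq, make_store
from oracles import assess_oracle, dag_from_parents, random_cluster_instance


def _cluster_setup(term_sets, dag=None, ns_of=None, parents=None):
    if dag is None:
        dag = build_dag(parents, ns_of=ns_of)
    seqs = {sid: make_seq(sid) for sid in term_sets}
    store = make_store({f"P{sid}": ts for sid, ts in term_sets.items()})
    cluster = Cluster("C", frozenset(term_sets))
    return cluster, seqs, store, dag


class TestCollectTermSets:
    def test_namespace_split(self):
        cluster, seqs, store, dag = _cluster_setup(
            {"s1": {"M1", "B1"}},
            parents={"M1": [], "B1": []},
            ns_of={"M1": "MF", "B1": "BP"},
        )
        ts = collect_term_sets(cluster, seqs, store, dag)
        assert ts.sequence_ns["s1"]["MF"] == {"M1"}
        assert ts.sequence_ns["s1"]["BP"] == {"B1"}

    def test_cluster_set_is_union(self):
        cluster, seqs, store, dag = _cluster_setup(
            {"s1": {"A"}, "s2": {"A"}},
            parents={"A": []},
        )
        ts = collect_term_sets(cluster, seqs, store, dag)
        assert ts.cluster_terms == {"A"}

    def test_unannotated_member_carries_empty_set(self):
        cluster, seqs, store, dag = _cluster_setup(
            {"s1": {"A"}, "s2": set()}, parents={"A": []}
        )
        ts = collect_term_sets(cluster, seqs, store, dag)
        assert ts.sequence_terms["s2"] == frozenset()

    def test_no_annotated_members_raises(self):
        cluster, seqs, store, dag = _cluster_setup(
            {"s1": set()}, parents={"A": []}
        )
        with pytest.raises(NoAnnotatedMembersError):
            collect_term_sets(cluster, seqs, store, dag)


class TestReductaseScenario:
    """Cluster of reductase domains with three related specificities."""

    @pytest.fixture()
    def analysed(self):
        sc = reductase_cluster()
        return analyse_cluster(sc.cluster, sc.seqs_by_id, sc.store, sc.dag)

    def test_initial_core_from_minimum_size_sets(self, analysed):
        _, core, _, _ = analysed
        assert core.initial_core == {"C1", "P1"}

    def test_final_core_most_specific_children(self, analysed):
        _, core, _, _ = analysed
        assert core.final_core == {"C1", "C2", "C3"}

    def test_no_ancillary_terms_identified(self, analysed):
        _, core, _, _ = analysed
        assert core.found_in_iteration == {}
        # the filter holds only the core terms' own ancestors
        assert core.filter_set == {"P1", "R"}

    def test_coherent_with_fully_annotated_witness(self, analysed):
        _, _, _, verdict = analysed
        assert verdict.assessment_type == "MF"
        assert verdict.cluster_ta_set == {"C1", "C2", "C3"}
        assert verdict.coherent
        assert verdict.witness_sequence == "s3"


class TestHydrolaseScenario:
    """Cluster with ancillary and foreign-domain annotations to edit away."""

    @pytest.fixture()
    def analysed(self):
        sc = hydrolase_cluster()
        return analyse_cluster(sc.cluster, sc.seqs_by_id, sc.store, sc.dag)

    def test_core_sets(self, analysed):
        _, core, _, _ = analysed
        assert core.initial_core == {"P1", "P2"}
        assert core.final_core == {"C1", "C2"}

    def test_iterative_identification_order(self, analysed):
        _, core, _, _ = analysed
        # E1 via co-annotation with the core term C1; F2 via the core
        # ancestor P3 — both in the first pass; F1 only via E1 in the second
        assert core.found_in_iteration == {"E1": 1, "F2": 1, "F1": 2}

    def test_filter_contains_all_non_core_associated(self, analysed):
        _, core, _, _ = analysed
        assert {"E1", "F1", "F2"} <= core.filter_set
        assert core.filter_set.isdisjoint(core.final_core)

    def test_editing_leaves_core_terms_only(self, analysed):
        _, _, edited, _ = analysed
        assert edited.cluster_mf == {"C1", "C2"}

    def test_coherent(self, analysed):
        _, _, _, verdict = analysed
        assert verdict.coherent
        assert verdict.cluster_ta_set == {"C1", "C2"}


class TestCoreEdgeCases:
    def test_single_sequence_single_term(self):
        cluster, seqs, store, dag = _cluster_setup(
            {"s1": {"A"}}, parents={"A": []}
        )
        ts = collect_term_sets(cluster, seqs, store, dag)
        core = core_term_set(ts, dag)
        assert core.initial_core == core.final_core == {"A"}

    def test_all_mf_sets_empty_raises(self):
        cluster, seqs, store, dag = _cluster_setup(
            {"s1": {"B1"}}, parents={"B1": []}, ns_of={"B1": "BP"}
        )
        ts = collect_term_sets(cluster, seqs, store, dag)
        with pytest.raises(NoMfTermsError):
            core_term_set(ts, dag)

    def test_empty_mf_sets_do_not_define_minimum(self):
        # one unannotated member must not force m = 0
        cluster, seqs, store, dag = _cluster_setup(
            {"s1": {"A", "B"}, "s2": set()},
            parents={"A": [], "B": []},
        )
        ts = collect_term_sets(cluster, seqs, store, dag)
        assert core_term_set(ts, dag).initial_core == {"A", "B"}

    def test_no_larger_sets_no_iteration_finds(self):
        cluster, seqs, store, dag = _cluster_setup(
            {"s1": {"A"}, "s2": {"A"}}, parents={"A": []}
        )
        ts = collect_term_sets(cluster, seqs, store, dag)
        core = build_filter_set(core_term_set(ts, dag), ts, dag)
        assert core.found_in_iteration == {}

    def test_empty_filter_editing_is_identity(self):
        cluster, seqs, store, dag = _cluster_setup(
            {"s1": {"A"}}, parents={"A": []}
        )
        ts = collect_term_sets(cluster, seqs, store, dag)
        core = build_filter_set(core_term_set(ts, dag), ts, dag)
        assert core.filter_set == frozenset()
        assert edit_cluster_terms(ts, core) is ts

    def test_direct_children_mode_restricts_extension(self):
        # C is a grandchild of the core term P; transitive mode adds it,
        # direct-child mode does not
        parents = {"P": [], "Mid": ["P"], "C": ["Mid"], "X": []}
        cluster, seqs, store, dag = _cluster_setup(
            {"s1": {"P"}, "s2": {"C", "X"}}, parents=parents
        )
        ts = collect_term_sets(cluster, seqs, store, dag)
        transitive = core_term_set(ts, dag, CoherenceConfig())
        direct = core_term_set(
            ts, dag, CoherenceConfig(transitive_children=False)
        )
        assert "C" in transitive.final_core
        assert direct.final_core == {"P"}


class TestAssess:
    def test_single_annotated_sequence_coherent(self):
        cluster, seqs, store, dag = _cluster_setup(
            {"s1": {"A"}, "s2": set()}, parents={"A": []}
        )
        verdict = assess(cluster, seqs, store, dag)
        assert verdict.coherent and verdict.witness_sequence == "s1"

    def test_disjoint_specific_terms_incoherent(self):
        cluster, seqs, store, dag = _cluster_setup(
            {"s1": {"A"}, "s2": {"B"}}, parents={"A": [], "B": []}
        )
        verdict = assess(cluster, seqs, store, dag)
        assert not verdict.coherent
        assert verdict.witness_sequence is None

    def test_bp_fallback_when_no_mf(self):
        cluster, seqs, store, dag = _cluster_setup(
            {"s1": {"B1"}, "s2": {"B1"}},
            parents={"B1": []}, ns_of={"B1": "BP"},
        )
        verdict = assess(cluster, seqs, store, dag)
        assert verdict.assessment_type == "BP"
        assert verdict.coherent

    def test_ancestor_aware_mode_covers_parents(self):
        parents = {"P": [], "C": ["P"]}
        cluster, seqs, store, dag = _cluster_setup(
            # store-level reduction would not mix these: simulate two
            # proteins, one annotated at parent level only
            {"s1": {"C"}, "s2": {"P"}}, parents=parents
        )
        plain = assess(cluster, seqs, store, dag)
        aware = assess(
            cluster, seqs, store, dag,
            CoherenceConfig(ancestor_aware_coverage=True),
        )
        # editing removes P (core ancestor), so both modes agree here;
        # disable editing effects by checking the coverage predicate via
        # a BP-namespace copy where no editing applies
        bp_cluster, bp_seqs, bp_store, bp_dag = _cluster_setup(
            {"s1": {"C"}, "s2": {"P"}},
            parents=parents, ns_of={"P": "BP", "C": "BP"},
        )
        plain_bp = assess(bp_cluster, bp_seqs, bp_store, bp_dag)
        aware_bp = assess(
            bp_cluster, bp_seqs, bp_store, bp_dag,
            CoherenceConfig(ancestor_aware_coverage=True),
        )
        assert plain.coherent and aware.coherent
        assert not plain_bp.coherent
        assert aware_bp.coherent

    @pytest.mark.parametrize("seed", range(40))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(1000 + seed)
        parents, ns_of, seq_terms = random_cluster_instance(rng)
        dag = dag_from_parents(parents, ns_of)
        cluster, seqs, store, _ = _cluster_setup(seq_terms, dag=dag)
        verdict = assess(cluster, seqs, store, dag)
        ns, cluster_set, coherent = assess_oracle(seq_terms, parents, ns_of)
        assert verdict.assessment_type == ns
        assert verdict.cluster_ta_set == cluster_set
        assert verdict.coherent == coherent


def _verdict_map(dendrogram, seqs, store, dag, config=CoherenceConfig()):
    return assess_dendrogram(dendrogram, seqs, store, dag, config)


class TestPrune:
    def _dendrogram(self, term_sets, parents, ns_of=None):
        dag = build_dag(parents, ns_of=ns_of)
        seqs = {sid: make_seq(sid) for sid in term_sets}
        store = make_store({f"P{sid}": ts for sid, ts in term_sets.items()})
        clusters = [
            Cluster(f"SC{sid}", frozenset({sid})) for sid in sorted(term_sets)
        ]
        dend = agglomerate(clusters, seqs)
        return dend, seqs, store, dag

    def test_fully_coherent_tree_is_one_family(self):
        dend, seqs, store, dag = self._dendrogram(
            {"s1": {"A"}, "s2": {"A"}, "s3": {"A"}}, parents={"A": []}
        )
        fams = prune(dend, _verdict_map(dend, seqs, store, dag))
        assert len(fams) == 1
        assert fams[0].members == {"s1", "s2", "s3"}

    def test_incoherent_root_splits(self):
        dend, seqs, store, dag = self._dendrogram(
            {"s1": {"A"}, "s2": {"B"}}, parents={"A": [], "B": []}
        )
        fams = prune(dend, _verdict_map(dend, seqs, store, dag))
        assert sorted((f.members for f in fams), key=sorted) == [
            frozenset({"s1"}), frozenset({"s2"}),
        ]

    def test_incoherent_leaf_flagged_singleton(self):
        # a leaf cluster of two sequences with disjoint terms cannot be
        # split further: retained, flagged
        dag = build_dag({"A": [], "B": []})
        seqs = {"s1": make_seq("s1"), "s2": make_seq("s2")}
        store = make_store({"Ps1": {"A"}, "Ps2": {"B"}})
        leaf = Cluster("SC0", frozenset({"s1", "s2"}))
        dend = agglomerate([leaf], seqs)
        fams = prune(dend, _verdict_map(dend, seqs, store, dag))
        assert len(fams) == 1
        assert fams[0].incoherent_leaf

    def test_keep_leaves_mode_never_assesses_leaves(self):
        dag = build_dag({"A": [], "B": []})
        seqs = {"s1": make_seq("s1"), "s2": make_seq("s2")}
        store = make_store({"Ps1": {"A"}, "Ps2": {"B"}})
        leaf = Cluster("SC0", frozenset({"s1", "s2"}))
        dend = agglomerate([leaf], seqs)
        verdicts = _verdict_map(
            dend, seqs, store, dag, CoherenceConfig(assess_leaves=False)
        )
        fams = prune(dend, verdicts)
        assert len(fams) == 1 and not fams[0].incoherent_leaf

    @pytest.mark.parametrize("seed", range(15))
    def test_partition_and_maximality(self, seed):
        rng = np.random.default_rng(2000 + seed)
        parents, ns_of, seq_terms = random_cluster_instance(
            rng, max_seqs=8
        )
        # ensure every sequence annotated so no cluster is dropped
        terms = sorted(parents)
        for sid in seq_terms:
            if not seq_terms[sid]:
                seq_terms[sid] = {terms[int(rng.integers(len(terms)))]}
        dag = dag_from_parents(parents, ns_of)
        seqs = {sid: make_seq(sid) for sid in seq_terms}
        store = make_store({f"P{sid}": ts for sid, ts in seq_terms.items()})
        clusters = [
            Cluster(f"SC{sid}", frozenset({sid})) for sid in sorted(seq_terms)
        ]
        dend = agglomerate(clusters, seqs)
        verdicts = _verdict_map(dend, seqs, store, dag)
        fams = prune(dend, verdicts)
        # partition of all leaves
        all_members = [m for f in fams for m in f.members]
        assert sorted(all_members) == sorted(seq_terms)
        # no selected family is an ancestor of another (disjointness implies)
        for i, a in enumerate(fams):
            for b in fams[i + 1:]:
                assert a.members.isdisjoint(b.members)
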