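"""Small worked-example scenarios used in the documentation and tests.

Two kinds of scenario are provided:

* ``worked_example()`` — the two-superfamily prediction walk-through: a
  six-member family carrying two functions at probability 0.5 each, a
  three-member family carrying one function at probability 1.0, and a
  two-domain target protein whose integrated prediction is the per-term
  maximum over its domain assignments.

* ``reductase_cluster()`` / ``hydrolase_cluster()`` — the two annotation
  scenarios that exercise core-set compilation and annotation editing: a
  cluster of reductase domains with three closely related substrate
  specificities (no ancillary terms), and a cluster of hydrolase domains
  whose parent proteins contribute ancillary ("extra") and foreign-domain
  terms that the editing iteration must identify and filter.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from funfams.annotations import AnnotationStore
from funfams.clustering import Cluster, DomainSequence
from funfams.families import FunFam, associate_functions, build_model
from funfams.ontology import GoDag

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"


def _mini_dag(parents: dict[str, list[str]], namespace: str = "MF") -> GoDag:
    dag = GoDag()
    for term, ps in parents.items():
        dag.terms.add(term)
        dag.namespace_of[term] = namespace
        dag.parents_of[term] = set(ps)
    dag.validate()
    return dag


def store_from_terms(term_sets: dict[str, set[str]]) -> AnnotationStore:
    """Build a store directly from per-protein (already most-specific) sets."""
    store = AnnotationStore()
    for protein, terms in term_sets.items():
        if terms:
            store.terms_of[protein] = frozenset(terms)
    return store


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(AMINO_ACIDS[i] for i in rng.integers(0, 20, length))


def _mutated(rng: np.random.Generator, seq: str, rate: float) -> str:
    out = list(seq)
    for pos in range(len(out)):
        if rng.random() < rate:
            choices = [a for a in AMINO_ACIDS if a != out[pos]]
            out[pos] = choices[rng.integers(0, len(choices))]
    return "".join(out)


# ---------------------------------------------------------------------------
# the prediction walk-through
# ---------------------------------------------------------------------------

YELLOW = "GO:0000010"
ORANGE = "GO:0000011"
VIOLET = "GO:0000012"


@dataclass
class WorkedExample:
    dag: GoDag
    seqs_by_id: dict[str, DomainSequence]
    store: AnnotationStore
    family_two_function: FunFam  # six members: three 'yellow', three 'orange'
    family_single_function: FunFam  # three members, all 'violet'
    target_domains: list[DomainSequence]  # one per superfamily


def worked_example(seed: int = 0, with_models: bool = True) -> WorkedExample:
    """Build the two families and the two-domain target protein.

    Family A (superfamily SFA) has six member domains whose parent proteins
    split 3/3 between two sibling functions, so function association yields
    p = 3/6 = 0.5 for each.  Family B (superfamily SFB) has three members
    all carrying one function: p = 3/3 = 1.0.  The target's two domains are
    near-copies of one member of each family, so each family's model is the
    top-scoring hit for the corresponding domain.
    """
    rng = np.random.default_rng(seed)
    dag = _mini_dag(
        {"GO:0000001": [], YELLOW: ["GO:0000001"], ORANGE: ["GO:0000001"],
         VIOLET: ["GO:0000001"]}
    )

    ancestor_a = _random_seq(rng, 110)
    ancestor_b = _random_seq(rng, 95)
    seqs_by_id: dict[str, DomainSequence] = {}
    term_sets: dict[str, set[str]] = {}

    members_a = []
    for i in range(6):
        sid = f"A{i}"
        seqs_by_id[sid] = DomainSequence(
            seq_id=sid, parent_protein_id=f"P{sid}", superfamily_id="SFA",
            residues=_mutated(rng, ancestor_a, 0.03),
        )
        members_a.append(sid)
        term_sets[f"P{sid}"] = {YELLOW if i < 3 else ORANGE}
    members_b = []
    for i in range(3):
        sid = f"B{i}"
        seqs_by_id[sid] = DomainSequence(
            seq_id=sid, parent_protein_id=f"P{sid}", superfamily_id="SFB",
            residues=_mutated(rng, ancestor_b, 0.03),
        )
        members_b.append(sid)
        term_sets[f"P{sid}"] = {VIOLET}

    store = store_from_terms(term_sets)

    family_a = FunFam(
        funfam_id="SFA-FF0001", superfamily_id="SFA",
        members=tuple(members_a),
    )
    family_b = FunFam(
        funfam_id="SFB-FF0001", superfamily_id="SFB",
        members=tuple(members_b),
    )
    if with_models:
        family_a.model = build_model(
            [seqs_by_id[m] for m in members_a], name=family_a.funfam_id
        )
        family_b.model = build_model(
            [seqs_by_id[m] for m in members_b], name=family_b.funfam_id
        )
    associate_functions(family_a, seqs_by_id, store, dag)
    associate_functions(family_b, seqs_by_id, store, dag)

    target_domains = [
        DomainSequence(
            seq_id="T1_d1", parent_protein_id="T1", superfamily_id="SFA",
            residues=_mutated(rng, seqs_by_id["A0"].residues, 0.02),
            segments=((1, 110),),
        ),
        DomainSequence(
            seq_id="T1_d2", parent_protein_id="T1", superfamily_id="SFB",
            residues=_mutated(rng, seqs_by_id["B0"].residues, 0.02),
            segments=((120, 214),),
        ),
    ]
    return WorkedExample(
        dag=dag,
        seqs_by_id=seqs_by_id,
        store=store,
        family_two_function=family_a,
        family_single_function=family_b,
        target_domains=target_domains,
    )


# ---------------------------------------------------------------------------
# the two annotation-editing scenarios
# ---------------------------------------------------------------------------

@dataclass
class ClusterScenario:
    dag: GoDag
    cluster: Cluster
    seqs_by_id: dict[str, DomainSequence]
    store: AnnotationStore


def _scenario(
    parents: dict[str, list[str]], seq_terms: dict[str, set[str]], seed: int
) -> ClusterScenario:
    rng = np.random.default_rng(seed)
    dag = _mini_dag(parents)
    ancestor = _random_seq(rng, 80)
    seqs_by_id = {
        sid: DomainSequence(
            seq_id=sid, parent_protein_id=f"P{sid}", superfamily_id="SFX",
            residues=_mutated(rng, ancestor, 0.05),
        )
        for sid in sorted(seq_terms)
    }
    store = store_from_terms(
        {f"P{sid}": terms for sid, terms in seq_terms.items()}
    )
    cluster = Cluster(cluster_id="C", members=frozenset(seq_terms))
    return ClusterScenario(
        dag=dag, cluster=cluster, seqs_by_id=seqs_by_id, store=store
    )


def reductase_cluster() -> ClusterScenario:
    """Four domain sequences with conserved reductase activity.

    The parent terms: P1 is the general reductase activity with the three
    substrate-specific children C1, C2, C3.  Annotations are partially
    incomplete: two proteins carry a single term ({C1} and {P1}), two carry
    the full specific set {C1, C2, C3}.  Expected: initial core {C1, P1},
    final core {C1, C2, C3}, no ancillary terms, cluster coherent.
    """
    parents = {
        "R": [],
        "P1": ["R"],
        "C1": ["P1"],
        "C2": ["P1"],
        "C3": ["P1"],
    }
    seq_terms = {
        "s1": {"C1"},
        "s2": {"P1"},
        "s3": {"C1", "C2", "C3"},
        "s4": {"C1", "C2", "C3"},
    }
    return _scenario(parents, seq_terms, seed=11)


def hydrolase_cluster() -> ClusterScenario:
    """Hydrolase-domain cluster with extra and foreign-domain annotations.

    P3 is a joint multi-domain function with parents P1 and P2 and children
    C1, C2.  E1 is an ancillary ("extra") activity; F1 and F2 are functions
    of a different domain of the parent proteins (children of PF).
    Expected: initial core {P1, P2}, final core {C1, C2}; editing identifies
    E1 and F2 in iteration 1 (co-annotation with the core terms C1/C2 and
    with the core ancestor P3, respectively) and F1 in iteration 2 (via E1);
    the surviving cluster MF set {C1, C2} is covered and the cluster is
    coherent.
    """
    parents = {
        "R": [],
        "P1": ["R"],
        "P2": ["R"],
        "P3": ["P1", "P2"],
        "C1": ["P3"],
        "C2": ["P3"],
        "PE": ["R"],
        "E1": ["PE"],
        "PF": ["R"],
        "F1": ["PF"],
        "F2": ["PF"],
    }
    seq_terms = {
        "s1": {"P1"},
        "s2": {"P2"},
        "s3": {"C1", "C2", "E1"},
        "s4": {"P3", "F2"},
        "s5": {"E1", "F1"},
    }
    return _scenario(parents, seq_terms, seed=13)
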