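import numpy as np
import pytest

from funfams.annotations import AnnotationStore
from funfams.clustering import DomainSequence
from funfams.ontology import GoDag

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"


def build_dag(parents: dict[str, list[str]], namespace: str = "MF",
              ns_of: dict[str, str] | None = None) -> GoDag:
    """Construct a GoDag directly from a parents mapping."""
    dag = GoDag()
    for term, ps in parents.items():
        dag.terms.add(term)
        dag.namespace_of[term] = (ns_of or {}).get(term, namespace)
        dag.parents_of[term] = set(ps)
    dag.validate()
    return dag


def make_store(term_sets: dict[str, set[str]]) -> AnnotationStore:
    store = AnnotationStore()
    for protein, terms in term_sets.items():
        if terms:
            store.terms_of[protein] = frozenset(terms)
    return store


def make_seq(seq_id: str, residues: str = "ACDEFGHIKLMNPQRSTVWY",
             protein: str | None = None, superfamily: str = "SF1"
             ) -> DomainSequence:
    return DomainSequence(
        seq_id=seq_id,
        parent_protein_id=protein or f"P{seq_id}",
        superfamily_id=superfamily,
        residues=residues,
    )


def random_protein(rng: np.random.Generator, length: int) -> str:
    return "".join(AMINO_ACIDS[i] for i in rng.integers(0, 20, length))


@pytest.fixture
def chain_dag() -> GoDag:
    """A is_a B is_a C."""
    return build_dag({"C": [], "B": ["C"], "A": ["B"]})


@pytest.fixture
def diamond_dag() -> GoDag:
    """A is_a {B, C}; B, C is_a D."""
    return build_dag({"D": [], "B": ["D"], "C": ["D"], "A": ["B", "C"]})
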