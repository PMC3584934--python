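"""Brute-force reference implementations, independent of the package internals.

Everything here works on plain dicts (``parents``: term -> set of parents,
``ns_of``: term -> namespace, ``seq_terms``: sequence -> set of terms) and
recomputes every closure recursively from scratch, so it can serve as an
oracle for the library's graph traversal, count propagation and coherence
assessment.
"""

from __future__ import annotations

import numpy as np

from funfams.ontology import GoDag


def anc(parents: dict, t: str) -> set:
    out = set()
    for p in parents.get(t, ()):
        out.add(p)
        out |= anc(parents, p)
    return out


def desc(parents: dict, t: str) -> set:
    return {u for u in parents if t in anc(parents, u)}


def antichain(parents: dict, terms: set) -> set:
    """Most-specific reduction: drop any term with a descendant in the set."""
    return {t for t in terms if not (desc(parents, t) & terms)}


def up_propagate_oracle(parents: dict, seq_terms: dict) -> dict:
    """count(t) = |{s : seq_terms[s] intersects {t} union desc(t)}|, count>=1."""
    counts = {}
    for t in parents:
        supporting = {t} | desc(parents, t)
        n = sum(1 for terms in seq_terms.values() if terms & supporting)
        if n:
            counts[t] = n
    return counts


def assess_oracle(
    seq_terms: dict, parents: dict, ns_of: dict
) -> tuple[str, set, bool]:
    """Exhaustive set-algebra re-derivation of the coherence verdict.

    Returns (assessment namespace, cluster term set of that namespace,
    coherent flag).
    """
    mf = {s: {t for t in ts if ns_of[t] == "MF"} for s, ts in seq_terms.items()}
    mf_nonempty = {s: ts for s, ts in mf.items() if ts}

    if mf_nonempty:
        m = min(len(ts) for ts in mf_nonempty.values())
        initial = set().union(
            *(ts for ts in mf_nonempty.values() if len(ts) == m)
        )
        larger = [ts for ts in mf_nonempty.values() if len(ts) > m]
        extended = set(initial)
        for ts in larger:
            for t in ts:
                if t not in extended and anc(parents, t) & initial:
                    extended.add(t)
        final = antichain(parents, extended)

        core_assoc = set(final)
        for t in final:
            core_assoc |= anc(parents, t)
        while True:
            novel = set()
            for ts in larger:
                if ts & core_assoc:
                    novel |= ts - core_assoc
            if not novel:
                break
            for t in novel:
                core_assoc |= {t} | anc(parents, t) | desc(parents, t)
        filter_set = core_assoc - final
        edited_mf = {s: ts - filter_set for s, ts in mf.items()}
    else:
        edited_mf = mf

    per_ns_seq = {}
    for s, ts in seq_terms.items():
        per_ns_seq[s] = {
            "MF": edited_mf[s],
            "BP": {t for t in ts if ns_of[t] == "BP"},
            "CC": {t for t in ts if ns_of[t] == "CC"},
        }
    for namespace in ("MF", "BP", "CC"):
        cluster_set = set().union(*(d[namespace] for d in per_ns_seq.values()))
        if cluster_set:
            coherent = any(
                d[namespace] and cluster_set <= d[namespace]
                for d in per_ns_seq.values()
            )
            return namespace, cluster_set, coherent
    raise ValueError("no terms in any namespace")


# ---------------------------------------------------------------------------
# random micro-instances
# ---------------------------------------------------------------------------

def random_dag(
    rng: np.random.Generator, max_terms: int = 15
) -> tuple[dict, dict]:
    """Random two-namespace rooted DAG; returns (parents, ns_of).

    Terms are added in topological order (parents always precede children),
    so acyclicity holds by construction.
    """
    n_mf = int(rng.integers(2, max(3, max_terms - 3)))
    n_bp = int(rng.integers(1, 4))
    parents: dict[str, set] = {}
    ns_of: dict[str, str] = {}
    for prefix, count, ns in (("M", n_mf, "MF"), ("B", n_bp, "BP")):
        ids = [f"{prefix}{i}" for i in range(count)]
        for i, t in enumerate(ids):
            ns_of[t] = ns
            if i == 0:
                parents[t] = set()
            else:
                k = int(rng.integers(1, min(i, 2) + 1))
                idx = rng.choice(i, size=k, replace=False)
                parents[t] = {ids[int(j)] for j in idx}
    return parents, ns_of


def random_cluster_instance(
    rng: np.random.Generator,
    max_seqs: int = 8,
    max_terms: int = 15,
) -> tuple[dict, dict, dict]:
    """Random DAG plus per-sequence antichain term sets; >=1 annotated seq."""
    while True:
        parents, ns_of = random_dag(rng, max_terms)
        terms = sorted(parents)
        n_seqs = int(rng.integers(1, max_seqs + 1))
        seq_terms = {}
        for i in range(n_seqs):
            size = int(rng.integers(0, 4))
            if size and terms:
                idx = rng.choice(len(terms), size=min(size, len(terms)),
                                 replace=False)
                chosen = {terms[int(j)] for j in idx}
                seq_terms[f"s{i}"] = antichain(parents, chosen)
            else:
                seq_terms[f"s{i}"] = set()
        if any(seq_terms.values()):
            return parents, ns_of, seq_terms


def dag_from_parents(parents: dict, ns_of: dict) -> GoDag:
    dag = GoDag()
    for t, ps in parents.items():
        dag.terms.add(t)
        dag.namespace_of[t] = ns_of[t]
        dag.parents_of[t] = set(ps)
    dag.validate()
    return dag
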