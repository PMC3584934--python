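"""Gene Ontology DAG: parsing, traversal, reduction and count up-propagation.

The ontology is modelled as a directed acyclic graph over term identifiers
restricted to ``is_a`` edges (child points to parent).  Each term belongs to
one of the three GO namespaces — molecular function (MF), biological process
(BP), cellular component (CC).  Obsolete terms are flagged at parse time and
excluded from traversal; annotations to them are remapped via ``replaced_by``
when available.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping

logger = logging.getLogger(__name__)

#: Canonical short namespace labels keyed by the OBO namespace strings.
NAMESPACES = {
    "molecular_function": "MF",
    "biological_process": "BP",
    "cellular_component": "CC",
}


class OboParseError(ValueError):
    """Raised when an OBO stanza cannot be interpreted."""


class UnknownTermError(KeyError):
    """Raised when a term identifier is not present in the DAG."""


@dataclass
class GoDag:
    """An is-a ontology graph over GO term identifiers.

    Attributes
    ----------
    terms:
        Non-obsolete primary term identifiers.
    namespace_of:
        Term identifier -> one of ``"MF"``, ``"BP"``, ``"CC"``.
    parents_of:
        Term identifier -> set of direct is-a parents (same namespace).
    alt_id_map:
        Alternate or replaced identifier -> primary, non-obsolete identifier.
    obsolete:
        Identifiers of obsolete terms seen at parse time (excluded from
        ``terms`` and from traversal).
    """

    terms: set[str] = field(default_factory=set)
    namespace_of: dict[str, str] = field(default_factory=dict)
    parents_of: dict[str, set[str]] = field(default_factory=dict)
    alt_id_map: dict[str, str] = field(default_factory=dict)
    obsolete: set[str] = field(default_factory=set)

    # -- resolution ---------------------------------------------------------

    def resolve(self, term: str) -> str | None:
        """Map *term* to its primary identifier, or ``None`` if unknown.

        Alternate identifiers and obsolete terms carrying a ``replaced_by``
        pointer resolve to their primary replacement; obsolete terms without
        one resolve to ``None``.
        """
        if term in self.terms:
            return term
        if term in self.alt_id_map:
            return self.alt_id_map[term]
        return None

    def __contains__(self, term: str) -> bool:
        return self.resolve(term) is not None

    def _require(self, term: str) -> str:
        primary = self.resolve(term)
        if primary is None:
            raise UnknownTermError(f"unknown GO term: {term!r}")
        return primary

    # -- traversal ----------------------------------------------------------

    def ancestors(self, term: str) -> set[str]:
        """Transitive is-a closure above *term*, excluding *term* itself."""
        start = self._require(term)
        out: set[str] = set()
        stack = list(self.parents_of.get(start, ()))
        while stack:
            t = stack.pop()
            if t not in out:
                out.add(t)
                stack.extend(self.parents_of.get(t, ()))
        return out

    def descendants(self, term: str) -> set[str]:
        """Transitive is-a closure below *term*, excluding *term* itself."""
        start = self._require(term)
        children = self._children_index()
        out: set[str] = set()
        stack = list(children.get(start, ()))
        while stack:
            t = stack.pop()
            if t not in out:
                out.add(t)
                stack.extend(children.get(t, ()))
        return out

    def children_of(self, term: str) -> set[str]:
        """Direct is-a children of *term*."""
        return set(self._children_index().get(self._require(term), ()))

    def _children_index(self) -> dict[str, set[str]]:
        cached = getattr(self, "_children_cache", None)
        if cached is None:
            cached = {}
            for child, parents in self.parents_of.items():
                for p in parents:
                    cached.setdefault(p, set()).add(child)
            object.__setattr__(self, "_children_cache", cached)
        return cached

    def namespace(self, term: str) -> str:
        return self.namespace_of[self._require(term)]

    # -- validation ---------------------------------------------------------

    def validate(self) -> None:
        """Check the structural invariants; raise :class:`OboParseError`."""
        self._check_acyclic()
        for term, parents in self.parents_of.items():
            ns = self.namespace_of.get(term)
            for p in parents:
                if p not in self.terms:
                    raise OboParseError(
                        f"term {term} has unknown parent {p}"
                    )
                if self.namespace_of.get(p) != ns:
                    raise OboParseError(
                        f"is_a edge crosses namespaces: {term} ({ns}) -> "
                        f"{p} ({self.namespace_of.get(p)})"
                    )
        for alt, primary in self.alt_id_map.items():
            if primary not in self.terms:
                raise OboParseError(
                    f"alt_id {alt} maps to unknown or obsolete term {primary}"
                )

    def _check_acyclic(self) -> None:
        # iterative three-colour DFS; recursion would overflow on deep chains
        WHITE, GREY, BLACK = 0, 1, 2
        colour = {t: WHITE for t in self.terms}
        for root in self.terms:
            if colour[root] != WHITE:
                continue
            stack: list[tuple[str, Iterable[str]]] = [
                (root, iter(self.parents_of.get(root, ())))
            ]
            colour[root] = GREY
            while stack:
                node, it = stack[-1]
                advanced = False
                for nxt in it:
                    if nxt not in colour:
                        continue
                    if colour[nxt] == GREY:
                        raise OboParseError(
                            f"is_a cycle detected through {nxt}"
                        )
                    if colour[nxt] == WHITE:
                        colour[nxt] = GREY
                        stack.append((nxt, iter(self.parents_of.get(nxt, ()))))
                        advanced = True
                        break
                if not advanced:
                    colour[node] = BLACK
                    stack.pop()


# ---------------------------------------------------------------------------
# OBO 1.2 flat-file reader
# ---------------------------------------------------------------------------

_KNOWN_RELATIONSHIPS = {"is_a"}


def parse_obo(path) -> GoDag:
    """Read an OBO 1.2 flat file into a :class:`GoDag`.

    Honours ``id``, ``alt_id``, ``is_a``, ``namespace``, ``is_obsolete`` and
    ``replaced_by``.  Unknown ``relationship:`` types (e.g. ``part_of``) are
    ignored with a logged warning.  A malformed stanza raises
    :class:`OboParseError` naming the offending line.
    """
    stanzas: list[dict] = []
    current: dict | None = None
    in_term = False
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.split("!", 1)[0].strip()
            if not line:
                continue
            if line.startswith("["):
                if not line.endswith("]"):
                    raise OboParseError(
                        f"{path}:{lineno}: malformed stanza header {raw.strip()!r}"
                    )
                in_term = line == "[Term]"
                if in_term:
                    current = {
                        "id": None,
                        "alt_ids": [],
                        "parents": [],
                        "namespace": None,
                        "obsolete": False,
                        "replaced_by": None,
                        "line": lineno,
                    }
                    stanzas.append(current)
                else:
                    current = None
                continue
            if not in_term or current is None:
                continue  # header or non-Term stanza content
            if ":" not in line:
                raise OboParseError(
                    f"{path}:{lineno}: malformed tag line {raw.strip()!r}"
                )
            tag, value = (part.strip() for part in line.split(":", 1))
            if tag == "id":
                current["id"] = value
            elif tag == "alt_id":
                current["alt_ids"].append(value)
            elif tag == "is_a":
                current["parents"].append(value.split()[0])
            elif tag == "namespace":
                current["namespace"] = value
            elif tag == "is_obsolete":
                current["obsolete"] = value.lower() == "true"
            elif tag == "replaced_by":
                current["replaced_by"] = value.split()[0]
            elif tag == "relationship":
                rel = value.split()[0] if value else ""
                if rel not in _KNOWN_RELATIONSHIPS:
                    logger.warning(
                        "%s:%d: ignoring relationship type %r", path, lineno, rel
                    )

    dag = GoDag()
    replaced: dict[str, str] = {}
    for st in stanzas:
        if st["id"] is None:
            raise OboParseError(
                f"{path}:{st['line']}: [Term] stanza without an id"
            )
        if st["obsolete"]:
            dag.obsolete.add(st["id"])
            if st["replaced_by"]:
                replaced[st["id"]] = st["replaced_by"]
            else:
                logger.warning(
                    "obsolete term %s has no replaced_by; dropped", st["id"]
                )
            continue
        term = st["id"]
        dag.terms.add(term)
        ns = st["namespace"]
        dag.namespace_of[term] = NAMESPACES.get(ns, ns or "MF")
        dag.parents_of[term] = set()
        for alt in st["alt_ids"]:
            dag.alt_id_map[alt] = term

    for st in stanzas:
        if st["obsolete"] or st["id"] is None:
            continue
        for parent in st["parents"]:
            if parent in dag.obsolete:
                logger.warning(
                    "term %s has obsolete parent %s; edge dropped",
                    st["id"], parent,
                )
                continue
            dag.parents_of[st["id"]].add(parent)

    # obsolete -> replacement, resolved through chains of replaced_by
    for old, new in replaced.items():
        seen = {old}
        while new in replaced and new not in seen:
            seen.add(new)
            new = replaced[new]
        if new in dag.terms:
            dag.alt_id_map[old] = new
        else:
            logger.warning(
                "replaced_by target %s of obsolete %s is not a live term", new, old
            )

    dag.validate()
    return dag


# ---------------------------------------------------------------------------
# module-level operations (thin wrappers over GoDag methods)
# ---------------------------------------------------------------------------

def ancestors(dag: GoDag, term: str) -> set[str]:
    """All transitive is-a ancestors of *term* (the term itself excluded)."""
    return dag.ancestors(term)


def descendants(dag: GoDag, term: str) -> set[str]:
    """All transitive is-a descendants of *term* (the term itself excluded)."""
    return dag.descendants(term)


def most_specific(dag: GoDag, terms: Iterable[str]) -> set[str]:
    """Drop every term that is an ancestor of another term in the set.

    The result is an antichain under the is-a partial order and a subset of
    the input.  Idempotent.
    """
    resolved = {dag._require(t) for t in terms}
    redundant: set[str] = set()
    for t in resolved:
        redundant |= dag.ancestors(t) & resolved
    return resolved - redundant


def up_propagate(
    dag: GoDag, seq_terms: Mapping[str, Iterable[str]]
) -> dict[str, int]:
    """Count, per term, the distinct sequences supporting it.

    A sequence supports term ``t`` if it is annotated with ``t`` or with any
    is-a descendant of ``t``; each sequence contributes at most once per term,
    so a downstream family probability ``count/N`` can never exceed 1.  Terms
    with a zero count are absent from the result.
    """
    counts: dict[str, int] = {}
    for _seq, terms in seq_terms.items():
        closure: set[str] = set()
        for t in terms:
            primary = dag._require(t)
            closure.add(primary)
            closure |= dag.ancestors(primary)
        for t in closure:
            counts[t] = counts.get(t, 0) + 1
    return counts
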