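"""Protein GO annotations: GAF parsing and the high-quality subset.

The quality rule keeps all non-IEA annotations (to SwissProt or TrEMBL
proteins alike) plus IEA annotations to SwissProt proteins produced by the
SwissProt Keyword2GO or EC2GO mappings, which translate manually curated
keyword/EC assignments into GO terms.  After filtering, each protein's term
set is reduced to its most specific terms (ancestors removed).

GAF files do not state UniProtKB review status, so the SwissProt/TrEMBL split
is supplied by a sidecar TSV (``protein_id<TAB>subset``); the mapping method
is read from the DB:Reference column matched against a configurable set of
GO_REF identifiers.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from funfams.ontology import GoDag, most_specific

logger = logging.getLogger(__name__)

#: GO_REF identifiers accepted as Keyword2GO / EC2GO provenance.  The GOA
#: release in use decides the exact identifiers; this default covers the
#: common ones and is overridable per call.
DEFAULT_CURATED_IEA_REFS = frozenset(
    {
        "GO_REF:0000003",  # EC2GO (ec2go)
        "GO_REF:0000004",  # SwissProt Keyword2GO (spkw2go)
        "GO_REF:0000037",  # UniProtKB keyword 2 GO (SwissProt entries)
        "GO_REF:0000038",
        "GOC:ec2go",
        "GOC:spkw2go",
    }
)


class GafParseError(ValueError):
    """Raised on a structurally invalid GAF line."""


@dataclass(frozen=True)
class AnnotationRecord:
    """One GO annotation line after parsing.

    ``db_subset`` is ``"SwissProt"``, ``"TrEMBL"`` or ``"unknown"``;
    ``mapping_source`` holds the DB:Reference field (e.g. a GO_REF identifier
    naming the Keyword2GO or EC2GO method for IEA lines).
    """

    protein_id: str
    term_id: str
    evidence_code: str
    db_subset: str = "unknown"
    mapping_source: str = ""

    def __post_init__(self):
        if not self.evidence_code:
            raise ValueError("evidence_code must be non-empty")


@dataclass
class AnnotationStore:
    """Per-protein most-specific GO term sets with retained provenance."""

    terms_of: dict[str, frozenset[str]] = field(default_factory=dict)
    records_of: dict[str, tuple[AnnotationRecord, ...]] = field(
        default_factory=dict
    )

    def terms(self, protein_id: str) -> frozenset[str]:
        return self.terms_of.get(protein_id, frozenset())

    def is_annotated(self, protein_id: str) -> bool:
        return bool(self.terms_of.get(protein_id))

    @property
    def proteins(self) -> set[str]:
        return set(self.terms_of)

    def __len__(self) -> int:
        return len(self.terms_of)


# ---------------------------------------------------------------------------
# GAF 2.x reader
# ---------------------------------------------------------------------------

_GAF_MIN_COLUMNS = 15


def parse_gaf(
    path, subset_of: dict[str, str] | None = None
) -> list[AnnotationRecord]:
    """Read a GAF 2.x file into :class:`AnnotationRecord` objects.

    Comment lines (``!``) are tolerated; lines qualified ``NOT`` are
    discarded.  Column 2 is the protein accession, column 5 the GO id,
    column 6 the DB:Reference (mapping source), column 7 the evidence code.
    *subset_of* optionally maps accessions to ``SwissProt``/``TrEMBL``.

    Raises :class:`GafParseError` with the line number on a line with fewer
    than 15 tab-separated columns.
    """
    subset_of = subset_of or {}
    records: list[AnnotationRecord] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            if not raw.strip() or raw.startswith("!"):
                continue
            cols = raw.rstrip("\n").split("\t")
            if len(cols) < _GAF_MIN_COLUMNS:
                raise GafParseError(
                    f"{path}:{lineno}: expected >= {_GAF_MIN_COLUMNS} "
                    f"tab-separated columns, got {len(cols)}"
                )
            qualifier = cols[3]
            if "NOT" in qualifier.split("|"):
                continue
            protein_id = cols[1]
            records.append(
                AnnotationRecord(
                    protein_id=protein_id,
                    term_id=cols[4],
                    evidence_code=cols[6],
                    db_subset=subset_of.get(protein_id, "unknown"),
                    mapping_source=cols[5],
                )
            )
    return records


def read_subset_tsv(path) -> dict[str, str]:
    """Read the sidecar review-status table: ``protein_id<TAB>subset``."""
    out: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        for row in csv.reader(fh, delimiter="\t"):
            if not row or row[0].startswith("#"):
                continue
            out[row[0]] = row[1]
    return out


def read_ec_tsv(path) -> dict[str, set[str]]:
    """Read the protein -> EC4 table: ``protein_id<TAB>EC4`` (one per line)."""
    out: dict[str, set[str]] = {}
    with open(path, encoding="utf-8") as fh:
        for row in csv.reader(fh, delimiter="\t"):
            if not row or row[0].startswith("#"):
                continue
            out.setdefault(row[0], set()).add(row[1])
    return out


# ---------------------------------------------------------------------------
# quality filter and store construction
# ---------------------------------------------------------------------------

def filter_high_quality(
    records: Sequence[AnnotationRecord],
    curated_iea_refs: Iterable[str] = DEFAULT_CURATED_IEA_REFS,
) -> list[AnnotationRecord]:
    """Keep high-quality annotations.

    A record is kept iff its evidence is non-IEA, or it is IEA on a SwissProt
    protein with a Keyword2GO/EC2GO mapping source.  Unknown review status is
    treated as TrEMBL (conservative).  Pure filter: output is an
    order-preserving subset of the input; idempotent.
    """
    refs = frozenset(curated_iea_refs)
    kept = []
    for rec in records:
        if rec.evidence_code != "IEA":
            kept.append(rec)
        elif rec.db_subset == "SwissProt" and rec.mapping_source in refs:
            kept.append(rec)
    return kept


def build_store(
    records: Sequence[AnnotationRecord], dag: GoDag
) -> AnnotationStore:
    """Group quality-filtered records per protein and reduce to most-specific.

    Terms are resolved through alternate ids; records whose term cannot be
    resolved in *dag* are dropped with a warning.  Reduction is applied
    jointly over the protein's whole term set — is-a ancestry only exists
    within a namespace, so terms of different namespaces never remove each
    other.
    """
    per_protein: dict[str, set[str]] = {}
    per_protein_records: dict[str, list[AnnotationRecord]] = {}
    for rec in records:
        primary = dag.resolve(rec.term_id)
        if primary is None:
            logger.warning(
                "dropping annotation of %s to unresolvable term %s",
                rec.protein_id, rec.term_id,
            )
            continue
        per_protein.setdefault(rec.protein_id, set()).add(primary)
        per_protein_records.setdefault(rec.protein_id, []).append(rec)

    store = AnnotationStore()
    for protein, terms in per_protein.items():
        reduced = most_specific(dag, terms)
        if reduced:
            store.terms_of[protein] = frozenset(reduced)
            store.records_of[protein] = tuple(per_protein_records[protein])
    return store
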