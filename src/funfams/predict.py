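"""Whole-protein GO prediction from per-domain family assignments.

Each identified domain of a target protein is scanned against the family
model library of its superfamily (HMMER3 pipeline, default reporting
thresholds).  Only the top-scoring model (bit score; ties broken
lexicographically by family id) contributes: the query inherits the full
term-probability map of that family.  Whole-protein integration takes the
per-term maximum over the protein's domains — an idempotent, commutative,
associative combination, so domain order never matters.  A domain whose
scan reports no model at all contributes nothing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pyhmmer

from funfams.clustering import DomainSequence
from funfams.families import FunFam

_ALPHABET = pyhmmer.easel.Alphabet.amino()


@dataclass(frozen=True)
class DomainHit:
    target_domain_id: str
    funfam_id: str
    bit_score: float


@dataclass
class ProteinPrediction:
    protein_id: str
    term_scores: dict[str, float] = field(default_factory=dict)


class ModelLibrary:
    """The scannable family models of one superfamily."""

    def __init__(self, families: Sequence[FunFam]):
        self.families = {f.funfam_id: f for f in families}
        self._hmms = [
            f.model.hmm
            for f in sorted(families, key=lambda f: f.funfam_id)
            if f.model is not None
        ]
        if not self._hmms:
            raise ValueError("model library is empty")

    def __len__(self) -> int:
        return len(self._hmms)

    @property
    def hmms(self) -> list[pyhmmer.plan7.HMM]:
        return self._hmms


def scan_domain(
    domain_seq: DomainSequence,
    library: ModelLibrary,
    report_e: float = 10.0,
    bit_floor: float | None = None,
) -> list[DomainHit]:
    """Scan one domain sequence against a family model library.

    Returns hits sorted by descending bit score (ties by funfam_id).
    *report_e* is the scanner's reporting threshold (hmmscan default 10);
    *bit_floor* optionally discards weaker hits, separating "not hit at all"
    from "not well enough for an assignment".
    """
    query = pyhmmer.easel.TextSequence(
        name=domain_seq.seq_id.encode(), sequence=domain_seq.residues
    ).digitize(_ALPHABET)
    (top_hits,) = pyhmmer.hmmer.hmmscan(
        [query], library.hmms, cpus=1, E=report_e
    )
    hits = [
        DomainHit(
            target_domain_id=domain_seq.seq_id,
            funfam_id=(
                hit.name.decode() if isinstance(hit.name, bytes) else hit.name
            ),
            bit_score=hit.score,
        )
        for hit in top_hits
        if hit.reported and (bit_floor is None or hit.score >= bit_floor)
    ]
    hits.sort(key=lambda h: (-h.bit_score, h.funfam_id))
    return hits


def assign_terms(
    top_hit: DomainHit, families: Mapping[str, FunFam]
) -> dict[str, float]:
    """Copy the hit family's term-probability map onto the query domain."""
    if top_hit.funfam_id not in families:
        raise KeyError(f"unknown family id {top_hit.funfam_id!r}")
    return dict(families[top_hit.funfam_id].term_probs)


def integrate(
    protein_id: str, domain_maps: Iterable[Mapping[str, float]]
) -> ProteinPrediction:
    """Per-term maximum over the protein's domain term maps."""
    scores: dict[str, float] = {}
    for mapping in domain_maps:
        for term, p in mapping.items():
            if p > scores.get(term, 0.0):
                scores[term] = p
    return ProteinPrediction(protein_id=protein_id, term_scores=scores)


def predict_protein(
    protein_id: str,
    domains: Sequence[DomainSequence],
    libraries: Mapping[str, ModelLibrary],
    report_e: float = 10.0,
    bit_floor: float | None = None,
) -> ProteinPrediction:
    """Full per-protein pipeline: scan each domain, take the top hit, integrate.

    Domains in superfamilies without a library, or without any reported hit,
    contribute nothing.
    """
    maps: list[dict[str, float]] = []
    for domain in domains:
        library = libraries.get(domain.superfamily_id)
        if library is None:
            continue
        hits = scan_domain(domain, library, report_e=report_e, bit_floor=bit_floor)
        if not hits:
            continue
        maps.append(assign_terms(hits[0], library.families))
    return integrate(protein_id, maps)


def read_domain_assignments(path) -> dict[str, list[tuple[str, str, int, int]]]:
    """Read the target domain table.

    Format: ``protein_id<TAB>domain_id<TAB>superfamily_id<TAB>start<TAB>end``
    with 1-based inclusive coordinates.  Returns protein -> list of
    (domain_id, superfamily_id, start, end).
    """
    out: dict[str, list[tuple[str, str, int, int]]] = {}
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            protein, domain, sf, start, end = line.split("\t")
            out.setdefault(protein, []).append((domain, sf, int(start), int(end)))
    return out


def write_predictions_tsv(
    path, predictions: Sequence[ProteinPrediction], decimals: int = 2
) -> None:
    """CAFA-style output: ``protein_id<TAB>go_id<TAB>score`` (rounded)."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("protein_id\tgo_id\tscore\n")
        for pred in predictions:
            for term in sorted(pred.term_scores):
                fh.write(
                    f"{pred.protein_id}\t{term}\t"
                    f"{pred.term_scores[term]:.{decimals}f}\n"
                )
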