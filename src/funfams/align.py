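"""Pairwise global alignment and a deterministic center-star multiple aligner.

Pairwise alignments use BLOSUM62 with affine gap penalties (open 11,
extend 1), the standard protein global-alignment parameterisation.  Percent
identity is defined as identical aligned residue pairs divided by the number
of alignment columns, so terminal gaps count against identity.
"""

from __future__ import annotations

from Bio import Align
from Bio.Align import substitution_matrices


def make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11.0
    aligner.extend_gap_score = -1.0
    return aligner


_ALIGNER = make_aligner()


def align_pair(a: str, b: str) -> tuple[str, str]:
    """Globally align two sequences; return the gapped strings.

    Biopython enumerates co-optimal alignments in a fixed order, so taking
    the first one keeps results deterministic.
    """
    alignment = _ALIGNER.align(a, b)[0]
    return str(alignment[0]), str(alignment[1])


def percent_identity(a: str, b: str) -> float:
    """Identity fraction over alignment columns of the global alignment."""
    ga, gb = align_pair(a, b)
    matches = sum(1 for x, y in zip(ga, gb) if x == y and x != "-")
    return matches / len(ga) if ga else 0.0


class IdentityCache:
    """Memoised percent identity keyed by sequence-id pairs."""

    def __init__(self, residues_of: dict[str, str]):
        self._residues = residues_of
        self._cache: dict[tuple[str, str], float] = {}

    def __call__(self, id_a: str, id_b: str) -> float:
        key = (id_a, id_b) if id_a <= id_b else (id_b, id_a)
        hit = self._cache.get(key)
        if hit is None:
            hit = percent_identity(self._residues[key[0]], self._residues[key[1]])
            self._cache[key] = hit
        return hit


def center_star_align(sequences: dict[str, str]) -> dict[str, str]:
    """Deterministic center-star multiple alignment.

    The center is the longest sequence (ties broken by lexicographically
    smallest id); every other sequence is aligned to the center pairwise and
    the pairwise alignments are merged on the center's coordinates, taking
    the union of gap columns.  Adequate for profile construction over
    families of closely related domain sequences; not a substitute for a
    progressive aligner on deeply diverged inputs.
    """
    if not sequences:
        raise ValueError("no sequences to align")
    ids = sorted(sequences, key=lambda i: (-len(sequences[i]), i))
    center_id = ids[0]
    center = sequences[center_id]
    if len(ids) == 1:
        return {center_id: center}

    # master center row with gaps accumulated across merges
    master_center = center
    rows: dict[str, str] = {}

    for sid in ids[1:]:
        ca, sa = align_pair(center, sequences[sid])
        master_center, rows, new_row = _merge_onto_center(
            master_center, rows, ca, sa
        )
        rows[sid] = new_row
    rows[center_id] = master_center
    return {sid: rows[sid] for sid in sorted(rows)}


def _merge_onto_center(
    master: str, rows: dict[str, str], ca: str, sa: str
) -> tuple[str, dict[str, str], str]:
    """Merge one pairwise alignment (center row *ca*) into the master MSA."""
    merged_master: list[str] = []
    merged_rows: dict[str, list[str]] = {k: [] for k in rows}
    merged_new: list[str] = []
    i = j = 0  # i over master, j over ca
    while i < len(master) or j < len(ca):
        m_gap = i < len(master) and master[i] == "-"
        c_gap = j < len(ca) and ca[j] == "-"
        if i < len(master) and j < len(ca) and not m_gap and not c_gap:
            merged_master.append(master[i])
            for k in rows:
                merged_rows[k].append(rows[k][i])
            merged_new.append(sa[j])
            i += 1
            j += 1
        elif m_gap:
            merged_master.append("-")
            for k in rows:
                merged_rows[k].append(rows[k][i])
            merged_new.append("-")
            i += 1
        else:  # gap in ca (insertion in the new sequence) or ca exhausted
            merged_master.append("-")
            for k in rows:
                merged_rows[k].append("-")
            merged_new.append(sa[j])
            j += 1
    return (
        "".join(merged_master),
        {k: "".join(v) for k, v in merged_rows.items()},
        "".join(merged_new),
    )
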