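"""Functional-family models and probabilistic GO-term association.

Each selected family gets a profile HMM built from a multiple alignment of
its member domain sequences (HMMER3 via pyhmmer, so model construction and
scoring behave exactly like ``hmmbuild``/``hmmscan``).  The alignment step
defaults to the built-in deterministic center-star aligner; a MAFFT adapter
using the high-quality flags ``--amino --localpair --maxiterate 1000`` can
be selected when the external tool is available.  Model scores are used for
RANKING candidate families only, never as calibrated absolute values.

Function association counts, for every GO term, how many distinct member
sequences support it (directly or through a more specific descendant, via
up-propagation in the DAG) and divides by the family size N, yielding a
per-term probability p = T/N in (0, 1].  The probabilities are deliberately
not normalised into a distribution: one family may carry several functions
each supported by most members.
"""

from __future__ import annotations

import logging
import shutil
import subprocess
import tempfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pyhmmer

from funfams.align import center_star_align
from funfams.annotations import AnnotationStore
from funfams.clustering import DomainSequence, write_domain_fasta
from funfams.coherence import PrunedFamily
from funfams.ontology import GoDag, up_propagate

logger = logging.getLogger(__name__)

_ALPHABET = pyhmmer.easel.Alphabet.amino()

MAFFT_FLAGS = ("--amino", "--localpair", "--maxiterate", "1000")


class ExternalToolError(RuntimeError):
    """A configured external tool is missing or failed."""


@dataclass
class ProfileModel:
    """Opaque handle around a profile HMM and the alignment it came from."""

    name: str
    hmm: pyhmmer.plan7.HMM
    alignment: dict[str, str]

    @property
    def length(self) -> int:
        return self.hmm.M


@dataclass
class FunFam:
    """A functional family: members, scannable model, term probabilities."""

    funfam_id: str
    superfamily_id: str
    members: tuple[str, ...]
    model: ProfileModel | None = None
    term_probs: dict[str, float] = field(default_factory=dict)
    incoherent_leaf: bool = False

    @property
    def n(self) -> int:
        return len(self.members)


# ---------------------------------------------------------------------------
# alignment backends
# ---------------------------------------------------------------------------

def _align_builtin(members: Sequence[DomainSequence]) -> dict[str, str]:
    return center_star_align({s.seq_id: s.residues for s in members})


def _align_mafft(members: Sequence[DomainSequence]) -> dict[str, str]:
    if shutil.which("mafft") is None:
        raise ExternalToolError("external aligner 'mafft' not found on PATH")
    with tempfile.TemporaryDirectory() as tmp:
        fasta = Path(tmp) / "members.fa"
        write_domain_fasta(fasta, members)
        proc = subprocess.run(
            ["mafft", *MAFFT_FLAGS, str(fasta)],
            capture_output=True,
            text=True,
        )
        if proc.returncode != 0:
            raise ExternalToolError(f"mafft failed: {proc.stderr.strip()}")
    rows: dict[str, str] = {}
    current = None
    for line in proc.stdout.splitlines():
        if line.startswith(">"):
            current = line[1:].split("|")[0].strip()
            rows[current] = ""
        elif current is not None:
            rows[current] += line.strip()
    return rows


ALIGNERS = {"builtin": _align_builtin, "mafft": _align_mafft}


# ---------------------------------------------------------------------------
# model construction
# ---------------------------------------------------------------------------

def build_model(
    members: Sequence[DomainSequence],
    name: str = "family",
    aligner: str = "builtin",
) -> ProfileModel:
    """Align the member sequences and build a profile HMM.

    A single-member family is modelled directly from its one sequence.
    HMMER applies its usual position-based (Henikoff) sequence weighting
    when building from the alignment.
    """
    if not members:
        raise ValueError("cannot build a model from zero sequences")
    builder = pyhmmer.plan7.Builder(_ALPHABET)
    background = pyhmmer.plan7.Background(_ALPHABET)
    if len(members) == 1:
        seq = members[0]
        digital = pyhmmer.easel.TextSequence(
            name=seq.seq_id.encode(), sequence=seq.residues
        ).digitize(_ALPHABET)
        hmm, _, _ = builder.build(digital, background)
        alignment = {seq.seq_id: seq.residues}
    else:
        alignment = ALIGNERS[aligner](members)
        msa = pyhmmer.easel.TextMSA(
            name=name.encode(),
            sequences=[
                pyhmmer.easel.TextSequence(
                    name=sid.encode(), sequence=alignment[sid]
                )
                for sid in sorted(alignment)
            ],
        )
        hmm, _, _ = builder.build_msa(msa.digitize(_ALPHABET), background)
    hmm.name = name.encode()
    return ProfileModel(name=name, hmm=hmm, alignment=alignment)


def write_stockholm(path, model: ProfileModel) -> None:
    """Export the model's alignment in Stockholm format."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("# STOCKHOLM 1.0\n")
        width = max(len(sid) for sid in model.alignment) + 2
        for sid in sorted(model.alignment):
            fh.write(f"{sid:<{width}}{model.alignment[sid]}\n")
        fh.write("//\n")


# ---------------------------------------------------------------------------
# function association
# ---------------------------------------------------------------------------

def associate_functions(
    family: FunFam,
    seqs_by_id: Mapping[str, DomainSequence],
    store: AnnotationStore,
    dag: GoDag,
) -> dict[str, float]:
    """Associate the family with GO terms, each with probability T/N.

    T counts distinct member sequences supporting the term after
    up-propagation; N is the total number of member domains, annotated or
    not.  Members sharing a parent protein count separately (T is a domain
    count).  Returns the mapping and stores it on the family.
    """
    seq_terms = {
        sid: store.terms(seqs_by_id[sid].parent_protein_id)
        for sid in family.members
    }
    if not any(seq_terms.values()):
        logger.warning(
            "family %s has no annotated members; empty term map",
            family.funfam_id,
        )
        family.term_probs = {}
        return {}
    counts = up_propagate(dag, seq_terms)
    n = family.n
    family.term_probs = {t: c / n for t, c in counts.items()}
    return family.term_probs


def build_funfams(
    pruned: Sequence[PrunedFamily],
    seqs_by_id: Mapping[str, DomainSequence],
    store: AnnotationStore,
    dag: GoDag,
    superfamily_id: str,
    with_models: bool = True,
    aligner: str = "builtin",
) -> list[FunFam]:
    """Turn pruned dendrogram roots into fully populated :class:`FunFam`s."""
    families: list[FunFam] = []
    for idx, fam in enumerate(pruned, start=1):
        funfam_id = f"{superfamily_id}-FF{idx:04d}"
        members = tuple(sorted(fam.members))
        funfam = FunFam(
            funfam_id=funfam_id,
            superfamily_id=superfamily_id,
            members=members,
            incoherent_leaf=fam.incoherent_leaf,
        )
        if with_models:
            funfam.model = build_model(
                [seqs_by_id[m] for m in members],
                name=funfam_id,
                aligner=aligner,
            )
        associate_functions(funfam, seqs_by_id, store, dag)
        families.append(funfam)
    return families


def write_term_probs_tsv(path, families: Sequence[FunFam]) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("funfam_id\tgo_id\tp\n")
        for fam in families:
            for term in sorted(fam.term_probs):
                fh.write(f"{fam.funfam_id}\t{term}\t{fam.term_probs[term]:.6f}\n")
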