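"""Self-contained synthetic fixtures: mini ontologies, superfamilies, annotations.

The generator emulates the study conditions of the family-identification
protocol at desk scale: a superfamily composed of ground-truth functional
families of point-mutated sequences, parent proteins with partially missing
annotations, loss of annotation specificity (a protein annotated with an
ancestor instead of the family's leaf term), ancillary "extra" terms
co-annotated with the core function, foreign-domain terms contributed by
other domains of the parent protein, and four-digit EC labels per family.

Every operation is deterministic under a fixed seed (one integer-seeded
numpy generator, no hash-order dependence).  Mutations never touch a
10-residue family-specific motif, so within-family identity always exceeds
between-family identity even for short sequences.  Substitutions only — no
indels — which keeps alignments trivial and is the main respect in which
these fixtures are easier than real superfamilies.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np

from funfams.clustering import DomainSequence, write_domain_fasta
from funfams.ontology import GoDag

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

MOTIF_START = 5  # 0-based; motif occupies [MOTIF_START, MOTIF_START + 10)
MOTIF_LEN = 10


@dataclass(frozen=True)
class SynthConfig:
    """Generator settings; defaults are the study conditions of the tests."""

    seed: int = 0
    n_families: int = 4
    seqs_per_family: int = 6
    seq_length: int = 120
    within_family_mutation_rate: float = 0.05
    between_family_divergence: float = 0.5
    annotation_completeness: float = 1.0
    extra_term_rate: float = 0.0
    foreign_term_rate: float = 0.0
    specificity_loss_rate: float = 0.0
    dag_depth: int = 3
    dag_branching: int = 2
    superfamily_id: str = "SF1"

    def __post_init__(self):
        rates = {
            "within_family_mutation_rate": self.within_family_mutation_rate,
            "between_family_divergence": self.between_family_divergence,
            "annotation_completeness": self.annotation_completeness,
            "extra_term_rate": self.extra_term_rate,
            "foreign_term_rate": self.foreign_term_rate,
            "specificity_loss_rate": self.specificity_loss_rate,
        }
        for name, value in rates.items():
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {value}")
        if self.within_family_mutation_rate >= self.between_family_divergence:
            raise ValueError(
                "within-family mutation rate must be below between-family "
                "divergence"
            )
        if self.seq_length < MOTIF_START + MOTIF_LEN:
            raise ValueError("sequences too short to carry the family motif")


# ---------------------------------------------------------------------------
# ontology
# ---------------------------------------------------------------------------

def make_dag(config: SynthConfig) -> GoDag:
    """Complete b-ary is-a tree per namespace, rooted, depth ``dag_depth``.

    Term ids are ``GO:<d><nnnnnn>`` with a namespace-specific leading digit;
    node count per namespace is the branching sum ``sum(b**i, i=0..depth)``.
    """
    dag = GoDag()
    for ns_digit, ns in ((1, "MF"), (2, "BP"), (3, "CC")):
        counter = 0

        def new_term():
            nonlocal counter
            counter += 1
            return f"GO:{ns_digit}{counter:06d}"

        root = new_term()
        dag.terms.add(root)
        dag.namespace_of[root] = ns
        dag.parents_of[root] = set()
        level = [root]
        for _ in range(config.dag_depth):
            nxt = []
            for parent in level:
                for _ in range(config.dag_branching):
                    child = new_term()
                    dag.terms.add(child)
                    dag.namespace_of[child] = ns
                    dag.parents_of[child] = {parent}
                    nxt.append(child)
            level = nxt
    dag.validate()
    return dag


def namespace_leaves(dag: GoDag, namespace: str) -> list[str]:
    """Terms of *namespace* with no children, sorted."""
    with_children = set()
    for parents in dag.parents_of.values():
        with_children |= parents
    return sorted(
        t
        for t in dag.terms
        if dag.namespace_of[t] == namespace and t not in with_children
    )


def write_obo(path, dag: GoDag) -> None:
    ns_long = {
        "MF": "molecular_function",
        "BP": "biological_process",
        "CC": "cellular_component",
    }
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("format-version: 1.2\n\n")
        for term in sorted(dag.terms):
            fh.write("[Term]\n")
            fh.write(f"id: {term}\n")
            fh.write(f"name: synthetic term {term}\n")
            fh.write(f"namespace: {ns_long[dag.namespace_of[term]]}\n")
            for parent in sorted(dag.parents_of.get(term, ())):
                fh.write(f"is_a: {parent}\n")
            fh.write("\n")


# ---------------------------------------------------------------------------
# sequences
# ---------------------------------------------------------------------------

def _random_sequence(rng: np.random.Generator, length: int) -> list[str]:
    return [AMINO_ACIDS[i] for i in rng.integers(0, len(AMINO_ACIDS), length)]


def _mutate(
    rng: np.random.Generator,
    residues: list[str],
    rate: float,
    protected: range,
) -> list[str]:
    out = list(residues)
    for pos in range(len(out)):
        if pos in protected:
            continue
        if rng.random() < rate:
            choices = [a for a in AMINO_ACIDS if a != out[pos]]
            out[pos] = choices[rng.integers(0, len(choices))]
    return out


def make_superfamily(
    config: SynthConfig,
) -> tuple[list[DomainSequence], dict[str, int]]:
    """Generate a superfamily with ground-truth family labels.

    One ancestral sequence per family (derived from a shared root sequence
    at the between-family divergence rate, plus a family-unique motif);
    members are point-mutated copies at the within-family rate.  One parent
    protein per domain sequence.  Returns (sequences, seq_id -> family idx).
    """
    rng = np.random.default_rng(config.seed)
    motif_range = range(MOTIF_START, MOTIF_START + MOTIF_LEN)
    root = _random_sequence(rng, config.seq_length)
    seqs: list[DomainSequence] = []
    truth: dict[str, int] = {}
    for fam in range(config.n_families):
        ancestor = _mutate(
            rng, root, config.between_family_divergence, motif_range
        )
        motif = _random_sequence(rng, MOTIF_LEN)
        for i, pos in enumerate(motif_range):
            ancestor[pos] = motif[i]
        for member in range(config.seqs_per_family):
            residues = _mutate(
                rng, ancestor, config.within_family_mutation_rate, motif_range
            )
            seq_id = f"F{fam:02d}S{member:02d}"
            seqs.append(
                DomainSequence(
                    seq_id=seq_id,
                    parent_protein_id=f"P_{seq_id}",
                    superfamily_id=config.superfamily_id,
                    residues="".join(residues),
                    segments=((1, config.seq_length),),
                )
            )
            truth[seq_id] = fam
    return seqs, truth


# ---------------------------------------------------------------------------
# annotations
# ---------------------------------------------------------------------------

_GAF_TEMPLATE = (
    "UniProtKB\t{protein}\t{protein}\t\t{term}\t{ref}\t{evidence}\t\t"
    "{aspect}\tsynthetic protein\t\tprotein\ttaxon:0\t20100924\tSynth\t\t"
)


def make_annotations(
    config: SynthConfig,
    truth: dict[str, int],
    dag: GoDag,
) -> dict:
    """Generate GAF lines, the review-status sidecar and EC labels.

    Each family maps to a distinct MF leaf term; a protein receives its
    family term with probability ``annotation_completeness``, degraded to a
    random proper ancestor with probability ``specificity_loss_rate``.
    Extra (family-linked ancillary) and foreign (other-domain) MF leaf terms
    are added at their configured rates.  EC4 labels (one per family) go to
    every protein.  Returns a dict with ``gaf_lines``, ``subset_of``,
    ``ec_of``, ``family_term`` and ``annotated`` (protein -> bool).
    """
    rng = np.random.default_rng(config.seed + 1)
    leaves = namespace_leaves(dag, "MF")
    if len(leaves) < config.n_families:
        raise ValueError(
            f"need >= {config.n_families} MF leaves, DAG has {len(leaves)}"
        )
    family_term = {
        fam: leaves[fam % len(leaves)] for fam in range(config.n_families)
    }
    extra_term = {
        fam: leaves[(fam + config.n_families) % len(leaves)]
        for fam in range(config.n_families)
    }

    gaf_lines: list[str] = []
    subset_of: dict[str, str] = {}
    ec_of: dict[str, set[str]] = {}
    annotated: dict[str, bool] = {}

    def emit(protein: str, term: str, evidence="IDA", ref="PMID:0000001"):
        aspect = {"MF": "F", "BP": "P", "CC": "C"}[dag.namespace_of[term]]
        gaf_lines.append(
            _GAF_TEMPLATE.format(
                protein=protein, term=term, ref=ref,
                evidence=evidence, aspect=aspect,
            )
        )

    for seq_id in sorted(truth):
        fam = truth[seq_id]
        protein = f"P_{seq_id}"
        subset_of[protein] = "SwissProt"
        ec_of[protein] = {f"1.1.1.{fam + 1}"}
        got_any = False
        if rng.random() < config.annotation_completeness:
            term = family_term[fam]
            if rng.random() < config.specificity_loss_rate:
                above = sorted(dag.ancestors(term))
                non_root = [t for t in above if dag.parents_of.get(t)]
                pool = non_root or above
                term = pool[rng.integers(0, len(pool))]
            emit(protein, term)
            got_any = True
        if rng.random() < config.extra_term_rate:
            emit(protein, extra_term[fam])
            got_any = True
        if rng.random() < config.foreign_term_rate:
            pool = [t for t in leaves if t != family_term[fam]]
            emit(protein, pool[rng.integers(0, len(pool))])
            got_any = True
        annotated[protein] = got_any

    return {
        "gaf_lines": gaf_lines,
        "subset_of": subset_of,
        "ec_of": ec_of,
        "family_term": family_term,
        "annotated": annotated,
    }


# ---------------------------------------------------------------------------
# fixture directory
# ---------------------------------------------------------------------------

def write_fixture(config: SynthConfig, outdir) -> dict[str, Path]:
    """Write a complete fixture directory: OBO, GAF, FASTA, TSVs, truth JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    dag = make_dag(config)
    seqs, truth = make_superfamily(config)
    ann = make_annotations(config, truth, dag)

    paths = {
        "obo": outdir / "ontology.obo",
        "fasta": outdir / "domains.fa",
        "gaf": outdir / "annotations.gaf",
        "subset": outdir / "subset.tsv",
        "ec": outdir / "ec.tsv",
        "truth": outdir / "truth.json",
    }
    write_obo(paths["obo"], dag)
    write_domain_fasta(paths["fasta"], seqs)
    with open(paths["gaf"], "w", encoding="utf-8") as fh:
        fh.write("!gaf-version: 2.0\n")
        fh.write("\n".join(ann["gaf_lines"]))
        if ann["gaf_lines"]:
            fh.write("\n")
    with open(paths["subset"], "w", encoding="utf-8") as fh:
        for protein in sorted(ann["subset_of"]):
            fh.write(f"{protein}\t{ann['subset_of'][protein]}\n")
    with open(paths["ec"], "w", encoding="utf-8") as fh:
        for protein in sorted(ann["ec_of"]):
            for ec in sorted(ann["ec_of"][protein]):
                fh.write(f"{protein}\t{ec}\n")
    with open(paths["truth"], "w", encoding="utf-8") as fh:
        json.dump(
            {
                "config": asdict(config),
                "labels": truth,
                "family_term": {
                    str(k): v for k, v in ann["family_term"].items()
                },
            },
            fh,
            indent=2,
            sort_keys=True,
        )
        fh.write("\n")
    return paths
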