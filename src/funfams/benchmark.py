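"""EC4-based quality score for superfamily partitionings.

For one partitioning, *diversity* is the mean number of distinct four-digit
EC numbers per family (a specificity measure — pure families score 1) and
*division* is the mean number of families per EC4 (a sensitivity measure —
unsplit functions score 1).  The raw score is the arithmetic mean of the
two; its floor is 1.0, attained when every family carries exactly one EC4
and every EC4 lives in exactly one family.  Averaging raw scores over
superfamilies gives the average performance (AP); lower is better.

Families without any EC4-labelled member are excluded from the diversity
average, and partial EC numbers (e.g. ``1.1.1.-``) are ignored.  A
superfamily qualifies for benchmarking only with at least two distinct EC4s.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from statistics import mean, quantiles
from typing import Mapping, Sequence

_EC4_RE = re.compile(r"^\d+\.\d+\.\d+\.(n?\d+)$")


def is_complete_ec4(ec: str) -> bool:
    return bool(_EC4_RE.match(ec))


@dataclass(frozen=True)
class EcScore:
    diversity: float
    division: float
    raw: float
    n_families_scored: int
    n_ec4s: int


def score_partition(
    family_of: Mapping[str, str],
    ec_map: Mapping[str, set[str]],
    protein_of: Mapping[str, str],
) -> EcScore:
    """Score one partitioning of domain sequences into families.

    *family_of* maps sequence id -> family id; *ec_map* maps protein -> set
    of EC strings; *protein_of* maps sequence id -> parent protein.
    """
    fam_ecs: dict[str, set[str]] = {}
    ec_fams: dict[str, set[str]] = {}
    for seq_id, fam_id in family_of.items():
        ecs = {
            ec
            for ec in ec_map.get(protein_of[seq_id], set())
            if is_complete_ec4(ec)
        }
        if not ecs:
            continue
        fam_ecs.setdefault(fam_id, set()).update(ecs)
        for ec in ecs:
            ec_fams.setdefault(ec, set()).add(fam_id)

    if not fam_ecs:
        raise ValueError("no EC4-labelled sequences in the partitioning")

    diversity = mean(len(ecs) for ecs in fam_ecs.values())
    division = mean(len(fams) for fams in ec_fams.values())
    return EcScore(
        diversity=diversity,
        division=division,
        raw=(diversity + division) / 2.0,
        n_families_scored=len(fam_ecs),
        n_ec4s=len(ec_fams),
    )


@dataclass(frozen=True)
class ApSummary:
    ap: float
    minimum: float
    q1: float
    median: float
    q3: float
    maximum: float
    n_superfamilies: int


def average_performance(scores: Sequence[EcScore]) -> ApSummary:
    """Mean raw score over superfamilies, with box-plot summary statistics."""
    if not scores:
        raise ValueError("no superfamily scores to average")
    raws = sorted(s.raw for s in scores)
    if len(raws) >= 2:
        q1, med, q3 = quantiles(raws, n=4, method="inclusive")
    else:
        q1 = med = q3 = raws[0]
    return ApSummary(
        ap=mean(raws),
        minimum=raws[0],
        q1=q1,
        median=med,
        q3=q3,
        maximum=raws[-1],
        n_superfamilies=len(raws),
    )


def top_score_shares(
    raw_by_method: Mapping[str, Sequence[float]]
) -> dict[str, float]:
    """Fraction of superfamilies where each method attains or shares the best
    (lowest) raw score — the bar-chart comparison layout for competing
    partitionings.  All sequences of raw scores must be index-aligned over
    the same superfamilies.
    """
    methods = list(raw_by_method)
    lengths = {len(v) for v in raw_by_method.values()}
    if len(lengths) != 1:
        raise ValueError("methods must be scored on the same superfamilies")
    (n,) = lengths
    if n == 0:
        raise ValueError("no superfamilies")
    wins = {m: 0 for m in methods}
    for i in range(n):
        best = min(raw_by_method[m][i] for m in methods)
        for m in methods:
            if raw_by_method[m][i] == best:
                wins[m] += 1
    return {m: wins[m] / n for m in methods}
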