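"""Per-patient candidate ranking and the rank coverage score.

The rank coverage score rewards orderings that place experimentally
positive candidates ahead of negatives:

    score = sum_{n in neg} rank(n) / (T * num(neg)) * coverage(neg)
          - sum_{p in pos} rank(p) / (T * num(pos)) * coverage(pos)

with coverage(group) = max rank within the group / T, applied as a
group-level constant. Higher is better. An element-level variant
(coverage computed per element as rank(k)/T) is available for
sensitivity checks.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import math

from .errors import DegenerateInputError, EmptyInputError, ValidationError

POSITIVE = "positive"
NEGATIVE = "negative"


@dataclass
class RankedEntry:
    candidate: str
    rank: int
    score: float
    top_k: bool = False
    validation_label: str | None = None


@dataclass
class RankedCandidateList:
    patient_id: str
    method: str
    entries: list[RankedEntry] = field(default_factory=list)

    def __post_init__(self) -> None:
        ranks = sorted(e.rank for e in self.entries)
        if ranks != list(range(1, len(self.entries) + 1)):
            raise ValidationError("ranks must be a permutation of 1..T")

    @property
    def total(self) -> int:
        return len(self.entries)

    def labeled_pairs(self) -> list[tuple[int, str]]:
        pairs = []
        for e in self.entries:
            if e.validation_label not in (POSITIVE, NEGATIVE):
                raise ValidationError(
                    f"entry {e.candidate!r} lacks a validation label"
                )
            pairs.append((e.rank, e.validation_label))
        return pairs


@dataclass
class PrioritizationConfig:
    top_k: int = 3

    def __post_init__(self) -> None:
        if self.top_k < 1:
            raise ValidationError("top_k must be >= 1")


def rank_candidates(
    scored: Mapping[str, float],
    direction: str,
    config: PrioritizationConfig | None = None,
    patient_id: str = "",
    method: str = "",
    secondary: Mapping[str, float] | None = None,
    labels: Mapping[str, str] | None = None,
) -> RankedCandidateList:
    """Order candidates by score; ties break by secondary score then key.

    ``direction`` is ``"lower_better"`` or ``"higher_better"``. The first
    ``top_k`` entries are flagged.
    """
    if direction not in ("lower_better", "higher_better"):
        raise ValidationError(f"unknown direction: {direction!r}")
    if not scored:
        raise EmptyInputError("no candidates to rank")
    for cand, value in scored.items():
        if not math.isfinite(value):
            raise ValidationError(f"non-finite score for {cand!r}: {value!r}")
    config = config or PrioritizationConfig()

    sign = 1.0 if direction == "lower_better" else -1.0

    def sort_key(cand: str):
        keys = [sign * scored[cand]]
        if secondary is not None:
            keys.append(sign * secondary.get(cand, 0.0))
        keys.append(cand)
        return tuple(keys)

    ordered = sorted(scored, key=sort_key)
    entries = [
        RankedEntry(
            candidate=cand,
            rank=i + 1,
            score=scored[cand],
            top_k=i < config.top_k,
            validation_label=labels.get(cand) if labels else None,
        )
        for i, cand in enumerate(ordered)
    ]
    return RankedCandidateList(patient_id=patient_id, method=method, entries=entries)


def _score_from_rank_labels(
    pairs: Sequence[tuple[int, str]], total: int, variant: str = "group"
) -> float:
    """Core rank coverage computation on (rank, label) pairs."""
    pos = [r for r, lab in pairs if lab == POSITIVE]
    neg = [r for r, lab in pairs if lab == NEGATIVE]
    if not pos or not neg:
        raise DegenerateInputError(
            "rank coverage requires both positive and negative entries"
        )
    if variant == "group":
        cov_pos = max(pos) / total
        cov_neg = max(neg) / total
        neg_term = sum(r / (total * len(neg)) for r in neg) * cov_neg
        pos_term = sum(r / (total * len(pos)) for r in pos) * cov_pos
    elif variant == "element":
        neg_term = sum(r / (total * len(neg)) * (r / total) for r in neg)
        pos_term = sum(r / (total * len(pos)) * (r / total) for r in pos)
    else:
        raise ValidationError(f"unknown variant: {variant!r}")
    return neg_term - pos_term


def rank_coverage_score(
    ranked: RankedCandidateList, variant: str = "group"
) -> float:
    """Rank coverage score of one labeled ranked list; higher is better."""
    return _score_from_rank_labels(ranked.labeled_pairs(), ranked.total, variant)


@dataclass
class MethodComparison:
    per_patient: dict[str, dict[str, float]]  # method -> patient -> score
    pooled: dict[str, float]  # method -> overall score
    missing: list[tuple[str, str]]  # (method, patient) absent pairs


def compare_methods(
    lists: Sequence[RankedCandidateList], variant: str = "group"
) -> MethodComparison:
    """Per-patient and pooled rank coverage per method.

    The pooled score concatenates each method's per-patient lists,
    keeping within-patient ranks, and applies the formula to the pooled
    multiset (T = pooled size). Patients missing from any method are
    excluded from the pooled comparison and reported.
    """
    by_method: dict[str, dict[str, RankedCandidateList]] = {}
    for lst in lists:
        by_method.setdefault(lst.method, {})[lst.patient_id] = lst

    methods = sorted(by_method)
    all_patients = sorted({p for m in by_method.values() for p in m})
    common = [p for p in all_patients if all(p in by_method[m] for m in methods)]
    missing = [
        (m, p) for m in methods for p in all_patients if p not in by_method[m]
    ]

    per_patient = {
        m: {
            p: rank_coverage_score(by_method[m][p], variant)
            for p in by_method[m]
        }
        for m in methods
    }

    pooled = {}
    for m in methods:
        pairs: list[tuple[int, str]] = []
        for p in common:
            pairs.extend(by_method[m][p].labeled_pairs())
        pooled[m] = _score_from_rank_labels(pairs, len(pairs), variant)

    return MethodComparison(per_patient=per_patient, pooled=pooled, missing=missing)
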