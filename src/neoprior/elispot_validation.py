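"""ELISpot fold-change computation and immunogenicity calls.

Fold change is mutant spots over wild-type spots; a candidate is called
immunogenic at the configured cutoff (default 2-fold, inclusive). DMSO
background is reported but not subtracted by default.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import pandas as pd

from .errors import ValidationError

logger = logging.getLogger(__name__)


@dataclass
class ElispotRecord:
    patient_id: str
    peptide_id: str
    mutant_spots: int
    wildtype_spots: int
    dmso_spots: int | None = None
    anti_cd3_spots: int | None = None
    method_tags: frozenset[str] = frozenset()
    # annotation fields, filled by fold_changes_and_calls
    fold_change: float | None = None
    call: bool | None = None
    flagged: bool = False
    evaluable: bool = True

    def __post_init__(self) -> None:
        for name in ("mutant_spots", "wildtype_spots"):
            value = getattr(self, name)
            if int(value) < 0:
                raise ValidationError(f"{name} must be >= 0, got {value}")
        if (
            self.anti_cd3_spots is not None
            and self.dmso_spots is not None
            and self.anti_cd3_spots <= self.dmso_spots
        ):
            logger.warning(
                "%s/%s: anti-CD3 control not above DMSO; assay may be invalid",
                self.patient_id,
                self.peptide_id,
            )


@dataclass
class ElispotConfig:
    fold_cutoff: float = 2.0
    strict: bool = False  # True: call requires fold > cutoff, not >=
    zero_wildtype_policy: str = "pseudocount_one"  # or "undefined"
    subtract_dmso: bool = False

    def __post_init__(self) -> None:
        if self.fold_cutoff <= 0:
            raise ValidationError("fold_cutoff must be > 0")
        if self.zero_wildtype_policy not in ("pseudocount_one", "undefined"):
            raise ValidationError(
                f"unknown zero_wildtype_policy: {self.zero_wildtype_policy!r}"
            )


def fold_changes_and_calls(
    records: Sequence[ElispotRecord], config: ElispotConfig | None = None
) -> list[ElispotRecord]:
    """Annotate records with fold change and immunogenicity call."""
    config = config or ElispotConfig()
    out = []
    for rec in records:
        mutant = float(rec.mutant_spots)
        wildtype = float(rec.wildtype_spots)
        if config.subtract_dmso and rec.dmso_spots is not None:
            mutant = max(mutant - rec.dmso_spots, 0.0)
            wildtype = max(wildtype - rec.dmso_spots, 0.0)
        flagged = False
        if wildtype == 0:
            if config.zero_wildtype_policy == "undefined":
                out.append(
                    replace(rec, fold_change=None, call=None, flagged=True,
                            evaluable=False)
                )
                continue
            wildtype = 1.0
            flagged = True
        fold = mutant / wildtype
        if config.strict:
            call = fold > config.fold_cutoff
        else:
            call = fold >= config.fold_cutoff
        out.append(
            replace(rec, fold_change=fold, call=call, flagged=flagged,
                    evaluable=True)
        )
    return out


@dataclass
class MethodSummary:
    nominated: int
    confirmed: int
    per_patient: dict[str, dict[str, int]]


def validation_summary(
    records: Sequence[ElispotRecord], methods: Sequence[str]
) -> dict[str, MethodSummary]:
    """Per-method nominated/confirmed counts; shared candidates count for
    every nominating method."""
    known = set(methods)
    for rec in records:
        if not rec.method_tags:
            raise ValidationError(
                f"record {rec.peptide_id!r} carries no method tag"
            )
        unknown = rec.method_tags - known
        if unknown:
            raise ValidationError(f"unknown method tags: {sorted(unknown)}")

    out = {}
    for method in methods:
        tagged = [r for r in records if method in r.method_tags]
        evaluable = [r for r in tagged if r.evaluable]
        per_patient: dict[str, dict[str, int]] = {}
        for rec in evaluable:
            slot = per_patient.setdefault(
                rec.patient_id, {"nominated": 0, "confirmed": 0}
            )
            slot["nominated"] += 1
            slot["confirmed"] += int(bool(rec.call))
        out[method] = MethodSummary(
            nominated=len(tagged),
            confirmed=sum(1 for r in evaluable if r.call),
            per_patient=per_patient,
        )
    return out


ELISPOT_COLUMNS = [
    "patient_id", "peptide_id", "mutant_spots", "wildtype_spots",
    "dmso_spots", "anti_cd3_spots", "methods",
]


def read_elispot_csv(path: str | Path) -> list[ElispotRecord]:
    df = pd.read_csv(path)
    for col in ("patient_id", "peptide_id", "mutant_spots", "wildtype_spots"):
        if col not in df.columns:
            raise ValidationError(f"{path}: missing required column {col!r}")
    records = []
    for row in df.itertuples(index=False):
        tags = getattr(row, "methods", "")
        tags = frozenset(t for t in str(tags).split(";") if t and t != "nan")

        def _opt(name):
            value = getattr(row, name, None)
            return None if value is None or pd.isna(value) else int(value)

        records.append(
            ElispotRecord(
                patient_id=str(row.patient_id),
                peptide_id=str(row.peptide_id),
                mutant_spots=int(row.mutant_spots),
                wildtype_spots=int(row.wildtype_spots),
                dmso_spots=_opt("dmso_spots"),
                anti_cd3_spots=_opt("anti_cd3_spots"),
                method_tags=tags,
            )
        )
    return records


def write_annotated_csv(records: Sequence[ElispotRecord], path: str | Path) -> None:
    rows = []
    for rec in records:
        rows.append(
            {
                "patient_id": rec.patient_id,
                "peptide_id": rec.peptide_id,
                "mutant_spots": rec.mutant_spots,
                "wildtype_spots": rec.wildtype_spots,
                "dmso_spots": rec.dmso_spots,
                "anti_cd3_spots": rec.anti_cd3_spots,
                "methods": ";".join(sorted(rec.method_tags)),
                "fold_change": rec.fold_change,
                "call": rec.call,
                "flagged": rec.flagged,
                "evaluable": rec.evaluable,
            }
        )
    pd.DataFrame(rows).to_csv(path, index=False)


def write_summary_json(
    summaries: dict[str, MethodSummary], path: str | Path
) -> None:
    payload = {
        m: {
            "nominated": s.nominated,
            "confirmed": s.confirmed,
            "per_patient": s.per_patient,
        }
        for m, s in summaries.items()
    }
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))
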