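"""Assembly of the labeled pHLA-TCR complex dataset.

Loads positive complexes, constructs negatives by pairing each positive
pHLA with randomly drawn TCRs, deduplicates, and performs the 70/30
discovery/validation split (peptide-disjoint by default).
"""

from __future__ import annotations

import hashlib
import json
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import (
    EmptyInputError,
    FormatError,
    PoolTooSmallError,
    StratificationError,
    ValidationError,
)
from .repertoire import AA_ALPHABET

logger = logging.getLogger(__name__)

LABEL_IMMUNOGENIC = "immunogenic"
LABEL_NON_IMMUNOGENIC = "non_immunogenic"
VALID_LABELS = {LABEL_IMMUNOGENIC, LABEL_NON_IMMUNOGENIC}

PEPTIDE_LENGTHS = range(8, 12)

_HLA_RE = re.compile(
    r"^(?:HLA-)?([A-C])\*?(\d{2})(?::(\d{2,3}))?$", flags=re.IGNORECASE
)


def normalize_hla(name: str, resolution: str = "four-digit") -> str:
    """Normalize an HLA class-I allele name to ``HLA-A*02:01`` style.

    ``resolution="two-digit"`` truncates to the allele group
    (``HLA-A*02``), matching typing at two-digit resolution.
    """
    m = _HLA_RE.match(name.strip())
    if not m:
        raise FormatError(f"unrecognized HLA allele name: {name!r}")
    locus, group, protein = m.group(1).upper(), m.group(2), m.group(3)
    if resolution == "two-digit" or protein is None:
        return f"HLA-{locus}*{group}"
    return f"HLA-{locus}*{group}:{protein}"


@dataclass(frozen=True)
class PHLATCRComplex:
    """A (peptide, HLA, CDR3beta) triple with an immunogenicity label."""

    peptide: str
    hla: str
    cdr3b: str
    label: str | None = None
    source: str = ""

    def __post_init__(self) -> None:
        if len(self.peptide) not in PEPTIDE_LENGTHS:
            raise ValidationError(
                f"peptide length must be 8-11, got {len(self.peptide)} "
                f"({self.peptide!r})"
            )
        if not set(self.peptide) <= AA_ALPHABET:
            raise ValidationError(f"peptide has invalid residues: {self.peptide!r}")
        if not self.cdr3b or not set(self.cdr3b) <= AA_ALPHABET:
            raise ValidationError(f"invalid CDR3b sequence: {self.cdr3b!r}")
        if not self.hla:
            raise ValidationError("hla must be non-empty")
        if self.label is not None and self.label not in VALID_LABELS:
            raise ValidationError(f"unknown label: {self.label!r}")

    @property
    def key(self) -> tuple[str, str, str]:
        return (self.peptide, self.hla, self.cdr3b)

    @property
    def phla(self) -> tuple[str, str]:
        return (self.peptide, self.hla)

    @property
    def is_immunogenic(self) -> bool:
        return self.label == LABEL_IMMUNOGENIC


@dataclass
class AssemblyConfig:
    negatives_per_phla: int = 10
    split_fraction: float = 0.70
    split_unit: str = "peptide"  # or "complex"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.negatives_per_phla < 1:
            raise ValidationError("negatives_per_phla must be >= 1")
        if not 0.0 < self.split_fraction < 1.0:
            raise ValidationError("split_fraction must be in (0, 1)")
        if self.split_unit not in ("peptide", "complex"):
            raise ValidationError(f"unknown split_unit: {self.split_unit!r}")


@dataclass
class SplitDataset:
    discovery: list[PHLATCRComplex]
    validation: list[PHLATCRComplex]
    split_seed: int
    split_unit: str

    def __post_init__(self) -> None:
        d_keys = {c.key for c in self.discovery}
        v_keys = {c.key for c in self.validation}
        if d_keys & v_keys:
            raise ValidationError("discovery and validation share complexes")
        if self.split_unit == "peptide":
            d_pep = {c.peptide for c in self.discovery}
            v_pep = {c.peptide for c in self.validation}
            if d_pep & v_pep:
                raise ValidationError("discovery and validation share peptides")

    def manifest(self, fraction: float) -> dict:
        def _checksum(records: Iterable[PHLATCRComplex]) -> str:
            h = hashlib.sha256()
            for key in sorted(c.key for c in records):
                h.update("|".join(key).encode())
            return h.hexdigest()

        return {
            "seed": self.split_seed,
            "fraction": fraction,
            "unit": self.split_unit,
            "n_discovery": len(self.discovery),
            "n_validation": len(self.validation),
            "checksum_discovery": _checksum(self.discovery),
            "checksum_validation": _checksum(self.validation),
        }


COMPLEX_COLUMNS = ["peptide", "hla", "cdr3b", "label", "source"]


def load_complexes(paths: Sequence[str | Path]) -> list[PHLATCRComplex]:
    """Load complex TSVs, dropping rows that violate type invariants.

    Duplicates across files are kept; deduplication is a separate step.
    """
    records: list[PHLATCRComplex] = []
    n_dropped = 0
    for path in paths:
        df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
        for col in ("peptide", "hla", "cdr3b", "label"):
            if col not in df.columns:
                raise FormatError(f"{path}: missing required column {col!r}")
        for row in df.itertuples(index=False):
            label = row.label or None
            if label is not None and label not in VALID_LABELS:
                raise FormatError(f"{path}: unknown label string {label!r}")
            try:
                records.append(
                    PHLATCRComplex(
                        peptide=row.peptide,
                        hla=row.hla,
                        cdr3b=row.cdr3b,
                        label=label,
                        source=getattr(row, "source", ""),
                    )
                )
            except ValidationError as exc:
                n_dropped += 1
                logger.info("load_complexes(%s): dropped row (%s)", path, exc)
    if n_dropped:
        logger.info("load_complexes: dropped %d invalid rows total", n_dropped)
    return records


def write_complexes(records: Sequence[PHLATCRComplex], path: str | Path) -> None:
    df = pd.DataFrame(
        [
            {
                "peptide": c.peptide,
                "hla": c.hla,
                "cdr3b": c.cdr3b,
                "label": c.label or "",
                "source": c.source,
            }
            for c in records
        ],
        columns=COMPLEX_COLUMNS,
    )
    df.to_csv(path, sep="\t", index=False)


def make_negatives(
    positives: Sequence[PHLATCRComplex],
    tcr_pool: Sequence[str],
    config: AssemblyConfig,
) -> list[PHLATCRComplex]:
    """Pair each distinct positive pHLA with k random TCRs from the pool.

    TCRs that already form a known positive with a given pHLA are
    excluded from that pHLA's draw; sampling is without replacement and
    deterministic given ``config.seed``.
    """
    if not positives:
        raise EmptyInputError("make_negatives requires at least one positive")
    pool = sorted(set(tcr_pool))
    k = config.negatives_per_phla
    if len(pool) < k:
        raise PoolTooSmallError(
            f"TCR pool has {len(pool)} sequences, need {k} per pHLA"
        )

    partners: dict[tuple[str, str], set[str]] = {}
    for c in positives:
        partners.setdefault(c.phla, set()).add(c.cdr3b)

    rng = np.random.default_rng(config.seed)
    negatives: list[PHLATCRComplex] = []
    for phla in sorted(partners):
        eligible = [t for t in pool if t not in partners[phla]]
        if len(eligible) < k:
            raise PoolTooSmallError(
                f"pHLA {phla}: only {len(eligible)} eligible TCRs after "
                f"excluding known positives, need {k}"
            )
        chosen = rng.choice(len(eligible), size=k, replace=False)
        for idx in sorted(chosen):
            negatives.append(
                PHLATCRComplex(
                    peptide=phla[0],
                    hla=phla[1],
                    cdr3b=eligible[idx],
                    label=LABEL_NON_IMMUNOGENIC,
                    source="random-pairing",
                )
            )
    return negatives


def deduplicate(records: Sequence[PHLATCRComplex]) -> list[PHLATCRComplex]:
    """Collapse to unique (peptide, hla, cdr3b); immunogenic wins conflicts."""
    out: dict[tuple[str, str, str], PHLATCRComplex] = {}
    n_conflicts = 0
    for rec in records:
        prev = out.get(rec.key)
        if prev is None:
            out[rec.key] = rec
        elif prev.label != rec.label:
            n_conflicts += 1
            if rec.is_immunogenic:
                out[rec.key] = rec
    if n_conflicts:
        logger.info("deduplicate: resolved %d label conflicts", n_conflicts)
    return list(out.values())


def split_discovery_validation(
    records: Sequence[PHLATCRComplex],
    config: AssemblyConfig,
) -> SplitDataset:
    """Label-stratified random split into discovery/validation sets.

    With ``split_unit="peptide"`` all complexes sharing a peptide land on
    the same side, preventing peptide leakage.
    """
    records = list(records)
    if len(records) < 10:
        raise EmptyInputError("need at least 10 records to split")
    for lab in VALID_LABELS:
        if sum(1 for r in records if r.label == lab) < 2:
            raise StratificationError(f"label class {lab!r} has < 2 records")

    rng = np.random.default_rng(config.seed)
    frac = config.split_fraction

    if config.split_unit == "complex":
        # largest-remainder allocation: per-label floors, then top up so the
        # overall discovery size is round(frac * n)
        groups = {
            lab: [r for r in records if r.label == lab]
            for lab in sorted(VALID_LABELS)
        }
        n_disc_total = int(round(frac * len(records)))
        floors = {lab: int(frac * len(g)) for lab, g in groups.items()}
        remainders = sorted(
            groups,
            key=lambda lab: (frac * len(groups[lab]) - floors[lab], lab),
            reverse=True,
        )
        short = n_disc_total - sum(floors.values())
        for lab in remainders[: max(short, 0)]:
            floors[lab] += 1
        discovery: list[PHLATCRComplex] = []
        validation: list[PHLATCRComplex] = []
        for lab, group in groups.items():
            order = rng.permutation(len(group))
            chosen = set(order[: floors[lab]].tolist())
            for i, rec in enumerate(group):
                (discovery if i in chosen else validation).append(rec)
    else:
        by_peptide: dict[str, list[PHLATCRComplex]] = {}
        for rec in records:
            by_peptide.setdefault(rec.peptide, []).append(rec)
        peptides = sorted(by_peptide)
        order = rng.permutation(len(peptides))
        target = frac * len(records)
        discovery, validation = [], []
        n_assigned = 0
        for idx in order:
            group = by_peptide[peptides[idx]]
            if n_assigned < target:
                discovery.extend(group)
                n_assigned += len(group)
            else:
                validation.extend(group)
        if not validation:
            raise StratificationError(
                "peptide-level split left validation empty; too few peptides"
            )

    return SplitDataset(
        discovery=discovery,
        validation=validation,
        split_seed=config.seed,
        split_unit=config.split_unit,
    )


def assemble(
    positives: Sequence[PHLATCRComplex],
    tcr_pool: Sequence[str],
    config: AssemblyConfig,
) -> SplitDataset:
    """Full pipeline: negatives, dedup, split. Deterministic given seed."""
    negatives = make_negatives(positives, tcr_pool, config)
    records = deduplicate(list(positives) + negatives)
    return split_discovery_validation(records, config)


def write_manifest(split: SplitDataset, fraction: float, path: str | Path) -> None:
    Path(path).write_text(json.dumps(split.manifest(fraction), indent=2))
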