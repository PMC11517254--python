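"""TCRbeta clonotype tables and repertoire diversity statistics.

Provides the clonotype data model, an AIRR-style TSV reader, Shannon
entropy / clonality, rarefaction by without-replacement subsampling,
cross-sample clonotype sharing, and V/J segment usage summaries.
"""

from __future__ import annotations

import json
import logging
import math
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import (
    DegenerateInputError,
    EmptyInputError,
    FormatError,
    ValidationError,
)

logger = logging.getLogger(__name__)

AA_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWY")

#: required columns per input dialect
AIRR_COLUMNS = {
    "junction_aa": "cdr3_aa",
    "v_call": "v_call",
    "j_call": "j_call",
    "duplicate_count": "count",
}

_FREQ_TOL = 1e-9


def _valid_cdr3(seq: str) -> bool:
    return bool(seq) and set(seq) <= AA_ALPHABET


@dataclass(frozen=True)
class Clonotype:
    """A unique TCRbeta rearrangement with its UMI-collapsed read count."""

    cdr3_aa: str
    v_call: str
    j_call: str
    count: int

    def __post_init__(self) -> None:
        if not _valid_cdr3(self.cdr3_aa):
            raise ValidationError(
                f"invalid CDR3 amino-acid sequence: {self.cdr3_aa!r}"
            )
        if not self.v_call or not self.j_call:
            raise ValidationError("v_call and j_call must be non-empty")
        if int(self.count) < 1:
            raise ValidationError(f"count must be >= 1, got {self.count}")

    @property
    def key(self) -> tuple[str, str, str]:
        return (self.cdr3_aa, self.v_call, self.j_call)


@dataclass
class ClonotypeTable:
    """One sample's clonotypes; basis of all repertoire statistics."""

    sample_id: str
    clonotypes: list[Clonotype]
    n_skipped: int = 0

    def __post_init__(self) -> None:
        keys = [c.key for c in self.clonotypes]
        if len(keys) != len(set(keys)):
            raise ValidationError("duplicate clonotype keys in table")

    def __len__(self) -> int:
        return len(self.clonotypes)

    @property
    def total_reads(self) -> int:
        return sum(c.count for c in self.clonotypes)

    @property
    def counts(self) -> np.ndarray:
        return np.array([c.count for c in self.clonotypes], dtype=np.int64)

    @property
    def frequencies(self) -> np.ndarray:
        counts = self.counts
        return counts / counts.sum()

    def keys(self) -> set[tuple[str, str, str]]:
        return {c.key for c in self.clonotypes}


@dataclass
class RepertoireProfile:
    """Per-sample summary of diversity, CDR3 length and segment usage."""

    sample_id: str
    n_clonotypes: int
    n_singletons: int
    n_multi: int
    total_reads: int
    shannon: float
    clonality: float | None
    cdr3_length_median: float
    cdr3_length_min: int
    cdr3_length_max: int
    v_usage: dict[str, int] = field(default_factory=dict)
    j_usage: dict[str, int] = field(default_factory=dict)
    vj_pairing: dict[tuple[str, str], int] = field(default_factory=dict)

    def to_json(self) -> str:
        payload = {
            "sample_id": self.sample_id,
            "n_clonotypes": self.n_clonotypes,
            "n_singletons": self.n_singletons,
            "n_multi": self.n_multi,
            "total_reads": self.total_reads,
            "shannon": self.shannon,
            "clonality": self.clonality,
            "cdr3_length": {
                "median": self.cdr3_length_median,
                "min": self.cdr3_length_min,
                "max": self.cdr3_length_max,
            },
            "v_usage": self.v_usage,
            "j_usage": self.j_usage,
            "vj_pairing": {f"{v}|{j}": n for (v, j), n in self.vj_pairing.items()},
        }
        return json.dumps(payload, indent=2, sort_keys=True)


def read_airr_table(
    path: str | Path,
    dialect: str = "airr",
    column_map: Mapping[str, str] | None = None,
    sample_id: str | None = None,
) -> ClonotypeTable:
    """Read a clonotype TSV, merging duplicate keys and skipping bad rows.

    Parameters
    ----------
    path:
        TSV file (gzip transparent). AIRR dialect expects columns
        ``junction_aa, v_call, j_call, duplicate_count``.
    dialect:
        ``"airr"`` or ``"generic-tsv"``; the latter requires ``column_map``
        mapping file columns onto ``cdr3_aa, v_call, j_call, count``.
    """
    path = Path(path)
    if dialect == "airr":
        mapping = AIRR_COLUMNS
    elif dialect == "generic-tsv":
        if not column_map:
            raise FormatError("generic-tsv dialect requires a column_map")
        mapping = dict(column_map)
    else:
        raise FormatError(f"unknown dialect: {dialect!r}")

    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in mapping:
        if col not in df.columns:
            raise FormatError(f"missing required column: {col!r}")

    df = df.rename(columns=mapping)[["cdr3_aa", "v_call", "j_call", "count"]]

    merged: Counter[tuple[str, str, str]] = Counter()
    n_skipped = 0
    for row in df.itertuples(index=False):
        cdr3 = "" if pd.isna(row.cdr3_aa) else str(row.cdr3_aa)
        v = "" if pd.isna(row.v_call) else str(row.v_call)
        j = "" if pd.isna(row.j_call) else str(row.j_call)
        try:
            count = int(float(row.count))
        except (TypeError, ValueError):
            count = 0
        if not _valid_cdr3(cdr3) or not v or not j or count < 1:
            n_skipped += 1
            continue
        merged[(cdr3, v, j)] += count

    if n_skipped:
        logger.info("read_airr_table(%s): skipped %d invalid rows", path, n_skipped)
    if not merged:
        raise EmptyInputError(f"no valid clonotypes in {path}")

    clonotypes = [
        Clonotype(cdr3_aa=k[0], v_call=k[1], j_call=k[2], count=n)
        for k, n in merged.items()
    ]
    return ClonotypeTable(
        sample_id=sample_id or path.stem,
        clonotypes=clonotypes,
        n_skipped=n_skipped,
    )


def filter_by_count(table: ClonotypeTable, min_count: int) -> ClonotypeTable:
    """Retain clonotypes with count >= min_count."""
    if min_count < 1:
        raise ValidationError(f"min_count must be >= 1, got {min_count}")
    kept = [c for c in table.clonotypes if c.count >= min_count]
    if not kept:
        raise EmptyInputError(
            f"all clonotypes removed by min_count={min_count} "
            f"in sample {table.sample_id}"
        )
    return ClonotypeTable(sample_id=table.sample_id, clonotypes=kept)


def _check_freqs(freqs: Sequence[float]) -> np.ndarray:
    p = np.asarray(freqs, dtype=float)
    if p.size == 0:
        raise ValidationError("empty frequency vector")
    if np.any(p <= 0):
        raise ValidationError("all frequencies must be > 0")
    if abs(p.sum() - 1.0) > _FREQ_TOL:
        raise ValidationError(f"frequencies sum to {p.sum()!r}, expected 1")
    return p


def shannon_entropy(freqs: Sequence[float]) -> float:
    """Shannon diversity -sum(p_i ln p_i) in nats."""
    p = _check_freqs(freqs)
    return float(-(p * np.log(p)).sum())


def clonality(freqs: Sequence[float]) -> float:
    """Normalized clonal-expansion index 1 - H/ln(n), in [0, 1]."""
    p = _check_freqs(freqs)
    n = p.size
    if n < 2:
        raise DegenerateInputError("clonality undefined for fewer than 2 clones")
    value = 1.0 - shannon_entropy(p) / math.log(n)
    return float(min(1.0, max(0.0, value)))  # guard float round-off at bounds


def rarefaction_curve(
    table: ClonotypeTable,
    depths: Sequence[int],
    n_reps: int = 100,
    seed: int = 0,
) -> list[tuple[int, float, float]]:
    """Mean +/- sd clonotype richness from without-replacement subsamples.

    For each depth, reads are subsampled without replacement ``n_reps``
    times and the number of distinct clonotypes observed is recorded.
    """
    if n_reps < 1:
        raise ValidationError("n_reps must be >= 1")
    counts = table.counts
    total = int(counts.sum())
    depths = [int(d) for d in depths]
    if any(d < 1 for d in depths):
        raise ValidationError("depths must be positive")
    if any(d > total for d in depths):
        raise ValidationError(f"depth exceeds total reads ({total})")
    if sorted(depths) != depths:
        raise ValidationError("depths must be increasing")

    rng = np.random.default_rng(seed)
    out: list[tuple[int, float, float]] = []
    for depth in depths:
        richness = np.empty(n_reps)
        for rep in range(n_reps):
            draw = rng.multivariate_hypergeometric(counts, depth)
            richness[rep] = int(np.count_nonzero(draw))
        out.append((depth, float(richness.mean()), float(richness.std())))
    return out


@dataclass
class SharingSummary:
    """Cross-sample clonotype overlap over the union of clonotypes."""

    n_union: int
    n_private: int
    n_shared: int
    per_clonotype_samples: dict[tuple, int]

    @property
    def private_fraction(self) -> float:
        return self.n_private / self.n_union

    @property
    def shared_fraction(self) -> float:
        return self.n_shared / self.n_union


def clonotype_sharing(
    tables: Sequence[ClonotypeTable],
    key: str = "full",
) -> SharingSummary:
    """Count clonotypes private to one sample vs shared by >= 2 samples.

    ``key="full"`` identifies clonotypes by (CDR3, V, J); ``key="cdr3"``
    by CDR3 alone, matching a cross-patient comparison that ignores
    segment calls.
    """
    if len(tables) < 2:
        raise EmptyInputError("clonotype_sharing requires at least 2 tables")
    if key not in ("full", "cdr3"):
        raise ValidationError(f"unknown sharing key: {key!r}")

    occupancy: Counter[tuple] = Counter()
    for table in tables:
        keys: Iterable[tuple]
        if key == "full":
            keys = table.keys()
        else:
            keys = {(c.cdr3_aa,) for c in table.clonotypes}
        for k in keys:
            occupancy[k] += 1

    n_union = len(occupancy)
    n_private = sum(1 for n in occupancy.values() if n == 1)
    return SharingSummary(
        n_union=n_union,
        n_private=n_private,
        n_shared=n_union - n_private,
        per_clonotype_samples=dict(occupancy),
    )


def segment_usage(table: ClonotypeTable) -> RepertoireProfile:
    """Full per-sample profile: diversity, CDR3 lengths, V/J usage."""
    if len(table) == 0:
        raise EmptyInputError("empty clonotype table")
    counts = table.counts
    freqs = counts / counts.sum()
    lengths = np.array([len(c.cdr3_aa) for c in table.clonotypes])

    v_usage = Counter(c.v_call for c in table.clonotypes)
    j_usage = Counter(c.j_call for c in table.clonotypes)
    vj = Counter((c.v_call, c.j_call) for c in table.clonotypes)

    n = len(table)
    return RepertoireProfile(
        sample_id=table.sample_id,
        n_clonotypes=n,
        n_singletons=int((counts == 1).sum()),
        n_multi=int((counts >= 2).sum()),
        total_reads=int(counts.sum()),
        shannon=shannon_entropy(freqs),
        clonality=clonality(freqs) if n >= 2 else None,
        cdr3_length_median=float(np.median(lengths)),
        cdr3_length_min=int(lengths.min()),
        cdr3_length_max=int(lengths.max()),
        v_usage=dict(v_usage),
        j_usage=dict(j_usage),
        vj_pairing=dict(vj),
    )
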