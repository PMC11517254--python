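"""Two-feature representation of pHLA-TCR complexes.

Each complex (or aggregated key) carries a pHLA percentile rank and a
pHLA-TCR rank, both on a 0-100 scale where lower means stronger
predicted binding. Predictor outputs come in through a pluggable
adapter: a table lookup fed by externally computed score files, or a
deterministic synthetic stand-in for tests.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from pathlib import Path
from typing import Hashable, Mapping, Sequence

import pandas as pd

from .dataset_assembly import PHLATCRComplex
from .errors import EmptyInputError, MissingScoreError, ValidationError


@dataclass(frozen=True)
class FeatureRow:
    """A scored key: pHLA percentile rank + pHLA-TCR rank, lower = stronger."""

    key: tuple
    phla_rank: float
    ptcr_rank: float
    label: str | None = None

    def __post_init__(self) -> None:
        for name, value in (("phla_rank", self.phla_rank), ("ptcr_rank", self.ptcr_rank)):
            if not (0.0 <= value <= 100.0):
                raise ValidationError(f"{name} out of [0, 100]: {value!r}")


class PredictorAdapter:
    """Resolve a key to a percentile rank in [0, 100]."""

    name: str = "adapter"

    def query(self, key: tuple) -> float:  # pragma: no cover - interface
        raise NotImplementedError


class TableLookupAdapter(PredictorAdapter):
    """Score lookup backed by a dict or an externally computed score table."""

    def __init__(self, scores: Mapping[tuple, float], name: str = "table-lookup"):
        self.name = name
        self._scores = {}
        for key, value in scores.items():
            value = float(value)
            if not (0.0 <= value <= 100.0):
                raise ValidationError(
                    f"score {value!r} for key {key!r} out of [0, 100]"
                )
            self._scores[tuple(key)] = value

    def query(self, key: tuple) -> float:
        try:
            return self._scores[tuple(key)]
        except KeyError:
            raise MissingScoreError(f"no score for key {key!r}") from None


class SyntheticAdapter(PredictorAdapter):
    """Deterministic hash-seeded percentile; a stand-in needing no model.

    The rank is a pure function of (key, seed): uniform over [0, 100).
    """

    def __init__(self, seed: int = 0, name: str = "synthetic"):
        self.name = name
        self.seed = seed

    def query(self, key: tuple) -> float:
        digest = hashlib.blake2b(
            ("\x1f".join(map(str, key)) + f"\x1e{self.seed}").encode(),
            digest_size=8,
        ).digest()
        return int.from_bytes(digest, "big") / 2**64 * 100.0


def aggregate_min_phla(
    scores: Mapping[tuple[str, str, str], float],
) -> dict[str, float]:
    """Per unique peptide, the minimum percentile over all alleles/tools.

    Keys are (peptide, hla, tool) triples.
    """
    if not scores:
        raise MissingScoreError("empty pHLA score set")
    out: dict[str, float] = {}
    for (peptide, _hla, _tool), value in scores.items():
        value = float(value)
        if peptide not in out or value < out[peptide]:
            out[peptide] = value
    return out


def aggregate_min_tcr(
    ranks: Mapping[tuple[str, str, str], float],
    repertoire: Sequence[str],
) -> dict[tuple[str, str], float]:
    """Per pHLA, the minimum pHLA-TCR rank over the supplied repertoire.

    Keys of ``ranks`` are (peptide, hla, cdr3b); every (pHLA, repertoire
    TCR) pair queried must be present.
    """
    if not repertoire:
        raise EmptyInputError("empty TCR repertoire")
    repertoire = list(dict.fromkeys(repertoire))
    phlas = sorted({(p, h) for (p, h, _t) in ranks})
    if not phlas:
        raise MissingScoreError("empty pHLA-TCR rank set")
    out: dict[tuple[str, str], float] = {}
    for peptide, hla in phlas:
        best = None
        for tcr in repertoire:
            key = (peptide, hla, tcr)
            if key not in ranks:
                raise MissingScoreError(f"no pHLA-TCR rank for {key!r}")
            value = float(ranks[key])
            if best is None or value < best:
                best = value
        out[(peptide, hla)] = best
    return out


def wildtype_filter(
    pairs: Sequence[tuple[float, float, Hashable]],
) -> list[Hashable]:
    """Retain keys whose mutant percentile is strictly below wild-type.

    Each pair is (mutant score, wildtype score, key); ties drop.
    """
    missing = [key for mut, wt, key in pairs if mut is None or wt is None]
    if missing:
        raise MissingScoreError(f"missing mutant/wild-type scores for keys: {missing}")
    return [key for mut, wt, key in pairs if float(mut) < float(wt)]


def build_feature_table(
    complexes: Sequence[PHLATCRComplex],
    phla_adapter: PredictorAdapter,
    ptcr_adapter: PredictorAdapter,
) -> list[FeatureRow]:
    """One FeatureRow per complex; pHLA keyed by (peptide, hla), pHLA-TCR
    by (peptide, hla, cdr3b)."""
    rows = []
    for c in complexes:
        rows.append(
            FeatureRow(
                key=c.key,
                phla_rank=float(phla_adapter.query(c.phla)),
                ptcr_rank=float(ptcr_adapter.query(c.key)),
                label=c.label,
            )
        )
    return rows


FEATURE_COLUMNS = ["peptide", "hla", "cdr3b", "phla_rank", "ptcr_rank", "label"]


def write_feature_table(rows: Sequence[FeatureRow], path: str | Path) -> None:
    records = []
    for row in rows:
        key = tuple(row.key) + ("",) * (3 - len(row.key))
        records.append(
            {
                "peptide": key[0],
                "hla": key[1],
                "cdr3b": key[2],
                "phla_rank": row.phla_rank,
                "ptcr_rank": row.ptcr_rank,
                "label": row.label or "",
            }
        )
    pd.DataFrame(records, columns=FEATURE_COLUMNS).to_csv(path, sep="\t", index=False)


def read_feature_table(path: str | Path) -> list[FeatureRow]:
    df = pd.read_csv(
        path,
        sep="\t",
        dtype={"peptide": str, "hla": str, "cdr3b": str},
        float_precision="round_trip",
    )
    rows = []
    for rec in df.itertuples(index=False):
        cdr3b = "" if pd.isna(rec.cdr3b) else str(rec.cdr3b)
        key = (rec.peptide, rec.hla, cdr3b) if cdr3b else (rec.peptide, rec.hla)
        label = None if pd.isna(rec.label) or rec.label == "" else str(rec.label)
        rows.append(
            FeatureRow(
                key=key,
                phla_rank=float(rec.phla_rank),
                ptcr_rank=float(rec.ptcr_rank),
                label=label,
            )
        )
    return rows
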