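"""Synthetic generators for every pipeline input.

Clone counts follow a Zipf-type ranked distribution with heavy-tailed
expansion; pHLA / pHLA-TCR ranks are drawn from class-conditional
mixtures in which immunogenic complexes concentrate at low percentiles;
ELISpot counts are Poisson with a configurable true fold change. All
generators are deterministic given their seed.
"""

from __future__ import annotations

import string
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .dataset_assembly import (
    LABEL_IMMUNOGENIC,
    LABEL_NON_IMMUNOGENIC,
    PHLATCRComplex,
)
from .elispot_validation import ElispotRecord
from .errors import ValidationError
from .feature_engine import FeatureRow
from .repertoire import Clonotype, ClonotypeTable

AA = np.array(list("ACDEFGHIKLMNPQRSTVWY"))

DEFAULT_HLA_ALLELES = (
    "HLA-A*02:01", "HLA-A*01:01", "HLA-A*03:01", "HLA-A*11:01",
    "HLA-B*07:02", "HLA-B*08:01", "HLA-B*15:01", "HLA-B*44:02",
    "HLA-C*04:01", "HLA-C*07:01", "HLA-C*07:02",
)


def _random_peptide(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(AA, size=length))


def _unique_sequences(
    rng: np.random.Generator, n: int, lengths: Sequence[int]
) -> list[str]:
    seen: set[str] = set()
    out: list[str] = []
    i = 0
    while len(out) < n:
        seq = _random_peptide(rng, lengths[i % len(lengths)])
        if seq not in seen:
            seen.add(seq)
            out.append(seq)
            i += 1
    return out


@dataclass
class RepertoireSimConfig:
    n_clonotypes: int = 1000
    zipf_exponent: float = 1.5
    reads_per_clonotype: int = 30
    n_v_segments: int = 59
    n_j_segments: int = 13
    cdr3_length_mean: float = 14.0
    cdr3_length_sd: float = 2.0
    cdr3_length_min: int = 4
    cdr3_length_max: int = 43
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_clonotypes < 1 or self.zipf_exponent <= 0:
            raise ValidationError("n_clonotypes >= 1 and zipf_exponent > 0 required")
        if self.cdr3_length_min < 1 or self.cdr3_length_max < self.cdr3_length_min:
            raise ValidationError("invalid CDR3 length bounds")


def simulate_repertoire(config: RepertoireSimConfig) -> ClonotypeTable:
    """One sample's clonotype table with Zipf-ranked clone counts."""
    rng = np.random.default_rng(config.seed)
    n = config.n_clonotypes

    ranks = np.arange(1, n + 1, dtype=float)
    p = ranks ** -config.zipf_exponent
    p /= p.sum()
    total_reads = config.reads_per_clonotype * n
    # +1 baseline guarantees every clonotype is observed at least once
    counts = 1 + rng.multinomial(total_reads - n, p)

    lengths = np.clip(
        np.rint(rng.normal(config.cdr3_length_mean, config.cdr3_length_sd, n)),
        config.cdr3_length_min,
        config.cdr3_length_max,
    ).astype(int)
    cdr3s = _unique_sequences(rng, n, lengths.tolist())
    v_calls = rng.integers(1, config.n_v_segments + 1, n)
    j_calls = rng.integers(1, config.n_j_segments + 1, n)

    clonotypes = [
        Clonotype(
            cdr3_aa=cdr3s[i],
            v_call=f"TRBV{v_calls[i]}",
            j_call=f"TRBJ{j_calls[i]}",
            count=int(counts[i]),
        )
        for i in range(n)
    ]
    return ClonotypeTable(sample_id=f"sim{config.seed}", clonotypes=clonotypes)


@dataclass
class ComplexSimConfig:
    n_positive: int = 1000
    neg_ratio: int = 10
    pos_phla_scale: float = 2.0
    pos_ptcr_scale: float = 3.0
    pos_contamination: float = 0.30
    neg_low_weight: float = 0.20
    label_noise: float = 0.0
    hla_alleles: tuple[str, ...] = DEFAULT_HLA_ALLELES
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_positive < 1 or self.neg_ratio < 1:
            raise ValidationError("n_positive >= 1 and neg_ratio >= 1 required")
        for name in ("pos_contamination", "neg_low_weight", "label_noise"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValidationError(f"{name} must be in [0, 1]")


def _draw_rank(
    rng: np.random.Generator, low: bool, scale: float
) -> float:
    if low:
        return float(min(rng.exponential(scale), 100.0))
    return float(rng.uniform(0.0, 100.0))


def simulate_complexes(
    config: ComplexSimConfig,
) -> tuple[list[PHLATCRComplex], list[FeatureRow]]:
    """Labeled complexes plus their two-feature rows.

    Each positive pHLA gets one immunogenic complex and ``neg_ratio``
    non-immunogenic complexes with distinct random TCRs. Features are
    drawn conditionally independently given the class: positives from
    low-concentrated exponentials (with uniform contamination),
    negatives from a uniform/low mixture.
    """
    rng = np.random.default_rng(config.seed)
    n_pos = config.n_positive

    pep_lengths = rng.integers(8, 12, n_pos).tolist()
    peptides = _unique_sequences(rng, n_pos, pep_lengths)
    hlas = rng.choice(np.array(config.hla_alleles), size=n_pos)
    n_tcr = n_pos * (config.neg_ratio + 1)
    tcr_lengths = rng.integers(10, 19, n_tcr).tolist()
    tcrs = _unique_sequences(rng, n_tcr, tcr_lengths)

    complexes: list[PHLATCRComplex] = []
    rows: list[FeatureRow] = []
    tcr_idx = 0
    for i in range(n_pos):
        for j in range(config.neg_ratio + 1):
            positive = j == 0
            c = PHLATCRComplex(
                peptide=peptides[i],
                hla=str(hlas[i]),
                cdr3b=tcrs[tcr_idx],
                label=LABEL_IMMUNOGENIC if positive else LABEL_NON_IMMUNOGENIC,
                source="synthetic",
            )
            tcr_idx += 1
            if positive:
                phla_low = rng.random() >= config.pos_contamination
                ptcr_low = rng.random() >= config.pos_contamination
            else:
                phla_low = rng.random() < config.neg_low_weight
                ptcr_low = rng.random() < config.neg_low_weight
            phla_rank = _draw_rank(rng, phla_low, config.pos_phla_scale)
            ptcr_rank = _draw_rank(rng, ptcr_low, config.pos_ptcr_scale)
            complexes.append(c)
            rows.append(
                FeatureRow(
                    key=c.key, phla_rank=phla_rank, ptcr_rank=ptcr_rank,
                    label=c.label,
                )
            )

    if config.label_noise > 0:
        flip = rng.random(len(complexes)) < config.label_noise
        for idx in np.flatnonzero(flip):
            new_label = (
                LABEL_NON_IMMUNOGENIC
                if complexes[idx].is_immunogenic
                else LABEL_IMMUNOGENIC
            )
            complexes[idx] = replace(complexes[idx], label=new_label)
            rows[idx] = FeatureRow(
                key=rows[idx].key,
                phla_rank=rows[idx].phla_rank,
                ptcr_rank=rows[idx].ptcr_rank,
                label=new_label,
            )
    return complexes, rows


@dataclass
class ElispotSimConfig:
    n_records: int = 100
    lambda_wildtype: float = 20.0
    true_fold: float = 4.0
    seed: int = 0
    patient_id: str = "SIM"
    method_tags: tuple[str, ...] = ("combined",)

    def __post_init__(self) -> None:
        if self.lambda_wildtype <= 0 or self.true_fold <= 0:
            raise ValidationError("lambda_wildtype and true_fold must be > 0")
        if self.n_records < 1:
            raise ValidationError("n_records must be >= 1")


def simulate_elispot(config: ElispotSimConfig) -> list[ElispotRecord]:
    """Poisson spot counts: wildtype ~ Poisson(lambda), mutant ~
    Poisson(lambda * true_fold)."""
    rng = np.random.default_rng(config.seed)
    records = []
    for i in range(config.n_records):
        records.append(
            ElispotRecord(
                patient_id=config.patient_id,
                peptide_id=f"PEP{i + 1:04d}",
                mutant_spots=int(rng.poisson(config.lambda_wildtype * config.true_fold)),
                wildtype_spots=int(rng.poisson(config.lambda_wildtype)),
                dmso_spots=int(rng.poisson(2.0)),
                anti_cd3_spots=int(rng.poisson(300.0)),
                method_tags=frozenset(config.method_tags),
            )
        )
    return records
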