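"""End-to-end glue: simulate -> assemble -> features -> train -> prioritize.

Runs the whole pipeline on synthetic inputs from a single config, used
by the CLI, the smoke tests, and the acceptance report.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .dataset_assembly import AssemblyConfig, deduplicate, split_discovery_validation
from .errors import ValidationError
from .feature_engine import FeatureRow
from .immunogenicity_model import (
    ModelConfig,
    TrainedClassifier,
    cross_validate_select,
    evaluate_report,
    fit_final,
)
from .prioritization import (
    NEGATIVE,
    POSITIVE,
    PrioritizationConfig,
    RankedCandidateList,
    compare_methods,
    rank_candidates,
)
from .synthetic_data import ComplexSimConfig, simulate_complexes

METHOD_COMBINED = "combined"
METHOD_PHLA = "phla_only"


@dataclass
class PipelineConfig:
    sim: ComplexSimConfig = field(default_factory=ComplexSimConfig)
    assembly: AssemblyConfig = field(default_factory=AssemblyConfig)
    model: ModelConfig = field(default_factory=ModelConfig)
    prioritization: PrioritizationConfig = field(default_factory=PrioritizationConfig)
    n_patients: int = 8

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ValidationError("n_patients must be >= 1")


@dataclass
class PipelineResult:
    model: TrainedClassifier
    cv_mean_auc: dict[str, float]
    validation_auc: float
    ranked_lists: list[RankedCandidateList]
    per_patient_scores: dict[str, dict[str, float]]
    pooled_scores: dict[str, float]


def _assign_patients(
    rows: list[FeatureRow], n_patients: int
) -> dict[str, list[FeatureRow]]:
    # deterministic round-robin over sorted candidate keys
    assigned: dict[str, list[FeatureRow]] = {
        f"PT{i + 1:02d}": [] for i in range(n_patients)
    }
    patients = sorted(assigned)
    for i, row in enumerate(sorted(rows, key=lambda r: r.key)):
        assigned[patients[i % n_patients]].append(row)
    return assigned


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute the full synthetic pipeline and compare prioritization arms."""
    complexes, rows = simulate_complexes(config.sim)
    row_by_key = {tuple(r.key): r for r in rows}

    unique = deduplicate(complexes)
    split = split_discovery_validation(unique, config.assembly)
    disc_rows = [row_by_key[c.key] for c in split.discovery]
    val_rows = [row_by_key[c.key] for c in split.validation]

    cv = cross_validate_select(disc_rows, config.model)
    model = fit_final(disc_rows, cv.selected, config.model)
    report = evaluate_report(model, val_rows, config.model)

    per_patient = _assign_patients(val_rows, config.n_patients)
    ranked_lists: list[RankedCandidateList] = []
    for patient, patient_rows in per_patient.items():
        if not patient_rows:
            continue
        keys = ["|".join(map(str, r.key)) for r in patient_rows]
        labels = {
            k: POSITIVE if r.label == "immunogenic" else NEGATIVE
            for k, r in zip(keys, patient_rows)
        }
        combined_scores = dict(
            zip(keys, (float(s) for s in model.scores(patient_rows)))
        )
        phla_scores = {k: r.phla_rank for k, r in zip(keys, patient_rows)}
        if len(set(labels.values())) < 2:
            continue  # rank coverage undefined for single-label patients
        ranked_lists.append(
            rank_candidates(
                combined_scores, "higher_better", config.prioritization,
                patient_id=patient, method=METHOD_COMBINED, labels=labels,
            )
        )
        ranked_lists.append(
            rank_candidates(
                phla_scores, "lower_better", config.prioritization,
                patient_id=patient, method=METHOD_PHLA, labels=labels,
            )
        )

    comparison = compare_methods(ranked_lists)
    return PipelineResult(
        model=model,
        cv_mean_auc=cv.mean_auc,
        validation_auc=report.auc,
        ranked_lists=ranked_lists,
        per_patient_scores=comparison.per_patient,
        pooled_scores=comparison.pooled,
    )
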