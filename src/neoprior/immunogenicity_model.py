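"""Two-feature immunogenicity classifier and its evaluation.

Candidate algorithms (logistic regression, random forest, gradient
boosting) are compared by stratified k-fold cross-validated ROC AUC;
the winner is refit on the full discovery set and operating thresholds
are fixed at target specificities. Also implements the fixed-cutoff
quadrant analysis of the two percentile-rank features.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats
from sklearn.ensemble import HistGradientBoostingClassifier, RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold

from .dataset_assembly import LABEL_IMMUNOGENIC
from .errors import StratificationError, ValidationError
from .feature_engine import FeatureRow

logger = logging.getLogger(__name__)

ALGORITHMS = ("LR", "RF", "XGB")
#: tie-break precedence when mean CV AUCs are equal
SELECTION_PRECEDENCE = ("XGB", "RF", "LR")

FEATURE_SETS = {
    "phla_only": ["phla_rank"],
    "ptcr_only": ["ptcr_rank"],
    "combined": ["phla_rank", "ptcr_rank"],
}


@dataclass
class ModelConfig:
    algorithms: tuple[str, ...] = ALGORITHMS
    cv_folds: int = 10
    feature_set: str = "combined"
    specificity_targets: tuple[float, ...] = (0.95, 0.99)
    n_bootstrap: int = 2000
    seed: int = 0

    def __post_init__(self) -> None:
        unknown = set(self.algorithms) - set(ALGORITHMS)
        if unknown:
            raise ValidationError(f"unknown algorithms: {sorted(unknown)}")
        if self.cv_folds < 2:
            raise ValidationError("cv_folds must be >= 2")
        if self.feature_set not in FEATURE_SETS:
            raise ValidationError(f"unknown feature_set: {self.feature_set!r}")
        if any(not 0.0 < t < 1.0 for t in self.specificity_targets):
            raise ValidationError("specificity targets must be in (0, 1)")


def _design_matrix(
    rows: Sequence[FeatureRow], feature_set: str
) -> tuple[np.ndarray, np.ndarray]:
    cols = FEATURE_SETS[feature_set]
    data = {
        "phla_rank": np.array([r.phla_rank for r in rows]),
        "ptcr_rank": np.array([r.ptcr_rank for r in rows]),
    }
    X = np.column_stack([data[c] for c in cols])
    labels = [r.label for r in rows]
    if any(lab is None for lab in labels):
        raise ValidationError("all rows must be labeled for training/evaluation")
    y = np.array([1 if lab == LABEL_IMMUNOGENIC else 0 for lab in labels])
    return X, y


def _make_estimator(name: str, seed: int):
    # features are percentile ranks where LOW means strong binding; models
    # learn the orientation, score output is P(immunogenic)
    if name == "LR":
        return LogisticRegression(max_iter=1000, random_state=seed)
    if name == "RF":
        return RandomForestClassifier(n_estimators=100, random_state=seed, n_jobs=1)
    if name == "XGB":
        # extreme gradient boosting via sklearn's histogram GBDT
        return HistGradientBoostingClassifier(random_state=seed)
    raise ValidationError(f"unknown algorithm: {name!r}")


def roc_auc(scores: Sequence[float], y: Sequence[int]) -> float:
    """ROC AUC as the rank (Mann-Whitney) statistic; ties get 0.5 credit."""
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(y, dtype=int)
    n_pos = int(y.sum())
    n_neg = int(len(y) - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise ValidationError("AUC requires both classes")
    ranks = stats.rankdata(scores)
    u = ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


@dataclass
class CVReport:
    fold_aucs: dict[str, list[float]]
    mean_auc: dict[str, float]
    sd_auc: dict[str, float]
    selected: str


def cross_validate_select(
    rows: Sequence[FeatureRow], config: ModelConfig
) -> CVReport:
    """Stratified k-fold CV per algorithm; select by highest mean AUC.

    Ties are broken by the fixed precedence XGB > RF > LR.
    """
    X, y = _design_matrix(rows, config.feature_set)
    if y.sum() == 0 or y.sum() == len(y):
        raise StratificationError("both classes required for cross-validation")
    if len(y) < config.cv_folds:
        raise StratificationError("fewer rows than CV folds")
    if min(int(y.sum()), int(len(y) - y.sum())) < config.cv_folds:
        raise StratificationError(
            "minority class smaller than cv_folds; folds would lack a class"
        )

    skf = StratifiedKFold(
        n_splits=config.cv_folds, shuffle=True, random_state=config.seed
    )
    fold_aucs: dict[str, list[float]] = {a: [] for a in config.algorithms}
    for train_idx, test_idx in skf.split(X, y):
        if len(np.unique(y[test_idx])) < 2:
            raise StratificationError("a CV fold lacks one class")
        for algo in config.algorithms:
            est = _make_estimator(algo, config.seed)
            est.fit(X[train_idx], y[train_idx])
            scores = est.predict_proba(X[test_idx])[:, 1]
            fold_aucs[algo].append(roc_auc(scores, y[test_idx]))

    mean_auc = {a: float(np.mean(v)) for a, v in fold_aucs.items()}
    sd_auc = {a: float(np.std(v, ddof=1)) for a, v in fold_aucs.items()}
    best = max(mean_auc.values())
    selected = next(
        a for a in SELECTION_PRECEDENCE
        if a in mean_auc and mean_auc[a] == best
    )
    return CVReport(
        fold_aucs=fold_aucs, mean_auc=mean_auc, sd_auc=sd_auc, selected=selected
    )


@dataclass
class TrainedClassifier:
    """A fitted model; predicted-immunogenic iff score >= threshold."""

    algorithm: str
    feature_set: str
    estimator: object
    thresholds: dict[float, float] = field(default_factory=dict)
    cv_mean_auc: float | None = None

    def scores(self, rows: Sequence[FeatureRow]) -> np.ndarray:
        cols = FEATURE_SETS[self.feature_set]
        data = {
            "phla_rank": np.array([r.phla_rank for r in rows]),
            "ptcr_rank": np.array([r.ptcr_rank for r in rows]),
        }
        X = np.column_stack([data[c] for c in cols])
        return self.estimator.predict_proba(X)[:, 1]


def threshold_at_specificity(
    scores: Sequence[float], y: Sequence[int], target: float
) -> float:
    """Smallest observed score whose specificity strictly exceeds target.

    Specificity of the rule "positive iff score >= cutoff" is the
    fraction of negatives below the cutoff. Returns ``math.inf`` when no
    observed cutoff reaches the target (a warning is logged; sensitivity
    at the sentinel is 0).
    """
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(y, dtype=int)
    neg = np.sort(scores[y == 0])
    if neg.size == 0:
        raise ValidationError("threshold_at_specificity requires negatives")
    if target <= 0.0:
        # any cutoff satisfies a zero target; keep all candidates positive
        return float(scores.min())
    for cutoff in np.unique(scores):
        specificity = np.searchsorted(neg, cutoff, side="left") / neg.size
        if specificity > target:
            return float(cutoff)
    logger.warning(
        "specificity target %.3f unreachable; returning +inf sentinel", target
    )
    return math.inf


def fit_final(
    rows: Sequence[FeatureRow], algorithm: str, config: ModelConfig
) -> TrainedClassifier:
    """Fit on the full discovery set and fix the operating thresholds."""
    X, y = _design_matrix(rows, config.feature_set)
    if y.sum() == 0 or y.sum() == len(y):
        raise ValidationError("both classes required to fit")
    est = _make_estimator(algorithm, config.seed)
    est.fit(X, y)
    model = TrainedClassifier(
        algorithm=algorithm, feature_set=config.feature_set, estimator=est
    )
    scores = model.scores(rows)
    model.thresholds = {
        t: threshold_at_specificity(scores, y, t)
        for t in config.specificity_targets
    }
    return model


@dataclass
class OperatingPoint:
    specificity_target: float
    threshold: float
    sensitivity: float
    specificity: float
    ppv: float
    npv: float
    tp: int
    fp: int
    tn: int
    fn: int


@dataclass
class EvaluationReport:
    auc: float
    auc_ci_low: float
    auc_ci_high: float
    n: int
    operating_points: list[OperatingPoint]

    def to_dict(self) -> dict:
        return {
            "auc": self.auc,
            "auc_ci": [self.auc_ci_low, self.auc_ci_high],
            "n": self.n,
            "operating_points": [vars(op) for op in self.operating_points],
        }


def _safe_ratio(num: int, den: int) -> float:
    return num / den if den else float("nan")


def confusion_metrics(
    scores: np.ndarray, y: np.ndarray, threshold: float
) -> tuple[float, float, float, float, int, int, int, int]:
    pred = scores >= threshold
    tp = int(np.sum(pred & (y == 1)))
    fp = int(np.sum(pred & (y == 0)))
    tn = int(np.sum(~pred & (y == 0)))
    fn = int(np.sum(~pred & (y == 1)))
    return (
        _safe_ratio(tp, tp + fn),
        _safe_ratio(tn, tn + fp),
        _safe_ratio(tp, tp + fp),
        _safe_ratio(tn, tn + fn),
        tp,
        fp,
        tn,
        fn,
    )


def evaluate_report(
    model: TrainedClassifier, rows: Sequence[FeatureRow], config: ModelConfig
) -> EvaluationReport:
    """AUC with stratified-bootstrap 95% CI plus fixed-threshold metrics."""
    _, y = _design_matrix(rows, model.feature_set)
    if y.sum() == 0 or y.sum() == len(y):
        raise ValidationError("both classes required for evaluation")
    scores = model.scores(rows)
    auc = roc_auc(scores, y)

    rng = np.random.default_rng(config.seed)
    pos_scores = scores[y == 1]
    neg_scores = scores[y == 0]
    boot = np.empty(config.n_bootstrap)
    for b in range(config.n_bootstrap):
        ps = rng.choice(pos_scores, size=pos_scores.size, replace=True)
        ns = rng.choice(neg_scores, size=neg_scores.size, replace=True)
        boot[b] = roc_auc(
            np.concatenate([ps, ns]),
            np.concatenate([np.ones(ps.size, int), np.zeros(ns.size, int)]),
        )
    ci_low, ci_high = np.percentile(boot, [2.5, 97.5])

    points = []
    for target in sorted(model.thresholds):
        threshold = model.thresholds[target]
        sens, spec, ppv, npv, tp, fp, tn, fn = confusion_metrics(
            scores, y, threshold
        )
        points.append(
            OperatingPoint(
                specificity_target=target,
                threshold=threshold,
                sensitivity=sens,
                specificity=spec,
                ppv=ppv,
                npv=npv,
                tp=tp,
                fp=fp,
                tn=tn,
                fn=fn,
            )
        )
    return EvaluationReport(
        auc=auc,
        auc_ci_low=float(min(ci_low, auc)),
        auc_ci_high=float(max(ci_high, auc)),
        n=len(rows),
        operating_points=points,
    )


@dataclass
class QuadrantConfig:
    cutoff: float = 2.0

    def __post_init__(self) -> None:
        if not 0.0 < self.cutoff < 100.0:
            raise ValidationError("cutoff must be in (0, 100)")


@dataclass
class RuleMetrics:
    ppv: float
    sensitivity: float
    specificity: float


@dataclass
class QuadrantReport:
    """Fixed-cutoff analysis of the two rank features.

    Quadrant naming (invented labels, also emitted in output headers):
    Q1 = both ranks < cutoff, Q2 = pHLA only, Q3 = neither,
    Q4 = pHLA-TCR only.
    """

    cutoff: float
    counts: dict[str, dict[str, int]]  # quadrant -> {pos, neg}
    rules: dict[str, RuleMetrics]  # phla_binder / ptcr_binder / q1
    chi2: dict[str, tuple[float, float]]  # feature -> (statistic, p-value)


def pearson_chi2(table: Sequence[Sequence[float]]) -> tuple[float, float]:
    """Pearson chi-square on a contingency table, no continuity correction."""
    stat, p, _, _ = stats.chi2_contingency(np.asarray(table), correction=False)
    return float(stat), float(p)


def quadrant_analysis(
    rows: Sequence[FeatureRow], qconfig: QuadrantConfig | None = None
) -> QuadrantReport:
    qconfig = qconfig or QuadrantConfig()
    cutoff = qconfig.cutoff
    _, y = _design_matrix(rows, "combined")
    phla = np.array([r.phla_rank for r in rows])
    ptcr = np.array([r.ptcr_rank for r in rows])

    phla_bind = phla < cutoff
    ptcr_bind = ptcr < cutoff
    quadrant_masks = {
        "Q1": phla_bind & ptcr_bind,
        "Q2": phla_bind & ~ptcr_bind,
        "Q3": ~phla_bind & ~ptcr_bind,
        "Q4": ~phla_bind & ptcr_bind,
    }
    counts = {
        q: {
            "pos": int(np.sum(mask & (y == 1))),
            "neg": int(np.sum(mask & (y == 0))),
        }
        for q, mask in quadrant_masks.items()
    }

    rules = {}
    for name, mask in (
        ("phla_binder", phla_bind),
        ("ptcr_binder", ptcr_bind),
        ("q1", phla_bind & ptcr_bind),
    ):
        tp = int(np.sum(mask & (y == 1)))
        fp = int(np.sum(mask & (y == 0)))
        fn = int(np.sum(~mask & (y == 1)))
        tn = int(np.sum(~mask & (y == 0)))
        rules[name] = RuleMetrics(
            ppv=_safe_ratio(tp, tp + fp),
            sensitivity=_safe_ratio(tp, tp + fn),
            specificity=_safe_ratio(tn, tn + fp),
        )

    chi2 = {}
    for name, mask in (("phla", phla_bind), ("ptcr", ptcr_bind)):
        table = [
            [int(np.sum(mask & (y == 1))), int(np.sum(mask & (y == 0)))],
            [int(np.sum(~mask & (y == 1))), int(np.sum(~mask & (y == 0)))],
        ]
        if any(sum(r) == 0 for r in table) or any(
            sum(c) == 0 for c in zip(*table)
        ):
            chi2[name] = (float("nan"), float("nan"))
        else:
            chi2[name] = pearson_chi2(table)

    return QuadrantReport(cutoff=cutoff, counts=counts, rules=rules, chi2=chi2)
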