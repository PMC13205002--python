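"""Evaluation of a recommendation against behavioral accuracy data.

Given per-trial (or aggregated) recognition accuracies for each
subject-configuration pair, this module quantifies

* trend consistency: Pearson correlation between the per-configuration
  mean predicted PCS and the per-configuration mean accuracy across the
  cohort (j = 1..36 configurations);
* Top-k coverage: the 1-based rank of each subject's measured-best
  configuration inside the predicted ranking;
* pruning: configurations whose group mean accuracy falls below 61.5%
  while no single subject reaches 80% are flagged for exclusion;
* configuration-time accounting: percentage saving of the guided
  workflow over exhaustive testing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .config_space import enumerate_configs
from .recommend import RankedRecommendation

DEFAULT_MEAN_THRESH = 0.615
DEFAULT_MAX_THRESH = 0.80


@dataclass(frozen=True)
class BehavioralRecord:
    """Aggregate recognition outcome for one subject-configuration pair."""

    subject_id: str
    config_label: str
    n_trials: int
    n_correct: int

    def __post_init__(self) -> None:
        if not 0 <= self.n_correct <= self.n_trials:
            raise ValueError("n_correct must lie in [0, n_trials]")

    @property
    def accuracy(self) -> float:
        return self.n_correct / self.n_trials


def records_to_frame(records: Iterable[BehavioralRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "subject_id": r.subject_id,
                "config": r.config_label,
                "n_trials": r.n_trials,
                "n_correct": r.n_correct,
                "accuracy": r.accuracy,
            }
            for r in records
        ]
    )


def frame_to_records(df: pd.DataFrame) -> list[BehavioralRecord]:
    return [
        BehavioralRecord(
            subject_id=str(r["subject_id"]),
            config_label=str(r["config"]),
            n_trials=int(r["n_trials"]),
            n_correct=int(r["n_correct"]),
        )
        for _, r in df.iterrows()
    ]


def pearson_r(pcs_pred: Sequence[float], acc: Sequence[float]) -> float:
    """Product-moment correlation across configurations."""
    return pearson_test(pcs_pred, acc)[0]


def pearson_test(pcs_pred: Sequence[float], acc: Sequence[float]) -> tuple[float, float]:
    """(r, p) with the standard t-transform p-value."""
    x = np.asarray(pcs_pred, dtype=float)
    y = np.asarray(acc, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("need equal-length vectors of at least 3 values")
    if np.var(x) == 0 or np.var(y) == 0:
        raise ValueError("correlation undefined for zero-variance input")
    res = stats.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


def topk_rank(recommendation: RankedRecommendation, measured_best: str) -> int:
    """1-based rank of the experimentally best configuration."""
    return recommendation.rank_of(measured_best)


def exclusion_filter(
    records: Iterable[BehavioralRecord],
    mean_thresh: float = DEFAULT_MEAN_THRESH,
    max_thresh: float = DEFAULT_MAX_THRESH,
) -> list[str]:
    """Configurations with group mean accuracy < ``mean_thresh`` AND
    maximum per-subject accuracy < ``max_thresh``.

    Output is ordered by the candidate enumeration order.  Every
    configuration present must have at least one record (guaranteed by
    construction here); configurations absent from the table raise.
    """
    df = records_to_frame(list(records))
    if df.empty:
        raise ValueError("no behavioral records supplied")
    grouped = df.groupby("config")["accuracy"]
    means = grouped.mean()
    maxes = grouped.max()
    excluded = set(means.index[(means < mean_thresh) & (maxes < max_thresh)])
    order = {c.label: i for i, c in enumerate(enumerate_configs())}
    return sorted(excluded, key=lambda lab: order.get(lab, len(order)))


def time_saving_pct(t_exhaustive_min: float, t_recommended_min: float) -> float:
    """Percentage time saving, rounded half-up to one decimal."""
    if t_exhaustive_min <= 0 or t_recommended_min <= 0:
        raise ValueError("durations must be positive")
    raw = 100.0 * (1.0 - t_recommended_min / t_exhaustive_min)
    return float(Decimal(repr(raw)).quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


@dataclass
class EvaluationReport:
    pearson_r: float
    pearson_p: float
    per_subject_rank: dict[str, int]
    top1_rate: float
    top5_rate: float
    excluded_configs: list[str]
    mean_accuracy: float
    per_config_accuracy: dict[str, float] = field(default_factory=dict)
    time_saving_pct: float | None = None

    def to_dict(self) -> dict:
        return {
            "pearson_r": self.pearson_r,
            "pearson_p": self.pearson_p,
            "per_subject_rank": self.per_subject_rank,
            "top1_rate": self.top1_rate,
            "top5_rate": self.top5_rate,
            "excluded_configs": self.excluded_configs,
            "mean_accuracy": self.mean_accuracy,
            "per_config_accuracy": self.per_config_accuracy,
            "time_saving_pct": self.time_saving_pct,
        }


def measured_best_config(records: Iterable[BehavioralRecord]) -> str:
    """Highest-accuracy configuration for one subject's records; ties break
    by enumeration order."""
    recs = list(records)
    if not recs:
        raise ValueError("no records for subject")
    order = {c.label: i for i, c in enumerate(enumerate_configs())}
    best = max(recs, key=lambda r: (r.accuracy, -order.get(r.config_label, len(order))))
    return best.config_label


def evaluate(
    recommendations: Mapping[str, RankedRecommendation],
    records: Iterable[BehavioralRecord],
    mean_thresh: float = DEFAULT_MEAN_THRESH,
    max_thresh: float = DEFAULT_MAX_THRESH,
    t_exhaustive_min: float | None = None,
    t_recommended_min: float | None = None,
) -> EvaluationReport:
    """Full cohort evaluation of predicted rankings vs measured accuracy."""
    recs = list(records)
    df = records_to_frame(recs)
    per_config_acc = df.groupby("config")["accuracy"].mean()

    # Per-configuration mean predicted PCS across the cohort, aligned to
    # the configurations present in the behavioral table.
    pred_by_config: dict[str, list[float]] = {}
    for rec in recommendations.values():
        for lab, v in rec.ranking:
            pred_by_config.setdefault(lab, []).append(v)
    labels = [lab for lab in per_config_acc.index if lab in pred_by_config]
    if len(labels) < 3:
        raise ValueError("need at least 3 configurations common to predictions and behavior")
    pcs_mean = [float(np.mean(pred_by_config[lab])) for lab in labels]
    acc_mean = [float(per_config_acc[lab]) for lab in labels]
    r, p = pearson_test(pcs_mean, acc_mean)

    per_subject_rank: dict[str, int] = {}
    for sid, rec in recommendations.items():
        subj_records = [x for x in recs if x.subject_id == sid]
        if not subj_records:
            continue
        per_subject_rank[sid] = topk_rank(rec, measured_best_config(subj_records))
    n = len(per_subject_rank)
    top1 = sum(1 for v in per_subject_rank.values() if v == 1) / n if n else float("nan")
    top5 = sum(1 for v in per_subject_rank.values() if v <= 5) / n if n else float("nan")

    saving = None
    if t_exhaustive_min is not None and t_recommended_min is not None:
        saving = time_saving_pct(t_exhaustive_min, t_recommended_min)

    return EvaluationReport(
        pearson_r=r,
        pearson_p=p,
        per_subject_rank=per_subject_rank,
        top1_rate=top1,
        top5_rate=top5,
        excluded_configs=exclusion_filter(recs, mean_thresh, max_thresh),
        mean_accuracy=float(df["accuracy"].mean()),
        per_config_accuracy={k: float(v) for k, v in per_config_acc.items()},
        time_saving_pct=saving,
    )
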