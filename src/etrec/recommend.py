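"""PCS regression and configuration ranking.

The training set holds one PCS-labelled sample per subject-configuration
pair (5 training subjects x 36 candidates = 180 samples).  Model
selection runs ten candidates under one seeded shuffled 5-fold split -
linear regression, KNN with k in {1, 3, 5, 7}, random forests with
{100, 300, 500} trees, and gradient boosting with (n_estimators=100,
learning_rate=0.1, max_depth=3) or (200, 0.05, 4) - and picks the lowest
mean cross-validated MAE (ties break by candidate order).  Linear and
KNN candidates are standardised internally; tree ensembles are not.

Ranking a subject regenerates that subject's 36 feature vectors through
the simulation pipeline, predicts PCS for each, and sorts descending
with ties broken by the fixed enumeration order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import clone
from sklearn.ensemble import GradientBoostingRegressor, RandomForestRegressor
from sklearn.linear_model import LinearRegression
from sklearn.model_selection import GroupKFold, KFold
from sklearn.neighbors import KNeighborsRegressor
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler

from .config_space import ElectrodeConfig, enumerate_configs
from .pipeline import FEATURE_NAMES
from .tissue import SubjectDescriptors


@dataclass(frozen=True)
class TrainingSample:
    subject_id: str
    config_label: str
    features: tuple[float, ...]  # 9 components in FEATURE_NAMES order
    pcs_calc: float

    def __post_init__(self) -> None:
        if len(self.features) != len(FEATURE_NAMES):
            raise ValueError(f"feature vector must have {len(FEATURE_NAMES)} components")


def build_training_set(
    subjects: list[SubjectDescriptors],
    pipeline,
    configs: list[ElectrodeConfig] | None = None,
) -> list[TrainingSample]:
    """One sample per subject-configuration pair, in deterministic order.

    ``pipeline`` is any callable ``(subject, config) -> record`` exposing
    ``feature_vector`` and ``pcs.pcs`` (normally a
    :class:`~etrec.pipeline.SimulationPipeline`).
    """
    ids = [s.subject_id for s in subjects]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate subject ids in training cohort")
    if configs is None:
        configs = enumerate_configs()
    samples = []
    for s in subjects:
        for c in configs:
            try:
                rec = pipeline(s, c)
            except Exception as exc:
                raise RuntimeError(
                    f"training-set generation failed at subject={s.subject_id} "
                    f"config={c.label}"
                ) from exc
            samples.append(
                TrainingSample(
                    subject_id=s.subject_id,
                    config_label=c.label,
                    features=tuple(float(v) for v in rec.feature_vector),
                    pcs_calc=float(rec.pcs.pcs),
                )
            )
    return samples


def samples_to_frame(samples: list[TrainingSample]) -> pd.DataFrame:
    df = pd.DataFrame(
        [
            {"subject_id": s.subject_id, "config": s.config_label, "pcs_calc": s.pcs_calc}
            for s in samples
        ]
    )
    feats = pd.DataFrame([s.features for s in samples], columns=list(FEATURE_NAMES))
    return pd.concat([df[["subject_id", "config"]], feats, df[["pcs_calc"]]], axis=1)


def frame_to_samples(df: pd.DataFrame) -> list[TrainingSample]:
    return [
        TrainingSample(
            subject_id=str(r["subject_id"]),
            config_label=str(r["config"]),
            features=tuple(float(r[c]) for c in FEATURE_NAMES),
            pcs_calc=float(r["pcs_calc"]),
        )
        for _, r in df.iterrows()
    ]


def _design(samples: list[TrainingSample]) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    X = np.array([s.features for s in samples])
    y = np.array([s.pcs_calc for s in samples])
    groups = np.array([s.subject_id for s in samples])
    return X, y, groups


def mae(labels, predictions) -> float:
    """Mean absolute error between computed and predicted PCS."""
    a = np.asarray(labels, dtype=float)
    b = np.asarray(predictions, dtype=float)
    if a.shape != b.shape or a.size == 0:
        raise ValueError("labels and predictions must be equal-length and non-empty")
    return float(np.mean(np.abs(a - b)))


def candidate_models(seed: int) -> list[tuple[str, object]]:
    """The ten model-selection candidates, in tie-break order."""
    cands: list[tuple[str, object]] = [
        ("linreg", make_pipeline(StandardScaler(), LinearRegression()))
    ]
    for k in (1, 3, 5, 7):
        cands.append((f"knn_k{k}", make_pipeline(StandardScaler(), KNeighborsRegressor(k))))
    for n in (100, 300, 500):
        cands.append((f"rf_{n}", RandomForestRegressor(n_estimators=n, random_state=seed)))
    cands.append(
        (
            "gbr_n100_lr0.1_d3",
            GradientBoostingRegressor(
                n_estimators=100, learning_rate=0.1, max_depth=3, random_state=seed
            ),
        )
    )
    cands.append(
        (
            "gbr_n200_lr0.05_d4",
            GradientBoostingRegressor(
                n_estimators=200, learning_rate=0.05, max_depth=4, random_state=seed
            ),
        )
    )
    return cands


@dataclass
class ModelSelectionReport:
    fold_maes: dict[str, list[float]]
    mean_mae: dict[str, float]
    chosen: str
    seed: int

    def to_dict(self) -> dict:
        return {
            "fold_maes": self.fold_maes,
            "mean_mae": self.mean_mae,
            "chosen": self.chosen,
            "seed": self.seed,
        }


def cross_validate_models(
    samples: list[TrainingSample],
    seed: int,
    n_folds: int = 5,
    group_by_subject: bool = False,
) -> ModelSelectionReport:
    """Seeded k-fold CV of all ten candidates on a shared split."""
    if len(samples) < max(10, n_folds):
        raise ValueError("too few samples for cross-validation")
    X, y, groups = _design(samples)
    if group_by_subject:
        splitter = GroupKFold(n_splits=min(n_folds, len(set(groups))))
        splits = list(splitter.split(X, y, groups))
    else:
        splitter = KFold(n_splits=n_folds, shuffle=True, random_state=seed)
        splits = list(splitter.split(X, y))
    fold_maes: dict[str, list[float]] = {}
    for name, est in candidate_models(seed):
        errs = []
        for tr, te in splits:
            model = clone(est)
            model.fit(X[tr], y[tr])
            errs.append(mae(y[te], model.predict(X[te])))
        fold_maes[name] = errs
    mean_mae = {name: float(np.mean(errs)) for name, errs in fold_maes.items()}
    chosen = None
    best = np.inf
    for name, _ in candidate_models(seed):  # candidate order breaks ties
        if mean_mae[name] < best:
            best = mean_mae[name]
            chosen = name
    return ModelSelectionReport(fold_maes=fold_maes, mean_mae=mean_mae, chosen=chosen, seed=seed)


@dataclass
class PCSModel:
    """A fitted PCS predictor with its provenance."""

    name: str
    seed: int
    estimator: object
    cv_report: ModelSelectionReport | None = None

    def predict(self, X: np.ndarray) -> np.ndarray:
        return np.asarray(self.estimator.predict(np.asarray(X, dtype=float)))


def fit_final_model(
    samples: list[TrainingSample],
    spec: str,
    seed: int,
    cv_report: ModelSelectionReport | None = None,
) -> PCSModel:
    """Fit one named candidate on all samples with least-squares loss."""
    names = [n for n, _ in candidate_models(seed)]
    if spec not in names:
        raise ValueError(f"unknown model spec {spec!r}; candidates are {names}")
    X, y, _ = _design(samples)
    if not (np.isfinite(X).all() and np.isfinite(y).all()):
        raise ValueError("non-finite features or labels in training set")
    est = clone(dict(candidate_models(seed))[spec])
    est.fit(X, y)
    return PCSModel(name=spec, seed=seed, estimator=est, cv_report=cv_report)


def select_and_fit(samples: list[TrainingSample], seed: int) -> PCSModel:
    """Convenience: CV model selection followed by a full-data fit."""
    report = cross_validate_models(samples, seed)
    return fit_final_model(samples, report.chosen, seed, cv_report=report)


@dataclass
class RankedRecommendation:
    """Descending predicted-PCS ordering of all candidates for one subject."""

    subject_id: str
    ranking: list[tuple[str, float]]  # (config label, predicted PCS)

    def topk(self, k: int) -> list[str]:
        return [label for label, _ in self.ranking[:k]]

    @property
    def top1(self) -> str:
        return self.ranking[0][0]

    def rank_of(self, label: str) -> int:
        """1-based position of a configuration in the predicted ranking."""
        for i, (lab, _) in enumerate(self.ranking, start=1):
            if lab == label:
                return i
        raise KeyError(f"configuration {label!r} not in the ranking")


def recommend(
    subject: SubjectDescriptors,
    model: PCSModel,
    pipeline,
    configs: list[ElectrodeConfig] | None = None,
) -> RankedRecommendation:
    """Simulate the subject's feature vectors, predict PCS, rank descending.

    Ties in predicted PCS break by enumeration order (D-major), which is
    the order configurations are generated in.
    """
    if configs is None:
        configs = enumerate_configs()
    records = [pipeline(subject, c) for c in configs]
    X = np.array([r.feature_vector for r in records])
    preds = model.predict(X)
    order = sorted(range(len(configs)), key=lambda i: (-preds[i], i))
    ranking = [(configs[i].label, float(preds[i])) for i in order]
    return RankedRecommendation(subject_id=subject.subject_id, ranking=ranking)
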