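"""Synthetic cohorts and simulated psychophysics experiments.

The generator emulates the study conditions of the 5-alternative
pattern-recognition protocol: each subject completes 15 trials per
configuration (five spatial patterns, three repetitions each) with a
chance floor of 0.2.  Success probability is tied to the configuration's
computed PCS through a clipped logistic link on the standardised score,

    p = clip(chance + (1 - chance) * logistic(b0 + b1 * z), chance, cap)

so that behavior is monotone in PCS (the premise of the ranking method),
respects the 5-AFC chance floor, and saturates below a lapse-limited
ceiling.  Trial counts are binomial and fully seeded, so fixtures are
byte-identical under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit

from .config_space import enumerate_configs
from .evaluation import BehavioralRecord
from .tissue import SubjectDescriptors

N_PATTERNS = 5
CHANCE_RATE = 1.0 / N_PATTERNS


@dataclass(frozen=True)
class StimulusPattern:
    """One of the five spatial stimulation patterns on the 3 x 2 array.

    Electrode indices are row-major (0..5): row 0 is y = -pitch, row 2
    is y = +pitch; even indices are the left column.
    """

    name: str
    active_electrodes: frozenset[int]


def pattern_set() -> tuple[StimulusPattern, ...]:
    """Canonical electrode subsets for the five recognition patterns.

    The exact subsets are a fixture convention (sizes 1, 2, 3, 4, 6);
    PCS itself is pattern-agnostic.
    """
    return (
        StimulusPattern("single_point", frozenset({2})),  # centre-row left
        StimulusPattern("horizontal_line", frozenset({2, 3})),  # middle row
        StimulusPattern("vertical_line", frozenset({0, 2, 4})),  # left column
        StimulusPattern("small_area", frozenset({0, 1, 2, 3})),  # 2 x 2 block
        StimulusPattern("large_area", frozenset(range(6))),  # full array
    )


@dataclass(frozen=True)
class BehaviorGenSpec:
    """Accuracy-vs-PCS link and trial bookkeeping for the simulator."""

    chance_rate: float = CHANCE_RATE
    n_trials_per_config: int = 3 * N_PATTERNS  # 15
    beta0: float = 0.33
    beta1: float = 1.0
    accuracy_cap: float = 0.95

    def __post_init__(self) -> None:
        if not 0 < self.chance_rate < self.accuracy_cap <= 1.0:
            raise ValueError("need 0 < chance_rate < accuracy_cap <= 1")


# Sampling box for synthetic cohorts, informed by the published
# descriptor tables (young healthy adults).
AGE_RANGE = (22, 27)
HEIGHT_RANGE_CM = (165.0, 180.0)
WEIGHT_RANGE_KG = (50.0, 82.0)


def sample_subjects(n: int, seed: int) -> list[SubjectDescriptors]:
    """Draw a synthetic cohort uniformly from the descriptor box."""
    if n < 1:
        raise ValueError("n must be at least 1")
    rng = np.random.default_rng(seed)
    out = []
    for i in range(n):
        out.append(
            SubjectDescriptors(
                sex=int(rng.integers(0, 2)),
                age=float(rng.integers(AGE_RANGE[0], AGE_RANGE[1] + 1)),
                height_cm=float(rng.uniform(*HEIGHT_RANGE_CM)),
                weight_kg=float(rng.uniform(*WEIGHT_RANGE_KG)),
                subject_id=f"P{i + 1}",
            )
        )
    return out


def success_probabilities(pcs_values: np.ndarray, spec: BehaviorGenSpec) -> np.ndarray:
    """Per-configuration success probability under the clipped logistic link.

    ``pcs_values`` are standardised internally (z-scores over the given
    set); a zero-variance set maps to z = 0 everywhere.
    """
    v = np.asarray(pcs_values, dtype=float)
    sd = v.std()
    z = (v - v.mean()) / sd if sd > 0 else np.zeros_like(v)
    p = spec.chance_rate + (1.0 - spec.chance_rate) * expit(spec.beta0 + spec.beta1 * z)
    return np.clip(p, spec.chance_rate, spec.accuracy_cap)


def simulate_recognition_experiment(
    subject: SubjectDescriptors | str,
    pcs_values: np.ndarray,
    spec: BehaviorGenSpec = BehaviorGenSpec(),
    seed: int = 0,
) -> list[BehavioralRecord]:
    """Simulate one subject's 36-configuration recognition session.

    ``pcs_values`` must align with :func:`enumerate_configs` order.
    Returns one aggregate record per configuration with binomial trial
    counts; deterministic under ``seed``.
    """
    configs = enumerate_configs()
    v = np.asarray(pcs_values, dtype=float)
    if v.shape != (len(configs),):
        raise ValueError(f"expected {len(configs)} PCS values, got {v.shape}")
    sid = subject.subject_id if isinstance(subject, SubjectDescriptors) else str(subject)
    rng = np.random.default_rng(seed)
    probs = success_probabilities(v, spec)
    n = spec.n_trials_per_config
    counts = rng.binomial(n, probs)
    return [
        BehavioralRecord(
            subject_id=sid, config_label=c.label, n_trials=n, n_correct=int(k)
        )
        for c, k in zip(configs, counts)
    ]


def simulate_cohort_experiment(
    subjects: list[SubjectDescriptors],
    pcs_by_subject: dict[str, np.ndarray],
    spec: BehaviorGenSpec = BehaviorGenSpec(),
    seed: int = 0,
) -> list[BehavioralRecord]:
    """Simulate a whole cohort, one child seed per subject."""
    seeds = np.random.SeedSequence(seed).generate_state(len(subjects)) % (2**31)
    records: list[BehavioralRecord] = []
    for s, child in zip(subjects, seeds):
        records.extend(
            simulate_recognition_experiment(s, pcs_by_subject[s.subject_id], spec, int(child))
        )
    return records
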