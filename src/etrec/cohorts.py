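"""Published study cohorts: descriptor tables for the five simulation
training subjects (T1-T5) and the six psychophysics subjects (S1-S6).

These are inputs to the pipeline, shipped as constants so they can be
rebuilt without external files.  Sex is encoded 0 = female, 1 = male.
"""

from __future__ import annotations

import pandas as pd

from .tissue import SubjectDescriptors

TRAINING_COHORT: tuple[SubjectDescriptors, ...] = (
    SubjectDescriptors(sex=1, age=24, height_cm=176, weight_kg=70, subject_id="T1"),
    SubjectDescriptors(sex=0, age=22, height_cm=165, weight_kg=55, subject_id="T2"),
    SubjectDescriptors(sex=0, age=22, height_cm=167, weight_kg=50, subject_id="T3"),
    SubjectDescriptors(sex=1, age=25, height_cm=175, weight_kg=79, subject_id="T4"),
    SubjectDescriptors(sex=1, age=25, height_cm=180, weight_kg=80, subject_id="T5"),
)

EXPERIMENT_COHORT: tuple[SubjectDescriptors, ...] = (
    SubjectDescriptors(sex=1, age=25, height_cm=177, weight_kg=72, subject_id="S1"),
    SubjectDescriptors(sex=1, age=26, height_cm=178, weight_kg=81, subject_id="S2"),
    SubjectDescriptors(sex=1, age=24, height_cm=173, weight_kg=60, subject_id="S3"),
    SubjectDescriptors(sex=1, age=25, height_cm=175, weight_kg=80, subject_id="S4"),
    SubjectDescriptors(sex=1, age=27, height_cm=174, weight_kg=64, subject_id="S5"),
    SubjectDescriptors(sex=1, age=25, height_cm=178, weight_kg=82, subject_id="S6"),
)

_SEX_CODES = {"f": 0, "female": 0, "0": 0, "m": 1, "male": 1, "1": 1}


def subjects_from_frame(df: pd.DataFrame) -> list[SubjectDescriptors]:
    """Parse a subject table with columns sex, age, height, weight and an
    optional subject_id column (generated as P1.. if absent)."""
    cols = {c.lower(): c for c in df.columns}
    for req in ("sex", "age", "height", "weight"):
        if req not in cols:
            raise ValueError(f"subject table is missing required column {req!r}")
    out = []
    for i, row in enumerate(df.itertuples(index=False)):
        rec = {k.lower(): v for k, v in zip(df.columns, row)}
        sex_raw = str(rec["sex"]).strip().lower()
        if sex_raw not in _SEX_CODES:
            raise ValueError(f"cannot parse sex value {rec['sex']!r}")
        out.append(
            SubjectDescriptors(
                sex=_SEX_CODES[sex_raw],
                age=float(rec["age"]),
                height_cm=float(rec["height"]),
                weight_kg=float(rec["weight"]),
                subject_id=str(rec.get("subject_id", f"P{i + 1}")),
            )
        )
    return out


def load_subjects_csv(path: str) -> list[SubjectDescriptors]:
    return subjects_from_frame(pd.read_csv(path))


def subjects_to_frame(subjects: list[SubjectDescriptors]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "subject_id": [s.subject_id for s in subjects],
            "sex": [s.sex for s in subjects],
            "age": [s.age for s in subjects],
            "height": [s.height_cm for s in subjects],
            "weight": [s.weight_kg for s in subjects],
            "bmi": [round(s.bmi, 2) for s in subjects],
        }
    )
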