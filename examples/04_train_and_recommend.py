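"""Train the PCS ranker on the five-subject cohort and rank a new subject.

Simulates the 180 PCS-labelled training samples (about a minute), runs
the ten-candidate five-fold CV model selection, fits the winner, and
prints the Top-5 recommendation for an unseen subject described only by
sex, age, height, and weight.
"""

import numpy as np

from etrec import (
    TRAINING_COHORT,
    SimulationPipeline,
    SubjectDescriptors,
    build_training_set,
    recommend,
    select_and_fit,
)

pipe = SimulationPipeline()
samples = build_training_set(list(TRAINING_COHORT), pipe)
print(f"training samples: {len(samples)}")

model = select_and_fit(samples, seed=7)
labels = np.array([s.pcs_calc for s in samples])
print(f"selected model: {model.name}")
print(f"CV MAE {model.cv_report.mean_mae[model.name]:.4f} vs label SD {labels.std():.3f}")

new_subject = SubjectDescriptors(sex=1, age=26, height_cm=178, weight_kg=81, subject_id="new")
rec = recommend(new_subject, model, pipe)
print(f"\nTop-5 for {new_subject.subject_id}:")
for rank, (label, pred) in enumerate(rec.ranking[:5], start=1):
    print(f"  {rank}. {label:<8} predicted PCS {pred:.3f}")
print("verify these five psychophysically instead of all 36 candidates")
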