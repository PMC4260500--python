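#!/usr/bin/env python
"""Within-task classification of learning materials (alternating design).

Ten simulated learners study alternating theorem/comic 45-s windows; each
window is cut into three 15-s epochs, alpha band power per electrode is the
feature, and a stratified 10-fold CV of an RBF-SVM separates hard (theorem)
from easy (comic) study epochs.  Writes results/study1_results.json.
"""

import json
from pathlib import Path

import numpy as np

from wmlbci import Study1Config, run_study1_cohort

OUT = Path(__file__).resolve().parents[1] / "results"
OUT.mkdir(exist_ok=True)

cohort = run_study1_cohort(10, seed=1, config=Study1Config.desk())
rows = [{"subject": r.subject, "cv_accuracy": round(r.cv_accuracy, 4),
         "epochs": r.n_epochs} for r in cohort]
summary = {
    "n_subjects": len(cohort),
    "mean_cv_accuracy": round(float(np.mean([r.cv_accuracy for r in cohort])), 4),
    "n_at_or_above_80pct": int(sum(r.cv_accuracy >= 0.8 for r in cohort)),
    "subjects": rows,
}
(OUT / "study1_results.json").write_text(json.dumps(summary, indent=2))
print(json.dumps(summary, indent=2))
print("\nEvery simulated learner yields 45 epochs per material; the "
      "synthetic alpha contrast between materials is strong enough that "
      "within-task CV accuracy saturates near ceiling (cleaner than any "
      "real recording would be).")
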