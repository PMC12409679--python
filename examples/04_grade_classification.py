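"""End-to-end grading on a synthetic cohort: features -> fusion -> k-NN.

Runs the full pipeline on a reduced cohort (4 patients per grade,
shortened protocol), then compares the fused model against the
single-channel and single-feature baselines under identical
cross-validation folds.
"""

import pandas as pd

from spastemg import SynthConfig, run_synthetic_analysis

config = SynthConfig(
    n_patients_per_grade=4,
    trials_per_patient=2,
    rest_duration=4.0,
    cycle_duration=6.0,
    movement_duration=2.0,
    cycles_per_loop=3,
    loops=3,
    break_duration=6.0,
    seed=0,
)

result = run_synthetic_analysis(config=config, seed=0, per_grade=20, k=5)

print("Spearman correlations with MAS grade (channels x features):")
print(result.correlations.round(2).to_string())
print("\nfeatures retained by the |r| >= 0.7 screen:", result.retained)
print("\nper-class evaluation of the fused model (10-fold CV):")
print(result.report.to_frame().round(2).to_string())
print(f"\nmean CV accuracy (fused model, K={result.k}): "
      f"{result.mean_cv_accuracy:.3f}")
print("\nmodel comparison under identical folds:")
print(pd.Series(result.comparison).round(3).to_string())
print(
    "\nThe fused model uses the correlation-weighted combination of the "
    "three muscles' amplitude features; its accuracy should not fall "
    "below the single-channel baselines."
)
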