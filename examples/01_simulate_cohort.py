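"""Generate a small synthetic sEMG cohort and write it to disk.

Each recording follows the passive flexion-extension protocol (rests,
movement loops, breaks) at 1,024 Hz; the manifest records each trial's
MAS label and active-span sample interval for downstream segmentation.
A shortened protocol is used here so the example runs in seconds.
"""

import pandas as pd

from spastemg import SynthConfig, generate_cohort, write_cohort

config = SynthConfig(
    n_patients_per_grade=2,
    trials_per_patient=1,
    rest_duration=4.0,
    cycle_duration=6.0,
    movement_duration=2.0,
    cycles_per_loop=3,
    loops=2,
    break_duration=6.0,
    seed=42,
)

cohort = generate_cohort(config)
manifest_path = write_cohort(cohort, "scratch/example_cohort")
manifest = pd.read_csv(manifest_path)

print(f"wrote {len(cohort.recordings)} recordings to {manifest_path.parent}")
print(manifest[["subject_id", "mas_label", "span_start", "span_end"]].to_string(index=False))
print(
    "\nEach row is one trial; [span_start, span_end) marks the "
    "movement loops that the pipeline splits into segments A/B/C."
)
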