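"""Correlation screening and channel-weight derivation.

Starting from the per-channel Spearman coefficients between normalized
features and the MAS grade (here: the values published for a 40-patient
clinical stroke cohort), features are retained only when |r| >= 0.7 on
every channel, and each retained feature's channels are weighted by
ωᵢ = rᵢ / (r₁ + r₂ + r₃).
"""

import pandas as pd

from spastemg import compute_weights, round_half_away, screen, weight_table

clinical_correlations = pd.DataFrame(
    {
        "rms": [0.80, 0.83, 0.78],
        "iemg": [0.71, 0.79, 0.73],
        "ea": [0.77, 0.80, 0.81],
        "mpf": [-0.41, -0.65, -0.49],
        "mf": [-0.31, -0.54, -0.55],
    },
    index=["LB", "SB", "BR"],
)

retained = screen(clinical_correlations, threshold=0.7)
print("retained features:", retained)
print("dropped features: ", [f for f in clinical_correlations if f not in retained])

weights = weight_table(clinical_correlations, retained)
print("\nchannel weights (each column sums to 1):")
print(weights.map(lambda w: round_half_away(w, 2)).to_string())

w = compute_weights(0.80, 0.83, 0.78)
print("\nfused RMS of a sample with channel values (0.6, 0.5, 0.4):")
print(f"  e = {w[0]:.4f}*0.6 + {w[1]:.4f}*0.5 + {w[2]:.4f}*0.4 "
      f"= {w[0]*0.6 + w[1]*0.5 + w[2]*0.4:.4f}")
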