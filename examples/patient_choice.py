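"""Patient choice: how do patients distribute over the open hospitals?

Uses the conditional-logit model on a small synthetic region: choice
probabilities, predicted (fractional) hospital volumes, and a seeded
simulation draw.
"""

import hospvol as hv
from hospvol.synth import DEFAULT_COEFFS

cfg = hv.RegionConfig(
    seed=11, hospitals_per_province=(2, 2, 2), total_patients=300,
    patients_per_province=(140, 100, 60), T=20,
)
instance, patients, distances = hv.generate_region(cfg)
lagged = instance.hospitals["prev_volume"].astype(float)

P = hv.choice_probabilities(DEFAULT_COEFFS, patients, distances, lagged)
print(f"probability rows sum to 1: max |error| = {abs(P.sum(axis=1) - 1).max():.2e}")

predicted = hv.predict_volumes(DEFAULT_COEFFS, patients, distances, lagged)
print(f"\npredicted volumes (sum {predicted.sum():.1f} = {len(patients)} patients):")
print(predicted.round(1).to_string())

chosen = hv.simulate_choices(DEFAULT_COEFFS, patients, distances, lagged, seed=42)
print("\nsimulated choice counts (one seeded draw):")
print(chosen.value_counts().sort_index().to_string())

# Predicted volumes are probability sums, so they conserve the patient count
# exactly; a simulated draw scatters around them with multinomial noise.
# Patients trade distance against last year's volume (the quality signal).
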