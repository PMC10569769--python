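"""Train the two-stage workload predictor and score it on held-out patients.

Stage 1 clusters patient-weeks with k-prototypes (mixed numeric/categorical
features); stage 2 feeds the cluster id plus the features to a boosted-tree
regressor that predicts each patient's next-week encounter count.
"""

import numpy as np

from navfair import CohortConfig, MeanBaseline, WorkloadPredictor, generate_cohort
from navfair.cohort import SpecialtySpec
from navfair.preprocessing import build_model_table

config = CohortConfig(
    n_weeks=50,
    specialties=(SpecialtySpec("gi", 3, 20.1), SpecialtySpec("gu", 2, 13.4)),
    seed=7,
)
dataset = generate_cohort(config)
table = build_model_table(dataset)
train = table[table.patient_id.isin(dataset.train_ids)]
test = table[table.patient_id.isin(dataset.test_ids)]

predictor = WorkloadPredictor(seed=7, tune=False, k=5).fit(train)
y = test["target"].to_numpy(float)
mse = float(np.mean((predictor.predict(test) - y) ** 2))

baseline = MeanBaseline().fit(None, train["target"].to_numpy(float))
mse_base = float(np.mean((baseline.predict(test) - y) ** 2))

print(f"test rows: {len(test)}  (patients never seen in training)")
print(f"test MSE, two-stage predictor: {mse:.4f}")
print(f"test MSE, predict-the-mean:    {mse_base:.4f}")
print(f"variance explained vs baseline: {100 * (1 - mse / mse_base):.0f}%")
# The predictor's edge over the mean baseline is the signal the distributor
# exploits when placing new patients.
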