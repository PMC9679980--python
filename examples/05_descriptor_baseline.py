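"""Classical baseline: 5,494 sequence descriptors plus a standard regressor.

Computes the 20 descriptor families, standardizes them, and fits a random
forest on the synthetic thermal labels — the kind of feature-engineering
baseline the learned CNN representation is meant to outperform on real
corpora.
"""

import numpy as np

from thermoseq import (
    SyntheticSpec,
    apply_scaler,
    compute_all,
    fit_scaler,
    generate,
    regression_metrics,
    split,
)
from thermoseq.evalstats import make_regressor

data, _ = generate(SyntheticSpec(n=300, seed=5))
sr = split(data, test_fraction=0.2, seed=0)

vec = compute_all(sr.train.records[0])
print("per-family block widths:",
      {k: len(v) for k, v in list(vec.blocks.items())[:5]}, "...")
print(f"total features per sequence: {len(vec.total)}")

Xtr = np.stack([compute_all(r).total for r in sr.train.records])
Xte = np.stack([compute_all(r).total for r in sr.test.records])
stats = fit_scaler(Xtr)  # leakage-free: fit on training block only
Xtr, Xte = apply_scaler(Xtr, stats), apply_scaler(Xte, stats)

model = make_regressor("random_forest", n_estimators=100, random_state=0)
model.fit(Xtr, sr.train.labels)
report = regression_metrics(sr.test.labels, model.predict(Xte))
print(f"random forest on descriptors: R2={report.r2:.3f} "
      f"RMSE={report.rmse:.2f} degC (n={report.n})")
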