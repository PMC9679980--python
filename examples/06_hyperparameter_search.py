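"""Hyperparameter search: random sampling then greedy coordinate refinement.

Shown on a fast descriptor-baseline objective (ridge-style regression
validation loss) so the search machinery itself is the focus; the same
SearchSpace drives CNN architecture searches.
"""

import numpy as np

from thermoseq import SearchSpace, SyntheticSpec, generate, greedy_search, random_search, split
from thermoseq.descriptors import compute_family
from thermoseq.evalstats import make_regressor

data, _ = generate(SyntheticSpec(n=300, seed=9))
sr = split(data, test_fraction=0.25, seed=0)
Xtr = np.stack([compute_family(r, "CKSAAP") for r in sr.train.records])
Xva = np.stack([compute_family(r, "CKSAAP") for r in sr.test.records])


def objective(cfg):
    model = make_regressor("elastic_net", alpha=cfg["alpha"],
                           l1_ratio=cfg["l1_ratio"], max_iter=2000)
    model.fit(Xtr, sr.train.labels)
    err = model.predict(Xva) - sr.test.labels
    return float(np.mean(err**2))


space = SearchSpace(
    candidates={"alpha": [0.001, 0.01, 0.1, 1.0, 10.0],
                "l1_ratio": [0.1, 0.5, 0.9]},
    budget=8, seed=0,
)
ranked = random_search(space, objective)
print("random search (8 of 15 configs):")
for cfg, score in ranked[:3]:
    print(f"  val MSE {score:7.2f}  {cfg}")

refined = greedy_search(space, ranked[0][0], objective)
print(f"greedy refinement from the best draw -> {refined} "
      f"(val MSE {objective(refined):.2f})")
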