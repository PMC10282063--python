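"""Retrospective Bayesian-optimization campaign versus random search.

Replays the discovery loop over the bundled 56-record dataset for the
heteroselectivity objective (maximize P_r): 3 random initial points, then
12 iterations of fit -> propose 3 by expected improvement -> observe, for
10 independent runs. Convergence is the first iteration at which every
run has found the best record (the cross-run sd of best-so-far collapses
to zero); random search is the control.
"""

import numpy as np

from ropbo import AcquisitionConfig, convergence_iteration, random_baseline, run_campaign
from ropbo.data import literature_pool

pool = literature_pool("p_r")
global_max = max(pool.objective[i] for i in pool.ids)
print(f"searching {len(pool.ids)} literature complexes for the P_r optimum "
      f"({global_max:.2f})")

config = AcquisitionConfig(objective="p_r", seed=0)
bo = run_campaign(pool, config)
rnd = random_baseline(pool, config)

print("iteration:      ", "  ".join(f"{t:5d}" for t in range(bo.n_iterations + 1)))
print("BO mean best:   ", "  ".join(f"{v:.3f}" for v in bo.best_mean()))
print("BO sd:          ", "  ".join(f"{v:.3f}" for v in bo.best_sd()))
print("random sd:      ", "  ".join(f"{v:.3f}" for v in rnd.best_sd()))

it_bo = convergence_iteration(bo, global_max)
it_rnd = convergence_iteration(rnd, global_max)
print(f"BO converges at iteration {it_bo}; random search "
      f"{'never converges in 12 iterations' if it_rnd is None else f'at {it_rnd}'}")
print("a zero sd means every run has found the optimum - the hallmark of "
      "the guided search on this dataset")
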