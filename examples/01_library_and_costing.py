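"""Enumerate the combinatorial ligand library and cost it.

Builds the full design space of symmetric salen/salan ligands from the
bundled fragment registry, applies the synthetic-scale feasibility filter
(total expected synthesis steps of the two fragments), and evaluates the
theoretical molecular weight a living polymerization would reach.
"""

from ropbo import enumerate_library, filter_by_scale, synthetic_scale, theoretical_mn
from ropbo.catalyst_space import ARENE, Ligand
from ropbo.data import load_registry

registry = load_registry()
arenes = [f for f in registry.values() if f.family == ARENE]
linkers = [f for f in registry.values() if f.family != ARENE]

library = enumerate_library(arenes, linkers)
print(f"design space: {len(arenes)} arenes x {len(linkers)} linkers "
      f"= {len(library)} symmetric ligands")

feasible = filter_by_scale(library, registry, max_steps=3)
print(f"feasible within a 3-step synthesis budget: {len(feasible)} ligands")

demanding = Ligand("A15", "C3B1")
print(f"example: {demanding.id} needs {synthetic_scale(demanding, registry)} "
      "steps, so it is excluded from proposals")

# a chain grown at feed ratio [LA]/[Al] = 100 with 78.1% conversion
mw = theoretical_mn(conversion=0.781, feed_ratio=100)
print(f"theoretical M_n at 78.1% conversion, ratio 100: {mw:.1f} kDa "
      "(each initiator grows conversion x ratio lactide units)")
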