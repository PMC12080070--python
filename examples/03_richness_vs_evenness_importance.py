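"""Which indices respond to richness, which to evenness?

Simulates a small Richness x Evenness grid, fits a random forest of each
index on (log10 richness, alpha) and prints the permutation-importance
shares (they sum to 100% per index).
"""

import numpy as np

from tcrdiv import INDEX_NAMES, SimulationGrid, simulate_grid_diversity
from tcrdiv.compare import importance_table

grid = SimulationGrid(
    alpha_values=np.round(np.arange(1.1, 5.0, 0.6), 2),
    richness_values=np.array([10, 100, 1000, 10_000]),
    replicates=5,
    base_seed=23,
)
results = simulate_grid_diversity(grid)
table = importance_table(results, list(INDEX_NAMES), model_tags=["forest"], seed=23)
print(table.round(2).to_string(index=False))
print(
    "\nrichness_importance ~100 means the index is a pure richness readout"
    "\n(S); evenness_importance ~100 marks the clone-representation indices"
    "\n(Pielou, Basharin, d50, Gini). The Hill-number family sits in"
    "\nbetween, shifting toward evenness as the order q grows."
)
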