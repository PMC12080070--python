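"""Compare two repertoire groups with Mann-Whitney tests and RBCC effects.

Simulates 10 skewed (alpha=1.6) and 10 even (alpha=3.2) repertoires,
computes every index per sample, and prints the per-index U statistic,
p-value and rank-biserial effect size with its magnitude label.
"""

import pandas as pd

from tcrdiv import PowerLawSpec, cell_seed, compute_all, sample_counts
from tcrdiv.compare import effect_size_table

wide, labels = {}, {}
for gi, alpha in enumerate((1.6, 3.2)):
    for si in range(10):
        sid = f"g{gi}_s{si}"
        counts = sample_counts(PowerLawSpec(alpha, 800, cell_seed(99, gi, 0, si)))
        wide[sid] = compute_all(counts).as_series()
        labels[sid] = f"alpha={alpha}"

matrix = pd.DataFrame(wide).T
effects = effect_size_table(matrix, pd.Series(labels))
print(effects.round(4).to_string(index=False))
print(
    "\nRBCC = |1 - 2U/(n1 n2)| in [0,1]; 0.1/0.3/0.5/0.7 bound the"
    "\nsmall/medium/high/very-high bands. Evenness-driven indices separate"
    "\nthe two groups completely (RBCC = 1); S does not, because both"
    "\ngroups were simulated at the same richness."
)
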