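"""Simulate power-law repertoires and compute the twelve diversity indices.

Draws three repertoires of 1,000 clonotypes at evenness alpha = 1.3
(heavily skewed), 2.5 (moderate) and 4.5 (near-uniform), then prints the
full index vector for each.  Watch how the evenness indices (Pielou, Gini,
d50) track alpha while S stays pinned at the simulated richness.
"""

import pandas as pd

from tcrdiv import PowerLawSpec, compute_all, sample_counts

rows = {}
for alpha in (1.3, 2.5, 4.5):
    counts = sample_counts(PowerLawSpec(alpha=alpha, richness=1000, seed=17))
    rows[f"alpha={alpha}"] = compute_all(counts).as_series()

table = pd.DataFrame(rows)
print(table.round(4).to_string())
print(
    "\nS is always 1000 (the simulated richness). Moving from alpha=1.3 to"
    "\n4.5 the repertoire evens out: Pielou rises toward 1, Gini and d50's"
    "\ncomplementarity show the dominance structure dissolving, and the"
    "\nHill numbers (Inv.Simpson, D3, D4) climb toward S."
)
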