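"""Robustness of diversity indices to sequencing depth.

Subsamples one simulated repertoire over a log-spaced depth grid (25
repeats per depth), then prints the per-depth coefficient of variation
(CV) and median relative error (RE) for a few contrasting indices.
"""

from tcrdiv import PowerLawSpec, build_depth_grid, robustness_curves, sample_counts

counts = sample_counts(PowerLawSpec(alpha=2.0, richness=2000, seed=5))
design = build_depth_grid(50, int(counts.sum()), n_log=5, n_extra=0,
                          repeats=25, base_seed=5)
curves = robustness_curves(counts, design, sample_id="demo")

show = curves[curves["index"].isin(["S", "Chao1", "Gini.Simpson", "Pielou"])]
print(show.pivot(index="depth", columns="index", values="cv").round(4))
print()
print(show.pivot(index="depth", columns="index", values="median_re").round(4))
print(
    "\nTop table: CV across the 25 repeated draws at each depth (precision)."
    "\nBottom: median relative error against the full-sample value (bias)."
    "\nGini.Simpson stays near-exact at every depth, while the richness"
    "\nestimators (S, Chao1) carry large errors until the depth approaches"
    "\nthe full repertoire size."
)
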