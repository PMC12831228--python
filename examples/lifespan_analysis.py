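"""Replicate-combined lifespan analysis on a simulated worm assay.

Simulates 3 biological replicates of 90 treated + 90 control worms with
a planted +35% mean-lifespan extension, runs a log-rank test per
replicate, combines the p-values with Fisher's method, and prints the
summary table a lifespan figure legend would cite.
"""

from wormepi.survival import combined_lifespan_test, lifespan_report
from wormepi.synthetic import CohortSpec, gen_survival

exp, truth = gen_survival(CohortSpec(seed=1, extension_pct=35.0))
summary = combined_lifespan_test(exp)

print(f"planted extension: +{truth['extension_pct']:.0f}%")
print(f"estimated extension: {summary.mean_extension_pct:+.1f}%")
print(f"per-replicate log-rank p: {['%.2e' % p for p in summary.replicate_ps]}")
print(
    f"Fisher combined: chi2 = {summary.combined.chi2:.1f}, "
    f"df = {summary.combined.df}, p = {summary.combined.p:.3g}"
)
print()
print(lifespan_report([summary]).to_string(index=False))

# The estimated extension should sit within a few points of the planted
# +35%, and the combined p far below the 0.001 threshold a legend would
# star -- each replicate's n=90 log-rank is already well powered.
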