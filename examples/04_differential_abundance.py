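"""Negative-binomial differential abundance on a planted benchmark.

Simulates MAG counts for the 14-sample crossover with 30 differentially
abundant MAGs planted at |log2 fold change| 2 (20 enriched, 10 depleted
under restriction), runs the full-vs-reduced likelihood-ratio test
(~period + animal + diet against ~period + animal) and reports how well
the planted set is recovered.
"""

import numpy as np

from magcentric import da, simulate

counts, metadata, truth = simulate.da_benchmark_counts(lfc=2.0, seed=5)
results = da.nb_lrt(counts.round().astype(int), metadata)

hits = da.da_features(results, fdr=0.05)
planted = set(truth.da_mags)
found = hits["significant"]
total, up, down = hits["by_contrast"]["40vs80"]
print(f"{len(counts)} MAGs tested, {total} significant at FDR < 0.05 "
      f"({up} enriched, {down} depleted in the 40% vs 80% contrast)")
print(f"sensitivity: {len(found & planted) / len(planted):.2f}, "
      f"false discoveries: {len(found - planted)}")

errors = [results.loc[m, "lfc_40vs80"] - l40 for m, (l40, _) in truth.da_mags.items()]
print(f"median error of the estimated log2 fold changes: {np.median(errors):+.2f}")

print("\nStrongest calls:")
cols = ["base_mean", "lfc_40vs80", "lfc_60vs80", "p", "padj"]
print(results.sort_values("padj").head(5)[cols].round(4))
# The planted MAGs dominate the top of the list with fold-change
# estimates near the planted +/-2; null MAGs stay above the FDR cutoff.
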