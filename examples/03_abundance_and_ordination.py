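"""Abundance estimation, ordination and PERMANOVA on a simulated study.

Simulates the full crossover feeding study, corrects contig counts for
length and GC bias, aggregates them to MAG abundances, applies the
Hellinger transform and animal/period batch removal, then ordinates the
samples and tests whether community structure differs between diets.
"""

from magcentric import abundance, community, io, simulate

study = simulate.interplay_preset(seed=11)
metadata = io.filter_samples(study.metadata)  # drop period 1 and the 100% diet
samples = list(metadata["sample_id"])
print(f"{len(samples)} samples retained "
      f"({dict(metadata.groupby('diet').size())}; diet as %MER)")

corrected = abundance.correct_bias(study.contig_counts[samples], study.contig_map)
mag = abundance.aggregate_to_mag(corrected, study.contig_map, bias_corrected=True)
print(f"MAG abundance matrix: {mag.values.shape[0]} MAGs x {mag.values.shape[1]} samples")

phylum = abundance.phylum_relative_abundance(mag.values, study.taxonomy, metadata)
print("\nMean phylum relative abundance (%) per diet:")
print(phylum.round(2))

transformed = abundance.remove_batch(abundance.hellinger(mag), metadata)
distances = community.euclidean_distances(transformed.values)

ordination = community.pcoa(distances)
print("\nPCoA variance explained by the first two axes: "
      f"{100 * ordination.explained[0]:.1f}% and {100 * ordination.explained[1]:.1f}%")

diet = metadata.set_index("sample_id").loc[samples, "diet"]
result = community.permanova(distances, diet, n_perm=9999, seed=1)
print(f"\nPERMANOVA: pseudo-F = {result.pseudo_f:.2f}, "
      f"R2 = {result.r2:.3f}, p = {result.p:.4f}")
pairs = community.pairwise_permanova(distances, diet.to_numpy(), n_perm=999, seed=2)
print("\nPairwise comparisons (BH-adjusted):")
print(pairs.round(4))
# With the preset's planted diet effects the global test reaches the
# smallest attainable p at 9999 permutations (0.0001) and every diet pair
# separates significantly — the diet signal dominates community structure.
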