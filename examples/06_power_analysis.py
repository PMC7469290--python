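"""Bootstrap PERMANOVA power over alternative design sizes.

Takes the transformed, batch-corrected abundance table of a simulated
study and asks: had fewer animals per diet been sampled, would the diet
effect still have been detected?  Samples are resampled within diet
groups to each candidate design, distances recomputed and PERMANOVA
rerun; power is the fraction of resampled matrices rejecting at alpha.
"""

from magcentric import community, workflow

run = workflow.run_crossover_study(seed=11)
diet = run.metadata.set_index("sample_id").loc[
    run.transformed.values.columns, "diet"]

results = community.permanova_power(
    run.transformed.values, diet.to_numpy(),
    designs=[(3, 3, 3), (4, 4, 4), (4, 5, 5)],
    alpha=[0.05, 0.001], n_matrices=100, n_perm=999, seed=3,
)
print("design   alpha   median power")
for r in results:
    print(f"{':'.join(map(str, r.design)):8} {r.alpha:<7} {r.median_power:.2f}")
# With the preset's strong planted diet effect every design keeps full
# power at alpha 0.05, but at a stringent alpha of 0.001 the smallest
# design collapses: a 3:3:3 permutation test can rarely reach p = 0.001,
# so adequately sized groups are what rescue highly significant calls.
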