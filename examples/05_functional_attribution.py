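"""Pathway-level attribution of functional change to taxa.

Runs the complete genome-centric workflow on a simulated crossover study
with planted interplay scenarios: per-MAG KO annotations are scaled by
MAG abundance into a KO-per-sample functional potential, differential
abundance is tested at MAG and KO level, and pathway-level change is
decomposed into contributions of the differentially abundant MAGs by
taxonomic group.
"""

from magcentric import attribution, workflow

run = workflow.run_crossover_study(seed=11)

print(f"differentially abundant MAGs: {len(run.da_mags)}")
print(f"differentially abundant KOs:  {len(run.da_kos)}")

focus = ["amino_acid_metabolism", "carbohydrate_metabolism",
         "energy_metabolism", "nucleotide_metabolism"]
scen = run.scenarios[run.scenarios["pathway"].isin(focus)]
print("\nScenario classification per pathway and contrast:")
print(scen.round(2).to_string(index=False))

contrib = run.contributions
mask = (contrib["pathway"] == "amino_acid_metabolism") & (
    contrib["contrast"] == "60vs80")
print("\nTaxon contributions to amino acid metabolism (60% vs 80% MER):")
print(contrib[mask][["taxon_group", "count_low", "count_high", "lfc"]]
      .round(2).to_string(index=False))

recovery = workflow.scenario_recovery(run)
print(f"\nplanted scenario labels recovered: {100 * recovery:.0f}%")
# 'agreement': overall functional shift and the shift attributable to the
# differentially abundant MAGs point the same way; 'disconnect': they
# diverge; 'attribution-only': no KO shifts significantly overall yet the
# differentially abundant MAGs clearly reorganize the pathway.
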