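"""End-to-end drivers wiring the analysis stages together.

These helpers run the standard genome-centric workflow on one study —
bias correction, MAG aggregation, Hellinger transform and batch removal,
community statistics, MAG- and KO-level differential abundance, and the
taxon-contribution attribution — so examples, tests and the acceptance
script all execute the identical pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from . import abundance, attribution, community, da, io
from .simulate import SimulatedStudy, interplay_preset


@dataclass
class StudyResults:
    """Everything the crossover analysis produces for one study."""

    study: SimulatedStudy
    metadata: pd.DataFrame                  # filtered samples
    mag_abundance: abundance.AbundanceMatrix
    transformed: abundance.AbundanceMatrix  # Hellinger + batch-corrected
    mag_results: pd.DataFrame
    ko_per_sample: pd.DataFrame
    ko_results: pd.DataFrame
    da_mags: set[str]
    da_kos: set[str]
    contributions: pd.DataFrame
    scenarios: pd.DataFrame


def run_crossover_study(
    study: SimulatedStudy | None = None,
    seed: int = 0,
    fdr: float = 0.05,
    lfc_threshold: float = 0.5,
) -> StudyResults:
    """Run the full diet-restriction analysis on a (simulated) study.

    Samples from the first period and the compositionally distinct 100%
    maintenance-energy diet are excluded, contig counts are corrected for
    length and GC bias and aggregated to MAGs, differential abundance is
    tested at MAG and KO level, and pathway-level change is attributed to
    the differentially abundant MAGs.
    """
    if study is None:
        study = interplay_preset(seed=seed)
    md = io.filter_samples(study.metadata)
    samples = list(md["sample_id"])

    corrected = abundance.correct_bias(study.contig_counts[samples], study.contig_map)
    mag = abundance.aggregate_to_mag(corrected, study.contig_map, bias_corrected=True)
    transformed = abundance.remove_batch(abundance.hellinger(mag), md)

    mag_results = da.nb_lrt(mag.values.round().astype(int), md)
    da_mags = da.da_features(mag_results, fdr=fdr)["significant"]

    ko_sample = attribution.ko_per_sample(study.ko_mag, mag.values)
    ko_results = da.nb_lrt(ko_sample, md)
    da_kos = set(ko_results.index[ko_results["padj"] < fdr])

    ctx = attribution.DAContext(da_mags=da_mags, da_kos=da_kos, fdr=fdr)
    contributions = attribution.taxon_contribution(
        ctx, study.ko_mag, mag.values, study.taxonomy, md, study.pathway_map
    )
    overall = attribution.overall_pathway_lfc(
        ko_results, ko_sample, md, study.pathway_map, fdr=fdr
    )
    scenarios = attribution.classify_scenarios(
        overall, contributions, lfc_threshold=lfc_threshold
    )
    return StudyResults(
        study=study,
        metadata=md,
        mag_abundance=mag,
        transformed=transformed,
        mag_results=mag_results,
        ko_per_sample=ko_sample,
        ko_results=ko_results,
        da_mags=da_mags,
        da_kos=da_kos,
        contributions=contributions,
        scenarios=scenarios,
    )


def scenario_recovery(results: StudyResults) -> float:
    """Fraction of planted (pathway, contrast) scenario labels recovered."""
    truth = results.study.truth.scenarios or {}
    got = {
        (r.pathway, r.contrast): r.scenario for r in results.scenarios.itertuples()
    }
    if not truth:
        raise ValueError("study has no planted scenario labels")
    hits = sum(got.get(key) == label for key, label in truth.items())
    return hits / len(truth)
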