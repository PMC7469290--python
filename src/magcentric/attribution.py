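"""Functional-potential profiles and taxon-level attribution of change.

Per-MAG KO and CAZyme profiles are built from filtered annotation hits.
Multiplying the MAG-by-KO count matrix by the MAG-by-sample abundance
matrix yields a KO-per-sample matrix — the functional potential of each
metagenome.  For each diet contrast, the change in a metabolic pathway is
examined twice: overall (pooled counts of the pathway's significantly
differentially abundant KOs, all MAGs) and attributable (pathway counts
scaled only by the abundances of the differentially abundant MAGs, split
by taxonomic group).  Comparing the two log2 fold changes classifies each
pathway into one of three interplay scenarios:

* agreement — overall and attributable changes are both substantial and
  share a sign;
* disconnect — the attributable change is substantial but the overall
  change is small or of opposite sign;
* attribution-only — no KO in the pathway changes significantly overall,
  yet the attributable change is substantial.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import leaves_list, linkage

logger = logging.getLogger(__name__)

CONTRASTS = ("40vs80", "60vs80")
TOTAL_GROUP = "(all differentially abundant MAGs)"


@dataclass(frozen=True)
class AnnotationHit:
    """One protein-to-database hit prior to filtering."""

    protein_id: str
    mag_id: str
    target_id: str              # KO or CAZy family
    percent_identity: float = 100.0
    coverage_fraction: float = 1.0
    e_value: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.percent_identity <= 100.0:
            raise ValueError("percent identity outside [0, 100]")
        if not 0.0 <= self.coverage_fraction <= 1.0:
            raise ValueError("coverage outside [0, 1]")
        if self.e_value < 0.0:
            raise ValueError("negative E-value")


def filter_ko_hits(hits: Iterable[AnnotationHit]) -> list[AnnotationHit]:
    """KO hit filter: identity >= 50% (inclusive) and E-value < 1e-5 (strict)."""
    return [h for h in hits if h.percent_identity >= 50.0 and h.e_value < 1e-5]


def filter_cazy_hits(hits: Iterable[AnnotationHit]) -> list[AnnotationHit]:
    """CAZyme hit filter: coverage >= 35% (inclusive) and E-value < 1e-18 (strict)."""
    return [h for h in hits if h.coverage_fraction >= 0.35 and h.e_value < 1e-18]


def build_annotation_matrix(
    hits: Sequence[AnnotationHit], mag_ids: Sequence[str]
) -> pd.DataFrame:
    """MAG-by-target count matrix from filtered hits.

    A protein hitting several distinct targets counts once per target
    (best hit per (protein, target) by lowest E-value), so multi-domain
    proteins can contribute multiple annotation sites.
    """
    known = set(mag_ids)
    best: dict[tuple[str, str, str], AnnotationHit] = {}
    for h in hits:
        if h.mag_id not in known:
            raise ValueError(f"hit references unknown MAG {h.mag_id!r}")
        key = (h.mag_id, h.protein_id, h.target_id)
        if key not in best or h.e_value < best[key].e_value:
            best[key] = h
    targets = sorted({h.target_id for h in best.values()})
    mat = pd.DataFrame(0, index=list(mag_ids), columns=targets, dtype=int)
    for mag, _, target in best:
        mat.loc[mag, target] += 1
    mat.index.name = "genome_id"
    return mat


# ---------------------------------------------------------------------------
# CAZy summaries


def cazy_module_percentages(
    matrix: pd.DataFrame | pd.Series, module_map: Mapping[str, str] | None = None
) -> pd.DataFrame:
    """Dataset-wide counts and percentages per CAZy module.

    Accepts a MAG-by-family matrix with a family -> module map, or a
    Series of counts already indexed by module.  Percentages are of the
    total, to 2 decimal places.
    """
    if isinstance(matrix, pd.Series):
        counts = matrix.astype(int)
    else:
        if module_map is None:
            raise ValueError("family matrix requires a module map")
        fam_totals = matrix.sum(axis=0)
        missing = [f for f in fam_totals.index if f not in module_map]
        if missing:
            raise ValueError(f"families without module assignment: {missing[:5]}")
        counts = fam_totals.groupby(fam_totals.index.map(module_map)).sum().astype(int)
    total = int(counts.sum())
    out = pd.DataFrame({"count": counts})
    out["percent"] = (100.0 * out["count"] / total).round(2)
    out.index.name = "module"
    return out


def phylum_cazy_proportions(
    matrix: pd.DataFrame,
    taxonomy: pd.DataFrame,
    module_map: Mapping[str, str],
) -> pd.DataFrame:
    """Per-phylum percentage of CAZymes in each module (rows sum to 100)."""
    tx = taxonomy.set_index("genome_id")
    missing = matrix.index.difference(tx.index)
    if len(missing):
        raise ValueError(f"MAGs without phylum: {list(missing[:5])}")
    by_phylum = matrix.groupby(tx.loc[matrix.index, "phylum"]).sum()
    by_module = by_phylum.T.groupby(by_phylum.columns.map(module_map)).sum().T
    pct = 100.0 * by_module.div(by_module.sum(axis=1), axis=0)
    pct.index.name = "phylum"
    return pct.round(2)


def cazy_family_heatmap_input(
    matrix: pd.DataFrame, taxonomy: pd.DataFrame
) -> tuple[pd.DataFrame, list[str]]:
    """Log-scale CAZy family heatmap data plus a clustered column order.

    Cells are ``log(count + 1)``.  Columns (families) are ordered by
    average-linkage agglomeration on ``1 - Spearman rho`` between unpaired
    genus-level mean profiles; families constant across groups (undefined
    correlation) are placed last and flagged.  Rows follow taxonomy order.
    """
    tx = taxonomy.set_index("genome_id")
    group_means = matrix.groupby(tx.loc[matrix.index, "genus"]).mean()
    variable = [c for c in matrix.columns if group_means[c].nunique() > 1]
    constant = [c for c in matrix.columns if c not in variable]
    if constant:
        logger.warning("constant CAZy families placed last: %s", constant)
    if len(variable) > 2:
        rho = stats.spearmanr(group_means[variable].to_numpy()).statistic
        rho = np.atleast_2d(rho)
        dist = 1.0 - rho
        np.fill_diagonal(dist, 0.0)
        cond = dist[np.triu_indices(len(variable), 1)]
        order = leaves_list(linkage(cond, method="average"))
        ordered = [variable[i] for i in order] + constant
    else:
        ordered = variable + constant
    rows = (
        tx.loc[matrix.index]
        .sort_values(["phylum", "genus"])
        .index.tolist()
    )
    return np.log1p(matrix).loc[rows, ordered], ordered


# ---------------------------------------------------------------------------
# functional potential


def ko_per_sample(
    ko_matrix: pd.DataFrame, abundance: pd.DataFrame, round_counts: bool = True
) -> pd.DataFrame:
    """KO-per-sample functional potential: annotation counts x MAG abundance.

    ``entry(k, j) = sum_m count(m, k) * abundance(m, j)``, rounded to the
    nearest integer so downstream count models apply; pass
    ``round_counts=False`` for exact linearity (used internally where
    contributions must sum exactly across taxon groups).
    """
    if set(ko_matrix.index) != set(abundance.index):
        raise ValueError("MAG sets differ between annotation and abundance matrices")
    ab = abundance.loc[ko_matrix.index]
    out = ko_matrix.T @ ab
    out.index.name = "ko"
    if round_counts:
        return out.round().astype(np.int64)
    return out


def aggregate_pathways(
    ko_sample: pd.DataFrame, pathway_map: pd.DataFrame
) -> pd.DataFrame:
    """Sum KO-per-sample counts into pathway modules.

    A KO mapped to several pathways contributes to each; KOs absent from
    the map land in an ``unassigned`` bucket (logged).
    """
    mapped = pathway_map[pathway_map["ko"].isin(ko_sample.index)]
    unmapped = ko_sample.index.difference(pathway_map["ko"])
    pieces = {}
    for pathway, kos in mapped.groupby("pathway")["ko"]:
        pieces[pathway] = ko_sample.loc[kos].sum(axis=0)
    if len(unmapped):
        logger.warning("%d KOs without pathway assignment", len(unmapped))
        pieces["unassigned"] = ko_sample.loc[unmapped].sum(axis=0)
    for pathway in pathway_map["pathway"].unique():
        pieces.setdefault(pathway, pd.Series(0, index=ko_sample.columns))
    out = pd.DataFrame(pieces).T.sort_index()
    out.index.name = "pathway"
    return out


@dataclass
class DAContext:
    """Differential-abundance results feeding the attribution analysis."""

    da_mags: set[str]
    da_kos: set[str] = field(default_factory=set)
    fdr: float = 0.05


def _diet_samples(metadata: pd.DataFrame, diet: int) -> list[str]:
    md = metadata
    return list(md.loc[md["diet"].astype(int) == diet, "sample_id"])


def taxon_contribution(
    ctx: DAContext,
    ko_matrix: pd.DataFrame,
    abundance: pd.DataFrame,
    taxonomy: pd.DataFrame,
    metadata: pd.DataFrame,
    pathway_map: pd.DataFrame,
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """Pathway-level contribution of differentially abundant MAGs, by taxon.

    KO counts are scaled only by the abundances of the differentially
    abundant MAGs, aggregated per (taxon group, pathway, diet) over that
    diet's samples, and the change vs the 80 %MER diet reported as
    ``lfc = log2((sum_low + c) / (sum_high + c))``.  Rows with the special
    total group give the change over all differentially abundant MAGs.
    """
    if not ctx.da_mags:
        raise ValueError("empty differentially abundant MAG set")
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    tx = taxonomy.set_index("genome_id")
    missing = [m for m in ctx.da_mags if m not in tx.index]
    if missing:
        raise ValueError(f"DA MAGs missing taxonomy: {missing[:5]}")
    da = sorted(ctx.da_mags)
    groups = {g: sorted(members) for g, members in
              tx.loc[da].groupby("genus").groups.items()}

    rows = []
    for group, members in [(TOTAL_GROUP, da)] + sorted(groups.items()):
        members = list(members)
        ks = ko_per_sample(
            ko_matrix.loc[members], abundance.loc[members], round_counts=False
        )
        paths = aggregate_pathways(ks, pathway_map)
        for contrast in CONTRASTS:
            low_diet = int(contrast[:2])
            low = paths[_diet_samples(metadata, low_diet)].sum(axis=1)
            high = paths[_diet_samples(metadata, 80)].sum(axis=1)
            for pathway in paths.index:
                c_low, c_high = float(low[pathway]), float(high[pathway])
                rows.append(
                    {
                        "taxon_group": group,
                        "pathway": pathway,
                        "contrast": contrast,
                        "count_low": c_low,
                        "count_high": c_high,
                        "lfc": float(
                            np.log2((c_low + pseudocount) / (c_high + pseudocount))
                        ),
                    }
                )
    return pd.DataFrame(rows)


def overall_pathway_lfc(
    ko_results: pd.DataFrame,
    ko_sample: pd.DataFrame,
    metadata: pd.DataFrame,
    pathway_map: pd.DataFrame,
    fdr: float = 0.05,
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """Overall pathway change from significantly DA KOs, pooled per diet.

    For each pathway and contrast: pool the counts of the pathway's KOs
    with ``padj < fdr``, sum over each diet's samples, and report
    ``log2((sum_low + c)/(sum_high + c))`` plus the number of significant
    KOs (0 means the pathway shows no significant overall change).
    """
    sig = set(ko_results.index[ko_results["padj"] < fdr])
    rows = []
    for pathway, kos in pathway_map.groupby("pathway")["ko"]:
        members = sorted(set(kos) & sig & set(ko_sample.index))
        for contrast in CONTRASTS:
            low_diet = int(contrast[:2])
            if members:
                pooled = ko_sample.loc[members]
                c_low = float(pooled[_diet_samples(metadata, low_diet)].to_numpy().sum())
                c_high = float(pooled[_diet_samples(metadata, 80)].to_numpy().sum())
                lfc = float(np.log2((c_low + pseudocount) / (c_high + pseudocount)))
            else:
                lfc = np.nan
            rows.append(
                {
                    "pathway": pathway,
                    "contrast": contrast,
                    "n_significant_kos": len(members),
                    "overall_lfc": lfc,
                }
            )
    return pd.DataFrame(rows)


def classify_scenarios(
    overall: pd.DataFrame,
    contributions: pd.DataFrame,
    lfc_threshold: float = 0.5,
) -> pd.DataFrame:
    """Label each (pathway, contrast) with its interplay scenario.

    With ``o`` the overall LFC (NaN when the pathway has no significant
    KO) and ``a`` the attributable LFC over all differentially abundant
    MAGs:

    * ``attribution-only`` — no significant KO overall, ``|a| >= t``;
    * ``agreement`` — ``|o| >= t``, ``|a| >= t`` and same sign;
    * ``disconnect`` — ``|a| >= t`` and either opposite signs or
      ``|o| < t``;
    * ``none`` otherwise.
    """
    attr = contributions[contributions["taxon_group"] == TOTAL_GROUP].set_index(
        ["pathway", "contrast"]
    )["lfc"]
    rows = []
    for _, rec in overall.iterrows():
        key = (rec["pathway"], rec["contrast"])
        a = float(attr.get(key, np.nan))
        o = rec["overall_lfc"]
        n_sig = int(rec["n_significant_kos"])
        if np.isnan(a):
            label = "none"
            logger.warning("pathway %s absent from contributions", rec["pathway"])
        elif n_sig == 0:
            label = "attribution-only" if abs(a) >= lfc_threshold else "none"
        elif abs(a) >= lfc_threshold and (np.sign(o) != np.sign(a) or abs(o) < lfc_threshold):
            label = "disconnect"
        elif abs(o) >= lfc_threshold and abs(a) >= lfc_threshold:
            label = "agreement"
        else:
            label = "none"
        rows.append(
            {
                "pathway": rec["pathway"],
                "contrast": rec["contrast"],
                "overall_lfc": o,
                "attributable_lfc": a,
                "n_significant_kos": n_sig,
                "scenario": label,
            }
        )
    return pd.DataFrame(rows)


def phylum_proportion_correlation(
    counts_a: pd.Series, counts_b: pd.Series
) -> tuple[float, float]:
    """Pearson r and Spearman rho between two phylum proportion profiles.

    Inputs are genome counts per phylum; the union of phyla is taken with
    zero fill, proportions computed per dataset, and both coefficients
    returned (midranks for ties).
    """
    idx = counts_a.index.union(counts_b.index)
    a = counts_a.reindex(idx, fill_value=0).astype(float)
    b = counts_b.reindex(idx, fill_value=0).astype(float)
    if len(idx) < 3:
        raise ValueError("need at least 3 phyla")
    pa, pb = a / a.sum(), b / b.sum()
    r = stats.pearsonr(pa, pb).statistic
    rho = stats.spearmanr(pa, pb).statistic
    return float(r), float(rho)
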