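"""Synthetic rumen-community generator with recorded ground truth.

Everything downstream — dereplication, abundance estimation, ordination,
differential abundance, functional attribution — is exercised against data
from this module, which plants known structure and records it:

* ``simulate_genomes`` emits genomes with a two-level clonal structure
  (primary clusters at ~90% nucleotide identity, secondary clusters at
  ~99%), substitution-only mutations so divergence is analytically
  controlled, and a quality table spanning both sides of the 80/10
  completeness/contamination filter.
* ``simulate_counts`` emits contig-level read counts from a log-linear
  negative-binomial model: per-MAG baseline, planted diet log2 fold
  changes, additive animal/period batch effects on the log scale, contig
  length scaling and an optional monotone GC bias.
* ``simulate_annotations`` emits MAG-by-KO and MAG-by-CAZy-family count
  matrices from per-taxon profiles plus explicit planted carriage.
* ``interplay_preset`` wires the above into one study emulating a 6-animal,
  4-period crossover feeding trial at 40/60/80/100% of maintenance energy
  requirement, with planted pathway-level scenarios (agreement /
  disconnect / attribution-only) whose labels are derived analytically
  from the planted effects.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .reference import SECONDARY_CLUSTER_SIZES, crossover_metadata


def _rng(seed: int, *parts: int | str) -> np.random.Generator:
    """Independent deterministic stream for a labelled simulation component."""
    entropy = [seed] + [
        zlib.crc32(p.encode()) if isinstance(p, str) else int(p) for p in parts
    ]
    return np.random.default_rng(entropy)

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

FOCUS_PATHWAYS = (
    "amino_acid_metabolism",
    "carbohydrate_metabolism",
    "energy_metabolism",
    "nucleotide_metabolism",
)

CAZY_MODULE_OF_FAMILY = {
    "GH2": "GH", "GH3": "GH", "GH13": "GH", "GH43": "GH", "GH129": "GH",
    "GT2": "GT", "GT4": "GT", "GT35": "GT",
    "PL1": "PL", "PL11": "PL",
    "CE1": "CE", "CE4": "CE",
    "AA3": "AA",
    "CBM50": "CBM", "CBM6": "CBM",
}


# ---------------------------------------------------------------------------
# genomes


@dataclass
class GroundTruth:
    """Planted structure recorded alongside simulated data."""

    primary_clusters: dict[str, int] | None = None
    secondary_clusters: dict[str, int] | None = None
    winners: set[str] | None = None
    da_mags: dict[str, tuple[float, float]] | None = None  # (lfc 40vs80, lfc 60vs80)
    da_kos: set[str] | None = None
    scenarios: dict[tuple[str, str], str] | None = None  # (pathway, contrast) -> label


def _mutate(seq: np.ndarray, rate: float, rng: np.random.Generator) -> np.ndarray:
    """Substitute each position independently with probability ``rate``."""
    out = seq.copy()
    hits = np.flatnonzero(rng.random(seq.size) < rate)
    if hits.size:
        # shift by 1..3 in base space: never a silent substitution
        out[hits] = (out[hits] + rng.integers(1, 4, hits.size)) % 4
    return out


def _to_str(codes: np.ndarray) -> str:
    return _BASES[codes].tobytes().decode("ascii")


def simulate_genomes(
    sizes: Mapping[int, int] | Sequence[int],
    genome_length: int = 10_000,
    divergence: tuple[float, float] = (0.12, 0.005),
    secondary_per_primary: int = 1,
    within_primary_divergence: float = 0.025,
    seed: int = 0,
    k_min: int = 21,
) -> tuple[dict[str, str], pd.DataFrame, GroundTruth]:
    """Simulate clustered genomes plus a quality table and ground truth.

    ``sizes`` gives secondary-cluster sizes either as a mapping
    ``size -> number of clusters`` or a flat list of sizes.  All genomes of
    a secondary cluster derive from a founder mutated at half the secondary
    divergence each, so within-cluster pairwise divergence is ~``divergence[1]``
    (< 1% at the default).  Secondary founders within a primary cluster
    diverge at ``within_primary_divergence`` each; primary ancestors derive
    from one root mutated at ``divergence[0]`` each, so genomes from
    different primary clusters differ by > 10%.

    Quality metrics are drawn to straddle the 80%/10% filter: completeness
    uniform on [70, 100], contamination uniform on [0, 15].
    """
    d_primary, d_secondary = divergence
    if not d_primary > d_secondary:
        raise ValueError("primary divergence must exceed secondary divergence")
    if genome_length < k_min:
        raise ValueError(f"genome_length {genome_length} < k-mer size {k_min}")
    if isinstance(sizes, Mapping):
        cluster_sizes = [s for s, n in sorted(sizes.items()) for _ in range(n)]
    else:
        cluster_sizes = list(sizes)
    if not cluster_sizes or min(cluster_sizes) < 1:
        raise ValueError("cluster sizes must be positive")

    rng = np.random.default_rng(seed)
    root = rng.integers(0, 4, genome_length).astype(np.uint8)

    sequences: dict[str, str] = {}
    primary_of: dict[str, int] = {}
    secondary_of: dict[str, int] = {}
    rows = []
    g = 0
    for sec_id, size in enumerate(cluster_sizes):
        prim_id = sec_id // secondary_per_primary
        # regenerate the primary ancestor deterministically per primary id
        anc_rng = _rng(seed, "primary", prim_id)
        ancestor = _mutate(root, d_primary, anc_rng)
        founder_rng = _rng(seed, "secondary", sec_id)
        if secondary_per_primary > 1:
            founder = _mutate(ancestor, within_primary_divergence, founder_rng)
        else:
            founder = ancestor
        for _ in range(size):
            gid = f"mag{g:05d}"
            g += 1
            member_rng = _rng(seed, "member", gid)
            sequences[gid] = _to_str(_mutate(founder, d_secondary / 2.0, member_rng))
            primary_of[gid] = prim_id
            secondary_of[gid] = sec_id
            q_rng = _rng(seed, "quality", gid)
            rows.append(
                {
                    "genome_id": gid,
                    "completeness": round(float(q_rng.uniform(70, 100)), 2),
                    "contamination": round(float(q_rng.uniform(0, 15)), 2),
                    "strain_heterogeneity": round(float(q_rng.uniform(0, 50)), 2),
                    "contig_n50": int(10 ** q_rng.uniform(4, 5.5)),
                    "genome_size": genome_length,
                }
            )
    quality = pd.DataFrame(rows)

    # the true winner per secondary cluster maximizes the dereplication score
    from .derep import GenomeRecord, score_genome

    winners: set[str] = set()
    by_cluster: dict[int, list[str]] = {}
    for gid, c in secondary_of.items():
        by_cluster.setdefault(c, []).append(gid)
    qidx = quality.set_index("genome_id")
    for members in by_cluster.values():
        scored = sorted(
            members,
            key=lambda gid: (
                -score_genome(
                    GenomeRecord(
                        gid,
                        qidx.loc[gid, "completeness"],
                        qidx.loc[gid, "contamination"],
                        qidx.loc[gid, "strain_heterogeneity"],
                        int(qidx.loc[gid, "contig_n50"]),
                    )
                ),
                gid,
            ),
        )
        winners.add(scored[0])

    truth = GroundTruth(
        primary_clusters=primary_of,
        secondary_clusters=secondary_of,
        winners=winners,
    )
    return sequences, quality, truth


def paper_shape_genomes(
    genome_length: int = 10_000, seed: int = 0
) -> tuple[dict[str, str], pd.DataFrame, GroundTruth]:
    """1200 genomes in 850 secondary clusters, sized like the published catalogue."""
    return simulate_genomes(SECONDARY_CLUSTER_SIZES, genome_length=genome_length, seed=seed)


# ---------------------------------------------------------------------------
# counts


@dataclass
class EffectSpec:
    """Planted effect structure for the count simulator.

    ``mag_lfc`` maps MAG id to planted log2 fold changes (40 vs 80,
    60 vs 80 %MER); unlisted MAGs have no diet effect.  Dispersion is the
    negative-binomial ``alpha`` in ``var = mu + alpha * mu**2`` (0 gives
    Poisson counts).  Batch effects are additive animal/period offsets on
    the natural-log scale; ``gc_bias`` is a strictly positive multiplier
    of a contig's expected count as a function of its GC fraction (None
    means no bias).
    """

    baseline_mean: float = 200.0  # expected count per kb at the 80% diet
    dispersion: float = 0.4
    mag_lfc: dict[str, tuple[float, float]] = field(default_factory=dict)
    mag_dispersion: dict[str, float] = field(default_factory=dict)
    batch_sd_animal: float = 0.35
    batch_sd_period: float = 0.2
    gc_bias: Callable[[np.ndarray], np.ndarray] | None = None
    contigs_per_mag: int = 3
    length_range: tuple[int, int] = (8_000, 12_000)
    #: correlated ecological noise: label -> (member MAGs, log-scale sd).
    #: Every member of a group shares one lognormal abundance factor per
    #: sample, emulating co-varying taxa whose joint fluctuations do not
    #: average out when their counts are aggregated.
    noise_groups: dict[str, tuple[Sequence[str], float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.baseline_mean <= 0:
            raise ValueError("baseline mean must be positive")
        if self.dispersion < 0 or any(a < 0 for a in self.mag_dispersion.values()):
            raise ValueError("dispersion must be nonnegative")
        for mag, lfc in self.mag_lfc.items():
            if not np.all(np.isfinite(lfc)):
                raise ValueError(f"non-finite planted fold change for {mag}")


def _diet_multiplier(diet: int, lfc: tuple[float, float]) -> float:
    if diet == 40:
        return 2.0 ** lfc[0]
    if diet == 60:
        return 2.0 ** lfc[1]
    return 1.0  # 80 is the reference; 100 carries no planted effect


def simulate_counts(
    metadata: pd.DataFrame,
    mag_ids: Sequence[str],
    effects: EffectSpec,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Simulate a contig-by-sample count matrix plus the contig map.

    Expected counts follow ``log mu = log(baseline * length_kb) +
    ln2 * lfc(diet) + animal + period + log gc_bias(GC)``; counts are
    negative binomial with ``var = mu + alpha mu^2`` drawn as a
    gamma-Poisson mixture.
    """
    rng = np.random.default_rng(seed)
    samples = list(metadata["sample_id"])
    animals = sorted(metadata["animal"].unique())
    periods = sorted(metadata["period"].unique())
    animal_fx = dict(zip(animals, rng.normal(0.0, effects.batch_sd_animal, len(animals))))
    period_fx = dict(zip(periods, rng.normal(0.0, effects.batch_sd_period, len(periods))))

    contigs = []
    for mag in mag_ids:
        for c in range(effects.contigs_per_mag):
            contigs.append(
                {
                    "contig_id": f"{mag}_c{c}",
                    "mag_id": mag,
                    "length": int(rng.integers(*effects.length_range)),
                    "gc": float(rng.uniform(0.3, 0.7)),
                }
            )
    contig_map = pd.DataFrame(contigs).set_index("contig_id")

    length_kb = contig_map["length"].to_numpy() / 1000.0
    gc = contig_map["gc"].to_numpy()
    bias = np.ones_like(gc) if effects.gc_bias is None else np.asarray(
        effects.gc_bias(gc), dtype=float
    )
    if (bias <= 0).any():
        raise ValueError("gc_bias must be strictly positive")
    alpha = np.array(
        [
            effects.mag_dispersion.get(m, effects.dispersion)
            for m in contig_map["mag_id"]
        ]
    )

    group_sd = np.zeros(len(contig_map))
    group_idx = np.full(len(contig_map), -1)
    for gi, (_, (members, sd)) in enumerate(sorted(effects.noise_groups.items())):
        mask = contig_map["mag_id"].isin(set(members)).to_numpy()
        group_sd[mask] = sd
        group_idx[mask] = gi

    base = effects.baseline_mean * length_kb * bias
    counts = np.empty((len(contig_map), len(samples)))
    meta_idx = metadata.set_index("sample_id")
    for j, s in enumerate(samples):
        diet = int(meta_idx.loc[s, "diet"])
        batch = np.exp(
            animal_fx[meta_idx.loc[s, "animal"]] + period_fx[int(meta_idx.loc[s, "period"])]
        )
        diet_mult = np.array(
            [
                _diet_multiplier(diet, effects.mag_lfc.get(m, (0.0, 0.0)))
                for m in contig_map["mag_id"]
            ]
        )
        mu = base * diet_mult * batch
        if effects.noise_groups:
            factors = rng.normal(0.0, 1.0, len(effects.noise_groups))
            shared = np.where(group_idx >= 0, factors[group_idx], 0.0)
            mu = mu * np.exp(group_sd * shared)
        lam = np.where(
            alpha > 0, rng.gamma(np.where(alpha > 0, 1.0 / np.maximum(alpha, 1e-12), 1.0),
                                 alpha * mu), mu
        )
        counts[:, j] = rng.poisson(lam)

    count_df = pd.DataFrame(counts, index=contig_map.index, columns=samples)
    truth = GroundTruth(da_mags=dict(effects.mag_lfc))
    return count_df, contig_map, truth


# ---------------------------------------------------------------------------
# annotations


def simulate_annotations(
    taxonomy: pd.DataFrame,
    ko_carriage: pd.DataFrame,
    pathway_map: pd.DataFrame,
    cazy_profiles: Mapping[str, Mapping[str, int]] | None = None,
    jitter: bool = False,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Build MAG-by-KO and MAG-by-CAZy-family annotation count matrices.

    ``ko_carriage`` has columns ``ko, mag_id, count`` (explicit planted
    carriage); ``pathway_map`` has columns ``ko, pathway`` and must cover
    every KO.  CAZy counts come from per-phylum family profiles and are
    deterministic; with ``jitter`` the KO counts are Poisson draws around
    the planted means.
    """
    mags = list(taxonomy["genome_id"])
    kos = sorted(ko_carriage["ko"].unique())
    unmapped = set(kos) - set(pathway_map["ko"])
    if unmapped:
        raise ValueError(f"KOs absent from pathway map: {sorted(unmapped)[:5]}")
    ko_mat = pd.DataFrame(0, index=mags, columns=kos, dtype=int)
    for _, row in ko_carriage.iterrows():
        ko_mat.loc[row["mag_id"], row["ko"]] = int(row["count"])
    if jitter:
        rng = np.random.default_rng(seed)
        ko_mat = pd.DataFrame(
            rng.poisson(ko_mat.to_numpy()), index=mags, columns=kos
        )
    ko_mat.index.name = "genome_id"

    cazy_profiles = cazy_profiles or {}
    families = sorted({f for prof in cazy_profiles.values() for f in prof})
    cazy_mat = pd.DataFrame(0, index=mags, columns=families, dtype=int)
    phylum_of = dict(zip(taxonomy["genome_id"], taxonomy["phylum"]))
    for mag in mags:
        prof = cazy_profiles.get(phylum_of[mag], {})
        for fam, n in prof.items():
            cazy_mat.loc[mag, fam] = int(n)
    cazy_mat.index.name = "genome_id"
    return ko_mat, cazy_mat


# ---------------------------------------------------------------------------
# the end-to-end preset


@dataclass
class SimulatedStudy:
    """One complete synthetic crossover feeding study."""

    metadata: pd.DataFrame          # all 24 samples; filter before analysis
    taxonomy: pd.DataFrame
    effects: EffectSpec
    contig_counts: pd.DataFrame
    contig_map: pd.DataFrame
    ko_mag: pd.DataFrame            # MAG x KO annotation counts
    cazy_mag: pd.DataFrame          # MAG x CAZy family counts
    pathway_map: pd.DataFrame       # columns: ko, pathway
    truth: GroundTruth


def _mag_block(prefix: str, n: int) -> list[str]:
    return [f"{prefix}{i:03d}" for i in range(n)]


def interplay_preset(
    seed: int = 0,
    da_lfc: float = 3.0,
    drift_lfc: float = -0.2,
    n_background_kos: int = 1200,
    jitter_annotations: bool = False,
) -> SimulatedStudy:
    """Crossover study with planted pathway-level interplay scenarios.

    Community of 200 MAGs: 8 strongly enriched under diet restriction
    (log2 fold change +3 for both the 40vs80 and 60vs80 contrasts,
    dispersion 0.05), 4 strongly depleted (-3), 80 "drift" MAGs with a
    small shared depletion (-0.2, contig dispersion 0.3) that is undetectable
    per MAG but visible once aggregated over the group, and 108 flat
    MAGs (dispersion 0.15) in four taxa.  Two of the flat taxa
    (Prevotella, Bacteroidales; 80 MAGs) co-vary: all members of a taxon
    share one lognormal abundance factor per sample (sd 0.18), the
    ecological noise that keeps diluted community-wide shifts from
    reaching significance.  The two remaining flat taxa are quiet and carry
    the null background KOs, so library-size factors stay
    anchored.  KO carriage realizes the three interplay scenarios across
    the four focus pathways:

    * amino acid metabolism — carried by the enriched MAGs: the overall
      functional shift and the shift attributable to differentially
      abundant MAGs agree (both strongly positive).
    * energy metabolism — carried by the depleted MAGs: agreement in the
      negative direction.
    * carbohydrate metabolism — mostly carried by the drift group, whose
      many small shifts make the overall change significant but small,
      while the attributable change is strongly positive: a disconnect.
    * nucleotide metabolism — a large, noisy flat background dilutes the
      enriched MAGs' contribution so no KO shifts significantly overall,
      yet the attributable change is strongly positive: attribution-only.

    Scenario labels recorded in the ground truth follow analytically from
    this planted carriage.
    """
    up = _mag_block("up", 8)
    down = _mag_block("dn", 4)
    drift = _mag_block("dr", 80)
    flat = _mag_block("fl", 108)
    mags = up + down + drift + flat
    flat_taxa = {
        ("Bacteroidetes", "Prevotella"): flat[:50],        # co-varying
        ("Bacteroidetes", "Bacteroidales"): flat[50:80],   # co-varying
        ("Euryarchaeota", "Methanobrevibacter"): flat[80:100],  # quiet
        ("Spirochaetes", "Treponema"): flat[100:108],           # quiet
    }
    noisy = flat[:80]
    quiet = flat[80:]

    genus_of: dict[str, tuple[str, str]] = {}  # mag -> (phylum, genus)
    for m in up[:3]:
        genus_of[m] = ("Firmicutes", "Ruminococcus")
    for m in up[3:6]:
        genus_of[m] = ("Bacteroidetes", "Bacteroides")
    for m in up[6:]:
        genus_of[m] = ("Bacteroidetes", "Prevotella")
    for m in down:
        genus_of[m] = ("Firmicutes", "Clostridiales")
    for m in drift:
        genus_of[m] = ("Firmicutes", "Lachnospiraceae")
    for (phylum, genus), members in flat_taxa.items():
        for m in members:
            genus_of[m] = (phylum, genus)
    taxonomy = pd.DataFrame(
        {
            "genome_id": mags,
            "domain": ["Archaea" if genus_of[m][0] == "Euryarchaeota" else "Bacteria" for m in mags],
            "phylum": [genus_of[m][0] for m in mags],
            "genus": [genus_of[m][1] for m in mags],
        }
    )

    effects = EffectSpec(
        mag_lfc={
            **{m: (da_lfc, da_lfc) for m in up},
            **{m: (-da_lfc, -da_lfc) for m in down},
            **{m: (drift_lfc, drift_lfc) for m in drift},
        },
        mag_dispersion={
            **{m: 0.05 for m in up + down},
            **{m: 0.3 for m in drift},
            # dilution background: per-MAG noise dominates the shared
            # taxon factor, so no correlated block of abundance calls can
            # arise, while the factor still dominates once counts are
            # aggregated over the whole group
            **{m: 0.45 for m in noisy},
        },
        dispersion=0.15,
        noise_groups={
            "flat_Prevotella": (flat[:50], 0.18),
            "flat_Bacteroidales": (flat[50:80], 0.18),
        },
    )

    metadata = crossover_metadata()
    contig_counts, contig_map, _ = simulate_counts(metadata, mags, effects, seed=seed)

    # --- KO carriage per the scenario design ---
    carriage_rows: list[tuple[str, str, int]] = []
    pathway_rows: list[tuple[str, str]] = []

    def plant(ko: str, pathway: str, carriers: Sequence[str], count: int) -> None:
        pathway_rows.append((ko, pathway))
        carriage_rows.extend((ko, m, count) for m in carriers)

    for i in range(12):  # agreement, positive: carried by enriched MAGs
        ko = f"K_aa{i:02d}"
        plant(ko, "amino_acid_metabolism", up, 4)
        carriage_rows.extend((ko, m, 1) for m in quiet[:20])
    for i in range(10):  # agreement, negative: carried by depleted MAGs
        ko = f"K_en{i:02d}"
        plant(ko, "energy_metabolism", down, 8)
        carriage_rows.extend((ko, m, 1) for m in quiet[20:])
    for i in range(10):
        # disconnect: the pathway's significant KOs are depleted-MAG led
        # (pooled overall change negative), while enriched-MAG carriage —
        # diluted into insignificance by the noisy background — owns the
        # attributable change (positive)
        ko = f"K_cb{i:02d}"
        if i < 5:
            plant(ko, "carbohydrate_metabolism", up, 3)
            carriage_rows.extend((ko, m, 12) for m in noisy)
        else:
            plant(ko, "carbohydrate_metabolism", down, 6)
    for i in range(5):  # attribution-only: huge noisy flat background
        ko = f"K_nt{i:02d}"
        plant(ko, "nucleotide_metabolism", noisy, 15)
        carriage_rows.extend((ko, m, 2) for m in up)

    rng = _rng(seed, "background_kos")
    background_pathways = (
        "translation", "membrane_transport", "replication_repair",
        "cofactor_vitamin_metabolism",
    )
    for i in range(n_background_kos):
        ko = f"K_bg{i:04d}"
        # null background carried by the quiet flat taxa only
        carriers = rng.choice(len(quiet), size=12, replace=False)
        count = int(rng.integers(1, 4))
        plant(ko, background_pathways[i % 4], [quiet[c] for c in carriers], count)

    ko_carriage = pd.DataFrame(carriage_rows, columns=["ko", "mag_id", "count"])
    pathway_map = pd.DataFrame(pathway_rows, columns=["ko", "pathway"])

    cazy_profiles = {
        "Bacteroidetes": {"GH2": 30, "GH3": 24, "GH43": 12, "GT2": 10, "GT4": 6,
                          "PL1": 2, "CE1": 7, "CBM50": 3},
        "Firmicutes": {"GH13": 20, "GH3": 12, "GT2": 12, "GT35": 4, "CE4": 6,
                       "CBM6": 2, "AA3": 1},
        "Euryarchaeota": {"GT2": 8, "GT4": 6, "GH13": 1},
        "Spirochaetes": {"GH2": 8, "GH13": 6, "GT2": 5, "CE1": 2, "PL11": 1},
    }
    ko_mag, cazy_mag = simulate_annotations(
        taxonomy, ko_carriage, pathway_map, cazy_profiles,
        jitter=jitter_annotations, seed=_subseed(seed, "annotations"),
    )

    truth = GroundTruth(
        da_mags={m: effects.mag_lfc[m] for m in up + down},
        da_kos={f"K_aa{i:02d}" for i in range(12)}
        | {f"K_en{i:02d}" for i in range(10)}
        | {f"K_cb{i:02d}" for i in range(5, 10)},
        scenarios={
            (p, contrast): label
            for contrast in ("40vs80", "60vs80")
            for p, label in [
                ("amino_acid_metabolism", "agreement"),
                ("carbohydrate_metabolism", "disconnect"),
                ("energy_metabolism", "agreement"),
                ("nucleotide_metabolism", "attribution-only"),
            ]
        },
    )
    return SimulatedStudy(
        metadata=metadata,
        taxonomy=taxonomy,
        effects=effects,
        contig_counts=contig_counts,
        contig_map=contig_map,
        ko_mag=ko_mag,
        cazy_mag=cazy_mag,
        pathway_map=pathway_map,
        truth=truth,
    )


def _subseed(seed: int, label: str) -> int:
    return int(_rng(seed, label).integers(0, 2**31 - 1))


def da_benchmark_counts(
    n_da: int = 30,
    n_null: int = 300,
    lfc: float = 2.0,
    dispersion: float = 0.1,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """MAG-level count matrix for differential-abundance benchmarking.

    Plants ``n_da`` MAGs at the given |log2 fold change| (40 vs 80 %MER,
    the 60% diet halfway on the log scale) among ``n_null`` unaffected
    MAGs on the filtered 14-sample crossover.  Two thirds of the planted
    MAGs are enriched and one third depleted, mirroring the 20:10 split
    of the study's differentially abundant genomes; mixed signs also keep
    the planted fraction from biasing the median-of-ratios size factors.
    Returns (MAG counts, filtered metadata, truth).
    """
    from .io import filter_samples

    mags = [f"da{i:03d}" for i in range(n_da)] + [f"nu{i:03d}" for i in range(n_null)]
    n_up = (2 * n_da + 2) // 3
    effects = EffectSpec(
        mag_lfc={
            m: ((lfc, lfc / 2.0) if i < n_up else (-lfc, -lfc / 2.0))
            for i, m in enumerate(mags[:n_da])
        },
        dispersion=dispersion,
        contigs_per_mag=1,
        batch_sd_animal=0.25,
        batch_sd_period=0.15,
    )
    metadata = filter_samples(crossover_metadata())
    counts, contig_map, truth = simulate_counts(metadata, mags, effects, seed=seed)
    counts.index = contig_map["mag_id"]
    counts.index.name = "mag_id"
    return counts, metadata, truth
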