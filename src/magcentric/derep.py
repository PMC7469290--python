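"""Quality filtering, scoring and two-stage ANI dereplication of MAGs.

Genomes passing the completeness/contamination filter are grouped into
primary clusters by average-linkage hierarchical clustering on sketch
(MinHash) distances cut at 10% divergence (90% ANI), then each primary
cluster is refined into secondary clusters on exact full k-mer-set
distances cut at 1% (99% ANI).  One winner is retained per secondary
cluster: the genome maximizing the dereplication score

    S = completeness - 5 * contamination
        + contamination * (strain_heterogeneity / 100)
        + 0.5 * log10(contig N50),

with ties broken lexicographically on genome id.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .sketch import (
    DEFAULT_HASH_SEED,
    DEFAULT_K,
    DEFAULT_SKETCH_SIZE,
    Sketch,
    exact_kmer_distance,
    sketch_genome,
)

logger = logging.getLogger(__name__)


@dataclass
class GenomeRecord:
    """One MAG's quality metrics, optionally with its sketch attached."""

    genome_id: str
    completeness: float          # percent, 0..100
    contamination: float         # percent, >= 0
    strain_heterogeneity: float = 0.0
    contig_n50: int = 10_000     # bp
    genome_size: int = 0         # bp
    sketch: Sketch | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.completeness <= 100.0:
            raise ValueError(f"{self.genome_id}: completeness outside [0, 100]")
        if self.contamination < 0.0:
            raise ValueError(f"{self.genome_id}: negative contamination")
        if self.contig_n50 < 1:
            raise ValueError(f"{self.genome_id}: N50 < 1")


def records_from_quality_table(table: pd.DataFrame) -> list[GenomeRecord]:
    """Build records from a quality table (genome_id, completeness, ...)."""
    return [
        GenomeRecord(
            genome_id=str(row["genome_id"]),
            completeness=float(row["completeness"]),
            contamination=float(row["contamination"]),
            strain_heterogeneity=float(row.get("strain_heterogeneity", 0.0)),
            contig_n50=int(row.get("contig_n50", 10_000)),
            genome_size=int(row.get("genome_size", 0)),
        )
        for _, row in table.iterrows()
    ]


def filter_quality(
    records: Iterable[GenomeRecord],
    min_completeness: float = 80.0,
    max_contamination: float = 10.0,
) -> list[GenomeRecord]:
    """Keep genomes with completeness >= 80% and contamination <= 10% (inclusive)."""
    records = list(records)
    kept = [
        r
        for r in records
        if r.completeness >= min_completeness and r.contamination <= max_contamination
    ]
    if not kept:
        logger.warning("quality filter removed all %d genomes", len(records))
    return kept


def score_genome(record: GenomeRecord) -> float:
    """Dereplication score trading completeness against contamination and assembly quality."""
    return (
        record.completeness
        - 5.0 * record.contamination
        + record.contamination * (record.strain_heterogeneity / 100.0)
        + 0.5 * math.log10(record.contig_n50)
    )


def dereplicate(
    records: Sequence[GenomeRecord],
    sequences: Mapping[str, str],
    primary_ani: float = 0.90,
    secondary_ani: float = 0.99,
    k: int = DEFAULT_K,
    sketch_size: int = DEFAULT_SKETCH_SIZE,
    hash_seed: int = DEFAULT_HASH_SEED,
) -> pd.DataFrame:
    """Two-stage dereplication; returns one row per genome.

    Columns: ``primary_cluster``, ``secondary_cluster``, ``score``,
    ``is_winner``.  Cluster ids are dense integers; secondary ids refine
    primary ids.  Records without a sketch are sketched from ``sequences``.
    """
    if not records:
        raise ValueError("no genomes to dereplicate")
    ids = [r.genome_id for r in records]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate genome ids")
    missing = [r.genome_id for r in records if r.genome_id not in sequences]
    if missing:
        raise ValueError(f"missing sequences for {missing[:5]}")

    sketches = {}
    for r in records:
        if r.sketch is None:
            r.sketch = sketch_genome(sequences[r.genome_id], k, sketch_size, hash_seed)
        sketches[r.genome_id] = r.sketch

    primary_cut = 1.0 - primary_ani
    secondary_cut = 1.0 - secondary_ani

    # primary stage on raw hash arrays: tight loop over all pairs
    from .sketch import _bottom_s_jaccard, jaccard_to_distance

    hash_arrays = [sketches[g].hashes for g in ids]
    n = len(ids)
    if n > 1:
        mat = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                jac = _bottom_s_jaccard(hash_arrays[i], hash_arrays[j], sketch_size)
                mat[i, j] = mat[j, i] = jaccard_to_distance(jac, k)
        labels = fcluster(
            linkage(squareform(mat), method="average"), t=primary_cut,
            criterion="distance",
        )
        primary = {g: int(c) - 1 for g, c in zip(ids, labels)}
    else:
        primary = {ids[0]: 0}

    # refine each primary cluster on exact full k-mer-set distances
    secondary = {}
    next_id = 0
    for cluster_members in _group_members(primary):
        sub = _average_linkage_clusters(
            cluster_members,
            lambda a, b: exact_kmer_distance(sequences[a], sequences[b], k).distance,
            secondary_cut,
        )
        remap = {}
        for gid, c in sub.items():
            if c not in remap:
                remap[c] = next_id
                next_id += 1
            secondary[gid] = remap[c]

    by_id = {r.genome_id: r for r in records}
    out = pd.DataFrame(
        {
            "genome_id": ids,
            "primary_cluster": [primary[g] for g in ids],
            "secondary_cluster": [secondary[g] for g in ids],
            "score": [score_genome(by_id[g]) for g in ids],
        }
    ).set_index("genome_id")
    out["is_winner"] = False
    for _, members in out.groupby("secondary_cluster"):
        winner = members.sort_values(
            ["score", "genome_id"], ascending=[False, True],
            key=lambda s: s if s.name == "score" else s.astype(str),
        ).index[0]
        out.loc[winner, "is_winner"] = True
    return out


def _average_linkage_clusters(ids, dist, cut):
    if len(ids) == 1:
        return {ids[0]: 0}
    n = len(ids)
    mat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            mat[i, j] = mat[j, i] = dist(ids[i], ids[j])
    labels = fcluster(linkage(squareform(mat), method="average"), t=cut, criterion="distance")
    return {g: int(c) - 1 for g, c in zip(ids, labels)}


def _group_members(assignment: dict[str, int]) -> list[list[str]]:
    groups: dict[int, list[str]] = {}
    for gid, c in assignment.items():
        groups.setdefault(c, []).append(gid)
    return [groups[c] for c in sorted(groups)]


def cluster_size_summary(assignments: pd.DataFrame | Mapping[int, int]) -> pd.DataFrame:
    """Summarize secondary clusters by size, with a totals row.

    Accepts either a dereplication assignment table or a mapping
    ``cluster size -> number of clusters``.  Percentages are of all genomes,
    rounded to 2 decimal places; sizes are listed in decreasing order.
    """
    if isinstance(assignments, pd.DataFrame):
        sizes = assignments.groupby("secondary_cluster").size()
        counts = sizes.value_counts().to_dict()
    else:
        counts = dict(assignments)
    total_genomes = sum(size * n for size, n in counts.items())
    rows = []
    for size in sorted(counts, reverse=True):
        genomes = size * counts[size]
        rows.append(
            {
                "cluster_size": size,
                "n_clusters": counts[size],
                "n_genomes": genomes,
                "pct_genomes": round(100.0 * genomes / total_genomes, 2),
            }
        )
    rows.append(
        {
            "cluster_size": "total",
            "n_clusters": sum(counts.values()),
            "n_genomes": total_genomes,
            "pct_genomes": round(sum(r["pct_genomes"] for r in rows), 2),
        }
    )
    return pd.DataFrame(rows).set_index("cluster_size")
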