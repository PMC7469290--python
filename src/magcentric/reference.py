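"""Published summary tables for the African-cattle rumen MAG catalogue.

These are the printed, dataset-level summaries of the 1200 high-quality
African rumen MAGs and the public comparison catalogues (the original 913
Scottish-cattle RUGs, the RUG 2.0 release and the Hungate collection).  The
underlying reads and genomes live in public archives and are not required:
the numbers below are inputs to the desk-scale arithmetic the package
reproduces (cluster-size summaries, phylum proportions, CAZyme module
percentages, cross-catalogue correlations).
"""

from __future__ import annotations

import pandas as pd

#: Secondary-cluster size distribution of the 1200 high-quality MAGs after
#: two-stage dereplication: cluster size -> number of clusters.
SECONDARY_CLUSTER_SIZES: dict[int, int] = {
    7: 3, 6: 3, 5: 7, 4: 12, 3: 44, 2: 165, 1: 616,
}

#: Phylum-level genome counts per catalogue.  Columns: the 1200 high-quality
#: African MAGs, the 850 dereplicated "winning" MAGs, the 850 Scottish RUGs
#: column as printed, and the 4941 RUG 2.0 genomes.  "Bacteria" collects
#: genomes unresolved below domain.
PHYLUM_GENOME_COUNTS = pd.DataFrame(
    {
        "high_quality_mags": [385, 514, 85, 3, 3, 76, 7, 22, 9, 5, 1, 16, 1, 1, 7, 65],
        "winning_mags": [253, 377, 65, 2, 2, 50, 6, 16, 5, 4, 1, 13, 1, 1, 6, 48],
        "scottish_rugs": [288, 391, 30, 6, 30, 8, 10, 4, 4, 1, 0, 8, 0, 0, 29, 41],
        "rug2": [1707, 2407, 133, 42, 164, 20, 59, 118, 12, 0, 47, 26, 0, 0, 126, 80],
    },
    index=pd.Index(
        [
            "Bacteroidetes", "Firmicutes", "Proteobacteria", "Fibrobacteres",
            "Actinobacteria", "Lentisphaerae", "Spirochaetes", "Tenericutes",
            "Planctomycetes", "Fusobacteria", "Verrucomicrobia", "Elusimicrobia",
            "Synergistetes", "Ignavibacteriae", "Euryarchaeota", "Bacteria",
        ],
        name="phylum",
    ),
)

#: CAZyme counts per CAZy module in each catalogue (GH glycoside hydrolase,
#: GT glycosyl transferase, PL polysaccharide lyase, CE carbohydrate
#: esterase, AA auxiliary activity, CBM carbohydrate-binding module).
CAZY_MODULE_COUNTS = pd.DataFrame(
    {
        "african_mags": [39566, 17473, 1052, 9060, 111, 2366],
        "scottish_rugs": [40140, 19722, 1121, 9119, 154, 2545],
        "rug2": [235001, 120494, 6834, 55523, 907, 23928],
    },
    index=pd.Index(["GH", "GT", "PL", "CE", "AA", "CBM"], name="module"),
)

#: The crossover feeding design: 6 animals x 4 periods, diet given as
#: percent of maintenance energy requirement fed in that period.
CROSSOVER_DESIGN: dict[str, tuple[int, int, int, int]] = {
    "41": (80, 60, 40, 100),
    "43": (60, 40, 100, 80),
    "46": (100, 80, 60, 40),
    "47": (40, 100, 80, 60),
    "49": (40, 100, 80, 60),
    "52": (100, 80, 60, 40),
}


def crossover_metadata() -> pd.DataFrame:
    """The 24-sample crossover sample sheet implied by the feeding design."""
    rows = [
        {
            "sample_id": f"A{animal}P{period}",
            "animal": animal,
            "period": period,
            "diet": diet,
        }
        for animal, diets in CROSSOVER_DESIGN.items()
        for period, diet in enumerate(diets, start=1)
    ]
    return pd.DataFrame(rows, columns=["sample_id", "animal", "period", "diet"])
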