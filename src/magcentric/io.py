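"""Readers, writers and sample-filtering rules for the pipeline's tabular inputs.

All matrices travel as tab-separated UTF-8 text with a header row; feature
labels live in the first column.  Missing cells are an error rather than an
implicit zero: silently zero-filling a join is the classic way to hide a
mismatched annotation table.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

METADATA_COLUMNS = ("sample_id", "animal", "period", "diet")
TAXONOMY_RANKS = ("domain", "phylum", "class", "order", "family", "genus")
#: Sentinel used for ranks that could not be resolved.
UNCLASSIFIED = "unclassified"

_IUPAC = set("ACGTRYSWKMBDHVN")


class TableFormatError(ValueError):
    """A tabular input violates its contract (labels, signs, missing cells)."""


# ---------------------------------------------------------------------------
# count matrices


def read_count_table(path: str | Path) -> pd.DataFrame:
    """Read a feature-by-sample count table from TSV.

    The first column holds feature ids, the header row sample ids.  Cells
    must be numeric and nonnegative; duplicated row or column labels and
    missing cells are rejected with coordinates.
    """
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
    _check_unique(pd.Index(header[1:]), f"{path}: duplicated column header")
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    _check_unique(df.index, f"{path}: duplicated row label")
    for col in df.columns:
        if not pd.api.types.is_numeric_dtype(df[col]):
            bad = df.index[pd.to_numeric(df[col], errors="coerce").isna()][0]
            raise TableFormatError(
                f"{path}: non-numeric cell at row {bad!r}, column {col!r}"
            )
    if df.isna().any().any():
        r, c = _first_offender(df.isna())
        raise TableFormatError(f"{path}: missing cell at row {r!r}, column {c!r}")
    if (df.values < 0).any():
        r, c = _first_offender(df < 0)
        raise TableFormatError(
            f"{path}: negative value at row {r!r}, column {c!r}"
        )
    return df


def write_count_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t")


def _check_unique(labels: pd.Index, msg: str) -> None:
    if labels.duplicated().any():
        dup = labels[labels.duplicated()][0]
        raise TableFormatError(f"{msg}: {dup!r}")


def _first_offender(mask: pd.DataFrame) -> tuple[str, str]:
    stacked = mask.stack()
    r, c = stacked[stacked].index[0]
    return str(r), str(c)


# ---------------------------------------------------------------------------
# sequences


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read FASTA into an id -> uppercase sequence mapping.

    Duplicate ids and empty records are rejected.  Non-ACGT IUPAC symbols
    are retained but flagged through the module logger; k-mer code skips
    them downstream.
    """
    records: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in records:
            raise TableFormatError(f"{path}: duplicate sequence id {rec.id!r}")
        seq = str(rec.seq).upper()
        if not seq:
            raise TableFormatError(f"{path}: empty record {rec.id!r}")
        extra = set(seq) - set("ACGT")
        if extra:
            bad = extra - _IUPAC
            if bad:
                raise TableFormatError(
                    f"{path}: record {rec.id!r} contains non-IUPAC symbols {sorted(bad)}"
                )
            logger.warning(
                "record %s contains %d ambiguous symbols (%s)",
                rec.id, sum(seq.count(s) for s in extra), "".join(sorted(extra)),
            )
        records[rec.id] = seq
    if not records:
        raise TableFormatError(f"{path}: no FASTA records found")
    return records


def write_fasta(sequences: Mapping[str, str], path: str | Path, width: int = 80) -> None:
    recs = [
        SeqRecord(Seq(seq), id=name, description="")
        for name, seq in sequences.items()
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(recs)


# ---------------------------------------------------------------------------
# sample metadata


def validate_metadata(metadata: pd.DataFrame) -> pd.DataFrame:
    """Validate a crossover-design sample sheet.

    Expects columns ``sample_id, animal, period, diet`` with unique sample
    ids, at most one sample per (animal, period), periods in 1..4 and diets
    given as percent of maintenance energy requirement (40/60/80/100).
    """
    missing = set(METADATA_COLUMNS) - set(metadata.columns)
    if missing:
        raise TableFormatError(f"metadata missing columns {sorted(missing)}")
    md = metadata.copy()
    md["sample_id"] = md["sample_id"].astype(str)
    md["animal"] = md["animal"].astype(str)
    md["period"] = md["period"].astype(int)
    md["diet"] = md["diet"].astype(int)
    _check_unique(pd.Index(md["sample_id"]), "duplicated sample_id")
    if md.duplicated(subset=["animal", "period"]).any():
        pair = md[md.duplicated(subset=["animal", "period"])].iloc[0]
        raise TableFormatError(
            f"animal {pair['animal']!r} sampled twice in period {pair['period']}"
        )
    if not md["period"].between(1, 4).all():
        raise TableFormatError("period outside 1..4")
    if not md["diet"].isin([40, 60, 80, 100]).all():
        raise TableFormatError("diet must be one of 40/60/80/100 %MER")
    return md


def read_metadata(path: str | Path) -> pd.DataFrame:
    return validate_metadata(pd.read_csv(path, sep="\t"))


def filter_samples(
    metadata: pd.DataFrame,
    exclude_periods: Iterable[int] = (1,),
    exclude_diets: Iterable[int] = (100,),
) -> pd.DataFrame:
    """Drop samples from excluded periods and diet treatments.

    Defaults drop the first (no-glycerol storage) period and the
    compositionally distinct 100 %MER diet, which on the standard 6-animal,
    4-period crossover leaves 14 samples in 4:5:5 groups for 40/60/80 %MER.
    Idempotent; an empty result is an error.
    """
    md = validate_metadata(metadata)
    keep = ~md["period"].isin(set(exclude_periods)) & ~md["diet"].isin(set(exclude_diets))
    out = md[keep].reset_index(drop=True)
    if out.empty:
        raise TableFormatError("sample filtering removed every sample")
    return out


# ---------------------------------------------------------------------------
# taxonomy


def validate_taxonomy(taxonomy: pd.DataFrame) -> pd.DataFrame:
    """Validate a genome taxonomy table (``genome_id`` + domain..genus ranks).

    Unresolved ranks carry the ``unclassified`` sentinel; empty cells are
    promoted to it.  Ranks never resolve below genus.
    """
    if "genome_id" not in taxonomy.columns:
        raise TableFormatError("taxonomy table missing 'genome_id' column")
    tx = taxonomy.copy()
    tx["genome_id"] = tx["genome_id"].astype(str)
    _check_unique(pd.Index(tx["genome_id"]), "duplicated genome_id")
    for rank in TAXONOMY_RANKS:
        if rank not in tx.columns:
            tx[rank] = UNCLASSIFIED
        tx[rank] = tx[rank].fillna(UNCLASSIFIED).astype(str)
    return tx[["genome_id", *TAXONOMY_RANKS]]


def read_taxonomy(path: str | Path) -> pd.DataFrame:
    return validate_taxonomy(pd.read_csv(path, sep="\t"))


# ---------------------------------------------------------------------------
# configuration

#: Every tunable of every stage, with the pipeline's default values.
DEFAULT_CONFIG: dict = {
    "seed": 42,
    "sketch": {"k": 21, "size": 100000, "hash_seed": 42},
    "quality": {"min_completeness": 80.0, "max_contamination": 10.0},
    "dereplicate": {"primary_ani": 0.90, "secondary_ani": 0.99},
    "filter_samples": {"exclude_periods": [1], "exclude_diets": [100]},
    "bias": {"n_gc_bins": 10},
    "permanova": {"n_perm": 9999},
    "power": {"n_matrices": 1000, "n_perm": 9999, "alpha": [0.05, 0.01, 0.001]},
    "differential_abundance": {"fdr": 0.05, "dispersion_floor": 1e-8,
                               "max_iter": 100, "tol": 1e-8},
    "attribution": {"pseudocount": 1.0, "lfc_threshold": 0.5, "fdr": 0.05},
}


def load_config(path: str | Path | None = None) -> dict:
    """Load a YAML configuration, overlaying user values onto the defaults."""
    config = _deep_copy(DEFAULT_CONFIG)
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        _deep_update(config, user)
    return config


def _deep_copy(d: dict) -> dict:
    return {k: _deep_copy(v) if isinstance(v, dict) else v for k, v in d.items()}


def _deep_update(base: dict, extra: dict) -> None:
    for k, v in extra.items():
        if isinstance(v, dict) and isinstance(base.get(k), dict):
            _deep_update(base[k], v)
        else:
            base[k] = v
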