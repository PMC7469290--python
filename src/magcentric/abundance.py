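"""From contig-level read counts to bias-corrected MAG abundance profiles.

The pipeline is: (1) within-sample correction of contig counts for contig
length (counts per kb) and GC-content bias (full-quantile normalization
across GC deciles), (2) aggregation of contig values to their MAG,
(3) Hellinger transformation (square root of relative abundance),
(4) removal of additive animal/period batch effects by per-feature linear
residualization that preserves the diet component, and (5) phylum-level
relative-abundance summaries per diet treatment.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class AbundanceMatrix:
    """A MAG-by-sample abundance table with provenance flags.

    Flags are monotone: once a matrix is marked bias-corrected,
    transformed or batch-corrected it never loses the mark.
    """

    values: pd.DataFrame
    bias_corrected: bool = False
    transformed: bool = False
    batch_corrected: bool = False
    provenance: list[str] = field(default_factory=list)


def _check_contig_cover(counts: pd.DataFrame, contigs: pd.DataFrame) -> None:
    missing = counts.index.difference(contigs.index)
    if len(missing):
        raise ValueError(f"contigs absent from contig map: {list(missing[:5])}")


def correct_bias(
    counts: pd.DataFrame, contigs: pd.DataFrame, n_gc_bins: int = 10
) -> pd.DataFrame:
    """Correct contig counts for length and GC-content bias, per sample.

    Counts are first scaled to counts per kb.  Contigs are stratified into
    ``n_gc_bins`` equal-frequency GC bins (ties broken by contig id for
    determinism); within each sample, each stratum's empirical distribution
    of rates is replaced by the average quantile function over all strata
    (full-quantile normalization), which removes any monotone dependence of
    counts on GC while preserving within-stratum ranks.  Each sample is
    rescaled so its total equals the input total.
    """
    _check_contig_cover(counts, contigs)
    contigs = contigs.loc[counts.index]
    length_kb = contigs["length"].to_numpy(float) / 1000.0
    order = np.lexsort((counts.index.astype(str), contigs["gc"].to_numpy()))
    bins = np.empty(len(counts), dtype=int)
    bins[order] = np.arange(len(counts)) * n_gc_bins // len(counts)

    rates = counts.to_numpy(float) / length_kb[:, None]
    out = np.empty_like(rates)
    members = [np.flatnonzero(bins == b) for b in range(n_gc_bins)]
    for j in range(rates.shape[1]):
        col = rates[:, j]
        sorted_strata = [np.sort(col[m]) for m in members]
        knots = [(np.arange(s.size) + 0.5) / s.size for s in sorted_strata]
        for b in range(n_gc_bins):
            m = members[b]
            n = m.size
            ranks = np.empty(n)
            ranks[np.argsort(col[m], kind="stable")] = (np.arange(n) + 0.5) / n
            # average quantile function over all strata at this stratum's ranks
            ref = np.mean(
                [np.interp(ranks, knots[b2], sorted_strata[b2]) for b2 in range(n_gc_bins)],
                axis=0,
            )
            out[m, j] = ref
        total_in = col @ length_kb  # original counts
        total_out = out[:, j].sum()
        if total_out > 0:
            out[:, j] *= total_in / total_out
    return pd.DataFrame(out, index=counts.index, columns=counts.columns)


def aggregate_to_mag(
    counts: pd.DataFrame, contigs: pd.DataFrame, bias_corrected: bool = False
) -> AbundanceMatrix:
    """Sum contig-level values to MAG level; column totals are preserved."""
    _check_contig_cover(counts, contigs)
    mag = counts.groupby(contigs.loc[counts.index, "mag_id"]).sum()
    mag.index.name = "mag_id"
    return AbundanceMatrix(
        values=mag,
        bias_corrected=bias_corrected,
        provenance=["aggregated contigs to MAGs"],
    )


def hellinger(matrix: AbundanceMatrix | pd.DataFrame) -> AbundanceMatrix:
    """Square root of relative abundance, per sample (column).

    Each transformed sample has unit sum of squares, and the transform is
    invariant to rescaling a sample's library size.
    """
    values = matrix.values if isinstance(matrix, AbundanceMatrix) else matrix
    totals = values.sum(axis=0)
    zero = totals[totals <= 0]
    if len(zero):
        raise ValueError(f"all-zero sample(s): {list(zero.index[:5])}")
    trans = np.sqrt(values / totals)
    if isinstance(matrix, AbundanceMatrix):
        return AbundanceMatrix(
            values=trans,
            bias_corrected=matrix.bias_corrected,
            transformed=True,
            batch_corrected=matrix.batch_corrected,
            provenance=matrix.provenance + ["Hellinger transform"],
        )
    return AbundanceMatrix(values=trans, transformed=True,
                           provenance=["Hellinger transform"])


def _design_columns(metadata: pd.DataFrame, var: str) -> pd.DataFrame:
    return pd.get_dummies(metadata[var].astype(str), prefix=var, drop_first=True).astype(float)


def remove_batch(
    matrix: AbundanceMatrix | pd.DataFrame,
    metadata: pd.DataFrame,
    batch_vars: tuple[str, ...] = ("animal", "period"),
    keep_vars: tuple[str, ...] = ("diet",),
) -> AbundanceMatrix:
    """Remove additive batch effects, keeping the treatment component.

    Per feature, ordinary least squares is fit on an intercept plus dummy
    columns for ``keep_vars`` and ``batch_vars`` jointly, and only the
    estimated batch components are subtracted; refitting the same model on
    the output yields batch coefficients of zero.  Batch columns that are
    linear combinations of the kept design (aliasing) are an error.
    """
    values = matrix.values if isinstance(matrix, AbundanceMatrix) else matrix
    md = metadata.set_index("sample_id").loc[values.columns]
    keep = pd.concat(
        [pd.Series(1.0, index=md.index, name="intercept")]
        + [_design_columns(md, v) for v in keep_vars],
        axis=1,
    )
    batch = pd.concat([_design_columns(md, v) for v in batch_vars], axis=1)

    K = keep.to_numpy()
    B = batch.to_numpy()
    # alias check: each batch column must add rank over the kept design
    for name, col in zip(batch.columns, B.T):
        resid = col - K @ np.linalg.lstsq(K, col, rcond=None)[0]
        if np.linalg.norm(resid) < 1e-8 * max(1.0, np.linalg.norm(col)):
            raise ValueError(
                f"batch column {name!r} is aliased with kept variables {keep_vars}"
            )
    X = np.hstack([K, B])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        # aliasing within the batch columns themselves: drop later duplicates
        cols, keep_idx = [], []
        for i in range(X.shape[1]):
            trial = X[:, keep_idx + [i]]
            if np.linalg.matrix_rank(trial) == len(keep_idx) + 1:
                keep_idx.append(i)
        X = X[:, keep_idx]
        batch_mask = np.array([i >= K.shape[1] for i in keep_idx])
    else:
        batch_mask = np.array([False] * K.shape[1] + [True] * B.shape[1])

    Y = values.to_numpy().T  # samples x features
    coef, *_ = np.linalg.lstsq(X, Y, rcond=None)
    fitted_batch = X[:, batch_mask] @ coef[batch_mask]
    cleaned = pd.DataFrame((Y - fitted_batch).T, index=values.index, columns=values.columns)
    if isinstance(matrix, AbundanceMatrix):
        return AbundanceMatrix(
            values=cleaned,
            bias_corrected=matrix.bias_corrected,
            transformed=matrix.transformed,
            batch_corrected=True,
            provenance=matrix.provenance + [f"removed batch effects {batch_vars}"],
        )
    return AbundanceMatrix(values=cleaned, batch_corrected=True,
                           provenance=[f"removed batch effects {batch_vars}"])


def phylum_relative_abundance(
    matrix: AbundanceMatrix | pd.DataFrame,
    taxonomy: pd.DataFrame,
    metadata: pd.DataFrame,
) -> pd.DataFrame:
    """Mean per-sample phylum percentages within each diet treatment.

    Per sample the MAG counts are collapsed to phylum percentages; the
    percentages are then averaged over the samples of each diet, so each
    diet column sums to 100.
    """
    values = matrix.values if isinstance(matrix, AbundanceMatrix) else matrix
    tx = taxonomy.set_index("genome_id")
    missing = values.index.difference(tx.index)
    if len(missing):
        raise ValueError(f"MAGs missing taxonomy: {list(missing[:5])}")
    phylum = values.groupby(tx.loc[values.index, "phylum"]).sum()
    pct = 100.0 * phylum / phylum.sum(axis=0)
    md = metadata.set_index("sample_id").loc[values.columns]
    out = pct.T.groupby(md["diet"]).mean().T
    out.columns = [f"{d}% MER" for d in out.columns]
    out.index.name = "phylum"
    return out
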