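"""Community-structure statistics: distances, ordination, PERMANOVA, power.

PERMANOVA follows the classical one-way partitioning of a distance matrix:
with N samples in a groups,

    SS_total  = sum_{i<j} d_ij^2 / N
    SS_within = sum_g sum_{i<j in g} d_ij^2 / n_g
    pseudo-F  = (SS_between / (a-1)) / (SS_within / (N-a)),
    R^2       = SS_between / SS_total,

and the p-value is the add-one permutation estimate
``(1 + #{F_perm >= F_obs}) / (n_perm + 1)`` under free relabelling, so the
smallest attainable p at 9999 permutations is 0.0001.

Power analysis bootstraps the (transformed, batch-corrected) sample table:
samples are resampled with replacement within each group to a candidate
design size, distances recomputed, PERMANOVA run, and power estimated as
the rejection fraction, reported per batch of resampled matrices so a
distribution and median are available.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from statsmodels.stats.multitest import multipletests


def euclidean_distances(matrix: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Euclidean distances between samples (columns)."""
    if matrix.shape[1] < 2:
        raise ValueError("need at least 2 samples")
    d = squareform(pdist(matrix.to_numpy().T))
    return pd.DataFrame(d, index=matrix.columns, columns=matrix.columns)


@dataclass
class PcoaResult:
    coordinates: pd.DataFrame        # samples x axes
    explained: np.ndarray            # fraction of variance per axis
    eigenvalues: np.ndarray


def pcoa(distances: pd.DataFrame, n_axes: int | None = None) -> PcoaResult:
    """Classical metric scaling of a distance matrix.

    Eigendecomposition of the double-centered squared-distance (Gram)
    matrix; axes are ordered by eigenvalue and the explained fraction is
    relative to the sum of positive eigenvalues.  Substantially negative
    eigenvalues (non-Euclidean input) are clamped with a warning.
    """
    D2 = distances.to_numpy() ** 2
    n = D2.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    G = -0.5 * J @ D2 @ J
    evals, evecs = np.linalg.eigh((G + G.T) / 2.0)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    tol = 1e-8 * max(evals.max(), 1.0)
    if evals.min() < -tol:
        import warnings

        warnings.warn(
            f"non-Euclidean distances: clamping negative eigenvalue {evals.min():.3g}"
        )
    clamped = np.clip(evals, 0.0, None)
    pos = clamped > tol
    coords = evecs[:, pos] * np.sqrt(clamped[pos])
    explained = clamped[pos] / clamped[pos].sum()
    if n_axes is not None:
        coords, explained = coords[:, :n_axes], explained[:n_axes]
    cols = [f"PCo{i + 1}" for i in range(coords.shape[1])]
    return PcoaResult(
        coordinates=pd.DataFrame(coords, index=distances.index, columns=cols),
        explained=explained,
        eigenvalues=evals,
    )


@dataclass
class PermanovaResult:
    pseudo_f: float
    r2: float
    p: float
    n_perm: int
    n_samples: int
    n_groups: int
    seed: int | None = None


def _group_codes(groups) -> np.ndarray:
    codes, _ = pd.factorize(np.asarray(groups))
    return codes


def _f_and_r2(d2: np.ndarray, codes: np.ndarray, n_groups: int) -> tuple[float, float]:
    n = d2.shape[0]
    ss_total = d2[np.triu_indices(n, 1)].sum() / n
    ss_within = 0.0
    for g in range(n_groups):
        idx = np.flatnonzero(codes == g)
        sub = d2[np.ix_(idx, idx)]
        ss_within += sub[np.triu_indices(idx.size, 1)].sum() / idx.size
    ss_between = ss_total - ss_within
    f = (ss_between / (n_groups - 1)) / (ss_within / (n - n_groups))
    return f, ss_between / ss_total


def permanova(
    distances: pd.DataFrame | np.ndarray,
    groups,
    n_perm: int = 9999,
    seed: int | None = 0,
) -> PermanovaResult:
    """One-way PERMANOVA with free label permutation."""
    d = distances.to_numpy() if isinstance(distances, pd.DataFrame) else np.asarray(distances)
    codes = _group_codes(groups)
    if d.shape[0] != codes.size:
        raise ValueError("distance matrix and groups disagree in length")
    n_groups = codes.max() + 1
    if n_groups < 2:
        raise ValueError("need at least 2 groups")
    counts = np.bincount(codes)
    if counts.min() < 2:
        raise ValueError("every group needs at least 2 samples")
    d2 = d ** 2
    f_obs, r2 = _f_and_r2(d2, codes, n_groups)

    rng = np.random.default_rng(seed)
    n = codes.size
    ss_total = d2[np.triu_indices(n, 1)].sum() / n
    # permute sample indices; group blocks are fixed column ranges
    order = np.argsort(codes, kind="stable")
    perms = np.array([rng.permutation(n) for _ in range(n_perm)])[:, order]
    ss_within = np.zeros(n_perm)
    start = 0
    for size in np.bincount(codes):
        block = perms[:, start:start + size]
        ss_within += d2[block[:, :, None], block[:, None, :]].sum(axis=(1, 2)) / (2.0 * size)
        start += size
    ss_between = ss_total - ss_within
    f_perm = (ss_between / (n_groups - 1)) / (ss_within / (n - n_groups))
    p = (1 + int((f_perm >= f_obs - 1e-12).sum())) / (n_perm + 1)
    return PermanovaResult(
        pseudo_f=float(f_obs), r2=float(r2), p=float(p),
        n_perm=n_perm, n_samples=n, n_groups=int(n_groups), seed=seed,
    )


def pairwise_permanova(
    distances: pd.DataFrame,
    groups,
    n_perm: int = 9999,
    seed: int | None = 0,
) -> pd.DataFrame:
    """PERMANOVA on every pair of groups, BH-adjusted across pairs."""
    labels = np.asarray(groups)
    uniq = sorted(pd.unique(labels))
    d = distances.to_numpy()
    rows = []
    for i, a in enumerate(uniq):
        for b in uniq[i + 1:]:
            mask = np.isin(labels, [a, b])
            res = permanova(d[np.ix_(mask, mask)], labels[mask], n_perm=n_perm, seed=seed)
            rows.append(
                {"group_a": a, "group_b": b, "pseudo_f": res.pseudo_f,
                 "r2": res.r2, "p": res.p}
            )
    out = pd.DataFrame(rows)
    out["padj"] = multipletests(out["p"], method="fdr_bh")[1]
    return out


@dataclass
class PowerResult:
    design: tuple[int, ...]
    alpha: float
    powers: np.ndarray       # rejection fraction per batch of resampled matrices
    median_power: float
    n_matrices: int
    n_perm: int


def _resample_group(rng: np.random.Generator, idx: np.ndarray, k: int) -> np.ndarray:
    """Draw k samples from a group: without replacement up to the group size.

    Exact duplicates fabricate within-group similarity that a permutation
    test reads as group structure, so replacement is used only for the
    slots a design demands beyond the group's actual size.
    """
    if k <= idx.size:
        return rng.choice(idx, size=k, replace=False)
    extra = rng.choice(idx, size=k - idx.size, replace=True)
    return np.concatenate([idx, extra])


def permanova_power(
    matrix: pd.DataFrame,
    groups,
    designs: list[tuple[int, ...]],
    alpha: float | list[float] = 0.05,
    n_matrices: int = 1000,
    n_perm: int = 999,
    n_batches: int = 20,
    seed: int = 0,
) -> list[PowerResult]:
    """Bootstrap PERMANOVA power over candidate group-size designs.

    For each design, samples are repeatedly drawn with replacement within
    each observed group to the design's group sizes; Euclidean distances
    are recomputed and PERMANOVA run on each resampled matrix.  Rejection
    fractions are collected in ``n_batches`` batches of matrices, giving a
    power distribution whose median is reported.
    """
    labels = np.asarray(groups)
    uniq = sorted(pd.unique(labels))
    member_idx = [np.flatnonzero(labels == g) for g in uniq]
    alphas = [alpha] if np.isscalar(alpha) else list(alpha)
    X = matrix.to_numpy()
    rng = np.random.default_rng(seed)

    results = []
    for design in designs:
        if len(design) != len(uniq):
            raise ValueError(f"design {design} does not match {len(uniq)} groups")
        if min(design) < 2:
            raise ValueError("design group sizes must be at least 2")
        pvals = np.empty(n_matrices)
        new_labels = np.repeat(np.arange(len(design)), design)
        for m in range(n_matrices):
            cols = np.concatenate(
                [_resample_group(rng, idx, k) for idx, k in zip(member_idx, design)]
            )
            d = squareform(pdist(X[:, cols].T))
            pvals[m] = permanova(
                d, new_labels, n_perm=n_perm,
                seed=int(rng.integers(0, 2**31 - 1)),
            ).p
        batches = np.array_split(pvals, n_batches)
        for a in alphas:
            powers = np.array([np.mean(b <= a) for b in batches])
            results.append(
                PowerResult(
                    design=tuple(design), alpha=float(a), powers=powers,
                    median_power=float(np.median(powers)),
                    n_matrices=n_matrices, n_perm=n_perm,
                )
            )
    return results
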