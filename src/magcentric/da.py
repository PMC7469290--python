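"""Negative-binomial differential abundance under the crossover design.

Per feature (MAG or KO), counts are modelled as NB(mu, alpha) with
``var = mu + alpha mu^2``, log link and log size-factor offsets.  A full
model with period, animal and diet effects is tested against a reduced
model with period and animal only, by a likelihood-ratio test with the
feature's dispersion held fixed in both fits; the statistic is referred to
a chi-squared distribution with df = (number of diet levels - 1).  Log2
fold changes per contrast (40 vs 80, 60 vs 80 %MER) come from the
full-model diet coefficients.  Benjamini-Hochberg adjustment is applied
across features.

Size factors are DESeq-style median-of-ratios; dispersions are per-feature
method-of-moments estimates on design-residualized normalized counts with
a small-sample degrees-of-freedom correction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.multitest import multipletests

DISPERSION_FLOOR = 1e-8
DIET_LEVELS = (80, 40, 60)  # 80 %MER is the reference level


@dataclass
class ModelSpec:
    """Design matrices and nuisance parameters for the NB LRT."""

    full: pd.DataFrame
    reduced: pd.DataFrame
    size_factors: pd.Series
    dispersions: pd.Series

    def __post_init__(self) -> None:
        if not set(self.reduced.columns) <= set(self.full.columns):
            raise ValueError("reduced design is not nested in the full design")
        if (self.size_factors <= 0).any():
            raise ValueError("size factors must be positive")


def _dummies(values: pd.Series, prefix: str, categories=None) -> pd.DataFrame:
    cat = pd.Categorical(
        values.astype(str),
        categories=[str(c) for c in categories] if categories is not None else None,
    )
    return pd.get_dummies(pd.Series(cat, index=values.index), prefix=prefix,
                          drop_first=True).astype(float)


def build_design(
    metadata: pd.DataFrame, with_diet: bool = True
) -> pd.DataFrame:
    """Design matrix ~ period + animal (+ diet), aliased columns dropped.

    Diet is coded against the 80 %MER reference so the diet coefficients
    are directly the 40-vs-80 and 60-vs-80 log fold changes.  Aliased
    columns are dropped deterministically, keeping first occurrences.
    """
    md = metadata.set_index("sample_id")
    parts = [pd.DataFrame({"intercept": 1.0}, index=md.index),
             _dummies(md["period"], "period"),
             _dummies(md["animal"], "animal")]
    if with_diet:
        present = [d for d in DIET_LEVELS if d in set(md["diet"].astype(int))]
        parts.append(_dummies(md["diet"].astype(int), "diet", categories=present))
    X = pd.concat(parts, axis=1)
    keep: list[str] = []
    for col in X.columns:
        if np.linalg.matrix_rank(X[keep + [col]].to_numpy()) == len(keep) + 1:
            keep.append(col)
    return X[keep]


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios library-size factors, normalized to geometric mean 1."""
    x = counts.to_numpy(float)
    positive = (x > 0).all(axis=1)
    if not positive.any():
        raise ValueError("no feature with nonzero counts in every sample")
    logx = np.log(x[positive])
    logref = logx.mean(axis=1, keepdims=True)  # log geometric mean per feature
    s = np.exp(np.median(logx - logref, axis=0))
    s = s / np.exp(np.mean(np.log(s)))
    return pd.Series(s, index=counts.columns, name="size_factor")


def genewise_dispersion(
    counts: pd.DataFrame,
    sf: pd.Series,
    design: pd.DataFrame,
    floor: float = DISPERSION_FLOOR,
    iters: int = 2,
) -> pd.Series:
    """Per-feature Pearson (pseudo-likelihood) dispersion estimate.

    Starting from the moment estimate, alternates fitting the NB mean
    model with solving ``sum (y - mu)^2 / (mu + alpha mu^2) = n - p`` for
    ``alpha`` — the Pearson-statistic estimating equation with a residual
    degrees-of-freedom correction for the fitted coefficients.
    """
    from scipy import optimize

    X = design.loc[counts.columns].to_numpy()
    offset = np.log(sf.loc[counts.columns].to_numpy())
    n, p = X.shape
    init = estimate_dispersion(counts, sf, design, floor=floor)
    out = {}
    for feature in counts.index:
        y = counts.loc[feature].to_numpy(float)
        alpha = min(max(float(init.loc[feature]), floor), 100.0)
        if y.sum() <= 0:
            out[feature] = floor
            continue
        for _ in range(iters):
            try:
                res = _fit_nb(y, X, offset, alpha)
            except Exception:
                break
            mu = np.maximum(np.asarray(res.fittedvalues), 1e-8)
            resid2 = (y - mu) ** 2

            def pearson_gap(a: float) -> float:
                return float(np.sum(resid2 / (mu + a * mu**2)) - (n - p))

            if pearson_gap(floor) <= 0:
                alpha = floor
            elif pearson_gap(100.0) >= 0:
                alpha = 100.0
            else:
                alpha = optimize.brentq(pearson_gap, floor, 100.0)
        out[feature] = alpha
    return pd.Series(out, name="dispersion")


def moderate_dispersion(
    genewise: pd.Series,
    base_mean: pd.Series,
    df_resid: int,
    min_prior_var: float = 0.0625,
    floor: float = DISPERSION_FLOOR,
) -> pd.Series:
    """Empirical-Bayes moderation of gene-wise dispersions toward a trend.

    With only a handful of residual degrees of freedom, per-feature
    dispersion estimates are far too noisy to hold fixed in a
    likelihood-ratio test; sharing information across features restores
    calibration.  A mean-dispersion trend is built from bin means of the
    gene-wise estimates over mean-count quantile bins (bin means rather
    than medians: the estimates are right-skewed but unbiased in the
    mean), and each log dispersion is shrunk toward the trend with weights
    from the sampling variance of a log dispersion estimate at
    ``df_resid`` degrees of freedom (``trigamma(df/2)``) and a prior
    variance estimated from the residual spread around the trend.
    """
    from scipy import special

    la = np.log(np.maximum(genewise.to_numpy(float), floor))
    lm = np.log(np.maximum(base_mean.loc[genewise.index].to_numpy(float), 1e-8))
    s2_sampling = float(special.polygamma(1, df_resid / 2.0))
    # robust trend: bin medians of the log estimates plus the log-normal
    # median-to-mean correction for their sampling skew; medians keep a
    # high-dispersion subpopulation from dragging the trend upward
    bias = s2_sampling / 2.0
    n_bins = int(max(1, min(10, la.size // 20)))
    edges = np.quantile(lm, np.linspace(0.0, 1.0, n_bins + 1))
    centers, levels = [], []
    for i in range(n_bins):
        hi = lm <= edges[i + 1] if i == n_bins - 1 else lm < edges[i + 1]
        mask = (lm >= edges[i]) & hi
        if mask.sum() >= 3:
            centers.append(lm[mask].mean())
            levels.append(np.median(la[mask]) + bias)
    if len(centers) > 1:
        trend = np.interp(lm, centers, levels)
    else:
        trend = np.full_like(la, np.median(la) + bias)
    resid = la - trend
    mad = np.median(np.abs(resid - np.median(resid)))
    prior_var = max((1.4826 * mad) ** 2 - s2_sampling, min_prior_var)
    post = (la / s2_sampling + trend / prior_var) / (1.0 / s2_sampling + 1.0 / prior_var)
    # dispersion outliers: features far above the trend keep their own
    # estimate — shrinking genuinely high dispersions down would make
    # their tests anticonservative, the costly direction.  Because that
    # estimate rests on only df_resid degrees of freedom, one sampling
    # standard deviation is added on the log scale as a margin against
    # underestimation; tests on such features are conservative rather
    # than inflated.
    outlier = resid > 1.5 * np.sqrt(s2_sampling)
    post = np.where(outlier, la + np.sqrt(s2_sampling), post)
    return pd.Series(np.maximum(np.exp(post), floor), index=genewise.index,
                     name="dispersion")


def estimate_dispersion(
    counts: pd.DataFrame,
    sf: pd.Series,
    design: pd.DataFrame,
    floor: float = DISPERSION_FLOOR,
) -> pd.Series:
    """Method-of-moments NB dispersion per feature.

    Normalized counts ``y = K / s`` are residualized on the design by least
    squares; with ``v`` the df-corrected residual variance and ``m`` the
    mean normalized count, ``alpha = (v - m * mean(1/s)) / m^2`` floored at
    a tiny positive value.  All-zero features get the floor and a warning.
    """
    X = design.loc[counts.columns].to_numpy()
    n, p = X.shape
    if n <= p:
        raise ValueError("design leaves no residual degrees of freedom")
    y = counts.to_numpy(float) / sf.loc[counts.columns].to_numpy()
    m = y.mean(axis=1)
    beta, *_ = np.linalg.lstsq(X, y.T, rcond=None)
    resid = y.T - X @ beta
    v = (resid ** 2).sum(axis=0) / (n - p)
    shot = m * np.mean(1.0 / sf.to_numpy())  # Poisson part of the variance
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha = (v - shot) / m**2
    alpha = np.where(np.isfinite(alpha), alpha, floor)
    zero = m <= 0
    if zero.any():
        warnings.warn(f"{int(zero.sum())} all-zero feature(s): dispersion floored")
    alpha = np.where(zero, floor, np.maximum(alpha, floor))
    return pd.Series(alpha, index=counts.index, name="dispersion")


def _fit_nb(y: np.ndarray, X: np.ndarray, offset: np.ndarray, alpha: float,
            max_iter: int = 100, tol: float = 1e-8):
    model = sm.GLM(y, X, family=sm.families.NegativeBinomial(alpha=alpha),
                   offset=offset)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = model.fit(maxiter=max_iter, tol=tol)
    return res


def nb_lrt(
    counts: pd.DataFrame,
    metadata: pd.DataFrame,
    model: ModelSpec | None = None,
    fdr: float = 0.05,
) -> pd.DataFrame:
    """Full-vs-reduced NB likelihood-ratio test per feature.

    Returns a table indexed by feature with columns ``base_mean``,
    ``lfc_40vs80``, ``lfc_60vs80``, ``lr_stat``, ``df``, ``p``, ``padj``
    and ``converged``.  Features that fail to converge get missing p and
    are excluded from the BH adjustment.
    """
    md = metadata.set_index("sample_id").loc[counts.columns]
    md.index.name = "sample_id"
    md = md.reset_index()
    if model is None:
        full = build_design(md, with_diet=True)
        reduced = build_design(md, with_diet=False)
        sf = size_factors(counts)
        gw = genewise_dispersion(counts, sf, full)
        base = pd.Series(
            (counts.to_numpy(float) / sf.loc[counts.columns].to_numpy()).mean(axis=1),
            index=counts.index,
        )
        disp = moderate_dispersion(gw, base, df_resid=len(counts.columns) - full.shape[1])
        model = ModelSpec(full=full, reduced=reduced, size_factors=sf,
                          dispersions=disp)
    Xf = model.full.loc[counts.columns].to_numpy()
    Xr = model.reduced.loc[counts.columns].to_numpy()
    offset = np.log(model.size_factors.loc[counts.columns].to_numpy())
    df = Xf.shape[1] - Xr.shape[1]
    diet_cols = [i for i, c in enumerate(model.full.columns) if c.startswith("diet_")]
    names = list(model.full.columns)

    rows = []
    for feature in counts.index:
        y = counts.loc[feature].to_numpy(float)
        alpha = max(float(model.dispersions.loc[feature]), DISPERSION_FLOOR)
        base_mean = float(np.mean(y / np.exp(offset)))
        row = {
            "feature_id": feature, "base_mean": base_mean,
            "lfc_40vs80": np.nan, "lfc_60vs80": np.nan,
            "lr_stat": np.nan, "df": df, "p": np.nan, "converged": False,
        }
        if y.sum() > 0:
            try:
                rf = _fit_nb(y, Xf, offset, alpha)
                rr = _fit_nb(y, Xr, offset, alpha)
                lr = max(0.0, 2.0 * (rf.llf - rr.llf))
                row["lr_stat"] = lr
                row["p"] = float(stats.chi2.sf(lr, df)) if df > 0 else 1.0
                if df == 0:
                    row["lr_stat"] = 0.0
                for i in diet_cols:
                    contrast = names[i].replace("diet_", "")
                    row[f"lfc_{contrast}vs80"] = float(rf.params[i] / np.log(2.0))
                row["converged"] = bool(np.all(np.isfinite(rf.params)))
            except Exception:
                pass
        rows.append(row)
    out = pd.DataFrame(rows).set_index("feature_id")
    out["padj"] = np.nan
    ok = out["p"].notna()
    if ok.any():
        out.loc[ok, "padj"] = bh_adjust(out.loc[ok, "p"].to_numpy())
    return out


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment (monotone, capped at 1)."""
    p = np.asarray(pvalues, float)
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def da_features(results: pd.DataFrame, fdr: float = 0.05) -> dict:
    """Split significant features by contrast and fold-change sign.

    Returns ``{"significant": set, "by_contrast": {contrast: (total, n_up,
    n_down)}}`` using ``padj < fdr``.
    """
    sig = results[results["padj"] < fdr]
    by_contrast = {}
    for contrast in ("40vs80", "60vs80"):
        col = f"lfc_{contrast}"
        if col in sig.columns:
            up = int((sig[col] > 0).sum())
            down = int((sig[col] < 0).sum())
            by_contrast[contrast] = (len(sig), up, down)
    return {"significant": set(sig.index), "by_contrast": by_contrast}
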