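"""Normalization and moderated differential-expression statistics.

Intensity matrices are quantile-normalized and log2-transformed; per-gene
two-group (or general cell-means) contrasts are tested with an empirical-
Bayes moderated t-statistic: the per-gene residual variance s²_g (d_g df) is
shrunk toward a prior (d0, s0²) fitted by method of moments on log s²_g under
a scaled-F model,

    s̃²_g = (d0·s0² + d_g·s²_g) / (d0 + d_g),
    t_g = (mean_A − mean_B) / sqrt(s̃²_g (1/n_A + 1/n_B)),

with two-sided p-values on d0 + d_g degrees of freedom. A gene is called
differentially expressed when BH-adjusted FDR < 0.05 and |log2 fold change|
is at least 1 (i.e. two-fold).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

#: d0 values above this cap are treated as "infinite" prior df.
D0_CAP = 1e6

_TINY = 1e-300


@dataclass
class ExpressionStudy:
    """An intensity matrix (genes x samples) plus its sample design table.

    ``design`` is indexed by sample_id with columns sirna, treatment,
    replicate; every design sample_id must match exactly one matrix column.
    """

    matrix: pd.DataFrame
    design: pd.DataFrame
    log_transformed: bool = False

    def __post_init__(self) -> None:
        for col in ("sirna", "treatment", "replicate"):
            if col not in self.design.columns:
                raise ValueError(f"design table missing column {col!r}")
        mat_cols = set(map(str, self.matrix.columns))
        des_ids = list(map(str, self.design.index))
        if len(des_ids) != len(set(des_ids)):
            raise ValueError("duplicate sample_ids in design table")
        missing = sorted(set(des_ids) - mat_cols)
        if missing:
            raise ValueError(f"design sample_ids absent from matrix: {missing}")
        if not self.log_transformed and (self.matrix.to_numpy() <= 0).any():
            raise ValueError("intensities must be > 0 before log transform")

    def log2(self) -> "ExpressionStudy":
        """Return a log2-transformed copy (no-op if already transformed)."""
        if self.log_transformed:
            return self
        return ExpressionStudy(np.log2(self.matrix), self.design, True)

    def samples(self, sirna: str | None = None, treatment: str | None = None) -> list[str]:
        """Sample ids matching the given design-cell filters."""
        mask = pd.Series(True, index=self.design.index)
        if sirna is not None:
            mask &= self.design["sirna"] == sirna
        if treatment is not None:
            mask &= self.design["treatment"] == treatment
        return list(self.design.index[mask])


def quantile_normalize(matrix: pd.DataFrame) -> pd.DataFrame:
    """Quantile-normalize columns to the common rank-mean reference distribution.

    After normalization every column holds the identical sorted value multiset
    (the per-rank cross-column means). Tied values within a column receive the
    mean of the reference values at the ranks they jointly occupy, so
    within-column rank order is preserved.
    """
    X = matrix.to_numpy(dtype=float)
    if X.shape[1] < 2:
        raise ValueError("quantile normalization needs >= 2 columns")
    if not np.isfinite(X).all():
        raise ValueError("matrix contains non-finite values")
    reference = np.sort(X, axis=0).mean(axis=1)
    out = np.empty_like(X)
    for j in range(X.shape[1]):
        col = X[:, j]
        order = np.argsort(col, kind="mergesort")
        ranked = np.empty_like(reference)
        ranked[order] = reference  # value at rank i -> position holding rank i
        # ties: average the reference values over each tied group's ranks
        ser = pd.Series(ranked)
        out[:, j] = ser.groupby(col).transform("mean").to_numpy()
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)


def bh_adjust(p_values: Sequence[float] | np.ndarray) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, returned in input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size and ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    if p.size == 0:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 (Newton iteration)."""
    if y <= 0:
        return np.inf
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x += dif
        if x <= 0:
            x = 1e-8
        if abs(dif) < 1e-10 * x:
            break
    return float(x)


def estimate_variance_prior(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Method-of-moments fit of the scaled-F prior (d0, s0²) to gene variances.

    Moments of log s² under s² | s0² ~ s0²·F(d, d0): the spread of
    e_g = log s²_g − digamma(d/2) + log(d/2) in excess of trigamma(d/2)
    identifies d0 via trigamma inversion; its mean identifies s0². When the
    excess spread is <= 0 (no detectable between-gene variance heterogeneity)
    the prior df is capped and s0² is the geometric mean of the observed s²,
    so that identical gene variances are a fixed point of the shrinkage.
    """
    s2 = np.asarray(s2, dtype=float)
    if df <= 0:
        raise ValueError("need positive residual df to estimate the prior")
    z = np.log(np.maximum(s2, _TINY))
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    emean = float(e.mean())
    n = e.size
    if n < 2:
        return D0_CAP, float(np.exp(emean))
    evar = float(e.var(ddof=1)) - float(special.polygamma(1, df / 2.0))
    if evar <= 0:
        # degenerate: no between-gene dispersion beyond sampling noise
        return D0_CAP, float(np.exp(z.mean()))
    d0 = 2.0 * _trigamma_inverse(evar)
    d0 = min(d0, D0_CAP)
    s0 = float(np.exp(emean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    return d0, s0


def fit_linear_contrast(
    log2_matrix: pd.DataFrame,
    groups: Sequence[Sequence[str]],
    weights: Sequence[float],
    moderation: str = "eb",
    d0_override: float | None = None,
) -> pd.DataFrame:
    """Fit a cell-means model and test the contrast sum_i w_i * mean_i.

    ``groups`` are disjoint lists of sample ids (the design cells); the
    residual variance is pooled within cells with df = N − n_cells. Returns a
    DataFrame indexed like the matrix with columns log2fc, t_stat, p_value,
    fdr, df_total, s2, s2_post.
    """
    if moderation not in ("eb", "plain"):
        raise ValueError("moderation must be 'eb' or 'plain'")
    if len(groups) != len(weights):
        raise ValueError("one weight per group required")
    flat = [s for g in groups for s in g]
    if len(flat) != len(set(flat)):
        raise ValueError("groups must be disjoint")
    sizes = np.array([len(g) for g in groups])
    if (sizes < 1).any():
        raise ValueError("every group needs >= 1 sample")
    n_total = int(sizes.sum())
    df_resid = n_total - len(groups)

    means = np.column_stack(
        [log2_matrix[list(g)].to_numpy(dtype=float).mean(axis=1) for g in groups]
    )
    w = np.asarray(weights, dtype=float)
    effect = means @ w
    var_factor = float((w**2 / sizes).sum())

    if df_resid > 0:
        ss = np.zeros(len(log2_matrix))
        for g, m in zip(groups, means.T):
            sub = log2_matrix[list(g)].to_numpy(dtype=float)
            ss += ((sub - m[:, None]) ** 2).sum(axis=1)
        s2 = ss / df_resid
    else:
        s2 = np.full(len(log2_matrix), np.nan)

    if moderation == "plain":
        if df_resid == 0:
            raise ValueError("zero residual df: cannot fit without moderation")
        d0, s0 = 0.0, 0.0
        s2_post = s2
    else:
        if d0_override is not None:
            d0 = min(float(d0_override), D0_CAP)
            if df_resid > 0:
                # anchor s0 to the forced d0 via the same moment relation
                z = np.log(np.maximum(s2, _TINY))
                e = z - special.digamma(df_resid / 2.0) + np.log(df_resid / 2.0)
                s0 = float(
                    np.exp(e.mean() + special.digamma(d0 / 2.0) - np.log(d0 / 2.0))
                )
            else:
                raise ValueError(
                    "zero residual df: provide prior variance via a study with replicates"
                )
        elif df_resid == 0:
            raise ValueError(
                "zero residual df: empirical-Bayes prior cannot be estimated"
            )
        else:
            d0, s0 = estimate_variance_prior(s2, df_resid)
        s2_post = (d0 * s0 + df_resid * s2) / (d0 + df_resid)

    df_total = d0 + df_resid if moderation == "eb" else float(df_resid)
    se = np.sqrt(s2_post * var_factor)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = effect / se
    # zero-variance genes (e.g. noise-free simulations): infinite t unless the
    # effect itself is zero
    zero_se = se == 0
    t = np.where(zero_se & (effect == 0), 0.0, t)
    with np.errstate(invalid="ignore"):
        t = np.where(zero_se & (effect != 0), np.sign(effect) * np.inf, t)
    p = 2.0 * stats.t.sf(np.abs(t), df_total)
    p = np.where(np.isinf(t), 0.0, p)
    p = np.where(zero_se & (effect == 0), 1.0, p)

    return pd.DataFrame(
        {
            "log2fc": effect,
            "t_stat": t,
            "p_value": p,
            "fdr": bh_adjust(p),
            "df_total": df_total,
            "s2": s2,
            "s2_post": s2_post,
        },
        index=log2_matrix.index,
    )


def fit_contrast(
    study: ExpressionStudy,
    group_a: Sequence[str],
    group_b: Sequence[str],
    moderation: str = "eb",
    d0_override: float | None = None,
) -> pd.DataFrame:
    """Two-group contrast (mean_A − mean_B) with moderated or plain t-test.

    ``group_a`` / ``group_b`` are sample-id lists (see
    :meth:`ExpressionStudy.samples`); each needs >= 2 samples for a plain fit.
    The study must be log2-transformed.
    """
    if not study.log_transformed:
        raise ValueError("study must be log2-transformed (use .log2())")
    group_a, group_b = list(group_a), list(group_b)
    if moderation == "plain" and (len(group_a) < 2 or len(group_b) < 2):
        raise ValueError("each group needs >= 2 samples for an unmoderated fit")
    return fit_linear_contrast(
        study.matrix, [group_a, group_b], [1.0, -1.0], moderation, d0_override
    )


def call_de(
    result: pd.DataFrame, fdr_max: float = 0.05, min_abs_log2fc: float = 1.0
) -> pd.Series:
    """Signed differential-expression calls: fdr < fdr_max AND |log2fc| >= cutoff.

    Returns a Series of +1/−1 (sign of the fold change) indexed by the
    selected genes.
    """
    if fdr_max <= 0 or min_abs_log2fc <= 0:
        raise ValueError("thresholds must be > 0")
    mask = (result["fdr"] < fdr_max) & (result["log2fc"].abs() >= min_abs_log2fc)
    return np.sign(result.loc[mask, "log2fc"]).astype(int)


def write_contrast_tsv(result: pd.DataFrame, path) -> None:
    out = result[["log2fc", "t_stat", "p_value", "fdr"]].rename(
        columns={"t_stat": "t", "p_value": "p"}
    )
    out.to_csv(path, sep="\t", index_label="gene")
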