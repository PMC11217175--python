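"""Quantile normalization and differential-expression calling.

The differential-expression stage supports the two designs of a paired
pre/post chemotherapy cohort:

* ``paired_pre_post`` — one-sample t test on within-patient (post - pre)
  log2 differences, optionally restricted to one resistance group (the
  AR_pre vs AR_post comparison is the paired contrast on AR patients).
* ``group_pre_vs_pre`` — pooled-variance two-sample t test between
  resistance groups at a single timepoint (PR_pre vs AR_pre).

Variance moderation follows the empirical-Bayes scheme of microarray
linear-model practice: per-gene sample variances are shrunk toward a common
prior fitted across all genes by a method-of-moments fit of a scaled
F distribution to the observed variances, and the t statistic gains the
prior degrees of freedom.  The unmoderated path is kept for hand-checkable
oracle testing.

A gene is called differentially expressed when its Benjamini-Hochberg
adjusted p-value is <= ``p_threshold`` (inclusive) AND |log2 fold change|
is strictly greater than ``fc_threshold``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from .io import ExpressionMatrix, SampleMetadata

__all__ = [
    "quantile_normalize",
    "bh_adjust",
    "diff_expr",
    "moderate_variances",
]


def quantile_normalize(X: ExpressionMatrix) -> ExpressionMatrix:
    """Force every sample onto the common reference distribution.

    The reference is the vector of row-wise means of the column-sorted
    matrix.  Within each column the input rank order is preserved; tied
    values receive the mean of the reference values their positions span.

    Raises
    ------
    ValueError
        If the matrix has fewer than two samples (nothing to equalize).
    """
    if X.n_samples < 2:
        raise ValueError("quantile normalization needs at least 2 samples")
    vals = X.values()
    n_genes = vals.shape[0]
    reference = np.sort(vals, axis=0).mean(axis=1)
    out = np.empty_like(vals)
    for j in range(vals.shape[1]):
        col = vals[:, j]
        order = np.argsort(col, kind="stable")
        ranks = np.empty(n_genes, dtype=int)
        ranks[order] = np.arange(n_genes)
        # tied values span a run of reference positions; assign the run mean
        col_sorted = col[order]
        boundaries = np.flatnonzero(np.diff(col_sorted)) + 1
        starts = np.concatenate(([0], boundaries))
        stops = np.concatenate((boundaries, [n_genes]))
        ref_cum = np.concatenate(([0.0], np.cumsum(reference)))
        run_means = (ref_cum[stops] - ref_cum[starts]) / (stops - starts)
        run_of_pos = np.zeros(n_genes, dtype=int)
        run_of_pos[starts[1:]] = 1
        run_of_pos = np.cumsum(run_of_pos)
        out[:, j] = run_means[run_of_pos[ranks]]
    return ExpressionMatrix(
        pd.DataFrame(out, index=X.data.index, columns=X.data.columns)
    )


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, capped at 1."""
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValueError("p_values must be one-dimensional")
    if p.size == 0:
        return p.copy()
    if not np.isfinite(p).all() or (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must be finite and within [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _inv_trigamma(x: np.ndarray | float) -> np.ndarray | float:
    """Solve trigamma(y) = x for y > 0 (Newton iteration)."""
    x = np.asarray(x, dtype=float)
    y = 0.5 + 1.0 / x  # good starting point for all x > 0
    for _ in range(50):
        tri = special.polygamma(1, y)
        dif = tri * (1.0 - tri / x) / special.polygamma(2, y)
        y = y + dif
        if np.all(np.abs(dif) < 1e-10 * y):
            break
    return y


def moderate_variances(s2: np.ndarray, df: float) -> tuple[np.ndarray, float, float]:
    """Shrink per-gene variances toward a common prior (empirical Bayes).

    Fits a scaled F distribution to the observed variances ``s2`` (each on
    ``df`` degrees of freedom) by the method of moments on log variances,
    then returns the posterior variances ``(d0*s0^2 + df*s2)/(d0 + df)``
    together with the prior degrees of freedom ``d0`` and prior variance
    ``s0^2``.  ``d0`` is infinite when the observed spread of log variances
    is no larger than expected from sampling alone; all posterior variances
    then equal the prior.
    """
    s2 = np.asarray(s2, dtype=float)
    if df <= 0:
        raise ValueError("residual degrees of freedom must be positive")
    # exclude exact zeros (constant genes) from the prior fit
    ok = s2 > 0
    if not ok.any():
        raise ValueError("all genes have zero variance; cannot fit a prior")
    z = np.log(s2[ok])
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    e_mean = e.mean()
    n = e.size
    e_var = np.sum((e - e_mean) ** 2) / (n - 1) if n > 1 else 0.0
    excess = e_var - special.polygamma(1, df / 2.0)
    if excess <= 0:
        # no excess spread beyond sampling: variances are exchangeable and
        # the prior is their arithmetic mean on infinite prior df
        d0 = np.inf
        s0_2 = float(s2[ok].mean())
    else:
        d0 = float(2.0 * _inv_trigamma(excess))
        s0_2 = float(np.exp(e_mean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    if np.isinf(d0):
        post = np.full_like(s2, s0_2)
    else:
        post = (d0 * s0_2 + df * s2) / (d0 + df)
    return post, d0, s0_2


def _t_table(
    gene_ids,
    effect: np.ndarray,
    s2: np.ndarray,
    stderr_factor: float,
    df_resid: float,
    moderation: str,
) -> pd.DataFrame:
    """Shared tail of both contrasts: moderation, t, p, flags."""
    zero_var = s2 <= 0
    if moderation == "empirical_bayes":
        post_s2, d0, _ = moderate_variances(s2, df_resid)
        df_total = df_resid + d0
        use_s2 = post_s2
    elif moderation == "none":
        df_total = df_resid
        use_s2 = s2
    else:
        raise ValueError(f"unknown moderation {moderation!r}")
    with np.errstate(divide="ignore", invalid="ignore"):
        t = effect / (np.sqrt(use_s2) * stderr_factor)
    if np.isinf(df_total):
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), df_total)
    # constant genes: t undefined -> conservative p = 1, flagged (never 0)
    t = np.where(zero_var, np.nan, t)
    p = np.where(zero_var, 1.0, p)
    df_col = np.full(effect.shape, df_total if np.isfinite(df_total) else np.inf)
    return pd.DataFrame(
        {
            "gene_id": gene_ids,
            "log2fc": effect,
            "t_stat": t,
            "df": df_col,
            "p_value": p,
            "zero_variance": zero_var,
        }
    )


def diff_expr(
    X: ExpressionMatrix,
    meta: SampleMetadata,
    contrast: str,
    *,
    group: str | None = None,
    group_a: str = "PR",
    group_b: str = "AR",
    timepoint: str = "pre",
    moderation: str = "empirical_bayes",
    p_threshold: float = 0.05,
    fc_threshold: float = 0.3,
    use_adjusted: bool = True,
) -> pd.DataFrame:
    """Call differentially expressed genes for one contrast.

    Parameters
    ----------
    contrast : {"paired_pre_post", "group_pre_vs_pre"}
        ``paired_pre_post``: one-sample t on within-patient (post - pre)
        differences; ``group`` restricts to one resistance group.
        ``group_pre_vs_pre``: pooled two-sample t of ``group_a`` minus
        ``group_b`` at ``timepoint``.
    moderation : {"none", "empirical_bayes"}
        Whether to shrink per-gene variances toward the across-gene prior.
    use_adjusted : bool
        Apply the significance threshold to BH-adjusted p-values (default)
        or to raw p-values.

    Returns
    -------
    pandas.DataFrame
        One row per gene with columns gene_id, log2fc, t_stat, df, p_value,
        adj_p, is_deg, direction, zero_variance; row order follows the
        matrix's gene order.
    """
    if contrast == "paired_pre_post":
        pairs = meta.pairs(group=group)
        if len(pairs) < 2:
            raise ValueError("paired contrast needs at least 2 complete pairs")
        pre = X.subset_samples(list(pairs["pre"])).values()
        post = X.subset_samples(list(pairs["post"])).values()
        diffs = post - pre  # sign convention: post minus pre
        n = diffs.shape[1]
        effect = diffs.mean(axis=1)
        s2 = diffs.var(axis=1, ddof=1)
        table = _t_table(
            X.gene_ids, effect, s2, 1.0 / np.sqrt(n), n - 1, moderation
        )
    elif contrast == "group_pre_vs_pre":
        a_ids = meta.select(group=group_a, timepoint=timepoint)
        b_ids = meta.select(group=group_b, timepoint=timepoint)
        if len(a_ids) < 2 or len(b_ids) < 2:
            raise ValueError(
                f"two-group contrast needs >=2 samples per group "
                f"(got {len(a_ids)} {group_a}, {len(b_ids)} {group_b})"
            )
        a = X.subset_samples(a_ids).values()
        b = X.subset_samples(b_ids).values()
        na, nb = a.shape[1], b.shape[1]
        effect = a.mean(axis=1) - b.mean(axis=1)
        pooled = (
            a.var(axis=1, ddof=1) * (na - 1) + b.var(axis=1, ddof=1) * (nb - 1)
        ) / (na + nb - 2)
        table = _t_table(
            X.gene_ids,
            effect,
            pooled,
            np.sqrt(1.0 / na + 1.0 / nb),
            na + nb - 2,
            moderation,
        )
    else:
        raise ValueError(f"unknown contrast {contrast!r}")

    table["adj_p"] = bh_adjust(table["p_value"].to_numpy())
    crit_p = table["adj_p"] if use_adjusted else table["p_value"]
    table["is_deg"] = (crit_p <= p_threshold) & (
        table["log2fc"].abs() > fc_threshold
    )
    table["direction"] = np.where(table["log2fc"] > 0, "up", "down")
    return table
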