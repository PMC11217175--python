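"""Single-sample gene-set enrichment scoring and group comparison.

Scores each gene set in each sample with the rank-weighted running-sum
statistic that underlies single-sample GSEA and signature-based cell-type
scoring: genes are ranked by decreasing expression, an in-set cumulative
fraction (weighting the gene at rank position i by (N - i + 1)**alpha,
normalized over in-set weights) is compared against the uniform out-of-set
cumulative fraction, and the score is the sum of the differences over all
positions.  Being a pure rank statistic, the score is invariant to any
strictly monotone transform of a sample's expression values.

Trained deconvolution machinery (signature calibration, spillover
compensation, fitted purity coefficients) is deliberately out of scope:
signatures are user-supplied GMT sets, and the immune / stromal / micro-
environment composites are simple means of signature scores with
microenvironment = immune + stromal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import ExpressionMatrix, GeneSetCollection, SampleMetadata

__all__ = [
    "EnrichmentMatrix",
    "ssgsea_score",
    "composite_scores",
    "compare_groups",
]


@dataclass(frozen=True)
class EnrichmentMatrix:
    """Gene-set x sample enrichment scores (dimensionless)."""

    data: pd.DataFrame  # sets in rows, samples in columns

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates or self.data.columns.has_duplicates:
            raise ValueError("enrichment matrix has duplicate set or sample ids")
        vals = self.data.to_numpy()
        if vals.size and not np.isfinite(vals).all():
            raise ValueError("enrichment scores must be finite")

    @property
    def set_names(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)


def _ranked_order(col: np.ndarray, lex_rank: np.ndarray) -> np.ndarray:
    """Gene ordering by decreasing expression, ties by gene-id lex order."""
    return np.lexsort((lex_rank, -col))


def ssgsea_score(
    X: ExpressionMatrix,
    sets: GeneSetCollection,
    alpha: float = 0.25,
    normalize: bool = False,
) -> EnrichmentMatrix:
    """Score every gene set in every sample.

    Parameters
    ----------
    alpha : float
        Rank-weight exponent on (N - i + 1) for in-set genes; 0 gives equal
        weights.
    normalize : bool
        Divide all scores by (max - min) over the whole score matrix.

    Each set is first intersected with the matrix's genes; a set with no
    overlap, or covering the full gene universe (empty out-set), is an error
    naming the set.  Expression ties are broken by gene-id lexicographic
    order after sorting by expression descending.
    """
    gene_ids = np.asarray(X.gene_ids)
    n = len(gene_ids)
    gene_pos = {g: i for i, g in enumerate(gene_ids)}
    lex_rank = np.empty(n, dtype=int)
    lex_rank[np.argsort(gene_ids, kind="stable")] = np.arange(n)

    masks: dict[str, np.ndarray] = {}
    for name in sets.set_names:
        members = [g for g in sets[name] if g in gene_pos]
        if not members:
            raise ValueError(f"gene set {name!r} has no overlap with the matrix genes")
        if len(members) == n:
            raise ValueError(
                f"gene set {name!r} covers the whole gene universe (empty out-set)"
            )
        mask = np.zeros(n, dtype=bool)
        mask[[gene_pos[g] for g in members]] = True
        masks[name] = mask

    vals = X.values()
    pos_weight = (n - np.arange(1, n + 1) + 1).astype(float) ** alpha
    scores = np.empty((len(masks), X.n_samples))
    for j in range(X.n_samples):
        order = _ranked_order(vals[:, j], lex_rank)
        for k, name in enumerate(masks):
            in_ranked = masks[name][order]
            w = np.where(in_ranked, pos_weight, 0.0)
            in_cum = np.cumsum(w) / w.sum()
            out_cum = np.cumsum(~in_ranked) / (n - in_ranked.sum())
            scores[k, j] = float(np.sum(in_cum - out_cum))
    if normalize:
        span = scores.max() - scores.min()
        if span > 0:
            scores = scores / span
    return EnrichmentMatrix(
        pd.DataFrame(scores, index=list(masks), columns=X.sample_ids)
    )


def composite_scores(
    E: EnrichmentMatrix,
    immune_sets: list[str],
    stromal_sets: list[str],
) -> pd.DataFrame:
    """Per-sample immune, stromal and microenvironment composite scores.

    immune = mean of the named immune signature scores, stromal likewise,
    microenvironment = immune + stromal.
    """
    if not immune_sets or not stromal_sets:
        raise ValueError("immune_sets and stromal_sets must be non-empty")
    for name in list(immune_sets) + list(stromal_sets):
        if name not in E.data.index:
            raise KeyError(f"signature {name!r} not in enrichment matrix")
    immune = E.data.loc[list(immune_sets)].mean(axis=0)
    stromal = E.data.loc[list(stromal_sets)].mean(axis=0)
    return pd.DataFrame(
        {
            "immune_score": immune,
            "stromal_score": stromal,
            "microenvironment_score": immune + stromal,
        }
    ).rename_axis("sample_id")


def _rank_sum_p(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Two-sided Mann-Whitney: exact for combined n <= 12 without ties,
    continuity-corrected tie-adjusted normal approximation otherwise."""
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        # fully tied data carries no rank information
        return float(len(a) * len(b) / 2.0), 1.0
    has_ties = len(np.unique(pooled)) < len(a) + len(b)
    if len(a) + len(b) <= 12 and not has_ties:
        res = stats.mannwhitneyu(a, b, alternative="two-sided", method="exact")
    else:
        res = stats.mannwhitneyu(
            a, b, alternative="two-sided", method="asymptotic", use_continuity=True
        )
    return float(res.statistic), float(res.pvalue)


def _signed_rank_p(d: np.ndarray) -> tuple[float, float, bool]:
    """Two-sided Wilcoxon signed-rank on paired differences.

    Returns (W, p, degenerate); all-zero differences give p = 1 flagged.
    """
    if np.all(d == 0):
        return 0.0, 1.0, True
    nz = d[d != 0]
    has_ties = len(np.unique(np.abs(nz))) < len(nz)
    method = "exact" if (len(nz) <= 12 and not has_ties) else "approx"
    res = stats.wilcoxon(d, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue), False


def compare_groups(
    E: EnrichmentMatrix,
    meta: SampleMetadata,
    design: str,
    a: tuple[str | None, str | None],
    b: tuple[str | None, str | None],
) -> pd.DataFrame:
    """Compare each signature's score distribution between two sample arms.

    Parameters
    ----------
    design : {"paired", "unpaired"}
        Unpaired uses the Mann-Whitney rank-sum test; paired uses the
        Wilcoxon signed-rank test on within-patient differences (arms must
        then cover the same patients).
    a, b : (group, timepoint)
        Arm selectors, e.g. ``("PR", "pre")`` vs ``("AR", "pre")`` or
        ``("AR", "pre")`` vs ``("AR", "post")``; ``None`` matches all.

    Returns one record per signature: statistic, p_value, group medians and
    the direction of the median difference (a vs b).
    """
    a_ids = meta.select(group=a[0], timepoint=a[1])
    b_ids = meta.select(group=b[0], timepoint=b[1])
    if design == "paired":
        df = meta.table.set_index("sample_id")
        a_by_patient = df.loc[a_ids, "patient_id"]
        b_by_patient = df.loc[b_ids, "patient_id"]
        if set(a_by_patient) != set(b_by_patient):
            raise ValueError("paired design requires the same patients in both arms")
        order = sorted(set(a_by_patient))
        a_ids = [a_by_patient.index[a_by_patient == p][0] for p in order]
        b_ids = [b_by_patient.index[b_by_patient == p][0] for p in order]
    elif design == "unpaired":
        if len(a_ids) < 2 or len(b_ids) < 2:
            raise ValueError("unpaired design needs >=2 samples per arm")
    else:
        raise ValueError(f"unknown design {design!r}")

    records = []
    for name in E.set_names:
        sa = E.data.loc[name, a_ids].to_numpy(dtype=float)
        sb = E.data.loc[name, b_ids].to_numpy(dtype=float)
        degenerate = False
        if design == "unpaired":
            stat, p = _rank_sum_p(sa, sb)
        else:
            stat, p, degenerate = _signed_rank_p(sa - sb)
        med_a, med_b = float(np.median(sa)), float(np.median(sb))
        records.append(
            {
                "set_name": name,
                "statistic": stat,
                "p_value": p,
                "median_a": med_a,
                "median_b": med_b,
                "direction": "up" if med_a > med_b else ("down" if med_a < med_b else "equal"),
                "degenerate": degenerate,
            }
        )
    return pd.DataFrame.from_records(records)
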