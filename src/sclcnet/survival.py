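"""Outcome association: median splits, Kaplan-Meier curves, log-rank tests,
and pathway-score association for candidate genes.

Samples (or patients) are divided into high / low expression arms at the
across-sample median of a candidate gene — values strictly above the median
are "high", values at or below it are "low", so the high arm strictly
exceeds the median.  Survival curves per arm come from the Kaplan-Meier
product-limit estimator and arms are compared with the standard two-group
log-rank test, whose variance term uses the hypergeometric form with the
(n - d)/(n - 1) factor so tied event times are handled exactly.

Pathway association offers both analyses a median split supports: a
rank-sum test of single-sample pathway scores between the high and low
arms, and the Pearson correlation of the gene's expression with each
pathway score.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from scipy import stats

from .io import ExpressionMatrix
from .scoring import EnrichmentMatrix, _rank_sum_p

__all__ = [
    "median_split",
    "pathway_association",
    "km_fit",
    "logrank_test",
    "SurvivalFit",
    "LogRankResult",
    "patient_level_expression",
]


def median_split(X: ExpressionMatrix, gene: str) -> pd.Series:
    """Label each sample 'high' or 'low' at the gene's across-sample median.

    Values strictly greater than the median are 'high'; values equal to the
    median go to 'low'.  A constant gene has no defined split and is an
    error.
    """
    if gene not in X.data.index:
        raise KeyError(f"gene {gene!r} not in expression matrix")
    if X.n_samples < 2:
        raise ValueError("median split needs at least 2 samples")
    vals = X.data.loc[gene]
    if float(vals.max()) == float(vals.min()):
        raise ValueError(f"gene {gene!r} is constant; median split undefined")
    med = float(vals.median())
    labels = pd.Series(
        np.where(vals.to_numpy(dtype=float) > med, "high", "low"),
        index=vals.index,
        name=gene,
    )
    return labels


def patient_level_expression(X: ExpressionMatrix, meta) -> ExpressionMatrix:
    """Collapse samples to one column per patient (mean over timepoints).

    Outcome times are recorded per patient, so gene-vs-outcome analyses run
    on this patient-level matrix.
    """
    df = meta.table.set_index("sample_id")
    patients = list(dict.fromkeys(df["patient_id"]))
    cols = {}
    for p in patients:
        ids = [s for s in X.sample_ids if s in df.index and df.loc[s, "patient_id"] == p]
        if not ids:
            continue
        cols[p] = X.data[ids].mean(axis=1)
    return ExpressionMatrix(pd.DataFrame(cols))


@dataclass(frozen=True)
class SurvivalFit:
    """Per-group Kaplan-Meier curves: stepwise tables time/at_risk/events/S(t)."""

    groups: dict[str, pd.DataFrame] = field(default_factory=dict)

    def survival_at(self, group: str, t: float) -> float:
        tab = self.groups[group]
        past = tab[tab["time"] <= t]
        return 1.0 if past.empty else float(past["survival"].iloc[-1])


@dataclass(frozen=True)
class LogRankResult:
    """Two-group log-rank test with per-group observed/expected event counts."""

    chi_square: float
    p_value: float
    observed: dict[str, float]
    expected: dict[str, float]


def km_fit(times, events, labels) -> SurvivalFit:
    """Kaplan-Meier product-limit fit per group.

    ``times`` are non-negative day counts, ``events`` booleans (False =
    censored), ``labels`` the group of each subject.  Ties of events and
    censorings at the same time are handled events-first (censored subjects
    remain in the risk set for that time's events).
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    labels = np.asarray(labels)
    if (times < 0).any():
        raise ValueError("negative survival time")
    if not (len(times) == len(events) == len(labels)):
        raise ValueError("times, events and labels must be aligned")
    groups: dict[str, pd.DataFrame] = {}
    for g in pd.unique(labels):
        sel = labels == g
        kmf = KaplanMeierFitter()
        kmf.fit(times[sel], event_observed=events[sel])
        tab = kmf.event_table.reset_index().rename(columns={"event_at": "time"})
        surv = kmf.survival_function_.iloc[:, 0].to_numpy()
        groups[str(g)] = pd.DataFrame(
            {
                "time": tab["time"].to_numpy(dtype=float),
                "at_risk": tab["at_risk"].to_numpy(dtype=int),
                "events": tab["observed"].to_numpy(dtype=int),
                "censored": tab["censored"].to_numpy(dtype=int),
                "survival": surv,
            }
        )
    return SurvivalFit(groups)


def logrank_test(times, events, labels) -> LogRankResult:
    """Standard two-group log-rank test.

    At each distinct event time the observed events in group 1 are compared
    with the hypergeometric expectation given the pooled risk set; the
    squared sum of differences over the summed variances is chi-square with
    1 degree of freedom under the null of equal hazards.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    labels = np.asarray(labels)
    uniq = sorted(map(str, pd.unique(labels)))
    if len(uniq) != 2:
        raise ValueError(f"log-rank test needs exactly 2 groups (got {uniq})")
    if not events.any():
        raise ValueError("no events observed; log-rank statistic undefined")
    g1 = labels.astype(str) == uniq[0]
    event_times = np.unique(times[events])
    u = 0.0
    v = 0.0
    obs = {uniq[0]: 0.0, uniq[1]: 0.0}
    exp = {uniq[0]: 0.0, uniq[1]: 0.0}
    for t in event_times:
        at_risk = times >= t
        n = int(at_risk.sum())
        n1 = int((at_risk & g1).sum())
        d = int((events & (times == t)).sum())
        d1 = int((events & (times == t) & g1).sum())
        e1 = d * n1 / n
        obs[uniq[0]] += d1
        obs[uniq[1]] += d - d1
        exp[uniq[0]] += e1
        exp[uniq[1]] += d - e1
        if n > 1:
            v += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
        u += d1 - e1
    if v == 0:
        # all events in risk sets where one group is absent: no information
        chi = 0.0
    else:
        chi = u * u / v
    p = float(stats.chi2.sf(chi, df=1))
    return LogRankResult(chi_square=float(chi), p_value=p, observed=obs, expected=exp)


def pathway_association(
    X: ExpressionMatrix,
    gene: str,
    E: EnrichmentMatrix,
    mode: str = "median_split",
) -> pd.DataFrame:
    """Associate one gene with per-sample pathway activity scores.

    ``median_split`` mode rank-sum-tests each pathway's scores between the
    gene's high and low arms and reports the median difference (high - low);
    ``correlation`` mode reports the Pearson r of gene expression against
    each pathway score with its t-transform p-value.
    """
    shared = [s for s in X.sample_ids if s in set(E.sample_ids)]
    if len(shared) < 3:
        raise ValueError("need >=3 shared samples between expression and scores")
    Xs = X.subset_samples(shared)
    records = []
    if mode == "median_split":
        labels = median_split(Xs, gene)
        hi = [s for s in shared if labels[s] == "high"]
        lo = [s for s in shared if labels[s] == "low"]
        if not hi or not lo:
            raise ValueError("median split produced an empty arm")
        for name in E.set_names:
            sh = E.data.loc[name, hi].to_numpy(dtype=float)
            sl = E.data.loc[name, lo].to_numpy(dtype=float)
            stat, p = _rank_sum_p(sh, sl)
            records.append(
                {
                    "set_name": name,
                    "statistic": stat,
                    "difference": float(np.median(sh) - np.median(sl)),
                    "p_value": p,
                }
            )
    elif mode == "correlation":
        gv = Xs.data.loc[gene].to_numpy(dtype=float)
        for name in E.set_names:
            ev = E.data.loc[name, shared].to_numpy(dtype=float)
            if gv.std() == 0 or ev.std() == 0:
                records.append(
                    {"set_name": name, "r": np.nan, "p_value": np.nan,
                     "degenerate": True}
                )
                continue
            r, p = stats.pearsonr(gv, ev)
            if abs(r) >= 1.0 - 1e-15:
                r, p = math.copysign(1.0, r), 0.0
            records.append(
                {"set_name": name, "r": float(r), "p_value": float(p),
                 "degenerate": False}
            )
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return pd.DataFrame.from_records(records)
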