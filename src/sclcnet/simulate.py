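"""Synthetic paired pre/post expression cohorts with planted ground truth.

The generator emulates a microarray study of chemotherapy resistance in
small-cell lung cancer: 17 patients (5 primary-resistance, 12
acquired-resistance), each sampled before and after etoposide-platinum
treatment, giving 34 samples of log2-scale Gaussian intensities.  On this
background it plants

* differentially expressed genes — a log2 shift ``delta`` applied either to
  every post-treatment sample (``pre_vs_post`` contrast) or to the
  pre-treatment samples of the PR group (``PRpre_vs_ARpre`` contrast);
* hub-centred co-expression modules — star topologies in which every leaf
  loads on its hub with coefficient ``rho``, so each leaf-hub pair has
  expected sample correlation ``rho`` and the hub is the unique
  connectivity maximiser of its module;
* progression (and overall-survival) outcomes — exponential event times
  whose log-hazard is ``log(baseline_hazard) + surv_beta * z`` where ``z``
  is the first planted hub's patient-level expression standardized across
  patients, with a configurable fraction administratively censored.

A patient-level random intercept shared by a patient's pre and post samples
gives the within-patient correlation that paired analysis assumes.  All
randomness flows from ``SimConfig.seed``; identical configs give
bit-identical outputs.  Alongside the cohort the generator emits a
:class:`PlantedTruth` record against which recovery of DE genes and hub
genes can be measured.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd

from .io import ExpressionMatrix, SampleMetadata

__all__ = [
    "DESpec",
    "ModuleSpec",
    "SimConfig",
    "PlantedTruth",
    "simulate_cohort",
    "truth_recovery_report",
    "default_study_config",
]

CONTRASTS = ("pre_vs_post", "PRpre_vs_ARpre")


@dataclass(frozen=True)
class DESpec:
    """One planted differentially expressed gene."""

    gene_index: int
    delta: float  # log2 effect
    contrast: str = "pre_vs_post"

    def __post_init__(self) -> None:
        if self.contrast not in CONTRASTS:
            raise ValueError(f"unknown contrast {self.contrast!r}")


@dataclass(frozen=True)
class ModuleSpec:
    """One planted star-shaped co-expression module.

    Leaves occupy the ``n_leaves`` gene indices immediately after
    ``hub_index``.
    """

    hub_index: int
    n_leaves: int = 9
    rho: float = 0.9

    def __post_init__(self) -> None:
        if not (0 < self.rho < 1):
            raise ValueError("rho must be in (0, 1)")
        if self.n_leaves < 5:
            raise ValueError("n_leaves must be >= 5 for a recoverable hub")

    @property
    def leaf_indices(self) -> range:
        return range(self.hub_index + 1, self.hub_index + 1 + self.n_leaves)


@dataclass(frozen=True)
class SimConfig:
    """Study-design parameters of the synthetic cohort.

    Defaults mirror the emulated study: 5 PR + 12 AR patients, two paired
    timepoints, 2000 genes at mean log2 intensity 8 with residual sd 1.0
    and a patient random-intercept sd of 0.5.
    """

    n_pr: int = 5
    n_ar: int = 12
    n_genes: int = 2000
    noise_sd: float = 1.0
    patient_sd: float = 0.5
    baseline_mean: float = 8.0
    de_spec: tuple[DESpec, ...] = ()
    module_spec: tuple[ModuleSpec, ...] = ()
    surv_beta: float = 0.0
    baseline_hazard: float = 1.0 / 180.0  # events/day; median progression ~4 months
    censor_rate: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_pr < 1 or self.n_ar < 1:
            raise ValueError("need at least one patient per resistance group")
        if self.noise_sd <= 0 or self.patient_sd < 0:
            raise ValueError("noise_sd must be > 0 and patient_sd >= 0")
        if not (0 <= self.censor_rate < 1):
            raise ValueError("censor_rate must be in [0, 1)")
        if self.baseline_hazard <= 0:
            raise ValueError("baseline_hazard must be positive")
        planted: set[int] = set()
        for spec in self.de_spec:
            if spec.gene_index in planted:
                raise ValueError(
                    f"gene index {spec.gene_index} planted more than once"
                )
            planted.add(spec.gene_index)
        for mod in self.module_spec:
            idxs = [mod.hub_index, *mod.leaf_indices]
            if idxs[-1] >= self.n_genes:
                raise ValueError(
                    f"module at hub {mod.hub_index} exceeds the {self.n_genes}-gene budget"
                )
            for i in idxs:
                if i in planted:
                    raise ValueError(f"gene index {i} planted more than once")
                planted.add(i)
        bad = [i for i in planted if not (0 <= i < self.n_genes)]
        if bad:
            raise ValueError(f"planted gene indices out of range: {sorted(bad)[:5]}")


@dataclass(frozen=True)
class PlantedTruth:
    """Ground truth emitted with a simulated cohort."""

    gene_ids: tuple[str, ...]
    de_genes: dict[str, dict[str, float]]  # contrast -> {gene_id: delta}
    hub_genes: tuple[str, ...]
    modules: dict[str, tuple[str, ...]]  # hub gene -> leaf gene ids
    surv_beta: float

    def to_json(self, path) -> None:
        payload = {
            "gene_ids": list(self.gene_ids),
            "de_genes": self.de_genes,
            "hub_genes": list(self.hub_genes),
            "modules": {k: list(v) for k, v in self.modules.items()},
            "surv_beta": self.surv_beta,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "PlantedTruth":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            gene_ids=tuple(d["gene_ids"]),
            de_genes={c: dict(v) for c, v in d["de_genes"].items()},
            hub_genes=tuple(d["hub_genes"]),
            modules={k: tuple(v) for k, v in d["modules"].items()},
            surv_beta=float(d["surv_beta"]),
        )


def _gene_ids(n: int) -> list[str]:
    width = max(4, len(str(n)))
    return [f"G{i:0{width}d}" for i in range(n)]


def simulate_cohort(
    config: SimConfig,
) -> tuple[ExpressionMatrix, SampleMetadata, PlantedTruth]:
    """Draw one synthetic cohort.

    Returns the log2 expression matrix (genes x 2*(n_pr+n_ar) samples), the
    sample metadata with per-patient progression and survival outcomes, and
    the planted ground truth.
    """
    rng = np.random.default_rng(config.seed)
    n_pat = config.n_pr + config.n_ar
    n_samp = 2 * n_pat
    genes = _gene_ids(config.n_genes)
    pat_width = max(2, len(str(n_pat)))
    patients = [f"P{i + 1:0{pat_width}d}" for i in range(n_pat)]
    groups = ["PR"] * config.n_pr + ["AR"] * config.n_ar

    sample_ids, sample_patient, sample_tp = [], [], []
    for p, pat in enumerate(patients):
        for tp in ("pre", "post"):
            sample_ids.append(f"{pat}_{tp}")
            sample_patient.append(p)
            sample_tp.append(tp)
    sample_patient = np.asarray(sample_patient)
    is_post = np.asarray([tp == "post" for tp in sample_tp])
    is_pr = np.asarray([groups[p] == "PR" for p in sample_patient])

    # background: mean + gene-by-patient intercept + residual noise
    intercepts = rng.normal(0.0, config.patient_sd, size=(config.n_genes, n_pat))
    noise = rng.normal(0.0, config.noise_sd, size=(config.n_genes, n_samp))
    vals = config.baseline_mean + intercepts[:, sample_patient] + noise

    for spec in config.de_spec:
        if spec.contrast == "pre_vs_post":
            vals[spec.gene_index, is_post] += spec.delta
        else:  # PRpre_vs_ARpre
            vals[spec.gene_index, is_pr & ~is_post] += spec.delta

    total_sd = float(np.hypot(config.noise_sd, config.patient_sd))
    for mod in config.module_spec:
        hub = vals[mod.hub_index]
        centered = hub - config.baseline_mean
        for leaf in mod.leaf_indices:
            eps = rng.normal(0.0, 1.0, size=n_samp)
            vals[leaf] = (
                config.baseline_mean
                + mod.rho * centered
                + np.sqrt(1.0 - mod.rho**2) * total_sd * eps
            )

    # outcomes per patient; hazard tied to the first planted hub, if any
    if config.module_spec:
        hub_row = vals[config.module_spec[0].hub_index]
        per_patient = np.array(
            [hub_row[sample_patient == p].mean() for p in range(n_pat)]
        )
        z = (per_patient - per_patient.mean()) / per_patient.std()
    else:
        z = np.zeros(n_pat)

    def _draw_outcomes(hazard0: float) -> tuple[np.ndarray, np.ndarray]:
        rate = hazard0 * np.exp(config.surv_beta * z)
        t_event = rng.exponential(1.0 / rate)
        if config.censor_rate > 0:
            # administrative censoring at end of follow-up: the cutoff is the
            # baseline-hazard quantile leaving censor_rate still event-free
            tau = -np.log(config.censor_rate) / hazard0
            censored = t_event > tau
            t_obs = np.minimum(t_event, tau)
        else:
            censored = np.zeros(n_pat, dtype=bool)
            t_obs = t_event
        return np.round(t_obs, 1), ~censored

    prog_days, prog_event = _draw_outcomes(config.baseline_hazard)
    surv_days, surv_event = _draw_outcomes(config.baseline_hazard / 2.0)

    X = ExpressionMatrix(pd.DataFrame(vals, index=genes, columns=sample_ids))
    meta = SampleMetadata(
        pd.DataFrame(
            {
                "sample_id": sample_ids,
                "patient_id": [patients[p] for p in sample_patient],
                "timepoint": sample_tp,
                "group": [groups[p] for p in sample_patient],
                "progression_days": prog_days[sample_patient],
                "progression_event": prog_event[sample_patient],
                "survival_days": surv_days[sample_patient],
                "survival_event": surv_event[sample_patient],
            }
        )
    )
    de_genes: dict[str, dict[str, float]] = {c: {} for c in CONTRASTS}
    for spec in config.de_spec:
        de_genes[spec.contrast][genes[spec.gene_index]] = spec.delta
    truth = PlantedTruth(
        gene_ids=tuple(genes),
        de_genes=de_genes,
        hub_genes=tuple(genes[m.hub_index] for m in config.module_spec),
        modules={
            genes[m.hub_index]: tuple(genes[i] for i in m.leaf_indices)
            for m in config.module_spec
        },
        surv_beta=config.surv_beta,
    )
    return X, meta, truth


def truth_recovery_report(
    truth: PlantedTruth,
    deg: pd.DataFrame | None = None,
    hubs: pd.DataFrame | None = None,
    contrast: str = "pre_vs_post",
) -> dict:
    """Score recovered DE genes and hub genes against the planted truth.

    Returns a dict with ``de_sensitivity`` (recovered / planted; None when
    nothing was planted), ``de_fdp`` (false-discovery proportion among
    called DEGs), and ``hub_recovery`` (fraction of planted hubs called).
    """
    out: dict[str, float | None] = {
        "de_sensitivity": None,
        "de_fdp": None,
        "hub_recovery": None,
    }
    universe = set(truth.gene_ids)
    if deg is not None:
        called = set(deg.loc[deg["is_deg"], "gene_id"])
        table_genes = set(deg["gene_id"])
        if not table_genes <= universe:
            raise ValueError("DEG table contains genes outside the simulated universe")
        planted = set(truth.de_genes.get(contrast, {}))
        out["de_fdp"] = (
            len(called - planted) / len(called) if called else 0.0
        )
        out["de_sensitivity"] = (
            len(called & planted) / len(planted) if planted else None
        )
    if hubs is not None:
        hub_genes = set(hubs["gene_id"])
        if not hub_genes <= universe:
            raise ValueError("hub report contains genes outside the simulated universe")
        called_hubs = set(hubs.loc[hubs["is_hub"], "gene_id"])
        planted_hubs = set(truth.hub_genes)
        out["hub_recovery"] = (
            len(called_hubs & planted_hubs) / len(planted_hubs)
            if planted_hubs
            else None
        )
    return out


def default_study_config(
    seed: int = 0,
    surv_beta: float = 1.0,
    panel_size: int = 100,
) -> tuple[SimConfig, list[int]]:
    """The default planted scenario used by the end-to-end pipeline.

    Two star modules (9 leaves each, rho = 0.9) sit inside the first
    ``panel_size`` genes — the synthetic analogue of a cancer-pathway gene
    panel — together with planted DE genes at |log2 effect| 1.0 for the
    paired contrast and 1.5 for the between-group contrast (the two-group
    comparison has far fewer samples, 5 vs 12, than the 17 pairs).

    Returns the config and the panel gene indices.
    """
    de = tuple(
        DESpec(gene_index=i, delta=d, contrast="pre_vs_post")
        for i, d in zip(range(200, 220), [1.0, -1.0] * 10)
    ) + tuple(
        DESpec(gene_index=i, delta=d, contrast="PRpre_vs_ARpre")
        for i, d in zip(range(220, 240), [1.5, -1.5] * 10)
    )
    modules = (ModuleSpec(hub_index=0, n_leaves=9, rho=0.9),
               ModuleSpec(hub_index=10, n_leaves=9, rho=0.9))
    cfg = SimConfig(
        de_spec=de,
        module_spec=modules,
        surv_beta=surv_beta,
        seed=seed,
    )
    return cfg, list(range(panel_size))
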