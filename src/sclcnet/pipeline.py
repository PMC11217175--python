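"""End-to-end orchestration: config validation, staged execution, manifest.

A single flat YAML config drives the whole analysis, in either of two
exclusive modes:

* real mode — paths to an expression table, metadata table, network panel
  gene list, signature GMT and pathway GMT;
* synthetic mode — a simulator block (``synthetic: true`` plus optional
  SimConfig overrides); the cohort, a synthetic signature GMT and a
  synthetic pathway GMT are generated from the run seed.

Stages run in a fixed order: (simulate) -> quantile normalization -> DEG
calling (paired pre/post; PR_pre vs AR_pre; AR_pre vs AR_post paired) ->
signature scoring + composites + group comparisons -> co-expression network
/ spanning forest / hub calling per resistance contrast -> hub-signature
correlation -> pathway association -> Kaplan-Meier / log-rank per hub.
Every intermediate is written as TSV and listed, with its row count, in a
JSON manifest that also echoes the config; manifests carry no timestamps,
so identical config + seed reproduce byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import dge, network, scoring, simulate, survival
from .io import (
    ExpressionMatrix,
    GeneSetCollection,
    SampleMetadata,
    read_expression,
    read_gene_list,
    read_gmt,
    read_metadata,
    write_expression,
    write_gmt,
    write_metadata,
)

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    """The pipeline config is malformed or inconsistent."""


_PATH_KEYS = ("expression", "metadata", "panel", "signatures", "pathways")

_DEFAULTS: dict[str, Any] = {
    "synthetic": False,
    "seed": 0,
    # simulator overrides (synthetic mode only)
    "n_pr": 5,
    "n_ar": 12,
    "n_genes": 2000,
    "noise_sd": 1.0,
    "surv_beta": 1.0,
    "panel_size": 100,
    # stage parameters
    "p_threshold": 0.05,
    "fc_threshold": 0.3,
    "moderation": "empirical_bayes",
    "alpha": 0.25,
    "beta": 6,
    "signed": False,
    "min_weight": 0.01,
    "top_frac": 0.30,
    "hub_degree_gt": 4,
}

_RANGES = {
    "p_threshold": (0.0, 1.0),
    "fc_threshold": (0.0, np.inf),
    "alpha": (0.0, np.inf),
    "top_frac": (0.0, 1.0),
    "min_weight": (0.0, 1.0),
    "noise_sd": (0.0, np.inf),
}


@dataclasses.dataclass(frozen=True)
class PipelineConfig:
    """Validated, fully-defaulted pipeline configuration."""

    params: dict[str, Any]
    paths: dict[str, Path]
    out_dir: Path

    def __getitem__(self, key: str) -> Any:
        return self.params[key]


def validate_config(
    path_or_mapping, out_dir, seed: int | None = None
) -> PipelineConfig:
    """Load, default-fill and validate a flat key-value pipeline config.

    Unknown keys are rejected by name; out-of-range values report the
    permitted range; exactly one of real input paths or synthetic mode must
    be present, and referenced files must exist.
    """
    if isinstance(path_or_mapping, (str, Path)):
        with open(path_or_mapping) as fh:
            raw = yaml.safe_load(fh) or {}
    else:
        raw = dict(path_or_mapping or {})
    if not isinstance(raw, dict):
        raise ConfigError("config must be a flat mapping of key: value pairs")
    allowed = set(_DEFAULTS) | set(_PATH_KEYS)
    for key in raw:
        if key not in allowed:
            raise ConfigError(f"unknown config key {key!r}")
    params = dict(_DEFAULTS)
    paths: dict[str, Path] = {}
    for key, val in raw.items():
        if key in _PATH_KEYS:
            paths[key] = Path(val)
        else:
            params[key] = val
    if seed is not None:
        params["seed"] = int(seed)
    for key, (lo, hi) in _RANGES.items():
        v = params[key]
        if not (lo <= float(v) <= hi):
            raise ConfigError(
                f"config key {key!r} = {v} outside permitted range [{lo}, {hi}]"
            )
    synthetic = bool(params["synthetic"])
    if synthetic and paths:
        raise ConfigError(
            "config must use either real input paths or synthetic mode, not both"
        )
    if not synthetic:
        missing = [k for k in _PATH_KEYS if k not in paths]
        if missing:
            raise ConfigError(
                f"real mode requires input paths for: {missing}"
            )
        absent = [str(p) for p in paths.values() if not p.exists()]
        if absent:
            raise ConfigError(f"input files not found: {absent}")
    return PipelineConfig(params=params, paths=paths, out_dir=Path(out_dir))


def _synthetic_gene_sets(
    genes: list[str], rng: np.random.Generator
) -> tuple[GeneSetCollection, GeneSetCollection, list[str], list[str]]:
    """Draw synthetic cell-type signatures and pathway sets from the universe."""
    pool = np.asarray(genes)
    sig_sets: dict[str, tuple[str, ...]] = {}
    sig_desc: dict[str, str] = {}
    cell_types = [
        "CD4_T_cells", "CD8_T_cells", "B_cells", "NK_cells", "Monocytes",
        "Macrophages_M1", "Megakaryocytes", "Tregs",
    ]
    stromal_types = ["Fibroblasts", "Endothelial_cells"]
    for name in cell_types + stromal_types:
        members = rng.choice(pool, size=25, replace=False)
        sig_sets[name] = tuple(sorted(members))
        sig_desc[name] = "synthetic cell-type signature"
    path_sets: dict[str, tuple[str, ...]] = {}
    path_desc: dict[str, str] = {}
    for i in range(10):
        name = f"PATHWAY_{i + 1:02d}"
        members = rng.choice(pool, size=40, replace=False)
        path_sets[name] = tuple(sorted(members))
        path_desc[name] = "synthetic hallmark-style pathway set"
    return (
        GeneSetCollection(sig_sets, sig_desc),
        GeneSetCollection(path_sets, path_desc),
        cell_types,
        stromal_types,
    )


def _write_tsv(df: pd.DataFrame, path: Path) -> int:
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")
    return len(df)


class _Manifest:
    def __init__(self, config: PipelineConfig) -> None:
        self.files: list[dict[str, Any]] = []
        self.config_echo = {
            **{k: (v if not isinstance(v, (np.bool_, np.integer, np.floating))
                   else v.item())
               for k, v in config.params.items()},
            **{k: str(p) for k, p in config.paths.items()},
        }
        self.status = "complete"
        self.failed_stage: str | None = None

    def add(self, name: str, n_rows: int) -> None:
        self.files.append({"file": name, "rows": int(n_rows)})

    def write(self, path: Path) -> None:
        payload = {
            "status": self.status,
            "failed_stage": self.failed_stage,
            "config": self.config_echo,
            "files": self.files,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception) -> None:
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage and return the manifest as a dict.

    Any stage error halts the run; the manifest written so far is flagged
    ``failed`` with the failing stage's name.
    """
    out = config.out_dir
    out.mkdir(parents=True, exist_ok=True)
    manifest = _Manifest(config)
    state: dict[str, Any] = {}
    stages = [
        ("simulate", _stage_simulate),
        ("normalize", _stage_normalize),
        ("dge", _stage_dge),
        ("scores", _stage_scores),
        ("network", _stage_network),
        ("pathway_association", _stage_pathways),
        ("survival", _stage_survival),
    ]
    try:
        for name, fn in stages:
            t0 = time.perf_counter()
            logger.info("START stage %s", name)
            try:
                fn(config, state, manifest)
            except Exception as exc:  # halt with stage context
                raise StageError(name, exc) from exc
            logger.info(
                "END stage %s (%.2fs)", name, time.perf_counter() - t0
            )
    except StageError:
        manifest.status = "failed"
        manifest.failed_stage = name
        manifest.write(out / "manifest.json")
        raise
    manifest.write(out / "manifest.json")
    with open(out / "manifest.json") as fh:
        return json.load(fh)


def _stage_simulate(config: PipelineConfig, state: dict, manifest: _Manifest) -> None:
    out = config.out_dir
    if config["synthetic"]:
        seed = int(config["seed"])
        sim_cfg, panel_idx = simulate.default_study_config(
            seed=seed,
            surv_beta=float(config["surv_beta"]),
            panel_size=int(config["panel_size"]),
        )
        sim_cfg = dataclasses.replace(
            sim_cfg,
            n_pr=int(config["n_pr"]),
            n_ar=int(config["n_ar"]),
            n_genes=int(config["n_genes"]),
            noise_sd=float(config["noise_sd"]),
        )
        X, meta, truth = simulate.simulate_cohort(sim_cfg)
        # per-stage substream for the synthetic gene sets
        rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(1)[0])
        signatures, pathways, immune, stromal = _synthetic_gene_sets(
            X.gene_ids, rng
        )
        panel = [X.gene_ids[i] for i in panel_idx]
        write_expression(X, out / "expression.tsv")
        manifest.add("expression.tsv", X.n_genes)
        write_metadata(meta, out / "metadata.tsv")
        manifest.add("metadata.tsv", len(meta.table))
        truth.to_json(out / "truth.json")
        manifest.add("truth.json", len(truth.gene_ids))
        write_gmt(signatures, out / "signatures.gmt")
        manifest.add("signatures.gmt", len(signatures))
        write_gmt(pathways, out / "pathways.gmt")
        manifest.add("pathways.gmt", len(pathways))
        state.update(
            X=X, meta=meta, truth=truth, panel=panel,
            signatures=signatures, pathways=pathways,
            immune_sets=immune, stromal_sets=stromal,
        )
    else:
        X = read_expression(config.paths["expression"])
        meta = read_metadata(config.paths["metadata"])
        signatures = read_gmt(config.paths["signatures"])
        pathways = read_gmt(config.paths["pathways"])
        panel = read_gene_list(config.paths["panel"])
        state.update(
            X=X, meta=meta, truth=None, panel=panel,
            signatures=signatures, pathways=pathways,
            immune_sets=list(signatures.set_names), stromal_sets=None,
        )


def _stage_normalize(config: PipelineConfig, state: dict, manifest: _Manifest) -> None:
    Xn = dge.quantile_normalize(state["X"])
    write_expression(Xn, config.out_dir / "expression_normalized.tsv")
    manifest.add("expression_normalized.tsv", Xn.n_genes)
    state["Xn"] = Xn


_DGE_CONTRASTS = {
    "deg_paired_pre_post": dict(contrast="paired_pre_post"),
    "deg_prpre_vs_arpre": dict(contrast="group_pre_vs_pre", group_a="PR", group_b="AR"),
    "deg_ar_pre_post": dict(contrast="paired_pre_post", group="AR"),
}


def _stage_dge(config: PipelineConfig, state: dict, manifest: _Manifest) -> None:
    state["deg"] = {}
    for name, kwargs in _DGE_CONTRASTS.items():
        table = dge.diff_expr(
            state["Xn"],
            state["meta"],
            moderation=str(config["moderation"]),
            p_threshold=float(config["p_threshold"]),
            fc_threshold=float(config["fc_threshold"]),
            **kwargs,
        )
        table = table.sort_values(
            ["adj_p", "gene_id"], ignore_index=True
        )
        n = _write_tsv(table, config.out_dir / f"{name}.tsv")
        manifest.add(f"{name}.tsv", n)
        state["deg"][name] = table


def _stage_scores(config: PipelineConfig, state: dict, manifest: _Manifest) -> None:
    E = scoring.ssgsea_score(
        state["Xn"], state["signatures"], alpha=float(config["alpha"])
    )
    E.data.rename_axis("set_name").to_csv(
        config.out_dir / "signature_scores.tsv", sep="\t", float_format="%.10g"
    )
    manifest.add("signature_scores.tsv", len(E.set_names))
    state["E_sig"] = E
    if state["stromal_sets"]:
        comp = scoring.composite_scores(
            E, state["immune_sets"], state["stromal_sets"]
        )
        comp.reset_index().pipe(
            _write_tsv, config.out_dir / "composite_scores.tsv"
        )
        manifest.add("composite_scores.tsv", len(comp))
    comparisons = {
        "scores_pre_vs_post": dict(design="paired", a=(None, "pre"), b=(None, "post")),
        "scores_prpre_vs_arpre": dict(design="unpaired", a=("PR", "pre"), b=("AR", "pre")),
        "scores_arpre_vs_arpost": dict(design="paired", a=("AR", "pre"), b=("AR", "post")),
    }
    for name, kwargs in comparisons.items():
        table = scoring.compare_groups(E, state["meta"], **kwargs)
        n = _write_tsv(table, config.out_dir / f"{name}.tsv")
        manifest.add(f"{name}.tsv", n)


def _network_genes(deg_table: pd.DataFrame, panel: list[str]) -> list[str]:
    called = set(deg_table.loc[deg_table["is_deg"], "gene_id"])
    genes = [g for g in panel if g in called]
    if len(genes) < 10:
        # too few panel DEGs for a meaningful network; use the whole panel
        logger.info(
            "network: DEG/panel intersection has %d genes; using full panel",
            len(genes),
        )
        return list(panel)
    return genes


def _stage_network(config: PipelineConfig, state: dict, manifest: _Manifest) -> None:
    net_cfg = network.NetworkConfig(
        beta=int(config["beta"]),
        signed=bool(config["signed"]),
        min_weight=float(config["min_weight"]),
        top_frac=float(config["top_frac"]),
        hub_degree_gt=int(config["hub_degree_gt"]),
    )
    state["hubs"] = {}
    for label, deg_name in (
        ("primary", "deg_prpre_vs_arpre"),
        ("acquired", "deg_ar_pre_post"),
    ):
        genes = _network_genes(state["deg"][deg_name], state["panel"])
        G = network.build_adjacency(state["Xn"], genes, net_cfg)
        Gf = network.filter_network(G, net_cfg)
        forest = network.spanning_forest(Gf)
        hubs = network.find_hubs(forest, net_cfg)
        network.write_edge_list(Gf, config.out_dir / f"network_{label}.tsv")
        manifest.add(f"network_{label}.tsv", Gf.number_of_edges())
        network.write_edge_list(forest, config.out_dir / f"forest_{label}.tsv")
        manifest.add(f"forest_{label}.tsv", forest.number_of_edges())
        n = _write_tsv(hubs, config.out_dir / f"hubs_{label}.tsv")
        manifest.add(f"hubs_{label}.tsv", n)
        state["hubs"][label] = hubs
        hub_genes = list(hubs.loc[hubs["is_hub"], "gene_id"])
        if hub_genes:
            corr = network.hub_cell_correlation(
                state["Xn"], hub_genes, state["E_sig"]
            )
            n = _write_tsv(corr, config.out_dir / f"hub_cell_corr_{label}.tsv")
            manifest.add(f"hub_cell_corr_{label}.tsv", n)


def _all_hub_genes(state: dict) -> list[str]:
    genes: list[str] = []
    for label in ("primary", "acquired"):
        hubs = state["hubs"].get(label)
        if hubs is not None:
            genes += list(hubs.loc[hubs["is_hub"], "gene_id"])
    return list(dict.fromkeys(genes))


def _stage_pathways(config: PipelineConfig, state: dict, manifest: _Manifest) -> None:
    E_path = scoring.ssgsea_score(
        state["Xn"], state["pathways"], alpha=float(config["alpha"])
    )
    E_path.data.rename_axis("set_name").to_csv(
        config.out_dir / "pathway_scores.tsv", sep="\t", float_format="%.10g"
    )
    manifest.add("pathway_scores.tsv", len(E_path.set_names))
    rows = []
    for gene in _all_hub_genes(state):
        for mode in ("median_split", "correlation"):
            tab = survival.pathway_association(state["Xn"], gene, E_path, mode=mode)
            tab.insert(0, "gene_id", gene)
            tab.insert(1, "mode", mode)
            rows.append(tab)
    if rows:
        table = pd.concat(rows, ignore_index=True)
        n = _write_tsv(table, config.out_dir / "pathway_association.tsv")
        manifest.add("pathway_association.tsv", n)


def _stage_survival(config: PipelineConfig, state: dict, manifest: _Manifest) -> None:
    meta: SampleMetadata = state["meta"]
    if "progression_days" not in meta.table.columns:
        logger.info("survival: no outcome columns in metadata; stage skipped")
        return
    Xp = survival.patient_level_expression(state["Xn"], meta)
    pat = meta.patient_table().set_index("patient_id")
    rows = []
    for gene in _all_hub_genes(state):
        labels = survival.median_split(Xp, gene)
        for time_col, event_col in (
            ("progression_days", "progression_event"),
            ("survival_days", "survival_event"),
        ):
            if time_col not in pat.columns:
                continue
            times = pat.loc[labels.index, time_col].to_numpy(dtype=float)
            events = pat.loc[labels.index, event_col].to_numpy(dtype=bool)
            if not events.any():
                continue
            res = survival.logrank_test(times, events, labels.to_numpy())
            rows.append(
                {
                    "gene_id": gene,
                    "outcome": time_col.replace("_days", ""),
                    "chi_square": res.chi_square,
                    "p_value": res.p_value,
                    "n_high": int((labels == "high").sum()),
                    "n_low": int((labels == "low").sum()),
                }
            )
    if rows:
        table = pd.DataFrame.from_records(rows)
        n = _write_tsv(table, config.out_dir / "survival_logrank.tsv")
        manifest.add("survival_logrank.tsv", n)
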