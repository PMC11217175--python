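"""Core data containers and text-format I/O.

Three containers flow through every stage of the pipeline:

* :class:`ExpressionMatrix` — a log2-scale gene x sample intensity matrix.
* :class:`SampleMetadata` — per-sample patient / timepoint / resistance-group /
  outcome annotations driving paired designs and group splits.
* :class:`GeneSetCollection` — named gene sets (cell-type signatures or
  pathway sets) in the Broad GMT dialect.

All on-disk formats are plain delimited text; the delimiter of tabular files
is auto-detected between tab and comma from the header line.  Gene
identifiers are opaque, case-sensitive strings — no symbol remapping is ever
attempted.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

TIMEPOINTS = ("pre", "post")
GROUPS = ("PR", "AR")


class DataFormatError(ValueError):
    """A file or table violates the format contract (duplicates, bad tokens, ...)."""


def _detect_delimiter(header: str, path) -> str:
    has_tab = "\t" in header
    has_comma = "," in header
    if has_tab and has_comma:
        raise DataFormatError(
            f"{path}: header mixes tab and comma delimiters; use one dialect"
        )
    if has_tab:
        return "\t"
    if has_comma:
        return ","
    # single-column header (e.g. one sample): default to tab
    return "\t"


def _read_table(path) -> pd.DataFrame:
    path = Path(path)
    with open(path) as fh:
        header = fh.readline()
    if not header.strip():
        raise DataFormatError(f"{path}: empty file")
    sep = _detect_delimiter(header.rstrip("\n"), path)
    return pd.read_csv(path, sep=sep, dtype=str, index_col=False)


@dataclass(frozen=True)
class ExpressionMatrix:
    """Log2-scale expression values, genes in rows and samples in columns.

    Parameters
    ----------
    data : pandas.DataFrame
        Numeric frame indexed by gene id with sample ids as columns.  Row and
        column order is meaningful and preserved by all I/O.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        if df.index.has_duplicates:
            dup = df.index[df.index.duplicated()][0]
            raise DataFormatError(f"duplicate gene id {dup!r}")
        if df.columns.has_duplicates:
            dup = df.columns[df.columns.duplicated()][0]
            raise DataFormatError(f"duplicate sample id {dup!r}")
        vals = df.to_numpy()
        if vals.size and not np.issubdtype(vals.dtype, np.number):
            raise DataFormatError("expression values must be numeric")
        if vals.size and not np.isfinite(vals).all():
            i, j = np.argwhere(~np.isfinite(vals))[0]
            raise DataFormatError(
                f"non-finite value at gene {df.index[i]!r}, sample {df.columns[j]!r}"
            )

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def n_genes(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    def subset_genes(self, genes: Sequence[str]) -> "ExpressionMatrix":
        missing = [g for g in genes if g not in self.data.index]
        if missing:
            raise KeyError(f"genes absent from matrix: {missing[:5]}")
        return ExpressionMatrix(self.data.loc[list(genes)])

    def subset_samples(self, samples: Sequence[str]) -> "ExpressionMatrix":
        missing = [s for s in samples if s not in self.data.columns]
        if missing:
            raise KeyError(f"samples absent from matrix: {missing[:5]}")
        return ExpressionMatrix(self.data[list(samples)])


def read_expression(path, missing_policy: str = "error") -> ExpressionMatrix:
    """Read a genes-in-rows expression table (TSV or CSV).

    The first column holds gene ids, the header row sample ids.  Under
    ``missing_policy="error"`` any non-numeric or empty cell is a parse error
    naming its row and column; under ``"drop_gene"`` every gene row containing
    a missing cell is removed and the count logged.
    """
    if missing_policy not in ("error", "drop_gene"):
        raise ValueError(f"unknown missing_policy {missing_policy!r}")
    raw = _read_table(path)
    gene_col = raw.columns[0]
    genes = raw[gene_col].astype(str)
    dup_genes = genes[genes.duplicated()]
    if len(dup_genes):
        raise DataFormatError(f"{path}: duplicate gene id {dup_genes.iloc[0]!r}")
    samples = list(raw.columns[1:])
    if len(samples) != len(set(samples)):
        seen: set[str] = set()
        for s in samples:
            if s in seen:
                raise DataFormatError(f"{path}: duplicate sample id {s!r}")
            seen.add(s)
    body = raw[samples].apply(pd.to_numeric, errors="coerce")
    bad = body.isna() | ~np.isfinite(body.fillna(0.0))
    if bad.to_numpy().any():
        if missing_policy == "error":
            i, j = np.argwhere(bad.to_numpy())[0]
            raise DataFormatError(
                f"{path}: non-numeric or missing value at gene {genes.iloc[i]!r}, "
                f"column {samples[j]!r}"
            )
        keep = ~bad.any(axis=1)
        n_drop = int((~keep).sum())
        logger.info("read_expression: dropped %d gene rows with missing cells", n_drop)
        body = body.loc[keep]
        genes = genes.loc[keep]
    body = body.astype(float)
    body.index = pd.Index(genes, name=gene_col)
    return ExpressionMatrix(body)


def write_expression(X: ExpressionMatrix, path, sep: str = "\t") -> None:
    df = X.data.copy()
    df.index.name = df.index.name or "gene_id"
    # repr-round-trip precision so write->read is the identity
    df.to_csv(path, sep=sep, float_format="%.17g")


@dataclass(frozen=True)
class SampleMetadata:
    """Per-sample annotations: patient, timepoint, resistance group, outcomes.

    Required columns: ``sample_id``, ``patient_id``, ``timepoint`` (pre/post),
    ``group`` (PR/AR).  Optional outcome columns: ``progression_days``,
    ``progression_event``, ``survival_days``, ``survival_event``.
    """

    table: pd.DataFrame

    REQUIRED = ("sample_id", "patient_id", "timepoint", "group")

    def __post_init__(self) -> None:
        df = self.table
        for col in self.REQUIRED:
            if col not in df.columns:
                raise DataFormatError(f"metadata missing required column {col!r}")
        if df["sample_id"].duplicated().any():
            dup = df.loc[df["sample_id"].duplicated(), "sample_id"].iloc[0]
            raise DataFormatError(f"duplicate sample_id {dup!r}")
        bad_tp = set(df["timepoint"]) - set(TIMEPOINTS)
        if bad_tp:
            raise DataFormatError(
                f"unknown timepoint token(s) {sorted(bad_tp)}; allowed: {TIMEPOINTS}"
            )
        bad_gr = set(df["group"]) - set(GROUPS)
        if bad_gr:
            raise DataFormatError(
                f"unknown group token(s) {sorted(bad_gr)}; allowed: {GROUPS}"
            )
        pair_dup = df.duplicated(subset=["patient_id", "timepoint"])
        if pair_dup.any():
            row = df.loc[pair_dup].iloc[0]
            raise DataFormatError(
                f"patient {row['patient_id']!r} has more than one "
                f"{row['timepoint']!r} sample"
            )
        n_groups = df.groupby("patient_id")["group"].nunique()
        incon = n_groups[n_groups > 1]
        if len(incon):
            raise DataFormatError(
                f"patient {incon.index[0]!r} assigned to more than one resistance group"
            )
        for col in ("progression_days", "survival_days"):
            if col in df.columns:
                vals = pd.to_numeric(df[col], errors="raise")
                if (vals.dropna() < 0).any():
                    raise DataFormatError(f"negative value in {col}")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table["sample_id"])

    def select(self, group: str | None = None, timepoint: str | None = None) -> list[str]:
        """Sample ids matching the given group and/or timepoint."""
        df = self.table
        mask = pd.Series(True, index=df.index)
        if group is not None:
            if group not in GROUPS:
                raise ValueError(f"unknown group {group!r}")
            mask &= df["group"] == group
        if timepoint is not None:
            if timepoint not in TIMEPOINTS:
                raise ValueError(f"unknown timepoint {timepoint!r}")
            mask &= df["timepoint"] == timepoint
        return list(df.loc[mask, "sample_id"])

    def pairs(self, group: str | None = None) -> pd.DataFrame:
        """One row per patient having both timepoints: patient_id, pre, post.

        Raises if any included patient is missing a timepoint.
        """
        df = self.table
        if group is not None:
            df = df[df["group"] == group]
        wide = df.pivot(index="patient_id", columns="timepoint", values="sample_id")
        for tp in TIMEPOINTS:
            if tp not in wide.columns:
                wide[tp] = np.nan
        missing = wide[wide[["pre", "post"]].isna().any(axis=1)]
        if len(missing):
            raise DataFormatError(
                "patients missing a timepoint in paired design: "
                f"{sorted(missing.index)}"
            )
        out = wide[["pre", "post"]].reset_index()
        out.columns.name = None
        return out

    def patient_table(self) -> pd.DataFrame:
        """One row per patient with group and (first non-null) outcome columns."""
        cols = [c for c in self.table.columns if c not in ("sample_id", "timepoint")]
        return self.table[cols].drop_duplicates("patient_id").reset_index(drop=True)


def read_metadata(path) -> SampleMetadata:
    """Read a sample metadata table (TSV or CSV) with the required columns."""
    df = _read_table(path)
    for col in ("progression_days", "survival_days"):
        if col in df.columns:
            df[col] = pd.to_numeric(df[col], errors="coerce")
    for col in ("progression_event", "survival_event"):
        if col in df.columns:
            df[col] = df[col].map(
                {"True": True, "False": False, "1": True, "0": False,
                 True: True, False: False}
            )
    return SampleMetadata(df)


def write_metadata(meta: SampleMetadata, path, sep: str = "\t") -> None:
    meta.table.to_csv(path, sep=sep, index=False)


@dataclass(frozen=True)
class GeneSetCollection:
    """Ordered named gene sets.  Set names unique; members unique within a set."""

    sets: Mapping[str, tuple[str, ...]]
    descriptions: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if len(members) == 0:
                raise DataFormatError(f"gene set {name!r} is empty")
            if len(set(members)) != len(members):
                raise DataFormatError(f"gene set {name!r} has duplicate members")

    @property
    def set_names(self) -> list[str]:
        return list(self.sets)

    def __getitem__(self, name: str) -> tuple[str, ...]:
        return self.sets[name]

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets)


def read_gmt(path) -> GeneSetCollection:
    """Read gene sets in the Broad GMT dialect.

    One set per line: name, description, then tab-separated member genes.
    Duplicate members within a line are collapsed with a logged warning;
    a duplicate set name or a line with fewer than 3 fields is an error.
    """
    sets: dict[str, tuple[str, ...]] = {}
    descriptions: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise DataFormatError(
                    f"{path}: line {lineno}: GMT line needs name, description "
                    f"and at least one member (got {len(fields)} fields)"
                )
            name, desc, *members = fields
            members = [m for m in members if m]
            if name in sets:
                raise DataFormatError(f"{path}: line {lineno}: duplicate set {name!r}")
            uniq = list(dict.fromkeys(members))
            if len(uniq) != len(members):
                logger.warning(
                    "read_gmt: set %r: collapsed %d duplicate members",
                    name, len(members) - len(uniq),
                )
            sets[name] = tuple(uniq)
            descriptions[name] = desc
    return GeneSetCollection(sets, descriptions)


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for name in collection.set_names:
            desc = collection.descriptions.get(name, "")
            fh.write("\t".join([name, desc, *collection[name]]) + "\n")


def read_gene_list(path) -> list[str]:
    """Read a plain one-gene-per-line list (e.g. the cancer-pathway panel)."""
    genes: list[str] = []
    with open(path) as fh:
        for line in fh:
            token = line.strip()
            if token:
                genes.append(token)
    if len(genes) != len(set(genes)):
        dup = next(g for i, g in enumerate(genes) if g in genes[:i])
        raise DataFormatError(f"{path}: duplicate gene {dup!r} in panel list")
    return genes
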