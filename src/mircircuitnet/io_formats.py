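"""Readers and writers for every external table the pipeline touches.

All tabular inputs are plain TSV (UTF-8, ``.`` decimal); gene sets use the
standard GMT layout; networks are serialized both as an edge-list TSV and as
GraphML.  Validation is strict: duplicated identifiers, missing values and
unknown tissue labels are hard errors raised as :class:`FormatError` — every
downstream statistic assumes complete, uniquely indexed matrices.

Identifiers are opaque strings throughout; no attempt is made to map between
identifier spaces (probe set vs gene symbol vs Entrez).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import networkx as nx
import numpy as np
import pandas as pd

TISSUE_CLASSES = ("N", "T", "M")

FEATURE_KINDS = ("miRNA", "gene")


class FormatError(ValueError):
    """Raised when an input file violates the documented layout or an invariant."""


# ---------------------------------------------------------------------------
# Domain containers
# ---------------------------------------------------------------------------


@dataclass
class ExpressionMatrix:
    """A features x samples matrix of log2 intensity values.

    Parameters
    ----------
    data:
        DataFrame with feature IDs as index and sample IDs as columns.
        Values are log2 intensities; must be finite.
    feature_kind:
        ``"miRNA"`` or ``"gene"``.
    """

    data: pd.DataFrame
    feature_kind: str

    def __post_init__(self) -> None:
        if self.feature_kind not in FEATURE_KINDS:
            raise FormatError(f"unknown feature kind {self.feature_kind!r}")
        idx = self.data.index.astype(str)
        cols = self.data.columns.astype(str)
        dup_f = idx[idx.duplicated()].unique().tolist()
        if dup_f:
            raise FormatError(f"duplicate feature IDs: {dup_f}")
        dup_s = cols[cols.duplicated()].unique().tolist()
        if dup_s:
            raise FormatError(f"duplicate sample IDs: {dup_s}")
        values = self.data.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            raise FormatError("expression matrix contains non-numeric cells")
        bad = np.argwhere(~np.isfinite(values.astype(float)))
        if bad.size:
            r, c = bad[0]
            raise FormatError(
                f"non-finite/missing value at feature {self.data.index[r]!r}, "
                f"sample {self.data.columns[c]!r}"
            )
        self.data = self.data.astype(float)
        self.data.index = idx
        self.data.columns = cols

    @property
    def feature_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    @property
    def n_features(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def subset_features(self, feature_ids: Iterable[str]) -> "ExpressionMatrix":
        ids = list(feature_ids)
        missing = set(ids) - set(self.data.index)
        if missing:
            raise KeyError(f"features not present: {sorted(missing)[:5]}")
        return ExpressionMatrix(self.data.loc[ids], self.feature_kind)

    def subset_samples(self, sample_ids: Iterable[str]) -> "ExpressionMatrix":
        ids = list(sample_ids)
        missing = set(ids) - set(self.data.columns)
        if missing:
            raise KeyError(f"samples not present: {sorted(missing)[:5]}")
        return ExpressionMatrix(self.data.loc[:, ids], self.feature_kind)


@dataclass
class SampleSheet:
    """Maps each sample to its patient and tissue class (N, T or M)."""

    data: pd.DataFrame  # columns: sample_id, patient_id, tissue

    def __post_init__(self) -> None:
        required = {"sample_id", "patient_id", "tissue"}
        missing = required - set(self.data.columns)
        if missing:
            raise FormatError(f"sample sheet missing columns: {sorted(missing)}")
        df = self.data.copy()
        for col in ("sample_id", "patient_id", "tissue"):
            df[col] = df[col].astype(str)
        dup = df.loc[df["sample_id"].duplicated(), "sample_id"].unique().tolist()
        if dup:
            raise FormatError(f"duplicate sample IDs in sheet: {dup}")
        bad = sorted(set(df["tissue"]) - set(TISSUE_CLASSES))
        if bad:
            raise FormatError(f"unknown tissue labels: {bad} (expected N/T/M)")
        pt = df[["patient_id", "tissue"]]
        dup_pt = pt[pt.duplicated()]
        if not dup_pt.empty:
            pair = tuple(dup_pt.iloc[0])
            raise FormatError(f"(patient, tissue) pair appears twice: {pair}")
        self.data = df.reset_index(drop=True)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data["sample_id"])

    def tissue_of(self) -> dict[str, str]:
        return dict(zip(self.data["sample_id"], self.data["tissue"]))

    def patient_of(self) -> dict[str, str]:
        return dict(zip(self.data["sample_id"], self.data["patient_id"]))

    def samples_in_class(self, tissue: str, restrict_to: Iterable[str] | None = None) -> list[str]:
        if tissue not in TISSUE_CLASSES:
            raise FormatError(f"unknown tissue class {tissue!r}")
        sel = self.data.loc[self.data["tissue"] == tissue, "sample_id"]
        if restrict_to is not None:
            keep = set(restrict_to)
            sel = sel[sel.isin(keep)]
        return list(sel)


def validate_target_predictions(df: pd.DataFrame) -> pd.DataFrame:
    """Validate a miRNA->gene prediction table (columns mirna_id, gene_id, score, conserved)."""
    required = {"mirna_id", "gene_id", "score", "conserved"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"prediction table missing columns: {sorted(missing)}")
    out = df.copy()
    out["mirna_id"] = out["mirna_id"].astype(str)
    out["gene_id"] = out["gene_id"].astype(str)
    out["score"] = pd.to_numeric(out["score"], errors="raise")
    if not np.isfinite(out["score"].to_numpy()).all():
        raise FormatError("prediction scores must be finite")
    out["conserved"] = out["conserved"].astype(bool)
    pairs = out[["mirna_id", "gene_id"]]
    dup = pairs[pairs.duplicated()]
    if not dup.empty:
        pair = tuple(dup.iloc[0])
        raise FormatError(f"duplicated (miRNA, gene) prediction pair: {pair}")
    return out.reset_index(drop=True)


def validate_interactions(df: pd.DataFrame) -> pd.DataFrame:
    """Validate a TF interaction table (regulator_id, target_id, target_kind, source_label)."""
    required = {"regulator_id", "target_id", "target_kind"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"interaction table missing columns: {sorted(missing)}")
    out = df.copy()
    if "source_label" not in out.columns:
        out["source_label"] = ""
    for col in ("regulator_id", "target_id", "target_kind", "source_label"):
        out[col] = out[col].astype(str)
    bad = sorted(set(out["target_kind"]) - {"gene", "miRNA"})
    if bad:
        raise FormatError(f"unknown target kinds: {bad}")
    pairs = out[["regulator_id", "target_id"]]
    dup = pairs[pairs.duplicated()]
    if not dup.empty:
        pair = tuple(dup.iloc[0])
        raise FormatError(f"duplicated (regulator, target) interaction: {pair}")
    return out.reset_index(drop=True)


@dataclass
class SurvivalRecord:
    """One patient's follow-up: time in months, event flag, optional covariates."""

    patient_id: str
    time: float
    event: bool
    covariates: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.time = float(self.time)
        if not (self.time > 0 and math.isfinite(self.time)):
            raise FormatError(f"survival time must be positive and finite, got {self.time}")
        self.event = bool(self.event)
        for name, value in self.covariates.items():
            if not math.isfinite(float(value)):
                raise FormatError(f"non-finite covariate {name!r} for {self.patient_id}")


# ---------------------------------------------------------------------------
# Expression matrices
# ---------------------------------------------------------------------------


def read_expression_matrix(path, feature_kind: str) -> ExpressionMatrix:
    """Read a features x samples TSV: first column feature IDs, header sample IDs."""
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")[1:]
    dup = sorted({h for h in header if header.count(h) > 1})
    if dup:
        raise FormatError(f"duplicate sample IDs in header: {dup}")
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    df.index = df.index.astype(str)
    numeric = pd.DataFrame(index=df.index)
    for col in df.columns:
        try:
            numeric[col] = pd.to_numeric(df[col], errors="raise")
        except (ValueError, TypeError) as exc:
            raise FormatError(f"non-numeric cell in column {col!r}: {exc}") from exc
    if numeric.isna().any().any():
        rows = numeric.index[numeric.isna().any(axis=1)].tolist()
        raise FormatError(f"missing values in rows: {rows[:5]}")
    return ExpressionMatrix(numeric, feature_kind)


def write_expression_matrix(matrix: ExpressionMatrix, path) -> None:
    out = matrix.data.copy()
    out.index.name = "feature_id"
    out.to_csv(path, sep="\t", float_format="%.6f")


# ---------------------------------------------------------------------------
# Sample sheets, predictions, interactions, survival
# ---------------------------------------------------------------------------


def read_sample_sheet(path) -> SampleSheet:
    df = pd.read_csv(path, sep="\t", dtype=str)
    return SampleSheet(df)


def write_sample_sheet(sheet: SampleSheet, path) -> None:
    sheet.data.to_csv(path, sep="\t", index=False)


def read_target_predictions(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    return validate_target_predictions(df)


def write_target_predictions(predictions: pd.DataFrame, path) -> None:
    validate_target_predictions(predictions).to_csv(path, sep="\t", index=False)


def read_interactions(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    return validate_interactions(df)


def write_interactions(interactions: pd.DataFrame, path) -> None:
    validate_interactions(interactions).to_csv(path, sep="\t", index=False)


def read_gene_sets(path) -> dict[str, list[str]]:
    """Read a GMT file: ``name<TAB>description<TAB>member1<TAB>member2...``."""
    sets: dict[str, list[str]] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"GMT line {lineno} has fewer than 3 fields")
            name = fields[0]
            if name in sets:
                raise FormatError(f"duplicated gene set name {name!r} at line {lineno}")
            members = [m for m in fields[2:] if m]
            if len(set(members)) != len(members):
                raise FormatError(f"gene set {name!r} has duplicated members")
            if not members:
                raise FormatError(f"gene set {name!r} is empty")
            sets[name] = members
    return sets


def write_gene_sets(sets: Mapping[str, Iterable[str]], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for name, members in sets.items():
            fh.write("\t".join([name, ""] + list(members)) + "\n")


def read_survival(path) -> list[SurvivalRecord]:
    """Read survival TSV: patient_id, time, event, then one column per covariate."""
    df = pd.read_csv(path, sep="\t")
    required = {"patient_id", "time", "event"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"survival table missing columns: {sorted(missing)}")
    covariate_cols = [c for c in df.columns if c not in required]
    records = []
    for _, row in df.iterrows():
        covs = {c: float(row[c]) for c in covariate_cols}
        records.append(
            SurvivalRecord(str(row["patient_id"]), float(row["time"]), bool(int(row["event"])), covs)
        )
    return records


def write_survival(records: list[SurvivalRecord], path) -> None:
    covariate_names = sorted({name for rec in records for name in rec.covariates})
    rows = []
    for rec in records:
        row = {"patient_id": rec.patient_id, "time": rec.time, "event": int(rec.event)}
        row.update({name: rec.covariates.get(name, np.nan) for name in covariate_names})
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Networks
# ---------------------------------------------------------------------------

NODE_KINDS = ("miRNA", "gene", "TF")


def write_network(network: nx.DiGraph, edge_list_path, graphml_path=None) -> None:
    """Serialize a typed regulatory network as an edge-list TSV and optionally GraphML.

    Every node must carry a ``kind`` attribute in {miRNA, gene, TF}; edges carry
    ``etype`` plus any numeric evidence attributes (r, p, q).
    """
    for node, attrs in network.nodes(data=True):
        if attrs.get("kind") not in NODE_KINDS:
            raise FormatError(f"node {node!r} lacks a valid 'kind' attribute")
    edge_attr_names = sorted({k for _, _, d in network.edges(data=True) for k in d})
    rows = []
    for u, v, d in network.edges(data=True):
        row = {"source": u, "target": v, "source_kind": network.nodes[u]["kind"],
               "target_kind": network.nodes[v]["kind"]}
        row.update({k: d.get(k, "") for k in edge_attr_names})
        rows.append(row)
    columns = ["source", "target", "source_kind", "target_kind"] + edge_attr_names
    pd.DataFrame(rows, columns=columns).to_csv(edge_list_path, sep="\t", index=False)
    if graphml_path is not None:
        clean = nx.DiGraph()
        for node, attrs in network.nodes(data=True):
            clean.add_node(node, **{k: _graphml_safe(v) for k, v in attrs.items()})
        for u, v, d in network.edges(data=True):
            clean.add_edge(u, v, **{k: _graphml_safe(val) for k, val in d.items()})
        nx.write_graphml(clean, graphml_path)


def _graphml_safe(value):
    if isinstance(value, (np.floating,)):
        return float(value)
    if isinstance(value, (np.integer,)):
        return int(value)
    if isinstance(value, (np.bool_,)):
        return bool(value)
    return value


def read_network_edge_list(path) -> nx.DiGraph:
    """Read back an edge-list TSV written by :func:`write_network`."""
    df = pd.read_csv(path, sep="\t")
    graph = nx.DiGraph()
    attr_cols = [c for c in df.columns if c not in
                 ("source", "target", "source_kind", "target_kind")]
    for _, row in df.iterrows():
        graph.add_node(row["source"], kind=row["source_kind"])
        graph.add_node(row["target"], kind=row["target_kind"])
        attrs = {}
        for col in attr_cols:
            value = row[col]
            if pd.notna(value) and value != "":
                attrs[col] = value
        graph.add_edge(row["source"], row["target"], **attrs)
    return graph
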