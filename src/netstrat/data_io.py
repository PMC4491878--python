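"""Readers and writers for alteration matrices, interaction networks and clinical tables.

All tabular formats are tab-separated with a header row, UTF-8 encoded;
empty cells and ``NA`` denote missing values.  Matrices round-trip exactly
(value and label order) through :func:`write_matrix` / :func:`read_matrix`.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import pandas as pd

log = logging.getLogger(__name__)

#: Recognized alteration classes of a selected functional event (SFE).
EVENT_CLASSES = ("cn_gain", "cn_loss", "mutation", "methylation")

_MISSING = {"", "na", "nan", "none", "null", "[not available]"}


def _is_missing(value) -> bool:
    if value is None or (isinstance(value, float) and pd.isna(value)):
        return True
    return str(value).strip().lower() in _MISSING


@dataclass
class EventMatrix:
    """Binary selected-functional-event profile: events x samples.

    Each event is a curated recurrent alteration (a copy-number gain/loss
    region, a recurrently mutated gene, or an epigenetically silenced gene)
    recorded as a 0/1 indicator per tumor sample.  Region events carry more
    than one member gene; single-gene events carry exactly one.
    """

    values: pd.DataFrame                 # events x samples, int8 in {0, 1}
    event_class: pd.Series               # event_id -> class
    member_genes: dict[str, tuple[str, ...]] = field(default_factory=dict)

    @property
    def event_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def class_counts(self) -> pd.Series:
        """Tally of events per alteration class."""
        return self.event_class.value_counts()

    def validate(self) -> None:
        if self.values.index.duplicated().any():
            dupes = self.values.index[self.values.index.duplicated()].tolist()
            raise ValueError(f"duplicate event ids: {dupes}")
        if self.values.columns.duplicated().any():
            dupes = self.values.columns[self.values.columns.duplicated()].tolist()
            raise ValueError(f"duplicate sample ids: {dupes}")
        bad = (self.values != 0) & (self.values != 1)
        if bad.any().any():
            row = bad.any(axis=1).idxmax()
            col = bad.loc[row].idxmax()
            raise ValueError(
                f"non-binary value {self.values.loc[row, col]!r} "
                f"at event {row!r}, sample {col!r}"
            )
        for event_id in self.values.index:
            genes = self.member_genes.get(event_id, ())
            if len(genes) == 0:
                raise ValueError(f"event {event_id!r} has no member genes")


def read_event_matrix(path, annotation_path=None) -> EventMatrix:
    """Read a binary event x sample TSV, with optional event annotations.

    The first column holds event ids; optional ``event_class`` and
    ``member_genes`` columns (the latter comma-separated) may appear inline,
    or in a separate annotation TSV with columns
    ``event_id, event_class, member_genes``.  Events with no recorded member
    genes default to the single gene named by the event id (the natural
    convention for mutation and methylation events); an annotation that
    explicitly lists no gene is an error.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    df.index = df.index.astype(str)

    classes: dict[str, str] = {}
    genes: dict[str, tuple[str, ...]] = {}

    def _take_annotation(table: pd.DataFrame) -> None:
        for event_id, row in table.iterrows():
            if "event_class" in table.columns and not _is_missing(row["event_class"]):
                classes[str(event_id)] = str(row["event_class"]).strip()
            if "member_genes" in table.columns:
                raw = row["member_genes"]
                if _is_missing(raw):
                    raise ValueError(f"event {event_id!r} annotated with no member genes")
                parsed = tuple(g.strip() for g in str(raw).split(",") if g.strip())
                if not parsed:
                    raise ValueError(f"event {event_id!r} annotated with no member genes")
                genes[str(event_id)] = parsed

    inline_cols = [c for c in ("event_class", "member_genes") if c in df.columns]
    if inline_cols:
        _take_annotation(df[inline_cols])
        df = df.drop(columns=inline_cols)
    if annotation_path is not None:
        ann = pd.read_csv(annotation_path, sep="\t", index_col=0, dtype=str)
        ann.index = ann.index.astype(str)
        _take_annotation(ann)

    values = pd.DataFrame(index=df.index, columns=df.columns, dtype="int8")
    for col in df.columns:
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = converted.isna() | ~converted.isin([0, 1])
        if bad.any():
            row = bad.idxmax()
            raise ValueError(
                f"non-binary value {df.loc[row, col]!r} at event {row!r}, sample {col!r}"
            )
        values[col] = converted.astype("int8")

    event_class = pd.Series(
        {e: classes.get(e, "mutation") for e in values.index}, name="event_class"
    ).reindex(values.index)
    member = {e: genes.get(e, (str(e),)) for e in values.index}

    em = EventMatrix(values=values, event_class=event_class, member_genes=member)
    em.validate()
    log.info("read %d events x %d samples; classes: %s",
             len(em.event_ids), len(em.sample_ids), em.class_counts().to_dict())
    return em


def read_network(path, min_weight: float = 0.0) -> nx.Graph:
    """Read a weighted undirected edge list (STRING-style TSV).

    Edges below ``min_weight`` and self-loops are dropped; duplicate edges
    (in either orientation) are collapsed keeping the maximum weight.
    Idempotent: re-reading its own written output changes nothing.
    """
    df = pd.read_csv(path, sep="\t", dtype={0: str, 1: str})
    if df.shape[1] < 3:
        raise ValueError(f"network file {path} needs >= 3 columns (a, b, weight)")
    a, b, w = df.columns[:3]
    edges = df[[a, b, w]].copy()
    edges.columns = ["a", "b", "weight"]
    edges["a"] = edges["a"].astype(str)
    edges["b"] = edges["b"].astype(str)
    edges["weight"] = pd.to_numeric(edges["weight"])
    if (edges["weight"] < 0).any():
        raise ValueError("negative edge weights are not allowed")

    n_raw = len(edges)
    edges = edges[edges["a"] != edges["b"]]
    edges = edges[edges["weight"] >= min_weight]
    # canonical orientation, then keep the max weight among duplicates
    lo = edges[["a", "b"]].min(axis=1)
    hi = edges[["a", "b"]].max(axis=1)
    edges = pd.DataFrame({"a": lo, "b": hi, "weight": edges["weight"].values})
    edges = edges.groupby(["a", "b"], as_index=False)["weight"].max()

    if edges.empty:
        raise ValueError(f"no edges remain after filtering (min_weight={min_weight})")
    graph = nx.Graph()
    graph.add_weighted_edges_from(edges.itertuples(index=False, name=None))
    log.info("read network: %d raw edges -> %d edges over %d nodes",
             n_raw, graph.number_of_edges(), graph.number_of_nodes())
    return graph


def write_network(graph: nx.Graph, path) -> None:
    rows = [(a, b, d.get("weight", 1.0)) for a, b, d in graph.edges(data=True)]
    pd.DataFrame(rows, columns=["node_a", "node_b", "weight"]).to_csv(
        path, sep="\t", index=False
    )


_STAGE_RE = re.compile(r"^(stage\s+)?([ivx0]+)\s*[abc]?[12]?$", re.IGNORECASE)

CLINICAL_COLUMNS = (
    "cancer_type", "subtype", "survival_time", "event_indicator", "stage", "grade"
)


def merge_stage(stage) -> object:
    """Collapse AJCC substages to their major stage (``Stage IIB`` -> ``Stage II``)."""
    if _is_missing(stage):
        return pd.NA
    text = str(stage).strip()
    m = _STAGE_RE.match(text)
    if m is None:
        return text
    prefix = "Stage " if m.group(1) else ""
    return f"{prefix}{m.group(2).upper()}"


def read_clinical(path) -> pd.DataFrame:
    """Read a per-sample clinical table indexed by sample id.

    Guarantees the standard columns (cancer_type, subtype, survival_time,
    event_indicator, stage, grade), merges stage substages to major stages,
    and keeps missing fields as missing — exclusion happens per analysis,
    not at load time.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    if "sample_id" not in df.columns:
        df = df.rename(columns={df.columns[0]: "sample_id"})
    if df["sample_id"].duplicated().any():
        dupes = df.loc[df["sample_id"].duplicated(), "sample_id"].tolist()
        raise ValueError(f"duplicate sample ids in clinical table: {dupes}")
    df = df.set_index("sample_id")

    out = pd.DataFrame(index=df.index)
    for col in CLINICAL_COLUMNS:
        if col in df.columns:
            out[col] = df[col].where(~df[col].map(_is_missing), pd.NA)
        else:
            out[col] = pd.NA
    if "cancer_type" not in df.columns:
        raise ValueError("clinical table must contain a cancer_type column")
    out["survival_time"] = pd.to_numeric(out["survival_time"], errors="raise")
    out["event_indicator"] = pd.to_numeric(out["event_indicator"], errors="raise")
    out["stage"] = out["stage"].map(merge_stage)
    out["grade"] = out["grade"].where(~out["grade"].map(_is_missing), pd.NA)
    return out


def write_matrix(df: pd.DataFrame, path, index_name: str | None = None) -> None:
    """Write a labelled matrix as TSV; round-trips exactly via read_matrix."""
    out = df.copy()
    if index_name is not None:
        out.index.name = index_name
    elif out.index.name is None:
        out.index.name = "id"
    out.to_csv(path, sep="\t", float_format="%.17g")


def read_matrix(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")


def apply_gene_mapping(names, mapping_path=None) -> dict[str, str]:
    """Two-column identifier mapping (e.g. symbol -> Ensembl); identity by default."""
    if mapping_path is None:
        return {str(n): str(n) for n in names}
    table = pd.read_csv(mapping_path, sep="\t", dtype=str)
    lookup = dict(zip(table.iloc[:, 0], table.iloc[:, 1]))
    return {str(n): lookup.get(str(n), str(n)) for n in names}


def write_subnetwork(graph: nx.Graph, path, format: str = "graphml") -> None:
    """Serialize a subnetwork module with its node attributes.

    ``graphml`` writes one GraphML file; ``edgelist`` writes ``<path>.edges.tsv``
    and ``<path>.nodes.tsv`` (node table with all node attributes).  Either
    form round-trips node set, edge set and attributes through
    :func:`read_subnetwork`.
    """
    path = Path(path)
    if format == "graphml":
        nx.write_graphml(graph, path)
    elif format == "edgelist":
        edges = [(a, b, d.get("weight", 1.0)) for a, b, d in graph.edges(data=True)]
        pd.DataFrame(edges, columns=["node_a", "node_b", "weight"]).to_csv(
            path.with_suffix(".edges.tsv"), sep="\t", index=False
        )
        nodes = pd.DataFrame.from_dict(dict(graph.nodes(data=True)), orient="index")
        nodes.index.name = "node"
        nodes.to_csv(path.with_suffix(".nodes.tsv"), sep="\t", float_format="%.17g")
    else:
        raise ValueError(f"unknown subnetwork format {format!r}")


def read_subnetwork(path, format: str = "graphml") -> nx.Graph:
    path = Path(path)
    if format == "graphml":
        return nx.read_graphml(path)
    if format == "edgelist":
        graph = nx.Graph()
        nodes = pd.read_csv(path.with_suffix(".nodes.tsv"), sep="\t", index_col=0,
                            float_precision="round_trip")
        for node, attrs in nodes.iterrows():
            clean = {}
            for key, val in attrs.items():
                if isinstance(val, str) and val in ("True", "False"):
                    val = val == "True"
                clean[key] = val
            graph.add_node(str(node), **clean)
        edges = pd.read_csv(path.with_suffix(".edges.tsv"), sep="\t", dtype={0: str, 1: str})
        for a, b, w in edges.itertuples(index=False, name=None):
            graph.add_edge(str(a), str(b), weight=float(w))
        return graph
    raise ValueError(f"unknown subnetwork format {format!r}")
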