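"""Report writers, schemas and graph exporters.

Every tabular report is long/tidy (one row per sample x layer x quantity)
so figure-style aggregations stay one-liners downstream.  The column schema
of each report ships with the package (:data:`REPORT_SCHEMAS`) and emitted
files can be validated against it with :func:`validate_report`.
"""

from __future__ import annotations

from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .distance import LayeredNetwork
from .graph_metrics import GlobalMetrics
from .node_metrics import NodeMetrics

#: Machine-readable column schemas: report name -> {column: dtype kind}.
#: Kinds: "i" integer, "f" float (NaN allowed), "s" string, "b" boolean.
REPORT_SCHEMAS: dict[str, dict[str, str]] = {
    "global_metrics": {
        "sample_id": "s", "layer": "i", "mode": "s", "metric": "s", "value": "f",
    },
    "node_metrics": {
        "sample_id": "s", "layer": "i", "mode": "s", "cdr3_aa": "s",
        "degree": "i", "transitivity": "f", "eigenvector": "f", "authority": "f",
        "pagerank": "f", "closeness": "f", "betweenness": "f", "coreness": "i",
    },
    "degree_fit": {
        "sample_id": "s", "layer": "i", "mode": "s", "family": "s",
        "x_min": "i", "alpha": "f", "exponential_rate": "f", "poisson_mean": "f",
        "ks_statistic": "f", "bootstrap_p": "f",
        "comparison_two_sided_p": "f", "comparison_one_sided_p": "f",
        "n_excluded_zero_degree": "i", "n_tail": "i",
    },
    "perturbation": {
        "sample_id": "s", "strategy": "s", "fraction": "f", "rep": "i",
        "family": "s", "bootstrap_p": "f", "n_nodes": "i", "n_edges": "i",
        "largest_component_size": "i",
    },
    "redundancy": {
        "sample_id": "s", "predictor_layer": "i", "target_layer": "i",
        "q2": "f", "press": "f", "tss": "f", "n_clones": "i",
    },
    "coreness_histogram": {
        "sample_id": "s", "layer": "i", "mode": "s", "k": "i", "core_size": "i",
    },
    "cumulative_degree": {
        "sample_id": "s", "layer": "i", "mode": "s", "k": "i", "p_k": "f",
    },
    "edgelist": {"source_index": "i", "target_index": "i", "ld": "i"},
}

_KIND_CHECK = {
    "i": lambda s: pd.api.types.is_integer_dtype(s),
    "f": lambda s: pd.api.types.is_numeric_dtype(s),
    "s": lambda s: pd.api.types.is_object_dtype(s) or pd.api.types.is_string_dtype(s),
    "b": lambda s: pd.api.types.is_bool_dtype(s),
}


class ReportSchemaError(ValueError):
    pass


def validate_report(df: pd.DataFrame, name: str) -> None:
    """Validate a report DataFrame against its shipped schema."""
    if name not in REPORT_SCHEMAS:
        raise ReportSchemaError(f"unknown report {name!r}")
    schema = REPORT_SCHEMAS[name]
    missing = set(schema) - set(df.columns)
    if missing:
        raise ReportSchemaError(f"report {name!r}: missing columns {sorted(missing)}")
    for col, kind in schema.items():
        series = df[col]
        if series.isna().all():
            continue  # fully-NA columns (e.g. undefined metrics) are legal
        if kind in ("i", "f") and series.isna().any():
            if not pd.api.types.is_numeric_dtype(series.dropna()):
                raise ReportSchemaError(f"report {name!r}: column {col} not numeric")
            continue
        if not _KIND_CHECK[kind](series):
            raise ReportSchemaError(
                f"report {name!r}: column {col} has dtype {series.dtype}, "
                f"expected kind {kind!r}"
            )


def global_metrics_long(
    gm: GlobalMetrics, sample_id: str, layer: int, mode: str
) -> pd.DataFrame:
    """Flatten a GlobalMetrics record into tidy rows (undefined -> NaN)."""
    d = gm.to_dict()
    d.pop("component_sizes")
    rows = [
        {
            "sample_id": sample_id,
            "layer": layer,
            "mode": mode,
            "metric": key,
            "value": np.nan if value is None else float(value),
        }
        for key, value in d.items()
    ]
    return pd.DataFrame(rows)


def node_metrics_table(
    nm: NodeMetrics, sequences: list[str], sample_id: str, layer: int, mode: str
) -> pd.DataFrame:
    df = nm.to_frame(sequences)
    df.insert(0, "mode", mode)
    df.insert(0, "layer", layer)
    df.insert(0, "sample_id", sample_id)
    return df


def _graph_with_attributes(net: LayeredNetwork, layer: int, mode: str) -> nx.Graph:
    lay = net.layer(layer, mode)
    g = lay.to_networkx()
    deg = lay.degrees()
    counts = net.counts if net.counts is not None else np.ones(net.n_nodes, dtype=int)
    vgenes = net.v_genes or [None] * net.n_nodes
    for i in range(net.n_nodes):
        g.nodes[i]["cdr3_aa"] = net.sequences[i]
        g.nodes[i]["count"] = int(counts[i])
        g.nodes[i]["degree"] = int(deg[i])
        if vgenes[i] is not None:
            g.nodes[i]["v_gene"] = vgenes[i]
    return g


def export_graph(
    net: LayeredNetwork,
    layer: int,
    mode: str,
    format: str,
    path: str | Path,
) -> Path:
    """Export one similarity layer as GraphML (with cdr3_aa/count/degree node
    attributes) or as an edge-list CSV (source_index, target_index, ld).

    GraphML exports round-trip losslessly through re-import.
    """
    path = Path(path)
    if format == "graphml":
        nx.write_graphml(_graph_with_attributes(net, layer, mode), path)
    elif format == "edgelist_csv":
        if mode == "exact":
            mask = net.edge_ld == layer
        elif mode == "cumulative":
            mask = net.edge_ld <= layer
        else:
            raise ValueError(f"unknown mode {mode!r}")
        df = pd.DataFrame(
            {
                "source_index": net.edge_src[mask],
                "target_index": net.edge_dst[mask],
                "ld": net.edge_ld[mask],
            }
        )
        df.to_csv(path, index=False)
    else:
        raise ValueError(f"unknown export format {format!r}")
    return path
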