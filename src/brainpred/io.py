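"""Plain-text (TSV) readers and writers for the pipeline's artifacts."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .types import BrainNetwork, CorrelationMatrix, NodeCoordinates, RegionalTimeSeries

__all__ = [
    "write_coordinates",
    "read_coordinates",
    "write_time_series",
    "read_time_series",
    "write_matrix",
    "read_correlation_matrix",
    "write_edge_list",
    "read_network_edge_list",
    "write_adjacency",
    "read_network_adjacency",
]


def write_coordinates(coords: NodeCoordinates, path: str | Path) -> None:
    df = pd.DataFrame(coords.positions, columns=["x", "y", "z"])
    df.insert(0, "label", coords.labels)
    df.to_csv(path, sep="\t", index=False)


def read_coordinates(path: str | Path) -> NodeCoordinates:
    df = pd.read_csv(path, sep="\t")
    return NodeCoordinates(
        labels=df["label"].astype(str).tolist(),
        positions=df[["x", "y", "z"]].to_numpy(float),
    )


def write_time_series(ts: RegionalTimeSeries, path: str | Path) -> None:
    # regions x timepoints; one row per region, first column the label
    df = pd.DataFrame(ts.values)
    df.insert(0, "label", ts.labels)
    df.to_csv(path, sep="\t", index=False)


def read_time_series(path: str | Path) -> RegionalTimeSeries:
    df = pd.read_csv(path, sep="\t")
    labels = df["label"].astype(str).tolist()
    return RegionalTimeSeries(labels=labels, values=df.drop(columns="label").to_numpy(float))


def write_matrix(labels: list[str], matrix: np.ndarray, path: str | Path) -> None:
    pd.DataFrame(matrix, index=labels, columns=labels).to_csv(path, sep="\t")


def read_correlation_matrix(path: str | Path) -> CorrelationMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return CorrelationMatrix(labels=[str(c) for c in df.columns], r=df.to_numpy(float))


def write_edge_list(network: BrainNetwork, path: str | Path) -> None:
    rows = [
        (network.labels[i], network.labels[j])
        for i, j in sorted(network.edge_set())
    ]
    pd.DataFrame(rows, columns=["node_a", "node_b"]).to_csv(path, sep="\t", index=False)


def read_network_edge_list(
    path: str | Path, labels: list[str], sparsity: float | None = None
) -> BrainNetwork:
    df = pd.read_csv(path, sep="\t")
    idx = {lab: i for i, lab in enumerate(labels)}
    n = len(labels)
    adjacency = np.zeros((n, n), dtype=np.int8)
    for a, b in zip(df["node_a"].astype(str), df["node_b"].astype(str)):
        i, j = idx[a], idx[b]
        adjacency[i, j] = adjacency[j, i] = 1
    return BrainNetwork(labels=list(labels), adjacency=adjacency, sparsity=sparsity)


def write_adjacency(network: BrainNetwork, path: str | Path) -> None:
    write_matrix(network.labels, network.adjacency, path)


def read_network_adjacency(path: str | Path) -> BrainNetwork:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return BrainNetwork(
        labels=[str(c) for c in df.columns], adjacency=df.to_numpy(int)
    )
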