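"""Core containers for brain-network link prediction.

All containers are thin dataclasses around numpy arrays with validation on
construction.  Graphs are simple, undirected and binary; node order is fixed
by the ``labels`` sequence and shared across every matrix that refers to the
same parcellation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

SIMILARITY_INDICES = ("CN", "HDI", "HPI", "LHN-I", "PA", "RA", "SI")


def edge_count_for_sparsity(n_nodes: int, sparsity: float) -> int:
    """Number of edges at a sparsity level: round-half-away-from-zero of
    S * n(n-1)/2."""
    x = sparsity * n_nodes * (n_nodes - 1) / 2.0
    return int(math.floor(x + 0.5))


def _check_labels(labels: Sequence[str]) -> list[str]:
    labels = [str(x) for x in labels]
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate node labels")
    return labels


@dataclass
class NodeCoordinates:
    """Region centroids in millimetres.

    Parameters
    ----------
    labels : sequence of str
        Region identifiers, one per node.
    positions : (n, 3) array
        3D centroid of each region, mm.
    """

    labels: list[str]
    positions: np.ndarray

    def __post_init__(self) -> None:
        self.labels = _check_labels(self.labels)
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.ndim != 2 or self.positions.shape[1] != 3:
            raise ValueError("positions must be an (n, 3) array")
        if self.positions.shape[0] != len(self.labels):
            raise ValueError("one position per label required")
        if not np.all(np.isfinite(self.positions)):
            raise ValueError("positions must be finite")

    @property
    def n_nodes(self) -> int:
        return len(self.labels)


@dataclass
class RegionalTimeSeries:
    """Regional mean time series, regions x timepoints."""

    labels: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.labels = _check_labels(self.labels)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2D (regions x timepoints) array")
        if self.values.shape[0] != len(self.labels):
            raise ValueError("one row per region label required")
        if self.values.shape[1] < 3:
            raise ValueError("at least 3 timepoints required")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("time series contain non-finite values")

    @property
    def n_regions(self) -> int:
        return self.values.shape[0]

    @property
    def n_timepoints(self) -> int:
        return self.values.shape[1]


@dataclass
class CorrelationMatrix:
    """Symmetric Pearson correlation matrix with unit diagonal."""

    labels: list[str]
    r: np.ndarray

    def __post_init__(self) -> None:
        self.labels = _check_labels(self.labels)
        self.r = np.asarray(self.r, dtype=float)
        n = len(self.labels)
        if self.r.shape != (n, n):
            raise ValueError("correlation matrix shape must match labels")
        if not np.allclose(self.r, self.r.T, atol=1e-12):
            raise ValueError("correlation matrix must be symmetric")
        if not np.allclose(np.diag(self.r), 1.0, atol=1e-12):
            raise ValueError("correlation matrix diagonal must be 1")
        if np.any(np.abs(self.r) > 1 + 1e-12):
            raise ValueError("correlations must lie in [-1, 1]")


@dataclass
class BrainNetwork:
    """Simple undirected binary graph on labelled nodes.

    ``sparsity`` records the thresholding level the network was built at,
    when there was one; edge count is validated against it.
    """

    labels: list[str]
    adjacency: np.ndarray
    sparsity: float | None = None
    coordinates: NodeCoordinates | None = None

    def __post_init__(self) -> None:
        self.labels = _check_labels(self.labels)
        a = np.asarray(self.adjacency)
        n = len(self.labels)
        if a.shape != (n, n):
            raise ValueError("adjacency shape must match labels")
        if not np.array_equal(a, a.T):
            raise ValueError("adjacency must be symmetric")
        if not np.all((a == 0) | (a == 1)):
            raise ValueError("adjacency must be binary")
        if np.any(np.diag(a) != 0):
            raise ValueError("self-loops are not allowed")
        self.adjacency = a.astype(np.int8)
        if self.sparsity is not None:
            expected = edge_count_for_sparsity(n, self.sparsity)
            if self.n_edges != expected:
                raise ValueError(
                    f"edge count {self.n_edges} does not match sparsity "
                    f"{self.sparsity} (expected {expected})"
                )
        if self.coordinates is not None and self.coordinates.labels != self.labels:
            raise ValueError("coordinate labels do not match network labels")

    @property
    def n_nodes(self) -> int:
        return len(self.labels)

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.sum()) // 2

    @property
    def degrees(self) -> np.ndarray:
        return self.adjacency.sum(axis=1).astype(int)

    def edge_set(self) -> set[tuple[int, int]]:
        iu, ju = np.triu_indices(self.n_nodes, k=1)
        mask = self.adjacency[iu, ju] == 1
        return set(zip(iu[mask].tolist(), ju[mask].tolist()))

    def to_networkx(self):
        import networkx as nx

        g = nx.Graph()
        g.add_nodes_from(range(self.n_nodes))
        iu, ju = np.triu_indices(self.n_nodes, k=1)
        mask = self.adjacency[iu, ju] == 1
        g.add_edges_from(zip(iu[mask].tolist(), ju[mask].tolist()))
        return g


@dataclass
class SimilarityMatrix:
    """Node-pair local-information scores for one index.

    The diagonal carries no meaning and is fixed at 0.
    """

    labels: list[str]
    index_name: str
    s: np.ndarray

    def __post_init__(self) -> None:
        self.labels = _check_labels(self.labels)
        if self.index_name not in SIMILARITY_INDICES:
            raise ValueError(
                f"unknown index {self.index_name!r}; valid: {SIMILARITY_INDICES}"
            )
        self.s = np.asarray(self.s, dtype=float)
        n = len(self.labels)
        if self.s.shape != (n, n):
            raise ValueError("similarity matrix shape must match labels")
        if not np.allclose(self.s, self.s.T):
            raise ValueError("similarity matrix must be symmetric")
        if not np.all(np.isfinite(self.s)):
            raise ValueError("similarity scores must be finite")
        if np.any(self.s < 0):
            raise ValueError("similarity scores must be nonnegative")
        np.fill_diagonal(self.s, 0.0)


@dataclass
class DistanceMatrix:
    """Pairwise Euclidean distances, mm."""

    labels: list[str]
    d: np.ndarray

    def __post_init__(self) -> None:
        self.labels = _check_labels(self.labels)
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.labels)
        if self.d.shape != (n, n):
            raise ValueError("distance matrix shape must match labels")
        if not np.allclose(self.d, self.d.T):
            raise ValueError("distance matrix must be symmetric")
        off = ~np.eye(n, dtype=bool)
        if np.any(self.d[off] <= 0):
            raise ValueError("off-diagonal distances must be positive")


@dataclass
class ScoreMatrix:
    """Connection scores P_ij from the distance + similarity model."""

    labels: list[str]
    p: np.ndarray
    gamma: float
    index_name: str
    distance_mode: str

    def __post_init__(self) -> None:
        self.labels = _check_labels(self.labels)
        self.p = np.asarray(self.p, dtype=float)
        n = len(self.labels)
        if self.p.shape != (n, n):
            raise ValueError("score matrix shape must match labels")
        if not np.allclose(self.p, self.p.T):
            raise ValueError("score matrix must be symmetric")
        if not np.all(np.isfinite(self.p)):
            raise ValueError("scores must be finite")


@dataclass
class DegreeFit:
    """Truncated power-law fit of the complementary cumulative degree
    distribution: P(K >= k) ~ k^(alpha-1) * exp(-k/k_c)."""

    alpha: float
    k_c: float
    fit_error: float

    def __post_init__(self) -> None:
        if not self.k_c > 0:
            raise ValueError("cutoff degree k_c must be positive")


@dataclass
class SyntheticConfig:
    """Parameters of the synthetic ground-truth generator."""

    n_regions: int = 90
    n_modules: int = 6
    n_timepoints: int = 238
    sparsity: float = 0.15
    distance_decay_lambda: float = 20.0
    within_module_boost: float = 20.0
    coupling_strength: float = 0.6
    noise_sd: float = 1.0
    seed: int = 0
    mirror: bool = True

    def __post_init__(self) -> None:
        if self.n_modules > self.n_regions:
            raise ValueError("n_modules must not exceed n_regions")
        if not (0 < self.sparsity < 1):
            raise ValueError("sparsity must lie in (0, 1)")
        if edge_count_for_sparsity(self.n_regions, self.sparsity) < 1:
            raise ValueError("sparsity too small: no edges would be drawn")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if self.coupling_strength < 0:
            raise ValueError("coupling_strength must be nonnegative")
        if self.within_module_boost < 1:
            raise ValueError("within_module_boost must be >= 1")


@dataclass
class GroundTruth:
    """A planted network with its geometry and module assignment."""

    network: BrainNetwork
    coordinates: NodeCoordinates
    module_assignment: np.ndarray = field(default_factory=lambda: np.array([]))

    def __post_init__(self) -> None:
        self.module_assignment = np.asarray(self.module_assignment, dtype=int)
        if self.module_assignment.size != self.network.n_nodes:
            raise ValueError("one module id per node required")
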