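"""Global topological properties of binary networks.

Eight properties are computed per network: assortativity (R), clustering
coefficient (C), characteristic path length (L), global and local
efficiency (E_glob, E_loc), modularity (Q), transitivity (T), and the
degree distribution summarized by a truncated power-law fit
P(K >= k) ~ k^(alpha-1) * exp(-k / k_c).

Undefined metrics (e.g. assortativity of a regular graph) propagate as
NaN — never as zeros — and are excluded pairwise from the AUC over the
sparsity grid.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy.optimize import least_squares

from .construction import sparsity_grid
from .types import BrainNetwork, DegreeFit

__all__ = [
    "assortativity",
    "clustering_coefficient",
    "characteristic_path_length",
    "global_efficiency",
    "local_efficiency",
    "modularity",
    "transitivity",
    "fit_degree_distribution",
    "fit_ccdf",
    "auc_over_sparsity",
    "topology_profile",
    "TopologyProfile",
    "SCALAR_METRICS",
]

log = logging.getLogger(__name__)

SCALAR_METRICS = ("R", "C", "L", "E_glob", "E_loc", "Q", "T")


def assortativity(network: BrainNetwork) -> float:
    """Degree assortativity: Pearson correlation of the degrees at the two
    ends of every edge (both orientations).  NaN when the degree variance
    over edge endpoints is zero (e.g. regular graphs)."""
    if network.n_edges < 2:
        raise ValueError("assortativity requires at least 2 edges")
    k = network.degrees
    iu, ju = np.nonzero(np.triu(network.adjacency, k=1))
    x = np.concatenate([k[iu], k[ju]]).astype(float)
    y = np.concatenate([k[ju], k[iu]]).astype(float)
    if np.var(x) == 0 or np.var(y) == 0:
        log.info("assortativity undefined: zero degree variance over edges")
        return float("nan")
    return float(np.corrcoef(x, y)[0, 1])


def clustering_coefficient(network: BrainNetwork) -> float:
    """Mean local clustering coefficient; degree < 2 nodes contribute 0."""
    if network.n_nodes == 0:
        raise ValueError("empty network")
    return float(nx.average_clustering(network.to_networkx()))


def characteristic_path_length(network: BrainNetwork) -> float:
    """Mean shortest-path length over connected ordered node pairs.

    Disconnected pairs are excluded (and logged); NaN when no two nodes
    are connected at all.
    """
    g = network.to_networkx()
    if g.number_of_nodes() == 0:
        raise ValueError("empty network")
    total, count = 0, 0
    n_pairs = g.number_of_nodes() * (g.number_of_nodes() - 1)
    for _, dists in nx.all_pairs_shortest_path_length(g):
        for d in dists.values():
            if d > 0:
                total += d
                count += 1
    if count == 0:
        log.info("characteristic path length undefined: no connected pair")
        return float("nan")
    if count < n_pairs:
        log.info(
            "path length computed over connected pairs only (%d of %d)",
            count,
            n_pairs,
        )
    return total / count


def global_efficiency(network: BrainNetwork) -> float:
    """Mean inverse shortest-path length over distinct pairs; disconnected
    pairs contribute 0."""
    if network.n_nodes == 0:
        raise ValueError("empty network")
    return float(nx.global_efficiency(network.to_networkx()))


def local_efficiency(network: BrainNetwork) -> float:
    """Mean over nodes of the global efficiency of each node's open
    neighbourhood subgraph; degree < 2 nodes contribute 0."""
    if network.n_nodes == 0:
        raise ValueError("empty network")
    return float(nx.local_efficiency(network.to_networkx()))


def newman_girvan_q(network: BrainNetwork, partition: list[set[int]]) -> float:
    """Newman-Girvan modularity Q = sum_c [l_c/m - (d_c/2m)^2] of a given
    node partition."""
    m = network.n_edges
    if m == 0:
        raise ValueError("modularity undefined on an edgeless graph")
    a = network.adjacency
    k = network.degrees
    q = 0.0
    for comm in partition:
        nodes = np.fromiter(comm, dtype=int)
        l_c = a[np.ix_(nodes, nodes)].sum() / 2.0
        d_c = k[nodes].sum()
        q += l_c / m - (d_c / (2.0 * m)) ** 2
    return float(q)


def modularity(network: BrainNetwork, seed: int = 0) -> float:
    """Modularity Q of the best partition found by greedy agglomerative
    community detection.

    The greedy merge order is deterministic; ``seed`` is recorded for
    interface stability with stochastic optimizers.
    """
    if network.n_edges == 0:
        log.info("modularity undefined: edgeless graph")
        return float("nan")
    g = network.to_networkx()
    communities = nx.community.greedy_modularity_communities(g)
    return newman_girvan_q(network, [set(c) for c in communities])


def transitivity(network: BrainNetwork) -> float:
    """Global transitivity: 3 * triangles / connected triples."""
    g = network.to_networkx()
    if g.number_of_nodes() == 0:
        raise ValueError("empty network")
    triples = sum(d * (d - 1) for _, d in g.degree()) / 2
    if triples == 0:
        log.info("transitivity undefined: no connected triple")
        return float("nan")
    return float(nx.transitivity(g))


def _ccdf(degrees: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Empirical complementary cumulative distribution P(K >= k) over the
    observed degree range."""
    degrees = np.asarray(degrees)
    kmin = max(1, int(degrees.min()))
    kmax = int(degrees.max())
    ks = np.arange(kmin, kmax + 1)
    ccdf = np.array([(degrees >= k).mean() for k in ks])
    keep = ccdf > 0
    return ks[keep], ccdf[keep]


def fit_degree_distribution(network_or_degrees) -> DegreeFit | None:
    """Fit the complementary cumulative degree distribution to
    c * k^(alpha-1) * exp(-k/k_c) by least squares on log scale.

    Returns None when fewer than 5 distinct positive degrees are present.
    """
    if isinstance(network_or_degrees, BrainNetwork):
        degrees = network_or_degrees.degrees
    else:
        degrees = np.asarray(network_or_degrees, dtype=float)
    degrees = degrees[degrees > 0]
    if np.unique(degrees).size < 5:
        log.info("degree fit undefined: fewer than 5 distinct positive degrees")
        return None
    ks, ccdf = _ccdf(degrees)
    return fit_ccdf(ks, ccdf, n_samples=degrees.size)


def fit_ccdf(
    ks: np.ndarray, ccdf: np.ndarray, n_samples: int | None = None
) -> DegreeFit:
    """Fit a given complementary cumulative curve to
    c * k^(alpha-1) * exp(-k/k_c) on log scale.

    When ``n_samples`` is given, residuals are weighted by
    sqrt(n * ccdf) — the inverse of the sampling standard deviation of a
    log empirical CCDF — so the sparse tail does not dominate the fit.
    The log model is linear in (log c, alpha-1, 1/k_c), so an ordinary
    linear solve provides one starting point; four further seeded random
    starts guard against the boundary k_c -> 0.
    """
    ks = np.asarray(ks, dtype=float)
    ccdf = np.asarray(ccdf, dtype=float)
    logk, logy = np.log(ks), np.log(ccdf)
    w = np.sqrt(n_samples * ccdf) if n_samples else np.ones_like(ccdf)

    def resid(theta):
        c, am1, inv_kc = theta
        return w * (c + am1 * logk - inv_kc * ks - logy)

    # linear initialization (weighted)
    design = np.column_stack([w, w * logk, -w * ks])
    lin, *_ = np.linalg.lstsq(design, w * logy, rcond=None)
    starts = [lin]
    rng = np.random.default_rng(12345)
    for _ in range(4):
        starts.append(
            np.array([rng.normal(0, 1), rng.normal(0, 1), rng.uniform(1e-3, 0.5)])
        )
    best = None
    for x0 in starts:
        x0 = np.clip(x0, [-50, -11, 1e-9], [50, 11, 1e3])
        try:
            sol = least_squares(
                resid,
                x0,
                bounds=([-50, -11, 1e-9], [50, 11, 1e3]),
                method="trf",
            )
        except Exception:  # pragma: no cover - optimizer failure
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None:  # pragma: no cover
        return None
    c, am1, inv_kc = best.x
    err = float(np.linalg.norm(resid(best.x)))
    return DegreeFit(alpha=float(am1 + 1.0), k_c=float(1.0 / inv_kc), fit_error=err)


def auc_over_sparsity(values, grid=None) -> float:
    """Trapezoidal integral of a property over the sparsity grid; NaN
    entries are dropped pairwise.  NaN when fewer than 2 valid points."""
    if grid is None:
        grid = sparsity_grid()
    values = np.asarray(values, dtype=float)
    grid = np.asarray(grid, dtype=float)
    if values.shape != grid.shape:
        raise ValueError("values must align with the sparsity grid")
    ok = ~np.isnan(values)
    if ok.sum() < 2:
        log.info("AUC undefined: fewer than 2 valid points")
        return float("nan")
    return float(np.trapezoid(values[ok], grid[ok]))


@dataclass
class TopologyProfile:
    """All eight properties per sparsity plus AUC summaries."""

    sparsities: list[float]
    values: dict[str, np.ndarray]
    degree_fits: list[DegreeFit | None]
    auc: dict[str, float] = field(default_factory=dict)
    reference_sparsity: float = 0.15

    def __post_init__(self) -> None:
        if not self.auc:
            self.auc = {
                prop: auc_over_sparsity(self.values[prop], self.sparsities)
                for prop in SCALAR_METRICS
            }

    def reference_degree_fit(self) -> DegreeFit | None:
        """Degree fit at the reference sparsity (nearest grid point)."""
        i = int(
            np.argmin(np.abs(np.asarray(self.sparsities) - self.reference_sparsity))
        )
        return self.degree_fits[i]


def topology_profile(
    networks: list[BrainNetwork],
    seed: int = 0,
    grid: list[float] | None = None,
    reference_sparsity: float = 0.15,
) -> TopologyProfile:
    """Compute the full property profile of one subject's networks across
    the sparsity grid."""
    if grid is None:
        grid = sparsity_grid()
    if len(networks) != len(grid):
        raise ValueError(
            f"expected one network per grid point ({len(grid)}), got {len(networks)}"
        )
    values = {prop: np.full(len(grid), np.nan) for prop in SCALAR_METRICS}
    fits: list[DegreeFit | None] = []
    for i, net in enumerate(networks):
        values["R"][i] = assortativity(net) if net.n_edges >= 2 else np.nan
        values["C"][i] = clustering_coefficient(net)
        values["L"][i] = characteristic_path_length(net)
        values["E_glob"][i] = global_efficiency(net)
        values["E_loc"][i] = local_efficiency(net)
        values["Q"][i] = modularity(net, seed=seed)
        values["T"][i] = transitivity(net)
        fits.append(fit_degree_distribution(net))
    return TopologyProfile(
        sparsities=list(grid),
        values=values,
        degree_fits=fits,
        reference_sparsity=reference_sparsity,
    )
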