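"""Local-information similarity indices.

Seven neighbourhood-based node-pair scores used for link prediction:

=======  =======================================================
CN       common neighbours |G_i & G_j|
HDI      hub-depressed,   CN / max(k_i, k_j)
HPI      hub-promoted,    CN / min(k_i, k_j)
LHN-I    Leicht-Holme-Newman, CN / (k_i * k_j)
PA       preferential attachment, k_i * k_j
RA       resource allocation, sum over common neighbours z of 1/k_z
SI       Sorensen, 2*CN / (k_i + k_j)
=======  =======================================================

The fast implementations are matrix-algebra (CN is the off-diagonal of
A @ A); :func:`compute_similarity_bruteforce` recomputes every index with
explicit neighbour-set operations and serves as an independent oracle.
Ratios with a zero denominator (isolated nodes) are defined as 0 so that
downstream scoring never sees non-finite values.
"""

from __future__ import annotations

import numpy as np

from .types import SIMILARITY_INDICES, BrainNetwork, SimilarityMatrix

__all__ = [
    "common_neighbors",
    "hub_depressed",
    "hub_promoted",
    "leicht_holme_newman",
    "preferential_attachment",
    "resource_allocation",
    "sorensen",
    "compute_similarity",
    "compute_similarity_bruteforce",
]


def _cn_matrix(network: BrainNetwork) -> np.ndarray:
    a = network.adjacency.astype(float)
    cn = a @ a
    np.fill_diagonal(cn, 0.0)
    return cn


def _ratio(num: np.ndarray, den: np.ndarray) -> np.ndarray:
    out = np.zeros_like(num, dtype=float)
    np.divide(num, den, out=out, where=den > 0)
    return out


def common_neighbors(network: BrainNetwork) -> SimilarityMatrix:
    return SimilarityMatrix(list(network.labels), "CN", _cn_matrix(network))


def hub_depressed(network: BrainNetwork) -> SimilarityMatrix:
    k = network.degrees.astype(float)
    den = np.maximum.outer(k, k)
    s = _ratio(_cn_matrix(network), den)
    return SimilarityMatrix(list(network.labels), "HDI", s)


def hub_promoted(network: BrainNetwork) -> SimilarityMatrix:
    k = network.degrees.astype(float)
    den = np.minimum.outer(k, k)
    s = _ratio(_cn_matrix(network), den)
    return SimilarityMatrix(list(network.labels), "HPI", s)


def leicht_holme_newman(network: BrainNetwork) -> SimilarityMatrix:
    k = network.degrees.astype(float)
    s = _ratio(_cn_matrix(network), np.outer(k, k))
    return SimilarityMatrix(list(network.labels), "LHN-I", s)


def preferential_attachment(network: BrainNetwork) -> SimilarityMatrix:
    k = network.degrees.astype(float)
    s = np.outer(k, k)
    np.fill_diagonal(s, 0.0)
    return SimilarityMatrix(list(network.labels), "PA", s)


def resource_allocation(network: BrainNetwork) -> SimilarityMatrix:
    a = network.adjacency.astype(float)
    k = network.degrees.astype(float)
    inv_k = np.zeros_like(k)
    np.divide(1.0, k, out=inv_k, where=k > 0)
    # s_ij = sum_z a_iz * (1/k_z) * a_zj
    s = a @ np.diag(inv_k) @ a
    np.fill_diagonal(s, 0.0)
    return SimilarityMatrix(list(network.labels), "RA", s)


def sorensen(network: BrainNetwork) -> SimilarityMatrix:
    k = network.degrees.astype(float)
    den = np.add.outer(k, k)
    s = _ratio(2.0 * _cn_matrix(network), den)
    return SimilarityMatrix(list(network.labels), "SI", s)


_DISPATCH = {
    "CN": common_neighbors,
    "HDI": hub_depressed,
    "HPI": hub_promoted,
    "LHN-I": leicht_holme_newman,
    "PA": preferential_attachment,
    "RA": resource_allocation,
    "SI": sorensen,
}


def compute_similarity(network: BrainNetwork, index_name: str) -> SimilarityMatrix:
    """Compute one of the seven indices by name."""
    if index_name not in _DISPATCH:
        raise ValueError(
            f"unknown index {index_name!r}; valid names: {list(SIMILARITY_INDICES)}"
        )
    return _DISPATCH[index_name](network)


def compute_similarity_bruteforce(
    network: BrainNetwork, index_name: str
) -> SimilarityMatrix:
    """Set-operation reference implementation of every index.

    Loops over all node pairs with explicit neighbour sets; quadratic-slow
    but definitionally transparent, used as the oracle in tests.
    """
    if index_name not in _DISPATCH:
        raise ValueError(
            f"unknown index {index_name!r}; valid names: {list(SIMILARITY_INDICES)}"
        )
    n = network.n_nodes
    nbrs = [set(np.flatnonzero(network.adjacency[i]).tolist()) for i in range(n)]
    deg = [len(nb) for nb in nbrs]
    s = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            common = nbrs[i] & nbrs[j]
            cn = len(common)
            ki, kj = deg[i], deg[j]
            if index_name == "CN":
                val = cn
            elif index_name == "HDI":
                val = cn / max(ki, kj) if max(ki, kj) > 0 else 0.0
            elif index_name == "HPI":
                val = cn / min(ki, kj) if min(ki, kj) > 0 else 0.0
            elif index_name == "LHN-I":
                val = cn / (ki * kj) if ki * kj > 0 else 0.0
            elif index_name == "PA":
                val = ki * kj
            elif index_name == "RA":
                val = sum(1.0 / deg[z] for z in common)
            else:  # SI
                val = 2.0 * cn / (ki + kj) if ki + kj > 0 else 0.0
            s[i, j] = s[j, i] = val
    return SimilarityMatrix(list(network.labels), index_name, s)
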