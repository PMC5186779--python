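"""Binary network construction from regional time series.

The pipeline is: regress nuisance signals out of each regional series,
correlate all region pairs (Pearson), then keep the strongest correlations
until the network holds exactly ``round(S * n(n-1)/2)`` edges at each
sparsity level S of the standard 5-40% grid.
"""

from __future__ import annotations

import numpy as np

from .types import (
    BrainNetwork,
    CorrelationMatrix,
    RegionalTimeSeries,
    edge_count_for_sparsity,
)

__all__ = [
    "regress_confounds",
    "pearson_correlation_matrix",
    "threshold_by_sparsity",
    "sparsity_grid",
]


def sparsity_grid() -> list[float]:
    """The 8-point sparsity grid, 5% to 40% in steps of 5%."""
    return [round(0.05 * k, 2) for k in range(1, 9)]


def regress_confounds(
    ts: RegionalTimeSeries, confounds: np.ndarray | None = None
) -> RegionalTimeSeries:
    """Residualize each regional series against nuisance signals.

    Each region's series is regressed (OLS, with intercept) on the confound
    columns; the residuals replace the series.  With no confounds this is
    mean removal.

    Parameters
    ----------
    ts : RegionalTimeSeries
    confounds : (timepoints, k) array or None
        Nuisance signals, e.g. CSF/WM means and motion parameters.
    """
    t = ts.n_timepoints
    if confounds is None:
        confounds = np.empty((t, 0))
    confounds = np.asarray(confounds, dtype=float)
    if confounds.ndim == 1:
        confounds = confounds[:, None]
    if confounds.shape[0] != t:
        raise ValueError(
            f"confounds have {confounds.shape[0]} rows; expected {t} timepoints"
        )
    design = np.column_stack([np.ones(t), confounds])
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        # identify offending columns by rank increment
        bad = []
        kept = np.ones((t, 1))
        for j in range(confounds.shape[1]):
            cand = np.column_stack([kept, confounds[:, j]])
            if np.linalg.matrix_rank(cand) == kept.shape[1]:
                bad.append(j)
            else:
                kept = cand
        raise ValueError(f"rank-deficient confound design; offending columns: {bad}")
    beta, *_ = np.linalg.lstsq(design, ts.values.T, rcond=None)
    resid = ts.values.T - design @ beta
    return RegionalTimeSeries(labels=list(ts.labels), values=resid.T)


def pearson_correlation_matrix(ts: RegionalTimeSeries) -> CorrelationMatrix:
    """Pearson correlation of every pair of regional series."""
    sd = ts.values.std(axis=1)
    zero = np.flatnonzero(sd == 0)
    if zero.size:
        names = [ts.labels[i] for i in zero]
        raise ValueError(f"zero-variance regions: {names}")
    r = np.corrcoef(ts.values)
    r = (r + r.T) / 2.0
    np.fill_diagonal(r, 1.0)
    r = np.clip(r, -1.0, 1.0)
    return CorrelationMatrix(labels=list(ts.labels), r=r)


def threshold_by_sparsity(
    corr: CorrelationMatrix,
    sparsity: float,
    tie_seed: int = 0,
    mode: str = "signed",
) -> BrainNetwork:
    """Binarize a correlation matrix at a fixed edge count.

    Keeps the m = round(S * n(n-1)/2) largest off-diagonal correlations
    (mode="signed") or absolute correlations (mode="absolute").  Ties at the
    cutoff value are broken by a seeded uniform draw so runs reproduce.
    """
    if mode not in ("signed", "absolute"):
        raise ValueError("mode must be 'signed' or 'absolute'")
    if not (0 < sparsity <= 1):
        raise ValueError("sparsity must lie in (0, 1]")
    n = len(corr.labels)
    n_pairs = n * (n - 1) // 2
    m = edge_count_for_sparsity(n, sparsity)
    if m == 0 or m > n_pairs:
        raise ValueError(f"edge count {m} out of range [1, {n_pairs}]")
    values = corr.r if mode == "signed" else np.abs(corr.r)
    iu, ju = np.triu_indices(n, k=1)
    keep = _top_m_pairs(values[iu, ju], m, tie_seed)
    adjacency = np.zeros((n, n), dtype=np.int8)
    adjacency[iu[keep], ju[keep]] = 1
    adjacency |= adjacency.T
    return BrainNetwork(labels=list(corr.labels), adjacency=adjacency, sparsity=sparsity)


def _top_m_pairs(flat: np.ndarray, m: int, tie_seed: int) -> np.ndarray:
    """Indices of the m largest entries of a flat pair-score vector, with
    seeded uniform tie-breaking at the cutoff value."""
    order = np.argsort(flat, kind="stable")[::-1]
    cutoff = flat[order[m - 1]]
    above = np.flatnonzero(flat > cutoff)
    at = np.flatnonzero(flat == cutoff)
    need = m - above.size
    if need == at.size:
        chosen_at = at
    else:
        rng = np.random.default_rng(tie_seed)
        chosen_at = rng.choice(at, size=need, replace=False)
    return np.concatenate([above, chosen_at])
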