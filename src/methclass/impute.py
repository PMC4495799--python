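"""k-nearest-neighbor imputation of missing beta values, in probe space.

A probe with missing cells is imputed from the k nearest other probes,
where distance is the Euclidean distance over mutually observed samples
scaled by the number of shared samples (the classic microarray KNNimpute
convention). Neighbors contributing to a given cell must themselves be
observed at that sample; their values are combined with inverse-distance
weights.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import sparse

from .errors import ImputationError, InputError
from .io import BetaMatrix

logger = logging.getLogger(__name__)

_EPS = 1e-12

# Below this many target x donor pairs, distances are computed by direct
# broadcasting (no dot-product cancellation); above it, via one dense Gram
# matrix plus sparse corrections for the missing entries.
_DIRECT_PAIR_LIMIT = 2_000_000


def _knn_distances(X: np.ndarray, targets: np.ndarray) -> np.ndarray:
    """(n_targets, n_probes) matrix of sqrt(mean squared diff over shared
    observed samples); +inf where no sample is shared."""
    n_probes, n_samples = X.shape
    if targets.size * n_probes <= _DIRECT_PAIR_LIMIT:
        diff = X[targets][:, None, :] - X[None, :, :]
        sq = diff * diff
        shared = ~np.isnan(sq)
        n_shared = shared.sum(axis=2)
        with np.errstate(invalid="ignore", divide="ignore"):
            dist = np.sqrt(np.nansum(sq, axis=2) / n_shared)
        dist[n_shared == 0] = np.inf
        return dist
    # Large path: squared distance over shared samples = zero-filled full
    # distance minus the energy at cells where exactly one probe is missing
    # (cells missing in both contribute zero either way). Single precision
    # and in-place updates: this path is memory-bandwidth bound.
    miss = np.isnan(X)
    Z = np.nan_to_num(X).astype(np.float32)
    Z2 = Z * Z
    sq_norm = Z2.sum(axis=1)
    s = Z[targets] @ Z.T
    s *= -2.0
    s += sq_norm[targets][:, None]
    s += sq_norm[None, :]
    miss_sp = sparse.csr_matrix(miss.astype(np.float32))
    s -= np.asarray(miss_sp[targets] @ Z2.T)    # target missing, donor observed
    s -= np.asarray(miss_sp @ Z2[targets].T).T  # donor missing, target observed
    np.maximum(s, 0.0, out=s)
    n_miss = miss.sum(axis=1)
    both = (miss_sp[targets] @ miss_sp.T).astype(np.int64)  # shared-missing counts
    n_shared = np.asarray(both.todense())
    n_shared += n_samples - n_miss[targets][:, None] - n_miss[None, :]
    zero_shared = n_shared == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        s /= n_shared.astype(np.float32)
    dist = np.sqrt(s, out=s)
    dist[zero_shared] = np.inf
    return dist


@dataclass(frozen=True)
class ImputeConfig:
    """Imputation parameters.

    k
        Number of neighbor probes averaged per missing cell.
    max_missing_fraction
        Probes missing a larger fraction of their samples are dropped
        instead of imputed.
    """

    k: int = 10
    max_missing_fraction: float = 0.5

    def __post_init__(self) -> None:
        if self.k < 1:
            raise InputError(f"k must be >= 1, got {self.k}")
        if not 0.0 <= self.max_missing_fraction <= 1.0:
            raise InputError(
                f"max_missing_fraction must be in [0, 1], got {self.max_missing_fraction}"
            )


def _find_donors(order, drow, obs_col, k: int):
    """First k candidates (in distance order) observed at the column, or
    None if the candidate list runs out first."""
    donors: list[int] = []
    for cand in order:
        if not np.isfinite(drow[cand]):
            break
        if obs_col[cand]:
            donors.append(int(cand))
            if len(donors) == k:
                return donors
    return None


def knn_impute(m: BetaMatrix, cfg: ImputeConfig = ImputeConfig()) -> BetaMatrix:
    """Fill every missing beta by a weighted mean of the k nearest probes.

    Observed cells are never modified; imputed values are convex
    combinations of observed neighbor values and therefore stay in [0, 1].
    Probes exceeding ``cfg.max_missing_fraction`` are dropped (and logged)
    before imputation. Raises :class:`ImputationError` if some cell has
    fewer than k usable donor probes.
    """
    X = m.values.copy()
    n_probes, n_samples = X.shape
    miss_frac = np.isnan(X).mean(axis=1)
    keep = miss_frac <= cfg.max_missing_fraction
    if not keep.all():
        dropped = [p for p, k_ in zip(m.probe_ids, keep) if not k_]
        logger.info(
            "dropping %d probes with missing fraction > %.2f: %s%s",
            len(dropped), cfg.max_missing_fraction, dropped[:5],
            "..." if len(dropped) > 5 else "",
        )
        X = X[keep]
        n_probes = X.shape[0]
    probe_ids = [p for p, k_ in zip(m.probe_ids, keep) if k_]

    targets = np.flatnonzero(np.isnan(X).any(axis=1))
    if targets.size == 0:
        out = m.df.loc[probe_ids] if not keep.all() else m.df
        return BetaMatrix(out)

    # sqrt(sum of squared diffs over shared samples / n_shared); pairs with
    # no shared observed sample are excluded as donors.
    dist = _knn_distances(X, targets)
    for t_row, i in enumerate(targets):
        dist[t_row, i] = np.inf  # never use a probe as its own donor
    dist[np.isnan(dist)] = np.inf

    # Candidate donors per target: the (k + pad) smallest distances via
    # argpartition; rows that exhaust the shortlist fall back to a full
    # stable sort (stable = ties broken by probe index, deterministically).
    pad = min(cfg.k + 32, n_probes - 1)
    if pad < n_probes - 1:
        short = np.argpartition(dist, pad, axis=1)[:, : pad + 1]
    else:
        short = np.argsort(dist, axis=1, kind="stable")

    def _row_order(t_row: int, full: bool) -> np.ndarray:
        if full:
            return np.argsort(dist[t_row], kind="stable")
        cand = short[t_row]
        return cand[np.lexsort((cand, dist[t_row, cand]))]

    observed = ~np.isnan(X)
    for t_row, i in enumerate(targets):
        order = _row_order(t_row, full=False)
        full = pad >= n_probes - 1
        for j in np.flatnonzero(np.isnan(X[i])):
            donors = _find_donors(order, dist[t_row], observed[:, j], cfg.k)
            if donors is None and not full:
                order = _row_order(t_row, full=True)
                full = True
                donors = _find_donors(order, dist[t_row], observed[:, j], cfg.k)
            if donors is None:
                n_found = int(np.sum(observed[:, j] & np.isfinite(dist[t_row])))
                raise ImputationError(
                    f"probe {probe_ids[i]!r}, sample {m.sample_ids[j]!r}: "
                    f"only {n_found} usable neighbor probes (k={cfg.k})"
                )
            d = dist[t_row, donors].astype(np.float64)
            vals = X[donors, j]
            if np.all(d == d[0]):
                X[i, j] = float(np.mean(vals))
            else:
                w = 1.0 / np.maximum(d, _EPS)
                X[i, j] = float(np.sum(w * vals) / np.sum(w))

    return BetaMatrix(pd.DataFrame(X, index=probe_ids, columns=m.sample_ids))
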