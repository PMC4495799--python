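"""Independent brute-force oracles used by the unit and acceptance tests.

These deliberately avoid the package's vectorized code paths: AUC by
exhaustive pair counting, kNN imputation by naive per-cell loops.
"""

from __future__ import annotations

import numpy as np


def pair_count_auc(in_class: np.ndarray, out_class: np.ndarray) -> float:
    """(wins + half-ties) / all in x out pairs, folded to [0.5, 1]."""
    wins = ties = 0
    for x in in_class:
        for y in out_class:
            if x > y:
                wins += 1
            elif x == y:
                ties += 1
    a = (wins + 0.5 * ties) / (len(in_class) * len(out_class))
    return max(a, 1.0 - a)


def brute_force_knn_impute(X: np.ndarray, k: int, eps: float = 1e-12) -> np.ndarray:
    """Naive row-space kNN imputation on a small matrix.

    Distance = sqrt(mean squared difference over mutually observed
    columns); donors must be observed at the target column; inverse
    distance weighting, plain mean when all selected distances tie.
    Cells with fewer than k donors are left NaN.
    """
    X = np.asarray(X, dtype=float)
    out = X.copy()
    n_rows, n_cols = X.shape
    for i in range(n_rows):
        for j in range(n_cols):
            if not np.isnan(X[i, j]):
                continue
            cands = []
            for l in range(n_rows):
                if l == i or np.isnan(X[l, j]):
                    continue
                shared = ~np.isnan(X[i]) & ~np.isnan(X[l])
                if shared.sum() == 0:
                    continue
                d = np.sqrt(np.sum((X[i, shared] - X[l, shared]) ** 2) / shared.sum())
                cands.append((d, l))
            if len(cands) < k:
                continue
            cands.sort()  # ties broken by row index, like the implementation
            sel = cands[:k]
            d = np.array([c[0] for c in sel])
            v = np.array([X[c[1], j] for c in sel])
            if np.all(d == d[0]):
                out[i, j] = v.mean()
            else:
                w = 1.0 / np.maximum(d, eps)
                out[i, j] = np.sum(w * v) / np.sum(w)
    return out
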