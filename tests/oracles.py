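"""Independent oracles used only by the test suite.

These deliberately avoid the code paths they check: the SVM oracle solves the
soft-margin dual by brute-force grid search over the multipliers (with the
equality constraint eliminated analytically), and the AUC oracle is the
rank-statistic (pairwise comparison) form.
"""

from __future__ import annotations

import itertools

import numpy as np


def dual_objective(lam: np.ndarray, Q: np.ndarray) -> float:
    return float(lam.sum() - 0.5 * lam @ Q @ lam)


def brute_force_dual_svm(
    X: np.ndarray,
    y_signed: np.ndarray,
    C: float,
    n_grid: int = 11,
    refinements: int = 5,
) -> dict:
    """Brute-force maximiser of the soft-margin dual over a lambda grid.

    All multipliers but the last are enumerated on a grid over [0, C]; the
    last is solved from sum(lambda * y) = 0.  The grid is recentred and
    refined around the best point several times.  Returns lambda, w, b and
    the dual objective.  Only usable for a handful of points.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y_signed, dtype=float)
    m = len(y)
    assert m >= 2 and set(np.unique(y)) == {-1.0, 1.0}
    Q = (y[:, None] * y[None, :]) * (X @ X.T)

    centers = np.full(m - 1, C / 2.0)
    half_width = C / 2.0
    best_lam, best_obj = None, -np.inf
    for _ in range(refinements):
        axes = [
            np.clip(np.linspace(c - half_width, c + half_width, n_grid), 0.0, C)
            for c in centers
        ]
        grid = np.array(list(itertools.product(*axes)))
        last = -(grid @ y[:-1]) / y[-1]
        ok = (last >= -1e-12) & (last <= C + 1e-12)
        if not ok.any():
            half_width *= 0.6
            continue
        lam_full = np.column_stack([grid[ok], np.clip(last[ok], 0.0, C)])
        objs = lam_full.sum(axis=1) - 0.5 * np.einsum("ij,jk,ik->i", lam_full, Q, lam_full)
        k = int(np.argmax(objs))
        if objs[k] > best_obj:
            best_obj = float(objs[k])
            best_lam = lam_full[k]
        centers = best_lam[:-1]
        half_width = half_width * (2.0 / (n_grid - 1)) * 1.5
    lam = best_lam
    w = (lam * y) @ X
    margin_sv = (lam > 1e-6 * C) & (lam < C * (1 - 1e-6))
    if margin_sv.any():
        b = float(np.mean(y[margin_sv] - X[margin_sv] @ w))
    else:
        # all multipliers at the bounds: b constrained only by inequalities
        scores = X @ w
        lo, hi = -np.inf, np.inf
        for i in range(m):
            if lam[i] <= 1e-6 * C:       # y_i (w.x_i + b) >= 1
                if y[i] > 0:
                    lo = max(lo, 1 - scores[i])
                else:
                    hi = min(hi, -1 - scores[i])
            else:                        # lam == C: y_i (w.x_i + b) <= 1
                if y[i] > 0:
                    hi = min(hi, 1 - scores[i])
                else:
                    lo = max(lo, -1 - scores[i])
        b = float((lo + hi) / 2.0) if np.isfinite(lo) and np.isfinite(hi) else float(lo if np.isfinite(lo) else hi)
    return {"lam": lam, "w": w, "b": b, "dual_objective": best_obj}


def rank_statistic_auc(scores: np.ndarray, y: np.ndarray, positive: str = "VE") -> float:
    """AUC as the fraction of (positive, negative) pairs ranked correctly."""
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(y)
    pos = scores[y == positive]
    neg = scores[y != positive]
    assert pos.size and neg.size
    greater = (pos[:, None] > neg[None, :]).sum()
    ties = (pos[:, None] == neg[None, :]).sum()
    return (greater + 0.5 * ties) / (pos.size * neg.size)
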