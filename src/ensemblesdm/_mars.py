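"""Minimal multivariate adaptive regression splines for binary response.

Additive (degree-1) MARS: a forward pass greedily adds mirrored hinge
pairs max(0, x_j - t) / max(0, t - x_j) by least-squares RSS on the 0/1
labels, a backward pass prunes single basis columns by the classic GCV
criterion, and the surviving basis is refit with a logistic regression so
predictions are proper probabilities.
"""

from __future__ import annotations

import numpy as np
from sklearn.linear_model import LogisticRegression


def _hinges(x: np.ndarray, var: int, knot: float) -> np.ndarray:
    v = x[:, var]
    return np.column_stack([np.maximum(0.0, v - knot), np.maximum(0.0, knot - v)])


def _rss(B: np.ndarray, y: np.ndarray) -> float:
    coef, *_ = np.linalg.lstsq(B, y, rcond=None)
    r = y - B @ coef
    return float(r @ r)


def _gcv(rss: float, n: int, n_basis: int, penalty: float) -> float:
    # effective parameters: one per basis column plus `penalty` per knot
    c = n_basis + penalty * max(n_basis - 1, 0) / 2.0
    denom = (1.0 - c / n) ** 2
    if denom <= 0:
        return np.inf
    return rss / n / denom


class MarsClassifier:
    """Hinge-basis additive model with logistic output scores."""

    def __init__(self, max_terms: int = 21, max_knots: int = 15, penalty: float = 3.0):
        self.max_terms = max_terms
        self.max_knots = max_knots
        self.penalty = penalty

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        n, p = X.shape
        # candidate knots: interior quantiles per predictor
        candidates = []
        for j in range(p):
            qs = np.unique(
                np.quantile(X[:, j], np.linspace(0.05, 0.95, self.max_knots))
            )
            candidates.extend((j, float(t)) for t in qs)

        basis = [np.ones((n, 1))]
        spec: list[tuple[int, float] | None] = [None]  # None = intercept
        used: set[tuple[int, float]] = set()
        rss = _rss(np.ones((n, 1)), y)
        # forward: add mirrored hinge pairs while they reduce RSS
        while sum(b.shape[1] for b in basis) + 2 <= self.max_terms:
            best = None
            B0 = np.hstack(basis)
            for j, t in candidates:
                if (j, t) in used:
                    continue
                cand_rss = _rss(np.hstack([B0, _hinges(X, j, t)]), y)
                if best is None or cand_rss < best[0] - 1e-12:
                    best = (cand_rss, j, t)
            if best is None or best[0] >= rss * (1 - 1e-6):
                break
            rss, j, t = best
            basis.append(_hinges(X, j, t))
            spec.extend([(j, t, +1), (j, t, -1)])
            used.add((j, t))

        # backward: prune columns by GCV (intercept always kept)
        cols = np.hstack(basis)
        keep = list(range(cols.shape[1]))
        best_keep = list(keep)
        best_gcv = _gcv(_rss(cols[:, keep], y), n, len(keep), self.penalty)
        while len(keep) > 1:
            trial_best = None
            for drop in keep[1:]:
                trial = [k for k in keep if k != drop]
                g = _gcv(_rss(cols[:, trial], y), n, len(trial), self.penalty)
                if trial_best is None or g < trial_best[0]:
                    trial_best = (g, trial)
            keep = trial_best[1]
            if trial_best[0] < best_gcv:
                best_gcv, best_keep = trial_best[0], list(keep)

        self.terms_ = [spec[k] for k in best_keep if spec[k] is not None]
        self._logit = LogisticRegression(max_iter=2000)
        design = self._design(X)
        if design.shape[1] == 0:  # pruned to the intercept: constant model
            self._logit = None
            self._const = float(y.mean())
        else:
            self._logit.fit(design, y.astype(int))
        return self

    def _design(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        cols = []
        for j, t, sign in self.terms_:
            v = X[:, j]
            cols.append(np.maximum(0.0, (v - t) if sign > 0 else (t - v)))
        return np.column_stack(cols) if cols else np.empty((len(X), 0))

    def predict_proba(self, X):
        if self._logit is None:
            p = np.full(len(X), self._const)
        else:
            p = self._logit.predict_proba(self._design(X))[:, 1]
        return np.column_stack([1 - p, p])
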