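"""Feature ranking: NCA weighting for classification, RReliefF for regression.

Both rankers are implemented directly (they are the selection mechanism the
pipeline depends on, not interchangeable infrastructure).  Selection is by
fixed count k: top-9 features feed the activity classifier, top-15 feed the
HR regressors.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

__all__ = ["SelectionResult", "nca_weights", "relieff_weights"]


@dataclass(frozen=True)
class SelectionResult:
    weights: np.ndarray
    selected_indices: np.ndarray
    method: str
    k: int

    def __post_init__(self) -> None:
        if len(self.selected_indices) != self.k:
            raise ValueError("selection must return exactly k indices")
        sel = set(self.selected_indices.tolist())
        out = [w for i, w in enumerate(self.weights) if i not in sel]
        if out and min(self.weights[self.selected_indices]) < max(out) - 1e-12:
            raise ValueError("every selected weight must dominate unselected weights")

    def to_json(self, names: list[str] | None = None) -> str:
        if names is None:
            names = [f"f{i}" for i in range(len(self.weights))]
        return json.dumps(
            {
                "method": self.method,
                "k": self.k,
                "weights": {n: float(w) for n, w in zip(names, self.weights)},
                "selected": [names[i] for i in self.selected_indices],
            },
            indent=2,
        )


def _top_k(weights: np.ndarray, k: int) -> np.ndarray:
    order = np.argsort(weights, kind="stable")[::-1]
    return np.sort(order[:k])


def nca_weights(
    X: np.ndarray,
    y: np.ndarray,
    k: int,
    lam: float | None = None,
    *,
    max_iter: int = 200,
    step: float = 0.1,
    tol: float = 1e-6,
    max_samples: int = 500,
    seed: int = 0,
) -> SelectionResult:
    """Per-feature weights from neighborhood component analysis.

    Maximizes the regularized leave-one-out stochastic-neighbor objective

        sum_i sum_{j != i, y_j = y_i} p_ij  -  lam * sum_r w_r^2,
        p_ij ∝ exp(-sum_r w_r^2 |x_ir - x_jr|),

    by gradient ascent from w = 1 (initial step 0.1, halved on any objective
    decrease).  Returned importances are the squared weights.  Datasets
    larger than ``max_samples`` rows are subsampled (stratified, seeded) to
    bound the O(n^2 d) pairwise tensor.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    n, d = X.shape
    if len(np.unique(y)) < 2:
        raise ValueError("NCA requires at least two classes")
    if k > d:
        raise ValueError(f"cannot select k={k} from {d} features")

    if n > max_samples:
        rng = np.random.default_rng(seed)
        idx: list[int] = []
        classes, counts = np.unique(y, return_counts=True)
        for cls, cnt in zip(classes, counts):
            pool = np.flatnonzero(y == cls)
            take = max(2, int(round(max_samples * cnt / n)))
            idx.extend(rng.choice(pool, size=min(take, len(pool)), replace=False))
        idx = np.sort(np.asarray(idx))
        X, y = X[idx], y[idx]
        n = len(y)

    if lam is None:
        lam = 1.0 / n

    # pairwise absolute differences, D[i, j, r] = |x_ir - x_jr|
    D = np.abs(X[:, None, :] - X[None, :, :])
    same = (y[:, None] == y[None, :]) & ~np.eye(n, dtype=bool)

    w = np.ones(d)

    def objective_and_grad(w: np.ndarray) -> tuple[float, np.ndarray]:
        dist = np.tensordot(D, w**2, axes=([2], [0]))
        np.fill_diagonal(dist, np.inf)
        dist -= dist.min(axis=1, keepdims=True)  # log-sum-exp stabilization
        K = np.exp(-dist)
        np.fill_diagonal(K, 0.0)
        P = K / K.sum(axis=1, keepdims=True)
        p_i = np.sum(P * same, axis=1)
        obj = float(p_i.sum()) - lam * float(np.sum(w**2))
        # d p_i / d w_r = 2 w_r [ p_i * sum_j P_ij D_ijr - sum_{j in class} P_ij D_ijr ]
        all_term = np.einsum("ij,ijr->ir", P, D)
        cls_term = np.einsum("ij,ijr->ir", P * same, D)
        grad = 2.0 * w * np.sum(p_i[:, None] * all_term - cls_term, axis=0)
        grad -= 2.0 * lam * w
        return obj, grad

    obj, grad = objective_and_grad(w)
    cur_step = step
    for _ in range(max_iter):
        if np.linalg.norm(grad) < tol:
            break
        w_new = w + cur_step * grad
        obj_new, grad_new = objective_and_grad(w_new)
        if obj_new < obj:
            cur_step *= 0.5
            if cur_step < 1e-8:
                break
            continue
        w, obj, grad = w_new, obj_new, grad_new

    weights = w**2
    return SelectionResult(weights=weights, selected_indices=_top_k(weights, k),
                           method="nca", k=k)


def relieff_weights(
    X: np.ndarray,
    y: np.ndarray,
    k: int,
    *,
    n_neighbors: int = 10,
    sigma: float = 50.0,
    max_samples: int | None = 2000,
    seed: int = 0,
) -> SelectionResult:
    """Per-feature relevance weights from regression ReliefF (RReliefF).

    For every observation the ``n_neighbors`` nearest points (Euclidean) are
    found and weighted by a distance-rank exponential exp(-(rank/sigma)^2).
    The probabilities of a changed feature value, changed response, and
    their conjunction accumulate into the standard update

        W[r] = N_dR&dA[r] / N_dR - (N_dA[r] - N_dR&dA[r]) / (m - N_dR).

    Features that vary with the response among near neighbors receive
    positive weights; features that vary independently of it are pushed
    negative.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, d = X.shape
    if k > d:
        raise ValueError(f"cannot select k={k} from {d} features")
    if n < n_neighbors + 1:
        raise ValueError("need at least n_neighbors + 1 observations")
    if np.ptp(y) <= 0:
        raise ValueError("RReliefF requires a non-constant response")

    if max_samples is not None and n > max_samples:
        rng = np.random.default_rng(seed)
        idx = np.sort(rng.choice(n, size=max_samples, replace=False))
        X, y = X[idx], y[idx]
        n = max_samples

    span = np.ptp(X, axis=0)
    span[span == 0] = 1.0
    y_span = np.ptp(y)

    ranks = np.arange(1, n_neighbors + 1, dtype=float)
    w_rank = np.exp(-((ranks / sigma) ** 2))
    w_rank /= w_rank.sum()

    dist = cdist(X, X)
    np.fill_diagonal(dist, np.inf)
    # nearest n_neighbors per row, ordered by distance
    nn = np.argpartition(dist, n_neighbors - 1, axis=1)[:, :n_neighbors]
    row_order = np.argsort(np.take_along_axis(dist, nn, axis=1), axis=1)
    nn = np.take_along_axis(nn, row_order, axis=1)

    n_dr = 0.0
    n_da = np.zeros(d)
    n_drda = np.zeros(d)
    for i in range(n):
        js = nn[i]
        d_resp = np.abs(y[i] - y[js]) / y_span  # (k,)
        d_attr = np.abs(X[i] - X[js]) / span  # (k, d)
        n_dr += float(w_rank @ d_resp)
        n_da += w_rank @ d_attr
        n_drda += (w_rank * d_resp) @ d_attr

    m = float(n)
    weights = n_drda / n_dr - (n_da - n_drda) / (m - n_dr)
    return SelectionResult(weights=weights, selected_indices=_top_k(weights, k),
                           method="relieff", k=k)
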