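"""k-prototypes clustering of mixed numeric/categorical patient-weeks.

Stage 1 of the workload prediction model.  The mixed dissimilarity between
a row ``x`` and a prototype ``c`` is

    d(x, c) = sum_numeric (x_j - c_j)^2  +  gamma * sum_categorical [x_j != c_j]

with numeric prototypes updated as cluster means and categorical prototypes
as cluster modes (Huang's algorithm).  Numeric features are standardized
internally; ``gamma`` defaults to half the mean per-column variance of the
standardized numerics (Huang's heuristic, i.e. 0.5 after standardization).

The cluster count is selected by the elbow of the cost-vs-k curve
(max-distance-to-chord rule); the shipped pipeline default is k=7.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["PrototypeModel", "fit_kprototypes", "assign_cluster", "select_k"]


@dataclass
class PrototypeModel:
    k: int
    gamma: float
    numeric_centroids: np.ndarray  # (k, p), in standardized space
    categorical_modes: np.ndarray  # (k, q) integer codes
    categories: list  # per categorical column, array of category values
    numeric_cols: list
    categorical_cols: list
    num_means: np.ndarray
    num_sds: np.ndarray
    cost: float
    seed: int
    n_iter: int = 0

    def to_json(self) -> str:
        return json.dumps(
            {
                "k": self.k,
                "gamma": self.gamma,
                "numeric_centroids": self.numeric_centroids.tolist(),
                "categorical_modes": self.categorical_modes.tolist(),
                "categories": [list(map(str, c)) for c in self.categories],
                "numeric_cols": list(self.numeric_cols),
                "categorical_cols": list(self.categorical_cols),
                "num_means": self.num_means.tolist(),
                "num_sds": self.num_sds.tolist(),
                "cost": self.cost,
                "seed": self.seed,
                "n_iter": self.n_iter,
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "PrototypeModel":
        d = json.loads(text)
        return cls(
            k=d["k"],
            gamma=d["gamma"],
            numeric_centroids=np.asarray(d["numeric_centroids"], dtype=float),
            categorical_modes=np.asarray(d["categorical_modes"], dtype=int),
            categories=[np.asarray(c, dtype=object) for c in d["categories"]],
            numeric_cols=d["numeric_cols"],
            categorical_cols=d["categorical_cols"],
            num_means=np.asarray(d["num_means"], dtype=float),
            num_sds=np.asarray(d["num_sds"], dtype=float),
            cost=d["cost"],
            seed=d["seed"],
            n_iter=d["n_iter"],
        )


def _prepare(numeric, categorical):
    if isinstance(numeric, pd.DataFrame):
        num_cols = list(numeric.columns)
        X = numeric.to_numpy(dtype=float)
    else:
        X = np.asarray(numeric, dtype=float)
        if X.ndim == 1:
            X = X.reshape(1, -1)
        num_cols = [f"num{j}" for j in range(X.shape[1])]
    if categorical is None:
        C = np.empty((X.shape[0], 0), dtype=object)
        cat_cols = []
    elif isinstance(categorical, pd.DataFrame):
        cat_cols = list(categorical.columns)
        C = categorical.to_numpy(dtype=object)
    else:
        C = np.asarray(categorical, dtype=object)
        if C.ndim == 1:
            C = C.reshape(1, -1)
        cat_cols = [f"cat{j}" for j in range(C.shape[1])]
    return X, num_cols, C, cat_cols


def _encode(C: np.ndarray, categories=None):
    """Factorize categorical columns to integer codes; unseen values -> -1."""
    q = C.shape[1]
    codes = np.empty(C.shape, dtype=int)
    cats = []
    for j in range(q):
        col = C[:, j]
        if categories is None:
            u, inv = np.unique(col.astype(str), return_inverse=True)
            cats.append(u)
            codes[:, j] = inv
        else:
            u = np.asarray(categories[j]).astype(str)
            lookup = {v: i for i, v in enumerate(u)}
            codes[:, j] = np.array([lookup.get(str(v), -1) for v in col])
            cats.append(u)
    return codes, cats


def _distances(Xs, codes, centroids, modes, gamma):
    num_d = ((Xs[:, None, :] - centroids[None, :, :]) ** 2).sum(axis=2)
    if codes.shape[1]:
        cat_d = (codes[:, None, :] != modes[None, :, :]).sum(axis=2)
    else:
        cat_d = 0.0
    return num_d + gamma * cat_d


def _init_plusplus(Xs, codes, k, gamma, rng):
    """k-means++-style seeding with the mixed distance."""
    n = Xs.shape[0]
    idx = [int(rng.integers(n))]
    d2 = None
    for _ in range(1, k):
        cen = Xs[idx[-1:]]
        mod = codes[idx[-1:]]
        d_new = _distances(Xs, codes, cen, mod, gamma)[:, 0]
        d2 = d_new if d2 is None else np.minimum(d2, d_new)
        total = d2.sum()
        if total <= 0:
            idx.append(int(rng.integers(n)))
            continue
        idx.append(int(rng.choice(n, p=d2 / total)))
    return np.asarray(idx)


def _fit_once(Xs, codes, k, gamma, rng, max_iter):
    n = Xs.shape[0]
    init_idx = _init_plusplus(Xs, codes, k, gamma, rng)
    centroids = Xs[init_idx].copy()
    modes = codes[init_idx].copy()
    labels = np.full(n, -1)
    for it in range(max_iter):
        D = _distances(Xs, codes, centroids, modes, gamma)
        new_labels = D.argmin(axis=1)  # argmin ties -> lowest index
        # re-seed empty clusters from the point farthest from its centroid
        for c in range(k):
            if not (new_labels == c).any():
                far = D[np.arange(n), new_labels].argmax()
                centroids[c] = Xs[far]
                modes[c] = codes[far]
                new_labels[far] = c
        if (new_labels == labels).all():
            labels = new_labels
            break
        labels = new_labels
        for c in range(k):
            mask = labels == c
            centroids[c] = Xs[mask].mean(axis=0)
            for j in range(codes.shape[1]):
                vals = codes[mask, j]
                modes[c, j] = np.bincount(vals[vals >= 0]).argmax() if (vals >= 0).any() else 0
    D = _distances(Xs, codes, centroids, modes, gamma)
    cost = float(D[np.arange(n), labels].sum())
    return centroids, modes, labels, cost, it + 1


def fit_kprototypes(
    numeric,
    categorical=None,
    k: int = 7,
    gamma: float | None = None,
    seed: int = 0,
    max_iter: int = 100,
    n_init: int = 5,
) -> PrototypeModel:
    """Fit a k-prototypes model; best of ``n_init`` random initializations."""
    X, num_cols, C, cat_cols = _prepare(numeric, categorical)
    n = X.shape[0]
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > n:
        raise ValueError(f"k={k} exceeds number of rows n={n}")
    means = X.mean(axis=0) if X.shape[1] else np.zeros(0)
    sds = X.std(axis=0) if X.shape[1] else np.zeros(0)
    sds = np.where(sds == 0, 1.0, sds)
    Xs = (X - means) / sds if X.shape[1] else X
    codes, cats = _encode(C)
    if gamma is None:
        gamma = 0.5 * float(Xs.var(axis=0).mean()) if Xs.shape[1] else 1.0

    rng = np.random.default_rng(seed)
    best = None
    for _ in range(max(1, n_init)):
        centroids, modes, labels, cost, n_iter = _fit_once(Xs, codes, k, gamma, rng, max_iter)
        if best is None or cost < best[3]:
            best = (centroids, modes, labels, cost, n_iter)
    centroids, modes, labels, cost, n_iter = best
    return PrototypeModel(
        k=k,
        gamma=float(gamma),
        numeric_centroids=centroids,
        categorical_modes=modes,
        categories=cats,
        numeric_cols=num_cols,
        categorical_cols=cat_cols,
        num_means=means,
        num_sds=sds,
        cost=cost,
        seed=seed,
        n_iter=n_iter,
    )


def assign_cluster(model: PrototypeModel, numeric, categorical=None) -> np.ndarray:
    """Assign rows to the nearest prototype (ties -> lowest cluster index)."""
    X, num_cols, C, cat_cols = _prepare(numeric, categorical)
    if X.shape[1] != len(model.numeric_cols) or C.shape[1] != len(model.categorical_cols):
        raise ValueError(
            f"schema mismatch: expected {len(model.numeric_cols)} numeric and "
            f"{len(model.categorical_cols)} categorical columns, got {X.shape[1]}/{C.shape[1]}"
        )
    Xs = (X - model.num_means) / model.num_sds if X.shape[1] else X
    codes, _ = _encode(C, categories=model.categories)
    D = _distances(Xs, codes, model.numeric_centroids, model.categorical_modes, model.gamma)
    return D.argmin(axis=1)


def select_k(numeric, categorical=None, k_grid=range(2, 13), seed: int = 0, n_init: int = 3) -> int:
    """Elbow selection on the cost-vs-k curve (max distance to the chord)."""
    ks = sorted(set(int(k) for k in k_grid))
    if not ks:
        raise ValueError("k_grid must be non-empty")
    if len(ks) == 1:
        return ks[0]
    costs = np.array(
        [fit_kprototypes(numeric, categorical, k=k, seed=seed, n_init=n_init).cost for k in ks],
        dtype=float,
    )
    span = costs[0] - costs[-1]
    if span <= 0:
        warnings.warn("cost curve is flat or non-decreasing; returning smallest k")
        return ks[0]
    # knee by max distance to the chord, on a log cost scale (robust when the
    # within-cluster cost collapses by orders of magnitude at the true k)
    logc = np.log(np.maximum(costs, 1e-12 * costs[0]))
    x = (np.array(ks, dtype=float) - ks[0]) / (ks[-1] - ks[0])
    y = (logc - logc[-1]) / (logc[0] - logc[-1])
    # chord from (0, y0) to (1, y_last): distance of each point to it
    x0, y0, x1, y1 = 0.0, y[0], 1.0, y[-1]
    dist = np.abs((y1 - y0) * x - (x1 - x0) * y + x1 * y0 - y1 * x0) / np.hypot(y1 - y0, x1 - x0)
    return ks[int(dist.argmax())]
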