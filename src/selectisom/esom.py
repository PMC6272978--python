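"""Emergent self-organizing map (ESOM) on a toroidal neuron grid.

The map is a rows x cols grid of neurons, each holding a weight vector in the
input (fingerprint) space. Online Kohonen training presents samples one at a
time: the best-matching unit (BMU) is the neuron whose weight is closest to
the sample under the configured distance, and every neuron is pulled toward
the sample with strength alpha(t) * h(g, t), where h is a Gaussian of the
grid distance g to the BMU with the current neighborhood radius. Learning
rate and radius decay linearly from their start to end values over epochs.
"Emergent" maps use thousands of neurons (default 50 x 82 = 4100) on a
boundless (toroidal) grid, so cluster structure can emerge as contiguous
low-distance regions rather than one-neuron-per-class codebooks.

Two landscape surfaces are derived from a trained map:

* U-matrix: per neuron, the sum of weight-space distances to its eight
  immediate (Moore) grid neighbors, normalized by the largest such sum.
  Ridges of high U-height separate clusters.
* P-matrix: per neuron, the number of data points within the Pareto radius
  of its weight vector (Pareto density estimation); default radius is the
  20th percentile of the data's pairwise distance distribution.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.utils.validation import check_array, check_is_fitted

_DISTANCES = ("euclidean", "tanimoto_dissimilarity")


def _cross_distances(X: np.ndarray, W: np.ndarray, distance: str) -> np.ndarray:
    """Pairwise distances between rows of X (n,d) and rows of W (m,d)."""
    X = np.asarray(X, dtype=np.float64)
    W = np.asarray(W, dtype=np.float64)
    dot = X @ W.T
    x2 = np.einsum("ij,ij->i", X, X)
    w2 = np.einsum("ij,ij->i", W, W)
    if distance == "euclidean":
        d2 = x2[:, None] - 2.0 * dot + w2[None, :]
        np.maximum(d2, 0.0, out=d2)
        return np.sqrt(d2)
    # continuous Tanimoto dissimilarity: 1 - <x,w> / (|x|^2 + |w|^2 - <x,w>)
    denom = x2[:, None] + w2[None, :] - dot
    sim = np.ones_like(dot)
    np.divide(dot, denom, out=sim, where=denom > 0)
    return 1.0 - sim


class SelfOrganizingMap(ClusterMixin, BaseEstimator):
    """Toroidal Kohonen map with U-/P-matrix landscapes.

    Parameters
    ----------
    rows, cols : int
        Grid shape. The emergent-map convention is rows*cols >= 4000; smaller
        grids are accepted (and used throughout the test suite).
    topology : {"toroid", "bounded"}
        Toroidal grids wrap around in both axes for neighborhoods, U-matrix
        and cluster adjacency.
    epochs : int
        Full passes over the training data.
    lr_start, lr_end : float
        Learning-rate schedule endpoints (linear decay), lr_start >= lr_end > 0.
    radius_start, radius_end : float or None
        Gaussian neighborhood radius endpoints; radius_start=None means
        max(rows, cols) / 2.
    distance : {"euclidean", "tanimoto_dissimilarity"}
        Metric for BMU search, quantization error and the U-matrix.
    random_state : int
        Seed for weight initialization and per-epoch sample shuffling.

    Attributes
    ----------
    weights_ : ndarray of shape (rows*cols, n_features)
        Trained codebook, row-major over the grid.
    labels_ : ndarray of shape (n_samples,)
        Flat BMU index of each training sample after the final epoch.
    quantization_error_trace_ : list of float
        Mean sample-to-BMU distance before training and after each epoch
        (length epochs + 1).
    """

    def __init__(
        self,
        rows: int = 50,
        cols: int = 82,
        topology: str = "toroid",
        epochs: int = 30,
        lr_start: float = 0.5,
        lr_end: float = 0.05,
        radius_start: float | None = None,
        radius_end: float = 1.0,
        distance: str = "euclidean",
        random_state: int = 0,
    ):
        self.rows = rows
        self.cols = cols
        self.topology = topology
        self.epochs = epochs
        self.lr_start = lr_start
        self.lr_end = lr_end
        self.radius_start = radius_start
        self.radius_end = radius_end
        self.distance = distance
        self.random_state = random_state

    # -- grid geometry ----------------------------------------------------
    def _grid_sqdist_from(self, flat_index: int) -> np.ndarray:
        """Squared grid distance from one neuron to every neuron (torus-aware)."""
        r0, c0 = divmod(flat_index, self.cols)
        dr = np.abs(self._grid_r - r0)
        dc = np.abs(self._grid_c - c0)
        if self.topology == "toroid":
            dr = np.minimum(dr, self.rows - dr)
            dc = np.minimum(dc, self.cols - dc)
        return (dr * dr + dc * dc).astype(np.float64)

    def neighbor_indices(self, flat_index: int) -> list[int]:
        """Flat indices of the 8 Moore neighbors (deduplicated on tiny grids)."""
        r0, c0 = divmod(flat_index, self.cols)
        out = []
        for dr in (-1, 0, 1):
            for dc in (-1, 0, 1):
                if dr == 0 and dc == 0:
                    continue
                r, c = r0 + dr, c0 + dc
                if self.topology == "toroid":
                    r %= self.rows
                    c %= self.cols
                elif not (0 <= r < self.rows and 0 <= c < self.cols):
                    continue
                out.append(r * self.cols + c)
        return sorted(set(out) - {flat_index})

    # -- training ---------------------------------------------------------
    def fit(self, X, y=None):
        X = check_array(X, dtype=np.float64)
        if self.distance not in _DISTANCES:
            raise ValueError(f"distance must be one of {_DISTANCES}")
        if self.topology not in ("toroid", "bounded"):
            raise ValueError("topology must be 'toroid' or 'bounded'")
        if not (self.lr_start >= self.lr_end > 0):
            raise ValueError("require lr_start >= lr_end > 0")
        n, d = X.shape
        m = self.rows * self.cols
        rng = np.random.default_rng(self.random_state)
        flat = np.arange(m)
        self._grid_r, self._grid_c = np.divmod(flat, self.cols)

        lo, hi = X.min(axis=0), X.max(axis=0)
        W = rng.uniform(size=(m, d)) * (hi - lo) + lo

        r_start = self.radius_start if self.radius_start is not None else max(self.rows, self.cols) / 2.0
        r_end = self.radius_end
        if not (r_start >= r_end >= 0):
            raise ValueError("require radius_start >= radius_end >= 0")

        trace = [self._quantization_error(X, W)]
        for epoch in range(self.epochs):
            frac = epoch / (self.epochs - 1) if self.epochs > 1 else 0.0
            alpha = self.lr_start + (self.lr_end - self.lr_start) * frac
            sigma = r_start + (r_end - r_start) * frac
            order = rng.permutation(n)
            for i in order:
                x = X[i]
                bmu = int(np.argmin(_cross_distances(x[None, :], W, self.distance)[0]))
                gsq = self._grid_sqdist_from(bmu)
                if sigma > 0:
                    # update only inside 3 sigma; h is negligible beyond
                    mask = gsq <= (3.0 * sigma) ** 2
                    h = np.exp(-gsq[mask] / (2.0 * sigma * sigma))
                    W[mask] += alpha * h[:, None] * (x - W[mask])
                else:
                    W[bmu] += alpha * (x - W[bmu])
            trace.append(self._quantization_error(X, W))

        self.weights_ = W
        self.n_features_in_ = d
        self.quantization_error_trace_ = trace
        self.labels_ = self.predict(X)
        return self

    def _quantization_error(self, X: np.ndarray, W: np.ndarray) -> float:
        return float(_cross_distances(X, W, self.distance).min(axis=1).mean())

    # -- lookup -----------------------------------------------------------
    def predict(self, X) -> np.ndarray:
        """Flat BMU index per sample; ties break to the lowest (row, col)."""
        check_is_fitted(self, "weights_")
        X = check_array(X, dtype=np.float64, ensure_min_samples=0)
        if X.shape[0] == 0:
            return np.zeros(0, dtype=np.intp)
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"X has {X.shape[1]} features, model expects {self.n_features_in_}"
            )
        return _cross_distances(X, self.weights_, self.distance).argmin(axis=1)

    def transform(self, X) -> np.ndarray:
        """Distances from each sample to every neuron (sklearn-style)."""
        check_is_fitted(self, "weights_")
        X = check_array(X, dtype=np.float64, ensure_min_samples=0)
        return _cross_distances(X, self.weights_, self.distance)

    def bmu(self, x) -> tuple[int, int]:
        """(row, col) of the best-matching unit for a single vector."""
        flat = int(self.predict(np.asarray(x, dtype=np.float64)[None, :])[0])
        return divmod(flat, self.cols)

    def project(self, X) -> np.ndarray:
        """(n, 2) array of BMU (row, col) coordinates; the model is unchanged."""
        flat = self.predict(X)
        return np.stack(np.divmod(flat, self.cols), axis=1)

    # -- landscapes -------------------------------------------------------
    def umatrix(self) -> np.ndarray:
        """Normalized U-matrix as a (rows, cols) array in [0, 1].

        Raw height of a neuron is the sum of weight-space distances to its
        Moore neighbors; the surface is divided by its maximum (taken as 1
        when all neighbors are everywhere equal, so a flat map returns 0).
        """
        check_is_fitted(self, "weights_")
        m = self.rows * self.cols
        raw = np.zeros(m)
        for idx in range(m):
            nbrs = self.neighbor_indices(idx)
            raw[idx] = _cross_distances(
                self.weights_[idx][None, :], self.weights_[nbrs], self.distance
            ).sum()
        peak = raw.max()
        if peak <= 0:
            return np.zeros((self.rows, self.cols))
        return (raw / peak).reshape(self.rows, self.cols)

    def pmatrix(
        self,
        X,
        pareto_radius: float | None = None,
        subsample: int = 2000,
        random_state: int | None = None,
    ) -> np.ndarray:
        """Pareto density per neuron: data points within the Pareto radius.

        Default radius is the 20th percentile of the pairwise distance
        distribution of ``X`` (subsampled to at most ``subsample`` points,
        seeded). Returns a (rows, cols) array of non-negative counts.
        """
        check_is_fitted(self, "weights_")
        X = check_array(X, dtype=np.float64)
        if pareto_radius is None:
            pareto_radius = self.default_pareto_radius(X, subsample, random_state)
        if pareto_radius <= 0:
            raise ValueError("pareto_radius must be positive")
        dists = _cross_distances(X, self.weights_, self.distance)
        return (dists <= pareto_radius).sum(axis=0).reshape(self.rows, self.cols)

    def default_pareto_radius(
        self, X, subsample: int = 2000, random_state: int | None = None
    ) -> float:
        X = np.asarray(X, dtype=np.float64)
        seed = self.random_state if random_state is None else random_state
        if X.shape[0] > subsample:
            idx = np.random.default_rng(seed).choice(X.shape[0], subsample, replace=False)
            X = X[idx]
        pd = _cross_distances(X, X, self.distance)
        off_diag = pd[~np.eye(pd.shape[0], dtype=bool)]
        return float(np.percentile(off_diag, 20))


def stratified_split(
    labels, train_fraction: float = 0.5, random_state: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Seeded stratified 50/50 (by default) split; returns (train_idx, test_idx).

    Within each label the sample order is shuffled; odd counts put the extra
    sample in the training half.
    """
    labels = np.asarray(labels)
    rng = np.random.default_rng(random_state)
    train, test = [], []
    for value in sorted(set(labels.tolist())):
        idx = np.flatnonzero(labels == value)
        idx = rng.permutation(idx)
        k = int(np.ceil(train_fraction * len(idx)))
        train.extend(idx[:k].tolist())
        test.extend(idx[k:].tolist())
    return np.sort(np.array(train, dtype=np.intp)), np.sort(np.array(test, dtype=np.intp))
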