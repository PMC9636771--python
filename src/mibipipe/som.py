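"""A small, seeded self-organizing map for cytometry-style meta-clustering.

Online Kohonen training on a rectangular grid with a Gaussian neighborhood
whose radius and learning rate decay linearly over training.  Deliberately
minimal: enough to reproduce the SOM-then-linkage meta-clustering idiom used
for single-object phenotyping, with strict seed determinism.
"""

from __future__ import annotations

import numpy as np

__all__ = ["SelfOrganizingMap"]


class SelfOrganizingMap:
    def __init__(self, grid: tuple[int, int] = (10, 10), n_features: int = 1,
                 learning_rate: float = 0.5, sigma: float | None = None,
                 seed: int = 0):
        self.grid = grid
        self.n_features = n_features
        self.learning_rate = learning_rate
        self.sigma = sigma if sigma is not None else max(grid) / 2.0
        self.seed = seed
        self._rng = np.random.default_rng(seed)
        self.weights = self._rng.normal(0, 0.1, (grid[0] * grid[1], n_features))
        gy, gx = np.mgrid[0:grid[0], 0:grid[1]]
        self._coords = np.column_stack([gy.ravel(), gx.ravel()]).astype(float)

    @property
    def n_nodes(self) -> int:
        return self.grid[0] * self.grid[1]

    def fit(self, X: np.ndarray, epochs: int = 10) -> "SelfOrganizingMap":
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != self.n_features:
            raise ValueError(f"expected (n, {self.n_features}) data")
        # seed the map from the data range for faster convergence
        lo, hi = X.min(axis=0), X.max(axis=0)
        self.weights = self._rng.uniform(0, 1, self.weights.shape) * (hi - lo) + lo
        n_steps = epochs * len(X)
        step = 0
        for _ in range(epochs):
            order = self._rng.permutation(len(X))
            for i in order:
                frac = step / max(n_steps - 1, 1)
                lr = self.learning_rate * (1 - frac)
                sig = max(self.sigma * (1 - frac), 0.5)
                x = X[i]
                bmu = int(np.argmin(((self.weights - x) ** 2).sum(axis=1)))
                d2 = ((self._coords - self._coords[bmu]) ** 2).sum(axis=1)
                h = np.exp(-d2 / (2 * sig * sig))
                self.weights += (lr * h)[:, None] * (x - self.weights)
                step += 1
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Best-matching node index per row."""
        X = np.asarray(X, dtype=float)
        d = ((X[:, None, :] - self.weights[None, :, :]) ** 2).sum(axis=2)
        return d.argmin(axis=1)
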