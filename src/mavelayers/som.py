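"""Self-organizing map on a toroidal hexagonal grid with bubble neighborhood.

The map is an online (sample-at-a-time) Kohonen network: each presentation
finds the best-matching unit (BMU, smallest Euclidean distance, ties to the
lowest unit index) and moves every unit within the current neighborhood radius
of the BMU toward the sample. The learning rate decreases linearly from
``alpha_start`` (default 0.05) to ``alpha_end`` over all presentations, and
the bubble radius decreases linearly from the 2/3 quantile of pairwise unit
distances to 1. Grid units are embedded as offset hexagons (odd rows shifted
by 0.5, row pitch sqrt(3)/2) and distances are minimized over the nine torus
wrap images, so opposite edges are adjacent.

``ToroidalHexSOM`` follows the scikit-learn estimator protocol (``fit``,
``predict``, ``transform``, fitted attributes with trailing underscores) and
``select_best_init`` retrains under consecutive seeds, keeping the map whose
codebook minimizes the total distance between the data and their BMUs.
"""

from __future__ import annotations

import math
from functools import lru_cache
from io import StringIO

import numpy as np
import pandas as pd
from numba import njit
from sklearn.base import BaseEstimator

DEFAULT_GRID = (13, 20)  # 260 neurons
DEFAULT_BEST_OF_N = 500


# ---------------------------------------------------------------------------
# grid geometry
# ---------------------------------------------------------------------------


def hex_coordinates(n_rows: int, n_cols: int) -> np.ndarray:
    """Planar embedding of the hex grid: odd rows offset 0.5, row pitch sqrt(3)/2."""
    rows, cols = np.divmod(np.arange(n_rows * n_cols), n_cols)
    x = cols + 0.5 * (rows % 2)
    y = rows * (math.sqrt(3.0) / 2.0)
    return np.column_stack([x, y]).astype(float)


def toroidal_hex_distance(unit_i: int, unit_j: int, n_rows: int, n_cols: int) -> float:
    """Distance between two units, minimized over the 9 torus wrap images."""
    n_units = n_rows * n_cols
    for u in (unit_i, unit_j):
        if not 0 <= u < n_units:
            raise ValueError(f"unit {u} off the {n_rows}x{n_cols} grid")
    matrix = unit_distance_matrix(n_rows, n_cols)
    return float(matrix[unit_i, unit_j])


@lru_cache(maxsize=8)
def unit_distance_matrix(n_rows: int, n_cols: int) -> np.ndarray:
    """All pairwise toroidal hex distances, shape (units, units)."""
    pitch = math.sqrt(3.0) / 2.0
    coords = hex_coordinates(n_rows, n_cols)
    xi, yi = coords[:, 0][:, None], coords[:, 1][:, None]
    best = np.full((n_rows * n_cols, n_rows * n_cols), np.inf)
    # wrap images are rigid lattice translations; a vertical wrap of an
    # odd-row grid also shifts x by 0.5 (row parity flips), keeping the
    # minimum-image distance a true metric
    for dr in (-1, 0, 1):
        y_img = coords[:, 1] + dr * n_rows * pitch
        x_shift = 0.5 * dr * (n_rows % 2)
        for dc in (-1, 0, 1):
            x_img = coords[:, 0] + dc * n_cols + x_shift
            d2 = (xi - x_img[None, :]) ** 2 + (yi - y_img[None, :]) ** 2
            np.minimum(best, d2, out=best)
    return np.sqrt(best)


# ---------------------------------------------------------------------------
# training kernel
# ---------------------------------------------------------------------------


@njit(cache=True)
def _train_online(codebook, data, order, alphas, radii, unit_dist, trace):
    """In-place online SOM training; returns per-epoch mean BMU distance."""
    n_units, n_features = codebook.shape
    n_samples = data.shape[0]
    t = 0
    n_epochs = order.shape[0] // n_samples
    for epoch in range(n_epochs):
        qe = 0.0
        for s in range(n_samples):
            row = order[t]
            # best-matching unit, ties to the lowest index
            best = 0
            best_d2 = np.inf
            for u in range(n_units):
                d2 = 0.0
                for f in range(n_features):
                    diff = data[row, f] - codebook[u, f]
                    d2 += diff * diff
                if d2 < best_d2:
                    best_d2 = d2
                    best = u
            qe += math.sqrt(best_d2)
            alpha = alphas[t]
            radius = radii[t]
            for u in range(n_units):
                if unit_dist[best, u] <= radius:
                    for f in range(n_features):
                        codebook[u, f] += alpha * (data[row, f] - codebook[u, f])
            t += 1
        trace[epoch] = qe / n_samples
    return codebook


class ToroidalHexSOM(BaseEstimator):
    """Online SOM on a toroidal hexagonal grid with bubble neighborhood.

    Parameters
    ----------
    n_rows, n_cols
        Grid dimensions; the codebook has ``n_rows * n_cols`` units.
    n_epochs
        Number of passes over the data (each in a fresh seeded random order).
    alpha_start, alpha_end
        Linear learning-rate schedule over all presentations.
    radius_start
        Initial bubble radius; ``None`` uses the 2/3 quantile of pairwise
        unit distances. Decreases linearly to ``radius_end``.
    random_state
        Seed for codebook initialization (data rows sampled without
        replacement) and presentation order.

    Attributes
    ----------
    codebook_ : ndarray of shape (n_units, n_features)
    quantization_errors_ : ndarray of shape (n_epochs,)
        Mean presentation-time BMU distance per epoch.
    unit_distances_ : ndarray of shape (n_units, n_units)
    """

    def __init__(
        self,
        n_rows: int = DEFAULT_GRID[0],
        n_cols: int = DEFAULT_GRID[1],
        n_epochs: int = 100,
        alpha_start: float = 0.05,
        alpha_end: float = 0.01,
        radius_start: float | None = None,
        radius_end: float = 1.0,
        random_state: int | None = 0,
    ):
        self.n_rows = n_rows
        self.n_cols = n_cols
        self.n_epochs = n_epochs
        self.alpha_start = alpha_start
        self.alpha_end = alpha_end
        self.radius_start = radius_start
        self.radius_end = radius_end
        self.random_state = random_state

    @property
    def n_units(self) -> int:
        return self.n_rows * self.n_cols

    def _validate(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[0] == 0:
            raise ValueError("data must be a non-empty 2-D array")
        if not np.isfinite(X).all():
            raise ValueError("data contains non-finite rows")
        return X

    def fit(self, X, y=None) -> "ToroidalHexSOM":
        if self.n_rows < 2 or self.n_cols < 2:
            raise ValueError("grid must be at least 2x2")
        if self.n_epochs < 1:
            raise ValueError("n_epochs must be >= 1")
        X = self._validate(X)
        n_samples = X.shape[0]
        rng = np.random.default_rng(self.random_state)
        unit_dist = unit_distance_matrix(self.n_rows, self.n_cols)
        init_rows = rng.choice(n_samples, size=self.n_units, replace=n_samples < self.n_units)
        codebook = X[init_rows].copy()
        order = np.concatenate(
            [rng.permutation(n_samples) for _ in range(self.n_epochs)]
        ).astype(np.int64)
        total = len(order)
        steps = np.arange(total) / max(total - 1, 1)
        alphas = self.alpha_start + (self.alpha_end - self.alpha_start) * steps
        r0 = self.radius_start
        if r0 is None:
            off_diag = unit_dist[np.triu_indices(self.n_units, k=1)]
            r0 = float(np.quantile(off_diag, 2.0 / 3.0))
        radii = r0 + (self.radius_end - r0) * steps
        trace = np.zeros(self.n_epochs)
        _train_online(codebook, X, order, alphas, radii, unit_dist, trace)
        self.codebook_ = codebook
        self.quantization_errors_ = trace
        self.unit_distances_ = unit_dist
        self.grid_coordinates_ = hex_coordinates(self.n_rows, self.n_cols)
        return self

    def transform(self, X) -> np.ndarray:
        """Euclidean distances from each row to every codebook vector."""
        X = self._validate(X)
        if X.shape[1] != self.codebook_.shape[1]:
            raise ValueError("feature dimension mismatch with codebook")
        diff = X[:, None, :] - self.codebook_[None, :, :]
        return np.sqrt((diff**2).sum(axis=2))

    def predict(self, X) -> np.ndarray:
        """BMU index per row (ties to the lowest unit index)."""
        return self.transform(X).argmin(axis=1)

    def map_to_bmu(self, X) -> tuple[np.ndarray, np.ndarray]:
        """Per-row (BMU index, Euclidean distance to the BMU)."""
        d = self.transform(X)
        units = d.argmin(axis=1)
        return units, d[np.arange(len(d)), units]

    def total_mapping_distance(self, X) -> float:
        """Sum over data rows of the distance to the best-matching unit."""
        return float(self.map_to_bmu(X)[1].sum())


def select_best_init(
    X,
    n_seeds: int = DEFAULT_BEST_OF_N,
    base_seed: int = 0,
    **som_params,
) -> ToroidalHexSOM:
    """Train maps under seeds base_seed..base_seed+n_seeds-1; keep the best.

    The winner minimizes the total distance between the data rows and their
    matching codebook vectors; deterministic given ``base_seed``.
    """
    if n_seeds < 1:
        raise ValueError("n_seeds must be >= 1")
    best_model, best_score = None, np.inf
    for k in range(n_seeds):
        model = ToroidalHexSOM(random_state=base_seed + k, **som_params).fit(X)
        score = model.total_mapping_distance(X)
        if score < best_score:
            best_model, best_score = model, score
    return best_model


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------


def som_to_text(model: ToroidalHexSOM) -> str:
    """Structured-text serialization: header lines then the codebook table."""
    header = {
        "n_rows": model.n_rows,
        "n_cols": model.n_cols,
        "n_epochs": model.n_epochs,
        "alpha_start": model.alpha_start,
        "alpha_end": model.alpha_end,
        "radius_end": model.radius_end,
        "random_state": model.random_state,
    }
    lines = [f"#{key}={value}" for key, value in header.items()]
    buf = StringIO()
    pd.DataFrame(model.codebook_).to_csv(buf, sep="\t", index_label="unit")
    return "\n".join(lines) + "\n" + buf.getvalue()


def som_from_text(text: str) -> ToroidalHexSOM:
    header, table_lines = {}, []
    for line in text.splitlines():
        if line.startswith("#"):
            key, value = line[1:].split("=", 1)
            header[key] = value
        elif line.strip():
            table_lines.append(line)
    codebook = pd.read_csv(StringIO("\n".join(table_lines)), sep="\t", index_col="unit")
    model = ToroidalHexSOM(
        n_rows=int(header["n_rows"]),
        n_cols=int(header["n_cols"]),
        n_epochs=int(header["n_epochs"]),
        alpha_start=float(header["alpha_start"]),
        alpha_end=float(header["alpha_end"]),
        radius_end=float(header["radius_end"]),
        random_state=None if header["random_state"] == "None" else int(header["random_state"]),
    )
    model.codebook_ = codebook.to_numpy(dtype=float)
    model.unit_distances_ = unit_distance_matrix(model.n_rows, model.n_cols)
    model.grid_coordinates_ = hex_coordinates(model.n_rows, model.n_cols)
    return model
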