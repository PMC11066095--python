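"""Affinity-propagation clustering of SOM codebook vectors.

Standard responsibility/availability message passing (Frey & Dueck) on a
similarity matrix of negative squared Euclidean distances. Exemplar
preferences are initialized from a quantile ``q`` (default 0.1) of the
off-diagonal similarities — lower ``q`` favors fewer clusters. Iteration stops
when the exemplar set is unchanged for ``conv_iter`` consecutive sweeps or at
``max_iter``; non-exemplars are assigned to the exemplar of maximal
similarity.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

DEFAULT_Q = 0.1
DEFAULT_DAMPING = 0.9
DEFAULT_MAX_ITER = 1000
DEFAULT_CONV_ITER = 100


@dataclass
class ApResult:
    """Exemplars and labels from affinity propagation."""

    exemplars: np.ndarray  # indices of exemplar items
    labels: np.ndarray  # per item: index of its exemplar
    preference: float
    damping: float
    n_iter: int
    converged: bool
    similarity: str = "negative_squared_euclidean"

    @property
    def n_clusters(self) -> int:
        return len(self.exemplars)

    def cluster_ids(self) -> np.ndarray:
        """Labels recoded to consecutive integers ordered by exemplar index."""
        mapping = {int(e): i for i, e in enumerate(self.exemplars)}
        return np.array([mapping[int(l)] for l in self.labels])


def negative_squared_distances(X: np.ndarray) -> np.ndarray:
    """Pairwise similarity matrix s(i, k) = -||x_i - x_k||^2."""
    X = np.asarray(X, dtype=float)
    diff = X[:, None, :] - X[None, :, :]
    return -(diff**2).sum(axis=2)


def preference_from_quantile(similarity: np.ndarray, q: float = DEFAULT_Q) -> float:
    """q-quantile (linear interpolation) of the off-diagonal similarities."""
    if not 0 <= q <= 1:
        raise ValueError("q must be in [0, 1]")
    similarity = np.asarray(similarity, dtype=float)
    n = similarity.shape[0]
    off = similarity[~np.eye(n, dtype=bool)]
    return float(np.quantile(off, q))


def affinity_propagation(
    similarity: np.ndarray,
    preference: float | None = None,
    damping: float = DEFAULT_DAMPING,
    max_iter: int = DEFAULT_MAX_ITER,
    conv_iter: int = DEFAULT_CONV_ITER,
    q: float = DEFAULT_Q,
) -> ApResult:
    """Cluster items on a square similarity matrix by message passing.

    ``preference`` defaults to the q-quantile of off-diagonal similarities and
    is written onto the diagonal. Every exemplar is labeled as itself.
    """
    S = np.array(similarity, dtype=float)
    if S.ndim != 2 or S.shape[0] != S.shape[1]:
        raise ValueError("similarity matrix must be square")
    if not 0.5 <= damping < 1:
        raise ValueError("damping must be in [0.5, 1)")
    n = S.shape[0]
    if preference is None:
        preference = preference_from_quantile(S, q)
    np.fill_diagonal(S, preference)

    R = np.zeros((n, n))
    A = np.zeros((n, n))
    idx = np.arange(n)
    last_exemplars: frozenset[int] | None = None
    stable = 0
    converged = False
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        # responsibilities
        AS = A + S
        first = AS.max(axis=1)
        first_k = AS.argmax(axis=1)
        AS[idx, first_k] = -np.inf
        second = AS.max(axis=1)
        new_R = S - first[:, None]
        new_R[idx, first_k] = S[idx, first_k] - second
        R = damping * R + (1 - damping) * new_R
        # availabilities
        Rp = np.maximum(R, 0.0)
        np.fill_diagonal(Rp, R.diagonal())
        col_sums = Rp.sum(axis=0)
        new_A = np.minimum(0.0, col_sums[None, :] - Rp)
        new_A[idx, idx] = col_sums - Rp.diagonal()  # sum of max(0, r(i', k)), i' != k
        A = damping * A + (1 - damping) * new_A
        exemplars = frozenset(np.flatnonzero((A + R).diagonal() > 0).tolist())
        if exemplars and exemplars == last_exemplars:
            stable += 1
            if stable >= conv_iter:
                converged = True
                break
        else:
            stable = 0
        last_exemplars = exemplars

    exemplar_idx = np.flatnonzero((A + R).diagonal() > 0)
    if len(exemplar_idx) == 0:
        exemplar_idx = np.array([int((A + R).diagonal().argmax())])
        logger.warning("affinity_propagation: no exemplar emerged; falling back to the best item")
    labels = exemplar_idx[S[:, exemplar_idx].argmax(axis=1)]
    labels[exemplar_idx] = exemplar_idx
    if not converged:
        logger.warning("affinity_propagation did not converge in %d iterations", max_iter)
    return ApResult(
        exemplars=exemplar_idx,
        labels=labels,
        preference=float(preference),
        damping=damping,
        n_iter=n_iter,
        converged=converged,
    )


def cluster_composition(
    variant_clusters: pd.Series, variant_classes: pd.Series
) -> pd.DataFrame:
    """Per-cluster counts and proportions of silent/missense/nonsense variants."""
    unmapped = variant_clusters.index.difference(variant_classes.index)
    if len(unmapped):
        raise KeyError(f"variants without a class: {list(unmapped[:5])}")
    classes = variant_classes.reindex(variant_clusters.index)
    table = pd.crosstab(variant_clusters, classes)
    for cls in ("silent", "missense", "nonsense"):
        if cls not in table.columns:
            table[cls] = 0
    table = table[["silent", "missense", "nonsense"]]
    props = table.div(table.sum(axis=1), axis=0)
    props.columns = [f"prop_{c}" for c in props.columns]
    out = pd.concat([table, props], axis=1)
    out.index.name = "cluster"
    return out


def assign_variants_to_clusters(bmu_per_variant: np.ndarray, ap: ApResult) -> np.ndarray:
    """Cluster id per variant via its BMU's affinity-propagation label."""
    return ap.cluster_ids()[np.asarray(bmu_per_variant)]


def exemplar_signatures(codebook: np.ndarray, ap: ApResult, columns) -> pd.DataFrame:
    """Codebook vector of each cluster exemplar (the representative expression)."""
    frame = pd.DataFrame(codebook[ap.exemplars], columns=list(columns))
    frame.index = pd.Index(range(len(ap.exemplars)), name="cluster")
    frame.insert(0, "exemplar_unit", ap.exemplars)
    return frame
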