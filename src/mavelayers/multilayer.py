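"""Multi-layer variant signatures.

Per-layer median frequencies are transformed to interquartile log ratios
(IQLR) by a four-step recipe — reclose each layer, CLR-transform, select
features with CLR variance inside the interquartile range, and take the log
ratio of each variant frequency to the geometric mean of the selected
features — then standardized within each layer and robustly centered to the
per-variant median across layers. The centering removes each variant's nominal
library abundance so that only the expression *topology* across layers is
learned by downstream clustering. Signed effect-size matrices (with the
low-protein flow population negated) feed hierarchical clustering of
differential variants.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

logger = logging.getLogger(__name__)

#: layers entering the clustering signature, in display order
DEFAULT_SIGNATURE_LAYERS = ("gDNA", "totalRNA", "polysome_F3", "polysome_F4", "flow_P1", "flow_P3")


def iqlr_across_layers(layer_freqs: pd.DataFrame) -> pd.DataFrame:
    """Interquartile log ratios of a variants x layers frequency matrix.

    Steps per layer column: (1) reclose (divide by the column total); (2) CLR;
    (3) per-variant CLR variance across layers, keeping variants with variance
    inside [Q1, Q3]; (4) IQLR = ln(closed frequency) minus the mean ln closed
    frequency of the selected variants. The result is invariant to rescaling
    any single layer by a positive constant.
    """
    if layer_freqs.shape[0] < 4:
        raise ValueError("IQLR needs at least 4 variants")
    values = layer_freqs.to_numpy(dtype=float)
    if (values <= 0).any():
        raise ValueError("layer frequencies must be strictly positive")
    closed = values / values.sum(axis=0, keepdims=True)
    logs = np.log(closed)
    clr = logs - logs.mean(axis=0, keepdims=True)
    variances = clr.var(axis=1, ddof=1)
    q1, q3 = np.quantile(variances, [0.25, 0.75])
    selected = (variances >= q1) & (variances <= q3)
    iqlr = logs - logs[selected].mean(axis=0, keepdims=True)
    return pd.DataFrame(iqlr, index=layer_freqs.index, columns=layer_freqs.columns)


def scale_and_center(iqlr_matrix: pd.DataFrame, ddof: int = 0) -> pd.DataFrame:
    """Standardize each layer column, then subtract each variant's across-layer median.

    Column standardization uses the population SD by default (``ddof=0``).
    Constant (zero-SD) layers are rejected.
    """
    if iqlr_matrix.shape[0] < 2:
        raise ValueError("need at least 2 variants")
    values = iqlr_matrix.to_numpy(dtype=float)
    sd = values.std(axis=0, ddof=ddof)
    zero = iqlr_matrix.columns[sd == 0]
    if len(zero):
        raise ValueError(f"zero-SD layers: {list(zero)}")
    z = (values - values.mean(axis=0)) / sd
    centered = z - np.median(z, axis=1, keepdims=True)
    return pd.DataFrame(centered, index=iqlr_matrix.index, columns=iqlr_matrix.columns)


def build_signed_effect_matrix(
    effect_tables: dict[str, pd.DataFrame],
    negate: tuple[str, ...] = ("flow_P3-vs-gDNA",),
    sign_flip: bool = True,
) -> pd.DataFrame:
    """Variants x comparisons effect matrix, intersecting the tables.

    Columns listed in ``negate`` (by default the low-protein flow comparison)
    are multiplied by -1 so negative values denote low protein abundance;
    variants absent from any table are excluded and logged.
    """
    if not effect_tables:
        raise ValueError("no effect tables given")
    series = {}
    for name, table in effect_tables.items():
        col = table.set_index("variant_id")["effect"]
        if sign_flip and name in negate:
            col = -col
        series[name] = col
    matrix = pd.DataFrame(series)
    complete = matrix.dropna()
    dropped = len(matrix) - len(complete)
    if dropped:
        logger.info("build_signed_effect_matrix: excluded %d variants missing from some table", dropped)
    return complete


def hierarchical_cluster(
    signature: pd.DataFrame, method: str = "complete", metric: str = "euclidean"
) -> tuple[np.ndarray, list]:
    """Agglomerative clustering of variant signatures.

    Returns the scipy linkage matrix and the deterministic leaf order (ties
    broken by input index by scipy's ordering).
    """
    if signature.shape[0] < 2:
        raise ValueError("need at least 2 variants to cluster")
    values = signature.to_numpy(dtype=float)
    if not np.isfinite(values).all():
        raise ValueError("signature contains non-finite entries")
    linkage = hierarchy.linkage(pdist(values, metric=metric), method=method)
    leaves = hierarchy.leaves_list(linkage)
    return linkage, [signature.index[i] for i in leaves]


def linkage_to_newick(linkage: np.ndarray, labels) -> str:
    """Serialize a scipy linkage matrix as a Newick tree string."""
    tree = hierarchy.to_tree(linkage)
    labels = list(labels)
    rendered: dict[int, str] = {}
    stack = [tree]
    while stack:  # iterative post-order; trees can be deep for many variants
        node = stack.pop()
        if node.is_leaf():
            rendered[node.id] = str(labels[node.id])
            continue
        if node.left.id in rendered and node.right.id in rendered:
            dl = node.dist - node.left.dist
            dr = node.dist - node.right.dist
            rendered[node.id] = (
                f"({rendered[node.left.id]}:{dl:.6g},{rendered[node.right.id]}:{dr:.6g})"
            )
        else:
            stack.extend([node, node.left, node.right])
    return rendered[tree.id] + ";"
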