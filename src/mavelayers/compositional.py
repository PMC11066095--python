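"""Compositional differential-abundance engine.

Counts-per-million columns are treated as compositions: per sample, Monte
Carlo instances are drawn from a Dirichlet posterior (counts + 0.5), each
instance is transformed to centered log ratios (CLR) against either all
features or the interquartile-variance feature set (IQLR), and per variant the
engine reports

* a median standardized between-group difference ("effect"): the median
  cross-group CLR difference divided by the larger within-group median
  absolute pairwise difference, summarized as the median over instances with a
  75% interval from the 12.5th/87.5th instance percentiles;
* Welch two-sample t p-values, Benjamini-Hochberg adjusted across variants
  within each instance, reported as means over instances.

Between- and within-group dispersions enumerate all sample pairs exactly
(deterministic; identical in expectation to random pairings).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .containers import EffectTable, FrequencyMatrix
from .preprocess import detection_mask, summarize_replicates, to_cpm

logger = logging.getLogger(__name__)

DEFAULT_MC_SAMPLES = 128
EFFECT_CI_PERCENTILES = (12.5, 87.5)  # 75% interval on per-instance effects
_MIN_EPS = 1e-8


# ---------------------------------------------------------------------------
# Monte Carlo instances and log-ratio transforms
# ---------------------------------------------------------------------------


def dirichlet_instances(cpm_counts: pd.DataFrame, n_instances: int, seed: int) -> np.ndarray:
    """Dirichlet(count + 0.5) probability instances, shape (V, S, K).

    CPM values are rounded half-up to integers first. ``n_instances=0``
    returns the single maximum-a-posteriori composition (counts + 0.5,
    closed) for deterministic point-mode testing.
    """
    if n_instances < 0:
        raise ValueError("n_instances must be >= 0")
    counts = np.floor(cpm_counts.to_numpy(dtype=float) + 0.5)
    if (counts < 0).any():
        raise ValueError("counts must be non-negative")
    alpha = counts + 0.5
    if n_instances == 0:
        point = alpha / alpha.sum(axis=0, keepdims=True)
        return point[:, :, None]
    rng = np.random.default_rng(seed)
    draws = rng.standard_gamma(alpha[:, :, None], size=(*alpha.shape, n_instances))
    return draws / draws.sum(axis=0, keepdims=True)


def clr_transform(probabilities: np.ndarray, denom_features=None) -> np.ndarray:
    """CLR values ln(p) minus the mean ln(p) over the denominator feature set.

    ``denom_features=None`` uses all features (the standard CLR, rows summing
    to zero per sample and instance).
    """
    probabilities = np.asarray(probabilities, dtype=float)
    if (probabilities <= 0).any():
        raise ValueError("probabilities must be strictly positive")
    logs = np.log(probabilities)
    if denom_features is None:
        denom_mean = logs.mean(axis=0, keepdims=True)
    else:
        denom_features = np.asarray(denom_features)
        if denom_features.size == 0:
            raise ValueError("denominator feature set is empty")
        denom_mean = logs[denom_features].mean(axis=0, keepdims=True)
    return logs - denom_mean


def iqlr_features(clr_all: np.ndarray) -> np.ndarray:
    """Features whose CLR variance lies within the interquartile range.

    Variance is taken across samples per instance (sample variance) and
    averaged over instances; quartiles use linear interpolation and the
    [Q1, Q3] bounds are inclusive, so degenerate all-equal variances return
    every feature.
    """
    if clr_all.shape[0] < 4:
        raise ValueError("IQLR needs at least 4 features")
    variances = clr_all.var(axis=1, ddof=1).mean(axis=1)
    q1, q3 = np.quantile(variances, [0.25, 0.75])
    return np.flatnonzero((variances >= q1) & (variances <= q3))


# ---------------------------------------------------------------------------
# effect sizes and tests
# ---------------------------------------------------------------------------


def _pairwise_abs_diffs(group: np.ndarray) -> np.ndarray:
    """|x_i - x_j| over all unordered sample pairs; shape (V, n_pairs, K)."""
    n = group.shape[1]
    if n < 2:
        raise ValueError("each group needs at least 2 samples")
    i, j = np.triu_indices(n, k=1)
    return np.abs(group[:, i, :] - group[:, j, :])


def effect_size(clr_a: np.ndarray, clr_b: np.ndarray) -> dict[str, np.ndarray]:
    """Median standardized difference of group B over group A, per variant.

    Per instance: ``diff_btw`` is the median of all cross-group differences
    (b - a); ``diff_win`` the larger of the two within-group median absolute
    pairwise differences; the instance effect their ratio (with an epsilon
    floor on the denominator: the smallest positive within-group difference in
    the instance, or 1e-8). Reported values are medians over instances; the
    CI spans the 12.5th-87.5th instance percentiles.
    """
    if clr_a.shape[0] != clr_b.shape[0] or clr_a.shape[2] != clr_b.shape[2]:
        raise ValueError("CLR arrays must share variants and instances")
    cross = clr_b[:, None, :, :] - clr_a[:, :, None, :]  # (V, nA, nB, K)
    v, n_a, n_b, k = cross.shape
    diff_btw = np.median(cross.reshape(v, n_a * n_b, k), axis=1)
    pairs_a, pairs_b = _pairwise_abs_diffs(clr_a), _pairwise_abs_diffs(clr_b)
    diff_win = np.maximum(np.median(pairs_a, axis=1), np.median(pairs_b, axis=1))
    all_pairs = np.concatenate([pairs_a, pairs_b], axis=1)
    positive = np.where(all_pairs > 0, all_pairs, np.inf)
    eps = positive.min(axis=(0, 1))  # per instance
    eps = np.where(np.isfinite(eps), eps, _MIN_EPS)
    floored = np.maximum(diff_win, eps[None, :])
    if (diff_win <= 0).any():
        logger.info(
            "effect_size: %d (variant, instance) cells used the epsilon dispersion floor",
            int((diff_win <= 0).sum()),
        )
    effects_k = diff_btw / floored
    ci_low, ci_high = np.percentile(effects_k, EFFECT_CI_PERCENTILES, axis=1)
    return {
        "diff_btw": np.median(diff_btw, axis=1),
        "diff_win": np.median(floored, axis=1),
        "effect": np.median(effects_k, axis=1),
        "ci_low": ci_low,
        "ci_high": ci_high,
        "effects_per_instance": effects_k,
    }


def benjamini_hochberg(pvalues: np.ndarray) -> np.ndarray:
    """BH step-up adjustment along the first axis (variants)."""
    p = np.asarray(pvalues, dtype=float)
    flat = p.ndim == 1
    if flat:
        p = p[:, None]
    m = p.shape[0]
    order = np.argsort(p, axis=0)
    ranked = np.take_along_axis(p, order, axis=0) * m / np.arange(1, m + 1)[:, None]
    adjusted = np.minimum.accumulate(ranked[::-1], axis=0)[::-1]
    adjusted = np.clip(adjusted, 0.0, 1.0)
    out = np.empty_like(adjusted)
    np.put_along_axis(out, order, adjusted, axis=0)
    return out[:, 0] if flat else out


def welch_bh(clr_a: np.ndarray, clr_b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Welch t p-values and BH FDR per variant, averaged over instances.

    Both groups having zero within-group variance in an instance is degenerate:
    the p-value is 1 when the group means are equal and otherwise the standard
    error is floored (logged).
    """
    n_a, n_b = clr_a.shape[1], clr_b.shape[1]
    if n_a < 2 or n_b < 2:
        raise ValueError("each group needs at least 2 samples")
    mean_a, mean_b = clr_a.mean(axis=1), clr_b.mean(axis=1)
    var_a, var_b = clr_a.var(axis=1, ddof=1), clr_b.var(axis=1, ddof=1)
    se2 = var_a / n_a + var_b / n_b
    degenerate = se2 <= 0
    if degenerate.any():
        logger.info("welch_bh: %d degenerate zero-variance cells", int(degenerate.sum()))
    se2_safe = np.where(degenerate, 1e-24, se2)
    t = (mean_b - mean_a) / np.sqrt(se2_safe)
    with np.errstate(divide="ignore", invalid="ignore"):
        df = se2_safe**2 / (
            (var_a / n_a) ** 2 / (n_a - 1) + (var_b / n_b) ** 2 / (n_b - 1)
        )
    df = np.where(np.isfinite(df) & (df > 0), df, n_a + n_b - 2)
    p = 2.0 * stats.t.sf(np.abs(t), df)
    p = np.where(degenerate & (mean_a == mean_b), 1.0, p)
    p = np.clip(p, 0.0, 1.0)
    fdr = benjamini_hochberg(p)
    return p.mean(axis=1), fdr.mean(axis=1)


# ---------------------------------------------------------------------------
# comparison driver
# ---------------------------------------------------------------------------


def run_comparison(
    ln_freqs: FrequencyMatrix,
    sheet: pd.DataFrame,
    comparison: tuple[str, str],
    n_instances: int = DEFAULT_MC_SAMPLES,
    denom: str = "iqlr",
    min_ln: float = -10.0,
    seed: int = 0,
    flip_low_protein: bool = True,
) -> EffectTable:
    """Full effect-size pipeline for one (test, reference) readout comparison.

    Chains the detection mask, CPM closure, Dirichlet instances, CLR with the
    configured denominator, effect sizes (positive = enriched in the test
    readout) and Welch/BH tests. When the test readout is the low-protein flow
    population (``flow_P3``) and ``flip_low_protein`` is set, effects and CI
    bounds are negated so that a negative sign denotes low protein abundance.
    """
    test, ref = comparison
    if ln_freqs.transform != "ln_freq":
        raise ValueError("run_comparison expects ln frequencies (technical-replicate level)")
    if denom not in ("iqlr", "all"):
        raise ValueError(f"unknown denominator mode {denom!r}")
    bio, bio_sheet = summarize_replicates(ln_freqs, sheet, "technical")
    for readout in (test, ref):
        n = (bio_sheet["readout"] == readout).sum()
        if n < 2:
            raise ValueError(f"comparison {test} vs {ref}: {readout} has {n} biological replicates")
    kept = detection_mask(bio, bio_sheet, readouts=[test, ref], min_ln=min_ln)
    if not len(kept):
        raise ValueError("no variants pass the detection mask")
    meta = bio_sheet.set_index("sample_id")
    cols_ref = meta.index[meta["readout"] == ref]
    cols_test = meta.index[meta["readout"] == test]
    raw = FrequencyMatrix(
        np.exp(bio.data.loc[kept, list(cols_ref) + list(cols_test)]), "raw_freq"
    )
    cpm = to_cpm(raw)
    instances = dirichlet_instances(cpm.data, n_instances, seed)
    if denom == "iqlr":
        features = iqlr_features(clr_transform(instances))
    else:
        features = None
    clr = clr_transform(instances, features)
    clr_ref = clr[:, : len(cols_ref), :]
    clr_test = clr[:, len(cols_ref) :, :]
    eff = effect_size(clr_ref, clr_test)
    p, fdr = welch_bh(clr_ref, clr_test)
    sign = -1.0 if (flip_low_protein and test == "flow_P3") else 1.0
    effect = sign * eff["effect"]
    lo, hi = sign * eff["ci_low"], sign * eff["ci_high"]
    if sign < 0:
        lo, hi = hi, lo
    name = f"{test}-vs-{ref}"
    table = pd.DataFrame(
        {
            "variant_id": kept,
            "comparison": name,
            "diff_btw": sign * eff["diff_btw"],
            "diff_win": eff["diff_win"],
            "effect": effect,
            "ci_low": lo,
            "ci_high": hi,
            "p": p,
            "fdr": fdr,
        }
    )
    return EffectTable(comparison=name, table=table)


def fold_change_point_estimate(
    ln_freqs: FrequencyMatrix, group_a, group_b
) -> pd.Series:
    """Per-variant fold change exp(mean ln-frequency difference A - B)."""
    if ln_freqs.transform != "ln_freq":
        raise ValueError("fold_change_point_estimate expects ln frequencies")
    group_a, group_b = list(group_a), list(group_b)
    if not group_a or not group_b:
        raise ValueError("both groups must be non-empty")
    diff = ln_freqs.data[group_a].mean(axis=1) - ln_freqs.data[group_b].mean(axis=1)
    return np.exp(diff).rename("fold_change")


def class_fold_summary(folds: pd.Series, classes: pd.Series) -> pd.DataFrame:
    """Mean and SD of per-variant fold changes within each variant class."""
    aligned = classes.reindex(folds.index)
    grouped = folds.groupby(aligned)
    return pd.DataFrame({"mean": grouped.mean(), "sd": grouped.std(ddof=1), "n": grouped.size()})
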