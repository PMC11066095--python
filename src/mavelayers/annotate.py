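"""Variant annotation and group statistics.

Covers codon-stability-coefficient (CSC) differences between alternate and
reference codons, per-amino-acid aggregation of effect sizes (median over the
codons encoding each substitution), and Wilcoxon rank-sum comparisons between
variant classes. CSC values are per-codon correlations of codon usage with
mRNA stability from external datasets; a synthetic fixture table generator is
provided for self-contained testing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .variants import (
    ALL_CODONS,
    STOP_CODONS,
    classify_variant,  # noqa: F401  (re-exported annotation entry point)
    parse_variant_id,
)

logger = logging.getLogger(__name__)

DEFAULT_EXACT_THRESHOLD = 8  # exact Wilcoxon when max(n, m) <= this and no ties


@dataclass(frozen=True)
class GroupComparison:
    """Wilcoxon rank-sum comparison between two groups."""

    group_a: str
    group_b: str
    statistic: float  # Mann-Whitney U for group A
    p_value: float
    sidedness: str
    exact: bool
    n_a: int
    n_b: int


# ---------------------------------------------------------------------------
# codon stability coefficients
# ---------------------------------------------------------------------------


def read_csc_table(path) -> pd.DataFrame:
    """Read a TSV of (codon, csc, source) rows; 61 sense codons per source."""
    table = pd.read_csv(path, sep="\t", dtype={"codon": str})
    required = {"codon", "csc", "source"}
    if not required.issubset(table.columns):
        raise ValueError(f"CSC table must have columns {sorted(required)}")
    for source, group in table.groupby("source"):
        missing = set(ALL_CODONS) - STOP_CODONS - set(group["codon"])
        if missing:
            raise ValueError(f"CSC source {source!r} missing sense codons: {sorted(missing)[:5]}")
        if not np.isfinite(group["csc"]).all():
            raise ValueError(f"CSC source {source!r} has non-finite values")
    return table


def synthetic_csc_table(seed: int = 0, source: str = "synthetic") -> pd.DataFrame:
    """A synthetic stand-in CSC table (seeded uniform [-0.5, 0.5] per sense codon).

    Real CSC tables come from external mRNA-stability datasets; this fixture
    only exercises the delta/bookkeeping machinery.
    """
    rng = np.random.default_rng(seed)
    codons = sorted(set(ALL_CODONS) - STOP_CODONS)
    return pd.DataFrame(
        {"codon": codons, "csc": rng.uniform(-0.5, 0.5, len(codons)), "source": source}
    )


def csc_delta(ref_codon: str, alt_codon: str, csc_table: pd.DataFrame, source: str | None = None) -> float:
    """CSC(alt) - CSC(ref); NaN (logged) when either codon is a stop."""
    table = csc_table if source is None else csc_table[csc_table["source"] == source]
    lookup = table.set_index("codon")["csc"]
    if alt_codon in STOP_CODONS or ref_codon in STOP_CODONS:
        logger.info("csc_delta: stop codon in %s>%s has no CSC; returning missing", ref_codon, alt_codon)
        return float("nan")
    for codon in (ref_codon, alt_codon):
        if codon not in lookup.index:
            raise KeyError(f"codon {codon} absent from the CSC table")
    return float(lookup[alt_codon] - lookup[ref_codon])


def annotate_effects(
    effect_table: pd.DataFrame,
    csc_table: pd.DataFrame | None = None,
    pause_flags: pd.Series | None = None,
) -> pd.DataFrame:
    """Add class, nt_changes, per-source csc_delta, and pause_overlap columns."""
    out = effect_table.copy()
    parsed = [parse_variant_id(v) for v in out["variant_id"]]
    out["position"] = [p for p, _, _ in parsed]
    classified = [classify_variant(r, a) for _, r, a in parsed]
    out["class"] = [c for c, _ in classified]
    out["nt_changes"] = [n for _, n in classified]
    if csc_table is not None:
        for source, group in csc_table.groupby("source"):
            out[f"csc_delta_{source}"] = [
                csc_delta(r, a, group) for _, r, a in parsed
            ]
    if pause_flags is not None:
        out["pause_overlap"] = (
            pause_flags.reindex(out["variant_id"]).fillna(False).to_numpy(dtype=bool)
        )
    return out


# ---------------------------------------------------------------------------
# aggregation and group tests
# ---------------------------------------------------------------------------


def aggregate_by_aa(
    effect_table: pd.DataFrame, statistic: str = "median"
) -> pd.DataFrame:
    """Position x alternate-amino-acid matrix of aggregated effects.

    Multiple codons encoding the same substitution are reduced by ``statistic``
    (default median); cells never observed are NaN (missing, not zero).
    """
    table = effect_table.copy()
    if "alt_aa" not in table.columns:
        parsed = [parse_variant_id(v) for v in table["variant_id"]]
        from .variants import translate_codon

        table["position"] = [p for p, _, _ in parsed]
        table["alt_aa"] = [translate_codon(a) for _, _, a in parsed]
    return table.pivot_table(
        index="position", columns="alt_aa", values="effect", aggfunc=statistic
    )


def wilcoxon_rank_sum(
    x,
    y,
    sidedness: str = "two-sided",
    exact_threshold: int = DEFAULT_EXACT_THRESHOLD,
) -> GroupComparison:
    """Wilcoxon rank-sum (Mann-Whitney) test.

    Exact p-value by enumeration of rank assignments when both groups are
    small (``max(n, m) <= exact_threshold``) and tie-free; otherwise the
    normal approximation with midrank tie correction and continuity
    correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both groups must be non-empty")
    has_ties = len(np.unique(np.concatenate([x, y]))) < len(x) + len(y)
    exact = max(len(x), len(y)) <= exact_threshold and not has_ties
    result = stats.mannwhitneyu(
        x, y, alternative=sidedness, method="exact" if exact else "asymptotic"
    )
    return GroupComparison(
        group_a="x",
        group_b="y",
        statistic=float(result.statistic),
        p_value=float(min(result.pvalue, 1.0)),
        sidedness=sidedness,
        exact=exact,
        n_a=len(x),
        n_b=len(y),
    )


def class_contrast(
    effect_table: pd.DataFrame,
    class_a: str,
    class_b: str,
    value_col: str = "effect",
    sidedness: str = "two-sided",
    exact_threshold: int = DEFAULT_EXACT_THRESHOLD,
) -> GroupComparison:
    """Wilcoxon comparison of effect sizes between two variant classes."""
    if "class" not in effect_table.columns:
        effect_table = annotate_effects(effect_table)
    values = {}
    for cls in (class_a, class_b):
        sub = effect_table.loc[effect_table["class"] == cls, value_col]
        if not len(sub):
            raise ValueError(f"class {cls!r} absent from the effect table")
        values[cls] = sub.to_numpy()
    comp = wilcoxon_rank_sum(
        values[class_a], values[class_b], sidedness=sidedness, exact_threshold=exact_threshold
    )
    return GroupComparison(
        group_a=class_a,
        group_b=class_b,
        statistic=comp.statistic,
        p_value=comp.p_value,
        sidedness=sidedness,
        exact=comp.exact,
        n_a=comp.n_a,
        n_b=comp.n_b,
    )
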