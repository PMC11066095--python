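"""Count preprocessing: wild-type normalization, filters, batch adjustment,
replicate summaries, and CPM closure.

The recipe converts raw variant counts to per-position wild-type-normalized
frequencies, ``(count + 0.5) / (wt_count + 0.5)``, removes variants below an
absolute frequency floor or indistinguishable from the negative-control
(wild-type plasmid) error background, removes additive batch structure on the
log scale, and summarizes technical replicates into biological replicates (and
biological replicates into layers) by medians.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .containers import CountData, FrequencyMatrix

logger = logging.getLogger(__name__)

DEFAULT_MIN_LOG10_FREQ = -5.8  # absolute detection floor on log10 frequency
DEFAULT_MIN_LN_FREQ = -10.0  # detection-mask floor on median ln frequency


def normalize_to_wildtype(
    counts: pd.DataFrame, wt_counts: pd.DataFrame, positions: pd.Series
) -> FrequencyMatrix:
    """Frequencies as (variant count + 0.5) / (wild-type count + 0.5) per position.

    ``positions`` maps each variant id to its codon position, selecting the
    wild-type denominator row; the +0.5 pseudocounts keep frequencies positive
    and finite.
    """
    missing = positions.index.difference(counts.index)
    if len(missing):
        raise KeyError(f"positions given for unknown variants: {list(missing[:5])}")
    no_pos = counts.index.difference(positions.index)
    if len(no_pos):
        raise KeyError(f"variants without a codon position: {list(no_pos[:5])}")
    bad_pos = set(positions.unique()) - set(wt_counts.index)
    if bad_pos:
        raise KeyError(f"missing wild-type counts for positions: {sorted(bad_pos)[:5]}")
    wt = wt_counts.loc[positions.loc[counts.index]].to_numpy(dtype=float)
    freq = (counts.to_numpy(dtype=float) + 0.5) / (wt + 0.5)
    return FrequencyMatrix(
        pd.DataFrame(freq, index=counts.index, columns=counts.columns), "raw_freq"
    )


def normalize_count_data(data: CountData, positions: pd.Series) -> FrequencyMatrix:
    return normalize_to_wildtype(data.counts, data.wt_counts, positions)


def filter_variants(
    freqs: FrequencyMatrix,
    negctrl_freqs: pd.Series,
    sheet: pd.DataFrame,
    min_log10_freq: float = DEFAULT_MIN_LOG10_FREQ,
    floor_readout: str = "gDNA",
    excluded: pd.Series | None = None,
) -> tuple[FrequencyMatrix, pd.DataFrame]:
    """Drop low-frequency variants and variants at the error background.

    Rules, recorded in a removal log with exactly one first-firing rule per
    removed variant:

    * ``flagged_exclusion`` — ``excluded`` marks the variant True (stands in
      for upstream error-model calls, e.g. sequencing false-positive flags);
    * ``min_frequency`` — the frequency in any ``floor_readout`` sample falls
      at or below the absolute floor ``10**min_log10_freq``;
    * ``below_negctrl`` — the median frequency within some input source
      (readout) is strictly lower than the variant's negative-control
      frequency (equality retains the variant).
    """
    if freqs.transform != "raw_freq":
        raise ValueError("filter_variants expects raw frequencies")
    data = freqs.data
    negctrl_freqs = negctrl_freqs.reindex(data.index)
    if negctrl_freqs.isna().any():
        raise KeyError("negative-control frequencies missing for some variants")
    meta = sheet.set_index("sample_id").loc[data.columns]
    floor = 10.0 ** min_log10_freq
    floor_samples = meta.index[meta["readout"] == floor_readout]
    removed: dict[str, tuple[str, str]] = {}
    if excluded is not None:
        for vid in data.index[excluded.reindex(data.index).fillna(False).astype(bool)]:
            removed[vid] = ("flagged_exclusion", "input")
    if len(floor_samples):
        fails = data[floor_samples].le(floor)
        for vid in data.index[fails.any(axis=1)]:
            sample = fails.columns[fails.loc[vid]][0]
            removed[vid] = ("min_frequency", sample)
    for readout, group in meta.groupby("readout", sort=True):
        if readout == "negctrl":
            continue
        source_median = data[group.index].median(axis=1)
        low = source_median < negctrl_freqs
        for vid in data.index[low]:
            removed.setdefault(vid, ("below_negctrl", str(readout)))
    keep = data.index.difference(removed, sort=False)
    log = pd.DataFrame(
        [(vid, rule, src) for vid, (rule, src) in removed.items()],
        columns=["variant_id", "rule", "source"],
    )
    logger.info("filter_variants: %d -> %d variants (%d removed)", len(data), len(keep), len(log))
    if not len(keep):
        logger.warning("filter_variants removed every variant")
    return FrequencyMatrix(data.loc[keep], "raw_freq"), log


def batch_adjust(
    ln_freqs: FrequencyMatrix,
    batches: pd.Series,
    preserve_groups: pd.Series | None = None,
) -> FrequencyMatrix:
    """Location-only batch adjustment on ln frequencies.

    Per variant, per batch, the batch mean (of residuals after removing group
    means when ``preserve_groups`` is given) is subtracted and the grand mean
    restored, leaving zero between-batch mean difference for every variant.
    A batch with a single sample is adjusted like any other (location shifts
    only; no scale adjustment is attempted).
    """
    if ln_freqs.transform != "ln_freq":
        raise ValueError("batch_adjust expects ln frequencies")
    data = ln_freqs.data
    batches = batches.reindex(data.columns)
    if batches.isna().any():
        raise KeyError("batch labels missing for some samples")
    values = data.to_numpy(dtype=float)
    if preserve_groups is not None:
        groups = preserve_groups.reindex(data.columns)
        if groups.isna().any():
            raise KeyError("group labels missing for some samples")
        confounded = (
            pd.crosstab(groups, batches).gt(0).sum(axis=1).eq(1).all() and batches.nunique() > 1
        )
        if confounded:
            raise ValueError("preserve_groups is confounded with batch")
        group_means = data.T.groupby(groups).mean().T
        resid = values - group_means.loc[:, groups].to_numpy()
    else:
        resid = values
    resid_df = pd.DataFrame(resid, index=data.index, columns=data.columns)
    batch_means = resid_df.T.groupby(batches).mean().T  # variants x batches
    shift = batch_means.loc[:, batches].to_numpy()
    grand = resid.mean(axis=1, keepdims=True)
    adjusted = values - shift + grand
    return FrequencyMatrix(
        pd.DataFrame(adjusted, index=data.index, columns=data.columns), "ln_freq"
    )


def summarize_replicates(
    freqs: FrequencyMatrix, sheet: pd.DataFrame, level: str
) -> tuple[FrequencyMatrix, pd.DataFrame]:
    """Median-summarize one replicate level.

    ``level="technical"`` takes medians across technical replicates within each
    (readout, biological replicate), yielding columns ``<readout>_b<k>``;
    ``level="biological"`` takes medians across biological replicates within
    each readout, yielding one column per readout. Even-sized groups use the
    mean of the two central values. Returns the summarized matrix and the
    sample sheet of the coarser unit.
    """
    meta = sheet.set_index("sample_id").loc[freqs.data.columns]
    if level == "technical":
        keys = ["readout", "bio_rep"]
        name = lambda readout, bio: f"{readout}_b{bio}"  # noqa: E731
    elif level == "biological":
        keys = ["readout"]
        name = lambda readout: str(readout)  # noqa: E731
    else:
        raise ValueError(f"unknown summarization level {level!r}")
    cols, rows, out = [], [], []
    for key, group in meta.groupby(keys, sort=True):
        if not len(group):
            raise ValueError(f"replicate group {key} has zero members")
        key = key if isinstance(key, tuple) else (key,)
        cols.append(name(*key))
        out.append(freqs.data[group.index].median(axis=1))
        row = dict(zip(keys, key))
        row["sample_id"] = cols[-1]
        row["batch"] = "|".join(sorted(set(group["batch"]))) if "batch" in group else ""
        rows.append(row)
    summarized = pd.concat(out, axis=1)
    summarized.columns = cols
    return FrequencyMatrix(summarized, freqs.transform), pd.DataFrame(rows)


def to_cpm(freqs: FrequencyMatrix) -> FrequencyMatrix:
    """Close each sample column to one million (idempotent)."""
    if freqs.transform == "cpm":
        return FrequencyMatrix(freqs.data.copy(), "cpm")
    if freqs.transform != "raw_freq":
        raise ValueError("to_cpm expects raw frequencies")
    sums = freqs.data.sum(axis=0)
    zero = sums.index[sums <= 0]
    if len(zero):
        raise ValueError(f"all-zero sample columns: {list(zero)}")
    return FrequencyMatrix(freqs.data * 1e6 / sums, "cpm")


def detection_mask(
    ln_freqs: FrequencyMatrix,
    sheet: pd.DataFrame,
    readouts,
    min_ln: float = DEFAULT_MIN_LN_FREQ,
) -> pd.Index:
    """Variants detected in every biological replicate of every given readout.

    A variant passes when its median ln frequency across technical replicates
    is strictly greater than ``min_ln`` in each (readout, biological
    replicate) group; missing a readout entirely drops the variant.
    """
    if ln_freqs.transform != "ln_freq":
        raise ValueError("detection_mask expects ln frequencies")
    meta = sheet.set_index("sample_id").loc[ln_freqs.data.columns]
    keep = pd.Series(True, index=ln_freqs.data.index)
    for readout in readouts:
        sub = meta[meta["readout"] == readout]
        if not len(sub):
            raise ValueError(f"no samples for readout {readout!r}")
        for _, group in sub.groupby("bio_rep"):
            med = ln_freqs.data[group.index].median(axis=1)
            keep &= med > min_ln
    return ln_freqs.data.index[keep]
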