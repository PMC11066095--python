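"""Shared in-memory containers for the pipeline stages."""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

#: readout layers in canonical order
READOUTS = (
    "negctrl",
    "gDNA",
    "totalRNA",
    "polysome_F1",
    "polysome_F2",
    "polysome_F3",
    "polysome_F4",
    "flow_P1",
    "flow_P2",
    "flow_P3",
    "flow_P4",
)

#: readouts excluded from analysis in the study design (low library yield)
LOW_YIELD_READOUTS = ("polysome_F1", "polysome_F2", "flow_P4")

VALID_TRANSFORMS = ("raw_freq", "ln_freq", "cpm")


@dataclass
class CountData:
    """Variant-by-sample integer counts plus per-position wild-type counts.

    ``counts`` is indexed by variant id; ``wt_counts`` by 1-based codon
    position. Both share the same sample columns.
    """

    counts: pd.DataFrame
    wt_counts: pd.DataFrame

    def __post_init__(self) -> None:
        if list(self.counts.columns) != list(self.wt_counts.columns):
            raise ValueError("counts and wt_counts must share sample columns")

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)


@dataclass
class FrequencyMatrix:
    """Variants x samples real matrix with a transform tag.

    ``raw_freq`` holds wild-type-normalized frequencies (strictly positive),
    ``ln_freq`` their natural logs, and ``cpm`` per-sample closures to 1e6.
    """

    data: pd.DataFrame
    transform: str = "raw_freq"

    def __post_init__(self) -> None:
        if self.transform not in VALID_TRANSFORMS:
            raise ValueError(f"unknown transform tag {self.transform!r}")

    @property
    def variants(self) -> pd.Index:
        return self.data.index

    @property
    def samples(self) -> list[str]:
        return list(self.data.columns)


@dataclass
class EffectTable:
    """Per-variant compositional effect results for one layer comparison."""

    comparison: str
    table: pd.DataFrame = field(repr=False)

    COLUMNS = (
        "variant_id",
        "comparison",
        "diff_btw",
        "diff_win",
        "effect",
        "ci_low",
        "ci_high",
        "p",
        "fdr",
    )
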