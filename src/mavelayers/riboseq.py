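"""Ribosome-footprint profiles, site-offset adjustment, and pause calling.

A profile holds per-nucleotide counts of ribosome-protected-fragment (RPF)
5' ends on a transcript (0-based positions, half-open coding interval). The 5'
end plus a fixed offset locates the decoded ribosomal site: the A-site offset
is 16 nt (determined from stop-codon metagene profiles in the source assay),
and the P and E sites trail the A site by one and two codons (-3 and -6 nt).
Pause positions are those whose counts-per-million signal strictly exceeds a
percentile (default the 90th) of the CPM distribution across the coding
region.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: nt offset from the RPF 5' end to each ribosomal site, relative to A = 16
SITE_OFFSETS_FROM_A = {"A": 0, "P": -3, "E": -6}
DEFAULT_A_OFFSET = 16
FOOTPRINT_LENGTH_WINDOW = (28, 35)  # inclusive length filter of the assay


@dataclass
class RpfProfile:
    """Per-nucleotide RPF 5'-end counts over a transcript."""

    counts: np.ndarray  # float, length = transcript length in nt
    cds_start: int  # 0-based, inclusive
    cds_end: int  # 0-based, exclusive
    norm: str = "raw"  # "raw" | "cpm"
    a_offset: int = DEFAULT_A_OFFSET

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 1:
            raise ValueError("profile counts must be one-dimensional")
        if np.any(self.counts < 0):
            raise ValueError("profile counts must be non-negative")
        if not (0 <= self.cds_start <= self.cds_end <= len(self.counts)):
            raise ValueError("coding interval outside the profile")
        if self.norm not in ("raw", "cpm"):
            raise ValueError(f"unknown normalization tag {self.norm!r}")
        if self.a_offset < 0:
            raise ValueError("site offsets must be non-negative")

    def site_offset(self, site: str) -> int:
        if site not in SITE_OFFSETS_FROM_A:
            raise ValueError(f"unknown ribosomal site {site!r}; expected A, P or E")
        offset = self.a_offset + SITE_OFFSETS_FROM_A[site]
        if offset < 0:
            raise ValueError(f"{site}-site offset is negative for A-offset {self.a_offset}")
        return offset


def cpm_normalize(profile: RpfProfile) -> RpfProfile:
    """Rescale counts to counts per million; idempotent on tagged CPM input."""
    if profile.norm == "cpm":
        return replace(profile, counts=profile.counts.copy())
    total = profile.counts.sum()
    if total <= 0:
        raise ValueError("cannot CPM-normalize an all-zero profile")
    return replace(profile, counts=profile.counts * 1e6 / total, norm="cpm")


def offset_adjust(profile: RpfProfile, site: str = "A") -> RpfProfile:
    """Attribute each 5'-end count to its decoded nt position (x + offset).

    Counts shifted beyond the transcript end are dropped and the dropped total
    is logged.
    """
    offset = profile.site_offset(site)
    n = len(profile.counts)
    shifted = np.zeros(n, dtype=float)
    if offset < n:
        shifted[offset:] = profile.counts[: n - offset]
    dropped = profile.counts[max(n - offset, 0):].sum()
    if dropped > 0:
        logger.info("offset_adjust(%s): dropped %.6g counts shifted past the 3' end", site, dropped)
    return replace(profile, counts=shifted)


def call_pauses(profile: RpfProfile, percentile: float = 90.0) -> pd.DataFrame:
    """Positions whose CPM strictly exceeds the CDS-wide percentile threshold.

    Returns a frame with columns ``position`` (0-based nt), ``codon`` (0-based
    index within the coding region), and ``cpm``. The threshold percentile is
    computed with linear interpolation over all coding positions, and
    "exceeds" is strict, so an all-equal profile yields no calls.
    """
    if profile.norm != "cpm":
        raise ValueError("call_pauses expects a CPM-normalized profile")
    if not 0 < percentile < 100:
        raise ValueError("percentile must be in (0, 100)")
    if profile.cds_end <= profile.cds_start:
        raise ValueError("empty coding region")
    cds = profile.counts[profile.cds_start : profile.cds_end]
    threshold = float(np.percentile(cds, percentile))
    positions = profile.cds_start + np.flatnonzero(cds > threshold)
    return pd.DataFrame(
        {
            "position": positions,
            "codon": (positions - profile.cds_start) // 3,
            "cpm": profile.counts[positions],
        }
    )


def pause_overlap(
    pause_codons,
    variant_positions,
    sites: tuple[str, ...] = ("A", "P", "E"),
    n_codons: int | None = None,
) -> pd.Series:
    """Flag variants whose codon coincides with a called pause under any site placement.

    ``pause_codons`` and ``variant_positions`` must share one codon coordinate
    system (tag offsets already removed). A pause called at codon ``c`` flags a
    variant at codon ``c`` (A-site placement), ``c + 1`` (P) or ``c + 2`` (E).
    """
    shifts = {"A": 0, "P": 1, "E": 2}
    unknown = set(sites) - set(shifts)
    if unknown:
        raise ValueError(f"unknown sites {sorted(unknown)}")
    variant_positions = pd.Series(variant_positions)
    if n_codons is not None and (variant_positions > n_codons).any():
        bad = variant_positions[variant_positions > n_codons]
        raise ValueError(f"variant codons beyond the CDS: {sorted(bad.unique())}")
    flagged = set()
    for c in set(pause_codons):
        for site in sites:
            flagged.add(c + shifts[site])
    return variant_positions.isin(flagged)
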