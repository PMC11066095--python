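"""Variant records and genetic-code classification.

A library member is one codon substitution in a coding sequence, identified as
``c<position>.<ref>><alt>`` where the position is the 1-based codon index in
the protein frame (any epitope-tag offset already removed). Classification
against the standard genetic code yields the three variant classes used
throughout the pipeline: silent (synonymous), missense, and nonsense (premature
stop; only the amber codon TAG is admitted into libraries).
"""

from __future__ import annotations

import re
from dataclasses import dataclass

from Bio.Data.CodonTable import standard_dna_table

NUCLEOTIDES = "ACGT"
STOP_CODONS = frozenset(standard_dna_table.stop_codons)  # TAA, TAG, TGA
AMBER_CODON = "TAG"

#: codon -> amino acid (one letter), stop codons map to "*"
GENETIC_CODE = dict(standard_dna_table.forward_table)
GENETIC_CODE.update({codon: "*" for codon in STOP_CODONS})

ALL_CODONS = tuple(sorted(GENETIC_CODE))

_VARIANT_ID_RE = re.compile(r"^c(\d+)\.([ACGT]{3})>([ACGT]{3})$")


@dataclass(frozen=True)
class VariantRecord:
    """One library member: a single-codon substitution."""

    variant_id: str
    position: int  # 1-based codon position in the protein frame
    ref_codon: str
    alt_codon: str
    ref_aa: str
    alt_aa: str
    vclass: str  # "silent" | "missense" | "nonsense"
    nt_changes: int  # Hamming distance 1-3; 1 => SNP, >=2 => MNP
    roi: str = ""


def _check_codon(codon: str, *, what: str) -> None:
    if len(codon) != 3:
        raise ValueError(f"{what} codon {codon!r} must have length 3")
    if any(nt not in NUCLEOTIDES for nt in codon):
        raise ValueError(f"{what} codon {codon!r} contains non-ACGT characters")


def translate_codon(codon: str) -> str:
    """Amino acid (one letter) for ``codon``; ``*`` for a stop codon."""
    _check_codon(codon, what="query")
    return GENETIC_CODE[codon]


def classify_variant(ref_codon: str, alt_codon: str) -> tuple[str, int]:
    """Classify a codon substitution and count its nucleotide mismatches.

    Returns ``(vclass, nt_changes)`` where ``vclass`` is ``silent`` when both
    codons encode the same amino acid, ``nonsense`` when the alternate codon is
    a stop, and ``missense`` otherwise. The reference codon must be a sense
    codon.
    """
    ref_codon = ref_codon.upper()
    alt_codon = alt_codon.upper()
    _check_codon(ref_codon, what="reference")
    _check_codon(alt_codon, what="alternate")
    if ref_codon in STOP_CODONS:
        raise ValueError(f"reference codon {ref_codon} is a stop codon")
    if ref_codon == alt_codon:
        raise ValueError("alternate codon equals the reference codon")
    nt_changes = sum(a != b for a, b in zip(ref_codon, alt_codon))
    if alt_codon in STOP_CODONS:
        vclass = "nonsense"
    elif GENETIC_CODE[alt_codon] == GENETIC_CODE[ref_codon]:
        vclass = "silent"
    else:
        vclass = "missense"
    return vclass, nt_changes


def make_variant_id(position: int, ref_codon: str, alt_codon: str) -> str:
    return f"c{position}.{ref_codon}>{alt_codon}"


def parse_variant_id(variant_id: str) -> tuple[int, str, str]:
    """Split ``c<pos>.<ref>><alt>`` into ``(position, ref_codon, alt_codon)``."""
    m = _VARIANT_ID_RE.match(variant_id)
    if m is None:
        raise ValueError(f"malformed variant id {variant_id!r}")
    return int(m.group(1)), m.group(2), m.group(3)


def make_variant_record(
    position: int, ref_codon: str, alt_codon: str, roi: str = ""
) -> VariantRecord:
    vclass, nt_changes = classify_variant(ref_codon, alt_codon)
    return VariantRecord(
        variant_id=make_variant_id(position, ref_codon, alt_codon),
        position=position,
        ref_codon=ref_codon,
        alt_codon=alt_codon,
        ref_aa=GENETIC_CODE[ref_codon],
        alt_aa=GENETIC_CODE[alt_codon],
        vclass=vclass,
        nt_changes=nt_changes,
        roi=roi,
    )


def synonymous_codons(codon: str) -> list[str]:
    """All sense codons encoding the same amino acid as ``codon`` (inclusive)."""
    aa = translate_codon(codon)
    if aa == "*":
        raise ValueError("stop codons have no synonymous sense codons")
    return [c for c in ALL_CODONS if GENETIC_CODE[c] == aa]
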