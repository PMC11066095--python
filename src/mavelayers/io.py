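"""On-disk formats, configuration, and design validation.

All tabular artifacts are TSV: count matrices (first column the variant id
``c<pos>.<ref>><alt>``), per-position wild-type counts, sample sheets, truth
tables, effect tables (fixed column set), and two-column RPF profiles
(0-based nt position, count). The template CDS travels as FASTA, pause calls
as BED (0-based half-open transcript coordinates). The pipeline configuration
is a flat ``key = value`` text file with a fixed schema; unknown keys are
errors so typos cannot silently fall back to defaults.
"""

from __future__ import annotations

import dataclasses
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .containers import LOW_YIELD_READOUTS, READOUTS, CountData
from .riboseq import RpfProfile

logger = logging.getLogger(__name__)

SAMPLE_SHEET_COLUMNS = ("sample_id", "readout", "bio_rep", "tech_rep", "batch")
EFFECT_COLUMNS = (
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


# ---------------------------------------------------------------------------
# count matrices and sample sheets
# ---------------------------------------------------------------------------


def read_count_matrix(path) -> pd.DataFrame:
    """Variants x samples non-negative integer matrix from TSV."""
    try:
        table = pd.read_csv(path, sep="\t", index_col=0)
    except pd.errors.EmptyDataError:
        raise ValueError(f"{path}: no variants (empty file)") from None
    if table.shape[0] == 0:
        raise ValueError(f"{path}: no variants")
    if table.index.duplicated().any():
        dupes = table.index[table.index.duplicated()].unique()
        raise ValueError(f"{path}: duplicate variant IDs: {list(dupes[:5])}")
    for col in table.columns:
        values = table[col]
        if values.isna().any():
            bad = values.index[values.isna()][0]
            raise ValueError(f"{path}: missing cell (ragged row?) at row {bad!r}, column {col!r}")
        if not np.issubdtype(values.dtype, np.number) or not (values == values.astype(np.int64)).all():
            bad = values.index[~values.apply(lambda v: float(v).is_integer())][:1]
            raise ValueError(f"{path}: non-integer count at row {bad[0]!r}, column {col!r}")
        negative = values.index[values < 0]
        if len(negative):
            raise ValueError(f"{path}: negative count at row {negative[0]!r}, column {col!r}")
    table.index.name = "variant_id"
    return table.astype(np.int64)


def write_count_matrix(matrix: pd.DataFrame, path) -> None:
    matrix.to_csv(path, sep="\t", index_label=matrix.index.name or "variant_id")


def read_wt_counts(path) -> pd.DataFrame:
    table = read_count_matrix(path)
    table.index = table.index.astype(int)
    table.index.name = "position"
    return table


def read_count_data(counts_path, wt_path) -> CountData:
    return CountData(counts=read_count_matrix(counts_path), wt_counts=read_wt_counts(wt_path))


def read_sample_sheet(path) -> pd.DataFrame:
    sheet = pd.read_csv(path, sep="\t", dtype={"batch": str})
    missing = set(SAMPLE_SHEET_COLUMNS) - set(sheet.columns)
    if missing:
        raise ValueError(f"{path}: sample sheet missing columns {sorted(missing)}")
    if sheet["sample_id"].duplicated().any():
        raise ValueError(f"{path}: duplicate sample_id entries")
    unknown = set(sheet["readout"]) - set(READOUTS)
    if unknown:
        raise ValueError(f"{path}: unknown readouts {sorted(unknown)}")
    return sheet


def write_sample_sheet(sheet: pd.DataFrame, path) -> None:
    sheet.to_csv(path, sep="\t", index=False)


def write_effect_table(table: pd.DataFrame, path) -> None:
    table[list(EFFECT_COLUMNS)].to_csv(path, sep="\t", index=False)


def read_effect_table(path) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t")
    missing = set(EFFECT_COLUMNS) - set(table.columns)
    if missing:
        raise ValueError(f"{path}: effect table missing columns {sorted(missing)}")
    return table


# ---------------------------------------------------------------------------
# sequences and profiles
# ---------------------------------------------------------------------------


def read_template_cds(path) -> str:
    records = list(SeqIO.parse(str(path), "fasta"))
    if len(records) != 1:
        raise ValueError(f"{path}: expected exactly one FASTA record, found {len(records)}")
    return str(records[0].seq).upper()


def write_template_cds(sequence: str, path, name: str = "template_cds") -> None:
    SeqIO.write([SeqRecord(Seq(sequence), id=name, description="")], str(path), "fasta")


def read_rpf_profile(path, cds_start: int, cds_end: int, a_offset: int = 16) -> RpfProfile:
    table = pd.read_csv(path, sep="\t")
    if list(table.columns[:2]) != ["position", "count"]:
        raise ValueError(f"{path}: RPF profile needs columns (position, count)")
    n = int(table["position"].max()) + 1
    counts = np.zeros(n)
    counts[table["position"].to_numpy()] = table["count"].to_numpy(dtype=float)
    return RpfProfile(counts=counts, cds_start=cds_start, cds_end=cds_end, a_offset=a_offset)


def write_rpf_profile(profile: RpfProfile, path) -> None:
    pd.DataFrame(
        {"position": np.arange(len(profile.counts)), "count": profile.counts}
    ).to_csv(path, sep="\t", index=False)


def write_pause_bed(pauses: pd.DataFrame, path, transcript: str = "transcript") -> None:
    """Pause calls as BED: 0-based half-open nt intervals with CPM scores."""
    with open(path, "w") as handle:
        for _, row in pauses.iterrows():
            handle.write(
                f"{transcript}\t{int(row['position'])}\t{int(row['position']) + 1}"
                f"\tpause_codon_{int(row['codon'])}\t{row['cpm']:.4f}\n"
            )


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------


def _parse_bool(text: str) -> bool:
    if text.lower() in ("true", "yes", "1"):
        return True
    if text.lower() in ("false", "no", "0"):
        return False
    raise ValueError(f"not a boolean: {text!r}")


@dataclass
class PipelineConfig:
    """Flat pipeline configuration with the study's defaults."""

    # simulation
    seed: int = 0
    depth: int = 1_000_000
    n_bio_reps: int = 4
    n_tech_reps: int = 4
    overdispersion: float = 1e7
    batch_sd: float = 0.15
    baseline: str = "equimolar"
    wildtype_mass: float = 0.9
    layers: tuple = ("negctrl", "gDNA", "totalRNA", "polysome_F4", "flow_P3")
    # preprocessing
    min_log10_freq: float = -5.8
    min_ln_freq: float = -10.0
    # effect engine
    mc_samples: int = 128
    denom: str = "iqlr"
    comparisons: tuple = ("totalRNA-vs-gDNA", "polysome_F4-vs-totalRNA", "flow_P3-vs-gDNA")
    flip_low_protein: bool = True
    # clustering
    som_rows: int = 13
    som_cols: int = 20
    som_epochs: int = 100
    som_seeds: int = 20
    ap_q: float = 0.1
    ap_damping: float = 0.9
    # pause calling
    pause_percentile: float = 90.0
    a_offset: int = 16

    _PARSERS = {
        "seed": int,
        "depth": int,
        "n_bio_reps": int,
        "n_tech_reps": int,
        "overdispersion": float,
        "batch_sd": float,
        "baseline": str,
        "wildtype_mass": float,
        "layers": lambda s: tuple(x.strip() for x in s.split(",") if x.strip()),
        "min_log10_freq": float,
        "min_ln_freq": float,
        "mc_samples": int,
        "denom": str,
        "comparisons": lambda s: tuple(x.strip() for x in s.split(",") if x.strip()),
        "flip_low_protein": _parse_bool,
        "som_rows": int,
        "som_cols": int,
        "som_epochs": int,
        "som_seeds": int,
        "ap_q": float,
        "ap_damping": float,
        "pause_percentile": float,
        "a_offset": int,
    }

    def __post_init__(self) -> None:
        if self.som_rows < 2 or self.som_cols < 2:
            raise ValueError("SOM grid must be at least 2x2")
        if self.mc_samples < 0:
            raise ValueError("mc_samples must be >= 0")
        for name in ("min_log10_freq", "min_ln_freq", "batch_sd", "wildtype_mass"):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")
        for comparison in self.comparisons:
            if "-vs-" not in comparison:
                raise ValueError(f"malformed comparison {comparison!r} (expected test-vs-ref)")

    def comparison_pairs(self) -> list[tuple[str, str]]:
        return [tuple(c.split("-vs-", 1)) for c in self.comparisons]

    def as_dict(self) -> dict:
        out = dataclasses.asdict(self)
        out["layers"] = ",".join(self.layers)
        out["comparisons"] = ",".join(self.comparisons)
        return out


def read_config(path) -> PipelineConfig:
    """Parse a flat ``key = value`` config file; unknown keys are errors."""
    overrides = {}
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"{path}:{lineno}: expected 'key = value', got {raw!r}")
        key, value = (part.strip() for part in line.split("=", 1))
        if key not in PipelineConfig._PARSERS:
            raise ValueError(f"{path}:{lineno}: unknown configuration key {key!r}")
        overrides[key] = PipelineConfig._PARSERS[key](value)
    return PipelineConfig(**overrides)


def write_config(config: PipelineConfig, path) -> None:
    lines = [f"{key} = {value}" for key, value in config.as_dict().items()]
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# design validation
# ---------------------------------------------------------------------------


def validate_design(
    counts: pd.DataFrame, sheet: pd.DataFrame, config: PipelineConfig
) -> pd.DataFrame:
    """Check that sheet metadata covers the matrix and comparisons are satisfiable.

    Readouts the study design dropped for low library yield (first two
    polysome metafractions, flow population 4) trigger a warning but still
    run. Returns the sheet restricted to the matrix columns.
    """
    orphan = [c for c in counts.columns if c not in set(sheet["sample_id"])]
    if orphan:
        raise ValueError(f"sample columns without sheet metadata: {orphan[:5]}")
    meta = sheet.set_index("sample_id").loc[counts.columns]
    for test, ref in config.comparison_pairs():
        for readout in (test, ref):
            if readout in LOW_YIELD_READOUTS:
                warnings.warn(
                    f"readout {readout} was excluded from the source analysis for low "
                    "library yield; proceeding anyway",
                    stacklevel=2,
                )
            n_bio = meta.loc[meta["readout"] == readout, "bio_rep"].nunique()
            if n_bio < 2:
                raise ValueError(
                    f"comparison {test}-vs-{ref} unsatisfiable: readout {readout} has "
                    f"{n_bio} biological replicates (need >= 2)"
                )
    return meta.reset_index()
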