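"""Synthetic variant libraries, multi-layer count matrices, and RPF profiles.

The generator emulates the count structure of a saturation codon-mutagenesis
experiment read out across gene-expression layers: a library of all silent and
missense alternate codons plus one amber nonsense codon at each position of
two regions of interest (ROIs), sequenced as variant counts per sample for a
negative-control plasmid, gDNA, total RNA, polysome metafractions and
flow-sorted populations, with technical/biological replicates and batch
structure. Ground-truth multiplicative effects per layer are recorded so that
downstream estimators can be checked for parameter recovery.

The statistical model per sample is Dirichlet-multinomial: expected variant
proportions are baseline library frequencies times layer effects times
per-batch lognormal factors, renormalized with the wild-type remainder, then
overdispersed by a Dirichlet draw (concentration = overdispersion x expected
proportions) and counted multinomially at the configured depth, so each sample
column sums exactly to the depth.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import CountData
from .riboseq import DEFAULT_A_OFFSET, FOOTPRINT_LENGTH_WINDOW, RpfProfile
from .variants import (
    AMBER_CODON,
    ALL_CODONS,
    STOP_CODONS,
    VariantRecord,
    make_variant_record,
)

logger = logging.getLogger(__name__)

#: layers simulated by default: the readouts retained for analysis
DEFAULT_LAYERS = ("negctrl", "gDNA", "totalRNA", "polysome_F3", "polysome_F4", "flow_P1", "flow_P3")


# ---------------------------------------------------------------------------
# library design
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LibraryDesign:
    """Mutagenesis design: ROIs (1-based codon spans) over a template CDS."""

    roi_list: tuple[tuple[str, int, int], ...]
    template_cds: str
    nonsense_codon: str = AMBER_CODON

    def __post_init__(self) -> None:
        cds = self.template_cds.upper()
        object.__setattr__(self, "template_cds", cds)
        if len(cds) % 3 != 0:
            raise ValueError("template CDS length must be divisible by 3")
        n_codons = len(cds) // 3
        for i in range(n_codons - 1):  # terminal stop is allowed
            if cds[3 * i : 3 * i + 3] in STOP_CODONS:
                raise ValueError(f"template contains an internal stop at codon {i + 1}")
        if self.nonsense_codon not in STOP_CODONS:
            raise ValueError(f"nonsense codon {self.nonsense_codon!r} is not a stop codon")
        spans = []
        for name, first, last in self.roi_list:
            if not 1 <= first <= last <= n_codons:
                raise ValueError(f"ROI {name} [{first}, {last}] outside template ({n_codons} codons)")
            spans.append((first, last, name))
        spans.sort()
        for (_, last_a, name_a), (first_b, _, name_b) in zip(spans, spans[1:]):
            if first_b <= last_a:
                raise ValueError(f"ROIs {name_a} and {name_b} overlap")

    def ref_codon(self, position: int) -> str:
        return self.template_cds[3 * (position - 1) : 3 * position]

    def roi_positions(self) -> list[tuple[int, str]]:
        """(position, roi_name) for every codon position under mutagenesis."""
        out = []
        for name, first, last in self.roi_list:
            out.extend((pos, name) for pos in range(first, last + 1))
        out.sort()
        return out


def _random_sense_cds(n_codons: int, rng: np.random.Generator) -> str:
    sense = [c for c in ALL_CODONS if c not in STOP_CODONS]
    codons = rng.choice(sense, size=n_codons, replace=True)
    return "".join(codons)


def default_library_design(seed: int = 7) -> LibraryDesign:
    """Two ROIs of 35 + 23 = 58 codon positions over a random sense template.

    The template is a seeded random coding sequence (no internal stops); the
    ROI spans mirror a typical early-CDS mutagenesis layout.
    """
    rng = np.random.default_rng(seed)
    template = _random_sense_cds(180, rng)
    return LibraryDesign(roi_list=(("ROI1", 40, 74), ("ROI2", 136, 158)), template_cds=template)


def generate_variant_library(design: LibraryDesign) -> list[VariantRecord]:
    """Every silent/missense alternate codon plus one amber nonsense per ROI position.

    At each position the 63 non-reference codons minus the two non-amber stop
    codons are emitted (61 records for a sense reference).
    """
    excluded_stops = STOP_CODONS - {design.nonsense_codon}
    records = []
    for position, roi in design.roi_positions():
        ref = design.ref_codon(position)
        if ref in STOP_CODONS:
            raise ValueError(f"reference codon at position {position} is a stop codon")
        for alt in ALL_CODONS:
            if alt == ref or alt in excluded_stops:
                continue
            records.append(make_variant_record(position, ref, alt, roi=roi))
    return records


# ---------------------------------------------------------------------------
# ground truth
# ---------------------------------------------------------------------------


@dataclass
class TruthTable:
    """Per-variant, per-layer multiplicative effects plus baseline frequencies.

    Effects are dimensionless folds applied to the variant's baseline library
    frequency in that layer; baseline frequencies are simplex weights summing
    to at most 1, the remainder being wild-type template mass.
    """

    effects: pd.DataFrame  # variants x layers, strictly positive
    baseline: pd.Series  # variant -> simplex weight
    wildtype_mass: float
    library: list[VariantRecord] = field(repr=False)

    def __post_init__(self) -> None:
        if (self.effects.values <= 0).any():
            raise ValueError("effects must be strictly positive")
        if (self.baseline <= 0).any():
            raise ValueError("baseline frequencies must be strictly positive")
        total = float(self.baseline.sum())
        if total > 1 + 1e-9:
            raise ValueError("baseline frequencies must sum to <= 1")
        if not np.isclose(total + self.wildtype_mass, 1.0, atol=1e-9):
            raise ValueError("baseline sum plus wild-type mass must equal 1")

    @property
    def classes(self) -> pd.Series:
        return pd.Series({r.variant_id: r.vclass for r in self.library}, name="class")

    @property
    def positions(self) -> pd.Series:
        return pd.Series({r.variant_id: r.position for r in self.library}, name="position")

    def log_folds(self, layer: str) -> pd.Series:
        return np.log(self.effects[layer])


def _resolve_selector(selector, library: list[VariantRecord]) -> list[str]:
    by_class = {"silent", "missense", "nonsense"}
    if selector == "all":
        return [r.variant_id for r in library]
    if selector in by_class:
        return [r.variant_id for r in library if r.vclass == selector]
    if isinstance(selector, str):
        ids = {r.variant_id for r in library}
        if selector not in ids:
            raise KeyError(f"unknown variant or class selector {selector!r}")
        return [selector]
    return list(selector)


def assign_truth(
    library: list[VariantRecord],
    effect_spec: dict | None,
    seed: int,
    layers: tuple[str, ...] = DEFAULT_LAYERS,
    baseline: str | np.ndarray = "uniform",
    baseline_sigma: float = 0.15,
    wildtype_mass: float = 0.9,
) -> TruthTable:
    """Build a ground-truth table from a class/variant -> layer -> fold spec.

    ``effect_spec`` maps a selector (variant class name, ``"all"``, a variant
    id, or an explicit id list) to a ``{layer: fold}`` mapping; folds may be a
    positive float or ``{"dist": "lognormal", "sigma": s[, "mu": m]}`` for
    per-variant random folds. Unlisted cells default to 1.0 (no effect). Later
    spec entries overwrite earlier ones cell-wise.

    Baseline frequencies are drawn uniform on the simplex (``"uniform"``),
    near-equimolar with lognormal spread (``"equimolar"``), or supplied as an
    array; they are scaled to ``1 - wildtype_mass``.
    """
    if not library:
        raise ValueError("empty variant library")
    if not 0 <= wildtype_mass < 1:
        raise ValueError("wildtype_mass must be in [0, 1)")
    rng = np.random.default_rng(seed)
    ids = [r.variant_id for r in library]
    effects = pd.DataFrame(1.0, index=pd.Index(ids, name="variant_id"), columns=list(layers))
    for selector, layer_folds in (effect_spec or {}).items():
        targets = _resolve_selector(selector, library)
        for layer, fold in layer_folds.items():
            if layer not in effects.columns:
                raise KeyError(f"layer {layer!r} not among simulated layers {list(layers)}")
            if isinstance(fold, dict):
                if fold.get("dist") != "lognormal":
                    raise ValueError(f"unsupported fold distribution {fold!r}")
                draws = rng.lognormal(fold.get("mu", 0.0), fold["sigma"], size=len(targets))
                effects.loc[targets, layer] = draws
            else:
                if fold <= 0:
                    raise ValueError(f"fold for {selector}/{layer} must be > 0, got {fold}")
                effects.loc[targets, layer] = float(fold)
    if isinstance(baseline, str):
        if baseline == "uniform":
            weights = rng.dirichlet(np.ones(len(ids)))
        elif baseline == "equimolar":
            weights = rng.lognormal(0.0, baseline_sigma, size=len(ids))
            weights /= weights.sum()
        else:
            raise ValueError(f"unknown baseline mode {baseline!r}")
    else:
        weights = np.asarray(baseline, dtype=float)
        if len(weights) != len(ids):
            raise ValueError("supplied baseline length mismatch")
        weights = weights / weights.sum()
    base = pd.Series(weights * (1 - wildtype_mass), index=effects.index, name="baseline")
    return TruthTable(effects=effects, baseline=base, wildtype_mass=wildtype_mass, library=library)


def default_effect_spec(low_protein_missense: tuple[str, ...] = (), low_load_missense: tuple[str, ...] = ()) -> dict:
    """Study-condition effect preset.

    Nonsense variants are depleted in RNA (fold 0.5, propagating to polysome
    fractions) and enriched in the low-protein flow population; missense
    variants carry graded lognormal RNA effects; silent variants are null.
    The negative control (wild-type plasmid) carries only an error-level
    background of every variant. Optional explicit missense subsets model
    protein-only and ribosome-load-only expression topologies.
    """
    spec: dict = {
        "all": {"negctrl": 0.02},
        "missense": {"totalRNA": {"dist": "lognormal", "sigma": 0.5}},
        "nonsense": {
            "totalRNA": 0.5,
            "polysome_F3": 0.45,
            "polysome_F4": 0.4,
            "flow_P1": 0.6,
            "flow_P3": 2.0,
        },
    }
    if low_protein_missense:
        # protein-only topology: RNA and ribosome load pinned at null
        spec[tuple(low_protein_missense)] = {
            "totalRNA": 1.0,
            "polysome_F3": 1.0,
            "polysome_F4": 1.0,
            "flow_P3": 2.5,
            "flow_P1": 0.5,
        }
    if low_load_missense:
        # ribosome-load-only topology: RNA and protein pinned at null
        spec[tuple(low_load_missense)] = {
            "totalRNA": 1.0,
            "polysome_F3": 0.5,
            "polysome_F4": 0.4,
            "flow_P1": 1.0,
            "flow_P3": 1.0,
        }
    return spec


# ---------------------------------------------------------------------------
# count simulation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SimDesign:
    """Sampling design for the count simulator."""

    layers: tuple[str, ...] = DEFAULT_LAYERS
    n_bio_reps: int = 4
    n_tech_reps: int = 4
    depth: int = 1_000_000
    batch_assignment: dict | None = None  # sample_id -> batch label
    n_batches: int = 2
    batch_sd: float = 0.15
    overdispersion: float = 1e7  # Dirichlet concentration scale; inf => multinomial
    seed: int = 0

    def __post_init__(self) -> None:
        if self.depth < 1:
            raise ValueError("depth must be >= 1")
        if not self.overdispersion > 0:
            raise ValueError("overdispersion must be > 0")
        if self.n_bio_reps < 1 or self.n_tech_reps < 1:
            raise ValueError("replicate counts must be >= 1")

    def sample_ids(self) -> list[tuple[str, str, int, int]]:
        out = []
        for layer in self.layers:
            for bio in range(1, self.n_bio_reps + 1):
                for tech in range(1, self.n_tech_reps + 1):
                    out.append((f"{layer}_b{bio}_t{tech}", layer, bio, tech))
        return out

    def batch_of(self, sample_id: str, bio: int) -> str:
        if self.batch_assignment is not None:
            return self.batch_assignment[sample_id]
        # default: biological replicates split evenly across batches
        return f"B{(bio - 1) % self.n_batches + 1}"


def simulate_counts(truth: TruthTable, sim: SimDesign) -> tuple[CountData, pd.DataFrame]:
    """Draw multi-layer count matrices and a sample sheet from the truth table.

    Wild-type mass is apportioned equally across the library's codon positions
    and counted per (position, sample), providing the denominator for
    wild-type normalization. Fixed seed gives byte-identical output.
    """
    missing = [layer for layer in sim.layers if layer not in truth.effects.columns]
    if missing:
        raise KeyError(f"layers missing from truth table: {missing}")
    positions = sorted({r.position for r in truth.library})
    n_var, n_pos = len(truth.baseline), len(positions)
    wt_per_pos = truth.wildtype_mass / n_pos

    ss = np.random.SeedSequence(sim.seed)
    batch_ss, samples_ss = ss.spawn(2)
    batch_rng = np.random.default_rng(batch_ss)
    batch_labels = sorted({sim.batch_of(sid, bio) for sid, _, bio, _ in sim.sample_ids()})
    # multiplicative lognormal batch factor per (variant, batch)
    batch_factors = {
        b: batch_rng.lognormal(0.0, sim.batch_sd, size=n_var) for b in batch_labels
    }

    sample_meta = sim.sample_ids()
    child_seeds = samples_ss.spawn(len(sample_meta))
    counts = np.empty((n_var, len(sample_meta)), dtype=np.int64)
    wt_counts = np.empty((n_pos, len(sample_meta)), dtype=np.int64)
    sheet_rows = []
    base = truth.baseline.to_numpy()
    for j, ((sid, layer, bio, tech), child) in enumerate(zip(sample_meta, child_seeds)):
        batch = sim.batch_of(sid, bio)
        rng = np.random.default_rng(child)
        p_var = base * truth.effects[layer].to_numpy() * batch_factors[batch]
        full = np.concatenate([p_var, np.full(n_pos, wt_per_pos)])
        full /= full.sum()
        if np.isfinite(sim.overdispersion):
            full = rng.dirichlet(sim.overdispersion * full)
        draw = rng.multinomial(sim.depth, full)
        counts[:, j] = draw[:n_var]
        wt_counts[:, j] = draw[n_var:]
        sheet_rows.append(
            {"sample_id": sid, "readout": layer, "bio_rep": bio, "tech_rep": tech, "batch": batch}
        )
    sample_ids = [sid for sid, *_ in sample_meta]
    data = CountData(
        counts=pd.DataFrame(counts, index=truth.baseline.index.copy(), columns=sample_ids),
        wt_counts=pd.DataFrame(
            wt_counts, index=pd.Index(positions, name="position"), columns=sample_ids
        ),
    )
    sheet = pd.DataFrame(sheet_rows)
    return data, sheet


# ---------------------------------------------------------------------------
# ribosome-footprint profile simulation
# ---------------------------------------------------------------------------


def simulate_rpf_profile(
    cds_length: int,
    pause_codons,
    pause_fold: float = 50.0,
    background_rate: float = 1.0,
    length_range: tuple[int, int] = FOOTPRINT_LENGTH_WINDOW,
    seed: int = 0,
    utr5: int = 30,
    utr3: int = 30,
    a_offset: int = DEFAULT_A_OFFSET,
) -> RpfProfile:
    """Poisson 5'-end profile with elevated signal at A-site-shifted pause codons.

    For each pause codon ``c`` (0-based within the CDS) the 5' position whose
    A-site decodes that codon (``utr5 + 3c - a_offset``) has its Poisson mean
    multiplied by ``pause_fold``; all other positions sit at
    ``background_rate``. Footprint lengths are sampled inside the inclusive
    ``length_range`` (a window outside the assay's 28-35 nt bounds warns).
    """
    if cds_length <= 0:
        raise ValueError("empty coding region")
    if pause_fold < 1:
        raise ValueError("pause_fold must be >= 1")
    lo, hi = length_range
    if lo > hi:
        raise ValueError("invalid footprint length window")
    if lo < FOOTPRINT_LENGTH_WINDOW[0] or hi > FOOTPRINT_LENGTH_WINDOW[1]:
        warnings.warn(
            f"footprint length window {length_range} outside the assay window "
            f"{FOOTPRINT_LENGTH_WINDOW}",
            stacklevel=2,
        )
    n_codons = cds_length // 3
    pause_codons = list(pause_codons)
    for c in pause_codons:
        if not 0 <= c < n_codons:
            raise ValueError(f"pause codon {c} outside the coding region")
    rng = np.random.default_rng(seed)
    n = utr5 + cds_length + utr3
    mean = np.full(n, background_rate, dtype=float)
    for c in pause_codons:
        x = utr5 + 3 * c - a_offset
        if x < 0:
            raise ValueError(f"pause codon {c}: 5'-end position {x} precedes the transcript")
        mean[x] *= pause_fold
    counts = rng.poisson(mean).astype(float)
    # lengths are drawn for realism of the read model but the 5'-end profile
    # is the analysis input; draw to keep the stream layout stable
    rng.integers(lo, hi + 1, size=max(int(counts.sum()), 1))
    return RpfProfile(
        counts=counts, cds_start=utr5, cds_end=utr5 + cds_length, norm="raw", a_offset=a_offset
    )
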