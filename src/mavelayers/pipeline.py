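"""End-to-end pipeline: simulate -> preprocess -> effects -> integrate ->
cluster -> pauses -> annotate -> report.

Each stage writes its artifacts under the output directory and a manifest
records inputs, configuration (with a content hash), seeds, and library
versions, so a run is reproducible bit-for-bit from the manifest alone.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .annotate import annotate_effects, class_contrast, synthetic_csc_table
from .apcluster import (
    affinity_propagation,
    assign_variants_to_clusters,
    cluster_composition,
    exemplar_signatures,
    negative_squared_distances,
    preference_from_quantile,
)
from .compositional import class_fold_summary, fold_change_point_estimate, run_comparison
from .containers import CountData, FrequencyMatrix
from .io import (
    PipelineConfig,
    validate_design,
    write_config,
    write_count_matrix,
    write_effect_table,
    write_pause_bed,
    write_rpf_profile,
    write_sample_sheet,
    write_template_cds,
)
from .multilayer import (
    build_signed_effect_matrix,
    hierarchical_cluster,
    iqlr_across_layers,
    linkage_to_newick,
    scale_and_center,
)
from .preprocess import (
    batch_adjust,
    detection_mask,
    filter_variants,
    normalize_count_data,
    summarize_replicates,
)
from .riboseq import call_pauses, cpm_normalize, offset_adjust, pause_overlap
from .som import select_best_init, som_to_text
from .synthetic import (
    LibraryDesign,
    SimDesign,
    assign_truth,
    default_effect_spec,
    default_library_design,
    generate_variant_library,
    simulate_counts,
    simulate_rpf_profile,
)

logger = logging.getLogger(__name__)

#: readouts carrying group structure for the batch model matrix
MODEL_MATRIX_READOUTS = ("gDNA", "totalRNA")


def _prune_spec(effect_spec: dict, layers) -> dict:
    """Restrict an effect spec to the layers actually simulated."""
    layers = set(layers)
    pruned = {}
    for selector, folds in effect_spec.items():
        kept = {layer: fold for layer, fold in folds.items() if layer in layers}
        if kept:
            pruned[selector] = kept
    return pruned


def default_truth_subsets(config: PipelineConfig, library) -> tuple[tuple, tuple]:
    """Seeded missense subsets carrying the protein-only / load-only topologies."""
    rng = np.random.default_rng(config.seed)
    missense = [r.variant_id for r in library if r.vclass == "missense"]
    low_protein = tuple(rng.choice(missense, size=min(60, len(missense)), replace=False))
    remaining = [v for v in missense if v not in set(low_protein)]
    low_load = tuple(rng.choice(remaining, size=min(60, len(remaining)), replace=False))
    return low_protein, low_load


def simulate_stage(config: PipelineConfig, design: LibraryDesign | None = None):
    """Generate the library, ground truth, counts, and sample sheet."""
    design = design or default_library_design()
    library = generate_variant_library(design)
    low_protein, low_load = default_truth_subsets(config, library)
    spec = _prune_spec(default_effect_spec(low_protein, low_load), config.layers)
    truth = assign_truth(
        library,
        spec,
        seed=config.seed,
        layers=tuple(config.layers),
        baseline=config.baseline,
        wildtype_mass=config.wildtype_mass,
    )
    sim = SimDesign(
        layers=tuple(config.layers),
        n_bio_reps=config.n_bio_reps,
        n_tech_reps=config.n_tech_reps,
        depth=config.depth,
        batch_sd=config.batch_sd,
        overdispersion=config.overdispersion,
        seed=config.seed,
    )
    data, sheet = simulate_counts(truth, sim)
    return design, library, truth, data, sheet


def preprocess_stage(data: CountData, sheet: pd.DataFrame, positions: pd.Series, config: PipelineConfig):
    """Wild-type normalization, filters, and batch adjustment (ln scale)."""
    freqs = normalize_count_data(data, positions)
    meta = sheet.set_index("sample_id")
    negctrl_cols = meta.index[meta["readout"] == "negctrl"]
    if len(negctrl_cols):
        negctrl = freqs.data[negctrl_cols].median(axis=1)
        assay_cols = [c for c in freqs.data.columns if c not in set(negctrl_cols)]
        assay = FrequencyMatrix(freqs.data[assay_cols], "raw_freq")
        filtered, removal_log = filter_variants(
            assay, negctrl, sheet, min_log10_freq=config.min_log10_freq
        )
    else:
        logger.warning("no negative-control samples; skipping the negative-control filter")
        filtered, removal_log = freqs, pd.DataFrame(columns=["variant_id", "rule", "source"])
    ln = FrequencyMatrix(np.log(filtered.data), "ln_freq")
    meta = meta.loc[ln.data.columns]
    model_cols = meta.index[meta["readout"].isin(MODEL_MATRIX_READOUTS)]
    plain_cols = meta.index[~meta["readout"].isin(MODEL_MATRIX_READOUTS)]
    pieces = []
    if len(model_cols):
        fm = FrequencyMatrix(ln.data[model_cols], "ln_freq")
        pieces.append(batch_adjust(fm, meta["batch"], preserve_groups=meta.loc[model_cols, "readout"]).data)
    if len(plain_cols):
        fm = FrequencyMatrix(ln.data[plain_cols], "ln_freq")
        pieces.append(batch_adjust(fm, meta["batch"]).data)
    adjusted = pd.concat(pieces, axis=1)[ln.data.columns]
    return FrequencyMatrix(adjusted, "ln_freq"), removal_log


def effects_stage(ln_freqs: FrequencyMatrix, sheet: pd.DataFrame, config: PipelineConfig):
    """One effect table per configured comparison."""
    tables = {}
    for i, (test, ref) in enumerate(config.comparison_pairs()):
        result = run_comparison(
            ln_freqs,
            sheet,
            (test, ref),
            n_instances=config.mc_samples,
            denom=config.denom,
            min_ln=config.min_ln_freq,
            seed=config.seed + 101 * (i + 1),
            flip_low_protein=config.flip_low_protein,
        )
        tables[result.comparison] = result.table
    return tables


def integrate_stage(
    ln_freqs: FrequencyMatrix,
    sheet: pd.DataFrame,
    effect_tables: dict[str, pd.DataFrame],
    config: PipelineConfig,
    fdr_threshold: float = 0.05,
):
    """Multi-layer IQLR signature and hierarchical clustering of differential variants."""
    signature_layers = [layer for layer in config.layers if layer != "negctrl"]
    bio, bio_sheet = summarize_replicates(ln_freqs, sheet, "technical")
    kept = detection_mask(bio, bio_sheet, readouts=signature_layers, min_ln=config.min_ln_freq)
    raw_bio = FrequencyMatrix(np.exp(bio.data.loc[kept]), "raw_freq")
    layer_medians, _ = summarize_replicates(raw_bio, bio_sheet, "biological")
    layer_freqs = layer_medians.data[signature_layers]
    signature = scale_and_center(iqlr_across_layers(layer_freqs))
    signed = build_signed_effect_matrix(effect_tables, sign_flip=config.flip_low_protein)
    differential = signed.index[
        pd.concat(
            [t.set_index("variant_id")["fdr"].reindex(signed.index) for t in effect_tables.values()],
            axis=1,
        ).min(axis=1)
        < fdr_threshold
    ]
    if len(differential) >= 2:
        linkage, leaf_order = hierarchical_cluster(signed.loc[differential])
        newick = linkage_to_newick(linkage, differential)
    else:
        logger.warning("fewer than 2 differential variants; skipping hierarchical clustering")
        linkage, leaf_order, newick = None, list(differential), ";"
    return signature, signed, differential, linkage, leaf_order, newick


def cluster_stage(signature: pd.DataFrame, classes: pd.Series, config: PipelineConfig):
    """SOM over variant signatures, then affinity propagation of the codebook."""
    som = select_best_init(
        signature.to_numpy(),
        n_seeds=config.som_seeds,
        base_seed=config.seed,
        n_rows=config.som_rows,
        n_cols=config.som_cols,
        n_epochs=config.som_epochs,
    )
    bmu, _ = som.map_to_bmu(signature.to_numpy())
    similarity = negative_squared_distances(som.codebook_)
    preference = preference_from_quantile(similarity, config.ap_q)
    ap = affinity_propagation(similarity, preference=preference, damping=config.ap_damping)
    variant_clusters = pd.Series(
        assign_variants_to_clusters(bmu, ap), index=signature.index, name="cluster"
    )
    composition = cluster_composition(variant_clusters, classes)
    exemplars = exemplar_signatures(som.codebook_, ap, signature.columns)
    return som, ap, pd.Series(bmu, index=signature.index, name="bmu"), variant_clusters, composition, exemplars


def pauses_stage(design: LibraryDesign, positions: pd.Series, config: PipelineConfig):
    """Simulated RPF profile, pause calls, and variant overlap flags."""
    cds_length = len(design.template_cds)
    n_codons = cds_length // 3
    rng = np.random.default_rng(config.seed + 7)
    # pauses land inside the mutagenized regions so overlap flags are informative
    roi_codons = [pos - 1 for pos, _ in design.roi_positions()]
    pause_codons = sorted(rng.choice(roi_codons, size=min(4, len(roi_codons)), replace=False))
    profile = simulate_rpf_profile(
        cds_length,
        pause_codons,
        pause_fold=50.0,
        background_rate=2.0,
        seed=config.seed + 8,
        a_offset=config.a_offset,
    )
    adjusted = offset_adjust(cpm_normalize(profile), "A")
    pauses = call_pauses(adjusted, percentile=config.pause_percentile)
    called_positions = pauses["codon"] + 1  # 0-based CDS codon -> 1-based template codon
    flags = pause_overlap(called_positions, positions, n_codons=n_codons)
    flags.index = positions.index
    return profile, pauses, flags, pause_codons


def run_pipeline(config: PipelineConfig, outdir) -> dict:
    """Run every stage, write artifacts plus a manifest, return in-memory results."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, str] = {}

    def save(name: str, writer) -> None:
        path = outdir / name
        writer(path)
        artifacts[name] = path.name

    design, library, truth, data, sheet = simulate_stage(config)
    validate_design(data.counts, sheet, config)
    positions = truth.positions
    classes = truth.classes
    save("counts.tsv", lambda p: write_count_matrix(data.counts, p))
    save("wt_counts.tsv", lambda p: write_count_matrix(data.wt_counts, p))
    save("sample_sheet.tsv", lambda p: write_sample_sheet(sheet, p))
    save("template_cds.fasta", lambda p: write_template_cds(design.template_cds, p))
    save("truth_effects.tsv", lambda p: truth.effects.to_csv(p, sep="\t"))
    save("truth_baseline.tsv", lambda p: truth.baseline.to_csv(p, sep="\t"))

    ln_freqs, removal_log = preprocess_stage(data, sheet, positions, config)
    assay_sheet = sheet[sheet["sample_id"].isin(ln_freqs.data.columns)]
    save("ln_freqs.tsv", lambda p: ln_freqs.data.to_csv(p, sep="\t"))
    save("removal_log.tsv", lambda p: removal_log.to_csv(p, sep="\t", index=False))

    effect_tables = effects_stage(ln_freqs, assay_sheet, config)
    for name, table in effect_tables.items():
        save(f"effects_{name}.tsv", lambda p, t=table: write_effect_table(t, p))

    signature, signed, differential, linkage, leaf_order, newick = integrate_stage(
        ln_freqs, assay_sheet, effect_tables, config
    )
    save("signature.tsv", lambda p: signature.to_csv(p, sep="\t"))
    save("signed_effects.tsv", lambda p: signed.to_csv(p, sep="\t"))
    save("differential_dendrogram.nwk", lambda p: Path(p).write_text(newick + "\n"))

    som, ap, bmu, variant_clusters, composition, exemplars = cluster_stage(
        signature, classes, config
    )
    save("som_model.txt", lambda p: Path(p).write_text(som_to_text(som)))
    save(
        "ap_clusters.tsv",
        lambda p: pd.DataFrame(
            {"neuron": np.arange(som.n_units), "exemplar": ap.labels, "cluster": ap.cluster_ids()}
        ).to_csv(p, sep="\t", index=False),
    )
    save("variant_clusters.tsv", lambda p: variant_clusters.to_csv(p, sep="\t"))
    save("cluster_composition.tsv", lambda p: composition.to_csv(p, sep="\t"))
    save("cluster_exemplars.tsv", lambda p: exemplars.to_csv(p, sep="\t"))

    profile, pauses, pause_flags, pause_codons = pauses_stage(design, positions, config)
    save("rpf_profile.tsv", lambda p: write_rpf_profile(profile, p))
    save("pause_calls.bed", lambda p: write_pause_bed(pauses, p))
    save("pause_calls.tsv", lambda p: pauses.to_csv(p, sep="\t", index=False))

    csc = synthetic_csc_table(config.seed)
    save("csc_table.tsv", lambda p: csc.to_csv(p, sep="\t", index=False))
    contrasts = []
    annotated = {}
    for name, table in effect_tables.items():
        ann = annotate_effects(table, csc_table=csc, pause_flags=pause_flags)
        annotated[name] = ann
        save(f"annotated_{name}.tsv", lambda p, t=ann: t.to_csv(p, sep="\t", index=False))
        comp = class_contrast(ann, "nonsense", "silent")
        contrasts.append(
            {
                "comparison": name,
                "class_a": comp.group_a,
                "class_b": comp.group_b,
                "statistic": comp.statistic,
                "p_value": comp.p_value,
                "sidedness": comp.sidedness,
                "exact": comp.exact,
            }
        )
    save("class_contrasts.tsv", lambda p: pd.DataFrame(contrasts).to_csv(p, sep="\t", index=False))

    rna_name = next((n for n in effect_tables if n == "totalRNA-vs-gDNA"), None)
    fold_summary = None
    if rna_name is not None:
        meta = assay_sheet.set_index("sample_id")
        bio, bio_sheet = summarize_replicates(ln_freqs, assay_sheet, "technical")
        bio_meta = bio_sheet.set_index("sample_id")
        kept = detection_mask(bio, bio_sheet, readouts=["totalRNA", "gDNA"], min_ln=config.min_ln_freq)
        fm = FrequencyMatrix(bio.data.loc[kept], "ln_freq")
        folds = fold_change_point_estimate(
            fm,
            bio_meta.index[bio_meta["readout"] == "totalRNA"],
            bio_meta.index[bio_meta["readout"] == "gDNA"],
        )
        fold_summary = class_fold_summary(folds, classes)
        save("fold_change_summary.tsv", lambda p: fold_summary.to_csv(p, sep="\t"))

    config_text = json.dumps(config.as_dict(), sort_keys=True)
    manifest = {
        "package": "mavelayers",
        "version": __version__,
        "config": config.as_dict(),
        "config_sha256": hashlib.sha256(config_text.encode()).hexdigest(),
        "seed": config.seed,
        "stages": [
            "simulate",
            "preprocess",
            "effects",
            "integrate",
            "cluster",
            "pauses",
            "annotate",
            "report",
        ],
        "artifacts": artifacts,
        "versions": {
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    write_config(config, outdir / "config.txt")

    return {
        "design": design,
        "library": library,
        "truth": truth,
        "counts": data,
        "sheet": sheet,
        "ln_freqs": ln_freqs,
        "removal_log": removal_log,
        "effect_tables": effect_tables,
        "annotated_tables": annotated,
        "signature": signature,
        "signed_effects": signed,
        "differential": differential,
        "newick": newick,
        "som": som,
        "ap": ap,
        "bmu": bmu,
        "variant_clusters": variant_clusters,
        "cluster_composition": composition,
        "pauses": pauses,
        "pause_codons": pause_codons,
        "pause_flags": pause_flags,
        "fold_change_summary": fold_summary,
        "class_contrasts": pd.DataFrame(contrasts),
        "manifest": manifest,
    }
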