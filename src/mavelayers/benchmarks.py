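"""Self-contained recovery benchmarks on the package's own synthetic data.

Each benchmark simulates data under the study conditions (58-position x
61-codon library, depth 1e6, four biological replicates), runs the relevant
pipeline stages from scratch, and measures how well known ground truth is
recovered. They back both the validation test suite and the reproducibility
script.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.metrics import adjusted_rand_score

from .apcluster import (
    affinity_propagation,
    assign_variants_to_clusters,
    negative_squared_distances,
    preference_from_quantile,
)
from .compositional import class_fold_summary, fold_change_point_estimate, run_comparison
from .containers import FrequencyMatrix
from .io import PipelineConfig
from .pipeline import (
    default_truth_subsets,
    integrate_stage,
    preprocess_stage,
    simulate_stage,
)
from .preprocess import detection_mask, summarize_replicates
from .riboseq import call_pauses, cpm_normalize, offset_adjust
from .som import select_best_init
from .synthetic import simulate_rpf_profile


def rna_recovery_benchmark(seed: int, mc_samples: int = 32) -> dict:
    """Recovery of programmed RNA-abundance effects from a full-scale simulation.

    Simulates the default library (nonsense RNA fold 0.5, graded missense
    folds, null silent variants) at depth 1e6 with 4 biological replicates,
    runs preprocessing and the totalRNA-vs-gDNA comparison, and reports:
    the nonsense class-mean fold estimate, nonsense recall at FDR < 0.1, the
    fraction of discoveries that are (null) silent variants, and the Pearson
    correlation between effect sizes and true log folds.
    """
    config = PipelineConfig(
        seed=seed, layers=("negctrl", "gDNA", "totalRNA"), mc_samples=mc_samples
    )
    _, library, truth, data, sheet = simulate_stage(config)
    ln, _ = preprocess_stage(data, sheet, truth.positions, config)
    assay_sheet = sheet[sheet["sample_id"].isin(ln.data.columns)]
    table = run_comparison(
        ln,
        assay_sheet,
        ("totalRNA", "gDNA"),
        n_instances=mc_samples,
        seed=seed + 101,
    ).table.set_index("variant_id")
    classes = truth.classes.reindex(table.index)

    discoveries = table["fdr"] < 0.1
    nonsense = classes == "nonsense"
    silent = classes == "silent"
    true_log_folds = np.log(truth.effects["totalRNA"]).reindex(table.index)
    pearson = float(np.corrcoef(table["effect"], true_log_folds)[0, 1])

    bio, bio_sheet = summarize_replicates(ln, assay_sheet, "technical")
    meta = bio_sheet.set_index("sample_id")
    kept = detection_mask(bio, bio_sheet, readouts=["totalRNA", "gDNA"])
    folds = fold_change_point_estimate(
        FrequencyMatrix(bio.data.loc[kept], "ln_freq"),
        meta.index[meta["readout"] == "totalRNA"],
        meta.index[meta["readout"] == "gDNA"],
    )
    summary = class_fold_summary(folds, truth.classes)

    return {
        "n_variants": int(len(table)),
        "n_library": int(len(library)),
        "nonsense_fold_mean": float(summary.loc["nonsense", "mean"]),
        "nonsense_fold_sd": float(summary.loc["nonsense", "sd"]),
        "silent_fold_mean": float(summary.loc["silent", "mean"]),
        "nonsense_recall_fdr10": float(discoveries[nonsense].mean()),
        "n_discoveries": int(discoveries.sum()),
        "silent_discovery_fraction": float(
            (discoveries & silent).sum() / max(int(discoveries.sum()), 1)
        ),
        "effect_truth_pearson": pearson,
        "table": table.assign(**{"class": classes}),
        "truth": truth,
    }


def topology_recovery_benchmark(seed: int, som_seeds: int = 5, mc_samples: int = 32) -> dict:
    """Recovery of three programmed expression topologies by SOM + AP.

    Three variant groups carry distinct multi-layer signatures (RNA-driven
    depletion propagating to all layers; protein-only; ribosome-load-only);
    the benchmark checks that affinity-propagation clusters of the SOM
    codebook separate them (adjusted Rand index over the labeled variants).
    """
    config = PipelineConfig(seed=seed, mc_samples=mc_samples, som_seeds=som_seeds)
    _, library, truth, data, sheet = simulate_stage(config)
    low_protein, low_load = default_truth_subsets(config, library)
    ln, _ = preprocess_stage(data, sheet, truth.positions, config)
    assay_sheet = sheet[sheet["sample_id"].isin(ln.data.columns)]

    from .pipeline import effects_stage

    tables = effects_stage(ln, assay_sheet, config)
    signature, *_ = integrate_stage(ln, assay_sheet, tables, config)

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
    ap = affinity_propagation(
        similarity, preference=preference_from_quantile(similarity, config.ap_q)
    )
    clusters = pd.Series(assign_variants_to_clusters(bmu, ap), index=signature.index)

    # ground-truth topology labels: nonsense, low-protein subset, low-load subset
    nonsense = truth.classes.index[truth.classes == "nonsense"]
    labeled = {}
    for label, ids in enumerate((nonsense, low_protein, low_load)):
        for vid in ids:
            if vid in clusters.index:
                labeled[vid] = label
    labeled = pd.Series(labeled)
    ari = float(adjusted_rand_score(labeled, clusters.reindex(labeled.index)))
    return {
        "ari": ari,
        "n_labeled": int(len(labeled)),
        "n_clusters": int(ap.n_clusters),
        "clusters": clusters,
        "signature": signature,
    }


def pause_recovery_benchmark(seed: int, n_trials: int = 10) -> dict:
    """Exact recovery of programmed pause codons at the 90th percentile.

    Spikes (fold 50 over a unit Poisson background) are programmed at one
    tenth of coding positions, so the strict top-decile rule should call
    exactly those positions in every seeded trial.
    """
    rng = np.random.default_rng(seed)
    exact = 0
    for trial in range(n_trials):
        # 30 pause codons of 100 => 30 spike nt among 300 CDS nt = the top decile
        pause_codons = sorted(int(c) for c in rng.choice(100, size=30, replace=False))
        profile = simulate_rpf_profile(
            300, pause_codons, pause_fold=50.0, background_rate=1.0, seed=seed + 1000 + trial
        )
        adjusted = offset_adjust(cpm_normalize(profile), "A")
        calls = call_pauses(adjusted, percentile=90)
        exact += sorted(set(calls["codon"])) == pause_codons
    return {"exact_fraction": exact / n_trials, "n_trials": n_trials}
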