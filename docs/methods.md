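# Methods

`mavelayers` analyzes multiplexed assays of variant effect (MAVEs) read out
across several gene-expression layers: a saturation codon-mutagenesis library
is sequenced as variant counts in a negative-control plasmid, genomic DNA,
total RNA, polysome metafractions (ribosome load), and flow-sorted populations
(protein abundance). The pipeline turns those counts into per-variant,
per-layer effect sizes, groups variants by their multi-layer expression
signature, and calls ribosome pause sites from footprint profiles. Everything
is exercisable without external data through a synthetic-data generator with
programmable ground truth.

## Count model and preprocessing

Variant frequencies are normalized to the wild-type count at each codon
position with half-count pseudocounts,

    freq[v, s] = (count[v, s] + 0.5) / (wt_count[pos(v), s] + 0.5),

which keeps frequencies positive and cancels the simplex closure (a depleted
variant does not inflate its neighbours' frequencies). Two filters follow: an
absolute floor on log10 frequency (default −5.8, applied per gDNA sample;
failing any sample removes the variant) and removal of variants whose
per-readout median frequency is strictly lower than their frequency in the
negative-control (wild-type plasmid) library — equality retains the variant.
Each removed variant is logged with the single first-firing rule.

Batch structure from library preparation is removed on the natural-log scale
by a location-only adjustment: per variant, batch means are subtracted and the
grand mean restored; when a model matrix is appropriate (gDNA and total RNA,
whose readouts share batches), group means are removed first so real
between-readout differences survive. This replaces a full empirical-Bayes
batch correction: no shrinkage hyperparameters are published for the original
analysis, the adjustment is idempotent and exactly removes constructed
offsets, and the simulated batch structure is location-only — which is also
the limit of what the tests can certify about real data.

Technical replicates are summarized by medians into biological replicates
(independent cell lines), and biological replicates by medians into layers;
even-sized groups use the mean of the central pair. A detection mask keeps
variants whose per-(readout, biological replicate) median ln frequency
exceeds −10 in every readout entering a comparison.

## Compositional effect engine

Frequencies for the two readouts of a comparison are closed to counts per
million and treated as compositions. Per sample, Monte-Carlo instances are
drawn from a Dirichlet posterior with concentrations `round(cpm) + 0.5`
(default 128 instances; 0 selects the deterministic maximum-a-posteriori
composition for testing). Each instance is transformed to centered log ratios
(CLR); with the `iqlr` denominator (default) the reference set is restricted
to features whose CLR variance across samples (averaged over instances) lies
within the interquartile range — robust to asymmetric perturbations such as a
depleted variant class.

The per-variant effect size is a median standardized difference: per
instance, the median of all cross-group CLR differences divided by the larger
within-group median absolute pairwise difference (all pairs enumerated
exactly — deterministic, and identical in expectation to the random pairing
used by the reference compositional tool). The reported effect is the median
over instances, with a 75% interval from the 12.5th/87.5th instance
percentiles. The interval is a posterior summary of the Dirichlet (counting)
uncertainty: we verified numerically that it is *not* a calibrated
frequentist interval for the large-K effect under count re-simulation
(coverage 55–70%, falling with depth), so it should be read as measurement
uncertainty, not a confidence statement. A zero within-group dispersion is
floored at the smallest positive within-group difference in the instance
(10⁻⁸ if none), logged.

Welch two-sample t tests run per instance and are Benjamini–Hochberg adjusted
across variants within the instance; reported p and FDR are means over
instances, so FDR ≥ p holds per variant. BH is applied within each
comparison, never across comparisons. When the test readout is the
low-protein flow population (P3), effects are multiplied by −1 so that
negative always means "less product".

Fold-change point estimates are `exp(mean ln-frequency difference)` between
groups, summarized per variant class as mean ± SD. (No trended
empirical-Bayes variance moderation is applied; with the default four
replicates per side and the class-level summary, plain group means are
adequate and fully transparent.)

## Multi-layer signatures and clustering

Per-layer median frequencies are transformed to interquartile log ratios by
four steps per layer: reclose; CLR; per-variant CLR variance across layers
with interquartile feature selection; log ratio of each variant frequency to
the geometric mean of the selected features. The IQLR matrix is standardized
within each layer (population SD, configurable) and each variant row is
robustly centered to its across-layer median — this removes the variant's
nominal library abundance so only the expression *shape* across layers is
learned.

Signatures are clustered by an online self-organizing map on a 13 × 20
toroidal grid (260 units) with hexagonal topology and bubble neighborhood:
each presentation moves every unit within the current radius of the
best-matching unit (BMU; ties to the lowest index) toward the sample. The
learning rate decreases linearly from 0.05 to 0.01 over all presentations
(the published recipe fixes only the 0.05 start and the linear decrease; the
0.01 end mirrors the reference SOM package's default) and the radius
decreases linearly from the 2/3 quantile of pairwise unit distances to 1.
Grid distances embed units as offset hexagons (odd rows shifted 0.5, row
pitch √3/2) and minimize over the nine torus translations; a vertical wrap of
an odd-row grid shifts x by 0.5 so the minimum-image distance is a true
metric. Training is repeated under consecutive seeds (package default 20;
500 reproduces the published protocol) and the map minimizing the summed
data-to-BMU distance is kept.

Codebook vectors are clustered by affinity propagation on negative squared
Euclidean distances, with exemplar preferences at the q = 0.1 quantile of
off-diagonal similarities, damping 0.9, up to 1000 iterations, convergence
declared after 100 sweeps with an unchanged exemplar set. Variants inherit
the cluster of their BMU; per-cluster class compositions and exemplar
codebook signatures summarize the result. Separately, variants differential
in any layer (minimum FDR < 0.05) are hierarchically clustered on the
signed effect matrix (Euclidean, complete linkage — the source analysis names
no method; both are configurable) and exported as Newick.

## Ribosome pause calling

Footprint 5′-end profiles (lengths restricted to 28–35 nt) are CPM-normalized
and shifted to ribosomal sites: the A-site offset is 16 nt, with P = A − 3
and E = A − 6 (one codon per site, canonical ribosome geometry). Pause
positions are coding-region positions whose CPM strictly exceeds the
90th percentile (linear interpolation) of CPM over the coding region; an
all-equal profile therefore yields no calls. A called pause at codon c flags
variants at codons c, c+1, and c+2 (the variant sitting in the A, P, or E
site of the paused ribosome's footprint).

## Annotation statistics

Variants are classed silent/missense/nonsense against the standard genetic
code (only the amber stop TAG enters libraries); codon-stability-coefficient
differences are CSC(alt) − CSC(ref), undefined (missing, logged) for stops.
Per-amino-acid maps take the median effect over codons encoding each
substitution; unobserved cells stay missing, never zero. Group comparisons
use Wilcoxon rank-sum tests: exact by enumeration when both groups have at
most 8 observations and no ties, otherwise the normal approximation with
midrank-tie and continuity corrections. One-sided tests are used where the
direction is pre-specified (e.g., ribosome-load losses should have lower
ΔCSC), two-sided otherwise.

## Synthetic data: what it emulates and what it does not

The generator reproduces the count *structure* of the assay: a 58-position ×
61-alternate-codon library over two ROIs (every silent and missense codon
plus the amber nonsense codon per position), multi-layer samples with
technical/biological replicates and batch structure, per-position wild-type
counts, and Dirichlet-multinomial counting with exact column totals.

Defaults define the study conditions and were fixed before validation:

| parameter | default | rationale |
| --- | --- | --- |
| depth | 1e6 reads/sample | stated study scale |
| biological replicates | 4 | the assay's design |
| technical replicates | 4 | deep-coverage library preparation; balanced grid |
| wild-type mass | 0.9 | open design choice, 90% of reads are template |
| baseline spread | lognormal sd 0.15 | equimolar pooling with high uniformity |
| overdispersion | 1e7 (concentration) | mild extra-multinomial technical noise |
| batch effect | lognormal sd 0.15, 2 batches | location-scale of prep batches |
| nonsense RNA fold | 0.5 | the programmed truth the engine must recover |
| missense RNA folds | lognormal(0, 0.5) | graded effects so effect-truth concordance is a continuous correlation |
| negative-control fold | 0.02 | variant signal in the wild-type plasmid is error background |

Two seeded missense subsets (60 variants each) carry protein-only and
ribosome-load-only expression topologies, giving three programmed
multi-layer signatures for clustering recovery.

Not emulated: read-level errors and PCR jackpots, nucleotide-level biological
mechanism (RNA structure, codon usage — effects are programmed, not caused),
position-dependent wild-type sequencing depth, and the reproducibility
differences between readout modalities seen in real data. Passing tests
therefore certify the *estimators* (normalization, compositional inference,
clustering, pause calling) against known truth under realistic counting
noise, not the biology of any particular gene.

RPF profiles are Poisson with a uniform background and single-position spikes
at the 5′ position whose A-site decodes each programmed pause codon. Exact
recovery tests place spikes at one tenth of coding positions because the
strict 90th-percentile rule calls the top decile.

## Numerical choices and degenerate inputs

* CPM values are rounded half-up before Dirichlet sampling (the engine needs
  integer-like concentrations).
* Quartiles/percentiles use linear interpolation throughout.
* Welch tests with two zero-variance groups return p = 1 when means are
  equal, otherwise the standard error is floored (logged).
* BMU and quantile ties break to the lowest index for determinism.
* All randomness flows from explicit integer seeds via
  `numpy.random.default_rng`; rerunning any stage with the same seed is
  bit-identical, and the pipeline manifest records config hash, seeds, and
  library versions.

## Problem sizes used in validation

The validation suite runs the full 3538-variant library at depth 1e6 with 32
Monte-Carlo instances for recovery checks (the analysis default is 128),
best-of-20 SOM initializations (500 reproduces the published protocol), and
the end-to-end reproducibility check at the pipeline's default configuration.

## Known limitations

* The location-only batch adjustment does not shrink batch estimates and
  does not address batch-specific scale changes.
* The 75% effect interval is a posterior summary, not a calibrated CI (see
  above).
* Affinity propagation on near-degenerate similarity matrices (identical
  points) may not formally converge; the fallback exemplar is logged and the
  partition is still returned.
* Exact Wilcoxon enumeration is skipped in the presence of ties (midrank
  approximation is used instead).
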