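# Methods

## Scoring model

A four-bin sort-seq experiment reads out each variant's steady-state
abundance through the distribution of its reads over bins drawn at the
quartiles of the cell population's fluorescence ratio. Within a replicate,
counts c_b are depth-normalized (c_b/N_b, N_b the bin's total sequencing
depth) and renormalized to frequencies f_b summing to 1, so a variant's
score does not depend on how deeply each bin happened to be sequenced
(scores are exactly invariant to multiplying all depths by a constant).
The score is the weighted average Σ_b w_b f_b with w = (0, 1/3, 2/3, 1):
equally spaced weights on the unit interval, the standard estimator for
this design. A variant needs `min_reads_per_variant` (default 5) total
reads in a replicate to be scored; below that it is *missing*, never zero.
Rows tagged as codon-level entries (`R130Q/tag`) are averaged, unweighted,
into their amino-acid variant before normalization, since the amino-acid
change is the unit of record.

Raw scores are anchored per replicate to the controls:
s' = (s − m_non)/(m_syn − m_non), with m the median (configurable to the
mean) of the nonsense and synonymous control scores. At least 5 scored
controls of each type are required; a replicate whose synonymous anchor
does not exceed its nonsense anchor fails with "replicate failed
separation". Anchored scores may legitimately fall outside [0, 1].

## Replicate filter

Variants observed in few replicates carry unreliable scores. The filter
demands n_reps ≥ k\*, with k\* chosen by scanning k = 0…15: at each k,
keep control variants with n_reps ≥ k, form composite (mean) scores, and
test whether the upper bound of the 95% confidence interval of the mean
nonsense composite lies strictly below the 5th percentile of synonymous
composites. The CI is the normal approximation over nonsense variants
(mean ± z·sd/√n, z = Φ⁻¹(0.975)); a bootstrap-percentile CI of the mean is
available as `ci_method="bootstrap_percentile"` since the construction is
a genuinely open choice. Reliability of the pass/fail call is estimated by
bootstrap (default 100 resamples): (composite score, n_reps) pairs are
resampled with replacement within each control class and the test
repeated; k\* is the smallest k whose pass fraction reaches
`pass_fraction` (default 0.95, matching a "minimal number of replicates"
selection rule). The bootstrap preserves the association between a
variant's score and its replicate count — that association is exactly
what the filter exploits. Setting `randomize_association=True` instead
shuffles the replicate-count labels across the pooled controls in every
resample; this destroys the association and serves as a negative control:
under it, no filter value should look better than any other, so a k\*
that survives only with the association intact is doing real work.

Composites report the mean over available replicate scores, sample sd
(ddof 1), se = sd/√n, and CV = sd/score. CV is suppressed
(`cv_undefined`) when the score is ≤ 0.05, where division by a
near-nonsense score is meaningless. Empirical percentiles use linear
interpolation between order statistics throughout.

Two score sets may be pooled without renormalization only when an OLS fit
of one on the other over shared variants has |slope − 1| ≤ 0.15 and
|intercept| ≤ 0.15 (configurable); `compare_score_sets` /
`check_aggregation_compatibility` implement the fit and the gate.

## Confidence classes and the four-way classification

Abundance calls use control percentiles of the composite distribution:
q_syn (lower 5% of synonymous) and q_non (upper 95% of nonsense), which
must separate. A variant is `wt_like` when score − 2·se > q_non and
score + 2·se ≥ q_syn; `low` under the mirrored condition; otherwise
`unclassified`. The ±2·se band means a variant is only classified when
its uncertainty does not straddle the control envelope.

Activity calls apply fixed cutoffs on the **raw** activity scale: WT-like
above 10⁻¹·¹¹ and loss below 10⁻²·¹³ (the lower-95th synonymous and
upper-95th nonsense percentiles of the source assay). Rescaling to a 0–1
reporting scale (mean nonsense → 0, WT → 1) happens after classification
and is cosmetic. The WT anchor is the mean of synonymous raw activities
by default, since a designated WT entry is not guaranteed in arbitrary
tables (`wt_anchor_policy` accepts a number to override).

Crossing the axes: (wt, wt) → `wt_like`; (low, wt) →
`loss_abundance_only`; (wt, loss) → `loss_activity_only`; (low, loss) →
`loss_both`; anything indeterminate or missing on either axis →
`unclassified`, with `unclassified_reason` distinguishing
`indeterminate` (both assays scored, at least one call uncertain) from
`missing_assay`, because the two mean different things when interpreting
coverage.

## SNV null spectrum and enrichment

Each nucleotide of the CDS is substituted to the three alternatives — 9
events per codon. The initiator codon and terminal stop are excluded by
default (both as flags): a 403-residue ORF then contributes 402 × 9 =
3618 events. Synonymous events are dropped; the rest collapse to unique
protein variants whose *frequency* is the number of producing events
(codon degeneracy). Expected class fractions under no selection are the
frequency-weighted class shares over spectrum variants covered by the
class map; coverage below `min_class_coverage` triggers a warning rather
than an error, since partial classification coverage is the normal case.
Mutation rates are uniform by default — transition/transversion or
signature weighting changed little in the source analyses — with a
`rate_weight(ref, alt)` hook for anything else.

Observed class fractions in a catalog support two counting modes:
`per_observation` (each tumor observation counts; right for somatic
catalogs with recurrence counts) and `unique_variant` (each distinct
variant counts once; right for clinical sets where frequency is
unreliable). Fold enrichment is observed/expected per class; an expected
fraction of zero yields +inf with a warning. By construction
Σ_class fold × baseline = 1 exactly for every category.

The catalog **generator** reweights spectrum variants by
frequency × fold(class) and renormalizes before multinomial sampling.
Because observed fractions must sum to 1, a requested fold vector f is
realizable only up to s = Σ_c baseline_c·f_c: recovered folds converge to
f_c/s, not f_c, whenever s ≠ 1. Closure tests therefore check recovery
against f/s; the identity above is checked to 1e-12.

## Synthetic data generator

The generator emulates the statistical structure the analysis relies on,
not any particular instrument:

- **Fluorescence**: each cell's log-ratio is true_abundance +
  N(0, `fluorescence_noise_sd`) on the unit interval — the simplest model
  preserving the monotone abundance→bin relationship the readout assumes.
  Default noise sd 0.10; `cells_per_variant` 100.
- **Gates**: 25/50/75th percentiles of the pooled simulated cells, i.e.
  equally populated quartiles by construction.
- **Reads**: multinomial per bin to `reads_per_bin` (default 50,000),
  probabilities proportional to each variant's cell count in the bin.
  Total reads per replicate are exactly 4 × reads_per_bin.
- **Dropout**: per-variant-per-replicate Bernoulli (default rate 0.20),
  fixed at library generation as presence flags — the replicate-count
  heterogeneity the filter exists to handle.
- **Library**: default 500 variants × 8 replicates with ≥ 20 synonymous
  and ≥ 20 nonsense controls; a desk-scale variant:read ratio. True
  abundances per class: wt-like and loss-activity-only draw U(0.8, 1.0),
  low-abundance classes U(0, 0.2), synonymous U(0.92, 1.0), nonsense
  U(0, 0.08). True activities draw log10-uniform within (−0.9, −0.1) for
  active classes and (−2.5, −2.3) for loss classes — margins sized so
  lognormal measurement noise of sd 0.1 (log10) rarely crosses a cutoff.
  Default class mixture: 50% wt-like, 20% loss-abundance-only, 10%
  loss-activity-only, 20% loss-both. With a CDS, the library is built as
  site saturation (consecutive positions × all 19 substitutions), giving
  the dense positional coverage that real NNK libraries have and the
  tolerance-clustering stage needs.
- All generators are pure functions of (config, seed); the pipeline
  derives per-stage child seeds by SHA-256 of `"{seed}:{stage}"`, so
  adding a stage never perturbs another stage's randomness.

What the generator does **not** emulate: barcode sequencing errors and
their correction, PCR jackpotting, bottlenecking during sorting,
multimodal or position-correlated abundance effects, or assay-specific
activity error structure. Passing tests therefore demonstrate that the
estimators recover truth under the stated noise model at desk scale —
they do not certify performance on any real dataset.

## Tolerance clustering

Profiles are the per-position vectors of composite scores over the 19
non-WT amino acids (stops excluded by default). Positions with ≥ 17
scored missense variants count as high coverage. Distances are Euclidean
over jointly scored amino acids, rescaled by √(19/n_shared) so sparser
overlaps are not systematically closer; positions sharing < 5 scored
amino acids with every other position are excluded with a warning, and
residual unordered pairs get 1.5 × the maximum observed distance.
Average-linkage agglomeration follows; input rows are sorted by position
first, so output is invariant to row order with ties broken by position
index. The dendrogram is exported as Newick. Group labels are a separate,
simpler summary: positional median ≥ 0.75 → tolerant, ≤ 0.35 →
intolerant, else partial — package defaults calibrated on synthetic
three-group data, exposed as configuration, and not claims about any
particular protein's boundaries. Linkage, metric, coverage threshold and
group boundaries are all configurable because none is forced by the
method.

## Degenerate inputs and numerical notes

Zero per-bin depth is an error (a sorted, sequenced bin cannot have zero
total reads); an all-zero variant row is simply unscored. Fewer than five
scored controls of a type fails normalization, and "insufficient
controls" marks filter values that leave fewer than five controls. CV of
near-zero scores is suppressed rather than reported as an explosion.
sd/se over a single replicate are NaN, and such variants can never be
confidence-classified. Score tables are written as decimal text with 12
significant digits so write/read round-trips preserve values.

## Limitations

- The replicate-filter bootstrap treats control composites as exchangeable
  within class; correlated replicate structure (batch effects) is not
  modeled.
- The weighted-average score is a method-of-moments estimator; no
  regression-based scoring or barcode-level error model is provided.
- Score-set comparison is a gate, not a harmonization: sets failing the
  slope/intercept tolerance need external renormalization before pooling.
- No imputation of missing scores; clustering and classification operate
  on observed values only.
- The bundled CDS is a synthetic stand-in (correct length; documented
  codons at the catalytic-motif and named panel residues; random sense
  codons elsewhere) — degeneracy results at undocumented positions do not
  correspond to the real gene.
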