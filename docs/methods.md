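# Methods

`bloodmirna` reproduces, as a tested pipeline, a cross-lineage analysis of
miRNA content in the five peripheral-blood hematopoietic cell types
(platelets, T-cells, B-cells, granulocytes, erythrocytes) profiled on a
hybridization-counting platform. This note records the models, the defaults
and the choices made where the design was genuinely open.

## Count model and normalization

Raw data are probe-level molecule counts (probes × samples) with probe
classes *Endogenous*, *Negative* (no-target background probes) and
*Positive*. Lane normalization scales each sample by

    factor_j = mean_j'( gm_j' ) / gm_j,

where `gm_j` is the geometric mean of sample *j*'s 100 highest endogenous
counts (`top_n` configurable; ties at the cutoff rank broken by probe-id
order, which is deterministic and, because tied values contribute equally to
a geometric mean, numerically inconsequential). This is the counting
platform's standard lane-normalization convention. A consequence worth
stating: rescaling one sample's raw counts leaves the normalized matrix
invariant only up to the cohort-mean reference — every per-sample profile
and every between-sample ratio is unchanged, but the absolute scale shifts
by a common factor because the reference is the mean of the cohort's
geometric means. Negative-control rows are scaled by the same factor so the
background threshold lives on the normalized scale.

The background threshold per sample is `mean + k·SD` of its normalized
negative controls (k = 2 by default; SD with n−1 denominator — the
convention is not dictated by the upstream software, so the unbiased sample
SD was chosen). The corrected value is `max(value − threshold, 0)`: a floor
at zero because expression cannot be negative, and "expressed above
background" is defined as a strictly positive corrected value. A `censor`
mode (zero at-or-below threshold, values above left unshifted) is provided
because thresholding can also be read as a pure filter; `subtract` is the
default.

**Erythrocyte override.** Erythrocyte preparations show anomalously low
negative-control values on this platform, which would flood the erythrocyte
profile with low-level calls. Samples of cell types named in the override
set (default: erythrocyte) therefore receive the mean of the *other*
lineages' own-sample thresholds. "Similar to the other cell types" admits
several readings; the mean-of-others rule is the simplest symmetric one and
both the override set and the rule's inputs are exposed in configuration.

## Relative abundance and detection

Relative abundance divides each probe's corrected value by the sample
total; lineage profiles are arithmetic means of member samples' fractions,
and per-lineage ranking is by average fraction (ties by probe id).
Detection defaults to the *mean* rule — a probe is detected in a lineage
iff its lineage-mean corrected value is positive — with an `any-sample`
alternative, since per-lineage detection summaries are compatible with
either. Expression classes use the conventional cutoffs on the corrected
count scale: *low* below 10 counts, *high* above 5,000, applied to the
lineage mean. The per-lineage "number expressed" is the mean over member
samples of per-sample above-background counts.

## Mass budget and blood-volume apportionment

The mass chain has fixed units: extracted RNA (ng) × 10⁶ / cells extracted
gives femtograms of total RNA per cell; the miRNA fraction of total RNA is
the product of two trapezoidal area fractions from capillary-electrophoresis
traces (total-RNA trace below 150 nt × small-RNA-assay trace below 40 nt;
both cutoffs configurable, with linear interpolation at the cutoff);
fg/cell × cells/µl × 10⁻³ gives pg of miRNA per µl of blood.

Apportionment of an individual miRNA's blood content across lineages uses
lineage-average relative abundances (not per-donor values):

    mass_c(m)  = fraction_c(m) · mirna_fg_per_cell_c · cells_per_ul_c
    share_c(m) = 100 · mass_c(m) / Σ_c' mass_c'(m).

Shares conserve 100% per probe at full floating-point precision; rounding
to whole percent happens only at serialization (rounded rows may sum to
99–101). Probes with zero total mass carry null shares and a flag.

The default cell-record table (cells extracted, RNA yields, cells per µl)
is back-computed from the published per-cell and per-volume mass table,
because the underlying complete-blood-count concentrations are not printed;
the back-computed concentrations (≈3.4×10⁵ platelets, 1.1×10³ T-cells,
2.0×10² B-cells, 4.9×10³ granulocytes and 4.6×10⁶ erythrocytes per µl) are
all physiologically ordinary, which is a useful consistency check.

## Differential expression

Per probe, the omnibus test is Welch's unequal-variance one-way ANOVA with
the Welch–Satterthwaite denominator df, applied by default to
log2(value + 1) of corrected values (`linear` available; the upstream
software's scale is unstated, and log2 is the conventional choice for
count-derived expression). Benjamini–Hochberg step-up control is applied
across probes; a probe is DE at q < 0.05. Degenerate probes with zero
variance everywhere are assigned F = 0, p = 1 rather than erroring; a
single zero-variance lineage within an otherwise varying probe has its
variance floored at 10⁻¹² of the grand variance, so an all-zero lineage
still registers as a (strong) mean separation.

Post-hoc separation uses the studentized-range distribution with pooled
within-group variance and Tukey–Kramer standard errors: Tukey HSD when the
probe is present in all lineages, Student–Newman–Keuls (range-dependent
critical values on ordered means, with non-significant ranges protecting
nested sub-ranges) when it is absent in one or more. "Absent" means every
member sample is zero after background subtraction — the natural reading on
a floored scale. The post-hoc family alpha is fixed at 0.05 per probe,
independent of the BH layer. Pairing a Welch omnibus with classical
equal-variance post-hoc ranges is statistically impure but mirrors the
profiling workflow this package reproduces; the impurity is deliberate and
confined to the post-hoc stage. A probe joins a lineage's DE list iff the
post-hoc test separates that lineage from all four others; "selectively
reduced" probes are those with lineage-mean expression above 5,000 in at
least two lineages and below 10 in at least one.

## Normalizer stability

Two criteria rank reference-miRNA candidates. The model-based score follows
the Andersen reference-gene model on log2(value + 1): values are
sample-centered (subtracting each sample's mean over candidates removes
per-sample loading), then for candidate *i* and lineage *g*

    stability_i = mean_g( |d~_ig| + sqrt(s²_ig / n_g) ),

with `d_ig` the centered lineage-mean deviation from the candidate's
overall mean, `s²_ig` the within-lineage variance bias-corrected by
subtracting the lineage's average candidate variance divided by (k − 1)
(compensating the covariance that sample-centering induces across
candidates) and floored at 0, and `d~_ig = d_ig · γ² / (γ² + s²_ig/n_g)`
where `γ² = max(0, Σ d² / ((G−1)k) − mean(s²/n))` is the moment estimate of
the true inter-lineage variance. Lower is more stable. The exact shrinkage
and bias-correction constants are as stated here and in the code; the model
admits minor variants, and these choices keep every estimate a simple
moment estimator floored at zero.

The second criterion is the coefficient of variation, SD/mean (n−1 SD) on
linear normalized values — scale-free and model-free. Candidates absent
from any lineage are excluded from both rankings: a normalizer must be
expressed everywhere. The source study reports the selected normalizer as
*miR-30c-5p* in the text and *miR-30c-3p* in a figure legend; the
discrepancy is noted here verbatim and deliberately not resolved. The
companion qRT-PCR transform `2^−(Ct_target − Ct_reference)` is provided for
validation workflows.

## Clustering

Samples are clustered on 1 − Pearson correlation with complete linkage
(deterministic; merge heights are monotone non-decreasing), conventionally
on the union of each lineage's top-20 most abundant miRNAs, log2(x + 1)
transformed. Heatmap display uses per-row log ratios
`log2((x + 1)/(row mean + 1))`; the +1 reference keeps zero-mean rows at
exactly zero and the row-mean reference is the simplest centering consistent
with "average log-ratio" displays. Flat clusters come from cutting the tree
at *k*; sample exclusion (e.g. a technically failed lane) is a
configuration list, not an algorithm.

## Synthetic-data generator

The generator emulates the study design: 5 donors × 5 lineages, 623
endogenous probes, 6 negative controls. Endogenous counts are
`round(2^(baseline_i + lineage_effect_ic + donor_d + ε))` — lognormal
around a lineage profile, then rounded, because the platform reports
deterministic molecule counts and all downstream statistics run on
normalized continuous values; a count-dispersion model would add nothing
the pipeline measures. Defaults: per-probe baselines N(6, 3.5²) on the log2
scale (spanning the several orders of magnitude real profiles show), donor
SD 0.3 (an additive log2 shift shared by one donor's samples, emulating
paired sampling), residual SD 0.25. The default planted structure places
six lineage-preferential miRNAs per lineage at fold changes 4–64, one
lymphoid-shared probe, one erythrocyte-dominant probe (512-fold on a high
baseline, emulating a single miRNA carrying much of the erythrocyte
content) and five zero-effect normalizer candidates at residual SD 0.05.
Negative controls are truncated-normal at zero with mean 8 and SD 3 counts
(raw background magnitudes are unpublished; tens of counts or less is a
realistic platform background, and only the first two moments enter the
threshold).

Electropherograms are mixtures of Gaussian peaks truncated at ±6 SD so
each component sits entirely on its side of the relevant assay cutoff: the
total-RNA trace has a small-RNA peak (70 ± 13 nt) and two ribosomal-like
peaks (1900 ± 100, 3900 ± 150 nt); the small-RNA trace has a miRNA peak
(22 ± 3 nt) and a larger small-RNA peak (95 ± 9 nt). Component weights are
the requested area fractions, so planted fractions are recovered to well
under 1%; pointwise multiplicative noise (SD 2%) perturbs traces without
moving area fractions. The study-scale trace set splits each lineage's
miRNA:total ratio evenly between the two assay fractions (each set to the
square root of the ratio).

**What the generator does not emulate:** probe cross-hybridization,
codeset batch effects, ligation bias, count overdispersion beyond
lognormal, extracellular/microvesicle miRNA pools, or donor-by-lineage
interactions. Passing tests therefore demonstrate correctness of the
computations under the stated error model, not robustness to those
platform artifacts.

## Numerical choices and degenerate inputs

- Geometric means are computed in log space; a zero in the top-n set (with
  zero pseudocount) is an error naming the sample.
- AUC fractions clamp cutoffs outside the size range to 0/1 and error on
  zero-area traces.
- BH adjustment is delegated to `statsmodels` (`fdr_bh`) and verified in
  the tests against an independent hand-written step-up; out-of-range
  p-values error.
- Complete-linkage agglomeration is delegated to `scipy.cluster.hierarchy`
  and verified against a brute-force O(n³) oracle; a constant sample vector
  (undefined correlation) errors, naming the sample.
- Welch ANOVA is implemented vectorized in-package (it runs per probe over
  the whole matrix) and verified against `pingouin.welch_anova`.
- All generators take explicit integer seeds and are bit-reproducible.

## Problem sizes used in validation

The packaged validation runs use the study-scale design (5 × 5 samples,
623 + 6 probes) for end-to-end checks; 1,000-probe null matrices (40
replicates) for type-I-error and FDR calibration; 100 simulated panels for
normalizer-selection frequency; 1,000 random abundance/budget draws for
share conservation; and ≤ 8-sample instances for the exact clustering
oracle. These sizes give stable Monte-Carlo estimates (binomial SEs well
inside the asserted tolerances) while keeping the suite quick to run.

## Known limitations

- The erythrocyte-override rule, the detection rule, the DE scale and the
  v1/v2 probe-rename reconciliation are under-determined by the source
  workflow; each is configurable, with the defaults documented above, and
  different readings will move headline counts (e.g. detected-in-all and DE
  totals) on real data.
- The GEO reader handles the series-matrix expression block and sample
  titles only; it does not fetch from the network and does not parse
  platform annotation blocks.
- SNK decisions are reported as significant/not at a fixed alpha; the
  stepwise procedure has no meaningful per-pair p-value.
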