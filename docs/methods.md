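# Methods

## Data model

A study is three tables: a probe panel (probe id, category, and three role
flags: myocyte-expressed, IF-suitable, contamination marker), a probe ×
segment matrix of nonnegative counts, and a per-segment annotation (donor,
ROI, cohort class, region class, compartment, infiltrate flag, and four QC
covariates). Cohort classes are `cs_biopsy`, `cs_explant`, `control_nicm`,
`control_nf`, `control_txp`; region classes are `granuloma`,
`peri_granuloma` (< 300 μm from a granuloma), `granuloma_remote` (> 500 μm),
and `vascular`; compartments are `full_roi`, `myocyte`, `stroma`,
`vascular`. Validation is strict: unknown enum values, duplicated ids and
axis mismatches are errors, never silently repaired, because a silently
coerced label corrupts every downstream stratum definition. The full-ROI
measurement is modeled as its own segment rather than a sum of compartment
AOIs; users importing real DSP exports where full-ROI data is collected
differently should check this convention.

## Segment QC

Segments are filtered on nuclei count, surface area, binding density and
background signal. The thresholds (defaults: ≥ 20 nuclei, ≥ 1600 μm²,
binding density in (0.1, 2.25), background ≤ 3× the negative-control
estimate) are conventional DSP practice, exposed in configuration and
echoed into the QC report. Filtering is deterministic and idempotent;
removing every segment is an error.

## Normalization and its selection

Quantile normalization maps every segment's sorted value vector onto the
across-segment mean of sorted vectors; ties within a segment receive the
mean of the reference values their rank range spans (this makes the result
independent of segment order, at the price that a tied segment's multiset
deviates slightly from the common reference). Alternatives: library-size
scaling to the mean total, geometric-mean scaling over designated
housekeeping probes (computed on v+1 so zero counts stay defined), and
background subtraction floored at zero. All strategies end with
log2(v + 1); base 2 makes coefficients readable as fold changes.

Strategy selection scores each candidate on sarcoid-vs-control behaviour:
(i) the absolute Spearman correlation between per-probe mean normalized
expression and the per-probe Welch-test p-value — a proxy for
intensity-dependent bias — and (ii) |fraction of significant probes
(p < 0.05) higher in sarcoid − 0.5|, a symmetry measure. Ranking is
lexicographic on (i) then (ii), lower better; ties break by method name.
The Welch test (not the mixed model) is used here deliberately: the
evaluation precedes model fitting and must be cheap; a method with no
significant probes gets symmetry 0 and a note.

## Contamination scoring

Within a myocyte segment all panel probes are ranked ascending with average
ranks; the top set is ranks strictly above 0.8 · P. The score is the
fraction of the designated immune-marker set inside the top set — a
simplified rank-percentile membership statistic rather than a full
recovery-curve AUC, because the quantity of interest is exactly "how many
immune markers sit in the top quintile". The score is invariant to any
monotone transform of the segment's values. With 8 markers and threshold
0.2, one marker in the top set keeps the segment (0.125 ≤ 0.2), two drop it
(strict inequality). Dropped segments leave only the myocyte-level view; no
probe-level floor is applied ("expressed probes" = all panel probes).

## Mixed-model differential expression

Per probe, log2 normalized expression is modeled with fixed covariates
drawn from {sarcoid, infiltrate, explant, distance} and a donor random
intercept. `distance` is the ordinal proximity code 0 (granuloma) /
1 (peri-granuloma) / 2 (granuloma-remote), entered linearly (1 df); control
and vascular-bed segments — which contain no granuloma — are coded 2 when a
contrast includes them, and the term is dropped automatically when it does
not vary in the analyzed subset.

Estimation is full maximum likelihood, not REML, so that log-likelihoods
are comparable across fixed-effect structures. The fitter profiles the
likelihood over the variance ratio ψ = σ²_donor/σ²_resid: given ψ, the GLS
coefficients and the ML residual variance are closed-form (block-diagonal
covariance, one rank-one update per donor), leaving a bounded 1-D
optimization with an explicit ψ = 0 boundary check. The test suite verifies
agreement with `statsmodels.MixedLM` (ML) to ~1e-6 in log-likelihood and
coefficients; the profiled implementation is ~25× faster, which is what
makes exhaustive model selection affordable.

Coefficient tests use Wald t statistics with between-within degrees of
freedom (donor-level covariates: donors − #between-terms; segment-level:
n − donors − #within-terms), as in `nlme` and SAS `ddfm=bw`. A plain normal
reference is measurably anticonservative at ~30 donors (null rejection
≈ 0.07 at nominal 0.05); the between-within t brings the donor-level terms
back to nominal.

Model selection fits all 2⁴ fixed-term subsets (random intercept always
kept) and compares each to the full model by a likelihood-ratio test with
df = number of dropped terms. The selected model is the smallest subset
whose LRT against the full model has p > 0.05 — i.e. the most parsimonious
model the data cannot distinguish from the full one — with ties at equal
size broken by AIC, then term order; if every reduction is significantly
worse, the full model stands. In contrasts the term of interest is
protected from removal so its coefficient is always reported.

Four contrasts are defined: `stage` (explant term; CS parenchymal
segments), `distance` (distance term; same subset), `infiltrate`
(infiltrate term; same subset) and `cs_vs_control` (sarcoid term;
granuloma-remote inflammation(−) CS segments plus control segments). For
the myocyte stratum, output is restricted to myocyte-expressed panel probes
and assumes contamination flags were applied to the matrix. BH adjustment
is applied within each (stratum, contrast) family; both raw and adjusted
p-values are emitted (conventional reporting thresholds: p < 0.05 within-CS,
p < 0.1 for CS-vs-control).

## Ordinal distance gradient

Segments are assigned distance classes 1/2/3 (inflammation(−)
peri-granuloma / inflammation(−) granuloma-remote / control) and each probe
is tested with a proportional-odds cumulative-logit model, class on
z-scored expression, Wald p on the single slope. Expression is the
predictor — the ordinal scale is the modeled variable — and z-scoring makes
odds ratios comparable across probes. Segments are treated as independent
(no donor effect; a limitation, stated), the proportional-odds assumption
is not tested per probe (3 classes and small n would make a Brant-style
test uninformative), and classes with fewer than 3 segments are excluded
with a warning.

## Granuloma heterogeneity

Variance comparison: per-probe sample variance of log2 values across
granuloma full-ROI segments versus across parenchymal full-ROI segments;
the headline fraction counts strict inequalities, ties are reported
separately. COV analysis: restricted to samples with ≥ 2 granuloma ROIs;
COV is computed on linear-scale values (2^x − 1; COV of log values is
scale-ambiguous), intra = sd/mean within one sample's granulomas, inter =
sd/mean across sample means. PCA nearest neighbor: PCA on z-scored log2
granuloma profiles, 2 components by default (mirroring a biplot), component
signs fixed so each component's largest-magnitude loading is positive
(bit-reproducibility); the statistic is the fraction of granuloma ROIs from
multi-granuloma samples whose nearest neighbor (Euclidean, PC space,
self excluded) belongs to a different sample.

## Diagnostic panel

Modeling segments are granuloma-remote inflammation(−) CS segments (label
1) and control segments (label 0), full-ROI stratum by default. Candidates
must be IF-suitable and show the same sign of (CS mean − subgroup mean) for
all three control subgroups — with a deliberately heterogeneous control
population this is a strong specificity filter. The split is stratified at
segment level (67/33 by default; a `donor_grouped` mode keeps each donor on
one side, offered because segment-level splitting lets one donor straddle
both sides — the report records the mode used). Scaling statistics come
from the training side only.

Screening: L1-penalized logistic regression at λ = 0.001 in the objective
(1/n)·Σloss + λ‖β‖₁ (scikit-learn saga solver; C = 1/(nλ)); the 4 folds
only report cross-validated accuracy at that penalty, they do not tune it.
Elimination: backward stepwise, removing at each step the feature whose
removal maximizes LOOCV accuracy (ties: higher LOOCV AUROC, then
alphabetical), forced while > 7 features remain; below that, a removal
happens only when it strictly improves LOOCV accuracy. On ties the larger
panel is kept deliberately: informative markers are often redundant, and a
tie-indifferent rule would collapse any strong panel to a minimal subset,
discarding markers a downstream IF assay could use. LOOCV refits use a Newton/IRLS solver with a
1e-6 ridge so perfect-separation folds stay finite. The classification
cut-point maximizes sensitivity × specificity (Liu criterion) over
midpoints of adjacent distinct LOOCV out-of-fold probabilities, ties to the
lowest threshold; using out-of-fold rather than resubstitution scores keeps
the cut-point honest. Held-out metrics: accuracy, AUROC (rank statistic),
sensitivity, specificity, PPV, NPV (0/0 cells reported as 0.0). The frozen
model is additionally applied to inflammation(−) peri-granuloma CS
segments, where "accuracy" is the fraction called sarcoid.

## Synthetic cohort generator

The generator reproduces the structure the inference assumes. Per probe p
and segment s of donor j:

    mu_ps = baseline_p + d_j + beta-terms(covariates of s) + compartment offset
    d_j ~ N(0, donor_sd²),  count_ps ~ Poisson(2^(mu_ps + eps)),  eps ~ N(0, residual_sd²)

A lognormal-Poisson mixture rather than a negative binomial: it realizes
the log-linear mixed model exactly in the log layer while keeping counts
integral. Myocyte segments are mixed on the linear scale with the ROI's
stroma profile using c ~ Beta(1, 45) (mean ≈ 2%), after the stroma profile
receives a +1.5 log2 boost on the 8 contamination markers and the myocyte
profile suppresses immune-class probes (−3.5 log2 for dedicated immune-cell
markers, −2 for broader immune probes) — under these settings roughly 4% of
myocyte segments exceed the 0.2 score threshold, the regime such studies
report. Full-ROI segments are area-weighted linear mixtures of the ROI's
compartment means (0.6/0.3/0.1 myocyte/stroma/vascular, configurable).
Granuloma segments add immune-marker offsets scaled by a donor-level
intensity (sd 0.8; granulomas of one donor share an activation state) plus
extra segment noise (sd 0.5) — this variance split puts the granuloma
statistics (variance fraction, cross-sample nearest-neighbor fraction) in
the range reported for real cohorts rather than at degenerate extremes.

The default study configuration is the published study design at roughly
half scale: 25 donors (7 sarcoid biopsy, 12 sarcoid explant, 2+2+2
controls), two granuloma + one peri-granuloma + three granuloma-remote +
one vascular ROI per sarcoid donor (controls: parenchymal and vascular
only), parenchymal ROIs segmented into full-ROI/myocyte/stroma AOIs, and
the built-in 79-probe panel — ~345 segments. Defaults: baseline log2 mean
6 ± 1 across probes, donor_sd = 0.5, residual_sd = 0.5 (stated assumptions;
no public dispersion estimates exist for this platform), infiltrate rate
0.2 on CS parenchymal ROIs, ~1% planted low-nuclei QC failures. Planted
effect directions follow the qualitative biology the package models (Treg
and MHC markers up in bland sarcoid parenchyma; immune effectors up with
infiltrates; fibrosis markers up, several immune markers down in explants;
MHC/adhesion markers decaying with distance). All randomness flows from one
seeded generator with a documented stream order; identical (config, seed)
pairs are bit-identical.

What the generator does not emulate: real probe-level abundance
distributions (unpublished), spatial autocorrelation beyond the donor
intercept, batch/slide effects, and segmentation artifacts other than the
stromal-contamination mixture. Passing tests therefore demonstrate the
statistical machinery recovers what it assumes, not that real data meets
those assumptions.

## Numerical choices and test design

Tolerances: the LMM is checked against `statsmodels.MixedLM` at 1e-6
(log-likelihood) and 1e-5 (coefficients); the lasso against a proximal
gradient oracle at 2e-3; rank-based statistics (contamination score, Liu
cut-point, AUROC) against brute-force oracles exactly. Simulation-based
checks (null calibration at 500 probes, power at 50–100 replicates,
classifier recovery at 20 replicates) use sizes that keep the default test
run to a few minutes while leaving binomial noise well inside the asserted
margins; each is fixed-seeded. One consequence of quantile normalization
worth knowing: strong one-directional differential expression on many
probes shifts the shared reference and induces compensating signal in null
probes, so model-recovery tests feed the model log2 counts directly — the
coupling is a property of the normalization, not of the mixed model, and is
exactly what the normalization-selection symmetry metric is designed to
catch on real data.

## Known limitations

Distance is a 3-level ordinal surrogate, not micrometers. The ordinal
gradient test ignores donor clustering. The variance comparison uses
full-ROI segments (compartment-level variance partitioning is not
implemented). PPV/NPV are undefined (reported 0.0) when a confusion-matrix
margin is empty. The classifier's segment-level split lets one donor
appear on both sides under the default mode — use `donor_grouped` for a
stricter generalization claim.
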