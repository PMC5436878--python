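# Methods

This note records the scientific model behind `vfprog`, the defaults and
why they were chosen, and what the synthetic cohort does and does not
emulate.

## The 24-2 grid and cluster criteria

The 24-2 pattern tests 54 points on a 6° lattice offset 3° from both
meridians; the two points at the physiologic blind spot (15° temporal,
y = ±3°) carry no analysable data and are removed at construction, leaving
52 locations. Coordinates are right-handed with superior y > 0 and, by
package convention, nasal x > 0 for OD; the OS grid is the OD grid
mirrored in x with indices preserved, so per-index arrays align
anatomically across eyes and all downstream logic is side-agnostic.

Cluster criteria require "adjacent locations in the same hemifield" but
clinical sources rarely pin down adjacency. The default is
**8-connectivity** on the lattice (diagonals count), matching common
cluster usage and maximizing the criterion's sensitivity; 4-connectivity
is a constructor switch. Likewise "non-edge" is not standardized: the
default rim is the superior/inferior extreme rows (|y| = 21°) plus the
extreme nasal column (|x| = 27°), 10 locations, and is configurable. The
edge exclusion applies only to the baseline screen's cluster rule — the
follow-up event criterion deliberately uses all 52 locations, mirroring
the asymmetry in how such criteria are usually stated.

An **event** is the earliest run of `1 + n_confirmations` (default 3)
consecutive *reliable* tests each containing a qualifying cluster
(≥ `min_cluster_size` same-hemifield connected locations at P < 5% or
worse on the pattern deviation plot, ≥ 1 at P < 1% or worse). Two
readings of "the cluster was confirmed" are possible: each confirming
test independently shows *a* qualifying cluster (default), or the
confirming clusters must overlap in ≥ `min_cluster_size` locations
(`same_locations_required=True`). The default is the weaker
same-definition reading; the stricter mode exists because illustrated
cases in the literature track the same three locations across tests. The
event is dated at the **final confirming test** (the onset is only
established once confirmed); dating at the first qualifying test is the
natural alternative and both are representable by reading
`qualifying_visits`. Unreliable exams (> 33% fixation losses, false
positives or false negatives) are removed before the scan, so
"consecutive" means consecutive reliable tests. Eyes with fewer than
three reliable tests are censored with a `too_few_tests` flag.

## Normative model and derived maps

The instruments' proprietary normative databases are unavailable, so the
package ships a fully synthetic normative model and accepts user tables
in the same CSV schema. Healthy sensitivity is modelled as a smooth
eccentricity decline (SAP 33 dB center, −0.25 dB/deg; FDT 30 dB,
−0.15 dB/deg) with Gaussian test-retest noise (SAP 1.7 dB, FDT 2.8 dB)
and instrument discretization (SAP 1 dB rounding; FDT snapped to its 15
levels). Every normative quantity — per-location means, total- and
pattern-deviation cutpoints at P = 5/2/1/0.5%, the PSD 95th percentile,
and the GHT-surrogate zone thresholds — is the corresponding empirical
quantile of 8,000 simulated healthy fields, so the flagging rates are
calibrated by construction rather than assumed. Pattern deviation uses
the classical general-height adjustment (subtract the 7th-best total
deviation, the 85th percentile of 52). MD and PSD are the unweighted
mean and SD of total deviation; the instruments' variance-weighted
formulas need proprietary weights, so the unweighted moments are used and
documented as an approximation (weights can be supplied via the normative
table). Probability levels read "or worse" inclusively: a deviation
exactly at a cutoff receives that level.

The **GHT surrogate** keeps the architecture of the Asman–Heijl glaucoma
hemifield test — five mirrored superior/inferior zone pairs scored by
probability-level ranks (1/2/5/10 for 5/2/1/0.5%), classified against
healthy percentiles (97% borderline, 99.5% outside normal limits) — but
its zones and limits are package-defined, not the proprietary algorithm.

## Scale conversion

One SAP dB is 0.1 log10 unit of Weber contrast sensitivity; one FDT dB is
0.05 log10 unit of Michelson contrast sensitivity. MD/PSD are therefore
divided by 10 (SAP) or 20 (FDT) for the common-scale analyses, and the
same linear 2:1 relation is applied throughout, including outside the
strictly linear psychophysical range (the known nonlinear correction near
the floor is out of scope). FDT quantization snaps to the nearest of the
15 levels with ties resolved to the **lower** level (conservative toward
worse sensitivity; configurable).

## Agreement and survival statistics

Cohen's κ uses the standard 2×2 definition with the non-null large-sample
variance (Fleiss–Cohen–Everitt) for its CI and the Landis–Koch bands for
interpretation; the conventional band list leaves (0, 0.01) unlabeled and
the package folds it into "slight". McNemar is the **exact binomial**
two-sided test on the discordant cells (it reproduces printed two-decimal
p-values that the χ² approximation does not).

Kaplan–Meier and the Gehan–Breslow test (weighted log-rank with the
number at risk as weight) compare time-to-detection between instruments,
pooling the two eyes of a subject as the original analyses appear to do.
The Cox model uses maximum partial likelihood under an independence
working assumption with a **cluster-robust sandwich** aggregating score
residuals within subjects. Estimation stands on lifelines, which handles
ties by Efron's method; tie handling is immaterial at the tie density of
visit-quantized onset times and the robust variance was verified against
a score-residual oracle on tie-free fixtures (where Efron and Breslow
coincide). Covariates are rescaled before fitting so hazard ratios come
out per reporting unit (RNFL per 10 µm, cup–disc area ratio per 0.1).

## Trend model

For MD and PSD in common log10 units:

y_ijt = β₀ + β₁·FDT + β₂·t + β₃·t·FDT + u₀ᵢ + u₁ᵢ·t + v_ij + ε_ijt

with SAP the reference type, t in years from each eye's baseline,
(u₀, u₁) an unstructured-covariance random intercept/slope per subject,
v an independent random intercept per eye nested in the subject, and
i.i.d. residuals. Fitting is REML (standard for variance components; ML
available), Wald tests use the normal approximation (no df correction).
The per-instrument rate of change in dB/yr is β₂×10 for SAP and
(β₂+β₃)×20 for FDT.

## Power simulation

The power analysis simulates the hierarchical model itself: balanced
design, default 100 subjects × 2 eyes × visits at years 0–4, 500
repetitions, α = 0.05, significance from the Wald test of the time slope.
The headline target slopes are −0.01 log10/yr (MD) and 0.005 log10/yr
(PSD). Variance-component defaults (subject intercept 1e-3, slope 2.5e-5,
covariance −5e-6, eye intercept 4e-4, residual 9e-4, log10² units) were
chosen to mimic a glaucoma-suspect cohort's PSD process: they put
baseline SAP PSD near 1.5 dB with test-retest scatter of ~0.3 dB and
between-subject slope scatter of the same order as the mean slope. Under
these defaults the design's power at the target slopes is effectively
saturated (≈100%), consistent with published empirical powers in the high
90s for the same design; the exact published figures are not claimed
because the underlying variance components were never printed.

## Synthetic cohort generator

Defaults follow the cohort the analyses were designed for: 155 subjects,
66 of them contributing both eyes (221 eyes, drawn as a fixed count so
the default scale is exact), GON:OHT mix 100:121, visit count
5 + Poisson(1.7) truncated at 13 (median 6, range 5–13 — a skewed count
is required for that median), inter-visit intervals N(11.0, 2.8) months
truncated at 3, ages N(57.2, 8.9). Progression is a per-eye Bernoulli
(default fraction 0.12) whose logit shares a subject-level propensity
(SD 1.0) between fellow eyes and increases with age (0.08/yr), creating
the within-subject correlation and age–risk association the survival
stage is meant to detect. A progressing eye receives a defect injected at
a uniformly drawn visit ≥ 2: a connected region grown by randomized
breadth-first search within one hemifield (initial 3 locations, +0.75
locations/visit, max 10), each location deepening linearly (2 dB/visit,
floor −22 dB, SAP scale). The same physiological loss is expressed as
twice as many FDT dB as SAP dB (equal loss in log10 units). Measurement
follows the instruments' signatures: SAP noise SD = 1.7 + 0.15·depth dB
(heteroscedastic), rounded to 1 dB in [0, 40]; FDT noise SD = 2.8 dB
(homoscedastic), snapped to the 15 levels. Baseline visits are resampled
until the eye passes the two-test baseline screen, matching the cohort's
defining property. "True onset" in the truth table is the first visit at
which ≥ 3 locations are truly beyond the SAP TD 5% cutoff; late or
shallow injections may never cross it within follow-up.

What the generator does **not** emulate: staircase/ZEST response
psychophysics, media-opacity and lid artifacts, diffuse-loss progression
phenotypes, learning effects, and real normative-database structure.
Passing tests therefore demonstrate the correctness and calibration of
the analysis chain under the stated data-generating model, not clinical
performance on real fields.

Two auxiliary generators draw tables *directly* from the downstream
models for parameter-recovery testing: a proportional-hazards event table
(age log-HR log 1.13, shared log-normal frailty SD 0.25, exponential
baseline hazard 0.06/yr, uniform 3–8-year administrative censoring) and a
long global-index table from the trend LMM at the default fixed effects
(PSD: intercept 0.154, FDT offset −0.015, slope 0.005/yr, interaction
−0.001). Recovery at these effect sizes is what the refit checks in
`tests/test_acceptance.py` assert.

## Numerical and design choices

* Cutpoint monotonicity is enforced after empirical-quantile estimation
  (running minimum) and validated on load; non-monotone user tables are
  rejected.
* Cluster search builds connected components (networkx) on the
  hemifield-restricted adjacency; a union-find oracle double-checks it in
  the tests.
* MixedLM fits try lbfgs, then powell, then cg; non-convergence raises,
  and near-zero variance components set a `singular` flag rather than
  failing.
* Eye-level random intercepts are coded by within-subject eye labels, so
  the variance-component design stays narrow regardless of cohort size.
* Times are integer days internally; months (365.25/12 days) and years
  (365.25 days) only at reporting boundaries.
* Problem sizes in the heavy test suites (500-rep coverage at 40
  subjects; 200-rep size check; 60-rep 3×3 power grid; 1,000 random maps
  for the cluster oracle) were chosen as the smallest scales at which the
  binomial/Monte-Carlo tolerances stated in the tests are meaningful.

## Known limitations

* The GHT surrogate and synthetic normative model are stand-ins; absolute
  abnormality rates on real exports will differ from machine printouts.
* MD/PSD are unweighted moments unless weights are supplied.
* Detection times are treated as exact at the confirming visit
  (no interval-censoring model), as in the analyses this mirrors.
* The Breslow test pools fellow eyes; a stratified or cluster-adjusted
  variant is not provided.
* The linear dB↔log10 conversion is applied everywhere, including the
  range where the true SAP–FDT relation is known to bend.
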