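# Methods

`corticomap` implements a case-control analysis pipeline for primary-motor-
cortex organization of trunk muscles in low back pain (LBP): transcranial
magnetic stimulation (TMS) mapping of four trunk muscles, spiral-tracking
motor control, a quantitative-sensory-testing (QST) battery, and the
multivariate multilevel models that compare groups and relate map features
to clinical tests. Because no participant-level data are public, the
package ships a synthetic-cohort generator with known ground truth; every
estimator is validated by parameter recovery against that truth.

## MEP extraction

EMG is high-pass filtered at 30 Hz with a 4th-order Butterworth applied
forward-backward (`sosfiltfilt`), i.e. zero-phase with the squared
magnitude response. Each stimulation defines a half-open 500 ms epoch
starting at the pulse (no pre-stimulus offset or artifact blanking by
default). An epoch is an MEP when its peak-to-peak amplitude strictly
exceeds 50 µV; within a muscle's session, accepted MEPs strictly below 25 %
of the largest accepted response are then discarded (ties with the 25 %
threshold are retained, and the peak always survives, so the retained set
is never empty and the filter is idempotent). The 25 % rule is scoped per
muscle × session.

## Map features

Sites are in template (MNI-like) millimetre coordinates: X medio-lateral,
Y posterior–anterior, Z vertical. Cohorts mix stimulated hemispheres
(contralateral to the most painful side), so maps are mirrored onto a
canonical side before group analysis. We pool onto the **left** hemisphere
(X < 0): "more lateral" is then *more negative* X, which makes a lateral
shift in the LBP group appear as a negative group coefficient.

The center of gravity is the amplitude-weighted centroid
CoG = (Σ V_i X_i / Σ V_i, Σ V_i Y_i / Σ V_i, Σ V_i Z_i / Σ V_i).
It is invariant to uniform amplitude scaling, equivariant under
translation, and always lies in the convex hull of the retained sites.

Cortical area is a planar extent: the 3-D site cloud is projected onto its
best-fit plane (centered SVD), and the area is that of the **alpha shape**
of the projected points — the union of Delaunay triangles with circumradius
≤ α, default α = 15 mm — with the convex hull available as the α → ∞
alternative. The alpha shape tolerates non-convex maps; its area is
monotone non-decreasing in α and bounded by the hull area. Fewer than
three non-collinear sites give area 0 with a degeneracy flag (the CoG is
still defined); a session with no accepted MEP at all is a missing outcome.
This planar alpha-shape definition is this package's own, reproducible
contract; cortical-surface mesh algorithms used elsewhere may differ.

## Spiral tracking

The target moves anticlockwise along an Archimedean spiral, r(θ) =
R_max·θ/θ_max with R_max = 6.25° and θ_max = 2π·n_turns (default 4 turns at
constant angular rate over a 120 s trial; only the extent, direction and
approximate duration are constrained by the protocol, so turns and rate are
package choices). The per-sample error is the Euclidean distance between
target and cursor. Outcomes: `angular_near`, the mean of the smallest
⌈q/100·n⌉ errors (q = 90 %); `time_near`, the percentage of samples with
error < r (r = 0.9°); and `path`, the sum of all per-sample errors. `path`
as defined grows with the sampling rate, so the rate is recorded with the
outcomes and an arc-length variant (`travelled_distance`) is provided as a
non-default alternative. The first of the two recorded trials is practice
and excluded from analysis.

## Clinical scoring

Vibration (0–8 tuning-fork scale) and pressure pain threshold (N) are means
of three trials. Temporal summation is mean(train-of-10 ratings) −
mean(single-stimulus ratings) over five repetitions (0–10 scale).
Conditioned pain modulation: absolute = mean(PPT during conditioning) −
mean(PPT before); relative = 100·absolute/before. Positive CPM means the
threshold rose (inhibition); a sign switch is available for the opposite
convention. Graphaesthesia is incorrect/20. Two-point discrimination uses
an ascending staircase from 20 mm in 5 mm steps per location (threshold =
first "two" report); the subject's score is the mean of six locations; a
staircase that never reports "two" is missing unless a ceiling value is
configured. NPRS ratings of the conditioning hand are carried in the
schema but enter no score.

## Statistical models

Outcomes of related tests are stacked long (one row per subject × test) and
analysed in one linear mixed model with a subject-level random intercept:
fixed effects Test + Group + Group×Test, parameterised as
`value ~ 0 + C(test) + C(test):lbp` so each interaction coefficient is the
per-test LBP − control difference. Families: area (4 muscles), one model
per CoG axis (muscles as the Test variable — axes are unit-incommensurable,
and this reproduces the per-axis presentation), QST-pain (TS, PPT, CPM
rel/abs), sensory accuracy (TPD, graphaesthesia, vibration) and motor test
(path, angular_near, time_near). Associations replace the group indicator
with a continuous clinical predictor (per-muscle slopes); a pooled
association significant at α = 0.05 is re-fitted within each group.
Two-point-discrimination association coefficients are reported ×5 in the
rendered tables, matching the test's 5 mm step.

Estimation is REML (statsmodels MixedLM); inference is Wald with normal
critical values, CI = β ± 1.96·SE — a large-sample approximation that
leaves coverage slightly below nominal at n = 25/group (measured ≈ 94.8 %).
Residual variance is homogeneous across a family's tests. Missing outcomes
are dropped, not imputed. No multiple-testing adjustment is applied; the
shared multivariate model is relied on to temper multiplicity. When the
REML subject-intercept variance is driven to zero the optimizer may report
non-convergence; the fit then falls back to the exact σ²_u = 0 limit (OLS
on the same fixed effects) and is flagged `random_intercept_boundary`.
Zero-variance degenerate input yields β = 0, SE = 0 with a `singular_fit`
flag.

## Synthetic cohorts

The generator emulates the study design: 25 LBP + 25 matched controls
(paired age/sex), hemisphere mix ≈ 9 left : 16 right, four trunk muscles,
100 stimulations per session, ~2-minute tracking trials, full QST battery,
and 6.5 % of motor-map outcomes deleted completely at random (a deleted
slot becomes a session in which no MEP can be elicited).

* **MEP surface** — isotropic Gaussian bump: amplitude = peak·exp(−d²/2σ²)
  with peak 400 µV and σ = 10 mm around the muscle's true CoG; white EMG
  noise of 5 µV SD per sample; each epoch embeds one biphasic 100 Hz
  deflection whose peak-to-peak equals the surface amplitude exactly in the
  noiseless case. Sites are uniform over a 60 × 60 mm patch in x–y with z
  on a paraboloidal scalp dome (radius 100 mm) — a strictly planar patch
  would make the vertical CoG constant. With these settings the median
  3-D CoG recovery error over sessions is ≈ 1.8 mm.
* **Outcomes** — value = test mean + group effect·1[LBP] + subject
  intercept + residual, with per-test (mean, subject SD, residual SD)
  triples and a single standard-normal subject draw scaled per test, which
  induces the within-subject correlation the mixed models exploit. Default
  planted effects are the study-scale ones a working pipeline should
  detect: temporal summation +0.992, longissimus-L5 medio-lateral CoG
  −5.916 mm, obliquus-internus vertical CoG −2.709 mm; all other effects 0.
* **Tracking** — spiral target through a first-order lag (τ = 0.15 s) plus
  isotropic angular noise (0.3° SD per axis); with lag 0, isotropic noise σ
  makes the mean error the Rayleigh mean σ√(π/2).
* **Raw QST records** — constructed to score back to the planted outcome
  values exactly, except where the instrument quantises (graphaesthesia to
  a count of 20, TPD to the 5 mm grid) and for relative CPM, which is
  functionally determined by PPT and absolute CPM in the raw path.
* **Determinism** — every entity draws from a substream keyed by a stable
  CRC-32 hash of (seed, subject, role); identical configs are byte-identical
  and adding subjects never reshuffles existing ones.

What the generator does **not** emulate: realistic EMG spectra beyond what
the 30 Hz filter and peak-to-peak detection exercise, anisotropic or
multi-peaked cortical representations, informative missingness, practice
effects in tracking, or heterogeneous residual variances within a model
family. Passing recovery tests therefore demonstrates correctness of the
estimators under the stated generative model, not robustness to every
property of real data. A planted *vertical* CoG group shift is visible to
the outcome-table route but not to the raw-session route (stimulation sites
are surface-constrained, so the weighted z-centroid cannot follow an
amplitude center below the surface).

## Problem sizes and numerical choices

Calibration simulations use 25 subjects/group with four stacked tests,
shared-scale variance components (subject SD = residual SD = 1), 250
replicates for CI coverage and 150 for type-I error; recovered-effect
reports average 150 replicate cohorts. Smoke/determinism runs use 3–4
subjects/group, 20 stimulations and 5 s trials. Ties at the closest-q%
cut are kept in stable-sort rank order; the alpha-shape excludes
zero-area triangles; Wald p-values are floored at the smallest positive
float; CSV output is UTF-8 with "." decimals, and every written file
carries the run-config hash in a `#` header line.
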