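# Methods

This note documents the models, defaults and numerical choices behind
`circdm`, and what the synthetic-data experiments do and do not establish
about real data.

## Global circRNA burden

Counts are converted to CPM by dividing by the per-sample count of reads
mapped to the transcriptome — supplied on the sample sheet and shared
between the circular and linear matrices — never by per-matrix column
sums: back-splice junction counts are a small fraction of a library, so a
circular matrix's own column sums would be a meaningless depth. The burden
statistic is the per-sample sum of CPM over either all detected circRNAs
("all") or the "common" set expressed in at least n − k samples (k = 1 by
default; shallow cohorts may need k = 5). "Expressed" means raw count ≥ 1;
the threshold is exposed (`min_count`) because no principled universal
value exists at back-splice depths. Groups are compared with a two-sided
Welch t test; p-values are reported unadjusted, one comparison per
stratum/feature-class panel, and muscle types are analysed as separate
strata rather than pooled.

## Candidate intersection filter

Thresholds follow their verbal definitions literally: the ratio criterion
is strict (">1" excludes exactly 1.0), the fold-change criterion is
inclusive ("at least 4-fold" keeps log₂FC = 2), and study B must show a
positive direction. The ratio criterion is evaluated in study A only;
`require_ratio_in_both=True` applies it to both, since conventions vary on
this point. Relaxing any threshold can only
grow the selected set (tested property).

## qPCR analytics

Replicate Cts are averaged before any difference is formed. Relative
expression is −ΔCt against the mean Ct of UBC and RPL23, which cancels any
per-sample additive Ct shift (RNA loading); the circ/lin ratio uses raw
Cts only and is independent of the reference genes entirely. Amplification
efficiency is assumed 100% (assays in the 93–100% range; no Pfaffl
correction). Sign convention: the raw subtraction Ct_circ − Ct_lin
*decreases* when the circular isoform rises; `circ_lin_ratio` therefore
reports Ct_lin − Ct_circ so that circular enrichment is positive, with
`literal_sign=True` giving the raw orientation. RNase R resistance is the
log₂ retained fraction −(Ct₊ − Ct₋); the conventional resistance call at
> −1 (at most twofold loss) is included as a convenience column.
Mann-Whitney U uses mid-ranks; for combined n ≤ 12 the p-value is an exact
enumeration of the permutation distribution of U (valid under ties, which
classical exact tables are not), otherwise a tie-corrected normal
approximation without continuity correction. Per-candidate p-values are
raw, with an optional Benjamini-Hochberg column.

## Biomarker evaluation

ROC thresholds sweep the unique scores with higher score ⇒ predicted
disease. The AUC is the trapezoid area and is asserted at run time to
equal the rank statistic U/(n₊n₋) (ties contribute ½) within 1e-9 — the
identity holds exactly under mid-ranks, so a violation indicates a bug,
not data trouble. Any strictly monotone transform of the score (ratio vs
log-ratio) leaves the curve unchanged. Pearson correlation p-values come
from t = r√((n−2)/(1−r²)); no multiplicity adjustment across candidates.

## Percent splicing rescue

%rescue = 100·(Ψ_DM1,NTC − Ψ_DM1,treated)/(Ψ_DM1,NTC − Ψ_CTRL,NTC). The
statistic is invariant to exchanging inclusion for exclusion percentages
and affine in the treated condition. When the three conditions share a
replicate labelling it is evaluated per matched replicate and summarised
as mean ± SEM; otherwise once on condition means. Values outside [0, 100]
are flagged but reported as computed — clamping would hide anti-rescue
(e.g. a miRNA mimic reversing the effect). A zero denominator (no
missplicing gap) raises rather than returning an arbitrary number.

## Foci imaging

The local mean threshold marks a pixel as foreground when its value
exceeds the mean over a (2w+1)×(2h+1) box centred on it plus an additive
offset; borders are padded by edge replication so the test is defined
everywhere. The (w, h, offset) presets — (250, 250, 0.06) for nuclei,
(4, 4, 0.02) for foci, and the MBNL1 union of (4, 4, 0.05) and
(2, 2, 0.1) — reflect the object scales: a window much larger than a
nucleus approximates a global background estimate, while the tight foci
window adapts to local nuclear background.

Refinement defaults: nuclei — fill holes, opening with a radius-5 disc,
and removal of components touching the image border (a partially imaged
nucleus cannot be scored; the border rule deliberately does *not* apply to
foci, which are kept if assigned to a surviving nucleus). Foci — opening
with a radius-1 disc and a 4-px minimum area, which suppresses
single-pixel noise crossings of the low offset. All radii/areas are
constructor parameters of `FociSegmenter`.

Watershed runs on the negated Euclidean distance transform with seeds at
regional maxima separated by at least `min_seed_distance` (set near the
expected object radius: 10 px nuclei, 2 px foci). Components containing a
single seed come out identical to connected-component labelling; touching
objects split at the distance-transform ridge. Mask pixels that receive no
seed (objects smaller than the seed separation) are kept as their own
labels rather than silently discarded. Labels are relabelled contiguously
from 1, and the whole chain is deterministic for a given image and
parameter set.

Foci are assigned to the nucleus covering the largest number of their
pixels, ties broken toward the lower label; unassigned foci are excluded
from all per-nucleus statistics. A focus is MBNL1-containing iff at least
one pixel lies in the MBNL1 union mask — a deliberately permissive rule at
the resolution of a binary mask. There is no algorithmic stand-in for
visual inspection of segmentation success; the label maps are written out
as 16-bit TIFFs for exactly that purpose.

## Nested mixed models

Per-nucleus and per-focus measurements are pseudo-replicated: hundreds of
nuclei per condition share sample- and experiment-level noise. Continuous
responses use a Gaussian LMM (statsmodels MixedLM, REML) with nested
random intercepts — `(1|experiment) + (1|experiment:sample)`, plus
`(1|experiment:sample:nucleus)` for focus-level intensity. Convergence is
attempted with L-BFGS and, when the gradient method stalls near a variance
boundary, certified with a derivative-free Powell restart; boundary
(singular) fits are flagged with a warning, never hidden, and outright
non-convergence raises.

Counts use an NB2 mixed model with log link fitted by Laplace
approximation, implemented in this package because no installed Python
library fits negative-binomial GLMMs: the random-effect mode is found by
damped Newton iterations on the strictly concave joint log-likelihood, the
curvature term corrects the maximised joint likelihood, and L-BFGS-B
optimises (β, log σ_experiment, log σ_sample, log θ) with bounds keeping
the variance parameters numerically safe. Standard errors come from the
numeric Hessian of the Laplace marginal log-likelihood. The fit is
cross-checked in the test suite against glmmTMB (fixed effects agree to
~1e-3 on a shared dataset). A treatment arm with all-zero counts raises a
separation error, since its log-mean is unidentified. With
`random_effects=False` both models reduce exactly to OLS / plain NB
regression (tested against statsmodels).

Contrasts: cell-means coding makes the per-state coefficients the
estimated marginal means directly (state is the only fixed term). Pairwise
differences are tested with t = Δ/SE(Δ) and adjusted with the studentized
range distribution on containment-style denominator degrees of freedom,
df = N − (#finest-level groups) − (k − 1) for the LMM — appropriate
because the treatment contrast is estimated against the residual stratum
in these designs — and asymptotic (large-df) for the count model. With two
states the adjustment is the identity. The 600-nuclei-per-condition scale
used in practice is a warning guideline, not a hard gate.

## Synthetic-data generators

The generators produce data *from the models the analyses assume*, with
recorded ground truth, so every pipeline stage can be validated for
correctness and calibration without external data.

* **Cohorts**: NB2 counts (`Var = μ + αμ²`, α = 0.3) with lognormal
  feature means and lognormal per-sample size factors (log-SD 0.3) that
  hit circular and linear counts alike, as sequencing depth does; the
  case/control circRNA effect is a single multiplicative factor on every
  circRNA mean (default 2, the magnitude of the global elevation the
  burden statistic is meant to detect), and library sizes are the summed
  linear counts (~10⁶ reads). Defaults n = 10 + 10, 300 circRNAs (mean
  count 20), 2000 genes.
* **qPCR**: Ct = base − true log₂ expression + loading shift + N(0,
  0.2²) technical noise, 3 replicates; biological log₂ SD 0.5; reference
  genes at Ct 20. Clinical covariates are linear in the anchor target's
  true circ/lin ratio (CTG slope +150 repeats, MRC slope −8 per log₂
  unit, around 400 repeats / 45 points), chosen to produce the strong
  positive/negative correlations reported for DM1 severity markers.
* **Nested responses**: count means are multiplied by lognormal
  experiment- and sample-level intercepts (log-SD 0.2 each; dispersion
  α = 1.5); dispersion 0 yields deterministic counts for unambiguous
  imaging fixtures. Treatment is a sample-level assignment for counts
  (a transfection is a property of a well/image); the Gaussian generator
  alternates states across nuclei within a sample so the state effect is
  a within-image contrast with near-nominal Wald coverage at the default
  4 × 3 × 50 design.
* **Images**: 512×512 fields; nuclei are discs (radius 12–18 px,
  intensity 0.8 on background 0.02) placed by rejection sampling with a
  ≥ 2 px gap and fully interior to the field; foci are radius-2 discs at
  intensity 0.9 on background 0.05, centres ≥ 2r+3 px apart and inside
  their nucleus; additive N(0, 0.01²) noise, clipped to [0, 1]. A stated
  fraction of foci is co-located on the MBNL1 channel. One
  `SeedSequence` per generator spawns independent child streams, so runs
  are bit-reproducible and sub-generators independent.

What passing these tests shows — and does not. Recovery and coverage
results certify the *algorithms*: thresholding recovers well-separated
bright discs, the watershed splits known geometry, the mixed models are
calibrated when their assumptions hold. Real micrographs add out-of-focus
light, intensity gradients, touching nuclei, variable focus brightness and
PSF blur; real cohorts add batch structure and outliers. None of these are
simulated (by design — see the generators' non-goals), so parameter
presets validated here still need visual QC on real images, which is why
label maps are always written out.

## Problem sizes and numerical conventions

Simulation-based checks use 200–500 replicates (test power/coverage bands
are set from the corresponding binomial standard errors), 20 seeds × 20
nuclei for image recovery, and 10,000 replicates for the Welch null
calibration; these sizes make the Monte-Carlo error small relative to
every asserted band while keeping the default suite fast. Images are
16-bit on disk (round-trip error ≤ 0.5/65535); pixel coordinates are
0-based row-major; TSVs are tab-separated UTF-8 with "." for missing
values; all stochastic entry points take an integer seed.
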