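# Methods

## The labelling statistic

A click-labelling image-cytometry sample is a set of N nuclei (N = 10,000
per sample throughout this package's protocols), each with a mean nuclear
fluorescence signal.  Incubation with EdU or EdC splits the population
into a labelled mode (cells that incorporated the analogue during the
incubation window) and an unlabelled mode (cells that did not replicate,
plus background).  Quantification proceeds in three steps.

**Labelled fraction.**  F is the proportion of nuclei above a separation
threshold on the signal histogram.  The default threshold is Otsu's
criterion applied to log10(signal + 1) with 256 bins (`otsu_log`):
fluorescence intensities are right-skewed, and the log transform makes
the two modes comparably shaped so the between-class variance criterion
lands in the valley.  Two alternatives are provided: `gmm2`, a
two-component Gaussian mixture on the log signal whose decision boundary
is the posterior crossing between the components, and `valley`, the
minimum of the smoothed log-histogram between the two modes.  `gmm2`
declares the mixture degenerate when the components overlap too much to
mark genuine bimodality (Ashman's D < 2) or one component carries < 2%
of the weight; it then warns and falls back to `otsu_log`.

**Trimmed specific signal.**  With trim margin δ (default 0.1), nuclei are
sorted by descending signal and the statistic is

    S = mean(top round((F − δ)·N) nuclei) − mean(bottom round((1 − δ − F)·N) nuclei).

The top slice stops δ·N nuclei short of the estimated labelled count and
the bottom slice stops δ·N short of the unlabelled count, so both slices
stay clear of the ambiguous boundary region even when F is off by a few
percent.  The difference form cancels any additive background common to
all nuclei exactly (offset invariance), and scales linearly with a common
gain (scale equivariance).  Counts use round-half-away-from-zero; ties in
signal are broken by a stable sort on nucleus id, which makes the
statistic independent of row order even with duplicated signal values.

F outside [δ, 1 − δ] (near-total or near-zero labelling) is an error by
default, since the trim slices would cross; a `clamp` policy instead pins
F to the nearest window edge with a warning and floors both slice counts
at one nucleus so the statistic remains defined at the edge.

**Control subtraction.**  The specific signal of an untreated control
sample (no nucleoside analogue) is subtracted from the treated sample's
specific signal.  The control is scored with the *identical* trimmed
statistic, using the treated sample's F, so the estimator form is
constant across samples; a plain-mean control mode is available by flag.
With a signal-free control the trimmed control statistic is essentially
the spread of the background, and the corrected signal approximates the
labelled-minus-unlabelled intensity gap.

**Ratios and normalization.**  Condition comparisons are summarized as
the mean of per-experiment ratios with its s.e.m. (sample sd / √n over
experiments; 0 when n = 1); mean-of-ratios rather than ratio-of-means is
used because experiments are the replication unit.  Condition panels are
normalized to a chosen reference condition as value × 100 / reference.

## Synthetic data

The generators emulate the study conditions with crisp ground truth:

* **Intensity tables** — a two-component mixture over nuclei.  Labelled
  nuclei draw a lognormal signal (median 2000, log-sd 0.5 by default):
  microscopy intensities are right-skewed and strictly positive, and the
  lognormal is the simplest two-parameter family with both properties.
  Unlabelled nuclei sit at mean 50 with Gaussian sd 10 (detector noise).
  A common additive background (default 0) affects both populations.
  Labelled assignment is exact-count — exactly round(F·N) nuclei are
  labelled — so ground-truth F is crisp for recovery tests; Bernoulli
  assignment is available by flag.  Negative draws clip to 0.
* **Images** — nuclei are non-overlapping disks (uniform radius 8–12 px,
  pairwise gap ≥ 2 px by rejection sampling with bounded retries), DAPI
  value 8000 inside the disk, click-signal value equal to the nucleus's
  true mean; pixel noise is additive Gaussian.  Images are float arrays
  clipped to [0, 65535]; quantization to uint16 happens only at TIFF
  write time, so the noiseless generate → segment → measure closure is
  exact in memory.  Not emulated: PSF blur, uneven illumination,
  chromatic shift, Poisson photon statistics, overlapping or mitotic
  nuclei — passing tests show the estimators are correct on separable
  disk-like nuclei, not that segmentation is robust to crowded or
  blurred real fields.
* **Plates** — responses are 4PL(c) + N(0, 5%) on the 8-point fivefold
  series 0.0032–250 µM, 4 replicates.
* **Pools** — concentrations proportional to prescribed shares with
  mean-preserving multiplicative lognormal noise of a given CV.

One top-level seed feeds fixed per-operation sub-streams
(`SeedSequence(seed, spawn_key=(tag,))`), so generating one output never
shifts the draws of another.

## Segmentation

Default threshold is Otsu on the raw DAPI histogram (256 bins); the label
count is invariant to rescaling the image by a positive constant.  The
default area filter is 50–5000 px, matched to the synthetic pixel scale
(disk radius 8–12 px → 200–450 px areas) and configurable for real
magnifications.  Touching-nucleus splitting is off by default (synthetic
scenes are non-overlapping); when enabled it is a watershed on the
distance transform seeded at local maxima with a minimum separation of
one minimum nucleus radius.  Border objects are kept by default; both
switches are explicit parameters.  Coordinates are x = column, y = row,
0-based.

## Dose-response fitting

Unweighted least squares on R(c) = bottom + (top − bottom)/(1 + (c/IC50)^hill),
with IC50 fitted as log10(IC50): the parameter is positive and
log-symmetric on a geometric dilution design, and the log scale keeps the
8-point fit well conditioned.  Initialization: top/bottom from the
extreme mean responses, hill = 1, IC50 at the concentration whose mean
response is nearest the midpoint.  Bounds: hill ∈ [0.1, 10], IC50 ∈
[min conc/100, max conc × 100].  The 95% CI on IC50 comes from the
covariance of log10(IC50) with a t critical value on n − 4 degrees of
freedom.  Responses are expected as % of the untreated control
(`normalize_responses` applies the explicit control constant).

A fit is right-censored ("IC50 ≥ max concentration") when the fitted
IC50 exceeds the highest tested concentration, when the fitted curve
never drops below 50% within the tested range, or when the optimizer
fails while the observed response at the top concentration is above 50%.
The absolute-50% clause assumes control-normalized responses; plates on
other scales should be normalized before fitting.

## Nucleoside quantification

Within one HPLC run, Beer–Lambert absorbance makes peak area / ε
proportional to molar amount (path length and injection volume cancel in
ratios), so all quantification is relative; absolute molarity needs an
explicit calibration constant and is never defaulted.  Built-in ε values:
dT 8700, dC 7400, dA 15,400, dG 11,700 l·mol⁻¹·cm⁻¹ at 260 nm, EdU
12,000 at 289 nm; EdC's coefficient must be supplied when EdC is
quantified.  The EdC detection flag compares the EdC:dT molar ratio to a
limit of 10⁻³ (≥ counts as detected) and reports the upper bound
limit × dT amount otherwise.  Pool shares are percentages of the summed
concentrations of a configurable *monitored* species list (non-detected
species contribute 0 but stay listed).  Phosphorylation-state ratios are
share quotients, additionally reported as a small-integer "p : q" form
when a pair with denominator ≤ 20 matches within 2% (30:70 → "3 : 7").

## Problem sizes and tolerances

Recovery protocols use the study's own scale — 10,000 nuclei per sample,
20 seeds for labelled-fraction recovery (tolerance ±0.02 on the mean),
100 seeds for IC50 CI coverage (≥ 90% nominal-95% coverage) — chosen
because the estimators are cheap enough that nothing needs scaling down.
Noiseless recovery checks use relative tolerance 1e-6 (optimizer
tolerance); exact structural identities (oracle equivalence, share
normalization) are asserted to the last floating-point digit or 1e-9.

## Known limitations

* The synthetic intensity distributions are plausible defaults, not
  fitted to empirical histograms; absolute signal levels are arbitrary
  units.
* Segmentation targets well-separated, roughly convex nuclei; heavily
  overlapping fields need the watershed mode and may still undersplit.
* The 4PL CI is a Wald interval on log10(IC50); very shallow or barely
  identified fits can report optimistic intervals (coverage is verified
  only at the operating points tested).
* Censoring uses an absolute 50%-of-control clause and therefore assumes
  normalized responses.
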