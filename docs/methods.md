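# Methods

## The problem and the analysis

When a luminance, colour or texture boundary must be grouped into an
oriented structure, the visual system weights the competing cues.  The
analysis implemented here quantifies that weighting with a two-condition
forced-choice design.  Two cues (always "Texture" against one of "Dark",
"Red" or "Violet") are shown either in *separate* stimuli (a two-interval
saliency judgement) or *combined* on orthogonal oblique axes of a single
lattice (an orientation judgement).  Each session sweeps eight
logarithmically spaced contrast-ratio levels (the ladder pairs the
increasing levels of one cue with the decreasing levels of the other:
a1–b8, a2–b7, …, a8–b1) with 20 trials per level.

The proportion of trials on which the non-texture cue is judged more
salient is modelled as a logistic function of the log contrast ratio
`x = log10(c_nontexture / c_texture)`:

    p(x) = 1 / (1 + exp(-beta * (x - alpha)))

`alpha` is the point of subjective equality (PSE): the ratio at which the
two cues group equally strongly.  `beta` is the slope per log10 unit.  The
quantity of interest is the per-observer PSE shift

    Delta = alpha_Combined - alpha_Separate,

which is zero if the cues do not interact beyond their separate saliencies.
A positive Delta means less texture contrast is needed to balance the other
cue when the cues compete — texture dominance.  Group inference is a paired
t test over observers, with Cohen's d = mean/SD and the repeated-measures
effect size r = sqrt(t²/(t²+df)).  A mean shift in log units is also
reported as "percent more contrast required", 100·(10^Delta − 1), truncated
(not rounded) to a whole percent; truncation is the convention that
reproduces the published whole-percent values from the published mean
shifts.  Because a PSE shift can be mimicked by a change in psychometric
slope, the same paired-t machinery is run on the per-observer slope changes
`Delta-beta` as a control analysis.

## Cardinal-mechanism stimulus algebra

Patch colours are Weber cone contrasts `(Lc, Mc, Sc)` against the mid-grey
background (chromaticity x = 0.282, y = 0.311; 40 cd/m²).  The three
post-receptoral mechanisms are modelled as

    LUM  = (k·Lc + Mc) / (k + 1)
    L−M  = Lc − Mc
    S    = Sc − (Lc + Mc) / 2

where `k` is the observer's L:M luminance weight (measured at isoluminance;
the seven measured values ship as a fixture table).  The exact coefficient
placement of `k` and the S-mechanism normalisation vary across the
literature; these standard forms are adopted as a convention and isolated
behind `mechanism_matrix`, with the *isolation constraints* — zero response
in the two non-target mechanisms, cue-contrast metric preserved — as the
binding, tested contract.  Cue directions are obtained by solving the 3×3
linear system that zeroes the two non-target rows and pins the cue's own
contrast metric:

* Dark: common cone contrast (all three cones equal), applied as a
  decrement; metric |Lc| (= |Mc| = |Sc|).
* Red: L−M increment at zero LUM and S response; metric |Lc − Mc|.
* Violet: S-cone increment at zero LUM and L−M response; metric |Sc|.

Texture is a second-order cue: binary luminance noise at ±amplitude about
the background, i.i.d. per pixel, so it adds no low-frequency luminance
signal and (being on the luminance axis) no L−M or S signal.  Its contrast
metric is amplitude/mean.  An optional balanced mode forces exactly equal
counts of light and dark pixels per circle; i.i.d. is the default because
the noise is conceptually unconstrained random allocation.

Cone contrasts map to linear display primaries through a 3×3
`lms_to_primary` calibration matrix anchored at the background.  The
default matrix composes the Hunt–Pointer–Estévez cone matrix with the
sRGB-to-XYZ primaries matrix — a documented stand-in for a measured
phosphor calibration; users with measured calibrations supply their own
matrix as JSON.  Out-of-gamut requests raise an error naming the offending
primary; values are never silently clamped, because clamping would corrupt
the cue-contrast metric that the whole analysis is calibrated in.

## Stimulus geometry and rendering

The lattice is a square grid rotated 45°, clipped to a disc: grid diameter
8.9°, circle diameter 0.383°, oblique separation 0.68° (cardinal 0.96° ≈
0.68·√2), each circle ringed by a 1-px black line, rendered at a
configurable 40 px/° by default.  Circles clipped by the disc boundary are
excluded entirely so every rendered circle carries a well-defined cue
contrast.  Cues occupy alternate rows of one oblique axis.  In the Combined
condition the orthogonal cue takes alternate rows of the other axis among
the circles not already claimed — every left-oblique row crosses every
right-oblique row in this lattice, so full alternate rows on both axes
cannot be spatially disjoint; giving the first cue precedence at crossings
keeps the assignment disjoint (no circle carries two cues) at the cost of
gaps in the second cue's rows.  The row stride (every second row) is
configurable.

Each presentation consists of two video pages alternating at the frame
rate: cue A on page 1, and on page 2 either mid-grey (Separate) or cue B
(Combined).  The temporal average therefore carries every cue at half its
nominal contrast, and all analysis-level contrasts refer to the halved
values.  Rendering is anti-alias-free for testability; presentation timing
(500 ms, 500 ms ISI) is carried as metadata only.

## Synthetic observers

The generator inverts the decision model: per level, responses are
`Binomial(n, p(x))` draws.  A cohort draws each observer's true shift from
`Normal(mean_shift, sd_shift)` — the minimal generative assumption when
only the mean and SD of observed shifts are reported — and shares
`base_alpha` and the condition slopes across observers.  The default study
conditions are 7 observers, 8 levels × 20 trials (160 trials/session),
true mean shifts 0.091 / 0.079 / 0.06 log units with SDs 0.04 / 0.034 /
0.05 for the Dark / Red / Violet comparisons, `base_alpha = −0.1`, and
`beta = 10` per log10 unit in both conditions.  The slope default is a
plausible fitted magnitude for this design (no per-observer slopes are
published); the ladder default spans 0.1–0.32 for both cues, giving log
ratios of ±0.505 in steps of 0.144 — wide enough to bracket the PSEs with
the outer levels near saturation, as a constant-stimulus design intends.

One master `SeedSequence` spawns a substream per observer session, so a
cohort is bit-reproducible from its seed while sessions stay independent.

What the generator does *not* emulate: lapses and finger errors, interval
or response bias, learning across sessions, between-observer variation in
slope or in Separate-condition PSE, and any stimulus-level nuisance
(fixation, adaptation).  Passing recovery tests therefore show that the
fitting and inference machinery is unbiased and calibrated *under the
decision model*, not that real observers satisfy that model.

## Fitting and uncertainty

`LogisticPsychometric` maximises the binomial log-likelihood with guess and
lapse rates fixed at zero (the model is a pure two-parameter logistic).
Because 8-point datasets can have flat or multimodal likelihoods, the
optimiser is a multi-start Nelder–Mead in `(alpha, log beta)` seeded from a
coarse 41×25 grid (alpha spanning the data range extended by a full range
either side; beta 0.25–400 per log10 unit), objective tolerance 1e−8.
Internally the abscissa is centred (making translation equivariance exact
to optimiser tolerance) and levels are sorted (making the fit invariant to
level reordering).  All-zero, all-ceiling or constant-proportion data raise
a non-identifiability error — no finite ML slope exists; a fitted slope
above 1e4 (a step function; perfect separation) marks the fit
non-converged rather than returning a silently unstable value.

Standard errors are parametric-bootstrap (400 resamples by default):
`k* ~ Binomial(n, p_hat)` per level, refit, SD of the refitted parameters,
deterministic given a seed.  Refits that fail identifiability are dropped;
if more than 20% fail, the result carries an unstable-fit warning.  The
bootstrap type is a design choice (the published analysis does not state
one); nonparametric trial resampling would require trial-level data that
the count format does not retain.

## Numerical and statistical conventions

* Degenerate paired samples (numerically zero SD) raise an error rather
  than returning an undefined t.
* p values are two-tailed; no multiple-testing correction across the three
  comparisons (matching the published analysis).
* The percent conversion truncates toward −∞; it is monotone and inverts
  exactly before truncation.
* The slope `beta` is in units of the log10-ratio abscissa; slope values
  are comparable across analyses only up to this parameterisation
  convention.
* Trial tables are CSV with a version-comment header; file writes are
  atomic (temp file + rename).  Workbook ingestion accepts .xlsx with a
  user-configurable column map, since deposited layouts vary.

## Problem sizes used in the test suite

Monte-Carlo tests run at the study-scale design (7 observers, 8 levels ×
20 trials).  Mean-shift recovery uses 200 replicate studies; the
null-rejection calibration uses 1000 replicate null studies (at 200
replicates the ±3 SE Monte-Carlo band spans 0.4–9.6% and single seed
blocks dominate the verdict); sampling-SD cross-checks use 500 replicate
sessions; bootstrap-based checks use 100–400 resamples.  These sizes keep
Monte-Carlo error well below the assertion margins.

## Known limitations

* The cone→primary default matrix is an sRGB-like convention, not a
  measured display calibration; absolute chromaticities of rendered PNGs
  are nominal.
* Gamma correction, LUT generation and hardware display loops are out of
  scope; rendered images are linear-light.
* The slope-change control analysis inherits the t test's normality
  assumption on fitted-slope differences, which is rough for 8-point fits.
* The estimator fixes lapse rate at zero; real observers' lapses bias
  fitted slopes downward and can inflate PSE variance.  With the deposited
  count format this is not recoverable, and the published model makes the
  same assumption.
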