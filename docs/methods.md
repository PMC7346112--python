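# Methods

## Model and assumptions

The pipeline treats a 1D ¹H NMR spectrum of an oxidising oil as a linear
superposition of Lorentzian lines. Under complete relaxation the area of each
line is concentration × proton count × a global constant, so concentrations
follow from area ratios alone. The triglyceride glyceryl *sn*-1/*sn*-3
protons are the internal reference: 4 protons per TG, present at exactly
1 mol TG per mol TG, and essentially untouched by oxidation (hydrolysis is
negligible over the 16-day course). All concentrations are therefore
expressed in mmol per mol TG; acyl-group closure holds at day 0
(Σ acyl = 3 chains × 1000 = 3000 mmol/mol TG).

Assumptions worth stating explicitly:

* one Lorentzian per catalogued signal — multiplet fine structure is not
  modelled, because only areas enter the quantification;
* flat baseline (true for the generator; a linear-baseline option is the
  obvious extension for real instrument data and is deliberately not applied
  by default to keep the core deterministic);
* the spectral axis is descending ppm (NMR convention); integration windows
  are closed ppm intervals.

## The signal catalogue

One row per quantifiable signal: owning compound class, center, window,
proton count *n*, multiplicity, role (`quantifier` / `reference` /
`qualifier`), and an ordered list of correction dependencies. Exactly one
compound is the reference; it is modelled as **two sub-windows**
(4.10–4.18 and 4.26–4.34 ppm) whose summed, truncation-compensated area is
`A_TG`, so late-oxidation interlopers between the two multiplets
(methine signals near 4.23–4.25 ppm) never enter the reference area, and
those catalogued there are additionally subtracted through the reference's
corrections list. The `total_OOH` channel is an *aggregate*: it is never
rendered, and is quantified from a window that deliberately collects the OOH
peaks of all hydroperoxy species — the narrow 8.38–8.52 ppm window before
day 9, the broad 8.3–9.3 ppm window from day 9 on (the switch day is
configurable). Since each hydroperoxy group contributes one OOH proton
(dihydroperoxides two), the channel reads directly in mmol of OOH groups per
mol TG, and it coincides with the sum of the two conjugated-diene
hydroperoxide isomers until other OOH species appear on day 9.

Where the source material quotes a chemical shift it is used verbatim; where
only a center is given, windows default to ±0.04 ppm and shrink where the
region is crowded (down to ±0.004 ppm in the aldehyde CHO cluster and
±0.005 ppm in the sterol methyl region). Windows, aldehyde CHO shifts and
proton counts for composite signals that are not explicitly printed are
reconstructed from the compound-class literature and flagged `assumed` —
composite channels default to *n* = 1 (explicit uncertainty rather than
silent invention); the epoxy-monoene methine channels use *n* = 2 (two
oxirane CH protons resonate inside the stated windows).

## Overlap corrections

Corrections are area bookkeeping, not deconvolution. For a window W of
signal *i*, each contributor *j* (already quantified from its own window, in
the topological order of the corrections DAG) is subtracted as

```
A_i,corr = A_i,raw − Σ_j  c_j · n_j · frac_j(W) · (A_TG/4) / 1000
```

where `frac_j(W)` is the closed-form Lorentzian mass fraction of peak *j*
inside W. Expressing the prediction through `A_TG/4` makes the subtraction
independent of the global intensity scale, so reference-normalisation
invariance holds exactly. Negative corrected areas are clamped to zero and
flagged rather than raised: near-equal subtraction under noise must not
crash a pipeline run. The reference itself may appear as a contributor (its
concentration is 1000 by definition, so it constrains no ordering), which
removes the small but real far-tail bias of the two large backbone peaks on
nearby minor channels.

The packaged correction edges are *generated*, not hand-curated: every
(peak, foreign window) pair is scored day-by-day against the packaged
trajectories for its worst-case relative contamination; pairs above 0.5 %
become candidate edges, peaks lying physically inside a foreign window take
priority, and candidates are merged greedily with compound-level cycle
refusal so the result is always a DAG. When two channels contaminate each
other, only the stronger direction is corrected; the residual is bounded by
the weaker leak (≈1–2.5 % on a few minor, closely-flanked channels such as
the 4-hydroperoxy-alkenal CHO line; <1 % on every anchored channel).

## Truncation handling

Windows capture a finite fraction of a Lorentzian's mass. Window widths here
range from ±2 to ±500 half-widths, so truncation does **not** cancel between
analyte and reference windows; instead every integrated area is divided by
the analytic in-window fraction of its own line, `(1/π)[arctan((hi−c)/γ) −
arctan((lo−c)/γ)]`, γ = fwhm/2. This is deterministic and exact for the
modelled lineshape; for real spectra it degrades gracefully into an
approximation controlled by the configured fwhm. `integrate_window` itself
stays a raw trapezoid on the native grid (plus interpolated window
endpoints); the compensation is applied in `quantify_spectrum`. A_TG from
the reference uses the same compensation. Aggregate windows use the fraction
at the channel's nominal center (error <0.4 % for the windows involved).

The quantifier runs two passes: concentrations are first solved with the raw
reference area, the reference's interloper corrections are then applied, and
everything is re-solved with the corrected `A_TG` (the correction is ~10⁻⁵
relative, so two passes converge to numerical precision).

## The synthetic generator and the trajectory fixture

`render_spectrum` evaluates every catalogued signal of every non-aggregate
compound as a Lorentzian of area `area_scale · c · n / 1000` on a 0–10 ppm
grid with step 5×10⁻⁴ ppm (≥4 points per default fwhm of 0.002 ppm ≈ 0.8 Hz
at 400 MHz), always including the reference at 1000 mmol/mol TG, then adds
optional N(0, σ²) noise from an explicit seed (identical seeds ⇒
bit-identical spectra). Replicate simulation mirrors duplicate experimental
determinations: independent noise, same truth.

The packaged fixture encodes the 16-day course as per-compound
piecewise-linear anchor lists. Anchors are tagged by provenance:
`reported` (printed concentrations, e.g. the day-13 hydroperoxide maxima
140.9 / 48.5, the day-16 epoxy-monoenes 27.3 / 17.0, day-14
hydroperoxy-epoxide 38.7, day-16 4-hydroxy-alkenals 19.8), `derived`
(integrated from printed per-stage rates between reported values, so
stage-wise OLS on the fixture returns those rates exactly), and `assumed`
(modelling choices where nothing is printed, e.g. the day-16 values of the
six aldehyde classes without printed concentrations, chosen once so the
printed total of ≈69 and the two printed classes hold; appearance-day
concentrations set to 0.8 mmol/mol TG, just above the default detection
limit). A compound is zero before its first anchor and constant after its
last. Inter-anchor behaviour is a declared modelling choice, not data.

What the generator does *not* emulate — and hence what passing tests do not
establish about real spectra: phase and baseline artefacts, solvent and
satellite peaks, J-multiplet structure, peak-position drift with matrix
changes, and any compound absent from the catalogue. The round-trip
identity (quantify ∘ render ≈ id) validates the bookkeeping, not the
assignment itself.

## Kinetics

Stage rates are OLS slopes within breakpoint intervals, inclusive at both
ends (a shared breakpoint day belongs to both adjacent stages, matching the
"from day 8 to day 11" phrasing of stage descriptions); stages with fewer
than two sampled days yield `None`. Rates are signed (negative =
degradation). The default scheme is day 0/8/11/14/16; γ-tocopherol uses its
own two-stage scheme (0/2/11) since the antioxidant's course has a lag phase
then a near-constant decline. Events: appearance = first sampled day above
the LOD; maximum ties break to the earliest day; disappearance = first
sampled day after appearance at or below the LOD. Formation fractions are
rate ratios, `100 · r_product / |r_substrate|`, undefined (None) for a flat
substrate. The molar-% → mmol/mol TG conversion is `pct × 3000 / 100`.

## Numerical and design choices

* LOD default 0.5 mmol/mol TG (configurable). The sterol-epoxide maxima
  (0.18 / 0.14 mmol/mol TG) sit below it; quantifying them requires an
  explicit lower LOD, which the tests exercise.
* Trapezoidal integration on the native grid; on an even grid the
  trapezoid error for a Lorentzian is exponentially small in fwhm/step.
* Diepoxides are catalogued with a diagnostic window but never generated;
  their channel must stay below the LOD on every fixture day (absence test).
* Noise for the stochastic rate-recovery test is σ = 6 intensity units,
  calibrated to ≈2 % relative error on the linoleic channel; recovery is
  asserted on seed-averaged stage rates (50 seeds) because single-seed
  slopes of the slow stage are noise-dominated.
* Problem sizes: 20 001-point spectra, 17-day courses, 50-seed Monte Carlo —
  the full suite and the acceptance script each run in seconds on one CPU.

## Known limitations

* Corrections assume the configured fwhm matches the data; for real spectra
  a mis-specified linewidth biases both truncation compensation and leak
  prediction (first order in the mismatch).
* Mutually-contaminating channel pairs are corrected in one direction only
  (DAG constraint); the uncorrected residual is small but nonzero.
* The stage-4 linoleic rate implied by the anchored day-14/16 values is
  −126.4 vs a described −123.7 mmol/mol TG per day (2.2 %): the printed
  endpoint concentrations and printed rate are not exactly consistent, and
  the fixture prefers the endpoint concentrations. Similarly the "18 % of
  groups degraded over days 11–13" figure is not exactly reconstructible
  from printed anchors; the package computes the analogous ratio rather
  than forcing agreement. (In the source narrative that sentence says
  "linolenic" where context indicates the linoleic groups are meant.)
* JCAMP-DX support is a minimal AFFN subset (even-grid XYDATA), not a full
  format implementation.
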