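# Methods

This note records the models behind each analysis stage, the defaults and
why they were chosen, what the synthetic generators do and do not emulate,
and the numerical decisions that were genuinely open.

## Hydrodynamics

All correlations assume laminar, Newtonian, incompressible flow.

- **Pipe flow** (needle, syringe barrels approximated as straight
  cylinders): Re = ρvd/μ with v = Q/A; wall shear γ_w = 4Q/(πR³) from the
  Poiseuille profile. Laminar/turbulent threshold fixed at Re = 2100.
- **Rectangular microchannel**: wall shear defaults to the wide-slot
  approximation γ_w = 6Q/(wh²) evaluated on the ungrooved section (the
  herringbone grooves locally deepen the channel and lower shear; the plain
  section bounds the maximum). An aspect-ratio-corrected form is available
  (`exact=True`). Hydraulic diameter D_h = 4A/P; by default the groove
  depth is added to the channel height for D_h, because the grooves are
  part of the section the flow samples on average. `channel_reynolds`
  therefore mixes conventions deliberately — mean velocity from the
  ungrooved w×h section (where the superficial velocity is set), D_h from
  the grooved section — which is the physically sensible pairing for this
  geometry; `strict=True` uses the plain section for both.
- **Micro-mixing time**: the chaotic-advection mixing length of a
  staggered-herringbone mixer grows as Δy = c·λ·ln(Pe) with λ the half
  mixing-cycle length and c an order-one constant. c·λ cannot be derived
  from the outer channel dimensions alone, so the default
  (`DEFAULT_SHM_MIXING_LENGTH` = 1.7084 mm) is calibrated once so the
  reference cartridge at 1 mL/min returns the manufacturer-quoted 21 ms.
  It is a calibration, not a prediction, and is documented as such.
- **Angular-speed conventions** differ between correlations and are set
  per function: `stirred_reynolds` and `tip_speed` read rotational speed
  in rad/s — the convention under which a 15 mm bar at 400 rpm gives
  Re ≈ 2514 and a tip speed of 1.97 m/s, matching how these quantities are
  quoted for this system — while `power_draw` (power-number convention,
  P = Np·ρ·N³·d⁵) and `integrated_shear_factor` use rev/s, the standard
  definitions. Every function takes a `convention` override; mixing them
  up silently is the classic error this module is designed to prevent,
  which is also why the config/CLI layer (`silkscale.units`) rejects bare
  numbers and requires explicit unit strings.
- **Fickian scales** use the 1-D convention L² = 4Dt; the prefactor is an
  argument (2, 4, and 6 are the half-space, 1-D, and 3-D choices).

Known inconsistencies in quoted values for this class of system — e.g. a
Peclet number of order 10¹¹ where v·D_h/D evaluates to 4.3×10⁵ — are not
reproduced; the calculators return the dimensionally consistent value.

## Mixing time (DISMT)

The dual-indicator method records a red→yellow color change; spatial
homogeneity is tracked by the population standard deviation σ_G of the
normalized green channel G/(R+G+B) over a rectangular mask (18,000 px by
default, matching common 1080p practice). Population rather than sample
SD is immaterial at these pixel counts but stated for exactness.
Zero-intensity pixels define normalized green as 0.

"Reaching 95% of the fully mixed standard deviation" is not a complete
operational rule, so the default criterion is **sustained entry**: t₉₅% is
the earliest time from which |σ_G − σ∞| stays within 5% of the initial
deviation |σ_G(0) − σ∞| for the rest of the record, with σ∞ the mean of
the final 10 frames. This prevents transient crossings from counting as
mixed; a single-crossing alternative is selectable. Non-convergence (the
band is reached only inside the baseline window, or never) is reported via
a flag rather than an exception.

Frames read from a directory are ordered lexicographically and the frame
rate must be given explicitly; container metadata is not trusted.

## FTIR amide-I deconvolution

Preprocessing follows the second-derivative protocol: Savitzky–Golay
second derivative (7-point, order 2) followed by two smoothing passes at
the same window. Half-window margins are dropped at every pass — no mirror
padding — so smoothing never fabricates band area at the window edges;
spectra should therefore extend some 20 cm⁻¹ beyond the amide-I window.

Band seeds are the second-derivative minima inside 1600–1700 cm⁻¹ with
prominence ≥ 2% of the global |minimum|; the minima search extends 4 cm⁻¹
past the window edge because peak detection is blind at the first/last
sample and the anti-parallel β-sheet band sits at ~1699 cm⁻¹.

**Fitting.** Two estimators are provided:

- `fit_bands` fits the second derivative directly with either the analytic
  second derivative of Gaussian bands (`profile="d2gauss"`, default) or
  plain negative Gaussians (`profile="gaussian"`, the classic shortcut).
- `fit_bands_smoothed` — the default inside `deconvolve` — pushes Gaussian
  absorbance bands through the *exact* preprocessing operator (the SG
  derivative and smoothing kernels composed into one convolution) and
  compares with the identically preprocessed data. With this
  operator-consistent estimator the preprocessing distortion cancels
  identically: on noiseless synthetic mixtures the class fractions are
  recovered to machine precision, and the fitted |areas| are true
  absorbance-space band areas. Plain negative-Gaussian fits in
  second-derivative space, by contrast, cannot represent the positive side
  lobes of real second-derivative profiles, which makes neighboring bands
  systematically steal area from one another.

Optimization is bounded trust-region least squares with per-parameter
scaling; centers are held within ±3 cm⁻¹ of their seeds and widths within
2.5–7 cm⁻¹ in the pipeline (the free-standing `fit_bands` defaults are the
permissive ±8 and 2–30 cm⁻¹). Width starting values come from the data:
the zero crossings flanking a second-derivative minimum sit at ±σ. The
fit runs from three starting points (plain seeds plus deterministic seed
jitters) and keeps the lowest residual, because a weak band next to a
strong one can otherwise be parked at zero amplitude in a local minimum.
Residual-driven augmentation then adds bands at remaining negative dips
(merged sub-bands such as random coil ~1645 / α-helix ~1659 can share one
second-derivative minimum) and keeps an augmentation only when it lowers
the residual norm.

**Baseline.** The anchored linear baseline — through the 2 (or
least-squares through 3) highest second-derivative maxima in the window —
is implemented and available (`baseline="anchors"`), but the pipeline
default is no baseline: on drift-free spectra the highest maxima are the
positive side lobes of the strongest band, so the anchored line sits above
zero and inflates every band area by a constant, which distorts the
*relative* areas that matter here. For measured spectra with instrument
artifacts the anchored variant is the right tool. (A linear baseline in
*absorbance* vanishes under the second derivative, so only
derivative-domain artifacts need it.)

**Assignment.** Literature band-class boundaries are not universal; the
defaults are contiguous half-open intervals — side-chain [1600, 1616),
intermolecular β-sheet [1616, 1638), random coil [1638, 1656), α-helix
[1656, 1663), β-turn [1663, 1697), anti-parallel β-sheet [1697, 1703] —
and are plainly editable. "Native β-sheet" is a configurable sub-interval
of the β-sheet region; no default split is imposed. Total β-sheet pools
the intermolecular, native, and anti-parallel classes. α-helix and random
coil are reported separately (sum them where a pooled figure is wanted).
Fitted bands whose centers leave the assignment's range, or whose area is
a negligible (<0.1%) share, are discarded before fractions are computed.

**Correlation coefficient.** R = Σxᵢyᵢ/√(Σxᵢ²Σyᵢ²) of the two spectra
after a 5-point, order-2 SG second derivative, two 5-point smoothing
passes, and restriction to 1600–1700 cm⁻¹; the reference is interpolated
onto the sample grid if the grids differ. R is scale-invariant and
symmetric; identical spectra give R = 1 to machine precision.

## Interlaboratory (round-robin) statistics

For participant i with mean m_i, sample SD s_i, and n_i replicates:

- grand average = unweighted mean of participant means (participants count
  equally, replicates do not);
- h_i = (m_i − grand)/s_d with s_d the SD of participant means;
- s_r = degrees-of-freedom-weighted root-mean-square pooled within SD;
  k_i = s_i/s_r;
- s_L² = max(0, s_d² − s_r²/n̄) (clamped one-way-ANOVA estimator, n̄ the
  mean cell size; a `direct` option takes s_L = s_d);
- s_R² = s_r² + s_L²; 95% limits are 2.8·s_r and 2.8·s_R (2.8 ≈ 1.96·√2).

Critical values at significance α = 0.005: h_crit = (p−1)t/√(p(t²+p−2))
with t the two-tailed Student-t critical value at p−2 degrees of freedom;
k_crit = √(p/(1+(p−1)/F)) with F the upper-α critical value at
df₁ = (p−1)(n−1), df₂ = n−1 — the standard-practice convention; the df
choice is overridable since conventions differ. Degenerate zero-variance
tables return flagged results (h ≡ 0, k undefined) rather than raising,
so pipelines on constant data do not crash.

Note that s_R cannot converge to its true value with a fixed handful of
participants however many replicates each runs — its uncertainty is set by
the participant degrees of freedom. The recovery checks therefore test
s_r convergence on the four-participant design and s_R convergence on a
larger simulated panel.

## Thermal analysis

Temperatures stay in °C throughout. Water content is the TGA mass-%
difference across 20–140 °C (interpolated at the bounds). The extrapolated
onset is the intersection of the pre-event baseline tangent (least-squares
line over the first 25% of the event window) with the tangent at the
maximum-slope point; the inflection is located on an 11-point quadratic
pre-smoothed derivative, refined by local quadratic interpolation, and the
tangent slope is taken as a short central secant of the smoothed signal
there (the smoothed-gradient value at the grid extremum is biased low,
which would shift the onset). Peak temperatures are derivative-mass-loss
extrema (TGA) or signal extrema of the stated sense (DSC), refined by a
quadratic fit over ±6 °C so grid-scale noise averages out. The desorption
enthalpy integrates the baseline-subtracted heat flow over time (scan rate
10 °C/min converts the axis), normalized to the dry-mass fraction; the
baseline is a straight line between the window endpoints with each anchor
level averaged over 2 °C, and a sigmoidal variant is available. Glass
transition extraction (half-height midpoint) is included but marked
experimental.

Known limitation: an endpoint-baselined enthalpy integral is only accurate
when the peak sits clear of the window edges; a desorption peak whose
flank crosses the 20 °C scan start loses tens of J/g by construction, for
synthetic and measured curves alike.

## Throughput

Feed-limited steady-state basis: the headline rate counts only precursor
feed time, so the semi-batch rate equals feed rate × concentration ×
yield and is independent of batch volume; the microfluidic rate is the
precursor fraction of the total flow, total/(1+ratio), times concentration,
yield, and chip count. Purification/centrifugation downtime — which
substantially reduces both formats' real rates — can be modelled with
`cycle_overhead` (extra non-productive time per unit feed time). % w/v is
g per 100 mL of precursor.

## Synthetic data

All generators are bit-reproducible under a fixed seed and return their
ground truth with the data.

- **Mixing videos**: frames whose masked normalized-green SD follows
  σ∞ + (σ₀−σ∞)e^(−t/τ) *exactly* — the per-frame pixel noise is
  standardized over the mask before scaling (and clipped at ±3.5 SD before
  standardization so every intensity stays positive). Without exact
  standardization, the sampling noise of the spatial SD estimate would
  dominate the one-frame recovery comparison at any realistic pixel
  count. Defaults: σ₀ = 0.12, σ∞ = 0.02, 240 fps, 90×80-px frames with a
  3000-px mask, duration 14τ — long enough that the tail bias of the
  10-frame baseline window moves the t₉₅% crossing by less than one frame.
  The generator does not emulate camera optics, illumination drift,
  quantization, or indicator chemistry; full-resolution frames are
  statistically identical, just larger.
- **Amide-I spectra**: six Gaussian bands (σ = 3.5 cm⁻¹ each, a
  silk-nanoparticle-like composition with 56% total β-sheet) on a 2 cm⁻¹
  storage grid, emulating a 4 cm⁻¹-resolution instrument whose software
  stores roughly two interpolated points per resolution element. Noise at
  SNR 50 (peak absorbance over noise SD) is drawn white on the 4 cm⁻¹
  resolution elements and interpolated to the storage grid, because
  instrument noise is band-limited by the lineshape just as the signal is.
  Equal band widths make the absorbance-area class fractions identical to
  the derivative-space fractions the pipeline estimates; real spectra have
  unequal widths, Voigt-like shapes, and baseline artifacts, so passing
  recovery here demonstrates estimator correctness, not instrument-grade
  accuracy on measured silk.
- **Round-robin tables**: value = grand mean + participant effect
  N(0, s_L²) + replicate noise N(0, s_r²). Defaults follow the
  four-participant microfluidic size study: grand mean 109 nm,
  n = (3, 4, 3, 4), s_r = 13/2.8 ≈ 4.64 nm and s_L ≈ 3.91 nm back-computed
  from 95% repeatability/reproducibility limits of 13 and 17 nm.
- **Thermograms**: TGA = 100% minus a logistic water step (midpoint 80 °C,
  scale 8 °C) minus a logistic decomposition step whose midpoint is the
  true T_dec and whose tangent-construction onset is exactly
  T_dec − 2·scale; DSC = Gaussian desorption endotherm (time-domain area
  −150 J/g by default) plus a logistic exotherm shoulder. Gaussian noise
  at instrument-grade levels (0.01 mass-%, 2 mW/g). Truths are the
  analytic values of the noiseless curves, with window clipping accounted
  for. No decomposition kinetics, buoyancy artifacts, or baseline
  curvature are modelled.

## Problem sizes

The recovery studies run at 20 seeded replicates per stage; mixing-time
recovery uses τ ∈ {0.5, 2, 10} s (up to ~34k frames, generated lazily and
streamed); variance-component recovery uses 200 replicates per participant
(and a 40-participant panel for s_R). These sizes give comfortably tight
statistics for every check while the full suite and the acceptance script
each complete in well under a minute of compute apiece.
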