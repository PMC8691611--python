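# Methods

## Problem setting

A wrist-worn accelerometer records triaxial acceleration a(t) = (a_x, a_y,
a_z) in units of g, sampled uniformly (default 10 Hz, full scale ±8 g).
"Activity" is obtained by reducing each non-overlapping epoch of length T_e
(default 60 s, i.e. n = 600 samples) to a single number with an *activity
metric* applied to a *preprocessed* version of the signal.  Neither the
metric nor the preprocessing is standardized across devices and studies;
this package implements the whole combinatorial space so the resulting
activity signals can be compared quantitatively.

## Dataset taxonomy

From one recording, six dataset types are derived (axial types expanded,
ten single series):

| kind   | definition |
|--------|------------|
| UFX/UFY/UFZ | raw axial accelerations |
| UFM    | √(UFX² + UFY² + UFZ²), carries the constant 1 g of gravity |
| UFNM   | \|UFM − 1 g\| — gravity removed by normalization |
| FX/FY/FZ | axial signals band-pass filtered |
| FMpre  | magnitude of the filtered axials |
| FMpost | band-pass filter applied to UFM |

The default filter is a causal 3rd-order Butterworth band-pass, 0.25–2.5 Hz,
implemented as cascaded second-order sections (so the order-30 robustness
variant remains numerically stable).  Filter state is initialized to the
steady-state response of the first sample, which suppresses the startup
transient a DC-level step would otherwise inject.  A zero-phase
(forward–backward) mode is available by configuration; it doubles the
effective order.  Whether the original hardware chain is causal or
zero-phase is generally unknown for commercial devices; causal is the
default because it is what an on-device implementation can do.

FMpre ≠ FMpost in general: the Euclidean norm is nonlinear and does not
commute with linear filtering.  A separate HFEN_M series (per-axis
4th-order 0.2 Hz high-pass, then magnitude) feeds the HFEN metric.

## Activity metrics

With r_1..r_n the epoch samples of the chosen dataset and T_s the sampling
interval:

* **PIM** (Proportional Integration Method): T_s·Σ r_i (Riemann, `PIMr`)
  or composite Simpson 3/8 quadrature (`PIMs`).  When n − 1 is not a
  multiple of 3 the trailing one or two intervals use the trapezoid rule.
  On signed datasets (FX/FY/FZ, FMpost) the absolute values are integrated,
  otherwise positive and negative excursions cancel.
* **ZCM** (Zero Crossing Method): number of adjacent sample pairs strictly
  on opposite sides of a threshold level T_ZCM.  Samples exactly on the
  level inherit the side of the previous strictly-off-level sample (leading
  on-level samples are ignored).  This is the minimal deterministic
  crossing rule; no hysteresis is applied, because the recommended
  SD-adaptive level sits well above the noise floor.
* **TAT** (Time Above Threshold): T_s times the number of samples strictly
  above T_TAT.
* **MAD** (Mean Amplitude Deviation): (1/n)·Σ|r_i − r̄|.
* **ENMO** (Euclidean Norm Minus One): (1/n)·Σ max(r_i − 1, 0); only
  meaningful on UFM, the one magnitude dataset still containing gravity.
* **HFEN**: epoch mean of the high-pass-filtered magnitude (HFEN_M).
* **AI** (Activity Index): max((1/3)·Σ_m(σ_m² − σ̄²), 0) over the three
  axial epoch variances σ_m², with σ̄² the systematic noise variance
  estimated from the stillest 1% of epochs (lowest summed axial variance).
  The formula is implemented per-axis under the max; a `sqrt` variant
  (square root of the floored term) is provided because part of the AI
  literature defines it that way.  The linear form is the default.

An applicability matrix guards every (metric, dataset) pair: PIM/ZCM/TAT
are undefined on raw axials (the unknown gravity projection cannot be
corrected without filtering), ENMO only applies to UFM, HFEN only to
HFEN_M, AI only to axial triples, MAD applies everywhere.  Violations raise
an error naming the rule rather than producing a number that looks valid.

## Threshold determination

ZCM and TAT need a level.  The recommended rule is *SD-adaptive*: the level
equals the population standard deviation (ddof = 0) of the entire dataset —
the whole recording, not per epoch — plus 1 g for UFM, whose values ride on
gravity.  The sweep machinery justifies it: activity signals are computed
on a cumulative grid (base offset + k·0.05 g) and correlated with ENMO and
HFEN (the two metrics that admit exactly one computation, avoiding extra
degrees of freedom).  On synthetic recordings the curve rises steeply (low
thresholds saturate the crossing count), plateaus, and decays (high
thresholds see only the strongest epochs); the SD lands on the plateau
within 0.02 of the grid maximum.  The default grid of 20 steps spans ≥ 3×
the default scenario's SD.

For per-axis computation each axis uses its own SD (the adaptive rule
applied axis-wise); the thresholds used are recorded in output metadata.

## Axial combination

Per-axis activity triples are merged per epoch by sum, sum of squares, or
VM3 = √(a_x² + a_y² + a_z²).  For nonnegative inputs VM3 ≤ sum (norm
inequality).

## Correlation comparison

All catalog entries (the built-in catalog enumerates every permitted
metric × dataset × combination, 57 definitions) are computed per subject on
the shared epoch grid; pairwise Pearson coefficients form one matrix per
subject; matrices are reduced across subjects to per-cell mean ± SD.
Frequency-domain comparison correlates Welch PSD estimates instead of the
raw activity values (Hann window, 256-epoch segments, 50% overlap, linear
detrend per segment; segment length is reduced for short recordings and
recorded in metadata).  Undefined coefficients (constant signals) are
reported as missing cells, never coerced to zero.

## Synthetic study conditions

The generator emulates free-living wrist data at desk scale: a unit-norm
gravity vector following an orientation random walk (0.05 rad/√s, spectral
content far below 0.25 Hz), movement bursts of band-limited Gaussian noise
(0.3–2.0 Hz) in alternating rest/active bouts with exponential durations
(means 250 s / 350 s — a waking-day duty cycle; a heavy-tailed Lomax
option exists), per-bout intensity drawn lognormally around 0.15 g per axis
(log-sd 0.2), white sensor noise (10 mg), and 4 mg quantization (12-bit
over ±8 g).  Default duration is 12 h; cohorts jitter bout durations,
intensity and noise per subject by ±20–30% from deterministic child seeds.

What the generator reproduces, and deliberately does not:

* It reproduces the qualitative structure that drives the framework's
  findings — gravity orientation slow compared with movement, movement
  energy inside the filter passband, epoch-graded intensity, a still-device
  noise floor.  The intensity distribution was chosen so the
  threshold-correlation curves show the rise/plateau/decay shape observed
  on real recordings, with the dataset SD on the plateau.
* The intensity spread (±~50%) is much narrower than real free-living
  data, where epoch intensities span orders of magnitude.  Pearson
  coefficients are tail-sensitive, so correlation *magnitudes* computed on
  synthetic cohorts are not calibrated to field values; only orderings and
  plateau/peak structure are meaningful.
* Bursts are isotropic across axes.  Real wrist movement is anisotropic,
  which is what degrades VM3-style combinations relative to single axes on
  real data; at desk scale the axial signals are near-identical and VM3
  behaves like a scaled single axis.  Tests therefore assert "single axis
  not systematically worse than VM3" rather than a strict ordering.
* The norm operation folds burst energy into a low-frequency envelope and
  doubled-frequency harmonics, so magnitude series (FMpre) never hold more
  than ~2/3 of their power inside the burst band; passband occupancy is
  validated on the filtered axial signals, where it exceeds 80%.

## Numerical choices

* Epochs start at sample 0; a trailing remainder shorter than one epoch is
  dropped.  No clock alignment is attempted.
* Population SD (ddof = 0) throughout; at recording scale the sample/
  population distinction is far below every tolerance used.
* PIM on UFM integrates gravity as printed in the triaxial definition; an
  optional `baseline_subtract` flag removes n·T_s·1 g per epoch, floored
  at zero.
* Exact-threshold ties in ZCM are resolved by side inheritance (above);
  TAT uses strictly-above comparison, so boundary samples do not count.
* Noise-variance estimation uses the 1% stillest epochs by summed axial
  variance; with fewer than 10 epochs the estimate is refused.
* Problem sizes: the reference scenario is 12 h per subject at 10 Hz
  (432 000 samples, 720 epochs) and 3 subjects per cohort, which makes
  every property measurable in seconds while keeping epoch counts large
  enough for stable correlation estimates.

## Known limitations

* No resampling, gap handling, or axis calibration; recordings are assumed
  uniform and in g.
* The catalog covers the built-in enumeration (57 definitions); device
  vendors' proprietary count algorithms are represented by PIM, which the
  accessible documentation describes as their closest published analogue.
* Correlation magnitudes from synthetic cohorts transfer to real data only
  as orderings (see above); running the pipeline on real deposited raw
  recordings is supported through the CSV/binary readers.
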