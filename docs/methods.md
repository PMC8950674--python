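# Methods

`cardiobeat` has two halves: a video pipeline that quantifies the beating of
a hiPSC-derived cardiomyocyte monolayer in a single well, and a
concentration–response half that turns per-well endpoint measurements into
benchmark concentrations (BMC) and an embryotoxicity classification. This
note records the models, the tunable parameters and their defaults, the
numerical choices, and what the synthetic validation does and does not
demonstrate.

## Video pipeline

### Model of the observable

A day-10 culture is a multilayered cell sheet that contracts in a
synchronized wave. On a well-scan video this appears as quasi-periodic
displacement of image texture inside the well. The pipeline measures that
displacement at a square lattice of reference points (spacing 20 px,
margin spacing/2 so the lattice is centred) and reduces each point to a
*distance profile* d(t): the Euclidean distance of its tracked position
from its first-frame position. One contraction is one excursion of d(t)
away from and back towards baseline, so a culture beating at f beats/s
produces f profile peaks per second.

### Tracking

Each reference point is tracked frame-to-frame with a pyramidal
Lucas–Kanade solver (window 21 px, 3 pyramid levels, iterative refinement
to 0.01 px): the displacement minimising the windowed intensity residual
between consecutive frames, solved coarse-to-fine. Points whose 2×2 normal
matrix becomes singular or that leave the frame are flagged lost and
excluded from all statistics; the count is logged. Tracking is validated
against an exhaustive integer block-matching search (±5 px, smallest
displacement wins ties), which is deliberately slow and simple and never
used in the pipeline itself.

The correlation window sets the spatial resolution: a point within ~half a
window (≈10 px) of a moving-region boundary measures an attenuated
mixture of moving and static texture. This is a physical limit of windowed
flow, and it shapes several calibration choices below.

### Noise threshold alpha

Inter-frame steps below `alpha` are zeroed and the position held before
d(t) is rebuilt, so sub-threshold jitter contributes nothing. Default
`alpha = 0.05 px/frame-step`. The bound is set by the slowest
physiological beat: at 0.5 beats/s and 3 px contraction amplitude sampled
at 30 fps, the largest true inter-frame step is 3·π·0.5/30 ≈ 0.16 px, and
boundary-attenuated points move about half that; alpha must sit well below
~0.08 px while staying above the per-frame tracking jitter (~0.02–0.04 px
on textured images). Any alpha ≥ 0.16 would erase slow beating entirely.

### Peak analysis and the beating decision

Peaks of the thresholded profile are detected with a *relative* prominence
threshold (0.2 × the profile's own range) and a minimum separation of
frame_rate/f_max frames (f_max = 5 beats/s, the physiological ceiling for
hiPSC-CM). A point is *beating* iff at least two peaks are accepted,
mirroring the recording rule of at least two contractive motions; its
frequency is (n_peaks − 1)/(t_last − t_first), the mean inter-beat
interval over the observed peak span, robust to dead time before the
first and after the last contraction.

The relative prominence alone cannot distinguish real contraction from
the residual random walk of a static point (every profile has *some*
range). The gate is the **median prominence of the detected peaks**,
default 0.9 px: a genuine contraction returns to baseline each beat, so
its peak prominences match its excursion amplitude, while a drifting
random walk has a large range but only shallow wiggles. Two simpler gates
were tried and rejected: an absolute per-peak prominence floor silently
drops individual peaks of boundary-attenuated points and corrupts their
frequency, and a gate on total profile range is fooled by drift. The
0.9 px default was calibrated once on the synthetic family (it sits midway
between the jitter prominences, ~0.2–0.4 px, and the attenuated boundary
signal, ~0.7–1.4 px, and places the detection boundary at the true region
edge) and verified on a held-out generator seed.

### Well ROI and cell mask

The well is located on the first frame by a Hough circle transform over
radii 0.3–0.6 × min(H, W) on a Canny edge map; the winning circle plus
10 px padding bounds everything downstream. If no circle clears a minimal
accumulator score (blank frame), the inscribed circle is used and a
warning logged.

The cell layer is segmented on the HSL lightness channel (L =
(max(R,G,B)+min(R,G,B))/2/255): cells in dense multilayers are darker
than the surrounding medium. The binarisation threshold is mean ROI
lightness × a multiplier from a quartile lookup table
{<0.25: 0.95, <0.5: 0.90, <0.75: 0.85, else 0.80} — a calibration stand-in
that is fully config-overridable and always reported with results. The
candidate mask is morphologically closed (disk 3) because the cell layer
is a continuous sheet and lightness speckle would otherwise punch single
reference points out of the mask, then 8-connected components smaller
than 0.05% of the ROI area are removed as dead cells or floating
artifacts. The mask is computed from the first frame only and is the
upper bound for all beating statistics.

### Well-level aggregation

Beating area = number of beating lattice points inside the cell mask ×
spacing² (one lattice cell per point; the area quantum is a package
choice), reported absolutely and as % of mask and % of ROI. Mean
frequency averages beating points only. The heatmap paints each beating
point's lattice cell from a fixed viridis ramp over 0–5 beats/s.

## Synthetic well videos

The generator renders what the pipeline needs to see and nothing more: a
dark well rim (Hough target), a band-limited noise texture (Gaussian
blur σ 2.5 px of white noise — local windows carry trackable gradients)
darker than the medium, immobile dark specks, additive Gaussian sensor
noise (σ 2 intensity units), and a contracting disc displaced by

    u(x, t) = amplitude · sin(π f t) · w(x) · direction,

so d(t) = amplitude·|sin(π f t)|·w — exactly f contraction peaks per
second. The weight w ramps 0→1 over a 4 px taper inside the region
boundary, keeping all motion strictly inside the region. The *core mask*
(w ≈ 1) is the ground-truth set on which per-point frequency recovery is
scored; taper points move but with attenuated, boundary-limited
amplitude. Specks are placed at least 12 px clear of the beating region
so that a tracking window over moving tissue never contains a static
artifact (a window straddling both measures neither correctly). Default
conditions: 256×256 px, 30 fps, 10 s, amplitude 3 px, well radius 0.45 ×
frame, cell disc 0.88 × well, beating disc 0.6 × cell disc (≈36% of the
mask). Everything is bit-reproducible under a fixed seed.

What passing these tests shows: the tracker, thresholding, peak logic and
aggregation recover known kinematics through the whole pipeline under
realistic sensor noise. What they do not show: robustness to focus drift,
meniscus shading, wave-propagation phase gradients, arrhythmic beating,
or debris that moves — real recordings can fail in ways this family
cannot express.

## Concentration–response half

### Design

48-well plate (6×8): six concentrations in a 1:3 serial dilution in
quadruplicate (series kept at full precision; displayed at 2 significant
figures), 4 solvent controls, 2 lysis controls, 2 background controls,
16 water border wells. The solvent control and the lowest concentration
each place exactly one replicate on a plate edge so edge effects can be
checked against their interior replicates. A full edge-aware layout is
geometrically over-constrained on 48 wells (26 wells would need the
24-well interior), so the two unavoidable extra edge wells go to the top
concentration, where edge effects matter least for low-dose inference.

### Normalisation, CoV, BMR

Viability-style readings normalise as (raw − mean BC)/(mean SC − mean BC)
× 100; lysis controls are a QC check only (must fall near background).
The benchmark response level comes from the coefficient of variation of
the controls: BMR = clamp(ceil(CoV/10)·10, 20, 50) — a quiet endpoint
still gets the broad BMR 20, a very noisy one is capped at BMR 50 (the
IC50/ID50 level). CoV may be computed pooled across plates (default) or
per plate.

### The 13-family pool and selection

Linear; quadratic; exponential decay; 2-, 3-, 4-, 5-parameter
log-logistic; Weibull types 1 and 2; asymptotic regression;
Michaelis–Menten-form decay; log-normal bell (non-monotone); and
Cedergreen-type hormesis. All are ordinary least-squares fits (scipy
`curve_fit`, bounded); non-converged fits are dropped with a log entry.
Selection is by small-sample-corrected AICc on the plain residual sum of
squares; ties go to fewer parameters, then a fixed pool order. A
signal-dependent (relative-error) likelihood was evaluated for selection
and rejected: its Σlog σᵢ term systematically rewards families that
predict low responses and biases the pool toward steep-drop shapes.

### BMC and its confidence limits

The BMC solves predicted(BMC) = predicted(0) × (1 − BMR/100) by a
log-grid scan for the first downward crossing refined with Brent's
method; a curve that never crosses inside the tested range is flagged
`not_reached` (a steep drop already below the level at the lowest tested
concentration reports that concentration). BMR = 50 reproduces the
IC50/ID50 identity exactly on noiseless data.

BMCL/BMCU (default 90% two-sided, 1000 resamples, seeded) come from a
**model-averaged parametric bootstrap**. Plain percentile bootstrap
refitting only the selected family undercovers badly here: on noisy
sigmoid plates the shoulder-free exponential family is selected a third
of the time with a large negative BMC bias, and resamples generated from
its own fitted curve re-select it almost surely, hiding model uncertainty
from the interval. Instead, each resample (i) draws its generating curve
from the competitive fits (AICc within 4 of the best, at most 5) by
Akaike weight, (ii) adds relative-error noise — the residual scale is
estimated per unit of predicted response, floored at 5% of control,
matching the CoV parameterisation the assay itself uses — (iii) divides
by a resampled solvent-control mean factor (the normalisation denominator
is itself an estimate shared by every well on the plate), and (iv) refits
all competitors and reselects before solving for the BMC. The percentile
interval of those draws is reported, clipped to bracket the point
estimate. The point estimate itself is the Akaike-weighted average of
the competitors' BMCs — the established remedy (EFSA-style model
averaging) for the large systematic bias a single shoulder-free family
carries when it happens to win the criterion; the selected family is
still reported as `model_family`. Measured at the validation conditions
(4PL truth, CoV 16%, 6×4 design, 200 plates × 200 resamples): median
relative BMC20 error ≈ 18–23%, 90% CI coverage ≈ 85–88% (two disjoint
seed sets).

### Classification

An endpoint is compared with viability by CI overlap:
overlap% = 100 × |endpoint CI ∩ viability CI| / endpoint CI width (the
denominator is the interval being classified; the rule's source does not
define it, so this interpretation is flagged). `specific` requires zero
overlap *and* the endpoint CI entirely below viability — an effect at
lower concentrations than cytotoxicity; zero overlap above viability is
`unspecific` (the effect appears only beyond cytotoxic concentrations).
Overlap ≥ 10% is `unspecific`; anything in (0, 10)% is `borderline`.
Width-zero endpoint intervals classify by containment. The rule is total
and deterministic over all interval geometries.

### Simulated plates

Responses are curve(c)·(1 + ε), ε ~ N(0, CoV/100) — multiplicative,
matching the CoV parameterisation — mapped onto raw fluorescence between
a background level (100) and a solvent-control level (1000); defaults are
the validation conditions (top 3 µM, 1:3 × 6, quadruplicate, 4PL with
EC50 0.7 µM, slope 2, CoV 16%).

## qPCR quantification

Standard curves are least-squares lines of Cq vs log10(copies/µL) over a
1:10 series (3.75×10²–3.75×10⁷ molecules/µL); replicate Cq values from
independent runs are averaged on the Cq scale before fitting (not as
copies — the mean of exponentials would bias high). Efficiency =
(10^(−1/slope) − 1)×100; a positive slope is rejected as an inverted
series. Unknowns convert as 10^((Cq − intercept)/slope); extrapolation is
permitted up to 1 Cq beyond the calibrated range with a warning flag,
refused beyond. Target copies normalise to the calnexin (CANX) reference
gene of the same sample.

## Problem sizes used in validation

Synthetic videos: 256×256 px, 30 fps, 10 s, five beat rates
(0.5–3 beats/s). Benchmark-concentration study: 200 simulated plates with
200 bootstrap resamples each (the library default of 1000 resamples is
used for single-plate analyses; the repeated study uses 200, which
changes the 90% percentile endpoints by less than the Monte-Carlo noise
between plates). Classification property check: 10,000 random interval
pairs.

## Known limitations

- The lightness→threshold lookup table is a stand-in calibration; real
  recordings need their own table (config-overridable, always reported).
- Beating area is quantised to lattice cells (spacing² per point); its
  boundary accuracy is limited to about half a tracking window.
- The beat-vs-jitter gate (median peak prominence 0.9 px) is calibrated
  for ~3 px contraction amplitude at 20 px grid spacing; substantially
  weaker contractions need a lower gate and a quieter camera.
- BMC interval calibration was measured under a 4PL truth; strongly
  non-monotone truths were not part of the coverage study.
- Stage drift is not subtracted; it is handled implicitly by peak
  prominence and will inflate profiles if severe.
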