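# Methods

`vasodyn` quantifies how vasodilation propagates through the cortical
arterial network during neurovascular coupling, and ships a generative model
of the imaging experiment so that every estimator can be validated by
parameter recovery against known ground truth.

## The generative model

A planar vessel network is a tree of polyline segments (µm coordinates,
origin top-left, y down, pixel centres at integer+0.5), each with a class
label and baseline diameter D₀, rooted at the activity/stimulation source.
Distances "along the vasculature" are traced arc lengths through the tree.

A stimulus launches a dilation wave at the source. The diameter at a point
with traced distance x is

    D(x, t) = D₀ · [1 + A₀ e^(−x/λ) · g(t − t₀ − x/v)] · [1 + η(t)]

where v is the propagation velocity (mm/s), λ the spatial decay length (µm),
A₀ the peak fractional amplitude at the source, and g a logistic rise with
timescale d (half-rise placed 5d after wave arrival so the curve is ~e⁻⁵ at
arrival) that plateaus for the stimulus duration and then relaxes
exponentially (timescale τ_relax, default 2 s). The relaxation shape is a
free simulator parameter: the estimators only fit the rising phase, and the
underlying experiments constrain decay kinetics only qualitatively.

η(t) is spontaneous vasomotion: Gaussian noise band-passed to 0.05–0.3 Hz
(the classic ~0.1 Hz vasomotion band, below the 0.5–1.3 Hz evoked-dilation
band used by the spectral noise gate), applied coherently along the vessel
within a trial. Coherent noise is the conservative choice — it does not
average out across positions, which is precisely what makes onset-based
velocity estimation hard. Its default standard deviation is 1.0% of the
baseline diameter per trial, calibrated so that the per-animal velocity
dispersion produced by measurement noise alone (sd ≈ 0.8 mm/s in the fast
regime) stays below the per-animal dispersion evident in published
optogenetic propagation measurements (≈1.3 mm/s, which additionally
contains biological between-animal variance).

### Rendering

IOS (530 nm reflectance) frames are background minus absorbance: each
vessel contributes a Gaussian cross-section whose FWHM equals the local
diameter and whose depth scales with blood content ((D/D_ref)^p, p = 1 by
default), so dilated vessels are simultaneously wider and darker. The
background level is 10⁴ counts — a typical widefield photoelectron budget —
and "photon noise" is Gaussian with variance proportional to the signal
(Poisson-like), applied last. Configurations whose absorbance would exceed
the background (negative intensities) are refused.

GCaMP (470 nm) frames are a baseline plus a Gaussian activity blob around
the source following the stimulus time course, multiplied by
(1 − κ·fractional absorbance) to emulate hemoglobin crosstalk.

Stimulus schedules follow the experimental designs: visual 4 s on / 29 s
inter-trial interval; optogenetic 2 s with Gaussian ITI (30 ± 5 s, floored
at 20 s).

### Behavior and coupling scenes

Per-trial locomotion and pupil covariates are drawn per mouse and centred
(deviation from the mouse mean); they contaminate trajectory amplitudes
additively through the true slopes (β₁₀, β₂₀). Gap-junction tracer scenes
paint a probe cell at fixed intensity on a vessel mask and decay the tracer
along the vessel (geodesic distance) as e^(−r/k); k = 0 is no transfer, k →
∞ a uniform fill.

## Trajectory extraction

Widefield IOS movies are inverted (higher = more total hemoglobin, HbT) and
sampled every 20 µm along manually supplied centerlines (45 µm for the
velocity analysis). At each sample the image is smoothed with a
one-dimensional Gaussian of σ = 5.6 µm oriented **along** the vessel
(averaging along the course without smearing the edges), and a 70 µm
perpendicular profile is bilinearly interpolated to 200 points. Profiles
are denoised by symlet-4 wavelet shrinkage (3 levels, soft universal
threshold) — the smallest standard symlet that preserves a 2-sample edge.
The parenchymal baseline is the mean of the intensity minima flanking the
peak; vessel width is the FWHM via linearly interpolated half-maximum
crossings, and HbT is the sum of the baseline-subtracted profile across the
FWHM, evaluated as the piecewise-linear integral between the interpolated
crossings (in sample units). The integral form matters: the integer-window
sum staircases as the crossings drift across sample boundaries, visibly
distorting ΔHbT/HbT time series.

Both ΔW/W and ΔHbT/HbT are referenced to each trial's pre-stimulus mean.
Samples whose chord or smoothing support leaves the frame are flagged
invalid and propagate as missing, never as zeros.

A domain limit worth knowing: with a 70 µm chord, Gaussian vessels wider
than ≈30 µm no longer reach background inside the window, so the in-window
flank minima inflate the baseline and the FWHM reads low (−1.7% at 30 µm,
−8% at 40 µm at 2 µm pixels). At the 15–25 µm pial-artery scale the FWHM
is accurate to <1%. HbT remains strictly monotone in true diameter up to
60 µm.

Two-photon (bright-lumen) movies are smoothed with a 1 µm Gaussian; edges
are half-maximum crossings of perpendicular profiles every 10 centerline
pixels; rungs with secondary peaks above half-max or out-of-window
crossings are discarded, and frames with >50% flagged rungs are missing.

## Activity maps

GCaMP frames are hemoglobin-corrected by dividing by the fractional 530 nm
reflectance (first-order Beer–Lambert at the isosbestic point; exponent
configurable), hot-pixel corrected (99.99th percentile → 3×3 median),
smoothed with a 90 µm Gaussian, normalized per pixel to the pre-stimulus
cross-trial mean, and rescaled so the session's 15th percentile ↦ 0 and
99th ↦ 1 (aperture-restricted percentiles). The evoked map averages a
1.12 s post-onset window across trials and binarizes at a strict >0.5
(>0.2 for the conservative local-activity mask). Distance-to-activity is
the Euclidean distance to the nearest activated pixel centre; the
local-activity statistic is l = Σ e^(−D⁴/(2σ⁴)) with σ = 400 µm, and
observations with pre-stimulus mean ln l > 6 are excluded.

## Quality control and behavioral correction

Two filters precede kinetic quantification of per-trial dilation data:

* **Baseline excursion**: pre-stimulus values are Z-scored against the
  session baseline; a trial is excluded iff the 96th percentile of |Z|
  exceeds 3 (a single 1% spike is tolerated; a 10% contamination is not).
* **Spectral gate**: mean power density in 0.5–1.3 Hz over 2.3 s
  post-onset, from a Hann/Welch spectrogram (4 s segments, 50% overlap);
  below 3 dB/Hz the trajectory is replaced by zeros (kept, not dropped).
  The threshold is calibrated for trajectories expressed in percent —
  a ~10% dilation at ~1 Hz sits near +20 dB/Hz in percent units but near
  −20 dB/Hz in fractional units — and the unit is recorded in output.
  Following the source experiments, the gate applies to per-trial
  two-photon-style ΔD/D analyses, not to the widefield velocity pipeline.

Behavioral state is removed with a random-intercept model
y = β₀₀ + β₁₀·l + β₂₀·p + U₀ⱼ + ε (REML, groups = vessel–stimulus
combination); slopes significant at p < 0.01 (large-sample normal
approximation) are subtracted term by term, others leave the data
untouched. Constant covariates are dropped with a warning.

## Kinetic estimators

* **Max dilation / time-to-peak**: maximum of the fractional trajectory in
  [onset, onset+4 s] (visual/blank) or [onset, onset+stimulus+4 s]
  (optogenetic).
* **Onset**: the across-replicate average trajectory is fitted with
  y(t) = a + b/(1 + e^((c−t)/d)) over the window from 1.5 s before onset to
  0.5 s after peak dilation; the onset is where the fit reaches 10% of its
  amplitude above baseline, the closed form c − d·ln 9. (The alternative
  reading — 10% of the absolute fitted maximum — is available behind a
  switch; the amplitude reading keeps onsets invariant to the arbitrary
  baseline.) Initialisation: a = pre-stimulus mean, b = peak − a, c =
  half-rise of a lightly smoothed copy, d = 0.25 s, d bounded in (0.01, 10] s.
* **Propagation velocity**: onsets at 45 µm intervals along one artery,
  unweighted least-squares line of onset versus arc distance, velocity =
  inverse slope (mm/s). Non-positive slopes are flagged non-propagating.
  By default the sigmoid fits run in passes: (1) free per-position fits;
  (2) refits with the rise timescale d shared (the median across
  positions) — the wave's rise time is position-independent, and freeing d
  at low-SNR distal positions lets the fit trade d against c, inflating
  onset noise roughly threefold; in this pass the fit window is also
  re-located with peak smoothing proportional to the rise time (2·d),
  because with slow rises a mid-rise noise bump can otherwise beat the
  plateau and the truncated window drags onsets early, a one-sided error;
  (3) refits with the amplitude b held at the running median over
  neighbouring positions (amplitude varies smoothly along an artery), so
  the final fit estimates essentially only the baseline and phase.
  Cohort-level speed: per-animal fits estimate an onset-versus-distance
  slope (a slowness, s/µm). Slownesses average linearly across animals
  sharing one true speed, so the cohort speed is reported as the inverse of
  the mean slope; the mean of per-animal reciprocal velocities (also
  reported, as the conventional per-animal statistic) inflates by ~CV² and
  acquires a heavy right tail when per-animal slope noise is appreciable.
* **Decay length**: max dilation versus distance fitted with
  y = A·e^(−x/λ) + floor, the floor fixed to the pooled blank-trial mean
  (a free offset trades off against λ at small bin counts); bootstrap CI
  over points; non-decaying data flagged unidentifiable. The blank floor is
  measured with the same max-dilation statistic on no-stimulus trials:
  because the maximum of sampled noise is positive, distal (signal ≈ 0)
  points carry the blank-level offset while strong proximal points carry
  almost none, so the fixed blank floor corrects the far tail exactly and
  over-corrects mid-range points slightly. Under the default noise level
  this leaves single-λ estimates biased low by ~15% at small trial counts
  while the between-genotype λ ratio — the comparative quantity — is
  recovered accurately (0.49 vs a true 0.50 in the shipped analysis run).

Numerical note: with post-plateau relaxation present, the fixed fit window
(−1.5 s to peak+0.5 s) clips a dip that lies outside the sigmoid model
class; this biases noiseless velocity inversion by ~0.1–0.4% depending on
regime. The closed-loop exactness checks therefore run with relaxation
disabled so the generative curve lies inside the fitted class; stochastic
recovery runs keep relaxation on and absorb the small bias inside their
tolerances.

## Cohort statistics

Per distance bin ({<1, 1–400, 400–800, 800–1200, 1200–1600, 1600–2000} µm;
blank trials pooled into a single bin), vasomotion is modelled as an
intercept plus nested random intercepts (trial within vessel within
field-of-view within mouse for two-photon data; trial within mouse for
widefield), fitted by REML; bins are fitted independently. The genotype
contrast adds a genotype indicator (optionally a centred baseline-diameter
slope; a covariate collinear with genotype is dropped). Fixed-effect CIs
use a group-level t quantile (df = #top-level units − #fixed effects):
simulation at cohort scale (12 mice) showed the large-sample normal value
undercovers (91.5% for nominal 95%), while the group-level t restores
~94–95%. Trajectory bands come from a hierarchical bootstrap (mice with
replacement, then trials within each sampled mouse), pointwise 2.5/97.5
percentiles, seed-deterministic.

## Coupling assay

The coupling index is (mean probe intensity − background) / (mean of the 3a
nearest contiguous-vasculature pixels − background), a = probe area in
pixels. Neighbors are ranked by Euclidean distance from the probe (ties
broken in raster order) within the probe's 8-connected vasculature
component, probe pixels excluded (including them would bias the index
toward 1). Non-positive denominators are censored-high and capped at the
batch's 99th percentile of finite indices, flagged. Vessel classes follow
the diameter/plexus/proximity decision tree with the 5.5–7 µm interval
closed on both ends.

## Validation strategy and scope of the synthetic data

Every estimator is tested three ways: analytic cases (exact FWHM of a
Gaussian, exact logistic onset, exact kernel values), independent oracles
(brute-force summation, exhaustive sorts, FFT band power, grid-search
minimizers, closed-form OLS), and closed-loop parameter recovery from
rendered movies. The headline recovery reproduces both published regimes:
cohorts of 16 synthetic animals (30 trials each) recover 4.13 mm/s and
1.53 mm/s waves with cohort-speed sampling errors of ~0.2 and ~0.09 mm/s.

The simulator reproduces the statistical structure that stresses the
estimators — amplitude decay with distance, coherent band-limited
vasomotion, hemoglobin crosstalk, photon noise, behavioral contamination —
but not photorealistic optics (no PSF or vignetting), 3-D geometry, motion
artifacts, or between-animal biological variability (all synthetic animals
share geometry and true parameters). Passing recovery therefore
demonstrates estimator correctness and robustness to measurement noise,
not robustness to unmodelled real-data pathologies such as registration
error or focal drift, which are assumed handled upstream.

## Problem sizes

Defaults keep a full two-regime velocity-recovery cohort (32 animals × 30
trials, each a rendered ~2,000-frame movie) plus the entire oracle suite
within roughly a quarter hour on one CPU core: movies are rendered at
10 µm/pixel over a 2.2 × 0.2 mm field at 0.14 s frame period, and profile
extraction is vectorised over frames and samples. The finer-resolution
(1–2 µm/pixel) renders are reserved for single-frame metrology checks.
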