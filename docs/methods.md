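# Methods

## Signals and their extraction

Two slow physiological signals are modelled, one value per fMRI frame:

* **RV (respiration variation)** — the population standard deviation
  (divisor *n*) of the raw respiration-belt waveform in a window of 6 s
  centred on the frame. Windows at the edges of a recording are truncated to
  the available samples rather than dropped, so the series always has one
  value per frame.
* **HR (heart rate)** — 60 divided by the mean inter-beat interval (IBI)
  whose midpoint falls inside the same 6-s window, in bpm. Frames whose
  window contains no IBI are filled by linear interpolation between the
  nearest valid frames (nearest value at the edges), because the downstream
  network requires gap-free sequences.

Cardiac beats are detected on a lightly smoothed pulse-oximetry waveform
(moving average, 0.05 s, forced to odd sample width so symmetric pulses are
not shifted by half a sample) using three gates: an adaptive amplitude
threshold (60th percentile of the smoothed signal), a minimum peak
prominence of 25% of the smoothed waveform's range, and a 0.25-s refractory
period (240 bpm ceiling). The prominence gate matters on waveforms with
sharp, low-duty-cycle pulses, where a percentile threshold alone sits at the
baseline and counts noise ripples as beats.

Interpolation of HR gaps happens before filtering: the zero-phase band-pass
requires a gap-free series.

Both series are band-pass filtered to 0.01–0.15 Hz with a 2nd-order
Butterworth filter applied forward–backward (zero phase, so the timing
relationship between physiology and BOLD is preserved), resampled to the
model's frame grid (1.44 s by default, i.e. a 0.72-s acquisition downsampled
by 2 by keeping every other frame), and z-scored to zero mean and unit
population variance. A constant series z-scores to all zeros with a warning
rather than an error. Because a Butterworth passband is only approximately
flat, re-filtering is only approximately idempotent: content in the flat
part of the band (≈ 0.02–0.08 Hz) is altered by well under 5% RMS, while
content near the 0.15-Hz edge (filtfilt gain ≈ 0.58 at 0.14 Hz) is
attenuated again on each pass.

### Quality control

A recording fails QC if any of these independent flags is raised: more than
1% of samples saturated at the ADC bounds (0/4095 in the 12-bit dialect; the
1% floor keeps isolated saturated samples from failing a scan), mean HR
below 30 or above 97 bpm, HR pinned within 0.5 bpm of 48 bpm at every frame
(a known failure mode of some pulse-oximetry units), or a missing channel.
The verdict is exactly the disjunction of the flags.

## Parcellation and ROI preprocessing

Four atlas parts are composed on one grid: a 400-region cortical
parcellation, 72 white-matter bundle regions from a probabilistic tract
atlas thresholded at 95% confidence, 16 subcortical regions, and 9
brainstem arousal-network nuclei — 497 ROIs. Voxels claimed by more than one
part go to the highest-precedence part; the default order
cortical > subcortical > arousal > white matter favours gray-matter
assignments (the white-matter part is the thresholded probabilistic one).
Global ROI ids are contiguous from 1 in part-listing order; the id order is
recorded in the sidecar because it defines the model's channel semantics.

ROI time series are unweighted voxel means. Preprocessing per row, in order:
OLS removal of a linear+quadratic trend, zero-phase band-pass (0.01–0.15
Hz), decimation keeping frames 0, 2, 4, … (output spacing dt×2, length
⌈T/2⌉), z-normalisation. Head-motion regression is deliberately absent from
model-input preprocessing — apparent motion carries respiratory information
the network can exploit; motion parameters enter only as optional nuisance
columns in the connectivity analysis.

## The reconstruction network

A single bidirectional LSTM layer (one layer per direction, hidden state *h*
per direction, inputs = R ROI channels), dropout on the concatenated
per-frame hidden state (length 2*h*), and two independent linear heads
producing one RV and one HR value per frame. Reading the sequence in both
directions removes the need to model the hemodynamic lag explicitly.

Defaults follow the full-scale protocol: *h* = 2000, batch 16, dropout 0.3,
Adam with initial lr 1e-3 and standard moments, lr × 0.5 after 2 epochs
without validation improvement, early stop after 6 such epochs (three
decays), cap of 100 epochs, weights restored from the epoch with minimum
validation loss. Desk-scale runs use *h* = 64 (see Problem sizes). The
objective is the equal-weighted sum of the two per-signal mean squared
errors on z-scored targets; a per-frame validity mask supports
variable-length scans padded to the batch maximum (masked frames contribute
nothing to loss or gradients, and the recurrent state passes through masked
steps unchanged, so a padded scan predicts bit-identically to the same scan
alone). A per-signal mask lets a scan with one missing target train on the
other alone.

Everything is NumPy: forward pass, backpropagation through time (verified
against central finite differences to ~1e-8 relative error), Adam, and the
schedule. Weight init is uniform (±1/√h) with the forget-gate bias set to 1
so early training does not truncate memory. All randomness (init, batch
order, dropout) flows from a single seed.

Cross-validation is subject-wise: subjects are shuffled once per seed and
dealt into k disjoint test sets; the remaining 80% is split 85/15 into
training and validation subjects, giving the 68/12/20 partition of the
total. All scans of a subject stay in one set.

Restricting `input_rois` reproduces the channel-subset experiments
(single-ROI models, top-p% models, region-exclusion models) purely through
configuration.

## Forward model and variance explained

The linear coupling from physiology to BOLD uses the two canonical response
functions, transcribed from the physiological-noise literature:

    RRF(t) = 0.6 t^2.1 e^(-t/1.6) - 0.0023 t^3.54 e^(-t/4.25)
    CRF(t) = 0.6 t^2.7 e^(-t/1.6) - 16/sqrt(18π) e^(-(t-12)^2/18)

(t in seconds, causal). Both are sampled on the frame grid over a 60-s
support; each is below 5% of its peak magnitude past 50 s, which the tests
verify by grid evaluation. Each signal contributes three mean-centred
columns: the canonical causal convolution (scaled by dt to approximate the
continuous integral), its first difference (leading 0) as a temporal
derivative, and a dispersion derivative computed as the finite difference of
the convolution over a stretch of the kernel time axis,
(conv[k(t/(1+ε))] − conv[k(t)])/ε with ε = 0.1 (configurable; the tests
check consistency of the finite difference as ε shrinks).

Percent variance explained of a series y by a column set X is
100·(1 − var(resid)/var(y)) after OLS of y on [1, X], clipped below at zero
(on held-out applications the raw quantity can be negative). Rank-deficient
designs are handled by the least-squares solver with a warning. The joint
map uses the 6-column RV+HR set per ROI or voxel; group maps are arithmetic
means of per-scan maps.

## Connectivity impact

Functional connectivity is the Pearson correlation matrix of ROI series
(symmetric, unit diagonal). The nuisance subspace — the physiological
regressor basis, optionally plus 6 rigid-body motion parameters and their
backward first differences (leading 0) — is projected out per row by OLS
against [1, N]; residuals are orthogonal to every retained column. Seed maps
correlate a seed series (single nearest voxel to the MNI-mm coordinate by
default, spherical mean optional; the default coordinate is the
default-mode-network seed (2, −58, 30)) with every voxel, before or after
nuisance projection. Group averaging of maps uses raw r (Fisher-z averaging
is available as an option). A seed that becomes (near-)constant after
projection yields an all-zero map with a warning.

## The synthetic forward simulator

The generator defines the study conditions for every test:

* **Latents.** Two independent Gaussian noises are AR(1)-tilted (pole 0.7)
  to concentrate power at the slow end of the band — real RV/HR variability
  is 1/f-like, and a flat in-band spectrum would make the 6-s extraction
  window's smoothing alone cap the waveform round trip near r ≈ 0.90 — then
  band-passed (order-4 Butterworth, 0.01–0.15 Hz), z-scored, and mixed after
  sample orthogonalisation so the RV–HR sample correlation equals ρ = 0.275
  (the typical resting coupling) exactly for every scan. Spectral
  confinement (≥ 95% of periodogram power in band, Hann-tapered to avoid
  rectangular-window leakage biasing the measure) holds across seeds.
* **Raw waveforms.** Respiration is a sinusoid at 1/3 Hz (20 breaths/min;
  chosen so the 6-s RV window spans exactly two respiratory cycles and the
  windowed SD tracks the amplitude envelope without breathing-phase ripple)
  with instantaneous amplitude following the RV latent; PPG is a sharp
  periodic pulse (raised-cosine-type, exp(κ(cos 2πφ − 1)), κ = 25) whose
  instantaneous rate follows the HR latent rescaled to 70 ± 5 bpm. Both are
  scaled into a clipping-free 12-bit ADC range at 400 Hz and rounded to
  integers. Extraction on these waveforms recovers the latents at r > 0.9.
* **ROI scans.** Row r = l_rv·z(rv∗RRF) + l_hr·z(hr∗CRF) + AR(1) noise
  (coefficient 0.3), then z-scored. Loadings are uniform on (0.3, 1.0) with
  a configurable zero-loading fraction (default 10%) of pure-noise regions.
  `noise_sd` sets the marginal noise SD directly; `varexp_target` instead
  scales noise per ROI so the true regressors explain a prescribed expected
  variance fraction (0.25 in the recovery runs, the 20–30% regime of
  physiology-rich regions). With zero noise every loaded row is an exact
  affine combination of the canonical regressor columns, so the
  variance-explained map returns ≥ 99% by construction.
* **Cohort.** Independent latents and noise per scan, shared loading
  distribution, 4 scans per synthetic subject.

What the generator does **not** emulate: scanner drift and motion artifacts,
nonlinear or regionally varying hemodynamic coupling, non-physiological
neural covariance structure between ROIs, waveform artifacts (clipping,
probe dropout) except where tests construct them explicitly, and real
spatial ROI geometry (the volumetric fixtures are tiny label blocks). A
model that passes here is validated for mechanics and identifiability under
the linear forward model, not for real-data accuracy.

## Numerical choices

* Filters: analysis band-passes are 2nd-order Butterworth filtfilt; the
  simulator's latent shaping uses order 4 for harder confinement. Series
  shorter than 3 filter lengths raise.
* Std convention: population (divisor n) everywhere; constant series
  normalise to zeros with a warning.
* Downsampling keeps frames 0, 2, 4, …; decimation requires integer factors,
  other grids use linear interpolation.
* Least squares via `numpy.linalg.lstsq`; rank deficiency warns and drops
  dependent directions implicitly.
* Detrend basis [1, t, t²] with t standardised for conditioning.
* Checkpoints are single-file `.npz` archives holding weights plus JSON
  metadata (config, channel count, ROI ids, data hash); loading restores a
  model that refuses inputs of the wrong channel width.

## Problem sizes

Desk-scale runs are dimensioned to finish quickly on one CPU while keeping
the statistics meaningful: the recovery study uses 200 scans (50 subjects ×
4), R = 50, T = 300 at dt = 1.44 s, hidden size 64, one CV fold (~1 minute);
unit fixtures use 10–50 ROIs and a few hundred frames. With these
conditions the held-out median r is ≈ 0.67–0.70 for both signals against a
shuffled-pair baseline of ≈ 0.

## Known limitations

* The validation-loss floor at desk scale is generalisation-limited: on the
  50-scan noiseless fixture training loss keeps falling while validation
  plateaus at ≈ 0.57× its starting value, so small cohorts cap the
  achievable held-out accuracy regardless of epochs.
* The reconstructed RV and HR are more strongly correlated with each other
  (≈ 0.9 at desk scale) than the generating latents (0.275): with a shared
  trunk and an MSE objective, the heads preferentially encode the common
  component. This mirrors the qualitative behaviour seen at full scale and
  is a property of joint learning, not a bug.
* Beat detection targets clean or simulated pulse waveforms; it is not an
  ECG R-peak detector and has no artifact rejection beyond the QC screen.
* The variance-explained analysis assumes the linear convolution model;
  the network itself does not.
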