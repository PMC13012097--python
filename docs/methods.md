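# Methods

`isocouple` analyses directed coupling among infraslow (< 0.1 Hz) brain
signals measured simultaneously at 10 Hz in three modalities: a hemodynamic
voxel volume (BOLD-like), electrode potentials (DC-EEG-like), and optical
chromophore concentrations with a water-sensitive channel (fNIRS-like).
This note describes the models, the estimators, the numerical choices, and
what the synthetic validation does and does not establish.

## Signal model and band limiting

All analyses operate on the infraslow band 0.01–0.08 Hz, which contains
slow vasomotor/hemodynamic activity while excluding respiratory (~0.25 Hz)
and cardiac (~1 Hz) bands.  Band limiting uses a 3001-tap Hamming-window
FIR band-pass at 10 Hz (order 3000, cutoffs 0.01 and 0.08 Hz).  The
symmetric taps are applied twice — equivalent to forward–backward
filtering — so the net filter is exactly zero-phase with squared magnitude
response; a zero-phase filter is essential because the subsequent analysis
lives entirely in the phase domain.  Before filtering, signals are
mirror-extended by one filter order (300 s) per side; the extension tiles
whole reflected copies, so records shorter than the filter remain
processable.  Band limiting is applied to the full continuous recording
*before* epoch extraction: a 2-min epoch is shorter than the filter, and
filtering epochs individually would let the mirror reflections dominate
the phase estimates.

Epochs are fixed-length (default 120 s) single-state segments cut from a
hypnogram of 30-s arousal-state labels (AWAKE / N1 / N2).  For each state
the epoch(s) are taken from the start of the longest continuous run of
that state, earliest run on ties; states whose longest run is shorter than
one epoch contribute nothing.  One epoch per state is the default, with a
switch for multiple non-overlapping epochs; when several epochs are used,
epoch-level coupling estimates are averaged within subject × state before
any group statistic.

EEG-rate data are aligned to 10 Hz by staged zero-phase FIR decimation
(integer ratios only).  Optical absorbance changes convert to chromophore
concentration changes (Hb, HbO, H2O) through the modified Beer–Lambert
law, `dC = (E·L)^-1 dA` with `L = diag(pathlength · DPF)`; the inversion is
exactly linear.  Extinction coefficients and differential pathlength
factors must be supplied for real optics — the identity-like defaults only
serve synthetic data.

## Spectral analysis

Time–frequency power uses complex Morlet wavelets (8 cycles) on a 50-step
logarithmic grid from 0.01 to 5 Hz (5 Hz = Nyquist of the 10 Hz
recordings; the top grid frequency is therefore allowed to equal Nyquist).
Kernels have Gaussian envelope SD `n_cycles / (2πf)` seconds, support
±4 SD, and unit energy; inside the convolution each frequency is
additionally scaled to unit gain for a tone at the kernel's centre
frequency, so reported power is in signal units squared and a pure tone
peaks at its own frequency (without that scaling the longer low-frequency
kernels would systematically drag spectral peaks downward).  Signals are
mirrored once on each side before convolution.  For a 2-min epoch every
frequency below 0.067 Hz has a kernel longer than the epoch; such
frequencies (fewer than 2 cycles per epoch) are flagged in the output and
their absolute power should be read as attenuated.

Infraslow band power is the time-averaged spectrum integrated over
0.01–0.08 Hz by the rectangle rule with bin widths from the geometric
midpoints of the log grid.  On whole-brain data a uniform 5 % random voxel
subsample (without replacement, seeded) bounds the cost; spectra are
averaged over voxels/electrodes within subject before group medians and
interquartile envelopes are formed.

## Phase transfer entropy

Instantaneous phases come from the Hilbert analytic signal,
θ[n] = arg z[n] ∈ [−π, π), and are discretized into 8 uniform bins (the
bin count is configurable; 8 balances resolution against bin occupancy at
1,200-sample epochs).  For a source x and target y the discrete-estimator
transfer entropy in bits is

    TE(x→y) = H(y_t, y_t') + H(y_t', x_t') − H(y_t') − H(y_t, y_t', x_t'),

with all entropies plug-in (empirical frequencies, log2, 0·log 0 = 0) over
the aligned triples (y_t, y_{t−δ}, x_{t−δ}).  The lag is fixed at one
oscillation cycle of the band's power peak: δ = round(fs / 0.03 Hz) = 333
samples.  This is the analysis's most sensitive knob and is exposed in
every API.  No small-sample bias correction is applied (the plug-in
estimator is used deliberately as the simplest discrete estimator); a
Miller–Madow correction is not provided because the analysis never
interprets a single directional TE in absolute terms.

The net-direction statistic is ΔTE(x, y) = TE(x→y) − TE(y→x).  Each
directional plug-in estimate is strongly positively biased at these sample
sizes (867 usable triples over 512 joint states), but the bias is
symmetric under exchange of x and y, so it cancels in ΔTE: for independent
signals E[ΔTE] = 0 exactly, and the sign of ΔTE indicates the dominant
prediction direction.  ΔTE is antisymmetric by construction and each TE is
non-negative up to 1e−12 float rounding.

A 2-min epoch contains only ~3.6 cycles at 0.03 Hz, so phases sweep the
bins slowly and the effective number of independent observations is on the
order of tens, not hundreds; a single-pair ΔTE therefore carries a
standard deviation of roughly 0.2 bits.  Sign inference relies on
averaging — over electrodes and voxels within an epoch, over epochs within
subject, and over subjects in group medians.

Pairwise maps follow fixed sign conventions: positive ΔTE(BOLD, EEG)
means the hemodynamic signal predicts the electrical signal (electrode-
averaged per voxel); positive ΔTE(BOLD, H2O) means it predicts the water
signal; positive ΔTE(EEG, H2O) (per electrode) means the electrical signal
predicts the water signal.  Aggregation reports whole-brain means, means
over the nine atlas regions (caudate, cerebellum, frontal, insula,
occipital, parietal, putamen, temporal, thalamus), and the directional
components alongside ΔTE; because aggregation is a mean, it commutes with
the ΔTE subtraction.

As a control against static propagation structure masquerading as coupling,
a voxelwise lag map is computed: the lag of maximum cross-correlation with
a frontal seed-mean signal within ±1 cycle (uniform-scaled correlation —
lag-proportional scaling would bias ultra-smooth signals toward extreme
lags), plus the Spearman correlation between the lag map and the ΔTE map
with a voxel-permutation p-value.

## Group statistics

Scalar summaries are compared with a two-tailed Wilcoxon rank-sum test:
midranks for ties, z from the normal approximation with tie-corrected
variance and 0.5 continuity correction, and the p-value from exact
enumeration of all rank assignments when n1 + n2 ≤ 12.  Families of tests
are corrected with Benjamini–Hochberg FDR.

Voxelwise map comparisons use a label-randomization test with
threshold-free cluster enhancement: the two-sided statistic is the
absolute difference of group mean maps, enhanced voxelwise by the Riemann
sum over thresholds h of `extent(h)^E · h^H · dh` with E = 0.5, H = 2,
dh = map-max/100, 6-neighbour connectivity, positive and negative tails
enhanced separately.  Label shuffles are exhaustive when the number of
distinct splits is at most `n_perm` (default 5,000), otherwise Monte-Carlo
with the observed labelling included in the null; the FWER-corrected voxel
p-value is the rank of the observed enhanced value in the null
distribution of the map-wise maximum.

## Synthetic data generator

Real recordings of this kind are access-restricted, so validation uses a
generator with known ground truth.  Three latent phase oscillators — ELEC,
BLOOD, WATER — follow

    θ_i[n+1] = θ_i[n] + 2π f_i / fs
               + Σ_j κ[j→i] sin(θ_j[n−δ] − θ_i[n]) + σ_θ ξ_i[n],

with natural frequencies jittered ±10 % around 0.03 Hz, per-step phase
noise σ_θ = 0.1 rad, and the coupling delay δ equal to one cycle — the
same delay the analysis assumes.  Directed coupling makes the target track
the driver's phase one cycle back, so the driver's phase innovations are
reproduced in the target later; that temporal asymmetry is exactly what
phase TE detects, while the phase noise keeps the relationship stochastic
enough that direction remains identifiable.  Amplitudes are separate:
latent i is `a_i cos θ_i` plus white noise (SD 0.5), with per-state
amplitude scales.  A burn-in of three delays precedes every simulated
segment so coupling is in steady state.  Row sums of κ must stay below π
per step or the update is rejected as unstable.

Defaults encode the study conditions: awake has one-way drive
ELEC→BLOOD = 0.3 and WATER→BLOOD = 0.3; sleep states have the same links
symmetric at 0.15 each (bidirectional coupling with no net direction);
sleep multiplies ELEC/BLOOD amplitudes by ~1.5–1.7 (≈2–3× infraslow band
power) while WATER is state-independent.  The awake strengths are design
choices — strong enough that the 2-min-epoch estimator recovers the
imposed direction, weak enough that per-subject ΔTE magnitudes land near
−0.1 bits, the scale reported for such recordings.

Rendering: BOLD voxels are a spatially smooth positive loading (Gaussian-
filtered field, 1 ± 0.5) times the BLOOD latent plus voxel noise and
shared 1 Hz / 0.25 Hz nuisance tones; EEG channels are per-channel gains
(1 ± 0.2) times ELEC plus noise; the optical channels are Hb = −0.3·BLOOD,
HbO = +1.0·BLOOD, and H2O = −0.2·BLOOD + WATER (+ noise), so the water
channel anticorrelates with the blood channels in the Monro–Kellie sense.
The blood loading in the water channel is kept small deliberately: a large
shared component would let signal mixing, rather than coupling, dominate
the BOLD↔H2O transfer entropy (shared content inflates TE toward the
cleaner copy of the shared signal).  With 0.2 the residual mixing bias on
ΔTE(BOLD, H2O) is a few hundredths of a bit, small against the planted
effects; it is the main known artifact of the rendering model.  A
consequence of mixing is that the anticorrelation is statistical, not
per-realization: over short records the two independent oscillators can
correlate by chance more than −0.2, so the contract holds in the median
over realizations.  The atlas partitions the full-grid mask into nine
contiguous index blocks named after the nine bilateral regions; grids too
small for nine non-empty regions are rejected.

What the generator does *not* emulate: hemodynamic response functions,
head geometry or leadfields, scanner artifacts, spatially propagating
waves (every voxel shares one hemodynamic latent), realistic sleep
architecture (hypnograms are constant per segment), and 1/f background
spectra.  Passing tests therefore demonstrate that the estimators recover
known directed phase coupling under realistic noise, sample sizes, and
filtering — not that real recordings satisfy the generator's assumptions.

## Validation conditions and problem sizes

The test suite runs the full chain at desk scale, chosen so the suite
completes in minutes while keeping the per-epoch sample size (1,200
samples at 10 Hz) identical to the 2-min-epoch analysis:

- Null calibration: 500 independent band-limited noise pairs; the mean ΔTE
  must lie within the 99 % Monte-Carlo CI of 0 bits.
- Direction recovery: 200 realizations of one-way κ = 0.3 coupling on a
  4×4×4 grid with 8 electrodes, 6-min state runs, analysing an interior
  2-min epoch; the whole-brain ΔTE sign must match the planted direction
  in ≥ 95 % of realizations, in both directions.
- Estimator oracle: exact agreement with a brute-force count-table TE on
  binary sequences of length ≤ 12, plus closed-form checks (copy process
  → 1 bit; constant series → 0; antisymmetry).
- Statistical layer: exact Wilcoxon against enumeration, BH against the
  hand-computed step-up, TFCE against the single-voxel closed form
  v^{H+1}/(H+1), and the permutation test's voxel type-I error ≤ 5 % over
  100 null datasets (8×8×8 grid, 500 shuffles).
- Spectral layer: tone-peak recovery on the log grid and detection of a
  configured 2× sleep/awake hemodynamic band-power ratio (p_adj < 0.05)
  in ≥ 9 of 10 cohorts of 20 synthetic subjects.
- Pipeline pattern: with the default state configurations, whole-brain
  ΔTE medians for both BOLD pairs are negative in awake cohorts and
  statistically indistinguishable from zero in sleep cohorts.

## Known limitations

- One fixed lag (one cycle at 0.03 Hz); no search for the
  information-maximizing delay, and no multivariate/conditional TE, so
  common drivers are not excluded by construction — the lag-map control
  only addresses static propagation structure.
- Plug-in TE values are bias-dominated at 2-min epochs; only differences
  and contrasts of ΔTE are interpretable, never absolute TE levels.
- The water channel's anticorrelation and its TE sign carry a small
  rendering-induced mixing bias (above).
- Wilcoxon exact enumeration is limited to n1 + n2 ≤ 12; beyond that the
  continuity-corrected normal approximation is used (the two agree to
  |Δp| < 0.02 at the switch point).
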