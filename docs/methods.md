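# Methods

`somatoprf` implements voxel-wise two-dimensional population receptive
field (pRF) mapping for vibrotactile fMRI of the hand representation in
somatosensory cortex, together with the Fourier travelling-wave (TW)
analysis that serves as its reference, and a synthetic-session generator
that makes every stage testable without scanner data.

## Stimulus model

Stimulation is delivered on a 4 x 4 grid: digits D2-D5 crossed with four
proximal-distal (PD) sites per digit, PD1 (tip) to PD4 (base). Grid
coordinates are dimensionless "grid units": digit coordinate d in 1..4
(1 = D2), PD coordinate pd in 1..4 (1 = tip). A travelling-wave run
activates lines of the grid in succession, 4 s per line at TR = 2 s:

* **between-digit (BD)** — the four digit columns; 16 s cycles;
* **within-digit (WD)** — the four PD rows; 16 s cycles;
* **diagonal** — the seven anti-diagonals ordered from the (D2, PD1)
  corner; 28 s cycles. The anti-diagonal orientation and ordering are a
  package convention (either orientation yields seven lines; one had to
  be fixed for determinism).

Twelve cycles give 96 volumes per BD/WD run and 168 per diagonal run.
Reverse runs are the time-reversed forward sequence. A session
concatenates runs (default layout: one BD forward/reverse pair, two WD
pairs, one diagonal run = 744 volumes) and records run boundaries; no
convolution or detrending ever crosses a boundary.

## pRF model families

Each family assigns a weight to every site:

* **2D Gaussian** (4 spatial parameters): the separable form
  `w(d_i, pd_i) = exp(-[(d0-d_i)^2 / (2 sigma_d^2) + (pd0-pd_i)^2 / (2 sigma_pd^2)])`.
  Its overall scale is fixed to 1; response amplitude is carried by the
  HRF amplitude parameter, which the printed total of 9 parameters
  requires.
* **1D BD** (11): four independently scaled and positioned Gaussians over
  digits, one per PD row; the PD1 row's scale is the reference, fixed
  to 1 (4 centres + 4 sigmas + 3 free scales).
* **1D WD** (11): the orthogonal construction, one Gaussian over PD per
  digit, digit D2 as the scale reference.
* **Unconstrained** (16): one free weight per site; the fit ceiling. Its
  preferred location is the argmax site; pRF size is undefined.

Every family additionally fits 5 HRF parameters per voxel, giving totals
of 9 / 16 / 16 / 21. pRF size is the Gaussian sigma in grid units
(FWHM = 2 sqrt(2 ln 2) sigma ~ 2.355 sigma). Centres are bounded to
[0.5, 4.5] grid units; sigmas to [0.1, 10] (the upper bound prevents
degenerate flat fits on a 4-unit axis, the lower prevents spikes between
sites). Note the unconstrained family's weight scale is collinear with
the HRF amplitude; the solver tolerates the flat direction and all
reported quantities (predictions, rss, AIC, argmax location) are
invariant along it.

## Haemodynamic response

The HRF is a double-gamma kernel with five parameters: peak delay
(default 6 s), undershoot delay (16 s), a shared dispersion (1 s),
peak:undershoot ratio (6), and amplitude. The kernel is peak-normalised
on a densely sampled grid so that the amplitude parameter is the kernel
maximum in percent-signal-change units and scales the kernel exactly
linearly. Any five-parameter smooth unimodal-with-undershoot kernel
would serve; this parameterisation is the field's default and is
config-exposed.

## Preprocessing and the matched forward model

Voxel series are processed per run: linear detrend, high-pass filtering
above 0.01 Hz by projecting out discrete-cosine regressors, and
conversion to percent signal change using the pre-detrend run mean
(runs shorter than one cutoff period are detrended only, with a
warning). The fitted forward model — site weights dotted with the
stimulus rows, convolved with the HRF per run — is projected onto the
orthogonal complement of the *same* per-run confound design before
residuals are formed. This matters: the sustained component of a
periodic stimulus lives partly in the confound subspace, and fitting an
unprojected prediction to projected data biases centre estimates by
~0.005-0.02 grid units even at zero noise. With matched projection the
noiseless chain recovers planted parameters to solver precision.

PSC conversion divides each run by its own mean, which includes a small
stimulus-driven component; this rescales runs by slightly different
factors (fractions of a percent). The effect is absorbed by the fitted
amplitude and is invisible at realistic noise levels.

## Fitting

Starting values come from a coarse grid search — centres on {1, 2, 3, 4}
per axis, sigma on {0.5, 1, 2}, HRF at its canonical values — with the
response amplitude solved linearly at every lattice point (for the 1D
families, all four profile scales are solved by linear least squares per
candidate; for the unconstrained family the 16 weights are the linear
solution directly). The best lattice point (ties to the lowest index)
seeds a bounded trust-region-reflective nonlinear least-squares solve
(`scipy.optimize.least_squares`, ftol = xtol = 1e-8). A bounded
trust-region method is used rather than unmodified Levenberg-Marquardt
because the centre bounds are part of the model contract; the objective
is identical. The final rss never exceeds the grid-search rss.

Goodness of fit: r^2, adjusted r^2 = 1 - (1-r^2)(n-1)/(n-p-1) (may be
negative; voxels are conventionally kept at adjusted r^2 > 0), and the
least-squares AIC = n ln(rss/n) + 2k used to rank families per voxel
(rss = 0 maps to -inf with the fit flagged).

## Travelling-wave analysis

Forward and time-reversed reverse runs are circularly shifted by the
assumed haemodynamic lag (default 2 TRs) in opposite directions and
averaged. At the stimulus frequency this cancels the haemodynamic phase
*exactly* — the combined spectrum at that bin is the stimulus component
times a real factor — so the phase estimate is lag-unbiased; a wrong lag
only attenuates amplitude (and flips sign if off by more than a quarter
cycle, hence the 2-TR default).

Amplitude and phase are read off the DFT bin at the stimulation
frequency; coherence is that amplitude over the root-sum-square of
amplitudes across all non-DC bins below Nyquist. The Nyquist bin of an
even-length series is excluded throughout: without it the squared
coherence of white Gaussian noise is exactly Beta(1, K-1) over the K
retained bins, making the p-value p = (1 - c^2)^(K-1) exactly calibrated
(Monte Carlo type-I error 0.050 at alpha = 0.05, 10,000 reps). P-values
are corrected across voxels with Hommel's stagewise-Bonferroni
procedure (statsmodels); a brute-force closed-testing oracle verifies it
in the tests. Note that Hommel's Simes-based closed testing leaves m
identical p-values unchanged (Simes of m equal p's is p), unlike a plain
Bonferroni stage.

Phases are binned into four contiguous bins of width pi/2 tiling
[0, 2 pi) — four labels must tile the cycle. The default bin offset is
-pi/cycle_len_tp: a line's ON block occupies samples
[l*s, (l+1)*s - 1], whose centroid sits half a sample before the
continuous block centre, and this offset puts each line's phase at its
bin centre. BD labels map to D2-D5, WD labels to PD1-PD4.

## Evaluation, ROI statistics, coverage maps

Continuous preferred locations are discretised to labels by rounding to
the nearest grid unit (clipped to 1..4) before Dice comparison;
2 |A∩B| / (|A| + |B|) per label, with the full 4 x 4 label-pair matrix
available. The AIC preference matrix reports, per family pair, the
percentage of voxels with the lower AIC; ties split evenly and the
diagonal is 50 by convention.

Sizes are aggregated subject-wise into 16 ROIs per scheme (digit x PD
location, or digit x area band) after thresholding at adjusted r^2 > 0;
group comparisons use a one-way ANOVA with the subject-level ROI mean as
the observational unit, followed by Tukey's HSD (studentised-range
distribution via statsmodels). ROI volumes are voxel count x voxel
volume (1.25 mm isotropic = 1.953125 mm^3 by default).

Coverage maps: each voxel's native 4 x 4 weight grid is interpolated to
20 x 20 with a bicubic spline over the native lattice hull (native
values are reproduced at their sample positions; bilinear mode is
available), embedded centred in a 60 x 60 frame, and the surround is
filled by solving the discrete Laplace equation with the known block as
Dirichlet data and zero flux at the frame edge (sparse solve, residual
< 1e-8; the maximum principle keeps filled values inside the known
range). The ROI summary flattens the voxel maps, runs one PCA pooled
across subjects, reconstructs each map from the first 3 components
(typically ~90%+ of variance), averages within subject and then across
subjects with equal weight so no subject dominates; a per-subject PCA
mode is available behind a flag (`pca_mode="per_subject"`), since either
reading of "subject-wise weighting" is defensible — pooled is the
default because it defines one common pattern basis for the ROI. Peak
alignment shifts each map by whole cells only (exactly invertible on the
common support) so its peak lands on the frame centre along the chosen
axis; out-of-frame cells are dropped and the average is
count-normalised. Map width is reported as the RMS second moment about
the map centroid.

## Synthetic data

The generator is the forward model run generatively on a flat voxel
lattice (no cortical mesh — all in-scope statistics are voxel-wise).
Defaults, chosen once to emulate the study's qualitative map structure
at plausible 7T vibrotactile effect sizes:

| parameter | default | meaning |
|---|---|---|
| lattice | 40 x 40 | voxels per patch |
| d0 gradient | 1 → 4 across columns | D2→D5 somatotopy |
| area bands | 3a, 3b, 1, 2 (row strips) | mirrored tip→base pd0 gradients, flipping at each border |
| sigma_d base | 0.8 grid units | between-digit pRF size |
| band sigma scale | 3a 0.9, 3b 0.8, 1 1.0, 2 1.3 | BA2-like > BA3b-like sizes |
| elongation | 2.0 | sigma_pd / sigma_d (within-digit elongation) |
| size slopes | +15% per digit unit, +10% per PD unit | growth D2→D5 and tip→base |
| amplitude | 2.0 PSC | peak response |
| jitter | 0.05 grid units | seeded scatter on centres |
| tSNR | 50 | noise sd = 100 / tSNR = 2 PSC |
| drift | 0.5 PSC per run | linear, removed by preprocessing |
| baseline | 1000 | raw embedding; `None` emits PSC directly |

Noise is white Gaussian (optional AR(1), rho config-exposed) in PSC
units, embedded multiplicatively on the raw baseline so the full
preprocessing chain is exercised. The patch's own seed fixes the ground
truth; the simulation seed drives only noise. What the generator does
*not* emulate: spatially correlated (physiological) noise, cortical
geometry and partial-volume effects, inter-subject variability in HRF
shape, or attention/cueing effects — so a passing recovery test shows
the estimator is correct and well-conditioned under the stated noise
model, not that real 7T data would behave as well.

## Problem sizes in the shipped checks

The exactness checks run on 5 x 5 noiseless patches; noisy recovery on
the full 40 x 40 patch at tSNR 50 (full 744-volume session); the
four-family comparison, Dice, ROI and coverage checks on a 12 x 12
patch; the coherence calibration on 10,000 white-noise series. These
sizes make the whole suite run in a couple of minutes on one CPU while
keeping every statistic comfortably away from its threshold.

## Known limitations

* With broad digit tuning (sigma_d ≳ 1.2), the TW phase is a circular
  mean over stimulation lines and pulls edge-digit (D2/D5) labels toward
  the grid centre; on synthetic patches the D5 band's TW-vs-pRF Dice
  drops to ~0.4 while D2-D4 stay at 0.7-0.9. The pRF estimates
  themselves are unbiased (truth Dice ~0.95); this is a limitation of
  phase-encoding labels, not of the fit.
* The within-digit axis is weakly constrained when sigma_pd is large
  relative to the 4-unit grid; pd0 errors are correspondingly larger
  than d0 errors at matched noise.
* HRF parameters are fitted per voxel and per family (the parameter
  totals count them in every family); no inter-family sharing is
  attempted.
* The unconstrained family's amplitude degeneracy (weights x HRF
  amplitude) makes its individual parameter values non-identifiable even
  though its fit quality is well-defined.
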