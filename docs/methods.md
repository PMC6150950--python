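# Methods

## The problem

MEG source images made with a beamformer (LCMV spatial filter) blur two
cortical sources that lie only millimetres apart, because the weights that
image one source must simultaneously minimise the other.  When an
experimental paradigm activates the two sources in *disjoint time windows*,
the sensor covariance can be segmented in time so that each set of weights
is computed from data in which only its own source is active.  This package
implements, end to end, the simulation framework that quantifies how much
spatial resolution that segmentation buys, and the volumetric
pseudo-t mapping pipeline that exploits it to separate the post-movement
beta rebound (PMBR, 13–30 Hz) of individual fingers.

## Forward model and geometry

Sources are current dipoles in a spherically symmetric conductor; the
external field is the closed-form (Sarvas) expression, evaluated per
channel against either one global sphere or one sphere per channel
("multiple local spheres", the default).  Local spheres are least-squares
fits to the head-surface patch within 4 cm of the surface point closest to
each channel — the conventional construction; the fitting procedure is not
standardised anywhere, and any per-channel fit of this kind is equivalent
for the conclusions here.  In local-spheres mode the source-containment
check uses the whole-head fitted sphere: an individual patch sphere need
not contain sources on the far side of the head, by construction.

The scanner is a synthetic stand-in for a 275-channel whole-head system
whose true geometry (and the subject's position in it) is not public: 275
point magnetometers quasi-uniformly covering the upper hemisphere of a
12 cm sphere, each reading the inward radial field component.  Channel
count, source–sensor distance scale and coverage — the quantities that
drive two-point resolution — are preserved; axial-gradiometer formation
and synthetic higher-order gradiometry are not modelled, since the
simulation injects noise directly at channel level so the gradiometer
transfer function is absorbed into the quoted noise amplitude.

The head surface is an ellipsoid with semi-axes (9.0, 7.0, 6.5) cm (adult
head scale).  All simulated dipoles sit on this surface shrunk by 1.5 cm
(each semi-axis reduced by the depth), so every source has comparable
depth, and tangential orientation with a uniformly random azimuth — radial
dipoles are magnetically silent in a spherical conductor.  Coordinates are
right-handed with +z superior; SI units internally, nAm and fT at the
interfaces.

## Simulated data

One trial lasts 20 s at 600 Hz.  Source 1 is active during 0–2 s, source 2
during 10–12 s.  Within its window a source's moment is white Gaussian
noise with a per-trial standard deviation drawn once per trial from
Normal(31, 3) nAm, truncated at zero (a fixed 31 nAm would produce an
across-trial spread far below the intended ±3).  A dataset is 44 such
trials.  Sensor noise is white Gaussian, equal on all channels and
uncorrelated, with per-sample standard deviation 36 / 21 / 8 fT for the
low / medium / high SNR conditions, or a multivariate phase-randomised
surrogate of a user-supplied multichannel record: one common random phase
per frequency bin, applied to every channel, preserves each channel's
Fourier amplitude spectrum exactly and every cross-spectrum (hence the
full zero-lag covariance), while scrambling the waveform.  DC and Nyquist
bins are left untouched to keep the output real.

All randomness descends from one `SeedSequence`; the source and noise
streams are separated so a noisy and a noiseless run of the same seed share
source samples exactly.  Covariance matrices for the full-size study are
accumulated trial by trial in float32 BLAS rank-k updates (never holding
the 44 × 275 × 12000 array), and this streaming path is draw-for-draw
identical to materialising the dataset.

## Beamformer statistics

Weights are the unit-gain minimum-variance solution
w = C⁻¹l / (lᵀC⁻¹l).  Three image constructions are compared for the
two-source paradigm (C over the whole trial, C₁ and C₂ over half-trials):

1. single weights from C, one image;
2. single weights from C, two images with C₁ resp. C₂ in the numerator;
3. separate weights from C₁ and C₂, one image each.

Two statistics are exposed at every scan point: the noise-normalised
pseudo-z, wᵀC_num w / (υ² wᵀw), and the raw projected power wᵀC_num w.
The scalar (single-orientation) scan optimises the dipole orientation per
point in the tangential subspace of the lead field, with the optimisation
objective matched to the imaged statistic — the generalised eigenvector of
(L₃ᵀC⁻¹L₃, L₃ᵀC⁻²L₃) for pseudo-z, the minimum eigenvector of L₃ᵀC⁻¹L₃ for
power.  Matching the objective to the statistic keeps the profile the
pointwise maximum of a continuous family, hence continuous; optimising one
statistic while plotting the other produces kinks at orientation
crossovers that corrupt dip measurements.

No diagonal loading is applied by default: the study design provides
264,000 raw (broadband) or 14,960 effective (beta-band, 2 × 17 Hz × 10 s ×
44 trials) samples per covariance, ample for a 275-channel matrix.
Loading is available as a fraction of the mean sensor variance for
degenerate inputs.  The sensor-noise variance υ² is the known injected
value in simulations; for band-limited covariances it is scaled by the
measured power gain of the zero-phase band-pass (a 4th-order forward–
backward Butterworth; the filter family is a free choice and zero-phase
filtering preserves boxcar timing), and for real data the smallest
eigenvalue of the full-data covariance is the fallback estimate.

## Resolvability criterion

Two sources are *resolved* when the 1-D image along the line joining them
(0.5 mm steps, 10 mm margins) shows two interior local maxima — each lying
nearer its own source than the other, so a sidelobe cannot stand in for a
missing source — whose intervening minimum is at most 80% of the reference
peak height (boundary inclusive).  Two-image methods are reduced to one
composite profile by the pointwise maximum before peak finding; the
criterion needs a single pair of peaks with one intervening minimum and
the reduction is not otherwise prescribed.

The criterion operates on the **projected-power** profiles.  With the
stated source strengths and noise amplitudes, the noise-normalised
pseudo-z image is essentially unlimited in two-point resolution (peaks of
order 10²–10³ against a dip pinned at the noise baseline ≈ 1, at any
separation), so a dip criterion there cannot produce finite resolution
limits; the power image, whose dip is governed by the beamformer's
suppression of correlated lead fields, is the quantity whose 80% dip
reproduces the known resolution behaviour.  The dip is referenced to the
**smaller** of the two peaks: the design places equal-strength sources at
equal depth, so genuine peaks have equal expected height and the choice is
immaterial for noise-free profiles, while on finite-data profiles it
additionally requires both peaks to rise ≥ 20% above the valley, which
stops few-percent estimation-noise bumps on the flank of a single
unresolved peak from registering as a second source.  Both choices
(statistic and peak reference) are configurable.

## Minimum-distance search and the study

For one placement, the minimum resolvable distance is the smallest
separation d (on a 0.5 mm grid) still resolved, starting from d = 30 mm.
The default search is bisection on the grid (~6–8 image evaluations per
method instead of ~30–60 for a strict sequential descent), assuming the
resolved/unresolved boundary is monotone in d; the sequential decrement is
available and agrees with bisection when the boundary is clean.  The study
draws random placements — midpoint uniform on the shrunken ellipsoid,
random in-surface direction, independent random azimuths — and moves the
sources symmetrically about the midpoint *along the surface* until their
chord distance equals d.  Placements not resolved at 30 mm by every method
are redrawn (logged, capped); within a repeat all methods share the
placement and the per-separation noise seed, so the per-repeat minima are
paired observations and the between-method comparison is a paired t-test.
Because the direction of the comparison is prespecified by the design
(segmentation is predicted to decrease the resolvable distance), the
headline significance is the one-sided p; the two-sided value is reported
alongside in the study summaries.

The scaled-down headline study uses 20 repeats (the reference experiment
uses 50) with methods 1 and 3 at medium SNR; it completes in roughly ten
minutes on one core.  Sampling the midpoint uniformly over the whole
ellipsoid means some pairs sit under the rim of the upper-hemisphere
helmet where coverage, and hence resolution, is poor — those placements
are the main source of redraws and of the large-d tail.

## Analytic (infinite-data) oracle

In the infinite-data limit the covariance of the boxcar design is exactly
C = υ²I + Σ δᵢ σᵢ² lᵢlᵢᵀ, with δ the duty cycle (0.1 per source for the
full 20 s window, 0.2 in its own 10 s half-window) and σ² = 31² + 3² nAm²
the within-window moment variance under the per-trial amplitude model.
Feeding these exact covariances through the *same* scanning code yields
the images a simulation converges to as trials grow; the package verifies
monotone convergence of simulated method-1 profiles to the analytic curve
over 11 → 44 → 176 trials and agreement within 5% at 176 trials.  A
Sherman–Morrison (rank-recursive) inverse cross-checks the direct solves.
Zero noise is guarded with a small floor since the images diverge at the
sources in that limit.  Method 2 has no analytic counterpart here.

## Beta-rebound mapping

The volumetric pipeline images each digit with its own half-trial
beta-band (13–30 Hz) covariance (the method-3 construction): weights and
scan orientation from the digit's 10 s window, pseudo-t contrast
T = (wᵀC_a w − wᵀC_c w) / (2 wᵀw) between the rebound window (2.5–4 s for
the first digit, 12.5–14 s for the second) and a late-rest control window
(7.5–9 s / 17.5–19 s), evaluated on a regular 2 mm grid; the denominator
removes the depth bias of raw projected power, and the contrast is
implemented exactly as written (no υ² factor), which leaves peak locations
unaffected.  Peaks are grid argmaxima with ties broken by lowest linear
index.  The synthetic two-digit condition places two rebound-only sources
(white moment noise gated to the rebound windows; the beta filter selects
the in-band component) 4 mm apart in z on a lateral patch of the source
surface, and the recovery check demands the per-digit peak separation be
4 ± 2 mm (one grid step) in z with a significant one-sided paired test
over 8 independent runs.

## What the synthetic data do and do not show

The generator reproduces the trial structure, source strength statistics,
sensor count/geometry scale and noise amplitudes of the reference design,
so passing tests demonstrate the *methodological* claims: temporal
covariance segmentation sharpens two-point resolution by several-fold, the
effect survives realistic covariance estimation noise, and the mapping
pipeline recovers millimetre-scale somatotopic offsets.  They do not show
performance on real recordings: physiological background (cortical
oscillations, cardiac and muscle artefacts), head movement, gradiometer
geometry and co-registration error are all absent, and real interference
is only approximated by the phase-randomised surrogate machinery.  The
absolute minimum-distance numbers depend on the unpublished scanner
geometry; with the synthetic helmet they land in the same regime as the
reference values (method 1 ≈ 13 mm vs 16.5 mm; method 3 ≈ 3 mm vs 2.8 mm)
but should be read as scale, not point estimates.  Method 2 (single
weights, segmented numerator) resolves about as well as method 3 in this
implementation; the reference work ranks it only qualitatively.

## Numerical notes

* Covariances are accumulated without mean subtraction (signals are
  zero-mean by construction; the beamformer operates on second moments).
* float32 streaming accumulation changes covariance entries by ~1e-7
  relative — negligible against estimation error — and float64 streaming
  is bit-consistent with the materialised path.
* `find_peaks` handles plateau maxima; profile ties in peak selection are
  broken by height then position, grid argmax ties by lowest index.
* The ellipsoid fit is the algebraic least-squares quadric (smallest
  singular vector of the scaled design matrix) with positive-definiteness
  checks; degenerate clouds (coplanar points, non-ellipsoidal quadrics)
  are rejected explicitly.
* Bisection seeds, placement draws and noise realisations all derive from
  `SeedSequence` keys of the form (master, tag, repeat, attempt, d-index),
  so every sub-experiment is independently reproducible and resumable.
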