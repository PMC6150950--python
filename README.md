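# betabeam

Spatial resolution of MEG beamformer imaging under temporal covariance
segmentation — simulation framework, LCMV imaging statistics, two-point
resolvability analysis, and volumetric beta-rebound mapping.

## The problem

Magnetoencephalography (MEG) reconstructs cortical current sources from a
few hundred magnetic field channels.  The LCMV beamformer estimates the
source amplitude at a location/orientation θ as q(t) = w_θᵀ m(t), with
unit-gain minimum-variance weights

    w_θᵀ = l_θᵀ C⁻¹ / (l_θᵀ C⁻¹ l_θ),

where l_θ is the forward (lead) field and C the sensor covariance over a
time–frequency window.  Because the weights for one source must minimise
every *other* source present in C, two sources a few millimetres apart blur
into one another.  If the experimental design activates the sources in
disjoint time windows (e.g. tapping the index finger, then the little
finger, within each trial), C can be segmented in time so each source's
weights are computed from data in which the other source is silent — and
the spatial resolution improves several-fold.

This package quantifies that effect end to end, for researchers in MEG
methods and sensorimotor neurophysiology:

* **Forward model** — current dipoles in single-sphere or multiple
  local-sphere conductors (closed-form field), a synthetic 275-channel
  helmet, and an ellipsoidal source surface 1.5 cm beneath the head surface.
* **Simulation** — 44 trials × 20 s at 600 Hz; two boxcar-gated stochastic
  dipoles (31 ± 3 nAm, active 0–2 s and 10–12 s); white sensor noise at
  36/21/8 fT per sample (low/medium/high SNR) or phase-randomised
  surrogates of a supplied interference record.
* **Beamformer** — covariance estimation with effective-sample accounting
  (2·BW·Δ), pseudo-z = wᵀCw/(υ²wᵀw) and projected-power images, pseudo-t
  active/control contrasts, and the three image constructions: (1) one
  weight vector and one image from the full-trial covariance, (2) one
  weight vector and two segmented-numerator images, (3) two weight vectors
  from the segmented covariances C₁, C₂.
* **Resolution analysis** — the 80%-dip two-peak criterion on 1-D profiles,
  minimum-resolvable-distance search, a repeated-placement study with
  paired statistics, and a closed-form infinite-data oracle the simulations
  converge to.
* **Mapping** — per-digit beta-band (13–30 Hz) pseudo-t volumes on a 2 mm
  grid with peak-coordinate statistics (superior–inferior shift,
  corresponding vs alternate digit distances).

## Worked example

Run the headline experiment from Python (about ten minutes on one core):

```python
from betabeam.config import build_geometry
from betabeam.resolution import StudyConfig, resolution_study

geo = build_geometry()  # 275-channel helmet, default head ellipsoids
cfg = StudyConfig(n_repeats=20, methods=(1, 3), snr_condition="medium", seed=1)
res = resolution_study(cfg, geo.source_surface, geo.head_model, geo.sensors)
print(res.summary())
print(res.paired_test(1, 3))
```

Output from this exact run:

```
{1: {'mean_mm': 12.775, 'sd_mm': 6.434845518122814, 'n': 20},
 3: {'mean_mm': 3.0,    'sd_mm': 1.7167901505579044, 'n': 20}}
(7.349320661013288, 5.769906068279828e-07)
```

Reading: over 20 random source pairs at medium SNR, the single-image
beamformer (method 1) resolves pairs down to a mean separation of
~12.8 mm, while splitting the weights by time window (method 3) resolves
~3.0 mm — a more than four-fold sharpening; the paired t-test across the
shared placements gives t ≈ 7.3, p ≈ 6 × 10⁻⁷.  The per-repeat spread for
method 1 is wide because resolution depends strongly on the (random)
relative orientation of the two dipoles — near-parallel pairs are the hard
case — and on where the pair sits under the helmet.

The same experiments are scriptable from the shell (`betabeam simulate`,
`betabeam profile`, `betabeam study`, `betabeam map`); each subcommand
reads a YAML config, embeds the config hash and seed in its outputs, and
`betabeam study --resume` restarts an interrupted study from the completed
repeats.

## Layout

```
src/betabeam/geometry.py     sensors, ellipsoids, local spheres, dipole fields
src/betabeam/simulate.py     paradigms, boxcar sources, noise, surrogates, filtering
src/betabeam/beamformer.py   covariances, weights, pseudo-z/t, method images, mapping
src/betabeam/resolution.py   dip criterion, distance search, study, peak statistics
src/betabeam/analytic.py     exact covariances and infinite-data images
src/betabeam/config.py       YAML experiment configuration
src/betabeam/cli.py          command-line entry points
docs/methods.md              modelling assumptions, parameters, numerical choices
```
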