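# Methods

## Scope and assumptions

`condyn` analyses 2D particle trajectories in physical units (μm, s).
It assumes localizations are pixel-centred with origin at the image
top-left (x rightward, y downward), 0-based frames, and a constant frame
interval within a trajectory; linking gaps are retained and all lag times
are computed from frame arithmetic, never from row order. Motion is treated
as planar: axial (z) displacement, defocus and motion blur are outside the
model.

## Motion models in the synthetic module

The generators exist so that every downstream estimator can be tested
against closed-form statistics. They emulate the motion regimes of
membrane-tethered condensates and inert probe particles: sub-diffusive /
tethered fluctuation, free diffusion, and motor-like directed runs at
0.1–0.3 μm/s, observed at 0.5 Hz (Δt = 2 s) or 50 Hz (Δt = 0.02 s) with
117 nm pixels and a 16 nm per-axis static localization error.

* **Brownian** — independent Gaussian increments, per-axis variance 2DΔt;
  2D ensemble MSD(τ) = 4Dτ.
* **Fractional Brownian motion (fBm)** — stationary-increment Gaussian
  process with Hurst index H = α/2, synthesized by exact factorization
  (Cholesky, eigendecomposition fallback near α = 2) of the fractional
  Gaussian noise covariance
  γ(k) = D Δt^α (|k+1|^α − 2|k|^α + |k−1|^α), which makes the ensemble MSD
  exactly 4Dτ^α. The factorization is O(n²) memory / O(n³) time — chosen
  for exactness at test scale (trajectories up to a few thousand frames);
  α = 1 short-circuits to independent increments and α = 2 to a shared
  Gaussian velocity (the exactly ballistic limit). The factor is cached per
  (n, α, D, Δt), so large ensembles cost one factorization.
* **Tethered** — per-axis Ornstein–Uhlenbeck relaxation about an anchor,
  simulated with the exact transition density
  x' = a + φ(x − a) + σ_c √(1−φ²) ξ, φ = e^(−Δt/τ_r), initialized at
  stationarity; ensemble MSD(τ) = 4σ_c²(1 − e^(−τ/τ_r)) with plateau 4σ_c².
  An Euler scheme was rejected because the plateau invariant must hold
  exactly in distribution.
* **Mode switching** — a schedule of (state, duration, params) segments
  with position continuity across switches. Directed segments move at
  constant velocity along a fixed direction; Brownian jitter on top is
  available (`D_jitter`) but defaults to off so detector fixtures have
  clean, exactly checkable geometry. Frame 0 carries the first segment's
  label; every later frame the label of the segment generating the step
  into it, so labels partition frames exactly.

The confined regime is deliberately offered as *either* fBm or OU: the
generative mechanism of condensate confinement (viscoelastic medium vs
molecular tether) is not identifiable from MSD exponents alone, and the
package does not claim one.

Localization error is i.i.d. Gaussian per axis per frame (default
σ_loc = 16 nm). A static emitter then shows an apparent mean step of
σ_loc·√π ≈ 28.4 nm — the basis of the 30 nm immobility threshold.

The mask generator produces a connected tubular network (random persistent
paths branched from the existing skeleton, dilated with a Euclidean disk of
radius tubule_width/2). It is a synthetic stand-in with the topological
features that matter for containment/distance tests — connectedness,
tubule width ≳ pixel size, area fraction ~10 % — not a morphologically
faithful ER. The spot renderer draws localizations as 2D Gaussians; the
alternating-excitation mode renders species A+B on 0-based even frames and
B only on odd frames, matching the cross-excitation scheme the channel
separator inverts.

Reproducibility: a single seed expands to per-trajectory sub-seeds through
`numpy.random.SeedSequence(seed).spawn(n)`, so trajectory i of a batch is
bit-identical regardless of batch size.

### What passing tests do not show

The generators omit photobleaching, blinking, detection dropouts coupled to
signal level, motion blur, camera noise beyond the Gaussian/Poisson
options, drift, and 3D excursions. Estimator performance demonstrated on
them bounds algorithmic correctness, not robustness to every real-data
pathology.

## Diffusion profiling

MSD uses the time-averaged estimator over all ordered pairs at each frame
lag. The log-log fit uses natural logarithms (the base cancels in α) and
recovers D = exp(intercept)/(2n) with n = 2; R² is that of the log-log
linear regression, and fits with R² < 0.6 are flagged excluded — kept on
the timeline, dropped from summary statistics. `fit_alpha_loglog` defaults
to fitting the first half of the curve, the usual "about half the
trajectory length" rule.

Running windows are 20 frames at stride 1 (maximal temporal resolution of
the overlap), with per-window lags up to ⌊W/2⌋ = 10 and all 10 fitted.
Windows containing a zero MSD lag (perfectly static stretches, which
tethered motion can produce) are flagged degenerate rather than failing
the trajectory. A vectorized sliding-sum path handles contiguous-frame
trajectories; gapped trajectories take a generic per-window path, and the
two are tested for exact agreement.

### Estimator bias at the window scale

OLS on the log of a noisy TA-MSD is biased low (Jensen): at lag 10 a
20-frame window averages 10 strongly overlapping pairs — roughly one
independent displacement — and E[log(χ²₂/2)] = −0.577, so the top lags sit
systematically below the true power law and drag the slope down. On pure
Brownian input the per-window mean α̂ measured by `scripts/acceptance.py`
is ≈ 0.93–0.95 rather than 1.0. This is a property of the estimator as
specified (and of any pipeline using it), not of the simulation; it is
scale-invariant in D and Δt, and identical on both code paths. Consumers
comparing populations profiled with the same windows are unaffected, but
the per-window α̂ is not an unbiased point estimate. For *trajectory-level*
exponent recovery the package therefore fits 10 lags (the same depth the
windows use) rather than half of a long trajectory: deeper fits only add
lags with fewer independent pairs and strictly more negative bias
(measured: −0.03 at 10 lags vs −0.10 at 50 lags for α = 1.5, 100-frame
tracks).

Step angles are undirected, in [0°, 180°] (0° = no directional change,
180° = full reversal); angles at zero-length steps are undefined and
skipped with a count. Ensemble MSD across segments weights each lag by
pair count and requires a common Δt.

## Event detection

Immobile trajectories (mean step < 30 nm) are removed before profiling and
detection. A step is a candidate when it and its immediate successor both
exceed the step threshold (the most literal reading of "two consecutive
steps"; the either-step alternative inflates false positives). An event is
a maximal run of candidate steps that (a) nets ≥ 585 nm start-to-end — net,
not path length, so reversals are not double-counted — and (b) is supported
by at least one running window whose frame span overlaps the run and passes
α > 1, D > D_min and R² > 0.6. "Overlaps" rather than "contains" because a
20-frame window cannot contain longer runs, and a window mixing run and
tether already dilutes α; requiring all windows would miss short runs.
Events are non-overlapping and ordered by construction. Velocity is net
displacement over duration.

The nm thresholds (234 = 2 px, 585 = 5 px at 117 nm/px) are coupled to the
0.5 Hz acquisition they calibrate; at other frame rates the caller
rescales them. The D floor behaves the same way: 0.01 μm²/s sits just
below the typical window-D of real condensate data (window-D mode
≈ 10^−1.8 μm²/s, driven by ~0.33 μm observed steps), i.e. it is a
data-scale noise floor, not a velocity gate. The synthetic planted
fixtures used in the tests have a far quieter tether (σ_c = 50 nm), whose
window-D scale is ~10× lower, so fixture runs use the same floor rescaled
to that scale (D_min = 0.001 μm²/s); all other gates stay at their
defaults. With it, planted 4 s runs at 0.16 μm/s are detected in ≈ 99 % of
replicates and pure tethered trajectories fire < 1 %. Detection of runs at
exactly 0.15 μm/s for exactly 4 s is intrinsically marginal at any
configuration: the net displacement (600 nm) exceeds the 585 nm gate by
only 15 nm, within endpoint localization noise (σ ≈ 23 nm along-track), so
about a quarter of such runs fall below the gate.

## Spatial analysis

Boundaries are traced by marching squares at the 0.5 iso-level, giving
half-pixel-resolution contours; distances are measured to contour
*segments*, because distances of interest (~100 nm) are comparable to the
117 nm pixel and vertex-only distances would quantize badly. Containment
is even-odd over closed contours — holes need no special-casing — with
on-contour points counted inside (a condensate centre on the membrane
trace is membrane-associated). Trajectory "centres" average the first 50 s
by default (photobleaching control); the full-trajectory mean is a flag
away. Density maps bin one representative per trajectory by default
(per-frame mode available), on a 58.5 nm grid (half a camera pixel), cells
half-open [edge, edge + spacing) so an on-edge point belongs to the higher
cell, and total counts conserve the number of representatives exactly.

Manders' coefficients are thresholded: M1 is the channel-1 intensity sum
over pixels above threshold in *both* channels divided by the sum over
channel-1 foreground (and symmetrically M2). Restricting the numerator to
channel-1 foreground keeps both coefficients in [0, 1] for any threshold
pair. Default thresholds are per-channel Otsu (the usual automatic
foreground split) with explicit override; a channel with no foreground
yields NaN, never 0. The Stokes–Einstein pair uses
k_B = 1.380649 × 10⁻²³ J/K and T = 310.15 K by default (37 °C imaging);
all nm/μm/m conversions go through one constant table, and the two
directions are exact inverses.

## Image preprocessing

DoG band-pass filters each frame between sigma_small and sigma_large
(typical pairs: 1 and 5 px for small condensates, 3 and 7 px for larger
bodies) with reflective boundaries; the operation is linear and removes DC
exactly. Alternating-excitation separation subtracts each odd frame from
its preceding even frame to isolate the cross-excited species, clamping
negatives to zero (intensities are non-negative); no registration is
applied between alternating 20 ms exposures, where motion is negligible —
an optional translation correction exists behind a flag.

## Problem sizes

The statistical suites use 1,000 trajectories × 100 frames per exponent
for fBm recovery, 5,000 × 40 frames for the OU plateau, ~10,000 windows
for the Brownian null, and 1,000-replicate planted sets for the detector —
sizes at which the Monte-Carlo error is several times smaller than each
assertion's tolerance.

## Known limitations

* Per-window α̂ and D̂ carry the negative log-fit bias quantified above.
* No changepoint/HMM state segmentation; events are rule-based only.
* 2D only; no photophysics; no drift correction; no CVE/MLE D estimators.
* Masks are accepted as inputs (or generated synthetically); the pixel
  classification that produces them in real pipelines is out of scope.
* The tracking-CSV reader expects a TrackMate-like dialect; XML and HDF5
  trajectory formats are not supported.
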