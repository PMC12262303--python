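# condyn

Single-particle-tracking (SPT) analysis of biomolecular-condensate motion.

Cytoplasmic condensates in live cells rarely diffuse freely: most are
tethered to membrane structures such as the endoplasmic reticulum (ER) and
show sub-diffusive, back-and-forth motion, while a small fraction is
intermittently carried along microtubules in short, directional
super-diffusive runs. Resolving this dual-mode behaviour from tracking data
requires time-resolved diffusion metrics rather than one fit per
trajectory. `condyn` implements that pipeline for 2D trajectories exported
by spot-tracking software (TrackMate-style CSV), plus the image
preprocessing and spatial quantification around it, and a synthetic-data
module that generates all of it with known ground truth.

## The model

For a trajectory r(t) sampled at frame interval Δt, the time-averaged mean
squared displacement is

    MSD(τ) = ⟨ |r(t + τ) − r(t)|² ⟩_t

and is fitted on a log-log scale to the anomalous-diffusion law

    log MSD = α log τ + log(2nD),   n = 2,

so the slope is the anomalous exponent α (α < 1 sub-diffusion, α = 1
Brownian, α > 1 super-diffusion, α = 2 ballistic) and the intercept yields
the generalized diffusion coefficient D. The fit is recomputed in
overlapping 20-frame windows (stride 1, lags up to 10, fits with R² < 0.6
flagged), giving per-window traces of α, D and mean step size that resolve
transient transport events inside otherwise tethered trajectories.

Super-diffusive events are detected by a conjunction of rules: two
consecutive steps above 2 px (234 nm at 117 nm/px), run net displacement
above 5 px (585 nm), and at least one overlapping window with α > 1,
D above a noise floor, and R² > 0.6. Event velocity is net displacement
over duration. Around the core sit: an immobility filter (mean step
< 30 nm, just above the 16 nm localization-error floor of 16·√π ≈ 28.4 nm
apparent steps), DoG band-pass spot enhancement, alternating-excitation
channel separation, trajectory density maps (58.5 nm grid), sub-pixel mask
boundary extraction with containment/distance queries, Manders'
colocalization coefficients, and the Stokes–Einstein pair
D = k_BT / (6πηr).

## Worked example

```python
import numpy as np
from condyn import (simulate_switching, add_localization_noise,
                    running_window_profile, detect_super_events, ClassifierConfig)

schedule = [
    ("tethered", 248.0, {"relaxation_time": 5.0, "sigma_c": 0.05}),
    ("directed",   4.0, {"v": 0.16}),
    ("tethered", 140.0, {"relaxation_time": 5.0, "sigma_c": 0.05}),
]
traj, truth = simulate_switching(schedule, dt=2.0, seed=42)
traj = add_localization_noise(traj, sigma_loc=16.0, seed=43)

profile = running_window_profile(traj)          # 20-frame windows, stride 1
print(f"windows: {len(profile)}, "
      f"median alpha: {np.nanmedian(profile.alpha):.2f}, "
      f"max alpha: {np.nanmax(profile.alpha):.2f}")

cfg = ClassifierConfig(D_min=0.001)             # D floor at the fixture's scale
for ev in detect_super_events(traj, profile, cfg):
    print(f"event: frames {ev.start_frame}-{ev.end_frame}, "
          f"net {ev.net_displacement:.2f} um in {ev.duration:.0f} s "
          f"-> {ev.velocity:.3f} um/s")
```

Output:

```
windows: 178, median alpha: 0.26, max alpha: 1.50
event: frames 124-126, net 0.65 um in 4 s -> 0.162 um/s
```

A particle tethered for 248 s (50 nm constraint scale), translocated for
4 s at 0.16 μm/s, then tethered again: the window profile stays deep in the
sub-diffusive regime (median α ≈ 0.26) except around the run, and the
detector recovers the planted event with its velocity to within the
localization noise.

A thin CLI mirrors the library: `condyn profile`, `condyn classify`,
`condyn preprocess`, `condyn spatial`, `condyn coloc` (see `--help`).

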