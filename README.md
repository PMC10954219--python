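# smtstates

Mobility-state analysis for slow-interval single-molecule tracking (SMT) of
chromatin-bound proteins.

At a 5 Hz frame rate (200 ms intervals, 10 ms exposures) freely diffusing
nuclear proteins (D ≈ 1.8 µm²/s) defocalize out of a ~400 nm detection slab
between frames with probability > 1 − 10⁻⁹, so the tracked molecules are
the chromatin-bound ones. `smtstates` asks what "bound" hides: how many
distinct low-mobility states the bound population occupies, how molecules
switch between them, and how long they stay bound. It is
written for microscopists and quantitative biologists analyzing HILO/TIRF
SMT of transcription factors, cofactors, and histones.

## What it computes

- **Detection & tracking** — top-hat/Wiener/Gaussian filtering, an
  SNR-driven intensity threshold (lowest threshold with < 5% of detections
  at SNR ≤ 1.5), isotropic 2D Gaussian sub-pixel localization, greedy
  nearest-neighbor linking (max jump 4 px = 416 nm, gap ≤ 1 frame, minimum
  6 frames), plus second-neighbor and fast-frame misconnection diagnostics.
- **Diffusive-state classification** — tracks are split into 7-frame
  sub-tracks whose per-axis displacement covariance is banded:

      Σ_k = 2 D_k Δt + 2 σ_k² − 4 R D_k Δt,   cov(lag 1) = −(σ_k² − 2 R D_k Δt)

  with R = (1/6)(Δt_exp/Δt) the motion-blur coefficient. A K-state Gaussian
  mixture over sub-tracks is fitted by EM with random reinitializations and
  perturbation restarts, K selected by BIC (1..15). Sub-tracks are assigned
  by maximum posterior; ambiguous ones (ΔPP ≤ 0.2) are excluded from
  population fractions, and states under 5% are folded into "other". The
  localization precision per state is recovered as
  σ_k = √[(Σ_k − 2 D_k Δt (1 − 2R))/2].
- **Mobility summaries** — ensemble MSD per state, exploration diameter
  d = 2√MSD(1.2 s), histone-derived jump thresholds (R_min/R_max, 99th
  percentiles of 1-frame and 6-frame jumps) and the unbound fraction.
- **Transition statistics** — 3×3 transition matrix over {state 1, state 2,
  other} with significance from 1000 global label shuffles that preserve
  population fractions.
- **Richardson–Lucy deconvolution** — the van Hove correlation of
  displacements is unmixed into a distribution of MSDs, P(M, τ); its minima
  classify whole tracks into RL mobility groups at τ = 0.8 s.
- **Survival analysis** — dwell-time survival curves, photobleaching rate
  from the slowest component of a triple-exponential fit, corrected
  survival Ŝ(t) = S(t)/e^(−k_PB t), power-law exponent fits, bootstrap
  confidence bands.
- **Synthetic data** — a generator reproducing the acquisition's
  statistical structure (switching diffusion, motion blur, per-state noise,
  bleaching, blinking, absorbing z-defocalization) and a TIFF movie
  renderer, so the whole chain is testable without any experimental data.

## Worked example

Simulate a 50/50 mixture of two bound states at the canonical acquisition
parameters and recover them blind:

```python
import numpy as np
from smtstates import (
    AcquisitionParams, EMOptions, SimStateSpec, SimulationConfig,
    assign_states, filter_minor_states, select_model, simulate_tracks,
    split_subtracks,
)

acq = AcquisitionParams(n_frames=400, field_size=(250, 250))
config = SimulationConfig(
    states=[SimStateSpec(0.002, 0.02, 0.5),   # D um^2/s, sigma um, fraction
            SimStateSpec(0.02, 0.04, 0.5)],
    bleach_time=13.03,
    n_molecules=420,
    seed=1,
)
truth, tracks = simulate_tracks(config, acq)
subtracks = split_subtracks(tracks)
model = select_model(
    subtracks, acq, k_max=4,
    em_opts=EMOptions(n_reinit=3, n_perturb=6, tol=1e-5, max_iter=2000, seed=0),
)
assignment = assign_states(model)
model, assignment = filter_minor_states(model, assignment)

print(f"{len(tracks)} tracks, {len(subtracks)} sub-tracks, BIC selects K={model.k}")
for i, s in enumerate(model.states, start=1):
    print(f"state {i}: D = {s.d:.4f} um^2/s, sigma = {1e3*s.sigma:.1f} nm, "
          f"fraction = {s.fraction:.2f}")
print(f"retained (unambiguous) sub-tracks: {assignment.retained.mean():.0%}")
```

Output:

```
495 tracks, 1091 sub-tracks, BIC selects K=2
state 1: D = 0.0021 um^2/s, sigma = 19.6 nm, fraction = 0.82
state 2: D = 0.0199 um^2/s, sigma = 40.9 nm, fraction = 0.18
retained (unambiguous) sub-tracks: 100%
```

BIC finds exactly two states; the diffusion coefficients land within a few
percent of the generating values (0.002 and 0.02 µm²/s) and the recovered
localization precisions match the simulated 20/40 nm noise. The sub-track
fractions are not 50/50 even though the molecule split is: the faster state
defocalizes sooner, so it contributes fewer sub-tracks — the same
acquisition bias a real experiment carries.

The same stages are available from the shell:

```bash
smtstates defocal --d 1.8 --dt 0.2 --dz 0.4
smtstates simulate --config cfg.yaml --out tracks.csv
smtstates classify --tracks tracks.csv --k-max 5 --out model.json
smtstates run --config cfg.yaml          # full pipeline with artifacts
```

## Layout

```
src/smtstates/
  acquisition.py     # camera timing/geometry, motion-blur coefficient
  simulate.py        # ground-truth generator and movie renderer
  detect.py          # filtering, thresholding, localization, linking
  states.py          # sub-tracks, banded likelihood, pEM-style EM + BIC
  mobility.py        # ensemble MSD, exploration diameter, unbound fraction
  transitions.py     # transition matrices and permutation significance
  rl.py              # van Hove, Richardson-Lucy, RL track groups
  survival.py        # dwell times, bleach correction, power laws
  defocalization.py  # absorbing-slab in-focus survival
  io.py, pipeline.py, cli.py
docs/methods.md      # model details, defaults, limitations
```
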