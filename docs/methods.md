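# Methods

`smtstates` analyzes slow-interval single-molecule tracking (SMT) of
chromatin-associated proteins: movies taken every Δt = 200 ms with a short
Δt_exp = 10 ms exposure, 104 nm pixels, and a ~400 nm depth of focus. At
this frame rate a freely diffusing protein (D ≈ 1.8 µm²/s) leaves the
detection slab between frames with overwhelming probability, so the tracked
population is chromatin-bound, and the scientific question shifts from
bound-vs-free to *which low-mobility state* a bound molecule occupies and
how it switches between states.

## Displacement model

A molecule in state k diffuses with coefficient D_k and is localized with
static per-axis noise σ_k. Because the camera averages the position over the
exposure, displacement statistics carry a motion-blur correction
R = (1/6)·(Δt_exp/Δt). For a constant-state track the per-axis displacement
covariance is banded:

    Σ_k      = 2 D_k Δt + 2 σ_k² − 4 R D_k Δt      (variance, lag 0)
    cov(lag1) = −(σ_k² − 2 R D_k Δt)                (noise-induced)
    cov(lag2) = 0

The band model is invertible: D = (Σ + 2·cov1)/(2Δt), σ² = 2RDΔt − cov1,
and the localization precision of a fitted state is read back as
σ_k = sqrt[(Σ_k − 2 D_k Δt (1 − 2R))/2]. These three bands ("three
covariance features") are the entire sufficient statistic the state
classifier uses.

## State classification

Tracks are cut into non-overlapping 7-frame sub-tracks (6 displacements per
axis) — long enough to classify, short enough that within-window state
switches are rare. Each sub-track is modelled as zero-mean Gaussian in its
6 displacements per axis (axes independent, isotropy assumed), with the
tridiagonal Toeplitz covariance above; a sub-track containing one bridged
blink keeps its 7 localizations, and the two-frame displacement's diagonal
entry is replaced by the lag-2 variance 2D(2Δt) + 2σ² − 4RDΔt.

A K-state mixture is fitted by EM. The E-step uses exact banded Gaussian
likelihoods (verified against a dense multivariate-normal evaluation to
1e-10); the M-step updates each state's bands as posterior-weighted
empirical moments (lag-1 squares for the variance band, adjacent products
for the lag-1 band, averaged over axes) and maps them back to (D, σ) with
clamping at the admissibility boundary. Convergence is |ΔlogL| < 1e-7 with
a 10,000-iteration cap. Each K is fitted from 20 random initializations
(D seeds log-spaced over the empirical variance-band range, σ = 20 nm,
equal weights) and the best solution is refined by 200 restarts from
parameters perturbed by exp(U(−0.3, 0.3)). K = 1..15 is scanned and the
model minimizing BIC = −2 logL + [(K−1) + 2K]·ln(n_subtracks) is kept.
Because the M-step is moment-based rather than exact-ML under the Toeplitz
constraint, the log-likelihood ascent is monotone only to numerical
tolerance; the suite asserts increments ≥ −1e-6·|logL|.

Sub-tracks are assigned to the maximum-posterior state. ΔPP — the gap
between the two largest posteriors — flags ambiguity: sub-tracks with
ΔPP ≤ 0.2 are kept in the model but excluded from population fractions and
ensemble MSDs. States holding < 5% of sub-tracks are folded into "other"
and fractions renormalized over retained sub-tracks.

## Mobility summaries

Ensemble MSD per state is the time-average within each retained sub-track
followed by the ensemble average across sub-tracks (SEM over sub-track
means); displacement pairs are matched by true frame difference so blink
bridges never contaminate lag 1. The exploration diameter at 1.2 s is
d = 2·sqrt(MSD(1.2 s)). Bound/unbound thresholds come from a histone
reference: R_min is the 99th percentile of consecutive-frame jumps, R_max
the 99th percentile of end-to-end displacements across six-frame windows
(the minimum track length); a track with any jump beyond either threshold
counts once as unbound, and the unbound fraction is unbound tracks over all
tracks. The six-frame displacement is read as end-to-end (first to last
localization of the window), the maximum-over-window variant being the
obvious alternative; end-to-end matches the "between six frames" phrasing.

## Transition statistics

Per-track sub-track labels over {state 1, state 2, other} (all
argmax-assigned sub-tracks, including ΔPP-ambiguous ones — ambiguity
filtering applies to population reporting, not to sequence contiguity) form
sequences; tracks with < 3 sub-tracks are dropped. Adjacent-pair counts give
T(i,j) and the row-normalized transition matrix P_t. The null preserves
population fractions but destroys temporal order: pooled labels are globally
permuted and redistributed into the original sequence lengths, 1000 times;
significance s(i,j) is the proportion of permuted ensembles with strictly
larger P̂_t(i,j). Persistent dynamics therefore show diagonal s = 0. The
column means of the null matrices equal the pooled label fractions — an
internal calibration check the suite asserts.

## Richardson–Lucy MSD distribution

The self van Hove correlation G_s(r, τ) — the radial density of 2D
displacement magnitudes at lag τ, normalized so ∫ d²r G_s = 1 — is modelled
as a superposition of Gaussian kernels q(r, M) = exp(−r²/M)/(πM), with M
the MSD of a sub-population. The mixing distribution P(M) is recovered by
the multiplicative Richardson–Lucy update

    P[n+1](M) = P[n](M) · ∫ d²r q(r, M) · G_s(r) / G_s[n](r)

from P⁰(M) ∝ exp(−M/M₀), each iterate clipped non-negative and
renormalized. Defaults: 200 log-spaced M points on [1e-4, 1] µm² (noise
floor to free diffusion at these lags), 100 equal-width radial bins to the
99.9th displacement percentile, M₀ = the empirical mean squared
displacement, 500 iterations with an L1 stop at 1e-8. The data/model KL
divergence is recorded per iterate and must be non-increasing. Minima of
the 3-point-smoothed P(M) become MSD thresholds, with a prominence guard:
a valley counts only if both flanking peaks reach ≥ 5% of the global
maximum and ≥ 1.5× the valley floor (unguarded minima at the sparse low-M
tail produce spurious thresholds). Whole tracks are classified by their
time-averaged MSD at τ = 0.8 s into RL group 1 (below the first threshold),
group 2, or higher.

## Survival analysis

A track's dwell time is its first-to-last-frame span (blinks count as bound
time). The raw survival S(t) confounds unbinding with photobleaching; the
bleaching rate k_PB is the reciprocal of the slowest time constant of a
triple-exponential fit to a long-lived reference's survival, and the
corrected curve is Ŝ(t) = S(t)/exp(−k_PB·t), renormalized at the first
point and truncated where the amplified binomial noise exceeds the value.
Division (not multiplication) is the correction that turns permanently
bound molecules observed through bleaching into a flat Ŝ — the behavior the
suite constructs and asserts. The triple-exponential fit is weighted
1/sqrt(n at risk) with multi-start over log-spaced τ seeds; components
below 5% of total amplitude are treated as fit artifacts when reading
k_PB, and adjacent time constants within a factor of 2 — unresolvable
scales in survival data — trigger a refit with one fewer component.
Power-law dwell regimes are quantified by a least-squares line on
log Ŝ vs log t over a stated range; 99% confidence bands are percentile
bootstrap over tracks.

## Defocalization model

The probability that a molecule of diffusivity D starting uniformly in a
slab of thickness Δz survives (never crosses ±Δz/2) for Δt is evaluated by
64-node Gauss–Legendre quadrature over the start position of the
absorbing-slab solution: the alternating image-charge (erfc) series for
D·Δt/Δz² ≤ 0.2 and the Fourier eigenfunction series above (each converges
fast in its regime; they agree at the crossover). Values below 1e-15 are
reported as that floor (an upper bound), quadrature noise dominating below
it. At D = 1.8 µm²/s, Δt = 0.2 s, Δz = 0.4 µm the survival is ≈ 1.8e-10.

## Synthetic data

The generator emulates the acquisition's statistical structure: Markov
state switching at frame boundaries (the analysis cannot resolve sub-frame
switches), motion blur by averaging 10 sub-steps across the exposure
(converging to the R-coefficient model), per-state static noise, exponential
photobleaching (default time constant 13.03 s), one-frame blinks, and 1D
Brownian z-motion through the detection slab with absorbing behavior
enforced by Brownian-bridge crossing sampling between frames — a molecule
that leaves the slab ends its track and re-entry starts a new one. The
histone-like fixture uses two bound states (D = 0.002/0.02 µm²/s,
σ = 20/40 nm, the regime of the two low-mobility chromatin states), a
per-frame stay probability of 0.95 (mean state dwell ~4 s, matching the
multi-second dwells seen in long tracks), a 5% free population at
1.8 µm²/s, and 2% blink probability (the fluorophore's true blink rate
under these conditions is not established; this is a fixture parameter,
not a claim). Dwell-time fixtures draw from triple-exponential or
power-law survival laws and floor-discretize to whole frame intervals,
dropping sub-interval dwells — the discretization under which the
empirical survival at grid times is unbiased.

What the generator does not emulate: EM-CCD gain-register noise,
astigmatic/3D PSFs, chromatic effects, anomalous (viscoelastic) diffusion
within a state, spatial heterogeneity of states across the nucleus, and
density-dependent misconnections beyond what the linker fixtures construct.
Passing tests therefore demonstrate correctness of the estimators under
the stated model, not robustness to every property of real nuclei.

## Problem sizes and schedules

Production EM defaults follow the schedule above (20 reinitializations,
200 perturbations, tol 1e-7, K up to 15). The test-suite and acceptance
fixtures use reduced schedules (3–4 reinitializations, 6–10 perturbations,
tol 1e-5, K up to 3–4) on simulations of ~1,500–5,000 sub-tracks, sizes at
which the recovery tolerances asserted (D within 10–15%, σ within 20%,
fractions within 0.05) hold with margin. Monte-Carlo oracles use 1e5–1e6
walkers; permutation calibration uses 200 replicate experiments of 300
sequences × 1000 shuffles.

## Known limitations

- The x/y likelihood treats axes as independent; a correlated-axis model
  is not implemented.
- The moment-based M-step is not exact ML under the banded constraint
  (standard for this family of classifiers); likelihood ascent is
  asserted only to numerical tolerance.
- Transition probabilities are sub-track-scale quantities; no
  continuous-time rate estimation is attempted.
- The unbound-fraction rule tests every jump in a track against a 99%
  threshold, so its false-positive floor grows with track length; it is a
  comparative statistic, not an absolute bound fraction.
- Survival of the full synthetic acquisition confounds bleaching with slow
  defocalization of the bound states; bleaching-constant recovery is
  validated on dedicated dwell-time fixtures.
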