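# Methods

## Model

Two cortical populations are reduced to phase oscillators; their phase
difference θ (rad) obeys

    θ̇ = 2π (Δω + ε G(θ) + η),     η ~ N(0, 2σ²)   [Hz; 1 Hz = 2π rad/s]

- **Δω** — detuning: the intrinsic frequency difference the oscillators
  would have without interaction.  Distinct from the *measured* mean
  frequency difference, which synchronization attenuates.
- **ε ≥ 0** — interaction strength (Hz): amplitude of the mutual
  phase-adjusting force.
- **G(θ)** — interaction function: periodic, zero-mean, unit-amplitude.
  Default is the Kuramoto sinusoid G(θ) = −sin θ (attractive convention:
  at Δω = 0 the stable phase difference is θ* = 0, and for Δω > 0 the
  locked phase arcsin(Δω/ε) is positive — the faster oscillator leads).
- **σ** — phase-noise SD (Hz) *per oscillator*; the difference equation
  carries the combined variance 2σ².

### Noise convention (simulator ↔ analytics)

The model is integrated by explicit Euler–Maruyama at fs = 1000 Hz with
i.i.d. per-sample noise (no sub-stepping; the deterministic rates are a few
Hz, three orders below the step rate).  The matching diffusion constant for
the continuous-time description is

    D = (2π σ)² / fs    [rad²/s]

held in a single named `NoiseConvention` object used by both the simulator
and the analytic solver, so the two are consistent by construction.  The
step size is a package choice: the analysis it emulates used 1.8 s trials
sampled at 1 kHz, and convergence is verified empirically (total-variation
distance between simulated occupancy and the analytic density < 0.02, and
in practice < 0.005, across locked, intermittent and uncoupled regimes).

### Stationary solution

For σ > 0 the stationary Fokker–Planck density on the circle with constant
probability current is

    p(θ) ∝ e^(−Φ(θ)) ∫_θ^{θ+2π} e^(Φ(ψ)) dψ,   Φ(θ) = −(1/D) ∫_0^θ 2π(Δω + εG)

evaluated on a uniform 1024-point grid.  The wrap-around integral is
computed by integrating the piecewise-exponential interpolant of Φ exactly
on each segment and summing segments in log space.  This matters: the
tilted potential spans hundreds of decades at small σ and develops
boundary layers narrower than the grid, where naive trapezoid sums
underflow to zero.  The implementation agrees with adaptive quadrature to
~1e−4 at moderate σ and converges to the noise-free occupancy density as
σ → 0 (verified down to σ = 0.35 Hz).  Grid refinement 1024 → 4096 moves
the predicted PLV by < 1e−5 (second-order quadrature).

Noise-free regimes are handled separately: point mass at the stable drift
root for |Δω| ≤ ε (PLV = 1), uniform for ε = 0, occupancy ∝ 1/|drift| in
the intermittent regime.  Predicted statistics are the circular moments of
the density: PLV = |∫ e^{iθ} p dθ|, preferred phase its argument.

## Estimation from data

### ΔIF(θ) curves and the conditioning convention

The time-averaged modulation of the instantaneous frequency difference as
a function of the wrapped phase difference estimates the deterministic
term Δω + εG(θ), because the phase noise is zero-mean within bins.  Phase
bins are 25 equal bins of 2π/25 ≈ 0.2513 rad ("0.25 rad nominal" — 0.25
does not divide 2π; the closest uniform partition is used).

A subtlety decides the binning convention: for a Markov phase trajectory,
the conditional mean of the *trailing* (or centred) increment given the
current phase is not the drift but J/p(θ) — probability current over
density — because the occupancy gradient leaks into the conditional noise
mean (E[θ̇ | θ] = v(θ) − D d(ln p)/dθ).  At σ = 18 Hz this bias reaches
~1 Hz, comparable to ε itself.  `delta_if_curve` therefore bins *forward*
increments at the pre-increment phase (Itô conditioning), which is exactly
unbiased on simulated trajectories; the final sample of each trial keeps
its trailing increment so the pooled count equals trials × samples.  For
Hilbert phases of band-limited signals the phase estimate is itself
time-smoothed and part of the bias returns (see Limitations).

### Estimators

- **Δω̂** — unweighted mean of the per-bin means over the full phase range.
  Equal weight per bin (not per sample) undoes the occupancy bias that
  synchronization creates: sample-weighted averaging would drag the
  measured detuning toward the low-ΔIF preferred phase.
- **ε̂** — modulation amplitude of the binned curve.  Two estimators are
  exposed: `(max − min)/2` (the default, simple but upward-biased by bin
  noise — at 30 trials the bias is ~+0.2 Hz, vanishing at high trial
  counts) and an unweighted least-squares sinusoid fit (`"sine"`,
  unbiased for sinusoidal G; used by the pipeline and wherever accuracy
  at low ε matters).
- **Ĝ** — curves with |Δω̂| above 4 Hz (configurable) are centred
  (detuning subtracted), reflected through the origin when Δω̂ < 0
  (equivalent to swapping the pair order so detuning is positive),
  amplitude-normalized, averaged, and re-normalized to zero mean and unit
  amplitude.  The detuning gate exists because near Δω = 0 the occupancy
  concentrates at the locked phase and the recovered shape deforms; only
  exclusion is implemented.
- **σ̂** — from the growth rate of the lagged phase-increment variance
  (diffusion fit): integrate the IF back to phase, compute
  Var[φ(t+τ) − φ(t)] over a range of lags, fit the slope, convert to Hz.
  The slope is invariant to smoothing/filtering of the trace (which only
  adds a bounded offset), making the estimate usable on band-limited
  signals where the naive sample-SD of the IF is several-fold too small.
  The per-trial de-meaning deflation (factor 1 − τ/T) is corrected
  exactly.  Lags: 5–40 ms on raw oscillator traces; 80–300 ms on filtered
  sessions (beyond the FIR filter memory).  Contacts are pooled as
  σ̂ = √(mean of per-contact variances), matching the combined-noise
  convention η ~ N(0, 2σ²).  A plain sample-SD method is also exposed.
- **PLV / preferred phase** — modulus and argument of the mean unit
  phasor of pooled wrapped phase differences.

### Shuffle control

Permuting trial pairings (derangements, so no trial meets itself)
destroys true coupling; the residual ε̂ then measures the estimator's
noise floor.  With the sinusoid-fit amplitude the floor is analytically
E|ε̂| = √(π/2) · 2σ/√N over N pooled samples: ≈ 0.20 Hz at 30 trials of
1.8 s, 0.10 at 100, 0.05 at 500, 0.03 at 1000 — the monotone 1/√N decay
the acceptance suite reproduces.  The `(max−min)/2` estimator has a floor
about five times higher (expected range of 25 noisy bin means), which is
why the shuffle control uses the sinusoid fit.

### Circularity guard

The ε̂ used for prediction is never the pair's own raw value: pairs are
binned by cortical distance (±0.25 mm) and every pair in a bin receives
the bin-average ε̂ (singleton bins keep their own value, flagged).  This
breaks the circularity whereby signal quality inflates both ε̂ and
observed PLV.

## Signal chain

- **CSD** — second spatial difference of the laminar LFP,
  (lfp[i−1] − 2·lfp[i] + lfp[i+1])/spacing²; annihilates depth-linear
  volume-conducted far fields exactly.  Per-channel polarity is aligned by
  sign of the zero-lag correlation with the highest-power reference
  channel (flips logged), since the spatial derivative inverts the
  oscillation sign across sinks/sources.
- **Band extraction** — zero-phase FIR band-pass (Hamming window, ~3
  cycles of the low edge, forward–backward), default 25–45 Hz or centred
  on the spectral gamma peak.  The extractor sits behind a narrow
  interface so wavelet- or subspace-based oscillation extractors can be
  swapped in.
- **Analytic signal** — Hilbert transform; phase wrapped to (−π, π],
  amplitude as modulus, IF as the centred difference of unwrapped phase
  scaled to Hz.  The first 200 ms of each trial (stimulus transient /
  filter edge) and a 50 ms tail are trimmed before analysis.
- **Spike density** — spike trains binned at fs, Gaussian-smoothed
  (σ = 4 ms), de-meaned per trial; then processed identically to CSD
  (spike–CSD and spike–spike pair variants).

## Synthetic sessions

The generator emulates a dual-probe laminar experiment in visual cortex.
Defaults are the study conditions: 2 probes × 16 contacts (150 µm
spacing), 9 contrast-difference conditions × 30 trials × 1.8 s at 1 kHz;
contrast → gamma frequency affine with the ~21–66% range spanning 5 Hz
centred at 34 Hz; coupling decaying exponentially with distance through
(2.5 mm, 1.8 Hz) and (5 mm, 1.0 Hz); per-oscillator phase noise σ = 18 Hz.
The LFP model is: laminar gain (narrow peak in layers 2–4 plus a deep
secondary peak — narrow on purpose, since only laminar profiles with
appreciable curvature survive a second spatial derivative) × cos(phase) ×
slow log-normal envelope (~100 ms, so the analytic-signal stage sees
realistic amplitude bursts without violating the weak-coupling phase
description) + probe-local 1/f noise mixed across contacts (volume
conduction stand-in) + a depth-linear far field shared by all probes
(removed exactly by the CSD, giving the raw-LFP-vs-CSD correlation
contrast) + white measurement noise.  Spiking is an inhomogeneous
Bernoulli process with rate base·(1 + depth·cos phase).

What the generator does *not* emulate: biophysical (conductance-based)
LFP genesis, stimulus-onset transients, eye movements, non-stationary
firing rates, electrode drift, or common-input fluctuations.  Passing
recovery tests on this generator therefore demonstrates correctness of
the estimation chain under the model's own assumptions, not robustness to
every pathology of recorded data.

## Evaluation

R² = 1 − SS_res/SS_tot for PLV; for the preferred phase, residuals are
wrapped to (−π, π] and referenced to the circular mean (a documented
convention — plain R² is not defined for angles).  Three granularities
mirror standard reporting: all records pooled, per pair across conditions
(mean ± SE), and population bins of ±0.35 Hz detuning × ±0.3 mm distance.
Empirical Arnold tongues are cell means of observed PLV/phase over
(Δω̂, ε_assigned), with the noise-free border ε = |Δω| overlaid.

## Numerical choices and problem sizes

- Default θ grids: 1024 points (analytic), 512 inside the prediction loop.
- Acceptance-scale simulations: occupancy oracles use ~10⁷ pooled samples
  per parameter set (700 trials × 15 s); recovery grids use 13 detunings ×
  4 couplings × 200 trials; shuffle controls 6–8 pairs × 3–6 permutations.
  These sizes put Monte-Carlo noise well inside the asserted tolerances
  while keeping the whole suite at a few minutes on one core.
- Degenerate inputs: ε = Δω = 0 noise-free is flagged "degenerate"
  (any phase persists); empty spike trains produce zero signals, flagged;
  bins with fewer than 2 samples are flagged, never interpolated;
  estimates with >25% flagged bins carry a low-confidence diagnostic.

## Known limitations

- **Band-limited phase smoothing.**  Hilbert phases of filtered signals
  are effectively time-smoothed, which re-introduces part of the
  occupancy-gradient bias the forward-increment convention removes: on
  full synthetic sessions ε̂ is attenuated to ~0.75× truth and the
  observed PLV is inflated relative to the underlying oscillator process,
  so predicted and observed PLV co-vary strongly (rank correlation ≈ 0.9)
  but with a systematic offset.  Detuning, σ and the G shape are
  recovered accurately.  A principled SNR/smoothing correction is the
  main avenue for improvement.
- Only the bidirectional interaction function is estimated; unidirectional
  phase-response curves are out of reach of this symmetric-pair design.
- The stationary solver provides no transient (time-dependent) solutions
  and no amplitude dynamics; weak-to-moderate amplitude-phase coupling in
  data is quantified descriptively (`amplitude_by_phase`) but not
  modelled.
- The Δω̂ equal-bin-weight estimator assumes all bins are visited; in
  near-noise-free strongly locked regimes most bins are empty and the
  curve-based estimators are not meaningful (the analytic regime labels
  cover those cases instead).
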