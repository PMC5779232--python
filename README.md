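# gammasync

Weakly-coupled-oscillator analysis of cortical gamma synchronization:
simulation, estimation and Arnold-tongue prediction.

## The problem

Nearby cortical populations often oscillate in the gamma band at *different*
frequencies — local stimulus contrast shifts the gamma frequency by several
Hz across a few millimetres of visual cortex.  Synchronization between such
populations is not a fixed-frequency phenomenon: it is maintained through
continual modulations of the instantaneous frequency difference.  The theory
of weakly coupled oscillators reduces each population to a phase variable and
describes the phase difference θ between two populations by a single
stochastic differential equation

    θ̇ = Δω + ε·G(θ) + η,        η ~ N(0, 2σ²)

with Δω the detuning (intrinsic frequency difference, Hz), ε the interaction
strength (Hz), G(θ) the periodic interaction function (canonically the
Kuramoto sinusoid −sin θ), and η white phase noise (all in Hz, with
1 Hz = 2π rad/s).  In the (Δω, ε) plane, strong phase locking occupies an
inverted triangle — the **Arnold tongue** — bordered by ε = |Δω| in the
noise-free limit.

`gammasync` is for electrophysiologists and modellers who want to run this
analysis end to end:

- **simulate** noisy coupled phase oscillators (Euler–Maruyama, seeded) and
  synthetic laminar multi-electrode sessions with known ground truth
  (contrast-dependent gamma frequency, distance-dependent coupling, laminar
  gain profiles, volume conduction, phase-modulated spiking);
- **process** laminar LFP into instantaneous gamma phase/frequency/amplitude
  (current-source density → zero-phase band-pass → Hilbert transform, with a
  spike-density variant for multi-unit activity);
- **estimate** Δω, ε, G and σ from the binned modulation of the
  instantaneous frequency difference ΔIF(θ), whose time average equals the
  deterministic term Δω + ε·G(θ);
- **predict** phase-locking value (PLV) and preferred phase analytically
  from the stationary Fokker–Planck solution of the equation above, and
  compare predictions with observations (R² at three granularities);
- **reconstruct** the Arnold tongue empirically from many pairs and
  conditions.

## Worked example

```python
import gammasync as gs

# simulate two mutually coupled noisy gamma oscillators (Hz units)
pair = gs.simulate_oscillator_pair(
    omega1=35.4, omega2=32.6,       # detuning 2.8 Hz
    epsilon=1.8, sigma_each=18.0,   # coupling and phase noise
    n_trials=100, seed=0)

# binned instantaneous-frequency-difference curve and estimates
curve = gs.delta_if_curve(pair.phi1, pair.phi2, fs=1000.0)
est = gs.estimate_pair_params(curve, epsilon_estimator="sine")
print(f"detuning  = {est.delta_omega_hat:5.2f} Hz  (true 2.80)")
print(f"coupling  = {est.epsilon_hat:5.2f} Hz  (true 1.80)")

# observed phase locking vs the analytic prediction
theta = gs.PhaseDiffTrajectorySet(pair.phi1 - pair.phi2, 1000.0).wrapped()
obs = gs.phase_diff_stats(theta.ravel())
dist = gs.stationary_distribution(est.delta_omega_hat, est.epsilon_hat, sigma=18.0)
pred = gs.predict_stats(dist)
print(f"PLV       = {obs.plv:.3f} observed vs {pred['plv']:.3f} predicted")
print(f"phase     = {obs.mean_phase:.2f} rad observed vs {pred['mean_phase']:.2f} predicted")
```

prints

```
detuning  =  2.86 Hz  (true 2.80)
coupling  =  1.74 Hz  (true 1.80)
PLV       = 0.243 observed vs 0.248 predicted
phase     = 0.84 rad observed vs 0.91 predicted
```

The ΔIF(θ) curve dips to Δω − ε ≈ 1 Hz at the preferred phase: phase
precession nearly stalls there, which is exactly why that phase relation is
over-represented and a PLV of ~0.25 emerges despite a 2.8 Hz frequency
difference.  The positive mean phase says the faster oscillator leads.

Full sessions run the same way through `gs.generate_session` →
`gs.run_session_analysis` (records table with observed and predicted PLV and
phase per contact pair and condition), or from the shell:

```bash
gammasync simulate --seed 1 --out session.h5
gammasync estimate --session session.h5 --out records.csv
gammasync tongue   --records records.csv --out-prefix tongue
gammasync report   --records records.csv --out report.json
```

## Layout

```
src/gammasync/
  interaction.py   periodic interaction functions G(θ)
  oscillator.py    Euler–Maruyama simulation of Eq. above; noise convention
  analytic.py      stationary Fokker–Planck solutions, Arnold-tongue surfaces
  synthetic.py     synthetic laminar sessions with embedded ground truth
  signals.py       CSD, band extraction, Hilbert analytic signal, spike density
  estimation.py    ΔIF(θ) curves, parameter/function/noise estimators, PLV
  pipeline.py      session/cohort orchestration, ε assignment, evaluation
  io.py            HDF5 container
  cli.py           click command-line interface
docs/methods.md    model, estimators, numerical choices, limitations
```
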