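# momnet

Whole-brain network model of delay-coupled, noise-driven Stuart–Landau
oscillators, with the full analysis suite for studying how transient brain
rhythms (delta–beta) can emerge from metastable synchronization of locally
generated gamma oscillations.

## The scientific problem

MEG/EEG recordings of resting humans are dominated by oscillations well below
the gamma band (0.5–30 Hz), even though local neuronal circuits generate
rhythms above ~35 Hz. One mechanistic hypothesis holds that slower rhythms
are collective: when brain areas synchronize across conduction delays, the
locked state rotates at a reduced *collective* frequency. `momnet` implements
a minimal model of this scenario and every measurement needed to test it:

- **Node dynamics.** Each of N areas carries a complex state Z_n obeying the
  Stuart–Landau (Hopf normal form) equation in the subcritical regime,

      dZ_n/dt = Z_n (a + iω₀ − |Z_n|²)
                + K Σ_{p≠n} C_np [Z_p(t − τ_np) − Z_n(t)]
                + β(η₁ + iη₂),

  with a = −5 (damped response, ~1 s decay), ω₀ = 2π·40 Hz (gamma
  resonance), additive complex white noise of scale β = 0.001, diffusive
  coupling through a structural connectome C (normalized to ⟨C⟩ = 1), and
  per-edge delays τ_np = D_np/v from tract lengths D (mm) and a global
  conduction speed v.
- **Collective-frequency theory.** The synchronized one-cluster state obeys
  Ω = ω₀ − K·N·sin(Ωτ); the lowest branch is Ω_min = ω₀/(1 + K·N·τ). Both
  the closed form and a complete root enumeration (multistability) are
  provided.
- **Observables.** Kuramoto order parameter R(t) (synchrony ⟨R⟩ and
  metastability STD(R)), Welch power spectra and peak frequency, band-pass
  filtering and Hilbert amplitude envelopes.
- **Metastable oscillatory modes (MOMs).** Episodes where a node's
  band-limited envelope exceeds 5 standard deviations of its zero-delay
  baseline; summarized by duration, size and occupancy per frequency band.
- **Envelope functional connectivity.** Pairwise Pearson correlation of
  band-limited amplitude envelopes.
- **Spectral fitting.** Sweeps of the (K, ⟨τ⟩) plane — by default
  K = 10⁻¹…10^1.7 in steps of 10^0.1 and ⟨τ⟩ = 0…30 ms in 1 ms steps — with
  squared-Euclidean fitting of simulated spectra to per-subject empirical
  power spectra.

## Worked example

```python
import numpy as np
import momnet as mn

# modular synthetic connectome (30 areas), coupling normalized to <C> = 1
c = mn.normalize_to_unit_mean(mn.generate_synthetic_connectome(30, 3, 0.6, seed=42))

# optimal-range run: K = 30, mean delay 3 ms (K*N*tau = 2.7)
params = mn.SimulationParams(K=30.0, mean_delay_s=3e-3, duration=21.0, seed=21)
act = mn.integrate(c, params)

kop = mn.kuramoto_order_parameter(act.z, act.dt)
mean_r, std_r = mn.synchrony_metastability(kop, params.transient)
ps = mn.power_spectrum(np.real(act.post_transient()), act.dt)
peak = mn.peak_frequency(ps, f_min=0.25)
pred = mn.collective_frequency_closed_form(40.0, params.K, c.n, params.mean_delay_s)
r = mn.envelope_kop_correlation(act.z, act.dt)
print(f"synchrony={mean_r:.2f} metastability={std_r:.2f}")
print(f"peak={peak:.1f} Hz (analytic prediction {pred:.2f} Hz)")
print(f"envelope-KOP correlation r={r:.2f}")
```

prints

```
synchrony=0.75 metastability=0.20
peak=13.0 Hz (analytic prediction 10.81 Hz)
envelope-KOP correlation r=0.35
```

The network of 40 Hz units synchronizes partially (⟨R⟩ = 0.75) with strong
synchrony fluctuations, its collective spectral peak drops into the alpha
range near the analytic prediction ω₀/(1 + K·N·τ), and the sub-gamma
amplitude envelope co-fluctuates with the instantaneous phase synchrony —
the signature of metastable oscillatory modes.

## Command line

```bash
momnet simulate --config run.yaml --out out/        # one run + observables
momnet sweep    --config run.yaml --out out/        # (K, delay) plane
momnet moms     --config run.yaml --out out/        # thresholds, events, stats
momnet fc       --config run.yaml --out out/        # band-wise envelope FC
momnet predict  --k 10 --n 90 --tau 3               # analytic frequencies
momnet synth-connectome --n 30 --seed 1 --out sc/   # synthetic connectome
```

A config is a small YAML mapping, e.g.

```yaml
connectome:
  synthetic: {n: 30, n_modules: 3, density: 0.6, seed: 42}
params:
  K: 10.0
  mean_delay_s: 0.003
  duration: 50.0
  seed: 1
```

Every command writes its fully resolved configuration next to its outputs,
so runs are reproducible bit-for-bit from the output directory alone.

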