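# Methods

## Model

Each brain area is a Stuart–Landau oscillator — the normal form of the
Andronov–Hopf bifurcation — in the subcritical regime. The complex state
Z_n(t) evolves as

    dZ_n/dt = Z_n (a + iω₀ − |Z_n|²)
              + K Σ_{p≠n} C_np [Z_p(t − τ_np) − Z_n(t)]
              + β η₁ + i β η₂

For a < 0 the origin is a stable focus: a perturbation produces a damped
oscillation at ω₀ with envelope e^{a·t}. For a > 0 the unit holds a limit
cycle of amplitude √a. Coupling is linear, diffusive and delayed: node n
reads node p's state one conduction time τ_np = D_np/v in the past, with D
the tract-length matrix (mm) and v a homogeneous conduction speed (m/s).
The noise terms η₁, η₂ are independent standard normal deviates drawn per
node per step.

Key parameters, defaults and rationale:

| parameter | default | meaning |
|---|---|---|
| ω₀ | 2π·40 rad/s | gamma resonance of an isolated neural mass |
| a | −5 s⁻¹ | damped regime; 1% impulse decay at ln(100)/5 ≈ 0.92 s |
| β | 0.001 | background noise scale |
| K | free | global coupling, scales all connections |
| ⟨τ⟩ or v | free | mean conduction delay / speed; ⟨τ⟩ = ⟨D⟩/v |
| dt | 10⁻⁴ s | integration step; results stable for dt ≤ 10⁻⁴ s |
| duration | 50 s | simulated span; first 1 s discarded as transient |

With the coupling matrix normalized to unit off-diagonal mean (⟨C⟩ = 1), row
sums are of order N and the product K·N governs the collective dynamics.

### Noise convention

The default increment per step is β·η·dt per component ("paper" scaling); a
`sqrt-dt` option provides the standard Euler–Maruyama β·η·√dt increment for
a Wiener process of intensity β. The dynamics of all dimensionless
observables (R(t), peak frequencies, correlations, FC) are identical under
the two conventions because the coupled system operates in its linear range
at these noise levels — only the absolute amplitude scale changes.

### Integration scheme

The linear part Z(a + iω₀) is advanced by its exact propagator
φ = e^{(a+iω₀)dt}; the cubic term, the delayed coupling and the noise are
added explicitly (exponential Euler). A naive fully explicit Euler step is
unacceptable here: at ω₀·dt = 2π·40·10⁻⁴ ≈ 0.025 the rotation term alone
inflates |Z| by (ω₀dt)²/2 per step — an artificial antidamping of ≈ +3.2 s⁻¹
that would cut the effective damping at a = −5 to −1.8 s⁻¹ and triple the
impulse-response decay time. The exponential propagator removes this error
exactly; halving dt changes synchrony and peak frequency by well under 5%.

Delays are discretized to integer step lags by half-up rounding (per-edge
error ≤ dt/2) and served from a ring buffer of length max-lag+1. Infinite
conduction speed encodes the zero-delay condition. A run whose state becomes
non-finite raises, reporting the step index.

### History (pre-t = 0) states

The ring buffer is pre-filled with independent complex Gaussian states at
the *stationary* single-unit scale σ = β_step/√(2|a|dt), where β_step is the
per-step noise amplitude. Starting at the stationary scale (rather than at
an arbitrary magnitude) avoids a startup discontinuity whose band-filtered
ring-down — and its wrap-around through the FFT-based Hilbert transform —
would otherwise contaminate envelope analyses far beyond the nominal 1 s
transient. A zeros option is provided.

## Collective frequency theory

A fully synchronized one-cluster state rotating at Ω satisfies
Ω = ω₀ − K·N·sin(Ωτ) under the homogeneous-delay approximation τ := ⟨τ⟩ with
unit-mean coupling. Its lowest branch, reached as synchrony is approached,
is Ω_min = ω₀/(1 + K·N·τ). The root enumerator scans (0, ω₀ + K·N] with at
least 40 grid points per delay period and bisects each bracket to ~10⁻¹²
relative tolerance; for large K·N·τ multiple fixed points coexist
(multistability). Each root carries an advisory stability flag
|K·N·τ·cos(Ωτ)| < 1; full stability analysis of the delayed system is out
of scope.

## Observables

- **Band-pass filtering**: zero-phase (forward–backward) 4th-order
  Butterworth sections; zero-phase filtering avoids band-dependent group
  delays that would smear event onsets across bands. Canonical bands:
  delta 0.5–4, theta 4–8, alpha 8–13, beta 13–30 Hz.
- **Edge margins**: after zero-phase filtering and the FFT-based Hilbert
  transform, two cycles of the band's low edge are discarded at each series
  end before any statistic is computed. The edge artifact is *shared* across
  channels and, left in place, fakes envelope correlations between
  independent nodes.
- **Kuramoto order parameter**: phases are the analytic-signal argument of
  the real parts band-filtered around the ensemble spectral peak ± 2 Hz
  (config-exposed). The peak is estimated on post-transient samples.
  Synchrony is ⟨R(t)⟩ and metastability STD(R(t)) over the post-transient
  span. For noise-free phase-locked states the raw complex phases can be
  used directly (band=None).
- **Power spectra**: averaged modified periodograms (Welch), 2 s Hann
  windows, 50% overlap; multichannel input averages per-node spectra across
  units. Optional unit-mass normalization over 0–80 Hz. Peak frequency ties
  break toward the lower frequency.
- **Envelope–KOP correlation**: real parts low-passed below 30 Hz (the
  sub-gamma range), Hilbert envelopes averaged across nodes, Pearson
  correlation with R(t) over post-transient interior samples.

## MOM detection

Thresholds are calibrated from a matched run with delays forced to zero
(infinite speed) at the same coupling: for each node and band, threshold =
5 × SD of the band-limited envelope (the Fig-caption convention; a
mean + 5·SD variant is exposed as the multiplier/config). Calibration uses
an independent seed (recorded in provenance). Detection marks envelope >
threshold per node/band over a common interior window; maximal
supra-threshold runs form the event table. Statistics per band:

- duration — mean/SD of event lengths;
- size — mean/SD of the simultaneously supra-threshold node count, averaged
  over samples with ≥ 1 active node (an all-quiet recording should not drag
  size toward 0; the all-samples variant is a switch);
- occupancy — supra-threshold node-samples / (N × T).

Detecting on the calibration run itself yields sub-1% occupancy, the
Gaussian-tail rate of a 5-SD exceedance (for a Rayleigh-distributed
envelope the threshold sits at ≈ 3.3 envelope-σ, exceedance ≈ 0.5%).

## Envelope functional connectivity

Per band: band-pass → Hilbert envelope → pairwise Pearson correlation over
post-transient interior samples. Envelopes are not orthogonalized — the
simulated sources have no leakage to correct. A node whose envelope is
flatter than the residual filter ripple of a pure tone (< 2% relative
variation; genuine narrowband envelopes have order-one variation) has no
defined correlation and propagates as missing, never as zero.

## Parameter sweeps and spectral fitting

The default grid is the study plane: K = 10⁻¹…10^1.7 in multiplicative
steps of 10^0.1 (28 values) × ⟨τ⟩ = 0…30 ms in 1 ms steps (31 values). Each
cell runs one simulation with a seed derived deterministically from the
base seed and the cell indices, so sweeps are resumable (npz checkpoint)
and order-independent. The conduction speed per cell is v = ⟨D⟩/⟨τ⟩ over
connected pairs, honoring the delay axis for any connectome; ⟨τ⟩ = 0 maps
to infinite speed. Per cell: ⟨R⟩, STD(R), spectral peak, the analytic
Ω_min, and the across-unit mean spectrum resampled to a common 0–80 Hz grid
at 0.5 Hz and renormalized to unit mass. Fitting uses the squared Euclidean
distance on that grid; the best cell per subject breaks ties toward smaller
K, then smaller delay. Incoherent cells are reported as-is (the analytic
surface is not masked; masking is the caller's choice).

## Synthetic connectomes

The generator emulates tract-count networks: symmetric, non-negative,
zero-diagonal weights with lognormal (heavy-tailed) magnitudes, denser and
5× stronger within modules; node positions are drawn in 3-D around spread
module centres and lengths are the Euclidean inter-node distances rescaled
to a configurable mean (default 70 mm over connected pairs — centimetre-
scale brain geometry, so delays of a few ms at ~10–20 m/s). Lengths satisfy
the triangle inequality by construction. What it does **not** emulate:
geometry-weight coupling beyond the modular bias (real connectomes have
exponentially distance-dependent weights), hemispheric symmetry, and
log-normal degree structure of specific parcellations. Tests passing on
these networks therefore validate the machinery and the physics of
delay-reduced collective frequencies, not parcellation-specific spatial
claims.

## Scaled-down study conditions

Network-level tests run at N = 30 nodes with 10–20 s analysis windows; the
sub-gamma regimes are probed at the same dimensionless product K·N·⟨τ⟩ as a
90-area system (e.g. K = 30, ⟨τ⟩ = 3 ms at N = 30 matches K·N·τ = 2.7, an
alpha-range collective frequency). Two genuine costs of the reduction are
worth noting. First, the within-band signal-to-noise of the collective mode
against per-node noise scales with N, so measured synchrony and
envelope–KOP correlations at N = 30 sit below full-size values (r ≈ 0.3–0.45
versus ≈ 0.76–0.82); the orderings and signs are preserved. Second, full
synchrony (⟨R⟩ > 0.9) within the default coupling range is reached only for
sub-millisecond mean delays, so the analytic-agreement and regime-map tests
use delays of 0.25–1 ms — the same K·N·τ territory the full-size system
covers at 1–3 ms.

## Degenerate inputs and numerical tie-breaks

- Asymmetric matrices within 10⁻⁹ are symmetrized by averaging; beyond
  that, loading errors out (the model assumes reciprocal coupling).
- ⟨C⟩ = 1 normalization averages over all N(N−1) off-diagonal entries
  including zeros (making row sums ≈ N, the scaling the K·N theory
  assumes); a connected-pairs-only switch is provided. ⟨D⟩ (hence ⟨τ⟩)
  averages over connected pairs only.
- Delay rounding is half-up; sub-step delays degrade to instantaneous
  coupling.
- dt above 10⁻⁴ s requires an explicit override flag.
- An all-false MOM mask yields zero duration/size/occupancy; an all-zero
  weight matrix, a zero-variance baseline envelope, and an all-zero
  spectrum are errors, not silent zeros.

## Known limitations

- Homogeneous ω₀, a, β across nodes (per-node heterogeneity is untested).
- The analytic theory assumes the homogeneous-delay one-cluster state;
  agreement with heterogeneous-delay simulations degrades as Ωτ grows
  (simulated peaks sit systematically a few percent above Ω_min).
- Stability classification of multistable branches is advisory only.
- No sensor/forward modelling: simulated areas are compared directly to
  sensor-averaged spectra.
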