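# Methods

## Model

Each neuron is a single isopotential Hodgkin–Huxley compartment,

    C_m dV/dt = -g_l (V - E_l) - g_K n^4 (V - E_K) - g_Na m^3 h (V - E_Na)
                + I + I_syn + xi(t),

with the classic squid-axon parameter set, voltage-shifted so the resting
potential is −60 mV: C_m = 1 µF/cm², g_Na = 120, g_K = 36, g_l = 0.3 mS/cm²,
E_Na = +55, E_K = −72, E_l = −49.387 mV, and the standard α/β rate functions
shifted by the same 60 mV.  This set reproduces the three dynamical landmarks
the study relies on: rest at −60 mV, onset of sustained firing (fold of limit
cycles) at ≈ 6.3 µA/cm², and loss of rest-state stability (subcritical
Andronov–Hopf) at ≈ 9.8 µA/cm².  Between those two currents the model is
bistable, which is what makes silencing persistent: once the trajectory falls
into the rest basin, neither the weak signal nor the endogenous noise is
strong enough to lift it back onto the cycle.

Integration is explicit Euler with dt = 10 µs.  The scheme is first-order;
against an adaptive high-accuracy oracle the production step tracks a firing
trajectory to < 1 mV RMS over three firing cycles, with the residual error
dominated by phase accumulation on the spike upstroke (halving dt halves it).
Inside the compiled kernels the rate functions are evaluated from a dense
lookup table (0.02 mV grid, linear interpolation, relative error < 1e−6);
analysis-level code uses the exact closed forms.

**Noise.** xi(t) is drawn once per 10 µs step from N(0, D), with D quoted in
µA²/cm⁴ as a per-step current-density variance tied to the fixed step (no
√dt rescaling).  This convention is load-bearing: with it, noise alone
(I = 6.5 µA/cm², D ≥ 0.25) silences the whole primary layer within minutes
while D ≤ 0.10 silences nothing, the behavior the study design assumes.
Every neuron owns an independent substream spawned from the run seed
(`numpy SeedSequence`), so runs are bit-reproducible and the primary layer
can be integrated neuron-by-neuron with results identical to the full
network integration.

**Signal coupling.** The exogenous term is a voltage generator in series
with the membrane branches: every ionic driving force and every gating-rate
evaluation uses (V + v_signal) instead of V.  The signal is applied to the
25 primary neurons only.

**Synapses.** The secondary neuron receives the averaged AMPA current
I_syn = (ḡ_syn/25) Σ r_i (E_AMPA − V), ḡ_syn = 0.6, E_AMPA = 0 mV, written
in its depolarizing (excitatory) form.  Each gate obeys the minimal
two-state transmitter scheme dr/dt = α[T](1−r) − β r with α = 1.1 /(mM·ms),
β = 0.19 /ms and [T] = 1 mM for 1 ms after each presynaptic spike (standard
Destexhe-type constants).  With tonically firing primaries the secondary
follows 1:1; its long inter-spike gaps ("partial silencing", ISI > 1.5 s)
appear only once roughly half the primaries have stopped.

## The synthetic pulse train

The original device waveform is proprietary (patent-sampled at 1 ms) and not
publicly deposited, so the generator emulates its documented structure
rather than its exact samples: four bursts of 838 ms, each holding 16
couples of biphasic waveforms, followed by refractory periods of 110, 220,
330 and 1200 ms — a 5212 ms basic pattern repeated for up to 15 min.
Within a burst the 15 latencies form an arithmetic progression solved in
closed form to tile the burst exactly; `latency_growth` = 1 makes the last
latency twice the first, so the repetition frequency decreases through the
burst.  Pulse-to-pulse diversity is a seeded multiplicative jitter
(±`jitter_fraction`) on every lobe's amplitude and width.

Each pulse couple (4 ms) is two biphasic Gaussian-difference waveforms
back-to-back.  The lobe geometry — dominant lobe gain −1, rebound +0.2,
width 0.45 × the half-couple, centers at 0.3/0.7 of the half-couple — is the
one genuinely free design choice in the package, and it was fixed by
calibrating the *effect scale* of the surrogate against the documented
dose landmarks, then frozen:

* silencing knee at I = 7, D = 0.2 near max|CNP′| ≈ 0.7–0.8 mV (neurons
  silence within minutes at 0.8 mV, not at 0.6 mV);
* a silenced neuron is re-triggered by pulses only above ≈ 3–4 mV, so
  sub-mV exposures silence irreversibly;
* at 8 mV the firing phase-locks to the pulse grid.

The rationale: the coupling amplitude is defined as max|CNP′| *after*
upsampling (linear interpolation 1 ms → 10 µs), causal 5th-order Butterworth
filtering at 500 Hz, and first-difference differentiation, so the
biological efficacy per unit amplitude depends entirely on the pulse shape.
A hyperpolarization-leading lobe pair gives the derivative one brief
hyperpolarizing swing followed by a sustained depolarizing phase, which
reproduces all three landmarks simultaneously; the more obvious
depolarization-leading shapes proved several-fold too weak (knee near 3 mV)
or could not re-trigger below 12 mV.  Filtering is forward-only because the
physical signal chain is causal; the derivative repeats its last sample to
preserve length.

Signal modifications used in the waveform-dependence experiments keep the
timing grid fixed: `pulse:<i>` replaces every couple by couple *i* of the
first burst; `invert-latency` / `invert-refractory` reverse the respective
gap sequence.  All modifications conserve total duration exactly, and
identical specs (including seed) produce bit-identical signals.

## Quantification

* **Spikes**: upward crossings of −20 mV with a 2 ms hold-off (insensitive
  to ±10 mV threshold shifts), detected on-line inside the integrator.
* **Silencing time**: the last spike time, provided the spike-free tail
  reaches the end of the run and is at least 5 s long; gaps above 1.5 s but
  shorter than that count as partial silencing.  The first 500 ms of every
  run are excluded (ignition transient).  Both thresholds are arguments.
* **Decay fit**: per-run active counts N(t) on a 1 s grid are averaged
  across the (default 6) runs and fitted with N(t) = 25·exp(−t/τ) by least
  squares with the intercept fixed at 25 (a free-intercept variant is
  available); R² = 1 − SS_res/SS_tot on the mean curve.  τ is only reported
  for cells with ≥ 5 % silenced — below that the fit rests on a handful of
  events.  Normalized, the fitted curve is a survival (reliability)
  function and lies within DKW bands of the empirical one.
* **Containment ellipses**: Gaussian model on (V, I_K) samples of the
  resting segment — mean center, covariance eigenvectors, radius
  √(χ²₂ quantile).  At the 99.7 % level the empirical containment of 10⁵
  Gaussian points is within ±0.3 %.  Signal-on versus signal-off axis
  ratios quantify how the signal inflates the resting-state oscillations
  without moving their center.
* **Poincaré maps**: consecutive-interval pairs, from neuron ISIs or from
  the intervals between the minimum peaks of the forcing; a
  synchronization overlap (fraction of pulses with a spike within ±5 ms)
  separates the silenced / bursting / phase-locked regimes.

## Sweeps

`experiments.run_sweep` covers the grid (I × D × amplitude × variant) with
`n_runs` seeded repetitions per cell.  Per-run seeds are SHA-256-derived
from (master seed, I, D, amplitude, run) — *not* from the variant, so
variant comparisons at matched conditions are paired (common random
numbers); only the noise is re-randomized across runs, the signal being
fixed per variant.  Cells are cached on disk as JSON, making interrupted
sweeps resumable, and the whole sweep is a deterministic function of the
master seed.

Default problem sizes: the full reproduction profile uses 15 min exposures
and 6 runs per cell; the desk-scale profile used throughout the test suite
and the acceptance script shortens exposures to 1–5 min, which keeps every
analysis identical but truncates the observable part of slow decays — where
a scaled run cannot observe an endpoint directly (e.g., complete silencing
of all neurons within 15 min), the fitted τ is used to extrapolate the
expected number of survivors at 15 min.

## What the generator does and does not emulate

Passing tests show that the *mechanism* — noise-assisted escape from the
limit cycle under weak series-voltage pulsing, exponential population
silencing, secondary-neuron shutdown after half the drive is lost,
re-triggering and phase-locking at high amplitude — is reproduced with a
structurally faithful surrogate signal.  They do not show sample-level
equivalence with the original device waveform: quantities that depend on
the exact pulse shapes (per-cell percentages and τ values of the sweep
grids, ellipse growth percentages, the amplitude boundaries between the
silenced/bursting/synchronized regimes) are reproduced as orderings and
regimes, not as exact numbers.  In particular, with the frozen surrogate
the bursting window sits near 4–5 mV rather than ≈ 3.2 mV, and the
phase-locking overlap at 8 mV plateaus near 0.83 rather than above 0.9;
both boundaries move with pulse-shape details that the public record does
not constrain.

## Known limitations

* Explicit Euler phase error grows linearly along spiking trajectories;
  spike *times* carry an O(dt) bias common to all conditions.
* The noise convention ties D to the 10 µs step; comparing with solvers
  using another step requires rescaling.
* The secondary neuron shares the primary parameter set and receives no
  noise; no plasticity, delays, inhibition or recurrence.
* Field-to-tissue dosimetry is out of scope: the induced transmembrane
  voltage is taken as given in mV.
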