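"""Single-compartment Hodgkin-Huxley neuron with injected current noise and a
series signal-voltage term.

Model
-----
The membrane obeys the current balance per unit area

    C_m dV/dt = -g_l (V - E_l) - g_K n^4 (V - E_K) - g_Na m^3 h (V - E_Na)
                + I + xi(t)

with the classic squid-axon gating kinetics for m, h, n, voltage-shifted so
the resting potential is -60 mV.  xi(t) is Gaussian current noise drawn once
per integration step from N(0, D) (D in uA^2/cm^4, a per-step current-density
variance tied to the fixed 10 us step).  An exogenous pulsed-field term
enters as a voltage generator in series with the ionic branches: every
driving force and rate evaluation uses (V + v_signal) in place of V.

With the default parameter set the model is bistable for bias currents
between the fold of limit cycles (~6.3 uA/cm^2) and the subcritical
Andronov-Hopf point (~9.8 uA/cm^2): a stable limit cycle (tonic firing) and a
stable rest state coexist, which is what makes noise- or signal-induced
silencing persistent.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from . import _kernels

__all__ = [
    "NeuronParams",
    "NeuronState",
    "SimConfig",
    "Trace",
    "NeuronRun",
    "steady_state_gates",
    "rest_potential",
    "step",
    "simulate_neuron",
    "find_firing_threshold",
    "SPIKE_THRESHOLD_MV",
    "SPIKE_REFRACTORY_MS",
    "TRANSIENT_MS",
]

# spike criterion shared by the integrators and the analysis module:
# upward crossing of -20 mV with a 2 ms hold-off sits far above the resting
# oscillations and far below spike peaks (insensitive within +-10 mV).
SPIKE_THRESHOLD_MV = -20.0
SPIKE_REFRACTORY_MS = 2.0
# onset window excluded from silencing statistics
TRANSIENT_MS = 500.0

_NOISE_CHUNK_STEPS = 250_000  # per-chunk noise buffer (2 MB/neuron)


@dataclass(frozen=True)
class NeuronParams:
    """Biophysical constants (classic squid-axon set, rest shifted to -60 mV)."""

    C_m: float = 1.0      # uF/cm^2
    g_Na: float = 120.0   # mS/cm^2
    g_K: float = 36.0
    g_l: float = 0.3
    E_Na: float = 55.0    # mV
    E_K: float = -72.0
    E_l: float = -49.387

    def __post_init__(self) -> None:
        if self.C_m <= 0:
            raise ValueError("C_m must be positive")
        if min(self.g_Na, self.g_K, self.g_l) < 0:
            raise ValueError("conductances must be non-negative")
        if not self.E_Na > self.E_l > self.E_K:
            raise ValueError("require E_Na > E_l > E_K")

    def as_tuple(self) -> tuple[float, ...]:
        return (self.C_m, self.g_Na, self.g_K, self.g_l, self.E_Na, self.E_K, self.E_l)


@dataclass
class NeuronState:
    V: float
    m: float
    h: float
    n: float

    def __post_init__(self) -> None:
        for g in (self.m, self.h, self.n):
            if not 0.0 <= g <= 1.0:
                raise ValueError("gating variables must lie in [0, 1]")

    def as_array(self) -> np.ndarray:
        return np.array([self.V, self.m, self.h, self.n], dtype=np.float64)

    @classmethod
    def at_rest(cls, V: float = -60.0) -> "NeuronState":
        m, h, n = steady_state_gates(V)
        return cls(V=V, m=m, h=h, n=n)


@dataclass(frozen=True)
class SimConfig:
    """One simulation condition."""

    duration: float                 # ms
    I_bias: float = 0.0             # uA/cm^2
    D: float = 0.0                  # uA^2/cm^4 per-step current variance
    amplitude: float = 0.0          # mV, max|CNP'| of the forcing (bookkeeping)
    dt: float = 0.01                # ms
    seed: int = 0

    def __post_init__(self) -> None:
        if self.dt <= 0 or self.duration <= 0:
            raise ValueError("dt and duration must be positive")
        if self.D < 0:
            raise ValueError("noise variance D must be non-negative")

    @property
    def n_steps(self) -> int:
        return int(round(self.duration / self.dt))


@dataclass
class Trace:
    """Recorded membrane-potential series (possibly decimated)."""

    dt: float
    V: np.ndarray
    t0: float = 0.0

    @property
    def times(self) -> np.ndarray:
        return self.t0 + self.dt * (1 + np.arange(len(self.V)))


@dataclass
class NeuronRun:
    """Result of one single-neuron simulation."""

    config: SimConfig
    trace: Trace | None
    spike_times: np.ndarray
    final_state: NeuronState
    n_gate: np.ndarray | None = None   # potassium gate at the record stride

    def I_K(self, params: NeuronParams = NeuronParams()) -> np.ndarray:
        """Potassium current g_K n^4 (V - E_K) at the record stride."""
        if self.trace is None or self.n_gate is None:
            raise ValueError("run was recorded without V or n")
        return params.g_K * self.n_gate**4 * (self.trace.V - params.E_K)


def steady_state_gates(V: float) -> tuple[float, float, float]:
    """Steady-state (m, h, n) = alpha/(alpha+beta) at voltage V (mV)."""
    am, bm, ah, bh, an, bn = _kernels.rates(float(V))
    return am / (am + bm), ah / (ah + bh), an / (an + bn)


def _membrane_current(V: float, I_bias: float, params: NeuronParams) -> float:
    m, h, n = steady_state_gates(V)
    return (-params.g_l * (V - params.E_l)
            - params.g_K * n**4 * (V - params.E_K)
            - params.g_Na * m**3 * h * (V - params.E_Na) + I_bias)


def rest_potential(I_bias: float = 0.0, params: NeuronParams = NeuronParams()) -> float:
    """Voltage of the rest fixed point (steady-state gates) at a given bias."""
    return brentq(_membrane_current, -75.0, -35.0, args=(I_bias, params), xtol=1e-10)


def step(state: NeuronState, params: NeuronParams, I_ext: float, v_signal: float,
         dt: float, noise_draw: float = 0.0) -> NeuronState:
    """One explicit-Euler update of the membrane state.

    ``v_signal`` is the series signal voltage; ``noise_draw`` adds to the
    external current.  Raises on a non-finite result.
    """
    dV, dm, dh, dn = _kernels.hh_rhs(state.V, state.m, state.h, state.n,
                                     I_ext + noise_draw, v_signal,
                                     *params.as_tuple())
    new = NeuronState(V=state.V + dt * dV, m=state.m + dt * dm,
                      h=state.h + dt * dh, n=state.n + dt * dn)
    for name, val in (("V", new.V), ("m", new.m), ("h", new.h), ("n", new.n)):
        if not np.isfinite(val):
            raise FloatingPointError(f"non-finite {name} after Euler step")
    return new


def noise_streams(master_seed: int, n_streams: int) -> list[np.random.Generator]:
    """Independent, deterministically derived per-neuron noise substreams."""
    seqs = np.random.SeedSequence(master_seed).spawn(n_streams)
    return [np.random.default_rng(s) for s in seqs]


def simulate_neuron(config: SimConfig,
                    params: NeuronParams = NeuronParams(),
                    forcing=None,
                    *,
                    initial: NeuronState | None = None,
                    kick: tuple[float, float] | None = None,
                    record_stride: int = 1,
                    record_v: bool = True,
                    record_n: bool = False,
                    rng: np.random.Generator | None = None) -> NeuronRun:
    """Integrate one neuron for ``config.duration`` ms.

    Parameters
    ----------
    forcing : SampledSignal or None
        Series-voltage forcing term (mV); must be sampled at ``config.dt``
        and cover the whole duration.
    initial : NeuronState, optional
        Defaults to V = -60 mV with gates at steady state.
    kick : (amplitude uA/cm^2, duration ms), optional
        Extra bias current during the first ``duration`` ms, used to drop the
        state onto the limit cycle in deterministic protocols.
    record_stride : int
        Record V every this many steps (1 = full resolution); ``record_v=False``
        disables the trace entirely (spike times are always collected).
    record_n : bool
        Also record the potassium gate n (for phase-plane analyses that need
        I_K = g_K n^4 (V - E_K)).
    rng : numpy Generator, optional
        Externally supplied noise stream; by default a fresh substream is
        derived from ``config.seed``.  Used to reproduce one neuron of a
        multi-neuron run.
    """
    n_steps = config.n_steps
    if forcing is not None:
        if abs(forcing.dt - config.dt) > 1e-12:
            raise ValueError("forcing.dt must equal config.dt")
        if len(forcing.values) < n_steps:
            raise ValueError("forcing shorter than the simulation")
        fvals = forcing.values
    else:
        fvals = None

    state = (initial or NeuronState.at_rest()).as_array()
    stride = int(record_stride) if record_v else 0
    v_out = np.empty(n_steps // stride if stride else 0)
    n_out = np.empty(len(v_out) if record_n else 0)
    max_spikes = max(1024, int(config.duration / 2))
    spike_buf = np.empty(max_spikes)
    n_spk, t_last = 0, -1e12

    if rng is None:
        rng = noise_streams(config.seed, 1)[0]
    sigma = float(np.sqrt(config.D))
    zeros = np.zeros(_NOISE_CHUNK_STEPS)
    buf = np.empty(_NOISE_CHUNK_STEPS) if sigma > 0 else zeros

    done = 0
    while done < n_steps:
        k = min(_NOISE_CHUNK_STEPS, n_steps - done)
        if sigma > 0:
            noise = buf[:k]
            rng.standard_normal(out=noise)
            noise *= sigma
        else:
            noise = zeros[:k]
        f = fvals[done:done + k] if fvals is not None else zeros[:k]
        I = config.I_bias
        if kick is not None and done * config.dt < kick[1]:
            # apply the kick with a dedicated sub-chunk boundary
            k_kick = min(k, int(np.ceil(kick[1] / config.dt)) - done)
            n_spk, t_last = _kernels.neuron_chunk(
                state, config.dt, I + kick[0], f[:k_kick], noise[:k_kick],
                *params.as_tuple(), v_out, n_out, stride, done,
                spike_buf, n_spk, t_last, SPIKE_THRESHOLD_MV, SPIKE_REFRACTORY_MS,
                _kernels.RATE_TABLE)
            done += k_kick
            continue
        n_spk, t_last = _kernels.neuron_chunk(
            state, config.dt, I, f[:k], noise[:k],
            *params.as_tuple(), v_out, n_out, stride, done,
            spike_buf, n_spk, t_last, SPIKE_THRESHOLD_MV, SPIKE_REFRACTORY_MS,
                _kernels.RATE_TABLE)
        done += k

    if n_spk > max_spikes:
        raise RuntimeError("spike buffer overflow; increase max_spikes")
    trace = Trace(dt=config.dt * stride, V=v_out) if stride else None
    fs = NeuronState(V=state[0], m=min(max(state[1], 0.0), 1.0),
                     h=min(max(state[2], 0.0), 1.0), n=min(max(state[3], 0.0), 1.0))
    return NeuronRun(config=config, trace=trace,
                     spike_times=spike_buf[:n_spk].copy(), final_state=fs,
                     n_gate=n_out if record_n else None)


def find_firing_threshold(params: NeuronParams = NeuronParams(),
                          protocol: str = "cycle_persistence",
                          *, tol: float = 0.02, dt: float = 0.01) -> float:
    """Bisection for a bifurcation bias current of the deterministic neuron.

    ``cycle_persistence``: smallest bias at which periodic firing, initiated
    by a brief strong current kick, persists for >= 2 s (fold of limit
    cycles, ~6.3 uA/cm^2).  ``rest_stability``: smallest bias at which the
    rest state fails to attract a 0.1 mV perturbation (subcritical
    Andronov-Hopf, ~9.8 uA/cm^2).
    """
    if protocol == "cycle_persistence":
        lo, hi = 5.5, 7.5

        def fires(I: float) -> bool:
            cfg = SimConfig(duration=2200.0, I_bias=I, D=0.0, dt=dt, seed=0)
            run = simulate_neuron(cfg, params, kick=(20.0, 3.0), record_v=False)
            return run.spike_times.size > 0 and run.spike_times[-1] > 2100.0
    elif protocol == "rest_stability":
        lo, hi = 8.5, 10.8

        def fires(I: float) -> bool:
            V0 = rest_potential(I, params)
            init = NeuronState(V0 + 0.1, *steady_state_gates(V0))
            cfg = SimConfig(duration=3000.0, I_bias=I, D=0.0, dt=dt, seed=0)
            run = simulate_neuron(cfg, params, initial=init, record_v=False)
            return run.spike_times.size > 0
    else:
        raise ValueError(f"unknown protocol {protocol!r}")

    if fires(lo) or not fires(hi):
        raise RuntimeError(f"bisection bracket [{lo}, {hi}] does not straddle "
                           f"the {protocol} boundary")
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if fires(mid):
            hi = mid
        else:
            lo = mid
    return 0.5 * (lo + hi)
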