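"""Feed-forward network: 25 noisy primary neurons driving one secondary neuron.

Topology: every primary neuron receives the same bias current I, its own
Gaussian current noise and (when exposed) the shared pulsed-field forcing.
The secondary neuron receives no bias, no noise and no forcing; its only
input is the averaged excitatory AMPA current

    I_syn = (g_syn / 25) * sum_i r_i * (E_AMPA - V_sec),

where each synaptic gate r_i follows first-order transmitter kinetics
dr/dt = alpha [T] (1 - r) - beta r, with a rectangular transmitter pulse
[T] = 1 mM for 1 ms after every presynaptic spike (standard minimal
two-state AMPA scheme).  The current is written in its depolarizing
(excitatory) form.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np

from . import _kernels
from .hh_core import (NeuronParams, NeuronState, SimConfig, Trace,
                      SPIKE_THRESHOLD_MV, SPIKE_REFRACTORY_MS, noise_streams)

__all__ = ["SynapseParams", "NetworkResult", "run_network", "run_primaries",
           "synapse_gate_update", "N_PRIMARY"]

N_PRIMARY = 25
_CHUNK_STEPS = 100_000  # 20 MB noise buffer per chunk at 25 neurons


@dataclass(frozen=True)
class SynapseParams:
    """Averaged-AMPA synapse constants."""

    g_syn_bar: float = 0.6       # conductance-like scale (mS/cm^2-equivalent)
    E_AMPA: float = 0.0          # mV
    r_alpha: float = 1.1         # 1/(mM ms)
    r_beta: float = 0.19         # 1/ms
    transmitter_amp: float = 1.0  # mM
    transmitter_dur: float = 1.0  # ms

    def __post_init__(self) -> None:
        if self.g_syn_bar < 0:
            raise ValueError("g_syn_bar must be non-negative")
        if self.r_alpha < 0 or self.r_beta < 0:
            raise ValueError("rate constants must be non-negative")


@dataclass
class NetworkResult:
    """Spike output of one network run."""

    config: SimConfig
    primary_spike_trains: list[np.ndarray]
    secondary_spike_train: np.ndarray
    secondary_trace: Trace | None = None

    def to_json(self, path: str | Path) -> None:
        payload = {
            "config": asdict(self.config),
            "n_primary": len(self.primary_spike_trains),
            "primary_spike_counts": [int(s.size) for s in self.primary_spike_trains],
            "secondary_spike_count": int(self.secondary_spike_train.size),
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    def save_spikes_txt(self, path: str | Path) -> None:
        """Delimited text, rows (neuron_id, spike_time_ms); id 25 = secondary."""
        rows = []
        for i, s in enumerate(self.primary_spike_trains):
            rows.extend((i, t) for t in s)
        rows.extend((len(self.primary_spike_trains), t)
                    for t in self.secondary_spike_train)
        np.savetxt(path, np.asarray(rows, dtype=float),
                   fmt=["%d", "%.3f"], header="neuron_id spike_time_ms")


def run_primaries(config: SimConfig,
                  params: NeuronParams = NeuronParams(),
                  forcing=None,
                  *,
                  n_primary: int = N_PRIMARY) -> list[np.ndarray]:
    """Spike trains of the primary layer only.

    The network is feed-forward, so the primaries are statistically (and,
    with the shared per-neuron substream derivation, bit-for-bit) independent
    of the secondary neuron; when only primary-layer silencing statistics are
    needed this route integrates 25 independent neurons and skips the synapse
    and secondary, which is substantially cheaper.  Each neuron starts from
    V = -60 mV with gates at steady state and draws its noise from substream
    i of ``config.seed``, exactly as in :func:`run_network`.
    """
    from .hh_core import simulate_neuron
    rngs = noise_streams(config.seed, n_primary)
    return [simulate_neuron(config, params, forcing, record_v=False,
                            rng=rngs[i]).spike_times
            for i in range(n_primary)]


def synapse_gate_update(r: float, presyn_transmitter: float,
                        syn: SynapseParams, dt: float) -> float:
    """One Euler update of a synaptic gate r in [0, 1].

    ``presyn_transmitter`` is the instantaneous transmitter concentration
    (``syn.transmitter_amp`` during the post-spike window, else 0).
    """
    if not 0.0 <= r <= 1.0:
        raise ValueError("r must lie in [0, 1]")
    return r + dt * (syn.r_alpha * presyn_transmitter * (1.0 - r) - syn.r_beta * r)


def run_network(config: SimConfig,
                params: NeuronParams = NeuronParams(),
                syn: SynapseParams = SynapseParams(),
                forcing=None,
                *,
                n_primary: int = N_PRIMARY,
                record_secondary_stride: int = 0) -> NetworkResult:
    """Integrate the feed-forward network for ``config.duration`` ms.

    The forcing (series voltage, mV) is applied to the primaries only.  Each
    primary draws its noise from an independent substream derived from
    ``config.seed``; the run is therefore bit-reproducible.
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

    rest = NeuronState.at_rest()
    Vp = np.full(n_primary, rest.V)
    mp = np.full(n_primary, rest.m)
    hp = np.full(n_primary, rest.h)
    np_g = np.full(n_primary, rest.n)
    r = np.zeros(n_primary)
    t_pulse_left = np.zeros(n_primary)
    Vs = np.array([rest.V])
    ms = np.array([rest.m])
    hs = np.array([rest.h])
    ns = np.array([rest.n])

    max_spikes = max(1024, int(config.duration / 2))
    spike_times = np.empty((n_primary + 1, max_spikes))
    spike_count = np.zeros(n_primary + 1, dtype=np.int64)
    last_spike = np.full(n_primary + 1, -1e12)

    stride = int(record_secondary_stride)
    vs_out = np.empty(n_steps // stride if stride else 0)

    rngs = noise_streams(config.seed, n_primary)
    sigma = float(np.sqrt(config.D))
    zeros_f = np.zeros(_CHUNK_STEPS)

    done = 0
    while done < n_steps:
        k = min(_CHUNK_STEPS, n_steps - done)
        if sigma > 0:
            # draw each neuron's substream into a contiguous row, then
            # transpose to the step-major layout the kernel reads
            rows = np.empty((n_primary, k))
            for i, rng in enumerate(rngs):
                rng.standard_normal(out=rows[i])
            rows *= sigma
            noise = np.ascontiguousarray(rows.T)
        else:
            noise = np.zeros((k, n_primary))
        f = fvals[done:done + k] if fvals is not None else zeros_f[:k]
        _kernels.network_chunk(
            Vp, mp, hp, np_g, r, t_pulse_left, Vs, ms, hs, ns,
            config.dt, config.I_bias, f, noise,
            *params.as_tuple(),
            syn.g_syn_bar, syn.E_AMPA, syn.r_alpha, syn.r_beta,
            syn.transmitter_amp, syn.transmitter_dur,
            done,
            spike_times, spike_count, last_spike,
            SPIKE_THRESHOLD_MV, SPIKE_REFRACTORY_MS,
            vs_out, stride, _kernels.RATE_TABLE)
        done += k

    if np.any(spike_count > max_spikes):
        raise RuntimeError("spike buffer overflow; increase max_spikes")
    trains = [spike_times[i, :spike_count[i]].copy() for i in range(n_primary)]
    sec = spike_times[n_primary, :spike_count[n_primary]].copy()
    trace = Trace(dt=config.dt * stride, V=vs_out) if stride else None
    return NetworkResult(config=config, primary_spike_trains=trains,
                         secondary_spike_train=sec, secondary_trace=trace)
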