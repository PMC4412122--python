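"""Numba-compiled integration kernels.

The hot loops integrate the Hodgkin-Huxley equations with explicit Euler at a
10 us step.  All randomness is generated *outside* the kernels (per-neuron
substreams, chunked), so every kernel is a pure deterministic function of its
inputs.  Spike detection (upward threshold crossing of the membrane potential
with a refractory hold-off) runs inside the loop so that full-resolution
voltage traces never need to be stored for long runs.

Rate functions are the classic squid-axon ones, voltage-shifted so that the
resting potential sits at -60 mV.  Inside the kernels they are evaluated from
a dense lookup table (0.02 mV grid, linear interpolation; relative error
< 1e-6) because the exponential evaluations otherwise dominate the run time;
:func:`rates` keeps the exact closed forms for analysis-level code.  The
exogenous pulsed-field term enters as a series voltage source: every ionic
driving force and every gating-rate evaluation sees (V + v_signal) in place
of V.
"""

import numpy as np
from numba import njit

__all__ = ["neuron_chunk", "network_chunk", "rates", "hh_rhs", "RATE_TABLE"]

# rate lookup table: V in [-200, 300) mV, 0.02 mV spacing
_RATE_V0 = -200.0
_RATE_DV = 0.02
_RATE_N = 25001


@njit(cache=True, inline="always", fastmath=True)
def rates(V):
    """Classic Hodgkin-Huxley rate constants (1/ms) at membrane voltage V (mV),
    shifted so rest = -60 mV.  Removable singularities use their limits."""
    u = V + 60.0
    x = 25.0 - u
    if abs(x) < 1e-7:
        am = 1.0
    else:
        am = 0.1 * x / (np.expm1(x / 10.0))
    bm = 4.0 * np.exp(-u / 18.0)
    ah = 0.07 * np.exp(-u / 20.0)
    bh = 1.0 / (np.exp((30.0 - u) / 10.0) + 1.0)
    x = 10.0 - u
    if abs(x) < 1e-7:
        an = 0.1
    else:
        an = 0.01 * x / (np.expm1(x / 10.0))
    bn = 0.125 * np.exp(-u / 80.0)
    return am, bm, ah, bh, an, bn


def _build_rate_table() -> np.ndarray:
    tab = np.empty((_RATE_N, 6))
    for i in range(_RATE_N):
        tab[i] = rates(_RATE_V0 + _RATE_DV * i)
    return tab


RATE_TABLE = _build_rate_table()


@njit(cache=True, inline="always", fastmath=True)
def _rates_tab(tab, V):
    x = (V - _RATE_V0) / _RATE_DV
    if x < 0.0:
        x = 0.0
    hi = tab.shape[0] - 2
    if x > hi:
        x = float(hi)
    i = int(x)
    f = x - i
    am = tab[i, 0] + f * (tab[i + 1, 0] - tab[i, 0])
    bm = tab[i, 1] + f * (tab[i + 1, 1] - tab[i, 1])
    ah = tab[i, 2] + f * (tab[i + 1, 2] - tab[i, 2])
    bh = tab[i, 3] + f * (tab[i + 1, 3] - tab[i, 3])
    an = tab[i, 4] + f * (tab[i + 1, 4] - tab[i, 4])
    bn = tab[i, 5] + f * (tab[i + 1, 5] - tab[i, 5])
    return am, bm, ah, bh, an, bn


@njit(cache=True, inline="always", fastmath=True)
def hh_rhs(V, m, h, n, I_ext, v_sig, Cm, gNa, gK, gl, ENa, EK, El):
    """Time derivatives (dV, dm, dh, dn) of the H-H state (exact rates).

    The series signal voltage ``v_sig`` substitutes (V + v_sig) for V in all
    ionic driving forces and gating rates.
    """
    Veff = V + v_sig
    am, bm, ah, bh, an, bn = rates(Veff)
    INa = gNa * m * m * m * h * (Veff - ENa)
    IK = gK * n * n * n * n * (Veff - EK)
    Il = gl * (Veff - El)
    dV = (-Il - IK - INa + I_ext) / Cm
    dm = am * (1.0 - m) - bm * m
    dh = ah * (1.0 - h) - bh * h
    dn = an * (1.0 - n) - bn * n
    return dV, dm, dh, dn


@njit(cache=True, inline="always", fastmath=True)
def _hh_rhs_tab(tab, V, m, h, n, I_ext, v_sig, Cm, gNa, gK, gl, ENa, EK, El):
    Veff = V + v_sig
    am, bm, ah, bh, an, bn = _rates_tab(tab, Veff)
    INa = gNa * m * m * m * h * (Veff - ENa)
    IK = gK * n * n * n * n * (Veff - EK)
    Il = gl * (Veff - El)
    dV = (-Il - IK - INa + I_ext) / Cm
    dm = am * (1.0 - m) - bm * m
    dh = ah * (1.0 - h) - bh * h
    dn = an * (1.0 - n) - bn * n
    return dV, dm, dh, dn


@njit(cache=True, fastmath=True)
def neuron_chunk(state, dt, I_bias, forcing, noise,
                 Cm, gNa, gK, gl, ENa, EK, El,
                 v_out, n_out, stride, step0,
                 spike_times, spike_count, last_spike, spike_thr, refr_ms,
                 tab):
    """Integrate one neuron over ``len(noise)`` Euler steps.

    ``state`` = [V, m, h, n], updated in place.  ``forcing`` and ``noise``
    are per-step arrays for this chunk.  When ``stride > 0``, V (and, if
    ``n_out`` is non-empty, the potassium gate n) is recorded every
    ``stride`` global steps.  Spikes (upward crossings
    of ``spike_thr`` with ``refr_ms`` hold-off) are appended to
    ``spike_times``; the running count and last spike time are returned.
    Raises on numerical blow-up.
    """
    V = state[0]
    m = state[1]
    h = state[2]
    n = state[3]
    count = spike_count
    t_last = last_spike
    for k in range(noise.shape[0]):
        dV, dm, dh, dn = _hh_rhs_tab(tab, V, m, h, n, I_bias + noise[k],
                                     forcing[k], Cm, gNa, gK, gl, ENa, EK, El)
        Vn = V + dt * dV
        m += dt * dm
        h += dt * dh
        n += dt * dn
        t = (step0 + k + 1) * dt
        if V < spike_thr and Vn >= spike_thr and (t - t_last) > refr_ms:
            if count < spike_times.shape[0]:
                spike_times[count] = t
            count += 1
            t_last = t
        V = Vn
        if stride > 0 and (step0 + k + 1) % stride == 0:
            j = (step0 + k + 1) // stride - 1
            v_out[j] = V
            if n_out.shape[0] > 0:
                n_out[j] = n
    if not (np.isfinite(V) and np.isfinite(m) and np.isfinite(h) and np.isfinite(n)):
        raise FloatingPointError("membrane state blew up (non-finite V/m/h/n)")
    state[0] = V
    state[1] = m
    state[2] = h
    state[3] = n
    return count, t_last


@njit(cache=True, fastmath=True)
def network_chunk(Vp, mp, hp, np_, r, t_pulse_left,
                  Vs, ms, hs, ns,
                  dt, I_bias, forcing, noise,
                  Cm, gNa, gK, gl, ENa, EK, El,
                  g_syn, E_AMPA, r_alpha, r_beta, T_amp, T_dur,
                  step0,
                  spike_times, spike_count, last_spike, spike_thr, refr_ms,
                  vs_out, stride, tab):
    """Integrate the 25-primary + 1-secondary feed-forward network for a chunk.

    Primaries (arrays of length N) receive the shared forcing plus their own
    noise column; the secondary (scalars in the length-1 arrays ``Vs`` etc.)
    receives only the averaged AMPA current
    ``(g_syn / N) * sum_i r_i * (E_AMPA - V_sec)``.  Each synaptic gate r_i
    follows dr/dt = alpha*[T]*(1-r) - beta*r with [T] = ``T_amp`` for
    ``T_dur`` ms after every presynaptic spike.  Spike buffers are shared:
    row i < N is primary i, row N is the secondary.
    """
    N = Vp.shape[0]
    for k in range(noise.shape[0]):
        t = (step0 + k + 1) * dt
        vsig = forcing[k]
        for i in range(N):
            dV, dm, dh, dn = _hh_rhs_tab(tab, Vp[i], mp[i], hp[i], np_[i],
                                         I_bias + noise[k, i], vsig,
                                         Cm, gNa, gK, gl, ENa, EK, El)
            Vn = Vp[i] + dt * dV
            mp[i] += dt * dm
            hp[i] += dt * dh
            np_[i] += dt * dn
            spiked = Vp[i] < spike_thr and Vn >= spike_thr and (t - last_spike[i]) > refr_ms
            if spiked:
                if spike_count[i] < spike_times.shape[1]:
                    spike_times[i, spike_count[i]] = t
                spike_count[i] += 1
                last_spike[i] = t
                t_pulse_left[i] = T_dur
            Vp[i] = Vn
            # synaptic gate driven by this neuron's transmitter window
            T = T_amp if t_pulse_left[i] > 0.0 else 0.0
            r[i] += dt * (r_alpha * T * (1.0 - r[i]) - r_beta * r[i])
            if t_pulse_left[i] > 0.0:
                t_pulse_left[i] -= dt
        r_sum = 0.0
        for i in range(N):
            r_sum += r[i]
        I_syn = (g_syn / N) * r_sum * (E_AMPA - Vs[0])
        dV, dm, dh, dn = _hh_rhs_tab(tab, Vs[0], ms[0], hs[0], ns[0],
                                     I_syn, 0.0, Cm, gNa, gK, gl, ENa, EK, El)
        Vn = Vs[0] + dt * dV
        ms[0] += dt * dm
        hs[0] += dt * dh
        ns[0] += dt * dn
        if Vs[0] < spike_thr and Vn >= spike_thr and (t - last_spike[N]) > refr_ms:
            if spike_count[N] < spike_times.shape[1]:
                spike_times[N, spike_count[N]] = t
            spike_count[N] += 1
            last_spike[N] = t
        Vs[0] = Vn
        if stride > 0 and (step0 + k + 1) % stride == 0:
            vs_out[(step0 + k + 1) // stride - 1] = Vs[0]
    ok = True
    for i in range(N):
        if not np.isfinite(Vp[i]):
            ok = False
    if not (ok and np.isfinite(Vs[0])):
        raise FloatingPointError("network state blew up (non-finite V)")
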