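"""Synthetic CNP-like pulsed waveform: generation, preconditioning and variants.

The CNP (Complex Neuroelectromagnetic Pulse) is a low-intensity pulsed
magnetic-field signal organized in bursts of biphasic pulse couples whose
repetition frequency decreases within each burst.  The original device
waveform (sampled at 1 ms) is proprietary and not publicly deposited, so this
module synthesizes a surrogate with the documented *structure*: by default
four bursts of 838 ms, each containing 16 couples of biphasic waveforms,
separated by refractory periods of 110, 220, 330 and 1200 ms, for a basic
pattern of 5212 ms that is tiled to the desired exposure duration.

The quantity coupled into the neuron model is not the raw pulse train but its
time derivative (CNP'), scaled so that max|CNP'| equals a configured
transmembrane-voltage amplitude in mV.  The preprocessing chain mirrors a
physical signal path: linear-interpolation upsampling from the native 1 ms
grid to the integration step (10 us), causal 5th-order Butterworth low-pass
at 500 Hz, first-difference derivative, amplitude normalization.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy import signal as sps

__all__ = [
    "SignalSpec",
    "SampledSignal",
    "generate_cnp",
    "precondition",
    "derive_and_scale",
    "make_uniform_pulse_variant",
    "invert_lag_order",
    "tile_pattern",
    "detect_pulse_times",
    "count_pulse_couples",
    "make_forcing",
    "signal_minimum_times",
]

NATIVE_DT_MS = 1.0  # sampling step of the emulated source waveform


class SignalConfigError(ValueError):
    """Raised when a SignalSpec cannot produce a valid pulse train."""


@dataclass(frozen=True)
class SignalSpec:
    """Structural description of one basic CNP-like pattern.

    Parameters
    ----------
    n_bursts : int
        Number of bursts in the basic pattern.
    burst_duration : float
        Duration of each burst in ms.
    pulses_per_burst : int
        Number of biphasic pulse couples per burst.
    refractory_periods : tuple of float
        Silent gap (ms) following each burst; one entry per burst.  The last
        entry separates consecutive repetitions of the basic pattern.
    pulse_width : float
        Total width (ms) of one pulse couple (two biphasic waveforms).
    latency_growth : float
        Relative increase of the last intra-burst latency over the first
        (>= 0).  Latencies form an arithmetic progression solved in closed
        form so that pulses and latencies tile the burst exactly; a positive
        value makes the within-burst repetition frequency decrease in time.
    jitter_fraction : float
        Pulse-to-pulse shape variability in [0, 0.2]: lobe amplitudes and
        widths are multiplied by (1 + jitter_fraction * u), u ~ U[-1, 1].
    seed : int
        Seed of the jitter stream; identical specs give bit-identical output.
    """

    n_bursts: int = 4
    burst_duration: float = 838.0
    pulses_per_burst: int = 16
    refractory_periods: tuple[float, ...] = (110.0, 220.0, 330.0, 1200.0)
    pulse_width: float = 4.0
    latency_growth: float = 1.0
    jitter_fraction: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "refractory_periods", tuple(float(x) for x in self.refractory_periods)
        )
        if len(self.refractory_periods) != self.n_bursts:
            raise SignalConfigError(
                f"need {self.n_bursts} refractory periods, got "
                f"{len(self.refractory_periods)}"
            )
        if self.pulses_per_burst < 2:
            raise SignalConfigError("need at least 2 pulses per burst")
        if self.pulses_per_burst * self.pulse_width >= self.burst_duration:
            raise SignalConfigError(
                "pulses do not fit in the burst: "
                f"{self.pulses_per_burst} x {self.pulse_width} ms >= "
                f"{self.burst_duration} ms"
            )
        if self.latency_growth < 0:
            raise SignalConfigError("latency_growth must be >= 0")
        if not 0.0 <= self.jitter_fraction <= 0.2:
            raise SignalConfigError("jitter_fraction must lie in [0, 0.2]")

    @property
    def pattern_duration(self) -> float:
        """Total duration of the basic pattern in ms (5212 for defaults)."""
        return self.n_bursts * self.burst_duration + sum(self.refractory_periods)

    def latencies(self) -> np.ndarray:
        """Intra-burst gaps (ms) between consecutive pulse couples.

        ``pulses_per_burst - 1`` values forming an arithmetic progression
        with ``last = first * (1 + latency_growth)``, summing exactly to the
        burst time not occupied by pulses.
        """
        n_lat = self.pulses_per_burst - 1
        total = self.burst_duration - self.pulses_per_burst * self.pulse_width
        first = total / (n_lat * (1.0 + self.latency_growth / 2.0))
        step = first * self.latency_growth / (n_lat - 1) if n_lat > 1 else 0.0
        lat = first + step * np.arange(n_lat)
        # kill accumulated round-off so the tiling invariant holds exactly
        lat *= total / lat.sum()
        return lat


@dataclass
class SampledSignal:
    """A uniformly sampled waveform.

    ``values`` are in arbitrary units for the raw pulse train and in mV for
    the derivative forcing term; ``dt`` is the sample step in ms.
    """

    dt: float
    values: np.ndarray
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("signal contains non-finite samples")

    @property
    def duration(self) -> float:
        return self.dt * len(self.values)

    @property
    def times(self) -> np.ndarray:
        return self.t0 + self.dt * np.arange(len(self.values))

    def save_txt(self, path: str | Path) -> None:
        """Two-column text export: time_ms, value, with a ``# dt_ms=`` header."""
        arr = np.column_stack([self.times, self.values])
        np.savetxt(path, arr, header=f"dt_ms={self.dt!r}", comments="# ")

    @classmethod
    def load_txt(cls, path: str | Path) -> "SampledSignal":
        with open(path) as fh:
            header = fh.readline()
        if not header.startswith("# dt_ms="):
            raise ValueError(f"{path}: missing '# dt_ms=' header")
        dt = float(header.split("=", 1)[1])
        arr = np.loadtxt(path)
        t0 = float(arr[0, 0]) if arr.ndim == 2 and arr.size else 0.0
        return cls(dt=dt, values=arr[:, 1], t0=t0)

    def save_npz(self, path: str | Path) -> None:
        """Compact binary export for long traces (10 us sampling)."""
        np.savez_compressed(path, dt=self.dt, t0=self.t0, values=self.values)

    @classmethod
    def load_npz(cls, path: str | Path) -> "SampledSignal":
        with np.load(path) as z:
            return cls(dt=float(z["dt"]), values=z["values"], t0=float(z["t0"]))


# ---------------------------------------------------------------------------
# pulse synthesis
# ---------------------------------------------------------------------------

# One pulse "couple" = two biphasic Gaussian-difference waveforms
# back-to-back.  Each waveform is hyperpolarization-leading: a dominant
# negative lobe followed by a small positive rebound, so its time derivative
# carries one brief hyperpolarizing phase and one sustained depolarizing
# phase, mimicking the ability of the source pulses both to knock a firing
# neuron off its limit cycle at sub-mV forcing amplitudes and to re-trigger
# a resting neuron at a few mV.  Lobe widths are chosen so the native 1 ms
# grid samples every lobe.
_LOBE_CENTERS = (0.3, 0.7)    # fractions of the half-couple width
_LOBE_SIGMA = 0.45            # fraction of the half-couple width
_LOBE_GAINS = (-1.0, 0.2)     # dominant lobe, rebound lobe
_WAVEFORM_GAINS = (1.0, 1.0)  # the two waveforms of a couple

_N_JITTER = 8  # per couple: (amp, width) for each of the 4 lobes


def _pulse_param_table(spec: SignalSpec) -> np.ndarray:
    """Seeded jitter multipliers, shape (n_bursts, pulses_per_burst, _N_JITTER).

    Drawn in a fixed order so variants that reuse a reference pulse see the
    same numbers regardless of which pulses they keep.
    """
    rng = np.random.default_rng(spec.seed)
    u = rng.uniform(-1.0, 1.0, size=(spec.n_bursts, spec.pulses_per_burst, _N_JITTER))
    return 1.0 + spec.jitter_fraction * u


def _eval_couple(t_local: np.ndarray, width: float, jit: np.ndarray) -> np.ndarray:
    """Evaluate one pulse couple at local times in [0, width)."""
    half = width / 2.0
    out = np.zeros_like(t_local)
    for w in range(2):  # the two biphasic waveforms of the couple
        base = w * half
        for lobe in range(2):  # dominant lobe then rebound lobe
            j = 2 * w + lobe
            amp = _WAVEFORM_GAINS[w] * _LOBE_GAINS[lobe] * jit[2 * j]
            sigma = _LOBE_SIGMA * half * jit[2 * j + 1]
            center = base + _LOBE_CENTERS[lobe] * half
            out += amp * np.exp(-0.5 * ((t_local - center) / sigma) ** 2)
    return out


def _pulse_start_times(spec: SignalSpec, invert_latency: bool = False,
                       invert_refractory: bool = False) -> np.ndarray:
    """Start time (ms) of every pulse couple, shape (n_bursts, pulses_per_burst)."""
    lat = spec.latencies()
    if invert_latency:
        lat = lat[::-1]
    refr = np.asarray(spec.refractory_periods)
    if invert_refractory:
        refr = refr[::-1]
    starts = np.empty((spec.n_bursts, spec.pulses_per_burst))
    t = 0.0
    for b in range(spec.n_bursts):
        for p in range(spec.pulses_per_burst):
            starts[b, p] = t
            t += spec.pulse_width
            if p < spec.pulses_per_burst - 1:
                t += lat[p]
        t += refr[b]
    return starts


def _render(spec: SignalSpec, table: np.ndarray, *, invert_latency: bool = False,
            invert_refractory: bool = False) -> SampledSignal:
    n = int(round(spec.pattern_duration / NATIVE_DT_MS))
    t = NATIVE_DT_MS * np.arange(n)
    values = np.zeros(n)
    starts = _pulse_start_times(spec, invert_latency, invert_refractory)
    for b in range(spec.n_bursts):
        for p in range(spec.pulses_per_burst):
            s = starts[b, p]
            i0 = int(np.ceil(s / NATIVE_DT_MS))
            i1 = min(int(np.ceil((s + spec.pulse_width) / NATIVE_DT_MS)), n)
            values[i0:i1] += _eval_couple(t[i0:i1] - s, spec.pulse_width, table[b, p])
    return SampledSignal(dt=NATIVE_DT_MS, values=values)


def generate_cnp(spec: SignalSpec) -> SampledSignal:
    """Synthesize one basic pattern of the CNP-like pulse train at 1 ms sampling.

    The output emulates the structure of the source waveform: ``n_bursts``
    bursts of ``pulses_per_burst`` biphasic pulse couples with intra-burst
    latencies strictly non-decreasing in time, each burst followed by its
    refractory period.  Deterministic under a fixed ``spec.seed``.
    """
    return _render(spec, _pulse_param_table(spec))


def make_uniform_pulse_variant(spec: SignalSpec, pulse_index: int) -> SampledSignal:
    """Pattern in which pulse ``pulse_index`` (1-based, from the first burst)
    replaces every other pulse, keeping the original timing grid.
    """
    if not 1 <= pulse_index <= spec.pulses_per_burst:
        raise SignalConfigError(
            f"pulse_index must be in [1, {spec.pulses_per_burst}], got {pulse_index}"
        )
    table = _pulse_param_table(spec)
    ref = table[0, pulse_index - 1].copy()
    table[:, :] = ref
    return _render(spec, table)


def invert_lag_order(spec: SignalSpec, which: str) -> SampledSignal:
    """Pattern with the latency or refractory progression reversed in time.

    Pulse waveforms, counts and the total duration are unchanged.
    """
    if which not in ("latency", "refractory"):
        raise SignalConfigError(f"which must be 'latency' or 'refractory', got {which!r}")
    return _render(
        spec,
        _pulse_param_table(spec),
        invert_latency=(which == "latency"),
        invert_refractory=(which == "refractory"),
    )


def tile_pattern(sig: SampledSignal, duration_ms: float) -> SampledSignal:
    """Repeat the basic pattern to cover at least ``duration_ms``, then crop."""
    n_target = int(round(duration_ms / sig.dt))
    reps = int(np.ceil(n_target / len(sig.values)))
    return SampledSignal(dt=sig.dt, values=np.tile(sig.values, reps)[:n_target], t0=sig.t0)


# ---------------------------------------------------------------------------
# preconditioning chain
# ---------------------------------------------------------------------------

def precondition(raw: SampledSignal, target_dt: float = 0.01,
                 corner_hz: float = 500.0, order: int = 5) -> SampledSignal:
    """Upsample by linear interpolation and low-pass with a causal Butterworth.

    ``target_dt`` must divide ``raw.dt`` evenly; the corner frequency must be
    below the Nyquist frequency of the *target* rate.  The filter is applied
    forward-only, as in a physical signal chain.
    """
    if target_dt >= raw.dt:
        raise ValueError(f"target_dt={target_dt} must be smaller than raw dt={raw.dt}")
    factor = raw.dt / target_dt
    if abs(factor - round(factor)) > 1e-9:
        raise ValueError(f"target_dt={target_dt} does not divide raw dt={raw.dt} evenly")
    factor = int(round(factor))
    fs = 1000.0 / target_dt  # Hz
    if corner_hz >= fs / 2:
        raise ValueError(f"corner {corner_hz} Hz at or above Nyquist {fs / 2} Hz")
    t_old = raw.dt * np.arange(len(raw.values))
    t_new = target_dt * np.arange(len(raw.values) * factor)
    up = np.interp(t_new, t_old, raw.values)
    sos = sps.butter(order, corner_hz, btype="low", fs=fs, output="sos")
    filtered = sps.sosfilt(sos, up)
    return SampledSignal(dt=target_dt, values=filtered, t0=raw.t0)


def derive_and_scale(filtered: SampledSignal, amplitude_mv: float) -> SampledSignal:
    """First-difference time derivative rescaled so max|output| == amplitude_mv.

    The derivative of sample k is (x[k+1]-x[k])/dt; the last sample is
    repeated so length and dt are preserved.
    """
    if len(filtered.values) < 2:
        raise ValueError("need at least 2 samples to differentiate")
    if amplitude_mv <= 0:
        raise ValueError("amplitude_mv must be positive")
    d = np.diff(filtered.values) / filtered.dt
    d = np.append(d, d[-1])
    peak = np.max(np.abs(d))
    if peak == 0.0:
        raise ValueError("constant input has zero derivative; cannot normalize")
    return SampledSignal(dt=filtered.dt, values=d * (amplitude_mv / peak), t0=filtered.t0)


def make_forcing(spec: SignalSpec, amplitude_mv: float, duration_ms: float,
                 dt: float = 0.01, variant: str = "original") -> SampledSignal:
    """Full pipeline: generate -> tile -> upsample+filter -> derivative forcing.

    ``variant`` is one of ``original``, ``pulse:<i>`` (uniform pulse variant),
    ``invert-latency``, ``invert-refractory``.
    """
    if variant == "original":
        pattern = generate_cnp(spec)
    elif variant.startswith("pulse:"):
        pattern = make_uniform_pulse_variant(spec, int(variant.split(":", 1)[1]))
    elif variant == "invert-latency":
        pattern = invert_lag_order(spec, "latency")
    elif variant == "invert-refractory":
        pattern = invert_lag_order(spec, "refractory")
    else:
        raise SignalConfigError(f"unknown signal variant {variant!r}")
    raw = tile_pattern(pattern, duration_ms)
    return derive_and_scale(precondition(raw, target_dt=dt), amplitude_mv)


# ---------------------------------------------------------------------------
# structural detectors
# ---------------------------------------------------------------------------

def detect_pulse_times(sig: SampledSignal, threshold_frac: float = 0.1,
                       min_gap_ms: float = 10.0) -> np.ndarray:
    """Center times (ms) of pulse couples, found as suprathreshold groups.

    Samples with |value| above ``threshold_frac * max|value|`` are grouped;
    groups separated by more than ``min_gap_ms`` count as distinct pulses.
    Robust for jitter_fraction <= 0.2 because intra-burst latencies are an
    order of magnitude longer than the pulse width.
    """
    v = np.abs(sig.values)
    thr = threshold_frac * v.max()
    idx = np.nonzero(v > thr)[0]
    if idx.size == 0:
        return np.empty(0)
    gap = int(round(min_gap_ms / sig.dt))
    breaks = np.nonzero(np.diff(idx) > gap)[0]
    starts = np.concatenate([[0], breaks + 1])
    ends = np.concatenate([breaks, [idx.size - 1]])
    return sig.t0 + sig.dt * 0.5 * (idx[starts] + idx[ends])


def count_pulse_couples(sig: SampledSignal, spec: SignalSpec) -> list[int]:
    """Number of detected pulse couples in each burst of one basic pattern."""
    times = detect_pulse_times(sig)
    counts = []
    t = 0.0
    for b in range(spec.n_bursts):
        lo, hi = t, t + spec.burst_duration
        counts.append(int(np.sum((times >= lo) & (times < hi))))
        t = hi + spec.refractory_periods[b]
    return counts


def signal_minimum_times(forcing: SampledSignal, threshold_frac: float = 0.5,
                         min_gap_ms: float = 10.0) -> np.ndarray:
    """Times (ms) of the minimum peak of each forcing pulse.

    Used to build the signal-side interval sequence of the Poincare analysis:
    negative excursions below ``-threshold_frac * max|value|`` are grouped as
    for :func:`detect_pulse_times` and the minimum of each group is returned.
    """
    v = forcing.values
    thr = -threshold_frac * np.max(np.abs(v))
    idx = np.nonzero(v < thr)[0]
    if idx.size == 0:
        return np.empty(0)
    gap = int(round(min_gap_ms / forcing.dt))
    breaks = np.nonzero(np.diff(idx) > gap)[0]
    bounds = np.split(idx, breaks + 1)
    mins = [grp[np.argmin(v[grp])] for grp in bounds]
    return forcing.t0 + forcing.dt * np.asarray(mins, dtype=float)
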