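"""Post-simulation quantification.

Covers all the measurements made on simulated traces and spike trains:
spike/ISI extraction, persistent-silencing detection, the exponential decay
fit to the number of active primary neurons (time constant tau and R^2),
phase-plane containment ellipses around the resting state, interspike
Poincare return maps, partial-silencing events of the secondary neuron, and
the spike/pulse synchronization overlap used to classify the high-amplitude
regime.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit
from scipy.stats import chi2

from .hh_core import (SPIKE_THRESHOLD_MV, SPIKE_REFRACTORY_MS, TRANSIENT_MS)

__all__ = [
    "SpikeTrain",
    "SilencingResult",
    "EllipseFit",
    "PoincarePairs",
    "detect_spikes",
    "silencing_time",
    "active_count_curve",
    "fit_decay",
    "fit_containment_ellipse",
    "axis_growth",
    "poincare_map",
    "synchronization_overlap",
    "partial_silencing_events",
    "PARTIAL_SILENCE_THRESHOLD_MS",
    "MIN_TAIL_MS",
]

# a neuron counts as persistently silenced only if spike-free for >= 5 s
# through the end of the run (gaps > 1.5 s alone are "partial silencing")
MIN_TAIL_MS = 5000.0
PARTIAL_SILENCE_THRESHOLD_MS = 1500.0


@dataclass
class SpikeTrain:
    spike_times: np.ndarray   # strictly increasing, ms
    duration: float           # ms

    def __post_init__(self) -> None:
        self.spike_times = np.asarray(self.spike_times, dtype=float)
        if self.spike_times.size:
            if np.any(np.diff(self.spike_times) <= 0):
                raise ValueError("spike times must be strictly increasing")
            if self.spike_times[0] < 0 or self.spike_times[-1] > self.duration:
                raise ValueError("spike times outside [0, duration]")

    def isis(self) -> np.ndarray:
        return np.diff(self.spike_times)


@dataclass
class SilencingResult:
    silencing_times: list[float | None]     # per neuron, ms (None = active at end)
    curve_t: np.ndarray                     # ms
    curve_n: np.ndarray                     # mean active count across runs
    tau: float | None                       # ms
    r_squared: float | None
    n_runs: int


@dataclass
class EllipseFit:
    center: tuple[float, float]
    semi_axes: tuple[float, float]          # (major, minor)
    orientation: float                      # radians, major-axis angle
    containment_level: float
    mean: np.ndarray = None
    cov: np.ndarray = None

    def contains(self, points: np.ndarray) -> np.ndarray:
        """Boolean mask of points inside the ellipse (Mahalanobis test)."""
        d = points - self.mean
        inv = np.linalg.inv(self.cov)
        md2 = np.einsum("ij,jk,ik->i", d, inv, d)
        return md2 <= chi2.ppf(self.containment_level, df=2)


@dataclass
class PoincarePairs:
    pairs: np.ndarray        # shape (k, 2): (interval_i, interval_{i+1})
    source: str              # "neuron_isi" or "signal_minima"


def detect_spikes(t: np.ndarray, V: np.ndarray,
                  threshold_mv: float = SPIKE_THRESHOLD_MV,
                  refractory_ms: float = SPIKE_REFRACTORY_MS) -> SpikeTrain:
    """Spike times from a voltage trace: upward threshold crossings with a
    refractory hold-off (same criterion the integrators use on-line)."""
    t = np.asarray(t, float)
    V = np.asarray(V, float)
    up = np.nonzero((V[:-1] < threshold_mv) & (V[1:] >= threshold_mv))[0]
    times = []
    t_last = -np.inf
    for i in up:
        if t[i + 1] - t_last > refractory_ms:
            times.append(t[i + 1])
            t_last = t[i + 1]
    dur = float(t[-1]) if t.size else 0.0
    return SpikeTrain(spike_times=np.asarray(times), duration=dur)


def silencing_time(train: SpikeTrain, duration: float | None = None,
                   min_tail_ms: float = MIN_TAIL_MS,
                   transient_ms: float = TRANSIENT_MS) -> float | None:
    """Onset of persistent silencing, or None if the neuron stays active.

    Returns the time of the last spike when the subsequent spike-free tail
    reaches at least ``min_tail_ms`` and extends to the end of the run.
    Spikes during the initial transient are ignored; a neuron that never
    fires after the transient is silenced at the transient end.
    """
    dur = train.duration if duration is None else duration
    spikes = train.spike_times[train.spike_times > transient_ms]
    if spikes.size == 0:
        return transient_ms
    last = float(spikes[-1])
    if dur - last >= min_tail_ms:
        return last
    return None


def active_count_curve(silencing_times: list[float | None], n_neurons: int,
                       duration: float, dt_ms: float = 1000.0
                       ) -> tuple[np.ndarray, np.ndarray]:
    """Number of not-yet-silenced neurons on a regular time grid.

    A neuron contributes to the count up to its silencing time; neurons with
    ``None`` stay active through the whole run.  N(0) == n_neurons and the
    curve is non-increasing.
    """
    if len(silencing_times) != n_neurons:
        raise ValueError("one silencing time (or None) per neuron required")
    t = np.arange(0.0, duration + dt_ms / 2, dt_ms)
    n = np.full(t.shape, n_neurons, dtype=float)
    for st in silencing_times:
        if st is not None:
            n -= (t >= st)
    return t, n


def fit_decay(curves: list[tuple[np.ndarray, np.ndarray]], n_neurons: int,
              *, fix_intercept: bool = True
              ) -> tuple[float | None, float | None, np.ndarray, np.ndarray]:
    """Exponential fit to the mean active-count curve over runs.

    Averages the per-run curves pointwise (grids must match), then fits
    N(t) = n_neurons * exp(-t / tau) by least squares; with
    ``fix_intercept=False`` the prefactor is free.  Returns
    (tau_ms, r_squared, mean_t, mean_n); (None, None, ...) when no silencing
    occurred (flat curve) so the fit is undefined.
    """
    if not curves:
        raise ValueError("need at least one curve")
    t0 = curves[0][0]
    for t, _ in curves[1:]:
        if len(t) != len(t0) or not np.allclose(t, t0):
            raise ValueError("curves must share one time grid")
    mean_n = np.mean([n for _, n in curves], axis=0)
    if np.all(mean_n == mean_n[0]):
        return None, None, t0, mean_n

    if fix_intercept:
        def model(t, tau):
            return n_neurons * np.exp(-t / tau)
        p0 = [max(t0[-1] / 3.0, 1.0)]
    else:
        def model(t, tau, n0):
            return n0 * np.exp(-t / tau)
        p0 = [max(t0[-1] / 3.0, 1.0), float(n_neurons)]
    popt, _ = curve_fit(model, t0, mean_n, p0=p0, maxfev=20000)
    resid = mean_n - model(t0, *popt)
    ss_res = float(np.sum(resid**2))
    ss_tot = float(np.sum((mean_n - mean_n.mean())**2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else None
    return float(popt[0]), r2, t0, mean_n


def fit_containment_ellipse(points: np.ndarray,
                            level: float = 0.997) -> EllipseFit:
    """Gaussian containment ellipse of a 2-D point cloud.

    Center = sample mean; axes and orientation from the covariance
    eigendecomposition; radius scale sqrt of the chi^2(2) quantile at
    ``level``, so for Gaussian data the ellipse empirically contains a
    fraction ``level`` of the points.
    """
    pts = np.asarray(points, float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 100:
        raise ValueError("need an (n >= 100, 2) point array")
    if not 0.0 < level < 1.0:
        raise ValueError("level must lie in (0, 1)")
    mean = pts.mean(axis=0)
    cov = np.cov(pts, rowvar=False)
    evals, evecs = np.linalg.eigh(cov)
    if evals[0] <= 0 or evals[0] / evals[1] < 1e-12:
        raise np.linalg.LinAlgError("degenerate covariance (collinear points)")
    scale = np.sqrt(chi2.ppf(level, df=2))
    semi = np.sqrt(evals) * scale            # ascending
    major_vec = evecs[:, 1]
    return EllipseFit(center=(float(mean[0]), float(mean[1])),
                      semi_axes=(float(semi[1]), float(semi[0])),
                      orientation=float(np.arctan2(major_vec[1], major_vec[0])),
                      containment_level=level, mean=mean, cov=cov)


def axis_growth(on: EllipseFit, off: EllipseFit) -> tuple[float, float]:
    """Axis ratios (percent) of the signal-on ellipse over the signal-off one.

    Returns 100 * on/off for (major, minor); 100 means no growth.
    """
    if abs(on.containment_level - off.containment_level) > 1e-12:
        raise ValueError("ellipses must use the same containment level")
    return (100.0 * on.semi_axes[0] / off.semi_axes[0],
            100.0 * on.semi_axes[1] / off.semi_axes[1])


def poincare_map(intervals: np.ndarray, source: str = "neuron_isi") -> PoincarePairs:
    """Return map of consecutive intervals: points (interval_i, interval_{i+1}).

    Regular firing collapses onto a single point on the bisector; bursting
    produces an L-shaped pattern symmetric about it.
    """
    iv = np.asarray(intervals, float)
    if iv.size < 2:
        return PoincarePairs(pairs=np.empty((0, 2)), source=source)
    return PoincarePairs(pairs=np.column_stack([iv[:-1], iv[1:]]), source=source)


def synchronization_overlap(spike_times: np.ndarray, pulse_times: np.ndarray,
                            window_ms: float = 5.0) -> float:
    """Fraction of signal pulses with at least one spike within +-window_ms.

    Near 1 in the synchronized regime (every forcing pulse triggers a
    spike), near 0 once the neuron is silenced.
    """
    pulses = np.asarray(pulse_times, float)
    spikes = np.sort(np.asarray(spike_times, float))
    if pulses.size == 0:
        return 0.0
    if spikes.size == 0:
        return 0.0
    idx = np.searchsorted(spikes, pulses)
    hit = np.zeros(pulses.size, bool)
    for side in (idx - 1, idx):
        ok = (side >= 0) & (side < spikes.size)
        hit[ok] |= np.abs(spikes[side[ok]] - pulses[ok]) <= window_ms
    return float(hit.mean())


def partial_silencing_events(train: SpikeTrain,
                             threshold_ms: float = PARTIAL_SILENCE_THRESHOLD_MS
                             ) -> list[tuple[float, float]]:
    """Reversible silencing periods: ISIs exceeding ``threshold_ms``.

    Each event is (time of the preceding spike, gap duration).  Gaps below
    the threshold sit inside the normal ISI variability and are ignored.
    """
    out = []
    st = train.spike_times
    for a, b in zip(st[:-1], st[1:]):
        if b - a > threshold_ms:
            out.append((float(a), float(b - a)))
    return out
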