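"""Parameter sweeps over bias current, noise variance, signal amplitude and
signal variant, with seeded multi-run averaging and on-disk caching.

A sweep cell is one exposure condition (I, D, amplitude, variant).  For each
cell ``n_runs`` network simulations are integrated with independent noise
(the signal is fixed per variant), per-neuron silencing times are extracted,
the active-count curves are averaged across runs and fitted with
N(t) = 25 exp(-t/tau).  The cell report carries the percentage of silenced
primary neurons (mean over runs), tau and R^2; tau is reported only when at
least 5% of neurons silenced, because the exponential fit is unreliable with
fewer events.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .signal_gen import SignalSpec, make_forcing
from .hh_core import NeuronParams, SimConfig
from .network import SynapseParams, run_network, run_primaries, N_PRIMARY
from .dynamics_analysis import (SpikeTrain, silencing_time, active_count_curve,
                                fit_decay)

__all__ = ["SweepSpec", "CellResult", "SweepReport", "run_cell", "run_sweep",
           "compare_variants", "report_tables"]

log = logging.getLogger("cnpsim.experiments")

TAU_MIN_SILENCED_PCT = 5.0   # below this the exponential fit is unreliable


@dataclass(frozen=True)
class SweepSpec:
    """Grid definition for a sweep (defaults mirror the study design:
    3 bias currents x 4 noise variances, 6 runs per cell, 15 min)."""

    bias_currents: tuple[float, ...] = (6.5, 6.7, 7.0)
    noise_variances: tuple[float, ...] = (0.10, 0.20, 0.25, 0.30)
    amplitudes: tuple[float, ...] = (0.0, 0.4, 0.8, 1.6)
    variants: tuple[str, ...] = ("original",)
    n_runs: int = 6
    duration_ms: float = 900_000.0
    dt_ms: float = 0.01
    master_seed: int = 0
    signal: SignalSpec = field(default_factory=SignalSpec)

    def __post_init__(self) -> None:
        for name in ("bias_currents", "noise_variances", "amplitudes", "variants"):
            object.__setattr__(self, name, tuple(getattr(self, name)))
            if not getattr(self, name):
                raise ValueError(f"{name} must be non-empty")
        if self.duration_ms < 10_000:
            raise ValueError("duration_ms must be >= 10000 ms")
        if self.n_runs < 1:
            raise ValueError("n_runs must be >= 1")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SweepSpec":
        cfg = yaml.safe_load(Path(path).read_text())
        sig = SignalSpec(**cfg.pop("signal", {}))
        return cls(signal=sig, **cfg)


@dataclass
class CellResult:
    I: float
    D: float
    amplitude: float
    variant: str
    percent_silenced: float
    tau_ms: float | None
    r_squared: float | None
    n_runs: int
    silencing_times: list[list[float | None]] = field(default_factory=list)

    def record(self) -> dict:
        return {k: v for k, v in asdict(self).items() if k != "silencing_times"}


@dataclass
class SweepReport:
    cells: list[CellResult]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([c.record() for c in self.cells])

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps([c.record() for c in self.cells], indent=1))


def _cell_seed(master_seed: int, I: float, D: float, amplitude: float,
               run: int) -> int:
    """Deterministic per-run seed below 2^31, independent of cell order.

    Deliberately independent of the signal variant, so variant comparisons
    at matched (I, D, amplitude) share their noise realizations (paired
    common-random-number design); only the noise is re-randomized across the
    n_runs, the signal being fixed per variant.
    """
    key = f"{master_seed}|{I:.6g}|{D:.6g}|{amplitude:.6g}|{run}"
    return int.from_bytes(hashlib.sha256(key.encode()).digest()[:4], "big") % (2**31)


def run_cell(spec: SweepSpec, I: float, D: float, amplitude: float,
             variant: str = "original",
             params: NeuronParams = NeuronParams(),
             syn: SynapseParams = SynapseParams(),
             cache_dir: str | Path | None = None,
             primaries_only: bool = True) -> CellResult:
    """Run one sweep cell: n_runs seeded network simulations + decay fit.

    All cell metrics are primary-layer statistics, so by default only the
    primary neurons are integrated (bit-identical spike trains, see
    :func:`cnpsim.network.run_primaries`); pass ``primaries_only=False`` to
    integrate the secondary as well.
    """
    if cache_dir is not None:
        tag = hashlib.sha256(
            json.dumps([asdict(spec.signal), spec.duration_ms, spec.dt_ms,
                        spec.n_runs, spec.master_seed, I, D, amplitude, variant],
                       sort_keys=True).encode()).hexdigest()[:16]
        cache_file = Path(cache_dir) / f"cell_{tag}.json"
        if cache_file.exists():
            d = json.loads(cache_file.read_text())
            return CellResult(**d)
    forcing = None
    if amplitude > 0:
        forcing = make_forcing(spec.signal, amplitude, spec.duration_ms,
                               dt=spec.dt_ms, variant=variant)
    curves = []
    all_sts: list[list[float | None]] = []
    for run in range(spec.n_runs):
        seed = _cell_seed(spec.master_seed, I, D, amplitude, run)
        cfg = SimConfig(duration=spec.duration_ms, I_bias=I, D=D,
                        amplitude=amplitude, dt=spec.dt_ms, seed=seed)
        if primaries_only:
            trains = run_primaries(cfg, params, forcing)
        else:
            trains = run_network(cfg, params, syn, forcing).primary_spike_trains
        sts = [silencing_time(SpikeTrain(s, spec.duration_ms))
               for s in trains]
        all_sts.append(sts)
        curves.append(active_count_curve(sts, N_PRIMARY, spec.duration_ms))
        log.info("cell I=%.2f D=%.2f amp=%.2f %s run %d: %d/%d silenced",
                 I, D, amplitude, variant, run,
                 sum(s is not None for s in sts), N_PRIMARY)
    pct = 100.0 * np.mean([[s is not None for s in sts] for sts in all_sts])
    tau, r2, _, _ = fit_decay(curves, N_PRIMARY)
    if pct < TAU_MIN_SILENCED_PCT:
        tau, r2 = None, None
    out = CellResult(I=I, D=D, amplitude=amplitude, variant=variant,
                     percent_silenced=float(pct), tau_ms=tau, r_squared=r2,
                     n_runs=spec.n_runs, silencing_times=all_sts)
    if cache_dir is not None:
        Path(cache_dir).mkdir(parents=True, exist_ok=True)
        cache_file.write_text(json.dumps(asdict(out)))
    return out


def run_sweep(spec: SweepSpec, cache_dir: str | Path | None = None,
              params: NeuronParams = NeuronParams(),
              syn: SynapseParams = SynapseParams()) -> SweepReport:
    """Run the full (I x D x amplitude x variant) grid.

    Deterministic under ``spec.master_seed``; with ``cache_dir`` set,
    completed cells are reloaded from disk so an interrupted sweep resumes.
    """
    cells = []
    for variant in spec.variants:
        for I in spec.bias_currents:
            for D in spec.noise_variances:
                for amp in spec.amplitudes:
                    cells.append(run_cell(spec, I, D, amp, variant,
                                          params, syn, cache_dir))
    return SweepReport(cells=cells)


def compare_variants(spec: SweepSpec, cache_dir: str | Path | None = None
                     ) -> tuple[SweepReport, pd.DataFrame]:
    """Variant comparison at fixed (I, D): the sweep plus, per amplitude, the
    ordering of tau across variants (shorter tau = more efficient silencing).
    """
    if "original" not in spec.variants or len(spec.variants) < 2:
        raise ValueError("variants must include 'original' plus at least one "
                         "modified signal")
    report = run_sweep(spec, cache_dir)
    df = report.to_frame()
    orders = []
    for (I, D, amp), grp in df.groupby(["I", "D", "amplitude"]):
        g = grp.dropna(subset=["tau_ms"]).sort_values("tau_ms")
        orders.append({"I": I, "D": D, "amplitude": amp,
                       "tau_order": list(g["variant"]),
                       "tau_values": list(g["tau_ms"])})
    return report, pd.DataFrame(orders)


def report_tables(report: SweepReport) -> dict[tuple[float, str], pd.DataFrame]:
    """Pivot the sweep into one grid per (bias current, variant): rows = noise
    variance, columns = amplitude, cells = 'percent% (tau s)'."""
    df = report.to_frame()
    out = {}
    for (I, variant), grp in df.groupby(["I", "variant"]):
        def fmt(row):
            if pd.isna(row.tau_ms):
                return f"{row.percent_silenced:.0f}%"
            return f"{row.percent_silenced:.0f}% ({row.tau_ms / 1000:.0f} s)"
        grp = grp.assign(cell=grp.apply(fmt, axis=1))
        out[(I, variant)] = grp.pivot(index="D", columns="amplitude",
                                      values="cell")
    return out
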