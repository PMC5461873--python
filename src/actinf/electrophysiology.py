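"""Simulated electrophysiology from iteration-resolved belief traces.

Each iteration of the belief descent is read as ~16 ms of neuronal time:
state expectations are firing rates (rasters), and their band-pass
filtered fluctuations (4-32 Hz) stand in for perisaccadic local field
potentials.  Violation experiments subtract condition waveforms to give
mismatch-negativity-like and P300-like difference waveforms, and the
difference of differences probes the local-by-global interaction.

Sampling note: at 16 ms per iteration the Nyquist frequency (31.25 Hz)
sits just below the nominal 32 Hz band edge, so traces are linearly
upsampled 4x to a 4 ms grid before filtering and all waveforms are
reported on that grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

import numpy as np
from scipy.signal import butter, filtfilt

from .scheduler import TrialRecord

__all__ = [
    "ErpWaveform", "raster", "lfp", "difference_waveform", "peak_latency",
    "above_half_max_ms", "BandError",
]

DEFAULT_BAND = (4.0, 32.0)
UPSAMPLE = 4


class BandError(ValueError):
    """Requested band edges fall outside (0, Nyquist)."""


@dataclass
class ErpWaveform:
    """A (possibly filtered) multi-unit response, time-stamped in ms."""

    times_ms: np.ndarray
    values: np.ndarray                  # (n_units, n_times)
    level_id: int
    condition: str
    unit_labels: list = field(default_factory=list)
    align_ms: float = 0.0               # time 0 of the analysis frame
    parents: tuple = ()                 # condition labels of a difference

    def __post_init__(self):
        self.times_ms = np.asarray(self.times_ms, dtype=float)
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if np.any(np.diff(self.times_ms) <= 0):
            raise ValueError("times_ms must be strictly increasing")

    @property
    def n_units(self) -> int:
        return self.values.shape[0]

    def window(self, start_ms: float, stop_ms: float) -> "ErpWaveform":
        rel = self.times_ms - self.align_ms
        keep = (rel >= start_ms) & (rel <= stop_ms)
        return ErpWaveform(self.times_ms[keep], self.values[:, keep],
                           self.level_id, self.condition,
                           list(self.unit_labels), self.align_ms, self.parents)


def raster(record: TrialRecord, level_id: int, factor: int = 0) -> ErpWaveform:
    """Unit-by-iteration firing rates (Bayesian model averages of the
    initial-state expectations) over the whole trial.

    During epochs of the other level a unit's activity is held at its
    last value (sustained, delay-period-like firing); a leading gap is
    back-filled with the level's first expectation (its prior).
    """
    n_iter = record.total_iterations
    values = np.full((0, n_iter), np.nan)
    filled = np.zeros(n_iter, dtype=bool)
    n_units = None
    for rec, trace in zip(record.epochs, record.traces):
        if rec.level_id != level_id:
            continue
        block = trace.s0[factor].T            # (units, n_iter_epoch)
        if n_units is None:
            n_units = block.shape[0]
            values = np.full((n_units, n_iter), np.nan)
        sl = slice(rec.start_iter, rec.start_iter + rec.n_iter)
        values[:, sl] = block
        filled[sl] = True
    if n_units is None:
        raise ValueError(f"no epochs recorded for level {level_id}")
    # forward-fill holds, then back-fill the leading gap
    last = None
    for i in range(n_iter):
        if filled[i]:
            last = values[:, i]
        elif last is not None:
            values[:, i] = last
    first_idx = int(np.argmax(filled))
    values[:, :first_idx] = values[:, [first_idx]]
    times = np.arange(n_iter) * record.ms_per_iteration
    return ErpWaveform(times, values, level_id, "raster")


def lfp(wave: ErpWaveform, band: Tuple[float, float] = DEFAULT_BAND,
        upsample: int = UPSAMPLE, order: int = 2) -> ErpWaveform:
    """Zero-phase Butterworth band-pass of each unit's firing rate.

    The trace is linearly upsampled (default 4x, i.e. a 4 ms grid at the
    default 16 ms iteration) so the upper band edge is realisable, then
    filtered forward-backward; the result is reported on the fine grid.
    """
    dt = float(np.median(np.diff(wave.times_ms)))
    fine_dt = dt / upsample
    fs = 1000.0 / fine_dt
    lo, hi = band
    if not (0.0 < lo < hi < fs / 2.0):
        raise BandError(f"band {band} Hz invalid for Nyquist {fs / 2.0:.4g} Hz")
    t_fine = np.arange(wave.times_ms[0], wave.times_ms[-1] + fine_dt / 2, fine_dt)
    up = np.vstack([np.interp(t_fine, wave.times_ms, row) for row in wave.values])
    b, a = butter(order, [lo, hi], btype="bandpass", fs=fs)
    out = filtfilt(b, a, up, axis=-1)
    return ErpWaveform(t_fine, out, wave.level_id, wave.condition,
                       list(wave.unit_labels), wave.align_ms, wave.parents)


def difference_waveform(cond: ErpWaveform, standard: ErpWaveform) -> ErpWaveform:
    """Pointwise condition-minus-standard response per unit.  Applied to
    two difference waveforms this gives the difference of differences
    (the local-by-global interaction)."""
    if cond.values.shape != standard.values.shape or not np.allclose(
            cond.times_ms, standard.times_ms):
        raise ValueError("waveforms are misaligned (shape or time base differ)")
    return ErpWaveform(cond.times_ms.copy(), cond.values - standard.values,
                       cond.level_id, f"{cond.condition} - {standard.condition}",
                       list(cond.unit_labels), cond.align_ms,
                       parents=(cond.condition, standard.condition))


def peak_latency(wave: ErpWaveform, window_ms: Tuple[float, float],
                 polarity: str = "absmax",
                 unit: Optional[int] = None) -> Tuple[float, float]:
    """Latency (ms, relative to the alignment event) and amplitude of the
    extremal sample in the window; ties resolve to the earliest sample.

    With ``unit=None`` the extremum is taken across all units (the
    largest-magnitude deflection of the set of traces).
    """
    w = wave.window(*window_ms)
    if w.times_ms.size == 0:
        raise ValueError(f"window {window_ms} ms is empty")
    vals = w.values if unit is None else w.values[[unit]]
    if polarity == "max":
        score = vals
    elif polarity == "min":
        score = -vals
    elif polarity == "absmax":
        score = np.abs(vals)
    else:
        raise ValueError(f"unknown polarity {polarity!r}")
    per_time = score.max(axis=0)
    idx = int(np.argmax(per_time))          # argmax returns the earliest tie
    uidx = int(np.argmax(score[:, idx]))
    latency = float(w.times_ms[idx] - w.align_ms)
    amplitude = float(vals[uidx, idx])
    return latency, amplitude


def above_half_max_ms(wave: ErpWaveform, window_ms: Tuple[float, float]) -> float:
    """Total time the unit-maximal absolute response spends above half of
    its peak magnitude: a measure of how protracted a deflection is."""
    w = wave.window(*window_ms)
    env = np.abs(w.values).max(axis=0)
    if env.size == 0 or env.max() == 0:
        return 0.0
    dt = float(np.median(np.diff(w.times_ms)))
    return float((env >= env.max() / 2.0).sum() * dt)
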