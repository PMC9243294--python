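"""Time-series containers, file I/O and electrochemical unit conversion.

Biophotovoltaic (BPV) chronoamperometry produces uniformly sampled voltage
records across an external load. This module holds the in-memory containers
used throughout the package (:class:`TimeSeriesSignal`, :class:`LightSchedule`,
:class:`ReplicateSet`), converts raw voltage to current density via Ohm's law,
aggregates biological replicates to mean +/- SEM, and reads/writes the
delimited-text formats the CLI exchanges.

Internal time unit is seconds. Reported periods are in hours and frequencies
in mHz throughout the package.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "TimeSeriesSignal",
    "VoltageRecord",
    "LightSchedule",
    "ReplicateSet",
    "voltage_to_current_density",
    "load_timeseries",
    "save_timeseries",
    "aggregate_replicates",
    "light_events",
]

#: Relative tolerance on grid uniformity (fraction of dt).
_GRID_RTOL = 1e-9


class FormatError(ValueError):
    """Raised when an input file violates the uniform-grid contract."""


@dataclass(frozen=True)
class TimeSeriesSignal:
    """A uniformly sampled signal X(t).

    Parameters
    ----------
    t : np.ndarray
        Sample times in seconds since recording start, strictly increasing
        with constant spacing ``dt``.
    x : np.ndarray
        Signal values (uA m^-2 for current density, V for raw voltage).
    dt : float
        Sampling interval in seconds.
    units : str
        Unit label for ``x``.
    """

    t: np.ndarray
    x: np.ndarray
    dt: float
    units: str = "uA m^-2"

    def __post_init__(self) -> None:
        t = np.asarray(self.t, dtype=float)
        x = np.asarray(self.x, dtype=float)
        object.__setattr__(self, "t", t)
        object.__setattr__(self, "x", x)
        if t.ndim != 1 or x.ndim != 1 or t.size != x.size:
            raise ValueError("t and x must be 1-D arrays of equal length")
        if t.size >= 2:
            steps = np.diff(t)
            if np.any(steps <= 0):
                raise ValueError("t must be strictly increasing")
            if np.any(np.abs(steps - self.dt) > _GRID_RTOL * self.dt + 1e-12):
                raise ValueError("t spacing deviates from dt beyond tolerance")
        if np.any(~np.isfinite(x)):
            raise ValueError("signal contains missing/non-finite values; gaps are an error")

    def __len__(self) -> int:
        return self.t.size

    @property
    def duration(self) -> float:
        """Span of the record in seconds."""
        return float(self.t[-1] - self.t[0])

    def with_values(self, x: np.ndarray, units: str | None = None) -> "TimeSeriesSignal":
        """Return a copy on the same grid with new sample values."""
        return replace(self, x=np.asarray(x, dtype=float), units=units or self.units)

    @classmethod
    def from_values(
        cls, x: Sequence[float], dt: float, units: str = "uA m^-2", t0: float = 0.0
    ) -> "TimeSeriesSignal":
        x = np.asarray(x, dtype=float)
        t = t0 + dt * np.arange(x.size)
        return cls(t=t, x=x, dt=float(dt), units=units)


@dataclass(frozen=True)
class VoltageRecord:
    """Raw voltage record across an external load.

    ``v`` is the measured voltage series (V), ``r_ext`` the external load in
    ohms and ``area`` the electrode geometric area in m^2; the load and area
    must be constant over the record.
    """

    v: TimeSeriesSignal
    r_ext: float
    area: float

    def __post_init__(self) -> None:
        if self.r_ext <= 0:
            raise ValueError(f"external load must be positive, got {self.r_ext}")
        if self.area <= 0:
            raise ValueError(f"electrode area must be positive, got {self.area}")


@dataclass(frozen=True)
class LightSchedule:
    """Periodic light/dark pattern.

    Dawn is the dark-to-light transition, dusk the light-to-dark transition.
    ``origin_s`` anchors the first dawn; dawns recur every
    ``light_h + dark_h`` hours, each followed by a dusk ``light_h`` later.
    ``state_at_origin`` records the state of the chamber before the first
    dawn: with ``"dark"`` and a positive ``origin_s`` the record starts in
    darkness until the light first switches on at ``origin_s``.
    """

    light_h: float
    dark_h: float
    origin_s: float = 0.0
    state_at_origin: Literal["light", "dark"] = "light"

    def __post_init__(self) -> None:
        if self.light_h <= 0 or self.dark_h <= 0:
            raise ValueError("light_h and dark_h must be positive")
        if self.state_at_origin not in ("light", "dark"):
            raise ValueError("state_at_origin must be 'light' or 'dark'")

    @property
    def period_h(self) -> float:
        return self.light_h + self.dark_h

    @property
    def period_s(self) -> float:
        return self.period_h * 3600.0

    @property
    def frequency_mhz(self) -> float:
        """Entrainment frequency f_Iv of the applied light-dark period, mHz."""
        return 1000.0 / self.period_s

    def is_light(self, t: np.ndarray | float) -> np.ndarray | bool:
        """Light state at time(s) ``t`` (seconds)."""
        t = np.asarray(t, dtype=float)
        phase = np.mod(t - self.origin_s, self.period_s)
        out = phase < self.light_h * 3600.0
        if self.state_at_origin == "dark" and self.origin_s > 0:
            out = out & (t >= self.origin_s)
        return out if out.ndim else bool(out)

    def dawns(self, span: float) -> np.ndarray:
        """Dawn (dark->light) times in [0, span] seconds."""
        events = light_events(self, span)
        return np.array([t for t, kind in events if kind == "dawn"])

    def dusks(self, span: float) -> np.ndarray:
        events = light_events(self, span)
        return np.array([t for t, kind in events if kind == "dusk"])


@dataclass(frozen=True)
class ReplicateSet:
    """Replicate signals on a common grid with pointwise mean and SEM."""

    signals: tuple[TimeSeriesSignal, ...]
    mean: TimeSeriesSignal
    sem: np.ndarray = field(repr=False)


def voltage_to_current_density(rec: VoltageRecord) -> TimeSeriesSignal:
    """Convert a voltage record to current density via Ohm's law.

    J = V / (R x A), returned in uA m^-2 (1e6 x A m^-2).
    """
    j = rec.v.x / (rec.r_ext * rec.area) * 1e6
    return rec.v.with_values(j, units="uA m^-2")


def load_timeseries(
    path: str | Path,
    time_col: str = "time_s",
    value_col: str = "value",
    units: str = "uA m^-2",
    delimiter: str = ",",
    zero_origin: bool = True,
) -> TimeSeriesSignal:
    """Read a delimited text file into a validated :class:`TimeSeriesSignal`.

    The grid must be uniform; duplicated or irregular timestamps raise
    :class:`FormatError` listing the offending rows. The time origin is zeroed
    by default so downstream spectra share a common x-axis convention.
    """
    df = pd.read_csv(path, delimiter=delimiter, float_precision="round_trip")
    for col in (time_col, value_col):
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column {col!r}")
    t = df[time_col].to_numpy(dtype=float)
    x = df[value_col].to_numpy(dtype=float)
    if t.size < 1:
        raise FormatError(f"{path}: empty file")
    if np.any(~np.isfinite(x)) or np.any(~np.isfinite(t)):
        bad = np.nonzero(~np.isfinite(x) | ~np.isfinite(t))[0]
        raise FormatError(f"{path}: missing values at rows {bad.tolist()[:10]}")
    if t.size >= 2:
        steps = np.diff(t)
        dt = float(np.median(steps))
        bad = np.nonzero(np.abs(steps - dt) > _GRID_RTOL * dt + 1e-12)[0]
        if dt <= 0 or bad.size:
            raise FormatError(
                f"{path}: nonuniform sampling at rows {(bad + 1).tolist()[:10]} "
                f"(expected spacing {dt} s)"
            )
    else:
        dt = float("nan")
    if zero_origin:
        t = t - t[0]
    return TimeSeriesSignal(t=t, x=x, dt=dt, units=units)


def save_timeseries(sig: TimeSeriesSignal, path: str | Path) -> None:
    """Write ``time_s,value`` CSV with full float precision (round-trip exact)."""
    df = pd.DataFrame({"time_s": sig.t, "value": sig.x})
    df.to_csv(path, index=False)  # default repr is shortest round-trip


def aggregate_replicates(signals: Iterable[TimeSeriesSignal]) -> ReplicateSet:
    """Pointwise mean +/- standard error over replicate signals.

    All replicates must share the grid exactly. SEM uses the ddof=1 sample
    standard deviation divided by sqrt(n).
    """
    sigs = tuple(signals)
    if len(sigs) < 2:
        raise ValueError("need at least 2 replicates to aggregate")
    ref = sigs[0]
    for s in sigs[1:]:
        if len(s) != len(ref) or not np.array_equal(s.t, ref.t):
            raise ValueError("replicate grids are not aligned")
    stack = np.vstack([s.x for s in sigs])
    mean = stack.mean(axis=0)
    sem = stack.std(axis=0, ddof=1) / math.sqrt(len(sigs))
    return ReplicateSet(
        signals=sigs, mean=ref.with_values(mean), sem=sem
    )


def light_events(
    schedule: LightSchedule, span: float
) -> list[tuple[float, Literal["dawn", "dusk"]]]:
    """Ordered dawn/dusk events in [0, span] seconds.

    Events alternate with exact period ``light_h + dark_h``; the transition at
    ``origin_s`` into ``state_at_origin`` is included when it falls in range.
    """
    if span <= 0:
        raise ValueError("span must be positive")
    light_s = schedule.light_h * 3600.0
    period = schedule.period_s
    t_min = 0.0
    if schedule.state_at_origin == "dark" and schedule.origin_s > 0:
        # constant darkness before the first dawn: no events before origin
        t_min = schedule.origin_s
    events: list[tuple[float, Literal["dawn", "dusk"]]] = []
    # walk back far enough to cover t=0 even when origin_s > 0
    k = math.floor((0.0 - schedule.origin_s) / period) - 1
    while True:
        dawn = schedule.origin_s + k * period
        for t_ev, kind in ((dawn, "dawn"), (dawn + light_s, "dusk")):
            if t_min - 1e-9 <= t_ev <= span + 1e-9:
                events.append((float(t_ev), kind))
        if dawn > span:
            break
        k += 1
    events.sort(key=lambda e: e[0])
    return events
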