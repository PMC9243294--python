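"""Synthetic control and BPV-like current-density profiles.

Two families of test signals are generated:

* **Square waves** following a light-dark schedule — the control input for
  decomposition behaviour at step discontinuities, sampled at the same
  interval as the chronoamperometry recordings (dt = 120 s) and with
  amplitudes on the same scale (tens of uA m^-2).
* **BPV-like profiles** — a phenomenological sum of the components the
  decomposition is expected to separate: a monotone growth trend, an
  entrained light response with a first-order rise/decay (emulating the delay
  between light switching and biochemical activation), a near-diel sinusoid
  whose free-running period exceeds 24 h (optionally phase-reset at each dusk
  so peak-to-peak spacing entrains to the schedule while the instantaneous
  period reflects the free-running period), a frequency-modulated tri-peak
  mode (three peaks per light-dark period), and i.i.d. Gaussian measurement
  noise.

Condition presets rescale amplitudes, shift phases and magnify the trend the
way iron depletion and a 20% CO2 atmosphere alter real biofilms, so recovery
of those effects can be tested against ground truth. The generator always
returns its additive components separately.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .signal_io import LightSchedule, TimeSeriesSignal, light_events

__all__ = [
    "SquareWaveParams",
    "BPVProfileParams",
    "ConditionPreset",
    "PRESETS",
    "generate_square_wave",
    "generate_bpv_profile",
    "reference_decomposition_fixture",
]


@dataclass(frozen=True)
class SquareWaveParams:
    """Square wave locked to a light schedule.

    The wave sits at ``baseline`` in the dark and ``baseline + amplitude`` in
    the light; transitions are exact (the sample at or after a light event
    takes the new level). ``duration`` must cover at least 4 full periods so a
    decomposition can resolve the fundamental.
    """

    schedule: LightSchedule
    amplitude: float = 60.0
    baseline: float = 20.0
    dt: float = 120.0
    duration: float = 4 * 6 * 3600.0

    def __post_init__(self) -> None:
        if self.amplitude <= 0:
            raise ValueError("amplitude must be positive")
        if self.duration < 4 * self.schedule.period_s:
            raise ValueError("duration must cover >= 4 light-dark periods")


@dataclass(frozen=True)
class BPVProfileParams:
    """Parameters of the phenomenological BPV profile generator.

    Units: amplitudes in uA m^-2, times in hours where suffixed ``_h``.
    ``trend_level``/``trend_rate_per_h`` define the saturating growth trend
    ``level * (1 - exp(-rate * t))``. ``frp_h`` is the circadian free-running
    period; with ``reset_at_dusk`` the sinusoid's phase is re-anchored at
    every dusk (the dark pulse interrupts the oscillation), entraining the
    peak-to-peak spacing to the schedule while the instantaneous period stays
    at ``frp_h``. ``tripeak_offsets_h``/``tripeak_heights`` place three peaks
    per period at signed offsets from dawn with relative heights in (0, 1].
    """

    schedule: LightSchedule
    dt: float = 120.0
    duration: float = 96 * 3600.0
    trend_level: float = 25.0
    trend_rate_per_h: float = 0.02
    entrained_amp: float = 10.0
    rise_time_h: float = 0.3
    circadian_amp: float = 5.0
    frp_h: float = 25.8
    reset_at_dusk: bool = False
    circadian_phase_rad: float = 0.0
    tripeak_amp: float = 2.0
    tripeak_offsets_h: tuple[float, float, float] = (0.4, 2.6, 4.5)
    tripeak_heights: tuple[float, float, float] = (1.0, 0.85, 0.7)
    noise_sd: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.frp_h <= 0:
            raise ValueError("frp_h must be positive")
        if self.rise_time_h < 0:
            raise ValueError("rise_time_h must be >= 0")
        if any(a < 0 for a in (self.entrained_amp, self.circadian_amp,
                               self.tripeak_amp, self.noise_sd)):
            raise ValueError("amplitudes must be >= 0")
        if not all(0 < h <= 1 for h in self.tripeak_heights):
            raise ValueError("tripeak relative heights must be in (0, 1]")


@dataclass(frozen=True)
class ConditionPreset:
    """Multiplicative/phase transforms emulating a growth-condition effect.

    Relative to the iron-replete control: iron depletion damps the
    oscillations, shortens near-diel periods by about an hour, advances
    phases toward dawn and magnifies the trend severalfold; a 20% CO2
    atmosphere additionally flips all oscillations by pi radians.
    """

    name: str
    amp_scale: float = 1.0
    period_delta_h: float = 0.0
    phase_shift_rad: float = 0.0
    trend_scale: float = 1.0


PRESETS: dict[str, ConditionPreset] = {
    "FePlusAir": ConditionPreset(name="FePlusAir"),
    "FeMinusAir": ConditionPreset(
        name="FeMinusAir",
        amp_scale=0.6,
        period_delta_h=-1.1,
        phase_shift_rad=-math.pi / 4,  # advance toward dawn
        trend_scale=2.0,
    ),
    "FeMinusCO2": ConditionPreset(
        name="FeMinusCO2",
        amp_scale=0.5,
        period_delta_h=-1.2,
        phase_shift_rad=math.pi,
        trend_scale=2.0,
    ),
}


def _grid(dt: float, duration: float) -> np.ndarray:
    n = int(round(duration / dt)) + 1
    return dt * np.arange(n)


def generate_square_wave(p: SquareWaveParams) -> TimeSeriesSignal:
    """Square wave on the schedule: baseline + amplitude in light, baseline in dark."""
    t = _grid(p.dt, p.duration)
    x = p.baseline + p.amplitude * p.schedule.is_light(t).astype(float)
    return TimeSeriesSignal(t=t, x=x, dt=p.dt, units="uA m^-2")


def _entrained_response(
    t: np.ndarray, schedule: LightSchedule, amp: float, rise_time_h: float
) -> np.ndarray:
    """First-order low-pass response to the light square wave, amplitude ``amp``.

    Returned zero-mean: the oscillation rides on the basal level, whose DC
    belongs to the growth trend, not to an oscillatory mode.
    """
    target = amp * schedule.is_light(t).astype(float)
    tau = rise_time_h * 3600.0
    if tau == 0:
        return target - float(np.mean(target))
    dt = float(t[1] - t[0])
    alpha = 1.0 - math.exp(-dt / tau)
    y = np.empty_like(target)
    y[0] = target[0]
    for i in range(1, t.size):
        y[i] = y[i - 1] + alpha * (target[i] - y[i - 1])
    return y - float(np.mean(y))


def _circadian(
    t: np.ndarray,
    schedule: LightSchedule,
    amp: float,
    frp_h: float,
    reset_at_dusk: bool,
    phase_rad: float,
) -> np.ndarray:
    """Near-diel sinusoid with free-running period ``frp_h``.

    Without reset: a plain sinusoid peaking mid-day of the first period (plus
    ``phase_rad``). With reset: the phase restarts from the same anchor value
    at every dusk, so successive peaks are spaced by the schedule period while
    the local (instantaneous) period remains ``frp_h``.
    """
    frp_s = frp_h * 3600.0
    # anchor so that, from the first dawn, the peak falls mid-day
    day_mid = schedule.light_h * 3600.0 / 2.0
    phase0 = -2 * np.pi * day_mid / frp_s + phase_rad
    if not reset_at_dusk:
        theta = 2 * np.pi * (t - schedule.origin_s) / frp_s + phase0
        return amp * np.cos(theta)
    dusks = schedule.dusks(float(t[-1]) + schedule.period_s)
    if dusks.size == 0:
        theta = 2 * np.pi * (t - schedule.origin_s) / frp_s + phase0
        return amp * np.cos(theta)
    # phase value at the first dusk, re-anchored at every subsequent dusk
    first_dusk = dusks[0]
    theta_dusk = 2 * np.pi * (first_dusk - schedule.origin_s) / frp_s + phase0
    anchor = np.searchsorted(dusks, t, side="right") - 1
    theta = np.where(
        anchor < 0,
        2 * np.pi * (t - schedule.origin_s) / frp_s + phase0,
        theta_dusk + 2 * np.pi * (t - dusks[np.clip(anchor, 0, None)]) / frp_s,
    )
    return amp * np.cos(theta)


def _tripeak(
    t: np.ndarray,
    schedule: LightSchedule,
    amp: float,
    offsets_h: tuple[float, float, float],
    heights: tuple[float, float, float],
    phase_shift_rad: float = 0.0,
) -> np.ndarray:
    """Three raised-cosine peaks per period at signed offsets from dawn.

    The per-period mean is removed so the component is oscillatory (zero-mean)
    rather than a baseline shift. Peak width is an eighth of the period.
    """
    period = schedule.period_s
    shift_s = phase_shift_rad / (2 * np.pi) * period
    phase = np.mod(t - schedule.origin_s - shift_s, period)
    width = period / 8.0
    x = np.zeros_like(t, dtype=float)
    for off_h, h in zip(offsets_h, heights):
        center = (off_h * 3600.0) % period
        d = phase - center
        d = np.minimum(np.abs(d), period - np.abs(d))  # circular distance
        in_peak = d < width / 2
        x[in_peak] += amp * h * 0.5 * (1 + np.cos(2 * np.pi * d[in_peak] / width))
    return x - float(np.mean(x))


@dataclass(frozen=True)
class BPVProfile:
    """Generated profile plus its ground-truth additive components."""

    signal: TimeSeriesSignal
    components: dict[str, np.ndarray] = field(repr=False)
    params: BPVProfileParams = field(repr=False, default=None)
    preset: ConditionPreset = field(repr=False, default=None)


def generate_bpv_profile(
    p: BPVProfileParams, preset: ConditionPreset | None = None
) -> BPVProfile:
    """Sum trend + entrained response + circadian + tri-peak + noise.

    The preset transforms are applied to the component parameters before
    synthesis (amplitude scaling to oscillatory parts, period delta to the
    free-running period, phase shift to the entrained/circadian/tri-peak
    phases, trend scaling to the growth level), so the returned components are
    the post-preset ground truth. Deterministic given ``p.seed``; the seed
    only affects the noise realisation.
    """
    preset = preset or PRESETS["FePlusAir"]
    eff = replace(
        p,
        trend_level=p.trend_level * preset.trend_scale,
        entrained_amp=p.entrained_amp * preset.amp_scale,
        circadian_amp=p.circadian_amp * preset.amp_scale,
        tripeak_amp=p.tripeak_amp * preset.amp_scale,
        frp_h=p.frp_h + preset.period_delta_h,
        circadian_phase_rad=p.circadian_phase_rad + preset.phase_shift_rad,
    )
    t = _grid(eff.dt, eff.duration)
    t_h = t / 3600.0
    comps: dict[str, np.ndarray] = {}
    comps["trend"] = eff.trend_level * (1.0 - np.exp(-eff.trend_rate_per_h * t_h))
    # a pi shift inverts the light response (dark current exceeds photocurrent)
    ent = _entrained_response(t, eff.schedule, eff.entrained_amp, eff.rise_time_h)
    if abs(math.cos(preset.phase_shift_rad) + 1.0) < 1e-9:  # shift == pi
        ent = -ent
    comps["entrained"] = ent
    comps["circadian"] = _circadian(
        t, eff.schedule, eff.circadian_amp, eff.frp_h, eff.reset_at_dusk,
        eff.circadian_phase_rad,
    )
    comps["tripeak"] = _tripeak(
        t, eff.schedule, eff.tripeak_amp, eff.tripeak_offsets_h,
        eff.tripeak_heights, preset.phase_shift_rad,
    )
    rng = np.random.default_rng(p.seed)
    comps["noise"] = rng.normal(0.0, p.noise_sd, size=t.size) if p.noise_sd else np.zeros(t.size)
    x = sum(comps.values())
    sig = TimeSeriesSignal(t=t, x=x, dt=eff.dt, units="uA m^-2")
    return BPVProfile(signal=sig, components=comps, params=eff, preset=preset)


def reference_decomposition_fixture(regime: str = "3h") -> TimeSeriesSignal:
    """Canonical square-wave fixtures for decomposition studies.

    ``"3h"``: 3 h:3 h schedule over 36 h; ``"12h"``: 12 h:12 h over 96 h.
    Both at dt = 120 s with amplitude on the scale of the measured current
    densities (tens of uA m^-2). Deterministic (no noise), so the fixture is
    bit-reproducible across calls.

    The spans are a tunable choice matching the length of typical recordings
    in each regime; only the sampling interval and the at-least-4-periods
    floor are structural.
    """
    if regime == "3h":
        schedule = LightSchedule(light_h=3.0, dark_h=3.0)
        duration = 36 * 3600.0
    elif regime == "12h":
        schedule = LightSchedule(light_h=12.0, dark_h=12.0)
        duration = 96 * 3600.0
    else:
        raise ValueError(f"unknown regime {regime!r}; expected '3h' or '12h'")
    p = SquareWaveParams(
        schedule=schedule, amplitude=60.0, baseline=20.0, dt=120.0, duration=duration
    )
    sig = generate_square_wave(p)
    # fixtures span [0, duration) — an open-ended last period keeps the
    # sample count at an integer number of periods (1080 / 2880 samples)
    return TimeSeriesSignal(t=sig.t[:-1], x=sig.x[:-1], dt=sig.dt, units=sig.units)
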