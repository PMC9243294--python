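"""Rhythm descriptors of decomposed modes.

Turns IMFs and their analytic signals into the summaries used to interpret
entrained bioelectrochemical rhythms: peak timings relative to dawn/dusk,
peak-to-peak durations (mean +/- SE across light-dark periods), median
periods from the inverse median instantaneous frequency, per-mode frequency
bands and their ratio to the entrainment frequency f_Iv, amplitude trends,
and comparisons between growth conditions (phase shift, period change,
amplitude ratio, trend magnification).

A mode's frequency band is summarised by the 5th/50th/95th percentiles of its
masked-in instantaneous frequency (f_min, f_mid, f_max). A band is marked not
meaningful (NM) when more than half the samples are masked out.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from .hilbert_spectral import AnalyticSignal, median_frequency
from .signal_io import LightSchedule, light_events

__all__ = [
    "PeakEvent",
    "PeakPairStat",
    "ModeSummary",
    "ConditionComparison",
    "detect_peaks",
    "peak_to_peak_stats",
    "summarize_mode",
    "compare_conditions",
    "band_table",
    "DEFAULT_PROMINENCE",
    "TRIPEAK_PROMINENCE",
]

#: Default peak prominence as a fraction of the mode's range.
DEFAULT_PROMINENCE = 0.2
#: Lower prominence needed to resolve all three peaks of tri-peak modes.
TRIPEAK_PROMINENCE = 0.05


@dataclass(frozen=True)
class PeakEvent:
    """One detected peak, annotated with the nearest light event."""

    time_s: float
    height: float
    imf_index: int
    nearest_event_s: float
    nearest_event_kind: str  # "dawn" | "dusk"
    offset_h: float  # signed, positive = after the event


@dataclass(frozen=True)
class PeakPairStat:
    """Mean +/- SE duration between two per-period peak ordinals."""

    ordinal_pair: tuple[int, int]
    mean_h: float
    se_h: float | None
    n: int


@dataclass
class ModeSummary:
    """Per-IMF rhythm descriptors."""

    imf_index: int
    f_min_mhz: float | None
    f_mid_mhz: float | None
    f_max_mhz: float | None
    ratio_to_schedule: float | None  # f_mid / f_Iv
    median_period_h: float | None
    peak_to_peak: list[PeakPairStat] = field(default_factory=list)
    peaks: list[PeakEvent] = field(default_factory=list)
    per_period_offsets_h: list[list[float]] = field(default_factory=list)
    amplitude_per_period: np.ndarray | None = None
    amplitude_trend_slope: float | None = None
    nm: bool = False  # band not meaningful (mostly masked mode)


@dataclass(frozen=True)
class ConditionComparison:
    """Per-matched-mode deltas between two conditions plus the trend ratio."""

    matched_indices: list[tuple[int, int]]
    delta_period_h: list[float]
    delta_phase_rad: list[float]
    amplitude_ratio: list[float]
    trend_ratio: float | None


def detect_peaks(
    imf: np.ndarray,
    t: np.ndarray,
    schedule: LightSchedule,
    imf_index: int = 0,
    min_prominence_frac: float = DEFAULT_PROMINENCE,
) -> list[PeakEvent]:
    """Local maxima with prominence >= ``min_prominence_frac`` x mode range.

    Each peak is annotated with the nearest dawn or dusk and the signed
    offset from it in hours (positive = after the event).
    """
    rng = float(np.ptp(imf))
    if rng == 0:
        return []
    idx, _ = find_peaks(imf, prominence=min_prominence_frac * rng)
    if idx.size == 0:
        return []
    events = light_events(schedule, float(t[-1]) + schedule.period_s)
    ev_times = np.array([e[0] for e in events])
    ev_kinds = [e[1] for e in events]
    out = []
    for i in idx:
        j = int(np.argmin(np.abs(ev_times - t[i])))
        out.append(
            PeakEvent(
                time_s=float(t[i]),
                height=float(imf[i]),
                imf_index=imf_index,
                nearest_event_s=float(ev_times[j]),
                nearest_event_kind=ev_kinds[j],
                offset_h=float(t[i] - ev_times[j]) / 3600.0,
            )
        )
    return out


def _group_by_period(
    peaks: Sequence[PeakEvent], schedule: LightSchedule
) -> dict[int, list[PeakEvent]]:
    """Group peaks by the light-dark period (dawn-to-dawn window) they fall in."""
    groups: dict[int, list[PeakEvent]] = {}
    for p in peaks:
        k = int(np.floor((p.time_s - schedule.origin_s) / schedule.period_s))
        groups.setdefault(k, []).append(p)
    for g in groups.values():
        g.sort(key=lambda p: p.time_s)
    return groups


def peak_to_peak_stats(
    peaks: Sequence[PeakEvent], schedule: LightSchedule
) -> list[PeakPairStat]:
    """Mean +/- SE durations between consecutive per-period peak ordinals.

    Peaks are grouped per light-dark period; the duration between the j-th
    and (j+1)-th peak of each period is averaged across periods. Periods
    whose peak count differs from the modal count are dropped with a warning.
    SE (ddof=1 std / sqrt(n)) is reported only when >= 2 periods contribute.
    """
    groups = _group_by_period(peaks, schedule)
    if not groups:
        return []
    counts = [len(g) for g in groups.values()]
    modal = int(np.bincount(counts).argmax())
    kept = {k: g for k, g in groups.items() if len(g) == modal}
    if len(kept) < len(groups):
        warnings.warn(
            f"dropped {len(groups) - len(kept)} period(s) with non-modal peak count",
            RuntimeWarning,
            stacklevel=2,
        )
    if modal < 2:
        return []
    stats = []
    for j in range(modal - 1):
        durs = np.array(
            [(g[j + 1].time_s - g[j].time_s) / 3600.0 for g in kept.values()]
        )
        se = (
            float(np.std(durs, ddof=1) / np.sqrt(durs.size)) if durs.size >= 2 else None
        )
        stats.append(
            PeakPairStat(
                ordinal_pair=(j + 1, j + 2),
                mean_h=float(np.mean(durs)),
                se_h=se,
                n=int(durs.size),
            )
        )
    return stats


def summarize_mode(
    imf: np.ndarray,
    analytic: AnalyticSignal,
    t: np.ndarray,
    schedule: LightSchedule,
    imf_index: int = 0,
    min_prominence_frac: float = DEFAULT_PROMINENCE,
) -> ModeSummary:
    """Full rhythm summary for one mode.

    The frequency band is the (5th, 50th, 95th) percentile of the masked-in
    instantaneous frequency; the median period is the inverse of f_mid. The
    amplitude-per-period series is max |a(t)| within each light-dark period,
    with a least-squares slope as the amplitude trend.
    """
    mask = analytic.valid_mask
    nm = mask.sum() < 0.5 * mask.size
    summary = ModeSummary(
        imf_index=imf_index,
        f_min_mhz=None,
        f_mid_mhz=None,
        f_max_mhz=None,
        ratio_to_schedule=None,
        median_period_h=None,
        nm=nm,
    )
    if mask.any():
        f = analytic.f_mhz[mask]
        f_min, f_mid, f_max = np.percentile(f, [5, 50, 95])
        summary.f_min_mhz = float(f_min)
        summary.f_mid_mhz = float(f_mid)
        summary.f_max_mhz = float(f_max)
        summary.ratio_to_schedule = float(f_mid / schedule.frequency_mhz)
        if not nm:
            _, summary.median_period_h = median_frequency(analytic)
    peaks = detect_peaks(imf, t, schedule, imf_index, min_prominence_frac)
    summary.peaks = peaks
    summary.peak_to_peak = peak_to_peak_stats(peaks, schedule)
    groups = _group_by_period(peaks, schedule)
    summary.per_period_offsets_h = [
        [p.offset_h for p in groups[k]] for k in sorted(groups)
    ]
    # amplitude per light-dark period from the analytic energy
    n_per = max(1, int(round(schedule.period_s / analytic.dt)))
    n_full = analytic.a.size // n_per
    if n_full >= 1:
        amp = analytic.a[: n_full * n_per].reshape(n_full, n_per).max(axis=1)
        summary.amplitude_per_period = amp
        if n_full >= 2:
            slope = np.polyfit(np.arange(n_full), amp, 1)[0]
            summary.amplitude_trend_slope = float(slope)
    return summary


def _circular_mean(angles: np.ndarray) -> float:
    return float(np.angle(np.mean(np.exp(1j * angles))))


def _mode_phase_rad(s: ModeSummary, schedule: LightSchedule) -> float | None:
    """Circular mean phase of a mode's peaks within the light-dark period."""
    if not s.peaks:
        return None
    ph = np.array(
        [
            2 * np.pi * np.mod(p.time_s - schedule.origin_s, schedule.period_s)
            / schedule.period_s
            for p in s.peaks
        ]
    )
    return _circular_mean(ph)


def compare_conditions(
    a: Sequence[ModeSummary],
    b: Sequence[ModeSummary],
    schedule: LightSchedule,
    residue_a: np.ndarray | None = None,
    residue_b: np.ndarray | None = None,
    max_ratio_mismatch: float = 0.5,
) -> ConditionComparison:
    """Per-mode deltas of condition ``b`` relative to condition ``a``.

    Modes are matched by nearest ``f_mid / f_Iv`` ratio (within a relative
    mismatch of ``max_ratio_mismatch``). Delta period is period_b - period_a;
    delta phase is the circular difference of mean peak phases; amplitude
    ratio compares mean per-period amplitude maxima; the trend ratio compares
    mean |residue|.
    """
    usable_a = [s for s in a if s.ratio_to_schedule is not None and not s.nm]
    usable_b = [s for s in b if s.ratio_to_schedule is not None and not s.nm]
    matched: list[tuple[ModeSummary, ModeSummary]] = []
    used_b: set[int] = set()
    for sa in usable_a:
        best, best_err = None, np.inf
        for j, sb in enumerate(usable_b):
            if j in used_b:
                continue
            err = abs(np.log(sb.ratio_to_schedule / sa.ratio_to_schedule))
            if err < best_err:
                best, best_err = j, err
        if best is not None and best_err <= abs(np.log(1 + max_ratio_mismatch)):
            used_b.add(best)
            matched.append((sa, usable_b[best]))
    if not matched:
        warnings.warn("no modes matched between conditions", RuntimeWarning,
                      stacklevel=2)
    d_period, d_phase, amp_ratio, indices = [], [], [], []
    for sa, sb in matched:
        indices.append((sa.imf_index, sb.imf_index))
        if sa.median_period_h and sb.median_period_h:
            d_period.append(sb.median_period_h - sa.median_period_h)
        else:
            d_period.append(float("nan"))
        pa, pb = _mode_phase_rad(sa, schedule), _mode_phase_rad(sb, schedule)
        if pa is None or pb is None:
            d_phase.append(float("nan"))
        else:
            d_phase.append(float(np.angle(np.exp(1j * (pb - pa)))))
        if (
            sa.amplitude_per_period is not None
            and sb.amplitude_per_period is not None
            and sa.amplitude_per_period.mean() > 0
        ):
            amp_ratio.append(
                float(sb.amplitude_per_period.mean() / sa.amplitude_per_period.mean())
            )
        else:
            amp_ratio.append(float("nan"))
    trend_ratio = None
    if residue_a is not None and residue_b is not None:
        ma = float(np.mean(np.abs(residue_a)))
        if ma > 0:
            trend_ratio = float(np.mean(np.abs(residue_b)) / ma)
    return ConditionComparison(
        matched_indices=indices,
        delta_period_h=d_period,
        delta_phase_rad=d_phase,
        amplitude_ratio=amp_ratio,
        trend_ratio=trend_ratio,
    )


def band_table(
    summaries: Sequence[ModeSummary], schedule: LightSchedule
) -> pd.DataFrame:
    """Frequency-band table: per IMF f_min, f_max, f_mid and f_mid/f_Iv.

    NM (not meaningful) bands — modes with more than half their samples
    masked — are reported with empty band columns.
    """
    rows = []
    for s in summaries:
        nm = s.nm or s.f_mid_mhz is None
        rows.append(
            {
                "imf": s.imf_index,
                "f_min_mHz": None if nm else round(s.f_min_mhz, 3),
                "f_max_mHz": None if nm else round(s.f_max_mhz, 3),
                "f_mid_mHz": None if nm else round(s.f_mid_mhz, 3),
                "f_mid/f_Iv": None if nm else round(s.f_mid_mhz / schedule.frequency_mhz, 2),
                "median_period_h": None if nm or s.median_period_h is None
                else round(s.median_period_h, 2),
                "NM": nm,
            }
        )
    df = pd.DataFrame(
        rows,
        columns=["imf", "f_min_mHz", "f_max_mHz", "f_mid_mHz", "f_mid/f_Iv",
                 "median_period_h", "NM"],
    )
    df.attrs["f_Iv_mHz"] = schedule.frequency_mhz
    return df
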