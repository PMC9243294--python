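"""Analytic signals, instantaneous frequency, Hilbert and marginal spectra.

For each IMF d_k(t) the discrete analytic signal Z(t) = d_k(t) + i Y(t) is
built with an FFT-based Hilbert transform (exact quadrature for pure tones on
periodic windows). Its modulus a(t) is the instantaneous energy, its unwrapped
argument theta(t) the instantaneous phase, and the smoothed phase derivative
the instantaneous frequency — reported here as cyclic frequency in mHz.

Because the frequency comes from differentiation, several samples are needed
per cycle for a stable estimate; with a minimum of five data points per
derivative the highest stable frequency is f_max = 1/(n*dt) with n = 4
sampling intervals. Estimates above f_max or below zero are masked, never
clipped: negative instantaneous frequencies are physically meaningless and
indicate a locally asymmetric mode.

The Hilbert spectrum H(omega, t) deposits each mode's energy at its
instantaneous frequency over time; the final residue (trend) is excluded
because its energy would overpower the oscillatory modes. The marginal
spectrum h(omega) integrates H over time, giving the total energy
contribution of each frequency.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import hilbert as _scipy_hilbert
from scipy.signal import medfilt

from .emd_core import IMFSet

__all__ = [
    "AnalyticSignal",
    "HilbertSpectrum",
    "MarginalSpectrum",
    "analytic_signal",
    "max_stable_frequency",
    "build_hilbert_spectrum",
    "marginal_spectrum",
    "median_frequency",
]

#: Default number of sampling intervals between the five points of a stable
#: phase-derivative estimate.
DERIVATIVE_INTERVALS = 4

#: Fraction of samples masked at each edge for frequency statistics.
EDGE_TRIM_FRAC = 0.02


@dataclass(frozen=True)
class AnalyticSignal:
    """Per-IMF instantaneous energy, phase and frequency.

    ``a`` is the instantaneous energy a(t) (signal units), ``theta`` the
    unwrapped instantaneous phase (rad), ``f_mhz`` the instantaneous cyclic
    frequency (mHz), and ``valid_mask`` flags samples retained for frequency
    statistics (edge-trimmed, 0 < f <= f_max).
    """

    a: np.ndarray
    theta: np.ndarray
    f_mhz: np.ndarray
    valid_mask: np.ndarray
    dt: float
    f_max_mhz: float


@dataclass(frozen=True)
class HilbertSpectrum:
    """Energy surface H(omega, t) over all IMFs, residue excluded."""

    t: np.ndarray
    f_bins_mhz: np.ndarray  # bin edges, length n_bins + 1
    energy: np.ndarray  # (n_bins, n_times)

    @property
    def f_centers_mhz(self) -> np.ndarray:
        return np.sqrt(self.f_bins_mhz[:-1] * self.f_bins_mhz[1:])

    @property
    def total_energy(self) -> float:
        return float(self.energy.sum())


@dataclass(frozen=True)
class MarginalSpectrum:
    """Time-integrated Hilbert spectrum h(omega), units energy x seconds."""

    f_bins_mhz: np.ndarray
    h: np.ndarray
    dt: float = field(default=float("nan"))

    @property
    def f_centers_mhz(self) -> np.ndarray:
        return np.sqrt(self.f_bins_mhz[:-1] * self.f_bins_mhz[1:])

    @property
    def peak_frequency_mhz(self) -> float:
        return float(self.f_centers_mhz[int(np.argmax(self.h))])


def max_stable_frequency(dt: float, n: int = DERIVATIVE_INTERVALS) -> float:
    """Highest stable frequency 1/(n*dt) in mHz.

    ``n`` is the number of sampling intervals spanned by the minimum data
    points of the phase-derivative stencil (n=4 for the five-point heuristic).
    For dt = 120 s this gives 2.083 mHz, conventionally rounded to 2.1 mHz.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if n < 1:
        raise ValueError("n must be >= 1")
    return 1000.0 / (n * dt)


def _phase_derivative(theta: np.ndarray, dt: float) -> np.ndarray:
    """Five-point centred finite difference of the unwrapped phase, rad/s."""
    n = theta.size
    d = np.empty(n)
    if n >= 5:
        d[2:-2] = (-theta[4:] + 8 * theta[3:-1] - 8 * theta[1:-3] + theta[:-4]) / (
            12 * dt
        )
        # lower-order estimates at the borders
        d[:2] = np.gradient(theta[:5], dt)[:2]
        d[-2:] = np.gradient(theta[-5:], dt)[-2:]
    else:
        d[:] = np.gradient(theta, dt) if n > 1 else 0.0
    return d


def analytic_signal(
    imf: np.ndarray,
    dt: float,
    n_intervals: int = DERIVATIVE_INTERVALS,
    edge_trim_frac: float = EDGE_TRIM_FRAC,
    smooth_window: int = 5,
) -> AnalyticSignal:
    """Analytic-signal statistics of one IMF.

    The instantaneous frequency is the five-point centred difference of the
    unwrapped phase, median-filtered (window ``smooth_window``) to suppress
    differentiation noise. Samples with non-positive or super-``f_max``
    estimates, and the first/last ``edge_trim_frac`` of the record, are
    masked out.
    """
    x = np.asarray(imf, dtype=float)
    n = x.size
    f_max = max_stable_frequency(dt, n_intervals)
    if np.ptp(x) == 0:
        warnings.warn(
            "constant input: instantaneous frequency undefined", RuntimeWarning,
            stacklevel=2,
        )
        return AnalyticSignal(
            a=np.full(n, abs(x[0]) if n else 0.0),
            theta=np.zeros(n),
            f_mhz=np.full(n, np.nan),
            valid_mask=np.zeros(n, dtype=bool),
            dt=dt,
            f_max_mhz=f_max,
        )
    z = _scipy_hilbert(x)
    a = np.abs(z)
    theta = np.unwrap(np.angle(z))
    omega = _phase_derivative(theta, dt)  # rad/s
    f_mhz = omega / (2.0 * np.pi) * 1000.0
    if smooth_window and smooth_window >= 3 and n >= smooth_window:
        f_mhz = medfilt(f_mhz, kernel_size=smooth_window | 1)
    trim = int(np.ceil(edge_trim_frac * n))
    mask = (f_mhz > 0) & (f_mhz <= f_max)
    if trim:
        mask[:trim] = False
        mask[-trim:] = False
    return AnalyticSignal(
        a=a, theta=theta, f_mhz=f_mhz, valid_mask=mask, dt=dt, f_max_mhz=f_max
    )


def _default_bins(span_s: float, f_max_mhz: float, n_bins: int) -> np.ndarray:
    f_lo = 1000.0 / span_s  # lowest resolvable cyclic frequency, mHz
    if f_lo >= f_max_mhz:
        f_lo = f_max_mhz / 100.0
    return np.geomspace(f_lo, f_max_mhz, n_bins + 1)


def build_hilbert_spectrum(
    imfset: IMFSet,
    n_bins: int = 256,
    f_bins_mhz: np.ndarray | None = None,
    analytic: list[AnalyticSignal] | None = None,
) -> HilbertSpectrum:
    """Assemble H(omega, t) from all IMFs of a decomposition.

    Each mode's instantaneous energy a_k(t) is deposited in the frequency bin
    containing f_k(t) at each masked-in sample, so binning conserves the total
    masked-in energy. The residue is excluded by construction. Frequencies are
    binned on a log-spaced axis from 1/span to f_max unless explicit edges are
    given.
    """
    t = imfset.t
    span = float(t[-1] - t[0]) if t.size > 1 else imfset.dt
    f_max = max_stable_frequency(imfset.dt)
    bins = (
        np.asarray(f_bins_mhz, dtype=float)
        if f_bins_mhz is not None
        else _default_bins(span, f_max, n_bins)
    )
    energy = np.zeros((bins.size - 1, t.size))
    if analytic is None:
        analytic = [analytic_signal(imf, imfset.dt) for imf in imfset.imfs]
    for sig in analytic:
        m = sig.valid_mask & (sig.f_mhz >= bins[0]) & (sig.f_mhz <= bins[-1])
        if not m.any():
            continue
        idx = np.clip(np.searchsorted(bins, sig.f_mhz[m], side="right") - 1, 0,
                      bins.size - 2)
        np.add.at(energy, (idx, np.nonzero(m)[0]), sig.a[m])
    return HilbertSpectrum(t=t, f_bins_mhz=bins, energy=energy)


def marginal_spectrum(spectrum: HilbertSpectrum, dt: float | None = None) -> MarginalSpectrum:
    """Integrate the Hilbert spectrum over time, h(omega) = int H(omega,t) dt.

    The trend never enters because :func:`build_hilbert_spectrum` excludes the
    residue. The integral is a rectangle-rule sum over the sample grid, so
    ``sum(h) == total spectrum energy * dt`` exactly.
    """
    if dt is None:
        dt = float(spectrum.t[1] - spectrum.t[0]) if spectrum.t.size > 1 else 1.0
    h = spectrum.energy.sum(axis=1) * dt
    return MarginalSpectrum(f_bins_mhz=spectrum.f_bins_mhz, h=h, dt=dt)


def median_frequency(sig: AnalyticSignal) -> tuple[float, float]:
    """Median masked-in instantaneous frequency (mHz) and period (hours).

    Requires at least half the record to be masked-in, otherwise the estimate
    is dominated by edge effects and raised as an error.
    """
    n_valid = int(sig.valid_mask.sum())
    if n_valid == 0:
        raise ValueError("all samples masked: median frequency undefined")
    f = float(np.median(sig.f_mhz[sig.valid_mask]))
    if f <= 0:
        raise ValueError("non-positive median frequency")
    period_h = 1000.0 / f / 3600.0
    return f, period_h
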