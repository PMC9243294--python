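# Methods

## Signal model

The package treats a BPV chronoamperometry record as a uniformly sampled
series X(t) (current density, µA m⁻², after J = V/(R·A) conversion from the
voltage across the external load). Uniform sampling is a hard precondition:
gaps or irregular timestamps are rejected rather than interpolated, because
both the envelope construction in EMD and the phase differentiation in the
Hilbert step assume a constant Δt. Replicate recordings are combined as
pointwise mean ± SEM (ddof = 1 sample standard deviation over √n), the
convention for small numbers of independent biological replicates.

## Empirical mode decomposition

`emd_core.emd` implements classic EMD. The local mean of a signal is the
average of cubic-spline envelopes through its local maxima and minima;
sifting repeatedly subtracts the local mean until the candidate satisfies
the IMF conditions. Numerical choices:

* **Extrema.** Strict local extrema; a flat plateau (runs of equal samples,
  as produced by square light schedules) contributes a single extremum at
  its midpoint, which prevents spline oscillation between equal-valued
  knots.
* **Envelope boundaries.** The two extrema nearest each edge are mirrored
  about the record endpoints before spline fitting. This is the standard
  remedy for envelope divergence at the edges; endpoint clamping (treating a
  record end as an extremum when it escapes the envelope) was evaluated and
  rejected because it suppressed the slowest real modes on multi-day
  records.
* **Stop criterion.** Default is the Cauchy ratio
  SD = Σ(h_prev − h)²/Σh_prev² < 0.2, or the IMF conditions holding for 3
  consecutive sifts, capped at `max_sifts` = 5000. An envelope-symmetry
  criterion (|upper+lower|/(upper−lower) small almost everywhere), as used
  in several classic implementations, is available via
  `SiftConfig(criterion="envelope")`; it sifts considerably more and
  produces narrower-band modes at roughly 4× the cost.
* **Shift equivariance.** The signal mean is removed before sifting and
  restored in the residue. The Cauchy ratio is not invariant under DC
  offsets, so without this step `emd(x + c)` and `emd(x)` could stop at
  different sift counts; with it, adding a constant shifts only the trend.
* **Termination.** Decomposition stops when the residue has fewer than
  three interior extrema (monotone-ish trend).

## ICEEMDAN

`emd_core.iceemdan` implements the improved complete ensemble EMD with
adaptive noise. One full EMD of each of I white-noise realisations is
precomputed and reused across stages (the mode bank). At stage k the
residue's local mean is estimated as the ensemble average of local means of
r_{k−1} plus the k-th noise mode scaled to `noise_std` × std(r_{k−1});
modes are consecutive-residue differences d̃_k = r_{k−1} − r_k, so
Σd̃_k + r_K equals the input to machine precision by telescoping — the
conservation property every decomposition test asserts exactly.

Parameters: `noise_std` = 0.25 (centre of the conventional 0.2–0.3 range),
`n_realisations` I = 500, `max_sifts` = 5000. Two stage-noise schedules are
exposed. With `snr_increase=True` the noise modes keep their natural EMD
amplitudes, which decay stage by stage, so the stage SNR rises as residue
energy falls. The default (`snr_increase=False`) renormalises each noise
mode to unit standard deviation, holding the stage SNR constant; on the
square-wave fixtures this variant separates the 6 h / 12 h slow modes of the
3 h:3 h regime more cleanly, which is why it is the default even though the
rising-SNR schedule is the more commonly described one. Determinism: a
single master seed drives one generator from which all realisation streams
derive.

IMF condition tolerance: ensemble-averaged modes may mildly violate the
extrema/zero-crossing balance; a mismatch of ≤ 2 is accepted on ICEEMDAN
outputs (≤ 1 is enforced for plain EMD sifting).

## Hilbert spectral analysis

The analytic signal of each IMF is built with the FFT-based discrete
Hilbert transform (`scipy.signal.hilbert`), exact quadrature for pure tones
on periodic windows. The instantaneous frequency is the five-point centred
finite difference of the unwrapped phase — the minimum-stencil heuristic
that also sets the stability cap f_max = 1/(4Δt), i.e. 2.1 mHz at
Δt = 120 s — median-filtered with window 5 to suppress differentiation
noise. Estimates that are non-positive or above f_max are masked, never
clipped: negative instantaneous frequencies signal a locally asymmetric
mode, not a measurable rhythm. The first and last 2 % of samples are masked
for all frequency statistics (edge effect of both the spline envelopes and
the FFT transform).

The Hilbert spectrum deposits a_k(t) at (t, ω_k(t)) over all modes —
excluding the residue, whose energy would dominate the oscillatory modes —
on 256 log-spaced frequency bins between 1/span and f_max. The marginal
spectrum integrates over time with a rectangle rule on the sample grid, so
Σh = (total deposited energy)·Δt holds to round-off and is asserted at
1e-6 relative tolerance.

A mode's band is summarised by the 5th/50th/95th percentiles of its
masked-in instantaneous frequency (f_min, f_mid, f_max); the median period
is 1/f_mid. A band is marked NM (not meaningful) when more than half the
samples are masked — the criterion used for modes whose content lies mostly
above f_max or whose frequency estimates are unstable. Band edges from
different derivative/smoothing choices shift by a few percent; they should
be read as approximate.

## Rhythm summaries

Peaks are detected with prominence ≥ 0.2 × mode range by default; tri-peak
FM modes need 0.05 (three unequal peaks per period, the smallest of which
has low prominence). Peaks are annotated with the nearest dawn/dusk and
grouped per light–dark period; per-ordinal peak-to-peak durations are
averaged across periods, and periods whose peak count deviates from the
modal count are dropped with a warning. Both the peak-to-peak spacing and
the median instantaneous period are reported and never merged: under dusk
phase-resetting the former entrains to the schedule while the latter
reflects the oscillator's free-running period.

Condition comparisons match modes between two decompositions by nearest
f_mid/f_Iv ratio (within 50 % relative), then report Δperiod of the median
periods, Δphase as the circular difference of mean peak phases within the
light–dark period, the ratio of mean per-period amplitude maxima, and a
trend ratio of mean |residue| — the norm used for "fold-change of the
basal level" statements.

## Synthetic data

The generator emulates the statistical structure of BPV recordings, not
their biochemistry:

* **Square waves** lock exactly to the light schedule (baseline in dark,
  baseline + amplitude in light; the sample at or after a transition takes
  the new level). The canonical fixtures span 36 h (3 h:3 h) and 96 h
  (12 h:12 h) at Δt = 120 s with amplitude 60 µA m⁻² on a 20 µA m⁻²
  baseline — spans and scale chosen to match typical multi-day recordings
  in each regime; both are configurable.
* **BPV profiles** sum five components, returned individually for recovery
  tests: a saturating growth trend level·(1 − e^{−rate·t}); a zero-mean
  first-order low-pass response to the light square wave (default time
  constant 0.3 h, emulating the delay between light switching and
  biochemical activation — the DC of the light response belongs to the
  trend); a circadian sinusoid with free-running period `frp_h` (default
  25.8 h, the free-running period of *S. elongatus* at low light), whose
  phase can be re-anchored at every dusk so the peak-to-peak spacing
  entrains to the schedule while the instantaneous period stays at the free
  run — the mechanism proposed for dark-pulse resetting; a tri-peak
  raised-cosine FM component (three peaks per period at configurable dawn
  offsets and relative heights, per-period mean removed); and i.i.d.
  Gaussian noise (no instrument noise model is published for these
  devices, so white noise of configurable sd is used).
* **Condition presets** apply, relative to the iron-replete control
  (`FePlusAir`): `FeMinusAir` — amplitude scale 0.6, free-running period
  −1.1 h, phase advance π/4 toward dawn, trend ×2; `FeMinusCO2` —
  amplitude scale 0.5, period −1.2 h, phase shift π (inverting the light
  response: dark current exceeds photocurrent), trend ×2. The period,
  phase and trend factors sit inside the ranges reported for iron-depleted
  and CO₂-enriched biofilms; the trend factor uses the lower end (1.8–5.7×
  is reported early in operation) so amplitude and trend effects remain
  separately resolvable.

What passing tests show — and don't. Recovery of configured parameters from
these profiles demonstrates that the pipeline separates timescale-disjoint
components and measures their rhythms correctly. Real recordings add
features the generator omits: non-Gaussian electrochemical noise, slow
amplitude decay tied to nutrient depletion, mode mixing from irregular
transients, and drifts in the light response. Tests on synthetic data
therefore validate the estimator chain, not the biological conclusions
drawn from any particular recording.

## Square-wave reference behaviour and known limitations

On the 3 h:3 h fixture the decomposition yields an entrained 6.0 h
sinusoidal mode (median period 6.09 h), a frequency-modulated tri-peak mode
with ~2.1 h / ~1.9 h peak spacings, fast edge-wavelet modes at the light
transitions, and a low-energy slow mode near 10 h; on the 12 h:12 h fixture
the diel mode appears at 24–25 h and the tri-peak mode's first-to-second
peak spacing is ~9.8 h. Two artifacts are known and documented rather than
patched:

* the three near-Nyquist edge-wavelet scales tend to merge into a single
  fast mode, and the diel component of the 96 h fixture can split across
  two adjacent modes (~21.5 h and ~25.2 h) — both are manifestations of
  mode mixing/splitting, which is sensitive to the sift stop criterion and
  envelope details and differs between EMD implementations;
* a trailing near-zero-energy mode (≲ 0.1 % of total energy) appears for
  some noise seeds, so the raw mode count can vary by one between seeds.
  No energy floor is applied: the count reported is the count produced.

Problem sizes throughout (fixture spans, ensemble sizes in tests) were
chosen so the full decomposition study runs in minutes on a single core;
the unit and property tests use smaller ensembles (I = 20–50) where the
assertions concern properties that are stable well below I = 500.
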