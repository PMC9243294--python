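# bpvhht — Hilbert–Huang analysis of biophotovoltaic current-density rhythms

Biophotovoltaic (BPV) devices generate electrical current from photosynthetic
microorganisms such as the cyanobacterium *Synechococcus elongatus*. Under a
periodic light–dark schedule the measured current density J(t) is a
superposition of processes on very different timescales: a slow growth trend
of the biofilm's basal exoelectrogenic activity, a light-entrained
photoresponse with finite biochemical rise times, near-diel oscillations
whose free-running period reveals circadian control, fast transients at each
light change, and measurement noise. These components are nonstationary and
nonlinear, so Fourier-based analysis blurs them together.

`bpvhht` decomposes such recordings with the Hilbert–Huang transform:

1. **ICEEMDAN** (improved complete ensemble empirical mode decomposition with
   adaptive noise) splits J(t) into intrinsic mode functions (IMFs)
   d̃₁…d̃_K — each an oscillation of one characteristic timescale satisfying
   the IMF conditions (extrema and zero-crossing counts differ by ≤ 1;
   envelope mean ≈ 0) — plus a monotone residue r_K (the trend), with exact
   additive reconstruction X(t) = Σ d̃_k(t) + r_K(t).
2. **Hilbert spectral analysis** forms the analytic signal
   Z(t) = X(t) + iY(t) = a(t)·e^{iθ(t)} of each IMF; a(t) is the
   instantaneous energy and ω(t) = dθ/dt the instantaneous frequency,
   reliable up to f_max = 1/(nΔt) (n = 4 sampling intervals for the
   five-point derivative heuristic; 2.1 mHz at the 120 s sampling used in
   BPV chronoamperometry). Modes combine into the Hilbert spectrum H(ω, t)
   and the marginal spectrum h(ω) = ∫ H(ω, t) dt.
3. **Rhythm summaries** report, per mode, the frequency band
   (f_min/f_mid/f_max), the ratio f_mid/f_Iv to the entrainment frequency of
   the applied light–dark cycle, the median period 1/median(ω), peak timings
   relative to dawn and dusk, peak-to-peak durations (mean ± SE across
   periods), amplitude trends, and between-condition comparisons (phase
   shifts, period shortening, trend magnification).

A fully parameterised synthetic-data module generates square-wave control
signals and BPV-like profiles with known ground-truth components (trend,
entrained response, free-running circadian sinusoid with optional phase
reset at dusk, tri-peak FM mode, Gaussian noise) plus condition presets
emulating iron depletion and a 20 % CO₂ atmosphere, so the whole pipeline is
testable without instrument data.

## Worked example

Simulate a week-long control profile under a 3 h:3 h light–dark cycle with a
25.8 h free-running circadian component, decompose it, and summarise the
modes:

```python
import numpy as np
from bpvhht import (LightSchedule, BPVProfileParams, PRESETS,
                    generate_bpv_profile, ICEEMDANConfig, iceemdan,
                    analytic_signal, summarize_mode, band_table)

sched = LightSchedule(light_h=3, dark_h=3)
params = BPVProfileParams(schedule=sched, duration=168 * 3600, frp_h=25.8,
                          reset_at_dusk=False, noise_sd=0.3, seed=0)
profile = generate_bpv_profile(params, PRESETS["FePlusAir"])
result = iceemdan(profile.signal, ICEEMDANConfig(n_realisations=50, seed=2))
print(f"{result.k} IMFs extracted")
summaries = [summarize_mode(imf, analytic_signal(imf, result.dt),
                            result.t, sched, i + 1)
             for i, imf in enumerate(result.imfs)]
print(band_table(summaries, sched).to_string(index=False))
```

Output:

```
7 IMFs extracted
 imf  f_min_mHz  f_max_mHz  f_mid_mHz  f_mid/f_Iv  median_period_h    NM
   1        NaN        NaN        NaN         NaN              NaN  True
   2      0.287      1.376      0.782       16.89             0.36 False
   3      0.143      0.450      0.265        5.73             1.05 False
   4      0.116      0.179      0.134        2.90             2.07 False
   5      0.042      0.051      0.046        0.99             6.05 False
   6      0.002      0.026      0.017        0.37            16.28 False
   7      0.009      0.011      0.011        0.23            26.05 False
```

Mode 5 is the light-entrained oscillation: its band midpoint sits at the
schedule frequency (f_mid/f_Iv ≈ 1, 0.046 mHz ↔ 6.0 h). Mode 7 recovers the
configured circadian component — its 26.05 h median period estimates the
25.8 h free-running period despite the 6 h entrainment riding on top. Mode 1
is flagged NM (not meaningful): it holds the fast noise whose instantaneous
frequency is mostly above the 2.1 mHz stability cap. The residue (not shown)
carries the growth trend.

The same pipeline is available from the shell:

```sh
bpvhht simulate --regime 3h --preset FePlusAir --seed 0 --out profile.csv
bpvhht decompose profile.csv --ensembles 500 --seed 1 --out imfs.csv
bpvhht spectrum imfs.csv --out marginal.csv
bpvhht summarize imfs.csv --config sched.yaml --out summary.csv
```

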