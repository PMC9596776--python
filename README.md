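# stimartifact

Characterization and dipole modeling of electrical stimulation artifacts in
subdural ECoG recordings.

## The problem

Bi-directional brain-computer interfaces must record cortical activity while
delivering electrical stimulation through the same subdural grid. The injected
current contaminates every nearby electrode with artifacts that are orders of
magnitude larger than neural signals (tens of microvolts) and can saturate
low-power amplifier front-ends outright. Designing such systems — choosing
stimulation currents, electrode spacing, and front-end headroom — requires
knowing how far and how strongly artifacts propagate.

This package implements that characterization as a tested pipeline over
simulated bedside mapping sessions: 512 Hz multichannel recordings of 50 Hz
biphasic pulse trains (200–250 µs phase width, 2–12 mA) delivered through one
bipolar channel of a 4×5 standard (10 mm pitch) or 4×8 high-density (3–4 mm
pitch) grid. It covers:

- **Time domain** — zero-phase 1.5 Hz first-order Butterworth high-pass,
  epoch segmentation with duration-matched baselines, exclusion of the
  stimulation pair and of channels hitting the ±8.7 mV amplifier rail,
  per-pulse signed extremum amplitudes, ratcheting DC-drift quantification,
  and phase-locking statistics.
- **Frequency domain** — five-segment periodogram PSDs of stimulation and
  baseline epochs, the interference index
  `I(f) = ½·ln(σ_t²(f) / (σ_on(f)·σ_off(f)))` (a deflection-coefficient
  variant), and exact per-frequency two-sample Kolmogorov–Smirnov tests.
- **Spatial domain** — median artifact maps per epoch, piecewise-linear
  interpolation over the grid plane, the ±1,100 µV saturation region
  (2.2 V supply behind 66 dB gain) and the worst-case distance (WCD) from
  the stimulation-channel midpoint to the saturation contour.
- **Dipole model** — the lumped volume-conduction model

  `V_e = k·I·(1/‖r_e − r₊‖ − 1/‖r_e − r₋‖) + n`

  with slope `k` (Ω·mm, lumping conductivity, path geometry and interface
  impedance) and intercept `n` (µV, reference placement and background
  activity), fitted by ordinary least squares pooling all electrodes and
  currents of a stimulation channel, with R² goodness-of-fit and predicted
  artifact maps.
- **Electrode localization** — thresholding of CT-like intensity volumes,
  DBSCAN clustering, centroiding, and voxel-to-mm scaling.
- **Synthetic sessions** — a seeded generator producing all of the above
  inputs with ground truth attached: dipole-propagated single-sample pulse
  artifacts, ratcheting drift with seconds-scale decay, pink background
  noise, amplifier clipping, and CT-like volumes.

## Worked example

```sh
python analysis/01_simulate_session.py   # write the reference session
python analysis/02_time_domain.py
python analysis/04_spatial_maps.py
python analysis/05_dipole_fit.py
```

The time-domain step prints, per epoch (seed 0, defaults):

```
 amplitude_mA  n_pulses  median_iri_ms  phase_lock_offset_ms  ratchet_drift_raw_uv
        2.000       250         19.531                 0.000              -945.024
       10.000       250         19.531                 0.000              4410.744
```

Each 5 s epoch yields exactly 250 pulse responses recurring at the 20 ms
pulse period (quantized to 10 samples = 19.53 ms at 512 Hz); extrema across
the four strongest electrodes align to the same sample (phase-locked); the
raw DC drift grows with current and is removed by the 1.5 Hz high-pass.
The spatial step reports the saturation region growing with current:

```
   6 mA: no saturation region
   8 mA: WCD  16.34 mm (region reaches grid edge)
  10 mA: WCD  19.11 mm (region reaches grid edge)
```

and the dipole fit recovers the generator's parameters:

```
full pipeline fit: k = 3.086 Ohm mm, n = 2.7 uV, R^2 = 0.9996 (90 pooled points)
noiseless recovery:  k = 3.300000 Ohm mm (truth 3.3), R^2 = 1.000000
```

The full-pipeline slope sits a few percent below the generator's
k = 3.3 Ω·mm because the zero-phase high-pass removes the pulse train's
local mean — an attenuation common to all electrodes, hence R² ≈ 1 (see
`docs/methods.md`).

There is also a CLI over the same library (`stimartifact simulate`,
`localize`, `characterize`, `map`, `fitdipole`, `report`).

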