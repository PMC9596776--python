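# Methods

This note documents the models, numerical choices and limitations behind
`stimartifact`. Units throughout: voltages in µV, distances in mm, currents
in mA, times in s.

## The dipole forward model

Artifact propagation through cortical tissue is modelled as the potential
of a current source/sink pair in a homogeneous, isotropic, purely resistive
medium. The measured artifact amplitude at electrode *e* is

    V_e = k · I · (1/‖r_e − r₊‖ − 1/‖r_e − r₋‖) + n

with `k` in Ω·mm and `I` in mA, so `k·I/d` is in mV; the implementation
carries voltages in µV via an explicit ×1000 factor. `k` lumps the medium
conductivity, current-path geometry, electrode size/material and the
electrode–tissue interface impedance; `n` absorbs the reference-electrode
placement and background activity, and is fitted per stimulation channel.
The model is origin-free: regressors, fits and predictions are invariant
under rigid motions of all coordinates (property-tested).

Because the pulses are biphasic, the source/sink labeling of the pair is
observationally arbitrary: the fit runs unconstrained and is canonicalized
to k̂ ≥ 0 by swapping the pole assignment when the estimated slope is
negative. One fit pools all (electrode, current) observations of a
stimulation channel — stimulation-pair and saturated electrodes excluded —
and R² = 1 − SS_res/SS_tot is computed on the pooled points.

## The synthetic session generator

`synth.simulate_session` emulates a bedside mapping session. Defaults are
the study conditions, not tuning knobs:

| parameter | default | rationale |
|---|---|---|
| sampling rate | 512 Hz | clinical acquisition rate |
| pulse train | 50 Hz, 200 µs phase width | mapping-stimulator settings |
| epochs | 5 s per amplitude, ≥ 5 s baseline before each | upper end of the 2–5 s clinical range; duration-matched baselines |
| amplitudes | 2, 4, 6, 8, 10 mA | the typical 2 mA-increment ladder |
| grid | 4×5, 10 mm pitch (4×8, 3 mm pitch available) | standard vs high-density layouts |
| k_true | 3.3 Ω·mm | centre of the 2.1–3.9 Ω·mm range that the fits recover across subjects |
| n_true | 0 µV | intercept is reference-dependent; zero is the neutral choice |
| noise | pink (1/f), SD 20 µV | ECoG background is tens of µV with 1/f-like spectra |
| ratcheting | 6 µV/mA per pulse, τ = 2 s | see below |
| clipping | ±8711 µV | clinical amplifier saturation limit |

**Pulse rendering.** A 200–250 µs biphasic phase is ~10× shorter than the
1953 µs sample interval, so each pulse is rendered as a single-sample
signed impulse of amplitude `A_e` (the forward model above) at the sample
nearest the pulse onset. This reproduces exactly what a 512 Hz acquisition
records of such a pulse; no supersampled waveform is needed. A consequence
is phase-locking *by construction*: all electrodes receive pulse *j* at the
same sample.

**Ratcheting.** Charge-balanced biphasic pulses still leave a residual
potential when irreversible Faradaic reactions consume charge during one
phase. The generator models this as a per-pulse step of
`ratchet_step · I · sign(A_e)` decaying exponentially with τ = 2 s
(implemented as a one-pole IIR over the pulse-impulse train). Since pulses
arrive every 20 ms ≪ τ, the steps accumulate into a DC drift whose
steady-state magnitude is ≈ `ratchet_step·I·f_pulse·τ` ≈ 100·`ratchet_step`·I,
several-fold larger than the per-pulse amplitude at the highest currents —
large enough to occasionally drive neighbours of the stimulation pair into
the rails. The drift polarity follows the electrode's side of the dipole.
No quantitative drift magnitude is available to calibrate against, so these
are qualitative-realism choices, fixed once.

**Stimulation channels.** The pair's own channels are pinned at ±clip_limit
during their epochs: on clinical hardware they saturate and record nothing
usable. They are always excluded from analysis and from interpolation.

**Determinism.** All randomness flows from one integer seed through a named
`numpy` generator; identical config + seed ⇒ bit-identical recordings.

## Time-domain stage

- **High-pass:** first-order Butterworth at 1.5 Hz applied
  forward-backward (zero phase). Edges are reflect-padded by three filter
  time constants (≈ 0.32 s at 1.5 Hz) to suppress startup transients. The
  two-pass gain at 50 Hz is 1/(1+(1.5/50)²) ≈ 0.9991.
- **Windows:** sample windows are half-open `[round(start·fs),
  round(end·fs))` with round-half-to-even; baselines are the same length
  immediately before the epoch and must not overlap any stimulation epoch.
- **Extrema:** the epoch is tiled into consecutive windows of one pulse
  period anchored at the epoch start (no realignment to a stimulator
  clock); each window contributes the signed value of its
  largest-magnitude sample. The count is exactly `floor(duration·f_pulse)`
  regardless of content. Extremum *signs* are kept — the dipole fit needs
  signed V_e.
- **Drift:** quantified on the *raw* epoch as (mean of last 10%) − (mean of
  first 10%) of samples; all other stages consume filtered data.

**Filter attenuation of impulse extrema.** A zero-phase high-pass removes
the local mean of the 50 Hz impulse train, which for single-sample impulses
is ≈ A_e/10.24 (one part per inter-pulse sample count); detected extrema
are therefore scaled by ≈ 0.90 uniformly across electrodes. This biases k̂
of the *filtered* pipeline a few percent low while leaving R² and n̂
untouched; on real recordings the same scaling is invisible because it is
absorbed into the lumped k. Recovery experiments that generate no drift
(noise-only or noiseless sessions) therefore run the detector on unfiltered
data, where recovery of (k_true, n_true) is exact to machine precision.

**Sampling quantization of intervals.** At 512 Hz the 20 ms pulse period is
10.24 samples, so detected response times have median spacing 10 samples =
19.53 ms. The nominal 20 ms is reproduced at integer-ms precision; the
0.47 ms deficit is pure sample quantization, not a detector property.

## Spectral stage

Each epoch and its baseline are split into 5 equal, non-overlapping
segments (trailing remainder dropped); each segment gets a plain
rectangular-window periodogram with density scaling (one-sided, interior
bins doubled; `detrend=False`). Means and SDs across the 5 segments enter
the interference index

    I(f) = ½·ln( σ_t²(f) / (σ_on(f)·σ_off(f)) ),
    σ_t² = (σ_on² + σ_off²)/2 + (μ_on − μ_t)²/2 + (μ_off − μ_t)²/2,
    μ_t = (μ_on + μ_off)/2.

By AM–GM, I(f) ≥ 0 with equality iff the on/off distributions agree in
mean and variance; the implementation clips the tiny negative values that
floating-point cancellation can produce and flags bins with zero segment
SD as degenerate (+∞). The natural log is used; any base is a monotone
rescaling that moves no peak. SDs use the unbiased (n−1) denominator.

Per-frequency significance uses an exact two-sample KS test: with 5 + 5
segment powers, all C(10,5) = 252 label assignments are enumerated and the
p-value is the fraction of splits with D ≥ D_obs (for tie-free data a
precomputed null distribution is reused; ties fall back to enumerating the
actual values). Fully separated samples give p = 2/252 ≈ 0.0079. The
significance threshold is inclusive (p ≤ α): exact p-values are discrete,
and a level of 1 must flag every bin. No multiple-testing correction is
applied across bins. scipy's exact KS implementation serves as an
independent cross-check in the test suite, not as the implementation.

## Spatial stage

Median signed per-pulse amplitude per included electrode forms the epoch's
artifact map. Included positions are projected onto their least-squares
plane (SVD); the map is interpolated piecewise-linearly on a Delaunay
triangulation of the projected points and rasterized at 0.5 mm (0.25 mm
recommended for high-density grids). No extrapolation happens beyond the
electrode convex hull — corner and edge stimulation channels genuinely
under-sample their field, and the code surfaces `clipped_at_hull` instead
of guessing. Excluded electrodes contribute no interpolation nodes; values
at their positions come from neighbours.

The saturation region is the interior of the |V| = 1100 µV contour
(marching squares on the raster), the input-referred limit of a 2.2 V
supply behind 66 dB (2000×) gain. The WCD is the maximum 2-D plane
distance from the projected stimulation-channel midpoint to any contour
point. If no raster point reaches the limit the region is empty and WCD
is 0 — low-current epochs on the standard grid legitimately produce no
saturation region because the interpolated field between the neighbours of
the (excluded) stimulation pair stays below the limit. Because contouring
happens on a plane-aligned raster, rigid motions can move the WCD by up to
one raster cell; tests allow exactly that.

Fit statistics across stimulation channels are summarized as median and
raw MAD (median |x − median|), robust to the outliers contributed by
corner/edge channels.

## Electrode localization

Thresholding (default: robust background median + 5·MAD-SD) keeps the
bright metal voxels; DBSCAN (eps = 2 voxels, min_pts = 4 — blobs are
compact and separated by at least one pitch) clusters them one-per-
electrode; cluster centroids are unweighted voxel means
(intensity-weighting available); physical coordinates are the
componentwise product of centroid and voxel dimensions, with the volume
origin at voxel (0,0,0) and 0-based indices. Labels are assigned
row-major along the point set's principal axes — real grids are labeled
clinically, so recovered labels are positional only. MR co-registration
and brain segmentation are out of scope (external tools).

## Electrode-interface phase model

The apparent phase-locking is explained by interface phase shifts falling
below one sample. The interface is modelled as a double-layer resistance
R_dl ∥ capacitance C (15 µF/cm² over the exposed disc area, 1.5 mm
diameter by default) in series with an electrolyte resistance R_s = 150 Ω,
feeding the amplifier input impedance R_in = 1 GΩ. The per-frequency delay
−arg(H)/ω of the divider H(ω) = R_in/(R_in + R_s + R_dl/(1 + jωR_dl·C))
is in the microsecond range over 0–200 Hz — three orders of magnitude
below the 1.95 ms sample interval. R_dl = 100 kΩ is an assumption (no
measured value is available) and is exposed as a parameter.

## What the synthetic data does and does not show

The generator reproduces the *mechanisms* — dipole spatial decay,
ratcheting, clipping, phase-locking, harmonic structure — under idealized
conditions: a perfectly planar grid, exactly periodic pulses, tissue
homogeneity, and a current-independent k. Passing tests demonstrate that
the pipeline recovers what the forward model put in; they do not
demonstrate tissue-level validity. In particular the generator has no
neural evoked responses, no tissue inhomogeneity/anisotropy, no nonlinear
interface behaviour at high current, and single-sample pulses rather than
measured pulse-response shapes. Population statistics from clinical
recordings (per-subject WCD ranges, k̂/n̂/R² tables) are consequently out
of scope; the package checks its simulated WCDs only against the plausible
4.43–38.34 mm envelope, and only for epochs that produce a saturation
region at all.

## Problem sizes

Default analyses use one 20-channel 4×5 session of five 5 s epochs
(~28k samples/channel); the noisy parameter-recovery study uses 100 seeded
sessions; localization recovery uses ten 20-blob volumes of ~60×70×26
voxels. The full test suite runs in well under a minute on one core.
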