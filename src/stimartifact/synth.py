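"""Synthetic ECoG sessions with dipole-propagated stimulation artifacts.

The generator emulates a bedside cortical-mapping recording: a planar
subdural grid, a 50 Hz biphasic pulse train delivered through one bipolar
channel at several current amplitudes, and the artifact features seen on
clinical amplifiers — dipole-shaped per-pulse deflections, a ratcheting DC
drift that builds over each epoch, amplifier clipping, and 1/f background
noise.  Every run is reproducible from a single integer seed.

Pulse phases (200-250 us) are far shorter than the 512 Hz sample interval
(~1953 us), so each biphasic pulse is rendered as a single-sample signed
impulse at the sample nearest its onset: that is what a 512 Hz acquisition
records of such a pulse.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import signal as _signal

from .core import ElectrodeSet, EpochAnnotation, Recording

__all__ = [
    "GridSpec", "SimConfig", "GroundTruth", "CTVolume",
    "make_grid", "standard_grid", "high_density_grid",
    "dipole_amplitudes", "simulate_session", "synth_ct",
]


@dataclass(frozen=True)
class GridSpec:
    """Geometry of a rectangular subdural grid."""

    n_rows: int = 4
    n_cols: int = 5
    pitch: float = 10.0  # mm centre-to-centre
    electrode_diameter: float = 4.0  # mm
    exposure_diameter: float = 2.3  # mm
    label_prefix: str = "G"

    def __post_init__(self):
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("grid must have at least one row and column")
        if self.pitch <= 0:
            raise ValueError("pitch must be positive")
        if self.exposure_diameter > self.electrode_diameter:
            raise ValueError("exposure diameter cannot exceed electrode diameter")


def make_grid(spec: GridSpec,
              origin: Sequence[float] = (0.0, 0.0, 0.0),
              basis: Optional[Tuple[Sequence[float], Sequence[float]]] = None,
              ) -> ElectrodeSet:
    """Lay out ``n_rows x n_cols`` electrodes on a plane.

    Labels are row-major ``prefix + index`` starting at 1; adjacent
    electrodes within a row are ``pitch`` mm apart.  ``basis`` gives the
    in-plane row/column directions (defaults to the x/y axes); the two
    vectors must not be collinear.
    """
    origin = np.asarray(origin, dtype=float).reshape(3)
    if basis is None:
        u, v = np.array([1.0, 0.0, 0.0]), np.array([0.0, 1.0, 0.0])
    else:
        u = np.asarray(basis[0], dtype=float).reshape(3)
        v = np.asarray(basis[1], dtype=float).reshape(3)
    if np.linalg.norm(np.cross(u, v)) < 1e-12 * max(np.linalg.norm(u), 1.0) * max(np.linalg.norm(v), 1.0):
        raise ValueError("grid basis vectors are collinear")
    u = u / np.linalg.norm(u)
    # Gram-Schmidt so rows and columns are orthogonal even for a skew basis
    v = v - (v @ u) * u
    v = v / np.linalg.norm(v)

    labels, positions = [], []
    k = 1
    for r in range(spec.n_rows):
        for c in range(spec.n_cols):
            labels.append(f"{spec.label_prefix}{k}")
            positions.append(origin + spec.pitch * (c * u + r * v))
            k += 1
    return ElectrodeSet(labels, np.asarray(positions))


def standard_grid(**overrides) -> ElectrodeSet:
    """4x5 grid with 10 mm pitch (the clinical 'standard' layout)."""
    return make_grid(GridSpec(**{**dict(n_rows=4, n_cols=5, pitch=10.0), **overrides}))


def high_density_grid(**overrides) -> ElectrodeSet:
    """4x8 grid with 3 mm pitch (the 'high-density' layout)."""
    defaults = dict(n_rows=4, n_cols=8, pitch=3.0,
                    electrode_diameter=2.0, exposure_diameter=1.0)
    return make_grid(GridSpec(**{**defaults, **overrides}))


@dataclass(frozen=True)
class SimConfig:
    """Stimulation-session parameters.

    Defaults mirror a typical mapping session on a standard grid: 512 Hz
    acquisition, 50 Hz pulse train of 200 us phase width, 5 s epochs at
    2-10 mA in 2 mA steps, dipole slope k_true = 3.3 Ohm mm with zero
    intercept, 20 uV pink background noise, a ratcheting step of 6 uV/mA
    per pulse decaying with a 2 s time constant (several-fold larger than
    the per-pulse amplitude once accumulated at the highest currents), and
    clipping at +/-8711 uV.  ``clip_limit=None`` disables clipping.
    """

    fs: float = 512.0
    pulse_freq: float = 50.0
    pulse_width_us: float = 200.0
    epoch_duration: float = 5.0
    baseline_gap: Optional[float] = None  # defaults to epoch_duration
    amplitudes: Tuple[float, ...] = (2.0, 4.0, 6.0, 8.0, 10.0)
    k_true: float = 3.3  # Ohm mm
    n_true: float = 0.0  # uV
    noise_sd: float = 20.0  # uV
    ratchet_step: float = 6.0  # uV per mA per pulse
    ratchet_tau: float = 2.0  # s
    clip_limit: Optional[float] = 8711.0  # uV
    stim_pair: Tuple[str, str] = ("G8", "G9")
    seed: int = 0

    def __post_init__(self):
        if self.fs <= 2 * self.pulse_freq:
            raise ValueError("fs must exceed twice the pulse frequency")
        if self.epoch_duration <= 0:
            raise ValueError("epoch_duration must be positive")
        gap = self.epoch_duration if self.baseline_gap is None else self.baseline_gap
        if gap < self.epoch_duration:
            raise ValueError("baseline_gap must be >= epoch_duration")
        if any(a <= 0 for a in self.amplitudes):
            raise ValueError("all stimulation amplitudes must be positive")
        if self.ratchet_tau <= 0:
            raise ValueError("ratchet_tau must be positive")
        if self.clip_limit is not None and self.clip_limit <= 0:
            raise ValueError("clip_limit must be positive (or None)")
        object.__setattr__(self, "amplitudes", tuple(float(a) for a in self.amplitudes))
        object.__setattr__(self, "stim_pair", tuple(self.stim_pair))

    @property
    def gap(self) -> float:
        return self.epoch_duration if self.baseline_gap is None else self.baseline_gap


@dataclass(eq=False)
class GroundTruth:
    """Everything the generator knows: the answer key for downstream stages."""

    epochs: List[EpochAnnotation]
    pulse_onsets: List[np.ndarray]  # s, one array per epoch
    pulse_amplitudes: List[Dict[str, float]]  # uV per electrode per epoch
    k_true: float
    n_true: float
    electrodes: ElectrodeSet
    stim_pair: Tuple[str, str] = ("", "")

    def __post_init__(self):
        starts = np.array([e.start for e in self.epochs])
        ends = np.array([e.end for e in self.epochs])
        order = np.argsort(starts)
        for i, j in zip(order[:-1], order[1:]):
            if ends[i] > starts[j]:
                raise ValueError("epochs overlap")


def dipole_amplitudes(electrodes: ElectrodeSet, stim_pair: Sequence[str],
                      k: float, current: float) -> Dict[str, float]:
    """Forward model: per-electrode signed impulse amplitude in uV.

    ``A_e = 1000 * k * I * (1/|r_e - r_plus| - 1/|r_e - r_minus|)`` with k
    in Ohm mm, I in mA and distances in mm (k*I/d is mV, hence the 1000).
    The stimulation electrodes themselves are assigned 0 (they saturate and
    are handled separately).
    """
    r_plus = electrodes.position_of(stim_pair[0])
    r_minus = electrodes.position_of(stim_pair[1])
    out: Dict[str, float] = {}
    for lab, pos in zip(electrodes.labels, electrodes.positions):
        if lab in (stim_pair[0], stim_pair[1]):
            out[lab] = 0.0
            continue
        d_plus = float(np.linalg.norm(pos - r_plus))
        d_minus = float(np.linalg.norm(pos - r_minus))
        out[lab] = 1000.0 * k * current * (1.0 / d_plus - 1.0 / d_minus)
    return out


def _pink_noise(rng: np.random.Generator, shape: Tuple[int, int],
                sd: float) -> np.ndarray:
    """1/f-power noise, per-channel SD normalised to ``sd`` uV."""
    n_ch, n = shape
    if sd == 0 or n == 0:
        return np.zeros(shape)
    white = rng.standard_normal(shape)
    spec = np.fft.rfft(white, axis=1)
    f = np.fft.rfftfreq(n)
    scale = np.zeros_like(f)
    scale[1:] = 1.0 / np.sqrt(f[1:])
    x = np.fft.irfft(spec * scale, n=n, axis=1)
    x -= x.mean(axis=1, keepdims=True)
    s = x.std(axis=1, keepdims=True)
    s[s == 0] = 1.0
    return sd * x / s


def simulate_session(config: SimConfig, electrodes: ElectrodeSet,
                     ) -> Tuple[Recording, GroundTruth]:
    """Simulate one stimulation session.

    Each configured amplitude gets one epoch, preceded by a stimulation-free
    baseline of at least ``epoch_duration``.  The stimulation-pair channels
    are pinned at +/-clip_limit during their epochs (they saturate on the
    clinical amplifier and record no usable data).  Identical config and
    seed give bit-identical output.
    """
    a_lab, c_lab = config.stim_pair
    for lab in (a_lab, c_lab):
        if lab not in electrodes.labels:
            raise ValueError(f"stimulation electrode {lab!r} not in ElectrodeSet")
    pair_dist = float(np.linalg.norm(electrodes.position_of(a_lab)
                                     - electrodes.position_of(c_lab)))
    if len(electrodes) > 2:
        d = electrodes.positions[:, None, :] - electrodes.positions[None, :, :]
        dist = np.linalg.norm(d, axis=2)
        np.fill_diagonal(dist, np.inf)
        nn = float(dist.min())
        if pair_dist > 1.5 * nn:
            warnings.warn("stimulation pair is not adjacent on the grid",
                          stacklevel=2)

    fs, pf = config.fs, config.pulse_freq
    gap, dur = config.gap, config.epoch_duration

    epochs: List[EpochAnnotation] = []
    t = gap
    for amp in config.amplitudes:
        epochs.append(EpochAnnotation(start=t, end=t + dur,
                                      stim_pair=config.stim_pair,
                                      amplitude=amp, pulse_freq=pf,
                                      pulse_width_us=config.pulse_width_us))
        t += dur + gap
    total = t  # trailing gap doubles as post-session baseline
    n_samples = int(round(total * fs))
    n_ch = len(electrodes)

    rng = np.random.default_rng(config.seed)
    samples = _pink_noise(rng, (n_ch, n_samples), config.noise_sd)
    samples += config.n_true

    onsets_per_epoch: List[np.ndarray] = []
    amps_per_epoch: List[Dict[str, float]] = []
    ratchet_drive = np.zeros((n_ch, n_samples))
    for ep in epochs:
        amps = dipole_amplitudes(electrodes, ep.stim_pair, config.k_true,
                                 ep.amplitude)
        amps_per_epoch.append(amps)
        n_pulses = int(np.floor(ep.duration * pf))
        onsets = ep.start + np.arange(n_pulses) / pf
        onsets_per_epoch.append(onsets)
        idx = np.round(onsets * fs).astype(int)
        idx = idx[idx < n_samples]
        for ch, lab in enumerate(electrodes.labels):
            a_e = amps[lab]
            if a_e == 0.0:
                continue
            samples[ch, idx] += a_e
            if config.ratchet_step:
                ratchet_drive[ch, idx] += (config.ratchet_step * ep.amplitude
                                           * np.sign(a_e))

    if config.ratchet_step:
        # each pulse leaves a residual step decaying with tau: one-pole IIR
        a = np.exp(-1.0 / (fs * config.ratchet_tau))
        samples += _signal.lfilter([1.0], [1.0, -a], ratchet_drive, axis=1)

    if config.clip_limit is not None:
        np.clip(samples, -config.clip_limit, config.clip_limit, out=samples)
        pin = config.clip_limit
    else:
        pin = 8711.0
    # stimulation channel saturates rail-to-rail during its epochs
    ia, ic = electrodes.index_of(a_lab), electrodes.index_of(c_lab)
    for ep in epochs:
        s0 = int(round(ep.start * fs))
        s1 = min(int(round(ep.end * fs)), n_samples)
        samples[ia, s0:s1] = pin
        samples[ic, s0:s1] = -pin

    rec = Recording(samples, fs, list(electrodes.labels))
    gt = GroundTruth(epochs=epochs, pulse_onsets=onsets_per_epoch,
                     pulse_amplitudes=amps_per_epoch, k_true=config.k_true,
                     n_true=config.n_true, electrodes=electrodes,
                     stim_pair=config.stim_pair)
    return rec, gt


@dataclass(eq=False)
class CTVolume:
    """3-D intensity array with physical voxel dimensions in mm/voxel."""

    intensities: np.ndarray
    voxel_dims: np.ndarray  # (3,) mm per voxel

    def __post_init__(self):
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.intensities.ndim != 3 or self.intensities.size == 0:
            raise ValueError("intensities must be a non-empty 3-D array")
        self.voxel_dims = np.asarray(self.voxel_dims, dtype=float).reshape(3)
        if np.any(self.voxel_dims <= 0):
            raise ValueError("voxel dimensions must be positive")


def synth_ct(electrodes: ElectrodeSet,
             voxel_dims: Sequence[float] = (1.0, 1.0, 1.0),
             blob_sd: float = 1.0,
             noise_sd: float = 1.0,
             blob_amplitude: float = 100.0,
             seed: int = 0) -> Tuple[CTVolume, np.ndarray]:
    """Synthetic CT-like volume: one Gaussian bright blob per electrode.

    The volume's origin sits at voxel (0, 0, 0); physical position maps to
    voxel space as ``pos / voxel_dims``.  All electrodes must lie at least
    ``3 * blob_sd`` mm inside the positive octant so every blob is fully
    enclosed.  Returns the volume and the (N, 3) voxel-space ground-truth
    centres.
    """
    voxel_dims = np.asarray(voxel_dims, dtype=float).reshape(3)
    if np.any(voxel_dims <= 0):
        raise ValueError("voxel dimensions must be positive")
    margin = 3.0 * blob_sd
    rng = np.random.default_rng(seed)
    if len(electrodes) == 0:
        shape = (16, 16, 16)
        vol = rng.normal(0.0, noise_sd, size=shape) if noise_sd else np.zeros(shape)
        return CTVolume(vol, voxel_dims), np.empty((0, 3))

    pos = electrodes.positions
    if np.any(pos - margin < 0):
        raise ValueError("electrodes must lie >= 3*blob_sd inside the volume; "
                         "translate the grid into the positive octant")
    shape = tuple(int(np.ceil((pos[:, i].max() + margin) / voxel_dims[i])) + 1
                  for i in range(3))
    vol = rng.normal(0.0, noise_sd, size=shape) if noise_sd else np.zeros(shape)

    centers = pos / voxel_dims  # voxel space
    sd_vox = blob_sd / voxel_dims  # anisotropic in voxel units
    for c in centers:
        lo = np.maximum(np.floor(c - 4 * sd_vox).astype(int), 0)
        hi = np.minimum(np.ceil(c + 4 * sd_vox).astype(int) + 1, shape)
        gx = np.arange(lo[0], hi[0])
        gy = np.arange(lo[1], hi[1])
        gz = np.arange(lo[2], hi[2])
        dx = ((gx - c[0]) / sd_vox[0]) ** 2
        dy = ((gy - c[1]) / sd_vox[1]) ** 2
        dz = ((gz - c[2]) / sd_vox[2]) ** 2
        blob = blob_amplitude * np.exp(-0.5 * (dx[:, None, None]
                                               + dy[None, :, None]
                                               + dz[None, None, :]))
        vol[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] += blob
    return CTVolume(vol, voxel_dims), centers
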