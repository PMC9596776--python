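"""Shared containers for the stimulation-artifact pipeline.

Conventions used throughout the package: voltages in microvolts (uV),
distances in millimetres (mm), currents in milliamperes (mA), times in
seconds, sampling rates in Hz.  Sample indexing is 0-based and epoch
windows are half-open ``[start, end)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np


class PipelineError(RuntimeError):
    """Structured error raised when a pipeline stage cannot proceed.

    Carries the stage name so batch drivers can report which step of
    which epoch failed.
    """

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")


def _as_positions(positions) -> np.ndarray:
    pos = np.asarray(positions, dtype=float)
    if pos.size == 0:
        return pos.reshape(0, 3)
    if pos.ndim != 2 or pos.shape[1] != 3:
        raise ValueError("positions must be an (N, 3) array of mm coordinates")
    if not np.all(np.isfinite(pos)):
        raise ValueError("positions must be finite")
    return pos


@dataclass(eq=False)
class ElectrodeSet:
    """Electrode labels with 3-D positions in mm."""

    labels: List[str]
    positions: np.ndarray  # (N, 3) mm

    def __post_init__(self):
        self.labels = [str(l) for l in self.labels]
        self.positions = _as_positions(self.positions)
        if len(self.labels) != len(self.positions):
            raise ValueError("labels and positions must have equal length")
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("electrode labels must be unique")

    def __len__(self) -> int:
        return len(self.labels)

    def index_of(self, label: str) -> int:
        try:
            return self.labels.index(label)
        except ValueError:
            raise KeyError(f"unknown electrode label {label!r}") from None

    def position_of(self, label: str) -> np.ndarray:
        return self.positions[self.index_of(label)]

    def subset(self, labels: Sequence[str]) -> "ElectrodeSet":
        idx = [self.index_of(l) for l in labels]
        return ElectrodeSet(list(labels), self.positions[idx].copy())

    def transformed(self, rotation: Optional[np.ndarray] = None,
                    translation: Optional[np.ndarray] = None) -> "ElectrodeSet":
        """Return a rigidly moved copy: ``p -> R p + t``."""
        pos = self.positions
        if rotation is not None:
            pos = pos @ np.asarray(rotation, dtype=float).T
        if translation is not None:
            pos = pos + np.asarray(translation, dtype=float)
        return ElectrodeSet(list(self.labels), pos)


@dataclass(eq=False)
class Recording:
    """Multichannel voltage matrix (channels x samples, uV) at rate fs."""

    samples: np.ndarray
    fs: float
    labels: List[str]

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2:
            raise ValueError("samples must be a 2-D (channels x time) array")
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        self.labels = [str(l) for l in self.labels]
        if len(self.labels) != self.samples.shape[0]:
            raise ValueError("label count must match channel count")
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("channel labels must be unique")

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs

    def index_of(self, label: str) -> int:
        try:
            return self.labels.index(label)
        except ValueError:
            raise KeyError(f"unknown channel label {label!r}") from None

    def channel(self, label: str) -> np.ndarray:
        return self.samples[self.index_of(label)]

    def copy(self) -> "Recording":
        return Recording(self.samples.copy(), self.fs, list(self.labels))


@dataclass(frozen=True)
class EpochAnnotation:
    """One stimulation epoch: window, stimulated pair and pulse parameters."""

    start: float  # s
    end: float  # s
    stim_pair: Tuple[str, str]
    amplitude: float  # mA
    pulse_freq: float = 50.0  # Hz
    pulse_width_us: float = 200.0

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid epoch window [{self.start}, {self.end})")
        if self.amplitude <= 0:
            raise ValueError("stimulation amplitude must be positive (mA)")
        if self.pulse_freq <= 0:
            raise ValueError("pulse frequency must be positive (Hz)")
        object.__setattr__(self, "stim_pair", tuple(self.stim_pair))
        if len(self.stim_pair) != 2:
            raise ValueError("stim_pair must name exactly two electrodes")

    @property
    def duration(self) -> float:
        return self.end - self.start


@dataclass(eq=False)
class EpochData:
    """A half-open sample window cut from a Recording."""

    samples: np.ndarray  # (channels, n) uV
    fs: float
    labels: List[str]
    start_sample: int
    annotation: Optional[EpochAnnotation] = None

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs

    @property
    def t0(self) -> float:
        return self.start_sample / self.fs

    def channel(self, label: str) -> np.ndarray:
        return self.samples[self.labels.index(label)]


@dataclass(eq=False)
class PulseResponses:
    """Per-channel per-pulse extremum times (s) and signed amplitudes (uV)."""

    times: Dict[str, np.ndarray]
    amplitudes: Dict[str, np.ndarray]
    fs: float
    pulse_freq: float
    excluded: Dict[str, str] = field(default_factory=dict)

    @property
    def channels(self) -> List[str]:
        return list(self.times.keys())

    @property
    def n_pulses(self) -> int:
        if not self.times:
            return 0
        return len(next(iter(self.times.values())))


@dataclass(eq=False)
class ArtifactAmplitudeMap:
    """Median signed pulse-response amplitude per electrode for one epoch."""

    values: Dict[str, float]  # uV, included electrodes only
    stim_pair: Tuple[str, str]
    amplitude: float  # mA
    excluded: Dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        self.stim_pair = tuple(self.stim_pair)
        for lab, v in self.values.items():
            if not np.isfinite(v):
                raise ValueError(f"non-finite map value for electrode {lab!r}")


@dataclass(eq=False)
class DipoleChannel:
    """Current source/sink positions of one bipolar stimulation channel."""

    r_plus: np.ndarray  # mm
    r_minus: np.ndarray  # mm
    labels: Tuple[str, str] = ("+", "-")

    def __post_init__(self):
        self.r_plus = np.asarray(self.r_plus, dtype=float).reshape(3)
        self.r_minus = np.asarray(self.r_minus, dtype=float).reshape(3)
        if np.allclose(self.r_plus, self.r_minus):
            raise ValueError("source and sink positions must differ")
        self.labels = tuple(self.labels)

    @property
    def midpoint(self) -> np.ndarray:
        return 0.5 * (self.r_plus + self.r_minus)

    def swapped(self) -> "DipoleChannel":
        return DipoleChannel(self.r_minus.copy(), self.r_plus.copy(),
                             (self.labels[1], self.labels[0]))

    @classmethod
    def from_electrodes(cls, electrodes: ElectrodeSet,
                        pair: Sequence[str]) -> "DipoleChannel":
        a, b = pair
        return cls(electrodes.position_of(a), electrodes.position_of(b), (a, b))


@dataclass(eq=False)
class DipoleFitResult:
    """Least-squares dipole-model fit for one stimulation channel."""

    k_hat: float  # Ohm mm
    n_hat: float  # uV
    r_squared: float
    residuals: np.ndarray  # uV
    n_points: int
    channel: DipoleChannel
    pole_swapped: bool = False
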