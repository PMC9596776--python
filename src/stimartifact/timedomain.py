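"""Time-domain characterization: filtering, epoching, exclusions, per-pulse
extremum extraction, ratcheting drift and phase-locking statistics.

Processing order follows standard clinical practice: high-pass filter the
whole recording (removes ratcheting drift), segment stimulation epochs with
duration-matched preceding baselines, drop the stimulation-pair channels
and any channel that hits the amplifier saturation limit, then quantify
each biphasic pulse by the signed extremum of its response.  Raw
(unfiltered) epochs are kept around for drift quantification.
"""

from __future__ import annotations

from typing import Dict, List, Sequence, Tuple

import numpy as np
from scipy import signal as _signal

from .core import (EpochAnnotation, EpochData, PipelineError, PulseResponses,
                   Recording)

__all__ = ["highpass", "segment_epochs", "exclude_saturated",
           "detect_pulse_responses", "ratchet_drift", "phase_lock_stats",
           "strongest_channels", "sampling_resolution_ms"]

DEFAULT_CUTOFF_HZ = 1.5
DEFAULT_CLIP_LIMIT_UV = 8711.0


def sampling_resolution_ms(fs: float) -> float:
    """Temporal resolution of the acquisition in ms (1.95 ms at 512 Hz)."""
    if fs <= 0:
        raise ValueError("fs must be positive")
    return 1000.0 / fs


def highpass(rec: Recording, cutoff: float = DEFAULT_CUTOFF_HZ) -> Recording:
    """Zero-phase first-order Butterworth high-pass, per channel.

    Applied forward-backward (filtfilt), so the effective magnitude
    response is the square of the one-pass response and the phase is zero.
    Edges are reflect-padded by three filter time constants to suppress
    startup transients.
    """
    nyq = rec.fs / 2.0
    if not (0 < cutoff < nyq):
        raise ValueError(f"cutoff must lie in (0, {nyq}) Hz")
    b, a = _signal.butter(1, cutoff, btype="highpass", fs=rec.fs)
    tau = 1.0 / (2.0 * np.pi * cutoff)
    padlen = min(rec.n_samples - 1, max(6, int(round(3 * tau * rec.fs))))
    filtered = _signal.filtfilt(b, a, rec.samples, axis=1,
                                padtype="even", padlen=padlen)
    return Recording(filtered, rec.fs, list(rec.labels))


def _window_samples(ann: EpochAnnotation, fs: float) -> Tuple[int, int]:
    # round() is round-half-to-even, the stated tie-break
    return int(round(ann.start * fs)), int(round(ann.end * fs))


def segment_epochs(rec: Recording, annotations: Sequence[EpochAnnotation],
                   ) -> List[Tuple[EpochData, EpochData]]:
    """Cut (stimulation, duration-matched preceding baseline) window pairs.

    Windows are half-open in samples.  The baseline window must lie inside
    the recording and must not overlap any annotated stimulation epoch; a
    violation raises an error naming the offending annotation.
    """
    stim_windows = [_window_samples(a, rec.fs) for a in annotations]
    pairs: List[Tuple[EpochData, EpochData]] = []
    for ann, (s0, s1) in zip(annotations, stim_windows):
        n = s1 - s0
        b0, b1 = s0 - n, s0
        if b0 < 0 or s1 > rec.n_samples:
            raise PipelineError(
                "segment_epochs",
                f"epoch [{ann.start}, {ann.end}) s: baseline/stim window "
                f"[{b0}, {s1}) exceeds recording bounds [0, {rec.n_samples})")
        for other, (o0, o1) in zip(annotations, stim_windows):
            if other is ann:
                continue
            if b0 < o1 and o0 < b1:
                raise PipelineError(
                    "segment_epochs",
                    f"baseline of epoch [{ann.start}, {ann.end}) s overlaps "
                    f"stimulation epoch [{other.start}, {other.end}) s")
        stim = EpochData(rec.samples[:, s0:s1], rec.fs, list(rec.labels),
                         start_sample=s0, annotation=ann)
        base = EpochData(rec.samples[:, b0:b1], rec.fs, list(rec.labels),
                         start_sample=b0, annotation=ann)
        pairs.append((stim, base))
    return pairs


def exclude_saturated(epoch: EpochData, stim_pair: Sequence[str],
                      clip_limit: float = DEFAULT_CLIP_LIMIT_UV,
                      ) -> Dict[str, str]:
    """Channels to exclude from this epoch, with reasons.

    The two stimulation-pair channels are always excluded (they saturate
    by construction); any other channel whose magnitude reaches the
    amplifier saturation limit anywhere in the epoch is excluded as
    ``saturated``.
    """
    for lab in stim_pair:
        if lab not in epoch.labels:
            raise KeyError(f"stimulation electrode {lab!r} not in epoch")
    excluded: Dict[str, str] = {}
    for lab in stim_pair:
        excluded[lab] = "stim_channel"
    for ch, lab in enumerate(epoch.labels):
        if lab in excluded:
            continue
        if np.any(np.abs(epoch.samples[ch]) >= clip_limit):
            excluded[lab] = "saturated"
    return excluded


def detect_pulse_responses(epoch: EpochData, pulse_freq: float,
                           excluded: Dict[str, str] | None = None,
                           ) -> PulseResponses:
    """Per-pulse signed extremum amplitudes, using the known pulse rate.

    The epoch is tiled into consecutive half-open windows of one pulse
    period, anchored at the epoch start.  In each window and channel, the
    sample of largest magnitude gives (extremum time, signed amplitude).
    Exactly ``floor(duration * pulse_freq)`` responses per channel,
    regardless of signal content.
    """
    if pulse_freq <= 0:
        raise ValueError("pulse_freq must be positive")
    period = epoch.fs / pulse_freq  # samples per pulse
    if period < 2:
        raise ValueError("pulse-period window shorter than 2 samples")
    excluded = dict(excluded or {})
    n = epoch.n_samples
    n_win = int(np.floor(n / epoch.fs * pulse_freq))
    bounds = np.floor(np.arange(n_win + 1) * period).astype(int)
    bounds[-1] = min(bounds[-1], n)

    times: Dict[str, np.ndarray] = {}
    amps: Dict[str, np.ndarray] = {}
    for ch, lab in enumerate(epoch.labels):
        if lab in excluded:
            continue
        x = epoch.samples[ch]
        t = np.empty(n_win)
        a = np.empty(n_win)
        for j in range(n_win):
            w = x[bounds[j]:bounds[j + 1]]
            i = int(np.argmax(np.abs(w)))
            t[j] = (epoch.start_sample + bounds[j] + i) / epoch.fs
            a[j] = w[i]
        times[lab] = t
        amps[lab] = a
    return PulseResponses(times=times, amplitudes=amps, fs=epoch.fs,
                          pulse_freq=pulse_freq, excluded=excluded)


def ratchet_drift(raw_channel: np.ndarray) -> Tuple[float, int]:
    """DC drift across a raw (unfiltered) epoch and its polarity.

    Drift = mean of the final 10% of samples minus mean of the first 10%;
    polarity is its sign.  Quantifies the ratcheting accumulation of
    unrecovered charge over a stimulation epoch.
    """
    x = np.asarray(raw_channel, dtype=float)
    k = max(1, int(0.1 * len(x)))
    drift = float(x[-k:].mean() - x[:k].mean())
    return drift, int(np.sign(drift))


def phase_lock_stats(responses: PulseResponses,
                     channels: Sequence[str] | None = None,
                     ) -> Tuple[np.ndarray, float, float]:
    """Cross-channel alignment of per-pulse extrema.

    For pulse j, ``offset_j`` is the maximum pairwise difference of
    extremum times across the chosen channels.  Returns the per-pulse
    offsets (s), their maximum (s), and that maximum in samples.
    """
    chans = list(channels) if channels is not None else responses.channels
    if len(chans) < 2:
        raise ValueError("phase-locking needs at least 2 channels")
    t = np.vstack([responses.times[c] for c in chans])  # (C, J)
    offsets = t.max(axis=0) - t.min(axis=0)
    max_offset = float(offsets.max()) if offsets.size else 0.0
    return offsets, max_offset, max_offset * responses.fs


def strongest_channels(responses: PulseResponses, n: int = 4) -> List[str]:
    """Channels with the largest absolute median pulse amplitude."""
    order = sorted(responses.channels,
                   key=lambda c: -abs(float(np.median(responses.amplitudes[c]))))
    return order[:n]
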