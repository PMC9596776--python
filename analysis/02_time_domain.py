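#!/usr/bin/env python
"""Time-domain characterization of the simulated session.

High-passes the recording at 1.5 Hz (zero-phase first-order Butterworth),
segments stimulation/baseline epochs, excludes saturated channels,
extracts per-pulse extremum amplitudes, and quantifies ratcheting drift
and cross-channel phase-locking.  Findings echo the expected artifact
physics: responses recur at the 20 ms pulse period, extrema across strong
electrodes align within one sample, drift polarity follows the dipole
side, and high-passing removes the drift.  Writes
results/time_domain.csv (per-epoch summary) and
results/pulse_responses.csv.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from stimartifact import default_session
from stimartifact.timedomain import (detect_pulse_responses, exclude_saturated,
                                     highpass, phase_lock_stats, ratchet_drift,
                                     segment_epochs, strongest_channels)

ROOT = Path(__file__).resolve().parent.parent
OUT = ROOT / "results"


def main(seed: int = 0) -> None:
    rec, gt, electrodes = default_session(seed=seed)
    filt = highpass(rec)
    rows = []
    resp_rows = []
    for (stim, _), (raw_stim, _) in zip(segment_epochs(filt, gt.epochs),
                                        segment_epochs(rec, gt.epochs)):
        ann = stim.annotation
        excl = exclude_saturated(raw_stim, ann.stim_pair)
        resp = detect_pulse_responses(stim, ann.pulse_freq, excluded=excl)
        strong = strongest_channels(resp, 4)
        _, off_s, off_samp = phase_lock_stats(resp, strong)
        iri = 1000 * np.median(np.diff(resp.times[strong[0]]))
        drift_raw, pol = ratchet_drift(raw_stim.channel(strong[0]))
        drift_filt, _ = ratchet_drift(stim.channel(strong[0]))
        rows.append({
            "amplitude_mA": ann.amplitude,
            "n_pulses": resp.n_pulses,
            "median_iri_ms": iri,
            "phase_lock_offset_ms": 1000 * off_s,
            "phase_lock_offset_samples": off_samp,
            "ratchet_drift_raw_uv": drift_raw,
            "ratchet_polarity": pol,
            "ratchet_drift_filtered_uv": drift_filt,
            "n_excluded": len(excl),
        })
        for ch in resp.channels:
            med = float(np.median(resp.amplitudes[ch]))
            resp_rows.append({"amplitude_mA": ann.amplitude, "channel": ch,
                              "median_amplitude_uv": med})

    df = pd.DataFrame(rows)
    OUT.mkdir(exist_ok=True)
    df.to_csv(OUT / "time_domain.csv", index=False)
    pd.DataFrame(resp_rows).to_csv(OUT / "pulse_responses.csv", index=False)

    print(df.to_string(index=False, float_format=lambda v: f"{v:.3f}"))
    print(f"\npulse responses recur every {df.median_iri_ms.iloc[0]:.2f} ms "
          "(50 Hz pulse train, sample-quantized at 512 Hz)")
    print("max cross-channel extremum offset: "
          f"{df.phase_lock_offset_ms.max():.3f} ms (phase-locked)")
    print("raw drift grows with current and is removed by the 1.5 Hz "
          "high-pass (see ratchet_drift_filtered_uv)")


if __name__ == "__main__":
    main()
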