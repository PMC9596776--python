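#!/usr/bin/env python
"""Spatial artifact maps, saturation regions and worst-case distances.

Builds the median artifact map of every epoch, interpolates it over the
grid plane, extracts the +/-1100 uV saturation contour (the input-referred
limit of a 2.2 V / 66 dB implantable front-end) and computes the
worst-case distance (WCD) from the stimulation-channel midpoint.  WCD
grows monotonically with stimulation current; epochs whose artifacts
never reach the limit have no saturation region.  Writes
results/wcd.json.
"""

import json
from pathlib import Path

from stimartifact import default_session
from stimartifact.core import DipoleChannel
from stimartifact.spatial import (epoch_artifact_map, interpolate_map,
                                  saturation_region)
from stimartifact.timedomain import (detect_pulse_responses, exclude_saturated,
                                     highpass, segment_epochs)

OUT = Path(__file__).resolve().parent.parent / "results"
LIMIT_UV = 1100.0


def main(seed: int = 0) -> None:
    rec, gt, electrodes = default_session(seed=seed)
    filt = highpass(rec)
    chan = DipoleChannel.from_electrodes(electrodes, gt.stim_pair)
    results = []
    for stim, _ in segment_epochs(filt, gt.epochs):
        ann = stim.annotation
        excl = exclude_saturated(stim, ann.stim_pair)
        resp = detect_pulse_responses(stim, ann.pulse_freq, excluded=excl)
        amap = epoch_artifact_map(resp, ann)
        field = interpolate_map(amap, electrodes, resolution=0.5)
        sat = saturation_region(field, chan.midpoint, limit=LIMIT_UV)
        results.append({"amplitude_mA": ann.amplitude, "limit_uv": LIMIT_UV,
                        "wcd_mm": sat.wcd,
                        "clipped_at_hull": sat.clipped_at_hull,
                        "n_contour_points": int(len(sat.contour_points))})
        note = ("no saturation region" if sat.wcd == 0 else
                f"WCD {sat.wcd:6.2f} mm"
                + (" (region reaches grid edge)" if sat.clipped_at_hull
                   else ""))
        print(f"{ann.amplitude:4g} mA: {note}")

    OUT.mkdir(exist_ok=True)
    (OUT / "wcd.json").write_text(json.dumps(results, indent=1))
    print(f"\nwrote {OUT / 'wcd.json'}")


if __name__ == "__main__":
    main()
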