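#!/usr/bin/env python
"""Simulate the reference stimulation session and write it to disk.

A 4x5 standard grid (10 mm pitch) is stimulated through the central
bipolar pair G8-G9 with a 50 Hz biphasic pulse train at 2-10 mA, one 5 s
epoch per amplitude, each preceded by a 5 s stimulation-free baseline.
The session includes dipole-propagated artifacts (k = 3.3 Ohm mm),
ratcheting DC drift, 20 uV pink background noise and +/-8711 uV clipping.
Outputs: recording bundle, annotations, electrode table and ground truth
under scratch/session/ (the raw bundle is tens of MB; the small summary
tables the later steps derive from it live under results/).
"""

from pathlib import Path

from stimartifact import default_session
from stimartifact import io as sio

OUT = Path(__file__).resolve().parent.parent / "scratch" / "session"


def main(seed: int = 0) -> None:
    rec, gt, electrodes = default_session(seed=seed)
    OUT.mkdir(parents=True, exist_ok=True)
    sio.write_bundle(rec, OUT)
    sio.write_annotations(gt.epochs, OUT / "annotations.csv")
    sio.write_electrodes(electrodes, OUT / "electrodes.csv")
    sio.write_ground_truth(gt, OUT / "ground_truth.json")
    print(f"session: {rec.n_channels} channels, {rec.duration:.0f} s, "
          f"{len(gt.epochs)} stimulation epochs "
          f"({', '.join(f'{e.amplitude:g} mA' for e in gt.epochs)})")
    print(f"wrote bundle to {OUT}")


if __name__ == "__main__":
    main()
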