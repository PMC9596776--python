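"""File formats: recording bundles (CSV + JSON), EDF reading, annotation
and electrode tables, ground truth and NIfTI volumes.

The canonical on-disk recording format is a *bundle* directory holding
``recording.csv`` (samples x channels, full-precision decimal text) and
``meta.json`` (sampling rate, channel labels, units).  EDF files are read
through MNE when it is installed; voltages are always converted to uV.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .core import EpochAnnotation, Recording, ElectrodeSet
from .synth import CTVolume, GroundTruth

__all__ = ["write_bundle", "read_bundle", "read_recording",
           "write_annotations", "read_annotations",
           "write_electrodes", "read_electrodes",
           "write_ground_truth", "read_ground_truth",
           "write_nifti", "read_nifti"]

BUNDLE_SCHEMA_VERSION = 1
_ANNOT_COLUMNS = ["start_s", "end_s", "anode", "cathode", "amplitude_mA",
                  "pulse_freq_hz", "pulse_width_us"]


def write_bundle(rec: Recording, out_dir: Union[str, Path]) -> Path:
    """Write a recording bundle; round-trips bit-identically."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    df = pd.DataFrame(rec.samples.T, columns=rec.labels)
    df.to_csv(out / "recording.csv", index=False,
              float_format="%.17g")
    meta = {"schema_version": BUNDLE_SCHEMA_VERSION, "fs_hz": rec.fs,
            "labels": rec.labels, "units": "uV"}
    (out / "meta.json").write_text(json.dumps(meta, indent=1, sort_keys=True))
    return out


def read_bundle(path: Union[str, Path]) -> Recording:
    path = Path(path)
    meta_path = path / "meta.json"
    if not meta_path.exists():
        raise FileNotFoundError(f"bundle is missing {meta_path}")
    csv_path = path / "recording.csv"
    if not csv_path.exists():
        raise FileNotFoundError(f"bundle is missing {csv_path}")
    meta = json.loads(meta_path.read_text())
    for key in ("fs_hz", "labels", "units"):
        if key not in meta:
            raise ValueError(f"bundle meta.json is missing key {key!r}")
    df = pd.read_csv(csv_path, float_precision="round_trip")
    if list(df.columns) != list(meta["labels"]):
        raise ValueError("recording.csv columns do not match meta.json labels")
    samples = df.to_numpy(dtype=float).T
    scale = {"uV": 1.0, "mV": 1e3, "V": 1e6}.get(meta["units"])
    if scale is None:
        raise ValueError(f"unsupported units {meta['units']!r} in bundle")
    return Recording(samples * scale, float(meta["fs_hz"]),
                     list(meta["labels"]))


def _read_edf(path: Path) -> Recording:
    try:
        import mne
    except ImportError as exc:  # pragma: no cover - depends on environment
        raise ImportError("reading EDF requires the 'mne' package") from exc
    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    # MNE returns SI volts regardless of the EDF physical dimension
    samples = raw.get_data() * 1e6
    return Recording(samples, float(raw.info["sfreq"]), list(raw.ch_names))


def read_recording(path: Union[str, Path]) -> Recording:
    """Read an EDF file or a bundle directory into uV units."""
    path = Path(path)
    if path.is_dir():
        return read_bundle(path)
    if path.suffix.lower() == ".edf":
        return _read_edf(path)
    raise ValueError(f"unrecognized recording path {path} "
                     "(expected a bundle directory or an .edf file)")


def write_annotations(annotations: Sequence[EpochAnnotation],
                      path: Union[str, Path]) -> None:
    rows = [{"start_s": a.start, "end_s": a.end, "anode": a.stim_pair[0],
             "cathode": a.stim_pair[1], "amplitude_mA": a.amplitude,
             "pulse_freq_hz": a.pulse_freq, "pulse_width_us": a.pulse_width_us}
            for a in annotations]
    pd.DataFrame(rows, columns=_ANNOT_COLUMNS).to_csv(path, index=False)


def read_annotations(path: Union[str, Path]) -> List[EpochAnnotation]:
    df = pd.read_csv(path, float_precision="round_trip")
    missing = set(_ANNOT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"annotation table missing columns {sorted(missing)}")
    return [EpochAnnotation(start=r.start_s, end=r.end_s,
                            stim_pair=(str(r.anode), str(r.cathode)),
                            amplitude=r.amplitude_mA,
                            pulse_freq=r.pulse_freq_hz,
                            pulse_width_us=r.pulse_width_us)
            for r in df.itertuples()]


def write_electrodes(electrodes: ElectrodeSet, path: Union[str, Path]) -> None:
    df = pd.DataFrame({"label": electrodes.labels,
                       "x_mm": electrodes.positions[:, 0],
                       "y_mm": electrodes.positions[:, 1],
                       "z_mm": electrodes.positions[:, 2]})
    df.to_csv(path, index=False, float_format="%.17g")


def read_electrodes(path: Union[str, Path]) -> ElectrodeSet:
    df = pd.read_csv(path, float_precision="round_trip")
    missing = {"label", "x_mm", "y_mm", "z_mm"} - set(df.columns)
    if missing:
        raise ValueError(f"electrode table missing columns {sorted(missing)}")
    return ElectrodeSet([str(l) for l in df["label"]],
                        df[["x_mm", "y_mm", "z_mm"]].to_numpy(dtype=float))


def write_ground_truth(gt: GroundTruth, path: Union[str, Path]) -> None:
    doc = {
        "k_true_ohm_mm": gt.k_true,
        "n_true_uv": gt.n_true,
        "stim_pair": list(gt.stim_pair),
        "epochs": [{"start_s": e.start, "end_s": e.end,
                    "amplitude_mA": e.amplitude,
                    "stim_pair": list(e.stim_pair),
                    "pulse_freq_hz": e.pulse_freq,
                    "pulse_width_us": e.pulse_width_us}
                   for e in gt.epochs],
        "pulse_onsets_s": [list(map(float, o)) for o in gt.pulse_onsets],
        "pulse_amplitudes_uv": gt.pulse_amplitudes,
        "electrodes": {"labels": gt.electrodes.labels,
                       "positions_mm": gt.electrodes.positions.tolist()},
    }
    Path(path).write_text(json.dumps(doc, indent=1, sort_keys=True))


def read_ground_truth(path: Union[str, Path]) -> GroundTruth:
    doc = json.loads(Path(path).read_text())
    epochs = [EpochAnnotation(start=e["start_s"], end=e["end_s"],
                              stim_pair=tuple(e["stim_pair"]),
                              amplitude=e["amplitude_mA"],
                              pulse_freq=e["pulse_freq_hz"],
                              pulse_width_us=e["pulse_width_us"])
              for e in doc["epochs"]]
    es = ElectrodeSet(doc["electrodes"]["labels"],
                      np.asarray(doc["electrodes"]["positions_mm"]))
    return GroundTruth(epochs=epochs,
                       pulse_onsets=[np.asarray(o) for o in doc["pulse_onsets_s"]],
                       pulse_amplitudes=doc["pulse_amplitudes_uv"],
                       k_true=doc["k_true_ohm_mm"], n_true=doc["n_true_uv"],
                       electrodes=es, stim_pair=tuple(doc["stim_pair"]))


def write_nifti(vol: CTVolume, path: Union[str, Path]) -> None:
    import nibabel as nib
    affine = np.diag([*vol.voxel_dims, 1.0])
    img = nib.Nifti1Image(vol.intensities.astype(np.float32), affine)
    img.header.set_zooms(tuple(vol.voxel_dims))
    nib.save(img, str(path))


def read_nifti(path: Union[str, Path]) -> CTVolume:
    import nibabel as nib
    img = nib.load(str(path))
    zooms = img.header.get_zooms()[:3]
    return CTVolume(np.asarray(img.dataobj, dtype=float),
                    np.asarray(zooms, dtype=float))
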