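"""File interfaces: EDF recordings, JSON ground truth, delimited matrices.

``write_edf`` is a compact single-purpose EDF writer (16-bit, one-second
data records, physical range taken from the data); recordings written with
it round-trip through MNE's EDF reader.  Everything else is plain text:
ground truth as JSON, lead fields and networks as TSV, epoch sets as a
``.npy`` container with a JSON sidecar.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .preprocess import EpochSet, SensorRecording
from .srcloc import LeadField
from .syndata import GroundTruth

__all__ = [
    "write_edf",
    "read_edf",
    "write_ground_truth",
    "read_ground_truth",
    "write_lead_field",
    "read_lead_field",
    "write_network",
    "read_network",
    "write_epochs",
    "read_epochs",
]


def _pad(text: str, width: int) -> bytes:
    return text[:width].ljust(width).encode("ascii")


def write_edf(rec: SensorRecording, path: str | Path) -> Path:
    """Write a recording as EDF (int16, 1-s records, physical unit µV).

    The signal is padded with zeros to a whole number of records.
    """
    path = Path(path)
    fs = rec.fs
    if abs(fs - round(fs)) > 1e-9:
        raise ValueError("EDF writer requires an integer sampling rate")
    spr = int(round(fs))                       # samples per 1-s record
    n_ch = rec.n_channels
    n_rec = int(np.ceil(rec.n_samples / spr))
    data = np.zeros((n_ch, n_rec * spr))
    data[:, :rec.n_samples] = rec.data

    pmin = float(np.floor(data.min())) if data.min() < 0 else -1.0
    pmax = float(np.ceil(data.max())) if data.max() > 0 else 1.0
    dmin, dmax = -32768, 32767
    scale = (pmax - pmin) / (dmax - dmin)
    digital = np.round((data - pmin) / scale + dmin).astype("<i2")

    header = b"".join([
        _pad("0", 8),
        _pad(f"synthetic {rec.subject_id}", 80),
        _pad("synthetic EEG", 80),
        _pad("01.01.00", 8),
        _pad("00.00.00", 8),
        _pad(str(256 + 256 * n_ch), 8),
        _pad("", 44),
        _pad(str(n_rec), 8),
        _pad("1", 8),
        _pad(str(n_ch), 4),
    ])
    fields = [
        (16, rec.channel_labels),
        (80, ["AgAgCl electrode"] * n_ch),
        (8, ["uV"] * n_ch),
        (8, [f"{pmin:g}"] * n_ch),
        (8, [f"{pmax:g}"] * n_ch),
        (8, [str(dmin)] * n_ch),
        (8, [str(dmax)] * n_ch),
        (80, [""] * n_ch),
        (8, [str(spr)] * n_ch),
        (32, [""] * n_ch),
    ]
    sig_header = b"".join(
        b"".join(_pad(str(v), width) for v in values)
        for width, values in fields
    )
    with open(path, "wb") as fh:
        fh.write(header + sig_header)
        for r in range(n_rec):
            fh.write(digital[:, r * spr:(r + 1) * spr].tobytes())
    return path


def read_edf(path: str | Path, subject_id: str = "") -> SensorRecording:
    """Read an EDF file into a :class:`SensorRecording` via MNE (µV)."""
    import mne

    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    data = raw.get_data() * 1e6  # MNE loads volts
    return SensorRecording(data, float(raw.info["sfreq"]),
                           list(raw.ch_names), subject_id=subject_id)


def write_ground_truth(gt: GroundTruth, path: str | Path) -> Path:
    path = Path(path)
    payload = {
        "spike_event_samples": gt.spike_event_samples.tolist(),
        "burst_event_samples": gt.burst_event_samples.tolist(),
        "planted_edges": [list(e) for e in gt.planted_edges],
        "active_source_index": gt.active_source_index,
        "lead_field_ref": gt.lead_field_ref,
    }
    path.write_text(json.dumps(payload, indent=1))
    return path


def read_ground_truth(path: str | Path) -> GroundTruth:
    payload = json.loads(Path(path).read_text())
    return GroundTruth(
        np.array(payload["spike_event_samples"], dtype=int),
        np.array(payload["burst_event_samples"], dtype=int),
        [tuple(e) for e in payload["planted_edges"]],
        payload["active_source_index"],
        payload.get("lead_field_ref", ""),
    )


def write_lead_field(lf: LeadField, path: str | Path) -> Path:
    path = Path(path)
    header = "\t".join(lf.source_ids)
    np.savetxt(path, lf.gain, delimiter="\t", header=header, comments="# ")
    return path


def read_lead_field(path: str | Path) -> LeadField:
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
    ids = first.lstrip("# ").rstrip("\n").split("\t") if first.startswith("#") else []
    gain = np.loadtxt(path, delimiter="\t")
    return LeadField(gain, ids if ids and len(ids) == gain.shape[1] else [])


def write_network(weights: np.ndarray, path: str | Path,
                  node_labels: list[str] | None = None) -> Path:
    path = Path(path)
    header = "\t".join(node_labels) if node_labels else ""
    np.savetxt(path, np.asarray(weights), delimiter="\t",
               header=header, comments="# ")
    return path


def read_network(path: str | Path) -> np.ndarray:
    return np.loadtxt(Path(path), delimiter="\t")


def write_epochs(epochs: EpochSet, stem: str | Path) -> tuple[Path, Path]:
    """Epoch array as ``<stem>.npy`` plus a ``<stem>.json`` sidecar."""
    stem = Path(stem)
    npy = stem.with_suffix(".npy")
    np.save(npy, epochs.data)
    sidecar = stem.with_suffix(".json")
    sidecar.write_text(json.dumps({
        "fs": epochs.fs,
        "state": epochs.state,
        "events": epochs.events.tolist(),
        "window": list(epochs.window),
    }, indent=1))
    return npy, sidecar


def read_epochs(stem: str | Path) -> EpochSet:
    stem = Path(stem)
    data = np.load(stem.with_suffix(".npy"))
    meta = json.loads(stem.with_suffix(".json").read_text())
    return EpochSet(data, meta["fs"], meta["state"],
                    np.array(meta["events"], dtype=int),
                    tuple(meta["window"]))
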