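"""Recording and event-table containers plus on-disk formats.

Two interchange formats are supported for recordings:

* a plain delimited-text format (one column per channel, header row with
  channel labels) with a JSON sidecar holding the sampling rate and any
  extra metadata — lossless for float64 up to the printed precision;
* a minimal EDF (European Data Format) codec written against the published
  EDF header layout.  EDF stores 16-bit integers with per-channel physical
  scaling, so round-trips are exact only up to the declared quantization
  step ``(physical_max - physical_min) / 65535``.

Event tables are CSV with columns ``trial_index, onset_s, energy_J, rating``.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

EVENT_COLUMNS = ["trial_index", "onset_s", "energy_J", "rating"]


@dataclass
class Recording:
    """Continuous multichannel signal in microvolts.

    data is (n_samples, n_channels); channel_labels has one label per column.
    """

    data: np.ndarray
    sampling_rate: float
    channel_labels: list[str]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim == 1:
            self.data = self.data[:, None]
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (samples x channels)")
        if len(self.channel_labels) != self.data.shape[1]:
            raise ValueError(
                f"{len(self.channel_labels)} labels for {self.data.shape[1]} channels"
            )
        if not np.all(np.isfinite(self.data)):
            raise ValueError("recording contains non-finite samples")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def duration(self) -> float:
        """Duration in seconds; duration * sampling_rate == sample count."""
        return self.n_samples / self.sampling_rate

    def channel(self, label: str) -> np.ndarray:
        """Return one channel as a 1-D view."""
        try:
            idx = self.channel_labels.index(label)
        except ValueError:
            raise KeyError(
                f"channel {label!r} not in {self.channel_labels}"
            ) from None
        return self.data[:, idx]


# ---------------------------------------------------------------------------
# plain-text format
# ---------------------------------------------------------------------------

def write_recording_text(recording: Recording, path: str | Path) -> None:
    """Write a recording as TSV plus a ``<path>.json`` sidecar."""
    path = Path(path)
    header = "\t".join(recording.channel_labels)
    np.savetxt(path, recording.data, fmt="%.10g", delimiter="\t",
               header=header, comments="")
    sidecar = {
        "sampling_rate": recording.sampling_rate,
        "channel_labels": recording.channel_labels,
        "metadata": recording.metadata,
    }
    Path(str(path) + ".json").write_text(json.dumps(sidecar, indent=1))


def read_recording_text(path: str | Path) -> Recording:
    path = Path(path)
    sidecar = json.loads(Path(str(path) + ".json").read_text())
    data = np.loadtxt(path, delimiter="\t", skiprows=1, ndmin=2)
    return Recording(
        data=data,
        sampling_rate=sidecar["sampling_rate"],
        channel_labels=list(sidecar["channel_labels"]),
        metadata=sidecar.get("metadata", {}),
    )


# ---------------------------------------------------------------------------
# minimal EDF codec
# ---------------------------------------------------------------------------
# Plain EDF: fixed-width ASCII header, then data records of 2-byte little-
# endian integers.  One record per second here.  The final record is
# zero-padded; the true sample count is stashed in the reserved header field
# so our reader can trim (other EDF readers simply see trailing zeros).

_DIG_MIN, _DIG_MAX = -32768, 32767


def _ascii(value, width: int) -> bytes:
    s = f"{value}"
    if len(s) > width:
        s = s[:width]
    return s.ljust(width).encode("ascii")


def write_recording_edf(recording: Recording, path: str | Path) -> None:
    path = Path(path)
    fs = recording.sampling_rate
    if abs(fs - round(fs)) > 1e-9:
        raise ValueError("EDF writer requires an integer sampling rate")
    fs = int(round(fs))
    n_sig = len(recording.channel_labels)
    n_samples = recording.n_samples
    n_records = max(1, math.ceil(n_samples / fs))

    phys_min = recording.data.min(axis=0)
    phys_max = recording.data.max(axis=0)
    # avoid zero span on constant channels
    span = phys_max - phys_min
    phys_max = np.where(span == 0, phys_min + 1.0, phys_max)

    header = b""
    header += _ascii(0, 8)                       # version
    header += _ascii("X X X X", 80)              # patient id
    header += _ascii("Startdate X X X X", 80)    # recording id
    header += _ascii("01.01.00", 8)              # start date
    header += _ascii("00.00.00", 8)              # start time
    header += _ascii(256 * (1 + n_sig), 8)       # header bytes
    header += _ascii(f"NSAMP={n_samples}", 44)   # reserved: true sample count
    header += _ascii(n_records, 8)
    header += _ascii(1, 8)                       # record duration (s)
    header += _ascii(n_sig, 4)

    for label in recording.channel_labels:
        header += _ascii(label, 16)
    header += b" " * (80 * n_sig)                # transducer
    for _ in range(n_sig):
        header += _ascii("uV", 8)
    for v in phys_min:
        header += _ascii(f"{v:.8g}"[:8], 8)
    for v in phys_max:
        header += _ascii(f"{v:.8g}"[:8], 8)
    for _ in range(n_sig):
        header += _ascii(_DIG_MIN, 8)
    for _ in range(n_sig):
        header += _ascii(_DIG_MAX, 8)
    header += b" " * (80 * n_sig)                # prefiltering
    for _ in range(n_sig):
        header += _ascii(fs, 8)
    header += b" " * (32 * n_sig)                # reserved per signal

    # re-read the printed physical limits so scaling matches what a reader sees
    pmin = np.array([float(f"{v:.8g}"[:8]) for v in phys_min])
    pmax = np.array([float(f"{v:.8g}"[:8]) for v in phys_max])
    gain = (pmax - pmin) / (_DIG_MAX - _DIG_MIN)

    padded = np.zeros((n_records * fs, n_sig))
    padded[:n_samples] = recording.data
    digital = np.rint((padded - pmin) / gain + _DIG_MIN)
    digital = np.clip(digital, _DIG_MIN, _DIG_MAX).astype("<i2")

    with open(path, "wb") as fh:
        fh.write(header)
        for r in range(n_records):
            block = digital[r * fs:(r + 1) * fs]
            fh.write(block.T.tobytes())          # signal-major within record


def read_recording_edf(path: str | Path) -> Recording:
    raw = Path(path).read_bytes()
    reserved = raw[192:236].decode("ascii").strip()
    n_records = int(raw[236:244])
    n_sig = int(raw[252:256])

    off = 256
    labels = [raw[off + 16 * i:off + 16 * (i + 1)].decode().strip()
              for i in range(n_sig)]
    off += 16 * n_sig + 80 * n_sig + 8 * n_sig   # skip transducer, dimension
    pmin = np.array([float(raw[off + 8 * i:off + 8 * (i + 1)])
                     for i in range(n_sig)])
    off += 8 * n_sig
    pmax = np.array([float(raw[off + 8 * i:off + 8 * (i + 1)])
                     for i in range(n_sig)])
    off += 8 * n_sig
    dmin = np.array([int(raw[off + 8 * i:off + 8 * (i + 1)])
                     for i in range(n_sig)])
    off += 8 * n_sig
    dmax = np.array([int(raw[off + 8 * i:off + 8 * (i + 1)])
                     for i in range(n_sig)])
    off += 8 * n_sig + 80 * n_sig
    ns = [int(raw[off + 8 * i:off + 8 * (i + 1)]) for i in range(n_sig)]
    if len(set(ns)) != 1:
        raise ValueError("mixed per-signal sampling rates are not supported")
    fs = ns[0]

    data_start = 256 * (1 + n_sig)
    digital = np.frombuffer(raw, dtype="<i2", offset=data_start)
    digital = digital.reshape(n_records, n_sig, fs).transpose(0, 2, 1)
    digital = digital.reshape(n_records * fs, n_sig).astype(float)

    gain = (pmax - pmin) / (dmax - dmin)
    data = (digital - dmin) * gain + pmin

    if reserved.startswith("NSAMP="):
        data = data[:int(reserved[6:])]
    return Recording(data=data, sampling_rate=float(fs), channel_labels=labels)


def edf_quantization_step(recording: Recording) -> np.ndarray:
    """Per-channel amplitude resolution of the EDF round-trip."""
    span = recording.data.max(axis=0) - recording.data.min(axis=0)
    span = np.where(span == 0, 1.0, span)
    return span / (_DIG_MAX - _DIG_MIN)


def write_recording(recording: Recording, path: str | Path) -> None:
    """Dispatch on extension: ``.edf`` for EDF, anything else for text."""
    if str(path).lower().endswith(".edf"):
        write_recording_edf(recording, path)
    else:
        write_recording_text(recording, path)


def read_recording(path: str | Path) -> Recording:
    if str(path).lower().endswith(".edf"):
        return read_recording_edf(path)
    return read_recording_text(path)


# ---------------------------------------------------------------------------
# event tables
# ---------------------------------------------------------------------------

def validate_events(events: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in EVENT_COLUMNS if c not in events.columns]
    if missing:
        raise ValueError(f"event table missing columns {missing}")
    if not events["onset_s"].is_monotonic_increasing:
        raise ValueError("event onsets must be sorted increasing")
    if ((events["rating"] < 0) | (events["rating"] > 10)).any():
        raise ValueError("ratings must lie in [0, 10]")
    return events


def write_events(events: pd.DataFrame, path: str | Path) -> None:
    validate_events(events)[EVENT_COLUMNS].to_csv(path, index=False)


def read_events(path: str | Path) -> pd.DataFrame:
    return validate_events(pd.read_csv(path))
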