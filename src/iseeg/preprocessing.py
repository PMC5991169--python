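"""Filtering, band decomposition, segment/epoch extraction and N2-P2 scoring.

Conventions: times are in seconds, sample index = floor(t * sampling_rate),
all windows are half-open [start, end).
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import signal as sps

from .io import Recording

#: canonical band set; "full" is the broadband 1-30 Hz range
BANDS: dict[str, tuple[float, float]] = {
    "full": (1.0, 30.0),
    "delta": (1.0, 3.0),
    "theta": (4.0, 7.0),
    "alpha-1": (8.0, 10.0),
    "alpha-2": (11.0, 13.0),
    "beta": (14.0, 30.0),
}


@dataclass(frozen=True)
class BandDefinition:
    name: str
    low: float
    high: float

    def __post_init__(self) -> None:
        if not 0 < self.low < self.high:
            raise ValueError(f"invalid band edges {self.low}-{self.high} Hz")


@dataclass
class InterStimSegment:
    """Single-channel signal between 2 s post-stimulus and the next onset."""

    signal: np.ndarray
    start: float
    end: float
    sampling_rate: float

    @property
    def length(self) -> float:
        return self.end - self.start


@dataclass
class LepEpoch:
    """Peri-stimulus samples with a time axis zeroed at stimulus onset."""

    samples: np.ndarray
    times: np.ndarray
    trial_index: int


class FilterDesignError(ValueError):
    pass


def _design_numtaps(low: float, sampling_rate: float) -> int:
    # transition bandwidth: max(1 Hz, 25% of the lower band edge)
    trans = max(1.0, 0.25 * low)
    numtaps = int(np.ceil(3.3 * sampling_rate / trans))  # Hamming main lobe
    return numtaps + 1 - numtaps % 2


@lru_cache(maxsize=64)
def _fir_taps(low: float, high: float, sampling_rate: float,
              phase_mode: str, numtaps: int) -> np.ndarray:
    taps = sps.firwin(numtaps, [low, high], pass_zero=False,
                      window="hamming", fs=sampling_rate)
    if phase_mode == "minimum":
        taps = sps.minimum_phase(taps, method="homomorphic", half=False)
    return taps


def filter_order(low: float, high: float, sampling_rate: float,
                 phase_mode: str = "minimum") -> int:
    numtaps = _design_numtaps(low, sampling_rate)
    return len(_fir_taps(low, high, sampling_rate, phase_mode, numtaps)) - 1


def bandpass_fir(x: np.ndarray, low: float, high: float,
                 sampling_rate: float, phase_mode: str = "minimum") -> np.ndarray:
    """FIR band-pass along the last axis; output length equals input length.

    phase_mode "minimum" applies a causal minimum-phase filter (used for the
    band decomposition); "zero" applies the linear-phase kernel and removes
    its group delay (used for the broadband pre-filter).
    """
    nyq = sampling_rate / 2.0
    if not (0 < low < high < nyq):
        raise FilterDesignError(
            f"band edges ({low}, {high}) Hz must lie strictly inside (0, {nyq}) Hz"
        )
    if phase_mode not in ("minimum", "zero"):
        raise ValueError(f"unknown phase_mode {phase_mode!r}")
    x = np.asarray(x, dtype=float)
    numtaps = _design_numtaps(low, sampling_rate)
    if numtaps > x.shape[-1] - 1:
        # short input (e.g. a 2-s sub-epoch with a low band edge): widen the
        # transition so the filter fits; refuse only hopeless cases
        numtaps = x.shape[-1] - 1
        numtaps -= 1 - numtaps % 2
        if numtaps < 33:
            raise FilterDesignError(
                f"signal of {x.shape[-1]} samples too short to band-pass "
                f"filter at ({low}, {high}) Hz")
    taps = _fir_taps(low, high, sampling_rate, phase_mode, numtaps)
    full = sps.fftconvolve(x, np.broadcast_to(taps, x.shape[:-1] + (len(taps),)),
                           mode="full", axes=-1) if x.ndim > 1 else \
        sps.fftconvolve(x, taps, mode="full")
    if phase_mode == "minimum":
        return full[..., : x.shape[-1]]
    delay = (len(taps) - 1) // 2
    return full[..., delay: delay + x.shape[-1]]


def extract_interstim_segments(recording: Recording, events: pd.DataFrame,
                               channel: str, offset: float = 2.0
                               ) -> list[InterStimSegment]:
    """Segments from ``onset + offset`` to the next onset, one per onset pair."""
    onsets = np.asarray(events["onset_s"], dtype=float)
    if not np.all(np.diff(onsets) > 0):
        raise ValueError("events must be sorted by strictly increasing onset")
    sig = recording.channel(channel)
    fs = recording.sampling_rate
    segments = []
    for k in range(len(onsets) - 1):
        start, end = onsets[k] + offset, onsets[k + 1]
        if end - start <= 0:
            raise ValueError(
                f"inter-stimulus interval after trial {k} is <= {offset} s; "
                "segment would be empty"
            )
        i0, i1 = int(np.floor(start * fs)), int(np.floor(end * fs))
        segments.append(InterStimSegment(sig[i0:i1], start, end, fs))
    return segments


def segment_to_subepochs(segment: InterStimSegment,
                         epoch_duration: float = 2.0) -> list[np.ndarray]:
    """Tile non-overlapping windows from the segment start; drop the remainder."""
    k = int(round(epoch_duration * segment.sampling_rate))
    n = len(segment.signal) // k
    if n == 0:
        raise ValueError(
            f"segment of {segment.length:.3f} s is shorter than one "
            f"{epoch_duration} s sub-epoch"
        )
    return [segment.signal[i * k:(i + 1) * k] for i in range(n)]


def extract_lep_epochs(recording: Recording, events: pd.DataFrame,
                       channel: str,
                       window: tuple[float, float] = (-0.5, 1.0)
                       ) -> list[LepEpoch]:
    """One epoch per trial; time axis is zero at the stimulus sample."""
    if not (window[0] <= 0.15 and window[1] >= 0.5):
        raise ValueError(f"window {window} must cover [0.15, 0.5] s")
    sig = recording.channel(channel)
    fs = recording.sampling_rate
    epochs = []
    for trial, onset in zip(events["trial_index"], events["onset_s"]):
        onset_idx = int(np.floor(onset * fs))
        i0 = onset_idx + int(np.floor(window[0] * fs))
        i1 = onset_idx + int(np.floor(window[1] * fs))
        if i0 < 0 or i1 > len(sig):
            raise ValueError(
                f"epoch for trial {trial} ([{i0}, {i1})) exceeds recording "
                f"bounds [0, {len(sig)})"
            )
        times = (np.arange(i0, i1) - onset_idx) / fs
        epochs.append(LepEpoch(sig[i0:i1], times, int(trial)))
    return epochs


def n2p2_amplitude(epoch: LepEpoch,
                   search_window: tuple[float, float] = (0.150, 0.500)) -> float:
    """Peak-to-peak amplitude: most positive minus most negative deflection
    within the search window.  Ties resolve to the earliest sample (argmin /
    argmax already return the first occurrence)."""
    lo, hi = search_window
    dt = epoch.times[1] - epoch.times[0]
    # half-open window: the last sample needed is the one just below hi
    if epoch.times[0] > lo + 1e-12 or epoch.times[-1] < hi - dt - 1e-12:
        raise ValueError(
            f"search window {search_window} outside epoch span "
            f"[{epoch.times[0]:.3f}, {epoch.times[-1]:.3f}]"
        )
    mask = (epoch.times >= lo) & (epoch.times < hi)
    window = epoch.samples[mask]
    return float(window.max() - window.min())


def prefilter_recording(recording: Recording,
                        low: float = 1.0, high: float = 30.0,
                        phase_mode: str = "zero") -> Recording:
    """Broadband pre-filter applied once to the continuous recording."""
    filtered = bandpass_fir(recording.data.T, low, high,
                            recording.sampling_rate, phase_mode).T
    return Recording(filtered, recording.sampling_rate,
                     list(recording.channel_labels),
                     dict(recording.metadata, prefilter=[low, high, phase_mode]))


def trials_table(recording: Recording, events: pd.DataFrame, channel: str,
                 window: tuple[float, float] = (-0.5, 1.0),
                 search_window: tuple[float, float] = (0.150, 0.500)
                 ) -> pd.DataFrame:
    """Per-trial table of onset, rating and N2-P2 amplitude (x_i, y_i)."""
    epochs = extract_lep_epochs(recording, events, channel, window)
    amp = [n2p2_amplitude(ep, search_window) for ep in epochs]
    return pd.DataFrame({
        "trial_index": events["trial_index"].to_numpy(),
        "onset_s": events["onset_s"].to_numpy(),
        "energy_J": events["energy_J"].to_numpy(),
        "rating": events["rating"].to_numpy(),
        "n2p2_uV": amp,
    })


def subepoch_manifest(segments: list[InterStimSegment],
                      epoch_duration: float = 2.0) -> pd.DataFrame:
    """Bookkeeping table: one row per extracted sub-epoch."""
    rows = []
    for si, seg in enumerate(segments):
        for ei in range(int(seg.length // epoch_duration)):
            rows.append({"segment_index": si, "subepoch_index": ei,
                         "start_s": seg.start + ei * epoch_duration})
    return pd.DataFrame(rows, columns=["segment_index", "subepoch_index", "start_s"])
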