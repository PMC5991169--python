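"""Inter-stimulus EEG magnitude (RMS) and temporal variability (nMSSD).

Per channel and band, the per-subject feature value is estimated with a
randomized sub-epoch resampling scheme: on each repetition one 2-s sub-epoch
is drawn uniformly from every inter-stimulus segment, the feature is computed
on each draw and averaged across segments; the 50th percentile of the
repetition averages is the reported value.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .io import Recording
from .preprocessing import (BANDS, bandpass_fir, extract_interstim_segments,
                            segment_to_subepochs)

FEATURE_NAMES = ("rms", "nmssd")

#: (channel, band, feature) triple indexing one value of a feature vector
FeatureKey = tuple[str, str, str]


def rms(subepoch: np.ndarray) -> float:
    """Root mean square: sqrt(mean(s_k^2))."""
    x = np.asarray(subepoch, dtype=float)
    if x.size == 0:
        raise ValueError("empty sub-epoch")
    return float(np.sqrt(np.mean(np.square(x))))


def nmssd(subepoch: np.ndarray) -> float:
    """Mean squared successive difference normalized by RMS^2 (dimensionless).

    mean over the K-1 squared successive differences divided by RMS^2; scale
    invariant by construction.
    """
    x = np.asarray(subepoch, dtype=float)
    if x.size < 2:
        raise ValueError("nMSSD needs at least 2 samples")
    denom = np.mean(np.square(x))
    if denom == 0:
        raise ZeroDivisionError("nMSSD undefined for an all-zero sub-epoch")
    return float(np.mean(np.square(np.diff(x))) / denom)


def resampled_feature(segments: Sequence[Sequence[np.ndarray]],
                      feature_fn: Callable[[np.ndarray], float],
                      n_repetitions: int = 100,
                      percentile: float = 50.0,
                      rng: np.random.Generator | None = None) -> float:
    """Percentile of repetition averages of ``feature_fn`` over random draws.

    ``segments`` is a list of sub-epoch lists (one list per inter-stimulus
    segment).  Deterministic for a fixed rng state.  The feature is evaluated
    once per unique sub-epoch; only the sampling is repeated.
    """
    if len(segments) == 0:
        raise ValueError("no segments to resample from")
    for i, seg in enumerate(segments):
        if len(seg) == 0:
            raise ValueError(f"segment {i} has no sub-epochs")
    if rng is None:
        rng = np.random.default_rng()
    values = [np.array([feature_fn(ep) for ep in seg]) for seg in segments]
    counts = np.array([len(v) for v in values])
    draws = rng.integers(0, counts, size=(n_repetitions, len(values)))
    padded = np.zeros((len(values), counts.max()))
    for s, v in enumerate(values):
        padded[s, :len(v)] = v
    averages = padded[np.arange(len(values)), draws].mean(axis=1)
    return float(np.percentile(averages, percentile))


@dataclass
class SubjectFeatureVector:
    """All (channel x band x {rms, nmssd}) feature values for one subject."""

    subject_id: str
    values: pd.Series  # MultiIndex (channel, band, feature)

    def __post_init__(self) -> None:
        self.values = self.values.sort_index()
        if (self.values < 0).any():
            raise ValueError("feature values must be non-negative")

    def get(self, channel: str, band: str, feature: str) -> float:
        return float(self.values.loc[(channel, band, feature)])

    def to_frame(self) -> pd.DataFrame:
        df = self.values.rename("value").reset_index()
        df.columns = ["channel", "band", "feature", "value"]
        df.insert(0, "subject_id", self.subject_id)
        return df


def feature_frame(vectors: Sequence[SubjectFeatureVector]) -> pd.DataFrame:
    """Long-form table over subjects: subject_id, channel, band, feature, value."""
    return pd.concat([v.to_frame() for v in vectors], ignore_index=True)


def vector_from_frame(df: pd.DataFrame, subject_id: str) -> SubjectFeatureVector:
    sub = df[df["subject_id"] == subject_id]
    values = sub.set_index(["channel", "band", "feature"])["value"]
    return SubjectFeatureVector(subject_id, values)


def build_feature_vector(recording: Recording, events: pd.DataFrame,
                         channels: Sequence[str] | None = None,
                         bands: dict[str, tuple[float, float]] = BANDS,
                         n_repetitions: int = 100,
                         percentile: float = 50.0,
                         rng: np.random.Generator | None = None,
                         subject_id: str = "",
                         epoch_duration: float = 2.0) -> SubjectFeatureVector:
    """Compute RMS and nMSSD per channel x band on 2-s inter-stimulus sub-epochs.

    The recording is assumed already broadband (1-30 Hz) pre-filtered; the
    "full" band therefore uses the sub-epochs as-is, while the five narrow
    bands are obtained by minimum-phase causal FIR filtering of each sub-epoch.
    """
    if channels is None:
        channels = recording.channel_labels
    if rng is None:
        rng = np.random.default_rng()
    fs = recording.sampling_rate

    entries = {}
    for channel in channels:
        segments = extract_interstim_segments(recording, events, channel)
        subepochs = [segment_to_subepochs(seg, epoch_duration) for seg in segments]
        lengths = [len(s) for s in subepochs]
        stacked = np.vstack([ep for seg in subepochs for ep in seg])

        for band, (low, high) in bands.items():
            if band == "full":
                flt = stacked
            else:
                flt = bandpass_fir(stacked, low, high, fs, "minimum")
            # regroup filtered rows into their segments
            grouped, pos = [], 0
            for n in lengths:
                grouped.append(list(flt[pos:pos + n]))
                pos += n
            for feature, fn in (("rms", rms), ("nmssd", nmssd)):
                entries[(channel, band, feature)] = resampled_feature(
                    grouped, fn, n_repetitions, percentile, rng)

    index = pd.MultiIndex.from_tuples(entries.keys(),
                                      names=["channel", "band", "feature"])
    return SubjectFeatureVector(subject_id, pd.Series(list(entries.values()),
                                                      index=index))


def subject_rng(master_seed: int, subject_id: str) -> np.random.Generator:
    """Per-subject stream derived from the master seed and the subject id, so
    that cohort ordering does not change any subject's resampling draws."""
    import zlib
    return np.random.default_rng(
        np.random.SeedSequence([master_seed, zlib.crc32(subject_id.encode())]))
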