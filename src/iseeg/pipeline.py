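"""End-to-end composition: synthesis -> preprocessing -> features -> models.

Convenience layer used by the CLI, the test suite and the acceptance script;
each stage remains independently callable through its own module.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .features import SubjectFeatureVector, build_feature_vector, subject_rng
from .individualized_prediction import SubjectData
from .io import Recording
from .preprocessing import prefilter_recording, trials_table
from .synthetic_data import (GeneratorConfig, SubjectProfile,
                             draw_subject_profiles, generate_subject)


@dataclass
class ProcessedSubject:
    profile: SubjectProfile
    trials: pd.DataFrame
    features: SubjectFeatureVector

    def as_subject_data(self) -> SubjectData:
        return SubjectData(self.profile.subject_id, self.trials, self.features)


def process_recording(recording: Recording, events: pd.DataFrame,
                      channel: str, subject_id: str = "",
                      n_repetitions: int = 100, percentile: float = 50.0,
                      rng: np.random.Generator | None = None,
                      prefilter: bool = True,
                      feature_channels: list[str] | None = None
                      ) -> tuple[pd.DataFrame, SubjectFeatureVector]:
    """Broadband pre-filter once, then score trials and build the feature vector."""
    rec = prefilter_recording(recording) if prefilter else recording
    trials = trials_table(rec, events, channel)
    vector = build_feature_vector(
        rec, events,
        channels=feature_channels or [channel],
        n_repetitions=n_repetitions, percentile=percentile,
        rng=rng, subject_id=subject_id)
    return trials, vector


def simulate_cohort(config: GeneratorConfig,
                    n_repetitions: int = 100,
                    percentile: float = 50.0,
                    prefilter: bool = True) -> list[ProcessedSubject]:
    """Generate and fully process a synthetic cohort.

    Synthesis randomness comes from per-subject streams spawned off the master
    seed; feature-resampling randomness uses a stream keyed by (seed,
    subject_id), so cohort size and ordering never change a subject's values.
    """
    master = np.random.SeedSequence(config.seed)
    profile_rng = np.random.default_rng(master.spawn(1)[0])
    profiles = draw_subject_profiles(config, profile_rng)

    out = []
    for profile, child in zip(profiles, master.spawn(len(profiles) + 1)[1:]):
        rec_rng = np.random.default_rng(child)
        recording, events = generate_subject(profile, config, rec_rng)
        feat_rng = subject_rng(config.seed, profile.subject_id)
        trials, vector = process_recording(
            recording, events, config.lep_channel,
            subject_id=profile.subject_id,
            n_repetitions=n_repetitions, percentile=percentile,
            rng=feat_rng, prefilter=prefilter)
        out.append(ProcessedSubject(profile, trials, vector))
    return out
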