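"""Similarity-weighted cross-individual pain prediction with LOO evaluation.

For a held-out test subject, every training subject's linear model predicts
the test subject's ratings from evoked amplitudes; predictions are combined
with weights derived from the Euclidean distance between isEEG feature
sub-vectors: training subjects farther than the mean distance get weight 0,
the rest get max(diff) - diff.  The conventional baseline is the unweighted
mean over all training models.  Performance is the mean absolute error over
the held-out subject's fast-pain trials.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .correlation_analysis import run_group_correlation, significant_keys
from .features import SubjectFeatureVector, feature_frame
from .lep_pain_model import (LepPainModel, check_inclusion, fit_subject,
                             models_frame, select_fast_pain)

logger = logging.getLogger(__name__)


@dataclass
class SubjectData:
    """One subject's inputs to the prediction stage."""

    subject_id: str
    trials: pd.DataFrame                 # columns rating, n2p2_uV (at least)
    features: SubjectFeatureVector


@dataclass
class PredictionResult:
    subject_id: str
    true_ratings: np.ndarray
    individualized: np.ndarray
    conventional: np.ndarray
    mae_individualized: float
    mae_conventional: float
    n_trials: int
    fallback_used: bool
    selected_keys: list = field(default_factory=list)


def predict_with_model(x: float | np.ndarray, model: LepPainModel) -> np.ndarray:
    """Rating from amplitude: a*x + b (not clipped by default)."""
    return model.predict_rating(x)


def compute_diffs(test_vector: SubjectFeatureVector,
                  training_vectors: Sequence[SubjectFeatureVector],
                  selected_keys: Sequence[tuple[str, str, str]],
                  standardize: bool = True) -> np.ndarray:
    """Euclidean distance between (optionally z-scored) feature sub-vectors.

    Standardization parameters come from the training subjects only and are
    applied to the test subject (no leakage).
    """
    if len(selected_keys) == 0:
        raise ValueError("selected_keys must be non-empty")
    try:
        train = np.array([[v.values.loc[k] for k in selected_keys]
                          for v in training_vectors])
        test = np.array([test_vector.values.loc[k] for k in selected_keys])
    except KeyError as exc:
        raise KeyError(f"feature key missing from a vector: {exc}") from exc
    if standardize:
        mean = train.mean(axis=0)
        sd = train.std(axis=0, ddof=0)
        sd = np.where(sd == 0, 1.0, sd)  # constant key carries no distance
        train = (train - mean) / sd
        test = (test - mean) / sd
    return np.sqrt(np.sum((train - test) ** 2, axis=1))


def compute_weights(diffs: np.ndarray) -> np.ndarray:
    """Zero for diffs strictly above the mean, max(diff) - diff otherwise.

    Mean and max are taken over all N-1 diffs, including those zeroed.
    """
    d = np.asarray(diffs, dtype=float)
    if len(d) == 0:
        raise ValueError("need at least one diff")
    if not np.all(np.isfinite(d)) or (d < 0).any():
        raise ValueError("diffs must be finite and non-negative")
    return np.where(d > d.mean(), 0.0, d.max() - d)


def weighted_predict(per_model_predictions: np.ndarray,
                     weights: np.ndarray) -> float:
    """Weighted average; unweighted mean when all weights vanish."""
    p = np.asarray(per_model_predictions, dtype=float)
    w = np.asarray(weights, dtype=float)
    if p.shape != w.shape:
        raise ValueError(f"length mismatch: {p.shape} vs {w.shape}")
    total = w.sum()
    if total == 0:
        return float(p.mean())
    return float(np.sum(w * p) / total)


def mean_absolute_error(true: np.ndarray, predicted: np.ndarray) -> float:
    true = np.asarray(true, dtype=float)
    predicted = np.asarray(predicted, dtype=float)
    if true.shape != predicted.shape:
        raise ValueError("length mismatch")
    return float(np.mean(np.abs(true - predicted)))


def paired_ttest(mae_individualized: np.ndarray,
                 mae_conventional: np.ndarray) -> tuple[float, float]:
    """Paired t on per-subject MAE differences, two-sided."""
    a = np.asarray(mae_individualized, dtype=float)
    b = np.asarray(mae_conventional, dtype=float)
    if a.shape != b.shape or len(a) < 3:
        raise ValueError("need equal-length inputs with at least 3 pairs")
    diff = a - b
    if diff.std(ddof=1) == 0:
        raise ValueError("zero-variance differences: paired t undefined")
    t, p = stats.ttest_rel(a, b)
    return float(t), float(p)


def loocv_evaluate(subjects: Sequence[SubjectData],
                   alpha: float = 0.05,
                   feature_selection: str = "significant",
                   fallback_keys_channel: str | None = None,
                   standardize: bool = True,
                   clip_predictions: bool = False,
                   min_fast_trials: int = 3,
                   fit_direction: str = "rating_on_amplitude"
                   ) -> list[PredictionResult]:
    """Leave-one-individual-out evaluation of both prediction schemes.

    feature_selection "significant" re-identifies the isEEG correlates on the
    training subjects of each fold (keys significant in the group correlation);
    when none are significant — or with feature_selection "all" — every feature
    key (optionally restricted to fallback_keys_channel) is used.
    """
    included = []
    for s in subjects:
        if check_inclusion(s.trials):
            included.append(s)
        else:
            logger.info("subject %s excluded: no fast-pain trial with NRS >= 7",
                        s.subject_id)
    if len(included) < 3:
        raise ValueError(f"only {len(included)} included subjects; need >= 3")

    models = {s.subject_id: fit_subject(s.trials, s.subject_id,
                                        min_trials=min_fast_trials,
                                        fit_direction=fit_direction)
              for s in included}

    all_keys = list(included[0].features.values.index)
    if fallback_keys_channel is not None:
        all_keys = [k for k in all_keys if k[0] == fallback_keys_channel]

    results = []
    for m, test in enumerate(included):
        training = [s for i, s in enumerate(included) if i != m]

        if feature_selection == "significant":
            corr = run_group_correlation(
                feature_frame([s.features for s in training]),
                models_frame([models[s.subject_id] for s in training]),
                alpha=alpha, min_subjects=3)
            keys = [k for k in significant_keys(corr) if k in set(all_keys)]
            if not keys:
                keys = all_keys
        elif feature_selection == "all":
            keys = all_keys
        else:
            raise ValueError(f"unknown feature_selection {feature_selection!r}")

        diffs = compute_diffs(test.features,
                              [s.features for s in training], keys,
                              standardize=standardize)
        weights = compute_weights(diffs)
        fallback = bool(weights.sum() == 0)

        fast = select_fast_pain(test.trials)
        x = fast["n2p2_uV"].to_numpy()
        true = fast["rating"].to_numpy(dtype=float)
        per_model = np.array([
            predict_with_model(x, models[s.subject_id]) for s in training
        ])  # (n_training, n_trials)
        indiv = np.array([weighted_predict(per_model[:, i], weights)
                          for i in range(per_model.shape[1])])
        conv = per_model.mean(axis=0)
        if clip_predictions:
            indiv = np.clip(indiv, 0, 10)
            conv = np.clip(conv, 0, 10)

        results.append(PredictionResult(
            subject_id=test.subject_id,
            true_ratings=true,
            individualized=indiv,
            conventional=conv,
            mae_individualized=mean_absolute_error(true, indiv),
            mae_conventional=mean_absolute_error(true, conv),
            n_trials=len(true),
            fallback_used=fallback,
            selected_keys=keys,
        ))
    return results


def results_frame(results: Sequence[PredictionResult]) -> pd.DataFrame:
    return pd.DataFrame([{
        "subject_id": r.subject_id,
        "n_trials": r.n_trials,
        "mae_individualized": r.mae_individualized,
        "mae_conventional": r.mae_conventional,
        "fallback_used": r.fallback_used,
    } for r in results])


def summarize(results: Sequence[PredictionResult]) -> dict:
    """Cohort summary: MAE means/SDs per scheme and the paired comparison."""
    df = results_frame(results)
    t, p = paired_ttest(df["mae_individualized"].to_numpy(),
                        df["mae_conventional"].to_numpy())
    return {
        "n_subjects": int(len(df)),
        "mae_individualized_mean": float(df["mae_individualized"].mean()),
        "mae_individualized_sd": float(df["mae_individualized"].std(ddof=1)),
        "mae_conventional_mean": float(df["mae_conventional"].mean()),
        "mae_conventional_sd": float(df["mae_conventional"].std(ddof=1)),
        "t": t,
        "p": p,
    }
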