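"""Per-subject linear fast-pain models linking evoked amplitude and rating.

The rating-on-amplitude regression y = a*x + b is fitted by ordinary least
squares on fast-pain trials (rating > 4) and algebraically inverted to the
amplitude-on-rating form x = c*y + d with c = 1/a, d = -b/a.  The inversion
is exact algebra, not a second regression: both parameter pairs describe the
same fitted line.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

REPARAM_TOL = 1e-8
MIN_FAST_TRIALS = 3


class InsufficientDataError(ValueError):
    pass


class DegenerateDesignError(ValueError):
    pass


@dataclass
class LepPainModel:
    subject_id: str
    a: float            # rating per uV
    b: float            # rating
    c: float            # uV per rating unit (= 1/a)
    d: float            # uV (= -b/a)
    n_fast_trials: int
    fit_r: float

    def predict_rating(self, x: float | np.ndarray) -> np.ndarray:
        return self.a * np.asarray(x, dtype=float) + self.b


def select_fast_pain(trials: pd.DataFrame) -> pd.DataFrame:
    """Trials with rating strictly greater than 4, order preserved."""
    return trials[trials["rating"] > 4]


def check_inclusion(trials: pd.DataFrame) -> bool:
    """A subject is included only if some fast-pain trial reaches NRS >= 7."""
    fast = select_fast_pain(trials)
    return bool((fast["rating"] >= 7).any())


def reparameterize(a: float, b: float,
                   tol: float = REPARAM_TOL) -> tuple[float, float]:
    """(a, b) of rating-on-amplitude -> (c, d) of amplitude-on-rating.

    Involution: applying it twice returns (a, b).
    """
    if abs(a) <= tol:
        raise ZeroDivisionError(
            f"slope a = {a!r} too close to zero to invert (tol {tol})")
    return 1.0 / a, -b / a


def fit_lep_pain(x: np.ndarray, y: np.ndarray, subject_id: str = "",
                 min_trials: int = MIN_FAST_TRIALS,
                 fit_direction: str = "rating_on_amplitude") -> LepPainModel:
    """OLS fit of the fast-pain trials.

    fit_direction "rating_on_amplitude" (default) regresses y on x and derives
    (c, d) algebraically; "amplitude_on_rating" regresses x on y directly and
    derives (a, b) by the inverse map (the two differ under noise).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("x and y must have equal length")
    if len(x) < min_trials:
        raise InsufficientDataError(
            f"{len(x)} fast-pain trials < required minimum {min_trials}")
    if fit_direction == "rating_on_amplitude":
        if np.var(x) == 0:
            raise DegenerateDesignError("zero variance in LEP amplitudes")
        res = stats.linregress(x, y)
        a, b = float(res.slope), float(res.intercept)
        c, d = reparameterize(a, b)
    elif fit_direction == "amplitude_on_rating":
        if np.var(y) == 0:
            raise DegenerateDesignError("zero variance in ratings")
        res = stats.linregress(y, x)
        c, d = float(res.slope), float(res.intercept)
        a, b = reparameterize(c, d)
    else:
        raise ValueError(f"unknown fit_direction {fit_direction!r}")
    return LepPainModel(subject_id=subject_id, a=a, b=b, c=c, d=d,
                        n_fast_trials=len(x), fit_r=float(res.rvalue))


def fit_subject(trials: pd.DataFrame, subject_id: str = "",
                min_trials: int = MIN_FAST_TRIALS,
                fit_direction: str = "rating_on_amplitude") -> LepPainModel:
    """Select fast-pain trials from a per-trial table and fit."""
    fast = select_fast_pain(trials)
    return fit_lep_pain(fast["n2p2_uV"].to_numpy(), fast["rating"].to_numpy(),
                        subject_id=subject_id, min_trials=min_trials,
                        fit_direction=fit_direction)


def models_frame(models: list[LepPainModel],
                 included: dict[str, bool] | None = None) -> pd.DataFrame:
    rows = []
    for m in models:
        rows.append({
            "subject_id": m.subject_id, "a": m.a, "b": m.b, "c": m.c, "d": m.d,
            "n_fast_trials": m.n_fast_trials, "fit_r": m.fit_r,
            "included": True if included is None else included[m.subject_id],
        })
    return pd.DataFrame(rows)
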