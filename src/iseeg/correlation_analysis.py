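"""Cross-individual correlation of isEEG features with model parameters.

Every (channel, band, feature) value is correlated with each of the two
amplitude-on-rating parameters c and d across subjects; Bonferroni correction
is applied over the full grid of tests performed in the run.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats


def pearson(values_x: np.ndarray, values_y: np.ndarray) -> tuple[float, float]:
    """Pearson product-moment r with two-sided p (t distribution, n-2 df)."""
    x = np.asarray(values_x, dtype=float)
    y = np.asarray(values_y, dtype=float)
    if len(x) != len(y):
        raise ValueError("inputs must have equal length")
    if len(x) < 4:
        raise ValueError(f"need at least 4 pairs, got {len(x)}")
    if np.var(x) == 0 or np.var(y) == 0:
        raise ValueError("correlation undefined for a constant input")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def spearman(values_x: np.ndarray, values_y: np.ndarray) -> tuple[float, float]:
    r, p = stats.spearmanr(values_x, values_y)
    return float(r), float(p)


def bonferroni_mask(p_values: np.ndarray, alpha: float = 0.05,
                    n_tests: int | None = None) -> np.ndarray:
    """significant iff p < alpha / n_tests."""
    p = np.asarray(p_values, dtype=float)
    if n_tests is None:
        n_tests = len(p)
    if n_tests == 0:
        raise ValueError("n_tests must be positive")
    if n_tests < len(p):
        raise ValueError(f"n_tests {n_tests} < number of p-values {len(p)}")
    return p < alpha / n_tests


def run_group_correlation(features: pd.DataFrame, models: pd.DataFrame,
                          alpha: float = 0.05, min_subjects: int = 10,
                          method: str = "pearson") -> pd.DataFrame:
    """Correlate every feature key with c and d across subjects.

    features: long-form (subject_id, channel, band, feature, value);
    models: per-subject (subject_id, c, d).  Returns one row per
    (channel, band, feature, parameter) with r, p, p_threshold, significant.
    The Bonferroni family is every test performed in this run.
    """
    feat_subjects = set(features["subject_id"])
    model_subjects = set(models["subject_id"])
    if feat_subjects != model_subjects:
        raise ValueError(
            "feature/model subject sets differ; "
            f"features-only={sorted(feat_subjects - model_subjects)}, "
            f"models-only={sorted(model_subjects - feat_subjects)}")
    if len(feat_subjects) < min_subjects:
        raise ValueError(
            f"{len(feat_subjects)} subjects < required minimum {min_subjects}")

    corr_fn = {"pearson": pearson, "spearman": spearman}[method]
    params = models.set_index("subject_id")[["c", "d"]]
    wide = features.pivot_table(index="subject_id",
                                columns=["channel", "band", "feature"],
                                values="value")
    wide = wide.loc[params.index]

    rows = []
    for key in wide.columns:
        channel, band, feature = key
        for parameter in ("c", "d"):
            r, p = corr_fn(wide[key].to_numpy(), params[parameter].to_numpy())
            rows.append({"channel": channel, "band": band, "feature": feature,
                         "parameter": parameter, "r": r, "p": p})
    result = pd.DataFrame(rows)
    n_tests = len(result)
    result["p_threshold"] = alpha / n_tests
    result["significant"] = bonferroni_mask(result["p"].to_numpy(), alpha,
                                            n_tests)
    result.attrs["n_tests"] = n_tests
    result.attrs["alpha"] = alpha
    return result


def significant_keys(correlations: pd.DataFrame) -> list[tuple[str, str, str]]:
    """Feature keys significant for either parameter, deduplicated, ordered."""
    sig = correlations[correlations["significant"]]
    keys, seen = [], set()
    for _, row in sig.iterrows():
        key = (row["channel"], row["band"], row["feature"])
        if key not in seen:
            seen.add(key)
            keys.append(key)
    return keys
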