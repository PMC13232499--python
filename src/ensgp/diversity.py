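"""Ensemble averaging and the Diversity Prediction Theorem decomposition.

For N member predictions M_i of a true value V, with ensemble mean M_bar:

    (M_bar - V)^2 = sum_i (M_i - V)^2 / N  -  sum_i (M_i - M_bar)^2 / N

i.e. Many-Model (ensemble) error = mean member error - prediction
diversity. The identity is algebraic and is asserted on every
decomposition; it guarantees the ensemble's squared error never exceeds the
mean member squared error. Scenario-level term values are means over the
scenario's test samples, which makes term 1 equal the ensemble's MSE.

Term values are summarized per trait x dataset by mean, standard error of
the mean, and the coefficient of variation CV = sd / mean across
scenario-level values (CV is the dimensionless diversity metric; a larger
CV of the third term means more diverse member predictions).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["DiversityDecomposition", "ensemble_average", "decompose", "summarize_terms"]


@dataclass
class DiversityDecomposition:
    """Per-scenario theorem terms (scenario means and per-sample values)."""

    scenario_id: str
    n_models: int
    ensemble_error: float  # term 1 (scenario mean over test samples)
    mean_error: float  # term 2
    prediction_diversity: float  # term 3
    per_sample: pd.DataFrame | None = None


def ensemble_average(member_predictions: dict[str, np.ndarray]) -> np.ndarray:
    """Equal-weight ensemble: per-sample arithmetic mean of the member
    predictions (all members must be aligned to the same test set)."""
    if not member_predictions:
        raise ValueError("no member predictions")
    arrays = [np.asarray(v, dtype=float) for v in member_predictions.values()]
    n = {a.shape for a in arrays}
    if len(n) != 1:
        raise ValueError(f"member predictions misaligned: shapes {sorted(n)}")
    return np.mean(np.vstack(arrays), axis=0)


def decompose(
    member_predictions: dict[str, np.ndarray],
    observed: np.ndarray,
    scenario_id: str = "",
    keep_per_sample: bool = False,
) -> DiversityDecomposition:
    """Diversity Prediction Theorem terms for one prediction scenario.

    Terms are computed per test sample and averaged over the scenario's
    test set; the identity term1 = term2 - term3 is asserted to 1e-10
    relative tolerance.
    """
    if not member_predictions:
        raise ValueError("need at least one model")
    observed = np.asarray(observed, dtype=float)
    M = np.vstack([np.asarray(v, float) for v in member_predictions.values()])
    if M.shape[1] != len(observed):
        raise ValueError("observed values missing for some test samples")
    m_bar = M.mean(axis=0)
    t1 = (m_bar - observed) ** 2
    t2 = ((M - observed) ** 2).mean(axis=0)
    t3 = ((M - m_bar) ** 2).mean(axis=0)
    scale = max(np.abs(t2).max(), 1e-30)
    if np.abs(t1 - (t2 - t3)).max() > 1e-10 * scale:
        raise AssertionError("diversity identity violated beyond numerical tolerance")
    per_sample = None
    if keep_per_sample:
        per_sample = pd.DataFrame(
            {"ensemble_error": t1, "mean_error": t2, "prediction_diversity": t3}
        )
    return DiversityDecomposition(
        scenario_id=scenario_id,
        n_models=M.shape[0],
        ensemble_error=float(t1.mean()),
        mean_error=float(t2.mean()),
        prediction_diversity=float(t3.mean()),
        per_sample=per_sample,
    )


def summarize_terms(
    decompositions: list[DiversityDecomposition],
    group_labels: list | None = None,
) -> pd.DataFrame:
    """Mean, standard error and CV of the three theorem terms.

    One row per (group, term). ``group_labels`` (e.g. "trait|dataset"
    strings, one per decomposition) default to a single pooled group. The
    CV uses the sample standard deviation across scenario-level term values
    within the group; with a single scenario the CV is flagged unavailable
    (NaN), as it is when the term mean is 0.
    """
    if not decompositions:
        raise ValueError("no decompositions to summarize")
    labels = group_labels if group_labels is not None else ["all"] * len(decompositions)
    df = pd.DataFrame(
        {
            "group": labels,
            "ensemble_error": [d.ensemble_error for d in decompositions],
            "mean_error": [d.mean_error for d in decompositions],
            "prediction_diversity": [d.prediction_diversity for d in decompositions],
        }
    )
    rows = []
    for grp, sub in df.groupby("group"):
        for term in ("ensemble_error", "mean_error", "prediction_diversity"):
            vals = sub[term].to_numpy()
            mean = vals.mean()
            if len(vals) >= 2:
                sd = vals.std(ddof=1)
                se = sd / np.sqrt(len(vals))
                cv = sd / mean if mean != 0 else np.nan
            else:
                se, cv = np.nan, np.nan
            rows.append(
                {
                    "group": grp,
                    "term": term,
                    "mean": mean,
                    "se": se,
                    "cv": cv,
                    "n_scenarios": len(vals),
                }
            )
    return pd.DataFrame(rows)
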