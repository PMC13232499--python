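"""Per-marker effect extraction, normalization, ensembling and genome tracks.

Each fitted model yields a :class:`MarkerEffectProfile` by the method suited
to its family:

* rrBLUP / BayesB — allele substitution effects (posterior-mean marker
  coefficients);
* RF — impurity-based feature importance (total weighted impurity decrease
  per marker, averaged over trees);
* RKHS / SVR / MLP — Shapley scores from seeded permutation sampling with a
  background set supplying absent-feature values; the marker effect is the
  mean |Shapley value| over the explanation set.

Shapley scores are also applied to the RF at the pairwise level to estimate
marker-by-marker interaction effects (Shapley interaction index by subset
sampling); the top 0.01% of pairs by |score| form the reported
:class:`InteractionSet`.

Normalization is max-|value| scaling per model, so every profile lies in
[0, 1] and the equal-weight ensemble profile is the per-marker mean of the
six normalized member profiles. Profiles bin into 10 genome-track levels by
deciles of the normalized effect (ties share the lower level; level 10 is
strongest).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .simulate import GeneticMap

__all__ = [
    "MarkerEffectProfile",
    "InteractionSet",
    "effects_linear",
    "effects_impurity",
    "shapley_values",
    "shapley_effects",
    "pairwise_shapley_rf",
    "normalize_effects",
    "ensemble_effects",
    "quantile_bin_track",
]


@dataclass
class MarkerEffectProfile:
    """Raw and normalized per-marker effects from one model (or the ensemble)."""

    model_id: str
    method: str  # allele_substitution | impurity | shapley | ensemble
    marker_ids: list
    raw: np.ndarray
    normalized: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.raw = np.asarray(self.raw, dtype=float)
        if len(self.raw) != len(self.marker_ids):
            raise ValueError("one effect per marker required")
        if self.normalized is not None:
            self.normalized = np.asarray(self.normalized, dtype=float)
            if ((self.normalized < -1e-12) | (self.normalized > 1 + 1e-12)).any():
                raise ValueError("normalized effects must lie in [0, 1]")


@dataclass
class InteractionSet:
    """Top marker-pair interaction scores (selection quantile of 0.01%)."""

    pairs: pd.DataFrame  # marker_i, marker_j, score, within_chromosome
    selection_quantile: float = 1e-4
    all_scores: pd.DataFrame | None = field(default=None, repr=False)


# ---------------------------------------------------------------------------
# Per-model extraction
# ---------------------------------------------------------------------------


def effects_linear(model, marker_ids: list | None = None) -> MarkerEffectProfile:
    """Allele substitution effects of a fitted rrBLUP/BayesB model: the
    posterior-mean marker coefficients. A function of the training fit only;
    marker columns beyond ``marker_ids`` (e.g. environment factors) are
    dropped when ids are given."""
    if getattr(model, "effects_", None) is None:
        raise ValueError(f"{model.model_id}: no retained posterior-mean effects")
    raw = np.asarray(model.effects_, dtype=float)
    if marker_ids is not None:
        raw = raw[: len(marker_ids)]
        ids = list(marker_ids)
    else:
        ids = [f"m{j}" for j in range(len(raw))]
    return MarkerEffectProfile(model.model_id, "allele_substitution", ids, raw)


def effects_impurity(model, marker_ids: list | None = None) -> MarkerEffectProfile:
    """Impurity-based importance of a fitted RF: the total weighted impurity
    decrease contributed by each marker's split nodes, averaged over trees
    (nonnegative; sums to 1 after the library's normalization)."""
    if getattr(model, "forest_", None) is None:
        raise ValueError("RF model must be fitted")
    raw = model.forest_.feature_importances_
    if marker_ids is not None:
        raw = raw[: len(marker_ids)]
        ids = list(marker_ids)
    else:
        ids = [f"m{j}" for j in range(len(raw))]
    return MarkerEffectProfile(model.model_id, "impurity", ids, np.asarray(raw, float))


# ---------------------------------------------------------------------------
# Shapley scores
# ---------------------------------------------------------------------------


def shapley_values(
    predict_fn,
    X_explain: np.ndarray,
    background: np.ndarray,
    n_permutations: int = 30,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Permutation-sampling estimate of per-sample Shapley values.

    For each explained sample and each seeded random feature ordering, the
    sample's features replace those of a background draw one at a time; the
    prediction increments are the ordering's marginal contributions. The
    estimate satisfies the efficiency property exactly with respect to the
    drawn baselines: sum_j phi_j = f(x) - mean_k f(z_k).

    Returns ``(phi, baseline)`` where phi is (n_explain, p) and baseline the
    per-sample mean prediction over the drawn background rows.
    """
    X_explain = np.atleast_2d(np.asarray(X_explain, dtype=float))
    background = np.atleast_2d(np.asarray(background, dtype=float))
    if background.shape[0] == 0:
        raise ValueError("background set must be non-empty")
    n, p = X_explain.shape
    rng = np.random.default_rng(seed)
    phi = np.zeros((n, p))
    baseline = np.zeros(n)
    for i in range(n):
        x = X_explain[i]
        # states: per permutation a path of p+1 points from background to x
        states = np.empty((n_permutations, p + 1, p))
        orders = np.empty((n_permutations, p), dtype=np.int64)
        for k in range(n_permutations):
            z = background[rng.integers(background.shape[0])].copy()
            order = rng.permutation(p)
            orders[k] = order
            states[k, 0] = z
            for step, j in enumerate(order):
                z = z.copy()
                z[j] = x[j]
                states[k, step + 1] = z
        preds = np.asarray(predict_fn(states.reshape(-1, p))).reshape(
            n_permutations, p + 1
        )
        increments = np.diff(preds, axis=1)  # (k, p): contribution at step s
        for k in range(n_permutations):
            phi[i, orders[k]] += increments[k]
        phi[i] /= n_permutations
        baseline[i] = preds[:, 0].mean()
    return phi, baseline


def shapley_effects(
    model,
    X_explain: np.ndarray,
    background: np.ndarray,
    n_permutations: int = 30,
    seed: int = 0,
    marker_ids: list | None = None,
    efficiency_tol: float = 1e-3,
    y_spread: float | None = None,
) -> MarkerEffectProfile:
    """Shapley-score marker effects for a fitted RKHS/SVR/MLP model.

    Marker effect = mean |Shapley value| over the explanation set. The
    efficiency property |sum_j phi_j - (f(x) - baseline)| <= tol * spread(y)
    is asserted per explained sample (exact up to float rounding for this
    estimator).
    """
    phi, baseline = shapley_values(
        model.predict, X_explain, background, n_permutations, seed
    )
    fx = np.asarray(model.predict(np.atleast_2d(X_explain)))
    gap = np.abs(phi.sum(axis=1) - (fx - baseline))
    spread = y_spread if y_spread is not None else (np.abs(fx).max() + 1.0)
    if (gap > efficiency_tol * spread).any():
        raise AssertionError(
            f"Shapley efficiency violated: max gap {gap.max():.3g} "
            f"> {efficiency_tol} * spread {spread:.3g}"
        )
    raw = np.abs(phi).mean(axis=0)
    if marker_ids is not None:
        raw = raw[: len(marker_ids)]
        ids = list(marker_ids)
    else:
        ids = [f"m{j}" for j in range(len(raw))]
    return MarkerEffectProfile(model.model_id, "shapley", ids, raw)


# ---------------------------------------------------------------------------
# Pairwise interactions from RF
# ---------------------------------------------------------------------------


def _interaction_delta(predict_fn, x, background_row, subset, i, j, p):
    """Delta_ij(S) = f(S+i+j) - f(S+i) - f(S+j) + f(S), features outside
    S+i+j taken from the background row."""
    base = background_row.copy()
    base[subset] = x[subset]
    rows = np.tile(base, (4, 1))
    rows[0, i] = x[i]
    rows[0, j] = x[j]
    rows[1, i] = x[i]
    rows[2, j] = x[j]
    f = predict_fn(rows)
    return f[0] - f[1] - f[2] + f[3]


def pairwise_shapley_rf(
    model,
    X_explain: np.ndarray,
    seed: int = 0,
    n_samples: int = 20,
    background: np.ndarray | None = None,
    gmap: GeneticMap | None = None,
    marker_ids: list | None = None,
    candidate_pairs: list | None = None,
    selection_quantile: float = 1e-4,
) -> InteractionSet:
    """Pairwise Shapley interaction scores from a fitted random forest.

    The Shapley interaction index of a pair (i, j) is estimated by subset
    sampling: a subset size k is drawn uniformly on {0, ..., p-2} and then a
    uniform k-subset S of the remaining features — exactly the Shapley
    interaction kernel — and Delta_ij(S) is averaged over draws and over the
    explanation set; the score is the mean |interaction|. Scores are
    symmetric in (i, j) by construction. The reported set keeps the top
    0.01% of all p(p-1)/2 pairs by |score| (at least one pair), each flagged
    within/between chromosome when a map is given.

    ``candidate_pairs`` restricts the scored pairs (unscored pairs count as
    zero in the selection) — the standard way to keep dense panels tractable
    by pre-screening on single-marker importance.
    """
    X_explain = np.atleast_2d(np.asarray(X_explain, dtype=float))
    n, p = X_explain.shape
    if p < 2:
        raise ValueError("pairwise interactions need at least 2 markers")
    if background is None:
        background = X_explain
    rng = np.random.default_rng(seed)
    predict_fn = model.predict
    ids = list(marker_ids) if marker_ids is not None else [f"m{k}" for k in range(p)]
    p_markers = len(ids)
    pairs = (
        candidate_pairs
        if candidate_pairs is not None
        else [(i, j) for i in range(p_markers) for j in range(i + 1, p_markers)]
    )
    scores = {}
    others_template = np.arange(p_markers)
    for (i, j) in pairs:
        if i == j:
            raise ValueError("self-pairs are not allowed")
        acc = 0.0
        others = others_template[(others_template != i) & (others_template != j)]
        for _ in range(n_samples):
            k = rng.integers(0, p_markers - 1)  # |S| uniform on 0..p-2
            subset = rng.choice(others, size=k, replace=False) if k else np.empty(0, int)
            x = X_explain[rng.integers(n)]
            z = background[rng.integers(background.shape[0])]
            acc += _interaction_delta(predict_fn, x, z, subset, i, j, p)
        scores[(min(i, j), max(i, j))] = abs(acc / n_samples)

    n_pairs_total = p_markers * (p_markers - 1) // 2
    n_keep = max(1, math.ceil(selection_quantile * n_pairs_total))
    all_rows = []
    for (i, j), s in scores.items():
        within = (
            bool(gmap.chromosome[i] == gmap.chromosome[j]) if gmap is not None else True
        )
        all_rows.append((ids[i], ids[j], s, within))
    all_df = pd.DataFrame(
        all_rows, columns=["marker_i", "marker_j", "score", "within_chromosome"]
    ).sort_values("score", ascending=False, kind="mergesort")
    top = all_df.head(n_keep).reset_index(drop=True)
    return InteractionSet(pairs=top, selection_quantile=selection_quantile, all_scores=all_df)


# ---------------------------------------------------------------------------
# Normalization, ensembling, tracks
# ---------------------------------------------------------------------------


def normalize_effects(profile: MarkerEffectProfile) -> MarkerEffectProfile:
    """Max-|value| scaling: normalized_j = |raw_j| / max_k |raw_k|; an
    all-zero raw vector maps to all zeros. Scale-invariant in the raw
    effects (c * raw gives the same output for c != 0)."""
    raw = np.abs(profile.raw)
    top = raw.max() if raw.size else 0.0
    normalized = raw / top if top > 0 else np.zeros_like(raw)
    return MarkerEffectProfile(
        profile.model_id, profile.method, list(profile.marker_ids), profile.raw, normalized
    )


def ensemble_effects(profiles: list[MarkerEffectProfile]) -> MarkerEffectProfile:
    """Equal-weight ensemble effect: per-marker arithmetic mean of the
    member models' normalized effects (profiles are normalized on the fly
    if needed). Marker sets must agree exactly."""
    if not profiles:
        raise ValueError("need at least one member profile")
    ref = list(profiles[0].marker_ids)
    norms = []
    for pr in profiles:
        if list(pr.marker_ids) != ref:
            raise ValueError(
                f"marker sets differ between {profiles[0].model_id} and {pr.model_id}"
            )
        norms.append(
            pr.normalized if pr.normalized is not None else normalize_effects(pr).normalized
        )
    mean = np.mean(np.vstack(norms), axis=0)
    return MarkerEffectProfile("ensemble", "ensemble", ref, mean, mean)


def quantile_bin_track(
    profile: MarkerEffectProfile, gmap: GeneticMap, n_levels: int = 10
) -> pd.DataFrame:
    """Genome track of effect levels: markers binned into ``n_levels``
    decile levels of the normalized effect (level ``n_levels`` strongest;
    ties share the lower level, so a constant profile is all level 1).

    Returns a TSV-ready frame: chromosome, position_cM, marker_id,
    model_id, normalized_effect, level.
    """
    values = (
        profile.normalized
        if profile.normalized is not None
        else normalize_effects(profile).normalized
    )
    if len(values) != gmap.n_markers:
        raise ValueError("profile not aligned to map")
    qs = np.quantile(values, np.arange(1, n_levels) / n_levels)
    levels = 1 + (values[:, None] > qs[None, :]).sum(axis=1)
    return pd.DataFrame(
        {
            "chromosome": gmap.chromosome,
            "position_cM": gmap.position_cM,
            "marker_id": gmap.marker_id,
            "model_id": profile.model_id,
            "normalized_effect": values,
            "level": levels,
        }
    )
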