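"""Scenario grid construction, experiment driver and performance summaries.

A *prediction scenario* is one (population, train/test ratio, replicate)
unit: RILs are sampled without replacement into train and test sides at the
scenario's derived seed, all six member models are fitted on the training
side, predictions are scored on the test side with Pearson correlation and
MSE, the equal-weight ensemble is added, and the Diversity Prediction
Theorem terms are recorded. Models are then discarded — each scenario is an
independent prediction task. With multi-environment data all records of a
RIL stay on one side of the split, so no RIL leaks across sides.

Performance summaries follow the same aggregation as the study design:
group medians of Pearson r and MSE per model, top-3 shares over
trait-by-population groups under competition ranking, and
conventional-vs-machine-learning group correlations at the phenotype and
marker-effect levels.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import diversity as div
from . import effects as fx
from .io import RunConfig, derive_seed
from .models import (
    CONVENTIONAL_MODELS,
    MACHINE_LEARNING_MODELS,
    MODEL_GROUPS,
    BayesBModel,
    MLPModel,
    RandomForestModel,
    RKHSModel,
    RRBlupModel,
    SVRModel,
)
from .preprocess import DesignData, concat_environments
from .simulate import GenotypePanel

logger = logging.getLogger("ensgp")

__all__ = [
    "PredictionScenario",
    "build_scenarios",
    "pearson",
    "mse",
    "run_experiment",
    "ExperimentResult",
    "summarize_performance",
    "top3_share",
    "group_correlation",
]


@dataclass
class PredictionScenario:
    """One (population, ratio, replicate) train/test split."""

    scenario_id: str
    population_id: str
    ratio: tuple[float, float]
    replicate: int
    train_rils: list
    test_rils: list
    seed: int


def build_scenarios(
    populations: dict[str, list],
    ratios: list[tuple[float, float]],
    replicates: int,
    global_seed: int,
    min_test: int = 2,
) -> list[PredictionScenario]:
    """One scenario per (population, ratio, replicate).

    ``populations`` maps population id -> available RIL ids (>= 10 each).
    RILs are sampled without replacement at the scenario's derived seed;
    scenarios whose test side would hold fewer than ``min_test`` RILs are
    skipped with a log entry.
    """
    scenarios = []
    for pop, rils in populations.items():
        if len(rils) < 10:
            raise ValueError(f"population {pop} has fewer than 10 RILs")
        for r_idx, (train_frac, test_frac) in enumerate(ratios):
            if abs(train_frac + test_frac - 1.0) > 1e-9:
                raise ValueError("train+test fractions must sum to 1")
            for rep in range(replicates):
                seed = derive_seed(global_seed, pop, r_idx, rep, "split")
                n_train = int(round(train_frac * len(rils)))
                n_train = min(max(n_train, 1), len(rils) - 1)
                if len(rils) - n_train < min_test:
                    logger.warning(
                        "skipping scenario %s/r%d/rep%d: test set < %d RILs",
                        pop, r_idx, rep, min_test,
                    )
                    continue
                rng = np.random.default_rng(seed)
                perm = rng.permutation(len(rils))
                train = sorted(rils[i] for i in perm[:n_train])
                test = sorted(rils[i] for i in perm[n_train:])
                scenarios.append(
                    PredictionScenario(
                        scenario_id=f"{pop}|r{r_idx}|rep{rep}",
                        population_id=pop,
                        ratio=(train_frac, test_frac),
                        replicate=rep,
                        train_rils=train,
                        test_rils=test,
                        seed=seed,
                    )
                )
    return scenarios


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------


def pearson(observed: np.ndarray, predicted: np.ndarray) -> float:
    """Pearson correlation; NaN for zero-variance (degenerate) input."""
    observed = np.asarray(observed, float)
    predicted = np.asarray(predicted, float)
    if len(observed) != len(predicted):
        raise ValueError("length mismatch")
    if len(observed) < 2:
        raise ValueError("need at least 2 values")
    if observed.std() == 0 or predicted.std() == 0:
        return float("nan")
    return float(np.corrcoef(observed, predicted)[0, 1])


def mse(observed: np.ndarray, predicted: np.ndarray) -> float:
    """Mean squared error (squared trait units)."""
    observed = np.asarray(observed, float)
    predicted = np.asarray(predicted, float)
    if len(observed) != len(predicted):
        raise ValueError("length mismatch")
    return float(np.mean((observed - predicted) ** 2))


# ---------------------------------------------------------------------------
# Experiment driver
# ---------------------------------------------------------------------------


def _default_model_factory(config: RunConfig, scenario: PredictionScenario, trait: str):
    """Instantiate the configured member models with derived seeds."""
    hp = config.hyperparameters
    n_iter = hp.get("mcmc_iterations", 12_000)
    burn_in = hp.get("mcmc_burn_in", 2_000)
    n_trees = hp.get("rf_trees", 1_000)
    mlp_preset = hp.get("mlp_preset", "teonam")
    seed_of = lambda tag: derive_seed(config.seed, scenario.scenario_id, trait, tag)
    all_models = {
        "rrBLUP": lambda: RRBlupModel(n_iter, burn_in, seed=seed_of("rrBLUP")),
        "BayesB": lambda: BayesBModel(n_iter, burn_in, seed=seed_of("BayesB")),
        "RKHS": lambda: RKHSModel(
            n_iter, burn_in, bandwidth=hp.get("rkhs_bandwidth", 1.0), seed=seed_of("RKHS")
        ),
        "RF": lambda: RandomForestModel(n_trees, seed=seed_of("RF")),
        "SVR": lambda: SVRModel(seed=seed_of("SVR")),
        "MLP": lambda: MLPModel(mlp_preset, seed=seed_of("mlp_init")),
    }
    return {m: all_models[m]() for m in config.models}


@dataclass
class ExperimentResult:
    """All per-scenario outputs of one experiment run."""

    predictions: pd.DataFrame  # scenario, model, ril, environment, observed, predicted
    metrics: pd.DataFrame  # scenario, population, ratio, model, pearson_r, mse
    decompositions: list
    effect_profiles: dict = field(default_factory=dict)  # scenario -> {model: profile}
    failures: list = field(default_factory=list)

    @property
    def decomposition_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "scenario_id": [d.scenario_id for d in self.decompositions],
                "ensemble_error": [d.ensemble_error for d in self.decompositions],
                "mean_error": [d.mean_error for d in self.decompositions],
                "prediction_diversity": [d.prediction_diversity for d in self.decompositions],
            }
        )


def run_experiment(
    panels: list[GenotypePanel],
    phenotypes: pd.DataFrame,
    config: RunConfig,
    trait: str,
    compute_effects: bool = False,
    effects_kwargs: dict | None = None,
    scenario_limit: int | None = None,
    out_dir: str | Path | None = None,
) -> ExperimentResult:
    """Run the full scenario grid for one trait.

    For every scenario the configured member models are fitted, scored and
    ensembled; any model failure marks the scenario failed (member metrics
    are kept, ensemble rows are only written when all members succeed) and
    the run continues. ``compute_effects=True`` additionally extracts
    marker-effect profiles for the first replicate of every
    (population, ratio) cell. When ``out_dir`` is given, a JSONL prediction
    ledger is appended scenario by scenario and previously completed
    scenario ids are skipped, making the run resumable.
    """
    designs = {p.population_id: concat_environments(p, phenotypes, trait) for p in panels}
    populations = {
        pid: sorted(set(d.ril_ids)) for pid, d in designs.items()
    }
    scenarios = build_scenarios(populations, config.ratios, config.replicates, config.seed)
    if scenario_limit is not None:
        scenarios = scenarios[:scenario_limit]

    ledger_path = None
    done_ids: set = set()
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        ledger_path = out_dir / f"predictions_{trait}.jsonl"
        if ledger_path.exists():
            with open(ledger_path) as fh:
                done_ids = {json.loads(line)["scenario_id"] for line in fh if line.strip()}

    pred_rows, metric_rows, decomps, failures = [], [], [], []
    effect_profiles: dict = {}
    for sc in scenarios:
        if sc.scenario_id in done_ids:
            continue
        design = designs[sc.population_id]
        ril_arr = np.array(design.ril_ids)
        train_mask = np.isin(ril_arr, sc.train_rils)
        test_mask = np.isin(ril_arr, sc.test_rils)
        X_tr, y_tr = design.X[train_mask], design.y[train_mask]
        X_te, y_te = design.X[test_mask], design.y[test_mask]
        models = _default_model_factory(config, sc, trait)
        member_preds: dict[str, np.ndarray] = {}
        failed = False
        for mid, model in models.items():
            try:
                model.fit(X_tr, y_tr)
                member_preds[mid] = np.asarray(model.predict(X_te), float)
            except Exception as exc:  # noqa: BLE001 - run must continue
                failed = True
                failures.append((sc.scenario_id, mid, repr(exc)))
                logger.error("scenario %s model %s failed: %r", sc.scenario_id, mid, exc)
        preds_out = dict(member_preds)
        if not failed and member_preds:
            preds_out["ensemble"] = div.ensemble_average(member_preds)
            decomps.append(div.decompose(member_preds, y_te, sc.scenario_id))
        for mid, yhat in preds_out.items():
            metric_rows.append(
                {
                    "scenario_id": sc.scenario_id,
                    "population_id": sc.population_id,
                    "ratio": f"{sc.ratio[0]:.2f}-{sc.ratio[1]:.2f}",
                    "replicate": sc.replicate,
                    "trait": trait,
                    "model_id": mid,
                    "pearson_r": pearson(y_te, yhat),
                    "mse": mse(y_te, yhat),
                }
            )
            for k in range(len(y_te)):
                pred_rows.append(
                    {
                        "scenario_id": sc.scenario_id,
                        "model_id": mid,
                        "ril_id": ril_arr[test_mask][k],
                        "environment": np.array(design.environments)[test_mask][k],
                        "trait": trait,
                        "observed": float(y_te[k]),
                        "predicted": float(yhat[k]),
                    }
                )
        if compute_effects and not failed and sc.replicate == 0:
            effect_profiles[sc.scenario_id] = _extract_effects(
                models, design, train_mask, y_tr, config, sc, trait,
                **(effects_kwargs or {}),
            )
        if ledger_path is not None:
            with open(ledger_path, "a") as fh:
                fh.write(
                    json.dumps(
                        {
                            "scenario_id": sc.scenario_id,
                            "models": sorted(preds_out),
                            "failed": failed,
                        }
                    )
                    + "\n"
                )
    return ExperimentResult(
        predictions=pd.DataFrame(pred_rows),
        metrics=pd.DataFrame(metric_rows),
        decompositions=decomps,
        effect_profiles=effect_profiles,
        failures=failures,
    )


def _extract_effects(
    models: dict,
    design: DesignData,
    train_mask: np.ndarray,
    y_tr: np.ndarray,
    config: RunConfig,
    scenario: PredictionScenario,
    trait: str,
    n_permutations: int = 15,
    n_background: int = 100,
    max_explain: int = 30,
) -> dict:
    """Per-model normalized marker-effect profiles for one scenario.

    Explanation set = the scenario's training records (capped at
    ``max_explain`` rows for tractability); background = ``n_background``
    seeded draws from the training set.
    """
    X_tr = design.X[train_mask]
    marker_ids = design.marker_ids
    rng = np.random.default_rng(
        derive_seed(config.seed, scenario.scenario_id, trait, "effects")
    )
    bg = X_tr[rng.integers(0, X_tr.shape[0], size=min(n_background, X_tr.shape[0] * 4))]
    explain = X_tr if X_tr.shape[0] <= max_explain else X_tr[
        rng.choice(X_tr.shape[0], size=max_explain, replace=False)
    ]
    profiles = {}
    for mid, model in models.items():
        if mid in ("rrBLUP", "BayesB"):
            prof = fx.effects_linear(model, marker_ids)
        elif mid == "RF":
            prof = fx.effects_impurity(model, marker_ids)
        else:
            prof = fx.shapley_effects(
                model,
                explain,
                bg,
                n_permutations=n_permutations,
                seed=derive_seed(config.seed, scenario.scenario_id, trait, mid, "shap"),
                marker_ids=marker_ids,
                y_spread=float(np.ptp(y_tr)) or 1.0,
            )
        profiles[mid] = fx.normalize_effects(prof)
    if len(profiles) == len(models):
        profiles["ensemble"] = fx.ensemble_effects(list(profiles.values()))
    return profiles


# ---------------------------------------------------------------------------
# Summaries
# ---------------------------------------------------------------------------


def summarize_performance(
    metrics: pd.DataFrame, by: list[str] = ("trait", "model_id")
) -> pd.DataFrame:
    """Group medians of Pearson r and MSE.

    Missing (degenerate) Pearson values are excluded from the median with
    their count reported in ``n_missing_r``.
    """
    rows = []
    for keys, sub in metrics.groupby(list(by)):
        keys = keys if isinstance(keys, tuple) else (keys,)
        rows.append(
            {
                **dict(zip(by, keys)),
                "median_r": sub["pearson_r"].median(skipna=True),
                "median_mse": sub["mse"].median(),
                "n_scenarios": len(sub),
                "n_missing_r": int(sub["pearson_r"].isna().sum()),
            }
        )
    return pd.DataFrame(rows)


def top3_share(
    metrics: pd.DataFrame, metric: str = "pearson_r", top_k: int = 3
) -> pd.DataFrame:
    """Percentage of trait-by-population groups in which each model ranks in
    the top ``top_k`` by group median (descending for Pearson r, ascending
    for MSE). Ties use competition ranking ("1224"): every model tied at a
    counting rank is included.
    """
    ascending = metric == "mse"
    med = (
        metrics.groupby(["trait", "population_id", "model_id"])[metric]
        .median()
        .reset_index()
    )
    counts: dict[str, int] = {m: 0 for m in med["model_id"].unique()}
    n_groups = 0
    for _, sub in med.groupby(["trait", "population_id"]):
        n_groups += 1
        ranks = sub[metric].rank(method="min", ascending=ascending, na_option="bottom")
        for m, r in zip(sub["model_id"], ranks):
            if r <= top_k:
                counts[m] += 1
    return pd.DataFrame(
        {
            "model_id": list(counts),
            "top3_share_pct": [100.0 * counts[m] / n_groups for m in counts],
            "n_groups": n_groups,
        }
    ).sort_values("top3_share_pct", ascending=False, ignore_index=True)


def group_correlation(
    predictions: pd.DataFrame, effect_profiles: dict | None = None
) -> dict:
    """Pearson correlation between the conventional and machine-learning
    model groups at the phenotype and marker-effect levels.

    Phenotype level: each group's mean predicted phenotype per test record
    (pooled over scenarios), correlated across records. Marker-effect
    level: each group's mean normalized effect per marker (averaged over
    scenarios and group members), correlated across markers.
    """
    out: dict = {}
    conv = predictions[predictions["model_id"].isin(CONVENTIONAL_MODELS)]
    ml = predictions[predictions["model_id"].isin(MACHINE_LEARNING_MODELS)]
    if not conv.empty and not ml.empty:
        keys = ["scenario_id", "ril_id", "environment"]
        c = conv.groupby(keys)["predicted"].mean()
        m = ml.groupby(keys)["predicted"].mean()
        joined = pd.concat([c.rename("conv"), m.rename("ml")], axis=1).dropna()
        out["phenotype_r"] = pearson(joined["conv"].to_numpy(), joined["ml"].to_numpy())
    if effect_profiles:
        conv_stack, ml_stack = [], []
        for profs in effect_profiles.values():
            for mid, prof in profs.items():
                if mid == "ensemble":
                    continue
                vec = prof.normalized
                (conv_stack if MODEL_GROUPS[mid] == "conventional" else ml_stack).append(vec)
        if conv_stack and ml_stack:
            out["effect_r"] = pearson(
                np.mean(np.vstack(conv_stack), axis=0),
                np.mean(np.vstack(ml_stack), axis=0),
            )
    return out
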