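"""Shared fixtures.

The expensive fixture here is ``preset_runs``: one full scenario-grid
experiment per synthetic NAM preset (high-diversity backcross-derived
populations with two environments vs lower-diversity selfed populations
with a single record per line), at the scaled-down study size used
throughout the suite: 2 populations x 3 train/test ratios x 10 replicates,
200 markers, 150 RILs per population, shortened MCMC chains
(2,000 iterations / 500 burn-in). It is session-scoped so the grid runs
once and both the theorem-guarantee and the preset-contrast tests read
from it.
"""

from __future__ import annotations

import numpy as np
import pytest

from ensgp import evaluation as ev
from ensgp import simulate as sim
from ensgp.io import RunConfig

TEST_MCMC = {"mcmc_iterations": 2_000, "mcmc_burn_in": 500}


@pytest.fixture(scope="session")
def small_map():
    return sim.simulate_map(2, 15, chrom_length_cM=100.0, bp_per_cM=10_000, seed=11)


@pytest.fixture(scope="session")
def small_panel(small_map):
    design = sim.CrossDesign(scheme="self_only", n_self_generations=4, n_rils=80)
    return sim.simulate_ril_population(small_map, design, seed=12, population_id="popA")


@pytest.fixture(scope="session")
def small_architecture(small_map):
    mid = small_map.marker_id
    return sim.QTLArchitecture(
        trait_name="DTA",
        additive_qtl=[(mid[2], 1.0), (mid[9], -0.7), (mid[20], 0.5)],
        epistatic_pairs=[(mid[4], mid[25], 0.8)],
        target_h2_additive=0.5,
        target_h2_epistatic=0.1,
        env_effects={"env1": 0.0, "env2": 2.0},
    )


def _run_preset(preset_fn, mlp_preset: str, seed: int) -> ev.ExperimentResult:
    panels, phenotypes, _ = preset_fn(
        seed=seed,
        n_populations=2,
        markers_per_chromosome=20,
        n_chromosomes=10,
        n_rils_range=(150, 150),
    )
    config = RunConfig(
        dataset=mlp_preset,
        replicates=10,
        seed=seed,
        hyperparameters={**TEST_MCMC, "rf_trees": 1_000, "mlp_preset": mlp_preset},
    )
    return ev.run_experiment(panels, phenotypes, config, "DTA")


@pytest.fixture(scope="session")
def preset_runs():
    """Full scenario grids for the two NAM presets (60 scenarios each)."""
    return {
        "high_diversity": _run_preset(sim.teonam_like_preset, "teonam", seed=101),
        "low_diversity": _run_preset(sim.maizenam_like_preset, "maizenam", seed=202),
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
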