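"""Preprocessing chain: flanking imputation, sample filters, LD pruning,
environment concatenation, BLUP/BLUE derivation."""

import numpy as np
import pandas as pd
import pytest

from ensgp import preprocess as pp
from ensgp import simulate as sim
from ensgp.io import PipelineError


def _panel_from_matrix(matrix, positions_cM=None):
    matrix = np.asarray(matrix, dtype=float)
    m = matrix.shape[1]
    pos = np.asarray(positions_cM if positions_cM is not None else np.arange(m) * 10.0)
    gmap = sim.GeneticMap(
        np.array([f"m{j}" for j in range(m)], dtype=object),
        np.array(["chr1"] * m, dtype=object),
        pos,
        (pos * 1_000).astype(np.int64) + np.arange(m),
    )
    return sim.GenotypePanel(
        "pop", [f"r{i}" for i in range(matrix.shape[0])], gmap, matrix
    )


class TestImputeFlanking:
    def test_agreeing_flanks(self):
        panel = _panel_from_matrix([[2, np.nan, 2]])
        out = pp.impute_flanking(panel)
        assert out.genotypes[0, 1] == 2

    def test_chromosome_end_copies_single_flank(self):
        panel = _panel_from_matrix([[np.nan, 1, 0]])
        out = pp.impute_flanking(panel)
        assert out.genotypes[0, 0] == 1

    def test_nearer_flank_wins_left_on_tie(self):
        # marker at 10 cM: left flank at 0, right at 30 -> left is nearer
        panel = _panel_from_matrix([[0, np.nan, 2]], positions_cM=[0, 10, 30])
        assert pp.impute_flanking(panel).genotypes[0, 1] == 0
        # exact midpoint -> left flank by convention
        panel = _panel_from_matrix([[0, np.nan, 2]], positions_cM=[0, 10, 20])
        assert pp.impute_flanking(panel).genotypes[0, 1] == 0

    def test_matches_bruteforce_nearest_scan(self, small_panel):
        panel = sim.inject_missingness(small_panel, 0.15, 0.0, seed=9)
        out = pp.impute_flanking(panel)
        g, pos = panel.genotypes, panel.map.position_cM
        for _, idx in panel.map.chrom_slices().items():
            for i in range(panel.n_rils):
                row = g[i, idx]
                obs = np.flatnonzero(~np.isnan(row))
                for k in np.flatnonzero(np.isnan(row)):
                    d = np.abs(pos[idx][obs] - pos[idx][k])
                    expected = row[obs[np.argmin(d)]]  # argmin keeps first=left tie
                    assert out.genotypes[i, idx[k]] == expected

    def test_observed_genotypes_untouched(self, small_panel):
        panel = sim.inject_missingness(small_panel, 0.1, 0.0, seed=10)
        out = pp.impute_flanking(panel)
        mask = ~np.isnan(panel.genotypes)
        assert np.array_equal(out.genotypes[mask], panel.genotypes[mask])
        assert not np.isnan(out.genotypes).any()


def _pheno_for(panel, trait="DTA"):
    return pd.DataFrame(
        {
            "ril_id": panel.ril_ids,
            "population_id": panel.population_id,
            "environment": "env1",
            trait: np.arange(panel.n_rils, dtype=float),
        }
    )


class TestFilterSamples:
    def test_clean_panel_unchanged(self, small_panel):
        pheno = _pheno_for(small_panel)
        filtered, pheno_out, log = pp.filter_samples(small_panel, pheno)
        assert filtered.n_rils == small_panel.n_rils
        assert log.empty

    def test_whole_chromosome_missing_removed(self, small_panel):
        panel = small_panel.copy()
        chr1 = panel.map.chrom_slices()["chr1"]
        panel.genotypes[3, chr1] = np.nan
        filtered, _, log = pp.filter_samples(panel, _pheno_for(panel))
        assert small_panel.ril_ids[3] not in filtered.ril_ids
        assert log.iloc[0]["reason"] == "missing_chromosome"
        assert filtered.n_rils == small_panel.n_rils - 1

    def test_missing_phenotype_removed_with_reason(self, small_panel):
        pheno = _pheno_for(small_panel).iloc[1:]
        filtered, _, log = pp.filter_samples(small_panel, pheno)
        assert small_panel.ril_ids[0] not in filtered.ril_ids
        assert set(log["reason"]) == {"no_phenotype"}

    def test_idempotent(self, small_panel):
        panel = small_panel.copy()
        panel.genotypes[0, panel.map.chrom_slices()["chr2"]] = np.nan
        pheno = _pheno_for(panel)
        f1, p1, log1 = pp.filter_samples(panel, pheno)
        f2, _, log2 = pp.filter_samples(f1, p1)
        assert f2.n_rils == f1.n_rils and log2.empty

    def test_everything_removed_raises(self, small_panel):
        empty = _pheno_for(small_panel).iloc[0:0]
        with pytest.raises(PipelineError):
            pp.filter_samples(small_panel, empty)


class TestLDPrune:
    def test_duplicate_marker_removed(self, rng):
        base = rng.integers(0, 3, size=(40, 1)).astype(float)
        noise = rng.integers(0, 3, size=(40, 1)).astype(float)
        panel = _panel_from_matrix(
            np.hstack([base, base, noise]), positions_cM=[0.0, 0.001, 0.002]
        )
        pruned, kept = pp.ld_prune(panel)
        assert len(kept) == 2
        assert pruned.map.n_markers == 2

    def test_orthogonal_markers_kept(self):
        # four mutually uncorrelated dosage patterns
        g = np.array(
            [[0, 0, 0, 0], [0, 2, 0, 2], [2, 0, 0, 2], [2, 2, 0, 0],
             [0, 0, 2, 2], [0, 2, 2, 0], [2, 0, 2, 0], [2, 2, 2, 2]],
            dtype=float,
        )
        panel = _panel_from_matrix(g, positions_cM=np.arange(4) * 0.001)
        pruned, kept = pp.ld_prune(panel)
        assert len(kept) == 4

    def test_postprune_audit_no_high_r2_pairs(self, small_panel):
        pruned, kept = pp.ld_prune(small_panel, window_bp=30_000)
        g, bp, chrom = pruned.genotypes, pruned.map.position_bp, pruned.map.chromosome
        for a in range(pruned.map.n_markers):
            for b in range(a + 1, pruned.map.n_markers):
                if chrom[a] != chrom[b] or bp[b] - bp[a] > 30_000:
                    continue
                sa, sb = g[:, a].std(), g[:, b].std()
                if sa == 0 or sb == 0:
                    continue
                r2 = np.corrcoef(g[:, a], g[:, b])[0, 1] ** 2
                assert r2 < 0.8, f"pair ({a},{b}) survived with r2={r2:.3f}"

    def test_kept_subset_preserves_map_order(self, small_panel):
        pruned, kept = pp.ld_prune(small_panel)
        original = list(small_panel.map.marker_id)
        assert kept == [m for m in original if m in set(kept)]

    def test_missing_genotypes_rejected(self, small_panel):
        panel = sim.inject_missingness(small_panel, 0.1, 0.0, seed=1)
        with pytest.raises(ValueError):
            pp.ld_prune(panel)


class TestConcatEnvironments:
    def test_single_environment_constant_factor(self, small_panel):
        pheno = _pheno_for(small_panel)
        design = pp.concat_environments(small_panel, pheno, "DTA")
        assert design.X.shape == (small_panel.n_rils, small_panel.map.n_markers + 1)
        assert np.all(design.X[:, -1] == 0)

    def test_two_environments_stack(self, small_panel, small_architecture):
        pheno = sim.simulate_phenotypes(small_panel, small_architecture, 2, seed=4)
        design = pp.concat_environments(small_panel, pheno, "DTA")
        assert len(design.y) == 2 * small_panel.n_rils
        # each RIL's genotype row is shared across its environment records
        row_of = {r: i for i, r in enumerate(small_panel.ril_ids)}
        for k, ril in enumerate(design.ril_ids):
            assert np.array_equal(
                design.X[k, : small_panel.map.n_markers],
                small_panel.genotypes[row_of[ril]],
            )

    def test_env_shift_recovered_by_rrblup(self, small_panel):
        # markers carry no signal; environment 2 is shifted by delta
        from ensgp.models import RRBlupModel

        delta = 4.0
        rng = np.random.default_rng(8)
        rows = []
        for env, shift in (("env1", 0.0), ("env2", delta)):
            rows.append(
                pd.DataFrame(
                    {
                        "ril_id": small_panel.ril_ids,
                        "population_id": small_panel.population_id,
                        "environment": env,
                        "DTA": shift + rng.normal(0, 0.5, small_panel.n_rils),
                    }
                )
            )
        design = pp.concat_environments(small_panel, pd.concat(rows), "DTA")
        model = RRBlupModel(n_iter=2_000, burn_in=500, seed=1).fit(design.X, design.y)
        coef = model.effects_[-1]  # the env factor column
        assert coef == pytest.approx(delta, rel=0.25)


class TestBlupsAndBlues:
    @staticmethod
    def _replicated_pheno(n_rils=200, sigma_g=0.6, sigma_e=0.8, seed=0):
        rng = np.random.default_rng(seed)
        g = rng.normal(0, np.sqrt(sigma_g), n_rils)
        rows = []
        for env, shift in (("env1", 0.0), ("env2", 3.0)):
            rows.append(
                pd.DataFrame(
                    {
                        "ril_id": [f"r{i}" for i in range(n_rils)],
                        "population_id": "pop",
                        "environment": env,
                        "DTA": shift + g + rng.normal(0, np.sqrt(sigma_e), n_rils),
                    }
                )
            )
        return pd.concat(rows, ignore_index=True)

    def test_zero_residual_gives_line_means_and_h2_one(self):
        pheno = self._replicated_pheno(n_rils=50, sigma_g=1.0, sigma_e=1e-12, seed=1)
        blups, h2 = pp.fit_population_blups(pheno, "DTA")
        assert h2["pop"] == pytest.approx(1.0, abs=1e-6)
        centered = pheno.copy()
        centered["DTA"] -= centered.groupby("environment")["DTA"].transform("mean")
        line_means = centered.groupby("ril_id")["DTA"].mean()
        expected = (line_means - line_means.mean()).sort_index()
        got = blups.set_index("ril_id")["DTA"].sort_index()
        assert np.allclose(got, expected, atol=1e-6)

    def test_zero_genetic_variance_shrinks_to_zero(self):
        pheno = self._replicated_pheno(n_rils=150, sigma_g=1e-12, sigma_e=1.0, seed=2)
        blups, h2 = pp.fit_population_blups(pheno, "DTA")
        assert h2["pop"] < 0.25
        assert blups["DTA"].abs().mean() < 0.2

    def test_h2_recovery(self):
        # sigma_g=0.6, sigma_e=0.8, r=2 -> line-mean H2 = 0.6/(0.6+0.4) = 0.6
        pheno = self._replicated_pheno(seed=3)
        _, h2 = pp.fit_population_blups(pheno, "DTA")
        assert h2["pop"] == pytest.approx(0.6, abs=0.1)

    def test_blups_centered(self):
        blups, _ = pp.fit_population_blups(self._replicated_pheno(seed=4), "DTA")
        assert blups["DTA"].mean() == pytest.approx(0.0, abs=1e-9)

    def test_single_record_lines_rejected(self, small_panel):
        with pytest.raises(ValueError, match="raw"):
            pp.fit_population_blups(_pheno_for(small_panel), "DTA")

    def test_unshrink_identity_at_h2_one(self):
        blups, _ = pp.fit_population_blups(self._replicated_pheno(seed=5), "DTA")
        blues = pp.unshrink_to_blues(blups, {"pop": 1.0}, "DTA")
        assert np.allclose(blues["DTA"], blups["DTA"])

    def test_unshrink_arithmetic_and_variance(self):
        blups = pd.DataFrame(
            {
                "ril_id": ["a", "b", "c"],
                "population_id": "pop",
                "environment": "combined",
                "DTA": [0.5, -0.3, -0.2],
            }
        )
        blues = pp.unshrink_to_blues(blups, {"pop": 0.5}, "DTA")
        assert blues["DTA"].tolist() == [1.0, -0.6, -0.4]
        ratio = blues["DTA"].var() / blups["DTA"].var()
        assert ratio == pytest.approx(1 / 0.5**2)

    def test_zero_h2_rejected(self):
        blups = pd.DataFrame(
            {"ril_id": ["a"], "population_id": "pop", "environment": "combined", "DTA": [0.1]}
        )
        with pytest.raises(ValueError):
            pp.unshrink_to_blues(blups, {"pop": 0.0}, "DTA")
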