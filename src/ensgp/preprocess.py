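"""Preprocessing chain for NAM RIL panels.

Steps, in pipeline order:

1. :func:`impute_flanking` — fill missing genotypes from the nearest
   non-missing flanking marker (by cM) on the same chromosome of the same
   RIL; whole-missing chromosomes are left for the sample filter.
2. :func:`filter_samples` — drop RILs with an entirely missing chromosome or
   no phenotype for the target trait.
3. :func:`ld_prune` — LD pruning in PLINK indep-pairwise style: any marker
   pair within a 30 kb window with squared dosage correlation >= 0.8 loses
   one member; windows advance by 5 SNPs and sweeps repeat to a fixpoint so
   the pruned panel passes an all-pairs-within-window audit.
4. :func:`concat_environments` — stack per-environment records into one
   design with an environment factor column (one-hot minus reference).
5. :func:`fit_population_blups` / :func:`unshrink_to_blues` — two-stage line
   BLUPs with environment as a fixed effect, shrinkage by line-mean
   repeatability H2, and the BLUE as BLUP / H2 on the centered scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import PipelineError
from .simulate import GenotypePanel

__all__ = [
    "impute_flanking",
    "filter_samples",
    "ld_prune",
    "concat_environments",
    "fit_population_blups",
    "unshrink_to_blues",
]


# ---------------------------------------------------------------------------
# Imputation
# ---------------------------------------------------------------------------


def impute_flanking(panel: GenotypePanel) -> GenotypePanel:
    """Impute missing genotypes from flanking markers.

    Each missing call takes the value of the nearest non-missing marker on
    the same chromosome (distance in cM); on an exact tie the left flank
    wins. At chromosome ends the single available flank is copied. Observed
    genotypes are never altered. Chromosomes that are missing for every
    marker of a RIL stay missing (removed later by :func:`filter_samples`).
    """
    out = panel.copy()
    g = out.genotypes
    for _, idx in panel.map.chrom_slices().items():
        pos = panel.map.position_cM[idx]
        block = g[:, idx]
        missing_rows = np.flatnonzero(np.isnan(block).any(axis=1))
        for i in missing_rows:
            row = block[i]
            obs = np.flatnonzero(~np.isnan(row))
            if obs.size == 0:
                continue  # whole chromosome missing for this RIL
            mis = np.flatnonzero(np.isnan(row))
            # distance from each missing marker to each observed one
            d = np.abs(pos[mis][:, None] - pos[obs][None, :])
            # nearest; ties -> lower map index (the left flank)
            nearest = obs[np.argmin(d, axis=1)]
            row[mis] = row[nearest]
        g[:, idx] = block
    return out


# ---------------------------------------------------------------------------
# Sample filtering
# ---------------------------------------------------------------------------


def filter_samples(
    panel: GenotypePanel, phenotypes: pd.DataFrame, trait: str | None = None
) -> tuple[GenotypePanel, pd.DataFrame, pd.DataFrame]:
    """Remove RILs with a fully-missing chromosome or no phenotype.

    Returns (filtered panel, filtered phenotypes, removal log). The log has
    columns ``ril_id`` and ``reason`` in {"missing_chromosome",
    "no_phenotype"}. Raises :class:`PipelineError` when nothing survives.
    Idempotent: running twice removes nothing new.
    """
    slices = panel.map.chrom_slices()
    removals = []
    keep = []
    pheno_pop = phenotypes[phenotypes["population_id"] == panel.population_id]
    trait_cols = [trait] if trait else [
        c
        for c in phenotypes.columns
        if c not in ("ril_id", "population_id", "environment") and not c.startswith("_")
    ]
    for i, ril in enumerate(panel.ril_ids):
        row = panel.genotypes[i]
        if any(np.isnan(row[idx]).all() for idx in slices.values()):
            removals.append((ril, "missing_chromosome"))
            continue
        recs = pheno_pop[pheno_pop["ril_id"] == ril]
        if recs.empty or recs[trait_cols].isna().all().any():
            removals.append((ril, "no_phenotype"))
            continue
        keep.append(i)
    if not keep:
        raise PipelineError(
            f"population {panel.population_id}: all samples removed by filters"
        )
    filtered = panel.subset_rils(np.array(keep))
    kept_ids = set(filtered.ril_ids)
    pheno_out = phenotypes[
        (phenotypes["population_id"] != panel.population_id)
        | (phenotypes["ril_id"].isin(kept_ids))
    ].reset_index(drop=True)
    log = pd.DataFrame(removals, columns=["ril_id", "reason"])
    return filtered, pheno_out, log


# ---------------------------------------------------------------------------
# LD pruning
# ---------------------------------------------------------------------------


def _pairwise_r2(x: np.ndarray, y: np.ndarray) -> float:
    """Squared Pearson correlation of two dosage vectors; NaN if either is
    monomorphic (zero variance)."""
    sx, sy = x.std(), y.std()
    if sx == 0 or sy == 0:
        return np.nan
    r = np.corrcoef(x, y)[0, 1]
    return float(r * r)


def ld_prune(
    panel: GenotypePanel,
    r2_threshold: float = 0.8,
    window_bp: int = 30_000,
    step_snps: int = 5,
) -> tuple[GenotypePanel, list]:
    """Greedy windowed LD pruning of an imputed panel.

    Within each ``window_bp`` window, every marker pair with squared dosage
    correlation >= ``r2_threshold`` loses one member: the one with the lower
    minor-allele frequency, or the later map position on a tie. Windows step
    by ``step_snps`` kept markers and sweeps repeat until no removal occurs,
    which guarantees the audit post-condition (no surviving within-window
    pair at or above the threshold). Monomorphic pairs have undefined r2 and
    are skipped. Returns the pruned panel and the kept marker ids in map
    order.
    """
    if np.isnan(panel.genotypes).any():
        raise ValueError("ld_prune requires an imputed (fully observed) panel")
    g = panel.genotypes
    maf = np.minimum(g.mean(axis=0) / 2.0, 1 - g.mean(axis=0) / 2.0)
    bp = panel.map.position_bp
    chrom = panel.map.chromosome
    kept = np.ones(panel.map.n_markers, dtype=bool)

    changed = True
    while changed:
        changed = False
        kept_idx = np.flatnonzero(kept)
        for start in range(0, len(kept_idx), step_snps):
            i0 = kept_idx[start]
            window = [
                j
                for j in kept_idx[start:]
                if chrom[j] == chrom[i0] and bp[j] - bp[i0] <= window_bp and kept[j]
            ]
            for a in range(len(window)):
                ia = window[a]
                if not kept[ia]:
                    continue
                for b in range(a + 1, len(window)):
                    ib = window[b]
                    if not kept[ib]:
                        continue
                    r2 = _pairwise_r2(g[:, ia], g[:, ib])
                    if np.isnan(r2) or r2 < r2_threshold:
                        continue
                    # drop lower MAF; tie -> later map position (ib)
                    drop = ib if (maf[ia] > maf[ib] or maf[ia] == maf[ib]) else ia
                    kept[drop] = False
                    changed = True
                    if drop == ia:
                        break
    kept_indices = np.flatnonzero(kept)
    pruned = panel.subset_markers(kept_indices)
    return pruned, list(pruned.map.marker_id)


# ---------------------------------------------------------------------------
# Environment concatenation
# ---------------------------------------------------------------------------


@dataclass
class DesignData:
    """Model-ready stacked design: marker dosages plus environment factor
    columns, one record per (RIL, environment)."""

    X: np.ndarray  # (records, markers + env factor columns)
    y: np.ndarray
    ril_ids: list
    environments: list
    marker_ids: list
    factor_names: list

    @property
    def n_markers(self) -> int:
        return len(self.marker_ids)


def concat_environments(
    panel: GenotypePanel, phenotypes: pd.DataFrame, trait: str
) -> DesignData:
    """Stack per-environment phenotype records over shared genotype rows.

    Each (RIL, environment) record reuses the RIL's genotype row; the
    environment enters as one-hot-minus-reference numeric columns (zero
    columns when there is a single environment, in which case a constant
    factor column of zeros is appended for shape stability downstream).
    Records missing the trait value are dropped.
    """
    pheno = phenotypes[
        (phenotypes["population_id"] == panel.population_id)
        & phenotypes["ril_id"].isin(panel.ril_ids)
    ]
    pheno = pheno.dropna(subset=[trait])
    envs = sorted(pheno["environment"].unique())
    row_of = {r: i for i, r in enumerate(panel.ril_ids)}
    factor_envs = envs[1:]  # first environment is the reference level
    n_factor = max(len(factor_envs), 1)
    X_rows, y, rils, env_out = [], [], [], []
    for _, rec in pheno.iterrows():
        i = row_of[rec["ril_id"]]
        factor = np.zeros(n_factor)
        if rec["environment"] in factor_envs:
            factor[factor_envs.index(rec["environment"])] = 1.0
        X_rows.append(np.concatenate([panel.genotypes[i], factor]))
        y.append(rec[trait])
        rils.append(rec["ril_id"])
        env_out.append(rec["environment"])
    factor_names = [f"env_factor[{e}]" for e in factor_envs] or ["env_factor[const]"]
    return DesignData(
        X=np.array(X_rows),
        y=np.array(y, dtype=float),
        ril_ids=rils,
        environments=env_out,
        marker_ids=list(panel.map.marker_id),
        factor_names=factor_names,
    )


# ---------------------------------------------------------------------------
# BLUPs and BLUEs
# ---------------------------------------------------------------------------


def fit_population_blups(
    phenotypes: pd.DataFrame, trait: str
) -> tuple[pd.DataFrame, dict]:
    """Per-population line BLUPs from a one-way random-effects model.

    Environment enters as a fixed effect (records are centered per
    environment); line effects are random. From the one-way ANOVA mean
    squares, sigma2_g = (MS_line - MS_err) / r and the line-mean
    repeatability H2 = sigma2_g / (sigma2_g + sigma2_err / r) with r the
    (mean) number of records per line. BLUP_i = H2 * (line mean, centered);
    BLUPs are centered at 0 by construction.

    Returns (BLUP table with columns ril_id, population_id, environment
    ("combined"), trait; dict population_id -> H2). Raises ``ValueError``
    for single-record-per-line populations (use raw values instead).
    """
    out_rows = []
    h2: dict = {}
    for pop, sub in phenotypes.groupby("population_id"):
        sub = sub.dropna(subset=[trait])
        counts = sub.groupby("ril_id")[trait].count()
        if (counts < 2).any() or len(counts) < 2:
            raise ValueError(
                f"population {pop}: every RIL needs >= 2 records for BLUPs; "
                "use raw phenotype values instead"
            )
        # fixed environment effect: center within environment
        centered = sub.copy()
        centered[trait] = sub[trait] - sub.groupby("environment")[trait].transform("mean")
        line_means = centered.groupby("ril_id")[trait].mean()
        r = counts.mean()
        n_lines = len(line_means)
        ms_line = r * line_means.var(ddof=1)
        sse = ((centered.set_index("ril_id")[trait] - line_means) ** 2).sum()
        df_err = len(centered) - n_lines - (sub["environment"].nunique() - 1)
        ms_err = sse / max(df_err, 1)
        sigma_g = max((ms_line - ms_err) / r, 0.0)
        H2 = sigma_g / (sigma_g + ms_err / r) if (sigma_g + ms_err / r) > 0 else 1.0
        H2 = min(max(H2, 0.0), 1.0)
        h2[pop] = H2
        blup = H2 * (line_means - line_means.mean())
        for ril, val in blup.items():
            out_rows.append((ril, pop, "combined", val))
    table = pd.DataFrame(out_rows, columns=["ril_id", "population_id", "environment", trait])
    table.attrs["kind"] = "BLUP"
    return table, h2


def unshrink_to_blues(blups: pd.DataFrame, h2: dict, trait: str) -> pd.DataFrame:
    """BLUE_i = BLUP_i / H2 per population, on the centered scale.

    The one-parameter inverse of BLUP shrinkage: var(BLUE) =
    var(BLUP) / H2^2 within a population. H2 = 0 is an error.
    """
    out = blups.copy()
    for pop, sub_idx in out.groupby("population_id").groups.items():
        H2 = h2[pop]
        if H2 <= 0:
            raise ValueError(f"population {pop}: H2 must be positive to unshrink")
        out.loc[sub_idx, trait] = out.loc[sub_idx, trait] / H2
    out.attrs["kind"] = "BLUE"
    return out
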