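"""Readers, writers, run configuration and deterministic seed derivation.

All on-disk formats are plain text: genotype matrices as TSV (rows = RILs,
columns = markers), genetic maps as PLINK-MAP-style 4-column text
(chromosome, marker id, cM, bp), phenotypes as long-format TSV and
annotation tracks as BED-like text with centimorgan coordinates.
Readers validate and reject malformed input rather than coercing it;
every writer/reader pair is an identity on valid data.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .simulate import GeneticMap, GenotypePanel

#: tokens accepted as "missing genotype" on input; all normalized to NaN
MISSING_TOKENS = {"", "NA", "N/A", "-", ".", "nan", "NaN"}

ANNOTATION_CATEGORIES = {"QTL_source1", "QTL_source2", "SAM", "leaf", "other"}


class FormatError(ValueError):
    """Malformed on-disk data (names the offending row/column where known)."""


class PipelineError(RuntimeError):
    """A pipeline-level failure, e.g. every sample filtered out."""


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------


@dataclass
class RunConfig:
    """Configuration of a full prediction experiment.

    ``ratios`` are (train fraction, test fraction) pairs that must sum to 1;
    the defaults are the three train/test splits used throughout:
    0.8/0.2, 0.65/0.35 and 0.5/0.5.
    """

    dataset: str = "synthetic"
    traits: list[str] = field(default_factory=lambda: ["DTA", "ASI"])
    ratios: list[tuple[float, float]] = field(
        default_factory=lambda: [(0.8, 0.2), (0.65, 0.35), (0.5, 0.5)]
    )
    replicates: int = 10
    models: list[str] = field(
        default_factory=lambda: ["rrBLUP", "BayesB", "RKHS", "RF", "SVR", "MLP"]
    )
    hyperparameters: dict = field(default_factory=dict)
    seed: int = 0
    out_dir: str = "results"

    def __post_init__(self) -> None:
        if not self.models:
            raise ValueError("model list must be non-empty")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        for tr, te in self.ratios:
            if abs(tr + te - 1.0) > 1e-9:
                raise ValueError(f"train+test fractions must sum to 1, got {tr}+{te}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "ratios" in raw:
            raw["ratios"] = [tuple(r) for r in raw["ratios"]]
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        data = {
            "dataset": self.dataset,
            "traits": list(self.traits),
            "ratios": [list(r) for r in self.ratios],
            "replicates": self.replicates,
            "models": list(self.models),
            "hyperparameters": dict(self.hyperparameters),
            "seed": self.seed,
            "out_dir": self.out_dir,
        }
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)


# ---------------------------------------------------------------------------
# Seed derivation
# ---------------------------------------------------------------------------


def derive_seed(global_seed: int, *components) -> int:
    """Deterministic, collision-resistant child seed for one pipeline stage.

    Hashes the global seed together with any identifying components
    (population id, ratio index, replicate index, stage tag ...) with
    SHA-256 and returns a seed in [0, 2^31). Identical inputs always give
    identical output; distinct tuples collide with negligible probability.
    """
    key = repr((int(global_seed),) + tuple(components)).encode()
    digest = hashlib.sha256(key).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


# ---------------------------------------------------------------------------
# Genotypes + map
# ---------------------------------------------------------------------------


def write_map(gmap: GeneticMap, path: str | Path) -> None:
    """PLINK-MAP-style 4 columns: chromosome, marker id, cM, bp (no header)."""
    df = pd.DataFrame(
        {
            "chromosome": gmap.chromosome,
            "marker_id": gmap.marker_id,
            "position_cM": gmap.position_cM,
            "position_bp": gmap.position_bp,
        }
    )
    df.to_csv(path, sep="\t", header=False, index=False)


def read_map(path: str | Path) -> GeneticMap:
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        names=["chromosome", "marker_id", "position_cM", "position_bp"],
        dtype={"chromosome": str, "marker_id": str},
    )
    if df.isna().any().any():
        raise FormatError(f"{path}: map contains missing fields")
    return GeneticMap(
        marker_id=df["marker_id"].to_numpy(),
        chromosome=df["chromosome"].to_numpy(),
        position_cM=df["position_cM"].to_numpy(float),
        position_bp=df["position_bp"].to_numpy(np.int64),
    )


def write_genotypes(panel: GenotypePanel, path: str | Path) -> None:
    """TSV with a ``ril_id`` first column and one column per marker."""
    df = pd.DataFrame(panel.genotypes, columns=panel.map.marker_id)
    df.insert(0, "ril_id", panel.ril_ids)
    df.to_csv(path, sep="\t", index=False, na_rep="NA")


def read_genotypes(
    genotype_path: str | Path, map_path: str | Path, population_id: str = "pop"
) -> GenotypePanel:
    """Read a genotype TSV against its marker map.

    Marker columns must exactly match the map's marker ids (same order).
    Genotype codes are restricted to {0, 1, 2}; any token in
    :data:`MISSING_TOKENS` becomes the single NaN missing sentinel.
    """
    gmap = read_map(map_path)
    df = pd.read_csv(genotype_path, sep="\t", dtype=str, keep_default_na=False)
    if "ril_id" not in df.columns:
        raise FormatError(f"{genotype_path}: missing 'ril_id' column")
    marker_cols = [c for c in df.columns if c != "ril_id"]
    if marker_cols != list(gmap.marker_id):
        extra = set(marker_cols) - set(gmap.marker_id)
        missing = set(gmap.marker_id) - set(marker_cols)
        raise FormatError(
            f"{genotype_path}: marker columns do not match map "
            f"(unknown: {sorted(extra)[:5]}, absent: {sorted(missing)[:5]})"
        )
    ril_ids = df["ril_id"].tolist()
    raw = df[marker_cols].to_numpy()
    geno = np.empty(raw.shape, dtype=float)
    for j, col in enumerate(marker_cols):
        for i, tok in enumerate(raw[:, j]):
            tok = tok.strip()
            if tok in MISSING_TOKENS:
                geno[i, j] = np.nan
            elif tok in ("0", "1", "2", "0.0", "1.0", "2.0"):
                geno[i, j] = float(tok)
            else:
                raise FormatError(
                    f"{genotype_path}: unknown genotype code {tok!r} "
                    f"at row {ril_ids[i]!r}, column {col!r}"
                )
    return GenotypePanel(
        population_id=population_id, ril_ids=ril_ids, map=gmap, genotypes=geno
    )


# ---------------------------------------------------------------------------
# Phenotypes
# ---------------------------------------------------------------------------


def write_phenotypes(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index=False, na_rep="NA")


def read_phenotypes(path: str | Path) -> pd.DataFrame:
    """Long-format phenotype TSV: ril_id, population_id, environment, then
    one column per trait. Missing values read as NaN."""
    df = pd.read_csv(path, sep="\t", dtype={"ril_id": str})
    required = {"ril_id", "population_id", "environment"}
    if not required.issubset(df.columns):
        raise FormatError(f"{path}: phenotype table needs columns {sorted(required)}")
    trait_cols = [c for c in df.columns if c not in required]
    if not trait_cols:
        raise FormatError(f"{path}: phenotype table has no trait columns")
    for c in trait_cols:
        df[c] = pd.to_numeric(df[c], errors="raise")
    dup = df.duplicated(subset=["ril_id", "population_id", "environment"])
    if dup.any():
        raise FormatError(f"{path}: duplicate (ril, environment) record at row {dup.idxmax()}")
    return df


# ---------------------------------------------------------------------------
# Annotation
# ---------------------------------------------------------------------------


def read_annotation(path: str | Path) -> pd.DataFrame:
    """BED-like annotation with cM coordinates.

    Columns: chromosome, start_cM, end_cM, label, category. Intervals are
    closed. An empty file yields an empty track.
    """
    cols = ["chromosome", "start_cM", "end_cM", "label", "category"]
    try:
        df = pd.read_csv(path, sep="\t", header=None, names=cols, dtype={"chromosome": str})
    except pd.errors.EmptyDataError:
        return pd.DataFrame(columns=cols)
    if (df["start_cM"] > df["end_cM"]).any():
        bad = df.index[df["start_cM"] > df["end_cM"]][0]
        raise FormatError(f"{path}: interval start > end at row {bad}")
    unknown = set(df["category"]) - ANNOTATION_CATEGORIES
    if unknown:
        raise FormatError(f"{path}: unknown annotation categories {sorted(unknown)}")
    return df


def write_annotation(track: pd.DataFrame, path: str | Path) -> None:
    track.to_csv(path, sep="\t", header=False, index=False)
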