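"""Synthetic NAM RIL populations, genetic maps, QTL architectures and
multi-environment flowering-time-like phenotypes.

The generator emulates the structure of nested association mapping (NAM)
experiments: several biparental recombinant-inbred-line (RIL) populations
sharing a common recurrent parent, genotyped at biallelic SNPs on a known
genetic map and phenotyped for one or two flowering-time-like traits in one
or more environments.

Meiosis is modeled as a Poisson crossover process at 1 event per 100 cM with
no interference (Haldane map function). Two cross designs are supported:

* ``backcross_then_self`` — F1 backcrossed once to the recurrent parent,
  then ``n_self_generations`` of selfing by single-seed descent (the
  teosinte-NAM style BC1-derived RILs);
* ``self_only`` — selfing from the F1 (e.g. 4 selfs gives F5 lines).

Genotypes are coded as the dosage {0, 1, 2} of the *donor* parent allele;
missing values are NaN.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "GeneticMap",
    "CrossDesign",
    "QTLArchitecture",
    "GenotypePanel",
    "simulate_map",
    "simulate_gametes",
    "simulate_ril_population",
    "simulate_phenotypes",
    "inject_missingness",
    "teonam_like_preset",
    "maizenam_like_preset",
]


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class GeneticMap:
    """Marker map: per-marker id, chromosome, cM and bp position.

    Positions are strictly increasing within a chromosome in both
    coordinate systems, and marker ids are unique.
    """

    marker_id: np.ndarray
    chromosome: np.ndarray
    position_cM: np.ndarray
    position_bp: np.ndarray

    def __post_init__(self) -> None:
        self.marker_id = np.asarray(self.marker_id, dtype=object)
        self.chromosome = np.asarray(self.chromosome, dtype=object)
        self.position_cM = np.asarray(self.position_cM, dtype=float)
        self.position_bp = np.asarray(self.position_bp, dtype=np.int64)
        if len(set(self.marker_id)) != len(self.marker_id):
            raise ValueError("marker ids must be unique")
        for chrom in self.chromosomes:
            sel = self.chromosome == chrom
            cm, bp = self.position_cM[sel], self.position_bp[sel]
            if not (np.all(np.diff(cm) > 0) and np.all(np.diff(bp) > 0)):
                raise ValueError(f"positions not strictly increasing on {chrom}")

    @property
    def chromosomes(self) -> list:
        seen: dict = {}
        for c in self.chromosome:
            seen.setdefault(c, None)
        return list(seen)

    @property
    def n_markers(self) -> int:
        return len(self.marker_id)

    def chrom_slices(self) -> dict:
        """Map chromosome -> integer index array of its markers, map order."""
        return {c: np.flatnonzero(self.chromosome == c) for c in self.chromosomes}

    def subset(self, indices: np.ndarray) -> "GeneticMap":
        idx = np.asarray(indices)
        return GeneticMap(
            self.marker_id[idx],
            self.chromosome[idx],
            self.position_cM[idx],
            self.position_bp[idx],
        )

    def index_of(self, marker_id: str) -> int:
        hits = np.flatnonzero(self.marker_id == marker_id)
        if len(hits) != 1:
            raise KeyError(f"marker {marker_id!r} not in map")
        return int(hits[0])


@dataclass
class CrossDesign:
    """How each RIL population is derived from the parental cross."""

    scheme: str = "self_only"  # or "backcross_then_self"
    n_self_generations: int = 4
    recurrent_parent: str = "P1"
    donor_parent: str = "P2"
    n_rils: int = 200

    def __post_init__(self) -> None:
        if self.scheme not in ("self_only", "backcross_then_self"):
            raise ValueError(f"unknown cross scheme {self.scheme!r}")
        if self.n_self_generations < 1:
            raise ValueError("n_self_generations must be >= 1")
        if self.n_rils < 1:
            raise ValueError("n_rils must be >= 1")


@dataclass
class QTLArchitecture:
    """Trait genetic architecture: additive QTL, epistatic pairs, targets.

    ``target_h2_additive`` / ``target_h2_epistatic`` are the fractions of
    phenotypic variance explained by the additive and additive-by-additive
    components; their sum must not exceed 1. ``env_effects`` maps
    environment labels to additive shifts in trait units.
    """

    trait_name: str
    additive_qtl: list = field(default_factory=list)  # (marker_id, effect)
    epistatic_pairs: list = field(default_factory=list)  # (id_i, id_j, effect)
    target_h2_additive: float = 0.5
    target_h2_epistatic: float = 0.0
    env_effects: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0 <= self.target_h2_additive <= 1 or not 0 <= self.target_h2_epistatic <= 1:
            raise ValueError("heritability targets must lie in [0, 1]")
        if self.target_h2_additive + self.target_h2_epistatic > 1 + 1e-12:
            raise ValueError("target_h2_additive + target_h2_epistatic must be <= 1")
        for mi, mj, _ in self.epistatic_pairs:
            if mi == mj:
                raise ValueError(f"self-pair {mi!r} in epistatic_pairs")


@dataclass
class GenotypePanel:
    """RIL x marker donor-allele dosage matrix with its map.

    Values are restricted to {0, 1, 2, NaN}. Rows align with ``ril_ids``,
    columns with ``map.marker_id``.
    """

    population_id: str
    ril_ids: list
    map: GeneticMap
    genotypes: np.ndarray

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes, dtype=float)
        n, m = self.genotypes.shape
        if n != len(self.ril_ids) or m != self.map.n_markers:
            raise ValueError(
                f"genotype matrix {self.genotypes.shape} does not match "
                f"{len(self.ril_ids)} RILs x {self.map.n_markers} markers"
            )
        vals = self.genotypes[~np.isnan(self.genotypes)]
        if vals.size and not np.isin(vals, (0.0, 1.0, 2.0)).all():
            bad = vals[~np.isin(vals, (0.0, 1.0, 2.0))][0]
            raise ValueError(f"genotype code {bad!r} outside {{0,1,2,missing}}")

    @property
    def n_rils(self) -> int:
        return len(self.ril_ids)

    def copy(self) -> "GenotypePanel":
        return GenotypePanel(
            self.population_id, list(self.ril_ids), self.map, self.genotypes.copy()
        )

    def subset_markers(self, indices: np.ndarray) -> "GenotypePanel":
        idx = np.asarray(indices)
        return GenotypePanel(
            self.population_id,
            list(self.ril_ids),
            self.map.subset(idx),
            self.genotypes[:, idx],
        )

    def subset_rils(self, row_indices: np.ndarray) -> "GenotypePanel":
        idx = np.asarray(row_indices)
        return GenotypePanel(
            self.population_id,
            [self.ril_ids[i] for i in idx],
            self.map,
            self.genotypes[idx],
        )


# ---------------------------------------------------------------------------
# Map simulation
# ---------------------------------------------------------------------------


def simulate_map(
    n_chromosomes: int,
    markers_per_chromosome: int,
    chrom_length_cM: float = 150.0,
    bp_per_cM: float = 10_000.0,
    seed: int = 0,
) -> GeneticMap:
    """Simulate a jitter-spaced marker map.

    Markers are laid out approximately uniformly along each chromosome with
    random jitter, then sorted; bp positions are a monotone (locally
    jittered) transform of the cM positions at ``bp_per_cM``.
    """
    if n_chromosomes < 1 or markers_per_chromosome < 1:
        raise ValueError("counts must be positive")
    if chrom_length_cM <= 0 or bp_per_cM <= 0:
        raise ValueError("lengths must be positive")
    rng = np.random.default_rng(seed)
    ids, chroms, cms, bps = [], [], [], []
    for c in range(1, n_chromosomes + 1):
        base = np.linspace(0, chrom_length_cM, markers_per_chromosome + 2)[1:-1]
        jitter = rng.uniform(-0.3, 0.3, markers_per_chromosome) * (
            chrom_length_cM / (markers_per_chromosome + 1)
        )
        cm = np.sort(base + jitter)
        # enforce strict increase with a minimal gap
        cm = np.maximum.accumulate(cm + np.arange(markers_per_chromosome) * 1e-6)
        bp = np.round(cm * bp_per_cM).astype(np.int64)
        bp = np.maximum.accumulate(bp + np.arange(markers_per_chromosome))
        for k in range(markers_per_chromosome):
            ids.append(f"chr{c}_m{k + 1}")
            chroms.append(f"chr{c}")
        cms.append(cm)
        bps.append(bp)
    return GeneticMap(
        np.array(ids, dtype=object),
        np.array(chroms, dtype=object),
        np.concatenate(cms),
        np.concatenate(bps),
    )


# ---------------------------------------------------------------------------
# Meiosis and RIL development
# ---------------------------------------------------------------------------


def simulate_gametes(
    hap_a: np.ndarray, hap_b: np.ndarray, positions_cM: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """One gamete per individual from paired haplotypes on ONE chromosome.

    ``hap_a``/``hap_b`` are (n, m) haplotype allele matrices, ``positions_cM``
    the m marker positions. Crossovers fall as a Poisson process at
    1 / 100 cM along the chromosome (Haldane, no interference); the gamete
    starts on a random haplotype and switches at every crossover.
    """
    n, m = hap_a.shape
    length = positions_cM[-1] - positions_cM[0] if m > 1 else 0.0
    n_cross = rng.poisson(length / 100.0, size=n)
    max_c = int(n_cross.max()) if n else 0
    # parity[i, j] = (# crossovers left of marker j) mod 2, vectorized via
    # padded uniform crossover positions
    parity = np.zeros((n, m), dtype=np.int64)
    if max_c > 0:
        pos = rng.uniform(positions_cM[0], positions_cM[-1], size=(n, max_c))
        valid = np.arange(max_c)[None, :] < n_cross[:, None]
        pos = np.where(valid, pos, np.inf)
        parity = (pos[:, :, None] < positions_cM[None, None, :]).sum(axis=1) % 2
    start = rng.integers(0, 2, size=n)
    use_b = (start[:, None] + parity) % 2 == 1
    return np.where(use_b, hap_b, hap_a)


def _meiosis_whole_genome(
    hap_a: np.ndarray, hap_b: np.ndarray, gmap: GeneticMap, rng: np.random.Generator
) -> np.ndarray:
    out = np.empty_like(hap_a)
    for _, idx in gmap.chrom_slices().items():
        out[:, idx] = simulate_gametes(
            hap_a[:, idx], hap_b[:, idx], gmap.position_cM[idx], rng
        )
    return out


def simulate_ril_population(
    gmap: GeneticMap, design: CrossDesign, seed: int = 0, population_id: str | None = None
) -> GenotypePanel:
    """Develop a RIL population by gamete simulation.

    The recurrent parent carries allele 0 at every marker, the donor allele
    1. The F1 is heterozygous throughout. Under ``backcross_then_self`` one
    backcross to the recurrent parent precedes selfing; selfing proceeds by
    single-seed descent for ``design.n_self_generations`` generations.
    Returns donor-allele dosages in {0, 1, 2}.
    """
    if gmap.n_markers == 0:
        raise ValueError("map must be non-empty")
    rng = np.random.default_rng(seed)
    n, m = design.n_rils, gmap.n_markers

    # F1: haplotypes (recurrent=0, donor=1) for every prospective line
    hap_a = np.zeros((n, m), dtype=np.int8)
    hap_b = np.ones((n, m), dtype=np.int8)

    if design.scheme == "backcross_then_self":
        # BC1 = gamete(F1) x gamete(recurrent parent = all zeros)
        hap_a = _meiosis_whole_genome(hap_a, hap_b, gmap, rng)
        hap_b = np.zeros((n, m), dtype=np.int8)

    for _ in range(design.n_self_generations):
        new_a = _meiosis_whole_genome(hap_a, hap_b, gmap, rng)
        new_b = _meiosis_whole_genome(hap_a, hap_b, gmap, rng)
        hap_a, hap_b = new_a, new_b

    geno = (hap_a + hap_b).astype(float)
    pid = population_id or f"{design.recurrent_parent}x{design.donor_parent}"
    ril_ids = [f"{pid}_RIL{i + 1:04d}" for i in range(n)]
    return GenotypePanel(pid, ril_ids, gmap, geno)


# ---------------------------------------------------------------------------
# Phenotype simulation
# ---------------------------------------------------------------------------


def genetic_values(
    panel: GenotypePanel, architecture: QTLArchitecture
) -> tuple[np.ndarray, np.ndarray]:
    """Raw (unscaled) additive and epistatic genetic components per RIL."""
    g = panel.genotypes
    add = np.zeros(panel.n_rils)
    for marker, eff in architecture.additive_qtl:
        add += eff * g[:, panel.map.index_of(marker)]
    epi = np.zeros(panel.n_rils)
    for mi, mj, eff in architecture.epistatic_pairs:
        epi += eff * g[:, panel.map.index_of(mi)] * g[:, panel.map.index_of(mj)]
    return add, epi


def simulate_phenotypes(
    panel: GenotypePanel,
    architecture: QTLArchitecture,
    n_environments: int = 1,
    seed: int = 0,
    trait_scale: float = 1.0,
):
    """Simulate one phenotype record per RIL per environment.

    The additive and epistatic genetic components are rescaled so their
    variances across the population equal ``target_h2_additive`` and
    ``target_h2_epistatic`` times the total phenotypic variance
    (``trait_scale`` squared); residual noise supplies the remaining
    fraction. The epistatic component is first orthogonalized against the
    additive one (the standard variance-partition convention: epistatic
    variance is what interactions explain beyond their additive
    projection), so the two target fractions add. Environment shifts from ``architecture.env_effects`` are added
    (default 0). Returns a long-format ``pandas.DataFrame`` with columns
    ril_id, population_id, environment and the trait, plus the scaled
    genetic value column ``_genetic_value`` for auditability.
    """
    import pandas as pd

    if panel.genotypes.size and np.isnan(panel.genotypes).any():
        raise ValueError("panel must be fully genotyped for phenotype simulation")
    h2a, h2e = architecture.target_h2_additive, architecture.target_h2_epistatic
    if h2a + h2e > 1 + 1e-12:
        raise ValueError("heritability targets sum above 1")

    add, epi = genetic_values(panel, architecture)
    # orthogonalize interactions against the additive component so the two
    # variance fractions are additive (linked QTL induce covariance)
    if add.var() > 0 and epi.var() > 0:
        epi = epi - np.cov(epi, add)[0, 1] / add.var() * (add - add.mean())

    def _scaled(component: np.ndarray, target: float, label: str) -> np.ndarray:
        v = component.var()
        if target == 0:
            return np.zeros_like(component)
        if v == 0:
            raise ValueError(
                f"{label} target h2 > 0 but architecture has no {label} variance"
            )
        return (component - component.mean()) * np.sqrt(target / v) * trait_scale

    add_s = _scaled(add, h2a, "additive")
    epi_s = _scaled(epi, h2e, "epistatic")
    resid_sd = trait_scale * np.sqrt(max(0.0, 1.0 - h2a - h2e))

    rng = np.random.default_rng(seed)
    records = []
    for e in range(n_environments):
        env = f"env{e + 1}"
        shift = float(architecture.env_effects.get(env, 0.0))
        noise = rng.normal(0.0, resid_sd, panel.n_rils) if resid_sd > 0 else 0.0
        y = add_s + epi_s + shift + noise
        records.append(
            pd.DataFrame(
                {
                    "ril_id": panel.ril_ids,
                    "population_id": panel.population_id,
                    "environment": env,
                    architecture.trait_name: y,
                    "_genetic_value": add_s + epi_s,
                    "_additive_value": add_s,
                    "_epistatic_value": epi_s,
                }
            )
        )
    return pd.concat(records, ignore_index=True)


# ---------------------------------------------------------------------------
# Missingness injection
# ---------------------------------------------------------------------------


def inject_missingness(
    panel: GenotypePanel, rate: float = 0.0, block_rate: float = 0.0, seed: int = 0
) -> GenotypePanel:
    """Mark genotypes missing at random; with probability ``block_rate`` per
    RIL additionally blank one whole chromosome (exercises the
    whole-chromosome sample filter downstream)."""
    if not (0 <= rate <= 1 and 0 <= block_rate <= 1):
        raise ValueError("rates must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    out = panel.copy()
    if rate > 0:
        mask = rng.random(out.genotypes.shape) < rate
        out.genotypes[mask] = np.nan
    if block_rate > 0:
        slices = panel.map.chrom_slices()
        chroms = list(slices)
        for i in range(out.n_rils):
            if rng.random() < block_rate:
                c = chroms[rng.integers(len(chroms))]
                out.genotypes[i, slices[c]] = np.nan
    return out


# ---------------------------------------------------------------------------
# NAM presets
# ---------------------------------------------------------------------------


def _random_architecture(
    gmap: GeneticMap,
    trait_name: str,
    n_additive: int,
    n_epistatic: int,
    h2a: float,
    h2e: float,
    env_effects: dict,
    rng: np.random.Generator,
) -> QTLArchitecture:
    qtl_idx = rng.choice(gmap.n_markers, size=n_additive, replace=False)
    additive = [
        (gmap.marker_id[i], float(rng.normal(0, 1))) for i in qtl_idx
    ]
    pairs = []
    if n_epistatic > 0:
        flat = rng.choice(gmap.n_markers, size=(n_epistatic, 2), replace=False)
        for i, j in flat:
            pairs.append((gmap.marker_id[i], gmap.marker_id[j], float(rng.normal(0, 1))))
    return QTLArchitecture(
        trait_name=trait_name,
        additive_qtl=additive,
        epistatic_pairs=pairs,
        target_h2_additive=h2a,
        target_h2_epistatic=h2e,
        env_effects=env_effects,
    )


def _nam_dataset(
    n_populations: int,
    design_template: CrossDesign,
    n_chromosomes: int,
    markers_per_chromosome: int,
    n_environments: int,
    trait_targets: dict,
    n_rils_range: tuple[int, int],
    seed: int,
    recurrent_parent: str,
    scale_spread: tuple[float, float] = (1.0, 1.0),
    h2_spread: tuple[float, float] = (1.0, 1.0),
):
    """Shared machinery for the two NAM presets.

    ``scale_spread`` / ``h2_spread`` set the deterministic between-population
    heterogeneity: population k's trait scale and genetic-variance targets
    are multiplied by the k-th point of a linear ramp over the given range.
    A wide ramp emulates NAM designs whose populations differ strongly in
    phenotypic variance and variance-component composition; a narrow ramp
    emulates per-population-standardized (BLUE-like) phenotypes.
    """
    import pandas as pd

    rng = np.random.default_rng(seed)
    gmap = simulate_map(
        n_chromosomes, markers_per_chromosome, chrom_length_cM=150.0, seed=seed
    )
    scale_ramp = np.linspace(scale_spread[0], scale_spread[1], n_populations)
    h2_ramp = np.linspace(h2_spread[0], h2_spread[1], n_populations)
    panels, phenos = [], []
    for p in range(n_populations):
        n_rils = int(rng.integers(n_rils_range[0], n_rils_range[1] + 1))
        design = CrossDesign(
            scheme=design_template.scheme,
            n_self_generations=design_template.n_self_generations,
            recurrent_parent=recurrent_parent,
            donor_parent=f"DONOR{p + 1:02d}",
            n_rils=n_rils,
        )
        panel = simulate_ril_population(
            gmap, design, seed=int(rng.integers(2**31)), population_id=f"{recurrent_parent}xD{p + 1:02d}"
        )
        panels.append(panel)
        pop_pheno = []
        for trait, (h2a, h2e, n_add, n_epi) in trait_targets.items():
            env_effects = {
                f"env{e + 1}": float(rng.normal(0, 1.0)) for e in range(n_environments)
            }
            h2a_p = float(np.clip(h2a * h2_ramp[p], 0.05, 0.95 - h2e))
            arch = _random_architecture(
                gmap, trait, n_add, n_epi, h2a_p, h2e, env_effects, rng
            )
            base_scale = 3.0 if trait.startswith("DTA") else 1.5
            tbl = simulate_phenotypes(
                panel,
                arch,
                n_environments=n_environments,
                seed=int(rng.integers(2**31)),
                trait_scale=base_scale * float(scale_ramp[p]),
            )
            pop_pheno.append(tbl[["ril_id", "population_id", "environment", trait]])
        merged = pop_pheno[0]
        for extra in pop_pheno[1:]:
            merged = merged.merge(extra, on=["ril_id", "population_id", "environment"])
        phenos.append(merged)
    return panels, pd.concat(phenos, ignore_index=True), gmap


def teonam_like_preset(
    seed: int = 0,
    n_populations: int = 5,
    markers_per_chromosome: int = 30,
    n_chromosomes: int = 10,
    n_rils_range: tuple[int, int] = (438, 616),
):
    """High-diversity preset: BC1-derived selfed populations (one backcross to
    the shared recurrent parent, then 4 selfs), 2 environments per
    population, a higher-heritability DTA-like trait and a noisier, partly
    epistatic ASI-like trait. Populations differ strongly in phenotypic
    scale and variance-component composition (raw multi-environment
    phenotypes from divergent donors), which drives high between-scenario
    dispersion of the ensemble's diversity terms."""
    design = CrossDesign(scheme="backcross_then_self", n_self_generations=4)
    # trait -> (h2_additive, h2_epistatic, n additive QTL, n epistatic pairs)
    targets = {"DTA": (0.45, 0.15, 12, 3), "ASI": (0.30, 0.12, 10, 3)}
    return _nam_dataset(
        n_populations,
        design,
        n_chromosomes,
        markers_per_chromosome,
        2,
        targets,
        n_rils_range,
        seed,
        recurrent_parent="RP1",
        scale_spread=(0.6, 1.8),
        h2_spread=(0.6, 1.4),
    )


def maizenam_like_preset(
    seed: int = 0,
    n_populations: int = 25,
    markers_per_chromosome: int = 20,
    n_chromosomes: int = 10,
    n_rils_range: tuple[int, int] = (126, 196),
):
    """Lower-diversity preset: F5 selfed populations from a shared elite
    parent, single BLUE-like phenotype record per RIL, smaller genetic
    variance for the ASI-like trait. BLUE derivation centers phenotypes per
    population, so between-population scale heterogeneity is minimal."""
    design = CrossDesign(scheme="self_only", n_self_generations=4)
    targets = {"DTA": (0.55, 0.10, 12, 3), "ASI": (0.35, 0.10, 10, 3)}
    return _nam_dataset(
        n_populations,
        design,
        n_chromosomes,
        markers_per_chromosome,
        1,
        targets,
        n_rils_range,
        seed,
        recurrent_parent="RP2",
        scale_spread=(0.95, 1.05),
        h2_spread=(0.95, 1.05),
    )
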