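"""Synthetic data generators with known ground truth.

No genotype, GPS or morphometric data are distributed with the package, so
every analysis is exercised on simulated inputs whose generating process
mirrors the structure the pipeline assumes: K diverged genetic
subpopulations (Balding-Nichols model), habitat-use ecotypes coupled to the
genetic clusters with a tunable probability, phenotypes produced by a
hierarchical linear model with management-unit intercepts and an individual
homozygosity effect, and a translocation event table.

All generators are pure functions of (config, seed): the global seed is
expanded into independent per-stage substreams so each stage can be
regenerated on its own.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .datatypes import (
    HABITAT_CLASSES,
    MANAGEMENT_UNITS,
    GenotypeTable,
    HabitatUseTable,
    TranslocationTable,
    ValidationError,
)

# Two ecotype habitat profiles (Dirichlet concentrations over the 7 classes,
# ordered as HABITAT_CLASSES): a forest-dominated "montane" profile and an
# open/barren "alpine" profile.  Upland forest dominates the pooled sample
# (~50% of use) and wetland-herbaceous is rare (<1%), matching the relative
# ranking observed in collared bears.
DEFAULT_ECO_CONCENTRATIONS = (
    (3.0, 5.0, 5.0, 0.4, 4.0, 2.0, 35.0),   # montane: ~64% upland forest
    (4.0, 3.0, 6.0, 0.4, 10.0, 12.0, 15.0),  # alpine: barren/herbaceous heavy
)


@dataclass(frozen=True)
class PhenotypeCoeffs:
    """True fixed-effect values used to generate one log-scale response."""

    intercept: float = 3.92
    sex: float = 0.55          # male effect (females are the reference)
    age: float = 0.05          # per year
    northing: float = 0.10     # per planar northing unit (~100 km)
    spring: float = 0.05       # season dummies, fall is the reference
    summer: float = 0.07
    hl: float = 0.65           # homozygosity-by-loci effect


#: Straight-line-length coefficients: roughly a quarter of the mass effects,
#: with an intercept on the log-cm scale.
LENGTH_COEFFS = PhenotypeCoeffs(
    intercept=4.89, sex=0.11, age=0.01, northing=-0.01,
    spring=-0.01, summer=-0.02, hl=0.15,
)


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic study population.

    Defaults emulate the study system: 88 collared bears genotyped at 15
    microsatellites with ~8 alleles per locus, 3 genetic clusters at modest
    divergence, 2 habitat-use ecotypes coupled to the genetic clusters, and
    6 management units ordered south to north.
    """

    n_individuals: int = 88
    n_loci: int = 15
    alleles_per_locus: int = 8
    k_gen: int = 3
    fst: float = 0.10
    k_eco: int = 2
    eco_concentrations: tuple = DEFAULT_ECO_CONCENTRATIONS
    coupling: float = 0.6
    n_units: int = 6
    phenotype_coeffs: PhenotypeCoeffs = field(default_factory=PhenotypeCoeffs)
    length_coeffs: PhenotypeCoeffs = field(default_factory=lambda: LENGTH_COEFFS)
    sigma_unit: float = 0.15
    sigma_resid: float = 0.20
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.fst < 1.0):
            raise ValidationError("fst must lie strictly in (0, 1)")
        for name in ("n_individuals", "n_loci", "alleles_per_locus",
                     "k_gen", "k_eco", "n_units"):
            if getattr(self, name) < 1:
                raise ValidationError(f"{name} must be >= 1")
        if self.alleles_per_locus < 2:
            raise ValidationError("alleles_per_locus must be >= 2")
        if len(self.eco_concentrations) != self.k_eco:
            raise ValidationError("eco_concentrations must have k_eco rows")
        for row in self.eco_concentrations:
            if len(row) != len(HABITAT_CLASSES):
                raise ValidationError("each ecotype needs 7 concentrations")
            if any(a <= 0 for a in row):
                raise ValidationError("Dirichlet concentrations must be positive")
        if not (0.0 <= self.coupling <= 1.0):
            raise ValidationError("coupling must lie in [0, 1]")
        if not (0.0 <= self.missing_rate < 1.0):
            raise ValidationError("missing_rate must lie in [0, 1)")

    def with_(self, **kwargs) -> "SimulationConfig":
        return replace(self, **kwargs)

    def unit_names(self) -> list[str]:
        if self.n_units <= len(MANAGEMENT_UNITS):
            return list(MANAGEMENT_UNITS[: self.n_units])
        return [f"Unit{u + 1}" for u in range(self.n_units)]


@dataclass
class SyntheticTruth:
    """Ground-truth record for recovery tests."""

    genetic_cluster: np.ndarray       # (n,) labels in 1..k_gen
    ecotype: np.ndarray | None = None  # (n,) labels in 1..k_eco
    unit: np.ndarray | None = None     # (n,) indices in 0..n_units-1
    hl_effect: float | None = None
    unit_intercepts: np.ndarray | None = None
    ancestral_frequencies: list | None = None  # per locus (A,) array
    population_frequencies: list | None = None  # per locus (k_gen, A) array


# ---------------------------------------------------------------------------
# seed plumbing

_STAGES = ("genotypes", "habitat", "phenotypes", "translocations", "fixes")


def _stage_rng(seed: int, stage: str) -> np.random.Generator:
    ss = np.random.SeedSequence(seed, spawn_key=(_STAGES.index(stage),))
    return np.random.default_rng(ss)


# ---------------------------------------------------------------------------
# genotypes


def generate_genotypes(config: SimulationConfig) -> tuple[GenotypeTable, SyntheticTruth]:
    """Simulate diploid genotypes from K diverged subpopulations.

    Divergence follows the Balding-Nichols construction: ancestral allele
    frequencies ``p_anc`` are drawn from a symmetric Dirichlet(1), and each
    subpopulation's frequencies from Dirichlet(p_anc * (1 - fst) / fst), so
    ``fst`` directly controls the expected variance of frequencies across
    clusters.  Individuals fill the clusters in near-equal contiguous
    blocks, and each genotype is two independent draws from its cluster's
    frequencies.
    """
    rng = _stage_rng(config.seed, "genotypes")
    n, L, A, K = (config.n_individuals, config.n_loci,
                  config.alleles_per_locus, config.k_gen)

    labels = np.array_split(np.arange(n), K)
    cluster = np.empty(n, dtype=np.int64)
    for k, block in enumerate(labels):
        cluster[block] = k + 1

    anc, pops = [], []
    alleles = np.zeros((n, L, 2), dtype=np.int64)
    scale = (1.0 - config.fst) / config.fst
    for locus in range(L):
        p_anc = rng.dirichlet(np.ones(A))
        p_pop = np.vstack([rng.dirichlet(p_anc * scale) for _ in range(K)])
        anc.append(p_anc)
        pops.append(p_pop)
        for k in range(K):
            mask = cluster == k + 1
            m = int(mask.sum())
            draws = rng.choice(A, size=(m, 2), p=p_pop[k]) + 1
            alleles[mask, locus, :] = draws

    if config.missing_rate > 0:
        miss = rng.random((n, L)) < config.missing_rate
        alleles[miss] = 0

    ids = [f"bear{i + 1:03d}" for i in range(n)]
    loci = [f"L{j + 1:02d}" for j in range(L)]
    table = GenotypeTable(ids, loci, alleles)
    truth = SyntheticTruth(
        genetic_cluster=cluster,
        ancestral_frequencies=anc,
        population_frequencies=pops,
    )
    return table, truth


# ---------------------------------------------------------------------------
# habitat use


def generate_habitat_use(config: SimulationConfig,
                         truth: SyntheticTruth) -> HabitatUseTable:
    """Draw each individual's 7-class use vector from its ecotype Dirichlet.

    The ecotype equals the genetic cluster index (folded onto 1..k_eco by a
    monotone block mapping, the identity when k_eco = k_gen)
    with probability ``coupling``; otherwise it is drawn uniformly over all
    ``k_eco`` ecotypes, so ``coupling`` = 0 gives ecotypes independent of
    the genetic clusters and ``coupling`` = 1 ties them exactly.  This
    single probability controls the Pearson correlation between ecotype
    and genotype assignments that the clustering stage should recover.
    """
    if truth.genetic_cluster is None:
        raise ValidationError("truth must carry genetic cluster labels")
    rng = _stage_rng(config.seed, "habitat")
    n = config.n_individuals
    ke = config.k_eco

    coupled = (truth.genetic_cluster - 1) * ke // config.k_gen + 1
    eco = coupled.copy()
    flip = rng.random(n) >= config.coupling
    if ke > 1:
        eco[flip] = rng.integers(1, ke + 1, size=int(flip.sum()))

    conc = np.asarray(config.eco_concentrations, dtype=float)
    props = np.empty((n, len(HABITAT_CLASSES)))
    for i in range(n):
        props[i] = rng.dirichlet(conc[eco[i] - 1])
    props /= props.sum(axis=1, keepdims=True)

    truth.ecotype = eco
    ids = [f"bear{i + 1:03d}" for i in range(n)]
    return HabitatUseTable(ids, props)


def expand_fixes(use: HabitatUseTable, n_fixes: int = 1000,
                 seed: int = 0) -> pd.DataFrame:
    """Multinomially expand use proportions into a synthetic GPS fix table.

    Convenience only: fixes carry an individual id, a running timestamp
    index, placeholder planar coordinates and a land-cover class; no
    movement or autocorrelation model is attached.
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(7,)))
    rows = []
    for i, ind in enumerate(use.ids):
        counts = rng.multinomial(n_fixes, use.proportions[i])
        classes = np.repeat(np.arange(len(HABITAT_CLASSES)), counts)
        rng.shuffle(classes)
        for t, c in enumerate(classes):
            rows.append((ind, t, float(rng.random()), float(rng.random()),
                         HABITAT_CLASSES[c]))
    return pd.DataFrame(rows, columns=["id", "timestamp", "x", "y", "landcover"])


# ---------------------------------------------------------------------------
# phenotypes


def generate_phenotypes(config: SimulationConfig, truth: SyntheticTruth,
                        hl: np.ndarray) -> pd.DataFrame:
    """Generate capture metadata and morphometrics from the hierarchical model.

    log(mass) and log(SLL) are linear in sex, age, northing, season dummies
    and the individual homozygosity ``hl``, plus a management-unit intercept
    drawn N(0, sigma_unit^2) and residual noise N(0, sigma_resid^2).  Ages
    are a truncated geometric distribution on 2..25; capture coordinates
    fall inside unit-specific boxes stacked south to north (one planar unit
    of northing per management unit); season is spring/summer/fall.
    """
    hl = np.asarray(hl, dtype=float)
    n = config.n_individuals
    if hl.shape != (n,) or np.isnan(hl).any():
        raise ValidationError("hl must provide one value per individual")
    if ((hl < 0) | (hl > 1)).any():
        raise ValidationError("hl values must lie in [0, 1]")

    rng = _stage_rng(config.seed, "phenotypes")
    units = rng.integers(config.n_units, size=n)
    unit_names = config.unit_names()
    unit_icpt = rng.normal(0.0, config.sigma_unit, size=config.n_units)

    sex = rng.integers(0, 2, size=n)  # 0 = F, 1 = M
    ages = np.minimum(2 + rng.geometric(0.18, size=n) - 1, 25)
    x = rng.uniform(0.0, 1.0, size=n)
    y = units + rng.uniform(0.0, 1.0, size=n)  # northing box per unit
    season = rng.choice(["spring", "summer", "fall"], size=n)

    spring = (season == "spring").astype(float)
    summer = (season == "summer").astype(float)

    def linpred(c: PhenotypeCoeffs) -> np.ndarray:
        return (c.intercept + c.sex * sex + c.age * ages + c.northing * y
                + c.spring * spring + c.summer * summer + c.hl * hl)

    log_mass = (linpred(config.phenotype_coeffs) + unit_icpt[units]
                + rng.normal(0.0, config.sigma_resid, size=n))
    log_sll = (linpred(config.length_coeffs) + unit_icpt[units]
               + rng.normal(0.0, config.sigma_resid * 0.5, size=n))

    truth.unit = units
    truth.unit_intercepts = unit_icpt
    truth.hl_effect = config.phenotype_coeffs.hl

    return pd.DataFrame({
        "id": [f"bear{i + 1:03d}" for i in range(n)],
        "sex": np.where(sex == 1, "M", "F"),
        "age": ages,
        "x": x,
        "y": y,
        "season": season,
        "unit": [unit_names[u] for u in units],
        "mass": np.exp(log_mass),
        "sll": np.exp(log_sll),
        "hl": hl,
    })


# ---------------------------------------------------------------------------
# translocations


def generate_translocations(n_events: int, n_units: int, p_cross: float,
                            p_north: float, seed: int = 0,
                            year_range: tuple[int, int] = (1974, 2012),
                            ) -> TranslocationTable:
    """Simulate a management translocation event table.

    Each event has a uniformly drawn source unit and year.  With
    probability ``p_cross`` the destination differs from the source, and a
    cross-unit destination is a more northern unit with probability
    ``p_north`` (units carry a fixed south-to-north ordering).
    """
    if not (0.0 <= p_cross <= 1.0 and 0.0 <= p_north <= 1.0):
        raise ValidationError("probabilities must lie in [0, 1]")
    if n_units < 2 and p_cross > 0:
        raise ValidationError("cross-unit events require at least 2 units")

    rng = _stage_rng(seed, "translocations")
    units = (list(MANAGEMENT_UNITS[:n_units]) if n_units <= len(MANAGEMENT_UNITS)
             else [f"Unit{u + 1}" for u in range(n_units)])
    rows = []
    for e in range(n_events):
        year = int(rng.integers(year_range[0], year_range[1] + 1))
        if rng.random() < p_cross:
            # direction first, then a uniformly chosen compatible pair, so
            # the realised northward share matches p_north in expectation
            go_north = rng.random() < p_north
            lo = int(rng.integers(n_units - 1))
            hi = int(rng.integers(lo + 1, n_units))
            src, dst = (lo, hi) if go_north else (hi, lo)
        else:
            src = dst = int(rng.integers(n_units))
        rows.append((f"T{e + 1:04d}", year, units[src], units[dst]))
    return TranslocationTable(
        pd.DataFrame(rows, columns=["event_id", "year", "source_unit", "dest_unit"])
    )
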