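"""Forward simulator for progeny-array mating-system studies.

Generates populations with the statistical structure the downstream
analysis assumes: Dirichlet allele frequencies at unlinked microsatellite
loci, maternal plants drawn at a chosen adult inbreeding level, per-flower
herkogamy with among- and within-plant variance components, family selfing
rates tied to plant mean herkogamy through a logistic link, progeny arrays
produced under the mixed-mating model with early culling of selfed zygotes
(the mechanism that separates the primary selfing rate from the realised
one), and a paired self/outcross hand-pollination fitness experiment.

Everything is driven by a :class:`SimulationConfig` plus a seed; identical
(config, seed) pairs give byte-identical serialised outputs.  Ground truth
is returned alongside the data so every estimator can be checked by
parameter recovery.

The default configurations (:func:`study_config`) emulate a two-population
field study of *Datura inoxia*: 30 maternal families per population,
20 genotyped progeny each, 5 (Cañada de Moreno–like, one locus failed) or 6
(Mapimí-like) polymorphic microsatellite loci, herkogamy distributions with
the two populations' contrasting means, spreads and among-plant variance
shares, and treatment-level inbreeding depression of 0.09 / 0.25.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .io import (
    MISSING,
    ProgenyArray,
    arrays_to_collection,
    write_genepop,
    write_herkogamy_table,
    write_fitness_table,
    write_progeny_table,
)

__all__ = [
    "SimulationConfig",
    "SimulatedTruth",
    "SimulatedPopulation",
    "study_config",
    "draw_allele_frequencies",
    "draw_maternal_genotypes",
    "simulate_herkogamy",
    "family_selfing_rates",
    "simulate_progeny_arrays",
    "simulate_fitness_experiment",
    "simulate_population",
    "write_population",
]


@dataclass
class SimulationConfig:
    """Parameters of one simulated population.

    Herkogamy is in mm (pistil minus stamen length; negative = reverse
    herkogamy).  ``selfing_intercept``/``selfing_slope`` act on the logit
    scale: a family's true selfing rate is
    ``expit(intercept + slope * plant_mean_herkogamy)``.  ``delta_true`` is
    the probability that a selfed zygote is culled before genotyping
    (early inbreeding depression); culled offspring are redrawn so arrays
    always reach ``n_progeny``.
    """

    seed: int = 0
    population_id: str = "pop"
    n_families: int = 30
    n_progeny: int = 20
    n_loci: int = 6
    alleles_per_locus: int | list[int] = 5
    allele_freq_concentration: float = 1.0
    adult_F: float = 0.0
    herkogamy_mean: float = 0.0
    herkogamy_sd_among: float = 5.0
    herkogamy_sd_within: float = 3.0
    flowers_per_plant: tuple[int, int] = (4, 6)
    selfing_intercept: float = 0.0
    selfing_slope: float = -0.15
    delta_true: float = 0.0
    missing_rate: float = 0.0
    null_allele_rate: float = 0.0  # optional stress-test corruption, off by default
    # fitness experiment
    n_mothers_fitness: int = 100
    fruits_per_treatment: int = 2
    mean_ovules: int = 300
    outcross_seed_set: float = 0.8
    seed_set_concentration: float = 50.0
    seed_mass_mean: float = 15.0  # mg per seed
    seed_mass_sd: float = 3.0

    def __post_init__(self) -> None:
        if self.n_families < 1 or self.n_progeny < 1 or self.n_loci < 1:
            raise ValueError("counts must be >= 1")
        ks = self.alleles_per_locus if isinstance(self.alleles_per_locus, list) else [self.alleles_per_locus]
        if any(k < 2 for k in ks):
            raise ValueError("alleles_per_locus must be >= 2")
        if self.allele_freq_concentration <= 0:
            raise ValueError("allele_freq_concentration must be positive")
        for name in ("delta_true", "missing_rate", "null_allele_rate"):
            v = getattr(self, name)
            if not 0.0 <= v < 1.0:
                raise ValueError(f"{name} must lie in [0, 1)")
        if not -1.0 <= self.adult_F <= 1.0:
            raise ValueError("adult_F must lie in [-1, 1]")
        if self.herkogamy_sd_among < 0 or self.herkogamy_sd_within < 0:
            raise ValueError("herkogamy sd parameters must be >= 0")
        lo, hi = self.flowers_per_plant
        if lo < 1 or hi < lo:
            raise ValueError("flowers_per_plant must be a valid (low, high) range")

    def alleles_at(self, locus: int) -> int:
        if isinstance(self.alleles_per_locus, list):
            return self.alleles_per_locus[locus]
        return self.alleles_per_locus

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        raw = yaml.safe_load(Path(path).read_text())
        if "flowers_per_plant" in raw:
            raw["flowers_per_plant"] = tuple(raw["flowers_per_plant"])
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        d["flowers_per_plant"] = [int(v) for v in d["flowers_per_plant"]]
        d = {k: (float(v) if isinstance(v, (np.floating, float)) else v) for k, v in d.items()}
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True), encoding="utf-8")


@dataclass
class SimulatedTruth:
    """Generating values, kept for parameter-recovery checks only."""

    s_true: np.ndarray  # per family
    plant_herkogamy_mean: np.ndarray  # per family/plant
    allele_freqs: list[np.ndarray]
    sigma2_among: float
    sigma2_within: float
    delta_true: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "family": [f"F{i + 1:02d}" for i in range(len(self.s_true))],
                "s_true": self.s_true,
                "herkogamy_mean_true": self.plant_herkogamy_mean,
            }
        )


@dataclass
class SimulatedPopulation:
    """One simulated population bundle: data tables plus ground truth."""

    config: SimulationConfig
    arrays: list[ProgenyArray]
    maternal_genotypes: np.ndarray  # (n_families, n_loci, 2)
    herkogamy: pd.DataFrame
    fitness: pd.DataFrame
    truth: SimulatedTruth


def study_config(population: str, seed: int = 0) -> SimulationConfig:
    """Presets emulating the two focal *D. inoxia* populations.

    ``"CM"`` (Cañada de Moreno–like): reverse herkogamy on average
    (-4.72 mm, sd 5.5 with ~51% of variance among plants), five usable
    loci, predominantly selfing, delta 0.09.  ``"Map"`` (Mapimí-like):
    approach herkogamy on average (+2.57 mm, sd 11.15 with ~77% among
    plants), six loci, predominantly outcrossing, delta 0.25.  Intercepts
    put the mean selfing rate near the observed population means (s ~ 0.71
    and ~ 0.32) at the herkogamy mean under the shared slope of -0.15/mm.
    """
    if population == "CM":
        return SimulationConfig(
            seed=seed,
            population_id="CM",
            n_families=30,
            n_loci=5,
            herkogamy_mean=-4.72,
            herkogamy_sd_among=5.5 * np.sqrt(0.5062),
            herkogamy_sd_within=5.5 * np.sqrt(0.4938),
            selfing_intercept=float(np.log(0.706 / 0.294) - (-0.15) * (-4.72)),
            selfing_slope=-0.15,
            delta_true=0.09,
            missing_rate=0.02,
            n_mothers_fitness=77,
        )
    if population == "Map":
        return SimulationConfig(
            seed=seed,
            population_id="Map",
            n_families=30,
            n_loci=6,
            herkogamy_mean=2.57,
            herkogamy_sd_among=11.15 * np.sqrt(0.7732),
            herkogamy_sd_within=11.15 * np.sqrt(0.2268),
            selfing_intercept=float(np.log(0.318 / 0.682)) - (-0.15) * 2.57,
            selfing_slope=-0.15,
            delta_true=0.25,
            missing_rate=0.02,
            n_mothers_fitness=41,
        )
    raise ValueError("population must be 'CM' or 'Map'")


# ---------------------------------------------------------------------------
# primitive draws
# ---------------------------------------------------------------------------


def draw_allele_frequencies(config: SimulationConfig, rng: np.random.Generator) -> list[np.ndarray]:
    """Symmetric-Dirichlet allele frequencies, one vector per locus."""
    freqs = []
    for j in range(config.n_loci):
        k = config.alleles_at(j)
        f = rng.dirichlet(np.full(k, config.allele_freq_concentration))
        freqs.append(f)
    return freqs


def draw_maternal_genotypes(
    freqs: list[np.ndarray],
    n_families: int,
    adult_F: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Maternal multilocus genotypes at inbreeding level ``adult_F``.

    Genotype probabilities follow the F-model: P(ii) = p_i^2 + F p_i (1-p_i)
    and P(ij) = 2 p_i p_j (1-F).  Allele codes are 1-based per locus.
    """
    n_loci = len(freqs)
    geno = np.zeros((n_families, n_loci, 2), dtype=np.int64)
    for j, p in enumerate(freqs):
        k = p.size
        bound = float(np.max(-p / (1 - p)))
        if adult_F < bound - 1e-12:
            raise ValueError(
                f"adult_F={adult_F} infeasible at locus {j + 1}: requires F >= {bound:.4f}"
            )
        probs = np.zeros((k, k))
        for a in range(k):
            for b in range(k):
                if a == b:
                    probs[a, b] = p[a] ** 2 + adult_F * p[a] * (1 - p[a])
                else:
                    probs[a, b] = p[a] * p[b] * (1 - adult_F)
        flat = probs.ravel()
        flat = np.clip(flat, 0, None)
        flat /= flat.sum()
        draws = rng.choice(k * k, size=n_families, p=flat)
        a, b = np.divmod(draws, k)
        geno[:, j, 0] = np.minimum(a, b) + 1
        geno[:, j, 1] = np.maximum(a, b) + 1
    return geno


def simulate_herkogamy(config: SimulationConfig, rng: np.random.Generator) -> tuple[pd.DataFrame, np.ndarray]:
    """Per-flower herkogamy: population mean + plant effect + flower effect.

    Returns the flower-level table and the vector of true plant means
    (one plant per maternal family).
    """
    plant_means = config.herkogamy_mean + rng.normal(0.0, config.herkogamy_sd_among, config.n_families)
    lo, hi = config.flowers_per_plant
    rows = []
    for i, mu in enumerate(plant_means):
        n_fl = int(rng.integers(lo, hi + 1))
        values = mu + rng.normal(0.0, config.herkogamy_sd_within, n_fl)
        for f, v in enumerate(values):
            rows.append(
                {
                    "population": config.population_id,
                    "plant": f"F{i + 1:02d}",
                    "flower": f + 1,
                    "herkogamy": v,
                }
            )
    return pd.DataFrame(rows), plant_means


def family_selfing_rates(config: SimulationConfig, plant_means: np.ndarray) -> np.ndarray:
    """Logistic link from plant mean herkogamy to the true selfing rate."""
    eta = config.selfing_intercept + config.selfing_slope * plant_means
    return 1.0 / (1.0 + np.exp(-eta))


# ---------------------------------------------------------------------------
# progeny arrays
# ---------------------------------------------------------------------------


def _maternal_gamete(geno: np.ndarray, rng: np.random.Generator) -> int:
    return int(geno[rng.integers(0, 2)])


def simulate_progeny_arrays(
    config: SimulationConfig,
    maternal_genotypes: np.ndarray,
    s_true: np.ndarray,
    freqs: list[np.ndarray],
    rng: np.random.Generator,
) -> list[ProgenyArray]:
    """Mixed-mating progeny arrays with early culling of selfed zygotes.

    Each genotyped offspring is produced by rejection: draw selfed with
    probability ``s_true``; a selfed zygote survives to genotyping with
    probability ``1 - delta_true``, otherwise the draw is repeated.  The
    realised selfed fraction among genotyped offspring is therefore
    ``s(1-d) / (1 - s d)`` — below ``s_true`` whenever ``delta_true > 0``,
    which is exactly the gap the primary-selfing correction removes.
    Genotype entries are then set missing with ``missing_rate`` per locus;
    the optional null-allele corruption silently drops one allele (the
    genotype shows as a homozygote for the remaining allele).
    """
    n_loci = config.n_loci
    locus_names = [f"L{j + 1}" for j in range(n_loci)]
    arrays = []
    for fam in range(config.n_families):
        mom = maternal_genotypes[fam]
        s = float(s_true[fam])
        off = np.zeros((config.n_progeny, n_loci, 2), dtype=np.int64)
        for i in range(config.n_progeny):
            while True:
                selfed = rng.random() < s
                if selfed and config.delta_true > 0 and rng.random() < config.delta_true:
                    continue  # culled before genotyping; redraw
                break
            for j in range(n_loci):
                g1 = _maternal_gamete(mom[j], rng)
                if selfed:
                    g2 = _maternal_gamete(mom[j], rng)
                else:
                    g2 = int(rng.choice(freqs[j].size, p=freqs[j])) + 1
                a, b = sorted((g1, g2))
                off[i, j] = (a, b)
        if config.null_allele_rate > 0:
            null = rng.random(off.shape[:2]) < config.null_allele_rate
            keep = rng.integers(0, 2, size=off.shape[:2])
            kept = off[np.arange(off.shape[0])[:, None], np.arange(n_loci)[None, :], keep]
            off[null, 0] = kept[null]
            off[null, 1] = kept[null]
        if config.missing_rate > 0:
            miss = rng.random(off.shape[:2]) < config.missing_rate
            off[miss] = MISSING
        arrays.append(
            ProgenyArray(
                family_id=f"F{fam + 1:02d}",
                population_id=config.population_id,
                locus_names=locus_names,
                offspring=off,
                maternal=None,
            )
        )
    return arrays


# ---------------------------------------------------------------------------
# fitness experiment
# ---------------------------------------------------------------------------


def simulate_fitness_experiment(config: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Paired self/outcross hand pollinations on independent mothers.

    The generating inbreeding depression ``delta_true`` is split evenly
    between the two fitness components: self-treatment means of seed-set
    and per-seed mass are each scaled by ``sqrt(1 - delta)``, so the
    expected ratio of mean fitness products is ``1 - delta``.  Seed-set is
    Beta-distributed (mean m, concentration nu); seed mass is Gamma
    (guaranteeing positivity).
    """
    scale = float(np.sqrt(1.0 - config.delta_true))
    rows = []
    for m in range(config.n_mothers_fitness):
        for treatment, factor in (("outcross", 1.0), ("self", scale)):
            for fruit in range(config.fruits_per_treatment):
                mean_ss = min(config.outcross_seed_set * factor, 1.0 - 1e-9)
                nu = config.seed_set_concentration
                ss = rng.beta(mean_ss * nu, (1.0 - mean_ss) * nu)
                mass_mean = config.seed_mass_mean * factor
                shape = (mass_mean / config.seed_mass_sd) ** 2
                mass = rng.gamma(shape, mass_mean / shape)
                rows.append(
                    {
                        "population": config.population_id,
                        "mother": f"M{m + 1:03d}",
                        "treatment": treatment,
                        "fruit": f"{treatment[0]}{fruit + 1}",
                        "seed_set": ss,
                        "seed_mass": mass,
                    }
                )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# full population
# ---------------------------------------------------------------------------


def simulate_population(config: SimulationConfig, seed: int | None = None) -> SimulatedPopulation:
    """Generate one complete population from a config (and optional seed
    override), returning data plus ground truth."""
    rng = np.random.default_rng(config.seed if seed is None else seed)
    freqs = draw_allele_frequencies(config, rng)
    mothers = draw_maternal_genotypes(freqs, config.n_families, config.adult_F, rng)
    herk, plant_means = simulate_herkogamy(config, rng)
    s_true = family_selfing_rates(config, plant_means)
    arrays = simulate_progeny_arrays(config, mothers, s_true, freqs, rng)
    fitness = simulate_fitness_experiment(config, rng)
    truth = SimulatedTruth(
        s_true=s_true,
        plant_herkogamy_mean=plant_means,
        allele_freqs=freqs,
        sigma2_among=config.herkogamy_sd_among**2,
        sigma2_within=config.herkogamy_sd_within**2,
        delta_true=config.delta_true,
    )
    return SimulatedPopulation(
        config=config,
        arrays=arrays,
        maternal_genotypes=mothers,
        herkogamy=herk,
        fitness=fitness,
        truth=truth,
    )


def write_population(pop: SimulatedPopulation, outdir: str | Path) -> dict[str, Path]:
    """Serialise one simulated population (GenePop + TSV dialect + tables).

    The ground-truth table is written separately for test harnesses; it is
    not an input to any estimator.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    pid = pop.config.population_id
    paths = {
        "genepop": outdir / f"{pid}_progeny.gen",
        "progeny_tsv": outdir / f"{pid}_progeny.tsv",
        "herkogamy": outdir / f"{pid}_herkogamy.tsv",
        "fitness": outdir / f"{pid}_fitness.tsv",
        "truth": outdir / f"{pid}_truth.tsv",
        "config": outdir / f"{pid}_config.yaml",
    }
    write_genepop(arrays_to_collection(pop.arrays), paths["genepop"])
    write_progeny_table(pop.arrays, paths["progeny_tsv"])
    write_herkogamy_table(pop.herkogamy, paths["herkogamy"])
    write_fitness_table(pop.fitness, paths["fitness"])
    pop.truth.to_frame().to_csv(paths["truth"], sep="\t", index=False, lineterminator="\n")
    pop.config.to_yaml(paths["config"])
    return paths
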