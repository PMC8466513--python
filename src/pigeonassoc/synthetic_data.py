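"""Synthetic cohorts with known ground truth.

Generates everything the pipeline consumes — a multi-generation two-loft
pedigree, Mendelian (gene-dropped) genotypes at the assayed dinucleotide
variant, and a season of race records — from a single seeded random stream, and
retains the latent per-record performance so that variance components and the
injected genotype effect can be recovered and checked.

The generative model mirrors the association model: each record's latent
performance is the sum of genotype, sex, breeder, race-category and weather
effects, a polygenic value drawn with covariance sigma2_a * A, a permanent
individual effect (sigma2_i) and a residual (sigma2_e).  Finishing positions
are the within-race ranks of latent performance among all starters (phenotyped
birds plus simulated background competitors), so the AP distribution emerges
from the prize-list formula exactly as in a real race rather than being drawn
directly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .errors import InputError
from .pedigree_kinship import (
    Pedigree,
    PedigreeEntry,
    RelationshipMatrix,
    additive_relationship_matrix,
)
from .race_scoring import (
    BREEDER_LEVELS,
    WEATHER_END_LEVELS,
    WEATHER_START_LEVELS,
    score_races,
)

#: default race distances (km) for a 14-race season: 8 short, 6 long,
#: avoiding the undefined 400-500 km gap
DEFAULT_DISTANCES = (100, 150, 200, 250, 300, 350, 400, 400, 500, 550, 600, 650, 700, 800)


@dataclass(frozen=True)
class SimulationConfig:
    """Study-scale defaults: ~123 phenotyped birds from 2 breeders, 3
    generations of known pedigree, 14 races, ALT allele frequency 0.07,
    genotype shifts (0, +7, +4) AP on the latent scale and variance components
    (sigma2_a, sigma2_i, sigma2_e) = (100, 50, 400) AP^2."""

    n_founders: int = 40
    n_generations: int = 3
    n_birds_phenotyped: int = 123
    n_races: int = 14
    allele_freq_alt: float = 0.07
    genotype_effects: dict[str, float] = field(
        default_factory=lambda: {"AG/AG": 0.0, "AG/TT": 7.0, "TT/TT": 4.0}
    )
    sex_effects: dict[str, float] = field(
        default_factory=lambda: {"male": 2.0, "female": 0.0}
    )
    breeder_effects: dict[str, float] = field(
        default_factory=lambda: {"A": 0.0, "B": -3.0}
    )
    category_effects: dict[str, float] = field(
        default_factory=lambda: {"short": 0.0, "long": -2.0}
    )
    weather_start_effects: dict[str, float] = field(
        default_factory=lambda: {"sunny": 0.0, "changeable": -2.0}
    )
    weather_end_effects: dict[str, float] = field(
        default_factory=lambda: {
            "sunny": 0.0,
            "changeable": -1.0,
            "rainy": -3.0,
            "windy": -4.0,
            "cloudy": -1.0,
        }
    )
    sigma2_a: float = 100.0
    sigma2_i: float = 50.0
    sigma2_e: float = 400.0
    race_distances: tuple[float, ...] = DEFAULT_DISTANCES
    n_starters_range: tuple[int, int] = (50, 500)
    dnf_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.allele_freq_alt <= 1:
            raise InputError("allele_freq_alt must be in [0, 1]")
        if min(self.sigma2_a, self.sigma2_i, self.sigma2_e) < 0:
            raise InputError("variance components must be >= 0")
        if self.n_races < 1:
            raise InputError("n_races must be >= 1")
        if self.n_founders < 2:
            raise InputError("need at least 2 founders")


def _animal_id(gen: int, breeder: str, k: int) -> str:
    return f"G{gen}-{breeder}-{k:03d}"


def parse_generation(animal_id: str) -> int:
    return int(animal_id.split("-")[0][1:])


def parse_breeder(animal_id: str) -> str:
    return animal_id.split("-")[1]


def phenotyped_ids(ped: Pedigree) -> list[str]:
    """The final (youngest) generation — the birds that race."""
    top = max(parse_generation(a) for a in ped.ids)
    return [a for a in ped.ids if parse_generation(a) == top]


def simulate_pedigree(config: SimulationConfig, rng: Optional[np.random.Generator] = None) -> Pedigree:
    """Random-mating pedigree: founder generation, ``n_generations - 1``
    intermediate generations of founder size, and a final phenotyped cohort of
    ``n_birds_phenotyped``.  Mating is within breeder (two closed lofts).
    Deterministic given the config seed."""
    rng = np.random.default_rng(config.seed) if rng is None else rng
    entries: list[PedigreeEntry] = []
    by_gen_breeder: dict[tuple[int, str], list[PedigreeEntry]] = {}

    def make_generation(gen: int, breeder: str, size: int) -> None:
        if size < 1:
            raise InputError("generation size must be >= 1")
        # guarantee both sexes where possible so the loft can breed on
        sexes = ["male", "female"] * (size // 2) + (["male"] if size % 2 else [])
        sexes = list(rng.permutation(sexes))
        group = []
        if gen > 0:
            # lofts breed fixed pairs: mate males and females monogamously,
            # offspring assigned to random pairs (full-sib families)
            parents = by_gen_breeder[(gen - 1, breeder)]
            sires = [p for p in parents if p.sex == "male"]
            dams = [p for p in parents if p.sex == "female"]
            if not sires or not dams:
                raise InputError(
                    f"impossible mating structure: single-sex parental generation "
                    f"{gen - 1} in loft {breeder}"
                )
            n_pairs = min(len(sires), len(dams))
            pairs = list(
                zip(rng.permutation(len(sires))[:n_pairs],
                    rng.permutation(len(dams))[:n_pairs])
            )
        for k in range(size):
            aid = _animal_id(gen, breeder, k)
            if gen == 0:
                e = PedigreeEntry(aid, None, None, sexes[k])
            else:
                si, di = pairs[rng.integers(n_pairs)]
                e = PedigreeEntry(aid, sires[si].animal_id, dams[di].animal_id, sexes[k])
            group.append(e)
        by_gen_breeder[(gen, breeder)] = group
        entries.extend(group)

    half = config.n_founders // 2
    sizes_f = {"A": half, "B": config.n_founders - half}
    for breeder in BREEDER_LEVELS:
        make_generation(0, breeder, sizes_f[breeder])
    for gen in range(1, config.n_generations + 1):
        if gen == config.n_generations:
            half_p = config.n_birds_phenotyped // 2
            sizes = {"A": half_p, "B": config.n_birds_phenotyped - half_p}
        else:
            sizes = sizes_f
        for breeder in BREEDER_LEVELS:
            make_generation(gen, breeder, sizes[breeder])
    return Pedigree(entries)


def simulate_genotypes(
    ped: Pedigree,
    allele_freq_alt: float = 0.07,
    rng: Optional[np.random.Generator] = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Gene dropping: founder alleles drawn from Hardy-Weinberg proportions at
    ``allele_freq_alt``; each offspring receives one uniformly chosen allele
    from each parent.  Returns a (pigeon_id, genotype) table in pedigree order.
    """
    if not ped.is_sorted():
        raise InputError("pedigree must be topologically ordered for gene dropping")
    rng = np.random.default_rng(seed) if rng is None else rng
    alleles: dict[str, tuple[int, int]] = {}
    labels = {0: "AG/AG", 1: "AG/TT", 2: "TT/TT"}
    rows = []
    for e in ped.entries:
        pair = []
        for parent in (e.sire_id, e.dam_id):
            if parent is None:
                pair.append(int(rng.random() < allele_freq_alt))
            else:
                pair.append(alleles[parent][rng.integers(2)])
        alleles[e.animal_id] = (pair[0], pair[1])
        rows.append({"pigeon_id": e.animal_id, "genotype": labels[sum(pair)]})
    return pd.DataFrame(rows)


def draw_polygenic(
    A: RelationshipMatrix, sigma2_a: float, rng: np.random.Generator
) -> pd.Series:
    """One draw of breeding values with covariance sigma2_a * A (Cholesky)."""
    n = len(A.ids)
    L = np.linalg.cholesky(A.values + 1e-10 * np.eye(n))
    return pd.Series(np.sqrt(sigma2_a) * (L @ rng.standard_normal(n)), index=A.ids)


@dataclass
class SimulatedData:
    """A complete synthetic study with its truth ledger."""

    pedigree: Pedigree
    genotypes: pd.DataFrame
    races: pd.DataFrame  # scored records (ap, category filled)
    prize_sizes: dict[str, int]
    truth_records: pd.DataFrame  # records + genotype + latent + residual
    truth_birds: pd.DataFrame  # animal_id, genotype, breeding value, perm. env.
    relationship: RelationshipMatrix
    config: SimulationConfig
    degenerate: bool  # all-tie races resolved by seeded random tie-break


def simulate_races(
    ped: Pedigree,
    genotypes: pd.DataFrame,
    config: SimulationConfig,
    rng: Optional[np.random.Generator] = None,
) -> SimulatedData:
    """Simulate a racing season for the pedigree's final generation."""
    rng = np.random.default_rng(config.seed) if rng is None else rng
    cohort = phenotyped_ids(ped)
    n_phen = len(cohort)
    gmap = dict(zip(genotypes["pigeon_id"], genotypes["genotype"]))
    missing = [a for a in cohort if a not in gmap]
    if missing:
        raise InputError(f"phenotyped birds without genotypes: {missing[:5]}...")

    A = additive_relationship_matrix(ped)
    bv = draw_polygenic(A, config.sigma2_a, rng).to_dict()
    pe = dict(zip(cohort, np.sqrt(config.sigma2_i) * rng.standard_normal(n_phen)))

    sex = {a: ped[a].sex for a in cohort}
    breeder = {a: parse_breeder(a) for a in cohort}

    lo, hi = config.n_starters_range
    rows = []
    truth_rows = []
    degenerate = False
    for r in range(config.n_races):
        race_id = f"R{r + 1:02d}"
        distance = float(config.race_distances[r % len(config.race_distances)])
        category = "short" if distance <= 400 else "long"
        w_start = WEATHER_START_LEVELS[rng.integers(len(WEATHER_START_LEVELS))]
        w_end = WEATHER_END_LEVELS[rng.integers(len(WEATHER_END_LEVELS))]
        n_starters = max(int(rng.integers(lo, hi + 1)), n_phen)

        resid = np.sqrt(config.sigma2_e) * rng.standard_normal(n_phen)
        latent = np.array(
            [
                config.genotype_effects[gmap[a]]
                + config.sex_effects[sex[a]]
                + config.breeder_effects[breeder[a]]
                + config.category_effects[category]
                + config.weather_start_effects[w_start]
                + config.weather_end_effects[w_end]
                + bv[a]
                + pe[a]
                for a in cohort
            ]
        ) + resid

        n_bg = n_starters - n_phen
        if np.ptp(latent) == 0:
            degenerate = True
        scale = np.std(latent) if np.std(latent) > 0 else 1.0
        bg = rng.normal(np.mean(latent), scale, size=n_bg)
        combined = np.concatenate([latent, bg])
        # descending latent performance; seeded random tie-break
        order = np.lexsort((rng.random(n_starters), -combined))
        position = np.empty(n_starters, dtype=int)
        position[order] = np.arange(1, n_starters + 1)

        for i, a in enumerate(cohort):
            pos: Optional[int] = int(position[i])
            if config.dnf_rate > 0 and rng.random() < config.dnf_rate:
                pos = None
            rows.append(
                {
                    "pigeon_id": a,
                    "race_id": race_id,
                    "distance_km": distance,
                    "n_starters": n_starters,
                    "position": pos,
                    "weather_start": w_start,
                    "weather_end": w_end,
                    "breeder": breeder[a],
                    "sex": sex[a],
                }
            )
            truth_rows.append({"latent": latent[i], "residual": resid[i]})

    races = pd.DataFrame(rows)
    races["position"] = races["position"].astype("Int64")
    scored, prize_sizes = score_races(races)
    truth_records = pd.concat(
        [scored.reset_index(drop=True), pd.DataFrame(truth_rows)], axis=1
    )
    truth_records["genotype"] = truth_records["pigeon_id"].map(gmap)
    truth_birds = pd.DataFrame(
        {
            "animal_id": cohort,
            "genotype": [gmap[a] for a in cohort],
            "breeding_value": [bv[a] for a in cohort],
            "permanent_env": [pe[a] for a in cohort],
        }
    )
    return SimulatedData(
        pedigree=ped,
        genotypes=genotypes,
        races=scored,
        prize_sizes=prize_sizes,
        truth_records=truth_records,
        truth_birds=truth_birds,
        relationship=A,
        config=config,
        degenerate=degenerate,
    )


def simulate(config: SimulationConfig) -> SimulatedData:
    """Pedigree + genotypes + races from one seeded stream."""
    rng = np.random.default_rng(config.seed)
    ped = simulate_pedigree(config, rng=rng)
    geno = simulate_genotypes(ped, config.allele_freq_alt, rng=rng)
    return simulate_races(ped, geno, config, rng=rng)
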