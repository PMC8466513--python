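"""Shared fixtures: the published assay, pedigree builders, independent
oracles, and the simulation scenarios used by the model-validation tests."""

from __future__ import annotations

import numpy as np
import pytest

from pigeonassoc.mixed_model import DEFAULT_FACTORS
from pigeonassoc.pedigree_kinship import Pedigree, PedigreeEntry
from pigeonassoc.restriction_assay import MLUCI, SnpAssay
from pigeonassoc.synthetic_data import SimulationConfig

#: the forced forward primer of the published dCAPS assay (27 nt; the
#: penultimate base carries the engineered A-for-G mismatch)
FORCED_PRIMER = "AGAAACATTGGTTACTCTTATAGTTAA"
#: the unmodified genomic context the primer derives from
NATURAL_CONTEXT = "AGAAACATTGGTTACTCTTATAGTTGA"
AMPLICON_LENGTH = 176

#: fixed factors for the simulation scenarios (weather omitted: per-race
#: weather covariates are frequently aliased at ~10 races and the scenarios
#: zero those effects)
SCENARIO_FACTORS = {
    k: v for k, v in DEFAULT_FACTORS.items() if not k.startswith("weather")
}

_ZERO_WEATHER = {
    "weather_start_effects": {"sunny": 0.0, "changeable": 0.0},
    "weather_end_effects": {
        k: 0.0 for k in ("sunny", "changeable", "rainy", "windy", "cloudy")
    },
}


def recovery_config(seed: int) -> SimulationConfig:
    """The designed parameter-recovery / power scenario: 200 birds x 10 races,
    ALT frequency 0.25 so both frequent genotype classes are well filled,
    genotype shifts (0, +7, +4) and variances (100, 50, 400)."""
    return SimulationConfig(
        seed=seed,
        n_birds_phenotyped=200,
        n_races=10,
        n_founders=60,
        allele_freq_alt=0.25,
        **_ZERO_WEATHER,
    )


def null_config(seed: int) -> SimulationConfig:
    """Type-I-error scenario: same structure, all genotype effects zero,
    6 short races (category therefore dropped from the fitted model)."""
    return SimulationConfig(
        seed=seed,
        n_birds_phenotyped=120,
        n_races=6,
        n_founders=40,
        allele_freq_alt=0.25,
        genotype_effects={"AG/AG": 0.0, "AG/TT": 0.0, "TT/TT": 0.0},
        category_effects={"short": 0.0, "long": 0.0},
        **_ZERO_WEATHER,
    )


NULL_FACTORS = {
    k: v for k, v in SCENARIO_FACTORS.items() if k != "category"
}


@pytest.fixture
def assay() -> SnpAssay:
    return SnpAssay(forward_primer=FORCED_PRIMER, amplicon_length=AMPLICON_LENGTH)


@pytest.fixture
def trio_pedigree() -> Pedigree:
    """Two unrelated founders and their two full-sib offspring."""
    return Pedigree(
        [
            PedigreeEntry("sire", None, None, "male"),
            PedigreeEntry("dam", None, None, "female"),
            PedigreeEntry("kid1", "sire", "dam", "male"),
            PedigreeEntry("kid2", "sire", "dam", "female"),
        ]
    )


def random_pedigree(n_animals: int, rng: np.random.Generator) -> Pedigree:
    """Random acyclic pedigree: each animal draws parents (possibly unknown)
    from earlier animals of the right sex."""
    entries: list[PedigreeEntry] = []
    sexes = []
    for i in range(n_animals):
        sex = "male" if rng.random() < 0.5 else "female"
        males = [e.animal_id for e, s in zip(entries, sexes) if s == "male"]
        females = [e.animal_id for e, s in zip(entries, sexes) if s == "female"]
        sire = males[rng.integers(len(males))] if males and rng.random() < 0.7 else None
        dam = females[rng.integers(len(females))] if females and rng.random() < 0.7 else None
        entries.append(PedigreeEntry(f"a{i:02d}", sire, dam, sex))
        sexes.append(sex)
    return Pedigree(entries)


@pytest.fixture
def kinship_oracle():
    """Independent coancestry-recursion oracle: a(i,j) = 2 f(i,j), with

        f(i,i) = (1 + f(s_i, d_i)) / 2
        f(i,j) = (f(s_i, j) + f(d_i, j)) / 2   for i after j,

    memoized over a topologically ordered pedigree.  A different algorithm
    from the tabular method (recursive kinship, not a forward table)."""

    def oracle(ped: Pedigree):
        order = {a: k for k, a in enumerate(ped.ids)}
        memo: dict[tuple[str, str], float] = {}

        def f(i, j) -> float:
            if i is None or j is None:
                return 0.0
            if order[i] < order[j]:
                i, j = j, i
            key = (i, j)
            if key in memo:
                return memo[key]
            sire, dam = ped.parents(i)
            if i == j:
                val = 0.5 * (1.0 + f(sire, dam))
            else:
                val = 0.5 * (f(sire, j) + f(dam, j))
            memo[key] = val
            return val

        n = len(ped.ids)
        A = np.empty((n, n))
        for a, i in ((a, order[a]) for a in ped.ids):
            for b, j in ((b, order[b]) for b in ped.ids):
                A[i, j] = 2.0 * f(a, b)
        return A

    return oracle
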