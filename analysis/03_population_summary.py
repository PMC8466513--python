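#!/usr/bin/env python
"""Genotype/allele frequencies and Hardy-Weinberg testing.

Two inputs: the published cohort's genotype counts (107 AG/AG, 14 AG/TT,
2 TT/TT) and the simulated cohort written by 01_simulate_cohort.py.  Writes
results/popgen_summary.csv.
"""

from pathlib import Path

import pandas as pd

from pigeonassoc import io as pio
from pigeonassoc.popgen import (
    GenotypeCounts,
    allele_frequencies,
    genotype_frequencies,
    hwe_chi_square,
)

ROOT = Path(__file__).resolve().parents[1]
COHORT = ROOT / "results" / "cohort" / "genotypes.csv"
OUT = ROOT / "results" / "popgen_summary.csv"


def summarize(name: str, counts: GenotypeCounts) -> dict:
    gf = genotype_frequencies(counts)
    af = allele_frequencies(counts)
    hwe = hwe_chi_square(counts)
    row = {
        "dataset": name,
        "n": counts.n,
        "freq_AGAG": round(gf[0], 4),
        "freq_AGTT": round(gf[1], 4),
        "freq_TTTT": round(gf[2], 4),
        "freq_allele_AG": round(af[0], 4),
        "freq_allele_TT": round(af[1], 4),
        "hwe_chi2": round(hwe.chi2, 4),
        "hwe_p": round(hwe.p_value, 4),
        "low_expected": hwe.low_expected_warning,
    }
    print(f"{name}: n={row['n']}  genotype {gf[0]:.2f}/{gf[1]:.2f}/{gf[2]:.2f}  "
          f"alleles {af[0]:.2f}/{af[1]:.2f}  chi2={hwe.chi2:.4f} p={hwe.p_value:.4f}")
    return row


def main() -> None:
    rows = [summarize("published_counts", GenotypeCounts(107, 14, 2))]
    if COHORT.exists():
        geno = pio.read_genotypes(COHORT)
        races = pio.read_races(COHORT.parent / "races_scored.csv")
        cohort = geno[geno["pigeon_id"].isin(races["pigeon_id"])]
        rows.append(
            summarize("simulated_cohort", GenotypeCounts.from_genotypes(cohort["genotype"]))
        )
    else:
        print(f"note: {COHORT} not found; run 01_simulate_cohort.py first")
    OUT.parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(rows).to_csv(OUT, index=False)
    print(f"summary -> {OUT}")


if __name__ == "__main__":
    main()
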