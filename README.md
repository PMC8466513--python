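# pigeonassoc

Association analysis between a dinucleotide polymorphism in the cryptochrome-1
(*CRY1*) gene and the racing performance of homing pigeons — rebuilt as a
tested, reusable pipeline that runs end-to-end on synthetic data with known
ground truth.

Cryptochromes are blue-light flavoproteins implicated in avian
magnetoreception, which makes *CRY1* a natural candidate gene for navigational
performance. The pipeline covers every computational step of such a study:

* **`restriction_assay`** — in-silico *forced PCR-RFLP* (dCAPS) genotyping: a
  deliberate single-base mismatch near the 3' end of the forward primer
  creates an MluCI recognition site (AATT, cut 5' of the motif) together with
  the TT allele, so digestion separates the alleles on a gel. Includes motif
  scanning with IUPAC degeneracy, digestion prediction, automated forced-primer
  design and genotype calling from band patterns.
* **`popgen`** — genotype/allele frequencies and the Hardy-Weinberg
  chi-square test (1 df, no continuity correction).
* **`race_scoring`** — ace points per race record. With `a` birds on the
  prize list (20% of `n` starters, floor, minimum 1) and finishing position
  `b`,

  `AP = (a - b + 1) / a × 100` for `b ≤ a`, else `AP = 0`,

  so the winner always scores 100. Races are *short* (≤ 400 km) or *long*
  (≥ 500 km).
* **`pedigree_kinship`** — the additive (numerator) relationship matrix **A**
  by the tabular method over a topologically sorted, optionally
  three-generation-truncated pedigree.
* **`mixed_model`** — the repeated-measures animal model fitted by REML:

  `y = μ + genotype + sex + breeder + category + weather_start + weather_end + pe + a + e`

  with a permanent-individual effect `pe ~ N(0, σ²ᵢ I)`, a polygenic effect
  `a ~ N(0, σ²ₐ A)` and residual `e ~ N(0, σ²ₑ I)`; genotype least-squares
  means and pairwise Wald contrasts.
* **`synthetic_data`** — two-loft, three-generation pedigrees with fixed
  breeding pairs, gene-dropped genotypes, and race seasons in which finishing
  positions emerge from ranking latent performance, so the AP distribution
  arises from the prize-list formula exactly as in a real race.
* **`io` / `cli`** — CSV/FASTA dialects, in-silico PCR, and a `pigeonassoc`
  command with subcommands `simulate`, `design-assay`, `digest`, `genotype`,
  `freqs`, `hwe`, `score`, `kinship`, `associate`.

## Worked example

Genotype counts of 107 AG/AG, 14 AG/TT and 2 TT/TT birds:

```text
$ pigeonassoc freqs --counts 107,14,2
n = 123
genotype frequencies: AG/AG=0.8699 AG/TT=0.1138 TT/TT=0.0163
allele frequencies: AG=0.9268 TT=0.0732

$ pigeonassoc hwe --counts 107,14,2
chi2 = 3.1811, df = 1, p = 0.0745
warning: an expected class count is below 5
```

The genotype frequencies are 0.87/0.11/0.02 and the allele frequencies
0.93/0.07 at two decimals; the chi-square of 3.1811 does not reject
Hardy-Weinberg proportions, though the rare-homozygote class (expected count
0.66) makes the asymptotic test approximate, hence the warning.

Designing the forced primer from the unmodified genomic context and
predicting the gel:

```text
$ python analysis/02_design_assay.py
template 3' context : AGAAACATTGGTTACTCTTATAGTTGA
forced primer       : AGAAACATTGGTTACTCTTATAGTTAA
modification        : G -> A at primer position 25 (position -2 from the 3' end)
discriminating allele: TT
expected gel bands  AG/AG: 176 bp
expected gel bands  TT/TT: 151 + 25 bp
expected gel bands  AG/TT: 176 + 151 + 25 bp
```

A single A-for-G substitution at the penultimate primer base completes the
AATT motif together with the TT allele: TT amplicons cut to 151 + 25 bp, AG
amplicons stay undigested at 176 bp, and heterozygotes show all three bands.

## The analysis

Numbered drivers under `analysis/` run the full study on synthetic data and
write their tables under `results/`:

1. `01_simulate_cohort.py` — 123-bird, two-loft, 14-race synthetic season
   with known genotype effects and variance components.
2. `02_design_assay.py` — forced-primer design and per-allele digest report.
3. `03_population_summary.py` — frequencies and Hardy-Weinberg tests.
4. `04_genotype_means.py` — raw mean AP per genotype × race category.
5. `05_association_model.py` — kinship matrix, REML animal model, genotype
   least-squares means and contrasts.

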