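# Methods

## Forced PCR-RFLP (dCAPS) genotyping in silico

The assayed variant is a dinucleotide substitution (AG → TT) that does not by
itself create or destroy a restriction site. The assay therefore *forces* one:
the forward primer is copied from the genomic top strand ending immediately 5'
of the variant, and a single base is changed so that primer + TT completes the
MluCI motif AATT across the primer/variant junction while primer + AG does
not. MluCI cuts immediately 5' of its motif (`cut_offset = 0`).

Coordinates are 0-based with half-open intervals. Digestion reports fragment
*lengths*, the observable on a gel; a cut flush with an amplicon end would
produce a zero-length fragment and is dropped. Fragment lengths always sum to
the input length. Only the top strand is scanned by default: AATT is its own
reverse complement, so a bottom-strand scan adds nothing for this assay; a
`both_strands` flag maps bottom-strand sites to top-strand intervals for
non-palindromic motifs. Degeneracy is expanded in the motif only — an
ambiguity code in the *sequence* is a literal symbol, because an ambiguous
template base cannot be assumed to be cleavable.

Primer design enumerates candidate modifications by mismatch count (0, 1, …,
`max_mismatches`, default 1) and, within a count, positions from the 3' end
inward; the 3'-terminal base is never modified since a terminal mismatch
abolishes extension. A candidate is accepted when exactly one allele gains a
junction-spanning site; the search order makes the classic dCAPS placement
(single substitution as close to the variant as allowed) the first solution
found. No thermodynamic screening (Tm, hairpins, dimers) is attempted.

Genotype calling compares observed band sets with the three expected
patterns; the heterozygote expectation is the band-level union of the two
homozygote digests. A `tolerance_bp` parameter (default 0) absorbs gel sizing
error; a pattern matching nothing is reported as uncallable rather than
raised, since failed or partial digestion is a routine laboratory outcome.
The reverse primer enters the model only through the amplicon length, and
downstream amplicon sequence is assumed free of additional motif copies; a
full in-silico PCR against a supplied template is available in `io`.

## Hardy-Weinberg testing

For one biallelic locus with estimated allele frequencies (p, q) the test
compares observed genotype counts with (np², 2npq, nq²) by an uncorrected
chi-square on 1 degree of freedom (three classes − 1 − one estimated
frequency). A Yates-corrected variant is available behind a flag. Whenever an
expected class count is below 5 the result carries a warning: with a minor
allele near 0.07 in ~120 birds the rare-homozygote expectation is far below 5
and the asymptotic p-value is approximate. The p-value is always recomputed
from the statistic. Note for readers comparing with the published table: the
p printed there under "HWE" (0.9268) equals the major-allele frequency
228/246, not any chi-square tail probability of 3.1811, which on 1 df is
0.0745 — the implementation reports the recomputed value.

Pedigreed populations are not expected to satisfy Hardy-Weinberg exactly:
closed lofts with fixed breeding pairs accumulate inbreeding (mean F ≈ 0.05-
0.09 after three generations in the simulated cohorts), which produces a
genuine heterozygote deficit. The generator makes no attempt to hide this.

## Ace-points scoring

Each race awards `AP = (a − b + 1)/a × 100` to the first `a = max(⌊0.2 n⌋, 1)`
finishers of `n` starters and 0 to everyone else, including
did-not-finish records, which stay in the dataset. The floor-with-minimum-one
rounding is the default; `round` and `ceil` are available because federations
differ. Ties in finishing position are rejected (the formula is undefined for
ties). Distances in the open interval (400, 500) km belong to neither race
category; strict mode (default) raises, lenient mode assigns the nearest
boundary with a warning.

## Kinship

The additive relationship matrix is built by the tabular method over a
topologically ordered pedigree:

    a(i,i) = 1 + a(sire_i, dam_i)/2
    a(i,j) = (a(j, sire_i) + a(j, dam_i))/2   for j ordered before i,

with unknown parents contributing nothing — the standard convention that
unknown parents are unrelated, non-inbred founders. One known parent is
allowed. Pedigree truncation keeps each focal bird and its ancestors up to a
given number of meioses (default 3, matching a three-generation pedigree of
phenotyped birds); animals at the depth limit become founders. The matrix is
validated in tests against an independent coancestry-recursion oracle and for
symmetry and positive semidefiniteness. The matrix is built jointly over both
lofts; founders of different lofts are unrelated by construction.

## The animal model and REML

The response is modeled as

    y = μ + genotype + sex + breeder + category + weather_start + weather_end
        + pe + a + e

with fixed factors coded by reference levels (the first declared level is
absorbed into the intercept; factors observed at a single level are dropped
with a warning, a rank-deficient fixed design is an error). Both random
effects attach to pigeon identity, so with Z the record-on-bird incidence the
marginal covariance is

    V = Z (σ²ᵢ I + σ²ₐ A) Z' + σ²ₑ I.

Because the random structure lives on q birds rather than n records, the
restricted likelihood is evaluated through the Woodbury identity using only
q×q and p×p crossproducts; each evaluation costs O(q³) after a one-off O(nq²)
setup, which keeps thousands of records cheap.

Variance components are optimized on the log scale (bounds roughly
var(y)·e⁻²⁰ … var(y)·e⁶) with L-BFGS-B from two default starts — equal split
and residual-dominant — to guard against local optima; a user start may be
added. When a tolerance tighter than 1e-7 is requested, a Nelder-Mead polish
follows, because finite-difference gradients limit L-BFGS-B to ~1e-4 on the
variance scale. Components can be held fixed (fixing both bird components at
zero reduces the fit exactly to OLS with the residual mean square, computed in
closed form). A non-converged fit returns the best iterate flagged rather than
raising; the CLI maps that flag to exit code 3.

Fixed effects are GLS at the optimum with covariance (X'V⁻¹X)⁻¹. Least-squares
means weight every level of the other factors equally; pairwise genotype
contrasts are Wald tests with the large-sample normal approximation — no
Satterthwaite degrees of freedom, so p-values in very small genotype classes
(e.g. a two-bird rare-homozygote group) are approximate and their large
standard errors should be read as the real message. Raw group means
(mean AP and SE per genotype × all/short/long) are reported alongside the
model-based means, since the two answer different questions.

## Synthetic cohorts

The generator emulates the study design: two closed lofts (breeders A and B),
founder generation plus `n_generations` of descent, final-generation cohort
phenotyped (~123 birds by default, 63/60 male/female split arising from
random sex assignment), 14 races per season. Lofts breed *fixed sire-dam
pairs* — as real pigeon fanciers do — so the cohort contains full-sib
families; this also matters statistically, because full-sib covariance is
what separates the polygenic variance from the permanent-environment variance
at all. Genotypes are gene-dropped: founder alleles are Hardy-Weinberg draws
at the configured ALT frequency (default 0.07) and each offspring inherits
one uniformly chosen allele per parent.

Each record's latent performance is

    genotype shift + sex + breeder + category + weather_start + weather_end
    + breeding value + permanent effect + residual

with breeding values drawn with covariance σ²ₐ·A over the whole pedigree
(Cholesky), permanent effects iid N(0, σ²ᵢ), residuals iid N(0, σ²ₑ) per
record. Defaults: genotype shifts (0, +7, +4) AP for AG/AG, AG/TT, TT/TT —
the heterozygote-advantage ordering of the published means — and
(σ²ₐ, σ²ᵢ, σ²ₑ) = (100, 50, 400) AP², i.e. a repeatability of ~0.27 and
heritability of ~0.18 on the latent scale, plausible for a rank-derived
performance score. Sex/breeder/category/weather effects default to a few AP
each. Race distances default to 8 short + 6 long legs between 100 and 800 km,
avoiding the undefined 400-500 km gap; weather is drawn once per race (a race
has one sky) and shared by its records.

Finishing positions are the within-race rank of latent performance among all
starters. The field size is drawn uniformly from [50, 500] (clamped to at
least the cohort size); competitors outside the cohort are simulated as
background starters whose latent values follow the cohort's per-race mean and
spread. Positions then flow through the ace-points formula, so the AP
distribution — zero-inflated, 100-capped — emerges exactly as in a real race.
Everything derives from a single seeded NumPy generator; a run is
byte-reproducible from its config. All-tie races (a fully degenerate config)
are ranked by a seeded random tie-break and flagged.

What the generator does *not* emulate: attrition and selection across the
season, loft geography and wind-direction effects, multi-club result merging,
and top-loft superiority — background starters are drawn around the cohort's
own level, so simulated mean AP sits near the all-comers average (~10) rather
than the elevated means (~25-34) a championship loft records. A truth ledger
(per-record latent values and residuals, per-bird breeding values and
permanent effects) is retained for recovery testing.

## Validation scenarios and what they show

The degenerate equivalences (OLS when both bird variances are pinned at zero;
closed-form ANOVA REML on a balanced one-way layout; agreement with an
independent generic random-intercept implementation) check the estimator
exactly. The simulation scenarios check the whole pipeline:

* **Recovery/power scenario** — 200 birds × 10 races, ALT frequency 0.25,
  shifts (0, +7, +4), variances (100, 50, 400), fitted on the latent
  response. The frequency is a *designed* choice: at the study's 0.07 a
  200-bird cohort carries ~26 heterozygotes and an a-priori power calculation
  gives ~0.65 for the +7 contrast, so a power check would be testing the
  design rather than the software; at 0.25 both frequent classes are well
  filled. Weather effects are zeroed and the weather factors omitted here:
  with ~10 races per-race covariates are frequently perfectly aliased (a hard
  error by design), and because every bird flies every race, race-common
  effects are orthogonal to bird-level contrasts anyway.
* **Identifiability is the binding constraint on variance recovery.** A
  Fisher-information computation at the truth for this scenario gives
  asymptotic SDs of ~41 for σ²ₐ = 100 and ~26 for σ²ᵢ = 50 with sampling
  correlation −0.82 (their sum is far better identified: SD ~25 at 150), and
  ~13 for σ²ₑ = 400. No estimator does better at this cohort size, whatever
  the pedigree shape — scans over founder numbers, mating systems and
  multi-generation phenotyping all sit at this bound. The tests therefore
  hold the fit to bounds consistent with that information limit (medians over
  20 seeds: σ²ₑ within 15%, σ²ₐ within 40%, σ²ᵢ within 50%, the sum within
  25%) rather than to a precision the data cannot carry. Fitting is done on
  the latent response from the truth ledger because the rank→AP transform
  does not preserve the variance scale.
* **Null scenario** — same structure, no genotype effect, 200 replicates: the
  heterozygote-vs-common-homozygote Wald contrast must reject within the 95%
  binomial band around α = 0.05. Observed rate ≈ 0.065: the normal
  approximation is mildly liberal at this size, within the band.

Passing these tests demonstrates correct arithmetic, a calibrated test and an
unbiased, information-efficient estimator on data generated by the model the
fitter assumes. It does not demonstrate that real race records satisfy those
assumptions (normality of latent performance, no genotype-by-distance
interaction, complete pedigrees, missingness unrelated to performance).

## Numerical choices and degenerate inputs

* REML convergence: `tol` (default 1e-6) sets L-BFGS-B's gradient tolerance;
  the reported `grad_norm` is the max-abs gradient at the solution.
* Bird variance components at the optimizer's lower bound are reported as
  exactly 0; the residual is never allowed to reach 0.
* Cholesky factorizations carry no jitter except the 1e-10 ridge used when
  *sampling* breeding values from a possibly semidefinite A.
* Empty sequence digests to a single zero-band pattern of length 0 (no
  fragments); empty genotype tables and zero-count HWE inputs are errors.
* Race tables must be internally consistent (one distance, one field size,
  unique finisher positions per race); violations name the offending race or
  file line.
* CSV dialects: UTF-8, comma, header row; empty parent fields mean unknown;
  genotypes are exactly `AG/AG`, `AG/TT`, `TT/TT`; a missing position means
  did-not-finish. Exit codes: 0 success, 2 validation error, 3 model
  non-convergence.
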