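"""Single-locus population-genetic summaries.

Genotype and allele frequencies for one biallelic locus and the chi-square
goodness-of-fit test against Hardy-Weinberg proportions (p^2, 2pq, q^2).  The
test uses 1 degree of freedom — three genotype classes, minus one, minus one
allele frequency estimated from the same data — and no continuity correction.
Frequencies are kept at full precision internally; rounding is a presentation
concern.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

from scipy import stats

from .errors import InputError

GENOTYPE_LABELS = ("AG/AG", "AG/TT", "TT/TT")


@dataclass(frozen=True)
class GenotypeCounts:
    """Observed genotype counts at one biallelic locus."""

    n_refref: int
    n_refalt: int
    n_altalt: int

    def __post_init__(self) -> None:
        if min(self.n_refref, self.n_refalt, self.n_altalt) < 0:
            raise InputError("genotype counts must be non-negative")
        if self.n == 0:
            raise InputError("at least one individual is required")

    @property
    def n(self) -> int:
        return self.n_refref + self.n_refalt + self.n_altalt

    @classmethod
    def from_genotypes(cls, genotypes: Iterable[str]) -> "GenotypeCounts":
        """Tally genotype strings of the 'AG/AG' / 'AG/TT' / 'TT/TT' dialect."""
        tally = dict.fromkeys(GENOTYPE_LABELS, 0)
        for g in genotypes:
            if g not in tally:
                raise InputError(f"unrecognized genotype {g!r}; expected one of {GENOTYPE_LABELS}")
            tally[g] += 1
        return cls(*(tally[g] for g in GENOTYPE_LABELS))


@dataclass(frozen=True)
class HweResult:
    """Hardy-Weinberg chi-square test result.

    ``low_expected_warning`` flags any expected class count below 5, where the
    chi-square approximation is unreliable (with a rare allele the homozygote
    class is almost always below 5).
    """

    chi2: float
    df: int
    p_value: float
    expected_counts: tuple[float, float, float]
    low_expected_warning: bool


def genotype_frequencies(counts: GenotypeCounts) -> tuple[float, float, float]:
    """Relative genotype frequencies (ref/ref, ref/alt, alt/alt)."""
    n = counts.n
    return (counts.n_refref / n, counts.n_refalt / n, counts.n_altalt / n)


def allele_frequencies(counts: GenotypeCounts) -> tuple[float, float]:
    """Allele frequencies (p_ref, q_alt) by allele counting."""
    n = counts.n
    p = (2 * counts.n_refref + counts.n_refalt) / (2 * n)
    return (p, 1.0 - p)


def hwe_chi_square(counts: GenotypeCounts, yates: bool = False) -> HweResult:
    """Chi-square test of Hardy-Weinberg proportions, df = 1.

    Expected counts are (n p^2, 2npq, n q^2) with (p, q) estimated by allele
    counting from the observed counts.  No continuity correction by default;
    ``yates=True`` applies the Yates correction for users who want the
    conservative variant.  A monomorphic sample is a degenerate case: the data
    fit the (trivial) expectation exactly, chi2 = 0, p = 1.
    """
    n = counts.n
    p, q = allele_frequencies(counts)
    expected = (n * p * p, 2 * n * p * q, n * q * q)
    observed = (counts.n_refref, counts.n_refalt, counts.n_altalt)
    if yates:
        chi2 = sum(
            max(abs(o - e) - 0.5, 0.0) ** 2 / e
            for o, e in zip(observed, expected)
            if e > 0
        )
    else:
        chi2 = sum(
            (o - e) ** 2 / e for o, e in zip(observed, expected) if e > 0
        )
    p_value = float(stats.chi2.sf(chi2, df=1))
    return HweResult(
        chi2=float(chi2),
        df=1,
        p_value=p_value,
        expected_counts=expected,
        low_expected_warning=any(e < 5 for e in expected),
    )
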