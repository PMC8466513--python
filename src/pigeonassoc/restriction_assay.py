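"""In-silico forced PCR-RFLP (dCAPS) genotyping.

A dCAPS ("derived cleaved amplified polymorphic sequence", here called *forced*
PCR-RFLP) assay genotypes a variant that does not naturally alter a restriction
site: a deliberate mismatch near the 3' end of one primer completes a
recognition motif together with one allele of the variant, so that digestion of
the PCR product cleaves amplicons carrying that allele and leaves the other
allele's amplicons intact.  Genotypes are then read off the gel as fragment-
length patterns.

This module provides the sequence arithmetic behind such an assay: degenerate
motif scanning, in-silico digestion, automated design of the forced primer, and
genotype calling from observed fragment patterns.

Coordinates are 0-based with half-open intervals; only fragment *lengths* are
reported by digestion, matching gel-reading practice.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from enum import Enum
from typing import Optional

from Bio.Data.IUPACData import ambiguous_dna_values
from Bio.Seq import Seq

from .errors import InputError

#: IUPAC code -> set of unambiguous bases it stands for (T only, no U).
IUPAC_EXPANSION: dict[str, frozenset[str]] = {
    code.upper(): frozenset(bases) for code, bases in ambiguous_dna_values.items()
}

_BASES = "ACGT"


def _validate_sequence(seq: str, what: str = "sequence") -> str:
    seq = seq.upper()
    for i, ch in enumerate(seq):
        if ch not in IUPAC_EXPANSION:
            raise InputError(f"non-IUPAC character {ch!r} at position {i} in {what}")
    return seq


@dataclass(frozen=True)
class Enzyme:
    """A restriction endonuclease reduced to what digestion prediction needs.

    ``cut_offset`` is the 0-based position of the top-strand cut relative to the
    motif start; MluCI (AATT) cuts immediately 5' of its motif, offset 0.
    """

    name: str
    recognition: str
    cut_offset: int

    def __post_init__(self) -> None:
        if not self.recognition:
            raise InputError("enzyme recognition motif must be non-empty")
        object.__setattr__(
            self, "recognition", _validate_sequence(self.recognition, f"{self.name} motif")
        )
        if not 0 <= self.cut_offset <= len(self.recognition):
            raise InputError(
                f"cut_offset {self.cut_offset} outside motif of length {len(self.recognition)}"
            )


#: MluCI: blunt cutter, recognition AATT, cleaves 5' of the motif.
MLUCI = Enzyme(name="MluCI", recognition="AATT", cut_offset=0)


def find_recognition_sites(seq: str, enzyme: Enzyme) -> list[int]:
    """Return sorted 0-based start positions of the enzyme's motif in ``seq``.

    Degeneracy is expanded in the motif only: a motif character matches a
    sequence character iff the sequence character is in the motif character's
    IUPAC expansion.  Ambiguity codes in ``seq`` are validated but treated as
    literal symbols.
    """
    seq = _validate_sequence(seq)
    motif = enzyme.recognition
    m = len(motif)
    sites = []
    for p in range(len(seq) - m + 1):
        if all(seq[p + k] in IUPAC_EXPANSION[motif[k]] for k in range(m)):
            sites.append(p)
    return sites


@dataclass(frozen=True)
class FragmentPattern:
    """Multiset of restriction-fragment lengths (bp), stored sorted ascending."""

    lengths: tuple[int, ...]

    def __post_init__(self) -> None:
        if any(ln <= 0 for ln in self.lengths):
            raise InputError("fragment lengths must be positive")
        object.__setattr__(self, "lengths", tuple(sorted(self.lengths)))

    @property
    def bands(self) -> tuple[int, ...]:
        """Distinct lengths — what is visible as bands on a gel."""
        return tuple(sorted(set(self.lengths)))

    def total(self) -> int:
        return sum(self.lengths)

    def union_bands(self, other: "FragmentPattern") -> "FragmentPattern":
        """Band-level union: the pattern a heterozygote shows on a gel."""
        return FragmentPattern(tuple(set(self.bands) | set(other.bands)))


def digest(seq: str, enzyme: Enzyme, both_strands: bool = False) -> FragmentPattern:
    """Predict the fragment pattern of a complete digestion of ``seq``.

    Cut coordinates are ``site + cut_offset`` for every recognition site; the
    fragments are the intervals between consecutive cuts and the sequence ends.
    Zero-length fragments (a cut flush with an end) yield no observable band and
    are dropped.  Fragment lengths always sum to ``len(seq)``.

    ``both_strands`` additionally scans the reverse complement, maps each
    bottom-strand site to its top-strand interval, and cuts it with the same
    top-strand offset.  For palindromic motifs such as MluCI's AATT the mapped
    sites coincide with the top-strand scan and the flag adds nothing, hence
    it defaults to off.
    """
    seq = _validate_sequence(seq)
    m = len(enzyme.recognition)
    sites = set(find_recognition_sites(seq, enzyme))
    if both_strands:
        rc = str(Seq(seq).reverse_complement())
        for s in find_recognition_sites(rc, enzyme):
            sites.add(len(seq) - s - m)
    cuts = {s + enzyme.cut_offset for s in sites}
    bounds = sorted({0, len(seq), *cuts})
    lengths = [b - a for a, b in zip(bounds, bounds[1:]) if b > a]
    return FragmentPattern(tuple(lengths))


class GenotypeCall(Enum):
    """Diploid genotype at the assayed biallelic variant."""

    REF_REF = "ref/ref"
    HET = "ref/alt"
    ALT_ALT = "alt/alt"

    def label(self, allele_ref: str = "AG", allele_alt: str = "TT") -> str:
        if self is GenotypeCall.REF_REF:
            return f"{allele_ref}/{allele_ref}"
        if self is GenotypeCall.HET:
            return f"{allele_ref}/{allele_alt}"
        return f"{allele_alt}/{allele_alt}"


@dataclass(frozen=True)
class SnpAssay:
    """A forced PCR-RFLP assay for a biallelic dinucleotide variant.

    The variant sits immediately 3' of the forward primer, so the primer's
    engineered mismatch and one allele jointly complete the recognition motif.
    The reverse primer enters only through ``amplicon_length``; downstream
    filler is assumed free of additional sites (``filler_base`` controls the
    base used when reconstructing allelic amplicons in silico).
    """

    forward_primer: str
    amplicon_length: int
    allele_ref: str = "AG"
    allele_alt: str = "TT"
    enzyme: Enzyme = MLUCI
    filler_base: str = "C"

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "forward_primer", _validate_sequence(self.forward_primer, "forward primer")
        )
        for name in ("allele_ref", "allele_alt"):
            al = _validate_sequence(getattr(self, name), name)
            if len(al) != 2:
                raise InputError(f"{name} must be a dinucleotide, got {al!r}")
            object.__setattr__(self, name, al)
        if self.variant_offset + 2 > self.amplicon_length:
            raise InputError("amplicon too short to contain primer plus variant")

    @property
    def variant_offset(self) -> int:
        """0-based position of the variant dinucleotide in the amplicon."""
        return len(self.forward_primer)

    def amplicon(self, allele: str) -> str:
        """Reconstruct the allelic amplicon: primer + allele + neutral filler."""
        allele = _validate_sequence(allele, "allele")
        if allele not in (self.allele_ref, self.allele_alt):
            raise InputError(f"allele {allele!r} is neither {self.allele_ref} nor {self.allele_alt}")
        n_fill = self.amplicon_length - self.variant_offset - 2
        return self.forward_primer + allele + self.filler_base * n_fill

    def expected_patterns(self) -> dict[GenotypeCall, FragmentPattern]:
        """Band patterns expected for the three genotypes.

        The heterozygote shows the band-level union of the two homozygote
        digests (both allelic amplicons are present in the reaction).
        """
        ref = digest(self.amplicon(self.allele_ref), self.enzyme)
        alt = digest(self.amplicon(self.allele_alt), self.enzyme)
        return {
            GenotypeCall.REF_REF: ref,
            GenotypeCall.ALT_ALT: alt,
            GenotypeCall.HET: ref.union_bands(alt),
        }


def call_genotype(
    observed: FragmentPattern, assay: SnpAssay, tolerance_bp: int = 0
) -> Optional[GenotypeCall]:
    """Call a genotype from an observed band pattern, or ``None`` if uncallable.

    Matching is band-wise: the observed distinct lengths must pair one-to-one
    with an expected pattern's bands within ``± tolerance_bp`` each.  A pattern
    matching none of the three expectations is an uncallable sample, not an
    error — on a real gel this is a failed or partial digestion.
    """
    if tolerance_bp < 0:
        raise InputError("tolerance_bp must be non-negative")
    obs = observed.bands
    for call, expected in assay.expected_patterns().items():
        exp = expected.bands
        if len(obs) == len(exp) and all(abs(o - e) <= tolerance_bp for o, e in zip(obs, exp)):
            return call
    return None


@dataclass(frozen=True)
class ForcedPrimerDesign:
    """Result of forced-primer design.

    ``mismatches`` lists (position, template_base, primer_base) substitutions
    relative to the template; ``site_start`` is the recognition-site start in
    primer+discriminating-allele coordinates.
    """

    primer: str
    template_segment: str
    mismatches: tuple[tuple[int, str, str], ...]
    discriminating_allele: str
    site_start: int

    @property
    def n_mismatches(self) -> int:
        return len(self.mismatches)


def _junction_sites(primer: str, allele: str, enzyme: Enzyme) -> list[int]:
    """Recognition sites in primer+allele that span the primer/allele junction."""
    joint = primer + allele
    L = len(primer)
    m = len(enzyme.recognition)
    return [s for s in find_recognition_sites(joint, enzyme) if s < L < s + m]


def design_forced_primer(
    template_context: str,
    allele_ref: str,
    allele_alt: str,
    enzyme: Enzyme,
    max_mismatches: int = 1,
    primer_length: Optional[int] = None,
) -> Optional[ForcedPrimerDesign]:
    """Design a primer whose engineered mismatch makes digestion allele-specific.

    ``template_context`` is genomic sequence ending at the base immediately 5'
    of the variant; the candidate primer is its 3'-terminal ``primer_length``
    bases (default: all of it).  Up to ``max_mismatches`` substitutions are
    tried, never in the 3'-terminal base (a terminal mismatch would abolish
    extension).  A candidate is accepted when exactly one allele completes a
    junction-spanning recognition site; the search prefers fewer mismatches and,
    among single mismatches, positions closest to the 3' end, which reproduces
    the classic dCAPS placement.

    Returns ``None`` when no such modification exists (including the case where
    every candidate cuts both alleles).
    """
    if max_mismatches < 0:
        raise InputError("max_mismatches must be non-negative")
    template_context = _validate_sequence(template_context, "template context")
    for name, al in (("allele_ref", allele_ref), ("allele_alt", allele_alt)):
        if len(al) != 2:
            raise InputError(f"{name} must be a dinucleotide")
    if primer_length is None:
        primer_length = len(template_context)
    if not 0 < primer_length <= len(template_context):
        raise InputError("primer_length must be in 1..len(template_context)")

    segment = template_context[-primer_length:]
    L = len(segment)
    # mutable positions ordered 3'->5', excluding the 3'-terminal base
    positions = list(range(L - 2, -1, -1))

    def evaluate(primer: str) -> Optional[tuple[str, int]]:
        sites_alt = _junction_sites(primer, allele_alt, enzyme)
        sites_ref = _junction_sites(primer, allele_ref, enzyme)
        if sites_alt and not sites_ref:
            return allele_alt, sites_alt[0]
        if sites_ref and not sites_alt:
            return allele_ref, sites_ref[0]
        return None

    for k in range(max_mismatches + 1):
        for pos_combo in itertools.combinations(positions, k):
            base_choices = [
                [b for b in _BASES if b != segment[p]] for p in pos_combo
            ]
            for bases in itertools.product(*base_choices):
                primer = list(segment)
                for p, b in zip(pos_combo, bases):
                    primer[p] = b
                candidate = "".join(primer)
                hit = evaluate(candidate)
                if hit is not None:
                    allele, site = hit
                    mm = tuple(
                        (p, segment[p], b) for p, b in sorted(zip(pos_combo, bases))
                    )
                    return ForcedPrimerDesign(
                        primer=candidate,
                        template_segment=segment,
                        mismatches=mm,
                        discriminating_allele=allele,
                        site_start=site,
                    )
    return None
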