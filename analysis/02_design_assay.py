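#!/usr/bin/env python
"""Design the forced PCR-RFLP assay and predict its gel patterns.

Starting from the unmodified genomic context upstream of the AG->TT variant,
finds the single-base primer modification that creates an MluCI site together
with the TT allele, digests both allelic 176-bp amplicons in silico, and
writes the per-allele fragment report to results/assay_report.csv.
"""

from pathlib import Path

import pandas as pd

from pigeonassoc.restriction_assay import (
    MLUCI,
    SnpAssay,
    design_forced_primer,
    digest,
)

#: genomic top strand ending at the base immediately 5' of the variant
NATURAL_CONTEXT = "AGAAACATTGGTTACTCTTATAGTTGA"
OUT = Path(__file__).resolve().parents[1] / "results" / "assay_report.csv"


def main() -> None:
    design = design_forced_primer(NATURAL_CONTEXT, "AG", "TT", MLUCI, max_mismatches=1)
    assert design is not None, "no forcing modification found"
    print(f"template 3' context : {design.template_segment}")
    print(f"forced primer       : {design.primer}")
    for pos, was, now in design.mismatches:
        print(f"modification        : {was} -> {now} at primer position {pos} "
              f"(position {pos - len(design.primer)} from the 3' end)")
    print(f"discriminating allele: {design.discriminating_allele}")

    assay = SnpAssay(forward_primer=design.primer, amplicon_length=176)
    rows = []
    for genotype, pattern in assay.expected_patterns().items():
        label = genotype.label(assay.allele_ref, assay.allele_alt)
        rows.append(
            {
                "genotype": label,
                "bands_bp": "+".join(map(str, sorted(pattern.bands, reverse=True))),
                "discriminating": assay.allele_alt in label,
            }
        )
        print(f"expected gel bands {label:>6}: "
              f"{' + '.join(map(str, sorted(pattern.bands, reverse=True)))} bp")
    OUT.parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(rows).to_csv(OUT, index=False)
    print(f"report -> {OUT}")


if __name__ == "__main__":
    main()
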