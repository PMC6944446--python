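#!/usr/bin/env python
"""Audit the bundled human codon-usage reference.

Computes RSCU (normalized relative usage), the set of synonymous codons
used less than expected (RSCU < 1), and the per-amino-acid lowest-usage
("low usage") codons, and writes the full table to
results/codon_audit.tsv.
"""

from pathlib import Path

import pandas as pd

from gcfate import seqfeatures as sf

OUT = Path(__file__).resolve().parents[1] / "results"

if __name__ == "__main__":
    table = sf.load_reference_usage()
    low, lowest = sf.audit_low_usage_codons(table)
    rows = []
    for codon in sf.ALL_CODONS:
        aa = sf.CODON_TO_AA[codon]
        rows.append({
            "codon": codon, "amino_acid": aa,
            "count": table.counts[codon], "rscu": table.rscu[codon],
            "below_expected": codon in low,
            "lowest_of_family": lowest.get(aa) == codon})
    OUT.mkdir(exist_ok=True)
    out = OUT / "codon_audit.tsv"
    pd.DataFrame(rows).to_csv(out, sep="\t", index=False,
                              float_format="%.4f")
    au = sum(1 for c in low if c[2] in "AT")
    nna = sum(1 for c in lowest.values() if c[2] in "AT")
    exceptions = sorted(aa for aa, c in lowest.items() if c[2] not in "AT")
    print(f"codon audit -> {out}")
    print(f"  {len(low)} synonymous codons with RSCU < 1; {au} end in A/U")
    print(f"  {nna}/{len(lowest)} per-amino-acid lowest-usage codons are "
          f"NNA/NNU; exceptions encode {', '.join(exceptions)}")
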