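"""Classify a handful of SNVs by somatic status at a known purity.

Shows the state posterior machinery in isolation: three variants in a
diploid segment at purity 0.65 - a novel variant at the clonal-somatic
fraction, a dbSNP variant at the heterozygous-germline fraction, and a
dbSNP variant near 1 that lands in the contamination bin.
"""

import numpy as np

from allelecn.snv import classify_variants, expected_af
from allelecn.variants import VariantObservation, variants_frame

purity = 0.65
print(f"expected fractions at purity {purity}: "
      f"clonal somatic {expected_af(purity, 2, 1, 0):.3f}, "
      f"het germline {expected_af(purity, 2, 1, 1):.3f}")

variants = [
    VariantObservation("chr1", 1000, "C", "T", f=0.33, n=200),
    VariantObservation("chr1", 2000, "G", "A", f=0.50, n=200, in_dbsnp=True),
    VariantObservation("chr1", 3000, "T", "C", f=0.98, n=200, in_dbsnp=True),
]
seg_posterior = np.zeros((1, 9))
seg_posterior[0, 2] = 1.0  # copy number known to be 2

table = classify_variants(
    variants_frame(variants), np.zeros(3, dtype=int), seg_posterior, purity
)
for _, row in table.iterrows():
    h = "" if np.isnan(row["CELLFRACTION"]) else f", cell fraction {row['CELLFRACTION']:.2f}"
    print(
        f"pos {row['pos']}: f={row['f']:.2f} -> {row['ML.STATE']} "
        f"(P(somatic)={row['posterior_somatic']:.3f}{h})"
    )

# the ML state is (g, M, C): germline flag, multiplicity, copy number;
# the f=0.98 dbSNP variant is absorbed by the contamination-reference bin
# rather than distorting the fit.
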