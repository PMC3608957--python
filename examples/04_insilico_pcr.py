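"""In-silico PCR as a locus-uniqueness filter.

A candidate ditag survives criterion 3 only if its two tag sequences, used
as sense/antisense primers, amplify exactly one electronic product at the
ditag's own locus.  This script plants a two-copy repeat, then shows that a
ditag in unique sequence passes while a ditag inside the repeat amplifies
two products and is rejected.
"""

from Bio.Seq import reverse_complement

from ditagdel import (
    Ditag,
    SimConfig,
    epcr,
    get_enzyme,
    simulate_genome,
    single_product_test,
    tag_sequences,
)

taqi = get_enzyme("TaqI")
bundle = simulate_genome(
    SimConfig(seed=3, chrom_length=120_000, n_duplications=1)
)
genome = bundle.genome
idx = bundle.site_indexes["chr1"]
dup = bundle.duplications[0]

unique = Ditag("chr1", 5, 6)
repeated = Ditag("chr1", dup.src_left_serial, dup.src_left_serial + 1)

for label, ditag in (("unique locus", unique), ("two-copy repeat", repeated)):
    fwd, right = tag_sequences(genome["chr1"], idx, taqi,
                               ditag.left_serial, ditag.right_serial)
    products = epcr(fwd, reverse_complement(right), genome)
    verdict = single_product_test(ditag, genome, bundle.site_indexes, taqi)
    print(f"{label:16} {ditag.ditag_id:12} products={len(products)} "
          f"{[(p.start, p.end) for p in products]} -> "
          f"{'PASS' if verdict else 'REJECT'}")
# The repeat's tags prime at both copies, giving >= 2 feasible amplicons;
# exactly this ambiguity is what criterion 3 removes before validation PCR.
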