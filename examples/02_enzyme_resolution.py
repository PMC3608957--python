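"""Which enzyme detects which deletions?

A deletion is detectable by ditag skipping only if it swallows at least two
recognition sites, so detection resolution tracks an enzyme's cutting
frequency.  This script scores a random deletion set against two 4-cutters
and a 6-cutter on the same genome and prints the detectable fraction plus
the sequencing input needed to cover every fragment end at 12x with paired
50-bp reads.
"""

import numpy as np

from ditagdel import (
    DeletionRecord,
    DeletionSet,
    detection_resolution,
    estimate_input,
    get_enzyme,
    scan_sites,
)

rng = np.random.default_rng(2)
genome = {"chr1": "".join(rng.choice(list("ACGT"), size=500_000))}

records = []
for _ in range(400):
    size = int(np.exp(rng.uniform(np.log(100), np.log(10_000))))
    start = int(rng.integers(1, 480_000))
    records.append(DeletionRecord("chr1", start, start + size - 1))
deletions = DeletionSet(records)  # loader clips to the 100 bp - 10 kb window

print(f"{'enzyme':8} {'sites':>6} {'detectable':>10} {'fraction':>9} {'input (Mb)':>11}")
for name in ("TaqI", "MseI", "EcoRI"):
    enzyme = get_enzyme(name)
    indexes = {c: scan_sites(s, enzyme, c) for c, s in genome.items()}
    report = detection_resolution(deletions, indexes, enzyme)
    n_fragments = report.site_count + 1
    gb = estimate_input(n_fragments) / 1e6
    print(f"{name:8} {report.site_count:>6} {report.detectable:>10} "
          f"{report.detection_resolution:>9.2f} {gb:>11.1f}")
# The frequent cutters (TaqI, MseI) detect several-fold more medium-sized
# deletions than a 6-cutter, at proportionally higher sequencing input.
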