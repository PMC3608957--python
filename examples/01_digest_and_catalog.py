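"""In-silico digestion: sites, fragments, and the Ref-Ditag catalog.

Builds a small simulated genome, digests it with TaqI (T^CGA) and prints
the site/fragment bookkeeping.  Each internal fragment yields one reference
ditag joining the downstream end of site N (tag N_2) to the upstream end of
site N+1 (tag (N+1)_1); these are the expected mate-pair signatures of an
undeleted genome.
"""

from ditagdel import (
    SimConfig,
    digest,
    fragment_length_stats,
    get_enzyme,
    ref_ditag_catalog,
    scan_sites,
    simulate_genome,
)

taqi = get_enzyme("TaqI")
bundle = simulate_genome(SimConfig(seed=1, chrom_length=100_000))
seq = bundle.genome["chr1"]

sites = scan_sites(seq, taqi, "chr1")
fragments = digest(sites, len(seq), taqi)
catalog = ref_ditag_catalog(fragments)
stats = fragment_length_stats(fragments)

print(f"enzyme            : {taqi.name} ({taqi.recognition}, cut after base {taqi.cut_offset})")
print(f"restriction sites : {sites.n_sites}")
print(f"fragments         : {stats['count']} (median {stats['median']:.0f} bp)")
print(f"Ref-Ditags        : {len(catalog)} (internal fragments only)")
print(f"first Ref-Ditag   : {catalog[0].left_tag}/{catalog[0].right_tag} "
      f"spanning {catalog[0].fragment.start}-{catalog[0].fragment.end}")
# n sites always yield n+1 tiling fragments and n-1 reference ditags; the
# serial numbers in the tag IDs are the coordinate system of the caller.
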