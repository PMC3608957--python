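# Methods

## Coordinate and identity conventions

All intervals are 1-based inclusive internally, so a breakpoint pair
(start, end) has size `end − start + 1`; BED output converts to 0-based
half-open bit-exactly and GFF passes through unchanged. A recognition
match starting at position *p* with cut offset *c* cuts after coordinate
`p + c − 1` (TaqI T^CGA, offset 1: the T stays on the left fragment). *n*
sites on a chromosome yield *n* + 1 tiling fragments; the two terminal
fragments have only one restriction end and are excluded from the
Ref-Ditag catalog. The degenerate case of a cut exactly at a chromosome
boundary (possible only for offset 0 or offset = recognition length) would
produce an empty terminal fragment, which is dropped.

Restriction ends are identified as `#chrom-serial-side` (side 1 upstream,
side 2 downstream of the site), rendered in text as `17_141_2/17_145_1`
with any `chr` prefix stripped. A ditag's skip is the serial difference
minus one. Fragment-length medians use the lower-middle element for even
counts (deterministic and integer-valued).

## Ditag extraction geometry

Mate-pair libraries built from circularised restriction fragments put one
read exactly at a fragment end and displace the other ~100–200 bp inward
(nick translation). Anchoring is therefore purely positional — distance to
a cut plus extension direction — and platform-agnostic: a read starting at
`cut + 1` (± 2 bp end-repair tolerance, configurable) anchors as side 2;
a read ending at a cut anchors as side 1. The partner is then assigned to
the unique cut whose distance from the read's restriction-facing end falls
in the nick window, default [50, 300] bp, bracketing the ~100–200 bp the
protocol produces. If no cut lies in the window the default *advisory*
mode assigns the nearest restriction-facing cut (the distal position
confirms rather than defines the locus); *strict* mode discards the pair.
Two cuts inside a tolerance window make the assignment ambiguous and the
pair is discarded and counted. Counters reconcile exactly: pairs in =
emitted + cross-chromosome + unanchored + ambiguous + inconsistent +
duplicates (+ orphans, low-MAPQ). Read pairs with identical coordinates on
both mates collapse to one support unit by default (PCR-duplicate guard,
disable with `dedup=False`).

## Calling criteria and their order

Candidates are variant-type clusters (skip ≥ 1). Filters run 1 → 2 → 4 → 3
— the in-silico PCR test last because it is the expensive one — and each
rejected candidate records its first failing criterion:

1. **Skip + SNP exclusion.** Skip ≥ `min_skip` (default 2) and at least
   one skipped site whose recognition footprint contains no known SNP
   position. Single-site skips are explicable by partial digestion or a
   point mutation; an all-SNP skipped set by genotype alone.
2. **Support** ≥ `min_support` (default 2) distinct read pairs.
3. **Locus uniqueness.** The two tag sequences (default 30 bp), used as
   sense/antisense primers, must amplify exactly one electronic product,
   and that product must sit at the ditag's outer bounds ± 2 bp.
4. **Locus fraction** ≥ `fraction_threshold` (default 0.33, documented
   legal range 0.10–0.40): the candidate's support divided by the summed
   support of every cluster sharing either flanking restriction end. The
   denominator is symmetric and computable from clusters alone; it
   includes reference-type ditags at both flanks, so heterozygous
   deletions sit near 0.5 and duplication artifacts far below.

Reported breakpoints are the outer bounds (first base after the left
flanking cut through the right flanking cut); the inner bounds (first to
last skipped-site footprint) bound the deletion from inside, and the VCF
output encodes the gap as CIPOS/CIEND around a symbolic `<DEL>`.

**Zygosity.** A call is heterozygous when any reference-type ditag whose
fragment lies between the flanking sites has support ≥ 1, or when the
allele fraction — variant support over variant plus that internal
reference support — falls below `hom_fraction` (default 0.75). The allele
fraction deliberately excludes variant-type ditags that merely share a
flanking end: partial-digestion skips at a neighbouring fragment say
nothing about the allele inside the span, and using the criterion-4
fraction here mislabels homozygous calls at noisy loci.

**Burden arithmetic.** True positives = calls × validated/tested at full
precision; the genome-wide lower bound divides by the enzyme's target
fraction and the covered genome fraction *before* any rounding (rounding
the true-positive estimate first shifts the result by several counts).
Report-time rounding is nearest integer, half away from zero.

## In-silico PCR engine

A primer site is any genomic location, either strand, where the primer's
3′ seed (default 12 bp) matches perfectly and at most `max_mismatches`
(default 2) mismatches occur elsewhere; reference N never matches.
Products are convergent plus/minus site pairs on one chromosome spanning
at most `max_product_size` (default 20 kb) and at least the longer primer;
both role assignments amplify, so `epcr(F, R)` = `epcr(R, F)`. Product
coordinates run from the forward primer's 5′ base through the reverse
primer's 5′ base, inclusive — the downstream locus-coincidence check
depends on this convention. No thermodynamics: the filter is positional
uniqueness. Defaults approximate common electronic-PCR practice and all
four knobs are configuration.

## The simulator: what it emulates, what it does not

The generator reproduces the data-generating process stage by stage so
every pipeline property is testable offline:

* **Genome.** Random background at GC 0.41 scrubbed free of accidental
  recognition sites, with sites planted on a lattice at the target spacing
  (default 1,000 bp, the frequent-cutter regime where median fragments are
  ~1 kb); planted positions are therefore exactly what `scan_sites`
  recovers. Optional tandem-layout duplications copy whole fragments (with
  200 bp flanks) onto distant, identically spaced loci for ePCR tests.
* **Variants.** Deletions swallow runs of 2–6 consecutive sites with
  breakpoints at least `nick_hi + read_len + 10` bp clear of the flanking
  cuts (so every read maps unambiguously), sizes confined to 100 bp–10 kb;
  homozygous deletions hit both haplotypes, heterozygous only haplotype 1.
  Site-killing SNPs substitute one base inside a recognition site on both
  haplotypes; a configurable fraction is written to the known-SNP file,
  and adjacent killed pairs can be planted as the skip-2 confounder.
* **Pairs.** Per haplotype, fragments between consecutive surviving sites
  are sampled at half the configured depth (default total 6, the scale at
  which the ≥ 2-support rule starts to bite) with size bias
  `exp(−length/λ)`, λ = 1.5 kb, mimicking the preferential circularisation
  of small fragments; `size_bias=False` and a deterministic `fixed` depth
  mode exist for exactness tests. Each molecule's boundary sites fail
  independently with the partial-digestion probability (default 0.02,
  per-site overrides available), merging fragments and creating the
  single-skip confounder. One read anchors exactly at a cut, the other
  sits a uniform [100, 200] bp nick offset inside the opposite end.
  Alignments are emitted directly in reference coordinates (mapping is
  deliberately out of scope and determinism is required); reads that would
  cross a deletion breakpoint are dropped with a counter, as their real
  counterparts would fail to map.

Everything derives from seed-split generators, so a config reproduces its
FASTA/SAM/truth outputs byte for byte.

Not emulated: sequencing errors and base qualities, colorspace chemistry,
GC-coverage bias beyond the fragment-size bias, mapping ambiguity in
repeats (alignments are pre-solved), and structural variants other than
deletions. Passing tests therefore demonstrate the calling logic, the
geometry and the filters — not robustness to alignment artifacts, which on
real data is delegated to the aligner and criterion 3.

## Test-scale choices and stochastic margins

Test and acceptance runs use 100 kb–1 Mb genomes (100–1,000 fragments),
where every oracle (all-windows site scan, quadratic ePCR enumeration,
brute-force containment counts) is exact and fast. Exact-recovery checks
(20/20 planted homozygous deletions at depth 6) run with noise off in the
full sense: no partial digestion, no SNPs, deterministic fixed-depth
sampling — under Poisson sampling a deletion can legitimately draw support
below 2, which is a property of coverage, not of the caller.

The specificity property (zero calls from confounders under criteria 1–2
alone) holds per confounder class: adjacent known-SNP pairs are rejected
deterministically, and partial digestion needs the same two consecutive
independent failures in two molecules at one locus — probability ≈
`(d·p²)²/2` per locus, ≈ 1e-5 at depth 6 and p = 0.02, a few percent
summed over 50 × 100 kb simulations. The *combination* of both confounders
at one locus (a killed pair plus one adjacent failure) is callable by
criteria 1–2 and is asserted as the method's documented false-positive
mode; criterion 4 rejects it in the full pipeline.

## Known limitations

Only deletions that fully contain ≥ 2 recognition sites are visible;
detection resolution is bounded by the enzyme's cutting frequency and the
deletion-size spectrum. Breakpoints are resolved only to the flanking cut
coordinates (outer/inner bounds), not to base pair. Two adjacent sites
destroyed by unknown point mutations are indistinguishable from a deletion
(the published validation's one false positive). Heterozygous deletions
near the locus-fraction threshold are lost by design at high-specificity
settings. Insertions, inversions and translocations are out of scope.
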