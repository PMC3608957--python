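"""Four-criterion deletion calling from variant-type ditag clusters.

A variant cluster (skip >= 1) becomes a deletion call when it

1. skips at least ``min_skip`` consecutive sites, of which at least one is
   absent from the known-SNP set (a single skipped site, or all-SNP skipped
   sites, can be explained by point mutation or partial digestion);
2. is supported by at least ``min_support`` read pairs;
3. amplifies a single in-silico PCR product at its own locus when its two
   tag sequences are used as primers (locus uniqueness); and
4. carries at least ``fraction_threshold`` of all ditag support mapped to
   its locus (both flanking restriction ends), guarding against duplicated
   regions.

Filters run in the order 1, 2, 4, 3 (ePCR last, it is the expensive one);
rejected candidates are logged with their first failing criterion.  The
module also carries the downstream arithmetic: validated-fraction scaling
of the call count and extrapolation to a genome-wide deletion burden.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import pandas as pd
from Bio.Seq import reverse_complement

from .ditags import Ditag
from .enzymes import EnzymeSpec
from .epcr import EpcrConfig, single_product_test
from .restriction import SiteIndex

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class CallerConfig:
    min_skip: int = 2
    min_support: int = 2
    #: fraction of locus support the variant must carry; plausible settings
    #: span 0.10-0.40, default 0.33 for high specificity.
    fraction_threshold: float = 0.33
    #: allele fraction (variant over variant + internal reference support)
    #: at or above which a call is labelled homozygous.
    hom_fraction: float = 0.75
    epcr_enabled: bool = True
    epcr: EpcrConfig = field(default_factory=EpcrConfig)
    tag_length: int = 30

    def __post_init__(self) -> None:
        if self.min_skip < 1 or self.min_support < 1:
            raise ValueError("min_skip and min_support must be >= 1")
        if not 0 < self.fraction_threshold < 1:
            raise ValueError("fraction_threshold must be in (0, 1)")


class SnpSet:
    """Known single-nucleotide variant positions, (chrom, 1-based pos)."""

    def __init__(self, positions=()):
        self._pos = frozenset((c, int(p)) for c, p in positions)

    def __contains__(self, item) -> bool:
        return item in self._pos

    def __len__(self) -> int:
        return len(self._pos)

    def any_in(self, chrom: str, start: int, end: int) -> bool:
        return any((chrom, p) in self._pos for p in range(start, end + 1))


@dataclass
class DeletionCall:
    chrom: str
    left_serial: int           # flanking site N
    right_serial: int          # flanking site M
    support: int
    locus_total: int
    variant_fraction: float
    zygosity: str              # "homozygous" | "heterozygous"
    outer_start: int           # first base after the cut of site N
    outer_end: int             # cut coordinate of site M
    inner_start: int           # first skipped site start
    inner_end: int             # last skipped site end
    filters_passed: tuple[str, ...] = ()

    @property
    def skipped_serials(self) -> range:
        return range(self.left_serial + 1, self.right_serial)

    @property
    def skip(self) -> int:
        return self.right_serial - self.left_serial - 1

    @property
    def ditag_id(self) -> str:
        chrom = self.chrom[3:] if self.chrom.startswith("chr") else self.chrom
        return f"{chrom}_{self.left_serial}_2/{chrom}_{self.right_serial}_1"

    @property
    def breakpoints(self) -> str:
        return f"{self.chrom}:{self.outer_start}-{self.outer_end}"


def deletion_size(start: int, end: int) -> int:
    """Size of a 1-based inclusive breakpoint interval: end - start + 1."""
    if start > end:
        raise ValueError(f"inverted breakpoints {start} > {end}")
    return end - start + 1


def round_half_away(x: float) -> int:
    """Report-time rounding: nearest integer, half away from zero."""
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def filter_skip_and_snp(
    ditag: Ditag,
    site_index: SiteIndex,
    snps: SnpSet,
    enzyme: EnzymeSpec,
    min_skip: int = 2,
) -> tuple[bool, str]:
    """Criterion 1: enough skipped sites, not all explicable as known SNPs.

    Passes iff ``skip >= min_skip`` and at least one skipped site's
    recognition footprint contains no known SNP position.
    """
    if ditag.skip < min_skip:
        return False, "single-site skip" if ditag.skip == 1 else "below min_skip"
    for serial in range(ditag.left_serial + 1, ditag.right_serial):
        p = site_index.position(serial)
        if not snps.any_in(ditag.chrom, p, p + enzyme.length - 1):
            return True, "ok"
    return False, "all sites SNP"


class LocusIndex:
    """Support totals per flanking restriction end, over all clusters."""

    def __init__(self, clusters: list[Ditag]):
        self._clusters = clusters
        self._by_left: dict[tuple[str, int], list[int]] = {}
        self._by_right: dict[tuple[str, int], list[int]] = {}
        for i, d in enumerate(clusters):
            self._by_left.setdefault((d.chrom, d.left_serial), []).append(i)
            self._by_right.setdefault((d.chrom, d.right_serial), []).append(i)

    def locus_total(self, ditag: Ditag) -> int:
        """Total support of clusters sharing either flanking end (each
        cluster counted once)."""
        idx = set(self._by_left.get((ditag.chrom, ditag.left_serial), []))
        idx |= set(self._by_right.get((ditag.chrom, ditag.right_serial), []))
        return sum(self._clusters[i].support for i in idx)

    def internal_reference_support(self, chrom: str, n: int, m: int) -> int:
        """Support of reference-type ditags whose fragment lies between the
        flanking sites N and M (evidence of an undeleted allele)."""
        total = 0
        for d in self._clusters:
            if (
                d.chrom == chrom
                and d.is_reference_type
                and d.left_serial >= n
                and d.right_serial <= m
            ):
                total += d.support
        return total


def locus_fraction(ditag: Ditag, locus_index: LocusIndex) -> tuple[int, int, float]:
    """Criterion 4 arithmetic: (support, locus_total, fraction)."""
    total = locus_index.locus_total(ditag)
    return ditag.support, total, ditag.support / total


def zygosity_guess(
    chrom: str,
    left_serial: int,
    right_serial: int,
    variant_support: int,
    locus_index: LocusIndex,
    hom_fraction: float = 0.75,
) -> str:
    """Heterozygous when reference-type ditags survive inside the deleted
    span, or when the allele fraction — variant support over variant plus
    internal reference support — falls below ``hom_fraction``.

    The allele fraction deliberately excludes variant-type ditags that
    merely share a flanking end (partial-digestion noise): zygosity weighs
    the two alleles, not mapping specificity.
    """
    internal = locus_index.internal_reference_support(chrom, left_serial, right_serial)
    allele_fraction = variant_support / (variant_support + internal)
    if internal >= 1 or allele_fraction < hom_fraction:
        return "heterozygous"
    return "homozygous"


def call_deletions(
    clusters: list[Ditag],
    site_indexes: dict[str, SiteIndex],
    snps: SnpSet | None = None,
    genome: dict[str, str] | None = None,
    config: CallerConfig | None = None,
    enzyme: EnzymeSpec | None = None,
) -> tuple[list[DeletionCall], list[tuple[Ditag, str]]]:
    """Apply the four criteria to every variant-type cluster.

    Returns (calls sorted by chrom and flanking serial, rejected candidates
    with their first failing criterion).
    """
    config = config or CallerConfig()
    snps = snps or SnpSet()
    if enzyme is None:
        raise ValueError("enzyme specification required")
    if config.epcr_enabled and genome is None:
        raise ValueError("genome sequence required when the ePCR filter is enabled")

    locus_index = LocusIndex(clusters)
    calls: list[DeletionCall] = []
    rejected: list[tuple[Ditag, str]] = []
    for d in sorted(clusters, key=lambda x: x.key):
        if d.skip < 1:
            continue  # reference-type, not a candidate
        idx = site_indexes[d.chrom]
        ok, reason = filter_skip_and_snp(d, idx, snps, enzyme, config.min_skip)
        if not ok:
            rejected.append((d, f"criterion1:{reason}"))
            continue
        if d.support < config.min_support:
            rejected.append((d, "criterion2:support"))
            continue
        support, total, fraction = locus_fraction(d, locus_index)
        if fraction < config.fraction_threshold:
            rejected.append((d, "criterion4:locus-fraction"))
            continue
        if config.epcr_enabled and not single_product_test(
            d, genome, site_indexes, enzyme, config.epcr, config.tag_length
        ):
            rejected.append((d, "criterion3:epcr"))
            continue
        n, m = d.left_serial, d.right_serial
        calls.append(
            DeletionCall(
                chrom=d.chrom,
                left_serial=n,
                right_serial=m,
                support=support,
                locus_total=total,
                variant_fraction=fraction,
                zygosity=zygosity_guess(
                    d.chrom, n, m, support, locus_index, config.hom_fraction
                ),
                outer_start=idx.cut(n, enzyme) + 1,
                outer_end=idx.cut(m, enzyme),
                inner_start=idx.position(n + 1),
                inner_end=idx.position(m - 1) + enzyme.length - 1,
                filters_passed=("skip_snp", "support", "fraction")
                + (("epcr",) if config.epcr_enabled else ()),
            )
        )
    calls.sort(key=lambda c: (c.chrom, c.left_serial))
    return calls, rejected


def estimate_true_positives(n_called: int, n_validated: int, n_tested: int) -> float:
    """Scale the call count by the validated fraction (full precision)."""
    if n_tested < 1:
        raise ValueError("n_tested must be >= 1")
    if not 0 <= n_validated <= n_tested:
        raise ValueError("n_validated must lie in [0, n_tested]")
    return n_called * n_validated / n_tested


def extrapolate_genome_burden(
    true_positives: float, target_fraction: float, genome_coverage: float
) -> float:
    """Lower bound on the genome-wide deletion count.

    Divides the (unrounded) true-positive estimate by the fraction of
    deletions the enzyme targets and by the fraction of the genome covered
    by observed ditags.
    """
    if not 0 < target_fraction <= 1 or not 0 < genome_coverage <= 1:
        raise ValueError("proportions must be in (0, 1]")
    return true_positives / target_fraction / genome_coverage


def export_primers(
    calls: list[DeletionCall],
    genome: dict[str, str],
    site_indexes: dict[str, SiteIndex],
    enzyme: EnzymeSpec,
    tag_length: int = 30,
) -> pd.DataFrame:
    """Validation primers per call: the two tag sequences flanking the
    deleted span.

    Forward primer extends rightward from the cut after site N; reverse
    primer is the reverse complement of the ``tag_length`` bases ending at
    the cut of site M.  The expected mutant product is the reference span
    minus the deleted region; its maximum (deletion no smaller than the
    inner bounds) is reported.  Calls whose primer window leaves the
    chromosome are skipped with a warning.
    """
    if tag_length <= 0:
        raise ValueError("tag_length must be positive")
    rows = []
    for call in calls:
        seq = genome[call.chrom]
        idx = site_indexes[call.chrom]
        c_left = idx.cut(call.left_serial, enzyme)
        c_right = idx.cut(call.right_serial, enzyme)
        if c_left + tag_length > len(seq) or c_right - tag_length < 0:
            log.warning("%s: primer window out of bounds; skipped", call.ditag_id)
            continue
        fwd = seq[c_left : c_left + tag_length].upper()
        rev = reverse_complement(seq[c_right - tag_length : c_right].upper())
        ref_span = call.outer_end - call.outer_start + 1
        inner_span = call.inner_end - call.inner_start + 1
        rows.append(
            {
                "ditag_id": call.ditag_id,
                "forward": fwd,
                "reverse": rev,
                "reference_span": ref_span,
                "mutant_span_max": ref_span - inner_span,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["ditag_id", "forward", "reverse", "reference_span", "mutant_span_max"],
    )
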