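"""Electronic PCR: enumerate feasible amplicons of a primer pair.

The engine finds every genomic location (both strands) where a primer's 3'
seed matches perfectly and the remaining bases carry at most a configurable
number of mismatches, then pairs convergently oriented hits on the same
chromosome within a product-size cap.  No thermodynamics: the filter is
positional uniqueness, which is what the deletion caller needs — a candidate
ditag survives only if its two tag sequences, used as sense/antisense
primers, amplify a single product at the ditag's own locus.

Product coordinates run from the forward primer's 5' genomic base through
the reverse primer's 5' genomic base, 1-based inclusive.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from Bio.Seq import reverse_complement

from .enzymes import EnzymeSpec
from .restriction import SiteIndex

log = logging.getLogger(__name__)


class PrimerError(ValueError):
    pass


@dataclass(frozen=True)
class EpcrConfig:
    max_product_size: int = 20_000
    max_mismatches: int = 2          # per primer, outside the 3' seed
    seed_3prime: int = 12            # perfect-match bases at the 3' end
    min_primer_length: int = 15

    def __post_init__(self) -> None:
        if self.max_product_size <= 0:
            raise ValueError("max_product_size must be positive")


@dataclass(frozen=True)
class PrimerSite:
    chrom: str
    position: int  # 1-based genomic coordinate of the primer's 5' base
    strand: str    # '+' or '-'
    mismatches: int


@dataclass(frozen=True)
class EpcrProduct:
    chrom: str
    start: int  # forward primer 5' base
    end: int    # reverse primer 5' base
    fwd_mismatches: int
    rev_mismatches: int

    @property
    def size(self) -> int:
        return self.end - self.start + 1


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)


def _match_positions(
    chrom_arr: np.ndarray, primer: str, seed_at_end: bool, config: EpcrConfig
) -> tuple[np.ndarray, np.ndarray]:
    """0-based left-edge positions where `primer` matches the array.

    ``seed_at_end`` selects whether the perfect-match seed sits at the
    right (forward-oriented primer) or left (reverse-complemented primer)
    end of the pattern.  Returns (positions, mismatch counts).
    """
    p = _encode(primer)
    k = len(p)
    n = len(chrom_arr) - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
    seed = min(config.seed_3prime, k)
    seed_idx = range(k - seed, k) if seed_at_end else range(seed)
    seed_set = set(seed_idx)
    total = np.zeros(n, dtype=np.int32)
    seed_mm = np.zeros(n, dtype=np.int32)
    for j in range(k):
        mm = chrom_arr[j : j + n] != p[j]
        total += mm
        if j in seed_set:
            seed_mm += mm
    ok = (seed_mm == 0) & (total <= config.max_mismatches)
    pos = np.nonzero(ok)[0]
    return pos, total[pos]


def find_primer_sites(
    primer: str, genome: dict[str, str], config: EpcrConfig | None = None
) -> list[PrimerSite]:
    """All genomic sites (both strands) where the primer could prime.

    The 3' seed must match perfectly; at most ``max_mismatches`` elsewhere.
    Positions are the primer's 5' genomic base, 1-based.
    """
    config = config or EpcrConfig()
    primer = primer.upper()
    if len(primer) < config.min_primer_length:
        raise PrimerError(
            f"primer length {len(primer)} < minimum {config.min_primer_length}"
        )
    if not set(primer) <= set("ACGT"):
        raise PrimerError(f"primer contains non-ACGT bases: {primer!r}")
    rc = reverse_complement(primer)
    sites: list[PrimerSite] = []
    for chrom, seq in genome.items():
        arr = _encode(seq)
        # plus strand: primer as-is, 3' seed at the right end, 5' = left edge
        pos, mm = _match_positions(arr, primer, seed_at_end=True, config=config)
        sites += [
            PrimerSite(chrom, int(i) + 1, "+", int(m)) for i, m in zip(pos, mm)
        ]
        # minus strand: revcomp pattern, seed at the left edge, 5' = right edge
        pos, mm = _match_positions(arr, rc, seed_at_end=False, config=config)
        sites += [
            PrimerSite(chrom, int(i) + len(primer), "-", int(m))
            for i, m in zip(pos, mm)
        ]
    sites.sort(key=lambda s: (s.chrom, s.position, s.strand))
    return sites


def epcr(
    forward: str,
    reverse: str,
    genome: dict[str, str],
    config: EpcrConfig | None = None,
) -> list[EpcrProduct]:
    """Enumerate putative amplicons of a primer pair.

    A product is a convergent pair of primer sites on one chromosome —
    one primer on the plus strand 5'-of the other on the minus strand —
    spanning at most ``max_product_size`` bp.  Both role assignments
    (forward-plus/reverse-minus and reverse-plus/forward-minus) amplify and
    are enumerated, so ``epcr(F, R)`` equals ``epcr(R, F)``.
    """
    config = config or EpcrConfig()
    f_sites = find_primer_sites(forward, genome, config)
    r_sites = find_primer_sites(reverse, genome, config)
    min_size = max(len(forward), len(reverse))
    seen: set[tuple[str, int, int]] = set()
    products: list[EpcrProduct] = []

    def _pair(plus: list[PrimerSite], minus: list[PrimerSite], plus_is_fwd: bool):
        by_chrom: dict[str, list[PrimerSite]] = {}
        for s in minus:
            by_chrom.setdefault(s.chrom, []).append(s)
        for p in plus:
            for m in by_chrom.get(p.chrom, ()):
                size = m.position - p.position + 1
                if not min_size <= size <= config.max_product_size:
                    continue
                key = (p.chrom, p.position, m.position)
                if key in seen:
                    continue
                seen.add(key)
                fwd_mm, rev_mm = (
                    (p.mismatches, m.mismatches)
                    if plus_is_fwd
                    else (m.mismatches, p.mismatches)
                )
                products.append(
                    EpcrProduct(p.chrom, p.position, m.position, fwd_mm, rev_mm)
                )

    _pair([s for s in f_sites if s.strand == "+"],
          [s for s in r_sites if s.strand == "-"], plus_is_fwd=True)
    _pair([s for s in r_sites if s.strand == "+"],
          [s for s in f_sites if s.strand == "-"], plus_is_fwd=False)
    products.sort(key=lambda p: (p.chrom, p.start, p.end))
    return products


def tag_sequences(
    chrom_seq: str,
    site_index: SiteIndex,
    enzyme: EnzymeSpec,
    left_serial: int,
    right_serial: int,
    tag_length: int = 30,
) -> tuple[str, str] | None:
    """Extract a ditag's two tag sequences from the genome.

    Forward tag reads rightward from the cut after ``left_serial``; the
    right tag is the ``tag_length`` bases ending at the cut of
    ``right_serial`` (returned in genomic orientation).  None when a window
    leaves the chromosome.
    """
    if tag_length <= 0:
        raise ValueError("tag_length must be positive")
    c_left = site_index.cut(left_serial, enzyme)
    c_right = site_index.cut(right_serial, enzyme)
    if c_left + tag_length > len(chrom_seq) or c_right - tag_length < 0:
        return None
    fwd = chrom_seq[c_left : c_left + tag_length]
    right = chrom_seq[c_right - tag_length : c_right]
    return fwd.upper(), right.upper()


def single_product_test(
    ditag,
    genome: dict[str, str],
    site_indexes: dict[str, SiteIndex],
    enzyme: EnzymeSpec,
    config: EpcrConfig | None = None,
    tag_length: int = 30,
    locus_tolerance: int = 2,
) -> bool:
    """Locus-uniqueness filter: the ditag's tags, used as primers, must
    amplify exactly one product, and that product must sit at the ditag's
    own outer bounds (within ``locus_tolerance`` bp)."""
    config = config or EpcrConfig()
    idx = site_indexes[ditag.chrom]
    tags = tag_sequences(
        genome[ditag.chrom], idx, enzyme,
        ditag.left_serial, ditag.right_serial, tag_length,
    )
    if tags is None:
        log.warning("%s: tag window leaves chromosome; ePCR test fails", ditag.ditag_id)
        return False
    fwd, right = tags
    products = epcr(fwd, reverse_complement(right), genome, config)
    if len(products) != 1:
        return False
    p = products[0]
    outer_start = idx.cut(ditag.left_serial, enzyme) + 1
    outer_end = idx.cut(ditag.right_serial, enzyme)
    return (
        p.chrom == ditag.chrom
        and abs(p.start - outer_start) <= locus_tolerance
        and abs(p.end - outer_end) <= locus_tolerance
    )
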