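"""In-silico restriction digestion.

Scans a chromosome for recognition sites, numbers them serially (the
backbone of the ``#chrom-serial-side`` tag ID system), cuts the chromosome
into fragments, and derives the reference ditag (Ref-Ditag) catalog: one
predicted ditag per internal fragment, joining the downstream end of site N
(side 2) to the upstream end of site N+1 (side 1).

Coordinates are 1-based inclusive throughout; the cut falls *after*
``position + cut_offset - 1`` (TaqI T^CGA: the T stays on the left
fragment, CGA goes right).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .enzymes import EnzymeSpec


class DigestError(ValueError):
    """Inconsistent digestion inputs (e.g. sites beyond chromosome end)."""


@dataclass(frozen=True, order=True)
class TagID:
    """One restriction end: ``#chrom-serial-side``.

    ``side 1`` is the region upstream (left) of site ``serial``; ``side 2``
    is the region downstream (right) of it.  A reference fragment between
    sites N and N+1 is delimited by ``(N, side 2)`` and ``(N+1, side 1)``.
    """

    chrom: str
    serial: int
    side: int

    def __post_init__(self) -> None:
        if self.side not in (1, 2):
            raise ValueError(f"side must be 1 or 2, got {self.side}")
        if self.serial < 1:
            raise ValueError(f"serial must be >= 1, got {self.serial}")

    def __str__(self) -> str:
        chrom = self.chrom[3:] if self.chrom.startswith("chr") else self.chrom
        return f"{chrom}_{self.serial}_{self.side}"


@dataclass
class SiteIndex:
    """Sorted, serially numbered recognition-site positions on one chromosome.

    ``positions`` holds the 1-based starts of each recognition match; serial
    ``k`` (1-based) corresponds to ``positions[k - 1]``.
    """

    chrom: str
    positions: np.ndarray  # int64, strictly increasing, 1-based starts

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.int64)
        if self.positions.size and np.any(np.diff(self.positions) <= 0):
            raise ValueError(f"{self.chrom}: site positions not strictly increasing")

    @property
    def n_sites(self) -> int:
        return int(self.positions.size)

    def position(self, serial: int) -> int:
        """1-based start of the recognition match with the given serial."""
        if not 1 <= serial <= self.n_sites:
            raise IndexError(f"serial {serial} outside 1..{self.n_sites}")
        return int(self.positions[serial - 1])

    def cuts(self, enzyme: EnzymeSpec) -> np.ndarray:
        """Cut coordinates: the cut falls after ``cuts[k]`` (1-based)."""
        return self.positions + (enzyme.cut_offset - 1)

    def cut(self, serial: int, enzyme: EnzymeSpec) -> int:
        return self.position(serial) + enzyme.cut_offset - 1


@dataclass(frozen=True)
class Fragment:
    """One restriction fragment, 1-based inclusive.

    ``left_serial`` is the serial of the site whose cut opens the fragment
    (0 at the chromosome start); ``right_serial`` the site whose cut closes
    it (n_sites + 1 at the chromosome end).
    """

    chrom: str
    left_serial: int
    right_serial: int
    start: int
    end: int
    left_is_cut: bool = True
    right_is_cut: bool = True

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    @property
    def is_internal(self) -> bool:
        """True when both ends are restriction cuts (ditag-able fragment)."""
        return self.left_is_cut and self.right_is_cut


@dataclass(frozen=True)
class RefDitag:
    """The reference ditag predicted for one internal fragment."""

    chrom: str
    left_tag: TagID   # (N, side 2)
    right_tag: TagID  # (N+1, side 1)
    fragment: Fragment

    def __post_init__(self) -> None:
        if self.right_tag.serial != self.left_tag.serial + 1:
            raise ValueError("RefDitag serials must be consecutive")


def scan_sites(sequence: str, enzyme: EnzymeSpec, chrom: str = "chr") -> SiteIndex:
    """Find every recognition-site match on the top strand.

    Overlapping matches are all reported; ambiguous reference bases (N)
    never match.  Empty sequence yields an empty index.
    """
    seq = sequence.upper()
    positions = [m.start() + 1 for m in enzyme.regex().finditer(seq)]
    return SiteIndex(chrom=chrom, positions=np.asarray(positions, dtype=np.int64))


def digest(
    site_index: SiteIndex, chrom_length: int, enzyme: EnzymeSpec
) -> list[Fragment]:
    """Cut a chromosome at every site; n sites yield n+1 tiling fragments.

    Degenerate cuts exactly at a chromosome boundary (possible only for
    cut_offset 0 or cut_offset = recognition length) would create an empty
    terminal fragment, which is dropped.
    """
    n = site_index.n_sites
    if n and site_index.positions[-1] + enzyme.length - 1 > chrom_length:
        raise DigestError(
            f"{site_index.chrom}: last site at {int(site_index.positions[-1])} "
            f"exceeds chromosome length {chrom_length}"
        )
    cuts = site_index.cuts(enzyme)
    boundaries = [0, *cuts.tolist(), chrom_length]
    fragments = []
    for i in range(len(boundaries) - 1):
        start = boundaries[i] + 1
        end = boundaries[i + 1]
        if start > end:  # empty terminal fragment at a boundary cut
            continue
        fragments.append(
            Fragment(
                chrom=site_index.chrom,
                left_serial=i,
                right_serial=i + 1,
                start=start,
                end=end,
                left_is_cut=i >= 1,
                right_is_cut=i + 1 <= n,
            )
        )
    return fragments


def ref_ditag_catalog(fragments: list[Fragment]) -> list[RefDitag]:
    """One Ref-Ditag per internal fragment; terminal fragments are excluded
    (they have only one restriction end)."""
    catalog = []
    for frag in fragments:
        if not frag.is_internal:
            continue
        n = frag.left_serial
        catalog.append(
            RefDitag(
                chrom=frag.chrom,
                left_tag=TagID(frag.chrom, n, 2),
                right_tag=TagID(frag.chrom, n + 1, 1),
                fragment=frag,
            )
        )
    return catalog


DEFAULT_LENGTH_BINS = (0, 100, 200, 500, 1_000, 2_000, 5_000, 10_000, np.inf)


def median_lower(values) -> float:
    """Median with the lower-middle convention for even counts.

    Deterministic and integer-valued on integer input (the convention used
    for fragment-length summaries here)."""
    arr = np.sort(np.asarray(values))
    if arr.size == 0:
        return 0.0
    return float(arr[(arr.size - 1) // 2])


def fragment_length_stats(fragments: list[Fragment], bins=DEFAULT_LENGTH_BINS) -> dict:
    """Count / mean / median (lower-middle) / histogram of fragment lengths."""
    lengths = np.asarray([f.length for f in fragments], dtype=np.int64)
    if lengths.size == 0:
        return {
            "count": 0,
            "mean": 0.0,
            "median": 0.0,
            "histogram": {},
        }
    edges = np.asarray(bins, dtype=float)
    counts, _ = np.histogram(lengths, bins=edges)
    hist = {
        (float(edges[i]), float(edges[i + 1])): int(counts[i])
        for i in range(len(counts))
    }
    return {
        "count": int(lengths.size),
        "mean": float(lengths.mean()),
        "median": median_lower(lengths),
        "histogram": hist,
    }
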