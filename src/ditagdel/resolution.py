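"""Detection-resolution simulation.

For a candidate enzyme and a set of known deletions, estimate the fraction
of deletions the ditag approach could detect.  A deletion is *detectable*
when it fully contains at least two recognition sites: removing both sites
makes the flanking ditag skip >= 2 sites, the deletion signature.  The
module also estimates the sequencing input needed to cover every fragment
end at a target depth.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .enzymes import EnzymeSpec
from .restriction import SiteIndex

log = logging.getLogger(__name__)

#: Medium-size window targeted by the method (bp, inclusive).
DEFAULT_SIZE_WINDOW = (100, 10_000)

#: Default deletion-size bins for per-bin resolution fractions (bp edges).
DEFAULT_SIZE_BINS = (100, 200, 500, 1_000, 2_000, 5_000, 10_001)


@dataclass(frozen=True)
class DeletionRecord:
    chrom: str
    start: int  # 1-based inclusive
    end: int
    label: str = ""

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"inverted interval {self.chrom}:{self.start}-{self.end}")

    @property
    def size(self) -> int:
        return self.end - self.start + 1


@dataclass
class DeletionSet:
    """Deletion intervals restricted (on load) to the medium-size window."""

    records: list[DeletionRecord]
    size_window: tuple[int, int] | None = DEFAULT_SIZE_WINDOW

    def __post_init__(self) -> None:
        if self.size_window is not None:
            lo, hi = self.size_window
            self.records = [r for r in self.records if lo <= r.size <= hi]

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)


@dataclass
class ResolutionReport:
    enzyme: str
    site_count: int
    detectable: int
    total: int
    bin_fractions: dict[tuple[int, int], tuple[int, int]] = field(default_factory=dict)
    estimated_input_bp: float | None = None

    @property
    def detection_resolution(self) -> float:
        return self.detectable / self.total


def sites_contained(
    deletion: tuple[str, int, int],
    site_index: SiteIndex,
    enzyme: EnzymeSpec,
) -> int:
    """Number of recognition sites fully inside a 1-based inclusive interval."""
    _, start, end = deletion
    pos = site_index.positions
    lo = np.searchsorted(pos, start, side="left")
    hi = np.searchsorted(pos, end - enzyme.length + 1, side="right")
    return int(hi - lo)


def is_detectable(
    deletion: tuple[str, int, int],
    site_indexes: dict[str, SiteIndex],
    enzyme: EnzymeSpec,
) -> bool:
    """True iff the deletion fully contains >= 2 recognition sites.

    Deletions on chromosomes absent from the index are non-detectable (a
    warning is logged, not raised: real catalogs carry stray contigs).
    """
    chrom = deletion[0]
    idx = site_indexes.get(chrom)
    if idx is None:
        log.warning("deletion on unindexed chromosome %s; counted undetectable", chrom)
        return False
    return sites_contained(deletion, idx, enzyme) >= 2


def detection_resolution(
    deletions: DeletionSet,
    site_indexes: dict[str, SiteIndex],
    enzyme: EnzymeSpec,
    size_bins=DEFAULT_SIZE_BINS,
    estimated_num_fragments: int | None = None,
) -> ResolutionReport:
    """Fraction of deletions detectable by the enzyme, overall and per size bin."""
    if len(deletions) == 0:
        raise ValueError("empty deletion set: detection resolution undefined")
    edges = list(size_bins)
    bin_hits = {(edges[i], edges[i + 1]): [0, 0] for i in range(len(edges) - 1)}
    detectable = 0
    for rec in deletions:
        hit = is_detectable((rec.chrom, rec.start, rec.end), site_indexes, enzyme)
        detectable += hit
        for (lo, hi), counts in bin_hits.items():
            if lo <= rec.size < hi:
                counts[1] += 1
                counts[0] += hit
                break
    report = ResolutionReport(
        enzyme=enzyme.name,
        site_count=sum(ix.n_sites for ix in site_indexes.values()),
        detectable=detectable,
        total=len(deletions),
        bin_fractions={k: (v[0], v[1]) for k, v in bin_hits.items() if v[1] > 0},
    )
    if estimated_num_fragments is not None:
        report.estimated_input_bp = estimate_input(estimated_num_fragments)
    return report


def estimate_input(
    num_fragments: float, end_depth: float = 12, read_len: int = 50
) -> float:
    """Sequencing input (bp) to cover both ends of every fragment.

    Each fragment contributes one read pair per sampled molecule, so input =
    ``num_fragments * end_depth * 2 * read_len`` for an average end depth of
    ``end_depth`` with paired reads of ``read_len`` bases (defaults: 12x
    paired 50-bp reads).
    """
    if num_fragments <= 0 or end_depth <= 0 or read_len <= 0:
        raise ValueError("estimate_input requires positive arguments")
    return float(num_fragments) * end_depth * 2 * read_len
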