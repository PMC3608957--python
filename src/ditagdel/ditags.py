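"""Translate paired-read alignments into restriction ditags.

A mate pair produced from one restriction fragment has one *anchor* read
whose restriction-facing end coincides with a cut coordinate (within a small
end-repair tolerance) and one *distal* read displaced 100-200 bp into the
fragment by the nick-translation step of the mate-pair protocol.  Anchoring
is purely geometric (distance to cut plus extension direction), so the same
rules serve SOLiD- and Illumina-style libraries.

Each assigned end becomes a ``TagID`` (#chrom-serial-side); a pair becomes a
``Ditag`` joining side 2 of site N to side 1 of site M > N.  ``skip =
M - N - 1`` is the number of restriction sites jumped: 0 for the reference
structure, >= 2 for the deletion signature.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass

import numpy as np
import pysam

from .enzymes import EnzymeSpec
from .restriction import RefDitag, SiteIndex, TagID, median_lower


@dataclass(frozen=True)
class NickModel:
    """Geometry of the anchored/nick-translated read pair.

    ``anchor_tolerance`` absorbs end-repair wobble at the cut; the nick
    window brackets how far the distal read's restriction-facing end may sit
    inside the fragment (generously covering the protocol's ~100-200 bp).
    """

    anchor_tolerance: int = 2
    nick_lo: int = 50
    nick_hi: int = 300
    #: "advisory": a distal mate outside the nick window is still assigned to
    #: the nearest restriction-facing cut (the distal position confirms, not
    #: defines); "strict": such pairs are discarded.
    distal_mode: str = "advisory"

    def __post_init__(self) -> None:
        if not 0 <= self.nick_lo <= self.nick_hi:
            raise ValueError("nick window must satisfy 0 <= lo <= hi")
        if self.distal_mode not in ("advisory", "strict"):
            raise ValueError("distal_mode must be 'advisory' or 'strict'")


@dataclass(frozen=True)
class MateAlignment:
    """One aligned mate (1-based inclusive coordinates)."""

    chrom: str
    start: int
    end: int
    strand: str = "+"
    mapq: int = 60


@dataclass(frozen=True)
class AlignedPair:
    name: str
    mate1: MateAlignment
    mate2: MateAlignment


@dataclass
class Ditag:
    """An observed ditag: side 2 of site N joined to side 1 of site M > N."""

    chrom: str
    left_serial: int
    right_serial: int
    support: int = 1

    def __post_init__(self) -> None:
        if self.right_serial <= self.left_serial:
            raise ValueError("ditag requires right serial > left serial")
        if self.support < 1:
            raise ValueError("support must be >= 1")

    @property
    def left_tag(self) -> TagID:
        return TagID(self.chrom, self.left_serial, 2)

    @property
    def right_tag(self) -> TagID:
        return TagID(self.chrom, self.right_serial, 1)

    @property
    def skip(self) -> int:
        """Restriction sites jumped between the two tags."""
        return self.right_serial - self.left_serial - 1

    @property
    def is_reference_type(self) -> bool:
        return self.skip == 0

    @property
    def ditag_id(self) -> str:
        return f"{self.left_tag}/{self.right_tag}"

    @property
    def key(self) -> tuple[str, int, int]:
        return (self.chrom, self.left_serial, self.right_serial)


def parse_ditag_id(ditag_id: str, chrom_prefix: str = "chr") -> Ditag:
    """Parse the ``"7_50712_2/7_50719_1"`` dialect back into a Ditag."""
    left, right = ditag_id.split("/")
    lc, ls, lside = left.rsplit("_", 2)
    rc, rs, rside = right.rsplit("_", 2)
    if lc != rc or (lside, rside) != ("2", "1"):
        raise ValueError(f"malformed ditag id {ditag_id!r}")
    chrom = lc if lc.startswith(chrom_prefix) else chrom_prefix + lc
    return Ditag(chrom=chrom, left_serial=int(ls), right_serial=int(rs))


def _window_hits(cuts: np.ndarray, lo: float, hi: float) -> np.ndarray:
    """Indices i with lo <= cuts[i] <= hi."""
    return np.arange(
        np.searchsorted(cuts, lo, side="left"),
        np.searchsorted(cuts, hi, side="right"),
    )


def assign_tag_id(
    mate: MateAlignment,
    site_index: SiteIndex,
    enzyme: EnzymeSpec,
    model: NickModel,
    role: str = "anchor",
    partner: TagID | None = None,
) -> TagID | None:
    """Assign a restriction-end TagID to one mate, or None.

    * ``anchor`` role: the mate's restriction-facing end must coincide with
      a cut within ``anchor_tolerance``; a left-end match yields side 2
      (read extends downstream of the cut), a right-end match side 1.
    * ``distal`` role: the mate's restriction-facing end must sit inside the
      nick window of the fragment end opposite its partner's tag; requires
      ``partner``.

    Two qualifying sites (dense-site ambiguity) yield None.
    """
    cuts = site_index.cuts(enzyme)
    tol = model.anchor_tolerance
    if role == "anchor":
        # side 2: read starts at cut+1; side 1: read ends at the cut
        side2 = _window_hits(cuts, mate.start - 1 - tol, mate.start - 1 + tol)
        side1 = _window_hits(cuts, mate.end - tol, mate.end + tol)
        candidates = [(int(i) + 1, 2) for i in side2] + [(int(i) + 1, 1) for i in side1]
        if len(candidates) != 1:
            return None
        serial, side = candidates[0]
        return TagID(site_index.chrom, serial, side)
    if role == "distal":
        if partner is None:
            raise ValueError("distal assignment requires the partner's TagID")
        if partner.side == 2:
            # partner holds the left end; this mate sits nick_lo..nick_hi
            # left of some cut M with M > N
            hits = _window_hits(cuts, mate.end + model.nick_lo, mate.end + model.nick_hi)
            hits = [int(i) + 1 for i in hits if int(i) + 1 > partner.serial]
            side = 1
        else:
            hits = _window_hits(
                cuts, mate.start - 1 - model.nick_hi, mate.start - 1 - model.nick_lo
            )
            hits = [int(i) + 1 for i in hits if int(i) + 1 < partner.serial]
            side = 2
        if len(hits) == 1:
            return TagID(site_index.chrom, hits[0], side)
        if len(hits) == 0 and model.distal_mode == "advisory":
            # fall back to the nearest restriction-facing cut
            if side == 1:
                j = int(np.searchsorted(cuts, mate.end, side="right"))
                while j < len(cuts) and j + 1 <= partner.serial:
                    j += 1
                if j < len(cuts):
                    return TagID(site_index.chrom, j + 1, 1)
            else:
                j = int(np.searchsorted(cuts, mate.start - 1, side="left")) - 1
                while j >= 0 and j + 1 >= partner.serial:
                    j -= 1
                if j >= 0:
                    return TagID(site_index.chrom, j + 1, 2)
        return None
    raise ValueError(f"unknown role {role!r}")


def pair_to_ditag(
    pair: AlignedPair,
    site_indexes: dict[str, SiteIndex],
    enzyme: EnzymeSpec,
    model: NickModel,
) -> tuple[Ditag | None, str]:
    """Interpret one pair as a ditag; returns (ditag, reason).

    Reason is ``"ok"`` on success, else the discard category
    (``cross_chrom`` / ``unanchored`` / ``ambiguous`` / ``inconsistent``).
    """
    m1, m2 = pair.mate1, pair.mate2
    if m1.chrom != m2.chrom:
        return None, "cross_chrom"
    idx = site_indexes.get(m1.chrom)
    if idx is None:
        return None, "cross_chrom"

    a1 = assign_tag_id(m1, idx, enzyme, model, role="anchor")
    a2 = assign_tag_id(m2, idx, enzyme, model, role="anchor")
    if a1 is not None and a2 is not None:
        # both mates anchor exactly (degenerate zero-nick geometry)
        left, right = sorted((a1, a2), key=lambda t: t.serial)
        if left.side == 2 and right.side == 1 and right.serial > left.serial:
            return Ditag(m1.chrom, left.serial, right.serial), "ok"
        return None, "inconsistent"
    if a1 is None and a2 is None:
        return None, "unanchored"

    anchor_tag, distal_mate = (a1, m2) if a1 is not None else (a2, m1)
    distal_tag = assign_tag_id(
        distal_mate, idx, enzyme, model, role="distal", partner=anchor_tag
    )
    if distal_tag is None:
        return None, "inconsistent"
    if anchor_tag.side == 2:
        return Ditag(m1.chrom, anchor_tag.serial, distal_tag.serial), "ok"
    return Ditag(m1.chrom, distal_tag.serial, anchor_tag.serial), "ok"


def cluster_ditags(ditags) -> list[Ditag]:
    """Collapse identical (chrom, N, M) ditags, summing support.

    Output is deterministically ordered by (chrom, N, M).
    """
    support: Counter = Counter()
    for d in ditags:
        support[d.key] += d.support
    return [
        Ditag(chrom=c, left_serial=n, right_serial=m, support=s)
        for (c, n, m), s in sorted(support.items())
    ]


@dataclass
class ExtractionResult:
    clusters: list[Ditag]
    counters: dict[str, int]

    def reconciles(self) -> bool:
        """pairs_total == emitted + every discard category."""
        c = self.counters
        discards = sum(
            v for k, v in c.items() if k not in ("pairs_total", "emitted")
        )
        return c["pairs_total"] == c["emitted"] + discards


def pairs_from_sam(path: str):
    """Yield AlignedPairs from a SAM/BAM file, pairing mates by read name.

    Pairs with an unmapped mate are dropped upstream by the mapped-only
    requirement; singletons remaining at EOF are counted by the caller.
    """
    pending: dict[str, MateAlignment] = {}
    with pysam.AlignmentFile(path, check_sq=False) as sam:
        for read in sam:
            if read.is_unmapped or read.is_secondary or read.is_supplementary:
                continue
            mate = MateAlignment(
                chrom=read.reference_name,
                start=read.reference_start + 1,
                end=read.reference_end,
                strand="-" if read.is_reverse else "+",
                mapq=read.mapping_quality,
            )
            other = pending.pop(read.query_name, None)
            if other is None:
                pending[read.query_name] = mate
            else:
                yield AlignedPair(read.query_name, other, mate)
    for name in pending:  # orphaned mates (partner unmapped/absent)
        yield AlignedPair(name, None, None)


def extract_ditags(
    pairs,
    site_indexes: dict[str, SiteIndex],
    enzyme: EnzymeSpec,
    model: NickModel | None = None,
    min_mapq: int = 0,
    dedup: bool = True,
) -> ExtractionResult:
    """Run the full pair -> ditag -> cluster path over an iterable of pairs.

    ``dedup`` collapses read pairs with identical coordinates on both mates
    to one support unit (PCR-duplicate guard).
    """
    model = model or NickModel()
    counters: dict[str, int] = defaultdict(int)
    seen: set = set()
    ditags: list[Ditag] = []
    for pair in pairs:
        counters["pairs_total"] += 1
        if pair.mate1 is None or pair.mate2 is None:
            counters["orphan"] += 1
            continue
        if min(pair.mate1.mapq, pair.mate2.mapq) < min_mapq:
            counters["low_mapq"] += 1
            continue
        if dedup:
            coords = tuple(
                sorted(
                    (
                        (m.chrom, m.start, m.end, m.strand)
                        for m in (pair.mate1, pair.mate2)
                    )
                )
            )
            if coords in seen:
                counters["duplicate"] += 1
                continue
            seen.add(coords)
        ditag, reason = pair_to_ditag(pair, site_indexes, enzyme, model)
        if ditag is None:
            counters[reason] += 1
        else:
            counters["emitted"] += 1
            ditags.append(ditag)
    counters.setdefault("emitted", 0)
    return ExtractionResult(clusters=cluster_ditags(ditags), counters=dict(counters))


@dataclass
class DitagSummary:
    """Coverage bookkeeping over the Ref-Ditag catalog."""

    refditags_total: int
    refditags_observed: int
    mean_depth: float
    covered_bp: int
    genome_size: int
    median_fragment_length: float

    @property
    def fraction_observed(self) -> float:
        return self.refditags_observed / self.refditags_total if self.refditags_total else 0.0

    @property
    def covered_fraction(self) -> float:
        return self.covered_bp / self.genome_size if self.genome_size else 0.0


def summarize_ditags(
    clusters: list[Ditag],
    catalog: list[RefDitag],
    genome_size: int,
) -> DitagSummary:
    """Fraction of Ref-Ditags observed, their mean depth, covered genome and
    median observed fragment length."""
    by_key = {(r.chrom, r.left_tag.serial, r.right_tag.serial): r for r in catalog}
    observed: list[tuple[RefDitag, int]] = []
    for d in clusters:
        if d.is_reference_type and d.key in by_key:
            observed.append((by_key[d.key], d.support))
    if not observed:
        return DitagSummary(len(by_key), 0, 0.0, 0, genome_size, 0.0)
    depths = [s for _, s in observed]
    lengths = [r.fragment.length for r, _ in observed]
    covered = sum(lengths)
    return DitagSummary(
        refditags_total=len(by_key),
        refditags_observed=len(observed),
        mean_depth=float(np.mean(depths)),
        covered_bp=covered,
        genome_size=genome_size,
        median_fragment_length=median_lower(lengths),
    )
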