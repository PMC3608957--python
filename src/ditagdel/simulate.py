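"""Seeded diploid simulator for restriction-ditag sequencing.

Emulates the data-generating process end to end so every pipeline stage is
testable offline: a random genome with recognition sites planted at a
target spacing into otherwise site-free background; planted medium-sized
deletions (each swallowing a run of consecutive sites), site-killing SNPs
(the point-mutation confounder of criterion 1), optional tandem-layout
duplications (for the ePCR uniqueness filter); and mate pairs with one read
anchored exactly at a cut and the other nick-translated 100-200 bp into the
fragment, with smaller fragments over-sampled (circularisation bias) and
per-molecule partial-digestion failures.

Alignments are emitted directly in reference coordinates (mapping is out of
scope and determinism is required); reads never cross a deletion breakpoint
— such molecules are dropped with a counter, as their real counterparts
would fail to map.  Every stage draws from a seed-derived generator, so the
same config reproduces every output byte for byte.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field, asdict

import numpy as np
import pysam
import yaml

from .enzymes import EnzymeSpec, get_enzyme
from .restriction import SiteIndex, scan_sites

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


class SimulationError(ValueError):
    pass


@dataclass
class SimConfig:
    seed: int = 0
    chrom_length: int = 1_000_000
    n_chroms: int = 1
    gc: float = 0.41
    enzyme: str = "TaqI"
    #: target inter-site spacing (bp); sites are planted exactly on this
    #: lattice (offset spacing//2) unless jitter is requested.
    spacing: int = 1_000
    spacing_jitter: int = 0
    n_deletions: int = 20
    del_size_range: tuple[int, int] = (100, 10_000)
    del_min_sites: int = 2
    del_max_sites: int = 6
    hom_fraction: float = 0.5
    #: site-killing SNPs planted into recognition sites on both haplotypes.
    n_snp_sites: int = 10
    snp_known_fraction: float = 1.0
    #: pairs of *adjacent* killed sites (the skip-2 confounder); known=True
    #: puts them in the dbSNP-style file so criterion 1 rejects them.
    adjacent_snp_pairs: int = 0
    adjacent_pairs_known: bool = True
    n_duplications: int = 0
    #: consecutive fragments per duplicated block (>= 3 lets a skip-2
    #: candidate sit entirely inside the repeat).
    duplication_span: int = 3
    #: per-molecule probability that a given site fails to cut.
    partial_digestion: float = 0.02
    partial_site_overrides: dict = field(default_factory=dict)  # (chrom, serial) -> p
    #: mean read pairs per fragment, summed over the two haplotypes.
    depth: float = 6.0
    depth_mode: str = "poisson"  # "poisson" | "fixed"
    size_bias: bool = True
    size_bias_lambda: float = 1_500.0
    nick_range: tuple[int, int] = (100, 200)
    read_len: int = 50

    def __post_init__(self) -> None:
        for p in (self.gc, self.hom_fraction, self.snp_known_fraction,
                  self.partial_digestion):
            if not 0.0 <= p <= 1.0:
                raise SimulationError(f"probability {p} outside [0, 1]")
        if self.depth_mode not in ("poisson", "fixed"):
            raise SimulationError("depth_mode must be 'poisson' or 'fixed'")

    @property
    def margin_min(self) -> int:
        """Minimum undeleted flank inside a fragment so that both the anchor
        and the nick-translated read always fit and map."""
        return self.nick_range[1] + self.read_len + 10


@dataclass(frozen=True)
class DeletionTruth:
    chrom: str
    start: int  # 1-based inclusive
    end: int
    zygosity: str
    site_serials: tuple[int, ...]

    @property
    def size(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class SnpTruth:
    chrom: str
    position: int
    known: bool


@dataclass(frozen=True)
class DuplicationTruth:
    chrom: str
    src_left_serial: int  # duplicated fragment lies between this site and the next
    dst_left_serial: int
    window: tuple[int, int]


@dataclass
class TruthSet:
    deletions: list[DeletionTruth]
    snps: list[SnpTruth]
    duplications: list[DuplicationTruth]
    #: per haplotype: serials surviving on each chromosome
    surviving_serials: list[dict[str, list[int]]]
    #: per haplotype: the exhaustive fragment/ditag list (chrom, N, M)
    expected_fragments: list[list[tuple[str, int, int]]]


def _random_bases(rng: np.random.Generator, n: int, gc: float) -> np.ndarray:
    at = (1.0 - gc) / 2.0
    probs = [at, gc / 2.0, gc / 2.0, at]  # A C G T
    return _BASES[rng.choice(4, size=n, p=probs)]


def _clean_sequence(
    arr: np.ndarray,
    enzyme: EnzymeSpec,
    planted: set[int],
    protected: list[tuple[int, int]],
    rng: np.random.Generator,
    max_rounds: int = 200,
) -> None:
    """Mutate away recognition matches that are not planted sites.

    Never touches planted footprints or protected windows (duplicated
    segments must stay identical); a base just outside a protected window is
    used when an accidental match straddles its boundary.
    """
    pattern = enzyme.regex()
    planted_blocked = set()
    for p in planted:
        planted_blocked.update(range(p, p + enzyme.length))

    def blocked(pos1: int) -> bool:
        if pos1 in planted_blocked:
            return True
        return any(lo <= pos1 <= hi for lo, hi in protected)

    for _ in range(max_rounds):
        seq = arr.tobytes().decode("ascii")
        extra = [
            m.start() + 1 for m in pattern.finditer(seq) if m.start() + 1 not in planted
        ]
        if not extra:
            return
        for pos in extra:
            candidates = [
                q for q in range(pos, pos + enzyme.length) if not blocked(q)
            ]
            if not candidates:
                raise SimulationError(
                    "cannot break accidental site inside protected window"
                )
            q = candidates[len(candidates) // 2]
            current = arr[q - 1]
            choices = _BASES[_BASES != current]
            arr[q - 1] = rng.choice(choices)
    raise SimulationError("site cleaning did not converge")


@dataclass
class GenomeBundle:
    genome: dict[str, str]
    site_indexes: dict[str, SiteIndex]
    duplications: list[DuplicationTruth]


def simulate_genome(config: SimConfig) -> GenomeBundle:
    """Random genome with recognition sites planted at the target spacing.

    The background is scrubbed free of accidental sites, so the planted
    positions are exactly what :func:`scan_sites` recovers.
    """
    enzyme = get_enzyme(config.enzyme)
    if set(enzyme.recognition) - set("ACGT"):
        raise SimulationError("simulation requires a non-degenerate recognition")
    if config.spacing <= enzyme.length:
        raise SimulationError("spacing must exceed the recognition length")
    rng = np.random.default_rng([0, config.seed])
    rec = np.frombuffer(enzyme.recognition.encode(), dtype=np.uint8)
    genome: dict[str, str] = {}
    site_indexes: dict[str, SiteIndex] = {}
    duplications: list[DuplicationTruth] = []
    for ci in range(config.n_chroms):
        chrom = f"chr{ci + 1}"
        L = config.chrom_length
        arr = _random_bases(rng, L, config.gc).copy()
        offset = config.spacing // 2
        positions = []
        p = offset
        while p + enzyme.length - 1 <= L:
            q = p
            if config.spacing_jitter:
                q += int(rng.integers(-config.spacing_jitter, config.spacing_jitter + 1))
                q = max(1, min(q, L - enzyme.length + 1))
            positions.append(q)
            p += config.spacing
        for q in positions:
            arr[q - 1 : q - 1 + enzyme.length] = rec
        _clean_sequence(arr, enzyme, set(positions), [], rng)
        if ci == 0 and config.n_duplications:
            # copy cleaned content, then scrub any match born at a junction
            duplications, protected = _plant_duplications(
                arr, chrom, positions, enzyme, config
            )
            _clean_sequence(arr, enzyme, set(positions), protected, rng)
        genome[chrom] = arr.tobytes().decode("ascii")
        site_indexes[chrom] = SiteIndex(
            chrom=chrom, positions=np.asarray(positions, dtype=np.int64)
        )
        found = scan_sites(genome[chrom], enzyme, chrom)
        if not np.array_equal(found.positions, site_indexes[chrom].positions):
            raise SimulationError(f"{chrom}: planted sites not clean after scrub")
    return GenomeBundle(genome, site_indexes, duplications)


def _plant_duplications(arr, chrom, positions, enzyme, config):
    """Copy whole fragments (with flanks) onto distant, identically spaced
    loci so that their tags become two-copy repeats."""
    if config.spacing_jitter:
        raise SimulationError("duplication planting requires zero spacing jitter")
    n = len(positions)
    pad = 200
    span = config.duplication_span
    dups, protected = [], []
    for d in range(config.n_duplications):
        src = n // 4 + (span + 2) * d
        dst = 3 * n // 4 + (span + 2) * d
        if dst + span >= n:
            raise SimulationError("not enough sites to plant duplications")
        s0 = positions[src] - pad
        s1 = positions[src + span] + enzyme.length - 1 + pad
        t0 = positions[dst] - pad
        arr[t0 - 1 : t0 - 1 + (s1 - s0 + 1)] = arr[s0 - 1 : s1]
        dups.append(
            DuplicationTruth(
                chrom=chrom,
                src_left_serial=src + 1,
                dst_left_serial=dst + 1,
                window=(t0, t0 + (s1 - s0)),
            )
        )
        protected += [(s0, s1), (t0, t0 + (s1 - s0))]
    return dups, protected


def plant_variants(
    bundle: GenomeBundle, config: SimConfig
) -> tuple[list[dict[str, str]], TruthSet]:
    """Apply deletions, site-killing SNPs and zygosity to two haplotypes.

    Homozygous deletions hit both haplotypes, heterozygous only haplotype 1;
    SNPs hit both (homozygous site loss, the criterion-1 confounder).
    Returns ([hap1 sequences, hap2 sequences], truth).
    """
    rng = np.random.default_rng([1, config.seed])
    enzyme = get_enzyme(config.enzyme)
    reclen = enzyme.length
    snps: list[SnpTruth] = []
    killed: dict[str, set[int]] = {c: set() for c in bundle.genome}
    deletions: list[DeletionTruth] = []

    excluded: dict[str, set[int]] = {c: set() for c in bundle.genome}
    for dup in bundle.duplications:
        for s in (dup.src_left_serial, dup.dst_left_serial):
            excluded[dup.chrom].update(
                range(max(1, s - 1), s + config.duplication_span + 2)
            )

    chroms = sorted(bundle.genome)

    # --- site-killing SNPs -------------------------------------------------
    def _kill(chrom: str, serial: int, known: bool):
        killed[chrom].add(serial)
        pos = bundle.site_indexes[chrom].position(serial)
        snps.append(SnpTruth(chrom=chrom, position=pos + 1, known=known))

    planted_pairs: list[tuple[str, int]] = []
    for _ in range(config.adjacent_snp_pairs):
        chrom = chroms[int(rng.integers(len(chroms)))]
        n = bundle.site_indexes[chrom].n_sites
        for _attempt in range(100):
            s = int(rng.integers(2, n - 2))
            region = set(range(s - 1, s + 3))
            if region & killed[chrom] or region & excluded[chrom]:
                continue
            _kill(chrom, s, config.adjacent_pairs_known)
            _kill(chrom, s + 1, config.adjacent_pairs_known)
            planted_pairs.append((chrom, s))
            break
    for _ in range(config.n_snp_sites):
        chrom = chroms[int(rng.integers(len(chroms)))]
        n = bundle.site_indexes[chrom].n_sites
        for _attempt in range(100):
            s = int(rng.integers(2, n))
            if s in killed[chrom] or s in excluded[chrom]:
                continue
            _kill(chrom, s, bool(rng.random() < config.snp_known_fraction))
            break

    # --- deletions ---------------------------------------------------------
    used: dict[str, set[int]] = {c: set() for c in bundle.genome}
    margin = config.margin_min
    lo_size, hi_size = config.del_size_range
    for _ in range(config.n_deletions):
        placed = False
        for _attempt in range(200):
            chrom = chroms[int(rng.integers(len(chroms)))]
            idx = bundle.site_indexes[chrom]
            n = idx.n_sites
            if n < config.del_min_sites + 2:
                continue
            k_hi = min(config.del_max_sites, max(config.del_min_sites,
                                                 hi_size // config.spacing - 1))
            k = int(rng.integers(config.del_min_sites, k_hi + 1))
            s = int(rng.integers(2, n - k))  # first contained serial
            region = set(range(s - 1, s + k + 1))  # incl. flanks
            blockers = killed[chrom] | excluded[chrom] | used[chrom]
            if region & blockers:
                continue
            c_prev = idx.cut(s - 1, enzyme)
            c_next = idx.cut(s + k, enzyme)
            a_lo, a_hi = c_prev + margin + 1, idx.position(s)
            b_lo, b_hi = idx.position(s + k - 1) + reclen - 1, c_next - margin
            if a_lo > a_hi or b_lo > b_hi:
                continue
            a = int(rng.integers(a_lo, a_hi + 1))
            b = int(rng.integers(b_lo, b_hi + 1))
            if not lo_size <= b - a + 1 <= hi_size:
                continue
            zyg = "homozygous" if rng.random() < config.hom_fraction else "heterozygous"
            deletions.append(
                DeletionTruth(chrom, a, b, zyg, tuple(range(s, s + k)))
            )
            used[chrom].update(range(s - 1, s + k + 1))
            placed = True
            break
        if not placed:
            raise SimulationError("could not place all requested deletions")
    deletions.sort(key=lambda d: (d.chrom, d.start))

    # --- haplotype sequences ----------------------------------------------
    base: dict[str, np.ndarray] = {
        c: np.frombuffer(s.encode(), dtype=np.uint8).copy()
        for c, s in bundle.genome.items()
    }
    pattern = enzyme.regex()
    for snp in snps:  # applied to both haplotypes via the shared base copy
        arr = base[snp.chrom]
        orig = arr[snp.position - 1]
        for b in _BASES[_BASES != orig]:
            arr[snp.position - 1] = b
            lo = max(0, snp.position - 1 - reclen)
            hi = min(len(arr), snp.position - 1 + reclen)
            window = arr[lo:hi].tobytes().decode("ascii")
            if not pattern.search(window):
                break
        else:  # pragma: no cover - all three substitutions re-create a site
            raise SimulationError("could not kill site without creating another")

    haplotypes: list[dict[str, str]] = []
    for hap in (0, 1):
        seqs = {}
        for chrom, arr in base.items():
            keep = np.ones(len(arr), dtype=bool)
            for d in deletions:
                if d.chrom != chrom:
                    continue
                if hap == 1 and d.zygosity == "heterozygous":
                    continue
                keep[d.start - 1 : d.end] = False
            seqs[chrom] = arr[keep].tobytes().decode("ascii")
        haplotypes.append(seqs)

    surviving: list[dict[str, list[int]]] = []
    expected: list[list[tuple[str, int, int]]] = []
    for hap in (0, 1):
        per_chrom: dict[str, list[int]] = {}
        frags: list[tuple[str, int, int]] = []
        for chrom in chroms:
            idx = bundle.site_indexes[chrom]
            gone = set(killed[chrom])
            for d in deletions:
                if d.chrom != chrom:
                    continue
                if hap == 1 and d.zygosity == "heterozygous":
                    continue
                gone.update(d.site_serials)
            serials = [s for s in range(1, idx.n_sites + 1) if s not in gone]
            per_chrom[chrom] = serials
            frags += [
                (chrom, serials[i], serials[i + 1]) for i in range(len(serials) - 1)
            ]
        surviving.append(per_chrom)
        expected.append(frags)

    truth = TruthSet(
        deletions=deletions,
        snps=snps,
        duplications=list(bundle.duplications),
        surviving_serials=surviving,
        expected_fragments=expected,
    )
    return haplotypes, truth


@dataclass(frozen=True)
class PairRecord:
    qname: str
    chrom: str
    pos1: int  # 1-based leftmost, mate 1 (anchor)
    strand1: str
    pos2: int  # mate 2 (distal)
    strand2: str
    read_len: int


@dataclass
class PairSimResult:
    pairs: list[PairRecord]
    expected_ditags: Counter  # (chrom, N, M) -> molecule count
    counters: dict[str, int]


def simulate_pairs(
    bundle: GenomeBundle, truth: TruthSet, config: SimConfig
) -> PairSimResult:
    """Sample mate pairs from the diploid per the library geometry.

    Per haplotype, fragments between consecutive surviving sites are sampled
    with an exp(-len/lambda) size bias at half the configured depth; each
    molecule may extend over partially digested sites; one read anchors
    exactly at one cut, the other sits a nick offset inside the opposite
    end.  Reads that would cross a deletion breakpoint are dropped and
    counted, as are fragments shorter than the read length.
    """
    rng = np.random.default_rng([2, config.seed])
    enzyme = get_enzyme(config.enzyme)
    nick_lo, nick_hi = config.nick_range
    rl = config.read_len
    counters = {"emitted": 0, "too_short": 0, "breakpoint": 0}
    pairs: list[PairRecord] = []
    expected: Counter = Counter()
    serial = 0

    for hap in (0, 1):
        for chrom in sorted(bundle.genome):
            idx = bundle.site_indexes[chrom]
            S = truth.surviving_serials[hap][chrom]
            if len(S) < 2:
                continue
            cuts = {s: idx.cut(s, enzyme) for s in S}
            dels = sorted(
                (d.start, d.end)
                for d in truth.deletions
                if d.chrom == chrom
                and not (hap == 1 and d.zygosity == "heterozygous")
            )
            del_starts = np.asarray([a for a, _ in dels], dtype=np.int64)
            del_cum = np.cumsum([b - a + 1 for a, b in dels]) if dels else np.empty(0)

            def deleted_before(x: int) -> int:
                # total deleted bases at coordinates <= x (deletions never
                # straddle a surviving cut, so partial overlap cannot occur)
                j = int(np.searchsorted(del_starts, x, side="right"))
                return int(del_cum[j - 1]) if j else 0

            def segments(cl: int, cr: int) -> tuple[int, int, int]:
                """(sample length, left contiguous flank, right flank)."""
                inside = [(a, b) for a, b in dels if cl < a and b <= cr]
                sample = (cr - cl) - (deleted_before(cr) - deleted_before(cl))
                if not inside:
                    return sample, cr - cl, cr - cl
                return sample, inside[0][0] - 1 - cl, cr - inside[-1][1]

            frag_bounds = [(S[i], S[i + 1]) for i in range(len(S) - 1)]
            lengths = np.asarray(
                [segments(cuts[n], cuts[m])[0] for n, m in frag_bounds], dtype=float
            )
            if config.size_bias:
                w = np.exp(-lengths / config.size_bias_lambda)
            else:
                w = np.ones_like(lengths)
            w_mean = w.mean() if len(w) else 1.0
            per_hap_depth = config.depth / 2.0

            def p_fail(s: int) -> float:
                return float(
                    config.partial_site_overrides.get(
                        (chrom, s), config.partial_digestion
                    )
                )

            for i, (n0, m0) in enumerate(frag_bounds):
                if config.depth_mode == "fixed":
                    n_pairs = int(round(per_hap_depth))
                else:
                    n_pairs = int(rng.poisson(per_hap_depth * w[i] / w_mean))
                for _ in range(n_pairs):
                    li, ri = i, i + 1
                    while li > 0 and rng.random() < p_fail(S[li]):
                        li -= 1
                    while ri < len(S) - 1 and rng.random() < p_fail(S[ri]):
                        ri += 1
                    N, M = S[li], S[ri]
                    cl, cr = cuts[N], cuts[M]
                    sample_len, lseg, rseg = segments(cl, cr)
                    if sample_len < rl:
                        counters["too_short"] += 1
                        continue
                    u = int(rng.integers(nick_lo, nick_hi + 1))
                    anchor_left = bool(rng.random() < 0.5)
                    if anchor_left:
                        if rl > lseg or u + rl > rseg:
                            counters["breakpoint"] += 1
                            continue
                        p1, s1 = cl + 1, "+"
                        p2, s2 = cr - u - rl + 1, "-"
                    else:
                        if rl > rseg or u + rl > lseg:
                            counters["breakpoint"] += 1
                            continue
                        p1, s1 = cr - rl + 1, "-"
                        p2, s2 = cl + 1 + u, "+"
                    serial += 1
                    pairs.append(
                        PairRecord(
                            qname=f"sim{serial}",
                            chrom=chrom,
                            pos1=p1,
                            strand1=s1,
                            pos2=p2,
                            strand2=s2,
                            read_len=rl,
                        )
                    )
                    expected[(chrom, N, M)] += 1
                    counters["emitted"] += 1
    return PairSimResult(pairs=pairs, expected_ditags=expected, counters=counters)


def write_sam(
    pairs: list[PairRecord], genome: dict[str, str], path: str
) -> None:
    """Coordinate-sorted SAM with both mates of every simulated pair."""
    chroms = sorted(genome)
    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": c, "LN": len(genome[c])} for c in chroms],
    }
    tid = {c: i for i, c in enumerate(chroms)}
    reads = []
    for pr in pairs:
        for mate, (pos, strand, mpos, mstrand) in enumerate(
            [(pr.pos1, pr.strand1, pr.pos2, pr.strand2),
             (pr.pos2, pr.strand2, pr.pos1, pr.strand1)]
        ):
            a = pysam.AlignedSegment()
            a.query_name = pr.qname
            a.reference_id = tid[pr.chrom]
            a.reference_start = pos - 1
            a.cigarstring = f"{pr.read_len}M"
            a.mapping_quality = 60
            flag = 0x1 | 0x2 | (0x40 if mate == 0 else 0x80)
            if strand == "-":
                flag |= 0x10
            if mstrand == "-":
                flag |= 0x20
            a.flag = flag
            a.next_reference_id = tid[pr.chrom]
            a.next_reference_start = mpos - 1
            a.template_length = 0
            seq = genome[pr.chrom][pos - 1 : pos - 1 + pr.read_len]
            a.query_sequence = seq
            a.query_qualities = pysam.qualitystring_to_array("I" * len(seq))
            reads.append(a)
    reads.sort(key=lambda r: (r.reference_id, r.reference_start, r.query_name))
    with pysam.AlignmentFile(path, "wh", header=header) as out:
        for r in reads:
            out.write(r)


def write_fastq(
    pairs: list[PairRecord], genome: dict[str, str], path1: str, path2: str
) -> None:
    """Optional paired FASTQ export for users who want to run a real
    aligner; reverse-strand reads are reverse-complemented (5'->3')."""
    from Bio.Seq import reverse_complement

    with open(path1, "w") as r1, open(path2, "w") as r2:
        for pr in pairs:
            for fh, pos, strand in ((r1, pr.pos1, pr.strand1),
                                    (r2, pr.pos2, pr.strand2)):
                seq = genome[pr.chrom][pos - 1 : pos - 1 + pr.read_len]
                if strand == "-":
                    seq = reverse_complement(seq)
                fh.write(f"@{pr.qname}\n{seq}\n+\n{'I' * len(seq)}\n")


@dataclass
class SimulationResult:
    config: SimConfig
    bundle: GenomeBundle
    haplotypes: list[dict[str, str]]
    truth: TruthSet
    pairsim: PairSimResult


def simulate(config: SimConfig) -> SimulationResult:
    """Run the whole generator: genome, variants, mate pairs."""
    bundle = simulate_genome(config)
    haplotypes, truth = plant_variants(bundle, config)
    pairsim = simulate_pairs(bundle, truth, config)
    return SimulationResult(config, bundle, haplotypes, truth, pairsim)


def write_outputs(result: SimulationResult, outdir: str) -> dict[str, str]:
    """Write FASTA / SAM / truth BED / dbSNP BED / expected-ditag TSV /
    config YAML into ``outdir``; returns the path map."""
    import os

    from .io import write_fasta

    os.makedirs(outdir, exist_ok=True)
    paths = {
        "fasta": os.path.join(outdir, "genome.fa"),
        "sam": os.path.join(outdir, "pairs.sam"),
        "deletions": os.path.join(outdir, "truth_deletions.bed"),
        "snps": os.path.join(outdir, "dbsnp.bed"),
        "expected": os.path.join(outdir, "expected_ditags.tsv"),
        "config": os.path.join(outdir, "sim_config.yaml"),
    }
    write_fasta(result.bundle.genome, paths["fasta"])
    write_sam(result.pairsim.pairs, result.bundle.genome, paths["sam"])
    with open(paths["deletions"], "w") as fh:
        for d in result.truth.deletions:
            fh.write(f"{d.chrom}\t{d.start - 1}\t{d.end}\t{d.zygosity}\n")
    with open(paths["snps"], "w") as fh:
        for s in result.truth.snps:
            if s.known:
                fh.write(f"{s.chrom}\t{s.position - 1}\t{s.position}\n")
    with open(paths["expected"], "w") as fh:
        fh.write("chrom\tleft_serial\tright_serial\tmolecules\n")
        for (c, n, m), k in sorted(result.pairsim.expected_ditags.items()):
            fh.write(f"{c}\t{n}\t{m}\t{k}\n")
    cfg = asdict(result.config)
    cfg["partial_site_overrides"] = {
        f"{c}:{s}": p for (c, s), p in result.config.partial_site_overrides.items()
    }
    with open(paths["config"], "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)
    return paths
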