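"""Format layer: FASTA, SAM-adjacent tables, BED/GFF/VCF and coordinate
conventions.

Internally every interval is 1-based inclusive (the convention used for
breakpoints, where size = end - start + 1).  BED is 0-based half-open, GFF
1-based inclusive; conversions are bit-exact and round-trip.
"""

from __future__ import annotations

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .caller import DeletionCall, SnpSet, deletion_size
from .ditags import Ditag
from .resolution import DEFAULT_SIZE_WINDOW, DeletionRecord, DeletionSet
from .restriction import Fragment, RefDitag, SiteIndex


class FormatError(ValueError):
    pass


def _read_table(path: str, header=None) -> pd.DataFrame:
    """Tab-separated table; an empty file yields an empty frame."""
    try:
        return pd.read_csv(path, sep="\t", header=header, comment="#")
    except pd.errors.EmptyDataError:
        return pd.DataFrame()


# ---------------------------------------------------------------------------
# coordinate conventions

def convert_coordinates(
    record: tuple[str, int, int], frm: str, to: str
) -> tuple[str, int, int]:
    """Convert an interval between bed / gff / internal conventions.

    ``internal`` and ``gff`` are 1-based inclusive; ``bed`` is 0-based
    half-open.  Round trips are identities.
    """
    chrom, start, end = record
    if frm not in ("bed", "gff", "internal") or to not in ("bed", "gff", "internal"):
        raise FormatError(f"unknown convention {frm!r} or {to!r}")
    if frm == "bed":
        if start < 0 or end <= start:
            raise FormatError(f"invalid BED interval {record}")
        start, end = start + 1, end  # to 1-based inclusive
    else:
        if start < 1 or end < start:
            raise FormatError(f"invalid 1-based interval {record}")
    if to == "bed":
        return chrom, start - 1, end
    return chrom, start, end


# ---------------------------------------------------------------------------
# FASTA

def read_fasta(path: str) -> dict[str, str]:
    """Multi-record FASTA (wrapped lines) as an uppercase dict."""
    genome = {}
    try:
        for rec in SeqIO.parse(path, "fasta"):
            genome[rec.id] = str(rec.seq).upper()
    except (ValueError, UnicodeDecodeError) as exc:
        raise FormatError(f"cannot parse FASTA {path}: {exc}") from exc
    if not genome:
        raise FormatError(f"no FASTA records in {path}")
    return genome


def write_fasta(genome: dict[str, str], path: str) -> None:
    records = [
        SeqRecord(Seq(seq), id=chrom, description="") for chrom, seq in genome.items()
    ]
    SeqIO.write(records, path, "fasta")


# ---------------------------------------------------------------------------
# deletion test sets (resolution module inputs)

def read_deletions(
    path: str,
    fmt: str | None = None,
    size_window=DEFAULT_SIZE_WINDOW,
) -> DeletionSet:
    """Load a deletion set from BED, GFF or a 2-column-style TSV.

    Format is auto-detected from the extension unless ``fmt`` is given.
    BED coordinates are converted to 1-based inclusive on load.
    """
    if fmt is None:
        lower = path.lower()
        if lower.endswith(".bed"):
            fmt = "bed"
        elif lower.endswith((".gff", ".gff3", ".gtf")):
            fmt = "gff"
        else:
            fmt = "tsv"
    records = []
    if fmt == "bed":
        df = _read_table(path, header=None)
        for _, row in df.iterrows():
            chrom, start, end = convert_coordinates(
                (str(row[0]), int(row[1]), int(row[2])), "bed", "internal"
            )
            records.append(DeletionRecord(chrom, start, end))
    elif fmt == "gff":
        df = _read_table(path, header=None)
        if 0 < df.shape[1] < 5:
            raise FormatError(f"{path}: too few GFF columns")
        for _, row in df.iterrows():
            records.append(
                DeletionRecord(str(row[0]), int(row[3]), int(row[4]), str(row[2]))
            )
    elif fmt == "tsv":
        # DGV-style dialect: chrom, start, end in the first three columns,
        # 1-based inclusive, optional header line
        df = _read_table(path, header=0)
        if 0 < df.shape[1] < 3:
            raise FormatError(f"{path}: too few TSV columns")
        cols = df.columns[:3]
        for _, row in df.iterrows():
            records.append(
                DeletionRecord(str(row[cols[0]]), int(row[cols[1]]), int(row[cols[2]]))
            )
    else:
        raise FormatError(f"unknown deletion format {fmt!r}")
    return DeletionSet(records=records, size_window=size_window)


# ---------------------------------------------------------------------------
# SNP sets

def read_snps(path: str, fmt: str | None = None) -> SnpSet:
    """Known-SNP positions from BED (0-based) or VCF (1-based)."""
    if fmt is None:
        fmt = "vcf" if path.lower().endswith(".vcf") else "bed"
    positions = []
    if fmt == "bed":
        df = _read_table(path, header=None)
        for _, row in df.iterrows():
            positions.append((str(row[0]), int(row[1]) + 1))
    elif fmt == "vcf":
        import pysam

        with pysam.VariantFile(path) as vcf:
            for rec in vcf:
                positions.append((rec.chrom, rec.pos))
    else:
        raise FormatError(f"unknown SNP format {fmt!r}")
    return SnpSet(positions)


# ---------------------------------------------------------------------------
# tabular writers

def sites_to_bed(site_indexes: dict[str, SiteIndex], reclen: int, path: str) -> None:
    with open(path, "w") as fh:
        for chrom in sorted(site_indexes):
            for serial, pos in enumerate(site_indexes[chrom].positions, 1):
                c, s, e = convert_coordinates(
                    (chrom, int(pos), int(pos) + reclen - 1), "internal", "bed"
                )
                fh.write(f"{c}\t{s}\t{e}\tsite_{serial}\n")


def fragments_to_bed(fragments: list[Fragment], path: str) -> None:
    with open(path, "w") as fh:
        for f in fragments:
            c, s, e = convert_coordinates((f.chrom, f.start, f.end), "internal", "bed")
            fh.write(f"{c}\t{s}\t{e}\tfrag_{f.left_serial}_{f.right_serial}\n")


def catalog_to_tsv(catalog: list[RefDitag], path: str) -> None:
    rows = [
        {
            "chrom": r.chrom,
            "left_serial": r.left_tag.serial,
            "right_serial": r.right_tag.serial,
            "left_tag_id": str(r.left_tag),
            "right_tag_id": str(r.right_tag),
            "fragment_start": r.fragment.start,
            "fragment_end": r.fragment.end,
        }
        for r in catalog
    ]
    pd.DataFrame(
        rows,
        columns=[
            "chrom", "left_serial", "right_serial", "left_tag_id",
            "right_tag_id", "fragment_start", "fragment_end",
        ],
    ).to_csv(path, sep="\t", index=False)


def clusters_to_tsv(clusters: list[Ditag], path: str) -> None:
    rows = [
        {
            "chrom": d.chrom,
            "ditag_id": d.ditag_id,
            "left_serial": d.left_serial,
            "right_serial": d.right_serial,
            "skip": d.skip,
            "support": d.support,
        }
        for d in clusters
    ]
    pd.DataFrame(
        rows,
        columns=["chrom", "ditag_id", "left_serial", "right_serial", "skip", "support"],
    ).to_csv(path, sep="\t", index=False)


def calls_to_tsv(calls: list[DeletionCall], path: str) -> None:
    """Validation-table-style TSV: ditagID, breakpoints, DelSize, Notes."""
    rows = [
        {
            "ditagID": c.ditag_id,
            "Deletion breakpoints": c.breakpoints,
            "DelSize (bp)": deletion_size(c.outer_start, c.outer_end),
            "Notes": c.zygosity.capitalize(),
            "Support": c.support,
            "VariantFraction": round(c.variant_fraction, 4),
        }
        for c in calls
    ]
    pd.DataFrame(
        rows,
        columns=[
            "ditagID", "Deletion breakpoints", "DelSize (bp)", "Notes",
            "Support", "VariantFraction",
        ],
    ).to_csv(path, sep="\t", index=False)


def calls_to_vcf(
    calls: list[DeletionCall], contigs: dict[str, int], path: str
) -> None:
    """VCF 4.2 with symbolic <DEL> records at the outer bounds.

    The ditag resolves breakpoints only to the flanking cut coordinates, so
    CIPOS/CIEND span to the inner bounds (first/last skipped site).
    """
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##ALT=<ID=DEL,Description="Deletion">\n')
        fh.write('##INFO=<ID=SVTYPE,Number=1,Type=String,Description="SV type">\n')
        fh.write('##INFO=<ID=END,Number=1,Type=Integer,Description="End position">\n')
        fh.write('##INFO=<ID=SKIP,Number=1,Type=Integer,Description="Restriction sites skipped">\n')
        fh.write('##INFO=<ID=SUPPORT,Number=1,Type=Integer,Description="Supporting ditags">\n')
        fh.write('##INFO=<ID=VF,Number=1,Type=Float,Description="Variant locus fraction">\n')
        fh.write('##INFO=<ID=CIPOS,Number=2,Type=Integer,Description="Confidence around POS">\n')
        fh.write('##INFO=<ID=CIEND,Number=2,Type=Integer,Description="Confidence around END">\n')
        fh.write('##INFO=<ID=ZYG,Number=1,Type=String,Description="Zygosity guess">\n')
        for chrom in sorted(contigs):
            fh.write(f"##contig=<ID={chrom},length={contigs[chrom]}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for c in calls:
            info = (
                f"SVTYPE=DEL;END={c.outer_end};SKIP={c.skip};"
                f"SUPPORT={c.support};VF={c.variant_fraction:.4f};"
                f"CIPOS=0,{c.inner_start - c.outer_start};"
                f"CIEND={c.inner_end - c.outer_end},0;"
                f"ZYG={c.zygosity}"
            )
            fh.write(
                f"{c.chrom}\t{c.outer_start}\t{c.ditag_id.replace('/', '_')}\tN\t<DEL>"
                f"\t.\tPASS\t{info}\n"
            )


def resolution_report_to_tsv(reports, path: str) -> None:
    """One row per enzyme per size bin, plus the overall row."""
    rows = []
    for r in reports:
        rows.append(
            {
                "enzyme": r.enzyme,
                "bin": "all",
                "detectable": r.detectable,
                "total": r.total,
                "fraction": round(r.detection_resolution, 6),
            }
        )
        for (lo, hi), (det, tot) in r.bin_fractions.items():
            rows.append(
                {
                    "enzyme": r.enzyme,
                    "bin": f"[{lo},{hi})",
                    "detectable": det,
                    "total": tot,
                    "fraction": round(det / tot, 6),
                }
            )
    pd.DataFrame(rows, columns=["enzyme", "bin", "detectable", "total", "fraction"]).to_csv(
        path, sep="\t", index=False
    )
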