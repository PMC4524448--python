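"""Readers and writers for the pipeline's external formats.

All other modules exchange the dataclasses defined here: FASTQ records,
SAM records (text dialect; BAM accepted through the same pysam-backed
reader), a minimal transcript-annotation table (6-column TSV or GTF),
transcript blacklists, and the final gene-list table (CSV/TSV/HTML).

Coordinates are 1-based inclusive throughout (SAM convention); BED output
is converted to 0-based half-open inside the writers only.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import pandas as pd
import pysam
from Bio.SeqIO.QualityIO import FastqGeneralIterator

# SAM flag bits
FLAG_PAIRED = 0x1
FLAG_PROPER_PAIR = 0x2
FLAG_UNMAPPED = 0x4
FLAG_MATE_UNMAPPED = 0x8
FLAG_REVERSE = 0x10
FLAG_MATE_REVERSE = 0x20
FLAG_READ1 = 0x40
FLAG_READ2 = 0x80
FLAG_DUPLICATE = 0x400

_MATE_SUFFIX = re.compile(r"(?:/[12]|\.[12]|_[12])$")

_CIGAR_OP = re.compile(r"(\d+)([MIDNSHP=X])")


class FormatError(ValueError):
    """Malformed input file or record."""


@dataclass
class FastqRecord:
    read_id: str
    sequence: str
    qualities: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise FormatError(f"empty sequence for read {self.read_id!r}")
        if len(self.sequence) != len(self.qualities):
            raise FormatError(
                f"sequence/quality length mismatch for read {self.read_id!r}"
            )


@dataclass
class SamRecord:
    """One SAM alignment line. position is 1-based leftmost (0 if unmapped)."""

    read_id: str
    flag: int
    reference: str
    position: int
    mapq: int = 0
    cigar: str = "*"
    rnext: str = "*"
    pnext: int = 0
    tlen: int = 0
    sequence: str = "*"
    qualities: str = "*"
    mismatches: int | None = None  # NM tag

    # -- flag accessors -------------------------------------------------
    @property
    def is_paired(self) -> bool:
        return bool(self.flag & FLAG_PAIRED)

    @property
    def is_unmapped(self) -> bool:
        return bool(self.flag & FLAG_UNMAPPED)

    @property
    def mate_unmapped(self) -> bool:
        return bool(self.flag & FLAG_MATE_UNMAPPED)

    @property
    def is_reverse(self) -> bool:
        return bool(self.flag & FLAG_REVERSE)

    @property
    def mate_reverse(self) -> bool:
        return bool(self.flag & FLAG_MATE_REVERSE)

    @property
    def is_read1(self) -> bool:
        return bool(self.flag & FLAG_READ1)

    @property
    def is_read2(self) -> bool:
        return bool(self.flag & FLAG_READ2)

    @property
    def is_duplicate(self) -> bool:
        return bool(self.flag & FLAG_DUPLICATE)

    def set_duplicate(self, value: bool) -> None:
        if value:
            self.flag |= FLAG_DUPLICATE
        else:
            self.flag &= ~FLAG_DUPLICATE

    @property
    def reference_end(self) -> int:
        """1-based rightmost reference base covered by the alignment."""
        if self.is_unmapped or self.cigar == "*":
            return self.position
        return self.position + cigar_reference_length(self.cigar) - 1


def cigar_reference_length(cigar: str) -> int:
    """Number of reference bases consumed by a CIGAR string."""
    length = 0
    matched = 0
    for m in _CIGAR_OP.finditer(cigar):
        n, op = int(m.group(1)), m.group(2)
        matched += m.end() - m.start()
        if op in "MDN=X":
            length += n
    if matched != len(cigar):
        raise FormatError(f"malformed CIGAR {cigar!r}")
    return length


@dataclass(frozen=True)
class TranscriptAnnotation:
    transcript_id: str
    gene_id: str
    gene_name: str
    chromosome: str
    strand: str
    three_prime_end: int
    biotype: str = "protein_coding"

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-"}:
            raise FormatError(f"bad strand {self.strand!r}")


# ---------------------------------------------------------------------------
# FASTQ
# ---------------------------------------------------------------------------

def strip_mate_suffix(read_id: str) -> str:
    return _MATE_SUFFIX.sub("", read_id)


def read_fastq(path: str | Path) -> Iterator[FastqRecord]:
    with open(path) as handle:
        for title, seq, qual in FastqGeneralIterator(handle):
            yield FastqRecord(title.split()[0], seq.upper(), qual)


def read_fastq_pairs(
    path1: str | Path, path2: str | Path
) -> Iterator[tuple[FastqRecord, FastqRecord]]:
    """Yield lockstep read pairs; IDs must match after mate-suffix stripping."""
    it1, it2 = read_fastq(path1), read_fastq(path2)
    sentinel = object()
    while True:
        r1 = next(it1, sentinel)
        r2 = next(it2, sentinel)
        if r1 is sentinel and r2 is sentinel:
            return
        if r1 is sentinel or r2 is sentinel:
            raise FormatError("FASTQ files have unequal record counts")
        id1 = strip_mate_suffix(r1.read_id)
        id2 = strip_mate_suffix(r2.read_id)
        if id1 != id2:
            raise FormatError(f"read IDs out of sync: {r1.read_id!r} vs {r2.read_id!r}")
        r1.read_id = id1
        r2.read_id = id2
        yield r1, r2


def write_fastq(records: Iterable[FastqRecord], path: str | Path) -> None:
    with open(path, "w") as out:
        for rec in records:
            out.write(f"@{rec.read_id}\n{rec.sequence}\n+\n{rec.qualities}\n")


# ---------------------------------------------------------------------------
# SAM
# ---------------------------------------------------------------------------

def read_sam(path: str | Path) -> Iterator[SamRecord]:
    """Stream SamRecords from a SAM (or BAM) file via pysam."""
    with pysam.AlignmentFile(str(path), check_sq=False) as af:
        for seg in af:
            yield _from_pysam(seg)


def read_sam_references(path: str | Path) -> dict[str, int]:
    with pysam.AlignmentFile(str(path), check_sq=False) as af:
        return dict(zip(af.references, af.lengths))


def _from_pysam(seg: pysam.AlignedSegment) -> SamRecord:
    nm = seg.get_tag("NM") if seg.has_tag("NM") else None
    rnext = seg.next_reference_name or "*"
    if rnext != "*" and rnext == seg.reference_name:
        rnext = "="
    return SamRecord(
        read_id=seg.query_name,
        flag=seg.flag,
        reference=seg.reference_name or "*",
        position=(seg.reference_start + 1) if seg.reference_start is not None and seg.reference_start >= 0 else 0,
        mapq=seg.mapping_quality,
        cigar=seg.cigarstring or "*",
        rnext=rnext,
        pnext=(seg.next_reference_start + 1) if seg.next_reference_start is not None and seg.next_reference_start >= 0 else 0,
        tlen=seg.template_length,
        sequence=seg.query_sequence or "*",
        qualities=pysam.qualities_to_qualitystring(seg.query_qualities) if seg.query_qualities is not None else "*",
        mismatches=nm,
    )


def write_sam(
    records: Iterable[SamRecord],
    path: str | Path,
    references: Mapping[str, int],
) -> None:
    header = {
        "HD": {"VN": "1.6", "SO": "unknown"},
        "SQ": [{"SN": name, "LN": int(length)} for name, length in references.items()],
    }
    ref_ids = {name: i for i, name in enumerate(references)}
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for rec in records:
            seg = pysam.AlignedSegment(out.header)
            seg.query_name = rec.read_id
            seg.flag = rec.flag
            seg.reference_id = ref_ids.get(rec.reference, -1)
            seg.reference_start = rec.position - 1 if rec.position > 0 else -1
            seg.mapping_quality = rec.mapq
            if rec.cigar != "*":
                seg.cigarstring = rec.cigar
            seg.next_reference_id = (
                seg.reference_id if rec.rnext == "=" else ref_ids.get(rec.rnext, -1)
            )
            seg.next_reference_start = rec.pnext - 1 if rec.pnext > 0 else -1
            seg.template_length = rec.tlen
            if rec.sequence != "*":
                seg.query_sequence = rec.sequence
                if rec.qualities != "*":
                    seg.query_qualities = pysam.qualitystring_to_array(rec.qualities)
            if rec.mismatches is not None:
                seg.set_tag("NM", int(rec.mismatches))
            out.write(seg)


# ---------------------------------------------------------------------------
# Annotation
# ---------------------------------------------------------------------------

_ANNOTATION_COLUMNS = [
    "transcript_id", "gene_id", "gene_name", "chromosome", "strand", "three_prime_end",
]


def read_annotation_table(path: str | Path) -> list[TranscriptAnnotation]:
    """Read the minimal 6-column TSV (optional 7th column: biotype)."""
    df = pd.read_csv(path, sep="\t", dtype={"chromosome": str})
    missing = [c for c in _ANNOTATION_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"annotation table missing columns: {missing}")
    if df["transcript_id"].duplicated().any():
        raise FormatError("duplicate transcript_id in annotation table")
    records = []
    for row in df.itertuples(index=False):
        records.append(
            TranscriptAnnotation(
                transcript_id=row.transcript_id,
                gene_id=row.gene_id,
                gene_name=row.gene_name,
                chromosome=str(row.chromosome),
                strand=row.strand,
                three_prime_end=int(row.three_prime_end),
                biotype=getattr(row, "biotype", "protein_coding"),
            )
        )
    return records


def write_annotation_table(
    annotations: Sequence[TranscriptAnnotation], path: str | Path
) -> None:
    df = pd.DataFrame(
        [
            {
                "transcript_id": a.transcript_id,
                "gene_id": a.gene_id,
                "gene_name": a.gene_name,
                "chromosome": a.chromosome,
                "strand": a.strand,
                "three_prime_end": a.three_prime_end,
                "biotype": a.biotype,
            }
            for a in annotations
        ],
        columns=_ANNOTATION_COLUMNS + ["biotype"],
    )
    df.to_csv(path, sep="\t", index=False)


def read_annotation_gtf(path: str | Path) -> list[TranscriptAnnotation]:
    """Extract transcript 3' ends from a GTF (strand decides which endpoint)."""
    import gffutils

    db = gffutils.create_db(
        str(path), ":memory:", force=True, keep_order=True,
        disable_infer_genes=True, disable_infer_transcripts=True,
    )
    records = []
    for tx in db.features_of_type("transcript"):
        strand = tx.strand
        if strand not in {"+", "-"}:
            continue
        records.append(
            TranscriptAnnotation(
                transcript_id=tx.attributes.get("transcript_id", [tx.id])[0],
                gene_id=tx.attributes.get("gene_id", [""])[0],
                gene_name=tx.attributes.get("gene_name", [""])[0],
                chromosome=tx.seqid,
                strand=strand,
                three_prime_end=tx.end if strand == "+" else tx.start,
                biotype=tx.attributes.get(
                    "transcript_biotype", tx.attributes.get("gene_biotype", ["protein_coding"])
                )[0],
            )
        )
    return records


def read_blacklist(path: str | Path) -> set[str]:
    """One transcript ID per line; blank lines and '#' comments ignored."""
    ids: set[str] = set()
    with open(path) as handle:
        for line in handle:
            line = line.strip()
            if line and not line.startswith("#"):
                ids.add(line)
    return ids


# ---------------------------------------------------------------------------
# Gene list
# ---------------------------------------------------------------------------

# Fixed leading column order of the output table; per-sample raw/normalised
# count columns (count_<label>, norm_<label>) follow in sample order.
GENE_LIST_COLUMNS = [
    "chromosome",
    "region_start",
    "region_end",
    "tc_position",
    "tc_strand",
    "tc_support",
    "distance",
    "transcript_id",
    "gene_id",
    "gene_name",
    "biotype",
    "base_mean",
    "log2_fold_change",
    "p_value",
    "adjusted_p",
]


def gene_list_frame(rows: Sequence[Mapping]) -> pd.DataFrame:
    """Validate rows and return the table sorted by ascending adjusted p (missing last)."""
    if not rows:
        return pd.DataFrame(columns=GENE_LIST_COLUMNS)
    df = pd.DataFrame(list(rows))
    missing = [c for c in GENE_LIST_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"gene list rows missing fields: {missing}")
    extra = sorted(c for c in df.columns if c not in GENE_LIST_COLUMNS)
    df = df[GENE_LIST_COLUMNS + extra]
    df = df.sort_values(
        ["adjusted_p", "p_value", "chromosome", "region_start"],
        na_position="last",
        kind="mergesort",
    ).reset_index(drop=True)
    return df


def write_gene_list(rows: Sequence[Mapping], path: str | Path, fmt: str = "tsv") -> None:
    df = gene_list_frame(rows)
    if fmt == "csv":
        df.to_csv(path, index=False, na_rep="NA")
    elif fmt == "tsv":
        df.to_csv(path, sep="\t", index=False, na_rep="NA")
    elif fmt == "html":
        with open(path, "w") as out:
            out.write(df.to_html(index=False, na_rep="NA"))
    else:
        raise FormatError(f"unknown gene list format {fmt!r}")


def read_gene_list(path: str | Path, fmt: str = "tsv") -> pd.DataFrame:
    sep = "," if fmt == "csv" else "\t"
    return pd.read_csv(path, sep=sep, na_values=["NA"], keep_default_na=True)


# ---------------------------------------------------------------------------
# BED export (regions, TC ends)
# ---------------------------------------------------------------------------

def write_regions_bed(regions, path: str | Path) -> None:
    """Regions as BED: 0-based half-open, score = peak probability."""
    with open(path, "w") as out:
        for r in regions:
            out.write(
                f"{r.reference}\t{r.start - 1}\t{r.end}\tregion\t{r.peak_probability:.4f}\t.\n"
            )


def write_ends_bed(ends, path: str | Path) -> None:
    """TC 3' ends as BED6+1: name=verdict, score=support."""
    with open(path, "w") as out:
        for e in ends:
            verdict = e.reason if e.artifact else "pass"
            out.write(
                f"{e.reference}\t{e.position - 1}\t{e.position}\t{verdict}\t{e.support}\t{e.strand}\n"
            )


def read_false_ends(path: str | Path) -> set[tuple[str, int, str]]:
    """Known false TC 3' ends as (reference, 1-based position, strand)."""
    result: set[tuple[str, int, str]] = set()
    with open(path) as handle:
        for line in handle:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            chrom, start = fields[0], int(fields[1])
            strand = fields[5] if len(fields) > 5 else "+"
            result.add((chrom, start + 1, strand))
    return result


def write_fasta(sequences: Mapping[str, str], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as out:
        for name, seq in sequences.items():
            out.write(f">{name}\n")
            for i in range(0, len(seq), width):
                out.write(seq[i : i + width] + "\n")
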