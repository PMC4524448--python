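"""Transcript-counting 3' end prediction and artifact filtering.

The aligned base of trimmed read 1 next to the former polyT junction
marks a polyadenylated transcript's 3' terminus: read 1 primes off the
polyA tail and reads antisense, so the transcript strand is the opposite
of the read-1 alignment strand.  Candidate ends inside a region are
supported by their non-duplicate read pairs; candidates with fewer than
3 supporting reads or an A-enriched downstream genomic context (internal
oligo-dT mispriming) are discarded, and the surviving candidate with the
highest support represents the region.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .dedup import AlignmentPair
from .formats import SamRecord
from .peaks import Region

#: Empirically determined A-enrichment patterns; A = adenine, B = C, G or T.
POLYA_PATTERNS = (
    "AAABAAABBB",
    "AAABAABABB",
    "AAABABAABB",
    "AABAAAABBB",
    "AABAAABABB",
    "AABABAAABB",
    "ABAAAAABBB",
    "ABAAAABABB",
    "ABAAABAABB",
    "ABAABAAABB",
    "ABABAAAABB",
    "AABAABAABB",
)

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class TC3End:
    reference: str
    position: int  # 1-based single base
    strand: str  # transcript strand
    support: int
    downstream10: str = ""
    artifact: bool = False
    reason: str | None = None  # low_support | polyA_start | polyA_total | polyA_pattern

    def __post_init__(self) -> None:
        if self.support < 1:
            raise ValueError("support must be >= 1")
        if self.strand not in {"+", "-"}:
            raise ValueError(f"bad strand {self.strand!r}")


@dataclass
class RegionEnds:
    region: Region
    candidates: list[TC3End]
    selected: TC3End | None


def end_position(read1: SamRecord) -> tuple[str, int, str] | None:
    """(reference, position, transcript strand) from a mapped read 1.

    Forward-aligned read 1 starts at the junction, so the end is its
    leftmost aligned base and the transcript is on '-'; reverse-aligned
    read 1 ends at the junction (rightmost aligned base, transcript '+').
    Soft-clipped bases are outside the aligned portion and do not move
    the position.
    """
    if read1.is_unmapped:
        return None
    if read1.is_reverse:
        return read1.reference, read1.reference_end, "+"
    return read1.reference, read1.position, "-"


def collect_candidates(region: Region, pairs: Iterable[AlignmentPair]) -> list[TC3End]:
    """Candidate ends from read 1s whose mate read 2 lies in the region.

    Duplicate-flagged pairs do not contribute support.  One candidate per
    distinct (position, strand), sorted by position.
    """
    support: Counter[tuple[int, str]] = Counter()
    for pair in pairs:
        if pair.duplicate or pair.read1 is None or pair.read2 is None:
            continue
        r2 = pair.read2
        if r2.is_unmapped or r2.reference != region.reference:
            continue
        if not (region.start <= r2.position <= region.end):
            continue
        end = end_position(pair.read1)
        if end is None or end[0] != region.reference:
            continue
        support[(end[1], end[2])] += 1
    return [
        TC3End(region.reference, pos, strand, count)
        for (pos, strand), count in sorted(support.items())
    ]


def polya_artifact(downstream10: str) -> tuple[bool, str | None]:
    """Test a downstream 10-mer against the internal-polyA priming rules.

    Flags when the first 4 bases are all A (polyA_start), when more than
    6 of the bases are A (polyA_total), or when the sequence matches one
    of the empirical patterns with A = adenine and B = any of C/G/T
    (polyA_pattern).  N counts as non-A and does not satisfy B.
    """
    seq = downstream10.upper()
    if len(seq) >= 4 and seq[:4] == "AAAA":
        return True, "polyA_start"
    if seq.count("A") > 6:
        return True, "polyA_total"
    if len(seq) == 10:
        for pattern in POLYA_PATTERNS:
            if all(
                (c == "A") if p == "A" else (c in "CGT")
                for p, c in zip(pattern, seq)
            ):
                return True, "polyA_pattern"
    return False, None


def downstream_context(
    genome: Mapping[str, str], reference: str, position: int, strand: str, length: int = 10
) -> str:
    """Genomic sequence 3' of the end in transcript orientation.

    On '+' this is the length bases after the position; on '-' the length
    bases before it, reverse-complemented.  Truncated at contig edges.
    """
    seq = genome[reference]
    if strand == "+":
        return str(seq[position : position + length]).upper()
    start = max(position - 1 - length, 0)
    return reverse_complement(str(seq[start : position - 1]).upper())


def filter_candidates(
    candidates: Sequence[TC3End],
    genome: Mapping[str, str],
    min_support: int = 3,
) -> list[TC3End]:
    """Attach downstream context and artifact verdicts to candidates."""
    for cand in candidates:
        cand.downstream10 = downstream_context(
            genome, cand.reference, cand.position, cand.strand
        )
        if cand.support < min_support:
            cand.artifact, cand.reason = True, "low_support"
            continue
        cand.artifact, cand.reason = polya_artifact(cand.downstream10)
    return list(candidates)


def select_region_end(
    candidates: Sequence[TC3End],
    false_ends: set[tuple[str, int, str]] | None = None,
) -> TC3End | None:
    """The non-artifact candidate of maximal support (ties: lowest coordinate).

    Positions on a run-level known-false-ends list are excluded first.
    """
    eligible = [
        c
        for c in candidates
        if not c.artifact
        and not (false_ends and (c.reference, c.position, c.strand) in false_ends)
    ]
    if not eligible:
        return None
    return min(eligible, key=lambda c: (-c.support, c.position))


def region_ends(
    region: Region,
    pairs: Iterable[AlignmentPair],
    genome: Mapping[str, str],
    min_support: int = 3,
    false_ends: set[tuple[str, int, str]] | None = None,
) -> RegionEnds:
    candidates = collect_candidates(region, pairs)
    filter_candidates(candidates, genome, min_support=min_support)
    return RegionEnds(region, candidates, select_region_end(candidates, false_ends))
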