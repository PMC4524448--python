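"""UMI-aware PCR-duplicate marking on mapped read pairs.

Two pairs are duplicates when they share reference, outer mapping
coordinates (leftmost and rightmost mapped base over both mates), pair
orientation and UMI.  Within a duplicate group one representative stays
unflagged (highest summed base quality, ties broken by read id); pairs
with an unmapped mate are never flagged.  UMIs containing N never match
any other UMI.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .detag import parse_tagged_id
from .formats import SamRecord


@dataclass
class AlignmentPair:
    """A mapped read pair with the fields the duplicate key needs."""

    read_id: str
    reference: str
    outer_start: int
    outer_end: int
    orientation: str  # strand configuration, leftmost mate first, e.g. "FR"
    umi: str
    score: float = 0.0  # summed base quality (representative selection)
    mismatches: int = 0  # read-2 NM (binning filter downstream)
    duplicate: bool = False
    sample_label: str | None = None
    read1: SamRecord | None = None
    read2: SamRecord | None = None

    @property
    def both_mapped(self) -> bool:
        if self.read1 is not None and self.read2 is not None:
            return not (self.read1.is_unmapped or self.read2.is_unmapped)
        return self.outer_start > 0

    def __post_init__(self) -> None:
        if self.both_mapped and self.outer_start > self.outer_end:
            raise ValueError("outer_start must be <= outer_end")


def _quality_sum(record: SamRecord | None) -> float:
    if record is None or record.qualities in ("*", ""):
        return 0.0
    return float(sum(ord(c) - 33 for c in record.qualities))


def pair_records(
    records: Iterable[SamRecord],
    sample_for_index: dict[str, str] | None = None,
) -> list[AlignmentPair]:
    """Join SAM records into AlignmentPairs by read id.

    Read names are expected to carry UMI and index tokens appended by the
    detag step; sample_for_index optionally maps the index to a label.
    """
    mates: dict[str, dict[int, SamRecord]] = defaultdict(dict)
    order: list[str] = []
    for rec in records:
        if not rec.is_paired:
            continue
        slot = 1 if rec.is_read1 else 2
        if rec.read_id not in mates:
            order.append(rec.read_id)
        mates[rec.read_id][slot] = rec
    pairs = []
    for read_id in order:
        got = mates[read_id]
        if 1 not in got or 2 not in got:
            continue
        r1, r2 = got[1], got[2]
        try:
            _, umi, index = parse_tagged_id(read_id)
        except ValueError:
            umi, index = "", ""
        label = sample_for_index.get(index) if sample_for_index else None
        if r1.is_unmapped or r2.is_unmapped:
            outer_start = outer_end = 0
            reference = "*"
            orientation = ""
        else:
            reference = r1.reference
            starts = [(r1.position, r1.reference_end, r1.is_reverse),
                      (r2.position, r2.reference_end, r2.is_reverse)]
            starts.sort(key=lambda t: (t[0], t[1]))
            outer_start = starts[0][0]
            outer_end = max(starts[0][1], starts[1][1])
            orientation = "".join("R" if rev else "F" for _, _, rev in starts)
        pairs.append(
            AlignmentPair(
                read_id=read_id,
                reference=reference,
                outer_start=outer_start,
                outer_end=outer_end,
                orientation=orientation,
                umi=umi,
                score=_quality_sum(r1) + _quality_sum(r2),
                mismatches=r2.mismatches or 0,
                sample_label=label,
                read1=r1,
                read2=r2,
            )
        )
    return pairs


def duplicate_key(pair: AlignmentPair, use_umi: bool = True):
    """Duplicate-group key, or None when a mate is unmapped.

    UMIs containing N are treated as unique molecules: the key is
    augmented with the read id so such pairs never group together.
    """
    if not pair.both_mapped:
        return None
    key: tuple = (pair.reference, pair.outer_start, pair.outer_end, pair.orientation)
    if use_umi:
        if "N" in pair.umi:
            key = key + (pair.umi, pair.read_id)
        else:
            key = key + (pair.umi,)
    return key


def mark_duplicates(pairs: Sequence[AlignmentPair], use_umi: bool = True) -> Sequence[AlignmentPair]:
    """Set duplicate flags in place; exactly one unflagged pair per group.

    Re-running is idempotent: flags are recomputed from scratch.
    """
    groups: dict[tuple, list[AlignmentPair]] = defaultdict(list)
    for pair in pairs:
        key = duplicate_key(pair, use_umi=use_umi)
        if key is None:
            _set_flag(pair, False)
            continue
        groups[key].append(pair)
    for members in groups.values():
        members.sort(key=lambda p: (-p.score, p.read_id))
        _set_flag(members[0], False)
        for dup in members[1:]:
            _set_flag(dup, True)
    return pairs


def _set_flag(pair: AlignmentPair, value: bool) -> None:
    pair.duplicate = value
    if pair.read1 is not None:
        pair.read1.set_duplicate(value)
    if pair.read2 is not None:
        pair.read2.set_duplicate(value)


def duplicate_rate(pairs: Sequence[AlignmentPair], mode: str = "coords_plus_umi") -> float:
    """Fraction of keyable (both-mates-mapped) pairs flagged under a mode.

    Computed without disturbing existing flags.
    """
    if mode not in {"coords_only", "coords_plus_umi"}:
        raise ValueError(f"unknown mode {mode!r}")
    use_umi = mode == "coords_plus_umi"
    sizes: dict[tuple, int] = defaultdict(int)
    total = 0
    for pair in pairs:
        key = duplicate_key(pair, use_umi=use_umi)
        if key is None:
            continue
        total += 1
        sizes[key] += 1
    if total == 0:
        raise ValueError("duplicate_rate undefined on empty input")
    flagged = sum(n - 1 for n in sizes.values())
    return flagged / total
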