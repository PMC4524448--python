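"""Read-1 tag parsing, demultiplexing and trimming.

Read 1 of each pair begins with a 12-base unique molecular identifier
(UMI), an 8-base inline sample index, an optional short spacer and an
anchored polyT run primed off the transcript's polyA tail.  Everything
5' of the insert is removed and the UMI + index are carried in the read
name so that downstream duplicate marking and per-sample counting can
recover them.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping

from .formats import FastqRecord

TAG_DELIMITER = "#"


def hamming(a: str, b: str) -> int:
    if len(a) != len(b):
        raise ValueError("hamming distance requires equal-length strings")
    return sum(x != y for x, y in zip(a, b))


@dataclass(frozen=True)
class TagLayout:
    """Geometry of the read-1 tag and the sample-index whitelist.

    min_polyt is the minimum number of T bases in the polyT run; the run
    tolerates one non-T base per ten Ts (sequencing miscalls inside the
    anchored T14 tract).  The spacer between index and polyT is searched
    but optional: 0..len(spacer) bases may be consumed.
    """

    umi_length: int = 12
    index_length: int = 8
    spacer: str = "CG"
    min_polyt: int = 10
    index_whitelist: Mapping[str, str] = field(default_factory=dict)  # index -> label
    max_index_mismatches: int = 0
    fixed_trim: int | None = None  # optional fixed-length 3' trim of the insert

    def __post_init__(self) -> None:
        if self.umi_length <= 0 or self.index_length <= 0:
            raise ValueError("umi_length and index_length must be positive")
        indices = list(self.index_whitelist)
        for idx in indices:
            if len(idx) != self.index_length:
                raise ValueError(f"whitelist index {idx!r} has wrong length")
        for i, a in enumerate(indices):
            for b in indices[i + 1 :]:
                if hamming(a, b) <= self.max_index_mismatches:
                    raise ValueError(
                        f"whitelist indices {a!r} and {b!r} are not separable "
                        f"at {self.max_index_mismatches} mismatches"
                    )

    @property
    def min_read1_length(self) -> int:
        return self.umi_length + self.index_length + self.min_polyt


@dataclass
class TaggedRead:
    """A read pair after tag parsing (rejected reads keep a reason)."""

    read1: FastqRecord
    read2: FastqRecord
    umi: str = ""
    sample_index: str = ""
    sample_label: str | None = None
    trimmed_read1: FastqRecord | None = None
    rejected: bool = False
    reason: str | None = None


def _polyt_run(sequence: str, start: int, min_polyt: int) -> int | None:
    """Return the index one past the maximal tolerant polyT run, or None.

    The run may contain one non-T per ten Ts already seen and always ends
    on a T.  None if fewer than min_polyt Ts are found.
    """
    t_count = 0
    mismatches = 0
    end = start  # one past last T seen
    i = start
    n = len(sequence)
    while i < n:
        if sequence[i] == "T":
            t_count += 1
            end = i + 1
        elif mismatches + 1 <= t_count // 10:
            mismatches += 1
        else:
            break
        i += 1
    if t_count >= min_polyt:
        return end
    return None


def parse_read1(record: FastqRecord, layout: TagLayout, read2: FastqRecord | None = None) -> TaggedRead:
    """Parse the UMI/index/polyT structure off the start of read 1."""
    read2 = read2 if read2 is not None else record
    out = TaggedRead(read1=record, read2=read2)
    seq = record.sequence
    if len(seq) < layout.min_read1_length:
        out.rejected, out.reason = True, "too_short"
        return out
    umi = seq[: layout.umi_length]
    index = seq[layout.umi_length : layout.umi_length + layout.index_length]
    tag_end = layout.umi_length + layout.index_length

    # Prefer an exact spacer match, then try skipping 0..len(spacer) bases.
    skips = []
    ns = len(layout.spacer)
    if ns and seq[tag_end : tag_end + ns] == layout.spacer:
        skips.append(ns)
    skips.extend(k for k in range(ns + 1) if k not in skips)

    insert_start = None
    for skip in skips:
        end = _polyt_run(seq, tag_end + skip, layout.min_polyt)
        if end is not None:
            insert_start = end
            break
    if insert_start is None:
        out.umi, out.sample_index = umi, index
        out.rejected, out.reason = True, "no_polyT"
        return out
    if insert_start >= len(seq):
        out.umi, out.sample_index = umi, index
        out.rejected, out.reason = True, "empty_insert"
        return out

    out.umi, out.sample_index = umi, index
    insert = seq[insert_start:]
    quals = record.qualities[insert_start:]
    if layout.fixed_trim is not None:
        insert = insert[: layout.fixed_trim]
        quals = quals[: layout.fixed_trim]
    out.trimmed_read1 = FastqRecord(
        rename_with_tags(record.read_id, umi, index), insert, quals
    )
    return out


def assign_sample(index: str, layout: TagLayout) -> str | None:
    """Match an index against the whitelist; ambiguous or absent -> None."""
    label = layout.index_whitelist.get(index)
    if label is not None:
        return label
    if layout.max_index_mismatches == 0:
        return None
    hits = [
        lab
        for wl, lab in layout.index_whitelist.items()
        if hamming(index, wl) <= layout.max_index_mismatches
    ]
    if len(hits) == 1:
        return hits[0]
    return None


def rename_with_tags(read_id: str, umi: str, index: str) -> str:
    if not umi or not index:
        raise ValueError("umi and index must be non-empty")
    if TAG_DELIMITER in read_id or TAG_DELIMITER in umi or TAG_DELIMITER in index:
        raise ValueError(f"reserved delimiter {TAG_DELIMITER!r} present in input")
    return f"{read_id}{TAG_DELIMITER}{umi}{TAG_DELIMITER}{index}"


def parse_tagged_id(read_id: str) -> tuple[str, str, str]:
    """Inverse of rename_with_tags: (original id, umi, index)."""
    parts = read_id.rsplit(TAG_DELIMITER, 2)
    if len(parts) != 3:
        raise ValueError(f"read id {read_id!r} does not carry UMI/index tags")
    return parts[0], parts[1], parts[2]


@dataclass
class DetagSummary:
    total: int = 0
    accepted: int = 0
    rejected_by_reason: Counter = field(default_factory=Counter)
    accepted_by_sample: Counter = field(default_factory=Counter)


def detag_pairs(
    pairs: Iterable[tuple[FastqRecord, FastqRecord]], layout: TagLayout
) -> tuple[dict[str, list[TaggedRead]], list[TaggedRead], DetagSummary]:
    """Demultiplex a pair stream into per-sample accepted streams.

    Every input pair lands in exactly one output: an accepted per-sample
    list (index assigned via the whitelist; unassigned indices are a
    rejection reason) or the rejected list.
    """
    accepted: dict[str, list[TaggedRead]] = {
        label: [] for label in layout.index_whitelist.values()
    }
    rejected: list[TaggedRead] = []
    summary = DetagSummary()
    for r1, r2 in pairs:
        summary.total += 1
        tagged = parse_read1(r1, layout, read2=r2)
        if not tagged.rejected:
            label = assign_sample(tagged.sample_index, layout)
            if label is None:
                tagged.rejected, tagged.reason = True, "unassigned_index"
            else:
                tagged.sample_label = label
        if tagged.rejected:
            rejected.append(tagged)
            summary.rejected_by_reason[tagged.reason] += 1
        else:
            accepted.setdefault(tagged.sample_label, []).append(tagged)
            summary.accepted += 1
            summary.accepted_by_sample[tagged.sample_label] += 1
    return accepted, rejected, summary
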