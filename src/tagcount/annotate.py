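"""Associate TC 3' ends with the nearest annotated transcript 3' end.

Search is restricted to the same chromosome and strand; blacklisted
transcripts are removed before the search.  Distance is signed in
transcript orientation: negative means the annotated end lies 5' of the
TC end, positive 3' of it.  Two proximity windows are applied downstream:
stringent [-100, +100] and relaxed [-100, +5000], both inclusive.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass
from typing import Iterable, Sequence

from .formats import TranscriptAnnotation
from .peaks import Region
from .tc_ends import TC3End

PROXIMITY_WINDOWS = {
    "stringent": (-100, 100),
    "relaxed": (-100, 5000),
}


@dataclass
class AnnotatedEnd:
    tc_end: TC3End
    region: Region | None
    transcript: TranscriptAnnotation | None
    distance: int | None
    passes_stringent: bool = False
    passes_relaxed: bool = False
    passes_region_consistency: bool = True


class AnnotationIndex:
    """Transcript 3' ends indexed by (chromosome, strand) for nearest lookup."""

    def __init__(
        self,
        annotations: Iterable[TranscriptAnnotation],
        blacklist: set[str] | None = None,
    ) -> None:
        blacklist = blacklist or set()
        self._by_key: dict[tuple[str, str], tuple[list[int], list[TranscriptAnnotation]]] = {}
        grouped: dict[tuple[str, str], list[TranscriptAnnotation]] = {}
        for ann in annotations:
            if ann.transcript_id in blacklist:
                continue
            grouped.setdefault((ann.chromosome, ann.strand), []).append(ann)
        for key, group in grouped.items():
            # stable ordering: position, then transcript_id for the tie-break
            group.sort(key=lambda a: (a.three_prime_end, a.transcript_id))
            self._by_key[key] = ([a.three_prime_end for a in group], group)

    def nearest(
        self, chromosome: str, strand: str, position: int
    ) -> tuple[TranscriptAnnotation, int] | None:
        """Nearest transcript 3' end on the same chromosome and strand.

        Returns (transcript, genomic offset annotated_end - position);
        ties on |offset| break by lexicographic transcript_id.
        """
        entry = self._by_key.get((chromosome, strand))
        if entry is None:
            return None
        ends, group = entry
        i = bisect.bisect_left(ends, position)
        candidates: list[TranscriptAnnotation] = []
        best = None
        for j in (i - 1, i):
            if 0 <= j < len(ends):
                d = abs(ends[j] - position)
                if best is None or d < best:
                    best = d
        assert best is not None
        # gather every transcript end at exactly |best| distance either side
        for target in {position - best, position + best}:
            j = bisect.bisect_left(ends, target)
            while j < len(ends) and ends[j] == target:
                candidates.append(group[j])
                j += 1
        chosen = min(candidates, key=lambda a: a.transcript_id)
        return chosen, chosen.three_prime_end - position


def signed_distance(tc_end: TC3End, annotated_end: int) -> int:
    """Signed distance in transcript orientation (negative = annotated end 5')."""
    delta = annotated_end - tc_end.position
    return delta if tc_end.strand == "+" else -delta


def nearest_annotated_end(
    tc_end: TC3End,
    index: AnnotationIndex,
) -> tuple[TranscriptAnnotation, int] | None:
    """Nearest non-blacklisted same-strand transcript with signed distance."""
    hit = index.nearest(tc_end.reference, tc_end.strand, tc_end.position)
    if hit is None:
        return None
    transcript, _ = hit
    return transcript, signed_distance(tc_end, transcript.three_prime_end)


def proximity_filter(distance: int, window: str = "stringent") -> bool:
    """Inclusive signed-distance window test."""
    try:
        lo, hi = PROXIMITY_WINDOWS[window]
    except KeyError:
        raise ValueError(f"unknown window {window!r}") from None
    return lo <= distance <= hi


def region_consistency(region: Region, tc_end: TC3End, max_upstream: int = 150) -> bool:
    """The region's 3'-most coordinate may trail the end by at most max_upstream.

    In transcript orientation the region's 3' edge is region.end on '+'
    and region.start on '-'; the test passes when that edge is not more
    than max_upstream bases upstream (5') of the TC end position.
    """
    if tc_end.strand == "+":
        upstream_gap = tc_end.position - region.end
    else:
        upstream_gap = region.start - tc_end.position
    return upstream_gap <= max_upstream


def annotate_end(
    tc_end: TC3End,
    region: Region | None,
    index: AnnotationIndex,
    max_upstream: int = 150,
) -> AnnotatedEnd:
    hit = nearest_annotated_end(tc_end, index)
    if hit is None:
        return AnnotatedEnd(tc_end, region, None, None,
                            passes_region_consistency=(
                                region_consistency(region, tc_end, max_upstream)
                                if region is not None else True))
    transcript, distance = hit
    return AnnotatedEnd(
        tc_end=tc_end,
        region=region,
        transcript=transcript,
        distance=distance,
        passes_stringent=proximity_filter(distance, "stringent"),
        passes_relaxed=proximity_filter(distance, "relaxed"),
        passes_region_consistency=(
            region_consistency(region, tc_end, max_upstream)
            if region is not None
            else True
        ),
    )


def annotate_ends(
    ends: Sequence[tuple[TC3End, Region | None]],
    annotations: Iterable[TranscriptAnnotation],
    blacklist: set[str] | None = None,
    max_upstream: int = 150,
) -> list[AnnotatedEnd]:
    index = AnnotationIndex(annotations, blacklist)
    return [annotate_end(e, r, index, max_upstream) for e, r in ends]
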