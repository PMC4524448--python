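"""End-to-end orchestration: alignment pairs -> gene-list rows.

Thin glue over the stage modules; every step is also usable on its own.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .annotate import AnnotatedEnd, AnnotationIndex, annotate_end
from .dedup import AlignmentPair, mark_duplicates
from .formats import TranscriptAnnotation
from .peaks import Region, bin_reads, call_regions, fit_peak_model
from .quant_de import CountMatrix, call_hits, count_by_sample, de_analysis
from .tc_ends import RegionEnds, region_ends


@dataclass
class PipelineResult:
    regions: list[Region]
    region_ends: list[RegionEnds]
    annotated: list[AnnotatedEnd | None]
    matrix: CountMatrix
    results: pd.DataFrame
    gene_rows: list[dict]

    @property
    def selected_ends(self):
        return [re.selected for re in self.region_ends]


def run_pipeline(
    pairs: Sequence[AlignmentPair],
    genome: Mapping[str, str],
    annotations: Sequence[TranscriptAnnotation],
    samples: Sequence[tuple[str, str]],
    reference_lengths: Mapping[str, int] | None = None,
    bin_size: int = 100,
    max_mismatches: int = 2,
    posterior_threshold: float = 0.5,
    min_support: int = 3,
    alpha: float = 0.05,
    min_fc: float | None = None,
    window: str = "relaxed",
    blacklist: set[str] | None = None,
    false_ends: set[tuple[str, int, str]] | None = None,
    rerun_duplicates: bool = True,
) -> PipelineResult:
    """Duplicate marking, peak calling, end selection, annotation and DE."""
    pairs = list(pairs)
    if rerun_duplicates:
        mark_duplicates(pairs)

    read2s = [p.read2 for p in pairs if p.read2 is not None]
    tracks = bin_reads(
        read2s, bin_size=bin_size, max_mismatches=max_mismatches,
        reference_lengths=reference_lengths,
    )
    model = fit_peak_model(tracks)
    regions: list[Region] = []
    for ref in sorted(tracks):
        ref_len = reference_lengths.get(ref) if reference_lengths else None
        regions.extend(
            call_regions(tracks[ref], model, threshold=posterior_threshold,
                         reference_length=ref_len)
        )

    # index pairs by (reference, read-2 position) once; each region pulls its slice
    by_ref: dict[str, tuple[np.ndarray, list[AlignmentPair]]] = {}
    for ref in tracks:
        ref_pairs = [
            p for p in pairs
            if p.read2 is not None and not p.read2.is_unmapped and p.read2.reference == ref
        ]
        ref_pairs.sort(key=lambda p: p.read2.position)
        by_ref[ref] = (np.array([p.read2.position for p in ref_pairs]), ref_pairs)

    ends: list[RegionEnds] = []
    for region in regions:
        positions, ref_pairs = by_ref[region.reference]
        lo = int(np.searchsorted(positions, region.start, side="left"))
        hi = int(np.searchsorted(positions, region.end, side="right"))
        ends.append(
            region_ends(region, ref_pairs[lo:hi], genome,
                        min_support=min_support, false_ends=false_ends)
        )

    matrix = count_by_sample(regions, pairs, samples)
    results = de_analysis(matrix, alpha=alpha)

    index = AnnotationIndex(annotations, blacklist)
    annotated: list[AnnotatedEnd | None] = []
    for re_ in ends:
        if re_.selected is None:
            annotated.append(None)
        else:
            annotated.append(annotate_end(re_.selected, re_.region, index))

    gene_rows = call_hits(
        results, annotated, alpha=alpha, min_fc=min_fc, window=window
    )
    return PipelineResult(regions, ends, annotated, matrix, results, gene_rows)


def significant_end_count(result: PipelineResult, alpha: float = 0.05, window: str = "relaxed") -> int:
    """Annotated TC 3' ends passing the window with adjusted p <= alpha."""
    pass_field = f"passes_{window}"
    n = 0
    for (_, res), ann in zip(result.results.iterrows(), result.annotated):
        if ann is None or ann.distance is None or not getattr(ann, pass_field):
            continue
        apv = res["adjusted_p"]
        if not np.isnan(apv) and apv <= alpha:
            n += 1
    return n
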