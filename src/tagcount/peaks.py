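"""HMM peak calling on binned read-2 coverage.

Mapped, non-duplicate read 2s with at most 2 mismatches are pooled over
the whole experiment into fixed-width bins (100 bp default).  A two-state
hidden Markov model with Poisson emissions (background mean < peak mean)
is fitted to the bin counts by EM; bins whose posterior peak probability
reaches a threshold are selected and maximal runs of adjacent selected
bins are merged into regions — the counting units of the pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
from hmmlearn.hmm import PoissonHMM

from .formats import SamRecord


@dataclass
class BinTrack:
    """Per-reference bin counts; bin i covers [i*bin_size+1, (i+1)*bin_size]."""

    reference: str
    bin_size: int
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if (self.counts < 0).any():
            raise ValueError("bin counts must be non-negative")


@dataclass
class Region:
    reference: str
    start: int  # 1-based inclusive
    end: int
    peak_probability: float
    bin_start: int  # member bin index range, inclusive
    bin_end: int

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError("region start must be <= end")


@dataclass
class PeakModel:
    """Fitted two-state model; state 0 = background, state 1 = peak."""

    lambda_background: float
    lambda_peak: float
    transitions: np.ndarray
    start_probabilities: np.ndarray
    degenerate: bool = False
    log_likelihood: float = float("nan")
    _hmm: PoissonHMM | None = field(default=None, repr=False)
    _peak_state: int = 1


def bin_reads(
    records: Iterable[SamRecord],
    bin_size: int = 100,
    max_mismatches: int = 2,
    reference_lengths: Mapping[str, int] | None = None,
) -> dict[str, BinTrack]:
    """Bin read-2 leftmost positions, ignoring duplicates and noisy alignments."""
    positions: dict[str, list[int]] = {}
    seen_refs: set[str] = set()
    for rec in records:
        if not rec.is_unmapped:
            seen_refs.add(rec.reference)
        if not rec.is_read2 or rec.is_unmapped or rec.is_duplicate:
            continue
        if (rec.mismatches or 0) > max_mismatches:
            continue
        positions.setdefault(rec.reference, []).append(rec.position)
    tracks: dict[str, BinTrack] = {}
    refs = set(positions) | seen_refs
    if reference_lengths:
        refs |= set(reference_lengths)
    for ref in sorted(refs):
        pos = np.asarray(positions.get(ref, []), dtype=np.int64)
        if reference_lengths and ref in reference_lengths:
            n_bins = int(np.ceil(reference_lengths[ref] / bin_size))
        elif len(pos):
            n_bins = int((pos.max() - 1) // bin_size) + 1
        else:
            n_bins = 0
        counts = np.bincount((pos - 1) // bin_size, minlength=n_bins) if n_bins else np.zeros(0, dtype=np.int64)
        tracks[ref] = BinTrack(ref, bin_size, counts)
    return tracks


def fit_peak_model(
    tracks: Mapping[str, BinTrack] | BinTrack,
    max_iterations: int = 200,
    tolerance: float = 1e-6,
    min_separation: float = 2.0,
) -> PeakModel:
    """EM fit of the two-state Poisson HMM to the pooled bin counts.

    The fit is deterministic: initial parameters come from the data (no
    random initialisation).  A fit where the peak mean fails to exceed
    min_separation times the background mean is flagged degenerate and
    calls no regions.
    """
    if isinstance(tracks, BinTrack):
        tracks = {tracks.reference: tracks}
    arrays = [t.counts for t in tracks.values() if len(t.counts)]
    if not arrays or all((a == 0).all() for a in arrays):
        raise ValueError("no_signal: all bins are zero")
    X = np.concatenate(arrays).reshape(-1, 1).astype(np.float64)
    lengths = [len(a) for a in arrays if len(a)]

    flat = X.ravel()
    median = np.median(flat)
    low = flat[flat <= median]
    lam0 = max(float(low.mean()) if len(low) else 0.0, 1e-3)
    top = np.sort(flat)[-max(1, len(flat) // 100):]
    lam1 = max(float(top.mean()), lam0 * 5.0, lam0 + 1.0)

    hmm = PoissonHMM(
        n_components=2,
        n_iter=max_iterations,
        tol=tolerance,
        init_params="",
        params="stl",
    )
    hmm.startprob_ = np.array([0.99, 0.01])
    hmm.transmat_ = np.array([[0.999, 0.001], [0.1, 0.9]])
    hmm.lambdas_ = np.array([[lam0], [lam1]])
    hmm.fit(X, lengths=lengths)

    lambdas = hmm.lambdas_.ravel()
    peak_state = int(np.argmax(lambdas))
    lam_bg = float(lambdas.min())
    lam_pk = float(lambdas.max())
    degenerate = lam_pk < min_separation * max(lam_bg, 1e-9)
    return PeakModel(
        lambda_background=lam_bg,
        lambda_peak=lam_pk,
        transitions=hmm.transmat_.copy(),
        start_probabilities=hmm.startprob_.copy(),
        degenerate=degenerate,
        log_likelihood=float(hmm.monitor_.history[-1]) if hmm.monitor_.history else float("nan"),
        _hmm=hmm,
        _peak_state=peak_state,
    )


def peak_posteriors(track: BinTrack, model: PeakModel) -> np.ndarray:
    """Posterior probability that each bin is in the peak state."""
    if model._hmm is None:
        raise ValueError("model not fitted")
    if len(track.counts) == 0:
        return np.zeros(0)
    post = model._hmm.predict_proba(track.counts.reshape(-1, 1).astype(np.float64))
    return post[:, model._peak_state]


def call_regions(
    track: BinTrack,
    model: PeakModel,
    threshold: float = 0.5,
    reference_length: int | None = None,
) -> list[Region]:
    """Select bins at/above the posterior threshold and merge adjacent runs."""
    if model.degenerate or len(track.counts) == 0:
        return []
    post = peak_posteriors(track, model)
    selected = post >= threshold
    regions: list[Region] = []
    idx = np.flatnonzero(selected)
    if len(idx) == 0:
        return regions
    run_start = idx[0]
    prev = idx[0]
    for i in idx[1:]:
        if i != prev + 1:
            regions.append(_make_region(track, post, run_start, prev, reference_length))
            run_start = i
        prev = i
    regions.append(_make_region(track, post, run_start, prev, reference_length))
    return regions


def _make_region(
    track: BinTrack, post: np.ndarray, bin_start: int, bin_end: int,
    reference_length: int | None,
) -> Region:
    start = bin_start * track.bin_size + 1
    end = (bin_end + 1) * track.bin_size
    if reference_length is not None:
        end = min(end, reference_length)
    return Region(
        reference=track.reference,
        start=start,
        end=end,
        peak_probability=float(post[bin_start : bin_end + 1].max()),
        bin_start=int(bin_start),
        bin_end=int(bin_end),
    )
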