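"""Replicates-versus-depth experiment on pooled reads.

Per-condition read pools of equal size are randomly partitioned into k
pseudo-samples per condition by replacing the real sample indices with
fake ones; the full pipeline (duplicate marking within the merged pool,
peak calling, end selection, annotation, differential abundance) is
re-run for every (k, repetition) and the number of significant TC 3'
ends under the relaxed proximity window is tabulated as a function of k.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .dedup import AlignmentPair
from .formats import TranscriptAnnotation
from .pipeline import run_pipeline, significant_end_count


@dataclass
class PermutationPlan:
    reads_per_condition: int
    k_values: Sequence[int] = tuple(range(2, 12))
    repetitions: int = 10
    seed: int = 0
    alpha: float = 0.05
    window: str = "relaxed"

    def __post_init__(self) -> None:
        if any(k < 2 for k in self.k_values):
            raise ValueError("pseudo-sample pair counts must be >= 2")


def downsample(
    pairs: Sequence[AlignmentPair], n: int, rng: np.random.Generator
) -> list[AlignmentPair]:
    """Uniform random sample of exactly n pairs (mates stay together)."""
    if n > len(pairs):
        raise ValueError(f"cannot downsample {len(pairs)} pairs to {n}")
    idx = rng.choice(len(pairs), size=n, replace=False)
    idx.sort()
    return [pairs[i] for i in idx]


def assign_pseudo_samples(
    pairs: Sequence[AlignmentPair],
    k: int,
    rng: np.random.Generator,
    prefix: str = "ps",
) -> list[AlignmentPair]:
    """Assign each pair i.i.d. uniformly to one of k fake sample labels.

    Returns shallow copies relabelled f"{prefix}1" .. f"{prefix}{k}"; the
    originals are untouched.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    labels = rng.integers(0, k, size=len(pairs))
    out = []
    for pair, lab in zip(pairs, labels):
        clone = copy.copy(pair)
        clone.sample_label = f"{prefix}{lab + 1}"
        out.append(clone)
    return out


def run_permutation_experiment(
    plan: PermutationPlan,
    condition1_pairs: Sequence[AlignmentPair],
    condition2_pairs: Sequence[AlignmentPair],
    genome: Mapping[str, str],
    annotations: Sequence[TranscriptAnnotation],
    reference_lengths: Mapping[str, int] | None = None,
    **pipeline_kwargs,
) -> pd.DataFrame:
    """One row per (k, repetition): pseudo-sample sizes and significant ends.

    Reads are conserved: within a repetition the same downsampled pools
    are re-partitioned for every k, so total reads are constant across k.
    Duplicate marking is redone inside each merged pool.
    """
    rows = []
    seeds = np.random.SeedSequence(plan.seed).spawn(plan.repetitions)
    for rep, seed in enumerate(seeds):
        rng = np.random.default_rng(seed)
        pool1 = downsample(condition1_pairs, plan.reads_per_condition, rng)
        pool2 = downsample(condition2_pairs, plan.reads_per_condition, rng)
        for k in plan.k_values:
            relabelled1 = assign_pseudo_samples(pool1, k, rng, prefix="a")
            relabelled2 = assign_pseudo_samples(pool2, k, rng, prefix="b")
            samples = [(f"a{i + 1}", "cond1") for i in range(k)] + [
                (f"b{i + 1}", "cond2") for i in range(k)
            ]
            merged = relabelled1 + relabelled2
            result = run_pipeline(
                merged, genome, annotations, samples,
                reference_lengths=reference_lengths,
                window=plan.window, alpha=plan.alpha,
                **pipeline_kwargs,
            )
            label_counts = pd.Series(
                [p.sample_label for p in merged]
            ).value_counts()
            rows.append(
                {
                    "k": k,
                    "repetition": rep,
                    "mean_reads_per_pseudo_sample": float(label_counts.mean()),
                    "total_reads": len(merged),
                    "n_significant_ends": significant_end_count(
                        result, alpha=plan.alpha, window=plan.window
                    ),
                }
            )
    return pd.DataFrame(rows)
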