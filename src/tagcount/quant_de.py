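"""Per-region counting and negative-binomial differential abundance.

A region x sample matrix of non-duplicate read-2 counts is normalised by
median-of-ratios size factors, a negative-binomial model is fitted per
region (dispersion = method-of-moments estimate shrunk toward a fitted
1/mean trend), the condition effect is tested by a Wald test, and the
p-values are Benjamini-Hochberg adjusted after independent filtering of
low-mean regions.  This is a contract-compatible stand-in for a full DE
engine, not a numerical clone of one; the fitting routine is a
documented swap point.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .dedup import AlignmentPair
from .peaks import Region

_MIN_ALPHA = 1e-8
_MAX_ALPHA = 10.0


@dataclass
class CountMatrix:
    """Ordered regions x ordered samples matrix of raw read-2 counts."""

    regions: list  # Region or any hashable region identifier
    samples: list[tuple[str, str]]  # (sample_label, condition)
    counts: np.ndarray  # shape (n_regions, n_samples)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (len(self.regions), len(self.samples)):
            raise ValueError("counts shape does not match regions x samples")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def condition_of(self) -> dict[str, str]:
        return dict(self.samples)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.counts,
            columns=[label for label, _ in self.samples],
        )


def count_by_sample(
    regions: Sequence[Region],
    pairs: Iterable[AlignmentPair],
    samples: Sequence[tuple[str, str]],
) -> CountMatrix:
    """Count non-duplicate read 2s per region per sample.

    A read 2 contributes to the region containing its leftmost mapped
    base; reads outside every region contribute nowhere.  Samples with
    zero totals are retained but reported via `zero_samples`.
    """
    sample_index = {label: i for i, (label, _) in enumerate(samples)}
    by_ref: dict[str, list[tuple[int, int, int]]] = {}
    for i, region in enumerate(regions):
        by_ref.setdefault(region.reference, []).append((region.start, region.end, i))
    for ref in by_ref:
        by_ref[ref].sort()
    starts = {ref: np.array([s for s, _, _ in v]) for ref, v in by_ref.items()}

    counts = np.zeros((len(regions), len(samples)), dtype=np.int64)
    for pair in pairs:
        if pair.duplicate or pair.read2 is None or pair.read2.is_unmapped:
            continue
        if pair.sample_label not in sample_index:
            continue
        ref = pair.read2.reference
        if ref not in by_ref:
            continue
        pos = pair.read2.position
        j = int(np.searchsorted(starts[ref], pos, side="right")) - 1
        if j < 0:
            continue
        start, end, ridx = by_ref[ref][j]
        if start <= pos <= end:
            counts[ridx, sample_index[pair.sample_label]] += 1
    return CountMatrix(list(regions), list(samples), counts)


def size_factors(counts: np.ndarray) -> np.ndarray:
    """Median-of-ratios size factors.

    Rows containing a zero are excluded from the per-sample median (the
    geometric mean over samples must be positive); if no row qualifies
    the median falls back to each sample's positive ratios.
    """
    counts = np.asarray(counts, dtype=np.float64)
    if counts.ndim != 2 or counts.shape[0] == 0:
        raise ValueError("counts must be a non-empty 2-D array")
    with np.errstate(divide="ignore"):
        logs = np.log(counts)
    log_geomeans = logs.mean(axis=1)
    finite = np.isfinite(log_geomeans)
    if finite.any():
        ratios = logs[finite] - log_geomeans[finite, None]
        factors = np.exp(np.median(ratios, axis=0))
    else:
        # no all-positive region: per-sample median over its positive counts
        factors = np.empty(counts.shape[1])
        pseudo_geo = np.exp(np.where(np.isfinite(logs), logs, 0.0).mean(axis=1))
        for s in range(counts.shape[1]):
            pos = counts[:, s] > 0
            if not pos.any():
                raise ValueError("cannot compute size factor for all-zero sample")
            factors[s] = np.median(counts[pos, s] / pseudo_geo[pos])
    if not np.all(factors > 0):
        raise ValueError("non-positive size factor")
    return factors


def _group_masks(samples: Sequence[tuple[str, str]]) -> tuple[np.ndarray, np.ndarray, str, str]:
    conditions = []
    for _, cond in samples:
        if cond not in conditions:
            conditions.append(cond)
    if len(conditions) != 2:
        raise ValueError(f"need exactly two conditions, got {conditions}")
    cond1, cond2 = conditions
    mask1 = np.array([c == cond1 for _, c in samples])
    mask2 = ~mask1
    if mask1.sum() < 2 or mask2.sum() < 2:
        raise ValueError("need at least two samples per condition")
    return mask1, mask2, cond1, cond2


def estimate_dispersions(
    counts: np.ndarray,
    factors: np.ndarray,
    samples: Sequence[tuple[str, str]],
    shrinkage: float = 0.7,
) -> np.ndarray:
    """Per-region NB dispersion: method-of-moments shrunk toward a trend.

    The raw estimate uses within-condition variance of normalised counts;
    a trend a0 + a1/mean is fitted across regions and each estimate is
    shrunk toward it in log space with the given weight.
    """
    mask1, mask2, _, _ = _group_masks(samples)
    norm = counts / factors[None, :]
    mu = norm.mean(axis=1)
    # pooled within-condition variance
    def _ss(mask: np.ndarray) -> np.ndarray:
        sub = norm[:, mask]
        return ((sub - sub.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
    n = counts.shape[1]
    var_within = (_ss(mask1) + _ss(mask2)) / max(n - 2, 1)
    # correct for the Poisson (shot-noise) component on the normalised scale
    shot = mu * np.mean(1.0 / factors)
    with np.errstate(divide="ignore", invalid="ignore"):
        raw = (var_within - shot) / mu**2
    raw = np.clip(np.nan_to_num(raw, nan=_MIN_ALPHA), _MIN_ALPHA, _MAX_ALPHA)

    usable = (mu > 0) & (raw > _MIN_ALPHA * 10)
    if usable.sum() >= 10:
        # least-squares fit of alpha ~ a0 + a1/mu, one trimming pass
        X = np.column_stack([np.ones(usable.sum()), 1.0 / mu[usable]])
        y = raw[usable]
        coef, *_ = np.linalg.lstsq(X, y, rcond=None)
        pred = X @ coef
        resid = np.abs(y - pred)
        keep = resid <= np.quantile(resid, 0.9)
        if keep.sum() >= 10:
            coef, *_ = np.linalg.lstsq(X[keep], y[keep], rcond=None)
        a0 = max(float(coef[0]), _MIN_ALPHA)
        a1 = max(float(coef[1]), 0.0)
    else:
        a0, a1 = max(float(np.median(raw)), _MIN_ALPHA), 0.0
    with np.errstate(divide="ignore"):
        trend = a0 + a1 / np.where(mu > 0, mu, np.inf)
    trend = np.clip(trend, _MIN_ALPHA, _MAX_ALPHA)
    alpha = np.exp((1 - shrinkage) * np.log(raw) + shrinkage * np.log(trend))
    return np.clip(alpha, _MIN_ALPHA, _MAX_ALPHA)


def _fit_group_means(
    counts: np.ndarray, factors: np.ndarray, alpha: np.ndarray, mask: np.ndarray,
    max_iterations: int = 50, tolerance: float = 1e-10,
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised Fisher scoring for per-region NB group means.

    Model: count_ij ~ NB(mean = s_j * q_i, dispersion alpha_i) over the
    samples j in one condition.  Returns (log q, Fisher information).
    """
    y = counts[:, mask].astype(np.float64)
    s = factors[mask]
    a = alpha[:, None]
    # moment initialisation
    q = np.maximum((y / s[None, :]).mean(axis=1), 1e-8)
    b = np.log(q)
    for _ in range(max_iterations):
        mu = s[None, :] * np.exp(b)[:, None]
        w = 1.0 + a * mu
        score = ((y - mu) / w).sum(axis=1)
        info = (mu / w).sum(axis=1)
        step = score / np.maximum(info, 1e-12)
        step = np.clip(step, -5.0, 5.0)
        b = b + step
        b = np.clip(b, np.log(1e-10), np.log(1e12))
        if np.max(np.abs(step)) < tolerance:
            break
    mu = s[None, :] * np.exp(b)[:, None]
    info = (mu / (1.0 + a * mu)).sum(axis=1)
    return b, info


def nb_test(
    matrix: CountMatrix,
    factors: np.ndarray | None = None,
    shrinkage: float = 0.7,
    alphas: np.ndarray | None = None,
) -> pd.DataFrame:
    """Per-region NB Wald test of condition 2 versus condition 1.

    The Wald statistic is referred to a t distribution with 2(n_samples - 2)
    degrees of freedom, a small-sample allowance for the estimated
    dispersion calibrated on null simulations across dispersion and
    sample-size settings.  Regions with zero counts everywhere get
    missing p.
    Returns a frame with base_mean, log2_fold_change, se, p_value.
    """
    counts = matrix.counts
    if factors is None:
        factors = size_factors(counts)
    mask1, mask2, cond1, cond2 = _group_masks(matrix.samples)
    if alphas is None:
        alphas = estimate_dispersions(counts, factors, matrix.samples, shrinkage)
    b1, info1 = _fit_group_means(counts, factors, alphas, mask1)
    b2, info2 = _fit_group_means(counts, factors, alphas, mask2)
    lfc = (b2 - b1) / np.log(2.0)
    se = np.sqrt(1.0 / np.maximum(info1, 1e-12) + 1.0 / np.maximum(info2, 1e-12)) / np.log(2.0)
    z = lfc / se
    df = 2 * (counts.shape[1] - 2)
    p = 2.0 * stats.t.sf(np.abs(z), df)
    all_zero = counts.sum(axis=1) == 0
    p = np.where(all_zero, np.nan, p)
    lfc = np.where(all_zero, 0.0, lfc)
    base_mean = (counts / factors[None, :]).mean(axis=1)
    return pd.DataFrame(
        {
            "base_mean": base_mean,
            "log2_fold_change": lfc,
            "se": se,
            "p_value": p,
            "dispersion": alphas,
        }
    )


def independent_filter(
    results: pd.DataFrame,
    alpha: float = 0.05,
    n_bins: int = 40,
) -> pd.DataFrame:
    """BH adjustment after base-mean independent filtering.

    Candidate thresholds are quantiles of base_mean; the one maximising
    the number of rejections at the given alpha wins (smallest threshold
    on ties).  Filtered regions get missing adjusted_p.
    """
    out = results.copy()
    p = out["p_value"].to_numpy()
    base_mean = out["base_mean"].to_numpy()
    testable = ~np.isnan(p)
    quantiles = np.unique(
        np.quantile(base_mean[testable], np.linspace(0.0, 0.95, n_bins))
    ) if testable.any() else np.array([0.0])
    best_threshold, best_rejections = 0.0, -1
    for thr in quantiles:
        sel = testable & (base_mean >= thr)
        if sel.sum() == 0:
            continue
        rej = int(multipletests(p[sel], alpha=alpha, method="fdr_bh")[0].sum())
        if rej > best_rejections:
            best_rejections, best_threshold = rej, float(thr)
    adjusted = np.full(len(out), np.nan)
    sel = testable & (base_mean >= best_threshold)
    if sel.any():
        adjusted[sel] = multipletests(p[sel], alpha=alpha, method="fdr_bh")[1]
    out["adjusted_p"] = adjusted
    out.attrs["filter_threshold"] = best_threshold
    return out


def de_analysis(
    matrix: CountMatrix,
    alpha: float = 0.05,
    shrinkage: float = 0.7,
    filter_low_counts: bool = True,
) -> pd.DataFrame:
    """size factors -> NB Wald test -> independent filtering + BH."""
    factors = size_factors(matrix.counts)
    results = nb_test(matrix, factors, shrinkage=shrinkage)
    if filter_low_counts:
        results = independent_filter(results, alpha=alpha)
    else:
        out = results.copy()
        p = out["p_value"].to_numpy()
        adjusted = np.full(len(out), np.nan)
        testable = ~np.isnan(p)
        if testable.any():
            adjusted[testable] = multipletests(p[testable], method="fdr_bh")[1]
        out["adjusted_p"] = adjusted
        results = out
    results.attrs["size_factors"] = factors
    norm = matrix.counts / factors[None, :]
    for i, (label, _) in enumerate(matrix.samples):
        results[f"count_{label}"] = matrix.counts[:, i]
    for i, (label, _) in enumerate(matrix.samples):
        results[f"norm_{label}"] = norm[:, i]
    return results


def call_hits(
    results: pd.DataFrame,
    annotated: Sequence,
    alpha: float = 0.05,
    min_fc: float | None = 2.0,
    window: str = "relaxed",
    max_upstream: int = 150,
) -> list[dict]:
    """Gene-list rows passing significance, fold-change and proximity filters.

    `annotated` holds one AnnotatedEnd (or None) per results row.  Rows
    pass with adjusted_p <= alpha, |fold change| >= min_fc (when set), a
    proximity-window hit and region consistency; output is ordered by
    adjusted p.
    """
    from .annotate import AnnotatedEnd  # local import to avoid a cycle

    rows: list[dict] = []
    pass_field = f"passes_{window}"
    for (_, res), ann in zip(results.iterrows(), annotated):
        if ann is None or ann.transcript is None or ann.distance is None:
            continue
        apv = res["adjusted_p"]
        if np.isnan(apv) or apv > alpha:
            continue
        if min_fc is not None and 2 ** abs(res["log2_fold_change"]) < min_fc:
            continue
        if not getattr(ann, pass_field):
            continue
        if not ann.passes_region_consistency:
            continue
        region = ann.region
        row = {
            "chromosome": ann.tc_end.reference,
            "region_start": region.start if region else np.nan,
            "region_end": region.end if region else np.nan,
            "tc_position": ann.tc_end.position,
            "tc_strand": ann.tc_end.strand,
            "tc_support": ann.tc_end.support,
            "distance": ann.distance,
            "transcript_id": ann.transcript.transcript_id,
            "gene_id": ann.transcript.gene_id,
            "gene_name": ann.transcript.gene_name,
            "biotype": ann.transcript.biotype,
            "base_mean": res["base_mean"],
            "log2_fold_change": res["log2_fold_change"],
            "p_value": res["p_value"],
            "adjusted_p": apv,
        }
        for col in res.index:
            if col.startswith("count_") or col.startswith("norm_"):
                row[col] = res[col]
        rows.append(row)
    rows.sort(key=lambda r: (r["adjusted_p"], r["p_value"]))
    return rows
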