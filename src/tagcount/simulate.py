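"""Truth-annotated synthetic data for the whole pipeline.

Generates a toy genome with non-overlapping transcripts whose 3'-end
downstream contexts are controlled (A-poor at true polyA sites, A-rich at
planted internal misprime sites), then tagged read pairs — read 1 carries
UMI + sample index + polyT and reads antisense off the (mis)priming site,
read 2 reads the sense fragment — emitted as pre-aligned SAM records (and
optionally FASTQ), with PCR duplicates sharing UMIs at a configurable
rate.  Count-level shortcuts produce two-condition negative-binomial
matrices with known fold changes and an ERCC-style 4-tier spike design
(x5 / x1 / x0.2 / x0.1 in triplicate).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .dedup import AlignmentPair
from .detag import TagLayout, rename_with_tags
from .formats import FastqRecord, SamRecord, TranscriptAnnotation
from .quant_de import CountMatrix
from .tc_ends import polya_artifact, reverse_complement

_BASES = np.array(list("ACGT"))
_ADAPTER = "AGATCGGAAGAGCACACGTCTGAACTCCAGTCACGATCGGAAGAGCGTCGTGTAGGGAAAGAGTGTAGAT"


def default_index_whitelist(n_samples: int, seed: int = 20150805) -> dict[str, str]:
    """Deterministic 8-base sample indices at pairwise Hamming distance >= 3."""
    rng = np.random.default_rng(seed)
    chosen: list[str] = []
    while len(chosen) < n_samples:
        cand = "".join(rng.choice(_BASES, size=8))
        if all(sum(a != b for a, b in zip(cand, c)) >= 3 for c in chosen):
            chosen.append(cand)
    return {idx: f"s{i + 1}" for i, idx in enumerate(chosen)}


@dataclass
class SimConfig:
    """Study conditions for the synthetic experiment.

    Defaults describe the desk-scale reference experiment: 50 transcripts
    on 2 contigs, 6 mutant vs 6 sibling samples, ~200k read pairs in
    total, negative-binomial counts (dispersion 0.1) with ten transcripts
    at 4-fold change (five up, five down), a 5% PCR duplication rate and
    five internal misprime sites with rule-matching A-rich contexts.
    """

    seed: int = 0
    n_contigs: int = 2
    contig_length: int = 160_000
    n_transcripts: int = 50
    transcript_length: tuple[int, int] = (800, 2000)
    min_gap: int = 3000
    baseline_mean: float = 250.0  # median reads / transcript / sample
    baseline_sdlog: float = 0.7
    dispersion: float = 0.1
    n_samples_per_condition: int = 6
    conditions: tuple[str, str] = ("sib", "mut")
    fold_changes: Mapping[int, float] | None = None  # transcript index -> FC in mut
    duplication_rate: float = 0.05
    n_misprime_sites: int = 5
    misprime_fraction: float = 0.25
    error_rate: float = 0.001
    read1_length: int = 75
    read2_length: int = 54
    fragment_range: tuple[int, int] = (70, 270)
    depth_sdlog: float = 0.2
    spike_tiers: tuple[float, ...] = (5.0, 1.0, 0.2, 0.1)
    n_spikes: int = 92
    spike_replicates: int = 3

    def __post_init__(self) -> None:
        for rate in (self.duplication_rate, self.misprime_fraction, self.error_rate):
            if not 0.0 <= rate <= 1.0:
                raise ValueError("rates must lie in [0, 1]")
        if self.fold_changes is None:
            up = {i: 4.0 for i in range(0, min(5, self.n_transcripts))}
            down = {i: 0.25 for i in range(5, min(10, self.n_transcripts))}
            self.fold_changes = {**up, **down}

    def make_layout(self) -> TagLayout:
        n = 2 * self.n_samples_per_condition
        whitelist = default_index_whitelist(n)
        labels = self.sample_labels()
        mapping = {idx: labels[i] for i, idx in enumerate(whitelist)}
        return TagLayout(index_whitelist=mapping)

    def sample_labels(self) -> list[str]:
        c1, c2 = self.conditions
        k = self.n_samples_per_condition
        return [f"{c1}{i + 1}" for i in range(k)] + [f"{c2}{i + 1}" for i in range(k)]

    def samples(self) -> list[tuple[str, str]]:
        c1, c2 = self.conditions
        k = self.n_samples_per_condition
        return [(lab, c1 if i < k else c2) for i, lab in enumerate(self.sample_labels())]


@dataclass
class TranscriptTruth:
    transcript_id: str
    gene_id: str
    chromosome: str
    strand: str
    tx_start: int
    tx_end: int
    end_position: int  # true TC 3' end (1-based)
    baseline_mean: float
    fold_change: float
    misprime_position: int | None = None  # internal priming site, or None


@dataclass
class SimulatedExperiment:
    config: SimConfig
    genome: dict[str, str]
    annotations: list[TranscriptAnnotation]
    transcripts: list[TranscriptTruth]
    layout: TagLayout
    pairs: list[AlignmentPair] = field(default_factory=list)
    sam_records: list[SamRecord] = field(default_factory=list)
    truth_table: pd.DataFrame = field(default_factory=pd.DataFrame)

    @property
    def reference_lengths(self) -> dict[str, int]:
        return {name: len(seq) for name, seq in self.genome.items()}


def _random_sequence(rng: np.random.Generator, n: int) -> np.ndarray:
    return rng.choice(_BASES, size=n)


def _a_poor_context(rng: np.random.Generator) -> str:
    """A 10-mer that no mispriming rule flags (true-end downstream context)."""
    while True:
        seq = "".join(rng.choice(_BASES, size=10, p=[0.1, 0.3, 0.3, 0.3]))
        if seq.count("A") <= 3 and not polya_artifact(seq)[0]:
            return seq


def _a_rich_context(rng: np.random.Generator, kind: int) -> str:
    """A 10-mer satisfying one of the mispriming rules (cycled by kind)."""
    from .tc_ends import POLYA_PATTERNS

    kind = kind % 3
    if kind == 0:  # 4 leading As
        seq = "AAAA" + "".join(rng.choice(_BASES, size=6))
    elif kind == 1:  # more than 6 As in total
        n_a = int(rng.integers(7, 10))
        positions = rng.permutation(10)[:n_a]
        chars = rng.choice(np.array(list("CGT")), size=10)
        chars[positions] = "A"
        seq = "".join(chars)
    else:  # one of the empirical patterns
        pattern = POLYA_PATTERNS[int(rng.integers(len(POLYA_PATTERNS)))]
        seq = "".join(
            "A" if p == "A" else str(rng.choice(np.array(list("CGT")))) for p in pattern
        )
    assert polya_artifact(seq)[0]
    return seq


def simulate_genome_and_annotation(
    config: SimConfig, rng: np.random.Generator | None = None
) -> tuple[dict[str, str], list[TranscriptAnnotation], list[TranscriptTruth]]:
    """Toy genome + transcript set with controlled 3'-downstream contexts."""
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    contigs = {
        f"chr{i + 1}": _random_sequence(rng, config.contig_length)
        for i in range(config.n_contigs)
    }
    names = list(contigs)
    transcripts: list[TranscriptTruth] = []
    annotations: list[TranscriptAnnotation] = []
    lo, hi = config.transcript_length
    cursors = {name: 500 for name in names}
    misprime_every = (
        max(1, config.n_transcripts // config.n_misprime_sites)
        if config.n_misprime_sites
        else 0
    )
    placed_mispr = 0
    for t in range(config.n_transcripts):
        length = int(rng.integers(lo, hi + 1))
        strand = "+" if rng.random() < 0.5 else "-"
        placed = False
        for name in sorted(names, key=lambda n: cursors[n]):
            start = cursors[name] + int(rng.integers(0, 500))
            end = start + length - 1
            if end + config.min_gap < config.contig_length - 500:
                cursors[name] = end + config.min_gap
                placed = True
                break
        if not placed:
            raise ValueError("genome too small for requested transcripts")
        end_pos = end if strand == "+" else start
        seq = contigs[name]
        context = _a_poor_context(rng)
        if strand == "+":
            seq[end_pos : end_pos + 10] = list(context)
        else:
            seq[end_pos - 11 : end_pos - 1] = list(reverse_complement(context))

        misprime_position = None
        if (
            config.n_misprime_sites
            and placed_mispr < config.n_misprime_sites
            and t % misprime_every == 0
        ):
            offset = int(rng.integers(400, 501))
            mis_context = _a_rich_context(rng, placed_mispr)
            if strand == "+":
                misprime_position = end_pos - offset
                seq[misprime_position : misprime_position + 10] = list(mis_context)
            else:
                misprime_position = end_pos + offset
                seq[misprime_position - 11 : misprime_position - 1] = list(
                    reverse_complement(mis_context)
                )
            placed_mispr += 1

        baseline = float(np.exp(rng.normal(math.log(config.baseline_mean), config.baseline_sdlog)))
        fc = float(config.fold_changes.get(t, 1.0))
        tx = TranscriptTruth(
            transcript_id=f"TX{t + 1:04d}",
            gene_id=f"GENE{t + 1:04d}",
            chromosome=name,
            strand=strand,
            tx_start=start,
            tx_end=end,
            end_position=end_pos,
            baseline_mean=baseline,
            fold_change=fc,
            misprime_position=misprime_position,
        )
        transcripts.append(tx)
        annotations.append(
            TranscriptAnnotation(
                transcript_id=tx.transcript_id,
                gene_id=tx.gene_id,
                gene_name=f"gene{t + 1}",
                chromosome=name,
                strand=strand,
                three_prime_end=end_pos,
            )
        )
    genome = {name: "".join(arr) for name, arr in contigs.items()}
    return genome, annotations, transcripts


def simulate_reads(
    config: SimConfig,
    genome: dict[str, str],
    transcripts: Sequence[TranscriptTruth],
    rng: np.random.Generator | None = None,
) -> tuple[list[AlignmentPair], list[SamRecord], pd.DataFrame]:
    """Pre-aligned read pairs with per-read truth.

    Per sample and transcript the molecule count is negative-binomial
    with mean baseline x fold change (mutant condition) x depth factor;
    each molecule gets a random UMI and a geometric number of PCR copies
    so that the expected flagged-duplicate fraction equals the configured
    duplication rate.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed + 1)
    samples = config.samples()
    layout = config.make_layout()
    index_of_label = {lab: idx for idx, lab in layout.index_whitelist.items()}
    depth = np.exp(rng.normal(0.0, config.depth_sdlog, size=len(samples)))
    alpha = config.dispersion
    frag_lo, frag_hi = config.fragment_range
    insert1 = config.read1_length - (
        layout.umi_length + layout.index_length + len(layout.spacer) + 14
    )

    pairs: list[AlignmentPair] = []
    sam_records: list[SamRecord] = []
    truth_rows: list[dict] = []
    mutant_cond = config.conditions[1]
    mol_counter = 0
    for s_idx, (label, condition) in enumerate(samples):
        index_seq = index_of_label[label]
        for tx in transcripts:
            mean = tx.baseline_mean * depth[s_idx]
            if condition == mutant_cond:
                mean *= tx.fold_change
            if alpha > 0:
                n_mol = int(rng.negative_binomial(1.0 / alpha, 1.0 / (1.0 + alpha * mean)))
            else:
                n_mol = int(rng.poisson(mean))
            if n_mol == 0:
                continue
            mispr = (
                rng.random(n_mol) < config.misprime_fraction
                if tx.misprime_position is not None
                else np.zeros(n_mol, dtype=bool)
            )
            frag_lens = rng.integers(frag_lo, frag_hi + 1, size=n_mol)
            copies = rng.geometric(1.0 - config.duplication_rate, size=n_mol)
            umis = ["".join(u) for u in rng.choice(_BASES, size=(n_mol, layout.umi_length))]
            for m in range(n_mol):
                mol_counter += 1
                end_pos = tx.misprime_position if mispr[m] else tx.end_position
                origin = "misprime" if mispr[m] else "true_end"
                L = int(frag_lens[m])
                for c in range(int(copies[m])):
                    read_id = f"sim{mol_counter}c{c}"
                    tagged = rename_with_tags(read_id, umis[m], index_seq)
                    r1, r2 = _make_sam_pair(
                        tagged, tx, end_pos, L, insert1, config, rng
                    )
                    sam_records.extend((r1, r2))
                    pair = _pair_from_records(r1, r2, umis[m], label)
                    pairs.append(pair)
                    truth_rows.append(
                        {
                            "read_id": read_id,
                            "tagged_id": tagged,
                            "sample": label,
                            "condition": condition,
                            "transcript_id": tx.transcript_id,
                            "origin": origin,
                            "end_chrom": tx.chromosome,
                            "end_pos": end_pos,
                            "end_strand": tx.strand,
                            "umi": umis[m],
                            "molecule_id": mol_counter,
                            "pcr_copy": c > 0,
                        }
                    )
    truth = pd.DataFrame(truth_rows)
    return pairs, sam_records, truth


def _make_sam_pair(
    read_id: str,
    tx: TranscriptTruth,
    end_pos: int,
    frag_len: int,
    insert1: int,
    config: SimConfig,
    rng: np.random.Generator,
) -> tuple[SamRecord, SamRecord]:
    m1 = min(insert1, frag_len)
    m2 = min(config.read2_length, frag_len)
    nm1 = int(rng.binomial(m1, config.error_rate))
    nm2 = int(rng.binomial(m2, config.error_rate))
    if tx.strand == "+":
        # read 1 reverse, ending at the priming junction; read 2 forward
        r1_pos = end_pos - m1 + 1
        r2_pos = end_pos - frag_len + 1
        flag1, flag2 = 0x1 | 0x2 | 0x10 | 0x40, 0x1 | 0x2 | 0x20 | 0x80
        tlen = frag_len
    else:
        r1_pos = end_pos
        r2_pos = end_pos + frag_len - m2
        flag1, flag2 = 0x1 | 0x2 | 0x20 | 0x40, 0x1 | 0x2 | 0x10 | 0x80
        tlen = -frag_len
    r1 = SamRecord(
        read_id=read_id, flag=flag1, reference=tx.chromosome, position=r1_pos,
        mapq=60, cigar=f"{m1}M", rnext="=", pnext=r2_pos, tlen=tlen,
        mismatches=nm1,
    )
    r2 = SamRecord(
        read_id=read_id, flag=flag2, reference=tx.chromosome, position=r2_pos,
        mapq=60, cigar=f"{m2}M", rnext="=", pnext=r1_pos, tlen=-tlen,
        mismatches=nm2,
    )
    return r1, r2


def _pair_from_records(
    r1: SamRecord, r2: SamRecord, umi: str, label: str
) -> AlignmentPair:
    mates = sorted(
        [(r1.position, r1.reference_end, r1.is_reverse), (r2.position, r2.reference_end, r2.is_reverse)]
    )
    return AlignmentPair(
        read_id=r1.read_id,
        reference=r1.reference,
        outer_start=mates[0][0],
        outer_end=max(mates[0][1], mates[1][1]),
        orientation="".join("R" if rev else "F" for _, _, rev in mates),
        umi=umi,
        score=0.0,
        mismatches=r2.mismatches or 0,
        sample_label=label,
        read1=r1,
        read2=r2,
    )


def simulate_experiment(config: SimConfig) -> SimulatedExperiment:
    """Genome, annotation and reads in one deterministic step."""
    rng = np.random.default_rng(config.seed)
    genome, annotations, transcripts = simulate_genome_and_annotation(config, rng)
    pairs, sam_records, truth = simulate_reads(config, genome, transcripts, rng)
    return SimulatedExperiment(
        config=config,
        genome=genome,
        annotations=annotations,
        transcripts=transcripts,
        layout=config.make_layout(),
        pairs=pairs,
        sam_records=sam_records,
        truth_table=truth,
    )


def reads_to_fastq(
    experiment: SimulatedExperiment,
    rng: np.random.Generator | None = None,
) -> tuple[list[FastqRecord], list[FastqRecord]]:
    """Raw tagged FASTQ pairs matching the experiment's SAM records.

    Read 1 = UMI + index + spacer + T14 + antisense flank (adapter-padded
    to the read length); read 2 = the sense fragment start.  Sequencing
    errors are substitutions at the configured rate, applied outside the
    tag so a zero-error run detags perfectly.
    """
    config = experiment.config
    rng = rng if rng is not None else np.random.default_rng(config.seed + 2)
    layout = experiment.layout
    index_of_label = {lab: idx for idx, lab in layout.index_whitelist.items()}
    truth = experiment.truth_table.set_index("tagged_id")
    reads1: list[FastqRecord] = []
    reads2: list[FastqRecord] = []
    for pair in experiment.pairs:
        info = truth.loc[pair.read_id]
        genome_seq = experiment.genome[pair.reference]
        r1, r2 = pair.read1, pair.read2
        seg1 = genome_seq[r1.position - 1 : r1.reference_end]
        seg2 = genome_seq[r2.position - 1 : r2.reference_end]
        # read 1 reads the antisense flank off the priming site
        insert1 = reverse_complement(seg1) if r1.is_reverse else seg1
        read2_seq = reverse_complement(seg2) if r2.is_reverse else seg2
        tag = info["umi"] + index_of_label[info["sample"]] + layout.spacer + "T" * 14
        seq1 = (tag + _mutate(insert1, config.error_rate, rng) + _ADAPTER)[
            : config.read1_length
        ]
        seq2 = (_mutate(read2_seq, config.error_rate, rng) + _ADAPTER)[
            : config.read2_length
        ]
        plain_id = info.name.rsplit("#", 2)[0]
        reads1.append(FastqRecord(plain_id, seq1, "I" * len(seq1)))
        reads2.append(FastqRecord(plain_id, seq2, "I" * len(seq2)))
    return reads1, reads2


def _mutate(seq: str, rate: float, rng: np.random.Generator) -> str:
    if rate <= 0.0 or not seq:
        return seq
    arr = np.array(list(seq))
    hits = np.flatnonzero(rng.random(len(arr)) < rate)
    for i in hits:
        choices = [b for b in "ACGT" if b != arr[i]]
        arr[i] = choices[int(rng.integers(3))]
    return "".join(arr)


# ---------------------------------------------------------------------------
# Count-level shortcuts
# ---------------------------------------------------------------------------

def simulate_counts(
    config: SimConfig,
    rng: np.random.Generator | None = None,
    n_regions: int | None = None,
) -> tuple[CountMatrix, np.ndarray]:
    """NB counts per region x sample with known log2 fold changes.

    Means are log-normal around the configured baseline, depth factors
    log-normal, fold changes applied to the mutant condition.  Returns
    (matrix, true log2 fold change per region).
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    n = n_regions if n_regions is not None else config.n_transcripts
    samples = config.samples()
    mutant = config.conditions[1]
    means = np.exp(rng.normal(math.log(config.baseline_mean), config.baseline_sdlog, size=n))
    depth = np.exp(rng.normal(0.0, config.depth_sdlog, size=len(samples)))
    fc = np.ones(n)
    for i, value in (config.fold_changes or {}).items():
        if i < n:
            fc[i] = value
    mu = means[:, None] * depth[None, :]
    is_mut = np.array([cond == mutant for _, cond in samples])
    mu[:, is_mut] *= fc[:, None]
    counts = _nb_draw(mu, config.dispersion, rng)
    regions = [f"region{i + 1}" for i in range(n)]
    return CountMatrix(regions, samples, counts), np.log2(fc)


def _nb_draw(mu: np.ndarray, alpha: float, rng: np.random.Generator) -> np.ndarray:
    if alpha <= 0:
        return rng.poisson(mu)
    return rng.negative_binomial(1.0 / alpha, 1.0 / (1.0 + alpha * np.maximum(mu, 1e-12)))


def simulate_spike_counts(
    config: SimConfig,
    rng: np.random.Generator | None = None,
    n_background: int = 500,
    technical_dispersion: float = 0.02,
) -> tuple[CountMatrix, np.ndarray, dict[str, float]]:
    """The 4-tier spike design at the count level.

    92 spike units span an abundance ladder (so the low tail falls below
    detection) and are scaled per sample by its tier multiplier (x5, x1,
    x0.2, x0.1, in triplicate); constant-mean background regions model
    the endogenous transcriptome the size factors normalise against.
    Returns (matrix, spike-row mask, tier multiplier per sample).
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    tiers = config.spike_tiers
    reps = config.spike_replicates
    samples = [
        (f"x{tier:g}_r{r + 1}", f"x{tier:g}") for tier in tiers for r in range(reps)
    ]
    tier_of_sample = {label: tier for (label, _), tier in zip(
        samples, [t for t in tiers for _ in range(reps)]
    )}
    depth = np.exp(rng.normal(0.0, config.depth_sdlog, size=len(samples)))

    bg_means = np.exp(rng.normal(math.log(config.baseline_mean), config.baseline_sdlog, size=n_background))
    ladder = 2.0 ** np.linspace(12, -6, config.n_spikes)
    mult = np.array([tier_of_sample[label] for label, _ in samples])
    mu_bg = bg_means[:, None] * depth[None, :]
    mu_spike = ladder[:, None] * mult[None, :] * depth[None, :]
    counts = np.vstack(
        [
            _nb_draw(mu_bg, technical_dispersion, rng),
            _nb_draw(mu_spike, technical_dispersion, rng),
        ]
    )
    regions = [f"bg{i + 1}" for i in range(n_background)] + [
        f"spike{i + 1}" for i in range(config.n_spikes)
    ]
    spike_mask = np.zeros(len(regions), dtype=bool)
    spike_mask[n_background:] = True
    return CountMatrix(regions, samples, counts), spike_mask, tier_of_sample


def spike_pairwise_comparisons(
    matrix: CountMatrix,
    spike_mask: np.ndarray,
    tier_of_sample: dict[str, float],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """All pairwise tier comparisons: expected vs observed mean spike log2FC.

    For each condition pair the DE analysis runs on the six relevant
    samples; the observed value is the mean estimated log2 fold change
    over detected spikes.  Detection mirrors the read-level pipeline: a
    spike needs at least 3 supporting reads overall (the TC 3' end
    support threshold) and reads in both conditions so the fold change
    is estimable.
    """
    from itertools import combinations

    from .quant_de import de_analysis

    conditions = []
    for _, cond in matrix.samples:
        if cond not in conditions:
            conditions.append(cond)
    rows = []
    for cond_a, cond_b in combinations(conditions, 2):
        keep = [
            i for i, (_, cond) in enumerate(matrix.samples) if cond in (cond_a, cond_b)
        ]
        sub = CountMatrix(
            [matrix.regions[i] for i in range(len(matrix.regions))],
            [matrix.samples[i] for i in keep],
            matrix.counts[:, keep],
        )
        results = de_analysis(sub)
        tier_a = tier_of_sample[[lab for lab, c in sub.samples if c == cond_a][0]]
        tier_b = tier_of_sample[[lab for lab, c in sub.samples if c == cond_b][0]]
        expected = math.log2(tier_b / tier_a)  # condition 2 over condition 1
        in_a = np.array([c == cond_a for _, c in sub.samples])
        total_a = sub.counts[:, in_a].sum(axis=1)
        total_b = sub.counts[:, ~in_a].sum(axis=1)
        detected = (
            spike_mask
            & (total_a + total_b >= 3)
            & (total_a > 0)
            & (total_b > 0)
        )
        observed = float(results.loc[detected, "log2_fold_change"].mean())
        n_signif = int(
            (results.loc[detected, "adjusted_p"] <= alpha).sum()
        )
        rows.append(
            {
                "condition1": cond_a,
                "condition2": cond_b,
                "expected_log2fc": expected,
                "observed_log2fc": observed,
                "n_detected_spikes": int(detected.sum()),
                "n_significant_spikes": n_signif,
            }
        )
    return pd.DataFrame(rows)
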