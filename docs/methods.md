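# Methods

This note records the models, rules and numerical choices behind each
stage of `tagcount`, what the synthetic-data generator does and does not
emulate, and the design decisions taken where several readings were
defensible.

## Library model and coordinate conventions

The pipeline assumes 3′-tag paired-end libraries: each sequenced fragment
derives from the 3′ end of a polyadenylated transcript. Read 1 starts
with a 12-base UMI, an 8-base inline sample index, a short fixed spacer
(`CG` by default) and an anchored polyT run (T₁₄ in the priming oligo),
followed by antisense transcript sequence read off the priming junction.
Read 2 reads the sense strand from the fragment's 5′ end. Consequently
the aligned read-1 base adjacent to the trimmed polyT marks the
transcript's 3′ terminus, and the transcript strand is the *opposite* of
the read-1 alignment strand (forward-aligned read 1 ⇒ '−' transcript, end
at the leftmost aligned base; reverse-aligned ⇒ '+', end at the rightmost
aligned base). Soft-clipped bases are outside the aligned portion and do
not move the junction.

All internal coordinates are 1-based inclusive (SAM convention). BED
output converts to 0-based half-open inside the writers only.

## Tag parsing (detag)

* `min_polyt = 10` T bases (the oligo anchors 14, but sequencing miscalls
  occur); the polyT run tolerates one non-T base per ten Ts already seen
  and always ends on a T, so a trailing miscall belongs to the insert.
* The spacer is searched but optional: 0–2 bases may be consumed, with an
  exact spacer match preferred. Earlier-protocol primers lack it.
* Rejection reasons are `too_short`, `no_polyT`, `empty_insert` (an
  insert-free read is unmappable) and `unassigned_index`.
* Index matching is exact by default (`max_index_mismatches = 0`); the
  whitelist validator enforces pairwise separability when a tolerance is
  enabled. UMIs may contain N; such UMIs never match one another during
  duplicate marking.
* The UMI and index are appended to the read name with a reserved `#`
  delimiter; extraction is exact inversion and an input name containing
  `#` is an error rather than a silent ambiguity.
* The unspecified "quality trimming" of the original protocol is exposed
  only as an optional fixed-length 3′ trim of the insert
  (`TagLayout.fixed_trim`), not a quality heuristic.

## Duplicate marking (dedup)

The duplicate key is (reference, outer start, outer end, pair
orientation, UMI), where outer coordinates are the leftmost and rightmost
aligned bases over both mates and orientation is the strand pair ordered
by position (FR/RF/FF/RR). UMI comparison is exact — no error-network
correction. Within a group the representative is the pair with the
highest summed base quality, ties broken by lexicographic read id; this
convention is deterministic and Picard-like, since no published rule
exists for the UMI-aware variant. Pairs with an unmapped mate have no
outer coordinates and are never flagged; they are likewise excluded from
the denominator of `duplicate_rate`. Marking is idempotent (flags are
recomputed from scratch each call).

## Peak calling (peaks)

Non-duplicate, mapped read 2s with at most 2 mismatches (NM tag) are
pooled over all samples and binned by leftmost base into 100-bp bins. A
two-state HMM with Poisson emissions is fitted to the concatenated bin
counts by EM (per-contig sequence boundaries respected): background mean
λ₀ < peak mean λ₁ enforced by state relabelling. Choices:

* EM: ≤ 200 iterations, log-likelihood tolerance 1e-6, deterministic
  data-driven initialisation (λ₀ = mean of the lower half of bins,
  λ₁ = mean of the top 1 %), so repeated fits are identical without a
  random seed.
* Initial transitions favour background (background→background 0.999,
  peak→peak 0.9), matching sparse-peak expectations; both are
  re-estimated.
* Posterior decoding: bins with P(peak | data) ≥ 0.5 are selected and
  maximal runs of adjacent selected bins merge into regions, whose score
  is the maximum member posterior. Raising the threshold can only shrink
  the selected set, so total region length is monotone.
* A fit with λ₁ < 2·λ₀ is flagged degenerate (no genuine two-state
  structure) and calls no regions; an all-zero track is an error.

Poisson emissions are the simplest adequate family and a documented swap
point; the EM itself is delegated to `hmmlearn`.

## TC 3′-end calling (tc_ends)

For each region, candidates are the distinct (position, strand) read-1
junctions of non-duplicate pairs whose read 2 lies in the region (by
leftmost base — the stated reading of "read 2s aligned in that region").
A candidate is discarded when

* support < 3 reads (`low_support`), or
* the 10 genomic bases 3′ of the end in transcript orientation
  (reverse-complemented on '−') are A-enriched: first four bases all A
  (`polyA_start`), more than six A in total (`polyA_total`), or an exact
  match to one of the twelve empirical patterns with A = adenine and
  B ∈ {C, G, T} (`polyA_pattern`). N counts as non-A and does not
  satisfy B — conservative toward retention. At a contig edge the
  context truncates and only the rules applicable to the available bases
  fire.

The rules are applied in that order, so a sequence satisfying several
reports the first. The surviving candidate of maximal support represents
the region; ties break to the smaller coordinate. A run-level list of
known false ends (genomic positions) may be supplied and is subtracted
before selection; recurrent artifacts such as A-rich rRNA loci are
handled through that mechanism rather than hard-coding.

## Annotation association (annotate)

Transcript 3′ ends are indexed per (chromosome, strand); blacklisted
transcripts are removed before the search. The nearest end by absolute
genomic distance is reported with a signed distance in transcript
orientation (negative = annotated end 5′ of the TC end); equidistant ties
break by lexicographic transcript id. Both windows are closed intervals:
stringent [−100, +100], relaxed [−100, +5000], so the stringent-pass set
is a subset of the relaxed-pass set by construction. The
region-consistency rule passes when the region's 3′-most coordinate (its
right edge on '+', left edge on '−') trails the TC end by at most 150
bases. Direction constraints are imposed only by the asymmetric windows;
the search itself is two-sided.

## Counting and differential abundance (quant_de)

Counts are non-duplicate read 2s per region per sample (leftmost base in
the region). Size factors are classic median-of-ratios: per sample, the
median over regions (with all-positive counts) of count/geometric-mean;
no post-hoc rescaling, matching the reference implementation of that
estimator exactly (verified against an independent implementation in the
test suite).

Per region the model is count<sub>ij</sub> ~ NB(mean s<sub>j</sub>·q<sub>i,cond(j)</sub>,
dispersion α<sub>i</sub>). Group means are fitted by Fisher scoring,
vectorised across regions (one-dimensional in log q per condition), and
the condition effect is a Wald test on log₂(q₂/q₁) with variance from the
Fisher information. Numerical choices:

* Dispersion: method-of-moments from pooled within-condition variance of
  normalised counts, corrected for the shot-noise component, clipped to
  [1e-8, 10]; a trend α(μ) = a₀ + a₁/μ is fitted across regions by least
  squares with one 10 %-trimming pass; each raw estimate is shrunk toward
  the trend in log space with weight 0.7. The shrinkage weight is a
  parameter (`shrinkage`).
* Reference distribution: t with 2(n − 2) degrees of freedom, n = total
  samples. This small-sample allowance for dispersion-estimation noise
  was chosen by null-simulation calibration across dispersions 0.05–0.3
  and 3–6 samples per condition, where it holds the empirical type-I
  error at 0.046–0.052 for nominal 0.05 (a plain normal reference is
  liberal at 0.06–0.13 in the same settings).
* All-zero regions get a missing p-value. Group means are floored at
  1e-10 on the natural scale, so a condition with no reads yields an
  extreme but finite fold change with a correspondingly huge standard
  error.
* Independent filtering: candidate thresholds are 40 quantiles of the
  base mean (0–95 %); the threshold maximising BH rejections at the given
  α wins, smallest on ties; filtered regions get a missing adjusted p.
* Fold-change direction is condition 2 over condition 1 in the order the
  conditions first appear in the sample table (put the perturbed
  condition second).

This module is a contract-level stand-in for a dedicated DE engine, not a
numerical clone of one; the per-region fit is a documented swap point.

## Synthetic data (simulate)

The generator's defaults define the reference desk-scale experiment: 2
contigs × 160 kb, 50 non-overlapping transcripts (800–2000 bp, ≥ 3 kb
apart), 6 + 6 samples, per-transcript baseline log-normal with median 250
reads/sample and σ(log) = 0.7, NB dispersion 0.1, log-normal depth
factors (σ = 0.2), fold change 4 on five transcripts and 0.25 on five
more, 5 % PCR duplication, five internal misprime sites, substitution
error rate 0.001, fragment length uniform on [70, 270] (the library's
size-selection window), read lengths 75 (read 1) and 54 (read 2). That
yields ≈ 200–260 k read pairs.

Controlled features:

* True 3′ ends get planted downstream 10-mers that no artifact rule
  flags; misprime sites (400–500 bp upstream of the true end, inside the
  transcript) get contexts that satisfy one of the three rules, cycling
  through rule kinds. A configurable fraction (0.25) of a carrier
  transcript's molecules prime at the internal site.
* PCR copies per molecule are geometric with success probability
  1 − duplication_rate, so the expected flagged fraction equals the
  configured rate exactly; copies share coordinates and UMI.
* Each read pair joins the truth table (origin transcript, priming site,
  sample, UMI, molecule id, PCR-copy flag) by read id with no orphans.
* Count-level shortcuts: `simulate_counts` draws NB region × sample
  matrices directly; `simulate_spike_counts` implements the four-tier
  spike design (×5/×1/×0.2/×0.1 in triplicate) as 92 spike units on a
  2¹² … 2⁻⁶ abundance ladder — so the low tail falls below detection —
  over a 500-region constant background that anchors the size factors,
  with technical dispersion 0.02. `spike_pairwise_comparisons` runs all
  six pairwise tier comparisons and reports expected vs observed mean
  log₂ fold change over detected spikes (detected = ≥ 3 reads overall and
  reads in both conditions, mirroring the end-support threshold).

Not emulated: indels, position- or GC-dependent coverage bias, realistic
quality profiles, UMI errors introduced during amplification, and
read-level spike contigs (the spike design is exercised at the count
level). Passing tests therefore demonstrate the pipeline's logic and
statistics under idealised alignment, not robustness to aligner error.

## Replicates versus depth (permute)

Per repetition, both condition pools are downsampled to the same size,
then for each k split i.i.d.-uniformly (multinomial, not balanced) into k
pseudo-samples per condition — the simplest faithful reading of random
index replacement. Total reads are conserved across k within a
repetition. Duplicate marking is redone inside each merged pool, since
duplicates are defined within the pool being analysed, and the full
pipeline (peaks → ends → DE, relaxed window) is rerun per (k,
repetition). The plan defaults to k = 2…11 with 10 repetitions; the test
suite and the acceptance script run k ∈ {2, 11} with 5 repetitions on
pools of ≈ 15 k pairs with fold changes 1.5/0.67 on twenty transcripts —
sizes chosen so a single desk-scale run exercises the full design while
leaving the replicate-number effect visible (with constant total reads
the per-comparison information is flat in k, but the error degrees of
freedom grow with k, which is what drives the gain).

## Known limitations

* One TC 3′ end represents each region; closely spaced alternative ends
  inside one region are reported only through the candidate list.
* The duplicate-rate estimate shares the usual UMI caveats: UMI
  collisions between independent molecules and UMI errors during
  amplification bias it slightly in opposite directions.
* The Wald test's df correction is calibrated for the two-condition
  design only; multi-factor designs are out of scope.
* GTF support covers transcript features with standard attributes, not
  full feature hierarchies; CRAM and indexed random access are out of
  scope.
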