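import numpy as np
import pytest

from tagcount.dedup import (
    AlignmentPair,
    duplicate_key,
    duplicate_rate,
    mark_duplicates,
    pair_records,
)
from tagcount.formats import SamRecord


def _pair(read_id="r1", ref="chr1", start=100, end=300, orient="FR",
          umi="A" * 12, score=0.0):
    return AlignmentPair(
        read_id=read_id, reference=ref, outer_start=start, outer_end=end,
        orientation=orient, umi=umi, score=score,
    )


def random_pairs(rng, n, n_positions=12, n_umis=6):
    """Instances with heavy coordinate/UMI collisions."""
    pairs = []
    umis = ["".join(rng.choice(list("ACGT"), 12)) for _ in range(n_umis)]
    for i in range(n):
        start = int(rng.integers(1, n_positions)) * 50
        length = int(rng.integers(1, 4)) * 100
        pairs.append(
            _pair(
                read_id=f"r{i}",
                start=start,
                end=start + length,
                orient=str(rng.choice(["FR", "RF"])),
                umi=str(rng.choice(umis)),
                score=float(rng.integers(0, 5)),
            )
        )
    return pairs


def oracle_flags(pairs, use_umi=True):
    """Exhaustive pairwise comparison: connected components of key equality."""
    n = len(pairs)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def same(a, b):
        if not (a.both_mapped and b.both_mapped):
            return False
        if (a.reference, a.outer_start, a.outer_end, a.orientation) != (
            b.reference, b.outer_start, b.outer_end, b.orientation,
        ):
            return False
        if use_umi:
            if "N" in a.umi or "N" in b.umi:
                return False
            return a.umi == b.umi
        return True

    for i in range(n):
        for j in range(i + 1, n):
            if same(pairs[i], pairs[j]):
                parent[find(i)] = find(j)
    groups = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(i)
    flags = [False] * n
    for members in groups.values():
        if len(members) == 1:
            continue
        members.sort(key=lambda i: (-pairs[i].score, pairs[i].read_id))
        for i in members[1:]:
            flags[i] = True
    return flags


class TestDuplicateKey:
    def test_same_coordinates_and_umi_share_a_key(self):
        assert duplicate_key(_pair("a")) == duplicate_key(_pair("b"))

    def test_one_base_umi_difference_separates(self):
        a = _pair(umi="A" * 12)
        b = _pair(umi="A" * 11 + "C")
        assert duplicate_key(a) != duplicate_key(b)

    def test_outer_end_shift_separates(self):
        assert duplicate_key(_pair(end=300)) != duplicate_key(_pair(end=301))

    def test_orientation_in_key(self):
        assert duplicate_key(_pair(orient="FR")) != duplicate_key(_pair(orient="RF"))

    def test_umi_with_n_never_matches(self):
        a = _pair("a", umi="N" + "A" * 11)
        b = _pair("b", umi="N" + "A" * 11)
        assert duplicate_key(a) != duplicate_key(b)

    def test_unmapped_pair_not_keyable(self):
        pair = AlignmentPair("r", "*", 0, 0, "", "A" * 12)
        assert duplicate_key(pair) is None


class TestMarkDuplicates:
    def test_group_of_three_flags_two(self):
        pairs = [_pair(f"r{i}") for i in range(3)]
        mark_duplicates(pairs)
        assert sum(p.duplicate for p in pairs) == 2

    def test_all_distinct_keys_flag_nothing(self):
        pairs = [_pair(f"r{i}", start=100 + 10 * i, end=300 + 10 * i) for i in range(100)]
        mark_duplicates(pairs)
        assert not any(p.duplicate for p in pairs)

    def test_four_umis_twice_each(self):
        umis = ["A" * 12, "C" * 12, "G" * 12, "T" * 12]
        pairs = [_pair(f"r{i}{u[0]}", umi=u) for u in umis for i in range(2)]
        mark_duplicates(pairs)
        assert sum(p.duplicate for p in pairs) == 4
        kept = [p for p in pairs if not p.duplicate]
        assert len({p.umi for p in kept}) == 4

    def test_representative_is_best_quality_then_lexicographic(self):
        pairs = [_pair("rb", score=10), _pair("ra", score=10), _pair("rc", score=30)]
        mark_duplicates(pairs)
        kept = [p for p in pairs if not p.duplicate]
        assert [p.read_id for p in kept] == ["rc"]
        pairs2 = [_pair("rb", score=10), _pair("ra", score=10)]
        mark_duplicates(pairs2)
        assert [p.read_id for p in pairs2 if not p.duplicate] == ["ra"]

    def test_idempotent(self):
        rng = np.random.default_rng(5)
        pairs = random_pairs(rng, 100)
        mark_duplicates(pairs)
        first = [p.duplicate for p in pairs]
        mark_duplicates(pairs)
        assert [p.duplicate for p in pairs] == first

    def test_mate_flags_follow_pair(self):
        r1 = SamRecord("r#A#B", 99, "chr1", 100, cigar="50M")
        r2 = SamRecord("r#A#B", 147, "chr1", 250, cigar="50M")
        pair = _pair("r")
        pair.read1, pair.read2 = r1, r2
        mark_duplicates([pair, _pair("q")])
        flagged = [p for p in (pair,) if p.duplicate]
        if flagged:
            assert r1.is_duplicate and r2.is_duplicate

    def test_matches_exhaustive_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(20):
            pairs = random_pairs(rng, int(rng.integers(5, 120)))
            mark_duplicates(pairs)
            assert [p.duplicate for p in pairs] == oracle_flags(pairs)


class TestDuplicateRate:
    def test_counting_example(self):
        pairs = [_pair(f"r{i}") for i in range(5)]  # one group of five
        pairs += [_pair(f"u{i}", start=1000 + i * 100, end=1100 + i * 100) for i in range(5)]
        assert duplicate_rate(pairs) == pytest.approx(0.4)

    def test_all_unique_is_zero_under_both_modes(self):
        pairs = [_pair(f"r{i}", start=i * 500 + 1, end=i * 500 + 100) for i in range(10)]
        assert duplicate_rate(pairs, "coords_only") == 0.0
        assert duplicate_rate(pairs, "coords_plus_umi") == 0.0

    def test_empty_input_is_an_error(self):
        with pytest.raises(ValueError):
            duplicate_rate([])

    def test_umi_rate_never_exceeds_coords_rate(self):
        rng = np.random.default_rng(7)
        for _ in range(30):
            pairs = random_pairs(rng, int(rng.integers(10, 150)))
            assert duplicate_rate(pairs, "coords_plus_umi") <= duplicate_rate(
                pairs, "coords_only"
            )

    def test_simulated_duplication_fraction_recovered(self):
        from tagcount.simulate import SimConfig, simulate_experiment

        config = SimConfig(
            seed=13, n_transcripts=8, n_samples_per_condition=2,
            baseline_mean=120.0, duplication_rate=0.2, n_misprime_sites=0,
        )
        exp = simulate_experiment(config)
        rate = duplicate_rate(exp.pairs, "coords_plus_umi")
        assert rate == pytest.approx(0.2, abs=0.03)


class TestPairRecords:
    def test_outer_coordinates_and_umi_from_simulator(self, small_experiment):
        exp = small_experiment
        pairs = pair_records(exp.sam_records)
        assert len(pairs) == len(exp.pairs)
        by_id = {p.read_id: p for p in exp.pairs}
        for pair in pairs[:200]:
            truth = by_id[pair.read_id]
            assert (pair.outer_start, pair.outer_end) == (
                truth.outer_start, truth.outer_end,
            )
            assert pair.umi == truth.umi

    def test_unmapped_mate_gives_unkeyable_pair(self):
        r1 = SamRecord("r#AAAA#CCCC", 69, "chr1", 100, cigar="*")  # mate unmapped+unmapped
        r2 = SamRecord("r#AAAA#CCCC", 137, "chr1", 100, cigar="50M")
        (pair,) = pair_records([r1, r2])
        assert duplicate_key(pair) is None
        mark_duplicates([pair])
        assert not pair.duplicate
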