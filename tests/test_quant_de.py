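import numpy as np
import pandas as pd
import pytest

from tagcount.dedup import AlignmentPair
from tagcount.formats import SamRecord
from tagcount.peaks import Region
from tagcount.quant_de import (
    CountMatrix,
    call_hits,
    count_by_sample,
    de_analysis,
    independent_filter,
    nb_test,
    size_factors,
)
from tagcount.simulate import SimConfig, simulate_counts

SAMPLES_2x2 = [("a1", "c1"), ("a2", "c1"), ("b1", "c2"), ("b2", "c2")]


def _pair(read2_pos, sample, duplicate=False, read_id="r"):
    r2 = SamRecord(read_id, 0x1 | 0x80, "chr1", read2_pos, cigar="54M")
    r2.set_duplicate(duplicate)
    return AlignmentPair(
        read_id=read_id, reference="chr1", outer_start=read2_pos,
        outer_end=read2_pos + 100, orientation="FR", umi="A" * 12,
        duplicate=duplicate, sample_label=sample, read2=r2,
        read1=SamRecord(read_id, 0x1 | 0x40 | 0x10, "chr1", read2_pos + 60, cigar="39M"),
    )


class TestCountBySample:
    REGION = [Region("chr1", 1001, 1300, 0.9, 10, 12)]

    def test_counting_oracle(self):
        pairs = [_pair(1100, "a1", read_id=f"x{i}") for i in range(3)]
        pairs += [_pair(1100, "a2", read_id=f"y{i}") for i in range(5)]
        matrix = count_by_sample(self.REGION, pairs, [("a1", "c1"), ("a2", "c2")])
        assert matrix.counts.tolist() == [[3, 5]]

    def test_duplicates_excluded(self):
        pairs = [_pair(1100, "a1"), _pair(1100, "a1", duplicate=True)]
        matrix = count_by_sample(self.REGION, pairs, [("a1", "c1")])
        assert matrix.counts.tolist() == [[1]]

    def test_read_outside_regions_contributes_nowhere(self):
        matrix = count_by_sample(self.REGION, [_pair(2000, "a1")], [("a1", "c1")])
        assert matrix.counts.sum() == 0


class TestSizeFactors:
    def test_exact_doubling_gives_ratio_two(self):
        counts = np.column_stack([np.arange(1, 21), 2 * np.arange(1, 21)])
        factors = size_factors(counts)
        assert factors[1] / factors[0] == pytest.approx(2.0)

    def test_identical_samples_get_equal_factors(self):
        counts = np.tile(np.arange(1, 11)[:, None], (1, 4))
        assert np.allclose(size_factors(counts), 1.0)

    def test_depth_gradient_recovered_within_5_percent(self):
        rng = np.random.default_rng(0)
        base = rng.lognormal(4, 1, size=500)
        depth = np.array([0.5, 1.0, 2.0])
        counts = rng.poisson(base[:, None] * depth[None, :])
        factors = size_factors(counts)
        ratios = factors / factors[1]
        assert np.allclose(ratios, depth / depth[1], rtol=0.05)

    def test_rows_with_zeros_are_ignored(self):
        counts = np.array([[10, 20], [0, 5], [30, 60]])
        factors = size_factors(counts)
        assert factors[1] / factors[0] == pytest.approx(2.0)

    def test_matches_pydeseq2_median_of_ratios(self):
        pydeseq2 = pytest.importorskip("pydeseq2")
        from pydeseq2.dds import DeseqDataSet

        rng = np.random.default_rng(1)
        counts = rng.poisson(rng.lognormal(4, 1, size=(200, 6)))
        counts[counts == 0] = 1
        metadata = pd.DataFrame(
            {"condition": ["A"] * 3 + ["B"] * 3},
            index=[f"s{i}" for i in range(6)],
        )
        dds = DeseqDataSet(
            counts=pd.DataFrame(counts.T, index=metadata.index),
            metadata=metadata,
            design="~condition",
            quiet=True,
        )
        dds.fit_size_factors()
        theirs = np.asarray(dds.obs["size_factors"], dtype=float)
        ours = size_factors(counts)
        assert np.allclose(ours, theirs, rtol=1e-6)


class TestNbTest:
    def test_identical_conditions_give_zero_lfc_and_p_near_one(self):
        counts = np.tile([[100], [50], [20]], (1, 4))
        matrix = CountMatrix(["r1", "r2", "r3"], SAMPLES_2x2, counts)
        res = nb_test(matrix)
        assert np.allclose(res["log2_fold_change"], 0.0, atol=1e-6)
        assert (res["p_value"] > 0.99).all()

    def test_all_zero_region_gets_missing_p(self):
        counts = np.array([[0, 0, 0, 0], [10, 12, 50, 60]])
        matrix = CountMatrix(["r1", "r2"], SAMPLES_2x2, counts)
        res = nb_test(matrix, factors=np.ones(4))
        assert np.isnan(res["p_value"].iloc[0])
        assert res["p_value"].iloc[1] < 0.5

    def test_fourfold_change_recovered(self):
        # 100 changed regions in a mostly-unchanged background, so the
        # median-of-ratios normalisation is anchored by null regions
        config = SimConfig(
            seed=5, n_samples_per_condition=6,
            fold_changes={i: 4.0 for i in range(100)},
        )
        matrix, true_lfc = simulate_counts(config, n_regions=600)
        res = nb_test(matrix)
        assert abs(res["log2_fold_change"].iloc[:100].mean() - 2.0) < 0.3
        # unchanged background stays near zero (small shift is the known
        # median-of-ratios cost of a one-sided changed fraction)
        assert abs(res["log2_fold_change"].iloc[100:].mean()) < 0.3

    def test_null_p_values_are_uniform(self):
        from scipy import stats

        config = SimConfig(seed=6, fold_changes={})
        matrix, _ = simulate_counts(config, n_regions=2000)
        res = nb_test(matrix)
        ks = stats.kstest(res["p_value"].dropna(), "uniform")
        assert ks.pvalue > 0.01

    def test_matches_statsmodels_glm_oracle(self):
        import statsmodels.api as sm

        config = SimConfig(seed=7, n_samples_per_condition=4)
        matrix, _ = simulate_counts(config, n_regions=20)
        factors = size_factors(matrix.counts)
        from tagcount.quant_de import estimate_dispersions

        alphas = estimate_dispersions(matrix.counts, factors, matrix.samples)
        res = nb_test(matrix, factors=factors, alphas=alphas)
        X = np.column_stack(
            [np.ones(8), [0] * 4 + [1] * 4]
        )
        for i in range(20):
            glm = sm.GLM(
                matrix.counts[i],
                X,
                family=sm.families.NegativeBinomial(alpha=float(alphas[i])),
                offset=np.log(factors),
            ).fit()
            lfc_sm = glm.params[1] / np.log(2)
            se_sm = glm.bse[1] / np.log(2)
            assert res["log2_fold_change"].iloc[i] == pytest.approx(lfc_sm, abs=1e-4)
            assert res["se"].iloc[i] == pytest.approx(se_sm, rel=1e-3)

    def test_normalised_depth_equalised_on_depth_only_simulation(self):
        rng = np.random.default_rng(9)
        base = rng.lognormal(4, 0.8, size=400)
        depth = np.array([0.5, 0.8, 1.0, 1.0, 1.5, 2.0])
        counts = rng.poisson(base[:, None] * depth[None, :])
        factors = size_factors(counts)
        norm_sums = (counts / factors).sum(axis=0)
        assert norm_sums.max() / norm_sums.min() < 1.05


class TestIndependentFilter:
    def test_bh_arithmetic(self):
        results = pd.DataFrame(
            {"p_value": [0.01, 0.02, 0.9], "base_mean": [100.0, 100.0, 100.0]}
        )
        out = independent_filter(results)
        assert np.allclose(out["adjusted_p"], [0.03, 0.03, 0.9])

    def test_adjusted_p_monotone_in_p(self):
        rng = np.random.default_rng(2)
        results = pd.DataFrame(
            {"p_value": rng.uniform(size=300), "base_mean": np.full(300, 50.0)}
        )
        out = independent_filter(results)
        sub = out.dropna().sort_values("p_value")
        assert sub["adjusted_p"].is_monotonic_increasing

    def test_low_mean_regions_lose_adjusted_p_even_when_p_small(self):
        # 200 low-mean noise regions dilute BH enough that filtering them
        # rescues 50 borderline high-mean signals; the low-mean region
        # with a small p is then filtered despite that p.
        rng = np.random.default_rng(3)
        p = np.concatenate([[1e-8], rng.uniform(0.2, 1, 199), np.full(50, 0.01),
                            rng.uniform(0.2, 1, 150)])
        base_mean = np.concatenate([np.full(200, 0.5), np.full(200, 100.0)])
        results = pd.DataFrame({"p_value": p, "base_mean": base_mean})
        out = independent_filter(results)
        assert np.isnan(out["adjusted_p"].iloc[0])
        assert (out["adjusted_p"].iloc[200:250] <= 0.05).all()


def _annotated(distance, region=None, tc=None):
    from tagcount.annotate import AnnotatedEnd
    from tagcount.formats import TranscriptAnnotation
    from tagcount.tc_ends import TC3End

    tc = tc or TC3End("chr1", 1000, "+", 10)
    return AnnotatedEnd(
        tc_end=tc,
        region=region or Region("chr1", 901, 1100, 0.9, 9, 10),
        transcript=TranscriptAnnotation("T1", "G1", "g1", "chr1", "+", 1000 + distance),
        distance=distance,
        passes_stringent=-100 <= distance <= 100,
        passes_relaxed=-100 <= distance <= 5000,
        passes_region_consistency=True,
    )


class TestCallHits:
    def _results(self, apv, lfc):
        return pd.DataFrame(
            {
                "base_mean": [100.0] * len(apv),
                "log2_fold_change": lfc,
                "p_value": [a / 2 if not np.isnan(a) else np.nan for a in apv],
                "adjusted_p": apv,
            }
        )

    def test_adjusted_p_boundary_inclusive(self):
        results = self._results([0.05, 0.051], [3.0, 3.0])
        rows = call_hits(results, [_annotated(0), _annotated(0)], min_fc=None)
        assert len(rows) == 1

    def test_min_fold_change_excludes_small_changes(self):
        results = self._results([0.01, 0.01], [np.log2(1.9), -np.log2(2.5)])
        rows = call_hits(results, [_annotated(0), _annotated(0)], min_fc=2.0)
        assert len(rows) == 1
        assert rows[0]["log2_fold_change"] == pytest.approx(-np.log2(2.5))

    def test_relaxed_window_retains_distant_end_stringent_drops(self):
        results = self._results([0.01], [3.0])
        annotated = [_annotated(3000)]
        assert len(call_hits(results, annotated, window="relaxed")) == 1
        assert len(call_hits(results, annotated, window="stringent")) == 0

    def test_rows_ordered_by_adjusted_p(self):
        results = self._results([0.04, 0.01], [3.0, 3.0])
        rows = call_hits(results, [_annotated(0), _annotated(0)], min_fc=None)
        assert [r["adjusted_p"] for r in rows] == [0.01, 0.04]


class TestDeAnalysis:
    def test_end_to_end_finds_planted_changes(self):
        config = SimConfig(seed=10, fold_changes={0: 4.0, 1: 0.25})
        matrix, true_lfc = simulate_counts(config, n_regions=50)
        res = de_analysis(matrix)
        hits = res[res["adjusted_p"] <= 0.05]
        assert {0, 1} <= set(hits.index)
        assert res["log2_fold_change"].iloc[0] == pytest.approx(2.0, abs=0.7)
        assert res["log2_fold_change"].iloc[1] == pytest.approx(-2.0, abs=0.7)
        assert (res[res["adjusted_p"].notna()]["p_value"].notna()).all()
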