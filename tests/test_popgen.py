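import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from msatkit.io_core import RunConfig
from msatkit.popgen import (
    AlleleCounts,
    adjust_pvalues,
    allelic_richness,
    characterize,
    expected_het,
    genotyping_error_rate,
    hwe_test_mc,
    null_allele_freq,
    observed_het,
    summarize_locus,
)
from msatkit.synthetic import combine_matrices, simulate_genotypes

counts_strategy = st.lists(st.integers(1, 6), min_size=1, max_size=5).filter(
    lambda c: sum(c) % 2 == 0 and sum(c) >= 2
)


def _counts(values):
    return AlleleCounts("L", {i: v for i, v in enumerate(values)}, sum(values))


class TestHeterozygosity:
    def test_observed(self):
        assert observed_het([(1, 1), (1, 2)]) == 0.5
        assert observed_het([(1, 1), (2, 2)]) == 0.0
        with pytest.raises(ValueError):
            observed_het([])

    def test_expected_single_allele_is_zero(self):
        assert expected_het(_counts([4])) == 0.0

    def test_expected_hand_computed(self):
        # counts 3:1, n=2 -> (4/3)(1 - 9/16 - 1/16) = 0.5
        assert expected_het(_counts([3, 1])) == pytest.approx(0.5, abs=1e-12)

    def test_biased_variant_available(self):
        assert expected_het(_counts([2, 2]), unbiased=False) == pytest.approx(0.5)

    @settings(max_examples=100, derandomize=True)
    @given(counts_strategy)
    def test_equals_pair_draw_probability(self, values):
        """He must equal the probability that two copies drawn without
        replacement differ, by exhaustive pair enumeration."""
        copies = [a for a, v in enumerate(values) for _ in range(v)]
        pairs = list(itertools.combinations(range(len(copies)), 2))
        p_diff = sum(copies[i] != copies[j] for i, j in pairs) / len(pairs)
        assert expected_het(_counts(values)) == pytest.approx(p_diff, abs=1e-12)


class TestHweMc:
    def test_monomorphic_convention(self):
        assert hwe_test_mc([(1, 1)] * 10) == 1.0

    def test_extreme_homozygote_deficit(self):
        gts = [(1, 1)] * 10 + [(2, 2)] * 10  # no heterozygotes at p=q=0.5
        assert hwe_test_mc(gts, B=1999, seed=3) <= 0.01

    def test_seeded_reproducibility(self):
        gts = [(1, 1)] * 6 + [(1, 2)] * 8 + [(2, 2)] * 6
        p1 = hwe_test_mc(gts, B=499, seed=42)
        p2 = hwe_test_mc(gts, B=499, seed=42)
        assert p1 == p2
        assert 0 < p1 <= 1

    def test_equilibrium_data_has_large_p(self):
        # perfect HWE proportions at p=q=0.5, n=100
        gts = [(1, 1)] * 25 + [(1, 2)] * 50 + [(2, 2)] * 25
        assert hwe_test_mc(gts, B=999, seed=5) > 0.5


class TestAdjust:
    def test_single_p_unchanged(self):
        assert adjust_pvalues([0.2]) == [pytest.approx(0.2)]

    def test_holm_by_hand(self):
        assert adjust_pvalues([0.01, 0.04], "holm") == [
            pytest.approx(0.02), pytest.approx(0.04)
        ]

    def test_bh_by_hand(self):
        got = adjust_pvalues([0.01, 0.02, 0.03, 0.04], "bh")
        assert got == [pytest.approx(0.04)] * 4

    def test_order_preserved(self):
        got = adjust_pvalues([0.04, 0.01], "holm")
        assert got == [pytest.approx(0.04), pytest.approx(0.02)]

    def test_rejects_bad_pvalues(self):
        with pytest.raises(ValueError):
            adjust_pvalues([1.2])
        with pytest.raises(ValueError):
            adjust_pvalues([0.5], "sidak")


class TestNullAlleleFreq:
    @pytest.mark.parametrize("ho,he,reported", [
        (0.56, 0.82, 0.14),
        (0.57, 0.52, 0.00),  # truncated: observed exceeds expected
        (0.20, 0.78, 0.33),
        (0.50, 0.81, 0.17),
        (0.00, 0.28, 0.22),
    ])
    def test_reported_values(self, ho, he, reported):
        assert round(null_allele_freq(ho, he), 2) == pytest.approx(reported)

    @settings(max_examples=200, derandomize=True)
    @given(st.floats(0, 1), st.floats(0, 1))
    def test_range_and_truncation(self, ho, he):
        r = null_allele_freq(ho, he)
        assert 0 <= r < 1
        assert (r == 0) == (ho >= he)

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            null_allele_freq(-0.1, 0.5)


class TestAllelicRichness:
    def test_full_sample_gives_allele_count(self):
        c = _counts([5, 3, 2])
        assert allelic_richness(c, c.N) == pytest.approx(3.0, abs=1e-12)

    def test_single_copy_gives_one(self):
        assert allelic_richness(_counts([5, 3, 2]), 1) == pytest.approx(1.0, abs=1e-12)

    def test_two_by_two(self):
        assert allelic_richness(_counts([2, 2]), 2) == pytest.approx(5 / 3, abs=1e-12)

    def test_out_of_range_g(self):
        with pytest.raises(ValueError):
            allelic_richness(_counts([2, 2]), 5)
        with pytest.raises(ValueError):
            allelic_richness(_counts([2, 2]), 0)

    small_counts = st.lists(st.integers(1, 4), min_size=1, max_size=4).filter(
        lambda c: sum(c) % 2 == 0 and 2 <= sum(c) <= 12
    )

    @settings(max_examples=80, deadline=None, derandomize=True)
    @given(small_counts, st.data())
    def test_matches_subsample_enumeration(self, values, data):
        """Rarefaction equals the average distinct-allele count over every
        possible subsample of g copies (N <= 12)."""
        c = _counts(values)
        g = data.draw(st.integers(1, c.N))
        copies = [a for a, v in enumerate(values) for _ in range(v)]
        subs = list(itertools.combinations(range(c.N), g))
        mean_distinct = sum(len({copies[i] for i in s}) for s in subs) / len(subs)
        assert allelic_richness(c, g) == pytest.approx(mean_distinct, abs=1e-9)

    @settings(max_examples=50, derandomize=True)
    @given(counts_strategy)
    def test_monotone_in_g_and_bounded(self, values):
        c = _counts(values)
        rich = [allelic_richness(c, g) for g in range(1, c.N + 1)]
        assert all(b >= a - 1e-12 for a, b in zip(rich, rich[1:]))
        assert rich[-1] <= len(values) + 1e-12


class TestErrorRate:
    def test_identical_replicates(self):
        r = {f"i{k}": (1, 2) for k in range(10)}
        assert genotyping_error_rate(r, dict(r)) == 0.0

    def test_one_discordant_of_fifty(self):
        r1 = {f"i{k}": (1, 2) for k in range(50)}
        r2 = dict(r1)
        r2["i0"] = (1, 1)
        assert genotyping_error_rate(r1, r2) == pytest.approx(0.02)

    def test_unordered_pair_comparison(self):
        assert genotyping_error_rate({"a": (1, 2)}, {"a": (2, 1)}) == 0.0

    def test_incomplete_individuals_excluded(self):
        r1 = {"a": (1, 2), "b": (1, 1)}
        r2 = {"a": (1, 2)}
        assert genotyping_error_rate(r1, r2) == 0.0
        with pytest.raises(ValueError):
            genotyping_error_rate({"a": (1, 2)}, {"b": (1, 2)})

    def test_recovers_simulated_miscall_rate(self):
        rate = 0.05
        n = 500
        matrix, _ = simulate_genotypes(
            n, {100: 0.5, 104: 0.5}, miscall_rate=rate, seed=77
        )
        r1 = matrix.complete_genotypes("simlocus", 1)
        r2 = matrix.complete_genotypes("simlocus", 2)
        est = genotyping_error_rate(r1, r2)
        se = math.sqrt(rate * (1 - rate) / n)
        assert abs(est - rate) <= 3 * se


class TestSummarize:
    def test_monomorphic_toy_locus(self):
        gts = {f"i{k}": (100, 100) for k in range(10)}
        s = summarize_locus("mono", gts)
        assert (s.n, s.n_alleles) == (10, 1)
        assert s.obs_het == 0.0
        assert s.exp_het == 0.0
        assert s.hwe_p_raw == 1.0
        assert s.null_freq == 0.0
        assert s.range_min == s.range_max == 100
        assert s.allelic_richness == pytest.approx(1.0)

    def test_simulated_locus_matches_truth(self):
        freqs = {200 + 4 * i: 0.1 for i in range(10)}
        matrix, truth = simulate_genotypes(400, freqs, seed=9, replicate=False)
        gts = matrix.complete_genotypes("simlocus")
        cfg = RunConfig(mc_permutations=199, seed=1)
        s = summarize_locus("simlocus", gts, config=cfg)
        assert s.n == 400
        assert s.n_alleles == 10
        he_true = 1 - sum(p**2 for p in freqs.values())  # 0.9
        assert abs(s.obs_het - he_true) < 3 * math.sqrt(he_true * (1 - he_true) / 400)
        assert s.null_freq < 0.03
        assert s.hwe_p_raw > 0.01

    def test_characterize_adjusts_across_loci(self):
        mats = []
        for i in range(4):
            m, _ = simulate_genotypes(
                60, {100 + 4 * j: 0.25 for j in range(4)},
                seed=100 + i, locus_id=f"L{i}", replicate=True,
            )
            mats.append(m)
        mono, _ = simulate_genotypes(60, {100: 1.0}, seed=50, locus_id="mono")
        mats.append(mono)
        matrix = combine_matrices(mats)
        cfg = RunConfig(mc_permutations=199, seed=2)
        summaries = {s.locus_id: s for s in characterize(matrix, cfg)}
        assert set(summaries) == {"L0", "L1", "L2", "L3", "mono"}
        assert summaries["mono"].hwe_p_adj == 1.0
        for s in summaries.values():
            assert s.hwe_p_adj >= s.hwe_p_raw - 1e-12
            assert s.error_rate == 0.0  # replicates drawn without miscalls
        # rarefaction g = 2 x min n across loci keeps richness <= allele count
        for s in summaries.values():
            assert s.allelic_richness <= s.n_alleles + 1e-9
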