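import numpy as np
import pytest
from scipy import stats

from adnapop.fstats import BlockScheme
from adnapop.relatedness import (
    IbdSummary,
    baseline_b,
    classify_pair,
    expected_roh_total,
    ibd_calibration,
    kinship_r,
    pairwise_mismatch,
    roh_summarize,
    segment_age,
)

from conftest import make_table


class TestMismatch:
    def test_identical_vectors_zero(self):
        calls = np.tile([0, 2, 2, 0, 2], (2, 1)).T.astype(np.int8)
        table = make_table(calls, pseudo=True)
        blocks = BlockScheme.contiguous(table.snps, n_blocks=2)
        assert pairwise_mismatch(table, "ind0", "ind1", blocks).x == 0.0

    def test_hand_counted_rate(self):
        """10 overlapping SNPs with 3 mismatches give x = 0.3."""
        c0 = np.array([0, 0, 0, 0, 0, 0, 0, 2, 2, 2], dtype=np.int8)
        c1 = np.array([0, 0, 0, 0, 0, 0, 0, 0, 0, 0], dtype=np.int8)
        table = make_table(np.column_stack([c0, c1]), pseudo=True)
        blocks = BlockScheme.contiguous(table.snps, n_blocks=2)
        est = pairwise_mismatch(table, "ind0", "ind1", blocks)
        assert est.x == pytest.approx(0.3)
        assert est.n_overlap == 10
        assert est.ci95[0] <= est.x <= est.ci95[1]

    def test_point_estimate_invariant_under_permutation(self, rng):
        calls = (rng.random((60, 2)) < 0.4).astype(np.int8) * 2
        table = make_table(calls, pseudo=True)
        blocks = BlockScheme.contiguous(table.snps, n_blocks=4)
        x0 = pairwise_mismatch(table, "ind0", "ind1", blocks).x
        perm = rng.permutation(60)
        t2 = make_table(calls[perm], pseudo=True)
        assert pairwise_mismatch(t2, "ind0", "ind1", blocks).x == pytest.approx(x0)

    def test_no_overlap_and_het_input_errors(self):
        calls = np.array([[0, -1], [-1, 2]], dtype=np.int8)
        table = make_table(calls, pseudo=True)
        blocks = BlockScheme.contiguous(table.snps, n_blocks=1)
        with pytest.raises(ValueError, match="overlap"):
            pairwise_mismatch(table, "ind0", "ind1", blocks)
        het = make_table(np.array([[1, 0]], dtype=np.int8))
        with pytest.raises(ValueError, match="pseudo-haploid"):
            pairwise_mismatch(het, "ind0", "ind1", BlockScheme.contiguous(het.snps, n_blocks=1))


class TestKinship:
    def test_formula_identities(self):
        assert kinship_r(0.24, 0.24).r == pytest.approx(0.0)
        assert kinship_r(0.12, 0.24).r == pytest.approx(1.0)
        assert kinship_r(0.18, 0.24).r == pytest.approx(0.5)

    def test_out_of_band_warns_unclamped(self):
        with pytest.warns(UserWarning):
            est = kinship_r(0.5, 0.24)
        assert est.r < -1.0

    def test_bad_baseline_rejected(self):
        with pytest.raises(ValueError):
            kinship_r(0.2, 0.0)

    def test_baseline_is_mean_of_pair_rates(self, rng):
        # three pair rates engineered on disjoint chromosome blocks
        freq = np.full(300, 0.5)
        calls = (rng.random((300, 6)) < freq[:, None]).astype(np.int8) * 2
        table = make_table(calls, pseudo=True)
        blocks = BlockScheme.contiguous(table.snps, n_blocks=5)
        pairs = [("ind0", "ind1"), ("ind2", "ind3"), ("ind4", "ind5")]
        rates = [pairwise_mismatch(table, a, b, blocks).x for a, b in pairs]
        assert baseline_b(table, pairs, blocks) == pytest.approx(np.mean(rates))
        with pytest.raises(ValueError):
            baseline_b(table, pairs[:2], blocks)


class TestClassifyPair:
    def test_no_segments_unrelated(self):
        s = IbdSummary.from_segments("a", "b", [])
        assert classify_pair(s) == "unrelated"

    def test_short_segments_only_unrelated(self):
        s = IbdSummary.from_segments("a", "b", [9.0, 10.0, 14.0])
        assert classify_pair(s) == "unrelated"

    def test_three_long_segments_are_distant_relatives(self):
        """Three shared segments >16 cM land in the 5th-7th-degree band."""
        s = IbdSummary.from_segments("a", "b", [18.0, 22.0, 17.5])
        assert classify_pair(s) == "5th-7th"

    def test_monotone_in_added_segments(self):
        """Adding a segment never moves a pair to a more distant class."""
        order = {c: i for i, c in enumerate(
            ["identical/1st", "2nd-4th", "5th-7th", "unrelated-detectable", "unrelated"]
        )}
        rng = np.random.default_rng(99)
        lengths: list[float] = []
        prev = order[classify_pair(IbdSummary.from_segments("a", "b", lengths))]
        for _ in range(60):
            lengths.append(float(rng.uniform(8, 200)))
            cur = order[classify_pair(IbdSummary.from_segments("a", "b", lengths))]
            assert cur <= prev
            prev = cur

    def test_counts_non_increasing_with_threshold(self):
        s = IbdSummary.from_segments("a", "b", [9, 13, 17, 21, 25])
        assert s.n_over_12cm >= s.n_over_16cm >= s.n_over_20cm

    def test_calibration_table_shape(self):
        cal = ibd_calibration()
        assert cal["first_degree_sum_cM"] > cal["second_fourth_sum_cM"] > 0


class TestSegmentAge:
    def test_matches_printed_coalescent_dating(self):
        """16 cM at Ne=1000: median ~8, 95th percentile ~19-20
        generations."""
        post = segment_age(16.0, 1000.0)
        assert post.median == pytest.approx(8.0, rel=0.05)
        assert post.q95 == pytest.approx(19.5, rel=0.05)

    def test_posterior_normalized_and_tail_truncated(self):
        post = segment_age(16.0, 1000.0)
        assert post.pmf.sum() == pytest.approx(1.0, abs=1e-9)
        assert post.pmf[-1] < 1e-6

    def test_longer_segments_are_younger(self):
        a, b = segment_age(16.0), segment_age(32.0)
        assert b.median < a.median and b.q95 < a.q95

    def test_quantiles_monotone_in_ne(self):
        small, big = segment_age(16.0, 500.0), segment_age(16.0, 5000.0)
        assert big.median > small.median and big.q95 > small.q95

    def test_matches_continuous_gamma_limit(self):
        """Discrete posterior quantiles agree with the closed-form
        Gamma(3, 2l + lambda) continuous limit within 2%."""
        for l_cm, ne in ((10.0, 1000.0), (16.0, 1000.0), (25.0, 400.0)):
            post = segment_age(l_cm, ne)
            rate = 2 * l_cm / 100.0 - np.log1p(-1.0 / (2 * ne))
            for q, got in ((0.5, post.median), (0.95, post.q95)):
                want = stats.gamma.ppf(q, 3, scale=1.0 / rate)
                assert abs(got - want) / want < 0.02

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            segment_age(0.0)
        with pytest.raises(ValueError):
            segment_age(16.0, -5.0)


class TestRoh:
    def test_no_segments_outbred(self):
        s = roh_summarize("i", [])
        assert s.parental_class == "outbred"
        assert all(v == 0 for v in s.bin_totals_cm.values())

    def test_threshold_arithmetic(self):
        """22 + 31 cM of long ROH crosses the 50 cM close-kin line."""
        s = roh_summarize("i", [22.0, 31.0])
        assert s.sum_over_20cm == pytest.approx(53.0)
        assert s.parental_class == "close-kin-union"
        s2 = roh_summarize("i", [100.0, 150.0, 120.0])
        assert s2.parental_class == "second-degree-parents"

    def test_binning(self):
        s = roh_summarize("i", [5.0, 9.0, 15.0, 25.0, 4.0, 19.9])
        assert s.bin_totals_cm["[4,8)"] == pytest.approx(9.0)
        assert s.bin_totals_cm["[8,12)"] == pytest.approx(9.0)
        assert s.bin_totals_cm["[12,20)"] == pytest.approx(34.9)
        assert s.bin_totals_cm[">=20"] == pytest.approx(25.0)

    def test_coverage_gate_and_negatives(self):
        with pytest.raises(ValueError, match="gate"):
            roh_summarize("i", [5.0], min_snps_covered=100_000)
        with pytest.raises(ValueError):
            roh_summarize("i", [-1.0])


def test_half_sibling_offspring_autozygosity():
    """Offspring of half-siblings (parental kinship 1/8) carry F x map
    length of autozygosity on average, straddling the 350 cM long-ROH
    line that flags second-degree parental relatedness."""
    from adnapop.synthetic import second_degree_offspring_pedigree, simulate_pedigree

    totals, long_totals = [], []
    for rep in range(60):
        real = simulate_pedigree(second_degree_offspring_pedigree(), seed=4000 + rep)
        lengths = [e - s for _, s, e in real.roh_segments("O")]
        totals.append(sum(lengths))
        long_totals.append(roh_summarize("O", lengths).sum_over_20cm)
    # simulator map is 3500 cM, so its own expectation is 3500/8
    assert abs(np.mean(totals) - 3500.0 / 8) / (3500.0 / 8) < 0.15
    # restricted to ROH > 20 cM the mean sits at the classification line
    assert np.mean(long_totals) == pytest.approx(350.0, rel=0.15)


class TestExpectedRoh:
    def test_unrelated_is_zero(self):
        assert expected_roh_total("unrelated") == 0.0

    def test_first_cousins(self):
        assert expected_roh_total("first_cousins") == pytest.approx(3540.0 / 16)

    def test_f_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            expected_roh_total(0.3)
        with pytest.raises(ValueError):
            expected_roh_total(-0.01)
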