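import numpy as np
import pytest

from adnapop.fstats import BlockScheme, f4, lrt_nested, qpadm_fit
from adnapop.synthetic import (
    AdmixtureSpec,
    PopulationTree,
    draw_frequencies,
    make_cohort,
    make_snp_table,
)

from conftest import make_table


def frequency_table(freq_by_pop, n_per_pop=1):
    """Table whose per-population frequencies are exact: one pseudo-
    haploid individual per frequency value (0 -> call 0, 1 -> call 2,
    0.5 -> two individuals at 0 and 2)."""
    pops, cols, groups = list(freq_by_pop), [], []
    n_snps = len(next(iter(freq_by_pop.values())))
    for p in pops:
        f = np.asarray(freq_by_pop[p], dtype=float)
        # two haploid "individuals" carrying round(2f) alt alleles total
        alt = np.round(2 * f).astype(int)
        a = (alt >= 1).astype(np.int8) * 2
        b = (alt == 2).astype(np.int8) * 2
        cols += [a, b]
        groups += [p, p]
    calls = np.column_stack(cols)
    return make_table(calls, pseudo=True, groups=groups)


@pytest.fixture
def hand_freqs():
    return {
        "A": [0.0, 0.5, 1.0, 0.5, 0.0, 1.0],
        "B": [0.5, 0.0, 0.5, 1.0, 0.0, 0.5],
        "C": [1.0, 1.0, 0.0, 0.5, 0.5, 0.0],
        "D": [0.0, 0.5, 0.5, 0.0, 1.0, 1.0],
    }


class TestF4:
    def test_identical_last_pair_is_zero(self, hand_freqs):
        table = frequency_table(hand_freqs)
        blocks = BlockScheme.contiguous(table.snps, n_blocks=3)
        assert f4(table, "A", "B", "C", "C", blocks).value == 0.0

    def test_antisymmetry(self, hand_freqs):
        table = frequency_table(hand_freqs)
        blocks = BlockScheme.contiguous(table.snps, n_blocks=3)
        base = f4(table, "A", "B", "C", "D", blocks)
        assert f4(table, "B", "A", "C", "D", blocks).value == pytest.approx(-base.value)
        assert f4(table, "A", "B", "D", "C", blocks).value == pytest.approx(-base.value)
        # SEs are invariant under the sign flip
        assert f4(table, "B", "A", "C", "D", blocks).std_err == pytest.approx(base.std_err)

    def test_matches_brute_force_sum(self, hand_freqs):
        """Direct per-SNP summation oracle on hand-written frequencies."""
        table = frequency_table(hand_freqs)
        blocks = BlockScheme.contiguous(table.snps, n_blocks=2)
        est = f4(table, "A", "B", "C", "D", blocks)
        fa, fb, fc, fd = (np.array(hand_freqs[k]) for k in "ABCD")
        expected = np.mean((fa - fb) * (fc - fd))
        assert est.value == pytest.approx(expected, abs=1e-12)
        assert est.n_snps_used == 6

    def test_missing_population_is_labeled_error(self, hand_freqs):
        table = frequency_table(hand_freqs)
        blocks = BlockScheme.contiguous(table.snps, n_blocks=2)
        with pytest.raises(KeyError, match="Nope"):
            f4(table, "A", "B", "C", "Nope", blocks)

    def test_matches_tskit_f4_on_coalescent_data(self):
        """Independent oracle: on msprime-simulated haplotypes, the
        genotype-based f4 equals tskit's site-mode f4 on the same
        variants."""
        import msprime

        demog = msprime.Demography()
        for pop in ("A", "B", "C", "D"):
            demog.add_population(name=pop, initial_size=1000)
        demog.add_population(name="AB", initial_size=1000)
        demog.add_population(name="ABC", initial_size=1000)
        demog.add_population(name="ROOT", initial_size=1000)
        demog.add_population_split(time=500, derived=["A", "B"], ancestral="AB")
        demog.add_population_split(time=1000, derived=["AB", "C"], ancestral="ABC")
        demog.add_population_split(time=2000, derived=["ABC", "D"], ancestral="ROOT")
        ts = msprime.sim_ancestry(
            samples={p: 5 for p in "ABCD"}, demography=demog, ploidy=1,
            sequence_length=2e5, recombination_rate=1e-8, random_seed=9,
        )
        ts = msprime.sim_mutations(ts, rate=2e-7, random_seed=9)
        geno = ts.genotype_matrix()
        biallelic = (geno.max(axis=1) == 1)
        calls = (geno[biallelic] * 2).astype(np.int8)
        groups = [p for p in "ABCD" for _ in range(5)]
        table = make_table(calls, pseudo=True, groups=groups)
        blocks = BlockScheme.contiguous(table.snps, n_blocks=5)
        mine = f4(table, "A", "B", "C", "D", blocks)
        sets = [list(range(5 * i, 5 * i + 5)) for i in range(4)]
        oracle_sum = ts.f4(sets, indexes=(0, 1, 2, 3), mode="site", span_normalise=False)
        assert mine.value * mine.n_snps_used == pytest.approx(float(oracle_sum), rel=1e-6)

    def test_jackknife_se_shrinks_with_snps(self, rng):
        """On iid SNPs the jackknife SE scales like 1/sqrt(n)."""
        ses = []
        for n in (2000, 8000):
            freqs = {p: rng.uniform(0.2, 0.8, n) for p in "ABCD"}
            calls = np.column_stack(
                [(rng.random((n, 10)) < freqs[p][:, None]).astype(np.int8) * 2 for p in "ABCD"]
            )
            table = make_table(calls, pseudo=True, groups=[p for p in "ABCD" for _ in range(10)])
            blocks = BlockScheme.contiguous(table.snps, n_blocks=50)
            ses.append(f4(table, "A", "B", "C", "D", blocks).std_err)
        assert ses[1] / ses[0] == pytest.approx(0.5, abs=0.15)


TREE = PopulationTree.from_edges(
    [
        ("root", "Anchor", 0.05), ("root", "R1", 0.05), ("root", "R2", 0.06),
        ("root", "N1", 0.03), ("N1", "S1", 0.02), ("N1", "RS1", 0.02),
        ("root", "N2", 0.03), ("N2", "S2", 0.02), ("N2", "RS2", 0.02),
        ("root", "N3", 0.03), ("N3", "S3", 0.02), ("N3", "RS3", 0.02),
    ]
)
RIGHTS = ["Anchor", "RS1", "RS2", "RS3", "R1", "R2"]


def simulate_fit_dataset(alpha, seed, n_snps=20_000, missing=0.1):
    freqs = draw_frequencies(TREE, n_snps, seed)
    snps = make_snp_table(n_snps)
    spec = AdmixtureSpec("T", {"S1": alpha, "S2": 1 - alpha})
    return make_cohort(
        freqs, {p: 12 for p in ["S1", "S2", "S3"] + RIGHTS}, snps,
        missing_rate=missing, seed=seed + 1, admixed=[spec],
    )


class TestQpadm:
    def test_self_model(self):
        """A target drawn from one left population gets weight ~1 on it
        and a non-rejecting p-value."""
        freqs = draw_frequencies(TREE, 20_000, 42)
        snps = make_snp_table(20_000)
        spec = AdmixtureSpec("T", {"S1": 1.0})
        table = make_cohort(
            freqs, {p: 12 for p in ["S1", "S2"] + RIGHTS}, snps,
            missing_rate=0.1, seed=43, admixed=[spec],
        )
        blocks = BlockScheme.contiguous(table.snps, n_blocks=50)
        fit = qpadm_fit(table, "T", ["S1", "S2"], RIGHTS, blocks)
        assert fit.weights[0] == pytest.approx(1.0, abs=0.1)
        assert fit.p_value > 0.05
        assert fit.dof == len(RIGHTS) - 2

    def test_two_way_recovery_within_2se(self):
        table = simulate_fit_dataset(0.7, seed=7)
        blocks = BlockScheme.contiguous(table.snps, n_blocks=50)
        fit = qpadm_fit(table, "T", ["S1", "S2"], RIGHTS, blocks)
        assert abs(fit.weights[0] - 0.7) < 0.07
        assert abs(fit.weights[0] - 0.7) < 2.5 * fit.weight_ses[0]
        assert fit.weights.sum() == pytest.approx(1.0, abs=1e-9)

    def test_weights_invariant_to_right_relabeling(self):
        table = simulate_fit_dataset(0.4, seed=9)
        blocks = BlockScheme.contiguous(table.snps, n_blocks=40)
        fit = qpadm_fit(table, "T", ["S1", "S2"], RIGHTS, blocks)
        shuffled = [RIGHTS[0]] + RIGHTS[:0:-1]
        fit2 = qpadm_fit(table, "T", ["S1", "S2"], shuffled, blocks)
        np.testing.assert_allclose(fit.weights, fit2.weights, atol=1e-8)
        assert fit.chi_square == pytest.approx(fit2.chi_square, abs=1e-8)

    def test_insufficient_rights_rejected(self, tiny_table):
        blocks = BlockScheme.contiguous(tiny_table.snps, n_blocks=1)
        with pytest.raises(ValueError, match="right populations"):
            qpadm_fit(tiny_table, "ind0", ["a", "b"], ["r1", "r2"], blocks)


class TestLrt:
    def _fit(self, lefts, chi2):
        from adnapop.fstats import AdmixtureModelFit

        return AdmixtureModelFit(
            target="t", left_set=tuple(lefts), right_set=("r",) * 5,
            weights=np.ones(len(lefts)) / len(lefts), weight_ses=np.zeros(len(lefts)),
            chi_square=chi2, dof=5 - len(lefts), p_value=0.5, feasible=True, valid=True,
        )

    def test_identical_fits_give_p_one(self):
        assert lrt_nested(self._fit("a", 3.0), self._fit("ab", 3.0)) == 1.0

    def test_chi2_drop_3841_is_p_005(self):
        p = lrt_nested(self._fit("a", 5.0), self._fit("ab", 5.0 - 3.841))
        assert p == pytest.approx(0.05, abs=5e-4)

    def test_negative_drop_clamped(self):
        assert lrt_nested(self._fit("a", 2.0), self._fit("ab", 3.0)) == 1.0

    def test_non_nested_rejected(self):
        with pytest.raises(ValueError):
            lrt_nested(self._fit("a", 2.0), self._fit("abc", 1.0))
        with pytest.raises(ValueError):
            lrt_nested(self._fit("c", 2.0), self._fit("ab", 1.0))
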