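import math
from itertools import combinations

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from rnasomatic.mutation_spectrum import BMRTable, MutationCategory
from rnasomatic.smg import (
    GeneMutationProfile,
    SMGSampleResult,
    call_smgs,
    category_tail_probability,
    compare_mutation_rates,
    fcpt_combine,
)
from rnasomatic.smg import test_gene as smg_test_gene


def exact_binom_tail(k, n, p):
    """Term-by-term summation oracle for P(X >= k), plain Python floats."""
    if k <= 0:
        return 1.0
    total = 0.0
    for i in range(k):
        total += math.comb(n, i) * p**i * (1 - p) ** (n - i)
    return max(0.0, 1.0 - total)


def chi2_sf_even_df(x, df):
    """Closed-form chi-square survival function for even df:
    exp(-x/2) * sum_{i<df/2} (x/2)^i / i!"""
    m = df // 2
    half = x / 2.0
    term, acc = 1.0, 1.0
    for i in range(1, m):
        term *= half / i
        acc += term
    return math.exp(-half) * acc


class TestCategoryTailProbability:
    def test_zero_count_is_one(self):
        assert category_tail_probability(0, 1000, 0.01) == 1.0

    def test_zero_bases_is_one(self):
        assert category_tail_probability(5, 0, 0.5) == 1.0

    def test_exact_summation_oracle(self):
        got = category_tail_probability(2, 100, 0.001)
        assert got == pytest.approx(exact_binom_tail(2, 100, 0.001), rel=1e-10)

    def test_invalid_rate_errors(self):
        with pytest.raises(ValueError):
            category_tail_probability(1, 10, 1.5)
        with pytest.raises(ValueError):
            category_tail_probability(-1, 10, 0.5)

    def test_exclusive_variant(self):
        inc = category_tail_probability(2, 50, 0.1, inclusive=True)
        exc = category_tail_probability(2, 50, 0.1, inclusive=False)
        assert exc < inc
        assert exc == pytest.approx(exact_binom_tail(3, 50, 0.1), rel=1e-9)

    def test_poisson_model(self):
        from scipy import stats

        got = category_tail_probability(3, 1000, 0.002, model="poisson")
        assert got == pytest.approx(float(stats.poisson.sf(2, 2.0)), rel=1e-12)

    @given(
        st.integers(min_value=0, max_value=12),
        st.integers(min_value=0, max_value=60),
        st.floats(min_value=0.0, max_value=1.0),
    )
    @settings(max_examples=100, deadline=None)
    def test_matches_oracle_randomised(self, k, n, p):
        got = category_tail_probability(k, n, p)
        want = 1.0 if n == 0 else exact_binom_tail(min(k, n + 1), n, p)
        assert got == pytest.approx(want, rel=1e-8, abs=1e-12)


class TestFcptCombine:
    def test_all_ones(self):
        res = fcpt_combine([1.0] * 7)
        assert res.statistic == 0.0
        assert res.df == 14
        assert res.pvalue == 1.0

    def test_seven_halves(self):
        res = fcpt_combine([0.5] * 7)
        assert res.statistic == pytest.approx(-2 * 7 * math.log(0.5), rel=1e-12)
        assert res.statistic == pytest.approx(9.70406, abs=1e-4)
        assert res.pvalue == pytest.approx(chi2_sf_even_df(res.statistic, 14), rel=1e-10)

    def test_single_p_identity(self):
        res = fcpt_combine([0.05])
        assert res.df == 2
        assert res.pvalue == pytest.approx(0.05, abs=1e-12)

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            fcpt_combine([])

    def test_out_of_range_errors(self):
        with pytest.raises(ValueError):
            fcpt_combine([0.0, 0.5])
        with pytest.raises(ValueError):
            fcpt_combine([1.5])

    @given(st.lists(st.floats(min_value=1e-10, max_value=1.0), min_size=1, max_size=10))
    @settings(max_examples=100, deadline=None)
    def test_matches_closed_form_oracle(self, pvals):
        res = fcpt_combine(pvals)
        stat = -2 * sum(math.log(p) for p in pvals)
        assert res.statistic == pytest.approx(stat, rel=1e-12)
        assert res.pvalue == pytest.approx(chi2_sf_even_df(stat, 2 * len(pvals)), rel=1e-8, abs=1e-300)

    @given(st.lists(st.floats(min_value=1e-6, max_value=1.0), min_size=2, max_size=7))
    @settings(max_examples=50, deadline=None)
    def test_permutation_symmetry(self, pvals):
        a = fcpt_combine(pvals)
        b = fcpt_combine(list(reversed(pvals)))
        assert a.df == b.df
        assert a.statistic == pytest.approx(b.statistic, rel=1e-12)
        assert a.pvalue == pytest.approx(b.pvalue, rel=1e-9, abs=1e-300)


def make_bmr(rates, denom=100000):
    rates = np.asarray(rates, dtype=float)
    return BMRTable(
        sample_id="s",
        numerators=(rates * denom).astype(np.int64),
        denominators=np.full(7, denom, dtype=np.int64),
    )


def make_profile(k, n=1000, covered=1000, gene="g", sample="s"):
    return GeneMutationProfile(
        gene_id=gene,
        sample_id=sample,
        k=np.asarray(k, dtype=np.int64),
        n=np.full(7, n, dtype=np.int64),
        covered=covered,
    )


class TestTestGene:
    def test_zero_mutations_p_one(self):
        res = smg_test_gene(make_profile([0] * 7), make_bmr([1e-3] * 7))
        assert res.pvalue == 1.0
        assert res.df == 14

    def test_sample_mismatch_errors(self):
        with pytest.raises(ValueError, match="does not match"):
            smg_test_gene(make_profile([0] * 7, sample="other"), make_bmr([1e-3] * 7))

    def test_matches_manual_combination(self):
        k = [2, 0, 3, 0, 1, 0, 0]
        bmr = make_bmr([1e-3] * 7)
        res = smg_test_gene(make_profile(k), bmr)
        tails = [category_tail_probability(ki, 1000, bmr.rates[i]) for i, ki in enumerate(k)]
        want = fcpt_combine(tails)
        assert res.statistic == pytest.approx(want.statistic, rel=1e-10)
        assert res.pvalue == pytest.approx(want.pvalue, rel=1e-10)

    def test_doubling_counts_decreases_p(self):
        bmr = make_bmr([1e-3] * 7)
        k = np.array([1, 1, 2, 1, 1, 1, 1])
        p1 = smg_test_gene(make_profile(k), bmr).pvalue
        p2 = smg_test_gene(make_profile(2 * k), bmr).pvalue
        assert p2 < p1

    def test_eligibility_threshold(self):
        bmr = make_bmr([1e-3] * 7)
        assert not smg_test_gene(make_profile([0] * 7, covered=99), bmr).eligible
        assert smg_test_gene(make_profile([0] * 7, covered=100), bmr).eligible


def result(gene, sample, p, eligible=True, covered=500):
    return SMGSampleResult(
        gene_id=gene, sample_id=sample, statistic=0.0, df=14, pvalue=p,
        covered=covered, eligible=eligible,
    )


TUMORS, NORMALS = ["t1", "t2"], ["n1", "n2"]


def consensus(pt1, pt2, pn1, pn2, **kw):
    results = [
        result("g", "t1", pt1), result("g", "t2", pt2),
        result("g", "n1", pn1), result("g", "n2", pn2),
    ]
    smg_set, _ = call_smgs(results, TUMORS, NORMALS, **kw)
    return "g" in smg_set


class TestCallSmgs:
    def test_both_tumors_no_normals(self):
        assert consensus(0.005, 0.005, 0.5, 0.5)

    def test_fails_one_tumor(self):
        assert not consensus(0.005, 0.02, 0.5, 0.5)

    def test_significant_normal_blocks(self):
        assert not consensus(0.005, 0.005, 0.005, 0.5)

    def test_ineligible_tumor_blocks(self):
        results = [
            result("g", "t1", 0.005, eligible=False), result("g", "t2", 0.005),
            result("g", "n1", 0.5), result("g", "n2", 0.5),
        ]
        smg_set, _ = call_smgs(results, TUMORS, NORMALS)
        assert smg_set == set()

    def test_ineligible_normal_counts_as_clean(self):
        results = [
            result("g", "t1", 0.005), result("g", "t2", 0.005),
            result("g", "n1", 0.001, eligible=False), result("g", "n2", 0.5),
        ]
        smg_set, _ = call_smgs(results, TUMORS, NORMALS)
        assert smg_set == {"g"}

    def test_missing_sample_skips_gene(self, caplog):
        results = [result("g", "t1", 0.005)]
        smg_set, records = call_smgs(results, TUMORS, NORMALS)
        assert smg_set == set() and records == []

    def test_gene_order_invariance(self):
        results = []
        for g in ("a", "b", "c"):
            for s, p in [("t1", 0.001), ("t2", 0.001), ("n1", 0.9), ("n2", 0.9)]:
                results.append(result(g, s, p))
        s1, _ = call_smgs(results, TUMORS, NORMALS)
        s2, _ = call_smgs(list(reversed(results)), TUMORS, NORMALS)
        assert s1 == s2 == {"a", "b", "c"}


def exact_ranksum_pvalue(x, y):
    """Two-sided exact rank-sum P by full enumeration of group assignments."""
    pooled = sorted(x + y)
    ranks = {}
    # average ranks for ties
    import collections

    positions = collections.defaultdict(list)
    for i, v in enumerate(pooled, start=1):
        positions[v].append(i)
    rank_of = {v: sum(ps) / len(ps) for v, ps in positions.items()}
    all_vals = x + y
    nx = len(x)
    obs = sum(rank_of[v] for v in x)
    stats = []
    for combo in combinations(range(len(all_vals)), nx):
        s = sum(rank_of[all_vals[i]] for i in combo)
        stats.append(s)
    mean = sum(stats) / len(stats)
    extreme = sum(1 for s in stats if abs(s - mean) >= abs(obs - mean) - 1e-9)
    return extreme / len(stats)


class TestCompareMutationRates:
    def test_exact_enumeration_oracle(self):
        x = [0.001, 0.002, 0.0015, 0.003, 0.0025]
        y = [0.0005, 0.0007, 0.0012, 0.0009, 0.0004]
        genes = [f"g{i}" for i in range(10)]
        mutations = {g: int(r * 10000) for g, r in zip(genes, x + y)}
        covered = {g: 10000 for g in genes}
        res = compare_mutation_rates(set(genes[:5]), genes, mutations, covered)
        want = exact_ranksum_pvalue(
            [mutations[g] / 10000 for g in genes[:5]],
            [mutations[g] / 10000 for g in genes[5:]],
        )
        assert res.pvalue == pytest.approx(want, rel=1e-9)

    def test_identical_groups_null(self):
        genes = [f"g{i}" for i in range(20)]
        mutations = {g: 5 for g in genes}
        covered = {g: 1000 for g in genes}
        res = compare_mutation_rates(set(genes[:10]), genes, mutations, covered)
        assert res.rate_smg == res.rate_other
        assert res.pvalue > 0.9

    def test_empty_group_errors(self):
        with pytest.raises(ValueError):
            compare_mutation_rates(set(), ["g1"], {"g1": 1}, {"g1": 100})

    def test_planted_fold_recovered(self):
        """SMG/other rate ratio tracks the planted fold within sampling error."""
        from rnasomatic.pipeline import analyze
        from rnasomatic.synthetic_data import CohortConfig, simulate_cohort

        ratios = []
        for seed in range(5):
            cfg = CohortConfig(
                n_genes=120,
                seed=seed,
                somatic_rate_tumor=2e-3,
                cds_codons={"G0000": 500, "G0001": 500},
                smg_genes=[("G0000", 10.0), ("G0001", 10.0)],
            )
            c = simulate_cohort(cfg)
            res = analyze(c.models, c.sample_pairs(), blacklist=c.blacklist)
            if res.rate_comparison is not None and res.rate_comparison.rate_other > 0:
                ratios.append(res.rate_comparison.rate_smg / res.rate_comparison.rate_other)
        assert ratios, "no seed produced an SMG call"
        # called SMGs are a winner's-curse sample, so the ratio overshoots the
        # planted 10x; it must at least be strongly elevated
        assert np.mean(ratios) > 4
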