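import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.special import gammaln, logsumexp

from oligoland.burden import (
    binomial_tail_logsf,
    burden_scan,
    burden_test,
    per_set_gene_tally,
)
from oligoland.model import (
    CohortMutationTable,
    GeneSet,
    MutationRecord,
    OligolandError,
    VariantClass,
)


def brute_force_logsf(m_obs: int, k: int, p: float) -> float:
    """Independent oracle: direct log-space summation of the binomial PMF."""
    if m_obs <= 0:
        return 0.0
    x = np.arange(m_obs, k + 1)
    logpmf = (
        gammaln(k + 1)
        - gammaln(x + 1)
        - gammaln(k - x + 1)
        + x * np.log(p)
        + (k - x) * np.log1p(-p)
    )
    return float(logsumexp(logpmf))


def cohort(model, gene_hits: dict[str, int], n_samples=2):
    samples = [f"S{i+1}" for i in range(n_samples)]
    recs = []
    i = 0
    for gene, n in gene_hits.items():
        for _ in range(n):
            recs.append(
                MutationRecord(
                    samples[i % n_samples], gene, "1", 1 + i, "C", "T",
                    VariantClass.MISSENSE,
                )
            )
            i += 1
    return CohortMutationTable.from_records(recs, model, samples=samples)


class TestTailProbability:
    def test_empty_upper_tail_is_one(self):
        assert binomial_tail_logsf(0, 100, 0.3) == 0.0

    def test_all_successes_closed_form(self):
        # P(X >= k) = p^k
        assert np.exp(binomial_tail_logsf(3, 3, 0.5)) == pytest.approx(0.125)

    def test_frozen_oracle_value(self):
        # k=200, p=0.005, m=4; oracle = brute-force PMF summation
        val = np.exp(binomial_tail_logsf(4, 200, 0.005))
        assert val == pytest.approx(0.0186813393948, rel=1e-9)

    @given(
        k=st.integers(1, 5000),
        p=st.floats(1e-6, 0.5),
        frac=st.floats(0.0, 1.0),
    )
    @settings(max_examples=60, deadline=None)
    def test_matches_brute_force_summation(self, k, p, frac):
        m = int(round(frac * k))
        assert binomial_tail_logsf(m, k, p) == pytest.approx(
            brute_force_logsf(m, k, p), abs=1e-9
        )

    @given(k=st.integers(2, 2000), p=st.floats(1e-5, 0.3))
    @settings(max_examples=40, deadline=None)
    def test_monotone_decreasing_in_m(self, k, p):
        ms = [1, k // 2, k]
        vals = [binomial_tail_logsf(m, k, p) for m in sorted(set(ms))]
        assert all(a > b for a, b in zip(vals, vals[1:]))


class TestBurdenTest:
    def test_statistic_components(self, small_model):
        # universe L_G = 10,000 bp; set {A1, B2} L_P = 3,000; 2 samples
        table = cohort(small_model, {"A1": 3, "B2": 1, "C3": 6}, n_samples=2)
        res = burden_test(table, GeneSet("S", ("A1", "B2")))
        assert res.L_P == 3000
        assert res.k == 2 * 3000
        assert res.p == pytest.approx(10 / (2 * 10000))
        assert res.m_obs == 4
        assert res.p_value == pytest.approx(
            np.exp(brute_force_logsf(4, 6000, 0.0005))
        )

    def test_members_outside_universe_excluded(self, small_model):
        table = cohort(small_model, {"A1": 2})
        res = burden_test(table, GeneSet("S", ("A1", "NOT_SEQUENCED")))
        assert res.n_members == 2
        assert res.n_members_in_universe == 1
        assert res.L_P == 1000

    def test_empty_intersection_is_error(self, small_model):
        table = cohort(small_model, {"A1": 1})
        with pytest.raises(OligolandError):
            burden_test(table, GeneSet("S", ("X", "Y")))

    def test_zero_total_mutations_degenerate(self, small_model, caplog):
        table = CohortMutationTable.from_records([], small_model, samples=["S1"])
        with caplog.at_level("WARNING"):
            res = burden_test(table, GeneSet("S", ("A1",)))
        assert res.p_value == 1.0

    def test_larger_set_same_count_is_less_surprising(self, small_model):
        table = cohort(small_model, {"A1": 5})
        small = burden_test(table, GeneSet("S", ("A1",)))
        large = burden_test(table, GeneSet("L", ("A1", "D4")))
        assert small.m_obs == large.m_obs == 5
        assert large.p_value > small.p_value


class TestBurdenScan:
    def test_single_set_matches_burden_test(self, small_model):
        table = cohort(small_model, {"A1": 3, "C3": 2})
        s = GeneSet("S", ("A1",))
        assert burden_scan(table, [s])[0].p_value == pytest.approx(
            burden_test(table, s).p_value
        )

    def test_disjoint_sets_rank_by_excess_over_expectation(self, small_model):
        # A1 (1 kb) gets 8 hits, D4 (4 kb) gets 2: the short hot set must
        # rank far above the long cold one
        table = cohort(small_model, {"A1": 8, "D4": 2})
        results = burden_scan(
            table, [GeneSet("hot", ("A1",)), GeneSet("cold", ("D4",))]
        )
        assert results[0].set_name == "hot"
        assert results[0].p_value < results[1].p_value

    def test_bh_qvalues_monotone_in_ranked_p(self, rng, small_model):
        genes = list(small_model.genes)
        hits = {g: int(rng.integers(0, 6)) for g in genes}
        table = cohort(small_model, {g: n for g, n in hits.items() if n})
        sets = [GeneSet(f"P{i}", (genes[i % len(genes)],)) for i in range(8)]
        results = burden_scan(table, sets)
        qs = [r.q_value for r in results]  # results sorted by p
        assert all(a <= b + 1e-12 for a, b in zip(qs, qs[1:]))
        assert all(0 <= q <= 1 for q in qs)

    def test_per_set_tally(self, small_model):
        table = cohort(small_model, {"A1": 3, "B2": 1})
        tally = per_set_gene_tally(table, GeneSet("S", ("A1", "B2", "C3")))
        assert tally.tolist() == [3, 1, 0]
        assert tally.index.tolist() == ["A1", "B2", "C3"]


class TestCalibrationSmall:
    def test_null_cohort_gives_near_nominal_rate(self):
        """Small-scale sanity check of test calibration on the exact null."""
        from scipy import stats as sps

        from oligoland.synth import (
            generate_mutation_cohort,
            random_gene_sets,
            synthetic_gene_model,
        )

        model = synthetic_gene_model(n_genes=3000, total_mb=8.0, seed=5)
        table, _ = generate_mutation_cohort(
            n_samples=30, model=model, base_rate=2e-6, seed=5
        )
        counts = table.gene_counts().to_numpy()
        L = model.frame["coding_length_bp"].to_numpy()
        n, A, LG = table.n_samples, counts.sum(), L.sum()
        rng = np.random.default_rng(5)
        idx = np.array([rng.choice(len(L), 50, replace=False) for _ in range(2000)])
        k = n * L[idx].sum(axis=1)
        m = counts[idx].sum(axis=1)
        pv = sps.binom.sf(m - 1, k, A / (n * LG))
        assert 0.02 <= (pv < 0.05).mean() <= 0.08
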