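import itertools
from fractions import Fraction

import numpy as np
import pandas as pd
import pytest

from oligoland.expression import (
    ContrastConfig,
    differential_genes,
    gene_set_activity,
    hypergeom_enrichment,
)
from oligoland.model import ExpressionMatrix, GeneSet, OligolandError


def matrix(values, genes=None, samples=None):
    values = np.asarray(values, dtype=float)
    genes = genes or [f"G{i}" for i in range(values.shape[0])]
    samples = samples or [f"S{i}" for i in range(values.shape[1])]
    return ExpressionMatrix(pd.DataFrame(values, index=genes, columns=samples))


def brute_force_upper_tail(N, K, n, obs) -> Fraction:
    """Exact oracle: enumerate all C(N, n) draws and count overlaps >= obs."""
    universe = range(N)
    members = set(range(K))
    hits = total = 0
    for draw in itertools.combinations(universe, n):
        total += 1
        if len(members.intersection(draw)) >= obs:
            hits += 1
    return Fraction(hits, total)


class TestDifferentialGenes:
    def make_groups(self, rng, n_genes=300, n=10, shift_gene=None, shift=0.0):
        a = [f"A{i}" for i in range(n)]
        b = [f"B{i}" for i in range(n)]
        vals = rng.normal(7, 0.5, size=(n_genes, 2 * n))
        genes = [f"G{i}" for i in range(n_genes)]
        if shift_gene is not None:
            vals[genes.index(shift_gene), :n] += shift
        return matrix(vals, genes, a + b), a, b

    def test_planted_full_shift_recovered(self, rng):
        vals = rng.normal(7, 0.01, size=(5, 8))
        vals[0, :4] += 1.0
        expr = matrix(vals)
        table, sig = differential_genes(expr, ["S0", "S1", "S2", "S3"],
                                        ["S4", "S5", "S6", "S7"])
        assert "G0" in sig
        assert table.loc["G0", "logfc"] == pytest.approx(1.0, abs=0.05)

    def test_joint_rule_boundary_small_fold_change(self, rng):
        # highly significant p but |logFC| <= 0.6 must NOT pass
        vals = rng.normal(7, 0.01, size=(3, 12))
        vals[1, :6] += 0.5
        expr = matrix(vals)
        table, sig = differential_genes(
            expr, [f"S{i}" for i in range(6)], [f"S{i}" for i in range(6, 12)]
        )
        assert table.loc["G1", "p"] < 1e-6
        assert "G1" not in sig

    def test_downshift_gives_negative_logfc(self, rng):
        vals = rng.normal(7, 0.01, size=(2, 8))
        vals[0, :4] -= 1.0  # mutant group downregulated
        expr = matrix(vals)
        table, sig = differential_genes(expr, ["S0", "S1", "S2", "S3"],
                                        ["S4", "S5", "S6", "S7"])
        assert table.loc["G0", "logfc"] < -0.9
        assert "G0" in sig

    def test_null_type_one_rate_near_nominal(self, rng):
        expr, a, b = self.make_groups(rng, n_genes=2000, n=20)
        table, sig = differential_genes(expr, a, b)
        frac = (table["p"] < 0.05).mean()
        assert 0.03 <= frac <= 0.07
        # the joint rule passes almost nothing under the null
        assert len(sig) <= 5

    def test_group_validation(self, rng):
        expr, a, b = self.make_groups(rng, n_genes=10, n=3)
        with pytest.raises(OligolandError, match="overlap"):
            differential_genes(expr, a, a)
        with pytest.raises(OligolandError, match="at least 2"):
            differential_genes(expr, a[:1], b)
        with pytest.raises(OligolandError, match="absent"):
            differential_genes(expr, a, ["nope", "nope2"])

    def test_zero_variance_genes_dropped(self, rng):
        vals = rng.normal(7, 1, size=(4, 8))
        vals[2, :] = 5.0
        expr = matrix(vals)
        table, _ = differential_genes(expr, [f"S{i}" for i in range(4)],
                                      [f"S{i}" for i in range(4, 8)])
        assert "G2" not in table.index

    def test_pooled_variant_runs(self, rng):
        expr, a, b = self.make_groups(rng, n_genes=50, n=5)
        table, _ = differential_genes(expr, a, b, ContrastConfig(test="pooled"))
        assert ((table["p"] >= 0) & (table["p"] <= 1)).all()


class TestHypergeomEnrichment:
    def test_hand_case_1_over_252(self):
        universe = [f"G{i}" for i in range(10)]
        de = universe[:5]
        s = GeneSet("S", tuple(universe[:5]))
        (res,) = hypergeom_enrichment(de, [s], universe)
        assert res.n_overlap == 5
        assert res.p_value == pytest.approx(1 / 252, rel=1e-12)

    def test_empty_de_list_gives_one(self):
        universe = ["A", "B", "C"]
        res = hypergeom_enrichment([], [GeneSet("S", ("A",))], universe)
        assert all(r.p_value == 1.0 for r in res)

    def test_set_disjoint_from_universe(self):
        res = hypergeom_enrichment(["A"], [GeneSet("S", ("Z",))], ["A", "B"])
        assert res[0].n_set_in_universe == 0
        assert res[0].p_value == 1.0

    def test_de_outside_universe_rejected(self):
        with pytest.raises(OligolandError):
            hypergeom_enrichment(["Z"], [GeneSet("S", ("A",))], ["A"])

    @pytest.mark.parametrize(
        "N,K,n_de,seed", [(8, 3, 4, 0), (12, 5, 6, 1), (15, 6, 5, 2), (20, 8, 7, 3)]
    )
    def test_matches_brute_force_enumeration(self, N, K, n_de, seed):
        rng = np.random.default_rng(seed)
        universe = [f"G{i}" for i in range(N)]
        members = universe[:K]
        de = [universe[i] for i in rng.choice(N, size=n_de, replace=False)]
        (res,) = hypergeom_enrichment(de, [GeneSet("S", tuple(members))], universe)
        expected = brute_force_upper_tail(N, K, n_de, res.n_overlap)
        assert res.p_value == pytest.approx(float(expected), rel=1e-10)


class TestGeneSetActivity:
    def test_constant_matrix_ties_keep_id_order(self):
        expr = matrix(np.full((3, 4), 7.0), samples=["S1", "S2", "S3", "S4"])
        activity, ranking = gene_set_activity(expr, GeneSet("S", ("G0", "G1")))
        assert ranking == ["S1", "S2", "S3", "S4"]
        assert (activity == 7.0).all()

    def test_shifted_sample_ranks_first(self, rng):
        vals = rng.normal(7, 0.1, size=(5, 6))
        vals[:, 3] += 1.0
        expr = matrix(vals)
        _, ranking = gene_set_activity(expr, GeneSet("S", ("G0", "G1", "G2")))
        assert ranking[0] == "S3"

    def test_mean_over_present_members_only(self):
        expr = matrix([[1.0, 2.0], [3.0, 4.0]], genes=["A", "B"], samples=["S1", "S2"])
        activity, _ = gene_set_activity(expr, GeneSet("S", ("A", "B", "MISSING")))
        assert activity["S1"] == pytest.approx(2.0)
        assert activity["S2"] == pytest.approx(3.0)

    def test_no_members_present_is_error(self):
        expr = matrix([[1.0, 2.0]])
        with pytest.raises(OligolandError):
            gene_set_activity(expr, GeneSet("S", ("NOPE",)))
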