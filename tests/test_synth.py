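import numpy as np
import pytest

from oligoland import io as olio
from oligoland.cna import classify_cohort, list_focal_events
from oligoland.fusions import FusionFilterConfig, filter_fusions
from oligoland.model import OligolandError
from oligoland.synth import (
    generate_ascn_cohort,
    generate_cohort_bundle,
    generate_expression,
    generate_fusion_table,
    generate_mutation_cohort,
    random_gene_sets,
    synthetic_gene_model,
)


class TestGeneModel:
    def test_total_length_near_requested(self):
        model = synthetic_gene_model(n_genes=2000, total_mb=10.0, seed=1)
        assert len(model) == 2000
        assert model.total_length_bp == pytest.approx(10e6, rel=0.02)

    def test_named_genes_appended(self):
        model = synthetic_gene_model(
            n_genes=100, total_mb=1.0, seed=1,
            named_genes={"CIC": ("19", "q", 4833)},
        )
        assert "CIC" in model
        assert model.length_of("CIC") == 4833

    def test_disjoint_sets(self):
        model = synthetic_gene_model(n_genes=600, total_mb=2.0, seed=2)
        sets = random_gene_sets(list(model.genes), 10, 50, seed=2, disjoint=True)
        seen: set[str] = set()
        for s in sets:
            assert not seen & set(s.genes)
            seen |= set(s.genes)


class TestMutationCohort:
    def test_mean_burden_matches_expectation(self):
        # expectation: rate x L_G mutations per sample
        model = synthetic_gene_model(n_genes=4000, total_mb=10.0, seed=4)
        table, _ = generate_mutation_cohort(
            n_samples=40, model=model, base_rate=4e-6, seed=4
        )
        expected = 4e-6 * model.total_length_bp
        per_sample = table.frame["sample_id"].value_counts().reindex(
            table.samples, fill_value=0
        )
        se = np.sqrt(expected / 40)
        assert abs(per_sample.mean() - expected) <= 3 * se

    def test_zero_multiplier_silences_gene(self):
        model = synthetic_gene_model(n_genes=50, total_mb=5.0, seed=5)
        gene = str(model.genes[0])
        table, truth = generate_mutation_cohort(
            n_samples=30, model=model, base_rate=2e-5, spikes={gene: 0.0}, seed=5
        )
        assert (table.frame["gene"] == gene).sum() == 0
        assert truth.spiked_genes == {gene: 0.0}

    def test_spike_raises_gene_count(self):
        model = synthetic_gene_model(n_genes=200, total_mb=4.0, seed=6)
        gene = str(model.genes[0])
        table, _ = generate_mutation_cohort(
            n_samples=50, model=model, base_rate=2e-6, spikes={gene: 50.0}, seed=6
        )
        counts = table.gene_counts()
        assert counts[gene] > counts.drop(gene).max()

    def test_unknown_spike_rejected(self):
        model = synthetic_gene_model(n_genes=10, total_mb=0.1, seed=0)
        with pytest.raises(OligolandError, match="absent"):
            generate_mutation_cohort(5, model, spikes={"NOPE": 2.0}, seed=0)

    def test_deterministic_files(self, tmp_path):
        model = synthetic_gene_model(n_genes=100, total_mb=1.0, seed=7)
        for i in (1, 2):
            table, _ = generate_mutation_cohort(
                n_samples=10, model=model, base_rate=5e-6, seed=7
            )
            olio.write_mutation_table(table, tmp_path / f"run{i}.tsv")
        assert (tmp_path / "run1.tsv").read_bytes() == (tmp_path / "run2.tsv").read_bytes()

    def test_emitted_table_passes_validators(self, tmp_path):
        model = synthetic_gene_model(n_genes=100, total_mb=1.0, seed=8)
        table, _ = generate_mutation_cohort(10, model, base_rate=5e-6, seed=8)
        p = tmp_path / "m.tsv"
        olio.write_mutation_table(table, p)
        back = olio.read_mutation_table(p, model, samples=table.samples)
        assert len(back) == len(table)


class TestAscnCohort:
    def test_planted_focal_homdel_probe_boundary(self, arm_table):
        segments, ploidies, _ = generate_ascn_cohort(
            n_samples=2,
            arm_table=arm_table,
            seed=9,
            focal_homdels=[
                ("AO_01", "9", 1_000_000, 1_200_000, 4),
                ("AO_02", "9", 1_000_000, 1_200_000, 5),
            ],
        )
        calls = classify_cohort(segments, {p.sample_id: p for p in ploidies})
        focal = list_focal_events(calls)
        assert [c.segment.sample_id for c in focal] == ["AO_02"]

    def test_null_profile_all_neutral(self, arm_table):
        segments, ploidies, _ = generate_ascn_cohort(
            n_samples=3, arm_table=arm_table, arm_loss_freqs={}, seed=10
        )
        calls = classify_cohort(segments, {p.sample_id: p for p in ploidies})
        assert all(c.category.value == "neutral" for c in calls)
        assert not any(c.loh for c in calls)

    def test_segments_pass_validators_and_truth_consistent(self, arm_table, tmp_path):
        segments, ploidies, truth = generate_ascn_cohort(
            n_samples=20, arm_table=arm_table,
            arm_loss_freqs={"9p": 0.5}, seed=11,
        )
        p = tmp_path / "a.seg"
        olio.write_seg(segments, p)
        back = olio.read_seg(p)  # validates non-overlap
        assert back == segments
        lost = {s for s, arms in truth.arm_events.items() if "9p" in arms}
        loss_samples = {
            s.sample_id for s in segments if s.chrom == "9" and s.total_cn == 1.0
        }
        assert lost == loss_samples

    def test_unknown_arm_rejected(self, arm_table):
        with pytest.raises(OligolandError, match="unknown arm"):
            generate_ascn_cohort(2, arm_table, arm_loss_freqs={"zz": 0.1}, seed=0)


class TestExpression:
    def test_downshifted_set_ranks_mutants_last(self):
        from oligoland.expression import gene_set_activity

        sets = random_gene_sets([f"EG{i+1:05d}" for i in range(300)], 3, 30,
                                seed=12, prefix="XS", disjoint=True)
        mutant = [f"M{i}" for i in range(5)]
        wt = [f"W{i}" for i in range(20)]
        expr, truth = generate_expression(
            300, {"mutant": mutant, "wildtype": wt}, sets=sets,
            shifted_sets={sets[0].name: -1.0}, noise_sd=0.3, seed=12,
        )
        _, ranking = gene_set_activity(expr, sets[0])
        assert set(ranking[-5:]) == set(mutant)
        assert truth.shifted_sets == {sets[0].name: -1.0}

    def test_null_shift_near_nominal_significance(self):
        from oligoland.expression import differential_genes

        a = [f"A{i}" for i in range(20)]
        b = [f"B{i}" for i in range(20)]
        expr, _ = generate_expression(1000, {"a": a, "b": b}, seed=13)
        table, sig = differential_genes(expr, a, b)
        assert 0.02 <= (table["p"] < 0.05).mean() <= 0.08
        assert len(sig) <= 5

    def test_absent_gene_reference_rejected(self):
        from oligoland.model import GeneSet

        with pytest.raises(OligolandError, match="absent"):
            generate_expression(
                10, {"a": ["S1", "S2"], "b": ["S3", "S4"]},
                sets=[GeneSet("S", ("NOPE",))], shifted_sets={"S": 1.0}, seed=0,
            )

    def test_deterministic(self):
        kwargs = dict(
            n_genes=50,
            groups={"a": ["S1", "S2"], "b": ["S3", "S4"]},
            seed=14,
        )
        e1, _ = generate_expression(**kwargs)
        e2, _ = generate_expression(**kwargs)
        assert np.array_equal(e1.values, e2.values)


class TestFusionTable:
    def test_constructed_counts_survive_filter(self):
        candidates, blacklist, truth = generate_fusion_table(3, 4, 3, 2, seed=15)
        assert len(candidates) == 12
        cfg = FusionFilterConfig(blacklist=blacklist)
        retained, reasons = filter_fusions(candidates, cfg)
        assert len(retained) == 3
        labels = {r["label"] for r in truth.true_fusions if r["is_true"]}
        assert labels == {"true"}
        by_label = reasons["reason"].value_counts().to_dict()
        assert by_label == {
            "retained": 3, "spanning_reads": 4,
            "total_supporting_reads": 3, "blacklist": 2,
        }

    def test_empty_request_empty_output(self):
        candidates, _, truth = generate_fusion_table(0, 0, 0, 0, seed=16)
        assert candidates == [] and truth.true_fusions == []

    def test_deterministic(self):
        c1, b1, _ = generate_fusion_table(2, 2, 2, 1, seed=17)
        c2, b2, _ = generate_fusion_table(2, 2, 2, 1, seed=17)
        assert c1 == c2 and b1 == b2


class TestBundle:
    def test_bundle_writes_consistent_truth(self, tmp_path):
        paths, truth = generate_cohort_bundle(
            tmp_path, seed=18, n_samples=20, n_genes=1500, total_mb=4.0
        )
        model = olio.read_gene_model(paths["gene_model"])
        table = olio.read_mutation_table(paths["mutations"], model)
        # every truth entry refers to an entity present in the files
        assert set(truth.subtype_labels) == set(table.samples)
        for g in truth.spiked_genes:
            assert g in model
        sets = {s.name for s in olio.read_gmt(paths["gene_sets"])}
        assert set(truth.spiked_sets) <= sets
        esets = {s.name for s in olio.read_gmt(paths["expression_sets"])}
        assert set(truth.shifted_sets) <= esets
        carriers = set(truth.extras["tcf12_carriers"])
        assert carriers <= set(table.samples)
        assert carriers == set(
            table.frame.loc[table.frame["gene"] == "TCF12", "sample_id"]
        ) | carriers  # injected carriers always present among TCF12-mutated

    def test_bundle_byte_identical_reruns(self, tmp_path):
        import filecmp

        d1, d2 = tmp_path / "r1", tmp_path / "r2"
        for d in (d1, d2):
            generate_cohort_bundle(d, seed=19, n_samples=12, n_genes=800, total_mb=2.0)
        for name in ("mutations.tsv", "segments.seg", "expression.tsv",
                     "fusions.tsv", "truth.json", "gene_model.tsv"):
            assert filecmp.cmp(d1 / name, d2 / name, shallow=False), name
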