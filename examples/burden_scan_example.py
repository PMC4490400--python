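"""Gene-set mutation-burden scan on a synthetic cohort.

Builds a small exome universe, plants one gene set mutated at five times
the background rate, scans 20 candidate sets with the exact binomial
upper-tail test and prints the ranking.
"""
from oligoland.burden import burden_scan
from oligoland.synth import (
    generate_mutation_cohort,
    random_gene_sets,
    synthetic_gene_model,
)

model = synthetic_gene_model(n_genes=2000, total_mb=5.0, seed=7)
sets = random_gene_sets(list(model.genes), 20, 50, seed=7, disjoint=True)
spiked = sets[0]

table, truth = generate_mutation_cohort(
    n_samples=30,
    model=model,
    base_rate=1.6e-6,
    spikes={g: 5.0 for g in spiked.genes},
    seed=7,
)
print(f"cohort: {table.n_samples} samples, {len(table)} mutations, "
      f"A(G,S)={table.total_mutation_count}")

results = burden_scan(table, sets)
print(f"{'set':8s} {'L_P':>8s} {'m_obs':>6s} {'expected':>9s} {'p_value':>10s}")
for r in results[:5]:
    print(f"{r.set_name:8s} {r.L_P:8d} {r.m_obs:6d} {r.expected:9.2f} {r.p_value:10.3g}")

# The spiked set accumulates far more mutations than k*p expected under
# the uniform per-base rate, so it tops the ranking with a tiny p-value;
# null sets hover near their expectation with p-values spread over (0, 1).
assert results[0].set_name == spiked.name
print(f"\nspiked set {spiked.name} ranked first (truth: {truth.spiked_genes and '5x spike'})")
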