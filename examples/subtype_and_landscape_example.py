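"""Molecular subtyping and mutation-landscape summaries of a full bundle.

Generates a synthetic cohort directory (mutations, copy number, TERT
promoter assay), assigns each tumour to IDHmut-codel / IDHmut-noncodel /
IDHwt, and prints the burden and substitution-spectrum summaries that
describe the cohort's mutational landscape.
"""
import tempfile
from collections import Counter

from oligoland import io as olio
from oligoland import subtypes as st
from oligoland.landscape import (
    cohort_spectrum_fractions,
    compute_burden,
    gene_by_sample_matrix,
    order_for_oncoprint,
    spectrum_counts,
)
from oligoland.synth import generate_cohort_bundle

with tempfile.TemporaryDirectory() as d:
    paths, truth = generate_cohort_bundle(d, seed=5, n_samples=30,
                                          n_genes=3000, total_mb=8.0)
    model = olio.read_gene_model(paths["gene_model"])
    table = olio.read_mutation_table(paths["mutations"], model)
    segments = olio.read_seg(paths["segments"])
    ploidies = olio.read_ploidy(paths["ploidy"])
    promoter = olio.read_promoter_variants(paths["tert_promoter"])
    arms = olio.read_arm_table(paths["arms"])

muts = {s: [] for s in table.samples}
for r in table.records:
    if r.gene in ("IDH1", "IDH2"):
        muts[r.sample_id].append(r)
segs: dict = {s: [] for s in table.samples}
for seg in segments:
    segs[seg.sample_id].append(seg)

calls = st.call_cohort_subtypes(muts, segs, ploidies, arms, promoter)
print("subtype counts:", dict(Counter(c.subtype.value for c in calls)))
print("TERT hotspot carriers:",
      sum(c.tert_promoter.value in ("C228T", "C250T") for c in calls))
recovered = all(
    c.subtype.value == truth.subtype_labels[c.sample_id] for c in calls
)
print("subtypes match generator truth:", recovered)

# Burden per Mb against the ~8 Mb synthetic target and the collapsed
# six-class substitution spectrum (C>T dominates, as in adult gliomas).
burdens = compute_burden(table, target_mb=model.total_length_bp / 1e6)
rates = [b.rate_per_mb for b in burdens]
print(f"mean mutation rate: {sum(rates)/len(rates):.2f} per Mb")
print("spectrum:", cohort_spectrum_fractions(spectrum_counts(table)).round(3).to_dict())

# Memo-sorted sample order for an oncoprint of the five driver genes.
mat = gene_by_sample_matrix(table, ["IDH1", "IDH2", "CIC", "FUBP1", "TCF12"])
print("first five memo-sorted samples:", order_for_oncoprint(mat)[:5])
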