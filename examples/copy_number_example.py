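"""Ploidy-relative copy-number calls, focal events and arm recurrence.

Simulates a 40-sample cohort with recurrent chromosome-4, 9p and 14q
losses plus two planted focal homozygous deletions (one below, one at the
five-probe support minimum) and summarises what the caller recovers.
"""
from oligoland.cna import (
    arm_recurrence,
    chromosome_loss_fraction,
    classify_cohort,
    list_focal_events,
)
from oligoland.io import load_hg19_arms
from oligoland.synth import generate_ascn_cohort

arms = load_hg19_arms()
segments, ploidies, truth = generate_ascn_cohort(
    n_samples=40,
    arm_table=arms,
    arm_loss_freqs={("4p", "4q"): 0.29, "9p": 0.28, "14q": 0.19},
    ploidy=2.0,
    seed=11,
    focal_homdels=[
        ("AO_01", "10", 30_000_000, 30_400_000, 4),  # below the probe minimum
        ("AO_02", "10", 30_000_000, 30_400_000, 7),
    ],
)

calls = classify_cohort(segments, {p.sample_id: p for p in ploidies})
by_sample: dict = {}
for c in calls:
    by_sample.setdefault(c.segment.sample_id, []).append(c)

# Arm-level recurrence: a sample counts as lost when loss segments cover
# >= 90% of the arm; fractions estimate the planted frequencies.
for rec in arm_recurrence(by_sample, arms, arms=["4p", "9p", "14q"]):
    print(f"{rec.arm}: lost in {rec.n_lost}/40 samples "
          f"(fraction {rec.fraction_lost:.2f})")
print(f"whole chromosome 4 lost: {chromosome_loss_fraction(by_sample, arms, '4'):.2f} "
      f"(planted 0.29)")

# Focal events need >= 5 consecutive probes: only the 7-probe deletion
# survives the filter.
focal = list_focal_events(calls)
for c in focal:
    print(f"focal {c.category.value} in {c.segment.sample_id}: "
          f"chr{c.segment.chrom}:{c.segment.start}-{c.segment.end} "
          f"({c.segment.n_probes} probes, LOH={c.loh})")
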