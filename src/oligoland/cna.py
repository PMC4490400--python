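"""Ploidy-relative classification of allele-specific copy-number segments.

A segment's category is determined by comparing its total copy number to
the sample ploidy:

* homozygous deletion: total copy number = 0
* high-level amplification: total copy number > ploidy + 2
* gain: total copy number >= ploidy + 1
* loss: total copy number <= ploidy - 1
* neutral: otherwise

The printed rules overlap (CN = 0 also satisfies the loss rule, and
CN > ploidy + 2 also satisfies the gain rule); precedence is
homozygous deletion > high amplification > gain/loss > neutral. The LOH
flag is set independently whenever the minor-allele copy number is 0.
Copy numbers are compared as real values — no rounding is applied.
"""
from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .model import AscnSegment, OligolandError, SamplePloidy


class Aberration(str, enum.Enum):
    NEUTRAL = "neutral"
    GAIN = "gain"
    LOSS = "loss"
    HIGH_AMPLIFICATION = "high_amplification"
    HOMOZYGOUS_DELETION = "homozygous_deletion"


#: Minimum probe support for a focal event (homozygous deletion or
#: high-level amplification).
FOCAL_MIN_PROBES = 5

#: Fraction of an arm that must be covered by loss/gain segments for an
#: arm-level event call.
ARM_FRACTION_THRESHOLD = 0.9


@dataclass(frozen=True)
class AberrationCall:
    segment: AscnSegment
    category: Aberration
    loh: bool


def classify_segment(seg: AscnSegment, ploidy: float) -> AberrationCall:
    """Classify one segment against the sample's ploidy."""
    if ploidy <= 0:
        raise OligolandError(f"ploidy must be positive, got {ploidy}")
    cn = seg.total_cn
    if cn == 0:
        category = Aberration.HOMOZYGOUS_DELETION
    elif cn > ploidy + 2:
        category = Aberration.HIGH_AMPLIFICATION
    elif cn >= ploidy + 1:
        category = Aberration.GAIN
    elif cn <= ploidy - 1:
        category = Aberration.LOSS
    else:
        category = Aberration.NEUTRAL
    return AberrationCall(segment=seg, category=category, loh=seg.minor_cn == 0)


def classify_cohort(
    segments: Iterable[AscnSegment],
    ploidies: Mapping[str, SamplePloidy],
) -> list[AberrationCall]:
    calls = []
    for seg in segments:
        if seg.sample_id not in ploidies:
            raise OligolandError(f"no ploidy for sample {seg.sample_id}")
        calls.append(classify_segment(seg, ploidies[seg.sample_id].ploidy))
    return calls


def list_focal_events(
    calls: Iterable[AberrationCall], min_probes: int = FOCAL_MIN_PROBES
) -> list[AberrationCall]:
    """Homozygous deletions and high amplifications with enough probes.

    Events supported by fewer than ``min_probes`` consecutive probes are
    dropped; output sorted by sample, then chromosome, then start.
    """
    focal = [
        c
        for c in calls
        if c.category
        in (Aberration.HOMOZYGOUS_DELETION, Aberration.HIGH_AMPLIFICATION)
        and c.segment.n_probes >= min_probes
    ]
    return sorted(
        focal, key=lambda c: (c.segment.sample_id, c.segment.chrom, c.segment.start)
    )


def _overlap_bp(seg: AscnSegment, start: int, end: int) -> int:
    lo = max(seg.start, start)
    hi = min(seg.end, end)
    return max(0, hi - lo + 1)


def arm_event_fraction(
    calls: Sequence[AberrationCall],
    chrom: str,
    arm_start: int,
    arm_end: int,
    category: Aberration,
) -> float:
    """Fraction of an arm's length covered by segments of one category.

    Lengths are 1-based inclusive (end - start + 1).
    """
    arm_len = arm_end - arm_start + 1
    covered = sum(
        _overlap_bp(c.segment, arm_start, arm_end)
        for c in calls
        if c.segment.chrom == chrom and c.category == category
    )
    return covered / arm_len


def arm_covered_fraction(
    calls: Sequence[AberrationCall], chrom: str, arm_start: int, arm_end: int
) -> float:
    """Fraction of the arm covered by any segment (for missing-data checks)."""
    arm_len = arm_end - arm_start + 1
    covered = sum(
        _overlap_bp(c.segment, arm_start, arm_end)
        for c in calls
        if c.segment.chrom == chrom
    )
    return covered / arm_len


@dataclass(frozen=True)
class ArmRecurrence:
    arm: str
    n_lost: int
    n_gained: int
    fraction_lost: float
    fraction_gained: float


def arm_recurrence(
    calls_by_sample: Mapping[str, Sequence[AberrationCall]],
    arm_table: pd.DataFrame,
    arms: Sequence[str] | None = None,
    arm_fraction_threshold: float = ARM_FRACTION_THRESHOLD,
) -> list[ArmRecurrence]:
    """Cohort recurrence of arm-level losses and gains.

    A sample counts as "arm lost" (resp. gained) when loss- (gain-)
    classified segments cover at least ``arm_fraction_threshold`` of the
    arm's length. Denominator = cohort size (all samples in the mapping).
    """
    n = len(calls_by_sample)
    if n < 1:
        raise OligolandError("empty cohort")
    rows: list[ArmRecurrence] = []
    wanted = list(arms) if arms is not None else arm_table["arm_name"].tolist()
    known = set(arm_table["arm_name"])
    for arm_name in wanted:
        if arm_name not in known:
            raise OligolandError(f"arm {arm_name!r} absent from arm table")
        row = arm_table.loc[arm_table["arm_name"] == arm_name].iloc[0]
        chrom, start, end = str(row["chrom"]), int(row["start"]), int(row["end"])
        n_lost = n_gained = 0
        for calls in calls_by_sample.values():
            if (
                arm_event_fraction(calls, chrom, start, end, Aberration.LOSS)
                >= arm_fraction_threshold
            ):
                n_lost += 1
            elif (
                arm_event_fraction(calls, chrom, start, end, Aberration.GAIN)
                >= arm_fraction_threshold
            ):
                n_gained += 1
        rows.append(
            ArmRecurrence(
                arm=arm_name,
                n_lost=n_lost,
                n_gained=n_gained,
                fraction_lost=n_lost / n,
                fraction_gained=n_gained / n,
            )
        )
    return rows


def chromosome_loss_fraction(
    calls_by_sample: Mapping[str, Sequence[AberrationCall]],
    arm_table: pd.DataFrame,
    chrom: str,
    arm_fraction_threshold: float = ARM_FRACTION_THRESHOLD,
) -> float:
    """Fraction of samples losing BOTH arms of a chromosome."""
    arms = arm_table.loc[arm_table["chrom"].astype(str) == str(chrom)]
    if arms.empty:
        raise OligolandError(f"chromosome {chrom!r} absent from arm table")
    n_lost = 0
    for calls in calls_by_sample.values():
        lost_all = all(
            arm_event_fraction(
                calls, str(r["chrom"]), int(r["start"]), int(r["end"]), Aberration.LOSS
            )
            >= arm_fraction_threshold
            for _, r in arms.iterrows()
        )
        if lost_all:
            n_lost += 1
    return n_lost / len(calls_by_sample)


def calls_to_frame(calls: Iterable[AberrationCall]) -> pd.DataFrame:
    rows = [
        (
            c.segment.sample_id,
            c.segment.chrom,
            c.segment.start,
            c.segment.end,
            c.segment.n_probes,
            c.segment.total_cn,
            c.segment.minor_cn,
            c.category.value,
            c.loh,
        )
        for c in calls
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "sample_id",
            "chrom",
            "start",
            "end",
            "n_probes",
            "total_cn",
            "minor_cn",
            "category",
            "loh",
        ],
    )
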