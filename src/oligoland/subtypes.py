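"""Molecular subtype assignment for oligodendroglial tumours.

Three subtypes are used: IDH-mutant with 1p/19q co-deletion
(``IDHmut_codel``), IDH-mutant without co-deletion (``IDHmut_noncodel``)
and IDH-wild-type (``IDHwt``). IDH mutation means a hotspot substitution
at IDH1 codon R132 or IDH2 codon R172; any other IDH1/IDH2 variant does
not qualify. 1p/19q co-deletion means loss of (nearly) the whole of both
arms, assessed from allele-specific copy-number segments relative to the
sample ploidy.

TERT promoter status is annotated from the two recurrent hg19 hotspots on
chromosome 5: C228T at 1,295,228 bp and C250T at 1,295,250 bp (described
as G>A on the sequenced strand).
"""
from __future__ import annotations

import enum
import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from . import cna
from .model import AscnSegment, MutationRecord, SamplePloidy

logger = logging.getLogger(__name__)

TERT_CHROM = "5"
TERT_C228T_POS = 1_295_228
TERT_C250T_POS = 1_295_250


class Subtype(str, enum.Enum):
    IDHMUT_CODEL = "IDHmut_codel"
    IDHMUT_NONCODEL = "IDHmut_noncodel"
    IDHWT = "IDHwt"


class TertStatus(str, enum.Enum):
    C228T = "C228T"
    C250T = "C250T"
    WILDTYPE = "wildtype"
    UNKNOWN = "unknown"


@dataclass(frozen=True)
class SubtypeCall:
    sample_id: str
    subtype: Subtype
    idh_mutant: bool
    codel_1p19q: bool
    tert_promoter: TertStatus


def call_idh_status(muts: Iterable[MutationRecord]) -> bool:
    """True iff the sample carries IDH1 R132* or IDH2 R172*."""
    for m in muts:
        if m.gene not in ("IDH1", "IDH2"):
            continue
        if not m.protein_change:
            logger.info(
                "IDH record without protein_change in %s treated as "
                "non-qualifying",
                m.sample_id,
            )
            continue
        if m.gene == "IDH1" and m.protein_change.startswith("R132"):
            return True
        if m.gene == "IDH2" and m.protein_change.startswith("R172"):
            return True
    return False


def call_1p19q_codel(
    segments: Sequence[AscnSegment],
    ploidy: SamplePloidy,
    arm_table: pd.DataFrame,
    arm_fraction_threshold: float = cna.ARM_FRACTION_THRESHOLD,
    min_coverage: float = 0.5,
) -> bool:
    """True iff both 1p and 19q are lost over >= threshold of arm length.

    If either arm lacks segment coverage the status is unknown and is
    propagated as non-co-deleted with a warning.
    """
    calls = [cna.classify_segment(s, ploidy.ploidy) for s in segments]
    for arm_name in ("1p", "19q"):
        row = arm_table.loc[arm_table["arm_name"] == arm_name]
        if row.empty:
            raise KeyError(f"arm {arm_name} missing from arm table")
        r = row.iloc[0]
        chrom, start, end = str(r["chrom"]), int(r["start"]), int(r["end"])
        if cna.arm_covered_fraction(calls, chrom, start, end) < min_coverage:
            logger.warning(
                "sample %s: no usable coverage of %s; reporting non-codel",
                ploidy.sample_id,
                arm_name,
            )
            return False
        frac = cna.arm_event_fraction(calls, chrom, start, end, cna.Aberration.LOSS)
        if frac < arm_fraction_threshold:
            return False
    return True


def call_tert_promoter(
    variants: Sequence[tuple[str, int, str, str]] | None,
) -> TertStatus:
    """Classify the TERT promoter from assay records.

    ``variants`` is the sample's list of (chrom, pos, ref, alt) promoter
    records; an empty list means assayed and variant-free, ``None`` means
    not assayed.
    """
    if variants is None:
        return TertStatus.UNKNOWN
    status = TertStatus.WILDTYPE
    for chrom, pos, ref, alt in variants:
        if str(chrom).removeprefix("chr") != TERT_CHROM:
            continue
        if pos in (TERT_C228T_POS, TERT_C250T_POS):
            if (ref, alt) != ("G", "A"):
                logger.warning(
                    "TERT hotspot at %d with unexpected alleles %s>%s; "
                    "not called",
                    pos,
                    ref,
                    alt,
                )
                continue
            status = (
                TertStatus.C228T if pos == TERT_C228T_POS else TertStatus.C250T
            )
    return status


def assign_subtype(idh: bool, codel: bool) -> Subtype:
    """Deterministic three-way partition of the (IDH, codel) flag space."""
    if idh and codel:
        return Subtype.IDHMUT_CODEL
    if idh:
        return Subtype.IDHMUT_NONCODEL
    return Subtype.IDHWT


def call_cohort_subtypes(
    mutations_by_sample: Mapping[str, Sequence[MutationRecord]],
    segments_by_sample: Mapping[str, Sequence[AscnSegment]],
    ploidies: Mapping[str, SamplePloidy],
    arm_table: pd.DataFrame,
    promoter_by_sample: Mapping[str, Sequence[tuple[str, int, str, str]]] | None = None,
    arm_fraction_threshold: float = cna.ARM_FRACTION_THRESHOLD,
) -> list[SubtypeCall]:
    """Subtype every sample that has mutation data."""
    calls = []
    for sample_id in sorted(mutations_by_sample):
        idh = call_idh_status(mutations_by_sample[sample_id])
        segs = segments_by_sample.get(sample_id, [])
        if segs and sample_id in ploidies:
            codel = call_1p19q_codel(
                list(segs),
                ploidies[sample_id],
                arm_table,
                arm_fraction_threshold=arm_fraction_threshold,
            )
        else:
            logger.warning(
                "sample %s: no copy-number data; reporting non-codel", sample_id
            )
            codel = False
        tert = call_tert_promoter(
            None
            if promoter_by_sample is None
            else promoter_by_sample.get(sample_id)
        )
        calls.append(
            SubtypeCall(
                sample_id=sample_id,
                subtype=assign_subtype(idh, codel),
                idh_mutant=idh,
                codel_1p19q=codel,
                tert_promoter=tert,
            )
        )
    return calls


def subtype_calls_to_frame(calls: Iterable[SubtypeCall]) -> pd.DataFrame:
    rows = [
        (c.sample_id, c.subtype.value, c.idh_mutant, c.codel_1p19q, c.tert_promoter.value)
        for c in calls
    ]
    return pd.DataFrame(
        rows,
        columns=["sample_id", "subtype", "idh_mutant", "codel_1p19q", "tert_promoter"],
    )
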