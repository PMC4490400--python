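"""Readers and writers for the tab-delimited formats the pipeline consumes.

All files are UTF-8, tab-delimited, with ``#``-prefixed comment lines
ignored. Coordinates in files are 1-based inclusive.
"""
from __future__ import annotations

import logging
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .model import (
    AscnSegment,
    CohortMutationTable,
    FormatError,
    FusionCandidate,
    ExpressionMatrix,
    GeneModelTable,
    GeneSet,
    MUTATION_COLUMNS,
    SamplePloidy,
    ValidationError,
    VariantClass,
)

logger = logging.getLogger(__name__)

_VALID_CLASSES = {v.value for v in VariantClass}


def _read_tsv(path: str | Path, required: Sequence[str], dtypes=None) -> pd.DataFrame:
    path = Path(path)
    try:
        frame = pd.read_csv(path, sep="\t", comment="#", dtype=dtypes)
    except pd.errors.EmptyDataError:
        raise FormatError(f"{path}: empty file") from None
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s) {missing}")
    return frame


# ---------------------------------------------------------------- mutations

def read_mutation_table(
    path: str | Path,
    gene_model: GeneModelTable,
    samples: Sequence[str] | None = None,
    strict: bool = True,
) -> CohortMutationTable:
    """Read a MAF-like somatic mutation TSV.

    The sample roster defaults to the distinct ``sample_id`` values unless
    an explicit roster is supplied. Unknown ``variant_class`` values are
    rejected with the offending line number (1-based, header = line 1,
    comment lines counted).
    """
    path = Path(path)
    frame = _read_tsv(path, MUTATION_COLUMNS, dtypes={"chrom": str})
    bad = ~frame["variant_class"].isin(_VALID_CLASSES)
    if bad.any():
        # recover the physical line number for the first offender
        first_bad_value = frame.loc[bad, "variant_class"].iloc[0]
        lineno = _locate_line(path, str(first_bad_value))
        raise ValidationError(
            f"{path}: unknown variant_class {first_bad_value!r} on line {lineno}"
        )
    if (frame["pos"] < 1).any():
        raise ValidationError(f"{path}: pos must be >= 1")
    if (frame["ref"] == frame["alt"]).any():
        raise ValidationError(f"{path}: ref == alt in at least one record")
    return CohortMutationTable(frame, gene_model, samples=samples, strict=strict)


def _locate_line(path: Path, needle: str) -> int:
    with open(path, encoding="utf-8") as fh:
        for i, line in enumerate(fh, start=1):
            if line.startswith("#"):
                continue
            if needle in line.split("\t"):
                return i
    return -1


def write_mutation_table(table: CohortMutationTable, path: str | Path) -> None:
    table.frame.to_csv(path, sep="\t", index=False)


# --------------------------------------------------------------- gene model

def read_gene_model(path: str | Path) -> GeneModelTable:
    frame = _read_tsv(
        path, GeneModelTable.REQUIRED, dtypes={"chrom": str, "arm": str}
    )
    return GeneModelTable(frame.reset_index(drop=True))


def write_gene_model(model: GeneModelTable, path: str | Path) -> None:
    model.frame.to_csv(path, sep="\t", index=False)


# --------------------------------------------------------------------- GMT

def read_gmt(path: str | Path) -> list[GeneSet]:
    """Read gene sets in the standard GMT dialect.

    ``name TAB description TAB member...``; the description is discarded;
    duplicate members within a line are collapsed with a logged warning.
    """
    sets: list[GeneSet] = []
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path}:{lineno}: GMT line needs name, description and "
                    f"at least one member ({len(fields)} field(s) found)"
                )
            name = fields[0]
            members: list[str] = []
            seen: set[str] = set()
            dups = 0
            for g in fields[2:]:
                if not g:
                    continue
                if g in seen:
                    dups += 1
                    continue
                seen.add(g)
                members.append(g)
            if dups:
                logger.warning(
                    "%s:%d: collapsed %d duplicate member(s) in set %s",
                    path,
                    lineno,
                    dups,
                    name,
                )
            sets.append(GeneSet(name=name, genes=tuple(members)))
    return sets


def write_gmt(sets: Iterable[GeneSet], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for s in sets:
            fh.write("\t".join([s.name, "na", *s.genes]) + "\n")


# --------------------------------------------------------------------- SEG

SEG_COLUMNS = ["sample_id", "chrom", "start", "end", "n_probes", "total_cn", "minor_cn"]


def read_seg(path: str | Path) -> list[AscnSegment]:
    """Read a SEG-like TSV extended with a minor-allele copy-number column.

    Per-sample segments are validated non-overlapping per chromosome.
    """
    frame = _read_tsv(path, SEG_COLUMNS, dtypes={"chrom": str})
    segments = [
        AscnSegment(
            sample_id=str(r.sample_id),
            chrom=str(r.chrom),
            start=int(r.start),
            end=int(r.end),
            n_probes=int(r.n_probes),
            total_cn=float(r.total_cn),
            minor_cn=float(r.minor_cn),
        )
        for r in frame.itertuples(index=False)
    ]
    validate_segments_nonoverlapping(segments)
    return segments


def validate_segments_nonoverlapping(segments: Sequence[AscnSegment]) -> None:
    by_key: dict[tuple[str, str], list[AscnSegment]] = {}
    for seg in segments:
        by_key.setdefault((seg.sample_id, seg.chrom), []).append(seg)
    for (sample, chrom), segs in by_key.items():
        segs = sorted(segs, key=lambda s: s.start)
        for a, b in zip(segs, segs[1:]):
            if b.start <= a.end:
                raise ValidationError(
                    f"overlapping segments for sample {sample} on chr{chrom}: "
                    f"[{a.start}-{a.end}] and [{b.start}-{b.end}]"
                )


def write_seg(segments: Iterable[AscnSegment], path: str | Path) -> None:
    rows = [
        (s.sample_id, s.chrom, s.start, s.end, s.n_probes, s.total_cn, s.minor_cn)
        for s in segments
    ]
    pd.DataFrame(rows, columns=SEG_COLUMNS).to_csv(path, sep="\t", index=False)


# ------------------------------------------------------------------ ploidy

def read_ploidy(path: str | Path) -> dict[str, SamplePloidy]:
    frame = _read_tsv(path, ["sample_id", "ploidy"])
    out: dict[str, SamplePloidy] = {}
    for r in frame.itertuples(index=False):
        sp = SamplePloidy(sample_id=str(r.sample_id), ploidy=float(r.ploidy))
        if sp.sample_id in out:
            raise ValidationError(f"duplicate ploidy entry for {sp.sample_id}")
        out[sp.sample_id] = sp
    return out


def write_ploidy(ploidies: Iterable[SamplePloidy], path: str | Path) -> None:
    rows = [(p.sample_id, p.ploidy) for p in ploidies]
    pd.DataFrame(rows, columns=["sample_id", "ploidy"]).to_csv(
        path, sep="\t", index=False
    )


# ------------------------------------------------------------------- arms

def read_arm_table(path: str | Path) -> pd.DataFrame:
    """Arm coordinate table: chrom, arm, start, end (1-based inclusive)."""
    frame = _read_tsv(path, ["chrom", "arm", "start", "end"], dtypes={"chrom": str})
    if (frame["start"] > frame["end"]).any():
        raise ValidationError(f"{path}: arm with start > end")
    frame["arm_name"] = frame["chrom"].astype(str) + frame["arm"].astype(str)
    return frame


def load_hg19_arms() -> pd.DataFrame:
    """Packaged hg19 chromosome-arm coordinates."""
    with resources.as_file(
        resources.files("oligoland").joinpath("data/hg19_arms.tsv")
    ) as p:
        return read_arm_table(p)


# ----------------------------------------------------------------- fusions

FUSION_COLUMNS = [
    "sample_id",
    "gene5",
    "gene3",
    "spanning_reads",
    "total_supporting_reads",
]


def read_fusions(path: str | Path) -> list[FusionCandidate]:
    frame = _read_tsv(path, FUSION_COLUMNS)
    return [
        FusionCandidate(
            sample_id=str(r.sample_id),
            gene5=str(r.gene5),
            gene3=str(r.gene3),
            spanning_reads=int(r.spanning_reads),
            total_supporting_reads=int(r.total_supporting_reads),
        )
        for r in frame.itertuples(index=False)
    ]


def write_fusions(candidates: Iterable[FusionCandidate], path: str | Path) -> None:
    rows = [
        (c.sample_id, c.gene5, c.gene3, c.spanning_reads, c.total_supporting_reads)
        for c in candidates
    ]
    pd.DataFrame(rows, columns=FUSION_COLUMNS).to_csv(path, sep="\t", index=False)


# -------------------------------------------------------------- expression

def read_expression(path: str | Path) -> ExpressionMatrix:
    """Gene x sample TSV of log2 intensities; first column = gene symbol."""
    frame = pd.read_csv(path, sep="\t", comment="#", index_col=0)
    if frame.empty and frame.columns.empty:
        raise FormatError(f"{path}: empty expression matrix")
    return ExpressionMatrix(frame)


def write_expression(expr: ExpressionMatrix, path: str | Path) -> None:
    expr.frame.rename_axis("gene").to_csv(path, sep="\t")


# -------------------------------------------------- promoter assay records

def read_promoter_variants(path: str | Path) -> dict[str, list[tuple[str, int, str, str]]]:
    """Per-sample promoter assay records: sample_id, chrom, pos, ref, alt.

    A sample listed with pos 0 (and empty alleles) denotes an assayed,
    variant-free sample; absent samples are unassayed.
    """
    frame = _read_tsv(
        path, ["sample_id", "chrom", "pos", "ref", "alt"], dtypes={"chrom": str}
    )
    out: dict[str, list[tuple[str, int, str, str]]] = {}
    for r in frame.itertuples(index=False):
        out.setdefault(str(r.sample_id), [])
        if int(r.pos) > 0:
            out[str(r.sample_id)].append(
                (str(r.chrom), int(r.pos), str(r.ref), str(r.alt))
            )
    return out
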