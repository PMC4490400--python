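"""Shared domain types for the oligodendroglioma cohort analyses.

Conventions used throughout the package:

* genomic coordinates are 1-based and inclusive on both ends (MAF/SEG
  convention); half-open arithmetic happens only inside interval helpers;
* gene identity is the bare symbol, case-sensitive, with no alias
  resolution;
* "non-silent" is the fixed class subset ``NON_SILENT``.
"""
from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


class OligolandError(Exception):
    """Base class for package errors."""


class FormatError(OligolandError):
    """A file does not conform to the expected dialect."""


class ValidationError(OligolandError):
    """Parsed content violates a domain invariant."""


class VariantClass(str, enum.Enum):
    MISSENSE = "missense"
    NONSENSE = "nonsense"
    SPLICE_SITE = "splice_site"
    FRAMESHIFT = "frameshift"
    INFRAME_INDEL = "inframe_indel"
    SILENT = "silent"
    NONCODING = "noncoding"


#: Variant classes counted as non-silent (protein-affecting).
NON_SILENT = frozenset(
    {
        VariantClass.MISSENSE,
        VariantClass.NONSENSE,
        VariantClass.SPLICE_SITE,
        VariantClass.FRAMESHIFT,
        VariantClass.INFRAME_INDEL,
    }
)


@dataclass(frozen=True)
class MutationRecord:
    """One somatic mutation in one tumour sample."""

    sample_id: str
    gene: str
    chrom: str
    pos: int
    ref: str
    alt: str
    variant_class: VariantClass
    protein_change: str | None = None

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValidationError(f"pos must be >= 1, got {self.pos}")
        if self.ref == self.alt:
            raise ValidationError(f"ref == alt ({self.ref}) for {self.gene}")
        if not isinstance(self.variant_class, VariantClass):
            object.__setattr__(
                self, "variant_class", VariantClass(self.variant_class)
            )

    @property
    def non_silent(self) -> bool:
        return self.variant_class in NON_SILENT


@dataclass(frozen=True)
class GeneModel:
    """A gene with its coding footprint L(g) and arm location."""

    gene: str
    coding_length_bp: int
    chrom: str
    arm: str  # "p" or "q"

    def __post_init__(self) -> None:
        if self.coding_length_bp <= 0:
            raise ValidationError(
                f"coding_length_bp must be positive for {self.gene}"
            )
        if self.arm not in ("p", "q"):
            raise ValidationError(f"arm must be 'p' or 'q', got {self.arm!r}")


class GeneModelTable:
    """The sequenced gene universe G with per-gene coding lengths.

    Backed by a DataFrame indexed by symbol with columns
    ``coding_length_bp``, ``chrom``, ``arm``.
    """

    REQUIRED = ("gene", "coding_length_bp", "chrom", "arm")

    def __init__(self, frame: pd.DataFrame):
        missing = [c for c in self.REQUIRED if c not in frame.columns]
        if missing:
            raise FormatError(f"gene model missing columns: {missing}")
        if frame["gene"].duplicated().any():
            dup = frame.loc[frame["gene"].duplicated(), "gene"].iloc[0]
            raise ValidationError(f"duplicate gene symbol in model: {dup}")
        if (frame["coding_length_bp"] <= 0).any():
            bad = frame.loc[frame["coding_length_bp"] <= 0, "gene"].iloc[0]
            raise ValidationError(f"non-positive coding length for {bad}")
        self._frame = frame.set_index("gene", drop=False)

    @classmethod
    def from_models(cls, models: Iterable[GeneModel]) -> "GeneModelTable":
        rows = [
            (m.gene, m.coding_length_bp, m.chrom, m.arm) for m in models
        ]
        return cls(pd.DataFrame(rows, columns=list(cls.REQUIRED)))

    @property
    def frame(self) -> pd.DataFrame:
        return self._frame

    @property
    def genes(self) -> pd.Index:
        return self._frame.index

    def __contains__(self, gene: str) -> bool:
        return gene in self._frame.index

    def __len__(self) -> int:
        return len(self._frame)

    def length_of(self, gene: str) -> int:
        return int(self._frame.at[gene, "coding_length_bp"])

    def lengths(self, genes: Iterable[str] | None = None) -> pd.Series:
        s = self._frame["coding_length_bp"]
        if genes is None:
            return s
        present = [g for g in genes if g in self._frame.index]
        return s.loc[present]

    @property
    def total_length_bp(self) -> int:
        """L(G): summed coding length of the whole universe."""
        return int(self._frame["coding_length_bp"].sum())


@dataclass(frozen=True)
class GeneSet:
    """A named gene set P (unique member symbols)."""

    name: str
    genes: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValidationError(f"gene set {self.name!r} is empty")
        if len(set(self.genes)) != len(self.genes):
            raise ValidationError(f"gene set {self.name!r} has duplicates")

    def __len__(self) -> int:
        return len(self.genes)

    def members_in(self, universe: Iterable[str]) -> list[str]:
        uni = set(universe)
        return [g for g in self.genes if g in uni]


MUTATION_COLUMNS = [
    "sample_id",
    "gene",
    "chrom",
    "pos",
    "ref",
    "alt",
    "variant_class",
    "protein_change",
]


class CohortMutationTable:
    """All somatic mutations of a cohort plus the sequenced universe.

    Holds the sample roster S (size n), the gene universe G and the
    mutation records; ``total_mutation_count`` is A(G, S), the count of
    records whose gene belongs to the universe.
    """

    def __init__(
        self,
        records: pd.DataFrame,
        universe: GeneModelTable,
        samples: Sequence[str] | None = None,
        strict: bool = True,
    ):
        missing = [c for c in MUTATION_COLUMNS if c not in records.columns]
        if missing:
            raise FormatError(f"mutation table missing columns: {missing}")
        records = records.copy()
        # normalise the optional column so frames compare equal regardless
        # of whether they came from memory (None) or disk (NaN)
        pc = records["protein_change"].astype(object)
        records["protein_change"] = pc.where(pd.notna(pc), None)
        records["chrom"] = records["chrom"].astype(str)
        bad = ~records["variant_class"].isin([v.value for v in VariantClass])
        if bad.any():
            i = int(np.flatnonzero(bad.to_numpy())[0])
            raise ValidationError(
                f"unknown variant_class {records['variant_class'].iloc[i]!r}"
            )
        outside = ~records["gene"].isin(universe.genes)
        if outside.any():
            n_out = int(outside.sum())
            if strict:
                g = records.loc[outside, "gene"].iloc[0]
                raise ValidationError(
                    f"{n_out} mutation(s) in genes absent from the gene "
                    f"model (first: {g!r}); pass strict=False to drop them"
                )
            logger.warning(
                "dropping %d mutation(s) in genes absent from the model", n_out
            )
            records = records.loc[~outside]
        if samples is None:
            samples = sorted(records["sample_id"].unique().tolist())
        else:
            samples = list(samples)
            if len(set(samples)) != len(samples):
                raise ValidationError("duplicate sample_id in roster")
            unknown = set(records["sample_id"]) - set(samples)
            if unknown:
                raise ValidationError(
                    f"records for samples outside the roster: {sorted(unknown)[:3]}"
                )
        self.samples: list[str] = samples
        self.universe = universe
        self._records = records.reset_index(drop=True)

    @classmethod
    def from_records(
        cls,
        records: Iterable[MutationRecord],
        universe: GeneModelTable,
        samples: Sequence[str] | None = None,
        strict: bool = True,
    ) -> "CohortMutationTable":
        rows = [
            (
                r.sample_id,
                r.gene,
                r.chrom,
                r.pos,
                r.ref,
                r.alt,
                r.variant_class.value,
                r.protein_change,
            )
            for r in records
        ]
        frame = pd.DataFrame(rows, columns=MUTATION_COLUMNS)
        if not rows:
            frame = frame.astype({"pos": int})
        return cls(frame, universe, samples=samples, strict=strict)

    @property
    def frame(self) -> pd.DataFrame:
        return self._records

    @property
    def records(self) -> list[MutationRecord]:
        return [
            MutationRecord(
                sample_id=row.sample_id,
                gene=row.gene,
                chrom=str(row.chrom),
                pos=int(row.pos),
                ref=row.ref,
                alt=row.alt,
                variant_class=VariantClass(row.variant_class),
                protein_change=(
                    None if pd.isna(row.protein_change) else row.protein_change
                ),
            )
            for row in self._records.itertuples(index=False)
        ]

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def __len__(self) -> int:
        return len(self._records)

    @property
    def total_mutation_count(self) -> int:
        """A(G, S): mutations in genes of the universe, all samples."""
        return int(self._records["gene"].isin(self.universe.genes).sum())

    def gene_counts(self) -> pd.Series:
        """Mutation count per universe gene, cohort-wide (0 for unmutated)."""
        if not hasattr(self, "_gene_counts"):
            counts = self._records["gene"].value_counts()
            self._gene_counts = counts.reindex(
                self.universe.genes, fill_value=0
            ).astype(int)
        return self._gene_counts

    def for_sample(self, sample_id: str) -> pd.DataFrame:
        return self._records[self._records["sample_id"] == sample_id]


@dataclass(frozen=True)
class AscnSegment:
    """An allele-specific copy-number segment (1-based inclusive)."""

    sample_id: str
    chrom: str
    start: int
    end: int
    n_probes: int
    total_cn: float
    minor_cn: float

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValidationError(
                f"segment start {self.start} > end {self.end}"
            )
        if self.n_probes < 0:
            raise ValidationError("n_probes must be non-negative")
        if self.total_cn < 0 or self.minor_cn < 0:
            raise ValidationError("copy numbers must be non-negative")
        if self.minor_cn > self.total_cn:
            raise ValidationError(
                f"minor_cn {self.minor_cn} > total_cn {self.total_cn}"
            )

    @property
    def length_bp(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class SamplePloidy:
    sample_id: str
    ploidy: float

    def __post_init__(self) -> None:
        if self.ploidy <= 0:
            raise ValidationError("ploidy must be positive")


@dataclass(frozen=True)
class FusionCandidate:
    """A chimeric-transcript candidate with its read support."""

    sample_id: str
    gene5: str
    gene3: str
    spanning_reads: int
    total_supporting_reads: int

    def __post_init__(self) -> None:
        if self.spanning_reads < 0 or self.total_supporting_reads < 0:
            raise ValidationError("read counts must be non-negative")
        if self.spanning_reads > self.total_supporting_reads:
            raise ValidationError(
                "spanning_reads exceeds total_supporting_reads"
            )


class ExpressionMatrix:
    """Gene x sample grid of log2 expression values."""

    def __init__(self, frame: pd.DataFrame):
        if frame.index.duplicated().any():
            raise ValidationError("duplicate gene symbols in expression matrix")
        if frame.columns.duplicated().any():
            raise ValidationError("duplicate sample ids in expression matrix")
        values = frame.to_numpy(dtype=float)
        if not np.all(np.isfinite(values)):
            raise ValidationError("expression values must be finite")
        self._frame = frame

    @property
    def frame(self) -> pd.DataFrame:
        return self._frame

    @property
    def genes(self) -> list[str]:
        return self._frame.index.tolist()

    @property
    def samples(self) -> list[str]:
        return self._frame.columns.tolist()

    @property
    def values(self) -> np.ndarray:
        return self._frame.to_numpy(dtype=float)


@dataclass
class SyntheticTruth:
    """Ground truth exported by the synthetic-cohort generators."""

    seed: int
    spiked_genes: dict[str, float] = field(default_factory=dict)
    spiked_sets: dict[str, float] = field(default_factory=dict)
    subtype_labels: dict[str, str] = field(default_factory=dict)
    arm_events: dict[str, list[str]] = field(default_factory=dict)
    arm_loss_freqs: dict[str, float] = field(default_factory=dict)
    shifted_sets: dict[str, float] = field(default_factory=dict)
    true_fusions: list[dict] = field(default_factory=list)
    extras: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "spiked_genes": self.spiked_genes,
            "spiked_sets": self.spiked_sets,
            "subtype_labels": self.subtype_labels,
            "arm_events": self.arm_events,
            "arm_loss_freqs": self.arm_loss_freqs,
            "shifted_sets": self.shifted_sets,
            "true_fusions": self.true_fusions,
            "extras": self.extras,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "SyntheticTruth":
        return cls(
            seed=d["seed"],
            spiked_genes=dict(d.get("spiked_genes", {})),
            spiked_sets=dict(d.get("spiked_sets", {})),
            subtype_labels=dict(d.get("subtype_labels", {})),
            arm_events={k: list(v) for k, v in d.get("arm_events", {}).items()},
            arm_loss_freqs=dict(d.get("arm_loss_freqs", {})),
            shifted_sets=dict(d.get("shifted_sets", {})),
            true_fusions=list(d.get("true_fusions", [])),
            extras=dict(d.get("extras", {})),
        )
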