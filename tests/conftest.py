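import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, deadline=None)
settings.load_profile("ci")

from oligoland.model import (
    AscnSegment,
    CohortMutationTable,
    GeneModelTable,
    GeneSet,
    MutationRecord,
    SamplePloidy,
    VariantClass,
)


@pytest.fixture
def small_model() -> GeneModelTable:
    frame = pd.DataFrame(
        {
            "gene": ["A1", "B2", "C3", "D4"],
            "coding_length_bp": [1000, 2000, 3000, 4000],
            "chrom": ["1", "1", "19", "19"],
            "arm": ["p", "q", "p", "q"],
        }
    )
    return GeneModelTable(frame)


@pytest.fixture
def small_cohort(small_model) -> CohortMutationTable:
    records = [
        MutationRecord("S1", "A1", "1", 10, "C", "T", VariantClass.MISSENSE),
        MutationRecord("S1", "B2", "1", 20, "G", "A", VariantClass.SILENT),
        MutationRecord("S2", "C3", "19", 30, "T", "G", VariantClass.NONSENSE),
        MutationRecord("S2", "A1", "1", 40, "A", "C", VariantClass.MISSENSE),
    ]
    return CohortMutationTable.from_records(
        records, small_model, samples=["S1", "S2", "S3"]
    )


@pytest.fixture
def arm_table():
    from oligoland.io import load_hg19_arms

    return load_hg19_arms()


def whole_arm_segment(
    sample: str,
    arm_table: pd.DataFrame,
    arm_name: str,
    total_cn: float,
    minor_cn: float,
    n_probes: int = 1000,
    fraction: float = 1.0,
) -> AscnSegment:
    row = arm_table.loc[arm_table["arm_name"] == arm_name].iloc[0]
    start, end = int(row["start"]), int(row["end"])
    end = start + int(fraction * (end - start + 1)) - 1
    return AscnSegment(
        sample_id=sample,
        chrom=str(row["chrom"]),
        start=start,
        end=end,
        n_probes=n_probes,
        total_cn=total_cn,
        minor_cn=minor_cn,
    )


@pytest.fixture
def diploid():
    def make(sample="S1"):
        return SamplePloidy(sample_id=sample, ploidy=2.0)

    return make


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)


def make_gene_set(name, genes):
    return GeneSet(name=name, genes=tuple(genes))
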