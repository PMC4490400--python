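"""Per-sample mutation burden, substitution spectrum and oncoprint layout."""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .model import CohortMutationTable, NON_SILENT, OligolandError, VariantClass

logger = logging.getLogger(__name__)

#: The six collapsed single-nucleotide substitution classes
#: (pyrimidine-reference convention).
SPECTRUM_CLASSES = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}


@dataclass(frozen=True)
class SampleBurden:
    sample_id: str
    n_total: int
    n_nonsilent: int
    rate_per_mb: float
    target_mb: float


@dataclass(frozen=True)
class SpectrumCounts:
    sample_id: str
    counts: dict[str, int]
    indel_count: int


def compute_burden(
    table: CohortMutationTable,
    target_mb: float | Mapping[str, float],
    non_silent_only: bool = False,
) -> list[SampleBurden]:
    """Mutation counts and rate per megabase for every cohort sample.

    The rate numerator counts all somatic mutations by default; set
    ``non_silent_only`` to restrict it to protein-affecting classes.
    """
    if not isinstance(target_mb, Mapping):
        if target_mb <= 0:
            raise OligolandError(f"target_mb must be positive, got {target_mb}")
        target_mb = {s: float(target_mb) for s in table.samples}
    frame = table.frame
    nonsilent_values = {v.value for v in NON_SILENT}
    out = []
    for sample in table.samples:
        mb = float(target_mb[sample])
        if mb <= 0:
            raise OligolandError(f"target_mb must be positive for {sample}")
        sub = frame[frame["sample_id"] == sample]
        n_total = len(sub)
        n_nonsilent = int(sub["variant_class"].isin(nonsilent_values).sum())
        numerator = n_nonsilent if non_silent_only else n_total
        out.append(
            SampleBurden(
                sample_id=sample,
                n_total=n_total,
                n_nonsilent=n_nonsilent,
                rate_per_mb=numerator / mb,
                target_mb=mb,
            )
        )
    rates = [b.rate_per_mb for b in out]
    if rates:
        logger.info(
            "cohort mutation rate per Mb: mean %.3f, median %.3f",
            float(np.mean(rates)),
            float(np.median(rates)),
        )
    return out


def flag_hypermutators(
    burdens: Sequence[SampleBurden], fold: float = 3.0
) -> list[str]:
    """Samples whose rate exceeds ``fold`` x the cohort median (flag only)."""
    if not burdens:
        return []
    median = float(np.median([b.rate_per_mb for b in burdens]))
    flagged = [b.sample_id for b in burdens if b.rate_per_mb > fold * median]
    for s in flagged:
        logger.warning("sample %s flagged as hypermutator (> %gx median)", s, fold)
    return flagged


def collapse_substitution(ref: str, alt: str) -> str | None:
    """Collapse a single-base substitution onto the six-class spectrum.

    Substitutions with a purine reference are reverse-complemented so the
    reference base is a pyrimidine. Non-ACGT or multi-base alleles return
    ``None`` (indel/other).
    """
    ref, alt = ref.upper(), alt.upper()
    if len(ref) != 1 or len(alt) != 1 or ref not in _COMPLEMENT or alt not in _COMPLEMENT:
        return None
    if ref == alt:
        raise OligolandError("ref and alt are identical")
    if ref in ("A", "G"):
        ref, alt = _COMPLEMENT[ref], _COMPLEMENT[alt]
    return f"{ref}>{alt}"


def spectrum_counts(table: CohortMutationTable) -> list[SpectrumCounts]:
    """Per-sample counts of the six collapsed classes plus indels/other."""
    out = []
    frame = table.frame
    for sample in table.samples:
        sub = frame[frame["sample_id"] == sample]
        counts = {c: 0 for c in SPECTRUM_CLASSES}
        indels = 0
        for ref, alt in zip(sub["ref"], sub["alt"]):
            cls = collapse_substitution(str(ref), str(alt))
            if cls is None:
                indels += 1
            else:
                counts[cls] += 1
        out.append(SpectrumCounts(sample_id=sample, counts=counts, indel_count=indels))
    return out


def cohort_spectrum_fractions(spectra: Sequence[SpectrumCounts]) -> pd.Series:
    """Cohort-wide proportion of each collapsed class among substitutions."""
    totals = pd.Series(
        {c: sum(s.counts[c] for s in spectra) for c in SPECTRUM_CLASSES}, dtype=float
    )
    n = totals.sum()
    return totals / n if n > 0 else totals


def gene_by_sample_matrix(
    table: CohortMutationTable,
    genes: Sequence[str],
    non_silent_only: bool = True,
) -> pd.DataFrame:
    """Binary gene x sample mutation matrix for the oncoprint."""
    frame = table.frame
    if non_silent_only:
        frame = frame[frame["variant_class"].isin({v.value for v in NON_SILENT})]
    mat = pd.DataFrame(0, index=list(genes), columns=table.samples, dtype=int)
    hit = frame[frame["gene"].isin(genes)]
    for g, s in zip(hit["gene"], hit["sample_id"]):
        mat.at[g, s] = 1
    return mat


def order_for_oncoprint(
    gene_by_sample: pd.DataFrame,
    gene_order: Sequence[str] | None = None,
) -> list[str]:
    """Memo-sort sample ordering that emphasises mutual exclusivity.

    Genes are ranked by descending mutation frequency (ties broken by
    symbol); samples are then sorted by descending binary word over the
    ranked genes, with a stable tie-break by ascending sample_id.
    """
    mat = (gene_by_sample != 0).astype(int)
    if gene_order is None:
        freq = mat.sum(axis=1)
        gene_order = sorted(mat.index, key=lambda g: (-freq[g], g))
    else:
        unknown = [g for g in gene_order if g not in mat.index]
        if unknown:
            raise OligolandError(f"gene_order contains unknown genes: {unknown}")
    ranked = mat.loc[list(gene_order)]
    return sorted(
        mat.columns,
        key=lambda s: (tuple(-ranked[s].to_numpy()), str(s)),
    )


def plot_landscape(
    gene_by_sample: pd.DataFrame,
    burdens: Sequence[SampleBurden] | None = None,
    path: str | None = None,
):
    """Optional oncoprint-style figure (requires matplotlib)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    order = order_for_oncoprint(gene_by_sample)
    mat = (gene_by_sample[order] != 0).astype(int)
    nrows = 2 if burdens else 1
    fig, axes = plt.subplots(
        nrows, 1, figsize=(max(6, 0.18 * mat.shape[1]), 1 + 0.4 * mat.shape[0] + (2 if burdens else 0)),
        sharex=False,
        gridspec_kw={"height_ratios": [1, 2] if burdens else [1]},
    )
    ax_onco = axes[-1] if burdens else axes
    if burdens:
        by_id = {b.sample_id: b.rate_per_mb for b in burdens}
        axes[0].bar(range(len(order)), [by_id.get(s, 0.0) for s in order], color="grey")
        axes[0].set_ylabel("mut/Mb")
        axes[0].set_xticks([])
    ax_onco.imshow(mat.to_numpy(), aspect="auto", cmap="Greys", interpolation="none")
    ax_onco.set_yticks(range(mat.shape[0]))
    ax_onco.set_yticklabels(mat.index)
    ax_onco.set_xticks([])
    ax_onco.set_xlabel(f"{mat.shape[1]} samples (memo-sorted)")
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
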