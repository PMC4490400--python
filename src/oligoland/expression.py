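"""Expression contrast between mutant and wild-type sample groups.

Differential expression uses a per-gene two-sample t-test on log2 values
(Welch by default, pooled-variance optional) with the joint significance
rule p < 0.05 AND |logFC| > 0.6, logFC being mean(mutant) - mean(wild-type).
Gene-set over-representation of the significant list uses the exact
hypergeometric upper tail. Gene-set activity is the per-sample mean over
member genes, with samples ranked descending.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .model import ExpressionMatrix, GeneSet, OligolandError

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ContrastConfig:
    p_threshold: float = 0.05
    abs_logfc_threshold: float = 0.6
    test: str = "welch"  # or "pooled"

    def __post_init__(self) -> None:
        if self.p_threshold <= 0 or self.abs_logfc_threshold <= 0:
            raise ValueError("contrast thresholds must be positive")
        if self.test not in ("welch", "pooled"):
            raise ValueError(f"unknown test {self.test!r}")


@dataclass(frozen=True)
class EnrichmentResult:
    set_name: str
    n_universe: int
    n_de: int
    n_set_in_universe: int
    n_overlap: int
    p_value: float


def differential_genes(
    expr: ExpressionMatrix,
    group_a: Sequence[str],
    group_b: Sequence[str],
    cfg: ContrastConfig | None = None,
) -> tuple[pd.DataFrame, list[str]]:
    """Per-gene contrast of group_a (mutant) vs group_b (wild-type).

    Returns the per-gene table (logfc, t, p, p_bh, significant) and the
    significant gene list. Zero-variance genes are excluded from the
    tested universe with a logged count.
    """
    cfg = cfg or ContrastConfig()
    group_a, group_b = list(group_a), list(group_b)
    if set(group_a) & set(group_b):
        raise OligolandError("groups overlap")
    if len(group_a) < 2 or len(group_b) < 2:
        raise OligolandError("each group needs at least 2 samples")
    missing = (set(group_a) | set(group_b)) - set(expr.samples)
    if missing:
        raise OligolandError(f"samples absent from matrix: {sorted(missing)[:3]}")
    frame = expr.frame
    a = frame[group_a].to_numpy(dtype=float)
    b = frame[group_b].to_numpy(dtype=float)
    var_ok = ~((a.var(axis=1) == 0) & (b.var(axis=1) == 0))
    n_dropped = int((~var_ok).sum())
    if n_dropped:
        logger.info("excluding %d zero-variance gene(s) from the DE universe", n_dropped)
    a, b = a[var_ok], b[var_ok]
    genes = frame.index[var_ok]
    logfc = a.mean(axis=1) - b.mean(axis=1)
    t, p = stats.ttest_ind(a, b, axis=1, equal_var=(cfg.test == "pooled"))
    p_bh = multipletests(p, method="fdr_bh")[1]
    significant = (p < cfg.p_threshold) & (np.abs(logfc) > cfg.abs_logfc_threshold)
    table = pd.DataFrame(
        {
            "gene": genes,
            "mean_a": a.mean(axis=1),
            "mean_b": b.mean(axis=1),
            "logfc": logfc,
            "t": t,
            "p": p,
            "p_bh": p_bh,
            "significant": significant,
        }
    ).set_index("gene", drop=False)
    return table, genes[significant].tolist()


def hypergeom_enrichment(
    de_genes: Sequence[str],
    sets: Sequence[GeneSet],
    universe: Sequence[str],
) -> list[EnrichmentResult]:
    """Exact over-representation of each set in the DE list.

    p = P(overlap >= observed) when n_de genes are drawn from the
    universe without replacement; results sorted ascending by p.
    """
    uni = list(dict.fromkeys(universe))
    if not uni:
        raise OligolandError("empty universe")
    uni_set = set(uni)
    outside = set(de_genes) - uni_set
    if outside:
        raise OligolandError(
            f"de_genes must be a subset of the universe; outside: {sorted(outside)[:3]}"
        )
    de = list(dict.fromkeys(de_genes))
    N, n_de = len(uni), len(de)
    de_set = set(de)
    out = []
    for s in sets:
        members = [g for g in s.genes if g in uni_set]
        K = len(members)
        overlap = len(de_set.intersection(members))
        if K == 0 or n_de == 0:
            p = 1.0
        else:
            p = float(stats.hypergeom.sf(overlap - 1, N, K, n_de))
        out.append(
            EnrichmentResult(
                set_name=s.name,
                n_universe=N,
                n_de=n_de,
                n_set_in_universe=K,
                n_overlap=overlap,
                p_value=min(p, 1.0),
            )
        )
    return sorted(out, key=lambda r: (r.p_value, r.set_name))


def gene_set_activity(
    expr: ExpressionMatrix, gene_set: GeneSet
) -> tuple[pd.Series, list[str]]:
    """Per-sample mean expression over the set's members present.

    Returns the activity series (matrix sample order) and the sample
    ranking, descending by activity with a stable tie-break by sample_id.
    """
    members = [g for g in gene_set.genes if g in expr.frame.index]
    if not members:
        raise OligolandError(
            f"no members of set {gene_set.name!r} present in the matrix"
        )
    activity = expr.frame.loc[members].mean(axis=0)
    ranking = sorted(activity.index, key=lambda s: (-activity[s], str(s)))
    return activity, ranking


def enrichment_to_frame(results: Sequence[EnrichmentResult]) -> pd.DataFrame:
    rows = [
        (r.set_name, r.n_universe, r.n_de, r.n_set_in_universe, r.n_overlap, r.p_value)
        for r in results
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "set_name",
            "n_universe",
            "n_de",
            "n_set_in_universe",
            "n_overlap",
            "p_value",
        ],
    )
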