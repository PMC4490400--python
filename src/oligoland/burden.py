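"""Binomial gene-set mutation-burden test.

Given the sequenced gene universe G, the tumour cohort S of size n and a
gene set P, the test asks whether P carries at least its observed number
of mutations under a uniform per-base mutation model:

    m_obs ~ Binomial(k, p),  k = n * L(P),  p = A(G, S) / (n * L(G))

where L(X) is the summed coding length (bp) of the genes of X present in
the universe, and A(G, S) is the total number of mutations observed in
universe genes across all samples. The reported p-value is the exact
upper-tail probability P(X >= m_obs), evaluated as the binomial survival
function at m_obs - 1 in log space — no normal approximation.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .model import CohortMutationTable, GeneSet, OligolandError

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class BurdenTestResult:
    set_name: str
    n_members: int
    n_members_in_universe: int
    L_P: int
    k: int
    p: float
    m_obs: int
    p_value: float
    log_p_value: float
    q_value: float | None = None

    @property
    def expected(self) -> float:
        return self.k * self.p


def _deep_tail_logsf(m: int, k: int, p: float) -> float:
    # log-space PMF summation anchored at the leading term; the term
    # ratio pmf(j)/pmf(j-1) = (k-j+1)/j * p/(1-p) is < 1 throughout the
    # deep upper tail, so the series converges geometrically
    from scipy.special import gammaln

    lead = (
        gammaln(k + 1)
        - gammaln(m + 1)
        - gammaln(k - m + 1)
        + m * np.log(p)
        + (k - m) * np.log1p(-p)
    )
    odds = p / (1.0 - p)
    total = term = 1.0
    for j in range(m + 1, k + 1):
        term *= (k - j + 1) / j * odds
        total += term
        if term < 1e-18 * total:
            break
    return float(lead + np.log(total))


def binomial_tail_logsf(m_obs: int, k: int, p: float) -> float:
    """log P(X >= m_obs) for X ~ Binomial(k, p), exact upper tail.

    Uses the regularized-beta survival function where it is representable
    in double precision and an anchored log-space PMF summation in the
    deep tail, so the result stays finite and accurate for tails far
    below the double-precision underflow threshold.
    """
    if m_obs <= 0:
        return 0.0
    if m_obs > k:
        return -np.inf
    if p <= 0.0:
        return -np.inf
    if p >= 1.0:
        return 0.0
    log_sf = float(stats.binom.logsf(m_obs - 1, k, p))
    if log_sf > -600.0:  # comfortably above double underflow
        return log_sf
    return _deep_tail_logsf(m_obs, k, p)


def burden_test(
    table: CohortMutationTable,
    gene_set: GeneSet,
    set_name: str | None = None,
) -> BurdenTestResult:
    """Exact binomial upper-tail burden test for one gene set."""
    universe = table.universe
    members_in = gene_set.members_in(universe.genes)
    excluded = len(gene_set) - len(members_in)
    if excluded:
        logger.info(
            "set %s: %d member(s) absent from the sequenced universe excluded",
            gene_set.name,
            excluded,
        )
    if not members_in:
        raise OligolandError(
            f"gene set {gene_set.name!r} has no members in the universe"
        )
    counts = table.gene_counts()
    L_P = int(universe.lengths(members_in).sum())
    L_G = universe.total_length_bp
    n = table.n_samples
    A = table.total_mutation_count
    k = n * L_P
    m_obs = int(counts.loc[members_in].sum())
    if A == 0:
        logger.warning("A(G,S) = 0: degenerate burden test, p_value = 1")
        p_rate, log_p = 0.0, 0.0
    else:
        p_rate = A / (n * L_G)
        log_p = binomial_tail_logsf(m_obs, k, p_rate)
    return BurdenTestResult(
        set_name=set_name or gene_set.name,
        n_members=len(gene_set),
        n_members_in_universe=len(members_in),
        L_P=L_P,
        k=k,
        p=p_rate,
        m_obs=m_obs,
        p_value=float(np.exp(log_p)),
        log_p_value=log_p,
    )


def burden_scan(
    table: CohortMutationTable, sets: Sequence[GeneSet]
) -> list[BurdenTestResult]:
    """Test every set; sort ascending by p; attach BH q-values.

    Sets with no members in the universe are skipped with a warning; an
    error is raised only if nothing remains. Overlapping sets are tested
    marginally, with no joint correction for overlap.
    """
    if not sets:
        raise OligolandError("no gene sets supplied")
    results = []
    for s in sets:
        try:
            results.append(burden_test(table, s))
        except OligolandError:
            logger.warning("skipping set %s: empty intersection with universe", s.name)
    if not results:
        raise OligolandError("every gene set was empty after intersection")
    pvals = np.array([r.p_value for r in results])
    qvals = multipletests(pvals, method="fdr_bh")[1]
    results = [
        BurdenTestResult(**{**r.__dict__, "q_value": float(q)})
        for r, q in zip(results, qvals)
    ]
    return sorted(results, key=lambda r: (r.p_value, r.set_name))


def per_set_gene_tally(
    table: CohortMutationTable, gene_set: GeneSet, top: int | None = None
):
    """Per-member mutation tallies within a set (most mutated first)."""
    counts = table.gene_counts()
    members = gene_set.members_in(table.universe.genes)
    tally = counts.loc[members].sort_values(ascending=False)
    return tally.head(top) if top else tally


def results_to_frame(results: Sequence[BurdenTestResult]):
    import pandas as pd

    rows = [
        (
            r.set_name,
            r.n_members,
            r.n_members_in_universe,
            r.L_P,
            r.k,
            r.p,
            r.m_obs,
            r.expected,
            r.p_value,
            r.q_value,
        )
        for r in results
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "set_name",
            "n_members",
            "n_members_in_universe",
            "L_P",
            "k",
            "p",
            "m_obs",
            "expected",
            "p_value",
            "q_value",
        ],
    )
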