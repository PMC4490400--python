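# Methods

This note documents the statistical models the package implements, the
conventions and tunable parameters behind them, what the synthetic-data
generators do and do not emulate, and the numerical choices that a
maintainer would otherwise have to reverse-engineer from the code.

## Gene-set mutation-burden test

Given the sequenced gene universe G with per-gene coding lengths L(g),
the cohort S of n tumours and a gene set P, the test models the number
of mutations falling in P (all samples pooled) as

    m ~ Binomial(k, p),   k = n · L(P),   p = A(G, S) / (n · L(G)),

where L(X) is the summed coding length of the genes of X that are
present in the universe and A(G, S) is the total number of mutations
observed in universe genes across all samples. The reported p-value is
the exact upper tail P(X ≥ m_obs).

Conventions and caveats:

* **Counting.** m_obs and A(G, S) count *all* mutation records (silent
  included); the numerator and denominator therefore use the same event
  definition. Callers who want a non-silent test can pre-filter the
  table; the class subset regarded as non-silent is fixed to
  {missense, nonsense, splice site, frameshift, in-frame indel}.
* **Universe restriction.** Set members absent from the gene model are
  excluded from L(P) (and logged); the test is undefined for sets with
  no member in the universe.
* **Tail evaluation.** P(X ≥ m) is the binomial survival function at
  m − 1. Where the survival function is representable in double
  precision it is taken from the regularized incomplete beta; in the
  deep tail (log p below −600) the implementation switches to a
  log-space PMF summation anchored at the leading term, whose term
  ratio (k−j+1)/j · p/(1−p) is < 1 throughout the upper tail, so the
  series converges geometrically. This keeps log p finite and accurate
  (|Δlog p| < 1e−9 against direct log-sum-exp summation) for tails far
  below the ~1e−308 underflow threshold and for k up to 1e8.
* **Multiplicity.** Scans report raw binomial p-values, the quantity the
  method is defined by, plus Benjamini–Hochberg q-values as a clearly
  separate column. Overlapping sets are tested marginally; no joint
  correction for overlap is attempted.
* **Calibration.** Because the null is the test's own sampling model,
  the per-base-uniform synthetic cohorts make calibration checks
  meaningful: on a 51-sample, ~50 Mb, 1.6e−6/bp null cohort the
  fraction of random 50-gene sets with p < 0.05 is ≈ 0.035–0.045 —
  slightly conservative, as expected from the discreteness of small
  counts and from estimating p from the same data.

## Molecular subtyping

A tumour is IDH-mutant iff it carries IDH1 R132* or IDH2 R172*
(protein_change prefix match); any other IDH1/IDH2 variant — including
the occasionally co-occurring IDH2 P162S — does not qualify, and IDH
records without a protein annotation are logged and ignored. 1p/19q
co-deletion requires loss-classified segments to cover at least 90% of
*both* arms (threshold `arm_fraction_threshold`, default 0.9). The
subtype partition is (IDH, codel) → IDHmut-codel / IDHmut-noncodel /
IDHwt, with IDH status taking precedence: a hypothetical IDH-wild-type
codel sample is labelled IDHwt.

The 0.9 arm-coverage threshold is our choice: co-deletion is a
whole-arm event, but segmentation jitter at the centromere and telomere
makes an exact-1.0 requirement brittle. A sample with no usable segment
coverage of either arm is reported non-codel with a warning rather than
given a third status, so downstream 2×2 contrasts stay well-defined.

TERT promoter status is matched on the hg19 coordinates
chr5:1,295,228 (C228T) and chr5:1,295,250 (C250T). The hotspots are
described as G>A on the sequenced strand; a variant at a hotspot
position with other alleles is warned about and not called. An empty
assay record list means assayed-and-wild-type; an absent record means
unknown.

## Mutation landscape

Rates per Mb divide each sample's *total* mutation count by the
targeted footprint in Mb (a 51-sample cohort reporting 4,733 mutations
over ~50 Mb yields ~1.6/Mb only on the all-mutations definition, which
is why total is the default; a flag switches to non-silent). Samples
above 3× the cohort median rate are flagged as hypermutators in the
log but never excluded automatically.

The substitution spectrum collapses the 12 ordered single-base changes
onto 6 classes by reverse-complementing purine-reference changes, so
each class aggregates a mutation and its complement (G>A and C>T, etc.).
Indels and non-ACGT alleles are tallied separately.

Oncoprint sample ordering is memo-sort: genes ranked by descending
mutation frequency (ties by symbol), samples sorted by the descending
binary word over the ranked genes. Ties between samples break by
ascending sample id — this makes the ordering invariant to the input
column order (the stronger property), at the cost that an all-zero
matrix comes back id-sorted rather than input-ordered.

## Copy-number aberrations and LOH

Segments are classified against the sample ploidy with the rules
gain CN ≥ ploidy+1, loss CN ≤ ploidy−1, high-level amplification
CN > ploidy+2, homozygous deletion CN = 0, comparing real-valued copy
numbers with no rounding. The printed rules overlap, so a precedence is
imposed: homozygous deletion > high amplification > gain/loss >
neutral. LOH (minor CN = 0) is flagged independently of the category,
which is what makes copy-neutral LOH representable. Focal events are
homozygous deletions and high amplifications with ≥ 5 consecutive
probes; no manual curation step is reproduced — the probe filter is the
only gate. Arm-level recurrence uses segment-length-weighted coverage
with 1-based inclusive lengths (end − start + 1) and the same 0.9
coverage threshold as subtyping; a chromosome counts as lost when both
arms are.

## Fusion filtering

A candidate is retained iff spanning reads > 2 (strict), total
supporting reads ≥ 10 (inclusive) and the gene pair is not blacklisted.
The rejection reason is the first failing rule in that order. Blacklist
matching defaults to unordered pairs (the conservative reading, since a
normal-tissue artefact is evidence against either orientation);
`ordered_blacklist=True` switches to 5'/3'-respecting matching.
Filtering is per candidate row, so it is idempotent and oblivious to
how candidates are grouped into samples.

## Expression contrast

Differential expression between mutant and wild-type groups uses a
per-gene two-sample t-test on log2 values — Welch by default, pooled
variance optionally. A moderated (empirical-Bayes) t-test is a
reasonable alternative for very small groups; we deliberately use the
plain t-test and define all recovery guarantees against it. logFC is
mean(mutant) − mean(wild-type), so downregulation in mutants is
negative. The significance rule is the joint p < 0.05 AND
|logFC| > 0.6; p-values are reported raw, with BH-adjusted values in a
separate column. Genes with zero variance in both groups are dropped
from the tested universe with a logged count.

Gene-set over-representation uses the exact hypergeometric upper tail
P(overlap ≥ observed) with the DE universe = all tested genes. Gene-set
activity is the per-sample mean over member genes present in the
matrix; rankings are descending with ties broken by sample id.

## Cohort statistics

Frequency confidence intervals are Clopper–Pearson exact: the bounds
invert the binomial tails via beta quantiles, with the degenerate
bounds exactly 0 (no carriers) and 1 (all carriers). This is the method
that reproduces published exact intervals such as 10/134 →
3.64–13.30%; note that at one decimal on the percent scale the upper
bound 13.296 truncates to 13.2 but rounds to 13.3. Exactness implies
conservative coverage (≥ the nominal level at every true frequency).

The 2×2 comparison reports the closed-form chi-square
N(ad−bc)²/((a+b)(c+d)(a+c)(b+d)) — Yates-corrected on request by
shrinking |ad−bc| by N/2 — and the two-sided Fisher exact p under the
point-probability convention (sum of table probabilities ≤ the observed
table's). Conventions differ across software for two-sided Fisher
p-values; this one is the common default. With a zero margin the
chi-square is undefined (reported as NaN) and the Fisher p is still
computed. For the cohort comparison 10/134 vs 1/75 the uncorrected
chi-square gives p = 0.057, Yates p = 0.116 and Fisher p = 0.102;
published figures for such comparisons depend on the variant used.

## Synthetic cohorts

The generators produce data with the statistical structure the analyses
assume, plus a `SyntheticTruth` record sufficient to score every
recovery test. Defaults mirror the motivating cohort: 51 samples, an
18,901-gene universe with log-normal coding lengths summing to ~50 Mb,
and a background rate of 1.6e−6 mutations per coding bp per sample
(~80 mutations/exome ≈ 1.6/Mb). Mutation counts per gene and sample are
Binomial(L(g), rate·multiplier(g)) — every coding base mutates
independently — because that is exactly the burden test's null:
calibration tests are meaningful, and spiked multipliers break the null
for recovery tests. The substitution mix is C>T-dominant (45%, with the
remainder spread over the other five classes) as in most adult solid
tumours; the non-silent fraction defaults to 0.40, the ratio implied by
a cohort with ~93 total calls and 37 non-silent calls per sample.
Copy-number cohorts emit whole-arm losses (total = ploidy−1,
minor = 0) drawn independently per sample at stated frequencies — the
bundle uses chromosome 4 jointly at 0.29, 9p at 0.28 and 14q at 0.19 —
on a neutral background, with optional planted focal homozygous
deletions. Expression matrices are Gaussian (baseline N(7, 1) per gene,
noise sd 0.5 per value) with additive log2 shifts of named sets in the
mutant group. Fusion tables are built class-by-class: true candidates
pass both thresholds (one pinned to the retained boundary spanning 3 /
total 10), and each decoy class violates exactly one rule (one pinned
to spanning = 2).

What the generators do *not* emulate: trinucleotide-context mutational
signatures, per-sample rate heterogeneity and covariate-dependent
mutability (gene expression, replication timing), subclonal copy-number
states and normal-cell contamination, heavy-tailed microarray noise,
and read-level artefacts. Passing recovery tests therefore demonstrate
that the statistics behave as specified under their own modelling
assumptions — not that those assumptions hold in real tumours, where
uniform-rate burden tests in particular are known to be anti-
conservative for long, late-replicating genes.

All randomness flows from one explicit seed per generator call (an
integer or a shared `numpy` Generator); identical parameters and seed
give byte-identical output files.

## Numerical and scale choices

* Coordinates are 1-based inclusive everywhere (MAF/SEG convention);
  interval arithmetic converts internally and never in files.
* Gene identity is the case-sensitive symbol; no alias resolution.
  Mutations in genes absent from the model are rejected by default
  (strict mode) to protect the burden-test denominator; a lenient flag
  drops them with a logged count.
* The deep-tail series switch for the binomial survival function sits
  at log p = −600; term summation stops when a term falls below 1e−18
  of the running total.
* Verification scales used by the test suite and the acceptance script:
  burden exactness on 500–1,000 random triples with k ≤ 1e4; null
  calibration on one 51-sample ~50 Mb cohort with 10,000 random
  50-gene sets; spike recovery over 200 replicate 20-sample cohorts on
  a 5,000-gene (~12.5 Mb) universe with 100 disjoint candidate sets;
  expression recovery over 100 replicates of 2,000 genes at 20 vs 20
  samples; interval coverage over 5,000 draws at p = 0.075, n = 134.
  These sizes keep each check's Monte-Carlo error an order of magnitude
  below the margin it must resolve while the whole suite runs in about
  a minute.

## Known limitations

* The burden test ignores per-gene mutability covariates by design; it
  is the uniform-rate statistic, not a MutSigCV-style driver caller.
* Subtyping has no unknown category: samples lacking copy-number data
  are reported non-codel (with a warning), which can under-call
  IDHmut-codel in sparse cohorts.
* The expression contrast is a plain t-test; for n < ~5 per group a
  moderated test has better power and its gene lists will differ.
* Arm recurrence assumes the provided arm table matches the genome
  build of the segments; only hg19 arm coordinates ship with the
  package.
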