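"""Synthetic cohorts with exported ground truth.

The generators emulate the statistical structure of a 51-sample
anaplastic-oligodendroglioma cohort: length-proportional background
mutation near 1.6 mutations/Mb with spiked driver genes, subtype-consistent
IDH / TERT / 1p-19q structure, whole-arm allele-specific copy-number
events at known frequencies, Gaussian log2 expression with gene-set shifts
in mutant samples, and fusion candidate tables built class-by-class around
the filter thresholds. Every generator is a pure function of its
parameters and an explicit seed.
"""
from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import io as olio
from .model import (
    AscnSegment,
    CohortMutationTable,
    ExpressionMatrix,
    FusionCandidate,
    GeneModelTable,
    GeneSet,
    MUTATION_COLUMNS,
    OligolandError,
    SamplePloidy,
    SyntheticTruth,
)

# Cohort-scale defaults: 51 tumours, an ~50 Mb coding universe of 18,901
# genes and a background rate of 1.6e-6 mutations per coding bp per sample
# (~1.6/Mb, ~80 mutations per exome).
DEFAULT_N_SAMPLES = 51
DEFAULT_N_GENES = 18_901
DEFAULT_TOTAL_MB = 50.0
DEFAULT_BASE_RATE = 1.6e-6

# Collapsed-substitution mix with the C>T dominance typical of adult
# solid tumours.
SPECTRUM_WEIGHTS = {
    "C>A": 0.10,
    "C>G": 0.08,
    "C>T": 0.45,
    "T>A": 0.09,
    "T>C": 0.20,
    "T>G": 0.08,
}

# Share of mutations that are protein-affecting (0.40: a 51-sample exome
# cohort reporting ~4,733 total calls alongside a mean of 37 non-silent
# per sample implies non-silent/total ~ 37/92.8).
DEFAULT_NONSILENT_FRACTION = 0.40

_NONSILENT_SPLIT = {
    "missense": 0.75,
    "nonsense": 0.08,
    "splice_site": 0.07,
    "frameshift": 0.07,
    "inframe_indel": 0.03,
}
_SILENT_SPLIT = {"silent": 0.55, "noncoding": 0.45}

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def sample_ids(n: int, prefix: str = "AO") -> list[str]:
    width = max(2, len(str(n)))
    return [f"{prefix}_{i:0{width}d}" for i in range(1, n + 1)]


# ------------------------------------------------------------ gene universe

def synthetic_gene_model(
    n_genes: int = DEFAULT_N_GENES,
    total_mb: float = DEFAULT_TOTAL_MB,
    seed=0,
    arm_table: pd.DataFrame | None = None,
    named_genes: Mapping[str, tuple[str, str, int]] | None = None,
) -> GeneModelTable:
    """A gene universe with log-normal coding lengths summing to ~total_mb.

    ``named_genes`` maps symbol -> (chrom, arm, coding_length_bp) and is
    appended verbatim (counted inside ``n_genes``); the remaining genes are
    placed on arms with probability proportional to arm length.
    """
    rng = _rng(seed)
    if arm_table is None:
        arm_table = olio.load_hg19_arms()
    named = dict(named_genes or {})
    n_anon = n_genes - len(named)
    if n_anon < 0:
        raise OligolandError("more named genes than n_genes")
    lengths = rng.lognormal(mean=7.6, sigma=0.6, size=n_anon)
    named_total = sum(v[2] for v in named.values())
    lengths = lengths * ((total_mb * 1e6 - named_total) / lengths.sum())
    lengths = np.maximum(lengths.astype(int), 150)
    arm_len = (arm_table["end"] - arm_table["start"] + 1).to_numpy(dtype=float)
    arm_idx = rng.choice(len(arm_table), size=n_anon, p=arm_len / arm_len.sum())
    width = len(str(n_genes))
    rows = [
        (
            f"G{i + 1:0{width}d}",
            int(lengths[i]),
            str(arm_table["chrom"].iloc[arm_idx[i]]),
            str(arm_table["arm"].iloc[arm_idx[i]]),
        )
        for i in range(n_anon)
    ]
    rows += [
        (gene, int(length), str(chrom), str(arm))
        for gene, (chrom, arm, length) in named.items()
    ]
    return GeneModelTable(
        pd.DataFrame(rows, columns=["gene", "coding_length_bp", "chrom", "arm"])
    )


def random_gene_sets(
    genes: Sequence[str],
    n_sets: int,
    set_size: int,
    seed=0,
    prefix: str = "SET",
    disjoint: bool = False,
) -> list[GeneSet]:
    """Random gene sets drawn without replacement within each set.

    With ``disjoint=True`` the sets are also mutually disjoint (requires
    n_sets * set_size <= len(genes)).
    """
    rng = _rng(seed)
    genes = list(genes)
    width = len(str(n_sets))
    out = []
    if disjoint:
        if n_sets * set_size > len(genes):
            raise OligolandError("not enough genes for disjoint sets")
        perm = rng.permutation(len(genes))
        for i in range(n_sets):
            idx = perm[i * set_size : (i + 1) * set_size]
            out.append(
                GeneSet(f"{prefix}{i + 1:0{width}d}", tuple(genes[j] for j in idx))
            )
    else:
        for i in range(n_sets):
            idx = rng.choice(len(genes), size=set_size, replace=False)
            out.append(
                GeneSet(f"{prefix}{i + 1:0{width}d}", tuple(genes[j] for j in idx))
            )
    return out


# ---------------------------------------------------------------- mutations

def _draw_alleles(rng: np.random.Generator, n: int) -> tuple[np.ndarray, np.ndarray]:
    classes = list(SPECTRUM_WEIGHTS)
    probs = np.array([SPECTRUM_WEIGHTS[c] for c in classes])
    picks = rng.choice(len(classes), size=n, p=probs)
    flip = rng.random(n) < 0.5  # emit on the purine strand half the time
    refs = np.empty(n, dtype="<U1")
    alts = np.empty(n, dtype="<U1")
    for i, (ci, fl) in enumerate(zip(picks, flip)):
        ref, alt = classes[ci].split(">")
        if fl:
            ref, alt = _COMPLEMENT[ref], _COMPLEMENT[alt]
        refs[i], alts[i] = ref, alt
    return refs, alts


def _draw_classes(rng: np.random.Generator, n: int, nonsilent_fraction: float) -> np.ndarray:
    labels = list(_NONSILENT_SPLIT) + list(_SILENT_SPLIT)
    probs = np.array(
        [nonsilent_fraction * v for v in _NONSILENT_SPLIT.values()]
        + [(1 - nonsilent_fraction) * v for v in _SILENT_SPLIT.values()]
    )
    probs = probs / probs.sum()
    return np.array(labels, dtype=object)[rng.choice(len(labels), size=n, p=probs)]


def generate_mutation_cohort(
    n_samples: int = DEFAULT_N_SAMPLES,
    model: GeneModelTable | None = None,
    base_rate: float = DEFAULT_BASE_RATE,
    spikes: Mapping[str, float] | None = None,
    seed=0,
    nonsilent_fraction: float = DEFAULT_NONSILENT_FRACTION,
    samples: Sequence[str] | None = None,
) -> tuple[CohortMutationTable, SyntheticTruth]:
    """Length-proportional background mutations with optional gene spikes.

    Each coding base of gene g mutates independently in each sample with
    probability base_rate * multiplier(g) — exactly the null of the
    burden test unless spikes break it.
    """
    if base_rate <= 0:
        raise OligolandError("base_rate must be positive")
    rng = _rng(seed)
    if model is None:
        model = synthetic_gene_model(seed=rng)
    if len(model) == 0:
        raise OligolandError("empty gene model")
    spikes = dict(spikes or {})
    unknown = [g for g in spikes if g not in model]
    if unknown:
        raise OligolandError(f"spiked genes absent from model: {unknown}")
    roster = list(samples) if samples is not None else sample_ids(n_samples)
    genes = model.genes.to_numpy()
    L = model.frame["coding_length_bp"].to_numpy()
    mult = np.ones(len(genes))
    for g, m in spikes.items():
        mult[model.genes.get_loc(g)] = m
    rate = np.clip(base_rate * mult, 0.0, 1.0)
    counts = rng.binomial(L[:, None], rate[:, None], size=(len(genes), len(roster)))
    gene_idx, samp_idx = np.nonzero(counts)
    reps = counts[gene_idx, samp_idx]
    gene_idx = np.repeat(gene_idx, reps)
    samp_idx = np.repeat(samp_idx, reps)
    n_mut = len(gene_idx)
    refs, alts = _draw_alleles(rng, n_mut)
    classes = _draw_classes(rng, n_mut, nonsilent_fraction)
    pos = 1 + (rng.random(n_mut) * L[gene_idx]).astype(int)
    chroms = model.frame["chrom"].to_numpy()[gene_idx]
    refs = refs.astype(object)
    alts = alts.astype(object)
    bases = np.array(["A", "C", "G", "T"], dtype=object)
    indel = np.isin(classes, ["frameshift", "inframe_indel"])
    if indel.any():  # give indels multi-base alt alleles
        extra = bases[rng.integers(0, 4, size=int(indel.sum()))]
        alts[indel] = np.char.add(
            refs[indel].astype(str), extra.astype(str)
        ).astype(object)
    frame = pd.DataFrame(
        {
            "sample_id": np.array(roster, dtype=object)[samp_idx],
            "gene": genes[gene_idx],
            "chrom": chroms,
            "pos": pos,
            "ref": refs,
            "alt": alts,
            "variant_class": classes,
            "protein_change": np.full(n_mut, None, dtype=object),
        },
        columns=MUTATION_COLUMNS,
    )
    frame = frame.sort_values(["sample_id", "chrom", "pos", "gene"], kind="stable")
    table = CohortMutationTable(frame, model, samples=roster)
    truth = SyntheticTruth(
        seed=int(seed) if not isinstance(seed, np.random.Generator) else -1,
        spiked_genes={g: float(m) for g, m in spikes.items()},
    )
    return table, truth


# --------------------------------------------------------------------- ASCN

def generate_ascn_cohort(
    n_samples: int,
    arm_table: pd.DataFrame,
    arm_loss_freqs: Mapping[str | tuple[str, ...], float] | None = None,
    ploidy: float = 2.0,
    probe_density: float = 30.0,
    seed=0,
    samples: Sequence[str] | None = None,
    forced_losses: Mapping[str, Sequence[str]] | None = None,
    focal_homdels: Sequence[tuple[str, str, int, int, int]] | None = None,
) -> tuple[list[AscnSegment], list[SamplePloidy], SyntheticTruth]:
    """Whole-arm loss events at stated frequencies, on a neutral background.

    ``arm_loss_freqs`` keys are arm names ("9p") or tuples of arms lost
    jointly (("4p", "4q")). Lost arms are emitted as single whole-arm
    segments at total = ploidy - 1 and minor = 0; other arms are neutral
    with minor = floor(ploidy / 2). ``forced_losses`` pins given samples'
    lost arms (on top of random draws); ``focal_homdels`` plants
    (sample, chrom, start, end, n_probes) homozygous deletions, splitting
    the harbouring arm segment so segments stay non-overlapping.
    """
    rng = _rng(seed)
    roster = list(samples) if samples is not None else sample_ids(n_samples)
    known = set(arm_table["arm_name"])
    freqs: dict[tuple[str, ...], float] = {}
    for key, f in (arm_loss_freqs or {}).items():
        arms = (key,) if isinstance(key, str) else tuple(key)
        for a in arms:
            if a not in known:
                raise OligolandError(f"unknown arm in arm_loss_freqs: {a!r}")
        if not 0 <= f <= 1:
            raise OligolandError(f"frequency for {key!r} outside [0, 1]")
        freqs[arms] = float(f)
    lost_by_sample: dict[str, set[str]] = {s: set() for s in roster}
    for arms, f in freqs.items():
        hit = rng.random(len(roster)) < f
        for s, h in zip(roster, hit):
            if h:
                lost_by_sample[s].update(arms)
    for s, arms in (forced_losses or {}).items():
        lost_by_sample.setdefault(s, set()).update(arms)
    homdels_by_sample: dict[str, list[tuple[str, int, int, int]]] = {}
    for sample, chrom, start, end, n_probes in focal_homdels or []:
        homdels_by_sample.setdefault(sample, []).append(
            (str(chrom), int(start), int(end), int(n_probes))
        )
    neutral_minor = float(np.floor(ploidy / 2))
    segments: list[AscnSegment] = []
    for s in roster:
        for _, row in arm_table.iterrows():
            chrom = str(row["chrom"])
            a_start, a_end = int(row["start"]), int(row["end"])
            lost = row["arm_name"] in lost_by_sample[s]
            total = ploidy - 1 if lost else ploidy
            minor = 0.0 if lost else min(neutral_minor, total)
            pieces = [(a_start, a_end)]
            for h_chrom, h_start, h_end, h_probes in homdels_by_sample.get(s, []):
                if h_chrom != chrom or h_start < a_start or h_end > a_end:
                    continue
                new_pieces = []
                for p_start, p_end in pieces:
                    if h_start > p_end or h_end < p_start:
                        new_pieces.append((p_start, p_end))
                        continue
                    if p_start < h_start:
                        new_pieces.append((p_start, h_start - 1))
                    if h_end < p_end:
                        new_pieces.append((h_end + 1, p_end))
                pieces = new_pieces
                segments.append(
                    AscnSegment(
                        sample_id=s,
                        chrom=chrom,
                        start=h_start,
                        end=h_end,
                        n_probes=h_probes,
                        total_cn=0.0,
                        minor_cn=0.0,
                    )
                )
            for p_start, p_end in pieces:
                n_probes = max(1, round((p_end - p_start + 1) / 1e6 * probe_density))
                segments.append(
                    AscnSegment(
                        sample_id=s,
                        chrom=chrom,
                        start=p_start,
                        end=p_end,
                        n_probes=n_probes,
                        total_cn=float(total),
                        minor_cn=float(minor),
                    )
                )
    ploidies = [SamplePloidy(sample_id=s, ploidy=float(ploidy)) for s in roster]
    truth = SyntheticTruth(
        seed=int(seed) if not isinstance(seed, np.random.Generator) else -1,
        arm_events={s: sorted(v) for s, v in lost_by_sample.items()},
        arm_loss_freqs={"+".join(k): v for k, v in freqs.items()},
        extras={
            "focal_homdels": [list(x) for x in (focal_homdels or [])],
            "ploidy": ploidy,
        },
    )
    return segments, ploidies, truth


# --------------------------------------------------------------- expression

def generate_expression(
    n_genes: int,
    groups: Mapping[str, Sequence[str]],
    sets: Sequence[GeneSet] | None = None,
    shifted_sets: Mapping[str, float] | None = None,
    noise_sd: float = 0.5,
    seed=0,
    shifted_group: str | None = None,
    baseline_mean: float = 7.0,
    baseline_sd: float = 1.0,
) -> tuple[ExpressionMatrix, SyntheticTruth]:
    """Gaussian log2 matrix with gene-set shifts in one group.

    Baseline per gene ~ N(baseline_mean, baseline_sd); each value adds
    N(0, noise_sd). Members of every set named in ``shifted_sets`` get the
    stated log2 shift added in the ``shifted_group`` samples (default: the
    first group).
    """
    if noise_sd <= 0:
        raise OligolandError("noise_sd must be positive")
    rng = _rng(seed)
    gene_names = [f"EG{i + 1:05d}" for i in range(n_genes)]
    gene_pos = {g: i for i, g in enumerate(gene_names)}
    all_samples: list[str] = []
    for members in groups.values():
        all_samples.extend(members)
    if len(set(all_samples)) != len(all_samples):
        raise OligolandError("groups overlap")
    shifted_sets = dict(shifted_sets or {})
    sets_by_name = {s.name: s for s in (sets or [])}
    for name in shifted_sets:
        if name not in sets_by_name:
            raise OligolandError(f"shifted set {name!r} not among supplied sets")
        absent = [g for g in sets_by_name[name].genes if g not in gene_pos]
        if absent:
            raise OligolandError(
                f"shifted set {name!r} references absent genes: {absent[:3]}"
            )
    if shifted_group is None:
        shifted_group = next(iter(groups))
    baseline = rng.normal(baseline_mean, baseline_sd, size=n_genes)
    values = baseline[:, None] + rng.normal(
        0.0, noise_sd, size=(n_genes, len(all_samples))
    )
    col = {s: j for j, s in enumerate(all_samples)}
    shift_cols = [col[s] for s in groups[shifted_group]]
    for name, shift in shifted_sets.items():
        rows = [gene_pos[g] for g in sets_by_name[name].genes]
        values[np.ix_(rows, shift_cols)] += shift
    frame = pd.DataFrame(values, index=gene_names, columns=all_samples)
    truth = SyntheticTruth(
        seed=int(seed) if not isinstance(seed, np.random.Generator) else -1,
        shifted_sets={k: float(v) for k, v in shifted_sets.items()},
        extras={"shifted_group": shifted_group, "groups": {k: list(v) for k, v in groups.items()}},
    )
    return ExpressionMatrix(frame), truth


# ------------------------------------------------------------------ fusions

def generate_fusion_table(
    n_true: int,
    n_decoys_below_spanning: int,
    n_decoys_below_total: int,
    n_blacklisted: int,
    seed=0,
) -> tuple[list[FusionCandidate], set[tuple[str, str]], SyntheticTruth]:
    """Candidates built class-by-class around the filter thresholds.

    True candidates satisfy both read thresholds and avoid the blacklist
    (the first one sits exactly on the retained boundary: spanning 3,
    total 10); each decoy class violates exactly its designated rule (the
    first spanning decoy sits on the rejected boundary spanning = 2).
    """
    rng = _rng(seed)
    blacklist = {(f"NRM{i + 1}A", f"NRM{i + 1}B") for i in range(max(n_blacklisted, 2))}
    candidates: list[FusionCandidate] = []
    truth_rows: list[dict] = []
    counter = 0

    def add(gene5, gene3, spanning, total, label):
        nonlocal counter
        counter += 1
        c = FusionCandidate(
            sample_id=f"AO_{(counter - 1) % 8 + 1:02d}",
            gene5=gene5,
            gene3=gene3,
            spanning_reads=int(spanning),
            total_supporting_reads=int(total),
        )
        candidates.append(c)
        truth_rows.append(
            {
                "gene5": gene5,
                "gene3": gene3,
                "spanning_reads": int(spanning),
                "total_supporting_reads": int(total),
                "label": label,
                "is_true": label == "true",
            }
        )

    for i in range(n_true):
        if i == 0:
            spanning, total = 3, 10  # retained boundary
        else:
            spanning = int(rng.integers(3, 16))
            total = int(max(10, spanning + rng.integers(7, 30)))
        g5, g3 = (("FGFR3", "TACC3") if i == 0 else (f"TRU{i}A", f"TRU{i}B"))
        add(g5, g3, spanning, total, "true")
    for i in range(n_decoys_below_spanning):
        spanning = 2 if i == 0 else int(rng.integers(0, 3))  # rejected boundary
        total = int(rng.integers(10, 40))
        add(f"DSP{i}A", f"DSP{i}B", spanning, total, "below_spanning")
    for i in range(n_decoys_below_total):
        spanning = int(rng.integers(3, 9))
        total = int(rng.integers(spanning, 10))
        add(f"DTO{i}A", f"DTO{i}B", spanning, total, "below_total")
    for i, pair in zip(range(n_blacklisted), sorted(blacklist)):
        spanning = int(rng.integers(3, 12))
        total = int(max(10, spanning + rng.integers(7, 20)))
        add(pair[0], pair[1], spanning, total, "blacklisted")
    truth = SyntheticTruth(
        seed=int(seed) if not isinstance(seed, np.random.Generator) else -1,
        true_fusions=truth_rows,
    )
    return candidates, blacklist, truth


# ------------------------------------------------------------ cohort bundle

#: Driver genes appended to the synthetic universe: symbol -> (chrom, arm,
#: coding length bp), arms matching their genomic locations.
NAMED_DRIVERS = {
    "IDH1": ("2", "q", 1245),
    "IDH2": ("15", "q", 1359),
    "CIC": ("19", "q", 4833),
    "FUBP1": ("1", "p", 1935),
    "TCF12": ("15", "q", 2121),
    "NOTCH1": ("9", "q", 7668),
    "ATRX": ("X", "q", 7479),
}

TCF12_CHANGES = ["E548fs*13", "S682fs*14", "R602M", "c.825+5G>T", "M260fs*5"]


def generate_cohort_bundle(
    outdir: str | Path,
    seed: int = 0,
    n_samples: int = DEFAULT_N_SAMPLES,
    n_genes: int = DEFAULT_N_GENES,
    total_mb: float = DEFAULT_TOTAL_MB,
    base_rate: float = DEFAULT_BASE_RATE,
    n_gene_sets: int = 50,
    gene_set_size: int = 50,
    spike_multiplier: float = 5.0,
    n_expression_genes: int = 2000,
    expression_noise_sd: float = 0.5,
    expression_shift: float = -1.0,
) -> tuple[dict[str, Path], SyntheticTruth]:
    """Write a full synthetic cohort directory and its ground truth.

    Emulated structure: most samples IDH-mutant and 1p/19q co-deleted
    (with TERT promoter hotspots in ~72% of them), a few IDH-mutant
    non-co-deleted and IDH-wild-type tumours; chromosome-4, 9p and 14q
    losses at 0.29 / 0.28 / 0.19; five TCF12-mutant tumours driving a
    down-shifted expression set; one spiked mutation gene set; fusion
    decoys around the filter boundaries.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    arm_table = olio.load_hg19_arms()
    roster = sample_ids(n_samples)

    # --- subtype labels: ~90% codel, ~6% IDH-mut non-codel, rest IDH-wt
    n_codel = max(1, round(0.90 * n_samples))
    n_noncodel = max(1, round(0.06 * n_samples))
    labels = (
        ["IDHmut_codel"] * n_codel
        + ["IDHmut_noncodel"] * n_noncodel
        + ["IDHwt"] * (n_samples - n_codel - n_noncodel)
    )
    perm = rng.permutation(n_samples)
    subtype_labels = {roster[i]: labels[perm[i]] for i in range(n_samples)}
    idh_samples = [s for s in roster if subtype_labels[s] != "IDHwt"]
    codel_samples = [s for s in roster if subtype_labels[s] == "IDHmut_codel"]

    # --- gene universe and mutations
    model = synthetic_gene_model(
        n_genes=n_genes, total_mb=total_mb, seed=rng, arm_table=arm_table,
        named_genes=NAMED_DRIVERS,
    )
    anon_genes = [g for g in model.genes if g not in NAMED_DRIVERS]
    # cap the disjoint-set plan to what the universe can hold (relevant
    # only for deliberately small cohorts)
    n_sets_eff = min(n_gene_sets, len(anon_genes) // gene_set_size)
    if n_sets_eff < 2:
        raise OligolandError("universe too small for the gene-set plan")
    sets = random_gene_sets(
        anon_genes, n_sets_eff, gene_set_size, seed=rng, disjoint=True
    )
    spiked_set = sets[0]
    spikes = {g: spike_multiplier for g in spiked_set.genes}
    table, _ = generate_mutation_cohort(
        n_samples=n_samples,
        model=model,
        base_rate=base_rate,
        spikes=spikes,
        seed=rng,
        samples=roster,
    )
    frame = table.frame

    # driver injection consistent with the subtype labels
    extra_rows = []
    for s in idh_samples:
        use_idh2 = rng.random() < 0.18
        gene, change = ("IDH2", "R172K") if use_idh2 else ("IDH1", "R132H")
        extra_rows.append(
            (s, gene, NAMED_DRIVERS[gene][0], 1, "G", "A", "missense", change)
        )
    tcf12_carriers = sorted(
        rng.choice(codel_samples, size=min(5, len(codel_samples)), replace=False)
    )
    for i, s in enumerate(tcf12_carriers):
        change = TCF12_CHANGES[i % len(TCF12_CHANGES)]
        cls = "frameshift" if "fs" in change else (
            "splice_site" if change.startswith("c.") else "missense"
        )
        ref, alt = ("C", "CA") if cls == "frameshift" else ("G", "T")
        extra_rows.append((s, "TCF12", "15", 2, ref, alt, cls, change))
    for gene, freq in (("CIC", 0.32), ("FUBP1", 0.22)):
        for s in codel_samples:
            if rng.random() < freq:
                extra_rows.append(
                    (s, gene, NAMED_DRIVERS[gene][0], 3, "C", "T", "nonsense", None)
                )
    frame = pd.concat(
        [frame, pd.DataFrame(extra_rows, columns=MUTATION_COLUMNS)],
        ignore_index=True,
    ).sort_values(["sample_id", "chrom", "pos", "gene"], kind="stable")
    table = CohortMutationTable(frame, model, samples=roster)

    # --- TERT promoter assay (72% of co-deleted samples carry a hotspot)
    tert_rows = []
    tert_status = {}
    for s in roster:
        tert_rows.append((s, "5", 0, "", ""))  # assayed marker row
        hit = subtype_labels[s] == "IDHmut_codel" and rng.random() < 0.72
        if hit:
            pos = 1_295_228 if rng.random() < 0.75 else 1_295_250
            tert_rows.append((s, "5", pos, "G", "A"))
            tert_status[s] = "C228T" if pos == 1_295_228 else "C250T"
        else:
            tert_status[s] = "wildtype"

    # --- copy number: forced 1p/19q codel plus recurrent arm losses
    segments, ploidies, ascn_truth = generate_ascn_cohort(
        n_samples=n_samples,
        arm_table=arm_table,
        arm_loss_freqs={("4p", "4q"): 0.29, "9p": 0.28, "14q": 0.19},
        ploidy=2.0,
        seed=rng,
        samples=roster,
        forced_losses={s: ["1p", "19q"] for s in codel_samples},
    )

    # --- expression with a down-shifted set in TCF12-mutant samples
    expr_sets = random_gene_sets(
        [f"EG{i + 1:05d}" for i in range(n_expression_genes)],
        10,
        40,
        seed=rng,
        prefix="XSET",
        disjoint=True,
    )
    wt_samples = [s for s in roster if s not in set(tcf12_carriers)]
    expr, _ = generate_expression(
        n_expression_genes,
        groups={"mutant": list(tcf12_carriers), "wildtype": wt_samples},
        sets=expr_sets,
        shifted_sets={expr_sets[0].name: expression_shift},
        noise_sd=expression_noise_sd,
        seed=rng,
        shifted_group="mutant",
    )

    # --- fusions
    candidates, blacklist, fusion_truth = generate_fusion_table(3, 4, 3, 2, seed=rng)

    # --- write everything
    from . import fusions as fus

    paths = {
        "gene_model": outdir / "gene_model.tsv",
        "mutations": outdir / "mutations.tsv",
        "gene_sets": outdir / "gene_sets.gmt",
        "segments": outdir / "segments.seg",
        "ploidy": outdir / "ploidy.tsv",
        "tert_promoter": outdir / "tert_promoter.tsv",
        "expression": outdir / "expression.tsv",
        "expression_sets": outdir / "expression_sets.gmt",
        "fusions": outdir / "fusions.tsv",
        "blacklist": outdir / "fusion_blacklist.tsv",
        "arms": outdir / "arms.tsv",
        "truth": outdir / "truth.json",
    }
    olio.write_gene_model(model, paths["gene_model"])
    olio.write_mutation_table(table, paths["mutations"])
    olio.write_gmt(sets, paths["gene_sets"])
    olio.write_seg(segments, paths["segments"])
    olio.write_ploidy(ploidies, paths["ploidy"])
    pd.DataFrame(
        tert_rows, columns=["sample_id", "chrom", "pos", "ref", "alt"]
    ).to_csv(paths["tert_promoter"], sep="\t", index=False)
    olio.write_expression(expr, paths["expression"])
    olio.write_gmt(expr_sets, paths["expression_sets"])
    olio.write_fusions(candidates, paths["fusions"])
    fus.write_blacklist(blacklist, paths["blacklist"])
    arm_table.drop(columns=["arm_name"]).to_csv(paths["arms"], sep="\t", index=False)

    truth = SyntheticTruth(
        seed=seed,
        spiked_genes=spikes,
        spiked_sets={spiked_set.name: spike_multiplier},
        subtype_labels=subtype_labels,
        arm_events=ascn_truth.arm_events,
        arm_loss_freqs=ascn_truth.arm_loss_freqs,
        shifted_sets={expr_sets[0].name: expression_shift},
        true_fusions=fusion_truth.true_fusions,
        extras={
            "tcf12_carriers": list(tcf12_carriers),
            "tert_status": tert_status,
            "base_rate": base_rate,
            "total_mb": total_mb,
        },
    )
    with open(paths["truth"], "w", encoding="utf-8") as fh:
        json.dump(truth.to_dict(), fh, indent=1, sort_keys=True)
    return paths, truth
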