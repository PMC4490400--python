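"""End-to-end orchestration of the cohort analyses from one config.

Stages run in order — subtyping, mutation landscape, gene-set burden scan,
copy-number calls, fusion filtering, expression contrast, cohort
statistics — and any stage whose inputs are absent is skipped with a log
line (the source study's own sub-analyses cover different sample subsets).
The manifest lists every written file with a SHA-256 checksum; identical
config and inputs give identical checksums.
"""
from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import burden, cna, expression, fusions, io as olio, landscape, stats, subtypes
from .model import GeneSet, OligolandError

logger = logging.getLogger(__name__)


class ConfigError(OligolandError):
    """The run configuration is invalid."""


class StageError(OligolandError):
    """A pipeline stage failed."""


_INPUT_KEYS = (
    "mutations",
    "gene_model",
    "gene_sets",
    "segments",
    "ploidy",
    "tert_promoter",
    "expression",
    "expression_sets",
    "fusions",
    "blacklist",
    "arms",
)


@dataclass
class RunConfig:
    outdir: Path
    inputs: dict[str, Path] = field(default_factory=dict)
    seed: int = 0
    target_mb: float = 50.0
    arm_fraction_threshold: float = cna.ARM_FRACTION_THRESHOLD
    focal_min_probes: int = cna.FOCAL_MIN_PROBES
    min_spanning_exclusive: int = 2
    min_total_inclusive: int = 10
    ordered_blacklist: bool = False
    p_threshold: float = 0.05
    abs_logfc_threshold: float = 0.6
    contrast_gene: str = "TCF12"
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        if "outdir" not in raw:
            raise ConfigError("config must set 'outdir'")
        inputs = {
            k: (path.parent / v).resolve() if not Path(v).is_absolute() else Path(v)
            for k, v in (raw.get("inputs") or {}).items()
        }
        unknown = set(inputs) - set(_INPUT_KEYS)
        if unknown:
            raise ConfigError(f"unknown input keys: {sorted(unknown)}")
        kwargs = {
            k: raw[k]
            for k in (
                "seed",
                "target_mb",
                "arm_fraction_threshold",
                "focal_min_probes",
                "min_spanning_exclusive",
                "min_total_inclusive",
                "ordered_blacklist",
                "p_threshold",
                "abs_logfc_threshold",
                "contrast_gene",
                "log_level",
            )
            if k in raw
        }
        cfg = cls(outdir=Path(raw["outdir"]), inputs=inputs, **kwargs)
        cfg.validate()
        return cfg

    def validate(self) -> None:
        for key, p in self.inputs.items():
            if not Path(p).exists():
                raise ConfigError(f"input {key!r} does not exist: {p}")
        if self.target_mb <= 0:
            raise ConfigError("target_mb must be positive")
        if not 0 < self.arm_fraction_threshold <= 1:
            raise ConfigError("arm_fraction_threshold must be in (0, 1]")
        if self.p_threshold <= 0 or self.abs_logfc_threshold <= 0:
            raise ConfigError("contrast thresholds must be positive")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(cfg: RunConfig) -> dict:
    """Run every stage whose inputs are present; return the manifest."""
    cfg.validate()
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    skipped: list[str] = []
    ins = cfg.inputs

    def have(*keys: str) -> bool:
        return all(k in ins for k in keys)

    arm_table = (
        olio.read_arm_table(ins["arms"]) if "arms" in ins else olio.load_hg19_arms()
    )

    table = None
    if have("mutations", "gene_model"):
        model = olio.read_gene_model(ins["gene_model"])
        table = olio.read_mutation_table(ins["mutations"], model)

    segments = olio.read_seg(ins["segments"]) if "segments" in ins else None
    ploidies = olio.read_ploidy(ins["ploidy"]) if "ploidy" in ins else None

    # ---- subtype stage
    if table is not None:
        muts_by_sample: dict = {s: [] for s in table.samples}
        for r in table.records:
            if r.gene in ("IDH1", "IDH2"):
                muts_by_sample[r.sample_id].append(r)
        segs_by_sample: dict = {s: [] for s in table.samples}
        if segments and ploidies:
            for seg in segments:
                segs_by_sample.setdefault(seg.sample_id, []).append(seg)
        promoter = (
            olio.read_promoter_variants(ins["tert_promoter"])
            if "tert_promoter" in ins
            else None
        )
        calls = subtypes.call_cohort_subtypes(
            muts_by_sample,
            segs_by_sample,
            ploidies or {},
            arm_table,
            promoter_by_sample=promoter,
            arm_fraction_threshold=cfg.arm_fraction_threshold,
        )
        p = outdir / "subtypes.tsv"
        subtypes.subtype_calls_to_frame(calls).to_csv(p, sep="\t", index=False)
        written.append(p)
    else:
        skipped.append("subtypes")

    # ---- landscape stage
    if table is not None:
        burdens = landscape.compute_burden(table, cfg.target_mb)
        landscape.flag_hypermutators(burdens)
        p = outdir / "sample_burden.tsv"
        pd.DataFrame(
            [
                (b.sample_id, b.n_total, b.n_nonsilent, b.rate_per_mb, b.target_mb)
                for b in burdens
            ],
            columns=["sample_id", "n_total", "n_nonsilent", "rate_per_mb", "target_mb"],
        ).to_csv(p, sep="\t", index=False)
        written.append(p)
        spectra = landscape.spectrum_counts(table)
        p = outdir / "spectrum.tsv"
        pd.DataFrame(
            [
                (s.sample_id, *[s.counts[c] for c in landscape.SPECTRUM_CLASSES], s.indel_count)
                for s in spectra
            ],
            columns=["sample_id", *landscape.SPECTRUM_CLASSES, "indel_other"],
        ).to_csv(p, sep="\t", index=False)
        written.append(p)
        freq = table.frame["gene"].value_counts()
        top_genes = freq.head(15).index.tolist()
        mat = landscape.gene_by_sample_matrix(table, top_genes)
        order = landscape.order_for_oncoprint(mat)
        p = outdir / "sample_order.tsv"
        pd.DataFrame({"sample_id": order}).to_csv(p, sep="\t", index=False)
        written.append(p)
    else:
        skipped.append("landscape")

    # ---- burden scan
    if table is not None and "gene_sets" in ins:
        sets = olio.read_gmt(ins["gene_sets"])
        results = burden.burden_scan(table, sets)
        p = outdir / "burden_scan.tsv"
        burden.results_to_frame(results).to_csv(p, sep="\t", index=False)
        written.append(p)
    else:
        skipped.append("burden_scan")

    # ---- copy-number stage
    if segments and ploidies:
        calls = cna.classify_cohort(segments, ploidies)
        p = outdir / "cn_calls.tsv"
        cna.calls_to_frame(calls).to_csv(p, sep="\t", index=False)
        written.append(p)
        focal = cna.list_focal_events(calls, min_probes=cfg.focal_min_probes)
        p = outdir / "focal_events.tsv"
        cna.calls_to_frame(focal).to_csv(p, sep="\t", index=False)
        written.append(p)
        by_sample: dict = {}
        for c in calls:
            by_sample.setdefault(c.segment.sample_id, []).append(c)
        rec = cna.arm_recurrence(
            by_sample, arm_table, arm_fraction_threshold=cfg.arm_fraction_threshold
        )
        p = outdir / "arm_recurrence.tsv"
        pd.DataFrame(
            [
                (r.arm, r.n_lost, r.n_gained, r.fraction_lost, r.fraction_gained)
                for r in rec
            ],
            columns=["arm", "n_lost", "n_gained", "fraction_lost", "fraction_gained"],
        ).to_csv(p, sep="\t", index=False)
        written.append(p)
    else:
        skipped.append("cn_aberrations")

    # ---- fusion stage
    if "fusions" in ins:
        blacklist = (
            fusions.load_blacklist(ins["blacklist"]) if "blacklist" in ins else set()
        )
        fcfg = fusions.FusionFilterConfig(
            min_spanning_exclusive=cfg.min_spanning_exclusive,
            min_total_inclusive=cfg.min_total_inclusive,
            blacklist=blacklist,
            ordered_blacklist=cfg.ordered_blacklist,
        )
        cands = olio.read_fusions(ins["fusions"])
        retained, reasons = fusions.filter_fusions(cands, fcfg)
        p = outdir / "fusions_retained.tsv"
        olio.write_fusions(retained, p)
        written.append(p)
        p = outdir / "fusion_reasons.tsv"
        reasons.to_csv(p, sep="\t", index=False)
        written.append(p)
    else:
        skipped.append("fusion_filter")

    # ---- expression contrast
    tcf12_carriers: list[str] = []
    if table is not None:
        tcf12_carriers = sorted(
            table.frame.loc[
                table.frame["gene"] == cfg.contrast_gene, "sample_id"
            ].unique()
        )
    if "expression" in ins and table is not None and len(tcf12_carriers) >= 2:
        expr = olio.read_expression(ins["expression"])
        group_a = [s for s in tcf12_carriers if s in expr.samples]
        group_b = [s for s in expr.samples if s not in set(group_a)]
        if len(group_a) >= 2 and len(group_b) >= 2:
            ccfg = expression.ContrastConfig(
                p_threshold=cfg.p_threshold,
                abs_logfc_threshold=cfg.abs_logfc_threshold,
            )
            de_table, de_genes = expression.differential_genes(
                expr, group_a, group_b, ccfg
            )
            p = outdir / "differential_expression.tsv"
            de_table.to_csv(p, sep="\t", index=False)
            written.append(p)
            if "expression_sets" in ins:
                esets = olio.read_gmt(ins["expression_sets"])
                enr = expression.hypergeom_enrichment(
                    de_genes, esets, de_table["gene"].tolist()
                )
                p = outdir / "enrichment.tsv"
                expression.enrichment_to_frame(enr).to_csv(p, sep="\t", index=False)
                written.append(p)
                activity_rows = []
                for s in esets:
                    try:
                        activity, ranking = expression.gene_set_activity(expr, s)
                    except OligolandError:
                        continue
                    for rank, sample in enumerate(ranking, start=1):
                        activity_rows.append((s.name, sample, activity[sample], rank))
                p = outdir / "gene_set_activity.tsv"
                pd.DataFrame(
                    activity_rows, columns=["set_name", "sample_id", "activity", "rank"]
                ).to_csv(p, sep="\t", index=False)
                written.append(p)
        else:
            skipped.append("expression_contrast")
    else:
        skipped.append("expression_contrast")

    # ---- cohort statistics
    if table is not None:
        est = stats.frequency_with_ci(len(tcf12_carriers), table.n_samples)
        p = outdir / "cohort_stats.json"
        with open(p, "w", encoding="utf-8") as fh:
            json.dump(
                {
                    "contrast_gene": cfg.contrast_gene,
                    "n_carriers": est.n_carriers,
                    "n_total": est.n_total,
                    "frequency_pct": 100 * est.point,
                    "ci_low_pct": 100 * est.ci_low,
                    "ci_high_pct": 100 * est.ci_high,
                    "level": est.level,
                },
                fh,
                indent=1,
                sort_keys=True,
            )
        written.append(p)
    else:
        skipped.append("cohort_stats")

    manifest = {
        "outputs": {str(p.name): _sha256(p) for p in written},
        "skipped_stages": skipped,
        "seed": cfg.seed,
    }
    with open(outdir / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    for s in skipped:
        logger.info("stage skipped (inputs absent): %s", s)
    return manifest
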