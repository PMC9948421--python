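"""End-to-end orchestration: triage -> germline classification ->
somatic tiering -> cohort summary -> survival, as one reproducible run.

Every threshold of the cascade, the consensus rule, the dichotomization
cut-points, and the collinearity threshold appear in the YAML run config
with their defaults, so each analysis decision is visible and
overridable.  Reruns with identical inputs and seed are byte-identical.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd
import yaml

from . import __version__
from .acmg import classify_germline_variant
from .filters import CascadeConfig, run_cascade
from .summary import build_landscape, categorize_genes, write_landscape
from .survival import dichotomize, screened_cox_fit
from .tiering import assign_tier, read_evidence_table, select_reportable
from .types import AnnotatedVariant, Origin
from .variant_io import (
    consensus_merge,
    infer_patient_id,
    read_annotation_table,
    read_gene_panel,
    read_pon,
    read_variant_calls,
    write_run_metadata,
    write_triage_report,
)

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    vcf_dir: str
    annotations: str
    germline_panel: str
    somatic_panel: str
    pon: str
    clinical: str
    category_map: str
    evidence: str
    out_dir: str
    callers: list[str] = field(default_factory=lambda: ["gatk", "snver", "lofreq"])
    min_callers: int = 2
    primary_caller: Optional[str] = None
    cascade: CascadeConfig = field(default_factory=CascadeConfig)
    age_cut_years: float = 50.0
    therapy_cut_months: float = 15.8
    collinearity_threshold: float = 0.7
    collinearity_anchor: str = "del5q"
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        cascade_kwargs = raw.pop("cascade", {})
        if "germline_het_band" in cascade_kwargs:
            cascade_kwargs["germline_het_band"] = tuple(
                cascade_kwargs["germline_het_band"]
            )
        return cls(cascade=CascadeConfig(**cascade_kwargs), **raw)

    def to_yaml(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        d["cascade"]["germline_het_band"] = list(d["cascade"]["germline_het_band"])
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))

    def validate_inputs(self) -> None:
        for name in ("vcf_dir", "annotations", "germline_panel", "somatic_panel",
                     "pon", "clinical", "category_map", "evidence"):
            p = Path(getattr(self, name))
            if not p.exists():
                raise FileNotFoundError(f"{name} input not found: {p}")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _discover_vcfs(vcf_dir: Path, callers: list[str]) -> dict[str, dict[str, Path]]:
    """Map sample -> caller -> path for files named ``<sample>.<caller>.vcf``."""
    out: dict[str, dict[str, Path]] = defaultdict(dict)
    for path in sorted(vcf_dir.glob("*.vcf")):
        stem = path.name[: -len(".vcf")]
        sample, _, caller = stem.rpartition(".")
        if not sample or caller not in callers:
            log.warning("skipping VCF with unrecognized name %s", path.name)
            continue
        out[sample][caller] = path
    return out


def triage_stage(cfg: RunConfig, out: Path) -> tuple[list[AnnotatedVariant], "object"]:
    annotations = read_annotation_table(cfg.annotations)
    germline_panel = read_gene_panel(cfg.germline_panel)
    somatic_panel = read_gene_panel(cfg.somatic_panel)
    pon = read_pon(cfg.pon)
    vcfs = _discover_vcfs(Path(cfg.vcf_dir), cfg.callers)

    tumor_variants: list[AnnotatedVariant] = []
    normals: dict[str, list] = {}
    for sample in sorted(vcfs):
        callsets = [
            (caller, read_variant_calls(path, sample, caller))
            for caller, path in sorted(vcfs[sample].items())
        ]
        merged = consensus_merge(
            callsets, min_callers=min(cfg.min_callers, len(callsets)),
            primary_caller=cfg.primary_caller,
        )
        if sample.endswith("-N"):
            normals[infer_patient_id(sample)] = merged
            continue
        for call in merged:
            ann = annotations.get(call.key)
            if ann is None:
                log.warning("no annotation for %s:%d %s>%s; skipped",
                            call.chrom, call.pos, call.ref, call.alt)
                continue
            tumor_variants.append(
                AnnotatedVariant(
                    call=call,
                    annotation=ann,
                    in_germline_panel=ann.gene in germline_panel,
                    in_somatic_panel=ann.gene in somatic_panel,
                )
            )

    result = run_cascade(tumor_variants, normals, pon, cfg.cascade)
    write_triage_report(result.all_variants(), out / "triage.tsv")
    return result.all_variants(), result


def run_all(cfg: RunConfig) -> dict:
    """Execute all stages in order; returns the run manifest."""
    cfg.validate_inputs()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": cfg.seed,
        "thresholds": {
            "min_callers": cfg.min_callers,
            "cascade": {
                **dataclasses.asdict(cfg.cascade),
                "germline_het_band": list(cfg.cascade.germline_het_band),
            },
            "age_cut_years": cfg.age_cut_years,
            "therapy_cut_months": cfg.therapy_cut_months,
            "collinearity_threshold": cfg.collinearity_threshold,
        },
        "stages": [],
        "inputs": {},
    }
    for name in ("annotations", "germline_panel", "somatic_panel", "pon",
                 "clinical", "category_map", "evidence"):
        manifest["inputs"][name] = _sha256(Path(getattr(cfg, name)))

    def stage(name, fn):
        try:
            result = fn()
        except Exception as exc:
            raise RuntimeError(f"pipeline aborted at stage '{name}': {exc}") from exc
        manifest["stages"].append(name)
        return result

    # 1. triage ------------------------------------------------------
    variants, cascade = stage("triage", lambda: triage_stage(cfg, out))

    # 2. germline classification ------------------------------------
    germline_panel = read_gene_panel(cfg.germline_panel)
    lof_genes = {g for g, meta in germline_panel.items() if meta["lof_mechanism"]}
    inh = {g: meta["inheritance"] for g, meta in germline_panel.items()
           if meta["inheritance"] != "unknown"}

    def classify():
        rows = []
        for av in cascade.germline_candidates():
            cls = classify_germline_variant(av, lof_genes=lof_genes,
                                            inheritance_overrides=inh)
            rows.append({
                "patient_id": av.call.patient_id, "sample_id": av.call.sample_id,
                "gene": av.annotation.gene, "hgvs_c": av.annotation.hgvs_c,
                "hgvs_p": av.annotation.hgvs_p, "origin": av.origin.value,
                "vaf": f"{av.call.vaf:.4f}", "depth": av.call.depth,
                "verdict": cls.verdict, "criteria": cls.criteria_string,
            })
        df = pd.DataFrame(rows, columns=["patient_id", "sample_id", "gene", "hgvs_c",
                                         "hgvs_p", "origin", "vaf", "depth",
                                         "verdict", "criteria"])
        if len(df):
            df = df.sort_values(["patient_id", "gene", "hgvs_c"], kind="mergesort")
        df.to_csv(out / "germline.tsv", sep="\t", index=False, lineterminator="\n")
        return df

    germline_df = stage("classify_germline", classify)

    # 3. somatic tiering --------------------------------------------
    evidence = read_evidence_table(cfg.evidence)

    def tier():
        tiered = [(av, assign_tier(av, evidence, cfg.cascade))
                  for av in cascade.somatic_candidates()]
        reportable = select_reportable(tiered)
        rows = [{
            "patient_id": av.call.patient_id, "sample_id": av.call.sample_id,
            "gene": av.annotation.gene, "hgvs_p": av.annotation.hgvs_p,
            "chrom": av.call.chrom, "pos": av.call.pos, "ref": av.call.ref,
            "alt": av.call.alt, "origin": av.origin.value,
            "vaf": f"{av.call.vaf:.4f}", "tier": t.tier, "evidence": t.evidence,
        } for av, t in reportable]
        df = pd.DataFrame(rows, columns=["patient_id", "sample_id", "gene", "hgvs_p",
                                         "chrom", "pos", "ref", "alt", "origin",
                                         "vaf", "tier", "evidence"])
        if len(df):
            df = df.sort_values(["patient_id", "sample_id", "chrom", "pos", "alt"],
                                kind="mergesort")
        df.to_csv(out / "somatic.tsv", sep="\t", index=False, lineterminator="\n")
        return [av for av, _ in reportable]

    somatic_reportable = stage("tier_somatic", tier)

    # 4. cohort summary ---------------------------------------------
    clinical = pd.read_csv(cfg.clinical, sep="\t")
    category_map = dict(
        pd.read_csv(cfg.category_map, sep="\t").itertuples(index=False, name=None)
    )

    def summarize():
        samples = sorted({av.call.sample_id for av in somatic_reportable})
        if not samples:
            (out / "landscape.tsv").write_text("gene\n")
            (out / "categories.tsv").write_text("patient_id\n")
            return None
        matrix = build_landscape(somatic_reportable, samples)
        write_landscape(matrix, out / "landscape.tsv")
        flags = categorize_genes(matrix.patient_gene_sets(), category_map)
        flags.to_csv(out / "categories.tsv", sep="\t", index_label="patient_id",
                     lineterminator="\n")
        freq = matrix.patient_frequency().mul(100).round(1)
        freq.to_csv(out / "gene_frequencies.tsv", sep="\t",
                    index_label="gene", header=["percent_patients"],
                    lineterminator="\n")
        return matrix

    matrix = stage("summarize", summarize)

    # 5. survival ----------------------------------------------------
    def survival():
        features = pd.DataFrame({
            "male": (clinical["sex"] == "M").astype(int),
            "radiotherapy": clinical["radiotherapy"].astype(int),
            "therapy_gt_cut": dichotomize(
                clinical["therapy_duration_months"], cfg.therapy_cut_months
            ).reindex(clinical.index, fill_value=0),
            "age_gt_cut": dichotomize(
                clinical["age_years"], cfg.age_cut_years
            ).reindex(clinical.index, fill_value=0),
            "del5q": clinical["del5q"].astype(int),
            "del7q": clinical["del7q"].astype(int),
            "complex_karyotype": clinical["complex_karyotype"].astype(int),
        })
        if matrix is not None and "TP53" in matrix.genes:
            tp53_patients = {
                p for p, genes in matrix.patient_gene_sets().items() if "TP53" in genes
            }
            features["tp53_somatic"] = clinical["patient_id"].isin(tp53_patients).astype(int)
        features = features.loc[:, features.std(ddof=0) > 0]
        fit = screened_cox_fit(
            clinical["os_months"], clinical["death"].astype(bool), features,
            threshold=cfg.collinearity_threshold, anchor=cfg.collinearity_anchor,
        )
        (out / "survival.json").write_text(
            json.dumps(fit.to_json_dict(), indent=2, sort_keys=True) + "\n"
        )
        return fit

    stage("survival", survival)

    manifest["n_variants_triaged"] = len(variants)
    manifest["n_germline_candidates"] = len(cascade.germline_candidates())
    manifest["n_germline_deleterious"] = int(
        germline_df["verdict"].isin(["P", "LP"]).sum()
    ) if len(germline_df) else 0
    manifest["n_somatic_reportable"] = len(somatic_reportable)
    write_run_metadata(out / "manifest.json", manifest)
    return manifest
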