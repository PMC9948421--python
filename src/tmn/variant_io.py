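"""Reading, writing, and consensus merging of variant call sets.

VCF conventions expected on input (one single-sample VCF per caller per
sample): per-sample FORMAT fields ``DP`` (total depth), ``AF``
(alternate allele fraction, Number=A) and, when strand information is
available, ``ADF``/``ADR`` (stranded allele depths, Number=R, reference
allele first).  When ``AF`` is absent, VAF is computed as the stranded
alternate sum over depth.  Multi-allelic records are split into one
:class:`~tmn.types.VariantCall` per ALT allele.
"""
from __future__ import annotations

import json
import logging
import statistics
from collections import defaultdict
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd
import pysam

from .types import AnnotatedVariant, AnnotationBundle, CONSEQUENCES, VariantCall, VariantKey

log = logging.getLogger(__name__)

_FREQ_COLUMNS = (
    "freq_gnomad_exome_all",
    "freq_gnomad_exome_eas",
    "freq_gnomad_genome_all",
    "freq_gnomad_genome_eas",
    "freq_kova",
    "freq_krgdb",
)


def trim_alleles(pos: int, ref: str, alt: str) -> tuple[int, str, str]:
    """Left-normalize an allele pair by trimming shared suffix then prefix.

    Keeps at least one base on each side so SNVs and anchored indels stay
    representable without the reference sequence.
    """
    while len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
        ref, alt = ref[:-1], alt[:-1]
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    return pos, ref, alt


def infer_sample_role(sample_id: str) -> str:
    if sample_id.endswith("-N"):
        return "non_malignant"
    if sample_id.endswith("-B"):
        return "tmn_progression"
    return "tmn_initial"


def infer_patient_id(sample_id: str) -> str:
    for suffix in ("-A", "-B", "-N"):
        if sample_id.endswith(suffix):
            return sample_id[: -len(suffix)]
    return sample_id


def read_variant_calls(path: str | Path, sample_id: str, caller: str) -> list[VariantCall]:
    """Read one per-caller VCF into a list of calls (one per ALT allele)."""
    path = Path(path)
    try:
        vf = pysam.VariantFile(str(path))
    except (ValueError, OSError) as exc:  # pragma: no cover - pysam message passthrough
        raise ValueError(f"malformed VCF {path}: {exc}") from exc
    calls: list[VariantCall] = []
    role = infer_sample_role(sample_id)
    patient = infer_patient_id(sample_id)
    with vf:
        for rec in vf:
            if not rec.alts:
                continue
            fmt = rec.samples[0] if rec.samples else {}
            depth = _first_present(fmt, rec.info, "DP")
            if depth is None:
                log.warning("%s:%s:%d has no DP; record skipped", path.name, rec.chrom, rec.pos)
                continue
            adf = _as_tuple(_first_present(fmt, rec.info, "ADF"))
            adr = _as_tuple(_first_present(fmt, rec.info, "ADR"))
            afs = _as_tuple(_first_present(fmt, rec.info, "AF"))
            for i, alt in enumerate(rec.alts):
                if alt is None or alt == rec.ref:
                    continue
                fwd = rev = None
                if adf is not None and adr is not None and len(adf) > i + 1:
                    fwd, rev = int(adf[i + 1]), int(adr[i + 1])  # index 0 is REF
                else:
                    log.warning(
                        "%s:%s:%d lacks stranded alt counts; strand-bias filter "
                        "will skip this record",
                        path.name,
                        rec.chrom,
                        rec.pos,
                    )
                if afs is not None and len(afs) > i and afs[i] is not None:
                    vaf = float(afs[i])
                elif fwd is not None and rev is not None and depth > 0:
                    vaf = (fwd + rev) / depth
                else:
                    log.warning(
                        "%s:%s:%d has neither AF nor strand counts; VAF set to 0",
                        path.name,
                        rec.chrom,
                        rec.pos,
                    )
                    vaf = 0.0
                pos, ref, alt_n = trim_alleles(rec.pos, rec.ref, alt)
                calls.append(
                    VariantCall(
                        sample_id=sample_id,
                        patient_id=patient,
                        sample_role=role,
                        chrom=str(rec.chrom),
                        pos=pos,
                        ref=ref,
                        alt=alt_n,
                        vaf=min(max(vaf, 0.0), 1.0),
                        depth=int(depth),
                        alt_forward=fwd,
                        alt_reverse=rev,
                        callers=frozenset({caller}),
                    )
                )
    return calls


def _first_present(fmt, info, key):
    if key in fmt:
        return fmt[key]
    if key in info:
        return info[key]
    return None


def _as_tuple(value):
    if value is None:
        return None
    if isinstance(value, (tuple, list)):
        return tuple(value)
    return (value,)


def consensus_merge(
    callsets: Sequence[tuple[str, Sequence[VariantCall]]],
    min_callers: int = 2,
    primary_caller: Optional[str] = None,
) -> list[VariantCall]:
    """Merge per-caller call sets, keeping variants seen by >= min_callers.

    VAF and depth are taken from ``primary_caller`` when it observed the
    variant, otherwise the per-field median across observing callers is
    used.  The output is sorted by (sample, chrom, pos, ref, alt) and never
    contains the same key twice for one sample.
    """
    if min_callers < 1:
        raise ValueError("min_callers must be >= 1")
    names = [name for name, _ in callsets]
    if len(set(names)) != len(names):
        raise ValueError("caller names must be distinct")
    if min_callers > len(callsets):
        raise ValueError(
            f"min_callers={min_callers} exceeds number of call sets ({len(callsets)})"
        )
    grouped: dict[tuple, dict[str, VariantCall]] = defaultdict(dict)
    for caller, calls in callsets:
        for call in calls:
            grouped[(call.sample_id,) + call.key][caller] = call
    merged: list[VariantCall] = []
    for group_key in sorted(grouped, key=_sort_key):
        by_caller = grouped[group_key]
        if len(by_caller) < min_callers:
            continue
        if primary_caller is not None and primary_caller in by_caller:
            base = by_caller[primary_caller]
            vaf, depth = base.vaf, base.depth
            fwd, rev = base.alt_forward, base.alt_reverse
        else:
            members = list(by_caller.values())
            vaf = statistics.median(c.vaf for c in members)
            depth = int(statistics.median(c.depth for c in members))
            stranded = [
                c for c in members if c.alt_forward is not None and c.alt_reverse is not None
            ]
            fwd = int(statistics.median(c.alt_forward for c in stranded)) if stranded else None
            rev = int(statistics.median(c.alt_reverse for c in stranded)) if stranded else None
        proto = next(iter(by_caller.values()))
        if fwd is not None and rev is not None and fwd + rev > depth:
            depth = fwd + rev
        merged.append(
            VariantCall(
                sample_id=proto.sample_id,
                patient_id=proto.patient_id,
                sample_role=proto.sample_role,
                chrom=proto.chrom,
                pos=proto.pos,
                ref=proto.ref,
                alt=proto.alt,
                vaf=vaf,
                depth=depth,
                alt_forward=fwd,
                alt_reverse=rev,
                callers=frozenset(by_caller),
            )
        )
    return merged


def _sort_key(group_key):
    sample, chrom, pos, ref, alt = group_key
    return (sample, _chrom_rank(chrom), pos, ref, alt)


def _chrom_rank(chrom: str):
    c = chrom.removeprefix("chr")
    return (0, int(c), "") if c.isdigit() else (1, 0, c)


def read_annotation_table(path: str | Path) -> dict[VariantKey, AnnotationBundle]:
    """Read the tab-delimited annotation table keyed by (chrom,pos,ref,alt).

    Empty cells and ``.`` mean missing.  Duplicate keys are an error.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, na_values=[".", ""], keep_default_na=False)
    required = {"chrom", "pos", "ref", "alt", "gene"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"annotation table {path} missing columns: {sorted(missing)}")
    out: dict[VariantKey, AnnotationBundle] = {}
    for row in df.itertuples(index=False):
        d = row._asdict()
        key = (str(d["chrom"]), int(d["pos"]), str(d["ref"]), str(d["alt"]))
        if key in out:
            raise ValueError(f"duplicate annotation key {key} in {path}")
        consequence = _get(d, "consequence", "other")
        if consequence not in CONSEQUENCES:
            raise ValueError(
                f"unknown consequence {consequence!r} for {key}; "
                f"allowed: {', '.join(CONSEQUENCES)}"
            )
        stars = _get(d, "clinvar_stars")
        out[key] = AnnotationBundle(
            gene=str(d["gene"]),
            transcript=_get(d, "transcript", ""),
            hgvs_c=_get(d, "hgvs_c", ""),
            hgvs_p=_get(d, "hgvs_p", ""),
            consequence=consequence,
            nmd_predicted=_get(d, "nmd_predicted", "unknown"),
            clinvar_significance=_get(d, "clinvar_significance"),
            clinvar_stars=int(stars) if stars is not None else None,
            hgmd_class=_get(d, "hgmd_class", "none"),
            cosmic_present=_get(d, "cosmic_present", "false").lower() in ("true", "1", "yes"),
            sift=_get(d, "sift", "missing"),
            polyphen2_hvar=_get(d, "polyphen2_hvar", "missing"),
            cadd_phred=_float(_get(d, "cadd_phred")),
            inheritance=_get(d, "inheritance", "unknown"),
            hotspot_domain=_get(d, "hotspot_domain", "false").lower() in ("true", "1", "yes"),
            protein_position=_int(_get(d, "protein_position")),
            domain_name=_get(d, "domain_name"),
            **{col: _float(_get(d, col)) for col in _FREQ_COLUMNS},
        )
    return out


def _get(d, key, default=None):
    v = d.get(key)
    if v is None or (isinstance(v, float) and pd.isna(v)):
        return default
    return v


def _float(v):
    return None if v is None else float(v)


def _int(v):
    return None if v is None else int(float(v))


def read_gene_panel(path: str | Path) -> dict[str, dict]:
    """Read a panel file: one gene per line, optional tab-separated
    inheritance (AD/AR/XL) and LOF-mechanism (yes/no) columns."""
    panel: dict[str, dict] = {}
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        gene = parts[0]
        panel[gene] = {
            "inheritance": parts[1] if len(parts) > 1 else "unknown",
            "lof_mechanism": (parts[2].lower() in ("yes", "true", "1"))
            if len(parts) > 2
            else True,
        }
    return panel


def read_pon(path: str | Path) -> dict[VariantKey, float]:
    """Read a panel-of-normals TSV (chrom, pos, ref, alt, recurrence_fraction)."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    out = {}
    for row in df.itertuples(index=False):
        frac = float(row.recurrence_fraction)
        if not 0.0 <= frac <= 1.0:
            raise ValueError(f"PoN recurrence fraction {frac} outside [0, 1]")
        out[(str(row.chrom), int(row.pos), str(row.ref), str(row.alt))] = frac
    return out


TRIAGE_COLUMNS = [
    "patient_id",
    "sample_id",
    "sample_role",
    "chrom",
    "pos",
    "ref",
    "alt",
    "gene",
    "transcript",
    "hgvs_c",
    "hgvs_p",
    "consequence",
    "vaf",
    "depth",
    "alt_forward",
    "alt_reverse",
    "callers",
    "in_germline_panel",
    "in_somatic_panel",
    "origin",
    "filter_trail",
    "germline_verdict",
    "germline_criteria",
    "somatic_tier",
]


def write_triage_report(
    variants: Iterable[AnnotatedVariant],
    path: str | Path,
    classifications: Optional[Mapping[int, tuple[str, str]]] = None,
    tiers: Optional[Mapping[int, str]] = None,
) -> None:
    """Write the triage TSV, one row per variant, deterministically ordered.

    ``classifications`` / ``tiers`` map ``id(variant)`` to downstream
    results when those stages have run.
    """
    classifications = classifications or {}
    tiers = tiers or {}
    rows = []
    for av in variants:
        c, a = av.call, av.annotation
        verdict, criteria = classifications.get(id(av), ("", ""))
        rows.append(
            {
                "patient_id": c.patient_id,
                "sample_id": c.sample_id,
                "sample_role": c.sample_role,
                "chrom": c.chrom,
                "pos": c.pos,
                "ref": c.ref,
                "alt": c.alt,
                "gene": a.gene,
                "transcript": a.transcript,
                "hgvs_c": a.hgvs_c,
                "hgvs_p": a.hgvs_p,
                "consequence": a.consequence,
                "vaf": f"{c.vaf:.4f}",
                "depth": c.depth,
                "alt_forward": "" if c.alt_forward is None else c.alt_forward,
                "alt_reverse": "" if c.alt_reverse is None else c.alt_reverse,
                "callers": ",".join(sorted(c.callers)),
                "in_germline_panel": av.in_germline_panel,
                "in_somatic_panel": av.in_somatic_panel,
                "origin": av.origin.value,
                "filter_trail": ";".join(f"{s}:{r}:{why}" for s, r, why in av.filter_trail),
                "germline_verdict": verdict,
                "germline_criteria": criteria,
                "somatic_tier": tiers.get(id(av), ""),
            }
        )
    df = pd.DataFrame(rows, columns=TRIAGE_COLUMNS)
    if len(df):
        df = df.sort_values(
            ["patient_id", "sample_id", "chrom", "pos", "alt"], kind="mergesort"
        )
    df.to_csv(path, sep="\t", index=False, lineterminator="\n")


def write_run_metadata(path: str | Path, metadata: Mapping) -> None:
    """JSON sidecar with caller set, thresholds, seed, and versions."""
    Path(path).write_text(json.dumps(metadata, indent=2, sort_keys=True) + "\n")
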