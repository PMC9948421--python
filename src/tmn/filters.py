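"""The variant-filtering cascade and germline/somatic origin partition.

Stage order: quality gate (depth, minimum VAF) -> strand-bias filter ->
origin partition, with the population-frequency and panel-of-normals
filters applied inside the somatic-candidacy branch.  Every variant
carries a ``filter_trail`` recording each stage it passed through.

The strand-bias rule generalizes the classical 2:8 / 8:2 alternate-count
ratio to "minority-strand fraction <= strand_bias_min_fraction", so
counts more extreme than 2:8 (e.g. 1:9) are also rejected.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

from .types import AnnotatedVariant, Origin, VariantCall, VariantKey

log = logging.getLogger(__name__)


@dataclass
class CascadeConfig:
    """Thresholds of the filtering cascade.

    Numeric cut-offs inside the published filtering diagrams are rarely
    printed; these defaults are conventional values and every one is
    overridable in the run config.
    """

    min_depth: int = 20
    min_vaf_somatic: float = 0.02
    strand_bias_min_fraction: float = 0.2
    common_maf_threshold: float = 0.01
    pon_recurrence_fraction: float = 0.05
    germline_het_band: tuple[float, float] = (0.30, 0.70)
    germline_hom_min: float = 0.90
    normal_support_min_vaf: float = 0.30

    def __post_init__(self) -> None:
        for name in (
            "min_vaf_somatic",
            "strand_bias_min_fraction",
            "common_maf_threshold",
            "pon_recurrence_fraction",
            "germline_hom_min",
            "normal_support_min_vaf",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        lo, hi = self.germline_het_band
        if not (0.0 <= lo < hi < self.germline_hom_min):
            raise ValueError(
                "germline_het_band must satisfy lower < upper < germline_hom_min"
            )


@dataclass
class FilterResult:
    passed: bool
    reason: str

    def __bool__(self) -> bool:
        return self.passed


def strand_bias_filter(call: VariantCall, cfg: CascadeConfig) -> FilterResult:
    """Fail calls whose alternate reads are concentrated on one strand."""
    fwd, rev = call.alt_forward, call.alt_reverse
    if fwd is None or rev is None:
        log.info(
            "strand bias not evaluated for %s:%d (missing strand counts)",
            call.chrom,
            call.pos,
        )
        return FilterResult(True, "not evaluated: missing strand counts")
    if fwd < 0 or rev < 0:
        raise ValueError("negative stranded alt counts")
    total = fwd + rev
    if total == 0:
        return FilterResult(True, "no alternate reads to assess")
    frac = min(fwd, rev) / total
    if frac <= cfg.strand_bias_min_fraction:
        return FilterResult(
            False, f"strand-biased: minority fraction {frac:.3f} <= "
            f"{cfg.strand_bias_min_fraction}"
        )
    return FilterResult(True, f"balanced strands (minority fraction {frac:.3f})")


def population_frequency_filter(av: AnnotatedVariant, cfg: CascadeConfig) -> FilterResult:
    """Flag common polymorphisms for somatic candidacy.

    For germline candidacy this filter only annotates (rarity is enforced
    downstream by the PM2 criterion); here it returns the somatic verdict.
    """
    offending = {
        db: f
        for db, f in av.annotation.population_frequencies().items()
        if f is not None and f >= cfg.common_maf_threshold
    }
    if offending:
        worst = max(offending, key=offending.get)
        return FilterResult(
            False,
            f"common polymorphism: {worst} MAF {offending[worst]:.4g} >= "
            f"{cfg.common_maf_threshold}",
        )
    return FilterResult(True, "rare in all population databases")


def panel_of_normals_filter(
    av: AnnotatedVariant,
    pon: Mapping[VariantKey, float],
    cfg: CascadeConfig,
) -> FilterResult:
    """Fail somatic candidates recurrent in the panel of normals."""
    frac = pon.get(av.call.key)
    if frac is None:
        return FilterResult(True, "absent from panel of normals")
    if not 0.0 <= frac <= 1.0:
        raise ValueError(f"PoN recurrence fraction {frac} outside [0, 1]")
    if frac >= cfg.pon_recurrence_fraction:
        return FilterResult(
            False,
            f"PoN-recurrent: fraction {frac:.3f} >= {cfg.pon_recurrence_fraction}",
        )
    return FilterResult(True, f"PoN fraction {frac:.3f} below cut-off")


def _normal_supports(
    av: AnnotatedVariant,
    matched_normal: Optional[Sequence[VariantCall]],
    cfg: CascadeConfig,
) -> bool:
    if not matched_normal:
        return False
    return any(
        nc.key == av.call.key and nc.vaf >= cfg.normal_support_min_vaf
        for nc in matched_normal
    )


def partition_by_origin(
    av: AnnotatedVariant,
    matched_normal: Optional[Sequence[VariantCall]],
    cfg: CascadeConfig,
    pon: Optional[Mapping[VariantKey, float]] = None,
) -> AnnotatedVariant:
    """Set ``av.origin`` for a variant that passed the upstream gates.

    Rules: confirmation in the matched non-malignant sample of a
    germline-panel gene gives ``presumed_germline``; without a matched
    normal, a germline-panel variant in the heterozygous band (or at
    homozygous VAF) is ``potential_germline``; a somatic-panel variant
    passing the population and PoN filters is ``somatic``; both at once
    is ``dual``; neither is ``unresolved``.
    """
    pon = pon or {}
    vaf = av.call.vaf

    if av.in_germline_panel and _normal_supports(av, matched_normal, cfg):
        av.origin = Origin.PRESUMED_GERMLINE
        av.record("origin", True, "confirmed in matched non-malignant sample")
        return av

    lo, hi = cfg.germline_het_band
    germline_compatible = (
        av.in_germline_panel
        and not matched_normal
        and (lo <= vaf <= hi or vaf >= cfg.germline_hom_min)
    )

    somatic_compatible = False
    if av.in_somatic_panel:
        popf = population_frequency_filter(av, cfg)
        av.record("population_frequency", popf.passed, popf.reason)
        if popf:
            ponf = panel_of_normals_filter(av, pon, cfg)
            av.record("panel_of_normals", ponf.passed, ponf.reason)
            somatic_compatible = ponf.passed

    if germline_compatible and somatic_compatible:
        av.origin = Origin.DUAL
        av.record("origin", True, "germline-compatible and somatic-compatible")
    elif germline_compatible:
        av.origin = Origin.POTENTIAL_GERMLINE
        av.record("origin", True, f"germline panel, VAF {vaf:.2f} germline-compatible")
    elif somatic_compatible:
        av.origin = Origin.SOMATIC
        av.record("origin", True, "somatic panel, passes population and PoN filters")
    else:
        av.origin = Origin.UNRESOLVED
        av.record("origin", False, "fits no origin bucket")
    return av


@dataclass
class CascadeResult:
    """Disjoint triage buckets (``dual`` members are additionally
    cross-listed into both downstream paths by the pipeline)."""

    presumed_germline: list[AnnotatedVariant] = field(default_factory=list)
    potential_germline: list[AnnotatedVariant] = field(default_factory=list)
    somatic: list[AnnotatedVariant] = field(default_factory=list)
    dual: list[AnnotatedVariant] = field(default_factory=list)
    rejected: list[AnnotatedVariant] = field(default_factory=list)
    unresolved: list[AnnotatedVariant] = field(default_factory=list)

    def all_variants(self) -> list[AnnotatedVariant]:
        return (
            self.presumed_germline
            + self.potential_germline
            + self.somatic
            + self.dual
            + self.rejected
            + self.unresolved
        )

    def germline_candidates(self) -> list[AnnotatedVariant]:
        return self.presumed_germline + self.potential_germline + self.dual

    def somatic_candidates(self) -> list[AnnotatedVariant]:
        return self.somatic + self.dual


def run_cascade(
    variants: Sequence[AnnotatedVariant],
    normals: Mapping[str, Sequence[VariantCall]],
    pon: Mapping[VariantKey, float],
    cfg: CascadeConfig,
) -> CascadeResult:
    """Run the full cascade over consensus-merged annotated variants.

    ``normals`` maps patient id to the calls observed in that patient's
    matched non-malignant sample (patients without one are absent).
    """
    result = CascadeResult()
    for av in variants:
        call = av.call
        if call.depth < cfg.min_depth:
            av.record("quality", False, f"depth {call.depth} < {cfg.min_depth}")
            av.origin = Origin.ARTIFACT
            result.rejected.append(av)
            continue
        if call.vaf < cfg.min_vaf_somatic:
            av.record("quality", False, f"VAF {call.vaf:.3f} < {cfg.min_vaf_somatic}")
            av.origin = Origin.ARTIFACT
            result.rejected.append(av)
            continue
        av.record("quality", True, "depth and VAF above minima")

        sb = strand_bias_filter(call, cfg)
        av.record("strand_bias", sb.passed, sb.reason)
        if not sb:
            av.origin = Origin.ARTIFACT
            result.rejected.append(av)
            continue

        partition_by_origin(av, normals.get(call.patient_id), cfg, pon)
        {
            Origin.PRESUMED_GERMLINE: result.presumed_germline,
            Origin.POTENTIAL_GERMLINE: result.potential_germline,
            Origin.SOMATIC: result.somatic,
            Origin.DUAL: result.dual,
            Origin.UNRESOLVED: result.unresolved,
        }[av.origin].append(av)
    return result
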