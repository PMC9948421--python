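"""Domain types shared across the triage pipeline.

Coordinates are 1-based VCF convention throughout. A "variant key"
is the tuple ``(chrom, pos, ref, alt)`` after allele trimming, so the
same event is keyed identically regardless of caller representation.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Optional

VariantKey = tuple[str, int, str, str]

SAMPLE_ROLES = ("tmn_initial", "tmn_progression", "non_malignant")

CONSEQUENCES = (
    "missense",
    "nonsense",
    "frameshift",
    "canonical_splice",
    "initiation_loss",
    "inframe_indel",
    "synonymous",
    "other",
)

#: Null-variant consequences eligible for the loss-of-function criterion.
NULL_CONSEQUENCES = frozenset(
    {"nonsense", "frameshift", "canonical_splice", "initiation_loss"}
)


class Origin(str, Enum):
    """Triage verdict for one consensus call.

    ``presumed_germline`` means the call was confirmed in a matched
    non-malignant sample; ``potential_germline`` is germline-compatible
    (predisposition gene, heterozygous/homozygous VAF band) without a
    matched normal; ``dual`` marks calls that are plausibly both germline
    and somatic (gene on both panels); ``artifact`` marks technical
    rejections; ``unresolved`` is everything that fits no bucket.
    """

    PRESUMED_GERMLINE = "presumed_germline"
    POTENTIAL_GERMLINE = "potential_germline"
    SOMATIC = "somatic"
    DUAL = "dual"
    ARTIFACT = "artifact"
    UNRESOLVED = "unresolved"


@dataclass
class VariantCall:
    """One observed alternate allele in one sample.

    ``alt_forward``/``alt_reverse`` are the stranded alternate-allele read
    counts; they may be ``None`` when the caller did not report strand
    information, in which case the strand-bias filter skips the record.
    """

    sample_id: str
    patient_id: str
    sample_role: str
    chrom: str
    pos: int
    ref: str
    alt: str
    vaf: float
    depth: int
    alt_forward: Optional[int] = None
    alt_reverse: Optional[int] = None
    callers: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if self.sample_role not in SAMPLE_ROLES:
            raise ValueError(f"unknown sample_role {self.sample_role!r}")
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if self.ref == self.alt:
            raise ValueError(f"ref == alt ({self.ref!r}) at {self.chrom}:{self.pos}")
        if not 0.0 <= self.vaf <= 1.0:
            raise ValueError(f"vaf {self.vaf} outside [0, 1]")
        if self.alt_forward is not None and self.alt_forward < 0:
            raise ValueError("negative alt_forward")
        if self.alt_reverse is not None and self.alt_reverse < 0:
            raise ValueError("negative alt_reverse")
        if (
            self.alt_forward is not None
            and self.alt_reverse is not None
            and self.alt_forward + self.alt_reverse > self.depth
        ):
            raise ValueError(
                f"stranded alt counts exceed depth at {self.chrom}:{self.pos}"
            )
        if not self.callers:
            raise ValueError("callers must be non-empty")
        self.callers = frozenset(self.callers)

    @property
    def key(self) -> VariantKey:
        return (self.chrom, self.pos, self.ref, self.alt)


@dataclass
class AnnotationBundle:
    """Functional and population annotation for one variant key."""

    gene: str
    transcript: str = ""
    hgvs_c: str = ""
    hgvs_p: str = ""
    consequence: str = "other"
    nmd_predicted: str = "unknown"  # yes / no / unknown
    freq_gnomad_exome_all: Optional[float] = None
    freq_gnomad_exome_eas: Optional[float] = None
    freq_gnomad_genome_all: Optional[float] = None
    freq_gnomad_genome_eas: Optional[float] = None
    freq_kova: Optional[float] = None
    freq_krgdb: Optional[float] = None
    clinvar_significance: Optional[str] = None
    clinvar_stars: Optional[int] = None
    hgmd_class: str = "none"  # DM_high / DM_low / other / none
    cosmic_present: bool = False
    sift: str = "missing"  # D / T / missing
    polyphen2_hvar: str = "missing"  # D / P / B / missing
    cadd_phred: Optional[float] = None
    inheritance: str = "unknown"  # AD / AR / XL / unknown
    hotspot_domain: bool = False
    protein_position: Optional[int] = None
    domain_name: Optional[str] = None

    def __post_init__(self) -> None:
        if self.consequence not in CONSEQUENCES:
            raise ValueError(
                f"unknown consequence {self.consequence!r}; "
                f"allowed: {', '.join(CONSEQUENCES)}"
            )
        for name in (
            "freq_gnomad_exome_all",
            "freq_gnomad_exome_eas",
            "freq_gnomad_genome_all",
            "freq_gnomad_genome_eas",
            "freq_kova",
            "freq_krgdb",
        ):
            v = getattr(self, name)
            if v is not None and not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.clinvar_stars is not None and self.clinvar_significance is None:
            raise ValueError("clinvar_stars present without clinvar_significance")

    def population_frequencies(self) -> dict[str, Optional[float]]:
        return {
            "gnomad_exome_all": self.freq_gnomad_exome_all,
            "gnomad_exome_eas": self.freq_gnomad_exome_eas,
            "gnomad_genome_all": self.freq_gnomad_genome_all,
            "gnomad_genome_eas": self.freq_gnomad_genome_eas,
            "kova": self.freq_kova,
            "krgdb": self.freq_krgdb,
        }

    def max_population_frequency(self) -> float:
        """Maximum frequency across all databases, missing treated as 0."""
        return max(
            (v for v in self.population_frequencies().values() if v is not None),
            default=0.0,
        )


@dataclass
class AnnotatedVariant:
    """A consensus call joined to its annotation and triage state."""

    call: VariantCall
    annotation: AnnotationBundle
    in_germline_panel: bool = False
    in_somatic_panel: bool = False
    origin: Origin = Origin.UNRESOLVED
    filter_trail: list[tuple[str, str, str]] = field(default_factory=list)

    def record(self, stage: str, passed: bool, reason: str) -> None:
        self.filter_trail.append((stage, "pass" if passed else "fail", reason))

    def __post_init__(self) -> None:
        if self.origin == Origin.DUAL and not (
            self.in_germline_panel and self.in_somatic_panel
        ):
            raise ValueError("dual origin requires membership in both panels")


@dataclass
class PatientRecord:
    """Clinical covariates for one patient."""

    patient_id: str
    age_years: float
    sex: str  # M / F
    primary_disease: str = "other"
    subtype: str = "MDS"  # MDS / MDS_MPN / AML
    chemo: bool = True
    radiotherapy: bool = False
    alkylating: bool = False
    topoII: bool = False
    antimetabolite: bool = False
    antitubulin: bool = False
    auto_pbsct: bool = False
    allo_pbsct: bool = False
    therapy_duration_months: float = 0.0
    latency_months: float = 0.0
    del5q: bool = False
    del7q: bool = False
    del17p: bool = False
    complex_karyotype: bool = False
    pml_rara: bool = False
    kmt2a_r: bool = False
    runx1_r: bool = False
    mecom_r: bool = False
    normal_karyotype: bool = False
    not_assessed: bool = False
    os_months: float = 0.0
    death: bool = False

    CYTO_FLAGS = (
        "del5q",
        "del7q",
        "del17p",
        "complex_karyotype",
        "pml_rara",
        "kmt2a_r",
        "runx1_r",
        "mecom_r",
        "normal_karyotype",
    )

    def __post_init__(self) -> None:
        if self.age_years < 0:
            raise ValueError("age_years must be non-negative")
        if self.sex not in ("M", "F"):
            raise ValueError(f"sex must be M or F, got {self.sex!r}")
        if self.subtype not in ("MDS", "MDS_MPN", "AML"):
            raise ValueError(f"unknown subtype {self.subtype!r}")
        if self.os_months < 0 or self.therapy_duration_months < 0:
            raise ValueError("durations must be non-negative")
        if self.not_assessed and any(getattr(self, f) for f in self.CYTO_FLAGS):
            raise ValueError("not_assessed excludes all other cytogenetic flags")

    @property
    def pediatric(self) -> bool:
        return self.age_years < 20
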