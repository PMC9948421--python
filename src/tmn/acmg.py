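"""ACMG/AMP germline classification engine.

Evidence criteria are represented as :class:`CriterionAssignment` tokens
carrying an effective strength, combined by :func:`combine_criteria`
into the five-class verdict (P / LP / VUS / LB / B).

Specializations implemented here:

* PVS1 follows the ClinGen SVI loss-of-function decision process in
  abbreviated form: null variants (nonsense, frameshift, canonical
  splice, initiation loss) in a gene whose disease mechanism is loss of
  function earn PVS1 at very strong when nonsense-mediated decay is
  predicted (or for canonical splice sites), downgraded one level to
  PVS1_Strong when the transcript is predicted to escape NMD.
* PM2 uses the gnomAD exome global frequency with a strict cut-off of
  1e-5 for dominant (and X-linked) disease and 1e-4 for recessive
  disease; unknown inheritance conservatively uses the dominant cut-off.
* PP3 requires concordance of three predictors: SIFT damaging,
  PolyPhen2-HVAR damaging or possibly damaging, and CADD phred > 20.
* PP5 (reputable source) fires for ClinVar pathogenic/likely-pathogenic
  assertions with at least one review star, or a high-confidence HGMD
  DM entry.  ClinVar VUS/conflicting records and low-confidence DM
  entries do not qualify.
* PM1 is consumed as a hotspot/benign-variation-free-domain flag
  supplied by annotation.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

from .types import AnnotatedVariant, AnnotationBundle, NULL_CONSEQUENCES, Origin

STRENGTHS = ("very_strong", "strong", "moderate", "supporting", "stand_alone")

_DEFAULT_STRENGTH = {
    "PVS": "very_strong",
    "PS": "strong",
    "PM": "moderate",
    "PP": "supporting",
    "BA": "stand_alone",
    "BS": "strong",
    "BP": "supporting",
}

_STRENGTH_SUFFIX = {
    "very_strong": "VeryStrong",
    "strong": "Strong",
    "moderate": "Moderate",
    "supporting": "Supporting",
    "stand_alone": "StandAlone",
}


def code_family(code: str) -> str:
    for prefix in ("PVS", "PS", "PM", "PP", "BA", "BS", "BP"):
        if code.startswith(prefix):
            return prefix
    raise ValueError(f"unknown criterion code {code!r}")


def is_benign_code(code: str) -> bool:
    return code_family(code) in ("BA", "BS", "BP")


@dataclass
class CriterionAssignment:
    """One fired evidence criterion with its effective strength."""

    code: str
    strength: str = ""
    rationale: str = ""

    def __post_init__(self) -> None:
        family = code_family(self.code)
        if not self.strength:
            self.strength = _DEFAULT_STRENGTH[family]
        if self.strength not in STRENGTHS:
            raise ValueError(f"unknown strength token {self.strength!r}")

    @property
    def is_default_strength(self) -> bool:
        return self.strength == _DEFAULT_STRENGTH[code_family(self.code)]

    @property
    def token(self) -> str:
        """Render as e.g. ``PVS1`` or ``PVS1_Strong`` for modified strength."""
        if self.is_default_strength:
            return self.code
        return f"{self.code}_{_STRENGTH_SUFFIX[self.strength]}"


def parse_token(token: str) -> CriterionAssignment:
    """Inverse of :attr:`CriterionAssignment.token`."""
    suffix_map = {v: k for k, v in _STRENGTH_SUFFIX.items()}
    if "_" in token:
        code, suffix = token.split("_", 1)
        return CriterionAssignment(code, suffix_map[suffix])
    return CriterionAssignment(token)


@dataclass
class GermlineClassification:
    verdict: str  # P / LP / VUS / LB / B
    criteria: list[CriterionAssignment] = field(default_factory=list)

    @property
    def deleterious(self) -> bool:
        return self.verdict in ("P", "LP")

    @property
    def criteria_string(self) -> str:
        return " + ".join(c.token for c in self.criteria)


def evaluate_pvs1(
    ann: AnnotationBundle, lof_mechanism: bool = True
) -> Optional[CriterionAssignment]:
    """Loss-of-function criterion, abbreviated ClinGen SVI decision tree."""
    if not lof_mechanism or ann.consequence not in NULL_CONSEQUENCES:
        return None
    if ann.consequence == "canonical_splice" or ann.nmd_predicted == "yes":
        return CriterionAssignment(
            "PVS1", "very_strong", f"null variant ({ann.consequence}), NMD anticipated"
        )
    if ann.nmd_predicted == "no":
        return CriterionAssignment(
            "PVS1", "strong", f"null variant ({ann.consequence}) predicted to escape NMD"
        )
    # NMD status unknown for a truncating variant: keep the conservative
    # one-level downgrade rather than full very-strong weight.
    return CriterionAssignment(
        "PVS1", "strong", f"null variant ({ann.consequence}), NMD status unknown"
    )


def evaluate_pm2(ann: AnnotationBundle) -> Optional[CriterionAssignment]:
    """Absent/extremely rare in gnomAD exomes (global)."""
    freq = ann.freq_gnomad_exome_all or 0.0
    cutoff = 1e-4 if ann.inheritance == "AR" else 1e-5
    if freq < cutoff:
        return CriterionAssignment(
            "PM2",
            rationale=f"gnomAD exome global {freq:g} < {cutoff:g} "
            f"({ann.inheritance or 'unknown'} inheritance)",
        )
    return None


def evaluate_pp3(ann: AnnotationBundle) -> Optional[CriterionAssignment]:
    """Concordant in-silico support: SIFT D, PolyPhen2-HVAR D/P, CADD > 20."""
    if ann.sift != "D":
        return None
    if ann.polyphen2_hvar not in ("D", "P"):
        return None
    if ann.cadd_phred is None or ann.cadd_phred <= 20:
        return None
    return CriterionAssignment(
        "PP3",
        rationale=f"SIFT D, PolyPhen2-HVAR {ann.polyphen2_hvar}, CADD {ann.cadd_phred}",
    )


_CLINVAR_PATHOGENIC = {
    "p",
    "lp",
    "pathogenic",
    "likely pathogenic",
    "likely_pathogenic",
    "pathogenic/likely pathogenic",
    "pathogenic/likely_pathogenic",
}


def evaluate_reputable_source(ann: AnnotationBundle) -> Optional[CriterionAssignment]:
    """PP5: pathogenic assertion from a reputable source."""
    sig = (ann.clinvar_significance or "").strip().lower()
    if sig in _CLINVAR_PATHOGENIC and (ann.clinvar_stars or 0) >= 1:
        return CriterionAssignment(
            "PP5",
            rationale=f"ClinVar {ann.clinvar_significance} "
            f"({ann.clinvar_stars} star review)",
        )
    if ann.hgmd_class == "DM_high":
        return CriterionAssignment("PP5", rationale="HGMD DM (high confidence)")
    return None


def evaluate_pm1(ann: AnnotationBundle) -> Optional[CriterionAssignment]:
    """Mutational hotspot / benign-variation-free functional domain."""
    if ann.hotspot_domain:
        return CriterionAssignment(
            "PM1", rationale=f"hotspot/critical domain {ann.domain_name or ''}".strip()
        )
    return None


def _count_pathogenic(criteria: Iterable[CriterionAssignment]) -> dict[str, int]:
    counts = {"very_strong": 0, "strong": 0, "moderate": 0, "supporting": 0}
    for c in criteria:
        if not is_benign_code(c.code):
            counts[c.strength] += 1
    return counts


def _count_benign(criteria: Iterable[CriterionAssignment]) -> dict[str, int]:
    counts = {"stand_alone": 0, "strong": 0, "supporting": 0}
    for c in criteria:
        if is_benign_code(c.code):
            counts[c.strength] += 1
    return counts


def combine_criteria(criteria: Iterable[CriterionAssignment]) -> str:
    """Combine fired criteria into the five-class verdict.

    Implements the standard combining rules over effective strengths.
    When both a pathogenic-side and a benign-side rule are satisfied the
    evidence is contradictory and the verdict is VUS.
    """
    criteria = list(criteria)
    for c in criteria:
        if c.strength not in STRENGTHS:
            raise ValueError(f"unknown strength token {c.strength!r}")
    pc = _count_pathogenic(criteria)
    vs, s, m, p = pc["very_strong"], pc["strong"], pc["moderate"], pc["supporting"]

    pathogenic = (
        (vs >= 1 and (s >= 1 or m >= 2 or (m == 1 and p >= 1) or p >= 2))
        or s >= 2
        or (s == 1 and (m >= 3 or (m == 2 and p >= 2) or (m == 1 and p >= 4)))
    )
    likely_pathogenic = (
        (vs >= 1 and m == 1)
        or (s == 1 and 1 <= m <= 2)
        or (s == 1 and p >= 2)
        or m >= 3
        or (m == 2 and p >= 2)
        or (m == 1 and p >= 4)
    )

    bc = _count_benign(criteria)
    benign = bc["stand_alone"] >= 1 or bc["strong"] >= 2
    likely_benign = (bc["strong"] == 1 and bc["supporting"] >= 1) or bc["supporting"] >= 2

    path_verdict = "P" if pathogenic else ("LP" if likely_pathogenic else None)
    benign_verdict = "B" if benign else ("LB" if likely_benign else None)
    if path_verdict and benign_verdict:
        return "VUS"  # conflicting evidence
    return path_verdict or benign_verdict or "VUS"


def classify_germline_variant(
    av: AnnotatedVariant,
    lof_genes: Optional[set[str]] = None,
    inheritance_overrides: Optional[dict[str, str]] = None,
) -> GermlineClassification:
    """Run all evaluators on a germline-candidate variant and combine.

    ``lof_genes``: genes whose disease mechanism is loss of function
    (PVS1 eligibility); ``None`` means all genes are eligible.
    ``inheritance_overrides``: per-gene inheritance mode from the panel
    file, used when the annotation row leaves inheritance unknown.
    """
    if av.origin not in (
        Origin.PRESUMED_GERMLINE,
        Origin.POTENTIAL_GERMLINE,
        Origin.DUAL,
    ):
        raise ValueError(
            f"germline classification requires a germline-candidate origin, "
            f"got {av.origin.value}"
        )
    ann = av.annotation
    if (
        inheritance_overrides
        and ann.inheritance == "unknown"
        and ann.gene in inheritance_overrides
    ):
        ann = AnnotationBundle(**{**ann.__dict__, "inheritance": inheritance_overrides[ann.gene]})
    lof = True if lof_genes is None else ann.gene in lof_genes
    fired = [
        c
        for c in (
            evaluate_pvs1(ann, lof_mechanism=lof),
            evaluate_pm1(ann),
            evaluate_pm2(ann),
            evaluate_pp3(ann),
            evaluate_reputable_source(ann),
        )
        if c is not None
    ]
    return GermlineClassification(verdict=combine_criteria(fired), criteria=fired)
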