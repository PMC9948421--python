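"""AMP/ASCO/CAP somatic tier assignment and reportable-variant selection.

Evidence is consumed from a user-supplied table (gene, optional
protein-change pattern, evidence token) rather than a live knowledge
base, keeping runs reproducible offline.  Tier mapping:
guideline/FDA-level evidence -> tier I; clinical trials or strong
studies -> tier II; no or unknown evidence -> tier III; benign-like
population frequency or explicit benign evidence -> tier IV.  Tiers
I-III are reportable.
"""
from __future__ import annotations

import fnmatch
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd

from .filters import CascadeConfig
from .types import AnnotatedVariant, Origin

EVIDENCE_LEVELS = (
    "fda_guideline",
    "clinical_trial_or_strong_study",
    "unknown_significance",
    "benign_or_likely_benign",
)

_EVIDENCE_TIER = {
    "fda_guideline": "I",
    "clinical_trial_or_strong_study": "II",
    "unknown_significance": "III",
    "benign_or_likely_benign": "IV",
}


@dataclass(frozen=True)
class EvidenceEntry:
    gene: str
    pattern: Optional[str]  # fnmatch pattern on hgvs_p, None = whole gene
    evidence: str

    def __post_init__(self) -> None:
        if self.evidence not in EVIDENCE_LEVELS:
            raise ValueError(
                f"unknown evidence token {self.evidence!r}; allowed: {EVIDENCE_LEVELS}"
            )


@dataclass(frozen=True)
class SomaticTier:
    tier: str  # I / II / III / IV
    evidence: str
    rationale: str = ""


def read_evidence_table(path: str | Path) -> list[EvidenceEntry]:
    df = pd.read_csv(path, sep="\t", dtype=str, na_values=[".", ""], keep_default_na=False)
    entries = []
    for row in df.itertuples(index=False):
        pattern = getattr(row, "pattern", None)
        if isinstance(pattern, float) or pattern in (None, ""):
            pattern = None
        entries.append(EvidenceEntry(gene=row.gene, pattern=pattern, evidence=row.evidence))
    return entries


def assign_tier(
    av: AnnotatedVariant,
    evidence_table: Sequence[EvidenceEntry],
    cfg: Optional[CascadeConfig] = None,
) -> SomaticTier:
    """Assign an AMP/ASCO/CAP tier to a somatic (or dual) variant.

    A variant-level pattern match beats a gene-level entry.  Without any
    entry the variant defaults to tier III unless its population
    frequency is benign-like (any MAF at or above the common-polymorphism
    threshold), which demotes it to tier IV.
    """
    if av.origin not in (Origin.SOMATIC, Origin.DUAL):
        raise ValueError(f"tiering requires somatic/dual origin, got {av.origin.value}")
    cfg = cfg or CascadeConfig()
    ann = av.annotation

    match: Optional[EvidenceEntry] = None
    for entry in evidence_table:
        if entry.gene != ann.gene:
            continue
        if entry.pattern is not None:
            if ann.hgvs_p and fnmatch.fnmatch(ann.hgvs_p, entry.pattern):
                match = entry
                break  # variant-level match is most specific
        elif match is None:
            match = entry

    benign_like = ann.max_population_frequency() >= cfg.common_maf_threshold
    if match is not None and match.evidence in (
        "fda_guideline",
        "clinical_trial_or_strong_study",
        "benign_or_likely_benign",
    ):
        tier = _EVIDENCE_TIER[match.evidence]
        return SomaticTier(tier, match.evidence, f"evidence entry for {match.gene}")
    if benign_like:
        return SomaticTier(
            "IV",
            "benign_or_likely_benign",
            f"population MAF {ann.max_population_frequency():.4g} benign-like",
        )
    return SomaticTier("III", "unknown_significance", "no clinical evidence entry")


def select_reportable(
    variants: Iterable[tuple[AnnotatedVariant, SomaticTier]],
) -> list[tuple[AnnotatedVariant, SomaticTier]]:
    """Keep tier I-III variants, drop tier IV; order preserved."""
    return [(av, t) for av, t in variants if t.tier in ("I", "II", "III")]
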