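"""Curated worked examples: deleterious germline predisposition variants.

Seven presumed/potential germline variants in cancer predisposition
genes observed across a 53-patient T-MN cohort, reconstructed from their
reported annotation fields (consequence, NMD prediction, gnomAD exome
frequency, inheritance mode, ClinVar/HGMD status).  They anchor the
classification engine: each must reproduce its expected verdict and
criterion set exactly, and counting pathogenic/likely-pathogenic
carriers against the 53-patient denominator gives the 13.2% germline
carrier rate.
"""
from __future__ import annotations

from dataclasses import dataclass

from .types import AnnotationBundle

#: Number of patients in the reference cohort the examples come from.
COHORT_SIZE = 53


@dataclass(frozen=True)
class GermlineExample:
    patient_id: str
    vaf: float
    depth: int
    annotation: AnnotationBundle
    expected_verdict: str
    expected_criteria: str  # "+"-joined token string


GERMLINE_EXAMPLES: tuple[GermlineExample, ...] = (
    GermlineExample(
        patient_id="tmn01",
        vaf=0.55,
        depth=164,
        annotation=AnnotationBundle(
            gene="BRIP1",
            transcript="NM_032043.3",
            hgvs_c="c.1794+1G>A",
            consequence="canonical_splice",
            nmd_predicted="unknown",
            inheritance="AR",
            freq_gnomad_exome_all=0.00000796,
            freq_gnomad_exome_eas=0.000109,
            clinvar_significance="likely_pathogenic",
            clinvar_stars=2,
            hgmd_class="none",
        ),
        expected_verdict="P",
        expected_criteria="PVS1 + PM2 + PP5",
    ),
    GermlineExample(
        patient_id="tmn12",
        vaf=0.68,
        depth=81,
        annotation=AnnotationBundle(
            gene="NF1",
            transcript="NM_000267.3",
            hgvs_c="c.1595T>G",
            hgvs_p="p.Leu532Arg",
            consequence="missense",
            inheritance="AD",
            freq_gnomad_exome_all=0.0,
            freq_gnomad_exome_eas=0.0,
            clinvar_significance="pathogenic",
            clinvar_stars=1,
            hgmd_class="DM_high",
            sift="D",
            polyphen2_hvar="D",
            cadd_phred=26.1,
            hotspot_domain=True,
        ),
        expected_verdict="LP",
        expected_criteria="PM1 + PM2 + PP3 + PP5",
    ),
    GermlineExample(
        patient_id="tmn30",
        vaf=0.35,
        depth=17,
        annotation=AnnotationBundle(
            gene="CEBPA",
            transcript="NM_004364.4",
            hgvs_c="c.801_802delCG",
            hgvs_p="p.Gly268fs",
            consequence="frameshift",
            nmd_predicted="no",
            inheritance="AD",
            freq_gnomad_exome_all=0.0,
            freq_gnomad_exome_eas=0.0,
        ),
        expected_verdict="LP",
        expected_criteria="PVS1_Strong + PM2",
    ),
    GermlineExample(
        patient_id="tmn36",
        vaf=0.44,
        depth=296,
        annotation=AnnotationBundle(
            gene="FANCM",
            transcript="NM_020937.4",
            hgvs_c="c.1972C>T",
            hgvs_p="p.Arg658*",
            consequence="nonsense",
            nmd_predicted="yes",
            inheritance="AR",
            freq_gnomad_exome_all=0.0000757,
            freq_gnomad_exome_eas=0.0,
            clinvar_significance="conflicting interpretations of pathogenicity",
            clinvar_stars=1,
            hgmd_class="DM_high",
        ),
        expected_verdict="P",
        expected_criteria="PVS1 + PM2 + PP5",
    ),
    GermlineExample(
        patient_id="tmn40",
        vaf=0.50,
        depth=111,
        annotation=AnnotationBundle(
            gene="DDX41",
            transcript="NM_016222.4",
            hgvs_c="c.308_309delAG",
            hgvs_p="p.Glu103fs",
            consequence="frameshift",
            nmd_predicted="yes",
            inheritance="AD",
            freq_gnomad_exome_all=0.0,
            freq_gnomad_exome_eas=0.0,
        ),
        expected_verdict="LP",
        expected_criteria="PVS1 + PM2",
    ),
    GermlineExample(
        patient_id="tmn49",
        vaf=0.46,
        depth=426,
        annotation=AnnotationBundle(
            gene="RUNX1",
            transcript="NM_001754.4",
            hgvs_c="c.39C>G",
            hgvs_p="p.Tyr13*",
            consequence="nonsense",
            nmd_predicted="yes",
            inheritance="AD",
            freq_gnomad_exome_all=0.0,
            freq_gnomad_exome_eas=0.0,
        ),
        expected_verdict="LP",
        expected_criteria="PVS1 + PM2",
    ),
    GermlineExample(
        patient_id="tmn52",
        vaf=0.54,
        depth=162,
        annotation=AnnotationBundle(
            gene="NBN",
            transcript="NM_002485.4",
            hgvs_c="c.2206G>T",
            hgvs_p="p.Glu736*",
            consequence="nonsense",
            nmd_predicted="no",
            inheritance="AR",
            freq_gnomad_exome_all=0.000004,
            freq_gnomad_exome_eas=0.0000544,
            clinvar_significance="uncertain significance",
            clinvar_stars=2,
            hgmd_class="DM_low",
        ),
        expected_verdict="LP",
        expected_criteria="PVS1_Strong + PM2",
    ),
)
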