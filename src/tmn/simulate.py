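"""Synthetic T-MN cohort generator.

Generates fully labelled cohorts — clinical records, per-caller variant
calls with annotations, matched non-malignant samples, and survival
times — with the statistical structure the downstream analysis assumes:

* 53 patients (7 pediatric), configured cohort prevalences for sex,
  subtype, therapy exposures and cytogenetic flags, with -5/del(5q)
  and -7/del(7q) drawn jointly under a configurable odds ratio;
* a fixed germline-carrier fraction (13.2% by default) whose carriers
  receive one deleterious predisposition variant patterned after the
  curated worked examples (null variant or hotspot missense with a
  PM2-compatible frequency), heterozygous VAF centred at 0.5, mirrored
  into the matched non-malignant sample when one exists;
* a TP53-dominant somatic spectrum with per-sample counts of median 2-3
  (range 0-7), pediatric samples carrying fewer variants than adults;
* injected technical noise: strand-biased calls, common polymorphisms,
  panel-of-normals-recurrent calls, and single-caller calls that fail
  consensus — every call carries its ground-truth label;
* survival times from an exponential baseline scaled by the configured
  per-covariate hazard ratios, with independent exponential censoring
  calibrated to the configured censored fraction.

The gene rosters and category map bundled here are synthetic stand-ins
for proprietary panel designs: realistic cancer-predisposition and
myeloid-neoplasm gene lists, not any published panel's exact contents.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .types import AnnotatedVariant, AnnotationBundle, PatientRecord, VariantCall, VariantKey
from .variant_io import consensus_merge

CALLERS = ("gatk", "snver", "lofreq")

#: Germline panel: gene -> (inheritance, LOF-mechanism flag).
GERMLINE_PANEL: dict[str, tuple[str, bool]] = {
    "ANKRD26": ("AD", True), "ATM": ("AR", True), "BARD1": ("AD", True),
    "BLM": ("AR", True), "BRCA1": ("AD", True), "BRCA2": ("AD", True),
    "BRIP1": ("AR", True), "CEBPA": ("AD", True), "CHEK2": ("AD", True),
    "DDX41": ("AD", True), "ETV6": ("AD", True), "FANCA": ("AR", True),
    "FANCC": ("AR", True), "FANCD2": ("AR", True), "FANCM": ("AR", True),
    "GATA2": ("AD", True), "MLH1": ("AD", True), "MPL": ("AR", False),
    "MSH2": ("AD", True), "NBN": ("AR", True), "NF1": ("AD", True),
    "PALB2": ("AD", True), "RUNX1": ("AD", True), "SAMD9": ("AD", False),
    "SAMD9L": ("AD", False), "SBDS": ("AR", True), "TERC": ("AD", True),
    "TERT": ("AD", True), "TP53": ("AD", True), "WRN": ("AR", True),
}

SOMATIC_PANEL: tuple[str, ...] = (
    "TP53", "KMT2C", "RUNX1", "DNMT3A", "KMT2D", "ARID1B", "ASXL1", "CBL",
    "DIS3", "TET2", "SRSF2", "SF3B1", "U2AF1", "ZRSR2", "EZH2", "NRAS",
    "KRAS", "PTPN11", "FLT3", "NPM1", "IDH1", "IDH2", "JAK2", "STAG2",
    "SMC3", "RAD21", "SMC1A", "GATA2", "CEBPA", "NF1", "ETV6", "WT1",
    "PHF6", "BCOR", "BCORL1", "SETBP1", "CUX1", "KIT", "MPL", "CSF3R",
    "ATM", "CDKN2A",
)

#: Functional categories for the somatic roster (seven named categories
#: plus explicit "other" for the remainder).
CATEGORY_MAP: dict[str, str] = {
    **dict.fromkeys(
        ["KMT2C", "KMT2D", "ARID1B", "ASXL1", "EZH2", "TET2", "DNMT3A",
         "BCOR", "BCORL1", "PHF6"],
        "chromatin modification",
    ),
    **dict.fromkeys(
        ["TP53", "RUNX1", "CEBPA", "GATA2", "ETV6", "WT1", "CUX1", "SETBP1"],
        "transcription factor",
    ),
    **dict.fromkeys(["NRAS", "KRAS", "PTPN11", "CBL", "NF1"], "RAS pathway"),
    **dict.fromkeys(["FLT3", "KIT", "JAK2", "MPL", "CSF3R"], "receptor/kinase"),
    **dict.fromkeys(["ATM", "CDKN2A"], "DNA repair/cell cycle"),
    **dict.fromkeys(["SRSF2", "SF3B1", "U2AF1", "ZRSR2"], "splicing factor"),
    **dict.fromkeys(["STAG2", "SMC3", "RAD21", "SMC1A"], "cohesin"),
    **dict.fromkeys(["DIS3", "NPM1", "IDH1", "IDH2"], "other"),
}

#: TP53-dominant somatic gene sampling weights (renormalized at use).
GENE_WEIGHTS: dict[str, float] = {
    "TP53": 0.16, "KMT2C": 0.07, "RUNX1": 0.065, "DNMT3A": 0.06,
    "KMT2D": 0.055, "ARID1B": 0.05, "ASXL1": 0.05, "CBL": 0.045,
    "DIS3": 0.04, "TET2": 0.04,
}
_REST = [g for g in SOMATIC_PANEL if g not in GENE_WEIGHTS]
GENE_WEIGHTS.update(dict.fromkeys(_REST, (1.0 - sum(GENE_WEIGHTS.values())) / len(_REST)))

#: Pseudo-loci: deterministic chrom/base-position per gene.
_ALL_GENES = sorted(set(GERMLINE_PANEL) | set(SOMATIC_PANEL))
GENE_LOCI: dict[str, tuple[str, int]] = {
    g: (str((i % 22) + 1), 1_000_000 + 50_000 * i) for i, g in enumerate(_ALL_GENES)
}

_BASES = ("A", "C", "G", "T")


@dataclass
class SimulationConfig:
    """Generator defaults are the study conditions of the cohort being
    emulated: 53 patients, 7 pediatric, 20 matched normals, 4 longitudinal
    pairs, the reference cohort's clinical prevalences, a 13.2% germline
    carrier rate, and its multivariate hazard ratios as survival truth."""

    n_patients: int = 53
    n_pediatric: int = 7
    n_matched_normals: int = 20
    n_longitudinal: int = 4
    prevalences: dict[str, float] = field(
        default_factory=lambda: {
            "male": 0.528,
            "del5q": 0.283,
            "del7q": 0.434,
            "del17p": 0.094,
            "complex_karyotype": 0.472,
            "pml_rara": 0.075,
            "kmt2a_r": 0.075,
            "runx1_r": 0.019,
            "mecom_r": 0.057,
            "not_assessed": 0.038,
            "subtype_MDS": 0.528,
            "subtype_MDS_MPN": 0.019,
            "subtype_AML": 0.453,
            "radiotherapy": 0.34,
            "alkylating": 0.849,
            "topoII": 0.679,
            "antimetabolite": 0.17,
            "antitubulin": 0.472,
            "auto_pbsct": 0.17,
            "allo_pbsct": 0.057,
        }
    )
    del5q_del7q_odds_ratio: float = 6.0
    germline_carrier_rate: float = 0.132
    # Somatic count law: zero-inflated, shifted Poisson truncated at 7 for
    # adults (median 3); truncated Poisson for pediatric samples (median 2,
    # range 0-2).
    somatic_zero_inflation: float = 0.094
    somatic_poisson_adult: float = 2.2
    somatic_poisson_pediatric: float = 1.7
    somatic_count_max: int = 7
    pediatric_count_max: int = 2
    gene_weights: dict[str, float] = field(default_factory=lambda: dict(GENE_WEIGHTS))
    # Expected injected artifacts per sample, by class.
    strand_bias_rate: float = 0.4
    common_polymorphism_rate: float = 0.4
    pon_artifact_rate: float = 0.3
    caller_noise_rate: float = 0.4
    true_hazard_ratios: dict[str, float] = field(
        default_factory=lambda: {
            "male": 2.99,
            "radiotherapy": 4.80,
            "therapy_gt_cut": 3.75,
            "age_gt_cut": 10.79,
            "del5q": 3.99,
        }
    )
    covariate_prevalences: dict[str, float] = field(
        default_factory=lambda: {
            "male": 0.528,
            "radiotherapy": 0.34,
            "therapy_gt_cut": 0.55,
            "age_gt_cut": 0.62,
            "del5q": 0.283,
        }
    )
    age_cut_years: float = 50.0
    therapy_cut_months: float = 15.8
    # Baseline rate calibrated so the median observed OS under the default
    # covariate prevalences and hazard ratios is ~10.6 months.
    baseline_hazard: float = 0.0011  # events per month at covariates = 0
    censoring_fraction: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        for name, v in self.prevalences.items():
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"prevalence {name}={v} outside [0, 1]")
        if not 0.0 <= self.germline_carrier_rate <= 1.0:
            raise ValueError("germline_carrier_rate outside [0, 1]")
        if not 0.0 <= self.censoring_fraction < 1.0:
            raise ValueError("censoring_fraction outside [0, 1)")
        if self.del5q_del7q_odds_ratio <= 0:
            raise ValueError("odds ratio must be positive")


def _joint_bernoulli_probs(p1: float, p2: float, odds_ratio: float) -> float:
    """Joint P(X=1, Y=1) for given marginals and odds ratio."""
    if odds_ratio == 1.0:
        p11 = p1 * p2
    else:
        a = odds_ratio - 1.0
        b = -((p1 + p2) * a + 1.0)
        c = odds_ratio * p1 * p2
        disc = b * b - 4 * a * c
        if disc < 0:
            raise ValueError("infeasible odds ratio / marginal combination")
        p11 = (-b - np.sqrt(disc)) / (2 * a)
    lo, hi = max(0.0, p1 + p2 - 1.0), min(p1, p2)
    if not lo - 1e-9 <= p11 <= hi + 1e-9:
        raise ValueError("infeasible odds ratio / marginal combination")
    return float(np.clip(p11, lo, hi))


def simulate_patients(cfg: SimulationConfig, rng: Optional[np.random.Generator] = None) -> list[PatientRecord]:
    """Draw the clinical cohort (survival fields filled separately)."""
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    pv = cfg.prevalences
    n = cfg.n_patients
    patients: list[PatientRecord] = []
    pediatric_ids = set(rng.choice(n, size=min(cfg.n_pediatric, n), replace=False))
    p11 = _joint_bernoulli_probs(pv["del5q"], pv["del7q"], cfg.del5q_del7q_odds_ratio)
    subtype_p = np.array([pv["subtype_MDS"], pv["subtype_MDS_MPN"], pv["subtype_AML"]])
    subtype_p = subtype_p / subtype_p.sum()
    for i in range(n):
        pid = f"tmn{i + 1:02d}"
        pediatric = i in pediatric_ids
        if pediatric:
            age = float(rng.uniform(1.5, 19.5))
        else:
            age = float(np.clip(rng.normal(58.0, 13.0), 20.7, 82.4))
        u = rng.uniform()
        if u < p11:
            del5q, del7q = True, True
        elif u < pv["del5q"]:
            del5q, del7q = True, False
        elif u < pv["del5q"] + pv["del7q"] - p11:
            del5q, del7q = False, True
        else:
            del5q, del7q = False, False
        flags = {
            "del5q": del5q,
            "del7q": del7q,
            "del17p": rng.uniform() < pv["del17p"],
            "complex_karyotype": rng.uniform() < pv["complex_karyotype"],
            "pml_rara": rng.uniform() < pv["pml_rara"],
            "kmt2a_r": rng.uniform() < pv["kmt2a_r"],
            "runx1_r": rng.uniform() < pv["runx1_r"],
            "mecom_r": rng.uniform() < pv["mecom_r"],
        }
        not_assessed = rng.uniform() < pv["not_assessed"]
        if not_assessed:
            flags = dict.fromkeys(flags, False)
        normal_kt = not not_assessed and not any(flags.values())
        subtype = ("MDS", "MDS_MPN", "AML")[rng.choice(3, p=subtype_p)]
        patients.append(
            PatientRecord(
                patient_id=pid,
                age_years=round(age, 1),
                sex="M" if rng.uniform() < pv["male"] else "F",
                subtype=subtype,
                chemo=True,
                radiotherapy=rng.uniform() < pv["radiotherapy"],
                alkylating=rng.uniform() < pv["alkylating"],
                topoII=rng.uniform() < pv["topoII"],
                antimetabolite=rng.uniform() < pv["antimetabolite"],
                antitubulin=rng.uniform() < pv["antitubulin"],
                auto_pbsct=rng.uniform() < pv["auto_pbsct"],
                allo_pbsct=rng.uniform() < pv["allo_pbsct"],
                therapy_duration_months=round(
                    float(np.clip(rng.lognormal(np.log(18.6), 0.9), 1.2, 122.8)), 1
                ),
                latency_months=round(
                    float(np.clip(rng.lognormal(np.log(52.0), 0.8), 12.0, 309.7)), 1
                ),
                **flags,
                normal_karyotype=normal_kt,
                not_assessed=not_assessed,
            )
        )
    return patients


def patient_covariates(patients: Sequence[PatientRecord], cfg: SimulationConfig) -> pd.DataFrame:
    """The five prognostic indicator covariates from clinical records."""
    return pd.DataFrame(
        {
            "male": [int(p.sex == "M") for p in patients],
            "radiotherapy": [int(p.radiotherapy) for p in patients],
            "therapy_gt_cut": [
                int(p.therapy_duration_months > cfg.therapy_cut_months) for p in patients
            ],
            "age_gt_cut": [int(p.age_years > cfg.age_cut_years) for p in patients],
            "del5q": [int(p.del5q) for p in patients],
        },
        index=[p.patient_id for p in patients],
    )


def draw_survival_covariates(
    n: int, cfg: SimulationConfig, rng: np.random.Generator
) -> pd.DataFrame:
    """Independent Bernoulli covariates at the configured prevalences
    (for large-n estimator-recovery experiments)."""
    return pd.DataFrame(
        {k: (rng.uniform(size=n) < p).astype(int) for k, p in cfg.covariate_prevalences.items()}
    )


def simulate_survival(
    cfg: SimulationConfig,
    covariates: pd.DataFrame,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Event/censoring times under the proportional-hazards model.

    Event times are exponential with rate ``baseline_hazard *
    exp(sum_k log(HR_k) x_k)``.  Censoring times are independent
    exponentials whose rate is solved so the expected censored fraction
    equals ``censoring_fraction``.  Times are reported in months rounded
    to 0.1 (minimum 0.1).
    """
    beta = np.array([np.log(cfg.true_hazard_ratios[c]) for c in covariates.columns])
    lam = cfg.baseline_hazard * np.exp(covariates.to_numpy(dtype=float) @ beta)
    t_event = rng.exponential(1.0 / lam)
    if cfg.censoring_fraction > 0:
        target = cfg.censoring_fraction

        def censored_fraction(theta: float) -> float:
            return float(np.mean(theta / (theta + lam))) - target

        theta = brentq(censored_fraction, 1e-9 * lam.min(), 1e6 * lam.max())
        t_cens = rng.exponential(1.0 / theta, size=len(lam))
        observed = np.minimum(t_event, t_cens)
        death = t_event <= t_cens
    else:
        observed, death = t_event, np.ones(len(lam), dtype=bool)
    observed = np.maximum(np.round(observed, 1), 0.1)
    return observed, death


@dataclass
class SimulatedCall:
    """One generated call with its ground truth.

    ``truth`` is one of germline / somatic / artifact; ``truth_detail``
    names the archetype (e.g. strand_bias, common_polymorphism,
    single_caller).  ``boundary`` marks calls generated near a filter
    threshold, for which origin recovery is not expected.
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
    alt_forward: int
    alt_reverse: int
    callers: tuple[str, ...]
    gene: str
    truth: str
    truth_detail: str
    boundary: bool

    @property
    def key(self) -> VariantKey:
        return (self.chrom, self.pos, self.ref, self.alt)

    def to_variant_call(self) -> VariantCall:
        return VariantCall(
            sample_id=self.sample_id,
            patient_id=self.patient_id,
            sample_role=self.sample_role,
            chrom=self.chrom,
            pos=self.pos,
            ref=self.ref,
            alt=self.alt,
            vaf=self.vaf,
            depth=self.depth,
            alt_forward=self.alt_forward,
            alt_reverse=self.alt_reverse,
            callers=frozenset(self.callers),
        )


@dataclass
class SimulatedCohort:
    config: SimulationConfig
    patients: list[PatientRecord]
    calls: list[SimulatedCall]
    annotations: dict[VariantKey, AnnotationBundle]
    pon: dict[VariantKey, float]
    germline_panel: dict[str, tuple[str, bool]]
    somatic_panel: tuple[str, ...]
    category_map: dict[str, str]
    carriers: set[str]
    matched_normal_patients: set[str]
    longitudinal_patients: set[str]

    def tumor_samples(self) -> list[str]:
        return sorted({c.sample_id for c in self.calls if c.sample_role != "non_malignant"})

    def normals_by_patient(self) -> dict[str, list[VariantCall]]:
        out: dict[str, list[VariantCall]] = {p: [] for p in self.matched_normal_patients}
        for c in self.calls:
            if c.sample_role == "non_malignant":
                out.setdefault(c.patient_id, []).append(c.to_variant_call())
        return out

    def callsets_for_sample(self, sample_id: str) -> list[tuple[str, list[VariantCall]]]:
        sets: dict[str, list[VariantCall]] = {c: [] for c in CALLERS}
        for call in self.calls:
            if call.sample_id != sample_id:
                continue
            for caller in call.callers:
                vc = call.to_variant_call()
                vc.callers = frozenset({caller})
                sets[caller].append(vc)
        return [(c, sets[c]) for c in CALLERS]

    def consensus_annotated(
        self, min_callers: int = 2, primary_caller: Optional[str] = None
    ) -> list[AnnotatedVariant]:
        """Consensus-merge tumor samples and join annotations/panels."""
        out: list[AnnotatedVariant] = []
        germline_genes = set(self.germline_panel)
        somatic_genes = set(self.somatic_panel)
        for sample in self.tumor_samples():
            merged = consensus_merge(
                self.callsets_for_sample(sample), min_callers=min_callers,
                primary_caller=primary_caller,
            )
            for vc in merged:
                ann = self.annotations[vc.key]
                out.append(
                    AnnotatedVariant(
                        call=vc,
                        annotation=ann,
                        in_germline_panel=ann.gene in germline_genes,
                        in_somatic_panel=ann.gene in somatic_genes,
                    )
                )
        return out

    def truth_by_key(self) -> dict[tuple[str, VariantKey], SimulatedCall]:
        return {(c.sample_id, c.key): c for c in self.calls}


def _draw_depth(rng: np.random.Generator) -> int:
    return int(np.clip(rng.normal(200, 45), 50, 500))


def _balanced_strands(alt_total: int, rng: np.random.Generator) -> tuple[int, int]:
    """Strand split for a genuine variant, kept away from the bias cut."""
    if alt_total == 0:
        return 0, 0
    fwd = int(rng.binomial(alt_total, 0.5))
    minority = min(fwd, alt_total - fwd)
    if alt_total >= 2 and minority / alt_total <= 0.25:
        fwd = int(np.ceil(alt_total * 0.35))
    return fwd, alt_total - fwd


class _LocusAllocator:
    """Hands out unique positions per gene so variant keys never collide."""

    def __init__(self) -> None:
        self._used: dict[str, int] = {}

    def next_pos(self, gene: str, rng: np.random.Generator) -> tuple[str, int]:
        chrom, base = GENE_LOCI[gene]
        offset = self._used.get(gene, 0) + int(rng.integers(1, 20))
        self._used[gene] = offset
        return chrom, base + offset


def _snv_alleles(rng: np.random.Generator) -> tuple[str, str]:
    ref = _BASES[rng.integers(4)]
    alt = _BASES[rng.integers(4)]
    while alt == ref:
        alt = _BASES[rng.integers(4)]
    return ref, alt


_GERMLINE_ARCHETYPES = ("nonsense_nmd", "frameshift_no_nmd", "splice", "hotspot_missense")


def _germline_annotation(
    gene: str, archetype: str, rng: np.random.Generator
) -> AnnotationBundle:
    inheritance, _ = GERMLINE_PANEL[gene]
    freq_cut = 1e-4 if inheritance == "AR" else 1e-5
    freq = float(rng.choice([0.0, freq_cut * rng.uniform(0.05, 0.5)]))
    protein_pos = int(rng.integers(20, 900))
    common = dict(
        gene=gene,
        transcript=f"NM_{rng.integers(100000, 999999)}.1",
        inheritance=inheritance,
        freq_gnomad_exome_all=freq,
        freq_gnomad_exome_eas=freq * rng.uniform(0.0, 3.0),
        protein_position=protein_pos,
    )
    if archetype == "nonsense_nmd":
        clinvar = rng.uniform() < 0.5
        return AnnotationBundle(
            consequence="nonsense", nmd_predicted="yes",
            hgvs_p=f"p.Trp{protein_pos}*",
            clinvar_significance="pathogenic" if clinvar else None,
            clinvar_stars=2 if clinvar else None,
            **common,
        )
    if archetype == "frameshift_no_nmd":
        return AnnotationBundle(
            consequence="frameshift", nmd_predicted="no",
            hgvs_p=f"p.Gly{protein_pos}fs", **common,
        )
    if archetype == "splice":
        return AnnotationBundle(
            consequence="canonical_splice", nmd_predicted="unknown",
            hgvs_c=f"c.{protein_pos * 3}+1G>A", **common,
        )
    return AnnotationBundle(
        consequence="missense", hgvs_p=f"p.Leu{protein_pos}Arg",
        sift="D", polyphen2_hvar="D", cadd_phred=float(rng.uniform(22, 35)),
        hotspot_domain=True, hgmd_class="DM_high",
        **common,
    )


def _somatic_annotation(gene: str, rng: np.random.Generator) -> AnnotationBundle:
    protein_pos = int(rng.integers(20, 900))
    consequence = str(rng.choice(
        ["missense", "nonsense", "frameshift", "inframe_indel"], p=[0.6, 0.2, 0.15, 0.05]
    ))
    return AnnotationBundle(
        gene=gene,
        consequence=consequence,
        nmd_predicted="unknown",
        hgvs_p=f"p.Arg{protein_pos}{'Trp' if consequence == 'missense' else '*'}",
        freq_gnomad_exome_all=0.0,
        cosmic_present=bool(rng.uniform() < 0.6),
        sift=str(rng.choice(["D", "T", "missing"])),
        polyphen2_hvar=str(rng.choice(["D", "P", "B", "missing"])),
        cadd_phred=float(rng.uniform(5, 35)),
        protein_position=protein_pos,
        domain_name="DNA-binding domain" if gene == "TP53" else None,
    )


def _polymorphism_annotation(gene: str, rng: np.random.Generator) -> AnnotationBundle:
    maf = float(rng.uniform(0.02, 0.3))
    return AnnotationBundle(
        gene=gene,
        consequence="missense",
        freq_gnomad_exome_all=maf,
        freq_gnomad_exome_eas=min(maf * rng.uniform(0.5, 2.0), 1.0),
        freq_kova=min(maf * rng.uniform(0.5, 2.0), 1.0),
        freq_krgdb=min(maf * rng.uniform(0.5, 2.0), 1.0),
        sift="T",
        polyphen2_hvar="B",
    )


def simulate_variants(
    cfg: SimulationConfig,
    patients: Sequence[PatientRecord],
    rng: Optional[np.random.Generator] = None,
) -> SimulatedCohort:
    """Generate all calls, annotations, and noise for a cohort."""
    rng = rng if rng is not None else np.random.default_rng(cfg.seed + 1)
    n = len(patients)
    ids = [p.patient_id for p in patients]
    n_carriers = int(round(cfg.germline_carrier_rate * n))
    carriers = set(rng.choice(ids, size=min(n_carriers, n), replace=False))
    matched = set(rng.choice(ids, size=min(cfg.n_matched_normals, n), replace=False))
    longitudinal = set(rng.choice(ids, size=min(cfg.n_longitudinal, n), replace=False))

    loci = _LocusAllocator()
    annotations: dict[VariantKey, AnnotationBundle] = {}
    calls: list[SimulatedCall] = []
    genes = list(cfg.gene_weights)
    weights = np.array([cfg.gene_weights[g] for g in genes])
    weights = weights / weights.sum()

    # Shared panel-of-normals sites (recurrent technical artifacts).
    pon: dict[VariantKey, float] = {}
    pon_sites: list[tuple[VariantKey, AnnotationBundle]] = []
    for _ in range(8):
        gene = str(rng.choice(SOMATIC_PANEL))
        chrom, pos = loci.next_pos(gene, rng)
        ref, alt = _snv_alleles(rng)
        key = (chrom, pos, ref, alt)
        ann = _somatic_annotation(gene, rng)
        annotations[key] = ann
        pon[key] = float(rng.uniform(0.08, 0.5))  # above the default 5% cut
        pon_sites.append((key, ann))

    def pick_callers(k_min: int = 2) -> tuple[str, ...]:
        k = int(rng.integers(k_min, len(CALLERS) + 1))
        return tuple(sorted(rng.choice(CALLERS, size=k, replace=False)))

    def add_call(sample_id, patient_id, role, key, gene, vaf, truth, detail,
                 boundary=False, callers=None, strand_frac=None, depth=None):
        depth = depth if depth is not None else _draw_depth(rng)
        alt_total = min(int(round(vaf * depth)), depth)
        if strand_frac is None:
            fwd, rev = _balanced_strands(alt_total, rng)
        else:
            fwd = int(round(strand_frac * alt_total))
            rev = alt_total - fwd
        calls.append(
            SimulatedCall(
                sample_id=sample_id, patient_id=patient_id, sample_role=role,
                chrom=key[0], pos=key[1], ref=key[2], alt=key[3],
                vaf=float(np.clip(vaf, 0.0, 1.0)), depth=depth,
                alt_forward=fwd, alt_reverse=rev,
                callers=callers if callers is not None else pick_callers(),
                gene=gene, truth=truth, truth_detail=detail, boundary=boundary,
            )
        )

    for patient in patients:
        pid = patient.patient_id
        sample_a = f"{pid}-A"

        # -- germline carrier variant ---------------------------------
        if pid in carriers:
            gene = str(rng.choice(sorted(GERMLINE_PANEL)))
            archetype = str(rng.choice(_GERMLINE_ARCHETYPES))
            # null-variant archetypes only make a deleterious call in genes
            # whose disease mechanism is loss of function
            if not GERMLINE_PANEL[gene][1]:
                archetype = "hotspot_missense"
            chrom, pos = loci.next_pos(gene, rng)
            ref, alt = _snv_alleles(rng)
            key = (chrom, pos, ref, alt)
            annotations[key] = _germline_annotation(gene, archetype, rng)
            vaf = float(rng.beta(40, 40))
            lo, hi = 0.30, 0.70
            boundary = not (lo + 0.02 <= vaf <= hi - 0.02)
            add_call(sample_a, pid, "tmn_initial", key, gene, vaf,
                     "germline", archetype, boundary=boundary)
            if pid in matched:
                add_call(f"{pid}-N", pid, "non_malignant", key, gene,
                         float(rng.beta(40, 40)), "germline", archetype)

        # -- somatic variants -----------------------------------------
        if patient.pediatric:
            count = min(int(rng.poisson(cfg.somatic_poisson_pediatric)),
                        cfg.pediatric_count_max)
        elif rng.uniform() < cfg.somatic_zero_inflation:
            count = 0
        else:
            count = min(1 + int(rng.poisson(cfg.somatic_poisson_adult)),
                        cfg.somatic_count_max)
        somatic_keys: list[tuple[VariantKey, str]] = []
        for _ in range(count):
            gene = genes[rng.choice(len(genes), p=weights)]
            chrom, pos = loci.next_pos(gene, rng)
            ref, alt = _snv_alleles(rng)
            key = (chrom, pos, ref, alt)
            annotations[key] = _somatic_annotation(gene, rng)
            vaf = float(np.clip(rng.beta(2.2, 5.0), 0.03, 0.95))
            boundary = vaf < 0.05
            add_call(sample_a, pid, "tmn_initial", key, gene, vaf,
                     "somatic", "somatic", boundary=boundary)
            somatic_keys.append((key, gene))

        # -- longitudinal progression sample --------------------------
        if pid in longitudinal:
            sample_b = f"{pid}-B"
            for key, gene in somatic_keys:
                if rng.uniform() < 0.7:  # persisting clone
                    vaf = float(np.clip(rng.beta(2.5, 4.0), 0.03, 0.95))
                    add_call(sample_b, pid, "tmn_progression", key, gene, vaf,
                             "somatic", "somatic_persistent", boundary=vaf < 0.05)
            for _ in range(int(rng.integers(1, 3))):  # newly acquired clone
                gene = genes[rng.choice(len(genes), p=weights)]
                chrom, pos = loci.next_pos(gene, rng)
                ref, alt = _snv_alleles(rng)
                key = (chrom, pos, ref, alt)
                annotations[key] = _somatic_annotation(gene, rng)
                vaf = float(np.clip(rng.beta(2.2, 5.0), 0.03, 0.95))
                add_call(sample_b, pid, "tmn_progression", key, gene, vaf,
                         "somatic", "somatic_gained", boundary=vaf < 0.05)

        # -- injected noise -------------------------------------------
        for _ in range(int(rng.poisson(cfg.strand_bias_rate))):
            gene = str(rng.choice(SOMATIC_PANEL))
            chrom, pos = loci.next_pos(gene, rng)
            ref, alt = _snv_alleles(rng)
            key = (chrom, pos, ref, alt)
            annotations[key] = _somatic_annotation(gene, rng)
            frac = float(rng.uniform(0.0, 0.12))
            add_call(sample_a, pid, "tmn_initial", key, gene,
                     float(rng.uniform(0.05, 0.4)), "artifact", "strand_bias",
                     boundary=frac > 0.17, strand_frac=frac)
        somatic_only = sorted(set(SOMATIC_PANEL) - set(GERMLINE_PANEL))
        for _ in range(int(rng.poisson(cfg.common_polymorphism_rate))):
            gene = str(rng.choice(somatic_only))
            chrom, pos = loci.next_pos(gene, rng)
            ref, alt = _snv_alleles(rng)
            key = (chrom, pos, ref, alt)
            annotations[key] = _polymorphism_annotation(gene, rng)
            add_call(sample_a, pid, "tmn_initial", key, gene,
                     float(rng.beta(40, 40)), "artifact", "common_polymorphism")
        for _ in range(int(rng.poisson(cfg.pon_artifact_rate))):
            key, ann = pon_sites[int(rng.integers(len(pon_sites)))]
            if any(c.sample_id == sample_a and c.key == key for c in calls):
                continue
            add_call(sample_a, pid, "tmn_initial", key, ann.gene,
                     float(rng.uniform(0.05, 0.3)), "artifact", "pon_recurrent")
        for _ in range(int(rng.poisson(cfg.caller_noise_rate))):
            gene = str(rng.choice(somatic_only))
            chrom, pos = loci.next_pos(gene, rng)
            ref, alt = _snv_alleles(rng)
            key = (chrom, pos, ref, alt)
            annotations[key] = _somatic_annotation(gene, rng)
            add_call(sample_a, pid, "tmn_initial", key, gene,
                     float(rng.uniform(0.03, 0.2)), "artifact", "single_caller",
                     callers=(str(rng.choice(CALLERS)),))

    return SimulatedCohort(
        config=cfg,
        patients=list(patients),
        calls=calls,
        annotations=annotations,
        pon=pon,
        germline_panel=dict(GERMLINE_PANEL),
        somatic_panel=SOMATIC_PANEL,
        category_map=dict(CATEGORY_MAP),
        carriers=carriers,
        matched_normal_patients=matched,
        longitudinal_patients=longitudinal,
    )


def simulate_cohort(cfg: Optional[SimulationConfig] = None) -> SimulatedCohort:
    """Full cohort: patients, survival, and variant calls, seed-determined."""
    cfg = cfg or SimulationConfig()
    rng = np.random.default_rng(cfg.seed)
    patients = simulate_patients(cfg, rng)
    covs = patient_covariates(patients, cfg)
    times, death = simulate_survival(cfg, covs, rng)
    for p, t, d in zip(patients, times, death):
        p.os_months, p.death = float(t), bool(d)
    cohort = simulate_variants(cfg, patients, rng)
    return cohort


# ---------------------------------------------------------------------------
# on-disk export
# ---------------------------------------------------------------------------

_VCF_HEADER_FIELDS = [
    '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Total read depth">',
    '##FORMAT=<ID=AF,Number=A,Type=Float,Description="Alternate allele fraction">',
    '##FORMAT=<ID=ADF,Number=R,Type=Integer,Description="Forward-strand allele depths">',
    '##FORMAT=<ID=ADR,Number=R,Type=Integer,Description="Reverse-strand allele depths">',
]


def _vcf_header(sample_id: str) -> "pysam.VariantHeader":
    import pysam

    header = pysam.VariantHeader()
    for chrom in [str(c) for c in range(1, 23)] + ["X", "Y"]:
        header.contigs.add(chrom, length=250_000_000)
    for line in _VCF_HEADER_FIELDS:
        header.add_line(line)
    header.add_sample(sample_id)
    return header


def write_cohort(cohort: SimulatedCohort, out_dir: str | Path) -> dict[str, Path]:
    """Write the cohort as the pipeline's on-disk input formats.

    Produces per-sample per-caller VCFs, the annotation TSV, panel and
    PoN files, the clinical table, category map, a toy tiering-evidence
    table, and the ground-truth labels TSV.
    """
    import pysam

    out = Path(out_dir)
    vcf_dir = out / "vcfs"
    vcf_dir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {"vcf_dir": vcf_dir}

    samples = sorted({c.sample_id for c in cohort.calls})
    for sample in samples:
        for caller in CALLERS:
            calls = [
                c for c in cohort.calls if c.sample_id == sample and caller in c.callers
            ]
            path = vcf_dir / f"{sample}.{caller}.vcf"
            header = _vcf_header(sample)
            with pysam.VariantFile(str(path), "w", header=header) as vf:
                for c in sorted(calls, key=lambda x: (int(x.chrom), x.pos, x.alt)):
                    rec = vf.new_record(
                        contig=c.chrom, start=c.pos - 1, stop=c.pos - 1 + len(c.ref),
                        alleles=(c.ref, c.alt),
                    )
                    rec.samples[sample]["DP"] = c.depth
                    rec.samples[sample]["AF"] = (round(c.vaf, 4),)
                    ref_reads = max(c.depth - c.alt_forward - c.alt_reverse, 0)
                    rec.samples[sample]["ADF"] = (ref_reads // 2, c.alt_forward)
                    rec.samples[sample]["ADR"] = (ref_reads - ref_reads // 2, c.alt_reverse)
                    vf.write(rec)

    ann_rows = []
    for key in sorted(cohort.annotations, key=lambda k: (int(k[0]), k[1], k[3])):
        a = cohort.annotations[key]
        ann_rows.append(
            {
                "chrom": key[0], "pos": key[1], "ref": key[2], "alt": key[3],
                "gene": a.gene, "transcript": a.transcript, "hgvs_c": a.hgvs_c,
                "hgvs_p": a.hgvs_p, "consequence": a.consequence,
                "nmd_predicted": a.nmd_predicted,
                "freq_gnomad_exome_all": _fmt(a.freq_gnomad_exome_all),
                "freq_gnomad_exome_eas": _fmt(a.freq_gnomad_exome_eas),
                "freq_gnomad_genome_all": _fmt(a.freq_gnomad_genome_all),
                "freq_gnomad_genome_eas": _fmt(a.freq_gnomad_genome_eas),
                "freq_kova": _fmt(a.freq_kova), "freq_krgdb": _fmt(a.freq_krgdb),
                "clinvar_significance": a.clinvar_significance or ".",
                "clinvar_stars": "." if a.clinvar_stars is None else a.clinvar_stars,
                "hgmd_class": a.hgmd_class,
                "cosmic_present": str(a.cosmic_present).lower(),
                "sift": a.sift, "polyphen2_hvar": a.polyphen2_hvar,
                "cadd_phred": _fmt(a.cadd_phred), "inheritance": a.inheritance,
                "hotspot_domain": str(a.hotspot_domain).lower(),
                "protein_position": "." if a.protein_position is None else a.protein_position,
                "domain_name": a.domain_name or ".",
            }
        )
    paths["annotations"] = out / "annotations.tsv"
    pd.DataFrame(ann_rows).to_csv(paths["annotations"], sep="\t", index=False,
                                  lineterminator="\n")

    paths["germline_panel"] = out / "germline_panel.txt"
    paths["germline_panel"].write_text(
        "".join(
            f"{g}\t{inh}\t{'yes' if lof else 'no'}\n"
            for g, (inh, lof) in sorted(cohort.germline_panel.items())
        )
    )
    paths["somatic_panel"] = out / "somatic_panel.txt"
    paths["somatic_panel"].write_text("".join(f"{g}\n" for g in sorted(cohort.somatic_panel)))

    paths["pon"] = out / "pon.tsv"
    pd.DataFrame(
        [
            {"chrom": k[0], "pos": k[1], "ref": k[2], "alt": k[3], "recurrence_fraction": v}
            for k, v in sorted(cohort.pon.items(), key=lambda kv: (int(kv[0][0]), kv[0][1]))
        ]
    ).to_csv(paths["pon"], sep="\t", index=False, lineterminator="\n")

    paths["clinical"] = out / "clinical.tsv"
    pd.DataFrame([p.__dict__ for p in cohort.patients]).to_csv(
        paths["clinical"], sep="\t", index=False, lineterminator="\n"
    )

    paths["category_map"] = out / "gene_categories.tsv"
    pd.DataFrame(
        sorted(cohort.category_map.items()), columns=["gene", "category"]
    ).to_csv(paths["category_map"], sep="\t", index=False, lineterminator="\n")

    paths["evidence"] = out / "evidence.tsv"
    pd.DataFrame(
        [
            {"gene": "TP53", "pattern": "", "evidence": "fda_guideline"},
            {"gene": "FLT3", "pattern": "", "evidence": "fda_guideline"},
            {"gene": "IDH1", "pattern": "", "evidence": "fda_guideline"},
            {"gene": "IDH2", "pattern": "", "evidence": "fda_guideline"},
            {"gene": "NRAS", "pattern": "", "evidence": "clinical_trial_or_strong_study"},
            {"gene": "KRAS", "pattern": "", "evidence": "clinical_trial_or_strong_study"},
            {"gene": "JAK2", "pattern": "", "evidence": "clinical_trial_or_strong_study"},
            {"gene": "KIT", "pattern": "", "evidence": "clinical_trial_or_strong_study"},
        ]
    ).to_csv(paths["evidence"], sep="\t", index=False, lineterminator="\n")

    paths["truth"] = out / "truth_labels.tsv"
    pd.DataFrame(
        [
            {
                "sample_id": c.sample_id, "chrom": c.chrom, "pos": c.pos,
                "ref": c.ref, "alt": c.alt, "gene": c.gene, "truth": c.truth,
                "truth_detail": c.truth_detail, "boundary": c.boundary,
                "callers": ",".join(c.callers),
            }
            for c in cohort.calls
        ]
    ).to_csv(paths["truth"], sep="\t", index=False, lineterminator="\n")
    return paths


def _fmt(v: Optional[float]) -> str:
    return "." if v is None else repr(float(v))
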